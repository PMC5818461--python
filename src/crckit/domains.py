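"""Protein-domain annotation of candidate elements.

All six reading frames of an element are translated and locally aligned
(BLOSUM62) against a bundled exemplar set of retroelement domains (GAG,
PR, RT, RH, INT, chromodomain).  Hits to the same domain that sit within
two codons of each other are merged across frames — a minimal frameshift
repair.  The CR targeting motif is handled separately as a nucleotide
profile near the 3' LTR, since it is a positional signal rather than a
conserved protein domain.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import edlib
from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Seq import Seq

DOMAIN_ORDER_GYPSY = ("GAG", "PR", "RT", "RH", "INT")
POL_DOMAINS = frozenset({"PR", "RT", "RH", "INT"})


@dataclass
class DomainConfig:
    min_rt_aa: int = 150
    min_aa_identity: float = 40.0
    min_aa_length: int = 25
    min_score: float = 80.0
    cr_motif_window_bp: int = 1000
    cr_max_edit_frac: float = 0.30
    frameshift_slack_codons: int = 2
    reference_set: str | None = None  # None -> bundled synthetic exemplars

    def __post_init__(self):
        if self.min_rt_aa < 1:
            raise ValueError("min_rt_aa must be >= 1")


@dataclass
class DomainHit:
    domain: str
    genomic_interval: tuple  # 0-based half-open on the element sequence
    frame: int  # +1..+3 / -1..-3
    aa_identity: float
    aa_length: int
    reference_id: str
    translated_seq: str
    score: float = 0.0


@dataclass
class RTDomain:
    aa_seq: str
    nt_seq: str
    genomic_interval: tuple
    hit: DomainHit


def _read_fasta_text(text: str):
    name, chunks, out = None, [], []
    for line in text.splitlines():
        if line.startswith(">"):
            if name is not None:
                out.append((name, "".join(chunks)))
            name, chunks = line[1:].split()[0], []
        elif name is not None:
            chunks.append(line.strip())
    if name is not None:
        out.append((name, "".join(chunks)))
    return out


def load_reference_domains(path=None):
    """Exemplar proteins as (id, domain_label, sequence); ids follow
    {DOMAIN}__{lineage}.  Raises on unreadable/empty sets."""
    try:
        if path is None:
            text = (resources.files("crckit.data") / "domain_refs_synthetic.faa").read_text()
        else:
            with open(path) as fh:
                text = fh.read()
    except OSError as exc:
        raise RuntimeError(f"cannot read reference domain set: {exc}") from exc
    refs = [(rid, rid.split("__")[0], seq) for rid, seq in _read_fasta_text(text)]
    if not refs:
        raise RuntimeError("reference domain set is empty")
    return refs


def load_cr_motif() -> str:
    return (resources.files("crckit.data") / "cr_motif_synthetic.txt").read_text().strip()


def _aligner():
    a = PairwiseAligner(scoring=None)
    a.substitution_matrix = substitution_matrices.load("BLOSUM62")
    a.open_gap_score = -11.0
    a.extend_gap_score = -1.0
    a.mode = "local"
    return a


def _frames(seq: str):
    """(frame, aa_string, to_genomic) for all six frames; to_genomic maps an
    aa index to the codon's forward-strand start coordinate."""
    n = len(seq)
    fwd = Seq(seq)
    rev = fwd.reverse_complement()
    out = []
    for off in range(3):
        usable = (n - off) // 3 * 3
        aa = str(fwd[off : off + usable].translate())
        out.append((off + 1, aa, lambda i, off=off: off + 3 * i))
        aar = str(rev[off : off + usable].translate())
        # codon i on the reverse frame covers forward [n-off-3i-3, n-off-3i)
        out.append((-(off + 1), aar, lambda i, off=off: n - off - 3 * i - 3))
    return out


def scan_domains(seq: str, cfg: DomainConfig | None = None):
    """Six-frame translated search of ``seq`` against the reference set.

    Returns merged DomainHits sorted by genomic position; hits under the
    identity/length/score floors are discarded.
    """
    cfg = cfg or DomainConfig()
    if not seq:
        raise ValueError("empty sequence")
    refs = load_reference_domains(cfg.reference_set)
    aligner = _aligner()
    raw: list[DomainHit] = []
    for frame, aa, to_g in _frames(seq):
        if not aa:
            continue
        for rid, dom, ref in refs:
            try:
                alns = aligner.align(aa, ref)
                if len(alns) == 0:
                    continue
                aln = alns[0]
            except (ValueError, OverflowError):
                continue
            if aln.score < cfg.min_score:
                continue
            counts = aln.counts()
            ncols = counts.identities + counts.mismatches
            if ncols < cfg.min_aa_length:
                continue
            ident = 100.0 * counts.identities / ncols
            if ident < cfg.min_aa_identity:
                continue
            qs, qe = int(aln.aligned[0][0][0]), int(aln.aligned[0][-1][1])
            if frame > 0:
                g0, g1 = to_g(qs), to_g(qe - 1) + 3
            else:
                g0, g1 = to_g(qe - 1), to_g(qs) + 3
            raw.append(
                DomainHit(
                    domain=dom,
                    genomic_interval=(g0, g1),
                    frame=frame,
                    aa_identity=ident,
                    aa_length=qe - qs,
                    reference_id=rid,
                    translated_seq=aa[qs:qe],
                    score=float(aln.score),
                )
            )
    return merge_hits(raw, cfg)


def merge_hits(raw: list, cfg: DomainConfig):
    """Merge same-domain hits whose genomic intervals overlap or sit within
    the frameshift slack; hits to different domains are never merged."""
    slack = 3 * cfg.frameshift_slack_codons
    merged: list[DomainHit] = []
    for dom in sorted({h.domain for h in raw}):
        hits = sorted((h for h in raw if h.domain == dom), key=lambda h: h.genomic_interval)
        cur: DomainHit | None = None
        for h in hits:
            if cur is None:
                cur = h
                continue
            if h.genomic_interval[0] <= cur.genomic_interval[1] + slack:
                # keep the stronger hit's identity/frame; extend the span
                a = cur if cur.score >= h.score else h
                lo = min(cur.genomic_interval[0], h.genomic_interval[0])
                hi = max(cur.genomic_interval[1], h.genomic_interval[1])
                cur = DomainHit(
                    domain=dom,
                    genomic_interval=(lo, hi),
                    frame=a.frame,
                    aa_identity=a.aa_identity,
                    aa_length=(hi - lo) // 3,
                    reference_id=a.reference_id,
                    translated_seq=a.translated_seq,
                    score=max(cur.score, h.score),
                )
            else:
                merged.append(cur)
                cur = h
        if cur is not None:
            merged.append(cur)
    merged.sort(key=lambda h: h.genomic_interval)
    return merged


def extract_rt(seq: str, hits: list, cfg: DomainConfig | None = None):
    """The element's RT domain if any hit reaches ``min_rt_aa`` residues.
    Longest wins; ties go to the higher identity, then the leftmost."""
    cfg = cfg or DomainConfig()
    rts = [h for h in hits if h.domain == "RT" and h.aa_length >= cfg.min_rt_aa]
    if not rts:
        return None
    best = sorted(rts, key=lambda h: (-h.aa_length, -h.aa_identity, h.genomic_interval[0]))[0]
    g0, g1 = best.genomic_interval
    return RTDomain(aa_seq=best.translated_seq, nt_seq=seq[g0:g1], genomic_interval=(g0, g1), hit=best)


def detect_targeting_motif(seq: str, hits: list, ltr3_start: int, cfg: DomainConfig | None = None):
    """Chromodomain vs CR motif vs none.

    A chromodomain is a CHROMO protein hit downstream of INT and upstream
    of the 3' LTR; the CR motif is a nucleotide-profile match within
    ``cr_motif_window_bp`` upstream of (or extending into) the 3' LTR.
    Protein evidence wins when both are present.
    """
    cfg = cfg or DomainConfig()
    ints = [h for h in hits if h.domain == "INT"]
    chromos = [h for h in hits if h.domain == "CHROMO"]
    for c in chromos:
        ok_pos = c.genomic_interval[1] <= ltr3_start + 3
        ok_int = not ints or any(c.genomic_interval[0] >= i.genomic_interval[0] for i in ints)
        if ok_pos and ok_int:
            return "chromodomain"
    motif = load_cr_motif()
    lo = max(0, ltr3_start - cfg.cr_motif_window_bp)
    hi = min(len(seq), ltr3_start + 60)
    window = seq[lo:hi]
    if window:
        res = edlib.align(motif, window.upper(), mode="HW", task="distance")
        if res["editDistance"] >= 0 and res["editDistance"] <= cfg.cr_max_edit_frac * len(motif):
            return "CR_motif"
    return "none"
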