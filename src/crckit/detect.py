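"""De novo structural discovery of LTR retrotransposons.

Strategy: exact k-mer seeds shared between two loci at an element-compatible
spacing are clustered by alignment diagonal and chained; each chained
candidate repeat is extended with padded global alignment and trimmed back
to its maximal-scoring homologous core (the flanks outside a direct repeat
score negative and fall away).  Boundaries are then polished against the
TG…CA terminal dinucleotides and an exact 4-6 bp target-site duplication,
and PBS/PPT signals are located to orient the element.

Candidates whose interior itself contains a near-copy of the candidate LTR
are deferred to a later pass: such "pairs" are usually two distinct nearby
insertions of one family, or a host with a same-family nested insert; after
the confidently accepted elements are masked, a further pass resolves what
remains.  Detected coordinates always refer to the original sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from . import seqs
from .seqs import best_scoring_segment, encode, infix_distance, kmer_codes, revcomp


@dataclass
class DetectionConfig:
    ltr_len_range: tuple = (100, 2500)
    element_len_range: tuple = (1000, 18000)
    seed_kmer: int = 20
    min_ltr_pair_identity: float = 80.0
    tsd_len_range: tuple = (4, 6)
    require_tg_ca: bool = True
    max_candidates_per_window: int = 50
    band: int = 30  # diagonal clustering band for seed chaining
    chain_gap: int = 600  # max gap between successive seeds in one chain
    boundary_slack: int = 25  # max polish shift for TG…CA / TSD
    n_passes: int = 3

    def __post_init__(self):
        for lo, hi in (self.ltr_len_range, self.element_len_range, self.tsd_len_range):
            if lo >= hi:
                raise ValueError("range min must be below max")
        if not 0 < self.min_ltr_pair_identity <= 100:
            raise ValueError("min_ltr_pair_identity must be in (0, 100]")


@dataclass
class LTRElement:
    """A structurally annotated candidate element (0-based half-open)."""

    genome_id: str
    interval: tuple
    ltr5: tuple
    ltr3: tuple
    strand: str = "+"
    tsd: str | None = None
    pbs: tuple | None = None
    ppt: tuple | None = None
    ltr_pair_identity: float = 0.0
    domains: list = field(default_factory=list)
    labels: dict = field(default_factory=dict)

    @property
    def length(self) -> int:
        return self.interval[1] - self.interval[0]


def _seed_matches(seq: str, cfg: DetectionConfig):
    """All (i, j) positions (i<j) sharing an exact k-mer at a spacing
    compatible with the element length range."""
    codes = kmer_codes(encode(seq), cfg.seed_kmer)
    if codes.size == 0:
        return []
    order = np.argsort(codes, kind="stable")
    sorted_codes = codes[order]
    valid = sorted_codes >= 0
    # run boundaries of equal codes
    breaks = np.flatnonzero(np.diff(sorted_codes) != 0) + 1
    starts = np.concatenate(([0], breaks))
    ends = np.concatenate((breaks, [sorted_codes.size]))
    lo = max(cfg.ltr_len_range[0], cfg.element_len_range[0] - cfg.ltr_len_range[1])
    hi = cfg.element_len_range[1]
    matches = []
    for s, e in zip(starts, ends):
        if e - s < 2 or not valid[s]:
            continue
        pos = np.sort(order[s:e])
        if e - s > 200:  # ultra-repetitive k-mer; sample to bound work
            pos = pos[:: max(1, pos.size // 200)]
        for a in range(pos.size - 1):
            i = pos[a]
            js = pos[a + 1 :]
            ok = js[(js - i >= lo) & (js - i <= hi)]
            for j in ok:
                matches.append((int(i), int(j)))
    return matches


def _chain_seeds(matches, cfg: DetectionConfig):
    """Cluster matches by diagonal (within band) then by position gaps.
    Yields raw candidate repeats ((i0,i1),(j0,j1))."""
    if not matches:
        return []
    arr = np.array(matches)
    diag = arr[:, 1] - arr[:, 0]
    order = np.lexsort((arr[:, 0], diag))
    arr, diag = arr[order], diag[order]
    clusters = []
    start = 0
    for t in range(1, len(arr) + 1):
        if t == len(arr) or diag[t] - diag[t - 1] > cfg.band:
            clusters.append(arr[start:t])
            start = t
    out = []
    k = cfg.seed_kmer
    for cl in clusters:
        cl = cl[np.argsort(cl[:, 0])]
        runs = np.flatnonzero(np.diff(cl[:, 0]) > cfg.chain_gap) + 1
        for chunk in np.split(cl, runs):
            i0, i1 = int(chunk[0, 0]), int(chunk[-1, 0]) + k
            j0, j1 = int(chunk[:, 1].min()), int(chunk[:, 1].max()) + k
            out.append(((i0, i1), (j0, j1), len(chunk)))
    return out


def _extend_and_trim(seq: str, a: tuple, b: tuple, cfg: DetectionConfig):
    """Pad both copies, globally align, and keep the maximal-scoring
    segment.  Returns ((a0,a1),(b0,b1), identity_percent) or None."""
    pad = 60
    a0, a1 = max(0, a[0] - pad), min(len(seq), a[1] + pad)
    b0, b1 = max(0, b[0] - pad), min(len(seq), b[1] + pad)
    if a1 > b0:  # copies must not overlap
        a1 = b0
        if a1 - a0 < cfg.ltr_len_range[0]:
            return None
    A, B = seq[a0:a1], seq[b0:b1]
    import edlib

    res = edlib.align(A, B, mode="NW", task="path")
    # per-column scores and coordinate maps
    ia = ib = 0
    cols, amap, bmap = [], [], []
    for n, op in seqs._iter_cigar(res["cigar"]):
        for _ in range(n):
            amap.append(ia)
            bmap.append(ib)
            if op == "=":
                cols.append(1.0)
                ia += 1
                ib += 1
            elif op == "X":
                cols.append(-3.0)
                ia += 1
                ib += 1
            elif op == "I":
                cols.append(-4.0)
                ia += 1
            else:
                cols.append(-4.0)
                ib += 1
    s, e = best_scoring_segment(np.array(cols))
    if e - s < cfg.ltr_len_range[0]:
        return None
    # X-drop extension: a terminal cluster of substitutions inside a true
    # LTR depresses the running score without ending homology; extend each
    # end to the furthest column whose cumulative drop stays within xdrop.
    xdrop = 12.0
    run = 0.0
    for t in range(e, len(cols)):
        run += cols[t]
        if run <= -xdrop:
            break
        if run > -1e-9:
            e = t + 1
            run = 0.0
    run = 0.0
    for t in range(s - 1, -1, -1):
        run += cols[t]
        if run <= -xdrop:
            break
        if run > -1e-9:
            s = t
            run = 0.0
    # shave isolated terminal matches (chance 1-2 bp extensions past the
    # true repeat end): a terminal run of < 3 matches preceded by a
    # penalty column is noise
    def _shave_end(s, e, step):
        while e - s > 0:
            i = e - 1 if step > 0 else s
            if cols[i] < 0:
                if step > 0:
                    e -= 1
                else:
                    s += 1
                continue
            run_len = 0
            j = i
            while s <= j < e and cols[j] > 0:
                run_len += 1
                j -= step
            if run_len >= 3:
                break
            if step > 0:
                e -= run_len
            else:
                s += run_len
        return s, e

    s, e = _shave_end(s, e, +1)
    s, e = _shave_end(s, e, -1)
    if e - s < cfg.ltr_len_range[0]:
        return None
    seg = cols[s:e]
    matches = sum(1 for c in seg if c == 1.0)
    ident = 100.0 * matches / len(seg)
    ra = (a0 + amap[s], a0 + amap[e - 1] + 1)
    rb = (b0 + bmap[s], b0 + bmap[e - 1] + 1)
    return ra, rb, ident


def find_ltr_pairs(seq: str, cfg: DetectionConfig | None = None):
    """Candidate (ltr5, ltr3) interval pairs with pair identity, sorted by
    start.  Sequences shorter than the minimum element length yield []."""
    cfg = cfg or DetectionConfig()
    if len(seq) < cfg.element_len_range[0]:
        return []
    raw = _chain_seeds(_seed_matches(seq, cfg), cfg)
    cands = []
    seen = set()
    for a, b, nseeds in raw:
        ext = _extend_and_trim(seq, a, b, cfg)
        if ext is None:
            continue
        ra, rb, ident = ext
        if ident < cfg.min_ltr_pair_identity:
            continue
        la, lb = ra[1] - ra[0], rb[1] - rb[0]
        if not (cfg.ltr_len_range[0] <= la <= cfg.ltr_len_range[1]):
            continue
        if not (cfg.ltr_len_range[0] <= lb <= cfg.ltr_len_range[1]):
            continue
        elen = rb[1] - ra[0]
        if not (cfg.element_len_range[0] <= elen <= cfg.element_len_range[1]):
            continue
        key = (ra[0] // 10, rb[1] // 10)
        if key in seen:
            continue
        seen.add(key)
        cands.append({"ltr5": ra, "ltr3": rb, "identity": ident, "seeds": nseeds})
    cands.sort(key=lambda c: c["ltr5"][0])
    return cands


def _interior_has_ltr_copy(seq: str, cand, max_frac: float = 0.25) -> bool:
    """True when the region between the two LTRs contains a near-copy of
    the LTR itself — the signature of a cross-insertion artifact or a
    same-family nested insert; such candidates are deferred to later
    passes (after masking)."""
    ltr = seq[cand["ltr5"][0] : cand["ltr5"][1]]
    interior = seq[cand["ltr5"][1] : cand["ltr3"][0]]
    if len(interior) < len(ltr) // 2:
        return False
    half = len(ltr) // 2
    d1 = infix_distance(ltr[:half], interior)
    d2 = infix_distance(ltr[half:], interior)
    return min(d1 / max(1, half), d2 / max(1, len(ltr) - half)) <= max_frac


def refine_boundaries(seq: str, cand: dict, cfg: DetectionConfig | None = None):
    """Polish element boundaries (<= boundary_slack bp) against TG…CA
    termini and an exact 4-6 bp target-site duplication.  Returns an
    LTRElement skeleton (strand provisionally '+'; orientation is settled
    by PBS/PPT detection)."""
    cfg = cfg or DetectionConfig()
    (s5, e5), (s3, e3) = cand["ltr5"], cand["ltr3"]
    slack = cfg.boundary_slack

    # A genuine terminus leaves its mark on BOTH LTR copies: the same
    # offset relative to the homologous trim boundaries shows TG (at the
    # starts) or CA (at the ends) in both.  Every shift stays allowed —
    # termini only add evidence weight (2 for the element's own terminus,
    # 1 for the partner LTR copy, which may sit off by one trim column) —
    # so a mutated terminal dinucleotide cannot veto a TSD-supported
    # boundary.
    def tg_shifts():
        opts = []
        for d in range(-slack, slack + 1):
            a, b = s5 + d, s3 + d
            if not (0 <= a <= len(seq) - 2 and 1 <= b <= len(seq) - 3):
                continue
            outer = seq[a : a + 2] == "TG"
            inner = "TG" in (seq[b - 1 : b + 1], seq[b : b + 2], seq[b + 1 : b + 3])
            opts.append((d, 2 * outer + inner))
        return opts

    def ca_shifts():
        opts = []
        for d in range(-slack, slack + 1):
            a, b = e3 + d, e5 + d
            if not (2 <= a <= len(seq) and 3 <= b <= len(seq) - 1):
                continue
            outer = seq[a - 2 : a] == "CA"
            inner = "CA" in (seq[b - 3 : b - 1], seq[b - 2 : b], seq[b - 1 : b + 1])
            opts.append((d, 2 * outer + inner))
        return opts

    d5_opts = tg_shifts() if cfg.require_tg_ca else [(0, 0)]
    d3_opts = ca_shifts() if cfg.require_tg_ca else [(0, 0)]
    if not d5_opts:
        d5_opts = [(0, 0)]
    if not d3_opts:
        d3_opts = [(0, 0)]

    best = None
    tmax, tmin = cfg.tsd_len_range[1], cfg.tsd_len_range[0]
    for d5, w5 in d5_opts:
        for d3, w3 in d3_opts:
            start, end = s5 + d5, e3 + d3
            tsd = None
            tsd_w = 0.0
            for t in range(tmax, tmin - 1, -1):
                if start - t >= 0 and end + t <= len(seq):
                    left, right = seq[start - t : start], seq[end : end + t]
                    if left == right:
                        tsd, tsd_w = left, float(t)
                        break
            if tsd is None:
                # a single substitution in either copy is common in old
                # elements; count a near-duplication at half weight
                for t in range(tmax, max(tmin, 5) - 1, -1):
                    if start - t >= 0 and end + t <= len(seq):
                        left, right = seq[start - t : start], seq[end : end + t]
                        if sum(1 for x, y in zip(left, right) if x != y) == 1:
                            tsd, tsd_w = left, t / 2.0
                            break
            # weighted evidence: an exact duplication corroborated by
            # TG/CA termini dominates; bare termini rank next; large
            # shifts from the alignment boundary are discouraged
            w = w5 + w3
            score = tsd_w * (1 + w) + 2 * w - (abs(d5) + abs(d3)) / 4.0
            if best is None or score > best[0]:
                best = (score, d5, d3, tsd)
    _, d5, d3, tsd = best
    ltr5 = (s5 + d5, max(s5 + d5 + 1, min(e5 + d3, len(seq))))
    ltr3 = (min(max(s3 + d5, 0), e3 + d3 - 1), e3 + d3)
    return LTRElement(
        genome_id="",
        interval=(ltr5[0], ltr3[1]),
        ltr5=ltr5,
        ltr3=ltr3,
        tsd=tsd,
        ltr_pair_identity=cand.get("identity", 0.0),
    )


def _find_pbs(region: str, trna_set: dict, min_len: int = 11, max_mismatch: int = 1):
    """Best PBS match in ``region``: a >= min_len stretch complementary to
    a tRNA 3' end, allowing one mismatch.  Returns (offset, length) or None."""
    best = None
    for name, t3 in trna_set.items():
        probe = revcomp(t3)
        for L in range(len(probe), min_len - 1, -1):
            for sub_off in range(0, len(probe) - L + 1):
                sub = probe[sub_off : sub_off + L]
                for off in range(0, len(region) - L + 1):
                    mm = sum(1 for x, y in zip(sub, region[off : off + L]) if x != y)
                    if mm <= max_mismatch:
                        cand = (L, -off, off)
                        if best is None or cand[:2] > best[:2]:
                            best = cand
    if best is None:
        return None
    return best[2], best[0]


def _find_ppt(region: str, min_len: int = 10, min_purine: float = 0.8):
    """Rightmost maximal purine-rich run (>=min_len, >=min_purine A/G) in
    ``region``; returns (offset, length) or None."""
    pur = [1 if b in "AG" else 0 for b in region]
    best = None
    n = len(region)
    for i in range(n):
        run_pur = 0
        for j in range(i + 1, min(n, i + 40) + 1):
            run_pur += pur[j - 1]
            L = j - i
            if L >= min_len and run_pur / L >= min_purine:
                cand = (i, L)
                if best is None or (cand[0] + cand[1], cand[1]) >= (best[0] + best[1], best[1]):
                    best = cand
    return best


def load_trna_set():
    text = (resources.files("crckit.data") / "trna_3prime.fa").read_text()
    out = {}
    name = None
    for line in text.splitlines():
        if line.startswith(">"):
            name = line[1:].strip()
            out[name] = ""
        elif name:
            out[name] += line.strip()
    return out


def detect_pbs_ppt(seq: str, element: LTRElement, cfg: DetectionConfig | None = None, trna_set: dict | None = None):
    """Locate PBS (within 20 bp downstream of the 5' LTR) and PPT (within
    30 bp upstream of the 3' LTR); sets element orientation.  If neither
    signal is found on the forward orientation the reverse complement is
    tried and, on success, the element is marked '-' (coordinates stay on
    the forward strand)."""
    trna_set = trna_set or load_trna_set()

    def scan(s5e, s3s, fwd_seq):
        win_pbs = fwd_seq[s5e : s5e + 20 + 15]
        pbs = _find_pbs(win_pbs, trna_set)
        pbs_iv = None
        if pbs is not None and pbs[0] <= 20:
            pbs_iv = (s5e + pbs[0], s5e + pbs[0] + pbs[1])
        win_lo = max(0, s3s - 30 - 40)
        ppt = _find_ppt(fwd_seq[win_lo:s3s])
        ppt_iv = None
        if ppt is not None and (s3s - (win_lo + ppt[0] + ppt[1])) <= 30:
            ppt_iv = (win_lo + ppt[0], win_lo + ppt[0] + ppt[1])
        return pbs_iv, ppt_iv

    pbs, ppt = scan(element.ltr5[1], element.ltr3[0], seq)
    if pbs is not None or ppt is not None:
        element.pbs, element.ppt, element.strand = pbs, ppt, "+"
        return element
    # reverse orientation: the 3' LTR of the element is the leftmost copy
    n = len(seq)
    rc = revcomp(seq)
    rc5_end = n - element.ltr3[0]  # rc coords of the (biological) 5' LTR end
    rc3_start = n - element.ltr5[1]
    pbs, ppt = scan(rc5_end, rc3_start, rc)
    if pbs is not None or ppt is not None:
        element.strand = "-"
        element.pbs = None if pbs is None else (n - pbs[1], n - pbs[0])
        element.ppt = None if ppt is None else (n - ppt[1], n - ppt[0])
    return element


def ltr_pair_identity(element: LTRElement, seq: str) -> float:
    """Percent identity of the two LTRs from a global alignment, gap
    columns excluded (the structural-annotation convention)."""
    if element.ltr5 is None or element.ltr3 is None:
        raise ValueError("element lacks an LTR pair (non-autonomous or fragment input)")
    a = seq[element.ltr5[0] : element.ltr5[1]]
    b = seq[element.ltr3[0] : element.ltr3[1]]
    return seqs.percent_identity(a, b, count_gap_columns=False)


def detect_elements(seq: str, cfg: DetectionConfig | None = None, genome_id: str = "") -> list:
    """Full structural pass: seed/chain/extend, polish, orient, and score;
    repeated over ``n_passes`` with accepted elements masked between passes
    so that nested elements and deferred candidates are resolved.
    Containment of one element inside another is allowed (nesting); partial
    overlaps are resolved in favor of identity x LTR length."""
    cfg = cfg or DetectionConfig()
    accepted: list[LTRElement] = []
    work = seq
    for _ in range(cfg.n_passes):
        cands = find_ltr_pairs(work, cfg)
        cands = [c for c in cands if not _interior_has_ltr_copy(work, c)]
        cands.sort(key=lambda c: -(c["identity"] * min(c["ltr5"][1] - c["ltr5"][0], c["ltr3"][1] - c["ltr3"][0])))
        new = []
        for c in cands:
            el = refine_boundaries(work, c, cfg)
            el.genome_id = genome_id
            s, e = el.interval
            clash = False
            for other in accepted + new:
                os, oe = other.interval
                if s < oe and os < e:  # overlap
                    if not (os <= s and e <= oe) and not (s <= os and oe <= e):
                        clash = True
                        break
            if clash:
                continue
            el = detect_pbs_ppt(work, el, cfg)
            el.ltr_pair_identity = ltr_pair_identity(el, work)
            if el.ltr_pair_identity < cfg.min_ltr_pair_identity:
                continue
            new.append(el)
        if not new:
            break
        accepted.extend(new)
        buf = list(work)
        for el in new:
            buf[el.interval[0] : el.interval[1]] = "N" * el.length
        work = "".join(buf)
    accepted.sort(key=lambda e: e.interval)
    return accepted


def structural_summary(element_seq: str, cfg: DetectionConfig | None = None) -> dict:
    """Structural metrics of a single, already-excised element sequence:
    total length, LTR length and pair identity from the internal direct
    repeat, and terminal-dinucleotide check.  Used for validating deposited
    representative elements."""
    cfg = cfg or DetectionConfig(element_len_range=(500, max(18000, len(element_seq) + 1)))
    pairs = find_ltr_pairs(element_seq, cfg)
    out = {
        "element_len": len(element_seq),
        "tg_ca": element_seq[:2].upper() == "TG" and element_seq[-2:].upper() == "CA",
    }
    if pairs:
        best = max(pairs, key=lambda c: (c["ltr3"][1] - c["ltr5"][0], c["identity"]))
        n = len(element_seq)
        (s5, e5), (s3, e3) = best["ltr5"], best["ltr3"]
        # an excised complete element starts with its 5' LTR and ends with
        # its 3' LTR, so anchor each copy's length at the sequence edge it
        # abuts; alignment-trim noise then only affects the inner ends
        l5 = e5 if s5 <= 20 else e5 - s5
        l3 = n - s3 if e3 >= n - 20 else e3 - s3
        out["ltr_len"] = max(l5, l3)
        out["ltr_identity"] = best["identity"]
    return out
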