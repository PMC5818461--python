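"""Low-level nucleotide sequence utilities shared across the package.

Sequences are plain Python strings over the IUPAC alphabet (uppercase
internally); numpy uint8 arrays of 2-bit codes are used for k-mer work.
All genomic coordinates inside the package are 0-based half-open.
"""

from __future__ import annotations

import numpy as np
import edlib

BASES = "ACGT"
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i

_COMP = str.maketrans("ACGTRYKMBDHVNacgtrykmbdhvn", "TGCAYRMKVHDBNtgcayrmkvhdbn")

# purine/pyrimidine partners: A<->G transitions, C<->T transitions
TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}


def revcomp(seq: str) -> str:
    """Reverse complement (IUPAC-aware)."""
    return seq.translate(_COMP)[::-1]


def gc_fraction(seq: str) -> float:
    s = seq.upper()
    gc = s.count("G") + s.count("C")
    return gc / len(s) if s else 0.0


def encode(seq: str) -> np.ndarray:
    """Map a sequence to uint8 codes; non-ACGT bases map to 255."""
    return _CODE[np.frombuffer(seq.upper().encode(), dtype=np.uint8)]


def kmer_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Integer code of every k-mer (int64); windows touching a non-ACGT
    base get -1.  Requires 2k <= 62."""
    if 2 * k > 62:
        raise ValueError("k too large for 64-bit packing")
    n = codes.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    bad = codes > 3
    c = np.where(bad, 0, codes).astype(np.int64)
    out = np.zeros(n, dtype=np.int64)
    for j in range(k):
        out = (out << 2) | c[j : j + n]
    if bad.any():
        invalid = np.convolve(bad.astype(np.int8), np.ones(k, dtype=np.int8))[k - 1 : k - 1 + n]
        out[invalid > 0] = -1
    return out


def is_transition(a: str, b: str) -> bool:
    return TRANSITION.get(a) == b


def _iter_cigar(cigar: str):
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            yield int(num), ch
            num = ""


_NT_ALIGNER = None


def _nt_aligner():
    """Affine-gap global nucleotide aligner (megablast-like scoring).

    Affine gaps matter: a unit-cost edit alignment will happily explain a
    cluster of substitutions with offsetting indels, which biases
    substitution counts (and hence K2P ages) downward.
    """
    global _NT_ALIGNER
    if _NT_ALIGNER is None:
        from Bio.Align import PairwiseAligner

        a = PairwiseAligner(scoring=None)
        a.match_score = 2.0
        a.mismatch_score = -3.0
        a.open_gap_score = -7.0
        a.extend_gap_score = -2.0
        a.mode = "global"
        _NT_ALIGNER = a
    return _NT_ALIGNER


def global_alignment_columns(a: str, b: str):
    """Globally align two sequences and tally column classes.

    Returns a dict with: matches, mismatches, transitions, transversions,
    gap_columns, aligned_columns (all columns incl. gaps).  Mismatch ts/tv
    classification only counts ACGT-vs-ACGT columns.
    """
    if not a or not b:
        raise ValueError("empty sequence in alignment")
    au, bu = a.upper(), b.upper()
    aln = _nt_aligner().align(au, bu)[0]
    blocks_a, blocks_b = aln.aligned
    matches = mismatches = ts = tv = 0
    aligned_a = aligned_b = 0
    for (a0, a1), (b0, b1) in zip(blocks_a, blocks_b):
        aligned_a += a1 - a0
        aligned_b += b1 - b0
        for x, y in zip(au[a0:a1], bu[b0:b1]):
            if x == y:
                matches += 1
            else:
                mismatches += 1
                if x in BASES and y in BASES:
                    if is_transition(x, y):
                        ts += 1
                    else:
                        tv += 1
    gaps = (len(au) - aligned_a) + (len(bu) - aligned_b)
    return {
        "matches": matches,
        "mismatches": mismatches,
        "transitions": ts,
        "transversions": tv,
        "gap_columns": gaps,
        "aligned_columns": matches + mismatches + gaps,
    }


def percent_identity(a: str, b: str, count_gap_columns: bool) -> float:
    """Global-alignment percent identity.

    count_gap_columns=True: identity = matches / all columns (stretcher-like,
    used for RT and census identities).  False: gap columns are excluded
    (used for LTR-pair identity).
    """
    c = global_alignment_columns(a, b)
    denom = c["aligned_columns"] if count_gap_columns else (c["matches"] + c["mismatches"])
    if denom == 0:
        raise ValueError("alignment has no columns")
    return 100.0 * c["matches"] / denom


def infix_distance(query: str, target: str) -> int:
    """Best edit distance of query against any infix of target (edlib HW)."""
    if not query or not target:
        return max(len(query), len(target))
    return edlib.align(query.upper(), target.upper(), mode="HW", task="distance")["editDistance"]


def best_scoring_segment(cols: np.ndarray) -> tuple[int, int]:
    """Kadane max-sum segment over per-column scores; returns [start, end).

    Used to trim a noisy global alignment down to the genuinely homologous
    core (the flanks outside a repeat drift to negative score).
    """
    best = cur = 0.0
    best_range = (0, 0)
    start = 0
    for i, v in enumerate(cols):
        cur += v
        if cur <= 0:
            cur = 0.0
            start = i + 1
        elif cur > best:
            best = cur
            best_range = (start, i + 1)
    return best_range
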