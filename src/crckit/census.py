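"""Genome-wide copy census, insertion dating, density tracks, tandem-array
detection, and region composition reports.

The census takes a family representative and finds its copies on both
genome strands with BLAST+ (`blastn`), merges nearby same-strand local
alignments, and classifies each merged copy against the strict coverage /
identity thresholds of the "80-80" (complete) and "80-10" (fragment)
convention.  Insertion ages come from the Kimura two-parameter divergence
of an element's two LTRs, T = K / (2r), the pair having been identical at
insertion time.
"""

from __future__ import annotations

import math
import shutil
import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import seqs
from .seqs import encode, kmer_codes

DEFAULT_RATE = 1.3e-8


@dataclass
class CensusConfig:
    complete_min_coverage: float = 0.80
    complete_min_identity: float = 0.80
    fragment_min_coverage: float = 0.10
    max_divergence_for_masking: float = 0.20
    merge_gap_bp: int = 50

    def __post_init__(self):
        for f in (self.complete_min_coverage, self.complete_min_identity, self.fragment_min_coverage, self.max_divergence_for_masking):
            if not 0 < f <= 1:
                raise ValueError("census fractions must be in (0, 1]")
        if self.fragment_min_coverage >= self.complete_min_coverage:
            raise ValueError("fragment_min_coverage must be below complete_min_coverage")


@dataclass
class RawAlignment:
    """One merged similarity hit of a representative against a genome."""

    family: str
    genome_id: str
    interval: tuple  # genome, 0-based half-open
    strand: str
    identity: float  # fraction, gap columns included
    coverage: float  # fraction of the representative aligned


@dataclass
class CopyHit(RawAlignment):
    completeness: str = "fragment"  # complete | fragment


@dataclass
class InsertionAge:
    element_id: str
    P: float
    Q: float
    K: float  # nan when saturated
    T: float  # years; nan when saturated
    r: float
    saturated: bool = False


@dataclass
class DensityTrack:
    genome_id: str
    window_bp: int
    step_bp: int
    mode: str
    starts: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    values: np.ndarray = field(default_factory=lambda: np.empty(0))


def _blastn(query: str, subject: str):
    """Raw blastn HSPs (qstart,qend,sstart,send 0-based half-open on the
    forward strand, strand, pident, length)."""
    if shutil.which("blastn") is None:
        raise RuntimeError("blastn (BLAST+) not found on PATH")
    with tempfile.TemporaryDirectory() as td:
        q = Path(td) / "q.fa"
        s = Path(td) / "s.fa"
        q.write_text(f">q\n{query}\n")
        s.write_text(f">s\n{subject}\n")
        res = subprocess.run(
            [
                "blastn", "-task", "blastn", "-query", str(q), "-subject", str(s),
                "-outfmt", "6 qstart qend sstart send pident length sstrand",
                "-evalue", "1e-10", "-dust", "no", "-soft_masking", "false",
            ],
            capture_output=True, text=True, check=True,
        )
    hsps = []
    for line in res.stdout.splitlines():
        qs, qe, ss, se, pid, ln, strand = line.split("\t")
        qs, qe, ss, se = int(qs), int(qe), int(ss), int(se)
        if strand == "minus":
            ss, se = se, ss
        hsps.append(
            {
                "q": (qs - 1, qe),
                "s": (ss - 1, se),
                "strand": "+" if strand == "plus" else "-",
                "pident": float(pid),
                "length": int(ln),
            }
        )
    return hsps


def _merge_intervals(ivs):
    out = []
    for s, e in sorted(ivs):
        if out and s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [(s, e) for s, e in out]


def census_scan(representative: str, genome: str, cfg: CensusConfig | None = None, family: str = "", genome_id: str = ""):
    """Similarity census of one representative against a genome.

    Same-strand HSPs separated by <= merge_gap_bp on the genome are merged;
    coverage is computed on the representative's coordinates after
    merging; merged hits below the fragment thresholds are dropped.
    """
    cfg = cfg or CensusConfig()
    if not representative or not genome:
        raise ValueError("empty input sequence")
    hsps = _blastn(representative, genome)
    qlen = len(representative)
    out = []
    for strand in "+-":
        sh = sorted((h for h in hsps if h["strand"] == strand), key=lambda h: h["s"])
        cluster: list = []
        for h in sh + [None]:
            if h is not None and (not cluster or h["s"][0] - cluster[-1]["s"][1] <= cfg.merge_gap_bp):
                cluster.append(h)
                continue
            if cluster:
                gs = min(x["s"][0] for x in cluster)
                ge = max(x["s"][1] for x in cluster)
                qcov = sum(e - s for s, e in _merge_intervals([x["q"] for x in cluster])) / qlen
                wid = sum(x["pident"] * x["length"] for x in cluster) / sum(x["length"] for x in cluster)
                hit = RawAlignment(
                    family=family, genome_id=genome_id, interval=(gs, ge), strand=strand,
                    identity=wid / 100.0, coverage=min(1.0, qcov),
                )
                if hit.identity > cfg.complete_min_identity and hit.coverage > cfg.fragment_min_coverage:
                    out.append(hit)
            cluster = [h] if h is not None else []
    out.sort(key=lambda h: h.interval)
    return out


def call_copies(hits, cfg: CensusConfig | None = None):
    """Strict-threshold completeness calls.

    complete: coverage > complete_min_coverage AND identity >
    complete_min_identity; fragment: identity > complete_min_identity AND
    fragment_min_coverage < coverage <= complete_min_coverage.  All
    comparisons are strict, matching the printed ">80%" / ">10%" rules;
    everything else is dropped.
    """
    cfg = cfg or CensusConfig()
    out = []
    for h in hits:
        cov, ident = h.coverage, h.identity
        if ident > cfg.complete_min_identity and cov > cfg.complete_min_coverage:
            cls = "complete"
        elif ident > cfg.complete_min_identity and cfg.fragment_min_coverage < cov <= cfg.complete_min_coverage:
            cls = "fragment"
        else:
            continue
        out.append(
            CopyHit(
                family=h.family, genome_id=h.genome_id, interval=h.interval, strand=h.strand,
                identity=ident, coverage=cov, completeness=cls,
            )
        )
    return out


def k2p_distance(ltr_a: str, ltr_b: str):
    """Kimura two-parameter distance of two alignable sequences.

    P and Q are the transition and transversion fractions over ungapped
    columns of a global alignment; K = -1/2 ln((1-2P-Q) sqrt(1-2Q)).
    Saturation (non-positive log argument) is flagged, never clipped.
    Returns (P, Q, K, saturated).
    """
    cols = seqs.global_alignment_columns(ltr_a, ltr_b)
    n = cols["matches"] + cols["mismatches"]
    if n == 0:
        raise ValueError("no ungapped columns to compare")
    P = cols["transitions"] / n
    Q = cols["transversions"] / n
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0 or w2 <= 0:
        return P, Q, math.nan, True
    return P, Q, -0.5 * math.log(w1 * math.sqrt(w2)), False


def insertion_time(K: float, r: float = DEFAULT_RATE) -> float:
    """T = K / (2r): both LTRs were identical at insertion and each has
    since accumulated K/2 substitutions per site."""
    if r <= 0:
        raise ValueError("substitution rate must be positive")
    if K < 0:
        raise ValueError("K must be non-negative")
    return K / (2.0 * r)


def date_element(seq: str, element, r: float = DEFAULT_RATE, element_id: str = "") -> InsertionAge:
    if element.ltr5 is None or element.ltr3 is None:
        raise ValueError("cannot date an element without both LTRs")
    a = seq[element.ltr5[0] : element.ltr5[1]]
    b = seq[element.ltr3[0] : element.ltr3[1]]
    P, Q, K, sat = k2p_distance(a, b)
    T = math.nan if sat else insertion_time(K, r)
    return InsertionAge(element_id=element_id, P=P, Q=Q, K=K, T=T, r=r, saturated=sat)


def density_profile(annotations, genome_length: int, window_bp: int, step_bp: int, mode: str = "coverage", genome_id: str = "") -> DensityTrack:
    """Per-window repeat density: covered-base fraction ('coverage', with
    overlaps flattened first) or hit-midpoint counts ('count')."""
    if not (window_bp >= step_bp >= 1):
        raise ValueError("need window >= step >= 1")
    if mode not in ("coverage", "count"):
        raise ValueError("mode must be 'coverage' or 'count'")
    if window_bp > genome_length:
        import warnings

        warnings.warn("window larger than genome; using a single whole-genome window")
        window_bp = genome_length
        step_bp = genome_length
    n_win = (genome_length - window_bp) // step_bp + 1
    starts = np.arange(n_win) * step_bp
    if mode == "coverage":
        cov = np.zeros(genome_length + 1)
        for s, e in _merge_intervals([tuple(iv) for iv in annotations]):
            cov[max(0, s)] += 1
            cov[min(genome_length, e)] -= 1
        covered = np.cumsum(cov)[:-1] > 0
        csum = np.concatenate(([0], np.cumsum(covered)))
        values = (csum[starts + window_bp] - csum[starts]) / window_bp
    else:
        mids = np.array([(s + e) // 2 for s, e in annotations], dtype=int)
        values = np.array([((mids >= s) & (mids < s + window_bp)).sum() for s in starts], dtype=float)
    return DensityTrack(genome_id=genome_id, window_bp=window_bp, step_bp=step_bp, mode=mode, starts=starts, values=values)


def detect_tandem_arrays(
    seq: str,
    min_period: int = 30,
    max_period: int = 1000,
    min_copies: int = 4,
    k: int = 12,
    min_monomer_identity: float = 0.80,
    min_support: float = 0.30,
):
    """Satellite-array scan by k-mer recurrence periodicity.

    A position supports periodicity when its k-mer last occurred at a lag
    within [min_period, max_period]; maximal dense runs of supported
    positions whose dominant lag p spans >= min_copies * p bases, and whose
    adjacent monomers align at >= 80% identity, are reported as
    (interval, period, copy_estimate).
    """
    if min_period < 2 or min_copies < 2:
        raise ValueError("need min_period >= 2 and min_copies >= 2")
    codes = kmer_codes(encode(seq), k)
    last: dict = {}
    pos_list, lag_list = [], []
    for i, c in enumerate(codes):
        if c < 0:
            continue
        prev = last.get(c)
        if prev is not None:
            lag = i - prev
            if min_period <= lag <= max_period:
                pos_list.append(i)
                lag_list.append(lag)
        last[c] = i
    arrays = []
    if not pos_list:
        return arrays
    pos = np.array(pos_list)
    lag = np.array(lag_list)
    # split supported positions into runs with bounded gaps
    breaks = np.flatnonzero(np.diff(pos) > max_period) + 1
    for chunk_idx in np.split(np.arange(pos.size), breaks):
        cpos, clag = pos[chunk_idx], lag[chunk_idx]
        vals, counts = np.unique(clag, return_counts=True)
        # dominant period: pool lags within +-2 bp
        best_p, best_n = 0, 0
        for v in vals:
            nsup = counts[np.abs(vals - v) <= 2].sum()
            if nsup > best_n:
                best_p, best_n = int(v), int(nsup)
        keep = np.abs(clag - best_p) <= 2
        if keep.sum() < 3:
            continue
        start = int(cpos[keep].min()) - best_p
        end = int(cpos[keep].max()) + k
        start = max(0, start)
        span = end - start
        if span < min_copies * best_p:
            continue
        # dense support: supported positions must cover a fair share of the span
        if best_n < min_support * (span - best_p):
            continue
        m1 = seq[start : start + best_p]
        m2 = seq[start + best_p : start + 2 * best_p]
        if len(m2) < best_p:
            continue
        ident = seqs.percent_identity(m1, m2, count_gap_columns=True) / 100.0
        if ident < min_monomer_identity:
            continue
        arrays.append({"interval": (start, end), "period": best_p, "copies": round(span / best_p, 1)})
    merged = []
    for arr in sorted(arrays, key=lambda a: a["interval"]):
        if merged and arr["interval"][0] < merged[-1]["interval"][1]:
            if arr["copies"] > merged[-1]["copies"]:
                merged[-1] = arr
        else:
            merged.append(arr)
    return merged


def region_composition(records, region: tuple) -> pd.DataFrame:
    """Percent of a region covered per hierarchical category.

    ``records``: iterables with .interval and .category (a tuple path such
    as ("TE", "LTR_RT", "CRC", "H")).  Coverage is flattened within each
    category path prefix, so a subcategory never exceeds its parent.
    """
    lo, hi = region
    span = hi - lo
    if span <= 0:
        raise ValueError("empty region")
    paths: dict = {}
    for r in records:
        s, e = r.interval
        if s < lo or e > hi:
            raise ValueError(f"annotation {r.interval} outside region {region}")
        for depth in range(1, len(r.category) + 1):
            paths.setdefault(tuple(r.category[:depth]), []).append((s, e))
    rows = []
    for path in sorted(paths):
        covered = sum(e - s for s, e in _merge_intervals(paths[path]))
        rows.append({"category": "/".join(path), "depth": len(path), "percent": 100.0 * covered / span})
    return pd.DataFrame(rows)


def plot_density(track: DensityTrack, path, label: str | None = None):
    """Static plot of a density track (simple helper; serious figures
    should be drawn from the bedGraph output)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(10, 2.5))
    ax.fill_between(track.starts / 1e6, track.values, step="post", color="seagreen", alpha=0.7)
    ax.set_xlabel("position (Mb)")
    ax.set_ylabel("density" if track.mode == "coverage" else "hits")
    ax.set_title(label or track.genome_id)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def age_histogram(ages, bin_width_years: float, min_prominence_ratio: float = 2.0):
    """Histogram of insertion times with simple local-maximum peak calls.

    A peak bin strictly exceeds both neighbors and reaches at least
    ``min_prominence_ratio`` times the median bin count (the background
    level; zero-heavy histograms therefore keep all local maxima).
    Returns (edges, counts, peak_bin_indices)."""
    if bin_width_years <= 0:
        raise ValueError("bin width must be positive")
    ts = np.array([a.T for a in ages if not a.saturated and not math.isnan(a.T)])
    if ts.size == 0:
        return np.array([0.0]), np.array([], dtype=int), []
    n_bins = int(ts.max() // bin_width_years) + 1
    edges = np.arange(n_bins + 1) * bin_width_years
    counts, _ = np.histogram(ts, bins=edges)
    floor = min_prominence_ratio * np.median(counts) if counts.size else 0
    peaks = []
    padded = np.concatenate(([0], counts, [0]))
    for i in range(len(counts)):
        if counts[i] >= floor and padded[i] < padded[i + 1] > padded[i + 2]:
            peaks.append(i)
    return edges, counts, peaks
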