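"""Superfamily assignment, family definition from RT phylogeny, identity
matrices, and non-autonomous element typing.

Superfamily follows coding-domain order: integrase downstream of RNase H
(…RT-RH-INT…) is Gypsy, integrase upstream of RT (…INT-RT-RH…) is Copia.
Families ("groups") are maximal well-supported clades of the RT
neighbor-joining tree whose members are mutually >= 80% identical at the
RT nucleotide level; non-autonomous elements are typed TRIM / LARD /
TR-GAG from their length, LTR length and residual domain content.
Identity conventions: RT/census identities count gap columns as
mismatches (stretcher-like); this is load-bearing for the identity-matrix
output and is therefore fixed here, not configurable.
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import seqs
from .domains import POL_DOMAINS
from .njtree import Tree, bootstrap_groups, neighbor_joining  # noqa: F401 (re-exported)

SUPERFAMILIES = ("Gypsy", "Copia", "unclassified_autonomous", "non_autonomous")


@dataclass
class GroupConfig:
    support_threshold: float = 70.0  # % bootstrap to accept a clade
    min_within_identity: float = 80.0  # % RT nucleotide identity within a group
    n_bootstrap: int = 1000
    trim_max_len: int = 1500
    trim_max_ltr: int = 250
    lard_min_len: int = 4000


@dataclass
class FamilyGroup:
    name: str
    members: list
    representative: str
    within_identity: float = 100.0
    targeting_motif: str = "none"


@dataclass
class NonAutonomousClass:
    label: str  # TRIM | LARD | TR_GAG | unclassified
    evidence: str


@dataclass
class DistanceMatrix:
    ids: list
    d: np.ndarray

    def __post_init__(self):
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.ids)
        if self.d.shape != (n, n):
            raise ValueError("matrix shape mismatch")
        if not np.allclose(np.diag(self.d), 0, atol=1e-12):
            raise ValueError("diagonal must be zero")
        if not np.allclose(self.d, self.d.T, atol=1e-9):
            raise ValueError("matrix must be symmetric")
        if (self.d < -1e-12).any() or (self.d > 1 + 1e-12).any():
            raise ValueError("entries must be in [0, 1]")


def assign_superfamily(hits: list) -> str:
    """Coding-domain-order superfamily call from a list of DomainHits."""
    pol = [h for h in hits if h.domain in POL_DOMAINS]
    if not pol:
        return "non_autonomous"
    pos = {d: min(h.genomic_interval[0] for h in pol if h.domain == d) for d in {h.domain for h in pol}}
    if "INT" in pos and "RH" in pos and pos["INT"] > pos["RH"]:
        if "RT" not in pos or pos["RT"] < pos["RH"]:
            return "Gypsy"
    if "INT" in pos and "RT" in pos and pos["INT"] < pos["RT"]:
        return "Copia"
    return "unclassified_autonomous"


def pairwise_rt_identity(rt_a: str, rt_b: str) -> float:
    """Global-alignment percent identity with gap columns counted as
    mismatching columns (full precision; round only for display)."""
    if not rt_a or not rt_b:
        raise ValueError("empty RT sequence")
    return seqs.percent_identity(rt_a, rt_b, count_gap_columns=True)


def identity_matrix(rts: dict) -> pd.DataFrame:
    ids = list(rts)
    n = len(ids)
    m = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            m[i, j] = m[j, i] = pairwise_rt_identity(rts[ids[i]], rts[ids[j]])
    return pd.DataFrame(m, index=ids, columns=ids)


def align_sequences(seqs_by_id: dict, protein: bool = False):
    """Multiple alignment of the given sequences, as (id, row) pairs.

    Uses MAFFT when more than two sequences differ in length or content
    layout demands it; equal-length inputs pass through unchanged (they
    are already columnwise comparable under the no-indel model).
    """
    items = list(seqs_by_id.items())
    lengths = {len(s) for _, s in items}
    if len(lengths) == 1:
        return items
    if shutil.which("mafft") is None:
        raise RuntimeError("mafft not found for multiple alignment of unequal-length sequences")
    with tempfile.TemporaryDirectory() as td:
        fin = Path(td) / "in.fa"
        with open(fin, "w") as fh:
            for k, s in items:
                fh.write(f">{k}\n{s}\n")
        args = ["mafft", "--retree", "2", "--maxiterate", "0", "--quiet"]
        if protein:
            args += ["--amino"]
        res = subprocess.run(args + [str(fin)], capture_output=True, text=True, check=True)
    out = {}
    name = None
    for line in res.stdout.splitlines():
        if line.startswith(">"):
            name = line[1:].split()[0]
            out[name] = []
        else:
            out[name].append(line.strip())
    return [(k, "".join(out[k]).upper()) for k, _ in items]


def define_groups(
    tree: Tree,
    supports: dict,
    rt_identities: pd.DataFrame,
    cfg: GroupConfig | None = None,
    motifs: dict | None = None,
) -> list:
    """Partition all RTs into family groups.

    Groups are maximal supported clades (bipartition support >= threshold)
    whose members are all pairwise >= min_within_identity; remaining taxa
    become singletons.  Group names are letters by decreasing size.
    """
    cfg = cfg or GroupConfig()
    ids = list(rt_identities.index)
    candidates: list[tuple] = [(frozenset(ids), 100.0)]
    for side, _len in tree.bipartitions().items():
        sup = supports.get(side, 0.0)
        other = frozenset(x for x in ids if x not in side)
        candidates.append((side, sup))
        candidates.append((other, sup))
    candidates.sort(key=lambda c: (-len(c[0]), sorted(c[0])[0]))

    def coherent(members):
        sub = rt_identities.loc[list(members), list(members)].to_numpy()
        return sub.min() >= cfg.min_within_identity

    chosen = []
    taken: set = set()
    for members, sup in candidates:
        if sup < cfg.support_threshold or members & taken:
            continue
        if coherent(members):
            chosen.append(sorted(members))
            taken |= members
    for x in ids:
        if x not in taken:
            chosen.append([x])
            taken.add(x)

    chosen.sort(key=lambda g: (-len(g), g[0]))
    groups = []
    for i, members in enumerate(chosen):
        name = chr(ord("A") + i) if i < 26 else f"G{i + 1}"
        sub = rt_identities.loc[members, members].to_numpy()
        if len(members) > 1:
            mean_to_others = (sub.sum(axis=1) - 100.0) / (len(members) - 1)
            rep = members[int(np.argmax(mean_to_others))]
            iu = np.triu_indices(len(members), k=1)
            within = float(sub[iu].mean())
        else:
            rep = members[0]
            within = 100.0
        motif = "none"
        if motifs:
            vals = [motifs.get(m, "none") for m in members]
            motif = max(set(vals), key=lambda v: (vals.count(v), v))
        groups.append(
            FamilyGroup(name=name, members=members, representative=rep, within_identity=within, targeting_motif=motif)
        )
    return groups


def group_identity_matrix(groups: list, rts: dict, all_vs_all: bool = False) -> pd.DataFrame:
    """Representative-vs-representative RT identity between groups
    (integer percent).  ``all_vs_all`` switches to the mean over all
    member pairs instead."""
    if not groups:
        raise ValueError("no groups")
    names = [g.name for g in groups]
    n = len(groups)
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            if all_vs_all:
                vals = [
                    pairwise_rt_identity(rts[a], rts[b])
                    for a in groups[i].members
                    for b in groups[j].members
                    if i != j or a < b
                ]
                v = float(np.mean(vals)) if vals else 100.0
            else:
                a, b = groups[i].representative, groups[j].representative
                v = 100.0 if a == b else pairwise_rt_identity(rts[a], rts[b])
            m[i, j] = m[j, i] = v
    return pd.DataFrame(np.rint(m).astype(int), index=names, columns=names)


def classify_nonautonomous(element, cfg: GroupConfig | None = None) -> NonAutonomousClass:
    """TRIM/LARD/TR-GAG decision table on an element with domain hits.

    TR-GAG: GAG present, no protease/RT/RNaseH/integrase.  TRIM: fully
    non-coding, short (<= trim_max_len) with short LTRs (<= trim_max_ltr).
    LARD: non-coding and long (>= lard_min_len).  Anything else is
    unclassified.  Autonomous input (any POL-region hit) is a wiring
    error and raises.
    """
    cfg = cfg or GroupConfig()
    doms = {h.domain for h in element.domains}
    if doms & POL_DOMAINS:
        raise ValueError("autonomous element passed to classify_nonautonomous")
    length = element.interval[1] - element.interval[0]
    ltr_lens = [iv[1] - iv[0] for iv in (element.ltr5, element.ltr3) if iv is not None]
    if "GAG" in doms:
        return NonAutonomousClass("TR_GAG", "GAG present without POL domains")
    if length <= cfg.trim_max_len and ltr_lens and all(l <= cfg.trim_max_ltr for l in ltr_lens):
        return NonAutonomousClass(
            "TRIM", f"non-coding, length {length} <= {cfg.trim_max_len}, LTRs {ltr_lens} <= {cfg.trim_max_ltr}"
        )
    if length >= cfg.lard_min_len:
        return NonAutonomousClass("LARD", f"non-coding, length {length} >= {cfg.lard_min_len}")
    return NonAutonomousClass("unclassified", f"non-coding, length {length}, LTRs {ltr_lens}: no rule fired")


def similarity_profile(alignment, window_cols: int) -> np.ndarray:
    """Sliding-window (step 1) mean pairwise column identity of a multiple
    alignment; result length = n_cols - window + 1.  Gap-containing pairs
    count as mismatches."""
    if window_cols < 1:
        raise ValueError("window must be >= 1")
    from .njtree import alignment_matrix

    _, mat = alignment_matrix(alignment)
    n, L = mat.shape
    if window_cols > L:
        raise ValueError("window longer than alignment")
    npairs = n * (n - 1) / 2
    eq = np.zeros(L)
    for i in range(n):
        ok = (mat[i + 1 :] == mat[i]) & (mat[i] != 45)
        eq += ok.sum(axis=0)
    col_ident = eq / npairs
    kernel = np.ones(window_cols) / window_cols
    return 100.0 * np.convolve(col_ident, kernel, mode="valid")
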