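"""Classification: superfamily order rules, NJ against brute-force
least-squares and dendropy, bootstrap, group definition, non-autonomous
decision table."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from crckit.classify import (
    DistanceMatrix,
    GroupConfig,
    assign_superfamily,
    classify_nonautonomous,
    define_groups,
    group_identity_matrix,
    identity_matrix,
    pairwise_rt_identity,
    similarity_profile,
)
from crckit.detect import LTRElement
from crckit.domains import DomainHit
from crckit.njtree import bootstrap_groups, neighbor_joining
from crckit.simulate import make_background, mutate

# ---------------------------------------------------------------- oracles


def enumerate_topologies(n):
    """All unrooted binary topologies on taxa 0..n-1 as edge lists over
    nodes (leaves 0..n-1, internals >= n), built by stepwise insertion."""
    assert n >= 4
    trees = [[(0, n), (1, n), (2, n)]]
    for leaf in range(3, n):
        new_trees = []
        for edges in trees:
            for i, (a, b) in enumerate(edges):
                u = max(max(e) for e in edges) + 1  # fresh node per insertion
                new = edges[:i] + edges[i + 1 :] + [(a, u), (b, u), (leaf, u)]
                new_trees.append(new)
        trees = new_trees
    return trees


def topology_bipartitions(edges, n):
    """Leaf bipartitions (canonical frozensets excluding taxon 0's side)."""
    adj = {}
    for a, b in edges:
        adj.setdefault(a, []).append(b)
        adj.setdefault(b, []).append(a)

    def side(a, b):
        seen, stack, out = {a, b}, [b], []
        if b < n:
            out.append(b)
        while stack:
            x = stack.pop()
            for y in adj[x]:
                if y not in seen:
                    seen.add(y)
                    if y < n:
                        out.append(y)
                    stack.append(y)
        return out

    bps = set()
    for a, b in edges:
        s = side(a, b)
        if 2 <= len(s) <= n - 2:
            s = set(s)
            if 0 in s:
                s = set(range(n)) - s
            bps.add(frozenset(s))
    return bps


def least_squares_topology(D):
    """Brute force: fit branch lengths per topology by least squares on
    path equations; return bipartitions of the best-fitting topology."""
    n = D.shape[0]
    best = None
    for edges in enumerate_topologies(n):
        adj = {}
        for ei, (a, b) in enumerate(edges):
            adj.setdefault(a, []).append((b, ei))
            adj.setdefault(b, []).append((a, ei))
        rows, y = [], []
        for i, j in itertools.combinations(range(n), 2):
            # path from i to j
            prev = {i: (None, None)}
            stack = [i]
            while j not in prev:
                x = stack.pop()
                for nb, ei in adj[x]:
                    if nb not in prev:
                        prev[nb] = (x, ei)
                        stack.append(nb)
            row = np.zeros(len(edges))
            node = j
            while prev[node][0] is not None:
                row[prev[node][1]] = 1.0
                node = prev[node][0]
            rows.append(row)
            y.append(D[i, j])
        A = np.array(rows)
        sol, *_ = np.linalg.lstsq(A, np.array(y), rcond=None)
        sse = float(((A @ sol) - y) ** 2 @ np.ones(len(y)))
        if best is None or sse < best[0] - 1e-12:
            best = (sse, edges)
    return topology_bipartitions(best[1], n)


def random_additive_matrix(n, rng):
    """Distances from a random binary tree with positive branch lengths."""
    edges = enumerate_topologies(n)[rng.integers(len(enumerate_topologies(n)))]
    lengths = {tuple(sorted(e)): rng.uniform(0.05, 1.0) for e in edges}
    adj = {}
    for a, b in edges:
        adj.setdefault(a, []).append(b)
        adj.setdefault(b, []).append(a)
    D = np.zeros((n, n))
    for i in range(n):
        dist = {i: 0.0}
        stack = [i]
        while stack:
            x = stack.pop()
            for y in adj[x]:
                if y not in dist:
                    dist[y] = dist[x] + lengths[tuple(sorted((x, y)))]
                    stack.append(y)
        for j in range(n):
            D[i, j] = dist[j]
    return D


def tree_bipartitions_as_indices(tree, ids):
    idx = {name: k for k, name in enumerate(ids)}
    out = set()
    for side in tree.bipartitions():
        s = {idx[x] for x in side}
        if 0 in s:
            s = set(range(len(ids))) - s
        out.add(frozenset(s))
    return out


# ---------------------------------------------------------------- tests


class TestSuperfamily:
    def _hits(self, order):
        return [DomainHit(d, (i * 1000, i * 1000 + 300), 1, 60.0, 100, "r", "M") for i, d in enumerate(order)]

    def test_gypsy_layout(self):
        assert assign_superfamily(self._hits(["GAG", "PR", "RT", "RH", "INT"])) == "Gypsy"

    def test_copia_layout(self):
        assert assign_superfamily(self._hits(["GAG", "PR", "INT", "RT", "RH"])) == "Copia"

    def test_no_pol_is_nonautonomous(self):
        assert assign_superfamily([]) == "non_autonomous"
        assert assign_superfamily(self._hits(["GAG"])) == "non_autonomous"

    def test_ambiguous_order(self):
        assert assign_superfamily(self._hits(["RT"])) == "unclassified_autonomous"


class TestPairwiseIdentity:
    def test_identical(self):
        assert pairwise_rt_identity("ACGTACGTAC", "ACGTACGTAC") == 100.0

    def test_hand_counted(self):
        assert pairwise_rt_identity("ACGTACGTAC", "ACGTACGTTC") == pytest.approx(90.0)

    def test_within_group_divergence_scale(self):
        # 0.05 expected subs/site per lineage -> ~90% pairwise identity
        rng = np.random.default_rng(3)
        base = make_background(810, 0.45, 9)
        a = mutate(base, 0.05, 2.0, rng)
        b = mutate(base, 0.05, 2.0, rng)
        ident = pairwise_rt_identity(a, b)
        assert 85.0 <= ident <= 95.0

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            pairwise_rt_identity("", "ACGT")


class TestNeighborJoining:
    def test_four_taxon_additive_exact(self):
        ids = ["A", "B", "C", "D"]
        D = np.array(
            [
                [0, 2, 4, 5],
                [2, 0, 4, 5],
                [4, 4, 0, 3],
                [5, 5, 3, 0],
            ],
            dtype=float,
        )
        tree = neighbor_joining(ids, D)
        bps = tree.bipartitions()
        assert set(bps) == {frozenset({"C", "D"})}
        # additive fit: external branches recover exactly
        # (A,B split their 2 evenly; C=1, D=2, internal=2)
        leaf_len = {}
        for node, name in tree.leaf_name.items():
            (nbr, ln), = tree.adj[node].items()
            leaf_len[name] = ln
        assert leaf_len == pytest.approx({"A": 1.0, "B": 1.0, "C": 1.0, "D": 2.0})
        assert bps[frozenset({"C", "D"})] == pytest.approx(2.0)

    def test_three_taxa_closed_form(self):
        ids = ["x", "y", "z"]
        D = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], dtype=float)
        tree = neighbor_joining(ids, D)
        leaf_len = {}
        for node, name in tree.leaf_name.items():
            (nbr, ln), = tree.adj[node].items()
            leaf_len[name] = ln
        assert leaf_len == pytest.approx({"x": 1.0, "y": 2.0, "z": 3.0})

    def test_taxon_order_invariance(self):
        rng = np.random.default_rng(7)
        D = random_additive_matrix(6, rng)
        ids = [f"t{i}" for i in range(6)]
        t1 = neighbor_joining(ids, D)
        perm = rng.permutation(6)
        ids_p = [ids[i] for i in perm]
        Dp = D[np.ix_(perm, perm)]
        t2 = neighbor_joining(ids_p, Dp)
        assert {frozenset(b) for b in t1.bipartitions()} == {frozenset(b) for b in t2.bipartitions()}

    def test_rejects_small_or_asymmetric(self):
        with pytest.raises(ValueError):
            neighbor_joining(["a", "b"], np.zeros((2, 2)))
        with pytest.raises(ValueError):
            neighbor_joining(["a", "b", "c"], np.array([[0, 1, 2], [1, 0, 3], [9, 3, 0.0]]))

    @pytest.mark.parametrize("n", [4, 5, 6])
    def test_matches_least_squares_oracle(self, n):
        # 200-case suite split across sizes; additive matrices have a
        # unique best topology which NJ must recover
        rng = np.random.default_rng(100 + n)
        n_cases = {4: 60, 5: 70, 6: 70}[n]
        for _ in range(n_cases):
            D = random_additive_matrix(n, rng)
            ids = [f"t{i}" for i in range(n)]
            nj_bps = tree_bipartitions_as_indices(neighbor_joining(ids, D), ids)
            assert nj_bps == least_squares_topology(D)

    def test_matches_dendropy_on_additive_matrix(self):
        dendropy = pytest.importorskip("dendropy")
        rng = np.random.default_rng(17)
        D = random_additive_matrix(6, rng)
        ids = [f"t{i}" for i in range(6)]
        ours = tree_bipartitions_as_indices(neighbor_joining(ids, D), ids)
        # dendropy NJ as the independent implementation
        csv = "," + ",".join(ids) + "\n"
        for i in range(6):
            csv += ids[i] + "," + ",".join(f"{D[i, j]:.8f}" for j in range(6)) + "\n"
        import io as _io

        pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(_io.StringIO(csv))
        dtree = pdm.nj_tree()
        theirs = set()
        dtree.encode_bipartitions()
        name_idx = {ids[i]: i for i in range(6)}
        for bp in dtree.bipartition_encoding:
            leaves = {name_idx[t.label] for t in dtree.taxon_namespace if bp.leafset_bitmask & dtree.taxon_namespace.taxon_bitmask(t)}
            if 2 <= len(leaves) <= 4:
                if 0 in leaves:
                    leaves = set(range(6)) - leaves
                theirs.add(frozenset(leaves))
        assert ours == theirs


class TestBootstrap:
    def _clades_alignment(self, rng):
        base = make_background(600, 0.45, 23)
        far = mutate(base, 0.5, 2.0, rng)
        rows = []
        for i in range(4):
            rows.append((f"a{i}", mutate(base, 0.05, 2.0, rng)))
        for i in range(4):
            rows.append((f"b{i}", mutate(far, 0.05, 2.0, rng)))
        return rows

    def test_separated_clades_full_support(self):
        rng = np.random.default_rng(31)
        aln = self._clades_alignment(rng)
        tree, sup = bootstrap_groups(aln, n_reps=100, seed=5)
        clade = frozenset({"b0", "b1", "b2", "b3"})
        assert sup[clade] == pytest.approx(100.0)

    def test_single_rep_supports_binary(self):
        rng = np.random.default_rng(37)
        aln = self._clades_alignment(rng)
        _, sup = bootstrap_groups(aln, n_reps=1, seed=6)
        assert set(sup.values()) <= {0.0, 100.0}

    def test_seed_reproducible(self):
        rng = np.random.default_rng(41)
        aln = self._clades_alignment(rng)
        _, s1 = bootstrap_groups(aln, n_reps=25, seed=7)
        _, s2 = bootstrap_groups(aln, n_reps=25, seed=7)
        assert s1 == s2


class TestDefineGroups:
    def _three_family_rts(self, rng, n_per=4):
        base = make_background(810, 0.45, 51)
        rts = {}
        truth = {}
        for f in range(3):
            anc = mutate(base, 0.35, 2.0, rng)
            for i in range(n_per):
                rid = f"f{f}_m{i}"
                rts[rid] = mutate(anc, 0.05, 2.0, rng)
                truth[rid] = f
        return rts, truth

    def test_three_planted_families_recovered(self):
        rng = np.random.default_rng(61)
        rts, truth = self._three_family_rts(rng)
        ident = identity_matrix(rts)
        aln = [(k, v) for k, v in rts.items()]
        tree, sup = bootstrap_groups(aln, n_reps=100, seed=8)
        groups = define_groups(tree, sup, ident)
        assert len(groups) == 3
        for g in groups:
            assert len({truth[m] for m in g.members}) == 1
            assert g.representative in g.members

    def test_identical_sequences_one_group(self):
        rts = {f"s{i}": "ACGT" * 200 for i in range(5)}
        ident = identity_matrix(rts)
        aln = [(k, v) for k, v in rts.items()]
        tree, sup = bootstrap_groups(aln, n_reps=10, seed=9)
        groups = define_groups(tree, sup, ident)
        assert len(groups) == 1
        assert sorted(groups[0].members) == sorted(rts)

    def test_partition_property(self):
        rng = np.random.default_rng(71)
        rts, _ = self._three_family_rts(rng, n_per=3)
        ident = identity_matrix(rts)
        aln = [(k, v) for k, v in rts.items()]
        tree, sup = bootstrap_groups(aln, n_reps=50, seed=10)
        groups = define_groups(tree, sup, ident)
        seen = [m for g in groups for m in g.members]
        assert sorted(seen) == sorted(rts)

    def test_group_identity_matrix_blocks(self):
        rng = np.random.default_rng(81)
        rts, truth = self._three_family_rts(rng)
        ident = identity_matrix(rts)
        aln = [(k, v) for k, v in rts.items()]
        tree, sup = bootstrap_groups(aln, n_reps=50, seed=11)
        groups = define_groups(tree, sup, ident)
        gm = group_identity_matrix(groups, rts)
        assert (np.diag(gm.to_numpy()) == 100).all()
        off = gm.to_numpy()[~np.eye(len(gm), dtype=bool)]
        assert off.max() < 80  # between-family band well below within


NONAUTO_CFG = GroupConfig()


def nonauto_oracle(length, ltr_len, doms):
    pol = {"PR", "RT", "RH", "INT"}
    if doms & pol:
        return "error"
    if "GAG" in doms:
        return "TR_GAG"
    if length <= NONAUTO_CFG.trim_max_len and ltr_len is not None and ltr_len <= NONAUTO_CFG.trim_max_ltr:
        return "TRIM"
    if length >= NONAUTO_CFG.lard_min_len:
        return "LARD"
    return "unclassified"


def _element(length, ltr_len, doms):
    el = LTRElement(
        genome_id="g",
        interval=(0, length),
        ltr5=(0, ltr_len) if ltr_len else None,
        ltr3=(length - ltr_len, length) if ltr_len else None,
    )
    el.domains = [DomainHit(d, (100, 400), 1, 60.0, 100, "r", "M") for d in doms]
    return el


class TestNonAutonomous:
    @pytest.mark.parametrize(
        "length,ltr,doms,want",
        [
            (900, 150, set(), "TRIM"),
            (6500, 700, set(), "LARD"),
            (3000, 400, {"GAG"}, "TR_GAG"),
            (3000, 400, set(), "unclassified"),
        ],
    )
    def test_examples(self, length, ltr, doms, want):
        assert classify_nonautonomous(_element(length, ltr, doms), NONAUTO_CFG).label == want

    def test_autonomous_input_guards(self):
        with pytest.raises(ValueError):
            classify_nonautonomous(_element(6000, 700, {"GAG", "RT"}), NONAUTO_CFG)

    @given(
        length=st.integers(min_value=300, max_value=20000),
        ltr=st.integers(min_value=50, max_value=2500),
        doms=st.sets(st.sampled_from(["GAG", "PR", "RT", "RH", "INT"])),
    )
    @settings(max_examples=300, derandomize=True, deadline=None)
    def test_matches_decision_table_oracle(self, length, ltr, doms):
        ltr = min(ltr, length // 2)
        want = nonauto_oracle(length, ltr, doms)
        el = _element(length, ltr, doms)
        if want == "error":
            with pytest.raises(ValueError):
                classify_nonautonomous(el, NONAUTO_CFG)
        else:
            assert classify_nonautonomous(el, NONAUTO_CFG).label == want


class TestSimilarityProfile:
    def test_identical_rows_flat_100(self):
        aln = [("a", "ACGT" * 50), ("b", "ACGT" * 50), ("c", "ACGT" * 50)]
        prof = similarity_profile(aln, 20)
        assert prof.shape == (200 - 20 + 1,)
        assert np.allclose(prof, 100.0)

    def test_divergent_block_shows_dip(self):
        base = "ACGT" * 75
        mid = list(base)
        for i in range(120, 180):
            mid[i] = "A" if base[i] != "A" else "C"
        aln = [("a", base), ("b", base), ("c", "".join(mid))]
        prof = similarity_profile(aln, 30)
        dip = np.argmin(prof)
        assert 100 <= dip <= 180
        assert prof[dip] < prof[0] - 20

    def test_degenerate_window_is_mean(self):
        aln = [("a", "AAAA"), ("b", "AAAT")]
        prof = similarity_profile(aln, 4)
        assert prof.shape == (1,)
        assert prof[0] == pytest.approx(75.0)

    def test_window_too_long_errors(self):
        with pytest.raises(ValueError):
            similarity_profile([("a", "ACGT"), ("b", "ACGT")], 5)


class TestDistanceMatrix:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            DistanceMatrix(ids=["a", "b"], d=np.array([[0, 0.5], [0.4, 0]]))
        with pytest.raises(ValueError):
            DistanceMatrix(ids=["a", "b"], d=np.array([[0, 1.5], [1.5, 0]]))
        dm = DistanceMatrix(ids=["a", "b"], d=np.array([[0, 0.3], [0.3, 0]]))
        assert dm.d[0, 1] == 0.3
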