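"""Census, dating, density, tandem arrays, composition, age histogram."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from crckit.census import (
    CensusConfig,
    InsertionAge,
    RawAlignment,
    age_histogram,
    call_copies,
    census_scan,
    density_profile,
    detect_tandem_arrays,
    insertion_time,
    k2p_distance,
    region_composition,
)
from crckit.simulate import make_background, mutate, plant_tandem_array


class TestCensusScan:
    def test_exact_copy_full_coverage(self, families):
        rep = families[7].sequence
        bg = make_background(60_000, 0.38, 91)
        genome = bg[:30_000] + rep + bg[30_000:]
        hits = census_scan(rep, genome, CensusConfig(), family="H")
        assert len(hits) == 1
        assert hits[0].coverage == pytest.approx(1.0, abs=0.02)
        assert hits[0].identity == pytest.approx(1.0, abs=0.005)

    def test_truncated_divergent_copy(self, families):
        rep = families[7].sequence
        rng = np.random.default_rng(5)
        half = mutate(rep, 0.1, 2.0, rng)[: len(rep) // 2]
        bg = make_background(60_000, 0.38, 92)
        genome = bg[:30_000] + half + bg[30_000:]
        hits = census_scan(rep, genome, CensusConfig(), family="H")
        assert len(hits) == 1
        # the copy's single LTR matches both LTR positions on the
        # representative, so coverage runs ~ltr/length above 0.5
        assert 0.45 <= hits[0].coverage <= 0.62
        assert hits[0].identity == pytest.approx(0.9, abs=0.03)

    def test_empty_background(self, families):
        rep = families[7].sequence
        for seed in (93, 94, 95):
            assert census_scan(rep, make_background(50_000, 0.38, seed), CensusConfig()) == []

    def test_reverse_strand_copy_found(self, families):
        from crckit.seqs import revcomp

        rep = families[2].sequence
        bg = make_background(40_000, 0.38, 96)
        genome = bg[:20_000] + revcomp(rep) + bg[20_000:]
        hits = census_scan(rep, genome, CensusConfig())
        assert len(hits) == 1
        assert hits[0].strand == "-"

    def test_noiseless_census_counts_equal_plantings(self, families):
        # planted age-0 copies: census must count them exactly
        rep = families[4].sequence
        bg = make_background(120_000, 0.38, 97)
        genome = bg
        for pos in (100_000, 60_000, 20_000):  # insert right to left
            genome = genome[:pos] + rep + genome[pos:]
        hits = census_scan(rep, genome, CensusConfig(), family="E")
        copies = call_copies(hits, CensusConfig())
        assert len(copies) == 3
        assert all(c.completeness == "complete" for c in copies)


class TestCallCopies:
    def _hit(self, cov, ident):
        return RawAlignment(family="F", genome_id="g", interval=(0, 100), strand="+", identity=ident, coverage=cov)

    @pytest.mark.parametrize(
        "cov,ident,want",
        [
            (0.85, 0.90, "complete"),
            (0.50, 0.85, "fragment"),
            (0.85, 0.80, None),  # identity exactly at threshold: strict >
            (0.80, 0.90, "fragment"),  # coverage exactly at complete threshold
            (0.10, 0.90, None),  # coverage exactly at fragment threshold
            (0.05, 0.99, None),
        ],
    )
    def test_strict_decision_table(self, cov, ident, want):
        out = call_copies([self._hit(cov, ident)], CensusConfig())
        if want is None:
            assert out == []
        else:
            assert out[0].completeness == want

    def test_exhaustive_grid_partition(self):
        cfg = CensusConfig()
        for cov in np.linspace(0.0, 1.0, 51):
            for ident in np.linspace(0.5, 1.0, 26):
                out = call_copies([self._hit(float(cov), float(ident))], cfg)
                complete = ident > 0.8 and cov > 0.8
                fragment = ident > 0.8 and 0.1 < cov <= 0.8
                if complete:
                    assert [c.completeness for c in out] == ["complete"]
                elif fragment:
                    assert [c.completeness for c in out] == ["fragment"]
                else:
                    assert out == []

    def test_idempotent(self):
        cfg = CensusConfig()
        hits = [self._hit(0.9, 0.9), self._hit(0.5, 0.9)]
        once = call_copies(hits, cfg)
        twice = call_copies(once, cfg)
        assert [(c.coverage, c.identity, c.completeness) for c in once] == [
            (c.coverage, c.identity, c.completeness) for c in twice
        ]


class TestK2P:
    def test_identical_zero(self):
        seq = make_background(500, 0.4, 1)
        assert k2p_distance(seq, seq) == (0.0, 0.0, 0.0, False)

    def test_closed_form_transitions_only(self):
        a = "A" * 693 + "G" * 7
        b = "A" * 700
        P, Q, K, sat = k2p_distance(a, b)
        assert (P, Q) == (0.01, 0.0)
        assert K == pytest.approx(-0.5 * math.log(0.98), abs=1e-12)
        assert not sat

    def test_saturation_flagged(self):
        # P=0.4, Q=0.2 -> 1-2P-Q = 0: outside the formula domain
        n = 10
        a = "A" * n
        b = "G" * 4 + "C" * 2 + "A" * 4
        P, Q, K, sat = k2p_distance(a, b)
        assert (P, Q) == (0.4, 0.2)
        assert sat and math.isnan(K)

    def test_symmetric(self):
        rng = np.random.default_rng(7)
        a = make_background(400, 0.4, 2)
        b = mutate(a, 0.1, 2.0, rng)
        assert k2p_distance(a, b) == k2p_distance(b, a)

    def test_closed_form_on_random_pairs(self):
        # estimator equals the closed form computed from its own P,Q
        rng = np.random.default_rng(11)
        for _ in range(50):
            a = make_background(300, 0.45, int(rng.integers(2**31)))
            b = mutate(a, rng.uniform(0, 0.2), 2.0, rng)
            P, Q, K, sat = k2p_distance(a, b)
            if sat:
                continue
            want = -0.5 * math.log((1 - 2 * P - Q) * math.sqrt(1 - 2 * Q))
            assert K == pytest.approx(want, abs=1e-12)


class TestInsertionTime:
    def test_examples(self):
        assert insertion_time(0.0) == 0.0
        assert insertion_time(0.026, 1.3e-8) == pytest.approx(1_000_000.0)

    def test_rejects_bad_rate(self):
        with pytest.raises(ValueError):
            insertion_time(0.01, 0.0)
        with pytest.raises(ValueError):
            insertion_time(-0.1, 1e-8)

    @given(K=st.floats(min_value=0, max_value=2), c=st.floats(min_value=0.1, max_value=10))
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_linear_in_K_inverse_in_r(self, K, c):
        r = 1.3e-8
        assert insertion_time(c * K, r) == pytest.approx(c * insertion_time(K, r), rel=1e-12)
        assert insertion_time(K, c * r) == pytest.approx(insertion_time(K, r) / c, rel=1e-12)


class TestDensity:
    def test_single_block(self):
        track = density_profile([(0, 10_000)], 100_000, 10_000, 10_000)
        assert track.values.shape == (10,)
        assert track.values[0] == pytest.approx(1.0)
        assert np.all(track.values[1:] == 0)

    def test_abutting_equals_union(self):
        t1 = density_profile([(100, 500), (500, 900)], 10_000, 1000, 500)
        t2 = density_profile([(100, 900)], 10_000, 1000, 500)
        assert np.allclose(t1.values, t2.values)

    def test_count_mode(self):
        track = density_profile([(100, 200), (5100, 5200)], 10_000, 1000, 1000, mode="count")
        assert track.values[0] == 1 and track.values[5] == 1

    def test_clustered_plantings_enrich_center(self):
        rng = np.random.default_rng(3)
        ivs = []
        # 80% of plantings in the central 20%
        for _ in range(80):
            s = int(rng.uniform(0.4, 0.6) * 1_000_000)
            ivs.append((s, s + 5000))
        for _ in range(20):
            s = int(rng.uniform(0, 0.35) * 1_000_000)
            ivs.append((s, s + 5000))
        track = density_profile(ivs, 1_000_000, 100_000, 20_000)
        centers = track.starts + 50_000
        central = track.values[(centers > 400_000) & (centers < 600_000)]
        flank = track.values[(centers < 300_000) | (centers > 700_000)]
        assert central.mean() > 3 * flank.mean()

    def test_window_longer_than_genome_warns(self):
        with pytest.warns(UserWarning):
            track = density_profile([(0, 10)], 100, 1000, 1000)
        assert track.values.shape == (1,)


class TestTandemArrays:
    def test_planted_array_recovered(self):
        bg = make_background(100_000, 0.38, 4)
        mono = make_background(170, 0.45, 5)
        genome, truth = plant_tandem_array(bg, mono, 50, 40_000, 0.02, seed=6)
        arrays = detect_tandem_arrays(genome, min_period=50, max_period=500, min_copies=5)
        assert len(arrays) == 1
        a = arrays[0]
        assert abs(a["period"] - 170) <= 2
        assert abs(a["copies"] - 50) <= 3
        assert abs(a["interval"][0] - 40_000) <= 200
        assert abs(a["interval"][1] - 48_500) <= 200

    def test_background_empty(self):
        for seed in (7, 8, 9, 10):
            assert detect_tandem_arrays(make_background(150_000, 0.38, seed), 50, 500, 5) == []

    def test_rejects_bad_params(self):
        with pytest.raises(ValueError):
            detect_tandem_arrays("ACGT" * 100, min_period=1, max_period=10, min_copies=5)
        with pytest.raises(ValueError):
            detect_tandem_arrays("ACGT" * 100, min_period=10, max_period=100, min_copies=1)


class TestComposition:
    class R:
        def __init__(self, cat, iv):
            self.category = cat
            self.interval = iv

    def test_single_element_full_chain(self):
        recs = [self.R(("TE", "LTR_RT", "CRC", "H"), (0, 1000))]
        table = region_composition(recs, (0, 1000))
        vals = dict(zip(table["category"], table["percent"]))
        assert vals["TE"] == vals["TE/LTR_RT"] == vals["TE/LTR_RT/CRC"] == vals["TE/LTR_RT/CRC/H"] == 100.0

    def test_subcategory_never_exceeds_parent(self):
        recs = [
            self.R(("TE", "LTR_RT", "CRC", "H"), (0, 400)),
            self.R(("TE", "LTR_RT", "CRC", "B"), (300, 600)),
            self.R(("TE", "transposon"), (700, 800)),
        ]
        table = region_composition(recs, (0, 1000))
        vals = dict(zip(table["category"], table["percent"]))
        assert vals["TE"] == pytest.approx(70.0)
        assert vals["TE/LTR_RT/CRC"] == pytest.approx(60.0)
        assert vals["TE/LTR_RT/CRC/H"] == pytest.approx(40.0)
        assert vals["TE/LTR_RT/CRC/B"] == pytest.approx(30.0)

    def test_outside_region_rejected(self):
        with pytest.raises(ValueError):
            region_composition([self.R(("TE",), (0, 2000))], (0, 1000))


class TestAgeHistogram:
    def _ages(self, ts):
        return [InsertionAge("e", 0, 0, t * 2 * 1.3e-8, t, 1.3e-8) for t in ts]

    def test_single_cluster_one_peak(self):
        rng = np.random.default_rng(8)
        ages = self._ages(rng.normal(0.5e6, 0.05e6, size=100))
        edges, counts, peaks = age_histogram(ages, 0.1e6)
        assert len(peaks) == 1

    def test_trimodal_recovered(self):
        rng = np.random.default_rng(9)
        ts = np.concatenate(
            [rng.normal(m, 0.08e6, size=60) for m in (0.5e6, 1.5e6, 3e6)]
        )
        edges, counts, peaks = age_histogram(self._ages(ts), 0.25e6)
        assert len(peaks) == 3
        centers = [(edges[i] + edges[i + 1]) / 2 for i in peaks]
        for want in (0.5e6, 1.5e6, 3e6):
            assert min(abs(c - want) for c in centers) < 0.3e6

    def test_empty_input(self):
        edges, counts, peaks = age_histogram([], 1e5)
        assert len(counts) == 0 and peaks == []
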