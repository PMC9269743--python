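import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.distance import jensenshannon

from glucosynth.cgm_io import DayMatrix, SAMPLES_PER_DAY
from glucosynth.evalgen import (ProbabilityHistogram, RangeThresholds,
                                glucose_histogram, js_distance, js_heatmap,
                                range_fractions, summary_stats,
                                wilcoxon_acceptance, z_test)
from glucosynth.simulate import SimPatientParams, simulate_patient
from glucosynth.cgm_io import to_day_matrix


def _hist2(p0):
    """Two-bin histogram embedded at the left edge of the support grid."""
    edges = np.array([40.0, 220.0, 400.0])
    return ProbabilityHistogram(edges, np.array([p0, 1.0 - p0]))


class TestRangeFractions:
    def test_single_band(self, day_matrix_from_values):
        dm = day_matrix_from_values([100.0])
        assert range_fractions(dm) == (0.0, 100.0, 0.0, 0.0)

    def test_one_sample_per_band(self, day_matrix_from_values):
        dm = day_matrix_from_values([53.0, 60.0, 100.0, 200.0])
        assert range_fractions(dm) == (25.0, 25.0, 25.0, 25.0)

    def test_54_belongs_to_l1_not_l2(self, day_matrix_from_values):
        hyper, tir, l1, l2 = range_fractions(day_matrix_from_values([54.0]))
        assert (l1, l2) == (100.0, 0.0)

    @pytest.mark.parametrize("value,band", [(69.999, 2), (70.0, 1), (179.999, 1),
                                            (180.0, 0), (53.999, 3)])
    def test_half_open_boundaries(self, day_matrix_from_values, value, band):
        fractions = range_fractions(day_matrix_from_values([value]))
        assert fractions[band] == 100.0

    def test_partition_sums_to_100(self):
        dm = to_day_matrix(simulate_patient(SimPatientParams(seed=2), 20))
        assert sum(range_fractions(dm)) == pytest.approx(100.0, abs=1e-9)

    def test_empty_matrix_rejected(self):
        dm = DayMatrix("P", np.empty((0, SAMPLES_PER_DAY)))
        with pytest.raises(ValueError, match="empty"):
            range_fractions(dm)

    def test_threshold_ordering_enforced(self):
        with pytest.raises(ValueError):
            RangeThresholds(l2_upper=80, l1_upper=70, tir_upper=180)


class TestSummaryStats:
    def test_constant_matrix(self, day_matrix_from_values):
        s = summary_stats(day_matrix_from_values([120.0]))
        assert (s.mean, s.sd, s.variance) == (120.0, 0.0, 0.0)

    def test_two_point_variance(self, day_matrix_from_values):
        s = summary_stats(day_matrix_from_values([100.0, 140.0]))
        assert s.mean == 120.0
        assert s.variance == 400.0

    def test_sd_squares_to_variance(self):
        dm = to_day_matrix(simulate_patient(SimPatientParams(seed=9), 10))
        s = summary_stats(dm)
        assert s.sd ** 2 == pytest.approx(s.variance, abs=1e-6)


class TestGlucoseHistogram:
    def test_degenerate_single_bin(self, day_matrix_from_values):
        h = glucose_histogram(day_matrix_from_values([45.0]))
        assert h.masses[0] == 1.0
        assert h.masses[1:].sum() == 0.0

    def test_uniform_samples_near_uniform_masses(self):
        rng = np.random.default_rng(0)
        rows = rng.uniform(40, 400, size=(40, SAMPLES_PER_DAY))
        h = glucose_histogram(DayMatrix("P", rows))
        assert h.masses.max() - h.masses.min() < 0.01

    def test_masses_sum_to_one(self):
        dm = to_day_matrix(simulate_patient(SimPatientParams(seed=1), 5))
        assert glucose_histogram(dm).masses.sum() == pytest.approx(1.0, abs=1e-12)

    def test_bad_bin_width_rejected(self, day_matrix_from_values):
        with pytest.raises(ValueError, match="bin_width"):
            glucose_histogram(day_matrix_from_values([100.0]), bin_width=7.0)


class TestJSDistance:
    def test_identical_histograms_zero(self):
        assert js_distance(_hist2(0.5), _hist2(0.5)) == 0.0

    def test_disjoint_supports_one(self):
        assert js_distance(_hist2(1.0), _hist2(0.0)) == pytest.approx(1.0, abs=1e-12)

    def test_hand_evaluated_oracle(self):
        # P=(1/2,1/2), Q=(1,0): M=(3/4,1/4)
        # D(P||M)=0.5*log2(2/3)+0.5*log2(2) ; D(Q||M)=log2(4/3)
        assert js_distance(_hist2(0.5), _hist2(1.0)) == pytest.approx(0.5579, abs=1e-4)

    def test_mismatched_edges_rejected(self):
        h = _hist2(0.5)
        other = ProbabilityHistogram(np.array([40.0, 100.0, 400.0]),
                                     np.array([0.5, 0.5]))
        with pytest.raises(ValueError, match="edges"):
            js_distance(h, other)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0.01, 1.0), min_size=5, max_size=5),
           st.lists(st.floats(0.01, 1.0), min_size=5, max_size=5))
    def test_properties_on_random_histograms(self, raw_p, raw_q):
        """Symmetry, [0, 1] bound, and agreement with an independent implementation."""
        edges = np.linspace(40, 400, 6)
        pm = np.array(raw_p) / np.sum(raw_p)
        qm = np.array(raw_q) / np.sum(raw_q)
        p = ProbabilityHistogram(edges, pm)
        q = ProbabilityHistogram(edges, qm)
        d_pq = js_distance(p, q)
        assert 0.0 <= d_pq <= 1.0
        assert d_pq == pytest.approx(js_distance(q, p), abs=1e-12)
        assert d_pq == pytest.approx(jensenshannon(pm, qm, base=2), abs=1e-9)

    def test_triangle_inequality_spot_check(self):
        rng = np.random.default_rng(7)
        edges = np.linspace(40, 400, 10)
        for _ in range(200):
            a, b, c = (ProbabilityHistogram(edges, m / m.sum())
                       for m in rng.uniform(0.01, 1, size=(3, 9)))
            assert js_distance(a, c) <= js_distance(a, b) + js_distance(b, c) + 1e-12


class TestJSHeatmap:
    def test_self_comparison_zero_diagonal(self):
        dm = to_day_matrix(simulate_patient(SimPatientParams(seed=3), 5))
        hm = js_heatmap(dm, dm)
        np.testing.assert_allclose(np.diag(hm), 0.0, atol=1e-12)

    def test_shape(self):
        a = to_day_matrix(simulate_patient(SimPatientParams(seed=3), 3))
        b = to_day_matrix(simulate_patient(SimPatientParams(seed=4), 2))
        assert js_heatmap(a, b).shape == (3, 2)


class TestZTest:
    def test_identical_sets_zero(self):
        dm = to_day_matrix(simulate_patient(SimPatientParams(seed=5), 6))
        assert z_test(dm, dm) == 0.0

    def test_equal_means_different_spread_zero(self):
        a = DayMatrix("P", np.vstack([np.full(SAMPLES_PER_DAY, v)
                                      for v in (100.0, 120.0, 140.0)]))
        b = DayMatrix("P", np.vstack([np.full(SAMPLES_PER_DAY, v)
                                      for v in (110.0, 120.0, 130.0)]))
        assert z_test(a, b) == 0.0

    def test_matches_hand_formula(self):
        a = to_day_matrix(simulate_patient(SimPatientParams(seed=6), 10))
        b = to_day_matrix(simulate_patient(SimPatientParams(basal_mean=170, seed=7), 12))
        ma, mb = a.rows.mean(axis=1), b.rows.mean(axis=1)
        expected = abs(ma.mean() - mb.mean()) / np.sqrt(
            ma.var(ddof=1) / 10 + mb.var(ddof=1) / 12)
        assert z_test(a, b) == pytest.approx(expected, rel=1e-12)

    def test_single_day_sets_rejected(self, day_matrix_from_values):
        dm = day_matrix_from_values([120.0])
        with pytest.raises(ValueError, match="two days"):
            z_test(dm, dm)


class TestWilcoxonAcceptance:
    def test_self_comparison_always_accepted(self):
        dm = to_day_matrix(simulate_patient(SimPatientParams(seed=8), 20))
        report = wilcoxon_acceptance(dm, dm, seed=0)
        assert report.accepted
        assert all(p == 1.0 for p in report.p_values.values())

    def test_mean_shift_rejected(self):
        real = to_day_matrix(simulate_patient(SimPatientParams(seed=9), 90))
        shifted = to_day_matrix(simulate_patient(
            SimPatientParams(basal_mean=230, seed=10), 90))
        report = wilcoxon_acceptance(real, shifted, seed=0)
        assert not report.accepted
        assert min(report.p_values.values()) < 0.05

    def test_too_few_synth_rows_rejected(self):
        real = to_day_matrix(simulate_patient(SimPatientParams(seed=11), 10))
        synth = to_day_matrix(simulate_patient(SimPatientParams(seed=12), 5))
        with pytest.raises(ValueError, match="synthetic rows"):
            wilcoxon_acceptance(real, synth)

    def test_same_generator_usually_accepted(self):
        real = to_day_matrix(simulate_patient(SimPatientParams(seed=13), 60))
        synth = to_day_matrix(simulate_patient(SimPatientParams(seed=14), 80))
        assert wilcoxon_acceptance(real, synth, seed=0).accepted

    def test_paired_mode_runs(self):
        real = to_day_matrix(simulate_patient(SimPatientParams(seed=15), 30))
        synth = to_day_matrix(simulate_patient(SimPatientParams(seed=16), 30))
        report = wilcoxon_acceptance(real, synth, seed=0, paired=True)
        assert set(report.p_values) == {"hyper", "tir", "l1", "l2", "mean"}

    def test_js_symmetry_across_comparison_kinds(self):
        """real-real, synth-synth and real-synth JS agree when drawn alike."""
        sets = [to_day_matrix(simulate_patient(SimPatientParams(seed=s), 60))
                for s in (20, 21, 22, 23)]
        from glucosynth.evalgen import glucose_histogram, js_distance
        rr = js_distance(glucose_histogram(sets[0]), glucose_histogram(sets[1]))
        ss = js_distance(glucose_histogram(sets[2]), glucose_histogram(sets[3]))
        rs = js_distance(glucose_histogram(sets[0]), glucose_histogram(sets[2]))
        assert abs(rr - ss) < 0.05 and abs(rr - rs) < 0.05
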