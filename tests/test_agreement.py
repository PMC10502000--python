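"""Dice, two-way agreement ICC, limits of agreement, comparison pipeline."""

import numpy as np
import pytest

from gutgaze.agreement import (
    PairedDiameters,
    compare,
    dice,
    icc_two_way_agreement,
    limits_of_agreement,
    sample_diameter_at,
)
from gutgaze.reconstruction import DiameterMap, LabelVolume, VolumeGrid


def icc_a1_oracle(x):
    """Brute-force two-way ANOVA ICC(A,1): explicit sums over subjects/raters."""
    x = np.asarray(x, dtype=float)
    n, k = x.shape
    gm = x.sum() / (n * k)
    ssr = ssc = sst = 0.0
    for i in range(n):
        row_mean = sum(x[i, j] for j in range(k)) / k
        ssr += k * (row_mean - gm) ** 2
    for j in range(k):
        col_mean = sum(x[i, j] for i in range(n)) / n
        ssc += n * (col_mean - gm) ** 2
    for i in range(n):
        for j in range(k):
            sst += (x[i, j] - gm) ** 2
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + (k / n) * (msc - mse))


class TestDice:
    def test_identical_nonempty(self):
        m = np.zeros((4, 4), bool)
        m[1:3, 1:3] = True
        assert dice(m, m) == 1.0

    def test_half_overlap(self):
        a = np.zeros(8, bool)
        b = np.zeros(8, bool)
        a[:4] = True
        b[2:6] = True
        assert dice(a, b) == pytest.approx(0.5)

    def test_disjoint_and_empty(self):
        a = np.zeros(4, bool)
        b = np.zeros(4, bool)
        a[0] = True
        assert dice(a, np.zeros(4, bool)) == 0.0
        assert np.isnan(dice(b, b))

    def test_symmetry(self, rng):
        a = rng.random((6, 6)) > 0.5
        b = rng.random((6, 6)) > 0.5
        assert dice(a, b) == dice(b, a)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            dice(np.zeros((2, 2), bool), np.zeros((3, 3), bool))


class TestICC:
    def test_duplicated_column_is_perfect(self):
        a = np.array([1.0, 2.0, 5.0, 9.0, 3.0, 7.0])
        res = icc_two_way_agreement(np.column_stack([a, a]))
        assert res.icc == pytest.approx(1.0)
        assert not res.degenerate

    def test_constant_table_degenerate(self):
        res = icc_two_way_agreement(np.full((5, 2), 3.0))
        assert res.icc == 1.0 and res.degenerate

    def test_worked_dataset_matches_anova_oracle(self):
        x = np.array(
            [[9.0, 2.0], [4.5, 4.0], [7.0, 6.5], [10.0, 9.0], [6.0, 5.5], [8.0, 7.0]]
        )
        res = icc_two_way_agreement(x)
        assert res.icc == pytest.approx(icc_a1_oracle(x), abs=1e-10)
        assert res.ci_low <= res.icc <= res.ci_high

    def test_matches_oracle_on_random_tables(self, rng):
        for _ in range(100):
            n = int(rng.integers(3, 30))
            x = rng.normal(rng.uniform(-5, 5), rng.uniform(0.5, 3), (n, 2))
            x[:, 1] += 0.5 * x[:, 0]
            res = icc_two_way_agreement(x)
            assert res.icc == pytest.approx(icc_a1_oracle(x), abs=1e-10)

    def test_independent_columns_have_null_icc(self):
        rng = np.random.default_rng(88)
        x = rng.standard_normal((10000, 2))
        res = icc_two_way_agreement(x)
        assert abs(res.icc) <= 0.05

    def test_shift_invariance(self, rng):
        x = rng.normal(0, 2, (12, 2))
        a = icc_two_way_agreement(x)
        b = icc_two_way_agreement(x + 100.0)
        assert a.icc == pytest.approx(b.icc, abs=1e-9)

    def test_matches_pingouin_icc2(self, rng):
        """Cross-check point estimate and CI against pingouin's ICC2."""
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        x = rng.normal(10, 3, (15, 2))
        x[:, 1] += rng.normal(0, 1, 15) + 1.0
        df = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(15), 2),
                "rater": np.tile([0, 1], 15),
                "score": x.reshape(-1),
            }
        )
        icc_tab = pingouin.intraclass_corr(df, "subject", "rater", "score")
        row = icc_tab[icc_tab.Type.isin(["ICC2", "ICC(A,1)"])].iloc[0]
        ci = row[[c for c in icc_tab.columns if c.startswith("CI95")][0]]
        res = icc_two_way_agreement(x)
        assert res.icc == pytest.approx(row.ICC, abs=1e-8)
        assert res.ci_low == pytest.approx(ci[0], abs=0.01)
        assert res.ci_high == pytest.approx(ci[1], abs=0.01)

    def test_too_small_rejected(self):
        with pytest.raises(ValueError):
            icc_two_way_agreement(np.zeros((2, 2)))


class TestLimitsOfAgreement:
    def test_constant_difference(self):
        a = np.array([5.0, 8.0, 11.0])
        bias, half = limits_of_agreement(PairedDiameters(a, a - 3.0))
        assert bias == pytest.approx(3.0)
        assert half == pytest.approx(0.0)

    def test_identical_vectors(self):
        a = np.array([5.0, 8.0, 11.0])
        bias, half = limits_of_agreement(PairedDiameters(a, a))
        assert (bias, half) == (0.0, 0.0)

    def test_monte_carlo_recovery(self):
        """bias 0.9 and half-width 1.96*5.1 recovered from simulated differences."""
        rng = np.random.default_rng(2024)
        n = 100_000
        b = rng.uniform(10, 40, n)
        a = b + rng.normal(0.9, 5.1, n)
        bias, half = limits_of_agreement((a, b))
        assert bias == pytest.approx(0.9, abs=0.05)
        assert half == pytest.approx(1.96 * 5.1, abs=0.1)

    def test_antisymmetry(self, rng):
        a = rng.uniform(10, 40, 50)
        b = rng.uniform(10, 40, 50)
        bias_ab, half_ab = limits_of_agreement((a, b))
        bias_ba, half_ba = limits_of_agreement((b, a))
        assert bias_ab == pytest.approx(-bias_ba)
        assert half_ab == pytest.approx(half_ba)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            limits_of_agreement((np.array([1.0]), np.array([2.0])))


def tube_map(masked=True):
    """A 9^3 map with a 30 mm value on the central 3x3 column."""
    grid = VolumeGrid((9, 9, 9), (1.0, 1.0, 1.0))
    values = np.zeros((9, 9, 9))
    values[3:6, 3:6, :] = 30.0
    if not masked:
        values[values == 0] = 12.0
    return DiameterMap(grid, values, units="mm", masked=masked)


class TestSampleDiameterAt:
    def test_center_of_tube(self):
        assert sample_diameter_at(tube_map(), (4.0, 4.0, 4.0)) == 30.0

    def test_nearest_nonzero_fallback(self):
        assert sample_diameter_at(tube_map(), (7.0, 4.0, 4.0), search_radius=5.0) == 30.0

    def test_dense_map_is_exact_nearest(self):
        assert sample_diameter_at(tube_map(masked=False), (8.0, 0.0, 0.0)) == 12.0

    def test_out_of_bounds_rejected(self):
        with pytest.raises(ValueError):
            sample_diameter_at(tube_map(), (20.0, 0.0, 0.0))

    def test_no_nonzero_within_radius_rejected(self):
        with pytest.raises(ValueError):
            sample_diameter_at(tube_map(), (0.0, 0.0, 0.0), search_radius=2.0)


def label_source(values_by_scan, diam_value=20.0):
    grid = VolumeGrid((8, 8, 4), (1.0, 1.0, 1.0))
    out = {}
    for sid, values in values_by_scan.items():
        labels = LabelVolume(grid, values, scheme="3")
        diam = DiameterMap(
            grid, np.where(values > 0, diam_value, 0.0), units="mm", masked=True
        )
        out[sid] = (labels, diam)
    return out


class TestCompare:
    def base_values(self):
        v = np.zeros((8, 8, 4), np.uint8)
        v[1:4, 1:4, :] = 1
        v[5:7, 5:7, :] = 2
        return v

    def test_self_comparison_is_perfect(self):
        src = label_source({"s1": self.base_values(), "s2": self.base_values()})
        sites = [("s1", (2.0, 2.0, 1.0)), ("s1", (5.5, 5.5, 2.0)),
                 ("s2", (2.0, 2.0, 1.0)), ("s2", (6.0, 6.0, 3.0))]
        report = compare(src, src, sites=sites)
        for part in ("1", "2", "all"):
            mean, sd, n = report.dice_stats[part]
            assert mean == 1.0 and n == 2
        assert report.icc.icc == 1.0 and report.icc.degenerate
        assert report.bias == 0.0 and report.loa_halfwidth == 0.0

    def test_part_absent_in_both_excluded(self):
        src = label_source({"s1": self.base_values()})
        report = compare(src, src)
        mean, sd, n = report.dice_stats["3"]  # hindgut never annotated
        assert n == 0 and np.isnan(mean)

    def test_part_absent_in_one_counts_as_zero(self):
        a_vals = self.base_values()
        b_vals = self.base_values()
        b_vals[b_vals == 2] = 0
        a = label_source({"s": a_vals})
        b = label_source({"s": b_vals})
        report = compare(a, b)
        mean, sd, n = report.dice_stats["2"]
        assert n == 1 and mean == 0.0

    def test_either_empty_rule_drops_scan(self):
        a_vals = self.base_values()
        b_vals = self.base_values()
        b_vals[b_vals == 2] = 0
        report = compare(
            label_source({"s": a_vals}), label_source({"s": b_vals}),
            exclusion_rule="either_empty",
        )
        assert report.dice_stats["2"][2] == 0

    def test_disjoint_sources_rejected(self):
        with pytest.raises(ValueError):
            compare(label_source({"a": self.base_values()}),
                    label_source({"b": self.base_values()}))

    def test_noisy_repetitions_smoke(self, small_phantom):
        """Two noisy gaze repetitions give an all-part Dice strictly in (0, 1)."""
        from gutgaze.phantom import GazeNoiseModel, simulate_gaze_recording
        from gutgaze.preprocessing import reduce_label_volume
        from gutgaze.reconstruction import reconstruct

        sources = []
        for rep, seed in ((1, 21), (2, 22)):
            ann = simulate_gaze_recording(
                small_phantom, GazeNoiseModel(jitter_sd=1.0), repetition=rep, seed=seed
            )
            labels, diam = reconstruct(ann, small_phantom.grid)
            sources.append({"p": (reduce_label_volume(labels), diam)})
        report = compare(sources[0], sources[1], comparison="rep1_vs_rep2")
        mean, sd, n = report.dice_stats["all"]
        assert 0.0 < mean < 1.0
        frame = report.to_frame()
        assert {"comparison", "part", "metric", "value", "n"} <= set(frame.columns)
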