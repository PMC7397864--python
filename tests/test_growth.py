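"""Growth-rate estimation, control-window truncation, t-test and FDR."""

import numpy as np
import pandas as pd
import pytest

from lncscreen.growth import (adjust_fdr, analyze_growth, eccentricity_shift_flags,
                              estimate_growth_rate, growth_significance,
                              morphology_effects, normalize_growth_rate,
                              normalized_rates_by_well, truncate_to_control_window)


def plate_table(series: dict, times) -> pd.DataFrame:
    """Long table from {well: (role, aso, values)}."""
    rows = []
    for well, (role, aso, values) in series.items():
        for t, v in zip(times, values):
            rows.append({"plate": "P1", "well": well, "role": role,
                         "aso_id": aso, "time_h": float(t), "confluence": v})
    return pd.DataFrame(rows)


class TestTruncation:
    times = np.arange(0, 49, 3.0)

    def test_truncates_when_controls_hit_90(self):
        ctrl = np.minimum(10 + 2.7 * self.times, 100)  # mean reaches 90 at t=30
        aso = np.minimum(10 + 1.0 * self.times, 100)
        df = plate_table({"w1": ("NC_A", "", ctrl), "w2": ("ASO", "a1", aso)},
                         self.times)
        kept = truncate_to_control_window(df)
        assert kept["time_h"].max() == 30.0

    def test_keeps_all_when_controls_stay_low(self):
        ctrl = 10 + 1.0 * self.times  # max 58
        df = plate_table({"w1": ("NC_A", "", ctrl)}, self.times)
        assert len(truncate_to_control_window(df)) == len(df)

    def test_error_when_too_few_points_remain(self):
        ctrl = np.minimum(85 + 3.0 * self.times, 100)  # >=90 already at t=3
        df = plate_table({"w1": ("NC_A", "", ctrl)}, self.times)
        with pytest.raises(ValueError, match="time points remain"):
            truncate_to_control_window(df)

    def test_error_without_controls(self):
        df = plate_table({"w1": ("ASO", "a1", 10 + self.times)}, self.times)
        with pytest.raises(ValueError, match="no NC_A"):
            truncate_to_control_window(df)


class TestSlope:
    def test_exact_on_noiseless_line(self):
        t = np.arange(0, 31, 3.0)
        assert estimate_growth_rate(t, 10 + 2 * t) == pytest.approx(2.0)

    def test_zero_on_constant(self):
        assert estimate_growth_rate([0, 3, 6], [50, 50, 50]) == pytest.approx(0.0)

    def test_negative_slope(self):
        assert estimate_growth_rate([0, 3, 6], [60, 54, 48]) == pytest.approx(-2.0)

    def test_degenerate_grid_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            estimate_growth_rate([3, 3, 3], [1, 2, 3])


class TestNormalization:
    @pytest.mark.parametrize("slope,controls,expected", [
        (1.5, [1.5, 1.5], 1.0),
        (-0.5, [1.0, 1.0], -0.5),  # negative rates pass through
        (0.0, [2.0, 2.0], 0.0),
    ])
    def test_examples(self, slope, controls, expected):
        assert normalize_growth_rate(slope, controls) == pytest.approx(expected)

    def test_failed_controls_rejected(self):
        with pytest.raises(ValueError, match="controls failed"):
            normalize_growth_rate(1.0, [-0.2, 0.1])

    def test_control_wells_average_to_one(self, small_null_screen):
        rates = normalized_rates_by_well(small_null_screen.confluence)
        for _, plate in rates.groupby("plate"):
            nc = plate.loc[plate["role"] == "NC_A", "normalized_rate"]
            assert nc.mean() == pytest.approx(1.0, abs=1e-12)


def pooled_t_oracle(a, b):
    """Textbook pooled two-sample t statistic."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    n1, n2 = len(a), len(b)
    sp2 = ((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / (n1 + n2 - 2)
    return (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / n1 + 1 / n2))


class TestSignificance:
    def test_identical_groups(self):
        assert growth_significance([1, 1], [1, 1, 1, 1, 1, 1]) == (0.0, 1.0)

    def test_duplicates_vs_six_controls(self):
        """Frozen from the pooled-t formula: t = -0.45/sqrt(0.005 * 2/3)."""
        reps = [0.5, 0.6]
        ctrls = [1.0, 1.1, 0.9, 1.0, 1.05, 0.95]
        t, p = growth_significance(reps, ctrls)
        assert t == pytest.approx(-7.7942286, rel=1e-6)
        assert t == pytest.approx(pooled_t_oracle(reps, ctrls), rel=1e-12)
        assert 0 < p < 0.001

    def test_group_swap_negates_t(self):
        t1, p1 = growth_significance([0.5, 0.6], [1.0, 1.1, 0.9])
        t2, p2 = growth_significance([1.0, 1.1, 0.9], [0.5, 0.6])
        assert t1 == pytest.approx(-t2)
        assert p1 == pytest.approx(p2)

    def test_matches_oracle_on_random_inputs(self):
        rng = np.random.default_rng(1)
        for _ in range(1000):
            a = rng.normal(size=rng.integers(2, 8))
            b = rng.normal(size=rng.integers(2, 8))
            t, _ = growth_significance(a, b)
            assert t == pytest.approx(pooled_t_oracle(a, b), abs=1e-10)

    def test_degenerate_unequal_means(self):
        with pytest.warns(UserWarning, match="degenerate"):
            t, p = growth_significance([1, 1], [2, 2])
        assert p == 0.0 and t == -np.inf


def bh_oracle(p):
    """Independent brute-force Benjamini–Hochberg step-up."""
    p = np.asarray(p, float)
    n = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(n)
    running_min = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        running_min = min(running_min, p[i] * n / rank)
        q[i] = running_min
    return q


class TestFDR:
    def test_worked_example(self):
        assert adjust_fdr([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_trivial_cases(self):
        assert adjust_fdr([1.0, 1.0]) == pytest.approx([1.0, 1.0])
        assert adjust_fdr([0.37]) == pytest.approx([0.37])

    def test_matches_stepup_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(1000):
            p = rng.random(rng.integers(1, 50))
            assert adjust_fdr(p) == pytest.approx(bh_oracle(p), abs=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            adjust_fdr([0.5, 1.2])


class TestAnalyzeGrowth:
    def test_null_screen_rarely_significant(self, small_null_screen):
        res = analyze_growth(small_null_screen.confluence)
        assert res["significant_inhibition"].mean() < 0.05
        assert res["fdr"].between(0, 1).all()

    def test_planted_inhibition_detected(self, effect_screen):
        res = analyze_growth(effect_screen.confluence)
        truth = effect_screen.truth
        hit_asos = {a for a, t in truth.aso_target.items()
                    if t in set(truth.growth_hits) and truth.kd_efficiency[a] > 0.5}
        called = set(res.loc[res["significant_inhibition"], "aso_id"])
        assert len(hit_asos & called) / len(hit_asos) > 0.8

    def test_missing_column_rejected(self):
        with pytest.raises(ValueError, match="missing columns"):
            analyze_growth(pd.DataFrame({"plate": [], "well": []}))


def morph_table(ecc_shift=0.0, count_shift=0.0, n_ctrl=6, n_aso=4, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_ctrl):
        rows.append({"plate": "P1", "well": f"c{i}", "role": "NC_A", "aso_id": "",
                     "eccentricity": 0.85 + 0.02 * rng.normal(),
                     "cell_count": 500 + 10 * rng.normal()})
    for i in range(n_aso):
        rows.append({"plate": "P1", "well": f"a{i}", "role": "ASO", "aso_id": "a1",
                     "eccentricity": 0.85 + ecc_shift + 0.02 * rng.normal(),
                     "cell_count": 500 + count_shift + 10 * rng.normal()})
    return pd.DataFrame(rows)


class TestMorphology:
    def test_no_effect_when_identical(self):
        df = morph_table()
        df.loc[df["role"] == "ASO", ["eccentricity", "cell_count"]] = \
            [0.85, 500.0]
        df.loc[df["role"] == "NC_A", ["eccentricity", "cell_count"]] = \
            [0.85, 500.0]
        effects = morphology_effects(df)
        assert (effects["effect"] == 0).all()
        assert (effects["p_value"] == 1).all()

    def test_eccentricity_pattern_flagged(self):
        effects = morphology_effects(morph_table(ecc_shift=-0.2))
        flags = eccentricity_shift_flags(effects)
        assert bool(flags.set_index("aso_id").loc["a1", "eccentricity_shift"])

    def test_pattern_not_flagged_when_cells_lost(self):
        effects = morphology_effects(
            morph_table(ecc_shift=-0.2, count_shift=-200))
        flags = eccentricity_shift_flags(effects)
        assert not bool(flags.set_index("aso_id").loc["a1", "eccentricity_shift"])

    def test_missing_controls_rejected(self):
        df = morph_table()
        with pytest.raises(ValueError, match="NC_A"):
            morphology_effects(df[df["role"] == "ASO"])
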