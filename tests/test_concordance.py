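"""Jaccard concordance, permutation nulls, conditional-cutoff hit calling."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from lncscreen.concordance import (build_target_map, call_lncrna_hits,
                                   concordance_table, conditional_cutoff,
                                   global_growth_concordance, jaccard,
                                   pair_concordance_test, reproducible_pairs,
                                   sample_null_jaccards)


class TestJaccard:
    def test_identical_sets(self):
        assert jaccard({("a", 1), ("b", -1)}, {("a", 1), ("b", -1)}) == 1.0

    def test_disjoint_sets(self):
        assert jaccard({("a", 1)}, {("b", 1)}) == 0.0

    def test_signed_definition(self):
        a = {("a", 1), ("b", 1), ("c", -1), ("d", -1)}
        b = {("c", -1), ("d", -1), ("e", 1)}
        assert jaccard(a, b) == pytest.approx(0.4)

    def test_sign_mismatch_not_common(self):
        assert jaccard({("a", 1)}, {("a", -1)}) == 0.0

    def test_both_empty(self):
        assert jaccard(set(), set()) == 0.0


def concordance_oracle(rates, targets):
    """Plain-Python exhaustive permutation distribution of D."""
    pairs = [(i, j) for i, j in itertools.combinations(range(len(rates)), 2)
             if targets[i] == targets[j]]

    def stat(values):
        return sum(abs(values[i] - values[j]) for i, j in pairs) / len(pairs)

    d_obs = stat(rates)
    count = total = 0
    for perm in itertools.permutations(rates):
        total += 1
        count += stat(perm) <= d_obs + 1e-12
    return d_obs, count / total


class TestGlobalGrowthConcordance:
    def test_degenerate_identical_rates(self):
        rates = {f"a{i}": 1.0 for i in range(4)}
        tm = {"a0": "t1", "a1": "t1", "a2": "t2", "a3": "t2"}
        out = global_growth_concordance(rates, tm, exhaustive=True)
        assert out["p_value"] == 1.0 and out["statistic"] == 0.0

    def test_matches_enumeration_oracle(self):
        """Exhaustive mode equals an independent enumerator on <=6 ASOs."""
        rng = np.random.default_rng(5)
        for n, groups in [(3, ["t1", "t1", "t2"]),
                          (4, ["t1", "t1", "t2", "t2"]),
                          (6, ["t1", "t1", "t1", "t2", "t2", "t3"])]:
            for _ in range(5):
                values = rng.normal(size=n)
                rates = {f"a{i}": values[i] for i in range(n)}
                tm = {f"a{i}": groups[i] for i in range(n)}
                out = global_growth_concordance(rates, tm, exhaustive=True)
                d_ref, p_ref = concordance_oracle(list(values), groups)
                assert out["statistic"] == pytest.approx(d_ref, abs=1e-12)
                assert out["p_value"] == pytest.approx(p_ref, abs=1e-12)

    def test_monte_carlo_plus_one_floor(self):
        """Concordant groups far apart: no shuffle beats D_obs -> p = 1/(B+1)."""
        rates, tm = {}, {}
        for t in range(6):
            for j in range(2):
                rates[f"t{t}_a{j}"] = float(t) * 10
                tm[f"t{t}_a{j}"] = f"t{t}"
        out = global_growth_concordance(rates, tm, n_perm=999, seed=0,
                                        exhaustive=False)
        assert out["p_value"] == pytest.approx(1 / 1000)

    def test_detects_planted_concordance(self, effect_screen):
        from lncscreen.growth import analyze_growth
        from lncscreen.kdqc import qc_table, records_from_table
        res = analyze_growth(effect_screen.confluence)
        tm = build_target_map(qc_table(records_from_table(effect_screen.kd_table)))
        rates = dict(zip(res["aso_id"], res["normalized_rate"]))
        out = global_growth_concordance(rates, tm, n_perm=2000, seed=1,
                                        exhaustive=False)
        assert out["p_value"] < 0.01

    def test_too_few_permutations_rejected(self):
        rates = {"a": 1.0, "b": 2.0, "c": 1.0, "d": 2.0}
        tm = {"a": "t1", "b": "t1", "c": "t2", "d": "t2"}
        with pytest.raises(ValueError, match="n_perm"):
            global_growth_concordance(rates, tm, n_perm=10, exhaustive=False)


def random_deg_sets(rng, n_targets=60, per_target=2, universe=300,
                    lo=5, hi=40):
    deg_sets, tm = {}, {}
    for t in range(n_targets):
        for j in range(per_target):
            aso = f"t{t}_a{j}"
            size = int(rng.integers(lo, hi))
            members = rng.choice(universe, size=size, replace=False)
            signs = rng.choice([-1, 1], size=size)
            deg_sets[aso] = set(zip(members.tolist(), signs.tolist()))
            tm[aso] = f"t{t}"
    return deg_sets, tm


class TestPairConcordance:
    def test_perfect_pair_gets_minimum_p(self):
        null = np.zeros(999)
        assert pair_concordance_test(1.0, null) == pytest.approx(1 / 1000)

    def test_zero_jaccard_gets_p_one(self):
        null = np.random.default_rng(0).random(500)
        assert pair_concordance_test(0.0, null) == 1.0

    def test_tiny_exhaustive_null(self):
        """With every nontargeting pair used, p matches hand enumeration."""
        deg_sets = {
            "t1_a": {("g1", 1), ("g2", 1)}, "t1_b": {("g1", 1), ("g2", 1)},
        }
        tm = {"t1_a": "t1", "t1_b": "t1"}
        # different-target fillers with known overlaps to t-pairs
        rng = np.random.default_rng(1)
        extra, tm2 = random_deg_sets(rng, n_targets=20, per_target=1,
                                     universe=50)
        deg_sets.update(extra)
        tm.update(tm2)
        null = sample_null_jaccards(deg_sets, tm, n_null=10**6, seed=0)
        asos = sorted(a for a in deg_sets if a in tm)
        expected = [jaccard(deg_sets[a], deg_sets[b])
                    for a, b in itertools.combinations(asos, 2)
                    if tm[a] != tm[b]]
        assert sorted(null.tolist()) == sorted(expected)
        j = jaccard(deg_sets["t1_a"], deg_sets["t1_b"])
        manual = (sum(1 for v in expected if v >= j) + 1) / (len(expected) + 1)
        assert pair_concordance_test(j, null) == pytest.approx(manual)

    def test_too_few_background_pairs_rejected(self):
        deg_sets = {f"a{i}": {("g", 1)} for i in range(6)}
        tm = {f"a{i}": f"t{i % 3}" for i in range(6)}
        with pytest.raises(ValueError, match="different-target pairs"):
            sample_null_jaccards(deg_sets, tm)

    def test_empirical_p_never_zero(self):
        rng = np.random.default_rng(2)
        deg_sets, tm = random_deg_sets(rng)
        pairs = concordance_table(deg_sets, tm, n_null=500, seed=0)
        assert (pairs["empirical_p"] > 0).all()
        assert (pairs["empirical_p"] <= 1).all()

    def test_sparse_null_p_is_superuniform(self):
        """On near-empty DEG sets the plus-one p is conservative, never anti-."""
        rng = np.random.default_rng(3)
        deg_sets, tm = random_deg_sets(rng, n_targets=150, universe=500,
                                       lo=1, hi=6)
        pairs = concordance_table(deg_sets, tm, n_null=5000, seed=1)
        p = np.sort(pairs["empirical_p"].to_numpy())
        for u in (0.01, 0.05, 0.1, 0.25, 0.5):
            assert (p <= u).mean() <= u + 0.03


class TestReproduciblePairs:
    def make(self, n_common, p):
        return pd.DataFrame({
            "aso_a": ["a"], "aso_b": ["b"], "target_id": ["t"],
            "pair_type": ["same_target"], "n_common_degs": [n_common],
            "jaccard": [0.2], "empirical_p": [p]})

    @pytest.mark.parametrize("n_common,p,kept", [
        (5, 0.04, 1),    # both gates pass
        (4, 0.001, 0),   # count gate fails
        (20, 0.2, 0),    # p gate fails
    ])
    def test_retention_rule(self, n_common, p, kept):
        out = reproducible_pairs(self.make(n_common, p))
        assert out["n_pairs"] == kept


def hypergeom_tail_oracle(pool, good, n, k):
    """P(X >= k), X = # significant in n draws without replacement."""
    total = 0
    for x in range(k, min(n, good) + 1):
        total += math.comb(good, x) * math.comb(pool - good, n - x)
    return total / math.comb(pool, n)


class TestConditionalCutoff:
    def test_zero_background(self):
        assert conditional_cutoff(5, [False] * 100) == 1

    def test_saturated_background(self):
        assert conditional_cutoff(5, [True] * 100) == 6

    def test_matches_closed_form_oracle(self):
        """Exact mode reproduces the math.comb hypergeometric tail."""
        rng = np.random.default_rng(4)
        alpha = 0.05
        for _ in range(300):
            pool = int(rng.integers(50, 300))
            good = int(rng.integers(0, pool + 1))
            n = int(rng.integers(1, 11))
            flags = np.zeros(pool, bool)
            flags[:good] = True
            k_min = conditional_cutoff(n, flags, alpha)
            expected = n + 1
            for k in range(1, n + 1):
                if hypergeom_tail_oracle(pool, good, n, k) < alpha:
                    expected = k
                    break
            assert k_min == expected, (pool, good, n)

    def test_ten_percent_pool_two_asos(self):
        """n=2 with a 10% background: P(>=1) ~ 0.19, P(>=2) ~ 0.009."""
        flags = np.zeros(100, bool)
        flags[:10] = True
        assert conditional_cutoff(2, flags) == 2

    def test_monte_carlo_mode_converges(self):
        flags = np.zeros(200, bool)
        flags[:20] = True
        exact = conditional_cutoff(6, flags)
        mc = conditional_cutoff(6, flags, n_resample=200000, seed=0)
        assert mc == exact

    def test_empty_pool_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            conditional_cutoff(2, [])


class TestHitCalling:
    def growth_frame(self, flags):
        return pd.DataFrame({
            "aso_id": list(flags),
            "significant_inhibition": list(flags.values()),
            "normalized_rate": [0.5] * len(flags),
        })

    def test_hit_logic_with_supplied_cutoffs(self):
        flags = {"t1_a": True, "t1_b": True, "t2_a": True, "t2_b": False}
        tm = {a: a.split("_")[0] for a in flags}
        hits = call_lncrna_hits(self.growth_frame(flags), tm,
                                cutoffs={"t1": 2, "t2": 2})
        hits = hits.set_index("target_id")
        assert bool(hits.loc["t1", "is_hit"]) and not bool(hits.loc["t2", "is_hit"])

    def test_missing_cutoff_rejected(self):
        flags = {"t1_a": True, "t1_b": True}
        tm = {a: "t1" for a in flags}
        with pytest.raises(KeyError, match="t1"):
            call_lncrna_hits(self.growth_frame(flags), tm, cutoffs={})

    def test_recovers_planted_growth_hits(self, effect_screen):
        from lncscreen.growth import analyze_growth
        from lncscreen.kdqc import qc_table, records_from_table
        res = analyze_growth(effect_screen.confluence)
        tm = build_target_map(qc_table(records_from_table(effect_screen.kd_table)))
        hits = call_lncrna_hits(res, tm)
        called = set(hits.loc[hits["is_hit"], "target_id"])
        truth = set(effect_screen.truth.growth_hits)
        assessed = set(hits["target_id"])
        assert called <= assessed
        assert len(called & truth) >= 0.6 * len(truth & assessed)
        assert (hits["k_min"] >= 1).all()
        assert (hits["k_min"] <= hits["n_successful_asos"] + 1).all()
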