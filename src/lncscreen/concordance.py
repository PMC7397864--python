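"""Concordance testing and lncRNA-level hit calling.

Different ASOs knocking down the same lncRNA should produce similar
phenotypes if the effect is target-specific rather than an off-target
artifact. This module provides the permutation frameworks used to test
that:

* a *global* growth-concordance test — the mean absolute difference in
  normalized growth rate over all same-target ASO pairs, compared with a
  label-shuffle null;
* a *per-pair* molecular concordance test — the Jaccard index of two
  ASOs' signed DEG sets, compared with Jaccard indices of sampled
  nontargeting (different-target) ASO pairs;
* *conditional cutoffs* for lncRNA-level hit calling — the minimum number
  k_min(n) of significant ASOs, out of a target's n successful ASOs,
  required so that the chance of reaching k_min by drawing n flags from
  the screen-wide background pool stays below 5%.

All empirical p-values use the plus-one rule (r+1)/(B+1), so they are
never exactly zero; exhaustive enumeration modes report exact tail
fractions instead.
"""

from __future__ import annotations

import itertools
import math
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "jaccard",
    "global_growth_concordance",
    "sample_null_jaccards",
    "pair_concordance_test",
    "concordance_table",
    "reproducible_pairs",
    "conditional_cutoff",
    "call_lncrna_hits",
    "build_target_map",
]

MIN_PERMUTATIONS = 100
MIN_NULL_PAIRS = 100
EXHAUSTIVE_LIMIT = 7  # up to 7! = 5040 label arrangements enumerated exactly


def jaccard(set_a, set_b) -> float:
    """|A ∩ B| / |A ∪ B| for two (signed) DEG sets; 0 when both empty."""
    a, b = set(set_a), set(set_b)
    union = a | b
    if not union:
        return 0.0
    return len(a & b) / len(union)


def build_target_map(qc_table: pd.DataFrame, min_asos: int = 2) -> dict[str, str]:
    """aso_id -> target_id for successful ASOs of sufficiently-covered targets.

    Keeps only ASOs passing knockdown QC whose target retains at least
    ``min_asos`` successful ASOs (pairwise analyses need two per target).
    """
    ok = qc_table[qc_table["success"].astype(bool)]
    counts = ok.groupby("target_id")["aso_id"].size()
    good_targets = set(counts.index[counts >= min_asos])
    sub = ok[ok["target_id"].isin(good_targets)]
    return dict(zip(sub["aso_id"], sub["target_id"]))


def _same_target_pair_indices(targets: Sequence[str]) -> list[tuple[int, int]]:
    by_target: dict[str, list[int]] = {}
    for i, t in enumerate(targets):
        by_target.setdefault(t, []).append(i)
    pairs = []
    for idx in by_target.values():
        pairs.extend(itertools.combinations(idx, 2))
    return pairs


def global_growth_concordance(rates: Mapping[str, float],
                              target_map: Mapping[str, str],
                              n_perm: int = 10000, seed=None,
                              exhaustive: bool | None = None) -> dict:
    """Screen-wide test that same-target ASOs respond concordantly.

    The statistic is ``D = mean |rate_a − rate_b|`` over all same-target
    ASO pairs; small D means concordance. The null shuffles the rate
    values across ASOs (preserving group sizes) ``n_perm`` times and the
    empirical p is the plus-one lower-tail fraction. With ``exhaustive``
    (defaulting to automatic for <= 7 ASOs) every label arrangement is
    enumerated and the exact tail fraction is returned.
    """
    asos = [a for a in rates if a in target_map]
    targets = [target_map[a] for a in asos]
    values = np.asarray([rates[a] for a in asos], float)
    pairs = _same_target_pair_indices(targets)
    if len(set(targets)) < 2 or not pairs:
        raise ValueError("need >= 2 targets with >= 2 ASOs each")
    ia = np.array([p[0] for p in pairs])
    ib = np.array([p[1] for p in pairs])

    def statistic(v: np.ndarray) -> float:
        return float(np.abs(v[ia] - v[ib]).mean())

    d_obs = statistic(values)
    if exhaustive is None:
        exhaustive = len(asos) <= EXHAUSTIVE_LIMIT
    if exhaustive:
        count = 0
        total = 0
        for perm in itertools.permutations(range(len(asos))):
            total += 1
            if statistic(values[list(perm)]) <= d_obs + 1e-12:
                count += 1
        p = count / total
        return {"statistic": d_obs, "p_value": p, "n_perm": total,
                "method": "exhaustive", "n_pairs": len(pairs)}
    if n_perm < MIN_PERMUTATIONS:
        raise ValueError(f"n_perm={n_perm} too small for a stable empirical p "
                         f"(need >= {MIN_PERMUTATIONS})")
    rng = np.random.default_rng(seed)
    hits = 0
    v = values.copy()
    for _ in range(n_perm):
        rng.shuffle(v)
        if statistic(v) <= d_obs + 1e-12:
            hits += 1
    p = (hits + 1) / (n_perm + 1)
    return {"statistic": d_obs, "p_value": p, "n_perm": n_perm,
            "method": "monte_carlo", "n_pairs": len(pairs)}


def sample_null_jaccards(deg_sets: Mapping[str, set],
                         target_map: Mapping[str, str],
                         n_null: int = 10000, seed=None) -> np.ndarray:
    """Jaccard indices of sampled nontargeting (different-target) ASO pairs.

    Pairs are sampled without replacement from all different-target pairs;
    if fewer than ``n_null`` exist, all of them are used. Fewer than 100
    available pairs is an error (the background would be unstable).
    """
    asos = [a for a in deg_sets if a in target_map]
    diff_pairs = [
        (a, b) for a, b in itertools.combinations(asos, 2)
        if target_map[a] != target_map[b]
    ]
    if len(diff_pairs) < MIN_NULL_PAIRS:
        raise ValueError(
            f"only {len(diff_pairs)} different-target pairs available "
            f"(need >= {MIN_NULL_PAIRS} for a background)")
    rng = np.random.default_rng(seed)
    if n_null < len(diff_pairs):
        idx = rng.choice(len(diff_pairs), size=n_null, replace=False)
        chosen = [diff_pairs[i] for i in idx]
    else:
        chosen = diff_pairs
    return np.asarray([jaccard(deg_sets[a], deg_sets[b]) for a, b in chosen])


def pair_concordance_test(j_obs: float, null_jaccards: np.ndarray) -> float:
    """Plus-one upper-tail empirical p of an observed pair Jaccard."""
    null_jaccards = np.asarray(null_jaccards, float)
    if null_jaccards.size == 0:
        raise ValueError("empty null Jaccard sample")
    hits = int((null_jaccards >= j_obs - 1e-12).sum())
    return (hits + 1) / (null_jaccards.size + 1)


def concordance_table(deg_sets: Mapping[str, set],
                      target_map: Mapping[str, str],
                      n_null: int = 10000, seed=None) -> pd.DataFrame:
    """Per same-target-pair concordance against a shared nontargeting null.

    One row per same-target ASO pair: common signed DEG count, Jaccard
    index, and the empirical p against ``n_null`` sampled
    different-target pairs.
    """
    null_j = sample_null_jaccards(deg_sets, target_map, n_null, seed)
    asos = sorted(a for a in deg_sets if a in target_map)
    rows = []
    for a, b in itertools.combinations(asos, 2):
        if target_map[a] != target_map[b]:
            continue
        sa, sb = deg_sets[a], deg_sets[b]
        j = jaccard(sa, sb)
        rows.append({
            "aso_a": a, "aso_b": b, "target_id": target_map[a],
            "pair_type": "same_target",
            "n_common_degs": len(set(sa) & set(sb)),
            "jaccard": j,
            "empirical_p": pair_concordance_test(j, null_j),
        })
    return pd.DataFrame(
        rows, columns=["aso_a", "aso_b", "target_id", "pair_type",
                       "n_common_degs", "jaccard", "empirical_p"])


def reproducible_pairs(pairs: pd.DataFrame, min_common: int = 5,
                       alpha: float = 0.05) -> dict:
    """Pairs with >= ``min_common`` common DEGs and empirical p <= alpha.

    Returns the retained pairs plus the number of distinct targets they
    cover (the screen-level "reproducible lncRNAs" count).
    """
    if len(pairs):
        keep = pairs[(pairs["n_common_degs"] >= min_common)
                     & (pairs["empirical_p"] <= alpha)].reset_index(drop=True)
    else:
        keep = pairs.copy()
    n_targets = keep["target_id"].nunique() if len(keep) else 0
    return {"pairs": keep, "n_pairs": len(keep), "n_targets": n_targets}


def conditional_cutoff(n: int, background_flags, alpha: float = 0.05,
                       n_resample: int | None = None, seed=None) -> int:
    """Minimum significant-ASO count that beats the screen background.

    ``background_flags`` are the per-ASO significance flags of the rest of
    the screen. k_min is the smallest k such that drawing ``n`` flags
    without replacement from that pool yields >= k significant ones with
    probability below ``alpha``; if no k <= n qualifies the target cannot
    be called (k_min = n + 1). By default the without-replacement tail is
    computed exactly (hypergeometric); pass ``n_resample`` to estimate it
    by Monte-Carlo resampling of the pool instead.
    """
    flags = np.asarray(background_flags, bool)
    if flags.size == 0:
        raise ValueError("empty background pool")
    if n < 1:
        raise ValueError("n must be >= 1")
    if n > flags.size:
        raise ValueError(f"cannot draw n={n} flags from a pool of {flags.size}")
    if flags.size < 50:
        warnings.warn(f"background pool has only {flags.size} flags; "
                      "conditional cutoffs may be unstable")
    pool = flags.size
    good = int(flags.sum())
    if n_resample is None:
        def tail(k: int) -> float:  # P(>= k significant among n draws)
            return float(stats.hypergeom.sf(k - 1, pool, good, n))
    else:
        rng = np.random.default_rng(seed)
        draws = rng.hypergeometric(good, pool - good, n, size=int(n_resample))

        def tail(k: int) -> float:
            return float((draws >= k).mean())
    for k in range(1, n + 1):
        if tail(k) < alpha:
            return k
    return n + 1


def call_lncrna_hits(growth_results: pd.DataFrame,
                     target_map: Mapping[str, str],
                     cutoffs: Mapping[str, int] | None = None,
                     alpha: float = 0.05,
                     n_resample: int | None = None, seed=None) -> pd.DataFrame:
    """lncRNA-level growth-hit calls with background-adjusted cutoffs.

    Only ASOs present in ``target_map`` (i.e. successful knockdowns) are
    counted. Each target with n successful ASOs, k of them significantly
    growth-inhibiting, is a hit iff k >= k_min(n); by default k_min is
    calibrated per target against the pool of all *other* targets'
    significance flags, or taken from ``cutoffs`` when supplied (a
    missing target is then an error).
    """
    sub = growth_results[growth_results["aso_id"].isin(target_map)].copy()
    sub["target_id"] = sub["aso_id"].map(target_map)
    flags = sub.set_index("aso_id")["significant_inhibition"].astype(bool)
    background_rate = float(flags.mean()) if len(flags) else 0.0
    rows = []
    for target, grp in sub.groupby("target_id"):
        n = len(grp)
        k = int(grp["significant_inhibition"].astype(bool).sum())
        if cutoffs is not None:
            if target not in cutoffs:
                raise KeyError(f"target {target!r} absent from supplied cutoffs")
            k_min = int(cutoffs[target])
        else:
            pool = flags[~flags.index.isin(grp["aso_id"])].to_numpy()
            k_min = conditional_cutoff(n, pool, alpha, n_resample, seed)
        rows.append({
            "target_id": target,
            "n_successful_asos": n,
            "n_significant_asos": k,
            "k_min": k_min,
            "is_hit": k >= k_min,
            "background_rate": background_rate,
        })
    return pd.DataFrame(rows).sort_values("target_id").reset_index(drop=True)
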