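"""Preranked gene-set enrichment with permutation p-values.

Genes are ranked by a per-ASO statistic (the experiment-wide Z-score or
log2FC); a gene set's enrichment score (ES) is the signed extremum of the
classic weighted Kolmogorov–Smirnov running sum: walking down the
ranking, set members add ``|stat|^w / sum_hits |stat|^w`` and non-members
subtract ``1 / (N − |set|)``. Null ES distributions come from gene-label
permutations preserving set size; NES normalizes ES by the mean
magnitude of same-sign null scores, and the nominal p is the plus-one
fraction of null scores at least as extreme in magnitude (so the observed
score is rank-exchangeable with its null and p is uniform under H0). The
per-set summary used to compare ASOs is the signed score
``−log10(p) × sign(NES)``.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

from .growth import adjust_fdr
from .mara import motif_growth_correlation

__all__ = [
    "enrichment_score",
    "preranked_gsea",
    "signed_enrichment",
    "pathway_growth_correlation",
]

DEFAULT_MIN_SIZE = 5


def _ranked(stats: pd.Series) -> pd.Series:
    """Strict descending order; ties broken by gene id for determinism."""
    if stats.index.has_duplicates:
        raise ValueError("duplicate genes in the ranking statistic")
    if not np.isfinite(stats.to_numpy(float)).all():
        raise ValueError("ranking statistics must be finite")
    order = sorted(stats.index, key=lambda g: (-stats[g], str(g)))
    return stats.loc[order]


def enrichment_score(stats: pd.Series, gene_set, weight: float = 1.0,
                     return_curve: bool = False):
    """Weighted running-sum enrichment score of one gene set.

    ``stats`` maps genes to ranking statistics (any order; ranked here).
    Raises when the set does not intersect the universe or swallows it
    whole. With all-zero hit statistics the hit increments fall back to
    equal weights.
    """
    ranked = _ranked(stats)
    universe = list(ranked.index)
    members = set(gene_set) & set(universe)
    if not members:
        raise ValueError("gene set does not intersect the ranked universe")
    if len(members) == len(universe):
        raise ValueError("gene set equals the whole universe; ES undefined")
    n = len(universe)
    m = len(members)
    miss_step = 1.0 / (n - m)
    hit_w = np.array([abs(ranked[g]) ** weight if g in members else 0.0
                      for g in universe])
    total_w = hit_w.sum()
    running = np.empty(n)
    total = 0.0
    for i, g in enumerate(universe):
        if g in members:
            total += (hit_w[i] / total_w) if total_w > 0 else 1.0 / m
        else:
            total -= miss_step
        running[i] = total
    max_dev, min_dev = float(running.max()), float(running.min())
    # positive extremum preferred on (numerical) ties
    es = max_dev if abs(max_dev) >= abs(min_dev) - 1e-12 else min_dev
    if return_curve:
        return es, running
    return es


def _batch_es(positions: np.ndarray, weights_by_rank: np.ndarray,
              n: int) -> np.ndarray:
    """ES for many hit-position sets at once (rows of ``positions``).

    ``positions`` holds 0-based ranks of the m hits per row (any order);
    ``weights_by_rank`` is ``|stat|^w`` along the ranking. Matches the
    reference running-sum loop exactly.
    """
    pos = np.sort(positions, axis=1)
    m = pos.shape[1]
    aw = weights_by_rank[pos]
    totals = aw.sum(axis=1, keepdims=True)
    flat = totals[:, 0] <= 0
    if flat.any():  # all-zero hit stats: equal weights
        aw[flat] = 1.0
        totals[flat] = float(m)
    hits_cum = np.cumsum(aw, axis=1) / totals
    miss_step = 1.0 / (n - m)
    k = np.arange(m)[None, :]
    misses = (pos - k) * miss_step
    after = hits_cum - misses           # running sum just after each hit
    before = hits_cum - aw / totals - misses  # just before each hit
    max_dev = after.max(axis=1)
    min_dev = before.min(axis=1)
    return np.where(np.abs(max_dev) >= np.abs(min_dev) - 1e-12,
                    max_dev, min_dev)


def signed_enrichment(p: float, nes: float) -> float:
    """The signed summary score ``−log10(p) × sign(NES)``; needs p in (0, 1]."""
    if not (0.0 < p <= 1.0):
        raise ValueError(f"p={p} outside (0, 1]; use plus-one empirical p "
                         "upstream so p is never 0")
    return float(-np.log10(p) * np.sign(nes))


def preranked_gsea(stats: pd.Series, gene_sets: Mapping[str, set],
                   n_perm: int = 1000, seed=None, weight: float = 1.0,
                   min_size: int = DEFAULT_MIN_SIZE) -> pd.DataFrame:
    """Permutation GSEA of many gene sets against one ranked list.

    Null ES per set comes from ``n_perm`` random same-size gene subsets
    (gene-label permutation), shared across sets of equal size. Sets with
    fewer than ``min_size`` genes in the universe are skipped and listed
    in ``result.attrs['skipped']``. Returns ES, NES, nominal p (plus-one
    fraction of null ES at least as extreme in magnitude), BH FDR across
    sets, and the signed score.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100 for stable empirical p-values")
    ranked = _ranked(stats)
    universe = list(ranked.index)
    rank_of = {g: i for i, g in enumerate(universe)}
    n = len(universe)
    wvec = np.abs(ranked.to_numpy(float)) ** weight
    rng = np.random.default_rng(seed)

    sizes_needed = {}
    kept, skipped = [], []
    for name, genes in gene_sets.items():
        members = set(genes) & set(universe)
        if len(members) < min_size or len(members) == n:
            skipped.append(name)
            continue
        kept.append((name, members))
        sizes_needed.setdefault(len(members), None)

    null_by_size = {}
    for m in sizes_needed:
        draws = np.argsort(rng.random((n_perm, n)), axis=1)[:, :m]
        null_by_size[m] = _batch_es(draws, wvec, n)

    rows = []
    for name, members in kept:
        m = len(members)
        pos = np.array([[rank_of[g] for g in members]])
        es = float(_batch_es(pos, wvec, n)[0])
        null = null_by_size[m]
        tail = int((np.abs(null) >= abs(es) - 1e-12).sum())
        p = (tail + 1) / (len(null) + 1)
        same = null[null > 0] if es > 0 else null[null < 0] if es < 0 else null
        denom = np.abs(same).mean() if len(same) else np.abs(null).mean()
        nes = es / denom if denom > 0 else 0.0
        rows.append({"gene_set": name, "size": m, "es": es, "nes": float(nes),
                     "p_value": float(p)})
    result = pd.DataFrame(
        rows, columns=["gene_set", "size", "es", "nes", "p_value"])
    if len(result):
        result["fdr"] = adjust_fdr(result["p_value"])
        result["signed_score"] = [
            signed_enrichment(p, nes)
            for p, nes in zip(result["p_value"], result["nes"])]
    result.attrs["skipped"] = skipped
    return result


def pathway_growth_correlation(signed_scores: pd.DataFrame, rates) -> pd.DataFrame:
    """Pearson correlation of per-set signed scores with growth rate.

    ``signed_scores`` is gene sets x ASOs; ``rates`` maps ASO ids to
    normalized growth rates. Constant score vectors are excluded with a
    warning; BH FDR across sets.
    """
    out = motif_growth_correlation(signed_scores, rates)
    return out.rename(columns={"motif": "gene_set"})
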