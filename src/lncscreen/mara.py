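"""Motif Activity Response Analysis (MARA), minimal ridge implementation.

Expression is modelled as a linear function of promoter motif content:

    E[p, s] = c_p + m_s + sum_m N'[p, m] * A[m, s]

where ``N`` holds motif site counts per promoter/gene (column-centred to
``N'``), and ``A`` is the unknown per-sample activity of each motif. With
the expression matrix double-centred (row and column means removed, which
absorbs c_p and m_s), the activities solve the ridge system

    (N'ᵀ N' + λ I) A = N'ᵀ Ẽ .

Standard errors come from the ridge sandwich covariance with per-sample
residual variance, and Z = A / se is the reported motif activity score.
λ defaults to generalized cross-validation over a log grid; the centring
constraint makes each motif's activities sum to zero across samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .growth import adjust_fdr

__all__ = ["MotifActivityTable", "fit_motif_activities", "motif_growth_correlation"]

GCV_GRID = np.logspace(-3, 3, 13)


@dataclass
class MotifActivityTable:
    """Fitted motif activities (motifs x samples) with errors and Z-scores."""

    activities: pd.DataFrame
    se: pd.DataFrame
    z: pd.DataFrame
    ridge_lambda: float
    df_effective: float


def _double_center(E: np.ndarray) -> np.ndarray:
    return (E - E.mean(axis=1, keepdims=True) - E.mean(axis=0, keepdims=True)
            + E.mean())


def fit_motif_activities(log2_expr: pd.DataFrame, site_counts: pd.DataFrame,
                         ridge_lambda: float | None = None) -> MotifActivityTable:
    """Fit per-sample motif activities by ridge-penalized least squares.

    ``log2_expr`` is genes x samples on the log2 scale; ``site_counts`` is
    genes x motifs over the same gene universe. ``ridge_lambda=None``
    selects λ by generalized cross-validation over ``GCV_GRID``; λ = 0 is
    only allowed when the centred site-count matrix has full column rank.
    All-zero motif columns are dropped with a warning.
    """
    if not log2_expr.index.equals(site_counts.index):
        if set(log2_expr.index) != set(site_counts.index):
            raise ValueError("expression and site-count matrices must share "
                             "the same gene/promoter universe")
        site_counts = site_counts.loc[log2_expr.index]
    zero = site_counts.columns[(site_counts != 0).sum(axis=0) == 0]
    if len(zero):
        warnings.warn(f"dropping {len(zero)} all-zero motif columns: "
                      f"{list(zero[:5])}")
        site_counts = site_counts.drop(columns=zero)
    if site_counts.shape[1] == 0:
        raise ValueError("no motifs left after filtering")
    if ridge_lambda is not None and ridge_lambda < 0:
        raise ValueError("ridge_lambda must be >= 0")

    N = site_counts.to_numpy(float)
    Nc = N - N.mean(axis=0, keepdims=True)
    E = _double_center(log2_expr.to_numpy(float))
    n_genes, n_motifs = Nc.shape

    G = Nc.T @ Nc
    eigval, eigvec = np.linalg.eigh(G)
    eigval = np.clip(eigval, 0.0, None)
    B = eigvec.T @ (Nc.T @ E)  # motifs x samples in the eigenbasis
    total_ss = float((E * E).sum())

    def _rss_df(lam: float) -> tuple[float, float]:
        shrink = 1.0 / (eigval + lam)
        fit = (B * B * shrink[:, None]).sum()
        fit2 = (B * B * (eigval * shrink**2)[:, None]).sum()
        rss = total_ss - 2.0 * fit + fit2
        df = float((eigval * shrink).sum())
        return float(rss), df

    if ridge_lambda is None:
        best = None
        for lam in GCV_GRID:
            rss, df = _rss_df(lam)
            denom = max(1.0 - df / n_genes, 1e-12) ** 2
            gcv = (rss / (n_genes * E.shape[1])) / denom
            if best is None or gcv < best[0]:
                best = (gcv, lam)
        ridge_lambda = float(best[1])
    elif ridge_lambda == 0 and eigval.min() <= 1e-10 * max(eigval.max(), 1.0):
        raise ValueError("centred site-count matrix is rank-deficient; "
                         "use ridge_lambda > 0")

    shrink = 1.0 / (eigval + ridge_lambda)
    A = eigvec @ (shrink[:, None] * B)
    resid = E - Nc @ A
    df_eff = float((eigval * shrink).sum())
    dof = max(n_genes - df_eff, 1.0)
    sigma2 = (resid * resid).sum(axis=0) / dof  # per sample
    # diag of K G K with K = (G + λI)^-1, in the eigenbasis
    kgk_diag = (eigvec**2 * (eigval * shrink**2)[None, :]).sum(axis=1)
    se = np.sqrt(np.outer(kgk_diag, sigma2))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, A / se, 0.0)

    motifs, samples = site_counts.columns, log2_expr.columns
    return MotifActivityTable(
        activities=pd.DataFrame(A, index=motifs, columns=samples),
        se=pd.DataFrame(se, index=motifs, columns=samples),
        z=pd.DataFrame(z, index=motifs, columns=samples),
        ridge_lambda=float(ridge_lambda),
        df_effective=df_eff,
    )


def motif_growth_correlation(activities: pd.DataFrame, rates) -> pd.DataFrame:
    """Pearson correlation of each motif's activity with growth rate.

    ``activities`` is motifs x samples; ``rates`` maps sample ids to
    normalized growth rates. Requires >= 10 shared samples; motifs with
    zero activity variance are excluded with a warning. Returns per-motif
    r, two-sided p and BH FDR across motifs.
    """
    rates = pd.Series(rates)
    shared = [s for s in activities.columns if s in rates.index]
    if len(shared) < 10:
        raise ValueError(f"only {len(shared)} shared samples (need >= 10)")
    y = rates[shared].to_numpy(float)
    rows = []
    dropped = []
    for motif in activities.index:
        x = activities.loc[motif, shared].to_numpy(float)
        if np.ptp(x) == 0:
            dropped.append(motif)
            continue
        r, p = stats.pearsonr(x, y)
        rows.append({"motif": motif, "r": float(r), "p_value": float(p)})
    if dropped:
        warnings.warn(f"excluded {len(dropped)} zero-variance motifs: "
                      f"{dropped[:5]}")
    out = pd.DataFrame(rows)
    if len(out):
        out["fdr"] = adjust_fdr(out["p_value"])
    return out
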