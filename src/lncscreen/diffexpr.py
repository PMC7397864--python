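"""Molecular phenotyping: per-ASO differential expression and DEG calling.

Expression is normalized to tags per million (TPM) per library, log2
transformed with a pseudocount, and each ASO's knockdown samples are
compared with the NC_A control libraries of the same run. The per-gene
test is control-anchored: the log2 fold change is tested against the
gene's variance estimated from NC_A control replicates — pooled
within-run across all of the screen's runs for stable degrees of
freedom, and floored at the 10th percentile of control variances to
protect genes whose variance is underestimated — giving a two-sided
p-value from the t distribution on the pooled degrees of freedom with
Benjamini–Hochberg FDR across genes.

To ask whether a change is unusual for a *particular* gene relative to
its behaviour across the whole screen, fold changes are additionally
scaled gene-wise across all ASO experiments into Z-scores. A gene is a
called DEG for an ASO only when all three statistics agree:
FDR < 0.05, |Z| > 1.645 and |log2FC| > 0.5, signed by direction.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .growth import adjust_fdr

__all__ = [
    "normalize_tpm",
    "differential_expression",
    "scale_changes",
    "call_degs",
    "de_screen",
    "divergent_partner_response",
    "DEG_FDR",
    "DEG_Z",
    "DEG_LOG2FC",
]

#: DEG thresholds used throughout the screen.
DEG_FDR = 0.05
DEG_Z = 1.645
DEG_LOG2FC = 0.5

VARIANCE_FLOOR_QUANTILE = 0.10


def normalize_tpm(matrix: pd.DataFrame) -> pd.DataFrame:
    """Scale every sample (column) to sum to one million.

    Idempotent on already-TPM input; a zero or negative column total is an
    error naming the sample.
    """
    values = matrix.to_numpy(float)
    if (values < 0).any():
        raise ValueError("expression matrix contains negative values")
    totals = values.sum(axis=0)
    bad = np.flatnonzero(totals <= 0)
    if bad.size:
        raise ValueError(f"sample {matrix.columns[bad[0]]!r} has zero total signal")
    return matrix * (1e6 / totals)


def differential_expression(tpm: pd.DataFrame, kd_samples, control_samples,
                            pseudocount: float = 1.0,
                            variance_groups=None) -> pd.DataFrame:
    """Per-gene log2 fold change and p-value for one ASO experiment.

    ``log2FC = mean log2(TPM + pc) over KD samples − mean over controls``;
    the p-value is a two-sided t tail of log2FC against the gene's
    control-derived variance (floored at its 10th percentile across
    genes). By default the variance comes from ``control_samples`` with
    df = n − 1; pass ``variance_groups`` (e.g. every run's NC_A replicate
    group) to pool the within-group control variance across the screen,
    which raises the degrees of freedom to Σ(n_g − 1) while the fold
    change stays anchored to the matched controls. Requires >= 1 KD and
    >= 2 control samples sharing the gene universe of ``tpm``.
    """
    kd_samples = list(kd_samples)
    control_samples = list(control_samples)
    if len(kd_samples) < 1 or len(control_samples) < 2:
        raise ValueError("need >= 1 knockdown and >= 2 control samples")
    groups = ([list(g) for g in variance_groups] if variance_groups is not None
              else [control_samples])
    needed = set(kd_samples) | set(control_samples) | {s for g in groups for s in g}
    missing = needed - set(tpm.columns)
    if missing:
        raise ValueError(f"samples absent from expression matrix: {sorted(missing)}")
    kd = np.log2(tpm[kd_samples].to_numpy(float) + pseudocount)
    ctrl = np.log2(tpm[control_samples].to_numpy(float) + pseudocount)
    log2fc = kd.mean(axis=1) - ctrl.mean(axis=1)
    ss = np.zeros(len(tpm))
    df = 0
    for grp in groups:
        g = np.log2(tpm[grp].to_numpy(float) + pseudocount)
        ss += ((g - g.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
        df += g.shape[1] - 1
    if df < 1:
        raise ValueError("control variance needs >= 2 replicates in a group")
    ctrl_var = ss / df
    floor = np.quantile(ctrl_var, VARIANCE_FLOOR_QUANTILE)
    var = np.maximum(ctrl_var, floor)
    se = np.sqrt(var * (1.0 / kd.shape[1] + 1.0 / ctrl.shape[1]))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, log2fc / se, 0.0)
    p = 2.0 * stats.t.sf(np.abs(t), df=df)
    out = pd.DataFrame({"log2fc": log2fc, "p_value": p}, index=tpm.index)
    out["fdr"] = adjust_fdr(out["p_value"])
    return out


def scale_changes(log2fc_matrix: pd.DataFrame) -> pd.DataFrame:
    """Gene-wise Z-scores of fold changes across the whole experiment.

    Each gene's log2FC row (one column per ASO experiment) is centred and
    scaled by its sample (n−1) standard deviation; rows with zero spread
    get Z = 0. Needs at least three experiments to be meaningful.
    """
    if log2fc_matrix.shape[1] < 3:
        raise ValueError("need >= 3 ASO experiments to scale fold changes")
    values = log2fc_matrix.to_numpy(float)
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(sd > 0, (values - mean) / sd, 0.0)
    return pd.DataFrame(z, index=log2fc_matrix.index,
                        columns=log2fc_matrix.columns)


def call_degs(de: pd.DataFrame, fdr: float = DEG_FDR, z: float = DEG_Z,
              log2fc: float = DEG_LOG2FC) -> set[tuple[str, int]]:
    """Signed DEG set from a table with log2fc, fdr and z columns.

    Returns ``{(gene, +1), (gene, -1), ...}``; a gene is up-regulated when
    fdr < 0.05, Z > 1.645 and log2FC > 0.5, down-regulated with all three
    reversed. Idempotent: depends only on the three statistics.
    """
    for col in ("log2fc", "fdr", "z"):
        if col not in de.columns:
            raise ValueError(f"DE table lacks column {col!r}")
    up = (de["fdr"] < fdr) & (de["z"] > z) & (de["log2fc"] > log2fc)
    down = (de["fdr"] < fdr) & (de["z"] < -z) & (de["log2fc"] < -log2fc)
    degs = {(g, 1) for g in de.index[up]}
    degs |= {(g, -1) for g in de.index[down]}
    return degs


def de_screen(expression: pd.DataFrame, sample_sheet: pd.DataFrame,
              pseudocount: float = 1.0, normalize: bool = True) -> dict:
    """Differential expression for every ASO in a screen.

    Controls are the NC_A libraries of the ASO's own run. Returns a dict
    with per-ASO DE tables (including the experiment-wide Z), the
    log2FC and Z matrices (genes x ASOs), and per-ASO signed DEG sets.
    """
    required = {"sample_id", "aso_id", "run_id", "is_control"}
    missing = required - set(sample_sheet.columns)
    if missing:
        raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
    unknown = set(sample_sheet["sample_id"]) - set(expression.columns)
    if unknown:
        raise ValueError(f"sample sheet rows without expression data: {sorted(unknown)[:5]}")
    tpm = normalize_tpm(expression) if normalize else expression
    sheet = sample_sheet
    controls_by_run = {
        run: sub.loc[sub["is_control"], "sample_id"].tolist()
        for run, sub in sheet.groupby("run_id")
    }
    variance_groups = [g for g in controls_by_run.values() if len(g) >= 2]
    tables = {}
    fc_cols = {}
    aso_rows = sheet[~sheet["is_control"].astype(bool)]
    for aso, sub in aso_rows.groupby("aso_id"):
        run = sub["run_id"].iloc[0]
        controls = controls_by_run.get(run, [])
        if len(controls) < 2:
            raise ValueError(f"run {run}: fewer than 2 control libraries")
        de = differential_expression(tpm, sub["sample_id"].tolist(), controls,
                                     pseudocount, variance_groups)
        tables[aso] = de
        fc_cols[aso] = de["log2fc"]
    log2fc_matrix = pd.DataFrame(fc_cols)
    z_matrix = scale_changes(log2fc_matrix)
    deg_sets = {}
    for aso, de in tables.items():
        de["z"] = z_matrix[aso]
        deg_sets[aso] = call_degs(de)
    return {"tables": tables, "log2fc": log2fc_matrix, "z": z_matrix,
            "deg_sets": deg_sets}


def divergent_partner_response(tables: dict, partner_map: dict,
                               aso_target: dict) -> dict:
    """Response of divergent-promoter partner genes to lncRNA knockdown.

    For every ASO experiment whose target has a mapped partner gene,
    reports the partner's log2FC and FDR; the summary statistic is the
    median |log2FC| across all (ASO, partner) records. Partners absent
    from the matrix are recorded as missing and excluded from the median,
    which is NaN (flagged) when no records remain.
    """
    records = []
    missing = []
    for aso, de in tables.items():
        target = aso_target.get(aso)
        if target is None or target not in partner_map:
            continue
        partner = partner_map[target]
        if partner not in de.index:
            missing.append((aso, partner))
            continue
        records.append({
            "aso_id": aso, "target_id": target, "partner_gene": partner,
            "log2fc": float(de.loc[partner, "log2fc"]),
            "fdr": float(de.loc[partner, "fdr"]),
        })
    table = pd.DataFrame(records)
    median_abs = float(table["log2fc"].abs().median()) if len(table) else float("nan")
    return {"table": table, "median_abs_log2fc": median_abs, "missing": missing}
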