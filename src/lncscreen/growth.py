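"""Growth-rate estimation and cellular-phenotype testing.

Per plate, the confluence timeline is truncated at the first time the mean
of the six NC_A control wells reaches 90% (keeping the analysis inside the
near-linear growth phase), each well's growth rate is the slope of an
ordinary least-squares regression of % confluence on time, and each ASO's
rate is normalized by the mean NC_A slope of its plate. Growth inhibition
is tested with an equal-variance two-sample t-test of the ASO's duplicate
well slopes against the six control slopes, with Benjamini–Hochberg FDR
control across the screen. Morphology feature tables (one row per well,
features from image segmentation) are scored the same way, feature by
feature, against plate-matched controls.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ConfluenceSeries",
    "GrowthResult",
    "truncate_to_control_window",
    "estimate_growth_rate",
    "normalize_growth_rate",
    "growth_significance",
    "adjust_fdr",
    "analyze_growth",
    "morphology_effects",
    "eccentricity_shift_flags",
]

CONTROL_ROLE = "NC_A"
CONTROL_CONFLUENCE_CAP = 90.0
MIN_POINTS = 3


@dataclass(frozen=True)
class ConfluenceSeries:
    """One well's confluence timeline with plate/role metadata."""

    plate_id: str
    well_id: str
    role: str  # ASO, NC_A, MALAT1 or mock
    aso_id: str
    times: tuple
    values: tuple

    def __post_init__(self):
        t = np.asarray(self.times, float)
        v = np.asarray(self.values, float)
        if t.size != v.size:
            raise ValueError(f"{self.well_id}: times and values differ in length")
        if t.size and np.any(np.diff(t) <= 0):
            raise ValueError(f"{self.well_id}: times must be strictly increasing")
        if v.size and (v.min() < 0 or v.max() > 100):
            raise ValueError(f"{self.well_id}: confluence outside [0, 100]")


@dataclass(frozen=True)
class GrowthResult:
    aso_id: str
    plate_id: str
    slope: float             # % confluence / h, mean over replicate wells
    normalized_rate: float   # slope / mean NC_A slope of the same plate
    t_stat: float
    p_value: float
    fdr: float
    significant_inhibition: bool


def truncate_to_control_window(plate_df: pd.DataFrame) -> pd.DataFrame:
    """Restrict a plate's long table to times before controls saturate.

    Keeps time points ``t <= t90`` where ``t90`` is the first time the
    NC_A mean confluence reaches 90%; if the controls never reach 90% the
    full series is kept. Raises if fewer than three points remain or the
    plate has no NC_A wells.
    """
    controls = plate_df[plate_df["role"] == CONTROL_ROLE]
    if controls.empty:
        plate = plate_df["plate"].iloc[0] if len(plate_df) else "?"
        raise ValueError(f"plate {plate}: no {CONTROL_ROLE} control wells")
    mean_by_time = controls.groupby("time_h")["confluence"].mean().sort_index()
    saturated = mean_by_time[mean_by_time >= CONTROL_CONFLUENCE_CAP]
    if saturated.empty:
        kept = plate_df
    else:
        t90 = saturated.index[0]
        kept = plate_df[plate_df["time_h"] <= t90]
    n_points = kept["time_h"].nunique()
    if n_points < MIN_POINTS:
        plate = plate_df["plate"].iloc[0]
        raise ValueError(
            f"plate {plate}: only {n_points} time points remain before the "
            f"{CONTROL_ROLE} controls reach {CONTROL_CONFLUENCE_CAP}% — "
            "cannot fit a growth rate")
    return kept


def estimate_growth_rate(times, values) -> float:
    """OLS slope of confluence on time (% confluence per hour)."""
    t = np.asarray(times, float)
    v = np.asarray(values, float)
    if t.size < MIN_POINTS:
        raise ValueError(f"need >= {MIN_POINTS} points to estimate a growth rate")
    if np.ptp(t) == 0:
        raise ValueError("degenerate time grid: all time points equal")
    return float(stats.linregress(t, v).slope)


def normalize_growth_rate(slope: float, control_slopes) -> float:
    """Slope divided by the mean control slope of the same plate.

    Negative slopes (cells shrinking or detaching) pass through as
    negative normalized rates. A non-positive mean control slope means the
    plate's controls failed to grow and is a plate-level error.
    """
    control_slopes = np.asarray(control_slopes, float)
    if control_slopes.size == 0:
        raise ValueError("no control slopes supplied")
    mean_control = control_slopes.mean()
    if mean_control <= 0:
        raise ValueError(
            f"mean control slope {mean_control:.4g} <= 0: plate controls failed")
    return float(slope / mean_control)


def growth_significance(replicate_slopes, control_slopes) -> tuple[float, float]:
    """Equal-variance two-sample t-test of ASO replicates vs plate controls.

    Returns ``(t, p)`` with a two-sided p from the t distribution on
    ``n1 + n2 - 2`` degrees of freedom. Degenerate zero-variance input:
    equal means give ``(0, 1)``; unequal means give ``(±inf, 0)`` with a
    warning.
    """
    a = np.asarray(replicate_slopes, float)
    b = np.asarray(control_slopes, float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need >= 2 slopes in each group for the t-test")
    pooled_var = (((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1))
                  / (a.size + b.size - 2))
    if pooled_var == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        warnings.warn("zero pooled variance with unequal means: degenerate t-test")
        return float(np.sign(a.mean() - b.mean()) * np.inf), 0.0
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return float(t), float(p)


def adjust_fdr(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (the screen's "FDR")."""
    p = np.asarray(p_values, float)
    if p.size == 0:
        return p
    if np.any(p < 0) or np.any(p > 1) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _plate_slopes(plate_df: pd.DataFrame) -> pd.DataFrame:
    """Per-well slopes for one plate, after control-window truncation."""
    kept = truncate_to_control_window(plate_df)
    rows = []
    for (well,), sub in kept.groupby(["well"]):
        sub = sub.sort_values("time_h")
        rows.append({
            "plate": sub["plate"].iloc[0],
            "well": well,
            "role": sub["role"].iloc[0],
            "aso_id": sub["aso_id"].iloc[0],
            "slope": estimate_growth_rate(sub["time_h"], sub["confluence"]),
        })
    return pd.DataFrame(rows)


def analyze_growth(confluence: pd.DataFrame, fdr_alpha: float = 0.05) -> pd.DataFrame:
    """Full growth analysis of a long confluence table.

    Returns one row per ASO: mean raw slope, normalized growth rate, the
    pooled t statistic and p-value of its replicate wells against the
    plate's NC_A controls, BH FDR across all ASOs in the table, and the
    one-directional inhibition call (FDR <= alpha and normalized rate < 1).
    """
    required = {"plate", "well", "role", "aso_id", "time_h", "confluence"}
    missing = required - set(confluence.columns)
    if missing:
        raise ValueError(f"confluence table missing columns: {sorted(missing)}")
    records = []
    for plate, plate_df in confluence.groupby("plate"):
        slopes = _plate_slopes(plate_df)
        control_slopes = slopes.loc[slopes["role"] == CONTROL_ROLE, "slope"].to_numpy()
        mean_control = control_slopes.mean()
        if mean_control <= 0:
            raise ValueError(f"plate {plate}: mean control slope <= 0")
        aso_wells = slopes[slopes["role"] == "ASO"]
        for aso, sub in aso_wells.groupby("aso_id"):
            reps = sub["slope"].to_numpy()
            t, p = growth_significance(reps, control_slopes)
            records.append({
                "aso_id": aso,
                "plate": plate,
                "slope": reps.mean(),
                "normalized_rate": normalize_growth_rate(reps.mean(), control_slopes),
                "t_stat": t,
                "p_value": p,
            })
    result = pd.DataFrame(records).sort_values("aso_id").reset_index(drop=True)
    result["fdr"] = adjust_fdr(result["p_value"])
    result["significant_inhibition"] = (
        (result["fdr"] <= fdr_alpha) & (result["normalized_rate"] < 1.0))
    return result


def normalized_rates_by_well(confluence: pd.DataFrame) -> pd.DataFrame:
    """Per-well normalized rates (the plate's NC_A wells average to 1 exactly)."""
    frames = []
    for plate, plate_df in confluence.groupby("plate"):
        slopes = _plate_slopes(plate_df)
        mean_control = slopes.loc[slopes["role"] == CONTROL_ROLE, "slope"].mean()
        if mean_control <= 0:
            raise ValueError(f"plate {plate}: mean control slope <= 0")
        slopes["normalized_rate"] = slopes["slope"] / mean_control
        frames.append(slopes)
    return pd.concat(frames, ignore_index=True)


def morphology_effects(feature_table: pd.DataFrame,
                       fdr_alpha: float = 0.05) -> pd.DataFrame:
    """Per ASO x feature effects against plate-matched NC_A wells.

    The effect is the standardized mean difference (difference of means in
    units of the control SD); p-values come from the equal-variance
    two-sample t-test and are BH-adjusted across ASOs within each feature.
    """
    id_cols = {"plate", "well", "role", "aso_id"}
    missing = {"plate", "role", "aso_id"} - set(feature_table.columns)
    if missing:
        raise ValueError(f"feature table missing columns: {sorted(missing)}")
    features = [c for c in feature_table.columns if c not in id_cols]
    if not features:
        raise ValueError("feature table has no feature columns")
    records = []
    for plate, plate_df in feature_table.groupby("plate"):
        controls = plate_df[plate_df["role"] == CONTROL_ROLE]
        if controls.empty:
            raise ValueError(f"plate {plate}: no {CONTROL_ROLE} rows in feature table")
        for aso, sub in plate_df[plate_df["role"] == "ASO"].groupby("aso_id"):
            for feat in features:
                ctrl = controls[feat].to_numpy(float)
                vals = sub[feat].to_numpy(float)
                sd = ctrl.std(ddof=1)
                effect = 0.0 if sd == 0 else (vals.mean() - ctrl.mean()) / sd
                t, p = growth_significance(vals, ctrl)
                records.append({"aso_id": aso, "plate": plate, "feature": feat,
                                "effect": effect, "p_value": p,
                                "direction": int(np.sign(effect))})
    out = pd.DataFrame(records)
    out["fdr"] = np.nan
    for feat in features:
        mask = out["feature"] == feat
        out.loc[mask, "fdr"] = adjust_fdr(out.loc[mask, "p_value"])
    return out.sort_values(["feature", "aso_id"]).reset_index(drop=True)


def eccentricity_shift_flags(effects: pd.DataFrame,
                             alpha: float = 0.05) -> pd.DataFrame:
    """Flag ASOs losing spindle shape without losing cells.

    True when eccentricity is significantly decreased (FDR < alpha,
    negative effect) while cell_count shows no significant decrease — the
    signature of a shift toward epithelial-like morphology rather than
    simple growth inhibition.
    """
    wide_eff = effects.pivot(index="aso_id", columns="feature", values="effect")
    wide_fdr = effects.pivot(index="aso_id", columns="feature", values="fdr")
    for col in ("eccentricity", "cell_count"):
        if col not in wide_eff.columns:
            raise ValueError(f"feature table lacks a '{col}' column")
    ecc_down = (wide_eff["eccentricity"] < 0) & (wide_fdr["eccentricity"] < alpha)
    count_down = (wide_eff["cell_count"] < 0) & (wide_fdr["cell_count"] < alpha)
    flags = (ecc_down & ~count_down)
    return flags.rename("eccentricity_shift").reset_index()
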