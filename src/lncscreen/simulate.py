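"""Synthetic ASO knockdown screens with known ground truth.

The generator emulates the statistical structure of an antisense
oligonucleotide (ASO) lncRNA knockdown screen in primary fibroblasts:

* plates carrying six non-targeting negative-control (NC_A) wells plus
  duplicated ASO wells, imaged every 3 h for 48 h;
* near-linear early-phase growth, so the per-well confluence series is
  ``start + slope * t`` plus Gaussian imaging noise, clipped to [0, 100] —
  the linear-regression slope used downstream is then the exact estimand;
* per-ASO knockdown efficiencies drawn from a Beta distribution and
  measured with three noisy qPCR primer pairs, so a realistic fraction of
  ASOs fails the knockdown-success rule;
* expression generated on the log2 scale: per-gene baseline, the targeted
  lncRNA reduced according to the ASO's true efficiency, a shared
  downstream gene module imposed on all successful ASOs of "true hit"
  targets, ASO-specific off-target modules, and i.i.d. Gaussian noise
  (mean-corrected so knockdown fractions hold exactly in expectation on
  the linear scale);
* a motif layer (promoter site counts x planted per-sample motif
  activities) that can optionally drive expression, making motif-activity
  recovery testable against truth;
* per-well morphology features with planted eccentricity shifts.

Setting every effect fraction and effect size to zero yields a *null
screen*: ASO wells and samples are then statistically exchangeable with
negative controls, which is how the hit-calling background is calibrated.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .kdqc import KnockdownRecord, classify_knockdown

__all__ = [
    "ScreenConfig",
    "ScreenTruth",
    "SyntheticScreen",
    "simulate_confluence",
    "simulate_screen",
    "null_config",
]

_DEFAULT_TIMEPOINTS = tuple(float(t) for t in range(0, 49, 3))

#: Morphology feature baselines as (mean, sd) per image field.
MORPHOLOGY_BASELINES = {
    "eccentricity": (0.85, 0.03),
    "compactness": (2.0, 0.15),
    "radius": (30.0, 2.5),
    "axis_length": (80.0, 7.0),
    "cell_count": (500.0, 40.0),
}


@dataclass(frozen=True)
class ScreenConfig:
    """Design and effect-size parameters of a simulated screen.

    Counts follow the screen design: ``asos_per_target`` defaults to the
    five non-overlapping ASOs designed per lncRNA, ``controls_per_plate``
    to the six NC_A wells anchoring each plate, ``replicate_wells`` to the
    imaging duplicates, and ``timepoints_h`` to the 3-hourly 48-h imaging
    grid. Effect parameters are fractions of targets carrying true
    effects and the sizes of those effects; a screen with all of them at
    zero is a null screen.
    """

    n_targets: int = 50
    asos_per_target: int = 5
    n_plates: int | None = None  # default: ~40 ASOs per plate
    controls_per_plate: int = 6
    replicate_wells: int = 2
    n_genes: int = 1000
    n_motifs: int = 20
    n_gene_sets: int = 50
    frac_true_growth_hits: float = 0.08
    frac_true_molecular_hits: float = 0.10
    frac_true_morph_hits: float = 0.07
    growth_effect_size: float = 0.4
    shared_module_size: int = 30
    shared_module_effect: float = 1.0
    offtarget_module_size: int = 10
    offtarget_effect: float = 1.0
    kd_efficiency_params: tuple | float = (2.5, 3.0)
    noise_sd_confluence: float = 1.0
    noise_sd_logexpr: float = 0.3
    timepoints_h: tuple = _DEFAULT_TIMEPOINTS
    baseline_slope: float = 1.6  # % confluence per hour for NC_A wells
    start_confluence: float = 12.0
    baseline_log2_mean: float = 5.0
    baseline_log2_sd: float = 2.0
    target_baseline_log2: float | None = None
    primer_pairs: int = 3
    primer_noise_sd: float = 0.05
    expr_replicates: int = 2
    expr_controls_per_run: int = 6
    motif_driven_expression: bool = False
    motif_activity_sd: float = 0.2
    seed: int = 0

    def __post_init__(self):
        counts = {
            "n_targets": self.n_targets,
            "asos_per_target": self.asos_per_target,
            "controls_per_plate": self.controls_per_plate,
            "replicate_wells": self.replicate_wells,
            "n_genes": self.n_genes,
            "n_motifs": self.n_motifs,
            "n_gene_sets": self.n_gene_sets,
            "shared_module_size": self.shared_module_size,
            "offtarget_module_size": self.offtarget_module_size,
            "primer_pairs": self.primer_pairs,
            "expr_replicates": self.expr_replicates,
            "expr_controls_per_run": self.expr_controls_per_run,
        }
        for name, value in counts.items():
            if not isinstance(value, (int, np.integer)) or value < 1:
                raise ValueError(f"ScreenConfig.{name} must be a count >= 1, got {value!r}")
        if self.n_plates is not None and (not isinstance(self.n_plates, (int, np.integer)) or self.n_plates < 1):
            raise ValueError(f"ScreenConfig.n_plates must be a count >= 1 or None, got {self.n_plates!r}")
        fracs = {
            "frac_true_growth_hits": self.frac_true_growth_hits,
            "frac_true_molecular_hits": self.frac_true_molecular_hits,
            "frac_true_morph_hits": self.frac_true_morph_hits,
            "growth_effect_size": self.growth_effect_size,
        }
        for name, value in fracs.items():
            if not (0.0 <= value <= 1.0):
                raise ValueError(f"ScreenConfig.{name} must lie in [0, 1], got {value!r}")
        if isinstance(self.kd_efficiency_params, (int, float)):
            if not (0.0 <= self.kd_efficiency_params <= 1.0):
                raise ValueError("ScreenConfig.kd_efficiency_params: constant efficiency must lie in [0, 1]")
        else:
            a, b = self.kd_efficiency_params
            if a <= 0 or b <= 0:
                raise ValueError("ScreenConfig.kd_efficiency_params: Beta parameters must be > 0")
        for name in ("noise_sd_confluence", "noise_sd_logexpr", "primer_noise_sd",
                     "motif_activity_sd", "shared_module_effect", "offtarget_effect",
                     "baseline_log2_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"ScreenConfig.{name} must be >= 0")
        if not (0.0 <= self.start_confluence <= 100.0):
            raise ValueError("ScreenConfig.start_confluence must lie in [0, 100]")
        t = np.asarray(self.timepoints_h, dtype=float)
        if t.size < 3 or np.any(np.diff(t) <= 0):
            raise ValueError("ScreenConfig.timepoints_h must be strictly increasing with >= 3 points")
        n_coding = self.n_genes - self.n_targets
        if n_coding < max(self.shared_module_size, self.offtarget_module_size, 1):
            raise ValueError(
                "ScreenConfig.n_genes too small: need more non-target genes "
                "than shared_module_size and offtarget_module_size")

    @property
    def n_asos(self) -> int:
        return self.n_targets * self.asos_per_target

    @property
    def plates(self) -> int:
        if self.n_plates is not None:
            return self.n_plates
        return max(1, math.ceil(self.n_asos / 40))

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def null_config(seed: int = 0, **overrides) -> ScreenConfig:
    """A screen configuration with no planted effects of any kind.

    Used for background calibration: every ASO well and sample is then
    drawn from the same distribution as the negative controls.
    """
    params = dict(
        frac_true_growth_hits=0.0,
        frac_true_molecular_hits=0.0,
        frac_true_morph_hits=0.0,
        growth_effect_size=0.0,
        shared_module_effect=0.0,
        offtarget_effect=0.0,
        seed=seed,
    )
    params.update(overrides)
    return ScreenConfig(**params)


@dataclass
class ScreenTruth:
    """Planted ground truth of a simulated screen (for recovery tests)."""

    growth_hits: list
    molecular_hits: list
    morph_hits: list
    kd_efficiency: dict          # aso_id -> true knocked-down fraction
    kd_success: dict             # aso_id -> bool (rule applied to measured primers)
    aso_target: dict             # aso_id -> target_id
    target_gene: dict            # target_id -> its lncRNA gene id
    partner_gene: dict           # target_id -> divergent-partner gene id
    shared_modules: dict         # target_id -> {gene: signed log2 effect}
    offtarget_modules: dict      # aso_id -> {gene: signed log2 effect}
    aso_slope: dict              # aso_id -> true well slope (% / h)
    motif_activities: pd.DataFrame | None = None  # motifs x samples

    def to_json(self) -> str:
        payload = dataclasses.asdict(self)
        if self.motif_activities is not None:
            payload["motif_activities"] = {
                "index": list(self.motif_activities.index),
                "columns": list(self.motif_activities.columns),
                "values": self.motif_activities.to_numpy().tolist(),
            }
        return json.dumps(payload, indent=1, sort_keys=True, default=str)


@dataclass
class SyntheticScreen:
    """All tables of one simulated screen plus its ground truth."""

    config: ScreenConfig
    confluence: pd.DataFrame     # plate, well, role, aso_id, time_h, confluence
    kd_table: pd.DataFrame       # aso_id, target_id, primer_id, efficiency
    expression: pd.DataFrame     # genes x samples, nonnegative TPM-like
    sample_sheet: pd.DataFrame   # sample_id, aso_id, target_id, run_id, is_control
    site_counts: pd.DataFrame    # genes x motifs
    gene_sets: dict
    morphology: pd.DataFrame     # plate, well, role, aso_id + feature columns
    truth: ScreenTruth

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        meta = {"config_hash": io.config_hash(self.config.to_dict()),
                "seed": self.config.seed}
        io.write_tsv(self.confluence, outdir / "confluence.tsv", meta)
        io.write_tsv(self.kd_table, outdir / "kd_efficiency.tsv", meta)
        io.write_tsv(self.expression.rename_axis("gene_id").reset_index(),
                     outdir / "expression.tsv", meta)
        io.write_tsv(self.sample_sheet, outdir / "sample_sheet.tsv", meta)
        io.write_tsv(self.site_counts.rename_axis("gene_id").reset_index(),
                     outdir / "site_counts.tsv", meta)
        io.write_gmt(self.gene_sets, outdir / "gene_sets.gmt")
        io.write_tsv(self.morphology, outdir / "morphology.tsv", meta)
        (outdir / "truth.json").write_text(self.truth.to_json())


def simulate_confluence(slope: float, times, start: float,
                        noise_sd: float = 0.0, rng=None) -> np.ndarray:
    """One well's % confluence series: ``start + slope * t`` plus noise.

    Values are clipped to [0, 100]; with ``noise_sd=0`` the series is the
    exact (clipped) line. ``times`` must be non-empty.
    """
    t = np.asarray(times, dtype=float)
    if t.size == 0:
        raise ValueError("simulate_confluence: empty time grid")
    if not (0.0 <= start <= 100.0):
        raise ValueError(f"simulate_confluence: start {start} outside [0, 100]")
    values = start + slope * t
    if noise_sd > 0:
        rng = np.random.default_rng() if rng is None else rng
        values = values + rng.normal(0.0, noise_sd, size=t.size)
    return np.clip(values, 0.0, 100.0)


def _draw_efficiencies(cfg: ScreenConfig, rng, n: int) -> np.ndarray:
    if isinstance(cfg.kd_efficiency_params, (int, float)):
        return np.full(n, float(cfg.kd_efficiency_params))
    a, b = cfg.kd_efficiency_params
    return rng.beta(a, b, size=n)


def simulate_screen(config: ScreenConfig) -> SyntheticScreen:
    """Generate a full synthetic screen; deterministic given ``config.seed``."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    times = np.asarray(cfg.timepoints_h, dtype=float)

    targets = [f"LNC{i + 1:04d}" for i in range(cfg.n_targets)]
    asos = []
    aso_target = {}
    for t in targets:
        for j in range(cfg.asos_per_target):
            aso = f"{t}_ASO{j + 1:02d}"
            asos.append(aso)
            aso_target[aso] = t

    # --- which targets carry planted effects -------------------------------
    def _pick(frac):
        k = int(round(frac * cfg.n_targets))
        chosen = rng.choice(targets, size=k, replace=False) if k else []
        return sorted(str(t) for t in chosen)

    growth_hits = _pick(cfg.frac_true_growth_hits)
    molecular_hits = _pick(cfg.frac_true_molecular_hits)
    morph_hits = _pick(cfg.frac_true_morph_hits)

    # --- knockdown efficiencies and QC truth -------------------------------
    true_eff = dict(zip(asos, _draw_efficiencies(cfg, rng, len(asos))))
    kd_rows = []
    kd_success = {}
    for aso in asos:
        measured = np.clip(
            true_eff[aso] + rng.normal(0.0, cfg.primer_noise_sd, cfg.primer_pairs),
            0.0, 1.0)
        for p, e in enumerate(measured, start=1):
            kd_rows.append({"aso_id": aso, "target_id": aso_target[aso],
                            "primer_id": f"primer_{p}", "efficiency": e})
        rec = KnockdownRecord(aso, aso_target[aso], tuple(measured))
        kd_success[aso] = classify_knockdown(rec)
    kd_table = pd.DataFrame(kd_rows)

    # --- plate layout and confluence ---------------------------------------
    n_plates = cfg.plates
    plate_of = {aso: f"P{(i % n_plates) + 1:02d}" for i, aso in enumerate(asos)}
    growth_hit_set = set(growth_hits)
    aso_slope = {
        aso: cfg.baseline_slope
        * (1.0 - cfg.growth_effect_size * true_eff[aso]
           if aso_target[aso] in growth_hit_set else 1.0)
        for aso in asos
    }

    conf_records = []
    well_rows = []  # (plate, well, role, aso_id, slope) for morphology reuse
    for p in range(1, n_plates + 1):
        plate = f"P{p:02d}"
        widx = 0
        for c in range(cfg.controls_per_plate):
            widx += 1
            well_rows.append((plate, f"{plate}_W{widx:03d}", "NC_A", "", cfg.baseline_slope))
        for aso in asos:
            if plate_of[aso] != plate:
                continue
            for r in range(cfg.replicate_wells):
                widx += 1
                well_rows.append((plate, f"{plate}_W{widx:03d}", "ASO", aso, aso_slope[aso]))
    for plate, well, role, aso, slope in well_rows:
        vals = simulate_confluence(slope, times, cfg.start_confluence,
                                   cfg.noise_sd_confluence, rng)
        for t, v in zip(times, vals):
            conf_records.append((plate, well, role, aso, t, v))
    confluence = pd.DataFrame(
        conf_records,
        columns=["plate", "well", "role", "aso_id", "time_h", "confluence"])

    # --- gene universe, modules, partners ----------------------------------
    coding_genes = [f"G{i + 1:05d}" for i in range(cfg.n_genes - cfg.n_targets)]
    genes = targets + coding_genes  # the lncRNA itself is a row in the matrix
    target_gene = {t: t for t in targets}
    partner_pool = rng.choice(coding_genes, size=cfg.n_targets, replace=False)
    partner_gene = dict(zip(targets, partner_pool.tolist()))

    gene_index = {g: i for i, g in enumerate(genes)}
    shared_modules: dict[str, dict] = {}
    for t in molecular_hits:
        module_genes = rng.choice(coding_genes, size=cfg.shared_module_size,
                                  replace=False)
        signs = rng.choice([-1.0, 1.0], size=cfg.shared_module_size)
        shared_modules[t] = {str(g): float(s * cfg.shared_module_effect)
                             for g, s in zip(module_genes, signs)}
    offtarget_modules: dict[str, dict] = {}
    for aso in asos:
        og = rng.choice(coding_genes, size=cfg.offtarget_module_size, replace=False)
        signs = rng.choice([-1.0, 1.0], size=cfg.offtarget_module_size)
        offtarget_modules[aso] = {str(g): float(s * cfg.offtarget_effect)
                                  for g, s in zip(og, signs)}

    # --- expression ---------------------------------------------------------
    baseline = rng.normal(cfg.baseline_log2_mean, cfg.baseline_log2_sd,
                          size=len(genes))
    if cfg.target_baseline_log2 is not None:
        baseline[: cfg.n_targets] = cfg.target_baseline_log2

    sample_ids, sheet_rows = [], []
    effects = []  # per sample log2 shift vector
    for p in range(1, n_plates + 1):
        run = f"P{p:02d}"
        for c in range(cfg.expr_controls_per_run):
            sid = f"{run}_NCA{c + 1:02d}"
            sample_ids.append(sid)
            sheet_rows.append((sid, "", "", run, True))
            effects.append(np.zeros(len(genes)))
    for aso in asos:
        run = plate_of[aso]
        eff_vec = np.zeros(len(genes))
        eff = min(true_eff[aso], 0.995)
        eff_vec[gene_index[aso_target[aso]]] += math.log2(1.0 - eff)
        if aso_target[aso] in shared_modules and kd_success[aso]:
            for g, e in shared_modules[aso_target[aso]].items():
                eff_vec[gene_index[g]] += e
        for g, e in offtarget_modules[aso].items():
            eff_vec[gene_index[g]] += e
        for r in range(cfg.expr_replicates):
            sid = f"{aso}_rep{r + 1}"
            sample_ids.append(sid)
            sheet_rows.append((sid, aso, aso_target[aso], run, False))
            effects.append(eff_vec)

    log2_expr = baseline[:, None] + np.column_stack(effects)

    # --- motif layer --------------------------------------------------------
    motifs = [f"MOTIF{m + 1:03d}" for m in range(cfg.n_motifs)]
    counts = rng.poisson(1.5, size=(len(genes), cfg.n_motifs)).astype(float)
    # guard: every motif must hit at least one promoter
    for m in range(cfg.n_motifs):
        if counts[:, m].sum() == 0:
            counts[rng.integers(len(genes)), m] = 1.0
    site_counts = pd.DataFrame(counts, index=genes, columns=motifs)
    planted_acts = None
    if cfg.motif_driven_expression:
        acts = rng.normal(0.0, cfg.motif_activity_sd,
                          size=(cfg.n_motifs, len(sample_ids)))
        planted_acts = pd.DataFrame(acts, index=motifs, columns=sample_ids)
        n_centered = counts - counts.mean(axis=0, keepdims=True)
        log2_expr = log2_expr + n_centered @ acts

    if cfg.noise_sd_logexpr > 0:
        sd = cfg.noise_sd_logexpr
        # mean-correct so E[2^noise] = 1: the knockdown fraction then holds
        # exactly in expectation on the linear scale
        mu = -0.5 * sd * sd * math.log(2.0)
        log2_expr = log2_expr + rng.normal(mu, sd, size=log2_expr.shape)
    expression = pd.DataFrame(np.exp2(log2_expr), index=genes, columns=sample_ids)
    sample_sheet = pd.DataFrame(
        sheet_rows,
        columns=["sample_id", "aso_id", "target_id", "run_id", "is_control"])

    # --- gene sets ----------------------------------------------------------
    gene_sets: dict[str, list] = {}
    max_size = min(80, len(coding_genes))
    min_size = min(15, max_size)
    for s in range(cfg.n_gene_sets):
        size = int(rng.integers(min_size, max_size + 1))
        members = rng.choice(coding_genes, size=size, replace=False)
        gene_sets[f"SET{s + 1:03d}"] = sorted(members.tolist())
    for t, module in shared_modules.items():
        gene_sets[f"MODULE_{t}"] = sorted(module)

    # --- morphology ---------------------------------------------------------
    morph_hit_set = set(morph_hits)
    morph_rows = []
    for plate, well, role, aso, slope in well_rows:
        row = {"plate": plate, "well": well, "role": role, "aso_id": aso}
        for feat, (mean, sd) in MORPHOLOGY_BASELINES.items():
            value = mean
            if role == "ASO":
                eff = true_eff[aso]
                if aso_target[aso] in morph_hit_set and kd_success[aso] and feat == "eccentricity":
                    value -= 3.0 * sd  # planted epithelial-like rounding
                if aso_target[aso] in growth_hit_set and feat == "cell_count":
                    value *= 1.0 - 0.8 * cfg.growth_effect_size * eff
            row[feat] = value + rng.normal(0.0, sd)
        morph_rows.append(row)
    morphology = pd.DataFrame(morph_rows)

    truth = ScreenTruth(
        growth_hits=list(growth_hits),
        molecular_hits=list(molecular_hits),
        morph_hits=list(morph_hits),
        kd_efficiency={a: float(true_eff[a]) for a in asos},
        kd_success=kd_success,
        aso_target=aso_target,
        target_gene=target_gene,
        partner_gene=partner_gene,
        shared_modules=shared_modules,
        offtarget_modules=offtarget_modules,
        aso_slope={a: float(aso_slope[a]) for a in asos},
        motif_activities=planted_acts,
    )
    return SyntheticScreen(
        config=cfg, confluence=confluence, kd_table=kd_table,
        expression=expression, sample_sheet=sample_sheet,
        site_counts=site_counts, gene_sets=gene_sets,
        morphology=morphology, truth=truth)
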