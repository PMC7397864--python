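"""End-to-end screen analysis: QC → growth → DE → concordance → MARA → GSEA.

`analyze_screen` drives the full analysis on in-memory tables (anything
with the attribute layout of :class:`lncscreen.simulate.SyntheticScreen`);
`run_pipeline` wraps it with file I/O: it reads the documented TSV/GMT
inputs, writes every stage's output table with a metadata header (config
hash + seed), and emits a JSON summary of the screen-level counts. Any
stage failure is re-raised tagged with the stage name.
"""

from __future__ import annotations

import dataclasses
import json
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, concordance, diffexpr, enrichment, growth, io, kdqc, mara

__all__ = ["AnalysisParams", "PipelineConfig", "ScreenData",
           "analyze_screen", "run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    """A stage failed; the message carries the stage name."""


@dataclass(frozen=True)
class AnalysisParams:
    """Thresholds and permutation settings for a screen analysis."""

    fdr_alpha: float = 0.05
    deg_log2fc: float = diffexpr.DEG_LOG2FC
    deg_z: float = diffexpr.DEG_Z
    min_common_degs: int = 5
    pair_alpha: float = 0.05
    background_alpha: float = 0.05
    min_asos_per_target: int = 2
    n_perm: int = 10000
    gsea_n_perm: int = 500
    gsea_min_size: int = 5
    pseudocount: float = 1.0
    ridge_lambda: float | None = None
    seed: int = 0

    def __post_init__(self):
        for name in ("fdr_alpha", "pair_alpha", "background_alpha"):
            if not (0 < getattr(self, name) <= 1):
                raise ValueError(f"AnalysisParams.{name} must lie in (0, 1]")
        for name in ("deg_log2fc", "deg_z", "pseudocount"):
            if getattr(self, name) < 0:
                raise ValueError(f"AnalysisParams.{name} must be >= 0")


@dataclass
class ScreenData:
    """Input tables of one screen (all but confluence/kd optional)."""

    confluence: pd.DataFrame
    kd_table: pd.DataFrame
    expression: pd.DataFrame | None = None
    sample_sheet: pd.DataFrame | None = None
    site_counts: pd.DataFrame | None = None
    gene_sets: dict | None = None
    morphology: pd.DataFrame | None = None
    partner_map: dict | None = None


@dataclass
class PipelineConfig:
    """File-level configuration: input paths, output directory, parameters."""

    indir: str
    outdir: str
    params: AnalysisParams = field(default_factory=AnalysisParams)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        params = AnalysisParams(**raw.get("params", {}))
        return cls(indir=raw["indir"], outdir=raw["outdir"], params=params)


def _stage(name: str):
    def wrap(fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:  # noqa: BLE001 - tag and re-raise
            raise PipelineError(f"stage '{name}' failed: {exc}") from exc
    return wrap


def analyze_screen(data, params: AnalysisParams = AnalysisParams()) -> dict:
    """Run every applicable analysis stage on in-memory screen tables.

    Returns a dict of result tables keyed by stage plus a ``summary``
    with the screen-level counts. Molecular stages are skipped when the
    corresponding inputs are absent (``expression``, ``site_counts``,
    ``gene_sets``, ``morphology``).
    """
    results: dict = {}

    records = _stage("qc")(kdqc.records_from_table, data.kd_table)
    qc = kdqc.qc_table(records)
    target_map = concordance.build_target_map(qc, params.min_asos_per_target)
    results["qc"] = qc
    results["target_map"] = target_map

    growth_res = _stage("growth")(growth.analyze_growth, data.confluence,
                                  params.fdr_alpha)
    results["growth"] = growth_res

    hits = _stage("hits")(
        concordance.call_lncrna_hits, growth_res, target_map,
        None, params.background_alpha)
    results["hits"] = hits

    rates = dict(zip(growth_res["aso_id"], growth_res["normalized_rate"]))
    mapped_targets = {target_map[a] for a in rates if a in target_map}
    if len(mapped_targets) >= 2:
        results["growth_concordance"] = _stage("growth_concordance")(
            concordance.global_growth_concordance, rates, target_map,
            params.n_perm, params.seed, False)

    summary = {
        "n_asos": int(qc.shape[0]),
        "n_successful_asos": int(qc["success"].sum()),
        "n_targets_assessed": int(hits.shape[0]),
        "n_significant_asos": int(growth_res["significant_inhibition"].sum()),
        "n_hit_lncrnas": int(hits["is_hit"].sum()),
        "growth_concordance_p": results.get("growth_concordance", {}).get("p_value"),
    }

    if data.expression is not None and data.sample_sheet is not None:
        de = _stage("de")(diffexpr.de_screen, data.expression,
                          data.sample_sheet, params.pseudocount)
        results["de"] = de
        deg_sets = {a: s for a, s in de["deg_sets"].items() if a in target_map}
        summary["n_asos_with_degs"] = int(
            sum(1 for s in de["deg_sets"].values() if len(s) >= 10))
        try:
            pairs = _stage("concord")(
                concordance.concordance_table, deg_sets, target_map,
                params.n_perm, params.seed)
            rep = concordance.reproducible_pairs(
                pairs, params.min_common_degs, params.pair_alpha)
            results["pairs"] = pairs
            results["reproducible"] = rep
            summary["n_reproducible_pairs"] = rep["n_pairs"]
            summary["n_reproducible_targets"] = rep["n_targets"]
        except ValueError:
            # too few nontargeting pairs for a background on tiny screens
            results["pairs"] = None
        if data.partner_map:
            aso_target = {r.aso_id: r.target_id for r in records}
            div = _stage("divergent")(
                diffexpr.divergent_partner_response, de["tables"],
                data.partner_map, aso_target)
            results["divergent"] = div
            summary["median_partner_abs_log2fc"] = div["median_abs_log2fc"]

        if data.site_counts is not None:
            tpm = diffexpr.normalize_tpm(data.expression)
            log2 = np.log2(tpm + params.pseudocount)
            fit = _stage("mara")(mara.fit_motif_activities, log2,
                                 data.site_counts, params.ridge_lambda)
            results["mara"] = fit
            aso_of = dict(zip(data.sample_sheet["sample_id"],
                              data.sample_sheet["aso_id"]))
            per_aso = fit.activities.T.groupby(
                [aso_of.get(s, "") for s in fit.activities.columns]).mean().T
            per_aso = per_aso.drop(columns=[""], errors="ignore")
            shared = [a for a in per_aso.columns if a in rates]
            if len(shared) >= 10:
                results["motif_growth"] = _stage("motif_growth")(
                    mara.motif_growth_correlation, per_aso[shared],
                    {a: rates[a] for a in shared})

        if data.gene_sets:
            score_cols = {}
            for aso in de["z"].columns:
                table = _stage("gsea")(
                    enrichment.preranked_gsea, de["z"][aso], data.gene_sets,
                    params.gsea_n_perm, params.seed, 1.0, params.gsea_min_size)
                score_cols[aso] = table.set_index("gene_set")["signed_score"]
            gsea_scores = pd.DataFrame(score_cols)
            results["gsea_scores"] = gsea_scores
            shared = [a for a in gsea_scores.columns if a in rates]
            if len(shared) >= 10:
                results["pathway_growth"] = _stage("pathway_growth")(
                    enrichment.pathway_growth_correlation,
                    gsea_scores[shared], {a: rates[a] for a in shared})

    if data.morphology is not None:
        morph = _stage("morphology")(growth.morphology_effects,
                                     data.morphology, params.fdr_alpha)
        results["morphology"] = morph
        results["morphology_flags"] = growth.eccentricity_shift_flags(
            morph, params.fdr_alpha)
        summary["n_eccentricity_shift_asos"] = int(
            results["morphology_flags"]["eccentricity_shift"].sum())

    results["summary"] = summary
    return results


def load_screen_dir(indir) -> ScreenData:
    """Read the documented screen-directory layout into memory."""
    indir = Path(indir)

    def need(name):
        path = indir / name
        if not path.exists():
            raise FileNotFoundError(f"required input missing: {path}")
        return path

    def maybe(name):
        path = indir / name
        return path if path.exists() else None

    expression = sample_sheet = site_counts = gene_sets = morphology = None
    if maybe("expression.tsv"):
        expression = io.read_tsv(maybe("expression.tsv"), index_col="gene_id")
        sample_sheet = io.read_tsv(need("sample_sheet.tsv"))
    if maybe("site_counts.tsv"):
        site_counts = io.read_tsv(maybe("site_counts.tsv"), index_col="gene_id")
    if maybe("gene_sets.gmt"):
        gene_sets = io.read_gmt(maybe("gene_sets.gmt"))
    if maybe("morphology.tsv"):
        morphology = io.read_tsv(maybe("morphology.tsv"))
    return ScreenData(
        confluence=io.read_tsv(need("confluence.tsv")),
        kd_table=io.read_tsv(need("kd_efficiency.tsv")),
        expression=expression, sample_sheet=sample_sheet,
        site_counts=site_counts, gene_sets=gene_sets, morphology=morphology)


def run_pipeline(config: PipelineConfig) -> dict:
    """Read inputs, run every stage, write all outputs; returns the summary."""
    params = config.params
    data = load_screen_dir(config.indir)
    results = analyze_screen(data, params)

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    meta = {"config_hash": io.config_hash(dataclasses.asdict(params)),
            "seed": params.seed, "lncscreen_version": __version__}

    io.write_tsv(results["qc"], outdir / "kd_qc.tsv", meta)
    io.write_tsv(results["growth"], outdir / "growth_results.tsv", meta)
    io.write_tsv(results["hits"], outdir / "lncrna_hits.tsv", meta)
    if results.get("pairs") is not None:
        io.write_tsv(results["pairs"], outdir / "pair_concordance.tsv", meta)
    if "de" in results:
        io.write_tsv(results["de"]["log2fc"].rename_axis("gene_id").reset_index(),
                     outdir / "log2fc_matrix.tsv", meta)
        io.write_tsv(results["de"]["z"].rename_axis("gene_id").reset_index(),
                     outdir / "z_matrix.tsv", meta)
    if "mara" in results:
        io.write_tsv(results["mara"].z.rename_axis("motif").reset_index(),
                     outdir / "motif_activity_z.tsv", meta)
    if "gsea_scores" in results:
        io.write_tsv(results["gsea_scores"].rename_axis("gene_set").reset_index(),
                     outdir / "gsea_signed_scores.tsv", meta)
    if "morphology" in results:
        io.write_tsv(results["morphology"], outdir / "morphology_effects.tsv", meta)

    summary = dict(results["summary"])
    summary["run"] = {
        "seed": params.seed,
        "n_perm": params.n_perm,
        "config_hash": meta["config_hash"],
        "lncscreen_version": __version__,
        "python": platform.python_version(),
    }
    (outdir / "summary.json").write_text(json.dumps(summary, indent=1,
                                                    sort_keys=True, default=str))
    return summary
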