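"""Motif activities (MARA) and preranked GSEA, correlated with growth.

MARA models log2 expression as promoter motif site-counts times unknown
per-sample motif activities, fitted by ridge regression (lambda by GCV);
the reported statistic is Z = activity / SE. Preranked GSEA scores each
ASO's gene ranking (experiment-wide Z) against gene sets; its per-set
summary is -log10(p) x sign(NES). Correlating either readout with the
normalized growth rate links molecular programmes to the cellular
phenotype.
"""

import numpy as np
import pandas as pd

from lncscreen import (ScreenConfig, analyze_growth, de_screen,
                       fit_motif_activities, motif_growth_correlation,
                       normalize_tpm, preranked_gsea, simulate_screen)

screen = simulate_screen(ScreenConfig(seed=41, n_targets=20, n_genes=500,
                                      n_motifs=15, n_gene_sets=12,
                                      motif_driven_expression=True,
                                      frac_true_molecular_hits=0.2))

log2 = np.log2(normalize_tpm(screen.expression) + 1.0)
fit = fit_motif_activities(log2, screen.site_counts)
print(f"MARA: {fit.z.shape[0]} motifs x {fit.z.shape[1]} samples, "
      f"ridge lambda {fit.ridge_lambda:g} (GCV)")
planted = screen.truth.motif_activities
planted = planted.sub(planted.mean(axis=1), axis=0)
r = np.corrcoef(planted.to_numpy().ravel(),
                fit.activities.to_numpy().ravel())[0, 1]
print(f"correlation with planted activities: r = {r:.3f}")

growth = analyze_growth(screen.confluence)
rates = dict(zip(growth["aso_id"], growth["normalized_rate"]))
aso_of = dict(zip(screen.sample_sheet["sample_id"],
                  screen.sample_sheet["aso_id"]))
per_aso = fit.activities.T.groupby(
    [aso_of.get(s, "") for s in fit.activities.columns]).mean().T
per_aso = per_aso.drop(columns=[""], errors="ignore")
corr = motif_growth_correlation(per_aso, rates)
top = corr.reindex(corr["r"].abs().sort_values(ascending=False).index).iloc[0]
print(f"motif most correlated with growth: {top['motif']} "
      f"(r = {top['r']:.2f}, FDR = {top['fdr']:.2g})")

de = de_screen(screen.expression, screen.sample_sheet)
aso = de["z"].columns[0]
gsea = preranked_gsea(de["z"][aso], screen.gene_sets, n_perm=1000, seed=2)
best = gsea.reindex(gsea["signed_score"].abs()
                    .sort_values(ascending=False).index).iloc[0]
print(f"{aso}: strongest gene set {best['gene_set']} "
      f"(ES {best['es']:.2f}, signed score {best['signed_score']:.2f})")
# positive signed score: set enriched at the top of the ranking;
# negative: enriched among down-regulated genes
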