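"""End-to-end: write a screen to disk, run the whole pipeline, read results.

Equivalent to the CLI:
    lncscreen simulate --out screen/ --seed 3 --n-targets 15 --n-genes 400
    lncscreen run --indir screen/ --outdir results/ --seed 3
"""

import json
import tempfile
from pathlib import Path

from lncscreen import (AnalysisParams, PipelineConfig, ScreenConfig,
                       run_pipeline, simulate_screen)

workdir = Path(tempfile.mkdtemp())
screen_dir, out_dir = workdir / "screen", workdir / "results"

simulate_screen(ScreenConfig(seed=3, n_targets=15, n_genes=400,
                             n_gene_sets=10,
                             frac_true_growth_hits=0.2,
                             frac_true_molecular_hits=0.2)).write(screen_dir)

summary = run_pipeline(PipelineConfig(
    indir=str(screen_dir), outdir=str(out_dir),
    params=AnalysisParams(n_perm=2000, gsea_n_perm=200, seed=3)))

print(json.dumps(summary, indent=1, default=str))
print("\noutputs:", sorted(p.name for p in out_dir.iterdir()))
# summary.json holds the screen-level counts; every TSV carries a header
# with the configuration hash and seed so runs are reproducible.
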