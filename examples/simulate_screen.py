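"""Generate a synthetic ASO knockdown screen and look at what was planted.

The simulator emulates the screen design: plates with six non-targeting
NC_A control wells, ASOs transfected in duplicate and imaged every 3 h
for 48 h, per-ASO knockdown efficiencies measured with three qPCR primer
pairs, and CAGE-style expression libraries with run-matched controls.
"""

from lncscreen import ScreenConfig, simulate_screen

config = ScreenConfig(
    n_targets=30,                 # lncRNAs targeted
    asos_per_target=5,            # non-overlapping ASOs per lncRNA
    frac_true_growth_hits=0.10,   # fraction with a real growth phenotype
    frac_true_molecular_hits=0.10,
    growth_effect_size=0.4,       # relative slope reduction at full knockdown
    seed=1,
)
screen = simulate_screen(config)

print(f"wells imaged:        {screen.confluence['well'].nunique()}")
print(f"expression libraries: {screen.expression.shape[1]} "
      f"({screen.expression.shape[0]} genes)")
n_success = sum(screen.truth.kd_success.values())
print(f"ASOs passing knockdown QC: {n_success}/{len(screen.truth.kd_success)}")
print(f"planted growth-hit lncRNAs: {sorted(screen.truth.growth_hits)}")
print(f"planted molecular-hit lncRNAs: {sorted(screen.truth.molecular_hits)}")

# The tables can be written to a directory in the documented TSV/GMT layout:
#   screen.write("my_screen/")
# and truth.json keeps the ground truth for recovery analyses.
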