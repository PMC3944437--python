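"""Spectral-level target-decoy FDR thresholding of a PSM table.

Simulates one small experiment, pools one tumor type's PSM tables, and
chooses a score threshold per (run, charge state) so that the estimated
false-discovery rate - decoys over targets above the cutoff - stays at or
below 1.6%.
"""

import pandas as pd

from xenomatrisome import compute_spectral_thresholds, filter_psms
from xenomatrisome.filtering import filtering_report, restrict_charges
from xenomatrisome.simulate import SimulationConfig, simulate_psm_tables

cfg = SimulationConfig(n_proteins=40)
tables, truth = simulate_psm_tables(cfg, seed=7)

pooled = pd.concat([tables[("A", "r1")], tables[("A", "r2")]], ignore_index=True)
pooled = restrict_charges(pooled)  # only charges 2-4 are analyzable
thresholds = compute_spectral_thresholds(pooled, target_fdr=0.016)
retained = filter_psms(pooled, thresholds)

print(filtering_report(pooled, thresholds).to_string(index=False))
print(
    f"\nretained {len(retained)} of {len(pooled)} PSMs; "
    f"decoy fraction among retained: {retained['is_decoy'].mean():.4f}"
)
print(
    "each row shows one LC-MS/MS run and charge state: the chosen score"
    "\nthreshold and the decoy/target ratio it achieves (the estimated FDR)."
)
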