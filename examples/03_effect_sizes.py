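"""Run the full in-memory pipeline and score treatment response.

Simulates a control vs FOLFOX experiment at the published LARC12 arm
medians, pushes the rendered images through segmentation, day-0/day-4
tracking and measurement, and prints the per-arm summaries with the
modified Glass's delta effect sizes.
"""

from organoidtrack.pipeline import run_experiment
from organoidtrack.presets import RECOVERY_SEG_PARAMS, reference_cohort

spec = reference_cohort("LARC12", n_per_arm=200, seed=3, treatments=["FOLFOX"])
result = run_experiment(spec, seg_params=RECOVERY_SEG_PARAMS)

cols = [
    "treatment", "modality", "median_control", "median_treatment",
    "sd_control", "mglass_delta", "p_value",
]
print(result.effects[cols].round(3).to_string(index=False))
print(
    "\nmGlass's delta = (control median - treatment median) / control SD."
    "\nThe generative conditions put the diameter effect at 1.32 and the"
    "\nORR effect at 0.47; a single n = 200/arm experiment estimates them"
    "\nwith a spread of roughly +/- 0.3 and 0.15 respectively, and the"
    "\nMann-Whitney p-value for the diameter contrast is far below 0.05."
)
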