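"""Prediction accuracy across a 15-patient virtual cohort.

Simulates a study-sized cohort with the default inter-individual
variability, assay noise and post-reversal inflation, then prints the
per-condition agreement table: mean predicted and measured plasma
concentrations, MDPE (bias), MDAPE (inaccuracy), the through-origin
regression slope and the correlation — the layout of a clinical
predicted-vs-measured comparison at the four protocol sampling points.
"""

from rocoloop.trial import run_cohort

cohort = run_cohort(15, master_seed=1)

cols = ["condition", "n", "mean_predicted", "mean_measured",
        "mdpe_pct", "mdape_pct", "origin_slope", "pearson_r"]
print(cohort.metrics[cols].round(3).to_string(index=False))

print(f"\nCe spread (max/min) at the %T1 = 3% recovery event: "
      f"{cohort.ce_spread_fold:.1f}-fold across the cohort — the few-fold "
      "inter-individual difference that motivates individualised dosing.")

incomplete = cohort.patients["case_flags"].str.contains("incomplete_stable_window")
print(f"cases without a 15-min stable window: {incomplete.sum()}/15 "
      "(such samples are missing, mirroring clinically excluded samples)")

print("\nBefore reversal the slope is near 1 (prediction tracks measurement); "
      "after sugammadex the measured total drug exceeds the free-drug "
      "prediction, so MDPE and the slope rise well above zero and one.")
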