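"""Simulate a two-group teratology study and run the full analysis.

Generates a control group (20 dams) and an exposed group (6 dams) whose
right-horn feti are 45% growth-restricted at four of five positions, then
runs inclusion filtering, positional collapse, outlier screening, the
traditional litter-mean t-test, and the positional Sidak contrasts.
"""

from hornwise import analyze_dataset, scenario_gd4_like, simulate_study

dataset = simulate_study(scenario_gd4_like(), seed=42)
report = analyze_dataset(dataset)

print(report.summary_text())
print()
contrasts = report.contrast_frame()
nfw = contrasts[contrasts["endpoint"] == "normalized_fetal_weight"]
sig = nfw[nfw["sidak_p"] < 0.05]
print(f"{len(sig)} of {len(nfw)} normalized-fetal-weight contrasts are "
      "significant after Sidak adjustment —")
print("the restriction is localized to specific uterine positions, "
      "not spread uniformly over the litter.")
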