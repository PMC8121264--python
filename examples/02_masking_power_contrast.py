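"""Why litter means hide localized growth restriction.

A 45% weight reduction confined to the right-horn middle positions barely
moves the whole-litter mean, so the traditional t-test often misses it;
the position-resolved Sidak contrast almost always finds it. 100 Monte
Carlo replicates take about two seconds.
"""

from hornwise import power_experiment, scenario_rmd_masked

result = power_experiment(scenario_rmd_masked(), n_replicates=100, seed=7)

rates = result.rejections.set_index(["method", "group", "horn_side", "position"])[
    "rejection_rate"
]
trad = rates[("traditional", "gd4", "", "")]
posn = rates[("positional", "gd4", "R", "MD")]
pct = result.traditional_percent_decrease["gd4"]
ratio = result.cell_mean_ratio[("gd4", "R", "MD")]

print(f"litter-mean percent decrease:            {pct:.1f}%")
print(f"right-middle normalized mean ratio:      {ratio:.3f} "
      f"(a {100 * (1 - ratio):.0f}% localized reduction)")
print(f"traditional t-test detection rate:       {trad:.2f}")
print(f"positional right-middle detection rate:  {posn:.2f}")
print()
print("A <10% change in the litter mean conceals a >40% positional deficit;")
print("only the positional analysis detects it reliably.")
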