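"""Iterative two-sided Grubbs screening of a positional cell.

Each group x side x position cell is screened separately before the ANOVA;
one point may be removed per pass until nothing exceeds the critical value.
"""

from hornwise import grubbs_critical, grubbs_screen

cell = [0.058, 0.061, 0.059, 0.062, 0.060, 0.057, 0.104]  # one aberrant value
kept, passes = grubbs_screen(cell, alpha=0.05)

print(f"critical value for n={len(cell)} at alpha=0.05: "
      f"{grubbs_critical(len(cell), 0.05):.3f}")
removed = [v for v in cell if v not in kept]
for i, p in enumerate(passes, 1):
    flagged = "none" if p.outlier_index is None else f"{removed[i - 1]:.3f}"
    print(f"pass {i}: G = {p.g_statistic:.3f} (critical {p.g_critical:.3f}), "
          f"removed: {flagged}")
print(f"kept {len(kept)} of {len(cell)} values: {kept}")
print("The 0.104 normalized weight is flagged on the first pass; the")
print("remaining cell is homogeneous so screening stops.")
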