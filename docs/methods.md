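# Methods

This note documents the statistical model implemented by `hornwise`, the
defaults of the synthetic-data generator, the numerical choices, and the
limitations. All quantitative statements here are computed by the test
suite (`tests/`) or by `scripts/acceptance.py`.

## Positional model

Each fetus is indexed 1..n from the ovarian end of its uterine horn. Horns
with n >= 5 map to five positions:

| position | indices |
|---|---|
| OE (ovarian end) | 1 |
| NOE (next to ovarian end) | 2 |
| MD (middle) | 3 .. n-2, averaged into one observation |
| NCE (next to cervical end) | n-1 |
| CE (cervical end) | n |

Dams with total litter size < 5 are excluded entirely; horns with < 5 feti
are excluded from the positional analysis (the dam's other horn, if large
enough, is kept). The traditional litter-mean analysis uses all feti of
every dam with litter >= 5, including feti in small horns, because that is
how litter means are conventionally formed.

## Endpoints

- **Normalized fetal weight** = fetal weight / (maternal GD20 weight /
  number of feti in the horn) = `fw * n / M`. This scales out maternal size
  and horn crowding; in simulated control data it sits near 0.06 g
  (`control_normalized_rmd_mean` in the acceptance output).
- **Raw placental weight** (g).
- **Placental efficiency** = fetal weight / placental weight (typically
  5–6 in controls).

Percent decrease for the traditional table is
`max(0, round(100 * (control - exposed) / control))` with half-away-from-zero
rounding, so a small increase reports as 0.

## Outlier screening

Each group x side x position x endpoint cell is screened with an iterative
two-sided Grubbs test at alpha = 0.05: compute
`G = max|x_i - mean| / sd` (sd with ddof = 1), compare against

```
G_crit = ((n-1)/sqrt(n)) * sqrt(t^2 / (n-2+t^2)),  t = t-quantile(1 - alpha/(2n), df = n-2)
```

remove the most extreme point if `G > G_crit`, and repeat while n >= 3.
`grubbs_critical(10, 0.05) = 2.290`, matching published tables; the
single-step false-positive rate on clean normal samples of 10 is 0.05
within Monte Carlo error (10,000 replicates in both the test suite and the
acceptance script). Constant cells (sd = 0) are never flagged.

## Inference

Two Type-III two-way ANOVA layers are run per endpoint on the screened
positional observations:

1. **Within group:** side x position, testing laterality and positional
   structure inside each group; pairwise R-vs-L contrasts at each position.
2. **Versus control:** group x position per side for each exposed group;
   pairwise exposed-vs-control contrasts at each position.

Type-III sums of squares are computed by nested least-squares model
comparison under sum-to-zero factor coding; the test suite verifies
equality with the textbook balanced decomposition (tolerance 1e-9) and
with `statsmodels` sum-contrast Type-III tables on unbalanced designs
(tolerance 1e-8). ANOVA requires every cell occupied and at least one
residual degree of freedom; otherwise that analysis is skipped with a
warning (the pipeline degrades gracefully on tiny studies).

Pairwise contrasts use the pooled ANOVA residual mean square and its
degrees of freedom, with Sidak adjustment over the m = 5 positions:
`p_adj = 1 - (1-p)^m` (`sidak_adjust(0.01, 5) = 0.049010`). At a fixed
position the cell entries come from distinct dams, so each contrast is an
independent-samples comparison; correlation across positions within a dam
makes the 5-contrast family conservative. Null calibration (no injected
effects, 20 control + 7 exposed dams) gives a per-family rejection rate
comfortably below 0.05 (1,000 replicates in the test suite, 300 in the
acceptance script).

The traditional analysis is reported alongside: dam means, group
mean ± SEM, pooled two-sample Student's t-test, percent decrease.

## Synthetic-data generator

Fetal weight is generated multiplicatively with additive noise:

```
fw = max(baseline * horn_mult[side] * pos_mult[side, pos] * (1 - reduction[group, side, pos])
         + dam_shift + noise,  0.5)
```

Defaults and rationale:

| parameter | default | rationale |
|---|---|---|
| `baseline_fetal_mean_g` | 2.62 | typical GD20 rat control fetal weight |
| `horn_multipliers` | R 1.02, L 0.98 | mild laterality in horn perfusion |
| `position_multipliers` | per (side, position), 0.92–1.08 | middle positions run heavier than the ends; right horn slightly heavier |
| `dam_effect_sd_g` | 0.15 | dam-level random intercept (litter effect); reproduces a dam-mean SD of ~0.18 g, i.e. SEM ~0.04 g at n = 20 dams, typical of control tables |
| `fetal_noise_sd_g` | 0.15 | within-litter fetal weight scatter |
| `maternal_gd20_weight_g` | N(330, 20), floored at total fetal + 50 | term dam weight |
| `litter_sizes` | uniform on {4..8} per horn | includes sub-threshold horns so inclusion rules are exercised |
| `placental_weight_g` | N(0.52, 0.05), min 0.05 | control placental weight; efficiency ≈ 5 |
| `fetal_placental_correlation` | 0.0 | optional shared-noise knob |
| truncation | fetal >= 0.5 g | weights below ~0.5 g would be resorptions, not weighed feti |

Effects are configured per (group, side, position) as fractional
reductions in [0, 1) of the cell mean. The generator recovers configured
effects: with a 45% right-middle reduction, the reduction re-estimated
from raw cell means over replicates is within 3 Monte Carlo standard
errors of 0.45 (200 replicates in the tests; seed-1 acceptance run: 0.4527
with SE 0.0034 at 100 replicates).

Two packaged scenarios:

- `scenario_gd4_like()` — 45% reduction at four of five right-horn
  positions in a 20-control / 6-exposed design (early-gestation insult to
  one horn).
- `scenario_rmd_masked()` — the same design with the reduction confined to
  the right middle position. This is the headline masking demonstration:
  the litter mean drops < 10% (not reliably significant by t-test) while
  normalized right-middle means differ by > 40% and the positional Sidak
  contrast detects the effect in essentially every replicate (500
  replicates in the tests, 200 in the acceptance script).

What the generator does **not** emulate: resorptions/post-implantation
loss, fetal sex, gestational-day variation, between-study baseline drift,
litter-size dependence on treatment, or non-normal weight distributions.

## Numerical choices

- CSV reading uses pandas `float_precision="round_trip"` so a
  write/read cycle is bit-exact; same-seed simulations serialize to
  byte-identical files.
- Least squares via `numpy.linalg.lstsq`; Sidak via
  `-expm1(m * log1p(-p))` clamped to `[p, 1]` for monotonicity at the
  boundaries.
- Student-t tail probabilities from `scipy.stats`; test oracles
  re-derive t-quantiles by direct numerical integration of the density
  (closed forms at df = 1, 2 where quadrature converges slowly).
- All Monte Carlo uses `numpy.random.default_rng` with explicit seeds;
  per-replicate child seeds are drawn once up front so results are
  reproducible and order-independent.

## Problem sizes and runtimes

A single simulated study is ~26 dams / ~300 feti; one full pipeline run
takes ~20 ms. The test suite (including 10,000-replicate Grubbs and Sidak
calibrations, a 1,000-replicate null calibration and a 500-replicate power
experiment) runs in a few minutes; `scripts/acceptance.py` uses smaller
replicate counts (300 null, 200 headline, 100 recovery) and finishes in
about a minute.

## Limitations

- Positional observations from the two horns of one dam are treated as
  independent in the ANOVA; the dam-level random effect is not modeled as
  such (no mixed model), which the null calibration shows is conservative
  for the Sidak families but is still an approximation.
- The MD position averages a variable number of feti, so its variance is
  litter-size dependent; the homoscedastic ANOVA ignores this.
- Grubbs screening assumes approximate normality within cells and is run
  per endpoint, so a fetus can be removed for one endpoint and kept for
  another.
- The five-position map requires horns of >= 5 feti; information in
  smaller horns is used only by the traditional analysis.
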