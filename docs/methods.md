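# Methods

## Effect sizes

Each observation contributes a log response ratio `lnRR = ln(X_T/X_C)` with
sampling variance `v = S_T²/(n_T X_T²) + S_C²/(n_C X_C²)` (delta method on
the log ratio, independent arms). Both arm means must be positive; rows with
non-positive means are rejected at ingestion with a logged reason rather
than offset, since no defensible offset exists for a ratio of contents.

Dispersion harmonization precedes the variance: `SD` passes through, `SE`
becomes `SE·√n`, and arms with only a 95% CI or nothing get `SD = mean/10`.
That imputation is the convention of the syntheses this package targets; it
is deliberately the default even though deriving SD from the CI half-width
(`SD = hw·√n/1.96`, available as `ci95_rule="half_width"`) is statistically
preferable, because fidelity to the established workflow matters when
auditing one. Every imputation is counted in the run manifest.

If both SDs are zero the sampling variance is zero and an inverse-variance
weight would be infinite; such variances are floored at 1e-10 (configurable)
and logged. Per-observation classification uses the normal interval
`lnRR ± 1.96·√v`: positive if the interval lies above zero, negative if
below, neutral otherwise.

## Pooling and heterogeneity

Fixed-effects weights are `1/v_i`; random-effects weights `1/(v_i+τ²)`. The
pooled estimate is the weighted mean, its standard error `1/√Σw`, and the
95% CI the Wald interval (no Knapp–Hartung adjustment, matching the default
of the standard reference implementation; the z critical value is a
parameter). Cochran's Q is computed with fixed-effect weights, referred to a
chi-square with `k−1` df, and summarized as `I² = max(0,(Q−df)/Q)·100`.

τ² estimators:

* **DerSimonian–Laird** (moment): `τ² = max(0, (Q−df)/C)` with
  `C = Σw − Σw²/Σw`.
* **REML** (default): fixed-point iteration on the restricted-likelihood
  estimating equation
  `τ² ← Σw²[(y−μ̂)² − v]/Σw² + 1/Σw`, `w = 1/(v+τ²)`,
  started at the DL value, truncated at zero, tolerance 1e-8 on τ², at most
  100 iterations, falling back to DL with a warning if not converged. Both
  estimators agree with R `metafor` to ~1e-8 on the cross-check fixture.

Model-selection mode `auto` pools under random effects when `I² > 50%` and
fixed effects otherwise; at exactly 50% the simpler fixed-effects model is
chosen (the rule is stated in the literature only for strict inequalities).
`random` and `fixed` force a model. Groups with a single observation are
reported unpooled with their own sampling CI and flagged; groups below the
configurable minimum size (default 2) are flagged `low_k` but never hidden.
Observations sharing a source study are pooled as independent — the
convention of the target syntheses — with an optional study-mean aggregation
only in the regression pairing (below).

## Subgroups

Nine stratifications are supported: organ; compound class; compound×organ;
inoculum mode×organ; fungal order, family, genus; genus×organ; and
physiological variable. Effects lacking a grouping key (e.g. consortium
inocula under a taxonomy grouping, since a mixture has no single genus) are
excluded from that table and counted in the manifest, so every grouping
reconciles: pooled k's + excluded = analyzed observations.

## Ingredient–physiology association

Ingredient and physiological effects are paired within a study: each
ingredient lnRR is matched to the study's lnRR for the factor (averaged if
the study reports that factor more than once). The pairing rule is the main
modelling choice here — published syntheses rarely state theirs — so a
study-mean alternative (one pair per study, ingredient lnRRs averaged) is
implemented alongside the default. Ordinary least squares of ingredient
lnRR on factor lnRR (scipy's `linregress`) gives slope, intercept,
r² (= squared Pearson correlation) and a two-sided p for the slope; at
least 3 pairs and a non-degenerate regressor are required. Regression is on
the lnRR scale: the percent transform is monotone but nonlinear and would
distort a linear relationship.

## The synthetic-data generator

The generator emulates a multi-study extraction database, not any
particular published one. Defaults are the conditions of a typical
synthesis at this scale:

* 28 studies, 233 ingredient observations (2–15 per study); each study has
  one species, one organ, one inoculum mode, one genus when single.
* Subgroup truths: compound-class base lnRRs (flavonoids 0.52, terpenoids
  0.43, quinones 0.22, organic acids 0.17, phenols 0.12, alkaloids −0.05,
  other −0.08) plus additive shifts for organ (±0.06), a strong-responder
  genus (*Rhizophagus* +0.15) and consortium inocula (−0.03). With the
  default compound mix this puts the overall mean truth near lnRR 0.25
  (≈ +28%).
* Between-observation heterogeneity: observation truths are
  `Normal(truth, τ²)` with τ = 0.2.
* Within-arm noise: control means are log-normal (median 10, log-SD 1,
  guaranteeing positivity); treatment mean = control mean × e^θ; arm CVs
  uniform on 5–20%; replicate counts uniform on 3–6; observed means are
  `Normal(μ, SD²/n)` and observed SDs carry the chi-square noise of a
  sample SD at n−1 df.
* Dispersion reporting: SD 50%, SE 35%, CI-only 10%, none 5% — the mixture
  of reporting styles an extractor actually meets.
* Physiological effects: per study, each factor is reported with
  probability 0.5; its truth is a linear function of the study's mean
  ingredient truth plus Normal(0, 0.15) noise, with slopes/intercepts
  placing factor means near typical observed responses (carotenoids ≈ +6%,
  chlorophylls ≈ +30/40%, conductance and photosynthesis ≈ +80/95%,
  carbohydrates ≈ −30%).

What passing tests on this generator do **not** show about real data: real
extraction tables have correlated observations within studies (shared
controls, multiple harvests), non-normal and occasionally misreported
dispersions, and publication bias — none of which are simulated. The
`simulate_paired_effects` helper draws factor effects with spread SD 0.5
(the span of physiological responses seen across inoculation studies) and
a configurable true slope/noise, for testing slope recovery directly; in
the full generator the per-observation pairing dilutes the study-level
factor signal with within-study compound variation, so r² values there are
small by construction — a realistic property, and the reason published r²
values cannot be validated without knowing the original pairing rule.

## Calibration experiments

`mycometa recover` (and the acceptance script) run five experiments:

1. **Q-test size**: 1000 homogeneous meta-analyses (k=30) drawn under the
   model's own assumptions — normal effects with *known* variances of
   realistic magnitude (`2·cv²/n`, cv 5–20%, n 3–6). Rejection at the 1%
   level lands in 0.5–2% and median I² at 0. With *estimated* variances at
   n=3–6 (2–5 df for each SD) Q is markedly anti-conservative — a
   well-known small-sample property worth remembering when reading Q tests
   on real 3-replicate data; the experiment therefore tests the statistic
   where its reference distribution is defined.
2. **Coverage**: 500 meta-analyses at the full scale (k=233, μ=0.24,
   τ=0.2, full arm-level noise); the DL random-effects 95% CI covers μ
   ~94–95% of the time (Wald intervals are slightly anti-conservative).
3. **Type-I error**: same design with μ=0, 1000 replicates; the
   significance flag fires ~5% of the time.
4. **Subgroup ordering**: four compound classes at truths 0.52/0.43/0.22/
   0.12, k=30 each, τ=0.2, 200 replicates; the pooled ranking reproduces
   the true ordering ≥90% of the time.
5. **Regression recovery**: true slope 0.8, noise SD 0.1, 50 pairs, 200
   replicates; the fitted slope is within ±0.1 with r² > 0.8 in ≈100% of
   replicates.

Experiment sizes were chosen to give stable rates while keeping a full run
in seconds on one CPU.

## Numerical choices and edge cases

* Percent transform default `(e^x−1)·100`; `x·100` always reported
  alongside, since published syntheses rarely state which they print.
* REML: tolerance 1e-8, max 100 iterations, DL fallback.
* Boundary `I² = 50%` → fixed effects; `Q = 0` → `I² = 0`.
* Ties and ordering: subgroup tables are sorted by label; input order never
  affects results beyond floating-point round-off (property-tested).
* Duplicate observations (same study, same compound, several harvests or
  doses) are preserved, not de-duplicated; `study_id` is carried through so
  users can aggregate if they prefer.
* A species whose pooled CI fails to exclude zero above is labelled
  "Ineffective" even if individual studies were beneficial; per-study
  labels are reported alongside the pooled verdict for exactly this case.

## Limitations

No publication-bias diagnostics (funnel plots, trim-and-fill), no
small-sample lnRR bias correction, no multilevel handling of within-study
correlation, no Knapp–Hartung intervals by default. These are deliberate
scope boundaries, not oversights: the package reproduces and audits a
specific, widely used analysis workflow, and each of these extensions would
change its results rather than check them.
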