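# Methods

## Titration model

A spot is one drop of volume `v` (default 5 µL) of the `10^-k` dilution of
a phage stock on a bacterial lawn. If the stock concentration is `T`
PFU/mL, the expected plaque count is `λ = T · 10^-k · v_mL`, and the titer
estimate from a counted spot is `c / v_mL · 10^k`. The estimate refers to
the undiluted suspension in the well the drop was taken from; the dilution
exponent is a pure decade shift, so titers are linear in counts.

### Plate-reading rules

For each phage–strain series the pipeline reads exactly one dilution:

1. **Anomaly resolution** per dilution triplicate. A coalesced (merged)
   pair of adjacent drops carries the combined count of the fused spot on
   both partner records; each partner contributes half of it (fractions are
   kept — rounding would bias the linear titer arithmetic). A missing drop
   (`no_drop`) contributes nothing and reduces the replicate count. An
   intact lawn contributes a count of zero; confluent lysis has no usable
   count.
2. **Dilution selection.** A dilution qualifies when it has no confluent
   spot, at least two usable replicates, and every effective count within
   `[min_countable, max_countable]` (defaults 1 and 50 — the ceiling above
   which individual plaques can no longer be distinguished). Among
   qualifiers the one with the largest mean count is read: it carries the
   most counting information, consistent with the observed precision law
   (below). Ties break toward the lower exponent, deterministically.
3. **Exclusions.** All-blank series are `no_activity`. Series showing
   clearance but never countable individual plaques are `excluded_no_pfu` —
   the lysis-from-without / abortive-infection pattern that must not be
   scored as productive activity. Series still above the countable ceiling
   at the highest tested dilution (or never retaining two usable
   replicates) are `excluded_unreliable_count`. Excluded results carry no
   numeric fields; a single surviving replicate is never reported as a
   titer because its CV is undefined.
4. **Aggregation.** Replicate titers give the arithmetic mean, the sample
   SD (n−1 denominator — this is the convention that reproduces the
   packaged validation data), and `CV = 100·s/x̄`. `precision_acceptable`
   flags CVs below `cv_acceptable_percent` (default 15%); the companion
   guideline `min_reliable_pfu = 15` marks the count above which that
   precision is typically attained. The count guideline gates a flag, not
   an exclusion.

## Potency

`EOP = T_test / T_reference`, computed from mean titers of the same
dataset. Bands are half-open so every positive EOP is classifiable:
`[0.1, ∞)` highly virulent (EOP > 1 — better plaquing on the test strain —
stays in this band), `[0.001, 0.1)` moderately virulent, `(0, 0.001)`
weakly or avirulent. The reference cell is set to exactly 1. A phage whose
reference-host titration is missing or not quantified yields a
`not_evaluable` column and a logged warning rather than an error; the
phagogram builder requires an explicit phage → reference-host mapping and
does not guess one (relevant for cocktails, which have no natural single
host).

## Method agreement

Paired titers (reference = manual, evaluated = automated) are analysed on
the ratio scale: `ℓ_i = log10(evaluated_i / reference_i)`.

- **Bland–Altman (ratio method):** bias `10^mean(ℓ)`, 95% limits of
  agreement `10^(mean ± 1.96·sd(ℓ))`, bias CI from the t distribution with
  n−1 df on the log scale (the CI method is a package choice; the limits
  use the standard 1.96 convention).
- **Lin's CCC:** `2·s_xy / (s_x² + s_y² + (x̄−ȳ)²)` with population
  moments; CI by Fisher z-transform with Lin's (1989) variance, clamped to
  a degenerate interval at |ccc| = 1. Computed on log10 titers by default —
  titers spanning several decades make raw-scale CCC a function of the
  largest tube almost alone; a raw-scale option exists. On the packaged
  data both conventions give ≈ 0.99; the originally reported 0.86 for this
  dataset is not recoverable under raw, log10, or per-tube-mean
  conventions, and is therefore documented rather than asserted anywhere.
- **CV comparison:** per-tube CVs of the two methods are screened with a
  one-sample Kolmogorov–Smirnov test against a normal with sample-estimated
  moments (anti-conservative at small n; the gate is reported, never
  silent). Both groups passing → equal-variance Student's t (Welch
  optional); otherwise Mann–Whitney. The branch, statistic, and exact p are
  always reported.

## Simulator

The generator emulates the automated assay, not an idealized one:

- **Serial dilution:** `c_0 = stock`, `c_k = c_{k−1}/10 · ε_k` with `ε_k`
  lognormal, median 1, CV `pipetting_cv` (default 0.05). Multiplicative,
  compounding error matches the ratio-scale analysis applied downstream.
- **Spotting:** with probability `p_no_drop` (default 0.0093) the drop
  never lands. Otherwise the realized volume is lognormal around the
  nominal 5 µL (CV 0.02) and the count is Poisson(`c · v_mL`). Counts of 0
  read as intact lawn; counts above `max_countable` (50) as confluent. The
  emitted record carries the *nominal* volume — an analyst never knows the
  jitter — so volume noise appears as extra count dispersion, as on a real
  plate.
- **Coalescence:** adjacent replicate pairs merge with probability
  `p_coalescence` (default 0.0197) each, examined in index order; a spot
  merges at most once, and merges never cross phages or dilutions. Both
  partners carry the combined count; totals are conserved.
- **Reproducibility:** each (strain, phage) series draws from its own
  `SeedSequence([seed, strain_idx, phage_idx])` child stream, so tables are
  byte-identical per seed and independent of evaluation order.
- **Study panel:** `study_panel_config` mirrors a realistic screening
  campaign — 10 phages plus a cocktail against 126 strains (33,264 spots),
  the first 10 strains being the phages' reference hosts, sparse extra
  positives up to 151 interactions in total, host stocks log-uniform over
  `10^8.3–10^10` PFU/mL and non-host positives carrying a log-uniform
  efficiency penalty down to `10^-4.5`.

**Anomaly-rate estimation.** The no-drop rate is events per attempted
spot. The coalescence probability is estimated on the subset of adjacent
pairs whose examination is decided by drop placement alone (the first
status-eligible pair of each replicate set, or a later pair when every
earlier one had a missing or confluent drop). Pairs that are examined only
because an earlier pair happened not to merge are excluded: including them
makes the number of trials depend on the outcomes and the exact binomial
interval demonstrably undercovers (measured 94.6% over 500 simulated
screens, vs 95.4% for the restricted estimator). On the retained trials
merging is i.i.d. Bernoulli, so Clopper–Pearson intervals are exact.

**Precision law.** With noise and anomalies off, triplicate counts at
expected count `N` are pure Poisson, and the triplicate CV concentrates at
`100/√N %`. The summary used is the root-mean-square CV: since
`E[s²] = λ`, the RMS is the unbiased measure, whereas the plain mean of
n = 3 sample CVs sits ~11% low (the c4 ≈ 0.886 small-sample bias of the
sample SD). The mean CV per count bin is still used for the qualitative
trend check (strict decrease across bins from ~3 to ~40 PFU per spot),
matching how bench data are usually tabulated. This law is checked with
the countability ceiling lifted; on real plates counts near 50 are
right-truncated by confluence, which the law deliberately ignores.

## Throughput arithmetic

One plate holds one strain's lawn spotted with up to 4 phages × 8
dilutions × 3 replicates (96 spots); a run serves up to 10 plates (960
spots); each tip aspirates `3·v·n + 10` µL for `n` plates. Campaign totals
count the factorial spots exactly (a partially filled last plate per
strain is still one plate) and runs as `ceil(total plates / 10)`.

## What the synthetic data do and do not show

The generator reproduces the count statistics, anomaly pattern, and the
design geometry of a robotic screen, so passing tests demonstrate that the
pipeline's arithmetic, filtering, and estimators behave correctly under
the stated generative model. It does not model plaque morphology, drop
spreading with agar dryness, operator reading variability, triple merges,
phage-resistant outgrowth inside cleared spots, or inter-run drift; results
on real plates additionally depend on those factors. Simulated problem
sizes in the test suite (a 33,264-spot screen per seed, 100 seeds for
coverage checks, 2,000 triplicates per precision point) were chosen to make
Monte-Carlo error comfortably smaller than the tolerances being checked.

## Known limitations

- The KS normality gate at n = 4 has essentially no power; the branch
  taken is reported so users can judge.
- CCC confidence intervals use the large-sample variance; at n = 16 they
  are approximate.
- Partial clearance with some discernible plaques must be encoded
  explicitly by the data enterer (`counted` vs `confluent`); the package
  does not guess.
- The no-drop probability is defined per attempted spot; a
  per-successful-aspiration definition would differ by a factor
  indistinguishable at these rates.
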