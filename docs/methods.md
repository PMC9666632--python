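# Methods

This note documents the statistical procedure the package implements, the
choices made where the design was genuinely open, what the synthetic
cohort generator does and does not emulate, and the known limitations.

## Data model and preprocessing

A cohort is a set of patient logs, one row per patient-night: usage
minutes, air leakage (L/s), AI and AHI (events/h), average mask pressure
(cmH2O, auto-titration mode only), plus static sex and titration mode.
Validation enforces the physical invariants: non-negative telemetry,
AHI ≥ AI, no physiology on zero-usage nights, pressure only in auto mode,
one record per patient-day.

**Short-night filter.** Event-per-hour indices are unreliable over short
nights, so only nights used for *more than* 30 minutes (strict) keep their
physiological fields. The night's usage duration itself is retained — a
short night is still real (non-)use and belongs in the usage features. An
alternative reading, dropping such nights entirely, is available via
`scope="night"`.

**Weeks** are fixed 7-day blocks anchored at the CPAP start date (therapy
weeks, not calendar weeks). Calendar days without a record are implicit
zero-usage nights. Only complete 7-day blocks are used; a trailing partial
week is dropped, never padded, because every weekly feature has a 7-day
denominator.

**Weekly adherence.** A night qualifies iff usage > 240 min (strict "more
than four hours"); a week is good iff ≥ 5 of its 7 nights qualify (the
70%-of-nights reading; a strict > 5 would be 6/7 ≈ 86% and contradict the
70% gloss of the CMS-style criterion). Both thresholds are parameters.
The per-patient outcome is *PA(p, t)* (first poor week t, all earlier
weeks good), *GA(p, t)* (t consecutive good weeks, no poor week observed —
right-censored), or undefined when week 1 itself is poor; undefined
patients cannot be ordered by time-to-poor and are excluded from modeling.

**Features.** The 18 weekly features: sex; mode; % of days > 4 h; % of
days used; % unused; mean/SD/total usage; mean/SD leak; mean/SD AI;
mean/SD AHI; mean/SD pressure (auto only); weekly OSAS severity (Normal /
Mild / Moderate / Severe from daily AHI at cuts 5/15/30, boundaries
inclusive upward, mirroring the printed "5 ≤ AI" convention of the
presence rule); weekly OSAS presence (Normal iff AI < 5). Weekly classes
are the most frequent daily class, ties broken toward the more abnormal
level (deterministic and clinically conservative). Usage features run
over all 7 days with non-use nights as 0 min; physiological features run
over physio-valid nights only; pressure features additionally require
auto mode. SDs use the population convention (divide by n; `ddof`
configurable).

**Encoding and standardization.** Sex and mode become single indicators
(female, auto); presence becomes the "Normal" indicator; severity is
one-hot by default (an ordinal 0–3 column is available) — per-level
indicators are what make per-level factor statements ("severity was
normal") expressible in the weight vector. Every encoded column, indicators
included, is z-scored against the *training* data only (per CV fold), so
that absolute weights are comparable across mixed qualitative/quantitative
factors. σ = 0 columns map to 0; missing entries (e.g. pressure under
fixed mode) map to 0, the standardized training mean, which is
weight-neutral for a linear score.

## Model

Comparable pairs are those whose ordering is observed under right
censoring: PA(m) < PA(n), or PA(m) < GA(n). Tied PA durations carry no
ordering; a censored patient can only be the "later" member; GA–GA pairs
are never comparable. Each comparable pair enters the likelihood once,
oriented earlier-first with y = +1: the mirrored y = −1 orientation
contributes the identical likelihood term by the symmetry of the logistic,
and double-counting would only rescale λ. (Whether N counts ordered or
unordered pairs is thus purely a λ-scale convention; ours is unordered.)

The objective Σ log σ(w·Δx) − λ‖w‖² is strictly concave for λ > 0, so the
maximizer is unique. It is found by damped Newton ascent from w = 0:
exact gradient Σ(1 − P)Δx − 2λw, exact negative Hessian
ΔXᵀdiag(P(1−P))ΔX + 2λI, backtracking halving for monotone ascent, and a
gradient 2-norm stopping rule at 1e-6 (cap 1000 iterations). Log-sigmoid
terms use `logaddexp`, so large |logits| cannot overflow. One numerical
subtlety: within float resolution of the maximizer the objective is flat
(true improvements fall below the representable difference at |objective|
~ 1e4), so the line search demands *strict* improvement and otherwise
takes the full Newton step, which still contracts the gradient there.

The PA risk score is ŵ·x, the logit of the pairwise preference against an
imaginary reference patient at x = 0; larger means earlier predicted poor
adherence. "Poor within the horizon" is predicted when score ≥ threshold
(boundary inclusive).

## Evaluation protocol

- **Cross-validation**: patient-level 5-fold partition (sizes differ by
  ≤ 1), reproducible from a seed and invariant to input order; the
  standardizer and the model are refitted inside each training fold.
- **Ranking accuracy**: concordance over comparable held-out pairs — the
  natural test-time analogue of the pairwise training objective — with
  score ties counting ½; undefined (reported as missing) when a fold has
  no comparable pair.
- **λ selection**: grid {0.1, 0.2, 0.5, 1, 2, 5, 10}, maximizing mean CV
  ranking accuracy; per-λ fold means and SDs are reported, along with the
  SD of the means across λ.
- **Horizon labeling** (default 12 weeks): PA with t ≤ 12 positive; PA
  with t > 12 or GA observed through week 12 negative; GA censored before
  week 12 excluded rather than imputed — their true label is unknown.
- **ROC** over thresholds swept in fixed 0.5-score increments from
  min(score) − step to max(score) + step, so both degenerate corners are
  always present; AUC by trapezoid in threshold order (sensitivity and FPR
  are both monotone in the threshold, so this traverses the curve).
  The Youden cutoff maximizes sensitivity + specificity − 1; ties break
  toward the smaller threshold (more sensitive operating point).
- **Factor report**: the 10 largest-|ŵ| features of the model refitted on
  the full cohort at the CV-selected λ; a positive weight reads "larger
  value associated with earlier poor adherence".

## Synthetic cohort generator

The generator emulates the statistical structure the analysis assumes,
calibrated to the scale of a real sleep-clinic cohort: nightly usage with
per-patient means N(334, 121²) min and within-patient SD 60 min plus a 5%
non-use night probability; log-normal leak (marginal ≈ 0.10 ± 0.15 L/s)
with between-patient level spread; gamma AI (≈ 1.35 ± 2.43 events/h) with
a gamma-distributed patient mean and AHI = AI + an independent gamma
excess (so AHI ≥ AI by construction, marginal AHI ≈ 2.0 ± 2.7); auto-mode
pressure normal around a patient mean (marginal ≈ 8.6 ± 2.0 cmH2O) with a
log-normal per-patient within-week SD, so pressure *variability* itself
varies across patients; 13.2% female, 98.2% auto mode.

Week 1 is drawn conditioned on good adherence. This makes the week-1
features exogenous (they are never edited after driving the hazard) and
gives every simulated patient a defined PA/GA outcome. The first poor
week T then follows a discrete-time hazard acting from week 2 on:
h = logistic(logit(h₀) + w_true·z) with z the cohort-standardized encoded
week-1 features and h₀ = 0.1 per week, so T − 1 ~ Geometric(h), censored
at the horizon (censoring ⇒ GA). Later weeks are generated to be
label-consistent — good before T, poor at T — rather than hazard-driven,
mirroring a design in which only week-1 features carry signal. Within the
final generated week a used night is permuted onto the last calendar day
(weekly features and labels are permutation-invariant) so the log always
spans complete weeks. All draws come from one seeded generator in a
documented order; cohorts are bitwise reproducible.

**Default ground-truth weights** form a graded spectrum: three strong
signals (|w| ≥ 1: mean leak +1.5, usage SD +1.2, pressure SD +1.0) over a
weak tail whose signs follow the factor directions reported for real
cohorts (longer/steadier usage protective; leak, variability and
low-severity classes risk-increasing). Two deliberate structural choices:
exactly collinear encoded pairs carry matched weights (equal on mean/total
usage, antisymmetric on the used/unused percentages), because only their
sum is identifiable in the pairwise design and the ridge penalty resolves
the split symmetrically; and an exact-null tail is *not* the default,
because rank-correlating |ŵ| against a truth vector with many tied zeros
has a hard ceiling (~0.61 even under perfect recovery of the strong
components) that would make rank-recovery unmeasurable. A null or sparse
`true_w` is still a one-argument override, and both configurations are
exercised in the tests.

What the generator does **not** emulate: seasonal effects, mid-course
titration-mode switches, therapy interruptions and resumptions, or
missing-data mechanisms beyond zero-usage nights. Passing recovery tests
on this cohort therefore demonstrates the estimator's correctness under
the model's own assumptions (exogenous week-1 features, proportional
discrete-time hazard, independent patients), not robustness to real-world
violations of them.

## Study sizes used by the test suite

The seeded studies run at the sizes the package declares as its reference
conditions: recovery and null calibration use 50 replicates of the default
300-patient, 12-week cohort; the weight-recovery protocol per replicate is
the same as the factor report's (5-fold CV λ selection, then full-data
refit). Measured this way, all three strong signals' signs are recovered
in 50/50 replicates, the median Spearman rank correlation between |ŵ| and
|w_true| is 0.70, held-out ranking accuracy exceeds chance in 50/50
replicates, and under a null truth the held-out concordance and 12-week
AUC average 0.50. Smaller behavioural checks (null-centering of fitted
weights, effect-size monotonicity) use 150-patient cohorts with 8–20
replicates.

## Known limitations

- Ranking accuracy is comparable-pair concordance; cohorts with few PA
  patients yield few comparable pairs and noisy fold estimates.
- The model is linear in week-1 features with time-invariant weights; no
  time-varying covariates, no nonlinearities, no interactions.
- Exactly collinear encoded columns (total = 7 × mean usage; the two
  percentage complements; a one-hot group within the difference design)
  are only jointly identifiable; individual weights among them are a
  ridge-resolved convention and should be interpreted as a group.
- The Youden cutoff is selected on the same out-of-fold scores used for
  the reported metrics; a fully honest operating-point estimate would
  nest the cutoff choice inside another validation layer.
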