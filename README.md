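# cpaprank

Censoring-aware pairwise learn-to-rank modeling of CPAP adherence from
nightly machine telemetry.

Continuous positive airway pressure (CPAP) is the standard therapy for
obstructive sleep apnea, and the machines log every night of use: usage
minutes, mask air leakage, apnea index (AI), apnea–hypopnea index (AHI),
and (in auto-titration mode) average mask pressure. A large fraction of
patients underuse or abandon the therapy, so a central clinical question is
**which usage patterns in the first week of therapy predict how soon a
patient's adherence will turn poor** — both to flag at-risk patients early
and to surface modifiable factors (leak, pressure instability, short and
irregular use).

`cpaprank` is a library for biostatisticians and sleep-medicine researchers
that implements this analysis end to end:

- **records** — parsing and validation of patient-night CSV logs, the
  short-night quality filter (physiological indices are kept only for
  nights used > 30 min), and segmentation into 7-day therapy weeks;
- **adherence** — the CMS-style weekly rule (good = used > 4 h/night on
  ≥ 5 of 7 nights) and the per-patient outcome: *PA(p, t)*, the first poor
  week, or *GA(p, t)*, t consecutive good weeks with no poor week observed
  (right-censored);
- **features** — the 18 weekly features (usage percentages/mean/SD/total,
  leak, AI, AHI and pressure summaries, plus weekly OSAS severity and
  presence classes from daily votes), one-hot encoding, and train-only
  z-scoring;
- **model** — the pairwise logistic ranking model;
- **evaluation** — cross-validated ranking accuracy for selecting the
  penalty λ, ROC/AUC in 0.5-score increments, the Youden cutoff,
  precision/recall/F1 at a 12-week horizon, and the top-10 factor report;
- **synthetic** — a cohort generator with known ground-truth weights, so
  the whole pipeline is testable without clinical data.

## The model

For patients *m*, *n* with encoded, standardized week-1 feature vectors
*x<sub>m</sub>*, *x<sub>n</sub>*, the probability that *m* turns poor
earlier is modeled as a logistic regression on the feature difference:

$$P(y\mid x_m, x_n; w) = \frac{1}{1+\exp(-y\, w\cdot(x_m - x_n))}$$

A pair enters training only when the ordering is actually observed under
censoring: *PA(m, t<sub>m</sub>) < PA(n, t<sub>n</sub>)* or
*PA(m, t<sub>m</sub>) < GA(n, t<sub>n</sub>)*; tied PA durations and
GA–GA pairs are incomparable. The weights maximize the L2-penalized
pairwise log-likelihood

$$\hat w = \arg\max_w \sum_{\text{pairs}} \log P(y\mid x_m,x_n;w) - \lambda \lVert w\rVert_2^2,$$

a strictly concave problem solved by damped Newton ascent. Each patient is
then scored by the **PA risk score** $\hat w\cdot x$ — the logit against an
imaginary reference patient with *x* = 0 — where larger scores mean earlier
predicted poor adherence; thresholding the score at the Youden-optimal
cutoff predicts poor adherence within a target horizon, and ranking
features by $|\hat w|$ gives the factor report.

## Worked example

`examples/fit_and_evaluate.py` simulates a 300-patient, 12-week cohort
with known generating weights and runs the full protocol:

```
modeled patients: 300 of 300
lambda grid (mean +/- sd held-out ranking accuracy over 5 folds):
  lambda= 0.1: 0.904 +/- 0.016
  ...
  lambda=10.0: 0.908 +/- 0.017
selected lambda = 10.0 (accuracy 0.908)

12-week prediction from out-of-fold PA risk scores:
  AUC = 0.950; Youden cutoff = -0.3 (score >= cutoff predicts poor within 12 weeks)
  precision 0.917, recall 0.842, F1 0.878

top factors by |weight| (positive -> earlier poor adherence):
  mean_leak          +1.49
  mean_ahi           +1.17
  sd_pressure        +0.89
  sd_usage           +0.77
  severity_normal    +0.73

recovery of the generating weights: sign agreement 0.85, Spearman(|w_hat|, |w_true|) 0.70, top-3 overlap 0.67
```

The held-out ranking accuracy (~0.91) is the fraction of comparable test
pairs the model orders correctly; the AUC and F1 describe the binary
"poor within 12 weeks" prediction at the Youden cutoff; and the top
factors recover the generator's strong signals (weekly leak level and
usage/pressure variability) with the correct signs. The other examples
show the preprocessing chain on a hand-made log
(`weekly_features_and_adherence.py`) and the cohort generator itself
(`simulate_cohort.py`).

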