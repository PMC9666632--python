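"""Generate a synthetic CPAP cohort and look at what it contains.

Builds a 300-patient cohort whose nightly telemetry matches the scale of a
real sleep-clinic population and whose week of first poor adherence is
driven by a known weight vector on the week-1 features, then prints the
outcome mix and a few telemetry summaries.
"""

import numpy as np

from cpaprank import CohortSpec, featurize_cohort, simulate_cohort, write_cpap_logs

spec = CohortSpec(n_patients=300, weeks=12, seed=0)
logs, truth = simulate_cohort(spec)
write_cpap_logs(logs, "synthetic_cohort.csv")

usage = np.array([r.usage_min for log in logs for r in log.records])
ahi = np.array([r.ahi for log in logs for r in log.records])
leak = np.array([r.leak for log in logs for r in log.records])
print(f"{len(logs)} patients, {usage.size} recorded nights -> synthetic_cohort.csv")
print(f"nightly usage  {usage.mean():6.1f} +/- {usage.std():.1f} min")
print(f"nightly AHI    {ahi.mean():6.2f} +/- {ahi.std():.2f} events/h")
print(f"nightly leak   {leak.mean():6.3f} +/- {leak.std():.3f} L/s")

cohort = featurize_cohort(logs)
n_pa = sum(o.kind == "PA" for o in cohort.outcomes)
n_ga = sum(o.kind == "GA" for o in cohort.outcomes)
print(f"outcomes: {n_pa} PA (poor adherence observed), {n_ga} GA (censored good)")
# PA(p, t): t is the first poor week; larger latent risk should mean smaller t
ts = [o.t for o in cohort.outcomes if o.kind == "PA"]
print(f"first poor week among PA patients: median {int(np.median(ts))}, range {min(ts)}-{max(ts)}")
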