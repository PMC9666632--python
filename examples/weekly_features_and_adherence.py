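"""From raw nightly logs to weekly features and an adherence outcome.

Walks one hand-made patient log through the preprocessing chain: the
short-night quality filter, 7-day segmentation, the weekly good/poor
adherence rule (> 4 h per night on >= 5 of 7 nights), and the 18 weekly
features used by the model.
"""

import datetime as dt

from cpaprank import (
    DailyRecord,
    PatientLog,
    apply_short_night_filter,
    compute_outcome,
    compute_weekly_features,
    label_week,
    segment_weeks,
)

start = dt.date(2020, 1, 6)
nights = []
# three weeks: solid use, then two skipped nights, then collapse to 4 nights
plan = [300, 320, 280, 350, 310, 290, 330,          # week 1: good
        310, 0, 290, 25, 300, 280, 310,             # week 2: 25-min night fails the >4 h rule -> 5 qualifying, still good
        260, 0, 0, 280, 270, 0, 290]                # week 3: only 4 qualifying nights -> poor
for i, minutes in enumerate(plan):
    if minutes == 0:
        continue  # a night without a record is an implicit zero-usage night
    nights.append(
        DailyRecord(
            date=start + dt.timedelta(days=i),
            usage_min=minutes,
            leak=0.1,
            ai=1.2,
            ahi=2.1,
            mask_pressure=8.5,
            mode="auto",
        )
    )
log = PatientLog("p_demo", "male", start, tuple(nights))

filtered = apply_short_night_filter(log)  # nights <= 30 min lose their physiology
windows = segment_weeks(filtered)
labels = [label_week(w) for w in windows]
for lab in labels:
    print(f"week {lab.week_index}: {lab.qualifying_nights}/7 qualifying nights -> {lab.label}")

outcome = compute_outcome(log.patient_id, labels)
print(f"outcome: {outcome.kind}(t={outcome.t})  # first poor week, counting from therapy start")

f = compute_weekly_features(windows[0], sex=log.sex, cpap_mode="auto")
print(f"week-1 features: mean usage {f.mean_usage:.0f} min, SD {f.sd_usage:.1f} min, "
      f"total {f.total_usage:.0f} min, {f.pct_days_over_4h:.0f}% of nights > 4 h")
print(f"                 leak {f.mean_leak:.2f} L/s, AHI {f.mean_ahi:.1f}/h -> "
      f"severity {f.weekly_severity}, presence {f.weekly_presence}")
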