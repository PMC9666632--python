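import datetime as dt

import pytest

from cpaprank import DailyRecord, PatientLog

D0 = dt.date(2020, 1, 1)


def build_log(
    usages,
    patient_id="p_001",
    sex="male",
    mode="auto",
    start=D0,
    physio=None,
):
    """Construct a PatientLog from nightly usage minutes.

    ``usages[i]`` is the usage on day i after ``start``; non-positive values
    become implicit zero-usage nights (no record).  ``physio`` optionally maps
    day index -> (leak, ai, ahi, mask_pressure).
    """
    records = []
    for i, u in enumerate(usages):
        if u <= 0:
            continue
        kwargs = {}
        if physio and i in physio:
            leak, ai, ahi, mp = physio[i]
            kwargs = {"leak": leak, "ai": ai, "ahi": ahi, "mask_pressure": mp}
        records.append(
            DailyRecord(
                date=start + dt.timedelta(days=i),
                usage_min=float(u),
                mode=mode,
                **kwargs,
            )
        )
    return PatientLog(patient_id, sex, start, tuple(records))


@pytest.fixture
def log_factory():
    return build_log
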