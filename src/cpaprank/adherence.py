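"""Weekly adherence labeling and the time-until-poor-adherence outcome.

Good adherence in a week follows the Centers for Medicare and Medicaid
Services style criterion: the machine was used for more than four hours per
night on at least five of the seven nights (70% of nights).  A patient's
outcome is then either

* ``PA(p, t)`` — poor adherence first observed in week ``t`` (weeks
  ``1..t-1`` all good), the event of interest;
* ``GA(p, t)`` — ``t`` consecutive good weeks with no poor week observed,
  a right-censored observation; or
* ``undefined`` — week 1 itself was poor, so neither quantity exists and
  the patient is excluded from modeling.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .records import WeekWindow

__all__ = ["WeekLabel", "AdherenceOutcome", "label_week", "compute_outcome"]

GOOD = "good"
POOR = "poor"

PA = "PA"
GA = "GA"
UNDEFINED = "undefined"


@dataclass(frozen=True)
class WeekLabel:
    week_index: int
    label: str  # "good" | "poor"
    qualifying_nights: int


@dataclass(frozen=True)
class AdherenceOutcome:
    """The auxiliary training outcome for one patient."""

    patient_id: str
    kind: str  # "PA" | "GA" | "undefined"
    t: int | None  # weeks, None iff undefined

    def __post_init__(self) -> None:
        if self.kind not in (PA, GA, UNDEFINED):
            raise ValueError(f"unknown outcome kind {self.kind!r}")
        if (self.t is None) != (self.kind == UNDEFINED):
            raise ValueError("t must be present exactly when the outcome is defined")
        if self.t is not None and self.t < 1:
            raise ValueError("t must be >= 1")


def label_week(
    window: WeekWindow,
    nightly_min: float = 240.0,
    nights_required: int = 5,
) -> WeekLabel:
    """Label one 7-day window good or poor.

    A night qualifies iff usage strictly exceeds ``nightly_min`` minutes
    ("more than four hours"); the week is good iff at least
    ``nights_required`` of its 7 nights qualify.  Unrecorded nights count as
    zero usage and never qualify.
    """
    for r in window.records:
        if not (0 <= (r.date - window.start).days < WeekWindow.N_DAYS):
            raise ValueError("window does not span exactly 7 days")
    qualifying = sum(u > nightly_min for u in window.usage_by_day())
    label = GOOD if qualifying >= nights_required else POOR
    return WeekLabel(window.week_index, label, qualifying)


def compute_outcome(patient_id: str, labels: Sequence[WeekLabel]) -> AdherenceOutcome:
    """Collapse consecutive weekly labels into a PA/GA/undefined outcome.

    ``labels`` must cover consecutive weeks 1..T.  The first poor week at
    index ``t`` gives ``PA(p, t)``; no poor week gives ``GA(p, T)``; a poor
    first week gives the undefined outcome.
    """
    if not labels:
        raise ValueError("empty label sequence")
    expected = list(range(1, len(labels) + 1))
    if [lab.week_index for lab in labels] != expected:
        raise ValueError("labels must cover consecutive weeks starting at 1")
    for lab in labels:
        if lab.label == POOR:
            if lab.week_index == 1:
                return AdherenceOutcome(patient_id, UNDEFINED, None)
            return AdherenceOutcome(patient_id, PA, lab.week_index)
    return AdherenceOutcome(patient_id, GA, len(labels))
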