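"""Health states, treatment arms and starting cohorts of the PNH model.

The model tracks a cohort of adult PNH patients on terminal complement
(C5) inhibition through eleven health states: a ladder of breakthrough
haemolysis (BTH) states distinguishing pharmacokinetic breakthrough
(incomplete C5 inhibition, only seen under eculizumab) from breakthrough
triggered by a complement-amplifying condition (CAC), a permanent
eculizumab up-dose branch entered after a second incomplete-inhibition
event, spontaneous remission, and two absorbing death states separating
background from PNH-attributable mortality.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass


class HealthState(enum.IntEnum):
    """The eleven model states; integer values index matrix rows/columns."""

    NO_BTH = 0
    INCC5_BTH = 1
    CAC_BTH = 2
    HX_NO_BTH = 3
    HX_INCC5_BTH = 4  # second incomplete-C5-inhibition event
    HX_CAC_BTH = 5
    UPDOSE = 6
    UPDOSE_CAC_BTH = 7
    REMISSION = 8
    DEATH_BACKGROUND = 9
    DEATH_PNH = 10


N_STATES = len(HealthState)

LIVING_STATES = tuple(s for s in HealthState if s < HealthState.DEATH_BACKGROUND)
DEATH_STATES = (HealthState.DEATH_BACKGROUND, HealthState.DEATH_PNH)

#: states during an incomplete-C5-inhibition BTH event (2-day excess-mortality window)
INCC5_EVENT_STATES = (HealthState.INCC5_BTH, HealthState.HX_INCC5_BTH)
#: states during a CAC-triggered BTH event (full-cycle excess-mortality window)
CAC_EVENT_STATES = (
    HealthState.CAC_BTH,
    HealthState.HX_CAC_BTH,
    HealthState.UPDOSE_CAC_BTH,
)
BTH_STATES = INCC5_EVENT_STATES + CAC_EVENT_STATES
#: living states without an ongoing BTH event (transfusion "No BTH" class)
NO_BTH_CLASS = (HealthState.NO_BTH, HealthState.HX_NO_BTH, HealthState.UPDOSE)
#: states occupying the permanently up-dosed eculizumab branch (1200 mg)
UPDOSED_STATES = (HealthState.UPDOSE, HealthState.UPDOSE_CAC_BTH)
#: living states in which drug is administered (remission stops treatment)
ON_TREATMENT_STATES = tuple(s for s in LIVING_STATES if s != HealthState.REMISSION)


class Arm(str, enum.Enum):
    """Treatment arm."""

    ECULIZUMAB = "eculizumab"
    RAVULIZUMAB = "ravulizumab"


class CohortId(str, enum.Enum):
    COHORT1 = "cohort1"  # complement-inhibitor naive (trial of naive adults)
    COHORT2 = "cohort2"  # clinically stable on labelled-dose eculizumab >= 6 months
    COHORT3 = "cohort3"  # stable on up-dosed (1200 mg) eculizumab; scenario only


@dataclass(frozen=True)
class Cohort:
    """A starting cohort with its entry conditions and aggregate-mix weight.

    ``entry_state`` applies to the eculizumab arm; a cohort switched to
    ravulizumab always enters in ``NO_BTH`` because ravulizumab has no
    up-dose branch.
    """

    id: CohortId
    start_age: float
    entry_state: HealthState = HealthState.NO_BTH
    vaccinate_at_entry: bool = False
    eculizumab_loading_phase: bool = False
    mix_weight: float = 0.0

    #: which cohort's transition/utility/transfusion parameters to use
    @property
    def param_cohort(self) -> CohortId:
        # cohort 3 borrows every trial-derived input from cohort 2
        return CohortId.COHORT2 if self.id == CohortId.COHORT3 else self.id

    def entry_state_for(self, arm: Arm) -> HealthState:
        if arm == Arm.RAVULIZUMAB:
            return HealthState.NO_BTH
        return self.entry_state


def default_cohorts() -> list[Cohort]:
    """The base-case cohorts: naive incident patients (8.3%) and stable
    prevalent patients (91.6%); weights are renormalised downstream."""
    return [
        Cohort(
            id=CohortId.COHORT1,
            start_age=45.5,
            entry_state=HealthState.NO_BTH,
            vaccinate_at_entry=True,
            eculizumab_loading_phase=True,
            mix_weight=0.083,
        ),
        Cohort(
            id=CohortId.COHORT2,
            start_age=47.7,
            entry_state=HealthState.NO_BTH,
            mix_weight=0.916,
        ),
    ]


def cohort3(mix_weight: float = 0.0) -> Cohort:
    """The scenario cohort of patients stable on up-dosed eculizumab."""
    return Cohort(
        id=CohortId.COHORT3,
        start_age=47.7,
        entry_state=HealthState.UPDOSE,
        mix_weight=mix_weight,
    )
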