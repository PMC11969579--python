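"""Health-state space of the glaucoma natural-history model.

The model follows two mutually exclusive disease arms using the ISGEO
staging: primary open-angle glaucoma (POAG, entered through an ocular
hypertension precursor) and primary angle-closure disease (PACD, entered
through the angle-closure-suspect stage).  Vision loss is irreversible, so
stages are ordered and transitions only move forward.  Each living diseased
state additionally carries two care flags -- ``diagnosed`` and ``treated``
(treated implies diagnosed) -- which the screening cascade flips and which
natural history leaves untouched.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from functools import lru_cache


class Arm(str, Enum):
    DISEASE_FREE = "disease_free"
    POAG = "poag"
    PACD = "pacd"
    DEAD = "dead"


#: ISGEO-ordered stages.  ``oht`` is the ocular-hypertension precursor of the
#: open-angle arm; ``pacs``/``pac`` precede angle-closure glaucoma.
POAG_STAGES: tuple[str, ...] = (
    "oht",
    "mild",
    "moderate",
    "severe",
    "unilateral_blind",
    "bilateral_blind",
)
PACD_STAGES: tuple[str, ...] = (
    "pacs",
    "pac",
    "pacg",
    "unilateral_blind",
    "bilateral_blind",
)

BLIND_STAGES = frozenset({"unilateral_blind", "bilateral_blind"})

#: Stages that count as manifest glaucoma for opportunistic (usual-care)
#: consultation: established disease, not the asymptomatic precursors.
MANIFEST_POAG = frozenset(POAG_STAGES[1:])
MANIFEST_PACD = frozenset(PACD_STAGES[2:])


@dataclass(frozen=True)
class State:
    arm: Arm
    stage: str | None = None
    diagnosed: bool = False
    treated: bool = False

    def __post_init__(self) -> None:
        if self.arm in (Arm.DISEASE_FREE, Arm.DEAD):
            if self.stage is not None or self.diagnosed or self.treated:
                raise ValueError(f"{self.arm.value} carries no stage or care flags")
        else:
            stages = POAG_STAGES if self.arm is Arm.POAG else PACD_STAGES
            if self.stage not in stages:
                raise ValueError(f"unknown stage {self.stage!r} for arm {self.arm.value}")
            if self.treated and not self.diagnosed:
                raise ValueError("treated implies diagnosed")

    @property
    def alive(self) -> bool:
        return self.arm is not Arm.DEAD

    @property
    def diseased(self) -> bool:
        return self.arm in (Arm.POAG, Arm.PACD)

    @property
    def blind(self) -> bool:
        return self.stage in BLIND_STAGES

    @property
    def manifest_glaucoma(self) -> bool:
        """True for stages a patient could present with to an ophthalmologist."""
        if self.arm is Arm.POAG:
            return self.stage in MANIFEST_POAG
        if self.arm is Arm.PACD:
            return self.stage in MANIFEST_PACD
        return False

    @property
    def label(self) -> str:
        if self.arm in (Arm.DISEASE_FREE, Arm.DEAD):
            return self.arm.value
        flags = "treated" if self.treated else ("diagnosed" if self.diagnosed else "undiagnosed")
        return f"{self.arm.value}_{self.stage}_{flags}"

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"State({self.label})"


#: The three care-flag combinations a living diseased state can carry.
CARE_FLAGS: tuple[tuple[bool, bool], ...] = ((False, False), (True, False), (True, True))

DISEASE_FREE = State(Arm.DISEASE_FREE)
DEAD = State(Arm.DEAD)


def _build_state_space() -> tuple[State, ...]:
    states: list[State] = [DISEASE_FREE]
    for arm, stages in ((Arm.POAG, POAG_STAGES), (Arm.PACD, PACD_STAGES)):
        for stage in stages:
            for diagnosed, treated in CARE_FLAGS:
                states.append(State(arm, stage, diagnosed, treated))
    states.append(DEAD)
    return tuple(states)


STATE_SPACE: tuple[State, ...] = _build_state_space()
STATE_INDEX: dict[State, int] = {s: i for i, s in enumerate(STATE_SPACE)}
N_STATES: int = len(STATE_SPACE)
DEAD_INDEX: int = STATE_INDEX[DEAD]
DISEASE_FREE_INDEX: int = STATE_INDEX[DISEASE_FREE]


def index_of(state: State) -> int:
    try:
        return STATE_INDEX[state]
    except KeyError:
        raise KeyError(f"state {state!r} not in model state space") from None


@lru_cache(maxsize=None)
def next_stage(arm: Arm, stage: str) -> str | None:
    """Successor stage within an arm, or None for the terminal (bilateral) stage."""
    stages = POAG_STAGES if arm is Arm.POAG else PACD_STAGES
    i = stages.index(stage)
    return stages[i + 1] if i + 1 < len(stages) else None


def stage_param_key(arm: Arm, stage: str) -> str:
    """Registry key suffix used for per-state prevalence/utility parameters."""
    return f"{arm.value}_{stage}"


#: (arm, stage) pairs for every living diseased state, in state-space order.
DISEASED_STAGES: tuple[tuple[Arm, str], ...] = tuple(
    (arm, stage)
    for arm, stages in ((Arm.POAG, POAG_STAGES), (Arm.PACD, PACD_STAGES))
    for stage in stages
)
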