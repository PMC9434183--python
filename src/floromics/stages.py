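"""Canonical developmental staging of Arabidopsis florets around anthesis.

The sampling design covers eight consecutive stages of flower development,
S9 through S16, spanning roughly eight days of floret age.  Anthesis — the
transition from closed bud to open flower — occurs at stage S13 (11.50 days).
Stages S9–S12 are preanthesis buds; S14–S16 are postanthesis (open to
senescing) flowers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

__all__ = [
    "StageMetadata",
    "CANONICAL_STAGES",
    "PHASES",
    "stage_ages",
    "stage_phase",
]

PHASES = ("preanthesis", "anthesis", "postanthesis")


@dataclass(frozen=True)
class StageMetadata:
    """One developmental stage: label, floret age in days, and phase.

    The age of the youngest stage (S9) is reported ambiguously in parts of
    the literature (7.25 vs 7.29 days); it is plain metadata here, defaulting
    to 7.25 d, and nothing downstream hard-codes an interpretation.
    """

    stage_label: str
    age_days: float
    phase: str

    def __post_init__(self) -> None:
        if self.phase not in PHASES:
            raise ValueError(f"unknown phase {self.phase!r}; expected one of {PHASES}")
        if self.age_days <= 0:
            raise ValueError("age_days must be positive")


def _canonical(s9_age: float = 7.25) -> tuple[StageMetadata, ...]:
    ages = (s9_age, 9.25, 10.25, 11.50, 13.25, 13.50, 14.25, 15.25)
    labels = ("S9", "S11", "S12", "S13", "S14a", "S14b", "S15", "S16")
    phases = ("preanthesis",) * 3 + ("anthesis",) + ("postanthesis",) * 4
    return tuple(StageMetadata(l, a, p) for l, a, p in zip(labels, ages, phases))


#: The eight canonical sampled stages; ages strictly increasing, anthesis at
#: S13 (11.50 d), three preanthesis bud stages (S9-S12) and four postanthesis
#: stages (S14-S16).  The standard flower-staging nomenclature provides only
#: three labels after anthesis, so the two young-open-flower samples taken
#: six hours apart (13.25 and 13.50 d) are distinguished as S14a/S14b.
CANONICAL_STAGES: tuple[StageMetadata, ...] = _canonical()

# sanity invariants, checked once at import
assert all(
    a.age_days < b.age_days for a, b in zip(CANONICAL_STAGES, CANONICAL_STAGES[1:])
)
assert sum(s.phase == "anthesis" for s in CANONICAL_STAGES) == 1


def stage_ages(stages: Sequence[StageMetadata] = CANONICAL_STAGES) -> list[float]:
    """Floret ages (days) of the given stages, in order."""
    return [s.age_days for s in stages]


def stage_phase(stage_label: str) -> str:
    """Phase (preanthesis / anthesis / postanthesis) of a canonical stage."""
    for s in CANONICAL_STAGES:
        if s.stage_label == stage_label:
            return s.phase
    raise KeyError(f"unknown stage label {stage_label!r}")
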