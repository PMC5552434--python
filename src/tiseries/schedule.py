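"""Three-phase transitive-inference experiment designs.

A session presents pairs drawn from an ordered list of ``n_items`` stimuli
(labelled ``A``, ``B``, ... with rank 1 = earliest item; choosing the
earlier-ranked item is always "correct").  Training proceeds in three
phases: a massed block showing only the last-two-items pair (FG for a
seven-item list), then all adjacent pairs plus every pair containing one
of the two massed items, then all pairs.  Each pair is described by two
orthogonal coordinates: symbolic distance (absolute rank difference) and
joint rank (rank sum), which together identify the pair uniquely.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import CounterbalanceError, DesignError, InvalidPairError

__all__ = [
    "StimulusItem",
    "Pair",
    "PhasePlan",
    "TrialSlot",
    "SpeciesProfile",
    "MONKEY",
    "HUMAN",
    "make_items",
    "all_pairs",
    "pair_coordinates",
    "phase_pairs",
    "phase_plans",
    "build_schedule",
    "phase_start_trial",
    "schedule_to_frame",
]

PHASES = (1, 2, 3)


@dataclass(frozen=True, order=True)
class StimulusItem:
    """One list item: rank 1 is the earliest (always-correct) item."""

    rank: int
    label: str

    def __post_init__(self):
        if self.rank < 1:
            raise DesignError(f"rank must be >= 1, got {self.rank}")


def make_items(n_items: int) -> tuple[StimulusItem, ...]:
    """Items labelled A.. with ranks 1..n_items in list order."""
    if n_items < 2:
        raise DesignError(f"a list needs at least 2 items, got {n_items}")
    if n_items > 26:
        raise DesignError("labels are single letters; n_items must be <= 26")
    return tuple(
        StimulusItem(rank=i + 1, label=string.ascii_uppercase[i])
        for i in range(n_items)
    )


@dataclass(frozen=True, order=True)
class Pair:
    """Unordered stimulus pair, stored as (earlier item, later item)."""

    lo: StimulusItem
    hi: StimulusItem

    def __post_init__(self):
        if self.lo.rank == self.hi.rank:
            raise InvalidPairError(
                f"pair items must have distinct ranks, got {self.lo} / {self.hi}"
            )
        if self.lo.rank > self.hi.rank:
            # normalise so lo is always the earlier (correct) item
            lo, hi = self.hi, self.lo
            object.__setattr__(self, "lo", lo)
            object.__setattr__(self, "hi", hi)

    @property
    def distance(self) -> int:
        """Symbolic distance: absolute rank difference."""
        return self.hi.rank - self.lo.rank

    @property
    def joint_rank(self) -> int:
        """Joint rank: sum of the two ranks (absolute list position)."""
        return self.lo.rank + self.hi.rank

    @property
    def label(self) -> str:
        return self.lo.label + self.hi.label

    def contains(self, label: str) -> bool:
        return label in (self.lo.label, self.hi.label)

    def __str__(self) -> str:  # pragma: no cover - repr sugar
        return self.label


def pair_coordinates(pair: Pair) -> tuple[int, int]:
    """(symbolic distance, joint rank) coordinates of a pair.

    For a seven-item list the pair BD maps to (2, 6); FG to (1, 13).
    """
    return pair.distance, pair.joint_rank


def all_pairs(n_items: int) -> frozenset[Pair]:
    """Every unordered pair of an ``n_items`` list (n*(n-1)/2 pairs)."""
    items = make_items(n_items)
    return frozenset(
        Pair(items[i], items[j])
        for i in range(n_items)
        for j in range(i + 1, n_items)
    )


def phase_pairs(phase: int, n_items: int = 7) -> frozenset[Pair]:
    """Pair set presented in each phase of the massed-training design.

    Phase 1: only the last-two-items pair.  Phase 2: all adjacent pairs
    plus every pair containing one of the two last items (15 pairs for
    n=7).  Phase 3: all pairs.
    """
    if phase not in PHASES:
        raise DesignError(f"unknown phase {phase!r}; expected one of {PHASES}")
    pairs = all_pairs(n_items)
    items = make_items(n_items)
    if phase == 1:
        return frozenset({Pair(items[-2], items[-1])})
    if phase == 2:
        last_two = (items[-1].label, items[-2].label)
        return frozenset(
            p
            for p in pairs
            if p.distance == 1 or p.contains(last_two[0]) or p.contains(last_two[1])
        )
    return pairs


@dataclass(frozen=True)
class PhasePlan:
    """One phase: its pair set and per-pair presentation count."""

    phase: int
    pairs: frozenset[Pair]
    presentations_per_pair: int

    def __post_init__(self):
        if self.phase not in PHASES:
            raise DesignError(f"unknown phase {self.phase!r}")
        if self.presentations_per_pair < 1:
            raise DesignError("presentations_per_pair must be positive")
        if self.presentations_per_pair % 2 != 0:
            raise CounterbalanceError(
                f"presentations_per_pair must be even to counterbalance sides, "
                f"got {self.presentations_per_pair} in phase {self.phase}"
            )

    @property
    def n_trials(self) -> int:
        return len(self.pairs) * self.presentations_per_pair


@dataclass(frozen=True)
class TrialSlot:
    """One scheduled trial (1-based index, continuous across phases)."""

    trial_index: int
    phase: int
    pair: Pair
    correct_side: str  # "left" | "right"


@dataclass(frozen=True)
class SpeciesProfile:
    """Session layout for one species.

    ``presentations`` maps phase -> presentations per pair.  Macaque
    sessions run 760 trials (40 massed + 15x20 + 21x20); human sessions
    use half as many presentations everywhere (380 trials, one session).
    """

    name: str
    presentations: dict[int, int] = field(default_factory=dict)
    sessions_per_subject: int = 1
    n_items: int = 7

    def __post_init__(self):
        if set(self.presentations) != set(PHASES):
            raise DesignError(
                f"presentations must cover phases {PHASES}, got {sorted(self.presentations)}"
            )
        if self.sessions_per_subject < 1:
            raise DesignError("sessions_per_subject must be >= 1")

    @property
    def session_length(self) -> int:
        return sum(p.n_trials for p in phase_plans(self))


MONKEY = SpeciesProfile(
    name="monkey", presentations={1: 40, 2: 20, 3: 20}, sessions_per_subject=20
)
HUMAN = SpeciesProfile(
    name="human", presentations={1: 20, 2: 10, 3: 10}, sessions_per_subject=1
)


def phase_plans(profile: SpeciesProfile) -> list[PhasePlan]:
    return [
        PhasePlan(
            phase=ph,
            pairs=phase_pairs(ph, profile.n_items),
            presentations_per_pair=profile.presentations[ph],
        )
        for ph in PHASES
    ]


def phase_start_trial(profile: SpeciesProfile, phase: int) -> int:
    """First (1-based) trial index of a phase within a session."""
    if phase not in PHASES:
        raise DesignError(f"unknown phase {phase!r}")
    start = 1
    for plan in phase_plans(profile):
        if plan.phase == phase:
            return start
        start += plan.n_trials
    raise AssertionError("unreachable")


def build_schedule(
    profile: SpeciesProfile,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> list[TrialSlot]:
    """Seeded session schedule: per phase, a uniform shuffle of the pair
    multiset with exact left/right counterbalancing of the correct item.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    slots: list[TrialSlot] = []
    trial = 1
    for plan in phase_plans(profile):
        entries: list[tuple[Pair, str]] = []
        for pair in sorted(plan.pairs):
            half = plan.presentations_per_pair // 2
            entries.extend([(pair, "left")] * half)
            entries.extend([(pair, "right")] * half)
        order = rng.permutation(len(entries))
        for idx in order:
            pair, side = entries[idx]
            slots.append(
                TrialSlot(trial_index=trial, phase=plan.phase, pair=pair, correct_side=side)
            )
            trial += 1
    return slots


def schedule_to_frame(slots: list[TrialSlot], session: int = 1) -> pd.DataFrame:
    """Tabular export of a schedule (one row per trial)."""
    return pd.DataFrame(
        {
            "session": session,
            "trial_index": [s.trial_index for s in slots],
            "phase": [s.phase for s in slots],
            "item_lo": [s.pair.lo.label for s in slots],
            "item_hi": [s.pair.hi.label for s in slots],
            "distance": [s.pair.distance for s in slots],
            "joint_rank": [s.pair.joint_rank for s in slots],
            "correct_side": [s.correct_side for s in slots],
        }
    )
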