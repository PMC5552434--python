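"""Behavioral agent simulators and reaction-time generation.

Two competing agent families stand in for the (undeposited) macaque and
human datasets.  The associative agent tracks scalar reward values per
stimulus (delta-rule update, softmax choice) with optional value
transfer, so massed training of the pair FG drives the value of F toward
ceiling and predicts a bias *toward* F when F later meets novel stimuli.
The representational agent maintains noisy ordinal position estimates;
with a "massed prior" (cross-session task knowledge that massed-phase
stimuli belong near the tail of the list) it instead *avoids* F on the
very first F-with-novel pairing — the discriminating signature of the
two accounts.

Reaction times are generated separately as log-normal draws whose mean
is linear in symbolic distance and trial number.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError
from .schedule import (
    Pair,
    SpeciesProfile,
    TrialSlot,
    build_schedule,
)

__all__ = [
    "TrialRecord",
    "AssociativeAgentConfig",
    "RepresentationAgentConfig",
    "RTConfig",
    "MONKEY_REPRESENTATIONAL",
    "HUMAN_REPRESENTATIONAL",
    "MONKEY_RT",
    "HUMAN_RT",
    "AssociativeAgent",
    "RepresentationAgent",
    "simulate_associative",
    "simulate_representational",
    "simulate_bernoulli",
    "simulate_rt",
    "generate_cohort",
    "records_to_frame",
    "frame_to_records",
    "RECORD_COLUMNS",
]


@dataclass(frozen=True)
class TrialRecord:
    """One observed or simulated trial outcome."""

    subject: str
    session: int
    trial_index: int
    phase: int
    pair: Pair
    chosen: str
    correct: int
    rt_seconds: float = float("nan")

    def __post_init__(self):
        if self.chosen not in (self.pair.lo.label, self.pair.hi.label):
            raise ConfigError(
                f"chosen item {self.chosen!r} not in pair {self.pair.label}"
            )
        expected = int(self.chosen == self.pair.lo.label)
        if self.correct != expected:
            raise ConfigError(
                f"correct flag {self.correct} inconsistent with chosen {self.chosen!r} "
                f"in pair {self.pair.label}"
            )


@dataclass(frozen=True)
class AssociativeAgentConfig:
    """Delta-rule value learner with softmax choice.

    alpha: learning rate in (0, 1]; beta: softmax inverse temperature
    (0 = random choice); theta: value-transfer coefficient in [0, 1]
    (fraction by which the unchosen partner's value is pulled toward a
    rewarded winner's value); v0: initial value of every stimulus.
    """

    alpha: float = 0.2
    beta: float = 5.0
    theta: float = 0.0
    v0: float = 0.5

    def __post_init__(self):
        if not 0.0 < self.alpha <= 1.0:
            raise ConfigError(f"alpha must be in (0, 1], got {self.alpha}")
        if self.beta < 0.0:
            raise ConfigError(f"beta must be >= 0, got {self.beta}")
        if not 0.0 <= self.theta <= 1.0:
            raise ConfigError(f"theta must be in [0, 1], got {self.theta}")


@dataclass(frozen=True)
class RepresentationAgentConfig:
    """Noisy-ordinal-position learner.

    position_noise: sd of the per-trial position readings; learn_rate:
    step applied after a correct choice; relearn_rate: (usually larger)
    step applied after an error; massed_prior: strength in [0, 1] of the
    cross-session prior that stimuli introduced during the massed phase
    rank below (later than) novel stimuli — monkey-like when > 0,
    task-naive-human-like when 0; margin: separation (in position units)
    at which feedback updates stop; repeat_boost: factor in (0, 1] by
    which position noise shrinks when the previous trial showed the same
    pair (a one-trial memory trace; massed blocks benefit, interleaved
    trials do not).
    """

    position_noise: float = 0.8
    learn_rate: float = 0.05
    massed_prior: float = 0.8
    relearn_rate: float = 0.1
    margin: float = 1.0
    repeat_boost: float = 0.5

    def __post_init__(self):
        for name in ("position_noise", "learn_rate", "massed_prior", "relearn_rate"):
            if getattr(self, name) < 0.0:
                raise ConfigError(f"{name} must be non-negative")
        if not 0.0 <= self.massed_prior <= 1.0:
            raise ConfigError(f"massed_prior must be in [0, 1], got {self.massed_prior}")
        if self.margin <= 0.0:
            raise ConfigError("margin must be positive")
        if not 0.0 < self.repeat_boost <= 1.0:
            raise ConfigError("repeat_boost must be in (0, 1]")


#: Monkey-like defaults: slow learning, strong cross-session massed prior.
MONKEY_REPRESENTATIONAL = RepresentationAgentConfig(
    position_noise=0.8, learn_rate=0.05, massed_prior=0.8, relearn_rate=0.1
)
#: Task-naive human defaults: ~10x faster learning, no massed prior,
#: rapid post-error correction.
HUMAN_REPRESENTATIONAL = RepresentationAgentConfig(
    position_noise=0.8, learn_rate=0.5, massed_prior=0.0, relearn_rate=0.8
)


@dataclass(frozen=True)
class RTConfig:
    """Log-normal reaction times: log RT ~ N(mu0 + distance_slope*d +
    practice_slope*t, sigma^2), all in log-seconds."""

    mu0: float
    distance_slope: float = 0.0
    practice_slope: float = 0.0
    sigma: float = 0.2

    def __post_init__(self):
        if self.sigma <= 0.0:
            raise ConfigError(f"sigma must be > 0, got {self.sigma}")


#: Oculomotor-speed macaque profile: median RT exp(-1.35) ~ 0.26 s, no
#: practice trend, mild distance speed-up.
MONKEY_RT = RTConfig(mu0=-1.35, distance_slope=-0.02, practice_slope=0.0, sigma=0.2)
#: Mouse-and-cursor human profile: median RT exp(0.5) ~ 1.65 s, steady
#: within-session speed-up, clearer distance effect.
HUMAN_RT = RTConfig(mu0=0.5, distance_slope=-0.03, practice_slope=-5e-4, sigma=0.25)


class AssociativeAgent:
    """Stateful value learner; one instance per session."""

    def __init__(self, config: AssociativeAgentConfig):
        self.config = config
        self.values: dict[str, float] = {}

    def _value(self, label: str) -> float:
        return self.values.setdefault(label, self.config.v0)

    def choice_prob_lo(self, pair: Pair) -> float:
        """Probability of choosing the earlier-ranked (correct) item."""
        d = self._value(pair.lo.label) - self._value(pair.hi.label)
        return float(1.0 / (1.0 + np.exp(-self.config.beta * d)))

    def step(self, slot: TrialSlot, rng: np.random.Generator) -> tuple[str, int]:
        pair = slot.pair
        p_lo = self.choice_prob_lo(pair)
        chose_lo = rng.random() < p_lo
        chosen = pair.lo.label if chose_lo else pair.hi.label
        other = pair.hi.label if chose_lo else pair.lo.label
        correct = int(chose_lo)
        cfg = self.config
        reward = float(correct)
        v = self._value(chosen)
        v_new = v + cfg.alpha * (reward - v)
        self.values[chosen] = v_new
        if correct and cfg.theta > 0.0:
            # value transfer: the rewarded winner's value leaks to its partner
            v_other = self._value(other)
            self.values[other] = v_other + cfg.theta * (v_new - v_other)
        return chosen, correct


class RepresentationAgent:
    """Stateful noisy-position learner; one instance per session."""

    def __init__(self, config: RepresentationAgentConfig, n_items: int = 7):
        self.config = config
        self.n_items = n_items
        self.positions: dict[str, float] = {}
        self._prev_pair: Pair | None = None

    @property
    def _mid(self) -> float:
        return (self.n_items + 1) / 2.0

    def _position(self, label: str, phase: int) -> float:
        if label not in self.positions:
            pos0 = self._mid
            if phase == 1:
                # massed-phase stimuli start shifted toward the list tail
                pos0 = self._mid + self.config.massed_prior * (self.n_items - self._mid)
            self.positions[label] = pos0
        return self.positions[label]

    def choice_prob_lo(self, pair: Pair, phase: int, repeated: bool = False) -> float:
        from scipy.stats import norm

        cfg = self.config
        noise = cfg.position_noise * (cfg.repeat_boost if repeated else 1.0)
        gap = self._position(pair.hi.label, phase) - self._position(pair.lo.label, phase)
        if noise == 0.0:
            return 1.0 if gap > 0 else (0.5 if gap == 0 else 0.0)
        return float(norm.cdf(gap / (np.sqrt(2.0) * noise)))

    def step(self, slot: TrialSlot, rng: np.random.Generator) -> tuple[str, int]:
        pair, phase = slot.pair, slot.phase
        cfg = self.config
        repeated = self._prev_pair == pair
        self._prev_pair = pair
        pos_lo = self._position(pair.lo.label, phase)
        pos_hi = self._position(pair.hi.label, phase)
        noise = cfg.position_noise * (cfg.repeat_boost if repeated else 1.0)
        z_lo = pos_lo + rng.normal(0.0, noise) if noise > 0 else pos_lo
        z_hi = pos_hi + rng.normal(0.0, noise) if noise > 0 else pos_hi
        if z_lo == z_hi:
            chose_lo = bool(rng.random() < 0.5)
        else:
            chose_lo = z_lo < z_hi
        chosen = pair.lo.label if chose_lo else pair.hi.label
        correct = int(chose_lo)
        # feedback: push the correct item earlier / incorrect later until
        # they are separated by at least `margin`
        rate = cfg.learn_rate if correct else cfg.relearn_rate
        d = pos_lo - pos_hi  # want d <= -margin
        if d > -cfg.margin:
            step = rate * (d + cfg.margin) / 2.0
            self.positions[pair.lo.label] = pos_lo - step
            self.positions[pair.hi.label] = pos_hi + step
        return chosen, correct


def _run_agent(
    schedule: Sequence[TrialSlot],
    agent,
    rng: np.random.Generator,
    subject: str,
    session: int,
) -> list[TrialRecord]:
    records = []
    for slot in schedule:
        chosen, correct = agent.step(slot, rng)
        records.append(
            TrialRecord(
                subject=subject,
                session=session,
                trial_index=slot.trial_index,
                phase=slot.phase,
                pair=slot.pair,
                chosen=chosen,
                correct=correct,
            )
        )
    return records


def simulate_associative(
    schedule: Sequence[TrialSlot],
    config: AssociativeAgentConfig,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    subject: str = "sim",
    session: int = 1,
) -> list[TrialRecord]:
    """Run one associative agent over a session schedule."""
    if rng is None:
        rng = np.random.default_rng(seed)
    return _run_agent(schedule, AssociativeAgent(config), rng, subject, session)


def simulate_representational(
    schedule: Sequence[TrialSlot],
    config: RepresentationAgentConfig,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    subject: str = "sim",
    session: int = 1,
    n_items: int = 7,
) -> list[TrialRecord]:
    """Run one representational agent over a session schedule."""
    if rng is None:
        rng = np.random.default_rng(seed)
    return _run_agent(
        schedule, RepresentationAgent(config, n_items=n_items), rng, subject, session
    )


def simulate_bernoulli(
    schedule: Sequence[TrialSlot],
    prob_correct: Callable[[TrialSlot], float],
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    subject: str = "sim",
    session: int = 1,
) -> list[TrialRecord]:
    """Parametric generator: correctness ~ Bernoulli(prob_correct(slot)).

    Useful for planting a known accuracy law (e.g. a linear trend in
    log-odds, or a built-in distance effect) that the analysis should
    recover.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    records = []
    for slot in schedule:
        p = float(prob_correct(slot))
        if not 0.0 <= p <= 1.0:
            raise ConfigError(f"prob_correct returned {p} outside [0, 1]")
        correct = int(rng.random() < p)
        chosen = slot.pair.lo.label if correct else slot.pair.hi.label
        records.append(
            TrialRecord(
                subject=subject,
                session=session,
                trial_index=slot.trial_index,
                phase=slot.phase,
                pair=slot.pair,
                chosen=chosen,
                correct=correct,
            )
        )
    return records


def simulate_rt(
    records: Sequence[TrialRecord],
    config: RTConfig,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> list[TrialRecord]:
    """Fill rt_seconds: log RT ~ N(mu0 + distance_slope*d + practice_slope*t, sigma^2)."""
    if rng is None:
        rng = np.random.default_rng(seed)
    out = []
    for rec in records:
        mu = (
            config.mu0
            + config.distance_slope * rec.pair.distance
            + config.practice_slope * rec.trial_index
        )
        rt = float(np.exp(rng.normal(mu, config.sigma)))
        out.append(replace(rec, rt_seconds=rt))
    return out


RECORD_COLUMNS = [
    "subject",
    "session",
    "trial_index",
    "phase",
    "item_lo",
    "item_hi",
    "distance",
    "joint_rank",
    "chosen",
    "correct",
    "rt_seconds",
]


def records_to_frame(records: Sequence[TrialRecord]) -> pd.DataFrame:
    """Tidy DataFrame with the canonical trial-record columns."""
    return pd.DataFrame(
        {
            "subject": [r.subject for r in records],
            "session": [r.session for r in records],
            "trial_index": [r.trial_index for r in records],
            "phase": [r.phase for r in records],
            "item_lo": [r.pair.lo.label for r in records],
            "item_hi": [r.pair.hi.label for r in records],
            "distance": [r.pair.distance for r in records],
            "joint_rank": [r.pair.joint_rank for r in records],
            "chosen": [r.chosen for r in records],
            "correct": [r.correct for r in records],
            "rt_seconds": [r.rt_seconds for r in records],
        }
    )


def frame_to_records(frame: pd.DataFrame, n_items: int | None = None) -> list[TrialRecord]:
    """Inverse of :func:`records_to_frame` (labels -> Pair objects)."""
    from .schedule import make_items

    if n_items is None:
        labels = set(frame["item_lo"]) | set(frame["item_hi"])
        n_items = max(ord(lb) - ord("A") + 1 for lb in labels)
    items = {it.label: it for it in make_items(n_items)}
    records = []
    for row in frame.itertuples(index=False):
        pair = Pair(items[row.item_lo], items[row.item_hi])
        records.append(
            TrialRecord(
                subject=str(row.subject),
                session=int(row.session),
                trial_index=int(row.trial_index),
                phase=int(row.phase),
                pair=pair,
                chosen=str(row.chosen),
                correct=int(row.correct),
                rt_seconds=float(row.rt_seconds),
            )
        )
    return records


def generate_cohort(
    profile: SpeciesProfile,
    agent_config,
    rt_config: RTConfig | None,
    n_subjects: int,
    seed: int,
    sessions_per_subject: int | None = None,
) -> pd.DataFrame:
    """Simulate a cohort: one fresh schedule + one fresh agent per
    (subject, session), fully reproducible under ``seed``.

    The agent family is dispatched on the config type.  RTs are filled
    from ``rt_config`` unless it is None.
    """
    if n_subjects < 1:
        raise ConfigError(f"n_subjects must be >= 1, got {n_subjects}")
    n_sessions = sessions_per_subject or profile.sessions_per_subject
    if isinstance(agent_config, AssociativeAgentConfig):
        simulate = lambda sched, rng, subj, sess: simulate_associative(  # noqa: E731
            sched, agent_config, rng=rng, subject=subj, session=sess
        )
    elif isinstance(agent_config, RepresentationAgentConfig):
        simulate = lambda sched, rng, subj, sess: simulate_representational(  # noqa: E731
            sched, agent_config, rng=rng, subject=subj, session=sess,
            n_items=profile.n_items,
        )
    else:
        raise ConfigError(f"unknown agent config type {type(agent_config).__name__}")

    frames = []
    streams = np.random.SeedSequence(seed).spawn(n_subjects * n_sessions)
    idx = 0
    for s in range(n_subjects):
        subject = f"{profile.name[0].upper()}{s + 1}"
        for sess in range(1, n_sessions + 1):
            rng = np.random.default_rng(streams[idx])
            idx += 1
            sched = build_schedule(profile, rng=rng)
            records = simulate(sched, rng, subject, sess)
            if rt_config is not None:
                records = simulate_rt(records, rt_config, rng=rng)
            frames.append(records_to_frame(records))
    return pd.concat(frames, ignore_index=True)
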