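"""Trial-record files, run configuration, and the end-to-end pipeline.

Trial records are the single interchange format (comma-separated, UTF-8,
'.' decimal, header required; gzip accepted by file extension), so real
lab data with the same columns can drop into the same analyses.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import analysis
from .agents import (
    RECORD_COLUMNS,
    AssociativeAgentConfig,
    HUMAN_REPRESENTATIONAL,
    HUMAN_RT,
    MONKEY_REPRESENTATIONAL,
    MONKEY_RT,
    RepresentationAgentConfig,
    RTConfig,
    generate_cohort,
)
from .errors import ConfigError, ValidationError
from .schedule import HUMAN, MONKEY, SpeciesProfile, phase_pairs

logger = logging.getLogger("tiseries")

__all__ = [
    "read_records",
    "write_records",
    "RunConfig",
    "run_pipeline",
]

_PROFILES = {"monkey": MONKEY, "human": HUMAN}


def write_records(frame: pd.DataFrame, path: str | Path) -> None:
    """Write trial records as CSV (gzip if the path ends in .gz)."""
    frame = frame[RECORD_COLUMNS]
    frame.to_csv(path, index=False)


def read_records(path: str | Path) -> pd.DataFrame:
    """Load and validate a trial-record CSV.

    Checks column presence, value ranges (phase in {1,2,3}, rt > 0,
    correct in {0,1}), pair-coordinate consistency, and that the chosen
    item belongs to the pair; errors name the offending row (1-based,
    excluding the header) and field.
    """
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"no such file: {path}")
    frame = pd.read_csv(path)
    missing = [c for c in RECORD_COLUMNS if c not in frame.columns]
    if missing:
        raise ValidationError(f"missing columns: {missing}")
    frame = frame[RECORD_COLUMNS]

    def fail_first(mask: pd.Series, fieldname: str, why: str):
        if mask.any():
            row = int(np.flatnonzero(mask.to_numpy())[0]) + 1
            raise ValidationError(f"row {row}: {fieldname} {why}")

    fail_first(~frame["phase"].isin([1, 2, 3]), "phase", "must be 1, 2 or 3")
    fail_first(~frame["correct"].isin([0, 1]), "correct", "must be 0 or 1")
    fail_first(
        frame["rt_seconds"].notna() & (frame["rt_seconds"] <= 0),
        "rt_seconds", "must be > 0",
    )
    in_pair = (frame["chosen"] == frame["item_lo"]) | (frame["chosen"] == frame["item_hi"])
    fail_first(~in_pair, "chosen", "must be one of item_lo/item_hi")
    fail_first(
        frame["correct"] != (frame["chosen"] == frame["item_lo"]).astype(int),
        "correct", "inconsistent with chosen item",
    )
    lo_rank = frame["item_lo"].map(lambda s: ord(str(s)) - ord("A") + 1)
    hi_rank = frame["item_hi"].map(lambda s: ord(str(s)) - ord("A") + 1)
    fail_first(lo_rank >= hi_rank, "item_lo", "must rank earlier than item_hi")
    fail_first(frame["distance"] != hi_rank - lo_rank, "distance", "inconsistent with items")
    fail_first(frame["joint_rank"] != hi_rank + lo_rank, "joint_rank", "inconsistent with items")
    return frame


@dataclass(frozen=True)
class RunConfig:
    """One reproducible simulate-then-analyze run."""

    species: str = "monkey"
    agent: str = "representational"
    n_subjects: int = 3
    sessions_per_subject: int | None = None
    seed: int = 0
    agent_params: dict = field(default_factory=dict)
    rt_params: dict = field(default_factory=dict)
    optimize_gp: bool = False
    trial_bin: int = 20
    out_dir: str = "tiseries_out"
    make_missing_dirs: bool = True
    verbosity: str = "INFO"

    def __post_init__(self):
        if self.species not in _PROFILES:
            raise ConfigError(f"species must be one of {sorted(_PROFILES)}")
        if self.agent not in ("associative", "representational"):
            raise ConfigError("agent must be 'associative' or 'representational'")

    def profile(self) -> SpeciesProfile:
        return _PROFILES[self.species]

    def agent_config(self):
        if self.agent == "associative":
            return AssociativeAgentConfig(**self.agent_params)
        base = (
            MONKEY_REPRESENTATIONAL if self.species == "monkey" else HUMAN_REPRESENTATIONAL
        )
        return dataclasses.replace(base, **self.agent_params)

    def rt_config(self) -> RTConfig:
        base = MONKEY_RT if self.species == "monkey" else HUMAN_RT
        return dataclasses.replace(base, **self.rt_params)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(**d)

    def to_file(self, path: str | Path) -> None:
        path = Path(path)
        text = (
            json.dumps(self.to_dict(), indent=2, sort_keys=True)
            if path.suffix == ".json"
            else yaml.safe_dump(self.to_dict(), sort_keys=True)
        )
        path.write_text(text)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        if path.suffix == ".json":
            return cls.from_dict(json.loads(path.read_text()))
        return cls.from_dict(yaml.safe_load(path.read_text()))


def _estimate_rows(fit: analysis.TimeSeriesFit) -> list[dict]:
    return [
        {
            "pair": fit.pair.label,
            "phase": fit.phase,
            "index": p.x[0],
            "mean": p.response_mean,
            "lo80": p.lo80,
            "hi80": p.hi80,
            "lo99": p.lo99,
            "hi99": p.hi99,
        }
        for p in fit.points
    ]


def run_pipeline(config: RunConfig) -> dict:
    """Simulate a cohort, run the four analysis stages, and write tidy
    tables plus a machine-readable JSON summary.

    Outputs in ``config.out_dir``: records.csv, accuracy_timeseries.csv,
    rt_timeseries.csv, transition.csv, learning_rates.csv, surface_pairs.csv,
    summary.json.  Returns the summary dict.
    """
    out = Path(config.out_dir)
    if not out.exists():
        if not config.make_missing_dirs:
            raise ConfigError(f"output directory {out} does not exist")
        out.mkdir(parents=True)
    logging.basicConfig(level=getattr(logging, config.verbosity.upper(), logging.INFO))
    logger.info("simulating %s cohort (%s agent), seed %d",
                config.species, config.agent, config.seed)

    profile = config.profile()
    frame = generate_cohort(
        profile,
        config.agent_config(),
        config.rt_config(),
        n_subjects=config.n_subjects,
        seed=config.seed,
        sessions_per_subject=config.sessions_per_subject,
    )
    write_records(frame, out / "records.csv")

    def stage(name, fn):
        logger.info("analysis stage: %s", name)
        try:
            return fn()
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

    acc_rows, rt_rows = [], []

    def timeseries():
        for phase in (1, 2, 3):
            for pair in sorted(phase_pairs(phase, profile.n_items)):
                acc_rows.extend(_estimate_rows(
                    analysis.accuracy_timeseries(frame, pair, phase, optimize=config.optimize_gp)
                ))
                rt_rows.extend(_estimate_rows(
                    analysis.rt_timeseries(frame, pair, phase, optimize=config.optimize_gp)
                ))

    stage("timeseries", timeseries)
    pd.DataFrame(acc_rows).to_csv(out / "accuracy_timeseries.csv", index=False)
    pd.DataFrame(rt_rows).to_csv(out / "rt_timeseries.csv", index=False)

    prof = stage("transition", lambda: analysis.transition_profile(frame))
    trans_rows = []
    for cls, ests in prof.classes().items():
        for e in ests:
            lo80, hi80 = e.interval(80)
            lo99, hi99 = e.interval(99)
            trans_rows.append(
                {
                    "class": cls, "presentation": e.presentation,
                    "outcome": e.outcome, "k": e.k, "m": e.m,
                    "mean": e.mean, "lo80": lo80, "hi80": hi80,
                    "lo99": lo99, "hi99": hi99,
                    "accuracy_mean": e.accuracy_mean,
                }
            )
    pd.DataFrame(trans_rows).to_csv(out / "transition.csv", index=False)

    rate_rows = []
    rates_by_phase = {}
    for phase in (2, 3):
        rates = stage(f"rates_phase{phase}",
                      lambda ph=phase: analysis.learning_rates(frame, ph, optimize=config.optimize_gp))
        rates_by_phase[phase] = rates
        for r in rates:
            e = r.estimate
            rate_rows.append(
                {
                    "pair": r.pair.label, "phase": phase, "index": e.x[0],
                    "mean": e.mean, "lo80": e.lo80, "hi80": e.hi80,
                    "lo99": e.lo99, "hi99": e.hi99,
                }
            )
    pd.DataFrame(rate_rows).to_csv(out / "learning_rates.csv", index=False)

    surf = stage("surface", lambda: analysis.joint_surface(
        frame, response="accuracy", trial_bin=config.trial_bin,
        optimize=config.optimize_gp, grid_step=0.5,
    ))
    surf_rt = stage("surface_rt", lambda: analysis.joint_surface(
        frame, response="rt", trial_bin=config.trial_bin,
        optimize=config.optimize_gp, grid_step=0.5,
    ))
    pair_rows = []
    for (pair, pt), (_, pt_rt) in zip(surf.pair_points, surf_rt.pair_points):
        pair_rows.append(
            {
                "pair": pair.label, "distance": pair.distance,
                "joint_rank": pair.joint_rank,
                "accuracy_mean": pt.response_mean,
                "accuracy_lo99": pt.lo99, "accuracy_hi99": pt.hi99,
                "logrt_mean": pt_rt.response_mean,
                "logrt_lo99": pt_rt.lo99, "logrt_hi99": pt_rt.hi99,
            }
        )
    pd.DataFrame(pair_rows).to_csv(out / "surface_pairs.csv", index=False)

    acc_stats = analysis.effect_stats(surf.pair_points, response="accuracy",
                                      seed=config.seed)
    rt_stats = analysis.effect_stats(surf_rt.pair_points, response="rt",
                                     seed=config.seed)
    first_xf = prof.xf[0] if prof.xf else None
    summary = {
        "config": config.to_dict(),
        "n_records": int(len(frame)),
        "first_xf_accuracy": (
            None if first_xf is None else round(first_xf.accuracy_mean, 6)
        ),
        "accuracy_distance_trend": round(acc_stats.distance_trend, 6),
        "accuracy_terminal_contrast": round(acc_stats.terminal_contrast, 6),
        "logrt_distance_trend": round(rt_stats.distance_trend, 6),
        "mean_learning_rate_phase2": round(
            float(np.mean([r.estimate.mean for r in rates_by_phase[2]])), 6
        ),
        "mean_learning_rate_phase3": round(
            float(np.mean([r.estimate.mean for r in rates_by_phase[3]])), 6
        ),
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    logger.info("pipeline complete; outputs in %s", out)
    return summary
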