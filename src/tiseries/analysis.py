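"""Analysis stages: per-pair time series, the phase-transition
presentation profile, learning rates at phase starts, the joint
(trial x distance x joint-rank) surface, and effect summaries.

All analyses consume the tidy trial-record DataFrame produced by the
simulators (or loaded from CSV) and never touch agent internals.
Accuracy series are aggregated across sessions/subjects to binomial
counts per trial index before GP fitting, which keeps exact O(n^3)
inference tractable at session length (<= 760 unique inputs).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import beta as beta_dist
from scipy.stats import spearmanr

from . import gp
from .errors import AnalysisError, ConvergenceError, GPNumericalError, ValidationError
from .schedule import Pair, all_pairs, make_items, phase_pairs

__all__ = [
    "BinomialSeries",
    "TimeSeriesFit",
    "TransitionEstimate",
    "TransitionProfile",
    "PairRate",
    "SurfaceEstimate",
    "EffectStats",
    "aggregate_counts",
    "accuracy_timeseries",
    "rt_timeseries",
    "transition_profile",
    "learning_rates",
    "joint_surface",
    "effect_stats",
]


def _select_pair(frame: pd.DataFrame, pair: Pair, phase: int) -> pd.DataFrame:
    return frame[
        (frame["phase"] == phase)
        & (frame["item_lo"] == pair.lo.label)
        & (frame["item_hi"] == pair.hi.label)
    ]


@dataclass(frozen=True)
class BinomialSeries:
    """Per-trial-index success counts for one pair in one phase."""

    pair: Pair
    phase: int
    trial_index: np.ndarray
    k: np.ndarray
    m: np.ndarray

    @property
    def empty(self) -> bool:
        return len(self.trial_index) == 0

    def __len__(self) -> int:
        return len(self.trial_index)


def aggregate_counts(frame: pd.DataFrame, pair: Pair, phase: int) -> BinomialSeries:
    """Sum correct flags per trial index across sessions and subjects."""
    sel = _select_pair(frame, pair, phase)
    if len(sel) == 0:
        return BinomialSeries(
            pair=pair, phase=phase,
            trial_index=np.empty(0, int), k=np.empty(0, int), m=np.empty(0, int),
        )
    g = sel.groupby("trial_index")["correct"].agg(["sum", "count"]).sort_index()
    return BinomialSeries(
        pair=pair,
        phase=phase,
        trial_index=g.index.to_numpy(int),
        k=g["sum"].to_numpy(int),
        m=g["count"].to_numpy(int),
    )


def _default_accuracy_params(t: np.ndarray) -> gp.KernelParams:
    span = float(np.ptp(t)) if len(t) > 1 else 1.0
    return gp.KernelParams(variance=4.0, lengthscales=(max(10.0, span / 4.0),))


#: Hyperparameter search bounds for binomial accuracy fits.  The signal
#: variance is capped at 36 (latent sd 6, probabilities ~0.0025-0.9975):
#: log-odds beyond that range are observationally indistinguishable, and
#: an unbounded amplitude is favored by the marginal likelihood whenever
#: counts saturate, destabilizing edge derivatives.
ACCURACY_BOUNDS = {"variance": (1e-3, 36.0)}


@dataclass
class TimeSeriesFit:
    """A fitted per-pair, per-phase curve with per-trial predictions."""

    pair: Pair
    phase: int
    posterior: gp.LatentPosterior
    points: list[gp.PredictionPoint]

    @property
    def trial_index(self) -> np.ndarray:
        return np.array([p.x[0] for p in self.points])

    @property
    def mean(self) -> np.ndarray:
        return np.array([p.response_mean for p in self.points])


def accuracy_timeseries(
    frame: pd.DataFrame,
    pair: Pair,
    phase: int,
    params: gp.KernelParams | None = None,
    optimize: bool = False,
    predict_at: np.ndarray | None = None,
) -> TimeSeriesFit:
    """Binomial-Laplace GP accuracy curve over trial index for one pair/phase."""
    series = aggregate_counts(frame, pair, phase)
    if series.empty:
        raise AnalysisError(
            f"no trials for pair {pair.label} in phase {phase}"
        )
    t = series.trial_index.astype(float)
    data = gp.GPData.binomial(t, series.k, series.m)
    if params is None:
        params = _default_accuracy_params(t)
    if optimize:
        params, _ = gp.optimize_hyperparameters(data, params, bounds=ACCURACY_BOUNDS)
    post = gp.fit_bernoulli_laplace(data, params)
    if predict_at is None:
        predict_at = np.arange(series.trial_index.min(), series.trial_index.max() + 1)
    points = gp.predict(post, np.asarray(predict_at, float))
    return TimeSeriesFit(pair=pair, phase=phase, posterior=post, points=points)


def rt_timeseries(
    frame: pd.DataFrame,
    pair: Pair,
    phase: int,
    params: gp.KernelParams | None = None,
    noise_variance: float | None = None,
    optimize: bool = False,
    predict_at: np.ndarray | None = None,
) -> TimeSeriesFit:
    """Gaussian GP on log RT over trial index for one pair/phase.

    Replicates at one trial index are averaged; their count scales down
    the observation noise (exact sufficient-statistic aggregation).
    """
    sel = _select_pair(frame, pair, phase)
    if len(sel) == 0:
        raise AnalysisError(f"no trials for pair {pair.label} in phase {phase}")
    if (sel["rt_seconds"] <= 0).any() or sel["rt_seconds"].isna().any():
        raise ValidationError("rt_seconds must be positive for RT analysis")
    logrt = np.log(sel["rt_seconds"].to_numpy(float))
    t_all = sel["trial_index"].to_numpy(float)
    g = pd.DataFrame({"t": t_all, "y": logrt}).groupby("t")["y"]
    t = np.array(sorted(g.groups))
    ybar = g.mean().to_numpy()
    m = g.count().to_numpy(float)
    if noise_variance is None:
        # pooled within-index variance when replicated, else overall variance
        resid = logrt - g.transform("mean").to_numpy()
        dof = len(logrt) - len(t)
        noise_variance = float(resid @ resid / dof) if dof > 0 else float(
            max(np.var(logrt), 1e-4)
        )
        noise_variance = max(noise_variance, 1e-6)
    span = float(np.ptp(t)) if len(t) > 1 else 1.0
    if params is None:
        params = gp.KernelParams(
            variance=max(float(np.var(ybar)), 1e-3),
            lengthscales=(max(10.0, span / 4.0),),
        )
    data = gp.GPData.gaussian(t, ybar, noise_variance, m=m)
    if optimize:
        params, noise_variance, _ = gp.optimize_hyperparameters(
            data, params, optimize_noise=True
        )
        data = gp.GPData.gaussian(t, ybar, noise_variance, m=m)
    post = gp.fit_gaussian(data, params)
    if predict_at is None:
        predict_at = np.arange(t.min(), t.max() + 1)
    points = gp.predict(post, np.asarray(predict_at, float))
    return TimeSeriesFit(pair=pair, phase=phase, posterior=post, points=points)


@dataclass(frozen=True)
class TransitionEstimate:
    """Beta-binomial posterior (uniform prior) for one presentation slot.

    ``outcome`` names the counted event: "choose_F" for FG and xF slots,
    "accuracy" (choosing the novel item) for xG slots.  Accuracy views
    flip the Beta posterior when the counted event is an error.
    """

    cls: str  # "FG_phase1" | "FG" | "xF" | "xG"
    presentation: int
    k: int
    m: int
    outcome: str
    counted_is_correct: bool

    @property
    def a(self) -> float:
        return self.k + 1.0

    @property
    def b(self) -> float:
        return self.m - self.k + 1.0

    @property
    def mean(self) -> float:
        return self.a / (self.a + self.b)

    def interval(self, level: int) -> tuple[float, float]:
        tail = {80: 0.10, 99: 0.005}[level]
        return (
            float(beta_dist.ppf(tail, self.a, self.b)),
            float(beta_dist.ppf(1.0 - tail, self.a, self.b)),
        )

    @property
    def accuracy_mean(self) -> float:
        return self.mean if self.counted_is_correct else 1.0 - self.mean

    def accuracy_interval(self, level: int) -> tuple[float, float]:
        lo, hi = self.interval(level)
        if self.counted_is_correct:
            return lo, hi
        return 1.0 - hi, 1.0 - lo


@dataclass
class TransitionProfile:
    """Presentation-indexed estimates around the phase 1 -> 2 boundary."""

    fg_phase1: list[TransitionEstimate]
    fg: list[TransitionEstimate]
    xf: list[TransitionEstimate]
    xg: list[TransitionEstimate]
    truncated: bool = False

    def classes(self) -> dict[str, list[TransitionEstimate]]:
        return {
            "FG_phase1": self.fg_phase1,
            "FG": self.fg,
            "xF": self.xf,
            "xG": self.xg,
        }


def _instance_counts(
    sel: pd.DataFrame, chose_event: pd.Series, n_slots: int, from_end: bool = False
) -> list[tuple[int, int, int]]:
    """Pool (k, m) per within-session presentation index (1-based)."""
    df = sel.copy()
    df["event"] = chose_event.to_numpy()
    df = df.sort_values(["subject", "session", "trial_index"])
    grp = df.groupby(["subject", "session"], sort=False)
    if from_end:
        df = grp.tail(n_slots).copy()
        grp2 = df.groupby(["subject", "session"], sort=False)
        sizes = grp2["trial_index"].transform("size")
        # index so the final presentation is n_slots
        df["slot"] = grp2.cumcount() + 1 + (n_slots - sizes)
    else:
        df["slot"] = grp.cumcount() + 1
        df = df[df["slot"] <= n_slots]
    out = []
    for slot in range(1, n_slots + 1):
        rows = df[df["slot"] == slot]
        out.append((slot, int(rows["event"].sum()), int(len(rows))))
    return out


def transition_profile(
    frame: pd.DataFrame, n_presentations: int = 6, n_last_phase1: int = 4
) -> TransitionProfile:
    """Choice profile around the massed-block boundary.

    For FG (the massed pair) the counted event is choosing F — the
    correct response.  For xF pairs (F with a not-previously-massed
    item) it is choosing F — an error, so above-chance accuracy means
    *avoiding* the previously always-rewarded F.  For xG pairs the
    counted event is choosing the novel item (accuracy).  Each slot gets
    a Beta-binomial posterior with uniform prior, pooled across
    sessions by within-session presentation order.
    """
    labels = set(frame["item_lo"]) | set(frame["item_hi"])
    n_items = max(ord(lb) - ord("A") + 1 for lb in labels)
    items = make_items(n_items)
    f_lab, g_lab = items[-2].label, items[-1].label

    is_fg = (frame["item_lo"] == f_lab) & (frame["item_hi"] == g_lab)
    is_xf = (frame["item_hi"] == f_lab)
    is_xg = (frame["item_hi"] == g_lab) & (frame["item_lo"] != f_lab)

    truncated = False

    def build(sel, event, cls, n_slots, counted_is_correct, outcome, from_end=False):
        nonlocal truncated
        ests = []
        for slot, k, m in _instance_counts(sel, event, n_slots, from_end=from_end):
            if m == 0:
                truncated = True
                continue
            ests.append(
                TransitionEstimate(
                    cls=cls, presentation=slot, k=k, m=m,
                    outcome=outcome, counted_is_correct=counted_is_correct,
                )
            )
        if len(ests) < n_slots:
            truncated = True
        return ests

    ph1 = frame[(frame["phase"] == 1) & is_fg]
    ph2 = frame[frame["phase"] == 2]
    if len(ph1) == 0 or len(ph2) == 0:
        raise AnalysisError("transition profile needs phases 1 and 2 in the data")

    fg1 = build(
        ph1, ph1["chosen"] == f_lab, "FG_phase1", n_last_phase1,
        counted_is_correct=True, outcome="choose_F", from_end=True,
    )
    sel_fg = ph2[is_fg.loc[ph2.index]]
    fg2 = build(
        sel_fg, sel_fg["chosen"] == f_lab, "FG", n_presentations,
        counted_is_correct=True, outcome="choose_F",
    )
    sel_xf = ph2[is_xf.loc[ph2.index]]
    xf = build(
        sel_xf, sel_xf["chosen"] == f_lab, "xF", n_presentations,
        counted_is_correct=False, outcome="choose_F",
    )
    sel_xg = ph2[is_xg.loc[ph2.index]]
    xg = build(
        sel_xg, sel_xg["correct"] == 1, "xG", n_presentations,
        counted_is_correct=True, outcome="accuracy",
    )
    return TransitionProfile(fg_phase1=fg1, fg=fg2, xf=xf, xg=xg, truncated=truncated)


@dataclass(frozen=True)
class PairRate:
    """Learning rate (latent log-odds slope) for one pair at a phase start."""

    pair: Pair
    estimate: gp.DerivativeEstimate


def _optimize_shared(
    datas: list[gp.GPData], init: gp.KernelParams, bounds: dict
) -> gp.KernelParams:
    """Common kernel hyperparameters for independent per-pair GPs, by
    maximizing the summed (Laplace) log marginal likelihood."""
    from scipy.optimize import minimize

    var_lo, var_hi = bounds.get("variance", (1e-3, 1e3))
    ls_lo, ls_hi = bounds.get("lengthscale", (5.0, 1000.0))

    def objective(log_theta):
        v, l = np.exp(log_theta)
        try:
            par = gp.KernelParams(v, (l,), jitter=init.jitter)
            return -sum(gp.fit_bernoulli_laplace(d, par).log_marginal for d in datas)
        except (GPNumericalError, ConvergenceError):
            return np.inf

    x0 = np.log([init.variance, init.lengthscales[0]])
    res = minimize(
        objective, x0, method="L-BFGS-B",
        bounds=[(np.log(var_lo), np.log(var_hi)), (np.log(ls_lo), np.log(ls_hi))],
    )
    best = res.x if np.isfinite(res.fun) and res.fun <= objective(x0) else x0
    v, l = np.exp(best)
    return gp.KernelParams(v, (l,), jitter=init.jitter)


def learning_rates(
    frame: pd.DataFrame,
    phase: int,
    params: gp.KernelParams | None = None,
    optimize: bool | str = False,
    at_trial: float | None = None,
) -> list[PairRate]:
    """Per-pair derivative of the latent accuracy at the phase's first
    trial, sorted by (symbolic distance, joint rank).

    ``optimize`` may be False (heuristic fixed kernel), True (per-pair
    marginal-likelihood optimization), or "shared" (one kernel optimized
    over the summed marginal likelihood of all pairs).  Sharing the
    kernel keeps the edge attenuation of the derivative comparable
    across pairs, which matters when ranking pairs by learning rate.
    """
    if phase not in (2, 3):
        raise AnalysisError(f"learning rates are defined at phase 2 or 3 starts, got {phase}")
    labels = set(frame["item_lo"]) | set(frame["item_hi"])
    n_items = max(ord(lb) - ord("A") + 1 for lb in labels)
    in_phase = frame[frame["phase"] == phase]
    if len(in_phase) == 0:
        raise AnalysisError(f"no phase-{phase} trials in the data")
    first_trial = float(in_phase["trial_index"].min()) if at_trial is None else at_trial
    pairs = sorted(phase_pairs(phase, n_items), key=lambda p: (p.distance, p.joint_rank))
    if optimize == "shared":
        datas = []
        for pair in pairs:
            s = aggregate_counts(frame, pair, phase)
            if s.empty:
                raise AnalysisError(f"no trials for pair {pair.label} in phase {phase}")
            datas.append(gp.GPData.binomial(s.trial_index.astype(float), s.k, s.m))
        init = params or _default_accuracy_params(
            in_phase["trial_index"].to_numpy(float)
        )
        shared = _optimize_shared(datas, init, ACCURACY_BOUNDS)
        rates = []
        for pair, data in zip(pairs, datas):
            post = gp.fit_bernoulli_laplace(data, shared)
            est = gp.derivative(post, np.array([[first_trial]]))[0]
            rates.append(PairRate(pair=pair, estimate=est))
        return rates
    rates = []
    for pair in pairs:
        fit = accuracy_timeseries(
            frame, pair, phase, params=params, optimize=bool(optimize),
            predict_at=np.array([first_trial]),
        )
        est = gp.derivative(fit.posterior, np.array([[first_trial]]))[0]
        rates.append(PairRate(pair=pair, estimate=est))
    return rates


def _valid_pair_mask(D: np.ndarray, J: np.ndarray, n_items: int) -> np.ndarray:
    """Where (distance, joint rank) corresponds to an actual pair."""
    with np.errstate(invalid="ignore"):
        lo = (J - D) / 2.0
        hi = (J + D) / 2.0
    integral = (np.mod(J - D, 2) == 0) & (np.mod(D, 1) == 0) & (np.mod(J, 1) == 0)
    return integral & (D >= 1) & (lo >= 1) & (hi <= n_items)


@dataclass
class SurfaceEstimate:
    """Joint-model estimates over the (distance, joint-rank) plane at a
    fixed trial.  Grid cells not on a valid pair coordinate are
    interpolated regions of the latent function."""

    response: str  # "accuracy" | "rt"
    at_trial: float
    distance: np.ndarray  # grid axis
    joint_rank: np.ndarray  # grid axis
    mean: np.ndarray  # (len(distance), len(joint_rank))
    lo99: np.ndarray
    hi99: np.ndarray
    valid_pair: np.ndarray  # bool mask, same shape
    pair_points: list[tuple[Pair, gp.PredictionPoint]]
    posterior: gp.LatentPosterior = field(repr=False, default=None)


def _binned_inputs(frame: pd.DataFrame, trial_bin: int) -> pd.DataFrame:
    df = frame.copy()
    starts = df.groupby("phase")["trial_index"].transform("min")
    df["bin"] = (df["trial_index"] - starts) // trial_bin
    df["bin_key"] = list(zip(df["phase"], df["bin"]))
    centers = df.groupby("bin_key")["trial_index"].transform("mean")
    df["t_center"] = centers
    return df


def joint_surface(
    frame: pd.DataFrame,
    at_trial: float | None = None,
    response: str = "accuracy",
    trial_bin: int = 20,
    params: gp.KernelParams | None = None,
    optimize: bool = False,
    grid_step: float = 0.1,
) -> SurfaceEstimate:
    """Single GP over (trial, distance, joint rank), evaluated at
    ``at_trial`` (default: the first phase-3 trial) on an interpolation
    grid and at the valid pair coordinates.

    Trial indices are binned within phase (``trial_bin`` trials per bin,
    bin-mean used as the trial coordinate) so the joint model keeps a
    tractable number of unique inputs.
    """
    if response not in ("accuracy", "rt"):
        raise AnalysisError(f"response must be 'accuracy' or 'rt', got {response!r}")
    labels = set(frame["item_lo"]) | set(frame["item_hi"])
    n_items = max(ord(lb) - ord("A") + 1 for lb in labels)
    ph3 = frame[frame["phase"] == 3]
    if len(ph3) == 0:
        raise AnalysisError("joint surface needs phase-3 data")
    if at_trial is None:
        at_trial = float(ph3["trial_index"].min())
    df = _binned_inputs(frame, trial_bin)
    keys = ["t_center", "distance", "joint_rank"]
    if response == "accuracy":
        g = df.groupby(keys)["correct"].agg(["sum", "count"]).reset_index()
        X = g[keys].to_numpy(float)
        data = gp.GPData.binomial(X, g["sum"].to_numpy(), g["count"].to_numpy())
        if params is None:
            span_t = max(float(np.ptp(X[:, 0])), 1.0)
            params = gp.KernelParams(
                variance=4.0, lengthscales=(max(20.0, span_t / 4.0), 2.0, 4.0)
            )
        if optimize:
            params, _ = gp.optimize_hyperparameters(data, params, bounds=ACCURACY_BOUNDS)
        post = gp.fit_bernoulli_laplace(data, params)
    else:
        if (df["rt_seconds"] <= 0).any() or df["rt_seconds"].isna().any():
            raise ValidationError("rt_seconds must be positive for RT analysis")
        df = df.assign(logrt=np.log(df["rt_seconds"]))
        g = df.groupby(keys)["logrt"].agg(["mean", "count", "var"]).reset_index()
        X = g[keys].to_numpy(float)
        within = g["var"].to_numpy()
        counts = g["count"].to_numpy(float)
        dof = counts - 1
        noise = (
            float(np.nansum(within * dof) / max(np.sum(dof), 1.0))
            if np.sum(dof) > 0
            else float(max(np.var(df["logrt"]), 1e-4))
        )
        noise = max(noise, 1e-6)
        data = gp.GPData.gaussian(X, g["mean"].to_numpy(), noise, m=counts)
        if params is None:
            span_t = max(float(np.ptp(X[:, 0])), 1.0)
            params = gp.KernelParams(
                variance=max(float(np.var(g["mean"])), 1e-3),
                lengthscales=(max(20.0, span_t / 4.0), 2.0, 4.0),
            )
        if optimize:
            params, noise, _ = gp.optimize_hyperparameters(data, params, optimize_noise=True)
            data = gp.GPData.gaussian(X, g["mean"].to_numpy(), noise, m=counts)
        post = gp.fit_gaussian(data, params)

    d_axis = np.round(np.arange(1.0, (n_items - 1) + grid_step / 2, grid_step), 10)
    j_axis = np.round(np.arange(3.0, (2 * n_items - 1) + grid_step / 2, grid_step), 10)
    D, J = np.meshgrid(d_axis, j_axis, indexing="ij")
    Xg = np.column_stack(
        [np.full(D.size, at_trial), D.ravel(), J.ravel()]
    )
    pts = gp.predict(post, Xg)
    mean = np.array([p.response_mean for p in pts]).reshape(D.shape)
    lo99 = np.array([p.lo99 for p in pts]).reshape(D.shape)
    hi99 = np.array([p.hi99 for p in pts]).reshape(D.shape)
    valid = _valid_pair_mask(D, J, n_items)

    pair_list = sorted(all_pairs(n_items), key=lambda p: (p.distance, p.joint_rank))
    Xp = np.array([[at_trial, p.distance, p.joint_rank] for p in pair_list], float)
    pair_pts = gp.predict(post, Xp)
    return SurfaceEstimate(
        response=response,
        at_trial=at_trial,
        distance=d_axis,
        joint_rank=j_axis,
        mean=mean,
        lo99=lo99,
        hi99=hi99,
        valid_pair=valid,
        pair_points=list(zip(pair_list, pair_pts)),
        posterior=post,
    )


@dataclass(frozen=True)
class EffectStats:
    """Distance-effect trend and terminal-item contrast with MC intervals."""

    response: str
    distance_trend: float
    distance_trend_ci99: tuple[float, float]
    terminal_contrast: float
    terminal_contrast_ci99: tuple[float, float]
    n_draws: int


def effect_stats(
    pair_points: list[tuple[Pair, gp.PredictionPoint]],
    response: str = "accuracy",
    n_draws: int = 2000,
    seed: int = 0,
    terminal_ranks: tuple[int, ...] | None = None,
) -> EffectStats:
    """Spearman trend of the response vs symbolic distance across pairs,
    and the terminal-item contrast (pairs containing a terminal item
    minus the rest), with Monte-Carlo credible intervals from
    independent latent marginal draws.
    """
    if len(pair_points) < 3:
        raise AnalysisError("effect statistics need at least 3 pairs")
    pairs = [p for p, _ in pair_points]
    dists = np.array([p.distance for p in pairs], float)
    if len(np.unique(dists)) < 3:
        raise AnalysisError("distance trend undefined with fewer than 3 distinct distances")
    ranks = sorted({p.lo.rank for p in pairs} | {p.hi.rank for p in pairs})
    if terminal_ranks is None:
        terminal_ranks = (ranks[0], ranks[-1])
    is_terminal = np.array(
        [p.lo.rank in terminal_ranks or p.hi.rank in terminal_ranks for p in pairs]
    )
    means = np.array([pt.response_mean for _, pt in pair_points])
    mus = np.array([pt.latent_mean for _, pt in pair_points])
    sds = np.array([pt.latent_sd for _, pt in pair_points])

    def stats(values):
        if np.ptp(values) == 0.0:  # constant response: no trend by definition
            trend = 0.0
        else:
            trend = spearmanr(values, dists).statistic
        contrast = float(np.mean(values[is_terminal]) - np.mean(values[~is_terminal]))
        return trend, contrast

    trend0, contrast0 = stats(means)
    rng = np.random.default_rng(seed)
    draws = rng.normal(mus, sds, size=(n_draws, len(pairs)))
    if response == "accuracy":
        draws = expit(draws)
    trends = np.empty(n_draws)
    contrasts = np.empty(n_draws)
    for i in range(n_draws):
        trends[i], contrasts[i] = stats(draws[i])
    return EffectStats(
        response=response,
        distance_trend=float(trend0),
        distance_trend_ci99=(
            float(np.quantile(trends, 0.005)),
            float(np.quantile(trends, 0.995)),
        ),
        terminal_contrast=contrast0,
        terminal_contrast_ci99=(
            float(np.quantile(contrasts, 0.005)),
            float(np.quantile(contrasts, 0.995)),
        ),
        n_draws=n_draws,
    )
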