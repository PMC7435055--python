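"""Per-organoid feature extraction and evolutionary least-squares fitting.

Each organoid's three trajectories are reduced to a 13-parameter static
feature vector.  Timing and level features (``t_min``, ``act_min``,
``t_max``, ``act_ss``, ``t_detach``) are read directly from the data;
rate constants and the theoretical actin maximum are estimated by
differential evolution on the regime-separated closed-form solutions,
minimizing the sum of squared residuals segment by segment.

Segment ownership: because the true regime switch generally falls
*between* samples, the sample at an extracted boundary (minimum, peak,
detachment point) may still lie on the previous regime's curve.  It is
therefore excluded from the following segment's fit; each segment is
anchored at its first unambiguous sample.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import differential_evolution, minimize_scalar

from .models import Trajectory

__all__ = [
    "PARAM_NAMES",
    "CellFeatureVector",
    "FitConfig",
    "NonConformingTrajectoryError",
    "TimingFeatures",
    "extract_timing_features",
    "detect_detachment",
    "fit_actin_rates",
    "fit_repair_rate",
    "fit_exfoliation",
    "fit_cell",
    "fit_cohort",
]

logger = logging.getLogger(__name__)

#: The 13 per-cell model parameters, in canonical reporting order.
PARAM_NAMES = (
    "act_depoly1",
    "act_depoly2",
    "act_poly",
    "act_max",
    "act_min",
    "act_ss",
    "dcd_max",
    "k_repair",
    "k_run",
    "k_stay",
    "t_detach",
    "t_max",
    "t_min",
)


class NonConformingTrajectoryError(ValueError):
    """Trajectory lacks the structure the model assumes (e.g. no peak)."""


@dataclass
class CellFeatureVector:
    """The static features of one organoid: 13 model parameters plus
    initial conditions, provenance labels and fit diagnostics."""

    organoid_id: str = "cell"
    treatment: str = "control"
    act_depoly1: float = np.nan
    act_depoly2: float = np.nan
    act_poly: float = np.nan
    act_max: float = np.nan
    act_min: float = np.nan
    act_ss: float = np.nan
    dcd_max: float = np.nan
    k_repair: float = np.nan
    k_run: float = np.nan
    k_stay: float = np.nan
    t_detach: float = np.nan
    t_max: float = np.nan
    t_min: float = np.nan
    act0: float = 1.0
    da0: float = 100.0
    dcd0: float = 0.0
    sse_actin: float = np.nan
    sse_da: float = np.nan
    sse_dcd: float = np.nan
    flags: tuple[str, ...] = ()

    def parameters(self) -> dict[str, float]:
        """The 13 model parameters as a plain dict."""
        return {name: getattr(self, name) for name in PARAM_NAMES}

    def to_row(self) -> dict:
        row = {"organoid_id": self.organoid_id, "treatment": self.treatment}
        row.update(self.parameters())
        row.update(
            act0=self.act0,
            da0=self.da0,
            dcd0=self.dcd0,
            sse_actin=self.sse_actin,
            sse_da=self.sse_da,
            sse_dcd=self.sse_dcd,
            flags=";".join(self.flags),
        )
        return row


@dataclass(frozen=True)
class FitConfig:
    """Settings of the evolutionary least-squares optimizer.

    ``rate_bounds`` (min⁻¹) bound every fitted rate constant;
    ``act_max_factor`` bounds the theoretical actin maximum at that
    multiple of the observed peak.  The seed makes fits bit-reproducible.
    """

    popsize: int = 30
    maxiter: int = 300
    tol: float = 1e-8
    seed: int = 42
    rate_bounds: tuple[float, float] = (0.0, 50.0)
    act_max_factor: float = 5.0
    ss_window: int = 3


@dataclass(frozen=True)
class TimingFeatures:
    """Directly extracted actin timing/level features."""

    t_min: float
    act_min: float
    t_max: float
    act_ss: float
    i_min: int
    i_max: int


def _de(objective, bounds, config: FitConfig):
    return differential_evolution(
        objective,
        bounds,
        popsize=config.popsize,
        maxiter=config.maxiter,
        tol=config.tol,
        seed=config.seed,
        polish=True,
        init="latinhypercube",
        updating="deferred",
    )


# ---------------------------------------------------------------------------
# direct extraction


def extract_timing_features(actin: Trajectory, ss_window: int = 3) -> TimingFeatures:
    """Read the actin timing events and levels directly from the data.

    ``t_min`` is the time of the global minimum restricted to samples
    before the global maximum; ``t_max`` the time of the global maximum
    after it; ``act_ss`` the mean of the final ``ss_window`` samples.
    Ties break to the earliest occurrence.  Trajectories without an
    interior minimum followed by an interior maximum (constant or
    monotone traces) are rejected.
    """
    if actin.channel != "actin":
        raise ValueError("expected the actin channel")
    if len(actin) < 5:
        raise NonConformingTrajectoryError("need at least 5 samples")
    v = actin.values
    i_peak = int(np.argmax(v))
    if i_peak == 0:
        raise NonConformingTrajectoryError("no samples before the global maximum")
    i_min = int(np.argmin(v[:i_peak]))
    rest = v[i_min:]
    i_max = i_min + int(np.argmax(rest))
    if not (0 < i_min < i_max < len(v) - 1):
        raise NonConformingTrajectoryError(
            "no interior minimum/maximum: trajectory is monotone or constant"
        )
    return TimingFeatures(
        t_min=float(actin.times[i_min]),
        act_min=float(v[i_min]),
        t_max=float(actin.times[i_max]),
        act_ss=float(np.mean(v[-ss_window:])),
        i_min=i_min,
        i_max=i_max,
    )


# ---------------------------------------------------------------------------
# detachment changepoint


@dataclass(frozen=True)
class DetachmentFit:
    t_detach: float
    index: int
    at_boundary: bool
    sse: float


def _saturating_sse(tau: float, y_tau: float, t: np.ndarray, y: np.ndarray,
                    k_hi: float = 50.0) -> float:
    """Best SSE of y ≈ L + (y_tau − L)·exp(−k(t−τ)) over (L, k).

    For fixed k the attractor L enters linearly and is solved in closed
    form; the scalar profile over k is minimized by bounded search.
    """
    dt = t - tau

    def profiled_sse(k: float) -> float:
        e = np.exp(-k * dt)
        w = 1.0 - e
        denom = float(w @ w)
        resid = y - y_tau * e
        L = float(w @ resid) / denom if denom > 1e-300 else 0.0
        r = resid - L * w
        return float(r @ r)

    res = minimize_scalar(
        profiled_sse, bounds=(1e-8, k_hi), method="bounded",
        options={"xatol": 1e-6, "maxiter": 200},
    )
    return min(float(res.fun), profiled_sse(1e-8))


def detect_detachment(dcd: Trajectory, min_segment: int = 3) -> DetachmentFit:
    """Locate the detachment time by exhaustive two-segment changepoint search.

    Every observed time τ (with at least ``min_segment`` samples on each
    side, the sample at τ shared) is scored by the total SSE of a straight
    line on [0, τ] plus a saturating exponential on [τ, end]; the argmin τ
    is returned.  A best fit at the first or last candidate — or a fit no
    better than a single global line (a cell that never detaches) — sets
    ``at_boundary``.
    """
    if len(dcd) < 2 * min_segment:
        raise NonConformingTrajectoryError(
            f"need at least {2 * min_segment} samples for changepoint search"
        )
    t, y = dcd.times, dcd.values
    lo, hi = min_segment - 1, len(t) - min_segment  # candidate index range
    best = (np.inf, lo)
    for i in range(lo, hi + 1):
        coef = np.polyfit(t[: i + 1], y[: i + 1], 1)
        sse_pre = float(np.sum((np.polyval(coef, t[: i + 1]) - y[: i + 1]) ** 2))
        sse_post = _saturating_sse(t[i], y[i], t[i:], y[i:])
        total = sse_pre + sse_post
        if total < best[0] - 1e-15:
            best = (total, i)
    sse, i = best
    line = np.polyfit(t, y, 1)
    sse_line = float(np.sum((np.polyval(line, t) - y) ** 2))
    no_break = sse_line <= sse * (1.0 + 1e-9) + 1e-12
    return DetachmentFit(
        t_detach=float(t[i]),
        index=i,
        at_boundary=bool(i in (lo, hi) or no_break),
        sse=sse,
    )


# ---------------------------------------------------------------------------
# evolutionary segment fits


@dataclass(frozen=True)
class ActinRateFit:
    act_depoly1: float
    act_poly: float
    act_depoly2: float
    act_max: float
    sse: float
    flags: tuple[str, ...]


def _decay_fit(t, y, attractor_bounds, config) -> tuple[float, float, float]:
    """Fit exponential relaxation (rate, attractor), anchored at the
    segment's first observation; returns (rate, attractor, sse).

    The attractor is estimated jointly with the rate: the decay targets
    (``act_min``, ``act_ss``) are model attractors that the trajectory
    approaches but need not reach, so pinning them to an observed level
    would bias the rate.
    """
    t0, y0 = t[0], y[0]

    def objective(x):
        r = x[1] + (y0 - x[1]) * np.exp(-x[0] * (t - t0)) - y
        return float(r @ r)

    res = _de(objective, [config.rate_bounds, attractor_bounds], config)
    return float(res.x[0]), float(res.x[1]), float(res.fun)


def fit_actin_rates(
    actin: Trajectory, timing: TimingFeatures, config: FitConfig | None = None
) -> ActinRateFit:
    """Fit the three actin rate constants and the theoretical maximum.

    Each rate is estimated on its own regime's samples with the
    closed-form segment solution anchored at the segment's first
    unambiguous observation: ``act_depoly1`` on the initial decay toward
    the (jointly fitted) minimum attractor, ``(act_poly, act_max)``
    jointly on the rise (the attractor is *theoretical* and may exceed
    the observed peak), and ``act_depoly2`` on the relaxation toward the
    (jointly fitted) steady-state attractor.  The samples at the
    extracted minimum and peak belong to the regimes that *end* there
    and are excluded from the following segment.
    """
    config = config or FitConfig()
    t, y = actin.times, actin.values
    i_min, i_max = timing.i_min, timing.i_max
    flags: list[str] = []
    sse = 0.0

    # initial decay: samples up to and including the extracted minimum
    if i_min + 1 >= 3:
        seg_t, seg_y = t[: i_min + 1], y[: i_min + 1]
        act_depoly1, _, s = _decay_fit(
            seg_t, seg_y, (0.0, float(np.max(seg_y))), config
        )
        sse += s
    else:
        act_depoly1 = np.nan
        flags.append("actin_decay1_too_short")

    # rise: strictly after the minimum, through the peak; act_max joint
    if i_max - i_min >= 3:
        seg_t, seg_y = t[i_min + 1 : i_max + 1], y[i_min + 1 : i_max + 1]
        peak = float(np.max(seg_y))
        a0, t0 = seg_y[0], seg_t[0]

        def rise_objective(x):
            poly, amax = x
            r = amax + (a0 - amax) * np.exp(-poly * (seg_t - t0)) - seg_y
            return float(r @ r)

        res = _de(
            rise_objective,
            [config.rate_bounds, (peak, config.act_max_factor * peak)],
            config,
        )
        act_poly, act_max = float(res.x[0]), float(res.x[1])
        sse += float(res.fun)
    else:
        act_poly = act_max = np.nan
        flags.append("actin_rise_too_short")

    # final decay: strictly after the peak
    if len(t) - i_max - 1 >= 3:
        seg_t, seg_y = t[i_max + 1 :], y[i_max + 1 :]
        act_depoly2, _, s = _decay_fit(
            seg_t, seg_y, (0.0, float(np.max(seg_y))), config
        )
        sse += s
    else:
        act_depoly2 = np.nan
        flags.append("actin_decay2_too_short")

    return ActinRateFit(
        act_depoly1=act_depoly1,
        act_poly=act_poly,
        act_depoly2=act_depoly2,
        act_max=act_max,
        sse=sse,
        flags=tuple(flags),
    )


@dataclass(frozen=True)
class RepairFit:
    k_repair: float
    da0: float
    sse: float


def fit_repair_rate(da: Trajectory, config: FitConfig | None = None) -> RepairFit:
    """Fit the exponential repair rate of the damaged area.

    The initial area is pinned to the first observation (damage is
    maximal at t = 0) and the single rate is found by evolutionary SSE
    minimization.  On noiseless data this coincides with the log-linear
    regression slope.
    """
    config = config or FitConfig()
    if np.any(da.values < 0) or da.values[0] <= 0:
        raise ValueError(
            "damaged-area values must be non-negative with a positive initial area"
        )
    t, y = da.times, da.values
    da0 = float(y[0])

    def objective(x):
        r = da0 * np.exp(-x[0] * (t - t[0])) - y
        return float(r @ r)

    res = _de(objective, [config.rate_bounds], config)
    return RepairFit(k_repair=float(res.x[0]), da0=da0, sse=float(res.fun))


def loglinear_repair_rate(da: Trajectory) -> float:
    """Analytic estimate of k_repair: minus the slope of log(DA) vs t."""
    slope = np.polyfit(da.times, np.log(da.values), 1)[0]
    return float(max(-slope, 0.0))


@dataclass(frozen=True)
class ExfoliationFit:
    k_stay: float
    k_run: float
    dcd_max: float
    sse: float
    flags: tuple[str, ...]


def fit_exfoliation(
    dcd: Trajectory, t_detach: float, config: FitConfig | None = None
) -> ExfoliationFit:
    """Fit the dead-cell drift and exfoliation parameters around ``t_detach``.

    ``k_stay`` is the least-squares slope of the pre-detachment segment
    (clipped at zero); ``(k_run, dcd_max)`` are fitted on the
    post-detachment samples with the saturating closed form anchored at
    the first post-detachment observation, attractor
    ``dcd_max + k_stay/k_run``.  The sample at ``t_detach`` itself sits
    at the regime boundary (the true switch falls between samples) and
    is excluded from both segments.
    """
    config = config or FitConfig()
    t, y = dcd.times, dcd.values
    pre = t < t_detach
    post = t > t_detach
    flags: list[str] = []

    if pre.sum() >= 2:
        k_stay = float(max(np.polyfit(t[pre], y[pre], 1)[0], 0.0))
        coef = np.polyfit(t[pre], y[pre], 1)
        sse = float(np.sum((np.polyval(coef, t[pre]) - y[pre]) ** 2))
    else:
        k_stay, sse = np.nan, 0.0
        flags.append("dcd_pre_too_short")

    if post.sum() >= 3 and np.isfinite(k_stay):
        pt, py = t[post], y[post]
        tau, y_tau = pt[0], py[0]
        y_hi = max(float(np.max(y)), 1e-6)

        def objective(x):
            k_run, dcd_max = x
            if k_run < 1e-9:
                pred = y_tau + k_stay * (pt - tau)
            else:
                L = dcd_max + k_stay / k_run
                pred = L + (y_tau - L) * np.exp(-k_run * (pt - tau))
            r = pred - py
            return float(r @ r)

        res = _de(
            objective, [config.rate_bounds, (1e-6, 5.0 * y_hi)], config
        )
        k_run, dcd_max = float(res.x[0]), float(res.x[1])
        sse += float(res.fun)
    else:
        k_run = dcd_max = np.nan
        flags.append("dcd_post_too_short")

    return ExfoliationFit(
        k_stay=k_stay, k_run=k_run, dcd_max=dcd_max, sse=sse, flags=tuple(flags)
    )


# ---------------------------------------------------------------------------
# per-cell and cohort drivers


def fit_cell(
    actin: Trajectory,
    da: Trajectory,
    dcd: Trajectory,
    config: FitConfig | None = None,
) -> CellFeatureVector:
    """Reduce one organoid's three trajectories to a feature vector.

    Composes direct timing extraction, detachment changepoint search and
    the segment-wise evolutionary fits.  Failures in one channel flag
    the vector and leave its fields missing rather than aborting.
    """
    config = config or FitConfig()
    cell = CellFeatureVector(organoid_id=actin.organoid_id, treatment=actin.treatment)
    flags: list[str] = []

    try:
        timing = extract_timing_features(actin, ss_window=config.ss_window)
        rates = fit_actin_rates(actin, timing, config)
        cell = replace(
            cell,
            t_min=timing.t_min,
            act_min=timing.act_min,
            t_max=timing.t_max,
            act_ss=timing.act_ss,
            act_depoly1=rates.act_depoly1,
            act_poly=rates.act_poly,
            act_depoly2=rates.act_depoly2,
            act_max=rates.act_max,
            act0=float(actin.values[0]),
            sse_actin=rates.sse,
        )
        flags.extend(rates.flags)
    except NonConformingTrajectoryError as exc:
        flags.append(f"actin_nonconforming:{exc}")

    try:
        repair = fit_repair_rate(da, config)
        cell = replace(cell, k_repair=repair.k_repair, da0=repair.da0, sse_da=repair.sse)
    except (ValueError, NonConformingTrajectoryError) as exc:
        flags.append(f"da_fit_failed:{exc}")

    try:
        det = detect_detachment(dcd)
        exfol = fit_exfoliation(dcd, det.t_detach, config)
        cell = replace(
            cell,
            t_detach=det.t_detach,
            k_stay=exfol.k_stay,
            k_run=exfol.k_run,
            dcd_max=exfol.dcd_max,
            dcd0=float(dcd.values[0]),
            sse_dcd=exfol.sse,
        )
        flags.extend(exfol.flags)
        if det.at_boundary:
            flags.append("dcd_detachment_at_boundary")
    except NonConformingTrajectoryError as exc:
        flags.append(f"dcd_nonconforming:{exc}")

    return replace(cell, flags=tuple(flags))


def fit_cohort(
    trajectories: Iterable[Trajectory], config: FitConfig | None = None
) -> pd.DataFrame:
    """Fit every organoid that has all three channels; one row per cell.

    Returns the cohort feature table (the input of the perturbation and
    machine-learning stages).  Organoids missing a channel are skipped
    with a logged reason.
    """
    config = config or FitConfig()
    by_cell: dict[str, dict[str, Trajectory]] = {}
    for tr in trajectories:
        by_cell.setdefault(tr.organoid_id, {})[tr.channel] = tr
    if not by_cell:
        raise ValueError("no trajectories supplied")
    rows = []
    for oid, chans in by_cell.items():
        missing = set(("actin", "damaged_area", "dead_cell_distance")) - set(chans)
        if missing:
            logger.warning("skipping %s: missing channels %s", oid, sorted(missing))
            continue
        cell = fit_cell(
            chans["actin"], chans["damaged_area"], chans["dead_cell_distance"], config
        )
        rows.append(cell.to_row())
    if not rows:
        raise ValueError("no organoid had all three channels")
    return pd.DataFrame(rows)


def summarize_cohort(cohort: pd.DataFrame) -> pd.DataFrame:
    """Per-treatment mean ± SD of every model parameter."""
    cols = [c for c in PARAM_NAMES if c in cohort.columns]
    return cohort.groupby("treatment")[list(cols)].agg(["mean", "std"])
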