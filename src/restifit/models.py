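"""Piecewise hybrid ODE models of single-cell gastric restitution.

Three independent one-variable processes describe the repair of a
photodamaged cell in a gastric organoid:

* **actin** — GFP-actin intensity in the cells neighboring the damage
  site (relative light units, RLU).  The signal decays to a minimum,
  polymerizes up toward a theoretical maximum, then depolymerizes down
  to a steady state.  Rate terms switch on and off at the timing events
  ``t_min`` and ``t_max``.
* **damaged_area** — the denuded area (μm²), repaired by migrating
  neighbors as a single exponential decay.
* **dead_cell_distance** — distance of the dead cell's nucleus from the
  damage site (μm).  The cell drifts linearly until it detaches from its
  neighbors at ``t_detach``, after which it relaxes exponentially toward
  a maximal distance.

Each model has an exact closed-form solution (the regimes are linear
ODEs) and a numerical integration route (`integrate_numerically`) that
restarts the solver at every switching event; the two act as mutual
oracles in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING

import numpy as np
from scipy.integrate import solve_ivp

if TYPE_CHECKING:  # pragma: no cover
    from .fitting import CellFeatureVector

__all__ = [
    "CHANNELS",
    "ActinParams",
    "RepairParams",
    "ExfoliationParams",
    "TimeGrid",
    "Trajectory",
    "simulate_actin",
    "simulate_damaged_area",
    "simulate_dead_cell",
    "simulate_cell",
    "integrate_numerically",
    "actin_closed_form",
    "damaged_area_closed_form",
    "dead_cell_closed_form",
]

#: Channel labels of the tidy trajectory format, in canonical order.
CHANNELS = ("actin", "damaged_area", "dead_cell_distance")

# Treat a first-order rate below this as "switched off" (degenerate regime).
_RATE_EPS = 1e-12


class ModelError(ValueError):
    """Invalid model parameters or failed simulation."""


@dataclass(frozen=True)
class ActinParams:
    """Parameters of the three-regime actin model.

    Rates are first-order (min⁻¹), levels are RLU, times are minutes.
    ``act_max`` is the *theoretical* attractor of the polymerization
    regime and may exceed the observed peak.  ``act0`` is the
    pre-damage baseline (the data are baseline-normalized, so 1.0).
    """

    act_depoly1: float
    act_depoly2: float
    act_poly: float
    act_max: float
    act_min: float
    act_ss: float
    t_min: float
    t_max: float
    act0: float = 1.0

    def __post_init__(self) -> None:
        for name in ("act_depoly1", "act_depoly2", "act_poly"):
            if getattr(self, name) < 0:
                raise ModelError(f"{name} must be >= 0")
        if not 0 <= self.t_min < self.t_max:
            raise ModelError("require 0 <= t_min < t_max")
        if self.act_min > self.act0:
            raise ModelError("act_min must not exceed the initial level act0")
        if not self.act_min <= self.act_ss <= self.act_max:
            raise ModelError("require act_min <= act_ss <= act_max")


@dataclass(frozen=True)
class RepairParams:
    """Damaged-area model: dDA/dt = -k_repair * DA.

    ``k_repair`` acts as a first-order rate in the equation; reports echo
    the conventional printed units (μm² min⁻¹).  ``da0`` is the damage
    size at t = 0 (maximal by construction).
    """

    k_repair: float
    da0: float

    def __post_init__(self) -> None:
        if self.k_repair < 0:
            raise ModelError("k_repair must be >= 0")
        if self.da0 <= 0:
            raise ModelError("da0 must be > 0")


@dataclass(frozen=True)
class ExfoliationParams:
    """Dead-cell distance model: dDCD/dt = k_stay + k_run * (dcd_max - DCD).

    ``k_run`` switches on at ``t_detach`` (loss of cell-cell contact);
    before that only the background drift ``k_stay`` acts.
    """

    k_stay: float
    k_run: float
    dcd_max: float
    t_detach: float
    dcd0: float = 0.0

    def __post_init__(self) -> None:
        if self.k_stay < 0 or self.k_run < 0:
            raise ModelError("k_stay and k_run must be >= 0")
        if self.dcd_max <= 0:
            raise ModelError("dcd_max must be > 0")
        if self.t_detach < 0:
            raise ModelError("t_detach must be >= 0")


@dataclass(frozen=True)
class TimeGrid:
    """Uniform sampling grid in minutes."""

    t_start: float = 0.0
    t_end: float = 20.0
    dt: float = 0.5

    def __post_init__(self) -> None:
        if self.t_start < 0 or self.t_start >= self.t_end:
            raise ModelError("require 0 <= t_start < t_end")
        if self.dt <= 0:
            raise ModelError("dt must be > 0")

    @property
    def times(self) -> np.ndarray:
        n = int(round((self.t_end - self.t_start) / self.dt))
        return self.t_start + self.dt * np.arange(n + 1)


@dataclass
class Trajectory:
    """One organoid × one channel time series in physical units."""

    organoid_id: str
    treatment: str
    channel: str
    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.channel not in CHANNELS:
            raise ModelError(f"unknown channel {self.channel!r}")
        if self.times.shape != self.values.shape or self.times.ndim != 1:
            raise ModelError("times and values must be 1-D arrays of equal length")
        if len(self.times) >= 2 and not np.all(np.diff(self.times) > 0):
            raise ModelError("times must be strictly increasing")
        if not (np.all(np.isfinite(self.times)) and np.all(np.isfinite(self.values))):
            raise ModelError("times and values must be finite")

    def __len__(self) -> int:
        return len(self.times)


# ---------------------------------------------------------------------------
# closed forms


def _relax(attractor: float, start: float, rate: float, elapsed) -> np.ndarray:
    """Exponential relaxation toward ``attractor`` from ``start``."""
    return attractor + (start - attractor) * np.exp(-rate * np.asarray(elapsed, float))


def actin_closed_form(p: ActinParams, t: np.ndarray) -> np.ndarray:
    """Exact piecewise solution of the actin model at times ``t`` (t >= 0).

    Regimes: decay to ``act_min`` (rate ``act_depoly1``) on [0, t_min];
    rise toward ``act_max`` (rate ``act_poly``) on [t_min, t_max]; decay
    to ``act_ss`` (rate ``act_depoly2``) afterwards.  The solution is
    continuous at both switch times by construction.
    """
    t = np.asarray(t, dtype=float)
    a_tmin = _relax(p.act_min, p.act0, p.act_depoly1, p.t_min)
    a_tmax = _relax(p.act_max, a_tmin, p.act_poly, p.t_max - p.t_min)
    out = np.empty_like(t)
    m1 = t <= p.t_min
    m2 = (t > p.t_min) & (t <= p.t_max)
    m3 = t > p.t_max
    out[m1] = _relax(p.act_min, p.act0, p.act_depoly1, t[m1])
    out[m2] = _relax(p.act_max, a_tmin, p.act_poly, t[m2] - p.t_min)
    out[m3] = _relax(p.act_ss, a_tmax, p.act_depoly2, t[m3] - p.t_max)
    return out


def damaged_area_closed_form(p: RepairParams, t: np.ndarray) -> np.ndarray:
    """DA(t) = da0 · exp(−k_repair · t)."""
    return p.da0 * np.exp(-p.k_repair * np.asarray(t, dtype=float))


def dead_cell_closed_form(p: ExfoliationParams, t: np.ndarray) -> np.ndarray:
    """Exact two-regime solution of the dead-cell distance model.

    Linear drift ``dcd0 + k_stay·t`` until ``t_detach``; afterwards
    exponential relaxation toward ``dcd_max + k_stay/k_run``.  When
    ``k_run`` is (numerically) zero the linear drift simply continues —
    the fixed point is undefined and the ODE stays linear.
    """
    t = np.asarray(t, dtype=float)
    out = p.dcd0 + p.k_stay * t
    post = t > p.t_detach
    if p.k_run > _RATE_EPS and np.any(post):
        attractor = p.dcd_max + p.k_stay / p.k_run
        d_detach = p.dcd0 + p.k_stay * p.t_detach
        out[post] = _relax(attractor, d_detach, p.k_run, t[post] - p.t_detach)
    return out


def _make_trajectory(channel, values, grid, organoid_id, treatment):
    return Trajectory(
        organoid_id=organoid_id,
        treatment=treatment,
        channel=channel,
        times=grid.times,
        values=values,
    )


def simulate_actin(
    params: ActinParams,
    grid: TimeGrid,
    organoid_id: str = "sim",
    treatment: str = "control",
) -> Trajectory:
    """Sample the closed-form actin solution on ``grid``."""
    return _make_trajectory(
        "actin", actin_closed_form(params, grid.times), grid, organoid_id, treatment
    )


def simulate_damaged_area(
    params: RepairParams,
    grid: TimeGrid,
    organoid_id: str = "sim",
    treatment: str = "control",
) -> Trajectory:
    """Sample the closed-form damaged-area solution on ``grid``."""
    return _make_trajectory(
        "damaged_area",
        damaged_area_closed_form(params, grid.times),
        grid,
        organoid_id,
        treatment,
    )


def simulate_dead_cell(
    params: ExfoliationParams,
    grid: TimeGrid,
    organoid_id: str = "sim",
    treatment: str = "control",
) -> Trajectory:
    """Sample the closed-form dead-cell-distance solution on ``grid``."""
    return _make_trajectory(
        "dead_cell_distance",
        dead_cell_closed_form(params, grid.times),
        grid,
        organoid_id,
        treatment,
    )


def simulate_cell(
    features: "CellFeatureVector", grid: TimeGrid
) -> dict[str, Trajectory]:
    """Simulate all three channels of one cell on a shared grid.

    Returns a dict keyed by channel.  Identical to calling the three
    per-channel simulators with the corresponding parameter subsets.
    """
    actin = ActinParams(
        act_depoly1=features.act_depoly1,
        act_depoly2=features.act_depoly2,
        act_poly=features.act_poly,
        act_max=features.act_max,
        act_min=features.act_min,
        act_ss=features.act_ss,
        t_min=features.t_min,
        t_max=features.t_max,
        act0=features.act0,
    )
    repair = RepairParams(k_repair=features.k_repair, da0=features.da0)
    exfol = ExfoliationParams(
        k_stay=features.k_stay,
        k_run=features.k_run,
        dcd_max=features.dcd_max,
        t_detach=features.t_detach,
        dcd0=features.dcd0,
    )
    oid, trt = features.organoid_id, features.treatment
    return {
        "actin": simulate_actin(actin, grid, oid, trt),
        "damaged_area": simulate_damaged_area(repair, grid, oid, trt),
        "dead_cell_distance": simulate_dead_cell(exfol, grid, oid, trt),
    }


# ---------------------------------------------------------------------------
# numerical oracle


def _actin_rhs(p: ActinParams, regime: int):
    if regime == 0:
        return lambda t, y: -p.act_depoly1 * (y - p.act_min)
    if regime == 1:
        return lambda t, y: p.act_poly * (p.act_max - y)
    return lambda t, y: -p.act_depoly2 * (y - p.act_ss)


def _integrate_segments(rhs_for_regime, events, y0, times, model_id):
    """Integrate piecewise, restarting the solver at each switching event.

    ``events`` are the interior switch times (in ascending order); each
    segment is solved with LSODA at tight tolerances and the grid points
    it owns are read off the dense solution.  A sample exactly on a
    switch time belongs to the earlier regime, matching the closed forms.
    """
    cuts = [e for e in events if times[0] < e < times[-1]]
    bounds = [times[0], *cuts, times[-1]]
    out = np.empty_like(times)
    y = float(y0)
    t_lo = bounds[0]
    for t_hi in bounds[1:]:
        regime = sum(0.5 * (t_lo + t_hi) > e for e in events)
        mask = (times >= t_lo) & (times <= t_hi)
        if t_lo != bounds[0]:
            mask &= times > t_lo  # boundary sample owned by earlier segment
        sol = solve_ivp(
            rhs_for_regime(regime),
            (t_lo, t_hi),
            [y],
            method="LSODA",
            rtol=1e-11,
            atol=1e-12,
            dense_output=True,
        )
        if not sol.success:
            raise ModelError(
                f"integration of {model_id!r} failed in regime {regime}: {sol.message}"
            )
        if np.any(mask):
            out[mask] = sol.sol(times[mask])[0]
        y = float(sol.sol(t_hi)[0])
        t_lo = t_hi
    return out


def integrate_numerically(
    model_id: str,
    params,
    grid: TimeGrid,
    organoid_id: str = "sim",
    treatment: str = "control",
) -> Trajectory:
    """Numerically integrate one piecewise model on ``grid``.

    This is the independent oracle for the closed forms: the ODE of each
    regime is solved with a stiff-capable solver and integration is
    restarted exactly at every switching event (``t_min``/``t_max`` for
    actin, ``t_detach`` for the dead cell), so events need not lie on
    grid points.
    """
    if model_id not in CHANNELS:
        raise ModelError(f"unknown model {model_id!r}")
    times = grid.times
    if model_id == "actin":
        if not isinstance(params, ActinParams):
            raise ModelError("actin model requires ActinParams")
        values = _integrate_segments(
            lambda r: _actin_rhs(params, r),
            [params.t_min, params.t_max],
            params.act0,
            times,
            model_id,
        )
    elif model_id == "damaged_area":
        if not isinstance(params, RepairParams):
            raise ModelError("damaged_area model requires RepairParams")
        k = params.k_repair
        values = _integrate_segments(
            lambda r: (lambda t, y: -k * y), [], params.da0, times, model_id
        )
    else:
        if not isinstance(params, ExfoliationParams):
            raise ModelError("dead_cell_distance model requires ExfoliationParams")
        p = params

        def rhs_for_regime(regime):
            if regime == 0:
                return lambda t, y: p.k_stay + 0.0 * y
            return lambda t, y: p.k_stay + p.k_run * (p.dcd_max - y)

        values = _integrate_segments(
            rhs_for_regime, [p.t_detach], p.dcd0, times, model_id
        )
    return _make_trajectory(model_id, values, grid, organoid_id, treatment)
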