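"""Feature extraction, changepoint detection and evolutionary fits."""

import numpy as np
import pytest

from restifit.fitting import (
    FitConfig,
    NonConformingTrajectoryError,
    detect_detachment,
    extract_timing_features,
    fit_actin_rates,
    fit_cell,
    fit_cohort,
    fit_exfoliation,
    fit_repair_rate,
    loglinear_repair_rate,
)
from restifit.io import frame_to_trajectories
from restifit.models import (
    ActinParams,
    RepairParams,
    TimeGrid,
    Trajectory,
    actin_closed_form,
    dead_cell_closed_form,
    simulate_actin,
    simulate_damaged_area,
)
from restifit.synthetic import CONTROL_MEANS as M
from restifit.synthetic import GeneratorConfig, generate_cohort

RECOVERY = {  # (true value, relative tolerance) for the control average
    "act_depoly1": (6.024, 0.01),
    "act_poly": (0.191, 0.01),
    "act_depoly2": (0.616, 0.01),
    "act_max": (2.484, 0.01),
    "k_repair": (0.255, 0.01),
    "k_stay": (0.035, 0.02),
    "k_run": (0.462, 0.02),
    "dcd_max": (10.507, 0.02),
}


def _traj(channel, times, values):
    return Trajectory("t", "control", channel, times, values)


# -- timing extraction -----------------------------------------------------


def test_timing_round_trip(actin_traj, fine_grid):
    tim = extract_timing_features(actin_traj)
    assert abs(tim.t_min - M["t_min"]) <= fine_grid.dt
    assert abs(tim.t_max - M["t_max"]) <= fine_grid.dt
    assert tim.t_min < tim.t_max
    assert tim.act_min == pytest.approx(M["act_min"], rel=0.01)
    assert tim.act_ss == pytest.approx(M["act_ss"], rel=0.01)


def test_timing_rejects_degenerate_trajectories():
    t = np.arange(10.0)
    with pytest.raises(NonConformingTrajectoryError):
        extract_timing_features(_traj("actin", t, np.full(10, 1.0)))
    with pytest.raises(NonConformingTrajectoryError):
        extract_timing_features(_traj("actin", t, np.linspace(1, 0.1, 10)))
    with pytest.raises(NonConformingTrajectoryError):
        extract_timing_features(_traj("actin", t[:4], np.array([1, 0.5, 2, 1.0])))


def test_timing_tie_breaks_to_earlier_time():
    t = np.arange(7.0)
    v = np.array([1.0, 0.4, 0.9, 2.0, 1.5, 2.0, 1.0])  # equal maxima at t=3, t=5
    tim = extract_timing_features(_traj("actin", t, v))
    assert tim.t_max == 3.0
    assert tim.t_min == 1.0


def test_timing_wrong_channel_rejected(da_traj):
    with pytest.raises(ValueError):
        extract_timing_features(da_traj)


# -- detachment changepoint ------------------------------------------------


def test_detachment_round_trip(dcd_traj, fine_grid):
    det = detect_detachment(dcd_traj)
    assert abs(det.t_detach - M["t_detach"]) <= fine_grid.dt
    assert not det.at_boundary


def test_detachment_flags_straight_line():
    t = np.arange(30.0)
    det = detect_detachment(_traj("dead_cell_distance", t, 0.05 * t))
    assert det.at_boundary


def test_detachment_noisy_monte_carlo(control_exfol_params, fine_grid):
    """Median |error| stays within two grid steps at σ = 0.2 μm."""
    base = dead_cell_closed_form(control_exfol_params, fine_grid.times)
    errs = []
    for seed in range(50):
        noisy = base + np.random.default_rng(seed).normal(0, 0.2, base.shape)
        det = detect_detachment(
            _traj("dead_cell_distance", fine_grid.times, np.clip(noisy, 0, None))
        )
        errs.append(abs(det.t_detach - M["t_detach"]))
    assert np.median(errs) <= 2 * fine_grid.dt


# -- actin rate fits -------------------------------------------------------


def test_actin_rates_round_trip(actin_traj):
    tim = extract_timing_features(actin_traj)
    fit = fit_actin_rates(actin_traj, tim)
    for name in ("act_depoly1", "act_poly", "act_depoly2", "act_max"):
        true, rel = RECOVERY[name]
        assert getattr(fit, name) == pytest.approx(true, rel=rel), name
    assert fit.flags == ()
    assert fit.sse < 1e-10


def test_flat_rise_fits_zero_rate(fine_grid):
    """A rise segment generated without polymerization stays flat: the
    fitted rise must be (near) zero-slope, with act_poly at its bound in
    the identifiable near-flat case."""
    from restifit.fitting import TimingFeatures

    levels = {}

    def make(act_poly):
        p = ActinParams(
            act_depoly1=6.0,
            act_depoly2=0.6,
            act_poly=act_poly,
            act_max=2.5,
            act_min=0.7,
            act_ss=0.71,
            t_min=1.0,
            t_max=6.0,
        )
        v = actin_closed_form(p, fine_grid.times)
        timing = TimingFeatures(
            t_min=1.0, act_min=v[10], t_max=6.0, act_ss=0.71, i_min=10, i_max=60
        )
        levels[act_poly] = v[11]
        return fit_actin_rates(_traj("actin", fine_grid.times, v), timing)

    near_flat = make(1e-3)
    assert near_flat.act_poly <= 0.01
    exactly_flat = make(0.0)  # (act_poly, act_max) degenerate; curve must be flat
    rise = (exactly_flat.act_max - levels[0.0]) * (
        1.0 - np.exp(-5.0 * exactly_flat.act_poly)
    )
    assert abs(rise) <= 1e-3  # predicted rise over the whole segment


def test_depoly2_noisy_monte_carlo(control_actin_params, fine_grid):
    """Median relative error of the final decay rate ≤ 15% at σ = 0.05 RLU."""
    base = actin_closed_form(control_actin_params, fine_grid.times)
    errs = []
    for seed in range(50):
        noisy = base + np.random.default_rng(1000 + seed).normal(0, 0.05, base.shape)
        tr = _traj("actin", fine_grid.times, noisy)
        try:
            fit = fit_actin_rates(tr, extract_timing_features(tr))
        except NonConformingTrajectoryError:
            continue
        if np.isfinite(fit.act_depoly2):
            errs.append(abs(fit.act_depoly2 - M["act_depoly2"]) / M["act_depoly2"])
    assert len(errs) >= 40
    assert np.median(errs) <= 0.15


# -- repair rate -----------------------------------------------------------


def test_repair_rate_round_trip(da_traj):
    fit = fit_repair_rate(da_traj)
    assert fit.k_repair == pytest.approx(0.255, rel=0.01)


def test_repair_rate_matches_loglinear_oracle(da_traj):
    fit = fit_repair_rate(da_traj)
    assert abs(fit.k_repair - loglinear_repair_rate(da_traj)) < 1e-4


def test_repair_constant_trajectory_gives_zero():
    t = np.arange(20.0)
    fit = fit_repair_rate(_traj("damaged_area", t, np.full(20, 80.0)))
    assert fit.k_repair == pytest.approx(0.0, abs=1e-6)


def test_repair_rejects_negative_values():
    t = np.arange(10.0)
    with pytest.raises(ValueError):
        fit_repair_rate(_traj("damaged_area", t, np.linspace(10, -1, 10)))


# -- exfoliation -----------------------------------------------------------


def test_exfoliation_round_trip(dcd_traj):
    det = detect_detachment(dcd_traj)
    fit = fit_exfoliation(dcd_traj, det.t_detach)
    for name in ("k_stay", "k_run", "dcd_max"):
        true, rel = RECOVERY[name]
        assert getattr(fit, name) == pytest.approx(true, rel=rel), name


def test_exfoliation_flat_pre_segment_gives_zero_drift(fine_grid):
    from restifit.models import ExfoliationParams

    p = ExfoliationParams(k_stay=0.0, k_run=0.5, dcd_max=10.0, t_detach=3.0)
    v = dead_cell_closed_form(p, fine_grid.times)
    fit = fit_exfoliation(_traj("dead_cell_distance", fine_grid.times, v), 3.0)
    assert fit.k_stay == 0.0
    assert fit.k_run == pytest.approx(0.5, rel=0.02)


def test_exfoliation_beats_true_params_on_noisy_data(
    control_exfol_params, fine_grid, rng
):
    """Fitted SSE must not exceed the SSE of the generating parameters."""
    p = control_exfol_params
    base = dead_cell_closed_form(p, fine_grid.times)
    noisy = np.clip(base + rng.normal(0, 0.2, base.shape), 0, None)
    tr = _traj("dead_cell_distance", fine_grid.times, noisy)
    det = detect_detachment(tr)
    fit = fit_exfoliation(tr, det.t_detach)
    t, y = tr.times, tr.values
    post = t > det.t_detach
    L = p.dcd_max + p.k_stay / p.k_run
    tau = t[post][0]
    truth_pred = L + (y[post][0] - L) * np.exp(-p.k_run * (t[post] - tau))
    pre = t < det.t_detach
    slope = np.polyfit(t[pre], y[pre], 1)
    sse_truth = float(np.sum((truth_pred - y[post]) ** 2)) + float(
        np.sum((np.polyval(slope, t[pre]) - y[pre]) ** 2)
    )
    assert fit.sse <= sse_truth + 1e-9


# -- cell and cohort -------------------------------------------------------


def test_fit_cell_round_trip_and_determinism(actin_traj, da_traj, dcd_traj, fine_grid):
    cell1 = fit_cell(actin_traj, da_traj, dcd_traj)
    cell2 = fit_cell(actin_traj, da_traj, dcd_traj)
    assert cell1 == cell2  # bit-identical under a fixed optimizer seed
    for name, truth in M.items():
        est = getattr(cell1, name)
        assert abs(est - truth) <= max(0.01 * abs(truth), fine_grid.dt), name


def test_fit_cell_partial_failure_is_flagged(actin_traj, dcd_traj):
    t = np.arange(10.0)
    bad_da = _traj("damaged_area", t, np.linspace(10, -1, 10))
    cell = fit_cell(actin_traj, bad_da, dcd_traj)
    assert np.isnan(cell.k_repair)
    assert any("da_fit_failed" in f for f in cell.flags)
    assert np.isfinite(cell.t_detach)  # other channels still fitted


def test_fit_cohort_requires_input():
    with pytest.raises(ValueError):
        fit_cohort([])


def test_fit_cohort_skips_incomplete_organoids(actin_traj, da_traj, dcd_traj):
    lonely = Trajectory("other", "control", "actin", actin_traj.times, actin_traj.values)
    cohort = fit_cohort([actin_traj, da_traj, dcd_traj, lonely])
    assert list(cohort["organoid_id"]) == [actin_traj.organoid_id]


def test_heterogeneous_cohort_recovery():
    """Noiseless fits recover each sampled cell's parameters; cohort means
    of fitted values match the ground-truth means of the retained cells."""
    cfg = GeneratorConfig(
        n_per_group=20,
        seed=0,
        grid=TimeGrid(0.0, 20.0, 0.1),
        noise_sd={"actin": 0.0, "damaged_area": 0.0, "dead_cell_distance": 0.0},
    )
    ds = generate_cohort(cfg)
    cohort = fit_cohort(frame_to_trajectories(ds.trajectories)).set_index("organoid_id")
    truth = ds.truth.set_index("organoid_id")
    for name in ("act_depoly1", "act_poly", "act_depoly2", "k_repair", "k_run"):
        est = cohort[name].dropna()
        err = (est - truth.loc[est.index, name]).abs() / truth.loc[est.index, name]
        assert np.median(err) <= 0.02, name
        assert est.mean() == pytest.approx(truth.loc[est.index, name].mean(), rel=0.05)
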