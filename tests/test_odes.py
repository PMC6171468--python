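"""Unit + property tests for the ODE layer: resting fixed point,
conservation laws, oracle agreement and shuttle directionality."""

import numpy as np
import pytest

from ngvkit.metabolic_core import (
    ExternalDrive,
    NoSteadyStateError,
    PiecewiseConstant,
    RESTING_DRIVE,
    ValidationError,
    anls_summary,
    conservation_report,
    default_resting_guess,
    derivatives,
    integrate_unit,
    resting_state,
)
from ngvkit.metabolic_core.odes import rhs_vector

from conftest import rk4_oracle

STIM = ExternalDrive(j_rel=PiecewiseConstant((1.0, 2.0), (0.5,), 0.0))


def test_resting_state_residual(params, rest):
    r = rhs_vector(rest.to_array(), params, 0.0, 1.0, 0.0)
    assert np.max(np.abs(r)) < 1e-8


def test_resting_state_satisfies_invariants(params, rest):
    rest.validate(params)
    assert rest.ATP_n <= params.A_tot
    assert rest.NADHm_a <= params.Nm_tot


def test_resting_state_from_perturbed_guess(params):
    guess = default_resting_guess()
    guess.ATP_n *= 0.9
    guess.LAC_e *= 1.3
    guess.Na_a += 1.0
    s = resting_state(params, guess=guess)
    r = rhs_vector(s.to_array(), params, 0.0, 1.0, 0.0)
    assert np.max(np.abs(r)) < 1e-8


def test_resting_state_rejects_degenerate_pool(params):
    with pytest.raises(ValidationError):
        resting_state(params.replace(A_tot=0.0))


def test_no_steady_state_reported(params):
    # absurd pump rate: Newton cannot converge in 3 iterations
    with pytest.raises(NoSteadyStateError, match="residual"):
        resting_state(params.replace(k_pump=1e9), max_iter=3)


def test_pools_constant_along_stimulus_trajectory(params, rest):
    traj = integrate_unit(rest, params, STIM, (0.0, 3.0), 0.1)
    for stored, total in (("ATP_n", params.A_tot), ("NADHc_a", params.Nc_tot),
                          ("PCr_n", params.C_tot)):
        pool = traj.series(stored) + (total - traj.series(stored))
        np.testing.assert_array_equal(pool, np.full_like(pool, total))


def test_carbon_bookkeeping_closed_system(params, rest):
    closed = params.replace(disable_transport=True, disable_oxidation=True)
    y = rest.to_array()
    d = rhs_vector(y, closed, 0.0, 1.0, 0.0)
    from ngvkit.metabolic_core import SPECIES_INDEX as IX
    for comp_species in (
        [("GLC_n", 6), ("G6P_n", 6), ("PYR_n", 3), ("LAC_n", 3)],
        [("GLC_a", 6), ("G6P_a", 6), ("GLY_a", 6), ("PYR_a", 3), ("LAC_a", 3)],
    ):
        total = sum(w * d[IX[sp]] for sp, w in comp_species)
        assert total == pytest.approx(0.0, abs=1e-15)


def test_rest_is_fixed_point_100s(params, rest):
    traj = integrate_unit(rest, params, RESTING_DRIVE, (0.0, 100.0), 1.0)
    ref = rest.to_array()
    rel = np.abs(traj.y - ref) / np.maximum(np.abs(ref), 1e-9)
    assert rel.max() < 1e-6


def test_closed_system_carbon_drift(params, rest):
    closed = params.replace(disable_transport=True, disable_oxidation=True)
    traj = integrate_unit(rest, closed, RESTING_DRIVE, (0.0, 100.0), 1.0,
                          rtol=1e-9, atol=1e-12)
    rep = conservation_report(traj)
    assert rep["closed_system"]
    for comp in ("neuron", "astrocyte"):
        assert rep["carbon_drift"][comp] < 1e-6
    assert all(v == 0.0 for v in rep["pool_drift"].values())


def test_open_system_carbon_reported_not_asserted(params, rest):
    traj = integrate_unit(rest, params, STIM, (0.0, 3.0), 0.05)
    rep = conservation_report(traj)
    assert not rep["closed_system"]
    assert set(rep["carbon_drift"]) == {"neuron", "astrocyte", "ecs", "capillary"}


def test_conservation_report_rejects_empty(params, rest):
    traj = integrate_unit(rest, params, RESTING_DRIVE, (0.0, 1.0), 0.5)
    traj.t = np.empty(0)
    with pytest.raises(ValidationError):
        conservation_report(traj)


def test_adaptive_matches_rk4_oracle_short(params, rest):
    # 2 s window around the stimulus onset; the full 10 s run lives in
    # the acceptance suite
    drive = ExternalDrive(j_rel=PiecewiseConstant((0.5, 1.5), (0.5,), 0.0))
    traj = integrate_unit(rest, params, drive, (0.0, 2.0), 0.1,
                          rtol=1e-8, atol=1e-11)
    t_ref, y_ref = rk4_oracle(rest.to_array(), params, drive, (0.0, 2.0),
                              1e-4, 20)
    np.testing.assert_allclose(traj.t, t_ref, atol=1e-12)
    rel = np.abs(traj.y - y_ref) / (np.abs(y_ref) + 1e-9)
    assert rel.max() < 1e-4


def test_trajectory_invariants_hold(params, rest):
    traj = integrate_unit(rest, params, STIM, (0.0, 4.0), 0.05)
    for i in range(0, len(traj.t), 10):
        traj.state_at(i).validate(params, atol=1e-7)


def test_negative_initial_state_rejected(params, rest):
    bad = default_resting_guess()
    bad.O2_n = -0.1
    with pytest.raises(ValidationError, match="O2_n"):
        integrate_unit(bad, params, RESTING_DRIVE, (0.0, 1.0), 0.1)


def test_anls_directionality_under_stimulus(params, rest):
    traj = integrate_unit(rest, params, STIM, (0.0, 10.0), 0.02)
    summary = anls_summary(traj)
    assert summary["int_J_mct_a"] > 0
    assert summary["int_J_mct_n"] < 0


def test_anls_rest_near_basal(params, rest):
    traj = integrate_unit(rest, params, RESTING_DRIVE, (0.0, 5.0), 0.05)
    s = anls_summary(traj)
    # basal shuttle values of the documented default parameter set
    assert s["int_J_mct_a"] == pytest.approx(0.008 * 5.0, rel=1e-3)
    assert s["int_J_mct_n"] == pytest.approx(-0.002 * 5.0, rel=1e-3)


def test_ecs_lactate_mass_balance(params, rest):
    """Cells' export + capillary uptake must equal the ECS content change."""
    traj = integrate_unit(rest, params, STIM, (0.0, 5.0), 0.01,
                          rtol=1e-9, atol=1e-12)
    p = params
    influx = (p.v_n / p.v_e) * traj.flux_series("J_mct_n") \
        + (p.v_a / p.v_e) * traj.flux_series("J_mct_a") \
        - traj.flux_series("J_mct_ec")
    net = np.trapezoid(influx, traj.t)
    delta = traj.series("LAC_e")[-1] - traj.series("LAC_e")[0]
    assert net == pytest.approx(delta, rel=1e-4, abs=1e-8)


def test_ne_dose_response_monotone(params, rest):
    peaks, consumed = [], []
    for ne in (0.5, 1.0, 2.0):
        drive = ExternalDrive(ne=PiecewiseConstant((1.0, 3.0), (ne,), 0.0))
        traj = integrate_unit(rest, params, drive, (0.0, 15.0), 0.05)
        peaks.append(traj.flux_series("J_gp").max())
        consumed.append(rest.GLY_a - traj.series("GLY_a").min())
    assert peaks[0] < peaks[1] < peaks[2]
    assert consumed[0] < consumed[1] < consumed[2]


def test_trajectory_long_format(params, rest):
    traj = integrate_unit(rest, params, RESTING_DRIVE, (0.0, 1.0), 0.5)
    frame = traj.to_frame()
    assert set(frame.columns) == {"t", "compartment", "species", "value"}
    assert len(frame) == 3 * 28
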