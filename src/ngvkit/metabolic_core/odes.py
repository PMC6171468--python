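"""Derivative assembly, resting-state solve and trajectory integration.

Stoichiometry (per unit of flux, in the flux's own frame):

* HK lump: ``GLC + ATP -> G6P``
* PK lump: ``G6P + 2 ADP + 2 NADc -> 2 PYR + 2 ATP + 2 NADHc``
* LDH: ``PYR + NADHc <-> LAC + NADc``
* oxidative lump: ``PYR + NADHm + o2_per_pyr O2 -> n_atp_ox ATP``
* shuttle: ``NADHc -> NADHm``
* pump: ``ATP -> ADP`` extruding 3 Na
* CK: ``PCr + ADP <-> Cr + ATP``
* glycogen: ``G6P <-> GLY`` (phosphorylase returns G6P without ATP cost
  at this lumping)

Trans-membrane fluxes are converted between compartment frames with
volume-fraction ratios; capillary species relax toward arterial values
at rate ``CBF * F_0``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from .drive import ExternalDrive, RESTING_DRIVE
from .fluxes import FLUX_INDEX, flux_vector
from .state import (
    SPECIES,
    SPECIES_INDEX,
    FluxSet,
    ModelParams,
    NGVState,
    ValidationError,
    compartment_of,
    default_resting_guess,
)

__all__ = [
    "derivatives",
    "resting_state",
    "integrate_unit",
    "UnitTrajectory",
    "conservation_report",
    "anls_summary",
    "NoSteadyStateError",
    "IntegrationError",
]


class NoSteadyStateError(RuntimeError):
    """Resting-state root solve did not converge."""


class IntegrationError(RuntimeError):
    """Adaptive integration failed or produced an invalid state."""


def rhs_vector(y: np.ndarray, p: ModelParams, j_rel: float, cbf: float, ne: float) -> np.ndarray:
    """Time derivative of the packed state vector (no validation)."""
    J = flux_vector(y, p, j_rel, cbf, ne)
    (J_glut_ce, J_glut_en, J_glut_ea,
     J_hk_n, J_hk_a, J_pk_n, J_pk_a,
     J_ldh_n, J_ldh_a,
     J_mct_n, J_mct_a, J_mct_ec,
     J_mito_n, J_mito_a, J_shuttle_n, J_shuttle_a,
     J_pump_n, J_pump_a, J_leak_n, J_leak_a,
     J_ampa, J_eaat,
     J_ck_n, J_ck_a,
     J_gs, J_gp,
     J_o2_n, J_o2_a, J_o2_cap,
     J_camp) = J

    v_n, v_a, v_e, v_c = p.v_n, p.v_a, p.v_e, p.v_c
    relax = cbf * p.F_0
    if p.disable_transport:
        relax = 0.0
        j_rel = 0.0

    o2pp = p.o2_per_pyr
    dy = np.empty(28)
    # neuron
    dy[0] = J_leak_n + J_ampa - 3.0 * J_pump_n                       # Na_n
    dy[1] = J_glut_en - J_hk_n                                       # GLC_n
    dy[2] = J_hk_n - J_pk_n                                          # G6P_n
    dy[3] = 2.0 * J_pk_n - J_ldh_n - J_mito_n                        # PYR_n
    dy[4] = J_ldh_n - J_mct_n                                        # LAC_n
    dy[5] = 2.0 * J_pk_n - J_ldh_n - J_shuttle_n                     # NADHc_n
    dy[6] = J_shuttle_n - J_mito_n                                   # NADHm_n
    dy[7] = -J_hk_n + 2.0 * J_pk_n + p.n_atp_ox * J_mito_n - J_pump_n + J_ck_n  # ATP_n
    dy[8] = -J_ck_n                                                  # PCr_n
    dy[9] = J_o2_n - o2pp * J_mito_n                                 # O2_n
    # astrocyte
    dy[10] = J_leak_a + p.s_na * J_eaat * v_e / v_a - 3.0 * J_pump_a  # Na_a
    dy[11] = J_glut_ea - J_hk_a                                      # GLC_a
    dy[12] = J_hk_a - J_pk_a + J_gp - J_gs                           # G6P_a
    dy[13] = 2.0 * J_pk_a - J_ldh_a - J_mito_a                       # PYR_a
    dy[14] = J_ldh_a - J_mct_a                                       # LAC_a
    dy[15] = 2.0 * J_pk_a - J_ldh_a - J_shuttle_a                    # NADHc_a
    dy[16] = J_shuttle_a - J_mito_a                                  # NADHm_a
    dy[17] = -J_hk_a + 2.0 * J_pk_a + p.n_atp_ox * J_mito_a - J_pump_a + J_ck_a  # ATP_a
    dy[18] = -J_ck_a                                                 # PCr_a
    dy[19] = J_o2_a - o2pp * J_mito_a                                # O2_a
    dy[20] = J_gs - J_gp                                             # GLY_a
    dy[21] = J_camp                                                  # cAMP_a
    # extracellular space
    dy[22] = (j_rel + p.f_glu_recycle * J_eaat - J_eaat
              - p.k_glu_decay * y[22])                               # GLU_e
    dy[23] = J_glut_ce - (v_n / v_e) * J_glut_en - (v_a / v_e) * J_glut_ea  # GLC_e
    dy[24] = (v_n / v_e) * J_mct_n + (v_a / v_e) * J_mct_a - J_mct_ec       # LAC_e
    # capillary
    dy[25] = relax * (p.GLC_art - y[25]) - (v_e / v_c) * J_glut_ce   # GLC_c
    dy[26] = relax * (p.LAC_art - y[26]) + (v_e / v_c) * J_mct_ec    # LAC_c
    dy[27] = relax * (p.O2_art - y[27]) - J_o2_cap                   # O2_c
    return dy


def derivatives(state: NGVState, params: ModelParams, drive_at_t=(0.0, 1.0, 0.0)) -> NGVState:
    """d(state)/dt packaged as an :class:`NGVState` (fields are mM/s)."""
    params.validate()
    state.validate(params)
    j_rel, cbf, ne = drive_at_t
    return NGVState.from_array(rhs_vector(state.to_array(), params, j_rel, cbf, ne))


def _resting_rhs(y: np.ndarray, params: ModelParams) -> np.ndarray:
    return rhs_vector(y, params, 0.0, 1.0, 0.0)


def resting_state(
    params: ModelParams,
    guess: NGVState | None = None,
    tol: float = 1e-8,
    max_iter: int = 200,
) -> NGVState:
    """Steady state under resting drive (no release, CBF = 1, NE = 0).

    Damped Newton iteration with a forward-difference Jacobian, started
    from the balance-designed guess persisted in the default parameter
    file. Raises :class:`NoSteadyStateError` if the residual does not
    fall below ``tol`` (mM/s) within ``max_iter`` iterations.
    """
    params.validate()
    y = (guess or default_resting_guess()).to_array()
    n = y.size

    def norm(v):
        return float(np.max(np.abs(v)))

    f = _resting_rhs(y, params)
    for _ in range(max_iter):
        if norm(f) < tol:
            break
        jac = np.empty((n, n))
        h = 1e-7 * np.maximum(np.abs(y), 1e-3)
        for j in range(n):
            yj = y.copy()
            yj[j] += h[j]
            jac[:, j] = (_resting_rhs(yj, params) - f) / h[j]
        try:
            step = np.linalg.solve(jac, -f)
        except np.linalg.LinAlgError as exc:
            raise NoSteadyStateError(f"singular Jacobian (residual {norm(f):.3e} mM/s)") from exc
        lam = 1.0
        while lam > 1e-6:
            y_new = y + lam * step
            f_new = _resting_rhs(y_new, params)
            if np.all(np.isfinite(f_new)) and norm(f_new) < norm(f):
                y, f = y_new, f_new
                break
            lam *= 0.5
        else:
            raise NoSteadyStateError(
                f"no descent direction (residual {norm(f):.3e} mM/s)"
            )
    if norm(f) >= tol:
        raise NoSteadyStateError(
            f"no steady state within {max_iter} iterations "
            f"(residual {norm(f):.3e} mM/s, tol {tol:g})"
        )
    state = NGVState.from_array(np.maximum(y, 0.0) if np.all(y > -1e-12) else y)
    state.validate(params)
    return state


@dataclass
class UnitTrajectory:
    """Time-stamped state and flux samples of one integrated unit."""

    t: np.ndarray                 # (n_t,)
    y: np.ndarray                 # (n_t, 28), order SPECIES
    fluxes: np.ndarray            # (n_t, 30), order FluxSet.names
    params: ModelParams
    metadata: dict = field(default_factory=dict)

    def state_at(self, i: int) -> NGVState:
        return NGVState.from_array(self.y[i])

    def series(self, species: str) -> np.ndarray:
        return self.y[:, SPECIES_INDEX[species]]

    def flux_series(self, name: str) -> np.ndarray:
        return self.fluxes[:, FLUX_INDEX[name]]

    def to_frame(self):
        """Long-format (t, compartment, species, value) table."""
        import pandas as pd

        rows = []
        for j, sp in enumerate(SPECIES):
            rows.append(pd.DataFrame({
                "t": self.t,
                "compartment": compartment_of(sp),
                "species": sp,
                "value": self.y[:, j],
            }))
        return pd.concat(rows, ignore_index=True)


def integrate_unit(
    state0: NGVState,
    params: ModelParams,
    drive: ExternalDrive,
    t_span: tuple[float, float],
    dt_out: float,
    rtol: float = 1e-6,
    atol: float = 1e-9,
    method: str = "LSODA",
) -> UnitTrajectory:
    """Adaptive stiff-capable integration of one unit.

    The span is split at drive breakpoints so discontinuous inputs are
    handled exactly. Output is sampled every ``dt_out`` seconds
    (``floor(T/dt_out) + 1`` samples including both endpoints when the
    span is a multiple of ``dt_out``).
    """
    params.validate()
    state0.validate(params, atol=atol)
    t0, t1 = float(t_span[0]), float(t_span[1])
    if not t1 > t0:
        raise ValidationError("t_span must satisfy t1 > t0")

    n_out = int(np.floor((t1 - t0) / dt_out + 1e-9)) + 1
    t_out = t0 + dt_out * np.arange(n_out)
    seg_edges = np.unique(np.concatenate([[t0, t1], drive.breakpoints(t0, t1)]))

    y = state0.to_array()
    ys = [y.copy()]
    for a, b in zip(seg_edges[:-1], seg_edges[1:]):
        j_rel_sig, cbf_sig, ne_sig = drive.j_rel, drive.cbf, drive.ne

        def rhs(t, yy):
            return rhs_vector(yy, params, j_rel_sig.at(t), cbf_sig.at(t), ne_sig.at(t))

        mask = (t_out > a + 1e-12) & (t_out <= b + 1e-12)
        pts = np.clip(t_out[mask], a, b)
        # always evaluate the segment end so the state can be handed over
        t_eval = pts if pts.size and abs(pts[-1] - b) < 1e-12 else np.append(pts, b)
        sol = solve_ivp(
            rhs, (a, b), y, method=method, rtol=rtol, atol=atol, t_eval=t_eval,
        )
        if not sol.success:
            raise IntegrationError(
                f"integrator failed in segment [{a:g}, {b:g}] s: {sol.message} "
                f"(last good time {sol.t[-1] if sol.t.size else a:g} s)"
            )
        y = sol.y[:, -1].copy()
        ys.extend(list(sol.y[:, : pts.size].T))

    Y = np.asarray(ys)
    if Y.shape[0] != n_out:
        raise IntegrationError(
            f"expected {n_out} output samples, produced {Y.shape[0]}"
        )
    low = Y.min()
    if low < -atol:
        i, j = np.unravel_index(np.argmin(Y), Y.shape)
        raise IntegrationError(
            f"species {SPECIES[j]!r} went negative ({Y[i, j]:.3e} mM) "
            f"at t = {t_out[i]:g} s"
        )

    fx = np.array([
        flux_vector(Y[i], params, drive.j_rel.at(t_out[i]),
                    drive.cbf.at(t_out[i]), drive.ne.at(t_out[i]))
        for i in range(n_out)
    ])
    meta = {
        "t_span": (t0, t1), "dt_out": dt_out, "rtol": rtol, "atol": atol,
        "method": method,
        "disable_transport": params.disable_transport,
        "disable_oxidation": params.disable_oxidation,
    }
    return UnitTrajectory(t=t_out, y=Y, fluxes=fx, params=params, metadata=meta)


_CARBON_WEIGHTS = {
    # glucosyl species carry 6 carbons, triose-derived species 3
    "neuron": {"GLC_n": 6, "G6P_n": 6, "PYR_n": 3, "LAC_n": 3},
    "astrocyte": {"GLC_a": 6, "G6P_a": 6, "GLY_a": 6, "PYR_a": 3, "LAC_a": 3},
    "ecs": {"GLC_e": 6, "LAC_e": 3},
    "capillary": {"GLC_c": 6, "LAC_c": 3},
}


def conservation_report(traj: UnitTrajectory) -> dict:
    """Max relative drift of conserved pools and per-compartment carbon.

    Pool complements are derived from totals, so adenine, NAD and
    creatine pool drifts are identically zero; they are reported for
    completeness. Carbon drift is only an invariant for closed-system
    runs (transport and oxidation disabled, recorded in metadata).
    """
    if traj.t.size == 0:
        raise ValidationError("empty trajectory")
    p = traj.params
    pools = {
        "adenine_n": ("ATP_n", p.A_tot), "adenine_a": ("ATP_a", p.A_tot),
        "nad_cyt_n": ("NADHc_n", p.Nc_tot), "nad_cyt_a": ("NADHc_a", p.Nc_tot),
        "nad_mit_n": ("NADHm_n", p.Nm_tot), "nad_mit_a": ("NADHm_a", p.Nm_tot),
        "creatine_n": ("PCr_n", p.C_tot), "creatine_a": ("PCr_a", p.C_tot),
    }
    report: dict = {"pool_drift": {}, "carbon_drift": {}, "closed_system": bool(
        traj.metadata.get("disable_transport") and traj.metadata.get("disable_oxidation")
    )}
    for pool, (stored, total) in pools.items():
        series = traj.series(stored) + (total - traj.series(stored))
        report["pool_drift"][pool] = float(np.max(np.abs(series - total)) / total)
    for comp, weights in _CARBON_WEIGHTS.items():
        carbon = sum(w * traj.series(sp) for sp, w in weights.items())
        ref = carbon[0]
        drift = 0.0 if ref == 0 else float(np.max(np.abs(carbon - ref)) / abs(ref))
        report["carbon_drift"][comp] = drift
    return report


def anls_summary(traj: UnitTrajectory) -> dict:
    """Net time-integrated lactate transport per membrane (trapezoid rule).

    Positive means export to the ECS (cells) or ECS-to-capillary
    (``mct_ec``); the astrocyte-to-neuron shuttle signature is
    ``int_J_mct_a > 0`` with ``int_J_mct_n < 0``.
    """
    return {
        "int_J_mct_a": float(np.trapezoid(traj.flux_series("J_mct_a"), traj.t)),
        "int_J_mct_n": float(np.trapezoid(traj.flux_series("J_mct_n"), traj.t)),
        "int_J_mct_ec": float(np.trapezoid(traj.flux_series("J_mct_ec"), traj.t)),
    }
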