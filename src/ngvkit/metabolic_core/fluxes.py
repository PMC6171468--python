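"""Rate laws of the NGV reaction network.

Rate-law families (each unidirectional term vanishes with its substrate,
so exact integration cannot push a species negative):

* reversible carriers (GLUT, MCT): symmetric saturable
  ``T * (S1/(S1+K) - S2/(S2+K))`` — exactly zero at equal concentrations;
* LDH and creatine kinase: reversible mass action;
* hexokinase-PFK lump: linear in glucose, saturable in substrate ATP,
  Hill-inhibited by ATP;
* mitochondrial lump: Vmax times saturating factors in pyruvate, O2 and
  ADP, scaled by the mitochondrial NADH fraction (the lump re-oxidizes
  one shuttled NADH per pyruvate);
* glycogen phosphorylase: saturable in glycogen, Vmax scaled by
  ``cAMP/(cAMP+K_camp)``; glycogen synthase: saturable in G6P with a
  linear product cap at ``GLY_max``;
* EAAT: saturable in ECS glutamate, importing ``s_na`` Na per glutamate
  into the astrocyte.
"""

from __future__ import annotations

import numpy as np

from .state import SPECIES_INDEX as IX
from .state import FluxSet, ModelParams, NGVState, ValidationError

__all__ = ["compute_fluxes", "flux_vector", "FLUX_INDEX"]

FLUX_INDEX = {name: i for i, name in enumerate(FluxSet.names)}


def flux_vector(y, p: ModelParams, j_rel: float, cbf: float, ne: float) -> np.ndarray:
    """All fluxes (order ``FluxSet.names``) for a packed state vector."""
    (Na_n, GLC_n, G6P_n, PYR_n, LAC_n, NADHc_n, NADHm_n, ATP_n, PCr_n, O2_n,
     Na_a, GLC_a, G6P_a, PYR_a, LAC_a, NADHc_a, NADHm_a, ATP_a, PCr_a, O2_a,
     GLY_a, cAMP_a, GLU_e, GLC_e, LAC_e, GLC_c, LAC_c, O2_c) = y

    ADP_n = p.A_tot - ATP_n
    ADP_a = p.A_tot - ATP_a
    NADc_n = p.Nc_tot - NADHc_n
    NADc_a = p.Nc_tot - NADHc_a
    NADm_n = p.Nm_tot - NADHm_n
    NADm_a = p.Nm_tot - NADHm_a
    Cr_n = p.C_tot - PCr_n
    Cr_a = p.C_tot - PCr_a

    K = p.K_glut
    J_glut_ce = p.T_glut_ce * (GLC_c / (GLC_c + K) - GLC_e / (GLC_e + K))
    J_glut_en = p.T_glut_en * (GLC_e / (GLC_e + K) - GLC_n / (GLC_n + K))
    J_glut_ea = p.T_glut_ea * (GLC_e / (GLC_e + K) - GLC_a / (GLC_a + K))

    K = p.K_mct
    J_mct_n = p.T_mct_n * (LAC_n / (LAC_n + K) - LAC_e / (LAC_e + K))
    J_mct_a = p.T_mct_a * (LAC_a / (LAC_a + K) - LAC_e / (LAC_e + K))
    J_mct_ec = p.T_mct_ec * (LAC_e / (LAC_e + K) - LAC_c / (LAC_c + K))

    f_inh_n = 1.0 / (1.0 + (ATP_n / p.K_I_atp) ** p.n_H)
    f_inh_a = 1.0 / (1.0 + (ATP_a / p.K_I_atp) ** p.n_H)
    J_hk_n = p.k_hk * GLC_n * (ATP_n / (ATP_n + p.K_hk_atp)) * f_inh_n
    J_hk_a = p.k_hk * GLC_a * (ATP_a / (ATP_a + p.K_hk_atp)) * f_inh_a

    J_pk_n = p.k_pk * G6P_n * (NADc_n / p.Nc_tot) * (ADP_n / p.A_tot)
    J_pk_a = p.k_pk * G6P_a * (NADc_a / p.Nc_tot) * (ADP_a / p.A_tot)

    J_ldh_n = p.k_ldh_f_n * PYR_n * NADHc_n - p.k_ldh_r_n * LAC_n * NADc_n
    J_ldh_a = p.k_ldh_f_a * PYR_a * NADHc_a - p.k_ldh_r_a * LAC_a * NADc_a

    J_mito_n = (p.V_mito_n * PYR_n / (PYR_n + p.K_pyr)
                * O2_n / (O2_n + p.K_o2) * ADP_n / (ADP_n + p.K_adp)
                * NADHm_n / p.Nm_tot)
    J_mito_a = (p.V_mito_a * PYR_a / (PYR_a + p.K_pyr)
                * O2_a / (O2_a + p.K_o2) * ADP_a / (ADP_a + p.K_adp)
                * NADHm_a / p.Nm_tot)

    J_shuttle_n = p.k_shuttle_n * NADHc_n * (NADm_n / p.Nm_tot)
    J_shuttle_a = p.k_shuttle_a * NADHc_a * (NADm_a / p.Nm_tot)

    J_pump_n = p.k_pump * ATP_n * Na_n
    J_pump_a = p.k_pump * ATP_a * Na_a
    J_leak_n = p.g_leak_n
    J_leak_a = p.g_leak_a
    J_ampa = p.g_ampa * GLU_e / (GLU_e + p.K_ampa)
    J_eaat = p.V_eaat * GLU_e / (GLU_e + p.K_glu)

    J_ck_n = p.k_ck_f * PCr_n * ADP_n - p.k_ck_r * Cr_n * ATP_n
    J_ck_a = p.k_ck_f * PCr_a * ADP_a - p.k_ck_r * Cr_a * ATP_a

    # soft product cap: the (1 - GLY/GLY_max) factor is allowed to go
    # slightly negative so the resting point stays smooth and isolated
    J_gs = p.V_gs * G6P_a / (G6P_a + p.K_gs) * (1.0 - GLY_a / p.GLY_max)
    J_gp = p.V_gp * GLY_a / (GLY_a + p.K_gp) * cAMP_a / (cAMP_a + p.K_camp)

    J_o2_n = p.PS_o2 * (O2_c - O2_n)
    J_o2_a = p.PS_o2 * (O2_c - O2_a)

    J_camp = p.k_ne * ne - p.k_camp_deg * cAMP_a

    if p.disable_oxidation:
        J_mito_n = J_mito_a = 0.0
    if p.disable_transport:
        J_glut_ce = J_glut_en = J_glut_ea = 0.0
        J_mct_n = J_mct_a = J_mct_ec = 0.0
        J_o2_n = J_o2_a = 0.0

    J_o2_cap = (p.v_n * J_o2_n + p.v_a * J_o2_a) / p.v_c

    return np.array([
        J_glut_ce, J_glut_en, J_glut_ea,
        J_hk_n, J_hk_a, J_pk_n, J_pk_a,
        J_ldh_n, J_ldh_a,
        J_mct_n, J_mct_a, J_mct_ec,
        J_mito_n, J_mito_a, J_shuttle_n, J_shuttle_a,
        J_pump_n, J_pump_a, J_leak_n, J_leak_a,
        J_ampa, J_eaat,
        J_ck_n, J_ck_a,
        J_gs, J_gp,
        J_o2_n, J_o2_a, J_o2_cap,
        J_camp,
    ])


def compute_fluxes(state: NGVState, params: ModelParams, drive_at_t=(0.0, 1.0, 0.0)) -> FluxSet:
    """Validated flux evaluation at one instant.

    ``drive_at_t`` is ``(j_rel, cbf, ne)`` sampled at the time of interest.
    """
    params.validate()
    state.validate(params)
    j_rel, cbf, ne = drive_at_t
    return FluxSet.from_array(flux_vector(state.to_array(), params, j_rel, cbf, ne))
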