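"""State vector, parameter set and flux container for the NGV unit model.

Conventions (stated once, used everywhere):

* Units: concentrations in mM (cAMP in uM), time in s, length in um.
* Compartments: neuron (``n``), astrocyte (``a``), extracellular space
  (``e``), capillary (``c``) with volume fractions ``v_n + v_a + v_e +
  v_c = 1``.
* Derived, never stored: ``ADP_x = A_tot - ATP_x``, ``NADc_x = Nc_tot -
  NADHc_x``, ``NADm_x = Nm_tot - NADHm_x``, ``Cr_x = C_tot - PCr_x``.
"""

from __future__ import annotations

import dataclasses
import tomllib
from dataclasses import dataclass
from importlib import resources

import numpy as np

__all__ = [
    "SPECIES",
    "SPECIES_INDEX",
    "compartment_of",
    "NGVState",
    "ModelParams",
    "FluxSet",
    "ValidationError",
    "default_params",
    "default_resting_guess",
    "load_params",
]

#: Order of the packed state vector.
SPECIES: tuple[str, ...] = (
    "Na_n", "GLC_n", "G6P_n", "PYR_n", "LAC_n",
    "NADHc_n", "NADHm_n", "ATP_n", "PCr_n", "O2_n",
    "Na_a", "GLC_a", "G6P_a", "PYR_a", "LAC_a",
    "NADHc_a", "NADHm_a", "ATP_a", "PCr_a", "O2_a",
    "GLY_a", "cAMP_a",
    "GLU_e", "GLC_e", "LAC_e",
    "GLC_c", "LAC_c", "O2_c",
)

SPECIES_INDEX: dict[str, int] = {name: i for i, name in enumerate(SPECIES)}

_COMPARTMENT = {"n": "neuron", "a": "astrocyte", "e": "ecs", "c": "capillary"}


def compartment_of(species: str) -> str:
    """Map a species name to its compartment label."""
    return _COMPARTMENT[species.rsplit("_", 1)[1]]


class ValidationError(ValueError):
    """Raised when a state, parameter set or input file fails validation."""


@dataclass
class NGVState:
    """Concentrations of one NGV unit (28 stored species).

    Pool complements (ADP, NAD+, Cr) are derived on demand via
    :meth:`derived` and are never stored.
    """

    Na_n: float; GLC_n: float; G6P_n: float; PYR_n: float; LAC_n: float
    NADHc_n: float; NADHm_n: float; ATP_n: float; PCr_n: float; O2_n: float
    Na_a: float; GLC_a: float; G6P_a: float; PYR_a: float; LAC_a: float
    NADHc_a: float; NADHm_a: float; ATP_a: float; PCr_a: float; O2_a: float
    GLY_a: float; cAMP_a: float
    GLU_e: float; GLC_e: float; LAC_e: float
    GLC_c: float; LAC_c: float; O2_c: float

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, s) for s in SPECIES], dtype=float)

    @classmethod
    def from_array(cls, y: np.ndarray) -> "NGVState":
        y = np.asarray(y, dtype=float)
        if y.shape != (len(SPECIES),):
            raise ValidationError(
                f"state vector must have shape ({len(SPECIES)},), got {y.shape}"
            )
        return cls(*[float(v) for v in y])

    def derived(self, params: "ModelParams") -> dict[str, float]:
        """Pool complements implied by the conserved totals."""
        return {
            "ADP_n": params.A_tot - self.ATP_n,
            "ADP_a": params.A_tot - self.ATP_a,
            "NADc_n": params.Nc_tot - self.NADHc_n,
            "NADc_a": params.Nc_tot - self.NADHc_a,
            "NADm_n": params.Nm_tot - self.NADHm_n,
            "NADm_a": params.Nm_tot - self.NADHm_a,
            "Cr_n": params.C_tot - self.PCr_n,
            "Cr_a": params.C_tot - self.PCr_a,
        }

    def validate(self, params: "ModelParams", atol: float = 1e-9) -> None:
        """Check non-negativity, finiteness and pool bounds.

        Raises :class:`ValidationError` naming the offending field.
        """
        for name in SPECIES:
            v = getattr(self, name)
            if not np.isfinite(v):
                raise ValidationError(f"state field {name!r} is not finite: {v}")
            if v < -atol:
                raise ValidationError(f"state field {name!r} is negative: {v}")
        bounds = {
            "ATP_n": params.A_tot, "ATP_a": params.A_tot,
            "NADHc_n": params.Nc_tot, "NADHc_a": params.Nc_tot,
            "NADHm_n": params.Nm_tot, "NADHm_a": params.Nm_tot,
            "PCr_n": params.C_tot, "PCr_a": params.C_tot,
        }
        for name, total in bounds.items():
            if getattr(self, name) > total + atol:
                raise ValidationError(
                    f"state field {name!r} exceeds its pool total {total}"
                )


@dataclass
class ModelParams:
    """All rate constants, pool totals and geometry of the unit model."""

    # conserved pools (mM)
    A_tot: float; Nc_tot: float; Nm_tot: float; C_tot: float
    # glucose transport
    T_glut_ce: float; T_glut_en: float; T_glut_ea: float; K_glut: float
    # lactate transport
    T_mct_n: float; T_mct_a: float; T_mct_ec: float; K_mct: float
    # glycolysis lumps
    k_hk: float; K_I_atp: float; n_H: float; K_hk_atp: float; k_pk: float
    # lactate dehydrogenase (mass action, per cell type)
    k_ldh_f_n: float; k_ldh_r_n: float; k_ldh_f_a: float; k_ldh_r_a: float
    # mitochondrial oxidative lump
    V_mito_n: float; V_mito_a: float
    K_pyr: float; K_o2: float; K_adp: float
    n_atp_ox: float; o2_per_pyr: float
    # NADH shuttle
    k_shuttle_n: float; k_shuttle_a: float
    # sodium handling
    k_pump: float; g_leak_n: float; g_leak_a: float
    g_ampa: float; K_ampa: float
    # glutamate handling
    V_eaat: float; K_glu: float; s_na: float
    k_glu_decay: float; f_glu_recycle: float
    # creatine kinase
    k_ck_f: float; k_ck_r: float
    # glycogen
    V_gs: float; K_gs: float; GLY_max: float
    V_gp: float; K_gp: float; K_camp: float
    # noradrenaline / cAMP
    k_ne: float; k_camp_deg: float
    # capillary exchange
    PS_o2: float; GLC_art: float; LAC_art: float; O2_art: float; F_0: float
    # compartment volume fractions
    v_n: float; v_a: float; v_e: float; v_c: float
    # run flags (recorded in trajectory metadata)
    disable_transport: bool = False
    disable_oxidation: bool = False

    def validate(self) -> None:
        positive = [
            f.name for f in dataclasses.fields(self)
            if f.type == "float" and f.name not in ("f_glu_recycle",)
        ]
        for name in positive:
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValidationError(f"parameter {name!r} must be > 0, got {v}")
        if not 0.0 <= self.f_glu_recycle < 1.0:
            raise ValidationError("f_glu_recycle must be in [0, 1)")
        vsum = self.v_n + self.v_a + self.v_e + self.v_c
        if abs(vsum - 1.0) > 1e-9:
            raise ValidationError(f"volume fractions must sum to 1, got {vsum}")

    def to_dict(self) -> dict[str, float | bool]:
        return dataclasses.asdict(self)

    def replace(self, **kwargs) -> "ModelParams":
        return dataclasses.replace(self, **kwargs)


# keep in sync with the [section] layout of data/default_params.toml
_FLUX_NAMES = (
    "J_glut_ce", "J_glut_en", "J_glut_ea",
    "J_hk_n", "J_hk_a", "J_pk_n", "J_pk_a",
    "J_ldh_n", "J_ldh_a",
    "J_mct_n", "J_mct_a", "J_mct_ec",
    "J_mito_n", "J_mito_a", "J_shuttle_n", "J_shuttle_a",
    "J_pump_n", "J_pump_a", "J_leak_n", "J_leak_a",
    "J_ampa", "J_eaat",
    "J_ck_n", "J_ck_a",
    "J_gs", "J_gp",
    "J_o2_n", "J_o2_a", "J_o2_cap",
    "J_camp",
)


@dataclass
class FluxSet:
    """All reaction and transport fluxes of one unit at one instant.

    Trans-membrane fluxes are expressed in mM/s in a stated frame:
    cell-frame for ``J_glut_en/ea``, ``J_mct_n/a`` (positive = export to
    ECS), ``J_o2_n/a`` (positive = into the cell); ECS-frame for
    ``J_glut_ce``, ``J_mct_ec`` (positive = ECS to capillary), ``J_eaat``;
    capillary-frame for ``J_o2_cap`` (positive = out of capillary).
    ``J_pump`` is in ATP units (Na extruded = 3x). ``J_camp`` is uM/s.
    """

    J_glut_ce: float; J_glut_en: float; J_glut_ea: float
    J_hk_n: float; J_hk_a: float; J_pk_n: float; J_pk_a: float
    J_ldh_n: float; J_ldh_a: float
    J_mct_n: float; J_mct_a: float; J_mct_ec: float
    J_mito_n: float; J_mito_a: float
    J_shuttle_n: float; J_shuttle_a: float
    J_pump_n: float; J_pump_a: float
    J_leak_n: float; J_leak_a: float
    J_ampa: float; J_eaat: float
    J_ck_n: float; J_ck_a: float
    J_gs: float; J_gp: float
    J_o2_n: float; J_o2_a: float; J_o2_cap: float
    J_camp: float

    names = _FLUX_NAMES

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in _FLUX_NAMES], dtype=float)

    @classmethod
    def from_array(cls, arr: np.ndarray) -> "FluxSet":
        return cls(*[float(v) for v in np.asarray(arr, dtype=float)])


def _flatten_toml(doc: dict) -> dict:
    flat: dict = {}
    for key, value in doc.items():
        if isinstance(value, dict):
            flat.update(value)
        else:
            flat[key] = value
    return flat


def _read_default_doc() -> dict:
    text = (
        resources.files("ngvkit.data")
        .joinpath("default_params.toml")
        .read_text(encoding="utf-8")
    )
    return tomllib.loads(text)


def default_params() -> ModelParams:
    """The packaged default parameter set (documented TOML file)."""
    doc = _read_default_doc()
    doc.pop("resting_state", None)
    params = ModelParams(**_flatten_toml(doc))
    params.validate()
    return params


def default_resting_guess() -> NGVState:
    """Initial guess for the resting-state root solve, from the default file."""
    doc = _read_default_doc()
    rest = doc["resting_state"]
    return NGVState(**{name: float(rest[name]) for name in SPECIES})


def load_params(path) -> ModelParams:
    """Read a user parameter TOML; unspecified symbols fall back to defaults."""
    with open(path, "rb") as fh:
        doc = tomllib.load(fh)
    doc.pop("resting_state", None)
    base = _read_default_doc()
    base.pop("resting_state", None)
    merged = _flatten_toml(base)
    flat = _flatten_toml(doc)
    unknown = set(flat) - set(merged)
    if unknown:
        raise ValidationError(f"unknown parameter(s): {sorted(unknown)}")
    merged.update(flat)
    params = ModelParams(**merged)
    params.validate()
    return params
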