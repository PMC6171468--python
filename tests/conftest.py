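"""Shared fixtures. Heavyweight objects are session-scoped; everything
is generated procedurally (no stored binary fixtures)."""

from __future__ import annotations

import numpy as np
import pytest

from ngvkit.metabolic_core import default_params, resting_state
from ngvkit.synthetic_data import SceneRecipe, make_neuropil


@pytest.fixture(scope="session")
def params():
    return default_params()


@pytest.fixture(scope="session")
def rest(params):
    return resting_state(params)


@pytest.fixture(scope="session")
def small_scene():
    recipe = SceneRecipe(n_axons=2, n_dendrites=1, n_boutons=3,
                         n_spines=2, n_astro_blobs=1, seed=7)
    meshes, manifest = make_neuropil(recipe)
    return meshes, manifest


def rk4_oracle(y0, params, drive, t_span, dt, n_record):
    """Independent fixed-step classic RK4 integrator (oracle path).

    Integrates piecewise between drive breakpoints with steps of exactly
    ``dt`` (breakpoints must be multiples of ``dt``); records the state
    at ``n_record + 1`` evenly spaced output times.
    """
    from ngvkit.metabolic_core.odes import rhs_vector

    t0, t1 = t_span
    edges = np.concatenate([[t0, t1], drive.breakpoints(t0, t1)])
    edges = np.unique(edges)
    t_rec = np.linspace(t0, t1, n_record + 1)
    out = [np.asarray(y0, dtype=float).copy()]
    y = out[0].copy()
    rec_i = 1
    for a, b in zip(edges[:-1], edges[1:]):
        n_steps = int(round((b - a) / dt))
        assert abs(n_steps * dt - (b - a)) < 1e-9, "segment not a dt multiple"
        jr = drive.j_rel.at((a + b) / 2)
        cb = drive.cbf.at((a + b) / 2)
        ne = drive.ne.at((a + b) / 2)
        for k in range(n_steps):
            k1 = rhs_vector(y, params, jr, cb, ne)
            k2 = rhs_vector(y + 0.5 * dt * k1, params, jr, cb, ne)
            k3 = rhs_vector(y + 0.5 * dt * k2, params, jr, cb, ne)
            k4 = rhs_vector(y + dt * k3, params, jr, cb, ne)
            y = y + (dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
            t_now = a + (k + 1) * dt
            while rec_i < len(t_rec) and t_now >= t_rec[rec_i] - 1e-9:
                out.append(y.copy())
                rec_i += 1
    return t_rec, np.asarray(out)
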