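"""Nucleus swelling initialisation.

The disc is pre-stressed before any external load: the nucleus pulposus
carries an initial pressure (0.2 MPa by default) balanced by tensile hoop
stress in the annulus. The mechanism here is an isotropic swelling
eigenstrain in the NP — the elastic deformation seen by the NP material is
``F / s`` for a swelling stretch ``s >= 1`` — whose magnitude is found by a
scalar root solve so that the volume-averaged NP hydrostatic pressure,
``-tr(sigma)/3`` with no external load applied, hits the target.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Optional

import numpy as np

from . import constitutive as con
from .fem import LoadCase, SolutionState, SolverConfig, SolverFailure, \
    solve_quasi_static
from .geometry import DiscMesh

__all__ = ["SwellingConfig", "initialize_swelling", "np_mean_pressure"]

log = logging.getLogger(__name__)

_NO_LOAD = LoadCase(axial_force=0.0, axial_rotation=0.0, lateral_bending=0.0,
                    flexion=0.0, compression_on=True, rotation_on=False,
                    bending_on=False, flexion_on=False, name="swelling")


@dataclass
class SwellingConfig:
    """Target mean NP pressure (MPa), equilibration increments per solve,
    relative tolerance on the achieved pressure, and root-solve bounds."""

    target_np_pressure: float = 0.2
    increments: int = 4
    tolerance: float = 0.02
    max_root_iters: int = 12
    s_max: float = 1.25

    def __post_init__(self) -> None:
        if self.target_np_pressure < 0:
            raise ValueError("target pressure must be non-negative")
        if not 0 < self.tolerance < 1:
            raise ValueError("tolerance must lie in (0, 1)")


def np_mean_pressure(state: SolutionState, mesh: DiscMesh) -> float:
    """Volume-averaged hydrostatic pressure -tr(sigma)/3 over NP elements."""
    npe = mesh.region_elements("NP")
    vols = mesh.volumes()[npe]
    p = -np.trace(state.stress[npe], axis1=1, axis2=2) / 3.0
    return float(np.average(p, weights=vols))


def initialize_swelling(mesh: DiscMesh,
                        materials: Dict[str, con.MaterialParams],
                        cfg: Optional[SwellingConfig] = None,
                        solver: Optional[SolverConfig] = None,
                        ) -> SolutionState:
    """Equilibrate the disc under NP swelling only and return the pre-stressed
    state (externally unloaded, in equilibrium, mean NP pressure on target).

    The achieved pressure is monotone in the swelling stretch, so a secant
    iteration from a linearised first guess converges in a few equilibrium
    solves; each solve ramps the eigenstrain over a handful of increments.
    """
    cfg = cfg or SwellingConfig()
    solver = solver or SolverConfig(increments=cfg.increments)

    if cfg.target_np_pressure == 0.0:
        zero = np.zeros((mesh.n_nodes, 3))
        ne = mesh.n_elements
        return SolutionState(u=zero, stress=np.zeros((ne, 3, 3)),
                             swelling_scale=1.0)

    def solve_at(s: float) -> SolutionState:
        return solve_quasi_static(
            mesh, materials, _NO_LOAD, solver,
            swelling_schedule=lambda t: 1.0 + t * (s - 1.0))

    # NP bulk modulus sets the linearised pressure response: p ~ K * 3(s-1)
    np_params = materials["NP"]
    bulk = 2.0 / np_params.d if hasattr(np_params, "d") else 10.0
    s = 1.0 + cfg.target_np_pressure / (3.0 * bulk)
    s_lo, p_lo = 1.0, 0.0
    state = None
    for it in range(cfg.max_root_iters):
        s = min(max(s, 1.0 + 1e-8), cfg.s_max)
        state = solve_at(s)
        p = np_mean_pressure(state, mesh)
        log.info("swelling solve %d: s=%.6f -> mean NP pressure %.4f MPa",
                 it, s, p)
        if abs(p - cfg.target_np_pressure) <= cfg.tolerance * \
                cfg.target_np_pressure:
            return state
        # secant update on the (monotone) pressure-stretch curve
        if p <= p_lo + 1e-12:
            s = s + (s - s_lo)  # no progress; expand
            continue
        s_new = s + (cfg.target_np_pressure - p) * (s - s_lo) / (p - p_lo)
        if p < cfg.target_np_pressure:
            s_lo, p_lo = s, p
        s = s_new
    raise SolverFailure(
        f"swelling failed to reach {cfg.target_np_pressure} MPa within "
        f"{cfg.max_root_iters} solves (last {p:.4f} MPa)", last_state=state)
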