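"""Quasi-static nonlinear finite elements on hexahedral meshes.

Equilibrium is solved either implicitly (Newton iteration on the reduced
system, with automatic increment cutting) or by explicit dynamic relaxation
(central differences with mass scaling and viscous damping, plus the
kinetic-energy quasi-static check).

Element technology: trilinear hexahedra with an F-bar treatment of the
volumetric response (the deformation-gradient determinant at each Gauss point
is replaced by its value at the element centroid) to avoid volumetric locking
of the nearly incompressible disc tissues. Affine deformation fields are
reproduced exactly, so the patch test is satisfied.

Loads are applied through a kinematic coupling: the cranial node set moves
rigidly with a virtual reference node at its centroid. All active rotation
components (flexion about the lateral axis, lateral bending about the
antero-posterior axis, axial rotation about the spine axis) are composed into
a single rotation vector and ramped proportionally together with the axial
force, which acts as a dead load on the reference node.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.spatial.transform import Rotation

from . import constitutive as con
from . import hexelem
from .geometry import DiscMesh

__all__ = [
    "LoadCase",
    "SolverConfig",
    "SolutionState",
    "FEError",
    "SolverFailure",
    "NotApplicableError",
    "KinematicCoupling",
    "apply_coupling",
    "Assembly",
    "ReducedSystem",
    "solve_quasi_static",
    "kinetic_energy_ratio",
]

log = logging.getLogger(__name__)


class FEError(RuntimeError):
    pass


class SolverFailure(FEError):
    """Non-convergence; carries the last converged state if any."""

    def __init__(self, msg: str, last_state: Optional["SolutionState"] = None):
        super().__init__(msg)
        self.last_state = last_state


class NotApplicableError(FEError):
    pass


# ---------------------------------------------------------------------------
# load case and solver configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LoadCase:
    """Prescribed rotations (degrees) and axial force (N, compression
    positive) applied to the cranial reference node. Components can be
    switched off individually; magnitudes of inactive components are ignored.
    """

    axial_force: float = 800.0
    axial_rotation: float = 4.0
    lateral_bending: float = 10.0
    flexion: float = 13.0
    compression_on: bool = True
    rotation_on: bool = True
    bending_on: bool = True
    flexion_on: bool = True
    name: str = "custom"

    def __post_init__(self) -> None:
        for nm in ("axial_force", "axial_rotation", "lateral_bending", "flexion"):
            if getattr(self, nm) < 0:
                raise ValueError(f"{nm} must be non-negative")
        if not (self.compression_on or self.rotation_on or self.bending_on
                or self.flexion_on):
            raise ValueError("at least one load component must be active")

    @property
    def force(self) -> float:
        return self.axial_force if self.compression_on else 0.0

    def rotation_vector(self, scale: float = 1.0) -> np.ndarray:
        """Combined rotation vector (radians). Flexion tilts the cranial
        endplate anteriorly (rotation about -x), lateral bending drops the
        contralateral (-x) side (rotation about +y), axial rotation is about
        +z. Simultaneous ramping keeps the application order-free."""
        fl = np.radians(self.flexion) if self.flexion_on else 0.0
        lb = np.radians(self.lateral_bending) if self.bending_on else 0.0
        ar = np.radians(self.axial_rotation) if self.rotation_on else 0.0
        return scale * np.array([-fl, lb, ar])


@dataclass
class SolverConfig:
    """Solution controls for both modes.

    Implicit: ``increments`` load steps, Newton with relative tolerance
    ``rtol`` and at most ``max_iter`` iterations, increment halving down to
    ``min_cut`` of the base increment. Explicit: ``n_steps`` central
    difference steps of pseudo-time step ``dt`` with Gershgorin-based mass
    scaling (factor ``mass_safety``) and viscous damping ``damping``.
    """

    mode: str = "implicit-newton"
    rtol: float = 1e-6
    max_iter: int = 30
    increments: int = 20
    min_cut: float = 1.0 / 64.0
    dt: float = 1.0
    n_steps: int = 5000
    damping: float = 0.08
    mass_safety: float = 4.0
    mass_updates: int = 20
    fd_step: float = 1e-5

    def __post_init__(self) -> None:
        if self.rtol <= 0:
            raise ValueError("rtol must be positive")
        if self.increments < 1:
            raise ValueError("increments must be >= 1")
        if self.mode not in ("implicit-newton", "explicit-relaxation"):
            raise ValueError(f"unknown solver mode {self.mode!r}")


@dataclass
class SolutionState:
    """Converged (or partially converged) solution."""

    u: np.ndarray                       # (nn, 3) nodal displacements, mm
    stress: np.ndarray                  # (ne, 3, 3) element-mean Cauchy, MPa
    mode: str = "implicit-newton"
    converged: bool = True
    ref_history: List[dict] = field(default_factory=list)
    energy_history: Optional[dict] = None   # explicit: {"kinetic","internal"}
    swelling_scale: float = 1.0             # NP eigenstrain stretch carried
    log: List[str] = field(default_factory=list)
    reactions: Optional[np.ndarray] = None  # (nn, 3) internal force at fixed set


# ---------------------------------------------------------------------------
# kinematic coupling
# ---------------------------------------------------------------------------

@dataclass
class KinematicCoupling:
    """Rigid coupling of a node set to a virtual reference node."""

    node_ids: np.ndarray
    x_ref: np.ndarray
    lever: np.ndarray  # (ns, 3) reference lever arms X - x_ref

    def targets(self, rotvec: np.ndarray, u_ref: np.ndarray) -> np.ndarray:
        """Slave displacements for a finite rotation + reference translation."""
        R = Rotation.from_rotvec(rotvec).as_matrix()
        return u_ref[None, :] + self.lever @ (R.T - np.eye(3))

    def offsets(self, rotvec: np.ndarray) -> np.ndarray:
        """Rotation-induced part of the slave displacements (u_ref = 0)."""
        return self.targets(rotvec, np.zeros(3))


def apply_coupling(mesh: DiscMesh, set_name: str = "cranial-coupled") -> KinematicCoupling:
    """Build the rigid kinematic constraint for a mesh node set."""
    ids = mesh.node_sets.get(set_name)
    if ids is None or len(ids) == 0:
        raise FEError(f"node set {set_name!r} is empty or missing")
    X = mesh.nodes[ids]
    x_ref = X.mean(axis=0)
    return KinematicCoupling(node_ids=np.asarray(ids), x_ref=x_ref,
                             lever=X - x_ref)


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------

class Assembly:
    """Vectorised internal-force / stiffness assembly over region groups."""

    def __init__(self, mesh: DiscMesh, materials: Dict[str, con.MaterialParams]):
        self.mesh = mesh
        self.materials = materials
        missing = set(np.unique(mesh.region)) - set(materials)
        if missing:
            raise FEError(f"materials missing for regions: {sorted(missing)}")
        self.dNdX, self.detJ = hexelem.precompute(mesh.nodes, mesh.hexes,
                                                  hexelem.GAUSS8)
        dNdX0, detJ0 = hexelem.precompute(mesh.nodes, mesh.hexes,
                                          hexelem.GAUSS1)
        self.dNdX0 = dNdX0[:, 0]
        if np.any(self.detJ <= 0) or np.any(detJ0 <= 0):
            raise con.KinematicsError("mesh contains inverted elements")
        self.groups = []
        for label in np.unique(mesh.region):
            idx = np.flatnonzero(mesh.region == label)
            params = materials[label]
            fibers = None
            if isinstance(params, con.AnisoHyperParams):
                if mesh.fiber_dirs is None or np.any(
                        np.isnan(mesh.fiber_dirs[idx])):
                    raise con.ConfigurationError(
                        f"region {label} needs fiber directions")
                fibers = mesh.fiber_dirs[idx]
            self.groups.append((label, idx, params, fibers))
        # isotropic swelling eigenstrain stretch per element (1 = none)
        self.swelling_scale = np.ones(mesh.n_elements)
        # invertible-element mode: principal stretches of near-degenerate
        # deformation gradients are clamped (SVD repair) instead of raising,
        # letting explicit dynamics traverse snap-through events
        self.repair_mode = False
        self.stretch_floor = 0.25
        self._edofs = (3 * mesh.hexes[:, :, None] +
                       np.arange(3)[None, None, :]).reshape(-1, 24)

    def set_np_swelling(self, s: float) -> None:
        self.swelling_scale[:] = 1.0
        self.swelling_scale[self.mesh.region == "NP"] = s

    # -- kinematics ---------------------------------------------------------

    def _repair(self, F: np.ndarray) -> np.ndarray:
        """Clamp principal stretches of (m,3,3) gradients to the floor.

        Inverted gradients are made proper by flipping the sign of the
        smallest singular value before clamping (invertible-element repair).
        """
        U, s, Vt = np.linalg.svd(F)
        neg = np.linalg.det(U @ Vt) < 0
        s[neg, -1] *= -1.0
        U[neg, :, -1] *= -1.0
        s = np.maximum(s, self.stretch_floor)
        return np.einsum("mik,mk,mkj->mij", U, s, Vt)

    def _fbar(self, ue: np.ndarray):
        """F-bar deformation gradients at the 8 Gauss points.

        Returns (Fbar, F, J) with shapes (ne,8,3,3), (ne,8,3,3), (ne,8).
        """
        F = np.eye(3) + np.einsum("eai,egaj->egij", ue, self.dNdX)
        F0 = np.eye(3) + np.einsum("eai,eaj->eij", ue, self.dNdX0)
        J = np.linalg.det(F)
        J0 = np.linalg.det(F0)
        floor3 = self.stretch_floor ** 3
        if np.any(J <= 0) or np.any(J0 <= 0) or (
                self.repair_mode and (np.any(J < floor3) or np.any(J0 < floor3))):
            if not self.repair_mode:
                bad = np.unique(np.nonzero(J <= 0)[0])
                raise con.KinematicsError(
                    f"element inversion (elements {bad[:5].tolist()}...)")
            shp = F.shape
            F = self._repair(F.reshape(-1, 3, 3)).reshape(shp)
            F0 = self._repair(F0)
            J = np.linalg.det(F)
            J0 = np.linalg.det(F0)
        Fbar = (J0[:, None] / J)[..., None, None] ** (1.0 / 3.0) * F
        return Fbar, F, J

    def element_forces(self, ue: np.ndarray, want_stress: bool = False):
        """Internal nodal forces per element for element displacements ``ue``
        (ne, 8, 3). Optionally also the Gauss-point Cauchy stresses."""
        Fbar, F, J = self._fbar(ue)
        ne = ue.shape[0]
        sig = np.empty((ne, 8, 3, 3))
        with np.errstate(over="ignore", invalid="ignore"):
            for label, idx, params, fibers in self.groups:
                Fg = Fbar[idx].reshape(-1, 3, 3)
                s = self.swelling_scale[idx]
                if np.any(s != 1.0):
                    Fg = Fg / np.repeat(s, 8)[:, None, None]
                fg = None
                if fibers is not None:
                    fg = np.repeat(fibers, 8, axis=0)
                sig[idx] = con.cauchy_batch(Fg, params, fg).reshape(-1, 8, 3, 3)
        if not np.all(np.isfinite(sig)):
            # extreme trial kinematics overflow the fiber exponential;
            # treated like inversion so the caller backtracks or cuts
            raise con.KinematicsError("non-finite stress at trial state")
        Finv = np.linalg.inv(F)
        # effective first Piola-Kirchhoff: P = J sigma F^{-T}
        P = J[..., None, None] * np.einsum("egik,egjk->egij", sig, Finv)
        fe = np.einsum("eg,egij,egaj->eai", self.detJ, P, self.dNdX)
        if want_stress:
            return fe, sig
        return fe

    def internal_force(self, u: np.ndarray, want_stress: bool = False):
        ue = u.reshape(-1, 3)[self.mesh.hexes]
        if want_stress:
            fe, sig = self.element_forces(ue, want_stress=True)
        else:
            fe = self.element_forces(ue)
        f = np.zeros(3 * self.mesh.n_nodes)
        np.add.at(f, self._edofs, fe.reshape(-1, 24))
        if want_stress:
            return f, sig
        return f

    def strain_energy(self, u: np.ndarray) -> float:
        ue = u.reshape(-1, 3)[self.mesh.hexes]
        Fbar, _, _ = self._fbar(ue)
        total = 0.0
        for label, idx, params, fibers in self.groups:
            Fg = Fbar[idx].reshape(-1, 3, 3)
            s = self.swelling_scale[idx]
            scale = np.repeat(s, 8) ** 3
            if np.any(s != 1.0):
                Fg = Fg / np.repeat(s, 8)[:, None, None]
            fg = None
            if fibers is not None:
                fg = np.repeat(fibers, 8, axis=0)
            psi = con.energy_batch(Fg, params, fg) * scale
            total += float(np.dot(psi, self.detJ[idx].ravel()))
        return total

    def _forces_batched(self, ue_b: np.ndarray) -> np.ndarray:
        """Element forces for a batch of displacement sets (B, ne, 8, 3)."""
        B, ne = ue_b.shape[:2]
        F = np.eye(3) + np.einsum("beai,egaj->begij", ue_b, self.dNdX, optimize=True)
        F0 = np.eye(3) + np.einsum("beai,eaj->beij", ue_b, self.dNdX0)
        J = np.linalg.det(F)
        J0 = np.linalg.det(F0)
        floor3 = self.stretch_floor ** 3
        if np.any(J <= 0) or np.any(J0 <= 0) or (
                self.repair_mode and (np.any(J < floor3) or np.any(J0 < floor3))):
            if not self.repair_mode:
                raise con.KinematicsError("element inversion in tangent batch")
            F = self._repair(F.reshape(-1, 3, 3)).reshape(F.shape)
            F0 = self._repair(F0.reshape(-1, 3, 3)).reshape(F0.shape)
            J = np.linalg.det(F)
            J0 = np.linalg.det(F0)
        Fbar = (J0[:, :, None] / J)[..., None, None] ** (1.0 / 3.0) * F
        sig = np.empty((B, ne, 8, 3, 3))
        with np.errstate(over="ignore", invalid="ignore"):
            for label, idx, params, fibers in self.groups:
                k = len(idx)
                Fg = Fbar[:, idx].reshape(-1, 3, 3)
                s = self.swelling_scale[idx]
                if np.any(s != 1.0):
                    Fg = Fg / np.tile(np.repeat(s, 8), B)[:, None, None]
                fg = None
                if fibers is not None:
                    fg = np.broadcast_to(
                        np.repeat(fibers, 8, axis=0)[None],
                        (B, k * 8, 2, 3)).reshape(-1, 2, 3)
                sig[:, idx] = con.cauchy_batch(Fg, params, fg).reshape(
                    B, k, 8, 3, 3)
        if not np.all(np.isfinite(sig)):
            raise con.KinematicsError("non-finite stress in tangent batch")
        Finv = np.linalg.inv(F)
        P = J[..., None, None] * np.einsum("begik,begjk->begij", sig, Finv, optimize=True)
        return np.einsum("eg,begij,egaj->beai", self.detJ, P, self.dNdX, optimize=True)

    def element_stiffness(self, u: np.ndarray, h: float = 1e-5) -> np.ndarray:
        """(ne, 24, 24) element tangents by central differences of the
        element internal forces (consistent with F-bar and swelling).

        Central differencing keeps the Jacobian accurate enough for Newton
        not to stagnate on the strongly curved fiber exponential; all 48
        perturbed force evaluations run as one batched kernel call.
        """
        ue = u.reshape(-1, 3)[self.mesh.hexes]
        ne = ue.shape[0]
        ue_b = np.broadcast_to(ue[None], (48, ne, 8, 3)).copy()
        for d in range(24):
            a, i = divmod(d, 3)
            ue_b[2 * d, :, a, i] += h
            ue_b[2 * d + 1, :, a, i] -= h
        fe = self._forces_batched(ue_b).reshape(48, ne, 24)
        return np.transpose((fe[0::2] - fe[1::2]) / (2.0 * h), (1, 2, 0))

    def tangent(self, u: np.ndarray, h: float = 1e-6) -> sp.csr_matrix:
        ke = self.element_stiffness(u, h)
        rows = np.repeat(self._edofs, 24, axis=1).ravel()
        cols = np.tile(self._edofs, (1, 24)).ravel()
        n = 3 * self.mesh.n_nodes
        K = sp.coo_matrix((ke.ravel(), (rows, cols)), shape=(n, n))
        return K.tocsr()

    def element_mean_stress(self, u: np.ndarray) -> np.ndarray:
        ue = u.reshape(-1, 3)[self.mesh.hexes]
        _, sig = self.element_forces(ue, want_stress=True)
        return sig.mean(axis=1)


# ---------------------------------------------------------------------------
# reduced system (Dirichlet + coupling elimination)
# ---------------------------------------------------------------------------

class ReducedSystem:
    """Master-slave elimination of fixed and coupled dofs.

    Full displacements: ``u = T q + g`` where ``q`` stacks the free nodal
    dofs and (if a coupling is present) the three reference-node
    translations; ``g`` carries the prescribed Dirichlet values and the
    rotation-induced part of the coupled-node motion.
    """

    def __init__(self, n_nodes: int,
                 dirichlet_idx: np.ndarray,
                 dirichlet_vals: np.ndarray,
                 coupling: Optional[KinematicCoupling] = None):
        self.nn = n_nodes
        self.dir_idx = np.asarray(dirichlet_idx, dtype=np.int64)
        self.dir_vals = np.asarray(dirichlet_vals, dtype=float)
        self.coupling = coupling
        ndof = 3 * n_nodes
        slave = np.zeros(ndof, dtype=bool)
        slave[self.dir_idx] = True
        self.slave_dofs = None
        if coupling is not None:
            sd = (3 * coupling.node_ids[:, None] + np.arange(3)).ravel()
            if np.any(slave[sd]):
                raise FEError("coupled nodes overlap the Dirichlet set")
            slave[sd] = True
            self.slave_dofs = sd
        self.free = np.flatnonzero(~slave)
        self.nq = len(self.free) + (3 if coupling is not None else 0)
        rows = [self.free]
        cols = [np.arange(len(self.free))]
        vals = [np.ones(len(self.free))]
        if coupling is not None:
            ns = len(coupling.node_ids)
            for i in range(3):
                rows.append(3 * coupling.node_ids + i)
                cols.append(np.full(ns, len(self.free) + i))
                vals.append(np.ones(ns))
        self.T = sp.csr_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=(ndof, self.nq))
        self.ref_slice = slice(len(self.free), self.nq) \
            if coupling is not None else None

    def g(self, t: float, rotvec: Optional[np.ndarray] = None) -> np.ndarray:
        out = np.zeros(3 * self.nn)
        out[self.dir_idx] = t * self.dir_vals
        if self.coupling is not None and rotvec is not None:
            out[self.slave_dofs] = self.coupling.offsets(rotvec).ravel()
        return out

    def expand(self, q: np.ndarray, t: float,
               rotvec: Optional[np.ndarray] = None) -> np.ndarray:
        return (self.T @ q + self.g(t, rotvec)).reshape(self.nn, 3)

    def reduce(self, f: np.ndarray) -> np.ndarray:
        return self.T.T @ f


# ---------------------------------------------------------------------------
# implicit solver
# ---------------------------------------------------------------------------

def _residual(assembly: Assembly, rsys: ReducedSystem, q, t, rotvec, fext_q):
    u = rsys.expand(q, t, rotvec)
    fint = assembly.internal_force(u.ravel())
    r = rsys.reduce(fint) - fext_q
    scale = max(1.0, np.linalg.norm(fint), np.linalg.norm(fext_q))
    return u, r, np.linalg.norm(r) / scale


def _newton(assembly: Assembly, rsys: ReducedSystem, q: np.ndarray, t: float,
            rotvec: np.ndarray, fext_q: np.ndarray, cfg: SolverConfig):
    """Damped (Levenberg-Marquardt) Newton iteration at fixed load level.

    Near limit points the reduced tangent turns indefinite and raw Newton
    directions explode; a diagonal shift, adapted multiplicatively from the
    step outcome, keeps iterates admissible while leaving the converged
    equilibrium unbiased. Returns (q, n_iter).
    """
    u, r, res = _residual(assembly, rsys, q, t, rotvec, fext_q)
    lam = 0.0
    best = res
    stagnant = 0
    Kq = None
    lu = None
    stale = True
    for it in range(cfg.max_iter):
        if res < cfg.rtol:
            return q, it
        if stale or Kq is None:
            K = assembly.tangent(u.ravel(), cfg.fd_step)
            Kq = (rsys.T.T @ K @ rsys.T).tocsc()
            lu = spla.splu(Kq) if lam == 0.0 else None
        dscale = float(np.abs(Kq.diagonal()).mean())
        accepted = False
        for _ in range(10):
            if lam == 0.0 and lu is not None:
                dq = lu.solve(-r)
            else:
                shifted = Kq + lam * dscale * sp.identity(rsys.nq, format="csc")
                dq = spla.spsolve(shifted.tocsc(), -r)
            if np.all(np.isfinite(dq)):
                try:
                    u_n, r_n, res_n = _residual(assembly, rsys, q + dq,
                                                t, rotvec, fext_q)
                except con.KinematicsError:
                    res_n = np.inf
                if np.isfinite(res_n) and res_n < max(1.2 * res, cfg.rtol):
                    accepted = True
                    break
            lam = max(4.0 * lam, 1e-6)
        if not accepted:
            if not stale:
                stale = True  # retry the iteration with a fresh tangent
                continue
            raise SolverFailure(
                f"damped Newton stalled at load level {t:.4f} "
                f"(residual {res:.3e})")
        ratio = res_n / max(res, 1e-300)
        q, u, r, res = q + dq, u_n, r_n, res_n
        # modified Newton: keep the factorised tangent while it converges fast
        stale = ratio > 0.2 or lam > 0.0
        lam *= 0.25
        if lam < 1e-9:
            lam = 0.0
        if res < 0.5 * best:
            best, stagnant = res, 0
        else:
            stagnant += 1
            if stagnant >= 8:
                raise SolverFailure(
                    f"Newton stagnating at load level {t:.4f} "
                    f"(residual {res:.3e})")
    raise SolverFailure(f"no convergence in {cfg.max_iter} iterations "
                        f"(residual {res:.3e}) at load level {t:.4f}")


def solve_quasi_static(mesh: DiscMesh,
                       materials: Dict[str, con.MaterialParams],
                       load: LoadCase,
                       cfg: Optional[SolverConfig] = None,
                       prestate: Optional[SolutionState] = None,
                       swelling_schedule: Optional[Callable[[float], float]] = None,
                       ) -> SolutionState:
    """Solve a load case on a disc mesh.

    The caudal node set is fixed, the cranial set is kinematically coupled to
    a reference node at which the rotations are prescribed and the axial
    force applied (dead load, -z). Rotations and force ramp proportionally
    over the increments. ``prestate`` supplies a swelling pre-stress (its
    displacements start the iteration and its NP eigenstrain is retained).
    ``swelling_schedule`` maps the load level t to an NP swelling stretch
    (used by the swelling initialisation itself).
    """
    cfg = cfg or SolverConfig()
    if cfg.mode == "explicit-relaxation":
        return _explicit_relax(mesh, materials, load, cfg, prestate)

    assembly = Assembly(mesh, materials)
    coupling = apply_coupling(mesh)
    fixed = mesh.node_sets["caudal-fixed"]
    dir_idx = (3 * np.asarray(fixed)[:, None] + np.arange(3)).ravel()
    rsys = ReducedSystem(mesh.n_nodes, dir_idx, np.zeros(dir_idx.size), coupling)

    s_pre = prestate.swelling_scale if prestate is not None else 1.0
    if swelling_schedule is None:
        assembly.set_np_swelling(s_pre)

    q = np.zeros(rsys.nq)
    if prestate is not None:
        # project the prestate displacements onto the reduced coordinates
        q[:len(rsys.free)] = prestate.u.ravel()[rsys.free]
        q[rsys.ref_slice] = prestate.u[coupling.node_ids].mean(axis=0)

    history: List[dict] = []
    logmsgs: List[str] = []
    t = 0.0
    dt = 1.0 / cfg.increments

    def make_state(qv, tv, converged=True):
        u = rsys.expand(qv, tv, load.rotation_vector(tv))
        fint = assembly.internal_force(u.ravel())
        stress = assembly.element_mean_stress(u.ravel())
        reac = np.zeros_like(u)
        reac.reshape(-1)[dir_idx] = fint[dir_idx]
        s_now = assembly.swelling_scale[mesh.region == "NP"]
        return SolutionState(u=u, stress=stress, mode="implicit-newton",
                             converged=converged, ref_history=list(history),
                             swelling_scale=float(s_now[0]) if s_now.size else 1.0,
                             log=list(logmsgs), reactions=reac)

    # weights for the incremental kinematic predictor: spread the rigid
    # motion of the coupled set linearly through the disc height
    z = mesh.nodes[:, 2]
    wz = (z - z.min()) / max(z.max() - z.min(), 1e-12)
    lever_all = mesh.nodes - coupling.x_ref

    def predictor(qv, t_old, t_new):
        R_new = Rotation.from_rotvec(load.rotation_vector(t_new)).as_matrix()
        R_old = Rotation.from_rotvec(load.rotation_vector(t_old)).as_matrix()
        dg = lever_all @ (R_new - R_old).T
        du = (wz[:, None] * dg).ravel()
        out = qv.copy()
        out[:len(rsys.free)] += du[rsys.free]
        return out

    while t < 1.0 - 1e-12:
        step = min(dt, 1.0 - t)
        t_try = t + step
        if swelling_schedule is not None:
            assembly.set_np_swelling(swelling_schedule(t_try))
        rotvec = load.rotation_vector(t_try)
        fext_q = np.zeros(rsys.nq)
        fext_q[rsys.nq - 1] = -load.force * t_try  # dead load along -z
        try:
            q_pred = predictor(q, t, t_try)
            q_new, nit = _newton(assembly, rsys, q_pred, t_try, rotvec,
                                 fext_q, cfg)
        except (SolverFailure, con.KinematicsError) as exc:
            if step <= cfg.min_cut / cfg.increments + 1e-15:
                if swelling_schedule is not None:
                    assembly.set_np_swelling(swelling_schedule(t))
                raise SolverFailure(
                    f"increment cutting exhausted at t={t:.4f}: {exc}",
                    last_state=make_state(q, t, converged=False) if t > 0
                    else None) from exc
            dt = step / 2.0
            logmsgs.append(f"cut increment to {dt:.4g} at t={t:.4f}")
            continue
        q, t = q_new, t_try
        log.info("increment converged: t=%.4f (%d iterations)", t, nit)
        history.append({"t": t, "rotvec": rotvec,
                        "force": -load.force * t,
                        "u_ref": np.array(q[rsys.ref_slice]),
                        "iterations": nit})
        if swelling_schedule is None and dt < 1.0 / cfg.increments:
            dt = min(2 * dt, 1.0 / cfg.increments)  # recover after cuts

    state = make_state(q, 1.0)
    return state


def solve_prescribed(mesh: DiscMesh, materials, dirichlet_idx: np.ndarray,
                     dirichlet_vals: np.ndarray,
                     cfg: Optional[SolverConfig] = None) -> SolutionState:
    """Newton solve with prescribed displacement dofs and no coupling.

    Used for patch tests and homogeneous-deformation verification: Dirichlet
    values ramp linearly over the increments, every other dof is free and
    load-free.
    """
    cfg = cfg or SolverConfig()
    assembly = Assembly(mesh, materials)
    rsys = ReducedSystem(mesh.n_nodes, dirichlet_idx, dirichlet_vals, None)
    q = np.zeros(rsys.nq)
    fext_q = np.zeros(rsys.nq)
    for inc in range(1, cfg.increments + 1):
        t = inc / cfg.increments
        q, _ = _newton(assembly, rsys, q, t, None, fext_q, cfg)
    u = rsys.expand(q, 1.0, None)
    fint = assembly.internal_force(u.ravel())
    stress = assembly.element_mean_stress(u.ravel())
    reac = np.zeros_like(u)
    reac.reshape(-1)[dirichlet_idx] = fint[dirichlet_idx]
    return SolutionState(u=u, stress=stress, reactions=reac)


# ---------------------------------------------------------------------------
# explicit dynamic relaxation
# ---------------------------------------------------------------------------

def _smoothstep(x: np.ndarray | float):
    x = np.clip(x, 0.0, 1.0)
    return x * x * (3.0 - 2.0 * x)


def _explicit_relax(mesh: DiscMesh, materials, load: LoadCase,
                    cfg: SolverConfig, prestate: Optional[SolutionState]):
    assembly = Assembly(mesh, materials)
    coupling = apply_coupling(mesh)
    fixed = mesh.node_sets["caudal-fixed"]
    dir_idx = (3 * np.asarray(fixed)[:, None] + np.arange(3)).ravel()
    rsys = ReducedSystem(mesh.n_nodes, dir_idx, np.zeros(dir_idx.size), coupling)

    s_pre = prestate.swelling_scale if prestate is not None else 1.0
    assembly.set_np_swelling(s_pre)
    assembly.repair_mode = True  # ride through snap-through events

    q = np.zeros(rsys.nq)
    if prestate is not None:
        q[:len(rsys.free)] = prestate.u.ravel()[rsys.free]
        q[rsys.ref_slice] = prestate.u[coupling.node_ids].mean(axis=0)

    dt, N, c = cfg.dt, cfg.n_steps, cfg.damping

    def masses(qv, t):
        u = rsys.expand(qv, t, load.rotation_vector(_smoothstep(t)))
        K = assembly.tangent(u.ravel(), cfg.fd_step)
        row = np.abs(K).sum(axis=1).A1 if hasattr(np.abs(K).sum(axis=1), "A1") \
            else np.asarray(np.abs(K).sum(axis=1)).ravel()
        m_full = cfg.mass_safety * dt * dt * row / 4.0
        m_full = np.maximum(m_full, m_full[m_full > 0].min() * 1e-3)
        mq = rsys.T.T @ m_full
        return m_full, np.maximum(mq, mq[mq > 0].min() * 1e-3)

    m_full, m_q = masses(q, 0.0)
    v = np.zeros(rsys.nq)
    kinetic, internal, times = [], [], []
    g_prev = rsys.g(0.0, load.rotation_vector(0.0))
    update_every = max(1, N // max(1, cfg.mass_updates))
    recoveries = 0
    q_ckpt, v_ckpt = q.copy(), v.copy()

    n = 0
    while n < N:
        tau = (n + 1) / N
        r = _smoothstep(tau)
        rotvec = load.rotation_vector(r)
        try:
            u = rsys.expand(q, r, rotvec)
            fint = assembly.internal_force(u.ravel())
            ie = assembly.strain_energy(u.ravel())
            bad = not np.all(np.isfinite(fint)) or not np.isfinite(ie)
        except con.KinematicsError:
            bad = True
        if bad:
            # instability from local stiffening: rewind, quadruple the mass
            # scaling and restart the step from rest
            recoveries += 1
            if recoveries > 12:
                raise SolverFailure(
                    "explicit relaxation diverged despite mass rescaling")
            q, v = q_ckpt.copy(), np.zeros_like(v)
            m_full, m_q = 4.0 * m_full, 4.0 * m_q
            log.warning("explicit step %d rewound; mass scaling x4 (%d)",
                        n, recoveries)
            continue
        fext_q = np.zeros(rsys.nq)
        fext_q[rsys.nq - 1] = -load.force * r
        resid = fext_q - rsys.reduce(fint)
        v = (1.0 - c) * v + dt * resid / m_q
        q_ckpt, v_ckpt = q.copy(), v.copy()
        q = q + dt * v
        if (n + 1) % update_every == 0 and n + 1 < N:
            try:
                m_new_full, m_new_q = masses(q, r)
                m_full = np.maximum(m_full, m_new_full)
                m_q = np.maximum(m_q, m_new_q)
            except con.KinematicsError:
                pass  # transiently inadmissible; next force eval will rewind
        # energies: kinetic from full nodal velocities incl. prescribed motion
        g_now = rsys.g(r, rotvec)
        v_full = (rsys.T @ v) + (g_now - g_prev) / dt
        g_prev = g_now
        ke = 0.5 * float(v_full @ (m_full * v_full))
        kinetic.append(ke)
        internal.append(ie)
        times.append(tau)
        n += 1

    u = rsys.expand(q, 1.0, load.rotation_vector(1.0))
    fint = assembly.internal_force(u.ravel())
    stress = assembly.element_mean_stress(u.ravel())
    reac = np.zeros_like(u)
    reac.reshape(-1)[dir_idx] = fint[dir_idx]
    return SolutionState(
        u=u, stress=stress, mode="explicit-relaxation", converged=True,
        ref_history=[{"t": 1.0, "rotvec": load.rotation_vector(1.0),
                      "force": -load.force, "u_ref": q[rsys.ref_slice]}],
        energy_history={"time": np.array(times), "kinetic": np.array(kinetic),
                        "internal": np.array(internal)},
        swelling_scale=s_pre, reactions=reac)


def kinetic_energy_ratio(state: SolutionState, floor: float = 1e-12) -> float:
    """Maximum kinetic/total energy ratio over the run history, in percent.

    Quasi-static acceptance requires the returned value to stay below 10.
    """
    if state.energy_history is None:
        raise NotApplicableError("kinetic energy ratio requires an "
                                 "explicit-relaxation solution")
    ke = state.energy_history["kinetic"]
    te = ke + state.energy_history["internal"]
    mask = te > max(floor, 1e-9 * float(te.max(initial=0.0)))
    if not np.any(mask):
        return 0.0
    return float(np.max(ke[mask] / te[mask]) * 100.0)
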