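"""Constitutive models for the intervertebral disc tissues.

Three material behaviours are supported:

* **Anisotropic hyperelastic** (annulus fibrosus): a Holzapfel--Gasser--Ogden
  strain energy with two dispersed fibre families,

  .. math::

      \\Psi = C_{10}(\\bar I_1 - 3)
            + \\frac{1}{D}\\Big(\\frac{J^2-1}{2} - \\ln J\\Big)
            + \\frac{K_1}{2 K_2}\\sum_{\\alpha=1,2}
              \\big[\\exp(K_2 \\langle \\bar E_\\alpha\\rangle^2) - 1\\big],

  with :math:`\\bar E_\\alpha = \\kappa(\\bar I_1 - 3)
  + (1-3\\kappa)(\\bar I_{4\\alpha} - 1)` and the Macaulay bracket switching
  the fibre contribution off when the dispersed fibre strain is compressive.

* **Neo-Hookean** (nucleus pulposus): the same volumetric term plus
  :math:`C_{10}(\\bar I_1-3)`.

* **Linear elastic** (cartilaginous and bony endplates): implemented as a
  compressible Neo-Hookean solid with the Lame constants of the tabulated
  (E, nu), :math:`\\Psi = \\frac{\\mu}{2}(I_1-3) - \\mu\\ln J
  + \\frac{\\lambda}{2}(\\ln J)^2`. This is objective under finite rotations,
  reduces exactly to Hooke's law in the small-strain limit, and -- unlike a
  Saint Venant--Kirchhoff solid -- remains elliptic under the severe
  through-thickness compression the thin endplate layers see, so the thin
  layers cannot collapse materially.

Units: stresses and energy densities in MPa, lengths in mm.

All stress evaluations are exposed twice: a convenience single-state API
(`strain_energy`, `cauchy_stress`, `material_tangent`) operating on a
:class:`DeformationState`, and vectorised batch kernels (``*_batch``) over
stacked deformation gradients, which the element assembly uses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np

__all__ = [
    "AnisoHyperParams",
    "NeoHookeanParams",
    "LinearElasticParams",
    "DeformationState",
    "KinematicsError",
    "ConfigurationError",
    "strain_energy",
    "cauchy_stress",
    "material_tangent",
    "pk2_batch",
    "cauchy_batch",
    "energy_batch",
    "OVINE_MATERIALS",
]


class KinematicsError(ValueError):
    """Raised for inadmissible kinematics (non-positive Jacobian)."""


class ConfigurationError(ValueError):
    """Raised for invalid material / model configuration."""


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AnisoHyperParams:
    """HGO parameters: matrix stiffness C10 (MPa), volumetric compliance D
    (1/MPa), fibre stiffness K1 (MPa), fibre exponent K2 (-), dispersion
    kappa in [0, 1/3]."""

    c10: float
    d: float
    k1: float
    k2: float
    kappa: float

    def __post_init__(self) -> None:
        if self.c10 <= 0:
            raise ConfigurationError("c10 must be positive")
        if self.d <= 0:
            raise ConfigurationError("d must be positive")
        if self.k1 < 0:
            raise ConfigurationError("k1 must be non-negative")
        if self.k2 <= 0:
            raise ConfigurationError("k2 must be positive")
        if not 0.0 <= self.kappa <= 1.0 / 3.0:
            raise ConfigurationError("kappa must lie in [0, 1/3]")


@dataclass(frozen=True)
class NeoHookeanParams:
    """Nearly incompressible Neo-Hookean: C10 (MPa), D (1/MPa)."""

    c10: float
    d: float

    def __post_init__(self) -> None:
        if self.c10 <= 0:
            raise ConfigurationError("c10 must be positive")
        if self.d <= 0:
            raise ConfigurationError("d must be positive")


@dataclass(frozen=True)
class LinearElasticParams:
    """Hookean solid: Young's modulus E (MPa) and Poisson ratio nu."""

    e: float
    nu: float

    def __post_init__(self) -> None:
        if self.e <= 0:
            raise ConfigurationError("e must be positive")
        if not -1.0 < self.nu < 0.5:
            raise ConfigurationError("nu must lie in (-1, 0.5)")

    @property
    def lam(self) -> float:
        return self.e * self.nu / ((1 + self.nu) * (1 - 2 * self.nu))

    @property
    def mu(self) -> float:
        return self.e / (2 * (1 + self.nu))


MaterialParams = Union[AnisoHyperParams, NeoHookeanParams, LinearElasticParams]


@dataclass
class DeformationState:
    """A deformation gradient plus (for fibre-reinforced materials) the two
    unit reference fibre directions."""

    f: np.ndarray
    fiber_dirs: Optional[np.ndarray] = field(default=None)

    def __post_init__(self) -> None:
        self.f = np.asarray(self.f, dtype=float)
        if self.f.shape != (3, 3):
            raise KinematicsError("deformation gradient must be 3x3")
        if np.linalg.det(self.f) <= 0:
            raise KinematicsError("det(F) must be positive")
        if self.fiber_dirs is not None:
            a = np.asarray(self.fiber_dirs, dtype=float)
            if a.shape != (2, 3):
                raise ConfigurationError("fiber_dirs must be shaped (2, 3)")
            norms = np.linalg.norm(a, axis=1)
            if not np.allclose(norms, 1.0, atol=1e-8):
                raise ConfigurationError("fiber directions must be unit vectors")
            self.fiber_dirs = a


# ---------------------------------------------------------------------------
# batch kernels (n, 3, 3) -> stresses / energies
# ---------------------------------------------------------------------------

_EYE = np.eye(3)


def _dets(F: np.ndarray) -> np.ndarray:
    J = np.linalg.det(F)
    if np.any(J <= 0):
        raise KinematicsError("det(F) must be positive for all states")
    return J


def _vol_energy(J: np.ndarray, d: float) -> np.ndarray:
    return (1.0 / d) * ((J * J - 1.0) / 2.0 - np.log(J))


def _vol_dU(J: np.ndarray, d: float) -> np.ndarray:
    return (1.0 / d) * (J - 1.0 / J)


def energy_batch(F: np.ndarray, params: MaterialParams,
                 fibers: Optional[np.ndarray] = None) -> np.ndarray:
    """Strain-energy density (MPa) for a stack of deformation gradients."""
    F = np.asarray(F, dtype=float)
    J = _dets(F)
    if isinstance(params, LinearElasticParams):
        # compressible Neo-Hookean with Lame constants of (E, nu)
        C = np.einsum("nki,nkj->nij", F, F)
        I1 = np.trace(C, axis1=1, axis2=2)
        lnJ = np.log(J)
        return (0.5 * params.mu * (I1 - 3.0) - params.mu * lnJ
                + 0.5 * params.lam * lnJ ** 2)

    C = np.einsum("nki,nkj->nij", F, F)
    I1 = np.trace(C, axis1=1, axis2=2)
    I1b = J ** (-2.0 / 3.0) * I1
    psi = params.c10 * (I1b - 3.0) + _vol_energy(J, params.d)
    if isinstance(params, AnisoHyperParams):
        if fibers is None:
            raise ConfigurationError(
                "anisotropic material requires fiber directions")
        if params.k1 > 0:
            I4 = np.einsum("nai,nij,naj->na", fibers, C, fibers)
            I4b = J[:, None] ** (-2.0 / 3.0) * I4
            Ebar = params.kappa * (I1b[:, None] - 3.0) + \
                (1.0 - 3.0 * params.kappa) * (I4b - 1.0)
            Ep = np.maximum(Ebar, 0.0)
            # exponent capped far outside the physical range to keep trial
            # states of the solvers finite
            arg = np.minimum(params.k2 * Ep ** 2, 400.0)
            psi = psi + (params.k1 / (2.0 * params.k2)) * np.sum(
                np.expm1(arg), axis=1)
    return psi


def pk2_batch(F: np.ndarray, params: MaterialParams,
              fibers: Optional[np.ndarray] = None) -> np.ndarray:
    """Second Piola-Kirchhoff stress for a stack of deformation gradients."""
    F = np.asarray(F, dtype=float)
    J = _dets(F)
    C = np.einsum("nki,nkj->nij", F, F)

    if isinstance(params, LinearElasticParams):
        Cinv = np.linalg.inv(C)
        lnJ = np.log(J)
        return (params.mu * (_EYE - Cinv)
                + (params.lam * lnJ)[:, None, None] * Cinv)

    Cinv = np.linalg.inv(C)
    I1 = np.trace(C, axis1=1, axis2=2)
    Jm23 = J ** (-2.0 / 3.0)
    I1b = Jm23 * I1

    # d(I1bar)/dC = J^{-2/3} (I - I1/3 Cinv)
    dI1b = Jm23[:, None, None] * (_EYE - (I1 / 3.0)[:, None, None] * Cinv)
    psi1 = np.full(F.shape[0], params.c10)
    S = 2.0 * psi1[:, None, None] * dI1b
    # volumetric: S_vol = J U'(J) Cinv
    S = S + (J * _vol_dU(J, params.d))[:, None, None] * Cinv

    if isinstance(params, AnisoHyperParams) and params.k1 > 0:
        if fibers is None:
            raise ConfigurationError(
                "anisotropic material requires fiber directions")
        I4 = np.einsum("nai,nij,naj->na", fibers, C, fibers)
        I4b = Jm23[:, None] * I4
        Ebar = params.kappa * (I1b[:, None] - 3.0) + \
            (1.0 - 3.0 * params.kappa) * (I4b - 1.0)
        active = Ebar > 0.0
        arg = np.minimum(params.k2 * Ebar ** 2, 400.0)  # overflow guard
        psi_f = np.where(active, params.k1 * np.exp(arg) * Ebar, 0.0)
        AA = np.einsum("nai,naj->naij", fibers, fibers)
        dI4b = Jm23[:, None, None, None] * (
            AA - (I4 / 3.0)[:, :, None, None] * Cinv[:, None, :, :])
        # chain rule through Ebar for each family
        S = S + 2.0 * np.einsum(
            "na,naij->nij", psi_f * params.kappa, np.broadcast_to(
                dI1b[:, None, :, :], AA.shape))
        S = S + 2.0 * (1.0 - 3.0 * params.kappa) * np.einsum(
            "na,naij->nij", psi_f, dI4b)
    return S


def cauchy_batch(F: np.ndarray, params: MaterialParams,
                 fibers: Optional[np.ndarray] = None) -> np.ndarray:
    """Cauchy (true) stress for a stack of deformation gradients."""
    F = np.asarray(F, dtype=float)
    J = _dets(F)
    S = pk2_batch(F, params, fibers)
    sig = np.einsum("nik,nkl,njl->nij", F, S, F, optimize=True) / J[:, None, None]
    return 0.5 * (sig + np.transpose(sig, (0, 2, 1)))


# ---------------------------------------------------------------------------
# single-state API
# ---------------------------------------------------------------------------

def _require_fibers(state: DeformationState, params: MaterialParams):
    if isinstance(params, AnisoHyperParams) and state.fiber_dirs is None:
        raise ConfigurationError(
            "anisotropic material requires two fiber directions")
    if state.fiber_dirs is None:
        return None
    return state.fiber_dirs[None, :, :]


def strain_energy(state: DeformationState, params: MaterialParams) -> float:
    """Strain-energy density Psi (MPa) at a single deformation state."""
    fib = _require_fibers(state, params)
    return float(energy_batch(state.f[None], params, fib)[0])


def cauchy_stress(state: DeformationState, params: MaterialParams) -> np.ndarray:
    """Symmetric Cauchy stress tensor (MPa) at a single deformation state."""
    fib = _require_fibers(state, params)
    return cauchy_batch(state.f[None], params, fib)[0]


def material_tangent(state: DeformationState, params: MaterialParams,
                     h: float = 1e-6) -> np.ndarray:
    """Fourth-order material tangent dS/dE (MPa) at a deformation state.

    Computed by central finite differences of the analytic second
    Piola-Kirchhoff stress with respect to the Green-Lagrange strain, then
    symmetrised; it therefore carries both minor symmetries and, for these
    hyperelastic models, the major symmetry. For the Saint Venant-Kirchhoff
    solid at the identity it equals the Hooke operator exactly.
    """
    fib = _require_fibers(state, params)
    F = state.f
    C0 = F.T @ F
    CC = np.zeros((3, 3, 3, 3))

    def S_of_C(C: np.ndarray) -> np.ndarray:
        # evaluate S through a synthetic F = C^{1/2} (S depends on C only)
        w, V = np.linalg.eigh(C)
        if np.any(w <= 0):
            raise KinematicsError("perturbed C not positive definite")
        Fs = V @ np.diag(np.sqrt(w)) @ V.T
        return pk2_batch(Fs[None], params, fib)[0]

    for k in range(3):
        for l in range(k, 3):
            dC = np.zeros((3, 3))
            dC[k, l] += 1.0
            dC[l, k] += 1.0  # dC = h(e_kl + e_lk)  =>  dE = (h/2)(e_kl + e_lk)
            Sp = S_of_C(C0 + h * dC)
            Sm = S_of_C(C0 - h * dC)
            # (Sp-Sm)/(2h) = C : (e_kl+e_lk)/2 = C_ijkl by minor symmetry
            dS = (Sp - Sm) / (2.0 * h)
            CC[:, :, k, l] = dS
            CC[:, :, l, k] = dS
    # enforce minor + major symmetry exactly
    CC = 0.5 * (CC + np.transpose(CC, (1, 0, 2, 3)))
    CC = 0.5 * (CC + np.transpose(CC, (0, 1, 3, 2)))
    CC = 0.5 * (CC + np.transpose(CC, (2, 3, 0, 1)))
    return CC


# ---------------------------------------------------------------------------
# default material table (region name -> parameters)
# ---------------------------------------------------------------------------

#: Default disc materials: anisotropic hyperelastic annulus regions,
#: Neo-Hookean nucleus, linear-elastic cartilaginous and bony endplates.
OVINE_MATERIALS: dict[str, MaterialParams] = {
    "AF-anterior": AnisoHyperParams(c10=0.06046, d=0.311, k1=24.0, k2=1700.0, kappa=0.01),
    "AF-lateral": AnisoHyperParams(c10=0.0327, d=0.6154, k1=5.0, k2=940.0, kappa=0.01),
    "AF-posterior": AnisoHyperParams(c10=0.0772, d=0.2609, k1=1.0, k2=50.0, kappa=0.01),
    "NP": NeoHookeanParams(c10=0.16779, d=0.12),
    "CEP-cranial": LinearElasticParams(e=24.0, nu=0.4),
    "CEP-caudal": LinearElasticParams(e=24.0, nu=0.4),
    "BEP-cranial": LinearElasticParams(e=1000.0, nu=0.3),
    "BEP-caudal": LinearElasticParams(e=1000.0, nu=0.3),
}


def materials_to_dict(materials: dict[str, MaterialParams]) -> dict:
    """Serialise a material table to plain dicts (for YAML/JSON round-trips)."""
    out = {}
    for name, p in materials.items():
        if isinstance(p, AnisoHyperParams):
            out[name] = {"behavior": "anisotropic_hyperelastic",
                         "c10": p.c10, "d": p.d, "k1": p.k1, "k2": p.k2,
                         "kappa": p.kappa}
        elif isinstance(p, NeoHookeanParams):
            out[name] = {"behavior": "neo_hookean", "c10": p.c10, "d": p.d}
        else:
            out[name] = {"behavior": "linear_elastic", "e": p.e, "nu": p.nu}
    return out


def materials_from_dict(data: dict) -> dict[str, MaterialParams]:
    """Inverse of :func:`materials_to_dict`."""
    out: dict[str, MaterialParams] = {}
    for name, d in data.items():
        kind = d["behavior"]
        if kind == "anisotropic_hyperelastic":
            out[name] = AnisoHyperParams(d["c10"], d["d"], d["k1"], d["k2"],
                                         d["kappa"])
        elif kind == "neo_hookean":
            out[name] = NeoHookeanParams(d["c10"], d["d"])
        elif kind == "linear_elastic":
            out[name] = LinearElasticParams(d["e"], d["nu"])
        else:
            raise ConfigurationError(f"unknown behavior {kind!r}")
    return out
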