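"""Constitutive-level checks: energies, stresses, tangents, invariances."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from discfem import constitutive as con

MATS = con.OVINE_MATERIALS


def _random_admissible_F(rng, scale=0.08):
    F = np.eye(3) + scale * rng.standard_normal((3, 3))
    while np.linalg.det(F) < 0.3:
        F = np.eye(3) + scale * rng.standard_normal((3, 3))
    return F


def _fibers():
    a = np.radians(30.0)
    return np.array([[np.cos(a), 0, np.sin(a)], [np.cos(a), 0, -np.sin(a)]])


def _state(F, params):
    fib = _fibers() if isinstance(params, con.AnisoHyperParams) else None
    return con.DeformationState(F, fib)


def _hgo_energy_oracle(F, p, fibers):
    """One-line-per-term independent evaluation of the documented energy."""
    J = np.linalg.det(F)
    C = F.T @ F
    I1b = J ** (-2 / 3) * np.trace(C)
    psi = p.c10 * (I1b - 3) + (1 / p.d) * ((J ** 2 - 1) / 2 - np.log(J))
    for a in fibers:
        I4b = J ** (-2 / 3) * (a @ C @ a)
        E = p.kappa * (I1b - 3) + (1 - 3 * p.kappa) * (I4b - 1)
        if E > 0:
            psi += (p.k1 / (2 * p.k2)) * (np.exp(p.k2 * E ** 2) - 1)
    return psi


@pytest.mark.parametrize("region", list(MATS))
def test_energy_zero_at_identity_and_rotation(region):
    """Rigid motions store no energy and produce no stress."""
    p = MATS[region]
    st = _state(np.eye(3), p)
    assert con.strain_energy(st, p) == pytest.approx(0.0, abs=1e-14)
    assert np.allclose(con.cauchy_stress(st, p), 0.0, atol=1e-12)
    R = Rotation.from_rotvec([0.3, -0.2, 0.5]).as_matrix()
    stR = _state(R, p)
    assert con.strain_energy(stR, p) == pytest.approx(0.0, abs=1e-12)
    assert np.allclose(con.cauchy_stress(stR, p), 0.0, atol=1e-10)


def test_hgo_energy_matches_scalar_oracle():
    """Uniaxial stretch along a fiber: energy equals the independent
    one-line evaluation of the documented expression."""
    p = MATS["AF-anterior"]
    fibers = _fibers()
    a = fibers[0]
    lam = 1.05
    F = np.eye(3) + (lam - 1) * np.outer(a, a)
    st = con.DeformationState(F, fibers)
    expected = _hgo_energy_oracle(F, p, fibers)
    assert expected > 0
    assert con.strain_energy(st, p) == pytest.approx(expected, rel=1e-12)


def test_np_small_shear_stress():
    """Simple shear of the nucleus at small strain: sigma_12 ~= 2 C10 gamma."""
    p = MATS["NP"]
    g = 1e-4
    F = np.eye(3)
    F[0, 1] = g
    sig = con.cauchy_stress(con.DeformationState(F), p)
    assert sig[0, 1] == pytest.approx(2 * p.c10 * g, rel=0.01)


@pytest.mark.parametrize("region", list(MATS))
def test_energy_stress_consistency(region):
    """Cauchy stress equals the energy derivative: PK2 from central finite
    differences of the strain energy w.r.t. Green-Lagrange strain matches the
    implementation over randomized admissible deformations."""
    p = MATS[region]
    fib = _fibers() if isinstance(p, con.AnisoHyperParams) else None
    rng = np.random.default_rng(hash(region) % 2 ** 31)
    h = 1e-6
    for _ in range(3):
        F = _random_admissible_F(rng)
        C0 = F.T @ F

        def psi_of_C(C):
            w, V = np.linalg.eigh(C)
            Fs = V @ np.diag(np.sqrt(w)) @ V.T
            return con.energy_batch(
                Fs[None], p, fib[None] if fib is not None else None)[0]

        S_fd = np.zeros((3, 3))
        for k in range(3):
            for l in range(3):
                dC = np.zeros((3, 3))
                dC[k, l] += 1.0
                dC[l, k] += 1.0
                S_fd[k, l] = (psi_of_C(C0 + h * dC)
                              - psi_of_C(C0 - h * dC)) / (2 * h)
        S = con.pk2_batch(F[None], p, fib[None] if fib is not None else None)[0]
        J = np.linalg.det(F)
        sig_fd = F @ S_fd @ F.T / J
        sig = con.cauchy_stress(con.DeformationState(F, fib), p)
        assert np.allclose(sig, sig_fd, rtol=1e-4,
                           atol=1e-6 * max(np.abs(sig_fd).max(), 1.0))


@pytest.mark.parametrize("region", ["AF-lateral", "NP", "BEP-cranial"])
def test_objectivity(region):
    """cauchy(R F) = R cauchy(F) R^T for random rotations."""
    p = MATS[region]
    fib = _fibers() if isinstance(p, con.AnisoHyperParams) else None
    rng = np.random.default_rng(7)
    for k in range(5):
        F = _random_admissible_F(rng)
        R = Rotation.random(random_state=100 + k).as_matrix()
        s0 = con.cauchy_stress(con.DeformationState(F, fib), p)
        s1 = con.cauchy_stress(con.DeformationState(R @ F, fib), p)
        assert np.allclose(s1, R @ s0 @ R.T, atol=1e-10 + 1e-8 * np.abs(s0).max())


def test_fibers_inactive_in_compression():
    """Compressing along both fiber directions with kappa small produces no
    fiber energy: the total equals the matrix + volumetric part alone."""
    p = MATS["AF-posterior"]
    fibers = _fibers()
    # contract along x (the common fiber component) -> both I4 < 1
    F = np.diag([0.93, 1.05, 1.0])
    st = con.DeformationState(F, fibers)
    C = F.T @ F
    for a in fibers:
        assert a @ C @ a < 1.0
    matrix_only = con.AnisoHyperParams(p.c10, p.d, k1=1e-12, k2=p.k2,
                                       kappa=p.kappa)
    psi_full = con.strain_energy(st, p)
    psi_matrix = con.strain_energy(con.DeformationState(F, fibers), matrix_only)
    assert psi_full == pytest.approx(psi_matrix, rel=1e-9, abs=1e-12)


@pytest.mark.parametrize("region", ["AF-anterior", "AF-lateral", "AF-posterior"])
def test_energy_monotone_in_uniaxial_stretch(region):
    """Energy grows monotonically under increasing uniaxial stretch > 1."""
    p = MATS[region]
    fibers = _fibers()
    lams = np.linspace(1.01, 1.15, 8)
    psis = []
    for lam in lams:
        F = np.diag([lam, 1.0, 1.0])
        psis.append(con.strain_energy(con.DeformationState(F, fibers), p))
    assert np.all(np.diff(psis) > 0)


def test_material_tangent_hooke_at_identity():
    """CEP linear-elastic tangent at the identity equals the Hooke operator
    with the closed-form Lame constants."""
    p = MATS["CEP-cranial"]
    lam = p.e * p.nu / ((1 + p.nu) * (1 - 2 * p.nu))
    mu = p.e / (2 * (1 + p.nu))
    I3 = np.eye(3)
    hooke = (lam * np.einsum("ij,kl->ijkl", I3, I3)
             + mu * (np.einsum("ik,jl->ijkl", I3, I3)
                     + np.einsum("il,jk->ijkl", I3, I3)))
    CC = con.material_tangent(con.DeformationState(np.eye(3)), p)
    assert np.allclose(CC, hooke, rtol=1e-6, atol=1e-6)


@pytest.mark.parametrize("region", ["AF-lateral", "NP", "CEP-caudal"])
def test_material_tangent_symmetries_and_energy_consistency(region):
    """Tangent has minor and major symmetries and matches the second finite
    difference of the strain energy."""
    p = MATS[region]
    fib = _fibers() if isinstance(p, con.AnisoHyperParams) else None
    rng = np.random.default_rng(11)
    F = _random_admissible_F(rng, scale=0.04)
    CC = con.material_tangent(con.DeformationState(F, fib), p)
    assert np.allclose(CC, np.transpose(CC, (1, 0, 2, 3)), atol=1e-8)
    assert np.allclose(CC, np.transpose(CC, (0, 1, 3, 2)), atol=1e-8)
    assert np.allclose(CC, np.transpose(CC, (2, 3, 0, 1)),
                       atol=1e-5 * max(1.0, np.abs(CC).max()))
    # independent second-difference oracle on one component pair
    C0 = F.T @ F

    def psi_of_C(C):
        w, V = np.linalg.eigh(C)
        Fs = V @ np.diag(np.sqrt(w)) @ V.T
        return con.energy_batch(Fs[None], p,
                                fib[None] if fib is not None else None)[0]

    h = 1e-4
    dC1 = np.zeros((3, 3)); dC1[0, 0] = 2.0       # dE_00 = h
    dC2 = np.zeros((3, 3)); dC2[0, 1] = dC2[1, 0] = 1.0  # dE_01 = dE_10 = h/...
    # d2psi/dE00 dE01 via mixed central differences (E perturbations of h)
    def psi_eps(e1, e2):
        return psi_of_C(C0 + e1 * dC1 + e2 * dC2)
    mixed = (psi_eps(h, h) - psi_eps(h, -h) - psi_eps(-h, h)
             + psi_eps(-h, -h)) / (4 * h * h)
    # dE00 = e1 and dE01 = dE10 = e2/2, so the mixed derivative equals
    # (C_0001 + C_0010)/2 = C_0001 by minor symmetry
    assert mixed == pytest.approx(CC[0, 0, 0, 1], rel=2e-3, abs=2e-4)


def test_parameter_validation():
    with pytest.raises(con.ConfigurationError):
        con.AnisoHyperParams(c10=0.1, d=0.3, k1=1.0, k2=50.0, kappa=0.5)
    with pytest.raises(con.ConfigurationError):
        con.NeoHookeanParams(c10=-0.1, d=0.3)
    with pytest.raises(con.ConfigurationError):
        con.LinearElasticParams(e=10.0, nu=0.6)
    with pytest.raises(con.KinematicsError):
        con.DeformationState(np.diag([1.0, 1.0, -1.0]))
    p = MATS["AF-anterior"]
    with pytest.raises(con.ConfigurationError):
        con.strain_energy(con.DeformationState(np.eye(3)), p)
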