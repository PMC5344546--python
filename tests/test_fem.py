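"""Solver verification: homogeneous states, patch test, coupling,
equilibrium, and implicit/explicit agreement on small fixtures."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from discfem import constitutive as con
from discfem import fem
from discfem import geometry as geo

MATS = con.OVINE_MATERIALS


def _affine_dirichlet(mesh, Fa, nodes=None):
    nodes = np.arange(mesh.n_nodes) if nodes is None else nodes
    disp = mesh.nodes[nodes] @ (Fa - np.eye(3)).T
    idx = (3 * nodes[:, None] + np.arange(3)).ravel()
    return idx, disp.ravel()


def test_single_element_matches_constitutive_oracle(single_element, materials):
    """A homogeneous deformation of one element reproduces the pointwise
    constitutive stress to near machine precision."""
    Fa = np.array([[0.97, 0.01, 0.0], [0.0, 0.99, 0.02], [0.0, 0.0, 1.04]])
    idx, vals = _affine_dirichlet(single_element, Fa)
    st = fem.solve_prescribed(single_element, materials, idx, vals)
    sig_oracle = con.cauchy_batch(Fa[None], materials["NP"], None)[0]
    assert np.abs(st.stress[0] - sig_oracle).max() < 1e-8 * np.abs(
        sig_oracle).max()


def test_patch_test_uniform_stress(materials):
    """Affine boundary displacements on a distorted block produce an exactly
    uniform stress field (patch test)."""
    m = geo.box_mesh(3, 3, 3, 3.0, 2.0, 1.0, "CEP-cranial")
    rng = np.random.default_rng(3)
    interior = np.ones(m.n_nodes, bool)
    for i, L in enumerate([3.0, 2.0, 1.0]):
        interior &= (m.nodes[:, i] > 1e-9) & (m.nodes[:, i] < L - 1e-9)
    m.nodes[interior] += 0.08 * rng.standard_normal((int(interior.sum()), 3))
    bnodes = np.flatnonzero(~interior)
    Fa = np.eye(3) + 1e-3 * np.array([[2.0, 1.0, 0.0], [1.0, -1.0, 0.5],
                                      [0.0, 0.5, 3.0]])
    idx, vals = _affine_dirichlet(m, Fa, bnodes)
    st = fem.solve_prescribed(m, materials, idx, vals)
    sig_oracle = con.cauchy_batch(Fa[None], materials["CEP-cranial"], None)[0]
    assert np.abs(st.stress - sig_oracle).max() < 1e-8


def test_zero_load_zero_state(mini_disc, materials):
    lc = fem.LoadCase(axial_force=0.0, axial_rotation=0.0,
                      lateral_bending=0.0, flexion=0.0,
                      rotation_on=False, bending_on=False, flexion_on=False,
                      name="null")
    st = fem.solve_quasi_static(mini_disc, materials, lc,
                                fem.SolverConfig(increments=1))
    assert np.abs(st.u).max() == pytest.approx(0.0, abs=1e-12)
    assert np.abs(st.stress).max() == pytest.approx(0.0, abs=1e-10)


def test_coupling_rigidity_and_translation(mini_disc):
    """Coupled nodes move rigidly: pairwise distances preserved under pure
    rotation; pure translation moves all nodes identically."""
    cp = fem.apply_coupling(mini_disc)
    rot = np.array([0.0, 0.0, np.radians(4.0)])
    X = mini_disc.nodes[cp.node_ids]
    x_new = X + cp.targets(rot, np.zeros(3))
    d_ref = np.linalg.norm(X[:1] - X, axis=1)
    d_new = np.linalg.norm(x_new[:1] - x_new, axis=1)
    assert np.abs(d_new - d_ref).max() < 1e-9
    tr = cp.targets(np.zeros(3), np.array([0.1, -0.2, 0.3]))
    assert np.allclose(tr, [0.1, -0.2, 0.3])


def test_combined_rotation_order_free():
    """Flexion + bending composed as one rotation vector is order-free and
    lies within the commutator bound of either sequential application."""
    a = np.array([np.radians(13.0), 0.0, 0.0])
    b = np.array([0.0, np.radians(10.0), 0.0])
    R_single = Rotation.from_rotvec(a + b).as_matrix()
    R_ab = (Rotation.from_rotvec(a) * Rotation.from_rotvec(b)).as_matrix()
    R_ba = (Rotation.from_rotvec(b) * Rotation.from_rotvec(a)).as_matrix()
    # commutator bound on the angle between the compositions
    bound = np.linalg.norm(a) * np.linalg.norm(b)
    for R_seq in (R_ab, R_ba):
        ang = Rotation.from_matrix(R_single.T @ R_seq).magnitude()
        assert ang < bound
    ang_seq = Rotation.from_matrix(R_ab.T @ R_ba).magnitude()
    assert ang_seq < 2 * bound


def test_empty_coupling_set_rejected(mini_disc):
    bad = geo.DiscMesh(nodes=mini_disc.nodes, hexes=mini_disc.hexes,
                       region=mini_disc.region,
                       node_sets={"cranial-coupled": np.array([], dtype=int)})
    with pytest.raises(fem.FEError):
        fem.apply_coupling(bad)


def test_global_equilibrium_reactions(mini_disc, materials, mini_prestate):
    """Caudal reactions balance the applied axial force to fine relative
    tolerance at the converged state."""
    lc = fem.LoadCase(axial_rotation=0.0, lateral_bending=0.0, flexion=0.0,
                      rotation_on=False, bending_on=False, flexion_on=False,
                      name="AC")
    st = fem.solve_quasi_static(mini_disc, materials, lc,
                                fem.SolverConfig(increments=5),
                                prestate=mini_prestate)
    Rz = st.reactions[:, 2].sum()
    assert Rz == pytest.approx(800.0, rel=1e-6)
    # lateral force balance: no applied lateral load
    assert abs(st.reactions[:, 0].sum()) < 1e-4 * 800
    assert abs(st.reactions[:, 1].sum()) < 1e-4 * 800


def test_implicit_explicit_agreement_single_element(single_element, materials):
    """The two solution modes agree on a single-element compression."""
    lc = fem.LoadCase(axial_force=0.05, axial_rotation=0.0,
                      lateral_bending=0.0, flexion=0.0, rotation_on=False,
                      bending_on=False, flexion_on=False, name="tiny-AC")
    imp = fem.solve_quasi_static(single_element, materials, lc,
                                 fem.SolverConfig(increments=4))
    exp = fem.solve_quasi_static(
        single_element, materials, lc,
        fem.SolverConfig(mode="explicit-relaxation", n_steps=2500,
                         damping=0.08))
    szz_i = imp.stress[0, 2, 2]
    szz_e = exp.stress[0, 2, 2]
    assert szz_i < 0  # compression
    assert szz_e == pytest.approx(szz_i, rel=0.02)


def test_implicit_explicit_agreement_bar(tension_bar, materials):
    """Implicit and explicit solutions of a compressed bar agree within 2%
    in the axial stress."""
    lc = fem.LoadCase(axial_force=0.02, axial_rotation=0.0,
                      lateral_bending=0.0, flexion=0.0, rotation_on=False,
                      bending_on=False, flexion_on=False, name="bar-AC")
    imp = fem.solve_quasi_static(tension_bar, materials, lc,
                                 fem.SolverConfig(increments=4))
    exp = fem.solve_quasi_static(
        tension_bar, materials, lc,
        fem.SolverConfig(mode="explicit-relaxation", n_steps=8000,
                         damping=0.08))
    mid = 5
    assert exp.stress[mid, 2, 2] == pytest.approx(imp.stress[mid, 2, 2],
                                                  rel=0.02)


def test_kinetic_energy_ratio_properties(tension_bar, materials):
    """Zero kinetic history gives ratio 0; implicit states are rejected;
    slowing the ramp never increases the ratio."""
    st = fem.SolutionState(u=np.zeros((2, 3)), stress=np.zeros((1, 3, 3)),
                           mode="explicit-relaxation",
                           energy_history={"time": np.array([0.5, 1.0]),
                                           "kinetic": np.zeros(2),
                                           "internal": np.array([1.0, 2.0])})
    assert fem.kinetic_energy_ratio(st) == 0.0
    with pytest.raises(fem.NotApplicableError):
        fem.kinetic_energy_ratio(
            fem.SolutionState(u=np.zeros((2, 3)), stress=np.zeros((1, 3, 3))))
    lc = fem.LoadCase(axial_force=0.02, axial_rotation=0.0,
                      lateral_bending=0.0, flexion=0.0, rotation_on=False,
                      bending_on=False, flexion_on=False, name="bar-AC")
    fast = fem.solve_quasi_static(
        tension_bar, materials, lc,
        fem.SolverConfig(mode="explicit-relaxation", n_steps=1200))
    slow = fem.solve_quasi_static(
        tension_bar, materials, lc,
        fem.SolverConfig(mode="explicit-relaxation", n_steps=2400))
    assert fem.kinetic_energy_ratio(slow) <= fem.kinetic_energy_ratio(fast) \
        + 1e-9


def test_element_inversion_detected(single_element, materials):
    """Prescribing a displacement field that flattens the element past
    inversion raises a kinematics/solver failure."""
    Fa = np.diag([1.0, 1.0, -0.2])
    idx, vals = _affine_dirichlet(single_element, Fa)
    with pytest.raises((fem.SolverFailure, con.KinematicsError)):
        fem.solve_prescribed(single_element, materials, idx, vals,
                             fem.SolverConfig(increments=1, min_cut=1.0))


def test_vtu_export_roundtrip(tmp_path, mini_disc):
    """The VTU export is well-formed XML carrying the mesh and cell data."""
    import xml.etree.ElementTree as ET
    from discfem.vtkio import write_vtu
    path = tmp_path / "mesh.vtu"
    write_vtu(path, mini_disc,
              cell_data={"volume": mini_disc.volumes()})
    root = ET.parse(path).getroot()
    piece = root.find(".//Piece")
    assert int(piece.get("NumberOfPoints")) == mini_disc.n_nodes
    assert int(piece.get("NumberOfCells")) == mini_disc.n_elements
    conn = piece.find("Cells/DataArray[@Name='connectivity']")
    vals = np.fromstring(conn.text, sep=" ", dtype=int)
    assert np.array_equal(vals, mini_disc.hexes.ravel())
    names = {d.get("Name") for d in piece.findall("CellData/DataArray")}
    assert {"volume", "region_id", "fiber_1"} <= names


def test_fe_deck_export(tmp_path, single_element):
    """The text input deck lists every node, element and set with 1-based
    numbering."""
    from discfem.vtkio import write_fe_deck
    path = tmp_path / "mesh.inp"
    write_fe_deck(path, single_element)
    text = path.read_text()
    assert text.count("*NSET") == len(single_element.node_sets)
    assert "*ELEMENT, TYPE=C3D8" in text
    line = text.splitlines()[1]
    assert line.startswith("1, ")
    conn_line = text.splitlines()[text.splitlines().index(
        "*ELEMENT, TYPE=C3D8") + 1]
    assert conn_line.split(", ")[0] == "1"
    assert set(map(int, conn_line.split(", ")[1:])) == set(range(1, 9))
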