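"""Section mapping and regional tensile-stress averaging."""

import numpy as np
import pytest

from discfem import fem
from discfem import geometry as geo
from discfem import sectioning as sec


def _uniform_state(mesh, sigma):
    ne = mesh.n_elements
    stress = np.tile(np.asarray(sigma, dtype=float), (ne, 1, 1))
    return fem.SolutionState(u=np.zeros((mesh.n_nodes, 3)), stress=stress)


def test_every_af_element_mapped_once(default_disc):
    smap = sec.build_section_map(default_disc)
    af = np.isin(default_disc.region, geo.AF_REGIONS)
    assert np.all(smap.axial_band[af] != "")
    assert np.all(smap.radial_band[af] != "")
    assert np.all(smap.section[~af] == "")
    # six subsections per section, volumes sum to the section volume
    vols = default_disc.volumes()
    for s in sec.SECTIONS:
        tot = vols[smap.elements(s)].sum()
        sub = sum(vols[smap.elements(s, ab, rb)].sum()
                  for ab in sec.AXIAL_BANDS for rb in sec.RADIAL_BANDS)
        assert sub == pytest.approx(tot, rel=1e-12)
        assert tot > 0


def test_post_sector_straddles_midline(default_disc):
    smap = sec.build_section_map(default_disc)
    cent = default_disc.element_centroids()
    post = smap.elements("POST")
    assert np.all(cent[post, 1] < 0)
    assert abs(cent[post, 0].mean()) < 1.0  # symmetric about the midline


def test_postlat_mirror_volumes(default_disc):
    """The POST-LAT sectors and their contralateral mirror images have equal
    volumes on the left-right symmetric mesh."""
    m = default_disc
    vols = m.volumes()
    deg = np.degrees(m.meta["elem_theta"]) % 360.0
    af = np.isin(m.region, geo.AF_REGIONS)
    for lo, hi in [(225.0, 250.0), (200.0, 225.0)]:
        sector = af & (deg >= lo) & (deg < hi)
        mlo, mhi = 360.0 - hi + 180.0, 360.0 - lo + 180.0  # mirror x -> -x
        mirror = af & (deg >= mlo % 360) & (deg < mhi % 360)
        assert vols[sector].sum() == pytest.approx(vols[mirror].sum(),
                                                   rel=0.01)


def test_uniform_axial_field_averages(default_disc):
    """sigma_zz = 5 everywhere: every axial entry is 5, the others 0."""
    st = _uniform_state(default_disc, np.diag([0.0, 0.0, 5.0]))
    smap = sec.build_section_map(default_disc)
    tab = sec.average_regional_stresses(st, smap, default_disc)
    d = tab.data
    assert np.allclose(d.loc[d.direction == "axial", "value"], 5.0)
    assert np.allclose(d.loc[d.direction != "axial", "value"], 0.0,
                       atol=1e-12)


def test_tensile_part_averaging_convention(default_disc):
    """Half of a symmetric sector at +4 MPa axial, half at -4 MPa: the
    Macaulay-positive average over the whole volume is 2 MPa."""
    m = default_disc
    smap = sec.build_section_map(m)
    stress = np.zeros((m.n_elements, 3, 3))
    cent = m.element_centroids()
    post = smap.elements("POST")
    stress[post, 2, 2] = np.where(cent[post, 0] > 0, 4.0, -4.0)
    st = fem.SolutionState(u=np.zeros((m.n_nodes, 3)), stress=stress)
    tab = sec.average_regional_stresses(st, smap, m)
    assert tab.value("POST", "all", "axial") == pytest.approx(2.0, rel=1e-9)
    # alternative convention: average only over tensile elements -> 4
    tab2 = sec.average_regional_stresses(st, smap, m,
                                         tensile_only_elements=True)
    assert tab2.value("POST", "all", "axial") == pytest.approx(4.0, rel=1e-9)


def test_partition_consistency_random_field(default_disc):
    """Section mean equals the volume-weighted mean of its six subsections."""
    m = default_disc
    rng = np.random.default_rng(5)
    stress = rng.standard_normal((m.n_elements, 3, 3))
    stress = 0.5 * (stress + np.transpose(stress, (0, 2, 1)))
    st = fem.SolutionState(u=np.zeros((m.n_nodes, 3)), stress=stress)
    smap = sec.build_section_map(m)
    tab = sec.average_regional_stresses(st, smap, m)
    vols = m.volumes()
    for s in sec.SECTIONS:
        num = den = 0.0
        for ab in sec.AXIAL_BANDS:
            for rb in sec.RADIAL_BANDS:
                idx = smap.elements(s, ab, rb)
                v = vols[idx].sum()
                num += tab.value(s, f"{ab}-{rb}", "axial") * v
                den += v
        assert tab.value(s, "all", "axial") == pytest.approx(num / den,
                                                             rel=1e-10)


def test_rigid_rotation_leaves_entries_unchanged(default_disc):
    """Co-rotating mesh frames and stress tensors leaves every averaged
    entry invariant."""
    from scipy.spatial.transform import Rotation
    m = default_disc
    rng = np.random.default_rng(8)
    stress = rng.standard_normal((m.n_elements, 3, 3))
    stress = 0.5 * (stress + np.transpose(stress, (0, 2, 1)))
    st = fem.SolutionState(u=np.zeros((m.n_nodes, 3)), stress=stress)
    smap = sec.build_section_map(m)
    tab0 = sec.average_regional_stresses(st, smap, m)
    R = Rotation.from_euler("z", 37.0, degrees=True).as_matrix()
    rotated = geo.DiscMesh(nodes=m.nodes @ R.T, hexes=m.hexes,
                           region=m.region, node_sets=m.node_sets,
                           fiber_dirs=m.fiber_dirs,
                           local_frame=np.einsum("ij,nkj->nki", R,
                                                 m.local_frame),
                           meta=m.meta)
    st_rot = fem.SolutionState(
        u=np.zeros((m.n_nodes, 3)),
        stress=np.einsum("ij,njk,lk->nil", R, stress, R))
    tab1 = sec.average_regional_stresses(st_rot, smap, rotated)
    pd0 = tab0.data.set_index(["section", "subsection", "direction"])
    pd1 = tab1.data.set_index(["section", "subsection", "direction"])
    assert np.allclose(pd0["value"], pd1["value"], atol=1e-10)


def test_interface_stress_uniform_field_on_disc(default_disc):
    """Uniform axial tension across the disc: every section's interface
    stress equals the imposed stress."""
    m = default_disc
    smap = sec.build_section_map(m)
    st = _uniform_state(m, np.diag([0.0, 0.0, 0.8]))
    iface = sec.interface_stress(st, m, smap)
    for sec_name, v in iface.items():
        assert v == pytest.approx(0.8, rel=1e-6), sec_name


def test_interface_zero_state(default_disc):
    m = default_disc
    smap = sec.build_section_map(m)
    st = _uniform_state(m, np.zeros((3, 3)))
    for v in sec.interface_stress(st, m, smap).values():
        assert v == pytest.approx(0.0, abs=1e-12)


def test_overlapping_bounds_rejected():
    with pytest.raises(sec.SectioningError):
        sec.SectionBounds(post_half_width=80.0, post_lat_width=60.0,
                          ant_half_width=80.0).ranges()
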