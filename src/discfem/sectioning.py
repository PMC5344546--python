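"""Regional averaging of tensile stresses in the annulus fibrosus.

The failure analysis reads stresses in a small number of annulus sectors
where damage is observed experimentally: a posterior sector straddling the
posterior midline (POST), two adjacent postero-lateral sectors on the side
stretched by the lateral bending (POST-LAT1 next to POST, then POST-LAT2),
and an anterior sector (ANT). Each sector is subdivided into cranial/middle/
caudal thirds and inner/outer halves — six subsections — and the tensile
(Macaulay-positive) parts of the local-frame normal stress components are
volume-averaged per subsection. The stress transmitted across the annulus-
endplate junction is the axial nodal-force resultant over the interface
patch divided by its reference area.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd

from .fem import SolutionState
from .geometry import AF_REGIONS, DiscMesh

__all__ = [
    "SectionBounds",
    "SectionMap",
    "RegionalStressTable",
    "build_section_map",
    "average_regional_stresses",
    "interface_stress",
    "SectioningError",
]

log = logging.getLogger(__name__)

SECTIONS = ("POST", "POST-LAT1", "POST-LAT2", "ANT")
AXIAL_BANDS = ("cranial", "middle", "caudal")
RADIAL_BANDS = ("inner", "outer")
DIRECTIONS = ("axial", "circumferential", "radial")
MARGINALS = ("cranial", "middle", "caudal", "inner", "outer")


class SectioningError(ValueError):
    pass


@dataclass(frozen=True)
class SectionBounds:
    """Angular extents (degrees, measured CCW from +x = right lateral).

    The posterior midline sits at 270 deg. POST straddles it symmetrically;
    the postero-lateral sectors lie between POST and the stretched (-x) side,
    POST-LAT1 adjacent to POST. The figure defining the sectors prints no
    angles, so the extents are configurable.
    """

    post_half_width: float = 20.0
    post_lat_width: float = 25.0
    ant_half_width: float = 20.0

    def ranges(self) -> Dict[str, Tuple[float, float]]:
        out = {
            "POST": (270.0 - self.post_half_width,
                     270.0 + self.post_half_width),
            "POST-LAT1": (270.0 - self.post_half_width - self.post_lat_width,
                          270.0 - self.post_half_width),
            "POST-LAT2": (270.0 - self.post_half_width - 2 * self.post_lat_width,
                          270.0 - self.post_half_width - self.post_lat_width),
            "ANT": (90.0 - self.ant_half_width, 90.0 + self.ant_half_width),
        }
        # pairwise overlap check on the circle
        def segs(lo, hi):
            lo, hi = lo % 360.0, hi % 360.0
            return [(lo, hi)] if lo <= hi else [(lo, 360.0), (0.0, hi)]

        names = list(out)
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                for lo1, hi1 in segs(*out[a]):
                    for lo2, hi2 in segs(*out[b]):
                        if max(lo1, lo2) < min(hi1, hi2) - 1e-12:
                            raise SectioningError(
                                f"overlapping angular bounds: {a} and {b}")
        return out


@dataclass
class SectionMap:
    """Per-element section / axial-band / radial-band assignment (AF only)."""

    section: np.ndarray      # (ne,) str, "" off the analysed sectors
    axial_band: np.ndarray   # (ne,) str, "" off the AF
    radial_band: np.ndarray  # (ne,) str
    bounds: SectionBounds = field(default_factory=SectionBounds)

    def elements(self, section: str, axial: Optional[str] = None,
                 radial: Optional[str] = None) -> np.ndarray:
        m = self.section == section
        if axial is not None:
            m &= self.axial_band == axial
        if radial is not None:
            m &= self.radial_band == radial
        return np.flatnonzero(m)


def build_section_map(mesh: DiscMesh,
                      bounds: Optional[SectionBounds] = None) -> SectionMap:
    """Assign every annulus element a (section, axial band, radial band).

    Sections are contiguous angular sectors of the AF; axial thirds and
    radial halves come from the element's core-layer index and annulus ring
    index recorded at mesh generation.
    """
    bounds = bounds or SectionBounds()
    ranges = bounds.ranges()
    ne = mesh.n_elements
    theta = mesh.meta["elem_theta"]
    ring = mesh.meta["elem_af_ring"]
    layer = mesh.meta["elem_core_layer"]
    res = mesh.meta["config"].resolution

    section = np.full(ne, "", dtype=object)
    axial_band = np.full(ne, "", dtype=object)
    radial_band = np.full(ne, "", dtype=object)

    is_af = np.isin(mesh.region, AF_REGIONS)
    deg = np.degrees(theta) % 360.0

    for name, (lo, hi) in ranges.items():
        lo_m, hi_m = lo % 360.0, hi % 360.0
        if lo_m <= hi_m:
            in_sec = (deg >= lo_m) & (deg < hi_m)
        else:
            in_sec = (deg >= lo_m) | (deg < hi_m)
        section[is_af & in_sec] = name

    frac = (layer + 0.5) / res.n_axial
    axial_band[is_af & (frac < 1 / 3)] = "caudal"
    axial_band[is_af & (frac >= 1 / 3) & (frac < 2 / 3)] = "middle"
    axial_band[is_af & (frac >= 2 / 3)] = "cranial"

    n_inner = res.n_rad_af // 2
    radial_band[is_af & (ring < n_inner)] = "inner"
    radial_band[is_af & (ring >= n_inner)] = "outer"

    return SectionMap(section=section.astype(str),
                      axial_band=axial_band.astype(str),
                      radial_band=radial_band.astype(str), bounds=bounds)


@dataclass
class RegionalStressTable:
    """Averaged tensile stresses per (section, subsection/marginal,
    direction), MPa, plus per-section AF-endplate interface stress."""

    data: pd.DataFrame                    # tidy: section, subsection, direction, value
    interface: Dict[str, float] = field(default_factory=dict)

    def value(self, section: str, subsection: str, direction: str) -> float:
        d = self.data
        m = ((d["section"] == section) & (d["subsection"] == subsection)
             & (d["direction"] == direction))
        if not m.any():
            return math.nan
        return float(d.loc[m, "value"].iloc[0])

    def section_max(self, sections=("POST", "POST-LAT1", "POST-LAT2"),
                    directions=DIRECTIONS) -> float:
        d = self.data
        m = d["section"].isin(sections) & d["direction"].isin(directions) \
            & (d["subsection"] == "all")
        vals = d.loc[m, "value"].to_numpy()
        vals = vals[np.isfinite(vals)]
        return float(vals.max()) if vals.size else math.nan


def _local_normal_stresses(state: SolutionState, mesh: DiscMesh) -> np.ndarray:
    """(ne, 3) normal stress components in the local (circ, rad, ax) frame."""
    fr = mesh.local_frame
    sig = state.stress
    # sigma_local = Q sigma Q^T with rows of Q the local axes
    loc = np.einsum("nai,nij,nbj->nab", fr, sig, fr)
    circ = loc[:, 0, 0]
    rad = loc[:, 1, 1]
    ax = loc[:, 2, 2]
    return np.stack([ax, circ, rad], axis=1)  # order matches DIRECTIONS


def average_regional_stresses(state: SolutionState, smap: SectionMap,
                              mesh: DiscMesh,
                              tensile_only_elements: bool = False,
                              ) -> RegionalStressTable:
    """Volume-weighted tensile averages per subsection and marginal band.

    By default the Macaulay-positive part of each stress component is
    averaged over the full subsection volume; with
    ``tensile_only_elements=True`` the average runs only over elements whose
    component is tensile (alternative convention, same spirit).
    """
    vols = mesh.volumes()
    comp = _local_normal_stresses(state, mesh)  # (ne,3) ax, circ, rad
    rows = []

    def add(section, subsection, idx):
        for d, dname in enumerate(DIRECTIONS):
            if idx.size == 0:
                rows.append((section, subsection, dname, math.nan))
                log.warning("empty subsection %s/%s", section, subsection)
                continue
            v = vols[idx]
            s = np.maximum(comp[idx, d], 0.0)
            if tensile_only_elements:
                m = comp[idx, d] > 0
                val = float(np.average(s[m], weights=v[m])) if m.any() else 0.0
            else:
                val = float(np.average(s, weights=v))
            rows.append((section, subsection, dname, val))

    for sec in SECTIONS:
        add(sec, "all", smap.elements(sec))
        for ab in AXIAL_BANDS:
            for rb in RADIAL_BANDS:
                add(sec, f"{ab}-{rb}", smap.elements(sec, ab, rb))
        for ab in AXIAL_BANDS:
            add(sec, ab, smap.elements(sec, axial=ab))
        for rb in RADIAL_BANDS:
            add(sec, rb, smap.elements(sec, radial=rb))

    df = pd.DataFrame(rows, columns=["section", "subsection", "direction",
                                     "value"])
    iface = interface_stress(state, mesh, smap)
    return RegionalStressTable(data=df, interface=iface)


def interface_stress(state: SolutionState, mesh: DiscMesh, smap: SectionMap,
                     side: str = "caudal") -> Dict[str, float]:
    """Axial force resultant across the AF-endplate junction per section,
    divided by the junction patch reference area (MPa, tensile positive).

    The resultant is assembled from the internal forces of the annulus
    elements on the disc side of the junction; by Newton's third law this is
    the traction the annulus applies to the endplate.
    """
    key = f"af-cep-interface-{side}"
    if key not in mesh.node_sets:
        raise SectioningError(f"mesh lacks node set {key!r}")
    meta = mesh.meta
    if "af_quads" not in meta:
        raise SectioningError("mesh lacks interface metadata")
    n2d = meta["n2d"]
    lev = meta["lev_core_bottom"] if side == "caudal" else meta["lev_core_top"]

    # nodal forces recovered from the element-mean stresses of the annulus
    # core elements only (discrete divergence over the AF subset)
    af_core = np.flatnonzero(np.isin(mesh.region, AF_REGIONS))
    from . import hexelem  # local import to avoid cycles at module load
    sub_hexes = mesh.hexes[af_core]
    dNdX, detJ = hexelem.precompute(mesh.nodes, sub_hexes, hexelem.GAUSS8)
    ue = state.u[sub_hexes]
    F = np.eye(3) + np.einsum("eai,egaj->egij", ue, dNdX)
    J = np.linalg.det(F)
    Finv = np.linalg.inv(F)
    sig = state.stress[af_core]  # element-mean Cauchy stress
    P = J[..., None, None] * np.einsum("eik,egjk->egij", sig, Finv)
    fe = np.einsum("eg,egij,egaj->eai", detJ, P, dNdX)

    e_theta = np.degrees(mesh.meta["elem_theta"][af_core]) % 360.0
    quads = meta["af_quads"]
    qtheta = np.degrees(meta["af_quad_theta"]) % 360.0
    ranges = smap.bounds.ranges()
    lev_lo, lev_hi = lev * n2d, (lev + 1) * n2d
    out: Dict[str, float] = {}
    # internal force of the section's own columns at the interface-level
    # nodes equals (minus) the traction the endplate applies to the annulus;
    # the annulus pulls the endplate with the opposite sign. Tension (plates
    # pulled apart) is positive.
    sgn = -1.0 if side == "caudal" else 1.0
    for name, (lo, hi) in ranges.items():
        lo_m, hi_m = lo % 360.0, hi % 360.0
        if lo_m <= hi_m:
            e_in = (e_theta >= lo_m) & (e_theta < hi_m)
            q_in = (qtheta >= lo_m) & (qtheta < hi_m)
        else:
            e_in = (e_theta >= lo_m) | (e_theta < hi_m)
            q_in = (qtheta >= lo_m) | (qtheta < hi_m)
        qs = quads[q_in]
        if qs.size == 0 or not np.any(e_in):
            out[name] = math.nan
            continue
        f = np.zeros((mesh.n_nodes, 3))
        np.add.at(f, sub_hexes[e_in].reshape(-1), fe[e_in].reshape(-1, 3))
        nids = np.arange(lev_lo, lev_hi)
        fz = float(f[nids, 2].sum())
        # reference patch area from the quad corner coordinates (planar
        # cross product, two triangles per quad)
        pts = mesh.nodes[qs + lev * n2d][:, :, :2]

        def cross2(a, b):
            return a[:, 0] * b[:, 1] - a[:, 1] * b[:, 0]

        a1 = cross2(pts[:, 1] - pts[:, 0], pts[:, 2] - pts[:, 0])
        a2 = cross2(pts[:, 2] - pts[:, 0], pts[:, 3] - pts[:, 0])
        area = float(0.5 * (np.abs(a1) + np.abs(a2)).sum())
        out[name] = sgn * fz / area
    return out
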