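"""Parametric generation of the lumbar disc mesh.

The cross-section outline is a superellipse through the configured lateral
width and antero-posterior depth. The nucleus boundary is the same contour,
scaled so that the nucleus occupies the configured area fraction, and shifted
slightly posteriorly. The in-plane mesh is a butterfly O-grid: a structured
square core inside the nucleus, transition rings out to the nucleus contour,
and annulus rings out to the outer contour. The grid is extruded axially into
a bony endplate / cartilaginous endplate / disc-core / CEP / BEP stack; the
disc-core height interpolates linearly from the anterior to the posterior
annulus height.

Coordinates: origin at the disc mid-height centroid; +x lateral (right),
+y anterior, +z axial (cranial). Lengths in mm.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Dict, Optional

import numpy as np

from . import hexelem

__all__ = [
    "DiscGeometryConfig",
    "MeshResolution",
    "DiscMesh",
    "GeometryError",
    "build_disc_mesh",
    "assign_fiber_field",
    "compute_local_frames",
    "box_mesh",
]

log = logging.getLogger(__name__)

AF_REGIONS = ("AF-anterior", "AF-lateral", "AF-posterior")


class GeometryError(ValueError):
    """Invalid geometry configuration."""


@dataclass(frozen=True)
class MeshResolution:
    """Element counts: circumferential (multiple of 8), nucleus transition
    rings, annulus rings, axial disc-core layers, CEP layers, BEP layers."""

    n_theta: int = 16
    n_rad_np: int = 2
    n_rad_af: int = 3
    n_axial: int = 3
    n_cep: int = 1
    n_bep: int = 1

    def __post_init__(self) -> None:
        if self.n_theta < 8 or self.n_theta % 8:
            raise GeometryError("n_theta must be a positive multiple of 8")
        for name in ("n_rad_np", "n_rad_af", "n_axial", "n_cep", "n_bep"):
            if getattr(self, name) < 1:
                raise GeometryError(f"{name} must be >= 1")
        if self.n_rad_af < 2:
            raise GeometryError("n_rad_af must be >= 2 (inner/outer split)")

    def refined(self, factor: int = 2) -> "MeshResolution":
        return MeshResolution(self.n_theta * factor, self.n_rad_np * factor,
                              self.n_rad_af * factor, self.n_axial * factor,
                              self.n_cep * factor, self.n_bep * factor)


@dataclass(frozen=True)
class DiscGeometryConfig:
    """Disc dimensions (mm) and meshing controls.

    Defaults reproduce the ovine L3-4 gross dimensions: 30 mm lateral width,
    22 mm antero-posterior depth, annulus height 4.5 mm anteriorly and
    2.5 mm posteriorly, 0.1 mm cartilaginous and 0.5 mm bony endplates.
    """

    width: float = 30.0
    depth: float = 22.0
    af_height_anterior: float = 4.5
    af_height_posterior: float = 2.5
    cep_thickness: float = 0.1
    bep_thickness: float = 0.5
    np_area_fraction: float = 0.44
    np_posterior_offset_fraction: float = 0.05
    superellipse_exponent: float = 2.5
    fiber_angle: float = 30.0  # degrees to the circumferential direction
    resolution: MeshResolution = field(default_factory=MeshResolution)

    def __post_init__(self) -> None:
        for name in ("width", "depth", "af_height_anterior",
                     "af_height_posterior", "cep_thickness", "bep_thickness"):
            if getattr(self, name) <= 0:
                raise GeometryError(f"{name} must be positive")
        if self.af_height_posterior > self.af_height_anterior:
            raise GeometryError("posterior AF height must not exceed anterior")
        if not 0.0 < self.np_area_fraction < 1.0:
            raise GeometryError("np_area_fraction must lie in (0, 1)")
        if self.superellipse_exponent < 2.0:
            raise GeometryError("superellipse exponent must be >= 2")
        if not 0.0 < self.fiber_angle < 90.0:
            raise GeometryError("fiber_angle must lie in (0, 90) degrees")


@dataclass
class DiscMesh:
    """Hexahedral disc mesh with region labels, node sets, fiber directions
    and per-element local circumferential/radial/axial frames."""

    nodes: np.ndarray                  # (nn, 3)
    hexes: np.ndarray                  # (ne, 8) int
    region: np.ndarray                 # (ne,) str labels
    node_sets: Dict[str, np.ndarray]
    fiber_dirs: Optional[np.ndarray] = None   # (ne, 2, 3), NaN off the AF
    local_frame: Optional[np.ndarray] = None  # (ne, 3, 3) rows = (circ, rad, ax)
    meta: dict = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    @property
    def n_elements(self) -> int:
        return self.hexes.shape[0]

    def volumes(self) -> np.ndarray:
        return hexelem.volumes(self.nodes, self.hexes)

    def element_centroids(self) -> np.ndarray:
        return hexelem.centroids(self.nodes, self.hexes)

    def region_elements(self, label: str) -> np.ndarray:
        return np.flatnonzero(self.region == label)


# ---------------------------------------------------------------------------
# cross-section construction
# ---------------------------------------------------------------------------

def _superellipse(theta: np.ndarray, a: float, b: float, p: float) -> np.ndarray:
    c, s = np.cos(theta), np.sin(theta)
    x = a * np.sign(c) * np.abs(c) ** (2.0 / p)
    y = b * np.sign(s) * np.abs(s) ** (2.0 / p)
    return np.stack([x, y], axis=-1)


def _square_boundary_ccw(m: int) -> list[tuple[int, int]]:
    """(i, j) grid indices of the core-square boundary, counter-clockwise,
    starting at the mid-point of the right edge. Requires even m."""
    idx = []
    half = m // 2
    for j in range(half, m):           # right edge, upward
        idx.append((m, j))
    for i in range(m, 0, -1):          # top edge, leftward
        idx.append((i, m))
    for j in range(m, 0, -1):          # left edge, downward
        idx.append((0, j))
    for i in range(0, m):              # bottom edge, rightward
        idx.append((i, 0))
    for j in range(0, half):           # right edge up to start
        idx.append((m, j))
    return idx


def build_disc_mesh(config: DiscGeometryConfig) -> DiscMesh:
    """Generate the parametric disc mesh (geometry, regions, node sets,
    fibers and local frames)."""
    res = config.resolution
    a, b = config.width / 2.0, config.depth / 2.0
    p = config.superellipse_exponent
    s_np = math.sqrt(config.np_area_fraction)
    y_off = -config.np_posterior_offset_fraction * config.depth
    n_t = res.n_theta
    m = n_t // 4  # core grid is m x m; n_theta % 8 == 0 ensures m even

    theta = 2.0 * np.pi * np.arange(n_t) / n_t
    outer = _superellipse(theta, a, b, p)                    # (n_t, 2)
    np_contour = np.array([0.0, y_off]) + s_np * outer       # (n_t, 2)

    # --- 2D nodes -----------------------------------------------------------
    # core square inside the nucleus
    h_c = 0.5 * s_np * min(a, b)
    gl = np.linspace(-h_c, h_c, m + 1)
    core_xy = np.stack(np.meshgrid(gl, gl, indexing="ij"), axis=-1)
    core_xy = core_xy + np.array([0.0, y_off])
    core_ids = np.arange((m + 1) * (m + 1)).reshape(m + 1, m + 1)
    pts2d = [core_xy.reshape(-1, 2)]
    n2d = (m + 1) * (m + 1)

    boundary = _square_boundary_ccw(m)
    ring0_ids = np.array([core_ids[i, j] for (i, j) in boundary])
    ring0_xy = np.array([core_xy[i, j] for (i, j) in boundary])

    ring_ids = [ring0_ids]
    n_rings = res.n_rad_np + res.n_rad_af
    for r in range(1, n_rings + 1):
        if r <= res.n_rad_np:
            t = r / res.n_rad_np
            xy = (1 - t) * ring0_xy + t * np_contour
        else:
            t = (r - res.n_rad_np) / res.n_rad_af
            xy = (1 - t) * np_contour + t * outer
        pts2d.append(xy)
        ring_ids.append(np.arange(n2d, n2d + n_t))
        n2d += n_t
    pts2d = np.concatenate(pts2d, axis=0)

    # --- 2D quads ------------------------------------------------------------
    quads, q_theta, q_ring = [], [], []
    for i in range(m):
        for j in range(m):
            quads.append([core_ids[i, j], core_ids[i + 1, j],
                          core_ids[i + 1, j + 1], core_ids[i, j + 1]])
            q_theta.append(np.nan)
            q_ring.append(-1 - res.n_rad_np)  # core marker (well inside NP)
    for r in range(n_rings):
        inner, outer_ids = ring_ids[r], ring_ids[r + 1]
        for k in range(n_t):
            k1 = (k + 1) % n_t
            quads.append([inner[k], outer_ids[k], outer_ids[k1], inner[k1]])
            q_theta.append(float(theta[k] + np.pi / n_t))
            q_ring.append(r - res.n_rad_np)  # <0: NP transition; >=0: AF ring
    quads = np.asarray(quads, dtype=np.int64)
    q_theta = np.asarray(q_theta)
    q_ring = np.asarray(q_ring, dtype=np.int64)
    nq = quads.shape[0]

    # --- axial extrusion ------------------------------------------------------
    def core_height(y: np.ndarray) -> np.ndarray:
        frac = np.clip((y + b) / (2 * b), 0.0, 1.0)
        return config.af_height_posterior + frac * (
            config.af_height_anterior - config.af_height_posterior)

    hcol = core_height(pts2d[:, 1])
    n_lay = res.n_bep + res.n_cep + res.n_axial + res.n_cep + res.n_bep
    # layer class per element layer
    lay_class = (["bep-caudal"] * res.n_bep + ["cep-caudal"] * res.n_cep +
                 ["core"] * res.n_axial + ["cep-cranial"] * res.n_cep +
                 ["bep-cranial"] * res.n_bep)
    core_layer_idx = np.full(n_lay, -1)
    core_layer_idx[res.n_bep + res.n_cep:
                   res.n_bep + res.n_cep + res.n_axial] = np.arange(res.n_axial)

    # z levels per 2D node column: n_lay + 1 levels
    frac_bep = np.linspace(0, 1, res.n_bep + 1)
    frac_cep = np.linspace(0, 1, res.n_cep + 1)
    frac_core = np.linspace(0, 1, res.n_axial + 1)
    levels = []  # list of (n2d,) z arrays
    zc = hcol / 2.0
    bot_bep = -zc - config.cep_thickness - config.bep_thickness
    for f in frac_bep[:-1]:
        levels.append(bot_bep + f * config.bep_thickness)
    bot_cep = -zc - config.cep_thickness
    for f in frac_cep[:-1]:
        levels.append(bot_cep + f * config.cep_thickness)
    for f in frac_core[:-1]:
        levels.append(-zc + f * hcol)
    for f in frac_cep[:-1]:
        levels.append(zc + f * config.cep_thickness)
    for f in frac_bep:
        levels.append(zc + config.cep_thickness + f * config.bep_thickness)
    assert len(levels) == n_lay + 1
    zlev = np.stack(levels, axis=0)  # (n_lay+1, n2d)

    nodes = np.empty(((n_lay + 1) * n2d, 3))
    for L in range(n_lay + 1):
        nodes[L * n2d:(L + 1) * n2d, :2] = pts2d
        nodes[L * n2d:(L + 1) * n2d, 2] = zlev[L]

    # --- hexes + regions ------------------------------------------------------
    n_af_inner = res.n_rad_af // 2  # rings < this are "inner"
    hexes = np.empty((n_lay * nq, 8), dtype=np.int64)
    region = np.empty(n_lay * nq, dtype=object)
    e_theta = np.empty(n_lay * nq)
    e_ring = np.empty(n_lay * nq, dtype=np.int64)
    e_layer = np.full(n_lay * nq, -1, dtype=np.int64)

    def af_label(th: float) -> str:
        deg = math.degrees(th) % 360.0
        if 45.0 <= deg < 135.0:
            return "AF-anterior"
        if 225.0 <= deg < 315.0:
            return "AF-posterior"
        return "AF-lateral"

    e = 0
    for L in range(n_lay):
        off0, off1 = L * n2d, (L + 1) * n2d
        cls = lay_class[L]
        for q in range(nq):
            hexes[e, :4] = quads[q] + off0
            hexes[e, 4:] = quads[q] + off1
            ring = q_ring[q]
            is_af = ring >= 0
            e_theta[e] = q_theta[q]
            e_ring[e] = ring
            e_layer[e] = core_layer_idx[L]
            if cls == "core":
                region[e] = af_label(q_theta[q]) if is_af else "NP"
            elif cls.startswith("cep"):
                if is_af and ring >= n_af_inner:
                    # outer annulus columns meet the bony rim directly
                    region[e] = "BEP-" + cls.split("-")[1]
                else:
                    region[e] = "CEP-" + cls.split("-")[1]
            else:
                region[e] = "BEP-" + cls.split("-")[1]
            e += 1
    region = region.astype(str)

    # --- node sets ------------------------------------------------------------
    caudal_fixed = np.arange(n2d)
    cranial_coupled = np.arange(n_lay * n2d, (n_lay + 1) * n2d)
    # AF-CEP interface levels: bottom / top of the disc core
    lev_bot = res.n_bep + res.n_cep
    lev_top = lev_bot + res.n_axial
    af_cols = np.unique(quads[q_ring >= 0])
    iface_caudal = lev_bot * n2d + af_cols
    iface_cranial = lev_top * n2d + af_cols

    node_sets = {
        "caudal-fixed": caudal_fixed,
        "cranial-coupled": cranial_coupled,
        "af-cep-interface-caudal": iface_caudal,
        "af-cep-interface-cranial": iface_cranial,
    }

    meta = {
        "config": config,
        "n2d": n2d,
        "n_lay": n_lay,
        "lev_core_bottom": lev_bot,
        "lev_core_top": lev_top,
        "elem_theta": e_theta,
        "elem_af_ring": e_ring,
        "elem_core_layer": e_layer,
        "af_quads": quads[q_ring >= 0],
        "af_quad_theta": q_theta[q_ring >= 0],
        "af_quad_ring": q_ring[q_ring >= 0],
        "contour_center": np.array([0.0, 0.0]),
    }

    mesh = DiscMesh(nodes=nodes, hexes=hexes, region=region,
                    node_sets=node_sets, meta=meta)

    msj = hexelem.min_scaled_jacobian(nodes, hexes)
    if msj <= 0.0:
        raise GeometryError(
            f"degenerate configuration: min scaled Jacobian {msj:.3g} <= 0")
    meta["min_scaled_jacobian"] = msj

    compute_local_frames(mesh)
    assign_fiber_field(mesh, config.fiber_angle)
    return mesh


def assign_fiber_field(mesh: DiscMesh, fiber_angle) -> DiscMesh:
    """Attach the two symmetric fiber families to every annulus element.

    ``fiber_angle`` is the inclination to the local circumferential direction
    in degrees, either a scalar or a mapping ``{AF region: degrees}``. The
    fibers lie in the circumferential-axial plane at +/- the angle.
    """
    if mesh.local_frame is None:
        compute_local_frames(mesh)
    if np.isscalar(fiber_angle):
        angles = {r: float(fiber_angle) for r in AF_REGIONS}
    else:
        angles = {r: float(fiber_angle[r]) for r in AF_REGIONS}
    for r, ang in angles.items():
        if not 0.0 < ang < 90.0:
            raise GeometryError("fiber angle must lie strictly in (0, 90) deg")

    ne = mesh.n_elements
    fibers = np.full((ne, 2, 3), np.nan)
    for r in AF_REGIONS:
        els = mesh.region_elements(r)
        if els.size == 0:
            continue
        ang = math.radians(angles[r])
        c = mesh.local_frame[els, 0, :]
        ax = mesh.local_frame[els, 2, :]
        fibers[els, 0] = math.cos(ang) * c + math.sin(ang) * ax
        fibers[els, 1] = math.cos(ang) * c - math.sin(ang) * ax
    mesh.fiber_dirs = fibers
    return mesh


def compute_local_frames(mesh: DiscMesh) -> DiscMesh:
    """Per-element orthonormal (circumferential, radial, axial) triads.

    Radial is the outward in-plane normal of the cross-section contour family
    through the element centroid; circumferential the in-plane tangent; axial
    the global spine axis. Elements whose centroid coincides with the contour
    center fall back to the global x direction (logged).
    """
    cfg: Optional[DiscGeometryConfig] = mesh.meta.get("config")
    cent = mesh.element_centroids()
    x, y = cent[:, 0], cent[:, 1]
    if cfg is not None:
        a, b, p = cfg.width / 2, cfg.depth / 2, cfg.superellipse_exponent
        # gradient of |x/a|^p + |y/b|^p
        gx = (p / a) * np.abs(x / a) ** (p - 1) * np.sign(x)
        gy = (p / b) * np.abs(y / b) ** (p - 1) * np.sign(y)
    else:
        gx, gy = x.copy(), y.copy()
    nrm = np.hypot(gx, gy)
    bad = nrm < 1e-12
    if np.any(bad):
        log.warning("local frame undefined at %d element(s); "
                    "falling back to the global x direction", int(bad.sum()))
        gx[bad], gy[bad], nrm[bad] = 1.0, 0.0, 1.0
    rad = np.stack([gx / nrm, gy / nrm, np.zeros_like(gx)], axis=1)
    ax = np.tile(np.array([0.0, 0.0, 1.0]), (cent.shape[0], 1))
    circ = np.cross(rad, ax)  # = rad x z, right-handed (circ, rad, ax)
    frame = np.stack([circ, rad, ax], axis=1)
    mesh.local_frame = frame
    return mesh


# ---------------------------------------------------------------------------
# simple box meshes for verification fixtures
# ---------------------------------------------------------------------------

def box_mesh(nx: int, ny: int, nz: int, lx: float, ly: float, lz: float,
             region_label: str = "NP") -> DiscMesh:
    """Structured box mesh on [0,lx] x [0,ly] x [0,lz] with a single region.

    Node sets: ``caudal-fixed`` (z=0), ``cranial-coupled`` (z=lz), and an
    ``af-cep-interface-caudal`` placeholder at the z=0 plane.
    """
    xs = np.linspace(0, lx, nx + 1)
    ys = np.linspace(0, ly, ny + 1)
    zs = np.linspace(0, lz, nz + 1)
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    nodes = np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=1)

    def nid(i, j, k):
        return (i * (ny + 1) + j) * (nz + 1) + k

    hexes = []
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                hexes.append([nid(i, j, k), nid(i + 1, j, k),
                              nid(i + 1, j + 1, k), nid(i, j + 1, k),
                              nid(i, j, k + 1), nid(i + 1, j, k + 1),
                              nid(i + 1, j + 1, k + 1), nid(i, j + 1, k + 1)])
    hexes = np.asarray(hexes, dtype=np.int64)
    region = np.full(hexes.shape[0], region_label, dtype=object).astype(str)
    bot = np.flatnonzero(np.isclose(nodes[:, 2], 0.0))
    top = np.flatnonzero(np.isclose(nodes[:, 2], lz))
    mesh = DiscMesh(nodes=nodes, hexes=hexes, region=region,
                    node_sets={"caudal-fixed": bot, "cranial-coupled": top,
                               "af-cep-interface-caudal": bot},
                    meta={"box": (lx, ly, lz)})
    # global frames; fibers along +/-30 deg in the x-z plane if annulus label
    ne = hexes.shape[0]
    frame = np.tile(np.eye(3), (ne, 1, 1))
    mesh.local_frame = frame
    if region_label.startswith("AF"):
        ang = math.radians(30.0)
        f1 = np.array([math.cos(ang), 0, math.sin(ang)])
        f2 = np.array([math.cos(ang), 0, -math.sin(ang)])
        mesh.fiber_dirs = np.tile(np.stack([f1, f2]), (ne, 1, 1))
    else:
        mesh.fiber_dirs = np.full((ne, 2, 3), np.nan)
    return mesh
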