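"""Trilinear 8-node hexahedron primitives shared by geometry and solver.

Node ordering follows the VTK/usual convention: bottom face counter-clockwise
(viewed from +z), then top face.
"""

from __future__ import annotations

import numpy as np

# reference nodal coordinates (8, 3)
XI_NODES = np.array([
    [-1, -1, -1], [1, -1, -1], [1, 1, -1], [-1, 1, -1],
    [-1, -1, 1], [1, -1, 1], [1, 1, 1], [-1, 1, 1],
], dtype=float)

_g = 1.0 / np.sqrt(3.0)
#: 2x2x2 Gauss points (8, 3) and unit weights
GAUSS8 = XI_NODES * _g
W8 = np.ones(8)
#: element centroid (single reduced point, weight 8)
GAUSS1 = np.zeros((1, 3))


def shape_functions(xi: np.ndarray) -> np.ndarray:
    """Trilinear shape functions N_a(xi) for points ``xi`` (m, 3) -> (m, 8)."""
    xi = np.atleast_2d(xi)
    return 0.125 * np.prod(1.0 + xi[:, None, :] * XI_NODES[None, :, :], axis=2)


def shape_gradients(xi: np.ndarray) -> np.ndarray:
    """dN_a/dxi at points ``xi`` (m, 3) -> (m, 8, 3)."""
    xi = np.atleast_2d(xi)
    m = xi.shape[0]
    out = np.empty((m, 8, 3))
    for j in range(3):
        terms = 1.0 + xi[:, None, :] * XI_NODES[None, :, :]  # (m,8,3)
        t = terms.copy()
        t[:, :, j] = XI_NODES[None, :, j]
        out[:, :, j] = 0.125 * np.prod(t, axis=2)
    return out


def precompute(nodes: np.ndarray, hexes: np.ndarray, points: np.ndarray):
    """Reference-configuration quantities at integration points.

    Returns ``(dNdX, detJ)`` with shapes (ne, m, 8, 3) and (ne, m) where the
    Jacobian determinant is that of the reference map (no Gauss weights).
    """
    Xe = nodes[hexes]                       # (ne, 8, 3)
    dNdxi = shape_gradients(points)         # (m, 8, 3)
    # J_ij = dX_i/dxi_j = sum_a X_ai dN_a/dxi_j
    Jac = np.einsum("eai,maj->emij", Xe, dNdxi)      # (ne, m, 3, 3)
    detJ = np.linalg.det(Jac)
    Jinv = np.linalg.inv(Jac)
    dNdX = np.einsum("maj,emji->emai", dNdxi, Jinv)  # (ne, m, 8, 3)
    return dNdX, detJ


def volumes(nodes: np.ndarray, hexes: np.ndarray) -> np.ndarray:
    """Exact trilinear element volumes via 2x2x2 quadrature."""
    _, detJ = precompute(nodes, hexes, GAUSS8)
    return detJ.sum(axis=1)


def min_scaled_jacobian(nodes: np.ndarray, hexes: np.ndarray) -> float:
    """Minimum Jacobian determinant over all Gauss points, normalised by the
    mean per-element value (1 for a parallelepiped; <= 0 flags inversion)."""
    _, detJ = precompute(nodes, hexes, GAUSS8)
    mean = detJ.mean(axis=1, keepdims=True)
    return float((detJ / mean).min())


def centroids(nodes: np.ndarray, hexes: np.ndarray) -> np.ndarray:
    return nodes[hexes].mean(axis=1)
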