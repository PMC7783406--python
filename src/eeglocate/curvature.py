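"""Per-vertex curvature of a scalp mesh.

Electrode and gel protrusions are convex bumps, so the detection signal
is a signed convexity measure.  Two estimators are provided:

``mean_cotan``
    Discrete mean curvature from the cotangent Laplacian,
    H_i = |L x|_i / (2 A_i), signed positive where the surface is convex
    with respect to the outward normal.  Units 1/m.  This is the default:
    concave folds get negative values and never compete with protrusions.

``angle_deficit``
    Angle deficit 2*pi minus the sum of incident triangle angles
    (integrated Gaussian curvature, radians).  Cheaper, unsigned in the
    convex/concave sense, kept as a fallback.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import trimesh

from .formats import GeometryError, TriangleMesh

CURVATURE_METHODS = ("mean_cotan", "angle_deficit")


@dataclass
class CurvatureField:
    """One curvature scalar per mesh vertex."""

    values: np.ndarray
    method: str

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)


def _check_edges(tm: trimesh.Trimesh) -> np.ndarray:
    """Return boundary-vertex mask; raise on non-manifold edges."""
    edges = tm.edges_sorted
    uniq, counts = np.unique(edges, axis=0, return_counts=True)
    bad = np.nonzero(counts > 2)[0]
    if bad.size:
        e = uniq[bad[0]]
        raise GeometryError(f"non-manifold edge between vertices {e[0]} and {e[1]}")
    boundary = np.zeros(len(tm.vertices), dtype=bool)
    b_edges = uniq[counts == 1]
    if b_edges.size:
        boundary[np.unique(b_edges)] = True
    return boundary


def _check_areas(tm: trimesh.Trimesh) -> np.ndarray:
    areas = tm.area_faces
    bad = np.nonzero(areas < 1e-14)[0]
    if bad.size:
        raise GeometryError(f"zero-area triangle at face {bad[0]}")
    return areas


def _outward(tm: trimesh.Trimesh) -> trimesh.Trimesh:
    """Consistent winding with outward normals (sign convention anchor)."""
    tm = tm.copy()
    trimesh.repair.fix_normals(tm)
    return tm


def _mixed_vertex_areas(v: np.ndarray, f: np.ndarray, areas: np.ndarray) -> np.ndarray:
    """Meyer-style mixed vertex areas: Voronoi for non-obtuse triangles,
    T/2 at the obtuse corner and T/4 elsewhere for obtuse ones."""
    n = len(v)
    # cot of the angle at each corner k, and squared edge lengths opposite it
    cots = np.empty_like(f, dtype=float)
    for k in range(3):
        a = v[f[:, (k + 1) % 3]] - v[f[:, k]]
        b = v[f[:, (k + 2) % 3]] - v[f[:, k]]
        cross = np.linalg.norm(np.cross(a, b), axis=1)
        cots[:, k] = np.einsum("ij,ij->i", a, b) / np.maximum(cross, 1e-30)
    obtuse_corner = np.argmin(cots, axis=1)
    any_obtuse = cots.min(axis=1) < 0.0
    e2 = np.empty_like(cots)
    for k in range(3):
        e2[:, k] = np.sum(
            (v[f[:, (k + 1) % 3]] - v[f[:, (k + 2) % 3]]) ** 2, axis=1
        )  # edge opposite corner k
    contrib = np.empty_like(cots)
    for k in range(3):
        # Voronoi area at corner k uses the two edges incident to k
        j, l = (k + 1) % 3, (k + 2) % 3
        contrib[:, k] = (e2[:, j] * cots[:, j] + e2[:, l] * cots[:, l]) / 8.0
        obt = any_obtuse
        contrib[obt, k] = np.where(
            obtuse_corner[obt] == k, areas[obt] / 2.0, areas[obt] / 4.0
        )
    va = np.zeros(n)
    np.add.at(va, f.ravel(), contrib.ravel())
    return va


def _cotangent_mean_curvature(tm: trimesh.Trimesh, boundary: np.ndarray) -> np.ndarray:
    v = tm.vertices.view(np.ndarray)
    f = tm.faces.view(np.ndarray)
    n = len(v)

    # cotangent of the angle opposite each halfedge, per corner
    rows, cols, cots = [], [], []
    for k in range(3):
        i, j, opp = f[:, k], f[:, (k + 1) % 3], f[:, (k + 2) % 3]
        a = v[i] - v[opp]
        b = v[j] - v[opp]
        cross = np.linalg.norm(np.cross(a, b), axis=1)
        cot = np.einsum("ij,ij->i", a, b) / np.maximum(cross, 1e-30)
        rows.append(i), cols.append(j), cots.append(cot)
        rows.append(j), cols.append(i), cots.append(cot)
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    w = sp.coo_matrix((np.concatenate(cots), (rows, cols)), shape=(n, n)).tocsr()
    w = 0.5 * w
    lap = w - sp.diags(np.asarray(w.sum(axis=1)).ravel())

    areas = _check_areas(tm)
    va = _mixed_vertex_areas(v, f, areas)

    hn = (lap @ v) / (2.0 * va[:, None])  # mean-curvature normal, points inward
    normals = tm.vertex_normals.view(np.ndarray)
    h = -np.einsum("ij,ij->i", hn, normals)  # convex (sphere) -> positive
    h[boundary] = -np.inf
    return h


def vertex_curvature(mesh: TriangleMesh, method: str = "mean_cotan") -> CurvatureField:
    """Curvature scalar for every vertex of `mesh`.

    Boundary vertices of a non-closed mesh get ``-inf`` so they can never
    be selected as protrusion candidates.
    """
    if method not in CURVATURE_METHODS:
        raise ValueError(f"unknown curvature method {method!r}")
    tm = mesh.to_trimesh()
    boundary = _check_edges(tm)
    if method == "angle_deficit":
        _check_areas(tm)
        values = trimesh.curvature.vertex_defects(tm).astype(float)
        values[boundary] = -np.inf
    else:
        values = _cotangent_mean_curvature(_outward(tm), boundary)
    if not np.all(np.isfinite(values[~boundary])):
        raise GeometryError("curvature produced non-finite values on interior vertices")
    return CurvatureField(values, method)
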