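"""Candidate electrode extraction from mesh curvature.

Pipeline (all thresholds exposed in :class:`LocalizeParams`):

1. restrict the search space to vertices with z > z_min (excludes nose,
   cheeks, lips in the fiducial frame);
2. keep the top-K highest-curvature vertices;
3. single-linkage cluster them at the electrode diameter (1 cm);
4. drop clusters smaller than min_cluster_size;
5. report cluster centroids as candidate electrode positions.

Candidate counts routinely exceed the montage size (empty holders,
reference electrodes, imaging artifacts); :func:`prune_candidates`
replaces the interactive clean-up step with an explicit, reproducible
keep/drop list.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .curvature import CurvatureField, vertex_curvature
from .formats import ElectrodeSet, GeometryError, TriangleMesh


class LocalizeError(RuntimeError):
    pass


@dataclass
class LocalizeParams:
    """Knobs of the localization stage (defaults follow a 64-channel cap
    on a ~10k-vertex head mesh; top_k in particular scales with electrode
    count and cap geometry and may need changing for other systems)."""

    z_min: float = 0.0              # m, lower bound of the search space
    top_k: int = 2000               # highest-curvature vertices kept
    cluster_radius: float = 0.01    # m, electrode diameter
    min_cluster_size: int = 10      # vertices
    n_expected: int = 64            # montage size
    curvature_method: str = "mean_cotan"

    def __post_init__(self):
        if self.top_k < self.n_expected:
            raise ValueError("top_k must be at least n_expected")
        if self.cluster_radius <= 0:
            raise ValueError("cluster_radius must be positive")
        if self.min_cluster_size < 1:
            raise ValueError("min_cluster_size must be >= 1")


@dataclass
class VertexCluster:
    member_indices: np.ndarray
    centroid: np.ndarray
    size: int


@dataclass
class CandidateSet:
    """Cluster centroids proposed as electrode positions."""

    points: np.ndarray
    cluster_sizes: np.ndarray
    source: str = ""

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        self.cluster_sizes = np.asarray(self.cluster_sizes, dtype=int)

    def __len__(self) -> int:
        return self.points.shape[0]


def restrict_search_space(mesh: TriangleMesh, z_min: float = 0.0) -> np.ndarray:
    """Indices of vertices with z > z_min."""
    idx = np.nonzero(mesh.vertices[:, 2] > z_min)[0]
    if idx.size == 0:
        raise LocalizeError(f"search space empty: no vertices with z > {z_min}")
    return idx


def top_k_vertices(curv: CurvatureField, eligible: np.ndarray, k: int) -> np.ndarray:
    """The min(k, |eligible|) eligible vertices of highest curvature.

    Ties at the cut are broken by ascending vertex index, so the result is
    deterministic for any input ordering.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    eligible = np.asarray(eligible, dtype=np.int64)
    vals = curv.values[eligible]
    # sort by (-curvature, vertex index): stable, deterministic cut
    order = np.lexsort((eligible, -vals))
    return eligible[order[: min(k, eligible.size)]]


def cluster_vertices(points: np.ndarray, radius: float) -> list[VertexCluster]:
    """Single-linkage clusters: connected components of the graph joining
    point pairs at Euclidean distance <= radius."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    points = np.asarray(points, dtype=float).reshape(-1, 3)
    n = points.shape[0]
    if n == 0:
        return []
    tree = cKDTree(points)
    pairs = tree.query_pairs(r=radius, output_type="ndarray")
    graph = sp.coo_matrix(
        (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(n, n)
    )
    n_comp, comp = connected_components(graph, directed=False)
    clusters = []
    for c in range(n_comp):
        members = np.nonzero(comp == c)[0]
        clusters.append(
            VertexCluster(members, points[members].mean(axis=0), members.size)
        )
    # deterministic order: largest first, then by first member index
    clusters.sort(key=lambda cl: (-cl.size, int(cl.member_indices[0])))
    return clusters


def filter_clusters(clusters: list[VertexCluster], min_size: int) -> list[VertexCluster]:
    if min_size < 1:
        raise ValueError("min_size must be >= 1")
    return [c for c in clusters if c.size >= min_size]


def localize_electrodes(
    mesh: TriangleMesh,
    params: LocalizeParams | None = None,
    curv: CurvatureField | None = None,
) -> CandidateSet:
    """Full restrict -> top-k -> cluster -> filter -> centroid pipeline."""
    params = params or LocalizeParams()
    if curv is None:
        curv = vertex_curvature(mesh, params.curvature_method)
    eligible = restrict_search_space(mesh, params.z_min)
    selected = top_k_vertices(curv, eligible, params.top_k)
    clusters = filter_clusters(
        cluster_vertices(mesh.vertices[selected], params.cluster_radius),
        params.min_cluster_size,
    )
    if not clusters:
        return CandidateSet(np.empty((0, 3)), np.empty(0, dtype=int), source="localize")
    return CandidateSet(
        np.array([c.centroid for c in clusters]),
        np.array([c.size for c in clusters]),
        source="localize",
    )


def prune_candidates(
    cands: CandidateSet,
    keep: list[int] | None = None,
    drop: list[int] | None = None,
    n_expected: int = 64,
) -> ElectrodeSet:
    """Reduce candidates to exactly `n_expected` unlabeled electrodes.

    Exactly one of `keep` / `drop` must be given (index lists into the
    candidate set); this stands in for the interactive removal of extra
    points, but as an explicit, logged operation.
    """
    if (keep is None) == (drop is None):
        raise ValueError("give exactly one of keep= or drop=")
    n = len(cands)
    if keep is not None:
        sel = sorted(set(int(i) for i in keep))
    else:
        dropset = set(int(i) for i in drop)
        sel = [i for i in range(n) if i not in dropset]
    if any(i < 0 or i >= n for i in sel):
        raise IndexError("candidate index out of range")
    if len(sel) != n_expected:
        raise LocalizeError(
            f"pruning left {len(sel)} candidates, expected exactly {n_expected}"
        )
    return ElectrodeSet(cands.points[sel], labels=None, frame="scs")
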