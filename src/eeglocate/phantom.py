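"""Synthetic head phantoms with electrode bumps and known labels.

The study's structural scans are not deposited, so testing needs a
stand-in: a genus-0 ellipsoidal head (~10k vertices, SCS frame) carrying
one convex gel-bump per montage site, optional unlabeled "dummy" bumps
(empty holders, REF/EOG sites), low-amplitude surface texture standing
in for MR reconstruction roughness, per-subject axis scatter and angular
placement jitter, and optional amplitude attenuation of posterior /
temporal bumps to mimic gel drying under a supine head.

Every bump is a Gaussian displacement of the surface along its outward
normal; the mesh vertex nearest each site is additionally relocated to
the exact analytic apex, so ground-truth electrode positions sit on bump
apices and left/right pairs are exactly mirror-symmetric before jitter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import trimesh
from scipy.spatial import cKDTree

from .formats import ElectrodeSet, TriangleMesh
from .label import MontageSpec, load_montage

# sites whose gel pads thin out first when the subject lies supine
ATTENUATED_LABELS = frozenset(
    {"O1", "O2", "OZ", "I1", "I2", "IZ", "T7", "T8", "TP7", "TP8", "M1", "M2"}
)


@dataclass
class PhantomParams:
    """Geometry of one synthetic head (lengths in meters, angles radians)."""

    ellipsoid_semiaxes: tuple = (0.095, 0.075, 0.08)  # anterior, left, superior
    semiaxis_scatter: float = 0.05       # +-5% per-subject uniform scatter
    mesh_vertices: int = 10000           # icosphere resolution target
    bump_height: float = 0.003
    bump_radius: float = 0.005           # Gaussian sigma of the bump profile
    angular_jitter_sd: float = 0.02      # per-site placement jitter, radians
    jitter_correlation: float = 0.7      # angular scale of the warp field, rad
    n_dummies: int = 15
    posterior_attenuation: float = 1.0   # bump-height factor for posterior sites
    posterior_dummy_bias: float = 0.7    # fraction of dummies forced posterior
    surface_noise_amplitude: float = 5e-5    # MR-roughness blob amplitude
    surface_noise_scale: float = 0.004       # roughness blob Gaussian sigma
    n_noise_blobs: int = 150
    mound_radius_factor: float = 1.72    # gel mound support radius / bump_radius
    n_nuisance: int = 40                 # nose-bridge / brow / nape ridges
    nuisance_amplitude: float = 0.002
    nuisance_scale: float = 0.005
    nuisance_zband: tuple = (0.03, 0.30)  # direction-z band of nuisance sites
    collar_rows: tuple = (0.05, 0.13)    # direction-z of basal fold rows
    collar_step: float = 0.0095           # azimuthal spacing of folds, m
    collar_amplitude: float = 0.002
    collar_scale: float = 0.005
    collar_clearance: float = 0.021      # fold distance from electrodes
    with_ears: bool = True               # fold-rich pinna patches below the rim
    ear_center_z: float = 0.08           # direction-z of the ear patch center
    ear_spread: float = 0.38             # angular radius of the patch, rad
    n_ear_ridges: int = 60               # sharp folds per ear
    ear_ridge_amplitude: float = 0.0022
    ear_ridge_scale: float = 0.005
    dummy_min_separation: float = 0.023  # from true electrodes
    seed: int = 0

    def __post_init__(self):
        if min(self.ellipsoid_semiaxes) <= 0:
            raise ValueError("semiaxes must be positive")
        if self.bump_radius >= min(self.ellipsoid_semiaxes):
            raise ValueError("bump_radius must be smaller than the head")
        if not 0.0 <= self.posterior_attenuation <= 1.0:
            raise ValueError("posterior_attenuation must be in [0, 1]")


@dataclass
class PhantomTruth:
    """One synthetic subject: mesh (may be None for meshless cohorts),
    ground-truth labeled electrodes, and dummy bump positions."""

    mesh: TriangleMesh | None
    electrodes: ElectrodeSet
    dummy_positions: np.ndarray
    params: PhantomParams


def _subdivisions_for(n_vertices: int) -> int:
    # icosphere vertex counts: 12, 42, 162, 642, 2562, 10242, 40962, ...
    counts = []
    v = 12
    for s in range(8):
        counts.append(v)
        v = 4 * v - 6
    return int(np.argmin([abs(c - n_vertices) for c in counts]))


def _ellipsoid_point(direction: np.ndarray, semi: np.ndarray) -> np.ndarray:
    """Intersection of the ray along `direction` with the ellipsoid."""
    u = np.asarray(direction, float)
    t = 1.0 / np.sqrt(np.sum((u / semi) ** 2))
    return t * u


def _ellipsoid_normal(p: np.ndarray, semi: np.ndarray) -> np.ndarray:
    n = p / semi**2
    return n / np.linalg.norm(n)


def _fibonacci_band(n: int, z_lo: float, z_hi: float, phase: float = 0.0) -> np.ndarray:
    """n unit directions spread evenly over the band z in [z_lo, z_hi]."""
    k = np.arange(n) + 0.5
    z = z_hi - (z_hi - z_lo) * k / n
    phi = phase + k * np.pi * (3.0 - np.sqrt(5.0))  # golden angle
    r = np.sqrt(np.clip(1.0 - z**2, 0.0, 1.0))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def make_head_mesh(params: PhantomParams, rng: np.random.Generator | None = None) -> TriangleMesh:
    """Bare head: an ellipsoidal scalp dome, closed underneath.

    Mimics a hole-filled scalp reconstruction: the vertex budget is
    concentrated on the scalp dome (above roughly the ear line) while
    the inferior closure, which a scalp segmentation only fills in, is
    meshed coarsely.  Closed genus-0 triangulation (convex hull of the
    sampled directions) in the SCS frame, plus low-amplitude
    surface-texture noise.
    """
    rng = rng if rng is not None else np.random.default_rng(params.seed)
    n_closure = max(120, int(0.04 * params.mesh_vertices))
    n_dome = params.mesh_vertices - n_closure
    z_cut = -0.15
    dirs = np.vstack([
        _fibonacci_band(n_dome, z_cut, 1.0),
        _fibonacci_band(n_closure, -1.0, z_cut, phase=1.0),
    ])
    from scipy.spatial import ConvexHull

    hull = ConvexHull(dirs)
    semi = np.asarray(params.ellipsoid_semiaxes, float)
    verts = dirs * semi
    faces = hull.simplices
    tm = trimesh.Trimesh(verts, faces, process=False)
    trimesh.repair.fix_normals(tm)
    verts = np.asarray(tm.vertices)
    faces = np.asarray(tm.faces)
    if params.n_noise_blobs > 0 and params.surface_noise_amplitude > 0:
        normals = verts / semi**2
        normals /= np.linalg.norm(normals, axis=1, keepdims=True)
        bdirs = rng.normal(size=(params.n_noise_blobs, 3))
        bdirs /= np.linalg.norm(bdirs, axis=1, keepdims=True)
        centers = np.array([_ellipsoid_point(d, semi) for d in bdirs])
        amps = rng.normal(0.0, params.surface_noise_amplitude, params.n_noise_blobs)
        disp = np.zeros(len(verts))
        s2 = 2.0 * params.surface_noise_scale**2
        tree = cKDTree(verts)
        reach = 3.0 * params.surface_noise_scale
        for c, a in zip(centers, amps):
            idx = tree.query_ball_point(c, reach)
            if not idx:
                continue
            idx = np.asarray(idx)
            d2 = np.sum((verts[idx] - c) ** 2, axis=1)
            disp[idx] += a * np.exp(-d2 / s2)
        verts = verts + disp[:, None] * normals
    return TriangleMesh(verts, faces, frame="scs")


class _CapWarp:
    """Smooth random warp of cap placement.

    A worn cap differs from its nominal geometry mostly by a rigid
    shift/rotation plus a smooth stretch, so per-site placement error is
    modeled as a sum of broad tangent Gaussian modes (angular scale
    `corr_scale`), normalized so each site direction moves with
    per-component standard deviation `sd` radians.  Neighboring sites
    move together, which keeps inter-electrode spacing realistic.
    """

    N_MODES = 12

    def __init__(self, sd: float, corr_scale: float, rng: np.random.Generator):
        self.sd = sd
        self.scale = corr_scale
        self.centers = rng.normal(size=(self.N_MODES, 3))
        self.centers /= np.linalg.norm(self.centers, axis=1, keepdims=True)
        self.amps = rng.normal(size=(self.N_MODES, 3))
        # per-mode, per-component variance of the sum at a point is
        # ~N_MODES * E[w^2]; normalize empirically on random directions
        probe = rng.normal(size=(256, 3))
        probe /= np.linalg.norm(probe, axis=1, keepdims=True)
        disp = self._raw(probe)
        rms = np.sqrt(np.mean(disp**2))
        self.gain = (sd / rms) if rms > 0 else 0.0

    def _raw(self, u: np.ndarray) -> np.ndarray:
        ang = np.arccos(np.clip(u @ self.centers.T, -1, 1))  # (n, K)
        w = np.exp(-(ang**2) / (2.0 * self.scale**2))
        return w @ self.amps

    def __call__(self, u: np.ndarray) -> np.ndarray:
        if self.sd <= 0:
            return u
        u = np.atleast_2d(u)
        g = self.gain * self._raw(u)
        g -= np.einsum("ij,ij->i", g, u)[:, None] * u  # tangent part
        v = u + g
        return np.squeeze(v / np.linalg.norm(v, axis=1, keepdims=True))


def place_montage(
    montage: MontageSpec,
    params: PhantomParams,
    rng: np.random.Generator | None = None,
) -> ElectrodeSet:
    """Ground-truth *surface* site per montage label (before bump raising).

    Sites follow the montage's canonical unit directions projected onto
    the ellipsoid; left/right pairs mirror in y and midline sites sit on
    the x-z plane before the smooth placement-warp jitter is applied.
    """
    if montage.canonical_directions is None:
        raise ValueError("montage has no canonical directions")
    rng = rng if rng is not None else np.random.default_rng(params.seed)
    semi = np.asarray(params.ellipsoid_semiaxes, float)
    warp = _CapWarp(params.angular_jitter_sd, params.jitter_correlation, rng)
    pts = []
    for lab in montage.ordered_labels:
        if lab not in montage.canonical_directions:
            raise ValueError(f"no canonical direction for label {lab}")
        u = montage.canonical_directions[lab]
        u = warp(u / np.linalg.norm(u))
        pts.append(_ellipsoid_point(u, semi))
    return ElectrodeSet(np.array(pts), list(montage.ordered_labels), frame="scs")


def _site_heights(labels, params: PhantomParams) -> np.ndarray:
    h = np.full(len(labels), params.bump_height)
    if params.posterior_attenuation < 1.0:
        for i, lab in enumerate(labels):
            if lab in ATTENUATED_LABELS:
                h[i] *= params.posterior_attenuation
    return h


def add_electrode_bumps(
    mesh: TriangleMesh,
    positions: np.ndarray,
    params: PhantomParams,
    heights: np.ndarray | None = None,
    snap_apex: bool = True,
) -> TriangleMesh:
    """Raise a gel-mound bump at each surface position.

    The mound is a compact quartic profile h * (1 - (d/R)^2)^2 for
    d < R = mound_radius_factor * bump_radius, displacing vertices along
    the outward normal: convex out to R/sqrt(2), with a concave skirt to
    R, like a gel pad squeezed under an electrode disc.  Around the
    mound the quartic's concave skirt separates the footprint from the
    surrounding scalp.  Overlapping bumps
    (< 2 * bump_radius apart) trigger a warning and their displacements
    sum.  With `snap_apex` the vertex nearest each site is relocated to
    the exact analytic apex.
    """
    positions = np.asarray(positions, float).reshape(-1, 3)
    heights = (
        np.full(len(positions), params.bump_height)
        if heights is None
        else np.asarray(heights, float)
    )
    if len(positions) == 0 or params.bump_height == 0:
        return mesh
    semi = np.asarray(params.ellipsoid_semiaxes, float)
    d = np.linalg.norm(positions[:, None] - positions[None, :], axis=2)
    np.fill_diagonal(d, np.inf)
    if d.min() < 2 * params.bump_radius:
        i, j = np.unravel_index(np.argmin(d), d.shape)
        warnings.warn(
            f"bumps {i} and {j} overlap ({d.min() * 1000:.1f} mm apart); "
            "displacements will sum"
        )
    verts = mesh.vertices.copy()
    normals = verts / semi**2
    normals /= np.linalg.norm(normals, axis=1, keepdims=True)
    disp = np.zeros(len(verts))
    mound_r = params.mound_radius_factor * params.bump_radius
    tree = cKDTree(verts)
    apex_vertex = {}
    for k, (c, h) in enumerate(zip(positions, heights)):
        idx = tree.query_ball_point(c, mound_r)
        if idx:
            idx = np.asarray(idx)
            dist = np.linalg.norm(verts[idx] - c, axis=1)
            u2 = (dist / mound_r) ** 2
            disp[idx] += np.where(u2 < 1.0, h * (1.0 - u2) ** 2, 0.0)
        if snap_apex:
            apex_vertex[int(tree.query(c)[1])] = c + h * _ellipsoid_normal(c, semi)
    out = verts + disp[:, None] * normals
    for vi, apex in apex_vertex.items():
        out[vi] = apex
    return TriangleMesh(out, mesh.faces, frame=mesh.frame)


def _sample_dummies(
    electrodes: np.ndarray,
    params: PhantomParams,
    rng: np.random.Generator,
) -> np.ndarray:
    """Random non-montage surface sites >= dummy_min_separation from any
    electrode, biased toward the posterior (x < 0) scalp."""
    semi = np.asarray(params.ellipsoid_semiaxes, float)
    out = []
    attempts = 0
    # holders sit on the cap skirt just below the outermost montage row,
    # high enough that their whole protrusion stays in the z > 0 space
    while len(out) < params.n_dummies and attempts < 60000:
        attempts += 1
        u = rng.normal(size=3)
        u /= np.linalg.norm(u)
        if not 0.10 <= u[2] <= 0.26:
            continue
        if rng.random() < params.posterior_dummy_bias and u[0] > 0:
            u[0] = -u[0]
        p = _ellipsoid_point(u, semi)
        ref = electrodes if not out else np.vstack([electrodes, out])
        if np.min(np.linalg.norm(ref - p, axis=1)) < params.dummy_min_separation:
            continue
        out.append(p)
    return np.asarray(out).reshape(-1, 3)


def _sample_band_features(
    electrodes: np.ndarray,
    n: int,
    zband: tuple,
    clearance: float,
    min_sep: float,
    semiaxes,
    rng: np.random.Generator,
) -> np.ndarray:
    """Random surface feature centers in a direction-z band, kept
    `clearance` away from electrode sites and `min_sep` apart."""
    semi = np.asarray(semiaxes, float)
    lo, hi = zband
    out = []
    attempts = 0
    while len(out) < n and attempts < 40000:
        attempts += 1
        u = rng.normal(size=3)
        u /= np.linalg.norm(u)
        if not lo <= u[2] <= hi:
            continue
        p = _ellipsoid_point(u, semi)
        if np.min(np.linalg.norm(electrodes - p, axis=1)) < clearance:
            continue
        if out and np.min(np.linalg.norm(np.asarray(out) - p, axis=1)) < min_sep:
            continue
        out.append(p)
    return np.asarray(out).reshape(-1, 3)


def _sample_nuisance(
    electrodes: np.ndarray,
    params: PhantomParams,
    rng: np.random.Generator,
) -> np.ndarray:
    """Nose-bridge / brow / nape ridge features low on the head."""
    return _sample_band_features(
        electrodes, params.n_nuisance, params.nuisance_zband, 0.025, 0.014,
        params.ellipsoid_semiaxes, rng,
    )


def _sample_collar(
    electrodes: np.ndarray,
    params: PhantomParams,
    rng: np.random.Generator,
) -> np.ndarray:
    """Hairline/neck-muscle fold mounds ringing the base of the head in
    regular rows below the cap rim, skipping spots near electrodes."""
    semi = np.asarray(params.ellipsoid_semiaxes, float)
    out = []
    for zrow in params.collar_rows:
        ring_r = np.sqrt(1 - zrow**2) * np.mean(semi[:2])
        n = max(4, int(round(2 * np.pi * ring_r / params.collar_step)))
        phase = rng.uniform(0, 2 * np.pi)
        for k in range(n):
            phi = phase + 2 * np.pi * k / n
            u = np.array([np.cos(phi) * np.sqrt(1 - zrow**2),
                          np.sin(phi) * np.sqrt(1 - zrow**2), zrow])
            p = _ellipsoid_point(u, semi)
            if np.min(np.linalg.norm(electrodes - p, axis=1)) < params.collar_clearance:
                continue
            out.append(p)
    return np.asarray(out).reshape(-1, 3)


def _sample_ear_ridges(
    params: PhantomParams,
    rng: np.random.Generator,
    electrodes: np.ndarray | None = None,
) -> np.ndarray:
    """Fold centers of the two pinnae: dense clumps of sharp ridges in
    mirrored lateral patches just below the cap rim.  Ears are the
    dominant non-electrode curvature structure on a real scalp surface
    and the classic source of spurious detections."""
    if not params.with_ears:
        return np.empty((0, 3))
    semi = np.asarray(params.ellipsoid_semiaxes, float)
    zc = params.ear_center_z
    centers = []
    for side in (1.0, -1.0):
        c = np.array([0.0, side * np.sqrt(1 - zc**2), zc])
        placed, attempts = [], 0
        while len(placed) < params.n_ear_ridges and attempts < 5000:
            attempts += 1
            u = c + rng.normal(0.0, params.ear_spread / 2.0, 3)
            u /= np.linalg.norm(u)
            if u[2] < 0.0:  # keep folds near or above the search plane
                u[2] = -u[2] * 0.3
                u /= np.linalg.norm(u)
            if u[2] > 0.18:  # pinna stays below the cap rim
                continue
            p = _ellipsoid_point(u, semi)
            if electrodes is not None and np.min(
                np.linalg.norm(electrodes - p, axis=1)
            ) < 0.022:
                continue
            # folds are distinct ridges, not piled on top of each other
            if placed and np.min(
                np.linalg.norm(np.asarray(placed) - p, axis=1)
            ) < 0.009:
                continue
            placed.append(p)
        centers.extend(placed)
    return np.asarray(centers)


def _add_ridges(
    mesh: TriangleMesh,
    centers: np.ndarray,
    amplitude: float,
    scale: float,
    semiaxes,
) -> TriangleMesh:
    """Raise Gaussian ridge features (no apex snapping) on the surface."""
    if len(centers) == 0 or amplitude <= 0:
        return mesh
    semi = np.asarray(semiaxes, float)
    verts = mesh.vertices.copy()
    normals = verts / semi**2
    normals /= np.linalg.norm(normals, axis=1, keepdims=True)
    disp = np.zeros(len(verts))
    s2 = 2.0 * scale**2
    tree = cKDTree(verts)
    for c in centers:
        idx = tree.query_ball_point(c, 3.5 * scale)
        if not idx:
            continue
        idx = np.asarray(idx)
        d2 = np.sum((verts[idx] - c) ** 2, axis=1)
        disp[idx] += amplitude * np.exp(-d2 / s2)
    return TriangleMesh(verts + disp[:, None] * normals, mesh.faces, frame=mesh.frame)


def make_phantom(
    montage: MontageSpec | None = None,
    params: PhantomParams | None = None,
    seed: int | None = None,
    with_mesh: bool = True,
) -> PhantomTruth:
    """One synthetic subject.

    Ground-truth electrode coordinates are the bump apices
    (surface site + bump_height * outward normal), matching what the
    localization stage should recover.
    """
    montage = montage or load_montage()
    params = params or PhantomParams()
    if seed is not None:
        params = replace(params, seed=seed)
    root = np.random.SeedSequence(params.seed)
    r_mesh, r_sites, r_dummy, r_nuis = (
        np.random.default_rng(s) for s in root.spawn(4)
    )

    sites = place_montage(montage, params, r_sites)
    heights = _site_heights(sites.labels, params)
    dummies = _sample_dummies(sites.points, params, r_dummy)
    nuisance = _sample_nuisance(sites.points, params, r_nuis)
    semi = np.asarray(params.ellipsoid_semiaxes, float)
    apices = np.array(
        [p + h * _ellipsoid_normal(p, semi) for p, h in zip(sites.points, heights)]
    )
    truth = ElectrodeSet(apices, list(sites.labels), frame="scs")

    mesh = None
    if with_mesh:
        mesh = make_head_mesh(params, r_mesh)
        ears = _sample_ear_ridges(params, r_nuis, sites.points)
        mesh = _add_ridges(
            mesh, ears, params.ear_ridge_amplitude, params.ear_ridge_scale,
            params.ellipsoid_semiaxes,
        )
        collar = _sample_collar(sites.points, params, r_nuis)
        mesh = _add_ridges(
            mesh, collar, params.collar_amplitude, params.collar_scale,
            params.ellipsoid_semiaxes,
        )
        mesh = _add_ridges(
            mesh, nuisance, params.nuisance_amplitude, params.nuisance_scale,
            params.ellipsoid_semiaxes,
        )
        centers = np.vstack([sites.points, dummies]) if len(dummies) else sites.points
        all_h = np.concatenate([heights, np.full(len(dummies), params.bump_height)])
        mesh = add_electrode_bumps(mesh, centers, params, all_h)
    return PhantomTruth(mesh, truth, dummies, params)


def make_cohort(
    n_subjects: int,
    montage: MontageSpec | None = None,
    params: PhantomParams | None = None,
    seed: int = 0,
    with_mesh: bool = True,
) -> list:
    """Independent subjects with per-subject semiaxis scatter and jitter."""
    if n_subjects < 1:
        raise ValueError("need at least one subject")
    montage = montage or load_montage()
    params = params or PhantomParams()
    subjects = []
    root = np.random.SeedSequence(seed)
    for ss in root.spawn(n_subjects):
        sub_seed = int(ss.generate_state(1)[0] % (2**31 - 1))
        scatter_rng = np.random.default_rng(sub_seed)
        s = params.semiaxis_scatter
        axes = tuple(
            float(a * scatter_rng.uniform(1 - s, 1 + s))
            for a in params.ellipsoid_semiaxes
        )
        p = replace(params, ellipsoid_semiaxes=axes, seed=sub_seed)
        subjects.append(make_phantom(montage, p, with_mesh=with_mesh))
    return subjects
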