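"""Mesh and electrode-table IO plus the subject coordinate system (SCS).

Everything downstream works in meters in a fiducial-based SCS:
origin at the midpoint of the preauricular points, +x through the
nasion projection (anterior), +y toward the left preauricular point,
+z superior.  Restricting electrode search to z > 0 in this frame
excludes nose, cheeks and lips.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import trimesh


class FormatError(ValueError):
    """A file failed to parse under the named dialect."""


class GeometryError(ValueError):
    """Geometric precondition violated (degenerate faces, collinear fiducials...)."""


MESH_DIALECTS = ("ply", "off", "stl", "freesurfer")
ELECTRODE_DIALECTS = ("sfp", "elc", "bids_tsv")


@dataclass
class TriangleMesh:
    """Closed triangulated scalp surface.

    vertices : (N, 3) float array, meters
    faces    : (M, 3) int array of vertex indices
    frame    : "scs" once fiducial-aligned, else "unknown"
    """

    vertices: np.ndarray
    faces: np.ndarray
    frame: str = "unknown"

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise GeometryError("vertices must be an (N, 3) array")
        if self.vertices.shape[0] < 4:
            raise GeometryError("a closed mesh needs at least 4 vertices")
        if not np.all(np.isfinite(self.vertices)):
            raise GeometryError("non-finite vertex coordinates")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise GeometryError("faces must be an (M, 3) array")
        n = self.vertices.shape[0]
        bad = np.nonzero((self.faces < 0) | (self.faces >= n))[0]
        if bad.size:
            raise GeometryError(
                f"face {bad[0]} references vertex index outside [0, {n})"
            )
        degen = np.nonzero(
            (self.faces[:, 0] == self.faces[:, 1])
            | (self.faces[:, 1] == self.faces[:, 2])
            | (self.faces[:, 0] == self.faces[:, 2])
        )[0]
        if degen.size:
            raise GeometryError(f"face {degen[0]} repeats a vertex (degenerate)")

    @property
    def n_vertices(self) -> int:
        return self.vertices.shape[0]

    @property
    def n_faces(self) -> int:
        return self.faces.shape[0]

    def to_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(self.vertices.copy(), self.faces.copy(), process=False)


@dataclass
class FiducialTriplet:
    """Nasion and left/right preauricular points, meters."""

    nasion: np.ndarray
    left_preauricular: np.ndarray
    right_preauricular: np.ndarray

    def __post_init__(self):
        self.nasion = np.asarray(self.nasion, dtype=float).reshape(3)
        self.left_preauricular = np.asarray(self.left_preauricular, dtype=float).reshape(3)
        self.right_preauricular = np.asarray(self.right_preauricular, dtype=float).reshape(3)
        v1 = self.left_preauricular - self.nasion
        v2 = self.right_preauricular - self.nasion
        if np.linalg.norm(np.cross(v1, v2)) < 1e-12:
            raise GeometryError("fiducial points are collinear")


@dataclass
class ElectrodeSet:
    """Electrode coordinate table; labels optional (None entries = unlabeled)."""

    points: np.ndarray
    labels: list | None = None
    frame: str = "unknown"

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise GeometryError("points must be an (n, 3) array")
        if self.points.shape[0] < 1:
            raise GeometryError("electrode set is empty")
        if not np.all(np.isfinite(self.points)):
            raise GeometryError("non-finite electrode coordinates")
        if self.labels is not None:
            self.labels = [
                (str(l).upper() if l not in (None, "") else None) for l in self.labels
            ]
            if len(self.labels) != self.points.shape[0]:
                raise GeometryError("labels/points length mismatch")
            named = [l for l in self.labels if l is not None]
            dupes = sorted({l for l in named if named.count(l) > 1})
            if dupes:
                raise FormatError(f"duplicate electrode labels: {', '.join(dupes)}")

    def __len__(self) -> int:
        return self.points.shape[0]


# ---------------------------------------------------------------------------
# meshes


def _infer_mesh_dialect(path: Path) -> str:
    ext = path.suffix.lower().lstrip(".")
    if ext in ("ply", "off", "stl"):
        return ext
    return "freesurfer"


def read_mesh(path, dialect: str | None = None) -> TriangleMesh:
    """Read a triangulated surface; `dialect` in {ply, off, stl, freesurfer}."""
    path = Path(path)
    if dialect is None:
        dialect = _infer_mesh_dialect(path)
    if dialect not in MESH_DIALECTS:
        raise FormatError(f"unknown mesh dialect {dialect!r}")
    if not path.exists():
        raise FormatError(f"{path}: file not found ({dialect})")
    if dialect == "freesurfer":
        try:
            from nibabel.freesurfer import read_geometry

            verts, faces = read_geometry(str(path))
        except Exception as exc:  # nibabel raises assorted types
            raise FormatError(f"{path}: not a FreeSurfer surface ({exc})") from exc
        # FreeSurfer surfaces are in millimeters
        return TriangleMesh(np.asarray(verts, float) / 1000.0, faces)
    try:
        tm = trimesh.load_mesh(str(path), file_type=dialect, process=False)
    except Exception as exc:
        raise FormatError(f"{path}: failed to parse as {dialect} ({exc})") from exc
    if not isinstance(tm, trimesh.Trimesh) or tm.faces.size == 0:
        raise FormatError(f"{path}: no triangle data found ({dialect})")
    return TriangleMesh(np.asarray(tm.vertices, float), np.asarray(tm.faces))


def write_mesh(mesh: TriangleMesh, path, dialect: str | None = None) -> None:
    path = Path(path)
    if dialect is None:
        dialect = _infer_mesh_dialect(path)
    if dialect == "freesurfer":
        from nibabel.freesurfer import write_geometry

        write_geometry(str(path), mesh.vertices * 1000.0, mesh.faces)
        return
    mesh.to_trimesh().export(str(path), file_type=dialect)


# ---------------------------------------------------------------------------
# subject coordinate system


def scs_transform(fiducials: FiducialTriplet) -> tuple[np.ndarray, np.ndarray]:
    """Rotation (rows = SCS axes) and origin of the fiducial frame."""
    origin = 0.5 * (fiducials.left_preauricular + fiducials.right_preauricular)
    ex = fiducials.nasion - origin
    nx = np.linalg.norm(ex)
    if nx < 1e-12:
        raise GeometryError("nasion coincides with preauricular midpoint")
    ex = ex / nx
    ey0 = fiducials.left_preauricular - origin
    ez = np.cross(ex, ey0)
    nz = np.linalg.norm(ez)
    if nz < 1e-12:
        raise GeometryError("fiducial points are collinear")
    ez = ez / nz
    ey = np.cross(ez, ex)
    rot = np.vstack([ex, ey, ez])
    return rot, origin


def to_scs(obj, fiducials: FiducialTriplet):
    """Rigidly map a TriangleMesh or ElectrodeSet into the SCS frame."""
    rot, origin = scs_transform(fiducials)
    if isinstance(obj, TriangleMesh):
        return TriangleMesh((obj.vertices - origin) @ rot.T, obj.faces, frame="scs")
    if isinstance(obj, ElectrodeSet):
        return replace(obj, points=(obj.points - origin) @ rot.T, frame="scs")
    raise TypeError(f"cannot transform object of type {type(obj).__name__}")


# ---------------------------------------------------------------------------
# electrode tables


def _infer_electrode_dialect(path: Path) -> str:
    ext = path.suffix.lower().lstrip(".")
    if ext == "sfp":
        return "sfp"
    if ext == "elc":
        return "elc"
    if ext in ("tsv", "txt"):
        return "bids_tsv"
    raise FormatError(f"cannot infer electrode dialect from {path.name!r}")


def read_electrodes(path, dialect: str | None = None, unit: str | None = None) -> ElectrodeSet:
    """Read electrodes from .sfp / .elc / BIDS electrodes.tsv.

    sfp and bids_tsv are assumed to be in meters unless `unit` overrides;
    elc honors its embedded UnitPosition line.
    """
    path = Path(path)
    if dialect is None:
        dialect = _infer_electrode_dialect(path)
    if dialect not in ELECTRODE_DIALECTS:
        raise FormatError(f"unknown electrode dialect {dialect!r}")
    if not path.exists():
        raise FormatError(f"{path}: file not found ({dialect})")
    if dialect == "sfp":
        return _read_sfp(path, unit or "m")
    if dialect == "elc":
        return _read_elc(path, unit)
    return _read_bids_tsv(path, unit or "m")


_UNIT_SCALE = {"m": 1.0, "cm": 0.01, "mm": 0.001}


def _scale(unit: str) -> float:
    try:
        return _UNIT_SCALE[unit.lower()]
    except KeyError:
        raise FormatError(f"unknown unit {unit!r}") from None


def _read_sfp(path: Path, unit: str) -> ElectrodeSet:
    s = _scale(unit)
    labels, pts = [], []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 4:
            raise FormatError(f"{path}:{lineno}: expected 'label x y z'")
        try:
            xyz = [float(v) for v in parts[1:]]
        except ValueError:
            raise FormatError(f"{path}:{lineno}: non-numeric coordinate") from None
        labels.append(parts[0])
        pts.append(xyz)
    if not pts:
        raise FormatError(f"{path}: no electrode rows")
    return ElectrodeSet(np.asarray(pts) * s, labels)


def _read_elc(path: Path, unit: str | None) -> ElectrodeSet:
    lines = path.read_text().splitlines()
    file_unit = None
    pts, labels = [], []
    in_positions = in_labels = False
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        low = line.lower()
        if low.startswith("unitposition"):
            file_unit = line.split()[-1]
            continue
        if low.startswith("numberpositions"):
            continue
        if low.startswith("positions"):
            in_positions, in_labels = True, False
            continue
        if low.startswith("labels"):
            in_positions, in_labels = False, True
            continue
        if in_positions:
            if ":" in line:  # "Fp1 : x y z"
                name, _, rest = line.partition(":")
                vals = rest.split()
                if len(vals) != 3:
                    raise FormatError(f"{path}:{lineno}: expected 3 coordinates")
                labels.append(name.strip())
            else:
                vals = line.split()
                if len(vals) != 3:
                    raise FormatError(f"{path}:{lineno}: expected 3 coordinates")
            try:
                pts.append([float(v) for v in vals])
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-numeric coordinate") from None
        elif in_labels:
            labels.extend(line.split())
    if not pts:
        raise FormatError(f"{path}: no Positions section")
    s = _scale(unit or file_unit or "mm")
    if labels and len(labels) != len(pts):
        raise FormatError(f"{path}: {len(labels)} labels for {len(pts)} positions")
    return ElectrodeSet(np.asarray(pts) * s, labels or None)


def _read_bids_tsv(path: Path, unit: str) -> ElectrodeSet:
    s = _scale(unit)
    try:
        df = pd.read_csv(path, sep="\t")
    except Exception as exc:
        raise FormatError(f"{path}: failed to parse TSV ({exc})") from exc
    cols = {c.lower(): c for c in df.columns}
    missing = [c for c in ("name", "x", "y", "z") if c not in cols]
    if missing:
        raise FormatError(f"{path}: missing column(s) {', '.join(missing)}")
    pts = df[[cols["x"], cols["y"], cols["z"]]].to_numpy(dtype=float) * s
    labels = [str(v) for v in df[cols["name"]]]
    return ElectrodeSet(pts, labels)


def write_electrodes(eset: ElectrodeSet, path, dialect: str | None = None,
                     unit: str = "m") -> None:
    """Write electrodes; unlabeled points get 'E<k>' placeholders with a warning."""
    path = Path(path)
    if dialect is None:
        dialect = _infer_electrode_dialect(path)
    if dialect not in ELECTRODE_DIALECTS:
        raise FormatError(f"unknown electrode dialect {dialect!r}")
    labels = list(eset.labels) if eset.labels is not None else [None] * len(eset)
    if any(l is None for l in labels):
        warnings.warn("unlabeled electrodes written with E<k> placeholder names")
        labels = [l if l is not None else f"E{i + 1}" for i, l in enumerate(labels)]
    pts = eset.points / _scale(unit)
    if dialect == "sfp":
        rows = [f"{l}\t{p[0]:.9f}\t{p[1]:.9f}\t{p[2]:.9f}" for l, p in zip(labels, pts)]
        path.write_text("\n".join(rows) + "\n")
    elif dialect == "elc":
        lines = [
            "# ASA electrode file",
            f"UnitPosition\t{unit}",
            f"NumberPositions=\t{len(eset)}",
            "Positions",
        ]
        lines += [f"{l}:\t{p[0]:.9f} {p[1]:.9f} {p[2]:.9f}" for l, p in zip(labels, pts)]
        path.write_text("\n".join(lines) + "\n")
    else:
        df = pd.DataFrame(
            {"name": labels, "x": pts[:, 0], "y": pts[:, 1], "z": pts[:, 2]}
        )
        df.to_csv(path, sep="\t", index=False, float_format="%.9f")
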