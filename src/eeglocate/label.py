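"""Distance-profile electrode labeling.

Each electrode's fingerprint is its *distance profile*: the vector of
Euclidean distances to every other electrode of the set, sorted in
descending order.  Profiles are invariant to rigid motion, so a labeled
template set from a different head can be compared to an unlabeled set
via Pearson correlation of profiles.  Each template electrode hands its
label to the best-correlated unlabeled electrode; with several templates
the proposals are tallied and the plurality label wins (ties go to the
earlier label in the montage's sequential order).  Electrodes that no
template electrode picked stay unlabeled — adding templates fills these
gaps, which is the main benefit of the voting scheme.

Profiles cannot tell left from right on a near-symmetric head, so after
voting the electrodes labeled FPZ and OZ define a midsagittal plane and
every symmetric-pair label is flipped to the member matching the
electrode's actual hemisphere.  When three or more electrodes end up
sharing a label the conflict is unresolvable and they stay unlabeled.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

from .formats import ElectrodeSet, GeometryError


class LabelingError(RuntimeError):
    pass


class MidplaneUndefinedError(LabelingError):
    """FPZ or OZ missing or duplicated: the symmetry step cannot run."""


# ---------------------------------------------------------------------------
# montage specification


@dataclass
class MontageSpec:
    """Ordered label sequence plus midline/symmetric-pair structure.

    `canonical_directions` (unit vectors, SCS axes) are optional; the
    phantom generator uses them to place ground-truth electrodes.
    """

    ordered_labels: list
    midline_labels: list
    symmetric_pairs: list
    anterior_midline: str = "FPZ"
    posterior_midline: str = "OZ"
    canonical_directions: dict | None = None
    name: str = "custom"

    def __post_init__(self):
        self.ordered_labels = [str(l).upper() for l in self.ordered_labels]
        self.midline_labels = [str(l).upper() for l in self.midline_labels]
        self.symmetric_pairs = [
            (str(a).upper(), str(b).upper()) for a, b in self.symmetric_pairs
        ]
        self.anterior_midline = self.anterior_midline.upper()
        self.posterior_midline = self.posterior_midline.upper()
        order = set(self.ordered_labels)
        if len(order) != len(self.ordered_labels):
            raise ValueError("ordered_labels contains duplicates")
        paired = [l for pair in self.symmetric_pairs for l in pair]
        if len(set(paired)) != len(paired):
            raise ValueError("a label appears in more than one symmetric pair")
        if set(paired) & set(self.midline_labels):
            raise ValueError("symmetric-pair labels overlap midline labels")
        for l in paired + self.midline_labels:
            if l not in order:
                raise ValueError(f"label {l} not in ordered_labels")
        for l in (self.anterior_midline, self.posterior_midline):
            if l not in self.midline_labels:
                raise ValueError(f"{l} must be a midline label")
        if self.canonical_directions is not None:
            self.canonical_directions = {
                str(k).upper(): np.asarray(v, dtype=float).reshape(3)
                for k, v in self.canonical_directions.items()
            }
        self._rank = {l: i for i, l in enumerate(self.ordered_labels)}
        self._partner = {}
        self._is_left = {}
        for left, right in self.symmetric_pairs:
            self._partner[left] = right
            self._partner[right] = left
            self._is_left[left] = True
            self._is_left[right] = False

    def __len__(self) -> int:
        return len(self.ordered_labels)

    def rank(self, label: str) -> int:
        """Position in the sequential order (vote tie-break key)."""
        return self._rank[label]

    def partner(self, label: str):
        return self._partner.get(label)

    def pair_member_for_side(self, label: str, left: bool) -> str:
        """The member of `label`'s pair lying on the requested hemisphere."""
        if label not in self._partner:
            return label
        if self._is_left[label] == left:
            return label
        return self._partner[label]


def load_montage(path=None) -> MontageSpec:
    """Load a montage JSON; default is the packaged 64-channel cap."""
    if path is None:
        text = resources.files("eeglocate.data").joinpath("quikcap64.json").read_text()
    else:
        text = Path(path).read_text()
    cfg = json.loads(text)
    return MontageSpec(
        ordered_labels=cfg["ordered_labels"],
        midline_labels=cfg["midline_labels"],
        symmetric_pairs=[tuple(p) for p in cfg["symmetric_pairs"]],
        anterior_midline=cfg.get("anterior_midline", "FPZ"),
        posterior_midline=cfg.get("posterior_midline", "OZ"),
        canonical_directions=cfg.get("canonical_directions"),
        name=cfg.get("name", "custom"),
    )


# ---------------------------------------------------------------------------
# distance profiles


@dataclass
class DistanceProfile:
    values: np.ndarray          # (n-1,) descending distances, meters
    owner_index: int


def distance_profile(points: np.ndarray, i: int) -> DistanceProfile:
    """Descending-sorted distances from point `i` to all other points."""
    points = np.asarray(points, dtype=float)
    n = points.shape[0]
    if n < 2:
        raise GeometryError("need at least two points for a distance profile")
    d = np.linalg.norm(points - points[i], axis=1)
    d = np.delete(d, i)
    if np.any(d <= 0):
        j = int(np.nonzero(np.linalg.norm(points - points[i], axis=1) <= 0)[0][-1])
        raise GeometryError(f"points {i} and {j} coincide")
    return DistanceProfile(np.sort(d)[::-1], i)


def profile_matrix(points: np.ndarray) -> np.ndarray:
    """All n profiles as an (n, n-1) matrix of descending distances."""
    points = np.asarray(points, dtype=float)
    n = points.shape[0]
    diff = points[:, None, :] - points[None, :, :]
    d = np.linalg.norm(diff, axis=2)
    off = d[~np.eye(n, dtype=bool)].reshape(n, n - 1)
    if np.any(off <= 0):
        i, j = np.argwhere((d <= 0) & ~np.eye(n, dtype=bool))[0]
        raise GeometryError(f"points {i} and {j} coincide")
    return -np.sort(-off, axis=1)


def _standardize_rows(m: np.ndarray) -> np.ndarray:
    """Rows centered and scaled to unit norm; zero-variance rows -> 0."""
    c = m - m.mean(axis=1, keepdims=True)
    norm = np.linalg.norm(c, axis=1, keepdims=True)
    zero = norm.ravel() < 1e-15
    if np.any(zero):
        warnings.warn("zero-variance distance profile; correlation set to 0")
        norm[zero[:, None] if norm.ndim == 2 else zero] = 1.0
    out = c / np.maximum(norm, 1e-300)
    out[zero] = 0.0
    return out


def profile_correlation(a: DistanceProfile, b: DistanceProfile) -> float:
    """Pearson correlation of two sorted distance profiles."""
    if a.values.shape != b.values.shape:
        raise LabelingError(
            f"profile length mismatch: {a.values.size} vs {b.values.size}"
        )
    sa = _standardize_rows(a.values[None, :])[0]
    sb = _standardize_rows(b.values[None, :])[0]
    return float(np.clip(sa @ sb, -1.0, 1.0))


def correlation_matrix(unlabeled_points: np.ndarray, template_points: np.ndarray) -> np.ndarray:
    """r[i, t] = Pearson correlation between unlabeled profile i and
    template profile t; both sets must have the same electrode count."""
    u = np.asarray(unlabeled_points, float)
    t = np.asarray(template_points, float)
    if u.shape[0] != t.shape[0]:
        raise LabelingError(
            f"profile length mismatch: sets have {u.shape[0]} and {t.shape[0]} electrodes"
        )
    su = _standardize_rows(profile_matrix(u))
    st = _standardize_rows(profile_matrix(t))
    return np.clip(su @ st.T, -1.0, 1.0)


# ---------------------------------------------------------------------------
# single-template matching


def template_proposals(
    unlabeled: ElectrodeSet, template: ElectrodeSet
) -> tuple[list, np.ndarray]:
    """Label proposals one template makes, as a list of label-lists.

    Each *template* electrode gives its label to the unlabeled electrode
    whose distance profile correlates best with its own.  An unlabeled
    electrode can therefore receive several labels (near-twin template
    profiles picking the same electrode) or none at all — electrodes
    that no template electrode picks are the main source of unlabeled
    outcomes with few templates.

    Returns (proposals, best_r): `proposals[i]` is the list of labels
    electrode i received, `best_r[i]` its best profile correlation
    against any template electrode.
    """
    if template.labels is None or any(l is None for l in template.labels):
        raise LabelingError("template must be fully labeled")
    r = correlation_matrix(unlabeled.points, template.points)
    proposals = proposals_from_correlation(r, template.labels)
    return proposals, r.max(axis=1)


def proposals_from_correlation(r: np.ndarray, template_labels: list) -> list:
    """Distribute template labels over unlabeled electrodes given the
    profile-correlation matrix r[unlabeled, template].

    Each template electrode picks its best-correlated electrode; on an
    exact tie (mirror-symmetric geometry) it prefers an electrode this
    template has not proposed to yet, so degenerate twins spread over
    the tied electrodes instead of piling onto one."""
    proposals = [[] for _ in range(r.shape[0])]
    taken = set()
    for t in range(r.shape[1]):
        col = r[:, t]
        tied = np.nonzero(col >= col.max() - 1e-12)[0]
        free = [u for u in tied if u not in taken]
        u = int(free[0] if free else tied[0])
        taken.add(u)
        proposals[u].append(template_labels[t])
    return proposals


def match_single_template(
    unlabeled: ElectrodeSet, template: ElectrodeSet, montage: MontageSpec
) -> tuple[list, np.ndarray]:
    """Per-electrode proposed label (or None) from a single template.

    Wraps :func:`template_proposals`; when an electrode received more
    than one label the one earliest in the montage's sequential order is
    kept, and electrodes that received none stay unproposed.
    """
    props, best = template_proposals(unlabeled, template)
    out = [min(p, key=montage.rank) if p else None for p in props]
    return out, best


# ---------------------------------------------------------------------------
# midplane and symmetry resolution


@dataclass
class Midplane:
    point: np.ndarray
    normal: np.ndarray  # unit, points toward subject's left

    def side(self, p: np.ndarray) -> int:
        """+1 left of the plane, -1 right, 0 on it."""
        return int(np.sign(self.signed_distance(p)))

    def signed_distance(self, p: np.ndarray) -> float:
        return float(np.dot(np.asarray(p, float) - self.point, self.normal))


def define_midplane(
    assigned: list, points: np.ndarray, montage: MontageSpec
) -> Midplane:
    """Midsagittal plane through the electrodes labeled FPZ and OZ.

    Normal is the unit vector along (OZ - FPZ) x z-hat, which points to
    the subject's left (+y) in SCS.  Raises MidplaneUndefinedError if
    either anchor is missing or duplicated.
    """
    points = np.asarray(points, float)
    for name, lab in (("anterior", montage.anterior_midline),
                      ("posterior", montage.posterior_midline)):
        count = sum(1 for a in assigned if a == lab)
        if count != 1:
            raise MidplaneUndefinedError(
                f"midplane undefined: {name} anchor {lab} assigned {count} times"
            )
    fpz = points[assigned.index(montage.anterior_midline)]
    oz = points[assigned.index(montage.posterior_midline)]
    axis = oz - fpz
    normal = np.cross(axis, [0.0, 0.0, 1.0])
    nn = np.linalg.norm(normal)
    if nn < 1e-12:
        raise MidplaneUndefinedError("midplane undefined: FPZ-OZ axis is vertical")
    return Midplane(fpz.copy(), normal / nn)


def resolve_symmetry(
    proposals: list,
    points: np.ndarray,
    midplane: Midplane,
    montage: MontageSpec,
    duplicate_unlabel_threshold: int = 3,
) -> tuple[list, dict]:
    """Flip symmetric-pair labels to match each electrode's hemisphere.

    1. every electrode carrying a paired label is re-labeled to the pair
       member on its side of the midplane (midline labels never move);
    2. if two electrodes then share a label, the pair is split one per
       side by signed distance (leftmost gets the left member);
    3. groups of >= `duplicate_unlabel_threshold` electrodes sharing a
       label become unlabeled (reason ``triple_duplicate``), as do any
       duplicates that survive to the end (``no_majority_conflict``).

    Returns (labels-with-None, {index: reason}).
    """
    points = np.asarray(points, float)
    out = list(proposals)
    unresolved: dict = {}
    sides = np.array([midplane.signed_distance(p) for p in points])

    # a label carried by >= threshold electrodes is an unresolvable clash
    by_label: dict = {}
    for i, lab in enumerate(out):
        if lab is not None:
            by_label.setdefault(lab, []).append(i)
    for lab, idx in by_label.items():
        if len(idx) >= duplicate_unlabel_threshold:
            for i in idx:
                out[i] = None
                unresolved[i] = "triple_duplicate"

    # each symmetric pair is assigned jointly, so corrections cannot
    # cascade into neighboring labels
    for left_lab, right_lab in montage.symmetric_pairs:
        claimants = [i for i, lab in enumerate(out) if lab in (left_lab, right_lab)]
        if len(claimants) == 1:
            i = claimants[0]
            if sides[i] > 0:
                out[i] = left_lab
            elif sides[i] < 0:
                out[i] = right_lab
        elif len(claimants) == 2:
            a, b = sorted(claimants, key=lambda i: -sides[i])
            out[a] = left_lab   # more toward the subject's left
            out[b] = right_lab
        elif len(claimants) > 2:
            # three or more electrodes claiming a two-member pair
            for i in claimants:
                out[i] = None
                unresolved[i] = "no_majority_conflict"

    # duplicated midline labels have no side information to split them
    for lab in montage.midline_labels:
        idx = [i for i, l in enumerate(out) if l == lab]
        if len(idx) > 1:
            for i in idx:
                out[i] = None
                unresolved[i] = "no_majority_conflict"
    return out, unresolved


# ---------------------------------------------------------------------------
# multi-template voting


@dataclass
class LabelingResult:
    """Final assignment plus the evidence that produced it."""

    assigned: list                   # n entries, label or None
    votes: list                      # n dicts label -> count
    correlations: np.ndarray         # (n_templates, n) best r per template
    unresolved: dict                 # index -> reason code

    def __post_init__(self):
        named = [l for l in self.assigned if l is not None]
        assert len(named) == len(set(named)), "duplicate labels in final assignment"


def vote_labels(
    unlabeled: ElectrodeSet,
    templates: list,
    montage: MontageSpec,
    duplicate_unlabel_threshold: int = 3,
) -> LabelingResult:
    """Label `unlabeled` by plurality vote over per-template proposals,
    then run midplane symmetry resolution once on the winners."""
    if not templates:
        raise LabelingError("at least one template is required")
    n = len(unlabeled)
    all_props, all_best = [], []
    for tmpl in templates:
        props, best = template_proposals(unlabeled, tmpl)
        all_props.append(props)
        all_best.append(best)
    votes = []
    winners = []
    for i in range(n):
        tally: dict = {}
        for props in all_props:
            for lab in props[i]:
                tally[lab] = tally.get(lab, 0) + 1
        votes.append(tally)
        if tally:
            top = max(tally.values())
            cands = [l for l, c in tally.items() if c == top]
            winners.append(min(cands, key=montage.rank))
        else:
            winners.append(None)
    midplane = define_midplane(winners, unlabeled.points, montage)
    assigned, unresolved = resolve_symmetry(
        winners, unlabeled.points, midplane, montage, duplicate_unlabel_threshold
    )
    for i in range(n):
        if assigned[i] is None and i not in unresolved:
            unresolved[i] = "never_proposed"
    return LabelingResult(assigned, votes, np.asarray(all_best), unresolved)
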