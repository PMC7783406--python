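# Methods

## Coordinate convention

All geometry lives in a fiducial-based subject coordinate system (SCS):
origin at the midpoint of the left/right preauricular points, +x through
the projection of the nasion (anterior), +y toward the left preauricular
point, +z superior. `to_scs` builds this frame from a fiducial triplet as
a rigid transform (pairwise distances preserved to better than 1e-9 m).
Restricting the electrode search to z > 0 in this frame excludes the
nose, cheeks and lips, at the cost of anything at or below the ear line
(mastoids on a real head sit near or below the plane, which is one
reason low electrodes are the hardest to detect in practice).

## Curvature

The detection signal is a per-vertex curvature scalar.

* `mean_cotan` (default): discrete mean curvature from the cotangent
  Laplacian, H_i = |(L x)_i| / (2 A_i) with Meyer-style mixed Voronoi
  vertex areas, signed so that convex-with-respect-to-the-outward-normal
  is positive. Units 1/m. Face orientation is normalized to outward
  before evaluation, so the sign does not depend on the input winding.
  On an icosphere of radius 0.1 m the estimator reproduces the closed
  form H = 1/R = 10 /m to well under 1% per vertex. Signed convexity is
  the right signal here: electrode bumps are convex, while concave
  features (ear creases, the skirt around a gel mound) get negative
  values and can never compete for the top-K cut.
* `angle_deficit`: 2π minus the sum of incident triangle angles
  (integrated Gaussian curvature, radians), computed via trimesh.
  Cheaper and parameter-free; kept as a fallback. Its total over any
  closed genus-0 mesh is 4π (Gauss–Bonnet), which the tests use as an
  exactness check.

Boundary vertices of a non-closed mesh get a −inf sentinel so they are
never selected; non-manifold edges and zero-area triangles are rejected
with the offending element identified.

## Localization

Pipeline on a mesh in SCS: keep vertices with z > z_min (default 0);
take the `top_k` (default 2000) highest-curvature vertices, ties at the
cut broken by ascending vertex index; single-linkage cluster them — the
connected components of the graph joining vertex pairs within
`cluster_radius` (default 1 cm, the electrode diameter); drop clusters
smaller than `min_cluster_size` (default 10); return cluster centroids
(unweighted member means). Single linkage was chosen over complete
linkage because it is parameter-free and order-independent; the O(n²)
union-find transitive closure serves as the test oracle. The candidate
count normally exceeds the montage size — empty electrode holders,
reference/EOG sites and ear/neck anatomy all produce protrusions — and
`prune_candidates` reduces the set to exactly 64 via an explicit,
reproducible keep/drop list in place of an interactive step. A
convenience ranking (largest clusters first) exists but the list is the
interface.

`top_k = 2000` is calibrated to a 64-electrode cap on a ~10k-vertex
scalp: roughly (64 electrodes + ~15 auxiliary sites) × ~25 vertices per
protrusion footprint. It scales with electrode count, head size and
mesh resolution and is exposed in `LocalizeParams` for other systems.

## Distance-profile labeling

An electrode's distance profile is the descending-sorted vector of its
Euclidean distances to the other 63 electrodes; frontal and occipital
electrodes have slowly-decaying profiles, central ones cluster their
distances — a rigid-motion-invariant fingerprint. Matching against a
labeled template compares profiles by Pearson correlation (profiles are
row-standardized once per set, so a 64×64 correlation matrix is one
matrix product). A zero-variance profile, which cannot occur for
generic geometry, correlates as 0 with a warning.

Direction of matching: each *template* electrode hands its label to the
best-correlated unlabeled electrode. Consequences worth being explicit
about, because they drive the whole error structure:

* an unlabeled electrode may receive no label at all (no template
  electrode picked it) — with a single template these collisions are
  the dominant error, and they appear as false negatives;
* an unlabeled electrode may receive several labels (near-twin template
  profiles picking the same electrode);
* with multiple templates all proposals are tallied and the plurality
  label wins; vote ties go to the label earliest in the montage's
  sequential channel order. Additional templates mostly fill in
  electrodes that earlier templates missed, which is why the false
  negative rate collapses as templates are added while false positives
  stay roughly flat.

On an exact correlation tie (possible only for perfectly symmetric
synthetic geometry) a template electrode prefers an unlabeled electrode
it has not proposed to yet, so degenerate left/right twins spread over
the tied pair instead of piling onto one electrode.

### Midplane and symmetry resolution

Left/right partners (C1/C2, FP1/FP2, …) have near-identical profiles on
a near-symmetric head, so after voting the electrodes labeled FPZ and
OZ define a midsagittal plane: normal along (OZ−FPZ) × ẑ, pointing to
the subject's left. If FPZ or OZ is missing or duplicated the run is
aborted (`MidplaneUndefinedError`) and counted as excluded — the same
failure mode the template experiment tracks.

Symmetry resolution runs once, on the voted winners, jointly per
symmetric pair so that corrections cannot cascade across labels:

* one electrode claims the pair → it gets the member on its side of the
  plane (an electrode exactly on the plane keeps its proposal);
* two electrodes claim the pair → the one further toward the subject's
  left gets the left member, the other the right member (this covers
  both "same label, one per side" and "both on one side" cases);
* three or more claimants, or any label carried by
  `duplicate_unlabel_threshold` (default 3) electrodes, are
  unresolvable: all of them become unlabeled. The threshold default
  follows the stricter of the two published phrasings, since a
  two-member pair cannot absorb three electrodes. Duplicated midline
  labels also become unlabeled — there is no side information to split
  them. Midline labels are never flipped.

Final assignments are unique by construction; unlabeled electrodes
carry a reason code (`never_proposed`, `triple_duplicate`,
`no_majority_conflict`).

## The packaged montage

`quikcap64.json` holds the 64-channel cap description: sequential
channel order (FP row to occipital row, left before right, including
mastoids M1/M2 and inion-flanking I1/I2), midline labels, the 28
symmetric pairs, the FPZ/OZ midplane anchors, and one canonical unit
direction per label used by the phantom. The order is a standard
vendor-style channel order (the exact cap sequence is vendor
documentation, and the file is user-overridable). The directions derive
from the standard 10–10 layout, exactly mirror-symmetrized, then
relaxed so every pair of sites is at least 2.35 cm apart on the default
head and the whole montage sits within 75° of the vertex. That metric
spreading is deliberate: with all 64 sites confined to z > 0 on a
phantom head, the literal 10–10 angular layout would put posterior rows
~1.5 cm apart, and the fixed 1 cm clustering radius would merge their
protrusion footprints — on real heads the cap wraps below the fiducial
plane and enjoys ~3 cm spacing. The phantom montage is therefore a
stylized cap, not a metrically faithful 10–10 net.

## The phantom

`make_phantom` builds one synthetic subject; `make_cohort` draws
independent subjects with ±5% per-axis size scatter.

* **Head**: ellipsoid with semiaxes (0.095, 0.075, 0.08) m; the mesh is
  a scalp dome — ~96% of the ~10 000 vertices Fibonacci-sampled above
  z_dir = −0.15, the inferior closure meshed coarsely, triangulated as
  a convex hull (closed, genus 0). This mimics how a hole-filled scalp
  segmentation spends its vertex budget and gives the dome the ~2.4 mm
  vertex spacing at which a 1 cm protrusion contains ~25 vertices; a
  uniformly meshed full ellipsoid at the same budget leaves protrusion
  footprints too sparse for the fixed top-2000 / min-10-vertex
  constants to behave as on real data.
* **Gel mounds**: compact quartic profile h(1 − (d/R)²)² with peak
  h = 3 mm and support R = 1.72 × 5 mm ≈ 8.6 mm — convex footprint out
  to R/√2 ≈ 6 mm, concave skirt beyond, like gel squeezed under an
  electrode disc. The vertex nearest each site is relocated to the
  exact analytic apex, so ground-truth positions (apices) coincide with
  mesh vertices and mirrored pairs stay exactly mirrored at zero
  jitter. A quartic rather than Gaussian profile keeps the
  high-curvature footprint hard-bounded, so neighboring footprints
  cannot chain through the 1 cm single-linkage radius.
* **Cap-placement jitter**: a smooth random warp of the site directions
  (12 broad tangent Gaussian modes, angular scale 0.7 rad) normalized
  to a per-site standard deviation of `angular_jitter_sd` (default
  0.02 rad ≈ 1.7 mm). A worn cap deviates from nominal mostly by rigid
  shift plus smooth stretch, so neighboring electrodes move together;
  independent per-site jitter would also erode the inter-site spacing
  floor that keeps clusters separable.
* **Nuisance structure**: 15 dummy holders (same mounds, no labels) on
  the cap skirt; two ear patches of sharp ridges; nose-bridge/brow/nape
  ridge features; rows of basal fold mounds below the rim; and
  low-amplitude surface texture. These reproduce the qualitative error
  sources of real scans — spurious candidates near the ears and the
  head base — and keep the top-2000 cut honest.
* **Gel drying**: `posterior_attenuation` scales bump height at
  occipital/temporal/mastoid sites, emulating gel thinning under a
  supine head. Off (1.0) by default.

What the phantom does *not* emulate: MR intensity artifacts, hair-driven
segmentation noise, truly asymmetric head shapes, electrodes below the
fiducial plane, or caps whose geometry differs from the template caps
beyond smooth warps. Detection on the phantom is therefore easier than
on real scans (the synthetic study recovers essentially all 64 sites,
versus ~94% reported on real heads), and labeling accuracy at matched
jitter runs higher than on real data; the *structure* of the results —
monotone gains from template voting, false negatives dominated by
unproposed electrodes, a flat small false-positive floor, occasional
runs excluded for an undefined midplane — is the part that transfers.

## The template experiment

`cohort_experiment` runs the leave-one-out design: each subject in turn
is the unlabeled set; template groups of size 1, 3 and 5 are drawn from
the remaining subjects (all combinations where feasible; k = 5 samples
a seeded random 30% of them, and `n_combos` caps groups per subject —
the acceptance script uses 60). Per-template proposals are cached per
ordered subject pair, so combination counts cost only the voting.
Excluded runs (undefined midplane) are counted and reported alongside
the aggregates. Problem sizes in the acceptance script — 6 meshed
subjects for detection, 26 meshless subjects at ~3 mm jitter for
labeling — keep a full from-scratch run around half a minute.

## Numerical choices

* Correlation ties and vote ties break toward the montage's sequential
  order; top-K curvature ties break toward the lower vertex index. All
  randomness flows from explicit seeds (`numpy` Generators spawned from
  a root SeedSequence), and every CLI artifact embeds the tool version,
  seed and config hash, so identical invocations are byte-identical.
* Greedy distance-ascending candidate/truth matching in the evaluation
  is verified against brute-force optimal assignment on small
  instances; the 5 mm match tolerance is a numeric stand-in for visual
  inspection and is configurable.
* Electrode files: `.sfp` and BIDS `.tsv` are assumed to be in meters
  unless overridden; `.elc` honors its embedded unit line. Labels are
  matched case-insensitively and stored uppercase.
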