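# eeglocate

Localize and label EEG electrodes directly from the scalp surface of a
structural MR head model.

In simultaneous EEG–fMRI, each gel-filled electrode raises a small bump
on the scalp of the T1-weighted scan. `eeglocate` turns those bumps into
a labeled electrode set in two steps, with no digitizer and no special
acquisition sequence:

1. **Localization.** Compute a per-vertex curvature scalar on the scalp
   mesh (signed cotangent-Laplacian mean curvature by default), restrict
   to the fiducial-based search space *z* > 0, keep the 2 000
   highest-curvature vertices, single-linkage cluster them at the
   electrode diameter (1 cm), discard clusters with fewer than 10
   vertices, and report cluster centroids as candidate electrodes.
2. **Labeling.** For each electrode compute its *distance profile* —
   the vector of Euclidean distances to all other electrodes, sorted in
   descending order. Profiles are rigid-motion invariant, so electrodes
   of an unlabeled 64-point set can be matched to labeled template sets
   by Pearson correlation of profiles: each template electrode hands its
   label to the best-correlated unlabeled electrode, several templates
   vote, and the plurality label wins (ties go to the earlier label in
   the cap's channel order). Because left/right twins such as C1/C2 have
   near-identical profiles, the electrodes labeled FPZ and OZ define a
   midsagittal plane and each symmetric-pair label is flipped to the
   member matching the electrode's hemisphere; three or more electrodes
   sharing one label stay unlabeled.

Because study MR scans are rarely shareable, the package also ships a
synthetic **phantom** generator: ellipsoidal scalp domes with quartic
gel mounds at 64 montage sites, dummy holders, ear/nose/neck nuisance
ridges, per-subject shape scatter and cap-placement jitter — enough
structure to exercise and score the whole pipeline against known ground
truth.

## Worked example

```python
import numpy as np
from eeglocate import (
    make_cohort, localize_electrodes, detection_metrics,
    vote_labels, labeling_metrics, load_montage, ElectrodeSet,
)

montage = load_montage()                      # packaged 64-channel cap
cohort = make_cohort(2, seed=1)               # two synthetic subjects

cands = localize_electrodes(cohort[0].mesh)   # curvature -> candidates
det = detection_metrics(cands, cohort[0].electrodes, tolerance=0.005)
print(f"detected {det.n_detected}/64 electrodes, {det.n_extra} extras")

unlabeled = ElectrodeSet(cohort[0].electrodes.points, None)
res = vote_labels(unlabeled, [cohort[1].electrodes], montage)
rep = labeling_metrics(res, cohort[0].electrodes.labels)
print(f"TP {rep.tp_pct:.1f}%  FP {rep.fp_pct:.1f}%  FN {rep.fn_pct:.1f}%")
```

prints

```
detected 64/64 electrodes, 7 extras
TP 81.2%  FP 0.0%  FN 18.8%
```

All 64 planted electrodes are recovered (the 7 extra candidates come
from dummy holders and ear/neck anatomy and would be pruned before
labeling), and a single template from a different synthetic head labels
52 of 64 electrodes correctly; the 12 unlabeled ones are electrodes no
template electrode claimed plus unresolvable label clashes — adding
templates fills most of these in.

The same steps are available from the shell:

```sh
eeglocate simulate --subjects 2 --seed 1 --out-dir work/
eeglocate localize --mesh work/sub-01_scalp.ply --out work/cand.tsv
eeglocate label --electrodes work/sub-01_electrodes.tsv \
    --template work/sub-02_electrodes.tsv \
    --out work/labeled.sfp --report work/report.json
eeglocate evaluate --pred work/labeled.sfp \
    --truth work/sub-01_electrodes.tsv --report work/eval.json
eeglocate experiment --subjects 26 --templates 1,3,5 --combos 60 \
    --seed 1 --out work/experiment.tsv
```

Meshes are read/written as PLY/OFF/STL/FreeSurfer surfaces; electrode
tables as BESA `.sfp`, ASA `.elc`, or BIDS `electrodes.tsv`.

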