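# facescreen

Markerless screening of Parkinson disease (PD) from short smile videos.

Hypomimia — the "masked face" of PD — shows up in 2-D video as a reduced
smile amplitude, asymmetric mouth-corner motion, and flattened fine texture
around the eyes and mouth.  `facescreen` implements the full classical
pipeline that turns a poker-face→smile frame sequence with 68-point iBUG
landmarks into a screening score, for researchers studying facial
biomarkers of PD and for anyone who needs a fully testable reference
implementation of this class of pipeline:

1. **Normalization** — each face is mapped to a canonical 256×256 frame by
   the exact similarity transform that places both eye centers on fixed
   anchors.
2. **Geometric features** — each mouth corner p48/p54 forms a
   *characteristic triangle* with the lip centers p51/p57; with θ the
   corner angle, the main feature is Δθ = θ(apex) − θ(neutral), the change
   between the poker-face frame and the smile apex.  Signed deviation
   angles of the mouth axis and of each corner capture asymmetry.
3. **Texture features** — HOG (9 unsigned bins, 8-px cells, 2×2 blocks,
   L2-Hys) and uniform LBP (P=8, R=1, 59 codes, per-cell L1 histograms)
   over mouth (64×32) and eye (128×32) regions of the normalized face.
4. **Classification** — SVM (RBF), KNN (k=5) and a 100-tree random forest
   on geometric, texture and combined ([geometric | texture], z-scored on
   training rows) feature sets, with stratified subject-level splits.
5. **Evaluation** — ROC curve and AUC (= pairwise concordance, ties
   half-weighted), Youden index J = max(TPR − FPR) with its optimal
   threshold, confusion metrics at that threshold, Pearson correlations
   with clinical covariates (Fisher-z 95% CIs), and the noncentral-F
   sample-size calculation for a between-groups repeated-measures ANOVA.

Because no public cohort of such videos exists, the package includes a
synthetic cohort generator (`facescreen.synthcohort`) producing two-group
cohorts of rendered face sequences with exact ground-truth landmarks,
controllable hypomimia effect sizes and clinical covariates.  All claims in
the test suite are validated against this ground truth; see
`docs/methods.md` for what the generator does and does not emulate.

## Worked example

Run the one-shot pipeline on the default synthetic cohort — 70 patients vs
70 controls, smile-angle effect 1.5 SD, texture contrast halved, 80/60
train/test split:

```
facescreen run --out report/ --seed 0
```

or equivalently from Python:

```python
from facescreen.cli import RunConfig, run_pipeline

bundle = run_pipeline(RunConfig(seed=0))
for key in ("geometric_rf", "texture_rf", "combined_rf"):
    print(key, round(bundle.metrics[key]["auc"], 3))
```

which prints (seed 0):

```
geometric_rf 0.832
texture_rf 0.891
combined_rf 0.918
```

Reading: on the held-out 60 subjects, the mouth-angle features alone reach
AUC 0.83, the eye/mouth texture descriptors 0.89, and their fusion 0.92 —
texture carries more signal than geometry and the combination improves on
both, the qualitative pattern this screening design is built around.  The
full report (`metrics.json`, `roc_points.csv`, `correlations.csv`) adds the
Youden threshold and the accuracy/precision/recall/F-measure at it for all
nine algorithm × feature-set combinations, plus patient-group correlations
between facial features and clinical covariates (null, by construction, in
the default cohort).  Every output embeds the config hash and seed; reruns
are byte-identical.

Other subcommands: `facescreen synth` (write a cohort to disk),
`extract`, `train`, `evaluate`, `correlate`, and

```
facescreen power --f 0.4 --alpha 0.05 --power 0.95 --groups 2 --m 120 --rho 0.5
# total N = 44 (22 per group)
```

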