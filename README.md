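# iridens

Corneal densitometry (CD) measured from Scheimpflug anterior-segment
images is widely used as a transparency biomarker, but it is not a pure
tissue property: reflections from the iris and the corneoscleral
periphery add spurious bright pixels to the image, and lightly pigmented
irises reflect far more than dark ones. `iridens` is a toolkit for
quantifying this pigmentation-induced bias. It is aimed at vision
scientists and ophthalmic-imaging researchers who want reproducible,
scriptable versions of three measurements:

1. **Densitometry and brightness artefacts.** CD is the mean pixel
   intensity (MPI) of the segmented cornea in each grayscale frame. An
   adaptive per-frame threshold

   $$T = \mathrm{MPI}_{\mathrm{cornea}} + 3\,\mathrm{SD}_{\mathrm{cornea}}$$

   flags spurious brightness; the artefact burden of the iris band and
   the lateral corneoscleral flanks is the percentage of their pixels
   strictly above `T`. Per-eye values average over the frame set
   (nominally 25 meridians).

2. **Objective iris pigmentation.** Each color slit-lamp photograph is
   converted to CIELAB (sRGB, D65); the iris ROI is reduced to per-eye
   L\*, a\*, b\* summaries; each component is normalised across the
   cohort with median and interquartile range,
   $X_n = (X - \mathrm{median}\,X)/\mathrm{IQR}\,X$; and the composite

   $$\mathrm{IrisColor} = -L_n + a_n + b_n$$

   scores pigmentation on one continuous, cohort-relative axis:
   negative = light iris, positive = dark iris.

3. **Association statistics.** Pearson correlations and linear
   mixed-effects models with a per-subject random intercept (fellow eyes
   are correlated), a light-vs-dark group comparison, and the headline
   bias summary: the absolute CD difference between light- and dark-iris
   eyes and its size relative to the dark-group mean.

Because no clinical images ship with the package, a first-class
synthetic module generates seeded phantoms (corneal arc + iris band +
flanks with exact planted artefact counts), iris photographs along a
blue-to-brown gradient, and whole cohorts with planted effect sizes, so
every stage is validated against known ground truth.

## Worked example

`examples/03_cohort_association.py` simulates a 47-subject / 91-eye
cohort (39 light, 52 dark eyes) with a planted 3.1 a.u. CD difference
and runs the full statistical layer:

```text
cohort: 47 subjects, 91 eyes (39 light / 52 dark)

associations (pooled Pearson r and mixed-model slope):
         cd ~ pct_iris   r=+0.32  beta=+1.21  p=0.0017
   pct_iris ~ iris_color r=-0.85  beta=-0.41  p=4.5e-54
         cd ~ iris_color r=-0.41  beta=-0.74  p=3.6e-05

light vs dark group comparison (mean +/- SD, LMM p):
            cd: light  50.2+/-2.8  dark  47.1+/-3.0  p=3.2e-06
      pct_iris: light   2.3+/-0.6  dark   1.0+/-0.6  p=4.3e-27
   pct_lateral: light   3.9+/-0.8  dark   3.3+/-0.7  p=0.00015
   pct_overall: light   6.5+/-1.0  dark   4.3+/-1.1  p=3.5e-20

CD bias: 3.1 a.u. = 6.7% relative overestimation in light-iris eyes (planted 3.1 a.u.)
```

Read: CD rises with the iris artefact percentage (positive r and slope),
artefacts fall steeply with darker pigmentation (strong negative r), and
the group comparison recovers the planted ~3 a.u. CD overestimation in
light-iris eyes. `examples/01_phantom_densitometry.py` and
`examples/02_iris_pigmentation.py` show the imaging stages individually.

## Command line

Each pipeline stage is also exposed as a thin CLI:

```bash
iridens simulate --out cohort/ --seed 7          # synthetic cohort + image bundles
iridens segment --in frame.png --out mask.png    # label mask (1=cornea 2=iris 3=lateral)
iridens densitometry --frames DIR/ --masks DIR/ --out eyes.csv
iridens iriscolor --images DIR/ --masks DIR/ --out iriscolor.csv
iridens stats --table study.csv --out results/
```

External masks from any segmentation tool are accepted everywhere the
automatic pipeline runs.

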