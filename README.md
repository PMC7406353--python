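# temporalign

Tools for aligning superior temporal cortices across individuals and
evaluating how well that alignment transfers cytoarchitectonically defined
areas — the machinery behind probabilistic auditory-cortex surface atlases.

The superior temporal plane (Heschl's gyrus and its surroundings, the seat of
auditory cortex) is one of the most anatomically variable regions of the
human brain: the transverse gyrus may be single, incompletely or completely
duplicated, and may merge with the superior temporal gyrus.  Standard
curvature-based surface registration (CBA), driven by the large gyri and
sulci, routinely compromises the alignment of this small but consistent
landmark.  This package implements, end to end:

* **CBA+** — spherical curvature-based registration augmented with smoothed
  indicator maps of four macro-anatomical landmarks (anterior Heschl's gyrus,
  superior temporal gyrus, superior temporal sulcus, middle temporal gyrus)
  added to the matching cost, optimized coarse-to-fine over four spatial
  scales with dynamic group averaging;
* the **rigid** spherical baseline and standard **CBA** it is compared with;
* **probabilistic atlas** construction (per-vertex subject counts for areas
  Te1.0–Te3, STS1/2), normalized overlap histograms, and leave-one-subject-out
  DICE tables;
* the **preprocessing stack**: structure-tensor edge-enhancing diffusion
  filtering of anatomical volumes, joint intensity/gradient-magnitude
  histogram segmentation, marching-cubes surface extraction with an
  Euler-characteristic topology gate, quadric decimation, inflation to the
  unit sphere, and resampling to the standard icosphere (level 7: 163842
  vertices);
* **in-vivo surface maps**: the T1w/T2\*w myelin index with an adaptive
  percentile threshold, and tonotopy estimated by ridge-regression encoding
  of 128-band cochlear-like sound features (best frequency = argmax weight);
* **seeded synthetic data** with stored ground truth for every stage, so the
  whole pipeline runs and is validated without any data download.

## The statistic at the core

For each labeled area $A$ and each left-out subject $s$, the atlas region is
$R_A = \{v : \#\{t \neq s : L_t(v) = A\} \ge k\}$ (default $k = 4$ of 9
training subjects), and alignment quality is the DICE overlap

$$\mathrm{DICE}(R_A, S_A) = \frac{2\,|R_A \cap S_A|}{|R_A| + |S_A|},$$

with $S_A$ the left-out subject's area after transport through the
registration warp.  The registration itself minimizes, per subject,

$$\sum_v \big(c_s(w(v)) - \bar c(v)\big)^2
  \;+\; w_\mathrm{lm}\sum_{\ell}\sum_v \big(m_{s,\ell}(w(v)) - \bar m_\ell(v)\big)^2
  \;+\; \lambda \sum_{(i,j)} \Big(\frac{\|w_i - w_j\| - L_{ij}}{L_{ij}}\Big)^2$$

over per-vertex spherical warps $w$, where $c_s$ is curvature, $m_{s,\ell}$
the landmark maps ($w_\mathrm{lm} = 0$ recovers plain CBA), and the last term
penalizes metric distortion.

## Worked example

Generate a ten-subject synthetic cohort (one template folding pattern,
per-subject smooth deformations plus an along-gyrus slide, labels tied to
the landmark strips) and compare the three alignment methods:

```python
from temporalign import synthdata as sd, pipeline as pl

cohort = sd.make_cohort(sd.CohortSpec(n_subjects=10, level=4, seed=1))
result = pl.run_alignment_comparison(cohort, seed=1)
for m in (result.rigid, result.cba, result.cba_plus):
    print(f"{m.name:6s} curvature r = {m.mean_pairwise_corr:.3f}   "
          f"mean LOO DICE = {m.mean_loo_dice:.3f}   "
          f"Heschl-area DICE = {m.loo_dice.loc[['Te1.0','Te1.1','Te1.2'],'Mean'].mean():.3f}")
```

prints (about two minutes on one CPU):

```
rigid  curvature r = 0.865   mean LOO DICE = 0.313   Heschl-area DICE = 0.242
cba    curvature r = 0.972   mean LOO DICE = 0.507   Heschl-area DICE = 0.460
cba+   curvature r = 0.982   mean LOO DICE = 0.700   Heschl-area DICE = 0.760
```

Reading the numbers: curvature correlation measures macro-anatomical
correspondence after alignment; the leave-one-out DICE measures how well the
group atlas predicts a held-out subject's areas.  Both rise from rigid to
CBA to CBA+, and the gain of CBA+ is largest exactly for the areas on
Heschl's gyrus whose position the global curvature pattern underdetermines —
the landmark prior is what pins them down.

A `temporalign` console script exposes the same stages for shell use
(`temporalign enhance|segment|surf|align|atlas|maps|synth --help`).

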