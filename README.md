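# amrsid

Quantitative 3D analysis of the T2-weighted MR signal intensity distribution
within segmented intervertebral discs (AMRSID: *analysis of MR signal
intensity distribution*).

Early disc changes in scoliosis and spondylolisthesis alter the water content
and structure of the nucleus pulposus (NP) and annulus fibrosus (AF) before
anything is visible to the naked eye on a T2-weighted image. This package
turns a T2-weighted volume plus a region segmentation (IVD / NP / AF, with
cerebrospinal-fluid and cancellous-bone reference samples) into a compact set
of quantitative indices of the 3D intensity distribution, and compares them
across patient groups. It is aimed at researchers studying disc degeneration
biomarkers who already have segmentations and want reproducible first-order
indices and cohort statistics.

## Method

For a segmented region with voxel intensities $I_i$ at world positions
$P_i$, $i = 1 \dots n$:

* **Normalization** — each voxel is weighted by its fraction of the region
  volume ($w_i = 1/n$ on a uniform grid), and intensities are divided by the
  mean intensity of a reference tissue: CSF (constant composition — cancels
  the acquisition gain) or the cancellous bone of the vertebra above (cancels
  the gain and folds in bone health).
* **Histogram indices** — eight volume-weighted descriptive statistics of
  the normalized histogram: standard deviation, standard error
  $\sigma/\sqrt{n}$, median, sum of squared values $\sum_i w_i x_i^2$, 75th
  percentile, maximal bin volume fraction, skewness, and the
  Kolmogorov–Smirnov distance
  $\sup_x |F_w(x) - \Phi((x-\mu)/\sigma)|$ between the weighted empirical
  CDF and the Gaussian fitted to the same data.
* **Center geometry** — the intensity-weighted center
  $W = \sum_i I_i P_i / \sum_i I_i$, the geometric center $G$ (unweighted
  centroid), and their normalized distance $d = \lVert W - G \rVert / N$
  with $N$ the region's voxel count.
* **Volume ratio** — NP voxel count over IVD voxel count.
* **Group statistics** — one-way ANOVA (or Kruskal–Wallis with Dunn's
  post-hoc when Shapiro–Wilk/Levene gates fail) across
  control/scoliosis/spondylolisthesis, and two-way (rank-transform) ANOVA
  for pathology × severity, summarized as a starred significance grid.

A synthetic phantom generator produces ellipsoidal disc volumes with a
bright NP core, dark AF shell, reference-tissue blocks, controllable NP
displacement, degeneration, gain and noise, so the entire pipeline is
testable without patient data.

## Worked example

```python
from amrsid import PhantomSpec, generate_phantom, disc_indices

vol, mask = generate_phantom(PhantomSpec(seed=11, np_offset=(2.0, 0, 0),
                                         degeneration=0.3))
df = disc_indices(vol, mask, subject_id="demo")
print(df[["region", "normalization", "std", "median", "p75", "skewness",
          "ks_distance", "center_distance", "volume_ratio"]].round(4))
```

```
region normalization    std  median    p75  skewness  ks_distance  center_distance  volume_ratio
   IVD           CSF 0.1916  0.2066 0.4235    1.0108       0.2023           0.0001           NaN
   IVD          BONE 0.6020  0.6492 1.3305    1.0108       0.2023           0.0001           NaN
    NP           CSF 0.1089  0.5954 0.6781   -0.2426       0.0770           0.0001        0.2753
    NP          BONE 0.3420  1.8705 2.1303   -0.2426       0.0770           0.0001        0.2753
    AF           CSF 0.0682  0.1719 0.2243    1.1936       0.1493           0.0001           NaN
    AF          BONE 0.2144  0.5399 0.7046    1.1936       0.1493           0.0001           NaN
```

Each row is one region under one normalization. CSF-normalized medians say
the NP is ~60% as bright as CSF while the AF sits near 17%; the NP occupies
27.5% of the disc volume; the nonzero `center_distance` of the IVD reflects
the 2 mm nucleus displacement pulling the intensity-weighted center away
from the geometric center. Scale-free indices (skewness, KS distance) are
identical under both normalizations — only the intensity scale differs.

The same pipeline runs from the shell:

```sh
amrsid phantom -o demo/                 # synthetic NIfTI pair
amrsid indices demo/phantom_volume.nii.gz demo/phantom_mask.nii.gz -o rows.csv
amrsid full-run -o study/ --seed 1      # 79-subject cohort -> significance grid
```

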