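# alaem

Automatic leaf azimuth estimation from nadir canopy images, with the
genotype x environment x management statistics used in maize plasticity
studies.

Maize leaves reorient under intraspecific competition: in rectangular
sowing patterns (wide rows, tight in-row spacing) a growing share of leaves
turns perpendicular to the row to exploit the inter-row light gap.
Quantifying this from field imagery requires measuring the azimuth of
hundreds of leaves per plot — infeasible by hand at scale.  `alaem` does it
from nadir RGB images, unsupervised, with a single scale parameter, and
provides the downstream statistics to compare orientation distributions
across genotypes, sites and sowing patterns.

## Method

**Detection.**  A leaf midrib appears as a bright elongated ridge.  The
image is cropped to a narrow field of view about nadir (pinhole model),
contrast-stretched, segmented into vegetation/soil with an excess-green
index (ExG = 2g − r − b on chromaticity channels, Otsu threshold), and
converted to [0, 1] grayscale by channel averaging.  After Gaussian
smoothing at scale σ, the per-pixel Hessian

    H f = [[f_xx, f_xy], [f_xy, f_yy]]

is diagonalised; with σ²-normalised derivatives, a pixel is classified
ridge when λ₁ ≤ −0.125 and |λ₂| < 0.5 |λ₁| inside the vegetation mask.
Each 8-connected ridge component becomes an oriented midrib via its convex
hull and minimum-area enclosing rectangle (rotating calipers: the optimal
rectangle has a side collinear with a hull edge); rectangle outliers
(aspect < 3 or log-area outside the Tukey fence) are flagged as Hessian
artifacts.  The rectangle's long-side orientation, folded against the row
direction, gives the row-relative azimuth in [0, 90°] — 0 parallel,
90 perpendicular.  σ tracks midrib width: 8 / 12 / 16 px at the 4- / 8- /
12-leaf stages for ~0.5 mm/px field imagery, ~2 px for the reduced-scale
synthetic scenes shipped here.

**Statistics.**  `fp`, the fraction of leaves beyond a 45° or 60°
threshold; Kolmogorov–Smirnov tests against Uniform(0, 90°) and between
sites; the AMMI decomposition

    Y_ij = μ + G_i + R_j + Σ_k λ_k b_ik z_jk + ε_ij

(main effects plus SVD of the double-centered interaction, Gollob degrees
of freedom g + e − 1 − 2k per axis); and the relative distance plasticity
index RDPI = (1/n) Σ |X_ij − X_i′j| / (X_ij + X_i′j) over environment
pairs.  A synthetic-canopy renderer with exact ground truth closes the
loop: every stage is testable without field data.

## Worked example

```python
import numpy as np
from alaem import (MidribDetector, random_scene, render_scene,
                   fraction_perpendicular, ks_uniform, ammi_fit)

# a 20-leaf synthetic canopy, 70% of leaves biased perpendicular to the row
scene = random_scene(n_leaves=20, seed=1, perpendicular_fraction=0.7)
image, truth = render_scene(scene)

res = MidribDetector(sigma=2.0).detect(image,
                                       row_azimuth_deg=scene.row_azimuth_deg)
print(res.counts)
fp_est = fraction_perpendicular(res.kept["rel_azimuth_deg"], 45.0)
fp_true = fraction_perpendicular(truth["rel_azimuth_deg"], 45.0)
print(f"fp(45) detected = {fp_est.fp:.2f}, ground truth = {fp_true.fp:.2f}")
ks = ks_uniform(res.kept["rel_azimuth_deg"])
print(f"KS vs Uniform(0,90): D = {ks.statistic:.3f}, p = {ks.p_value:.2e}")
```

prints

```
{'green_px': 28132, 'ridge_px': 2294, 'components': 20, 'kept': 19}
fp(45) detected = 0.79, ground truth = 0.80
KS vs Uniform(0,90): D = 0.589, p = 8.13e-07
```

19 of the 20 rendered midribs survive detection and denoising; the detected
fraction-perpendicular matches the ground truth to 0.01, and the KS test
firmly rejects a uniform orientation distribution — the canopy has a
preferential (perpendicular) orientation, as constructed.

Fitting AMMI on a simulated 5-genotype x 4-pattern fp table with a planted
rank-1 interaction (3 replicates, noise sd 0.02):

```python
from alaem.synthetic import (FpTableSpec, rank_one_interaction,
                             simulate_fp_table)
spec = FpTableSpec(mu=0.45, g_effects=[0.06, 0.02, 0.0, -0.03, -0.05],
                   r_effects=[-0.09, -0.03, 0.04, 0.08],
                   interaction=rank_one_interaction(
                       0.3, [2, 1, 0, -1, -2], [1.5, 0.5, -0.5, -1.5]),
                   noise_sd=0.02, replicates=3, seed=7,
                   env_names=["R1", "R2", "R4", "R8"])
model = ammi_fit(simulate_fp_table(spec), n_components=2,
                 env_label="Rectangularity")
print(model.anova_.round(4).to_string(index=False))
```

```
        source  df  sum_sq  mean_sq        F  p_value
Rectangularity   3  0.2558   0.0853   3.7855   0.0403
      Genotype   4  0.0831   0.0208   0.9229   0.4824
  Interactions  12  0.2703   0.0225      NaN      NaN
           PC1   6  0.2677   0.0446 498.2059   0.0020
           PC2   4  0.0024   0.0006   6.6932   0.1342
     Residuals   2  0.0002   0.0001      NaN      NaN
         Error  40  0.0144   0.0004      NaN      NaN
```

The planted rank-1 interaction loads almost entirely on PC1 (99% of the
interaction variance), with the Gollob df column (12, 6, 4, 2) as expected
for a 5 x 4 table.

## Command line

```bash
alaem simulate --spec scenes.yaml --out scenes/        # render + manifest
alaem detect --manifest scenes/manifest.csv \
             --config cfg.yaml --out detected/          # midrib + azimuth CSVs
alaem stats  --table detected/azimuths.csv \
             --threshold 45 --out stats/                # fp, AMMI, RDPI, KS
```

The simulate → detect → stats triple is fully reproducible from one seed
and one config file.

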