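# rnc — relational neural control

`rnc` is a toolkit for *relational neural control*: given encoding models
(or measured response stores) for two brain areas, it finds or evolves
stimuli that jointly control both areas' responses — **aligning** them
(both driven or both suppressed; similar representational geometries) or
**disentangling** them (one driven while the other is suppressed;
dissimilar geometries).  It is aimed at computational neuroscientists and
neuroimagers who work with voxelwise encoding models of visual cortex and
want to probe the *relationship* between two areas' representations
rather than each area in isolation.

## What it computes

**Univariate control.**  For an area, the univariate response to image
*i* is the mean over its voxels, *u(i)*.  A baseline is the mean response
of the random 25-image batch whose score lies closest to the centre of a
large random-batch null distribution (default 10⁶ samples).  Controlling
images are those whose responses beat each area's baseline by a margin
(default 0.04 z-units) in the required direction, ranked by the sum
*u_A + u_B* (alignment) or difference *u_A − u_B* (disentanglement).

**Multivariate control.**  For a 50-image batch, each area's
representational similarity matrix (RSM) holds the Pearson correlations
between the voxel patterns of every image pair; the RSA score between
two areas is the Pearson *r* of their RSMs' lower-triangle entries.  An
elitist genetic search (population 2,400; 200 elites; mutated copies
replacing 1, 5, 12, 25 and 38 images; 1,200 fresh random batches per
generation) finds batches with maximal *r* (align) or minimal |*r*|
(disentangle), against a random-batch RSA baseline.

**Generative control.**  A latent population evolves through a generator
under a two-phase score: until both areas pass their response thresholds
(baseline ± 0.6), latents are ranked by the condition-signed sum or
difference plus a constant 10¹⁰ penalty; afterwards the score is the PNG
byte size of the generated image, so evolution minimizes image
complexity while holding the response criterion.

**Evaluation machinery.**  Noise-ceiling estimation from trial repeats
(NCSNR = σ̂_signal/σ̂_noise; NC = 100·NCSNR²/(NCSNR² + 1/n)),
noise-ceiling-normalized explained variance, leave-one-participant-out
cross-validation, within-participant permutation tests with
Benjamini–Hochberg correction, population prevalence
P = 1 − BinomCDF(k; n, α), bootstrap CIs, and 2-D metric-MDS embeddings
of areas.

All of it runs end-to-end on a synthetic multi-area cortex with planted
shared/unique representational structure (`rnc.synthetic_cortex`), so no
neuroimaging download is needed.

## Worked example

```python
from rnc.synthetic_cortex import SyntheticCortexConfig, simulate_hierarchy
from rnc.response_store import univariate_profile
from rnc.univariate import (UniControlCondition, build_univariate_null,
                            select_univariate_controls)

cfg = SyntheticCortexConfig(n_participants=2, n_images=2000, seed=0)
sets, truth = simulate_hierarchy(cfg)                 # V1..V4 chain
pa = univariate_profile(sets[("sub01", "V1")])
pb = univariate_profile(sets[("sub01", "V4")])
na = build_univariate_null(pa, n_samples=100_000, seed=1)
nb = build_univariate_null(pb, n_samples=100_000, seed=2)
sol = select_univariate_controls(
    pa, pb, na.baseline_score, nb.baseline_score,
    UniControlCondition("drive_A_suppress_B"), n_select=25,
)
print(f"baselines  V1={na.baseline_score:+.4f}  V4={nb.baseline_score:+.4f}")
print(f"selected {sol.n_selected} images, top score {sol.selection_scores[0]:.3f}")
print(f"mean V1={pa.as_series()[sol.image_ids].mean():+.3f} "
      f"mean V4={pb.as_series()[sol.image_ids].mean():+.3f}")
```

prints

```
baselines  V1=-0.0006  V4=-0.0005
selected 25 images, top score 2.791
mean V1=+1.025 mean V4=-1.054
```

i.e. both baselines sit at the null-distribution centre (≈0 in z-units),
and the 25 selected images drive V1 about one z-unit above its baseline
while suppressing V4 about one z-unit below its — the areas' univariate
responses are disentangled.

The same pipeline is available from the shell:

```bash
rnc simulate --seed 0 --out store.h5
rnc uni   --store store.h5 --area-a V1 --area-b V4 \
          --condition drive_A_suppress_B --n-null 100000 --seed 1 --out sol.json
rnc multi --store store.h5 --area-a V1 --area-b V4 --objective disentangle \
          --population 240 --n-elite 20 --n-random 120 --generations 50 \
          --seed 1 --out multi.json
rnc gen   --condition drive_A_suppress_B --seed 1 --out trace/
rnc stats --k 3 --n 8
rnc demo  --seed 0 --out report.json
```

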