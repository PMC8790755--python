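# voxattrib

Integrated-gradients interpretability for voxel-based 3D-CNN protein–ligand
scorers.

Structure-based deep-learning scorers — clash detectors, docking-pose
classifiers, affinity regressors — consume a voxelized picture of a
protein–ligand complex and return a single number.  `voxattrib` answers the
question *which parts of the input that number came from*: it rasterizes a
complex onto a 16-channel pharmacophore grid (8 properties × protein/ligand),
scores it with a small differentiable 3D CNN, and attributes the score back
to voxels and atoms with Integrated Gradients

    IG_i(x) = (x_i − x′_i) ∫₀¹ ∂F/∂x_i (x′ + α(x − x′)) dα,

where F is the scorer, x the grid, and x′ an all-zero baseline (the empty
box).  The integral is approximated with a 100-step midpoint sum and its
quadrature error is reported through the completeness identity
Σᵢ IG_i = F(x) − F(x′).

Beyond per-complex maps (Gaussian `.cube` files, top-region summaries,
per-atom scores), the package quantifies *reciprocity*: if a scorer has
learned protein–ligand interactions, the top-attributed voxels of
complementary channels (protein donor ↔ ligand acceptor, the two occupancy
channels, …) should be spatially close.  It measures those top-voxel
distances against a random baseline of well-occupied voxels (feature value
> 0.75), tests the difference with a two-sided Mann–Whitney U test, and
correlates attribution magnitude with distance.  A synthetic
pocket–ligand–decoy generator makes the whole pipeline trainable and
reproducible on one CPU with no external downloads.

Intended users: method developers and computational chemists who want a
self-contained, inspectable reference implementation of voxel-grid
attribution and its quantitative sanity checks.

## Worked example

```python
import numpy as np
import voxattrib as va

# 1. synthesize a training set: 200 pockets, each with a clashed variant
data = va.make_clash_dataset(200, seed=1)
labels = [1.0 if lab.kind == "clashed" else 0.0 for _, lab in data]
grids = [va.voxelize(c) for c, _ in data]

# 2. train the clash detector (Adam, early stopping, 20% held out)
scorer = va.build_scorer("clash", seed=1)
scorer = va.train_scorer(scorer, grids, labels, va.TrainConfig(seed=1))
print(scorer.metrics)

# 3. attribute a fresh clashed complex and summarize
posed, label = va.make_clashed_pose(va.generate_complex(99), seed=7)
grid = va.voxelize(posed)
attr = va.integrated_gradients(scorer, grid, steps=100)
print(f"completeness gap: {attr.completeness_gap:.2e}")
summary = va.top_regions(attr)
print("channels with the strongest voxels:", summary.selected_channels)

# 4. is the clash what the model looked at?
pair = va.complementary_pairs()[-1]          # protein vs ligand occupancy
print("occupancy top-voxel distance:", va.pair_distance(attr, pair), "Å")
```

Output:

```
{'accuracy': 0.95, 'precision': 0.9761904761904762, 'n_validation': 80}
completeness gap: 2.38e-04
channels with the strongest voxels: [15, 7]
occupancy top-voxel distance: 1.0 Å
```

Reading: the detector separates clashed from crystal-like poses well even at
this small demo size (the full 500-complex protocol of
`scripts/acceptance.py` reaches ≥0.97 accuracy); the attribution sum matches
the logit difference to ~10⁻⁴ (quadrature error of the 100-step path
integral); the two strongest
channels are ligand occupancy (15) and protein occupancy (7); and their top
voxels sit 1 Å apart — both branches of the steric clash are highlighted at
the same spot, which is exactly the reciprocity a clash detector should
show.

## Command line

```bash
voxattrib train-demo --task clash --n-complexes 200 --outdir demo --seed 1
voxattrib attribute --protein prot.pdb --ligands poses.sdf \
    --checkpoint demo/clash_scorer.npz --steps 100 --outdir out
voxattrib analyze --checkpoint demo/clash_scorer.npz --n-complexes 100 \
    --outdir study --seed 1
```

`attribute` writes one `.cube` per channel (viewable in VMD/PyMOL), a JSON
region summary and a per-atom CSV for each ligand record (≤100 per job);
`analyze` writes a tidy per-complex distance table and a JSON of per-pair
U statistics, p-values and magnitude–distance correlations.

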