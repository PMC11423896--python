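# catselect

Analysis toolkit for **category-selective units in layered feature models**:
fMRI-style localization, causal lesioning, and sparse positive voxel
encoding — exercised end-to-end on synthetic planted-selectivity networks
where ground truth is known.

The package is built for computational neuroscientists who study how
category selectivity (faces, bodies, scenes, words) can be identified in a
hierarchical population code, what silencing those units does to
recognition behavior, and how well they account for responses of
category-selective brain regions. Every analysis runs on a synthetic world
whose selective units, mixing weights, and noise are planted by
construction, so recovery can be verified exactly.

## What it implements

**Localizer.** For each unit, contrast the preferred category against every
other category with a pooled-variance two-sample *t* test; threshold each
contrast with Benjamini–Hochberg FDR at *q* = 0.05; call a unit selective
for a domain only if it passes *every* contrast with *t* > 0 (so domain
sets are disjoint within a layer). A 2:1 response-ratio alternative,
probe-set generalization checks, and depth-trend summaries (Spearman rank
correlation of layer index with proportion selective and mean *t*) are
included.

**Lesioning.** A multinomial linear readout with L1-penalized weights
(proximal SGD under a one-cycle learning-rate schedule) is trained on the
deepest rectified stage, then frozen. Lesions zero the post-rectification
outputs of selective-unit groups, downstream activations are recomputed,
and per-category drops in top-*k* accuracy form a cost profile. The toolkit
quantifies dissociation between domain lesions (profile correlations,
cross-validated top-affected categories) and how well pre-lesion activation
predicts post-lesion cost, against random size-matched lesion nulls.

**Encoding.** Simulated voxels are sparse non-negative mixtures of one
domain's selective units, measured three times per stimulus in sessions
with affine instabilities. After per-session z-scoring, repeat averaging,
and NCSNR reliability filtering, each voxel is fit as

    min_{w >= 0}  (1/2n) ||y - Xw - c||^2 + alpha * sum(w)

using only units with *matched* selectivity. Correspondence is scored
univariately (ROI-mean response profile) and multivariately (veRSA: Pearson
correlation of RDM lower triangles), with best-layer selection on a
validation split, held-out test reporting, Monte-Carlo noise ceilings, and
Gabor / GistPC baseline feature spaces.

**Geometry.** Per-layer PCA, a Pearson-dissimilarity meta-RDM across
(image, layer) rows, classical MDS trajectories through the hierarchy, and
2D PC-projection maps with selective-unit tuning arrows.

See `docs/methods.md` for the model of the synthetic world, all defaults,
and what these benchmarks do and do not show.

## Worked example

Run the full pipeline at the default desk scale (3 layers x 200 units, four
planted domains, ~1 s per stage) and print the headline tables:

```bash
catselect all --out results_demo --seed 7
catselect report --out results_demo
```

Typical output (abridged):

```
== selectivity_summary.tsv ==
layer   layer_index  domain  n_selected  proportion  mean_t
layer1  0            face    10          0.05        13.64
layer1  0            body    10          0.05        13.12
...
layer3  2            word    10          0.05        8.00

== readout_accuracy.tsv ==
category  topk_accuracy  sparsity_fraction
body      0.92           0.619
face      0.925          0.619
...

== crossval_deficits.tsv ==
domain  top_categories  heldout_mean_deficit
face    face,scene      46.0
body    body,scene      48.0
scene   scene,body      44.5
word    word,scene      46.0

== activation_cost.tsv ==
domain  layer   activation_cost_r  random_lesion_mean_r
face    layer2  -0.998             -0.130
...
```

Reading this: the localizer recovers ~10 selective units per domain per
layer (the planted fraction is 0.05 of 200), with mean contrast *t* around
8–14. The sparse readout reaches ~92% top-1 accuracy with 62% of its
weights effectively zero. Lesioning a domain's units costs its own category
~45 percentage points of accuracy on held-out stimuli (the cross-validated
deficit), and a unit group's pre-lesion activation per category almost
perfectly anticipates the lesion's cost (r ~ −1), while random
size-matched lesions show no such relation.

Library use mirrors the stages:

```python
from catselect import (StimulusConfig, PlantedModelConfig, LocalizerDesign,
                       generate_stimulus_set, build_planted_model,
                       forward_activations, localize_selective_units)

stim  = generate_stimulus_set(StimulusConfig(), seed=7)
model = build_planted_model(stim, PlantedModelConfig(gain=4.0), seed=8)
store = forward_activations(model, stim)
smap  = localize_selective_units(store, LocalizerDesign())
smap.indices("layer2", "face")   # recovered face-selective unit indices
```

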