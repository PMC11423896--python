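# Methods

`catselect` re-creates, at desk scale and with known ground truth, a
three-stage analysis of category selectivity in layered feature models:
fMRI-style localization of category-selective units, causal lesioning with a
sparse linear readout, and sparse positive-constrained encoding of simulated
voxel responses. Everything runs on synthetic data with planted structure,
so every recovery claim can be checked against the generator's truth.

## The synthetic world

### Stimuli

Stimuli live in a `d`-dimensional feature space (default `d = 128`). Each
category `k` has a unit-norm template `t_k`; templates are rows of a random
orthonormal frame, so categories occupy mutually near-orthogonal directions.
A stimulus is

```
x = s * t_k + sigma_w * (z_perp + eta * z_par),      z ~ N(0, I_d)
```

where `z_par` / `z_perp` split the jitter inside/outside the template span.
Defaults: `sigma_w = 0.7` (probe split 0.8), `eta = 0.25`, `s = 1`.

Three choices matter and are deliberate:

* **Anisotropic jitter** (`eta < 1`). Exemplar variation is concentrated in
  non-category-diagnostic directions. This mirrors real image sets — two
  faces differ mostly along dimensions that do not distinguish faces from
  scenes — and it is what makes selectivity *recoverable*: a planted unit
  aligned with a category contrast sees little exemplar noise, while a
  random unit projects the full jitter.
* **Covariance-matched scrambles.** The "scrambled" control category is
  template-free noise with the *same covariance* as the exemplar jitter, the
  analog of phase-scrambled images (which preserve low-level statistics
  while destroying category structure). Fully isotropic scrambles would be
  disproportionately loud along category-diagnostic directions and break
  the scrambled contrast even for genuinely selective units.
* **The exchangeable null** (`template_scale = 0`). For false-positive-rate
  calibration all categories must be draws from one distribution. This is
  *not* the same as simply setting the planting gain to zero: with
  template-structured stimuli, even a purely random network inherits genuine
  category differences through random projections (the well-known
  observation that untrained networks already contain "selective" units), so
  a flag-rate bound can only be checked against label-exchangeable stimuli.

Splits (`localizer`, `probe`, `readout_train/eval`, `enc_train/val/test`)
mirror the roles of a localizer image set, an independent probe set,
recognition train/eval images, and encoding train/validation/test images.
Desk-scale defaults: 16 localizer and 20 probe images per category, 80/200
recognition train/eval, 60/40/40 encoding.

### The planted model

The model is a stack of fully connected rectified layers (default 3 x 200
units). Per layer and domain, a fraction `rho` (default 0.05) of units is
*planted*: constructed to prefer that domain, with ground-truth masks
retained. The remaining background units are random projections.

Construction, calibrated on a private 1000-per-category sample drawn from
the stimulus distribution (the "training diet" analog — tuning learned from
the diet, not from any analysis split):

* Every unit's weight row is normalized so its pre-rectification calibration
  response has unit SD; background biases sit 1.2 response-SDs below the
  calibration mean (rectification clips only the lower tail, which keeps the
  population code linearly decodable in depth), while planted biases clamp
  the largest non-preferred category mean to zero, so planted units rest
  near zero for non-preferred input.
* A planted unit's row mixes a random row with its tuning direction: the
  preferred-vs-rest contrast of the previous stage's calibration means, plus
  per-unit direction jitter (`direction_jitter = 0.3`, shrunk per unit until
  the target gain is reachable). Units in a selective population thus share
  similar but not identical tuning — which is also what makes voxel
  mixtures over them identifiable.
* The gain `g` parameterizes the unit's *contrast effect size*
  ((preferred − non-preferred mean) / within-category SD), not its output
  amplitude. Planted output SD is damped to 0.4 of the background scale
  (`planted_output_scale`). Letting planted units shout `g`-times louder
  would make every deeper-layer background unit genuinely selective through
  random projections of that signal, which is a property of amplitude, not
  of tuning; holding amplitude fixed lets `g` control selectivity alone.
* With `g = 0` the planted branch is skipped entirely, so the construction
  reduces exactly to the background one: the masks carry no preference.

Lesions are applied by forcing the post-rectification outputs of the listed
units to zero, with all deeper activations recomputed under the lesion.

### Voxels

A voxel is a noisy non-negative sparse mixture of one domain's truly
selective units in a source layer (default layer 2, post stage): support of
size `s = 5`, half-normal weights normalized to sum 1, trial response

```
r = gain_session * (w . a(stimulus)) + offset_session + N(0, sigma_v^2)
```

Each encoding stimulus is measured 3 times; trials are shuffled and cut into
contiguous sessions (default 150 trials), each with its own affine
instability (offset SD 0.3, gain SD 0.2) — the minimal structure that makes
per-session z-scoring a real correction rather than a no-op. Repeats of a
stimulus may land in different sessions. Default trial noise
`sigma_v = 0.15` gives NCSNR values straddling the 0.3 reliability
threshold; recovery benchmarks use `sigma_v = 0.02` (their point is
identifiability, not noise robustness).

## The analyses

### Localizer

For each unit, each domain's preferred category is contrasted against every
other contrast category with a pooled-variance two-sample t test; each
contrast's p-values are thresholded by Benjamini–Hochberg FDR at
`q = 0.05`, applied per layer-stage-contrast (a config switch allows pooling
across contrasts); a unit is selective only if it passes *every* contrast
with positive t. Because every domain's contrast set contains the other
domains' preferred categories, selective sets are disjoint within a layer by
construction. Pre- and post-rectification stages are localized separately.
A unit's reported "mean t" averages its per-contrast t values (other
aggregations — minimum, reference contrast — would also be defensible; the
mean is used consistently for ranking and reporting).

The 2:1 ratio alternative selects units whose preferred mean response is at
least twice each non-preferred mean; it is defined only for rectified
stages, denominators are floored at 1e-8, and a unit with zero preferred
mean is never selected. The two methods are compared per layer and domain by
intersection-over-union.

Generalization: contrast t values are recomputed on the probe split for the
previously selected units; the summary reports the fraction with positive
mean probe t and the localizer-vs-probe t correlation. On the localizer
split itself this reproduces the original t values exactly.

### Readout and lesioning

A multinomial linear readout is trained on the deepest post-rectification
stage with cross-entropy plus an L1 penalty, optimized by minibatch
proximal SGD (soft-thresholding after each step; biases unpenalized) under a
one-cycle learning-rate schedule (linear warm-up to `max_lr = 0.05` over the
first 30% of steps, cosine anneal down). The optimizer is plain SGD — the
simplest method compatible with a proximal L1 step. Desk-scale defaults
`l1_lambda = 5e-3`, 250 epochs, batch 64, top-1 accuracy over 5 categories;
at these data sizes a 10-epoch run is far from convergence, so the epoch
count is scaled with the dataset rather than copied from large-scale
practice.

Lesion cost profiles are per-category drops in top-k accuracy
(baseline − lesioned, in percentage points; the readout is never retrained).
Score ties in top-k break deterministically by ascending category index.
The cross-validated deficit first identifies the most affected categories on
a stratified half of the evaluation stimuli and quantifies them on the other
half (odd counts: the larger half identifies). The activation-cost analysis
correlates a unit group's mean pre-lesion activation per category with the
accuracy *change* (lesioned − baseline), so functionally involved groups
give negative r; random size-matched lesions are the null. Profiles with
zero variance make these correlations undefined; they are flagged with a
warning and returned as NaN rather than silently propagated.

### Encoding

Preparation: per-voxel per-session z-scoring (sample SD; zero-variance
voxel-sessions are left at zero and flagged), repeat averaging, and a
reliability filter keeping voxels with NCSNR > 0.3. NCSNR is computed as
noise SD = sqrt(mean over stimuli of the unbiased across-repeat variance),
signal SD = sqrt(max(0, single-trial variance − noise variance)), and their
ratio (infinite when the noise SD is zero).

The encoding model per voxel minimizes
`(1/2n) ||y − Xw − c||^2 + alpha * sum(w)` subject to `w >= 0`, with an
unpenalized, unconstrained intercept `c` (the natural choice for z-scored
responses). `X` contains only the units with *matched* selectivity for the
voxel's ROI domain. The default `alpha = 0.1` is conservative at this
feature scale; the benchmarks select `alpha` on the validation split from a
small grid. A model whose positivity constraint drives every weight to zero
predicts a constant; its correspondence is reported as 0 ("explains no
stimulus-driven structure") with a warning, which keeps model comparisons
well-defined.

Evaluation per split: the univariate metric correlates the ROI-mean of
per-voxel predictions with the measured ROI-mean profile across stimuli
(predicting each voxel then averaging, rather than predicting the mean — a
config-visible choice); the veRSA metric correlates the lower triangles of
the predicted-pattern and measured-pattern RDMs (Pearson dissimilarity,
voxel space). The best layer is chosen per metric on the validation split
(ties to the shallower layer); reported numbers come from the held-out test
split only.

Noise ceilings use Monte-Carlo simulation: draw a noiseless stimulus x voxel
pattern from the signal distribution, add noise averaged over the repeat
count, and correlate noiseless with noisy summaries; the ceiling is the mean
over at least 100 simulations. In the synthetic regime the signal/noise SDs
are the generator's true parameters; otherwise diagonal moment estimates
from the repeat structure stand in — a deliberately lighter substitute for
full generative noise modeling, sufficient for ceiling *behavior* (exactly 1
at zero noise, monotone decreasing in noise).

Baselines: a Gabor-energy bank (quadrature pairs, DC-corrected kernels,
cyclic convolution, 16 x 16 mean pooling; 12/8/6/4 orientations over four
octave-spaced frequencies, flattened length 7680) and its first 50 principal
components (GistPC).

### Geometry

Per layer, probe activations are reduced to 10 principal components; the
per-layer blocks are stacked and a Pearson-dissimilarity meta-RDM over all
(image, layer) rows is embedded by classical (Torgerson) MDS — chosen over
stress majorization because it is deterministic and initialization-free.
Principal-component signs are fixed by making each component's
largest-magnitude loading positive, so plots reproduce bitwise. Tuning
vectors of the most selective units (ranked by mean contrast t) are one-hot
vectors mapped through the 2D PCA component matrix and scaled for display;
angles are invariant to the scale constant. Trajectory analyses restrict
the probe to the four domain categories with 30 images each, the compact
probe-set regime these visualizations are designed for.

## Validation studies and what they show

The standing experiments (`catselect.experiments`, re-run by
`scripts/acceptance.py`) check, on freshly generated data:

1. the Gabor bank's published feature dimension (7680) and the RDM pair
   count for 515 stimuli (132,355);
2. FDR calibration: across 100 null models (2 x 1000 units), the flag rate
   stays within `q + 3 SE` (in practice the five-contrast intersection makes
   it essentially zero);
3. planted-unit recovery at gain 4: precision and recall at least 0.9 per
   domain against the planted masks;
4. the non-negative Lasso against a dense grid-search oracle on 3-feature
   problems, plus positivity of every fitted weight;
5. encoding recovery on simulated voxels (s = 5, low noise): support and
   weight recovery, matched-selectivity dominance over mismatched subsets,
   and selection of the generating layer — each in at least 90% of 50 seeds;
6. lesion dissociation: the own-domain deficit is the largest entry of its
   profile in at least 90% of 50 seeds; activation-cost correlations are
   negative for domain lesions and near zero for random size-matched ones;
7. noise-ceiling behavior (1 at zero noise, monotone decreasing); and
8. deepening category separation across layers in the MDS embedding.

Problem sizes (3 x 200-unit models, 16-image localizers, 50-seed Monte
Carlo) are the package's desk-scale study conditions: large enough for the
planted effects to be unambiguous, small enough that the full battery runs
in minutes on one CPU.

**What passing does not show.** The generator emulates the *statistical
shape* of the real pipeline's inputs — category-clustered stimuli,
hierarchically mixed nonlinear features with selective subpopulations,
session-structured noisy voxel mixtures — not images, trained networks, or
BOLD physiology. Selectivity here is planted, not learned, so these tests
validate the *analysis machinery* (that the localizer finds what is there
and nothing else, that lesions dissociate what is causally used, that the
constrained encoder recovers true mixtures) rather than any claim about
emergence in trained models or brains. Real activation distributions are
heavier-tailed and correlated in ways this generator does not reproduce;
absolute metric values (e.g. veRSA levels) should not be read across to
real data.

## Numerical conventions and degenerate inputs

* Two-sample t with zero pooled variance: t = 0, p = 1 when means agree,
  +/-inf with p = 0 otherwise.
* BH step-up includes all hypotheses up to the largest passing rank.
* Ratio-method denominators floored at 1e-8; zero preferred mean never
  selects.
* Lasso fits converge to KKT tolerance 1e-6 (`alpha = 0` solves NNLS on
  centered data exactly).
* RDM entries are clipped to the analytic range [0, 2] against
  floating-point drift; zero-variance patterns yield flagged NaN entries.
* All randomness flows through `numpy` Generators seeded from explicit
  integers; per-stage pipeline seeds derive deterministically from the
  global seed, and identical configurations reproduce every artifact
  bitwise.

## Known limitations

* The feature-vector regime is primary; the tiny-image regime exists to
  exercise the Gabor/GistPC baselines, and no image rendering of the
  planted model's inputs is attempted.
* The meta-RDM/MDS separation signal is modest at desk scale (ratios near
  1.0–1.2): with unit-variance background populations, category variance is
  a small share of total variance, exactly as in shallow real models.
* The moment-based Monte-Carlo noise ceiling ignores noise correlations
  between voxels.
* `alpha` for encoding is not auto-tuned in the pipeline (the benchmarks use
  validation selection); the pipeline default favors comparability across
  ROIs over per-ROI optimality.
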