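"""Planted-selectivity layered feature models.

Stands in for a trained hierarchy: instead of learning selectivity from an
image diet, a known subset of units per layer is *constructed* to prefer one
stimulus domain, with a gain parameter ``g`` controlling how strong that
preference is. Ground-truth masks make recovery benchmarks possible.

Construction, layer by layer (calibrated on the localizer split):

* Every unit's weight row is normalized so its pre-nonlinearity response has
  unit variance over the calibration stimuli, and its bias centers that
  response. Background units are otherwise pure Gaussian rows.
* A planted unit for domain ``d`` mixes a random row ``eps`` with the
  preferred-vs-rest contrast direction ``u`` of the previous stage's
  calibration responses. The mixing ratio is chosen so the unit's contrast
  effect size -- (mean preferred - mean non-preferred) / within-category SD
  -- equals ``g``. With ``g = 0`` the construction reduces exactly to the
  background one, so planted masks carry no preference.

Normalizing the output scale (rather than letting preferred responses grow
with ``g``) keeps a planted unit's *downstream influence* comparable to any
background unit's, so selectivity in deeper layers reflects the planted
directions rather than runaway activation magnitudes.

The nonlinearity is rectification; pre- and post-rectification responses are
exposed as distinct computational stages.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .containers import ActivationStore, LesionSpec, StimulusSet

_EPS = 1e-12


@dataclass
class PlantedModelConfig:
    layer_widths: list[int] = field(default_factory=lambda: [200, 200, 200])
    #: planted fraction per domain; a scalar applies to every layer, a
    #: sequence gives one fraction per layer (e.g. increasing with depth)
    rho: float | list[float] = 0.05
    gain: float = 4.0              # target contrast effect size of planted units
    domains: list[str] = field(default_factory=lambda: ["face", "body", "scene", "word"])
    #: stimuli per category in the builder's private calibration sample (the
    #: "training diet" analog); drawn fresh from the stimulus distribution so
    #: planted tuning directions do not overfit any analysis split.  Falls
    #: back to `calibration_split` when the stimulus set carries no
    #: generating configuration.
    calibration_size: int = 1000
    calibration_split: str = "localizer"
    #: response-SD of planted units relative to background units; < 1 keeps a
    #: planted unit's downstream drive modest so deeper-layer selectivity
    #: reflects planted directions, not sheer activation magnitude
    planted_output_scale: float = 0.4
    #: per-unit jitter of the planted tuning direction (relative to the
    #: domain contrast direction): units in a selective population share
    #: similar but not identical tuning, which decorrelates their responses
    #: enough for voxel mixtures over them to be identifiable
    direction_jitter: float = 0.3
    #: background biases sit this many response-SDs below the calibration
    #: mean, so rectification keeps most of a background unit's dynamic
    #: range and the population code stays linearly decodable in depth;
    #: planted units are centered instead, resting near zero for
    #: non-preferred input
    background_bias_sd: float = 1.2

    def rho_per_layer(self) -> list[float]:
        if np.isscalar(self.rho):
            return [float(self.rho)] * len(self.layer_widths)
        rhos = [float(r) for r in self.rho]
        if len(rhos) != len(self.layer_widths):
            raise ValueError("per-layer rho must match the number of layers")
        return rhos

    def validate(self) -> None:
        if len(self.layer_widths) < 2:
            raise ValueError("need at least 2 layers")
        rhos = self.rho_per_layer()
        for r in rhos:
            if not 0.0 <= r <= 0.5:
                raise ValueError("rho must be in [0, 0.5]")
        if self.gain < 0:
            raise ValueError("gain must be >= 0")
        for w, r in zip(self.layer_widths, rhos):
            if r > 0 and self.domains and int(r * w) < 1:
                raise ValueError(
                    f"rho * n_units = {r * w:.2f} < 1: no units to plant"
                )


@dataclass
class Layer:
    weights: np.ndarray  # (n_out, n_in)
    bias: np.ndarray     # (n_out,)


@dataclass
class PlantedModel:
    layers: list[Layer]
    layer_names: list[str]
    planted_mask: dict[str, dict[str, np.ndarray]]  # layer -> domain -> bool mask
    gain: float
    rho: float
    domains: list[str]
    seed: int

    @property
    def input_dim(self) -> int:
        return self.layers[0].weights.shape[1]

    def layer_sizes(self) -> dict[str, int]:
        return {n: l.weights.shape[0] for n, l in zip(self.layer_names, self.layers)}

    def planted_indices(self, layer: str, domain: str) -> np.ndarray:
        return np.flatnonzero(self.planted_mask[layer][domain])


def _normalize_rows(w: np.ndarray, acts: np.ndarray) -> np.ndarray:
    """Scale each weight row so its calibration response has unit SD."""
    resp = acts @ w.T
    sd = resp.std(axis=0, ddof=1)
    return w / np.maximum(sd, _EPS)[:, None]


def _within_sd(resp: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Pooled within-category SD of per-unit responses."""
    dev = np.zeros_like(resp)
    for cat in np.unique(labels):
        m = labels == cat
        dev[m] = resp[m] - resp[m].mean(axis=0)
    n_groups = len(np.unique(labels))
    denom = max(resp.shape[0] - n_groups, 1)
    return np.sqrt((dev**2).sum(axis=0) / denom)


def _calibration_stimuli(
    stimuli: StimulusSet, config: PlantedModelConfig, seed: int
) -> StimulusSet:
    """A large private draw from the stimulus distribution, when possible."""
    from dataclasses import replace as _replace

    from .stimuli import StimulusConfig, generate_stimulus_set

    sc = stimuli.config
    if config.calibration_size > 0 and isinstance(sc, StimulusConfig):
        cal_cfg = _replace(
            sc,
            splits={"localizer": config.calibration_size},
            scrambled_splits=("localizer",),
        )
        # same template frame as the analysis stimuli, fresh exemplar jitter
        cal_jitter_seed = int(
            np.random.SeedSequence([seed, 0x5EED]).generate_state(1)[0] % (2**31)
        )
        return generate_stimulus_set(
            cal_cfg, stimuli.seed, jitter_seed=cal_jitter_seed
        ).subset("localizer")
    return stimuli.subset(config.calibration_split)


def build_planted_model(
    stimuli: StimulusSet, config: PlantedModelConfig, seed: int
) -> PlantedModel:
    """Construct a layered model with known domain-selective unit subsets."""
    config.validate()
    rng = np.random.default_rng(seed)

    calib = _calibration_stimuli(stimuli, config, seed)
    acts = calib.features
    labels = calib.category
    for dom in config.domains:
        if dom not in labels:
            raise ValueError(f"domain {dom!r} absent from calibration split")

    layers: list[Layer] = []
    layer_names: list[str] = []
    planted: dict[str, dict[str, np.ndarray]] = {}

    rhos = config.rho_per_layer()
    for li, width in enumerate(config.layer_widths):
        name = f"layer{li + 1}"
        fan_in = acts.shape[1]
        n_plant = int(rhos[li] * width) if rhos[li] > 0 else 0

        w = rng.standard_normal((width, fan_in))
        mask = {dom: np.zeros(width, dtype=bool) for dom in config.domains}

        if n_plant > 0 and config.domains:
            # disjoint planted blocks at randomized unit positions
            perm = rng.permutation(width)
            cat_means = {
                cat: acts[labels == cat].mean(axis=0) for cat in np.unique(labels)
            }
            for di, dom in enumerate(config.domains):
                idx = perm[di * n_plant : (di + 1) * n_plant]
                mask[dom][idx] = True
                others = [c for c in cat_means if c != dom]
                # preferred-vs-rest contrast direction of the previous stage
                v = cat_means[dom] - np.mean([cat_means[c] for c in others], axis=0)
                u = v / max(np.linalg.norm(v), _EPS)
                if config.gain == 0:
                    continue
                for unit in idx:
                    # each unit's own tuning direction: shared contrast axis
                    # plus private jitter, effect size re-calibrated per unit.
                    # Jitter is shrunk per unit until the requested gain is
                    # reachable along its direction, so diversity never costs
                    # a unit its target selectivity.
                    eta = rng.standard_normal(fan_in)
                    eta /= max(np.linalg.norm(eta), _EPS)
                    tau = config.direction_jitter
                    for _ in range(8):
                        u_i = u + tau * eta
                        u_i /= max(np.linalg.norm(u_i), _EPS)
                        r_u = acts @ u_i
                        sigma_u = float(_within_sd(r_u[:, None], labels)[0])
                        delta_u = float(
                            r_u[labels == dom].mean()
                            - np.mean([r_u[labels == c].mean() for c in others])
                        )
                        cap = delta_u / max(sigma_u, _EPS)
                        if delta_u > 0 and cap > 1.1 * config.gain:
                            break
                        tau *= 0.5
                    s_e = float(_within_sd((acts @ w[unit])[:, None], labels)[0])
                    if delta_u <= 0 or config.gain >= cap:
                        # still unreachable: pure contrast direction
                        w[unit] = u_i
                    else:
                        b = (
                            config.gain
                            * s_e
                            / np.sqrt(delta_u**2 - config.gain**2 * sigma_u**2)
                        )
                        w[unit] = w[unit] + b * u_i

        w = _normalize_rows(w, acts)
        any_planted = np.zeros(width, dtype=bool)
        if config.gain > 0 and n_plant > 0:
            for dom in config.domains:
                any_planted |= mask[dom]
            w[any_planted] *= config.planted_output_scale
        pre = acts @ w.T
        # background: shifted up so rectification clips only the lower tail
        bias = -pre.mean(axis=0) + config.background_bias_sd * pre.std(axis=0, ddof=1)
        # planted: rest near zero for non-preferred input -- the largest
        # non-preferred category mean is mapped to zero, so rectification
        # silences everything but the preferred category
        if config.gain > 0 and n_plant > 0:
            for dom in config.domains:
                idx = np.flatnonzero(mask[dom])
                if len(idx) == 0:
                    continue
                nonpref = np.stack(
                    [
                        pre[np.ix_(labels == c, idx)].mean(axis=0)
                        for c in np.unique(labels)
                        if c != dom
                    ]
                )
                bias[idx] = -nonpref.max(axis=0)
        layers.append(Layer(weights=w, bias=bias))
        layer_names.append(name)
        planted[name] = mask

        acts = np.maximum(pre + bias, 0.0)  # post-rectification, next layer's input

    return PlantedModel(
        layers=layers,
        layer_names=layer_names,
        planted_mask=planted,
        gain=config.gain,
        rho=config.rho,
        domains=list(config.domains),
        seed=seed,
    )


def forward_activations(
    model: PlantedModel,
    stimuli: StimulusSet | np.ndarray,
    lesion: LesionSpec | None = None,
) -> ActivationStore:
    """Run the model forward, recording every pre/post stage.

    Under a lesion, masked units' post-rectification outputs are forced to
    zero *before* propagation, so all downstream activations are recomputed
    under the lesion.
    """
    if isinstance(stimuli, StimulusSet):
        x = stimuli.features
        category, split, sid = stimuli.category, stimuli.split, stimuli.stimulus_id
    else:
        x = np.asarray(stimuli, dtype=float)
        n = x.shape[0]
        category = np.asarray(["?"] * n, dtype=object)
        split = np.asarray(["?"] * n, dtype=object)
        sid = np.arange(n)
    if x.shape[1] != model.input_dim:
        raise ValueError(
            f"stimulus dim {x.shape[1]} != model input dim {model.input_dim}"
        )
    if lesion is not None:
        lesion.validate(model.layer_sizes())

    store: dict[tuple[str, str], np.ndarray] = {}
    a = x
    for name, layer in zip(model.layer_names, model.layers):
        pre = a @ layer.weights.T + layer.bias
        post = np.maximum(pre, 0.0)
        if lesion is not None and name in lesion.units:
            post = post.copy()
            post[:, lesion.units[name]] = 0.0
        store[(name, "pre")] = pre
        store[(name, "post")] = post
        a = post

    return ActivationStore(
        activations=store,
        layer_names=list(model.layer_names),
        category=category,
        split=split,
        stimulus_id=sid,
    )
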