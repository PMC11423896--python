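"""In-silico lesioning of selective unit groups and its behavioral cost.

A lesion silences a chosen set of units (post-rectification outputs forced
to zero) in the forward pass; the readout head is *never* retrained, so any
drop in per-category recognition accuracy is attributable to the silenced
units. Cost profiles (baseline minus lesioned top-k accuracy, in percentage
points) quantify per-category deficits; profile correlations quantify how
dissociable two lesions are; and pre-lesion activation magnitude within a
unit group predicts which categories that group's lesion will hurt.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .containers import ActivationStore, LesionSpec, StimulusSet
from .localizer import SelectivityMap
from .planted import PlantedModel, forward_activations
from .readout import ReadoutHead, topk_accuracy_per_category


@dataclass
class CostProfile:
    """Per-category drop in top-k accuracy (baseline - lesioned), in points."""

    categories: list[str]
    deficit: np.ndarray          # percentage points, positive = impaired
    baseline: np.ndarray         # baseline accuracy (fraction)
    lesioned: np.ndarray         # lesioned accuracy (fraction)
    split: str
    k: int

    def __post_init__(self) -> None:
        if np.any(np.abs(self.deficit) > 100 + 1e-9):
            raise ValueError("deficits must lie in [-100, 100] percentage points")

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.categories, self.deficit))


def domain_lesion_spec(
    smap: SelectivityMap,
    domain: str,
    layers: list[str] | None = None,
    stage: str = "post",
) -> LesionSpec:
    """All units selective for ``domain`` across the given (default all) layers."""
    layers = layers if layers is not None else list(smap.layer_names)
    units = {lay: smap.indices(lay, domain, stage) for lay in layers}
    return LesionSpec(units=units, provenance="domain")


def top_fraction_lesion_spec(
    smap: SelectivityMap,
    domain: str,
    fraction: float,
    layer_widths: dict[str, int],
    stage: str = "post",
) -> LesionSpec:
    """Only the most selective units (ranked by mean contrast t).

    ``fraction`` is relative to the layer width (e.g. 0.01 targets the top
    1% of units in each layer, capped at the number of selective units).
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    units = {}
    for lay in smap.layer_names:
        e = smap.get(lay, stage, domain)
        n_take = min(int(np.ceil(fraction * layer_widths[lay])), len(e.indices))
        order = np.argsort(-e.t_mean, kind="stable")[:n_take]
        units[lay] = np.sort(e.indices[order])
    return LesionSpec(units=units, provenance="top_fraction")


def _features(model: PlantedModel, stimuli: StimulusSet,
              lesion: LesionSpec | None) -> np.ndarray:
    store = forward_activations(model, stimuli, lesion=lesion)
    return store.get(model.layer_names[-1], "post")


def lesion_cost_profile(
    model: PlantedModel,
    head: ReadoutHead,
    eval_set: StimulusSet,
    spec: LesionSpec,
    k: int = 1,
) -> CostProfile:
    """Per-category deficit of a lesion, with no retraining of the head."""
    base = topk_accuracy_per_category(head, _features(model, eval_set, None),
                                      eval_set.category, k)
    les = topk_accuracy_per_category(head, _features(model, eval_set, spec),
                                     eval_set.category, k)
    cats = sorted(base)
    b = np.array([base[c] for c in cats])
    l = np.array([les[c] for c in cats])
    return CostProfile(
        categories=cats,
        deficit=100.0 * (b - l),
        baseline=b,
        lesioned=l,
        split=str(eval_set.split[0]) if len(eval_set.split) else "?",
        k=k,
    )


def crossval_top_affected(
    model: PlantedModel,
    head: ReadoutHead,
    eval_set: StimulusSet,
    spec: LesionSpec,
    n_top: int,
    k: int = 1,
    seed: int = 0,
) -> tuple[list[str], float]:
    """Identify the most-affected categories on one half, quantify on the other.

    Guards against circularity: a stratified per-category half split is
    drawn with ``seed``; the ``n_top`` categories with the largest deficits
    on half A are selected, and their mean deficit is measured on half B.
    With odd per-category counts the larger half goes to identification.
    """
    rng = np.random.default_rng(seed)
    cats = np.unique(eval_set.category)
    half_a = np.zeros(eval_set.n_stimuli, dtype=bool)
    for cat in cats:
        idx = np.flatnonzero(eval_set.category == cat)
        if len(idx) < 2:
            raise ValueError(f"category {cat!r} needs >= 2 eval stimuli")
        idx = rng.permutation(idx)
        n_a = int(np.ceil(len(idx) / 2))  # larger half identifies
        half_a[idx[:n_a]] = True

    def _mask_subset(mask: np.ndarray) -> StimulusSet:
        return StimulusSet(
            features=eval_set.features[mask],
            category=eval_set.category[mask],
            split=eval_set.split[mask],
            stimulus_id=eval_set.stimulus_id[mask],
            templates=eval_set.templates,
            category_names=eval_set.category_names,
            seed=eval_set.seed,
        )

    prof_a = lesion_cost_profile(model, head, _mask_subset(half_a), spec, k)
    order = np.argsort(-prof_a.deficit, kind="stable")[:n_top]
    selected = [prof_a.categories[i] for i in order]

    prof_b = lesion_cost_profile(model, head, _mask_subset(~half_a), spec, k)
    sel_idx = [prof_b.categories.index(c) for c in selected]
    return selected, float(prof_b.deficit[sel_idx].mean())


def _flagged_pearson(x: np.ndarray, y: np.ndarray, what: str) -> float:
    if np.std(x) == 0 or np.std(y) == 0:
        warnings.warn(f"{what}: zero-variance input, correlation undefined",
                      stacklevel=3)
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def compare_cost_profiles(p1: CostProfile, p2: CostProfile) -> float:
    """Pearson similarity of two per-category deficit profiles."""
    if p1.categories != p2.categories:
        raise ValueError("cost profiles cover different category sets")
    return _flagged_pearson(p1.deficit, p2.deficit, "compare_cost_profiles")


def activation_cost_correlation(
    store: ActivationStore,
    unit_indices: np.ndarray,
    cost: CostProfile,
    layer: str,
    stage: str = "post",
) -> float:
    """Correlate pre-lesion activation with lesion cost across categories.

    Activation profile: mean response per category within the lesioned unit
    group at ``layer``. Deficits are correlated on the (lesioned - baseline)
    sign convention, so functionally involved groups give negative r.
    """
    if len(unit_indices) == 0:
        warnings.warn("activation_cost_correlation: empty unit set, undefined",
                      stacklevel=2)
        return float("nan")
    acts = store.get(layer, stage)[:, unit_indices]
    profile = np.array(
        [acts[store.category == c].mean() for c in cost.categories]
    )
    return _flagged_pearson(profile, -cost.deficit, "activation_cost_correlation")


def random_lesion_null(
    model: PlantedModel,
    head: ReadoutHead,
    eval_set: StimulusSet,
    smap: SelectivityMap,
    reference_domain: str,
    n_draws: int,
    seed: int = 0,
    k: int = 1,
    stage: str = "post",
) -> list[CostProfile]:
    """Cost profiles of random unit lesions size-matched to a domain's counts."""
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    rng = np.random.default_rng(seed)
    sizes = {
        lay: len(smap.indices(lay, reference_domain, stage))
        for lay in smap.layer_names
    }
    widths = model.layer_sizes()
    profiles = []
    for _ in range(n_draws):
        units = {
            lay: rng.choice(widths[lay], size=n, replace=False)
            for lay, n in sizes.items()
        }
        spec = LesionSpec(units=units, provenance="random")
        profiles.append(lesion_cost_profile(model, head, eval_set, spec, k))
    return profiles


def downstream_selectivity_change(
    model: PlantedModel,
    smap: SelectivityMap,
    domain: str,
    probe: StimulusSet,
    early_layers: list[str],
    target_layer: str,
    stage: str = "post",
) -> dict[str, float]:
    """Effect of early-layer domain lesions on a deeper layer's selective units.

    Lesions the domain's selective units in ``early_layers`` only, then
    reports per probe category the change (lesioned - baseline) in mean
    activation within the *target* layer's domain-selective units.
    """
    order = {lay: i for i, lay in enumerate(model.layer_names)}
    if target_layer in early_layers:
        raise ValueError("target layer cannot be among the lesioned early layers")
    if any(order[lay] >= order[target_layer] for lay in early_layers):
        raise ValueError("target layer must be strictly downstream of early layers")

    spec = domain_lesion_spec(smap, domain, layers=early_layers, stage=stage)
    target_units = smap.indices(target_layer, domain, stage)
    base = forward_activations(model, probe)
    lesioned = forward_activations(model, probe, lesion=spec)
    out = {}
    for cat in np.unique(probe.category):
        m = probe.category == cat
        b = base.get(target_layer, stage)[np.ix_(m, target_units)].mean()
        l = lesioned.get(target_layer, stage)[np.ix_(m, target_units)].mean()
        out[str(cat)] = float(l - b)
    return out
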