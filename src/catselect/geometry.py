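"""Representational-geometry visualizations of a layered feature model.

Two views of how category structure emerges across the hierarchy:

* **Meta-RDM trajectories** -- each layer's probe activations are reduced to
  a few principal components, the per-layer blocks are stacked, a Pearson
  dissimilarity "meta-RDM" over all (image, layer) rows is computed, and
  classical (Torgerson) multidimensional scaling embeds it in 2D, so each
  image traces a trajectory through the layers.
* **PC-projection maps** -- a 2D PCA basis fit on a reference stimulus set;
  probe activations are projected into it and the most selective units'
  one-hot tuning vectors are mapped through the same component matrix
  (scaled for display), drawing each unit as an arrow from the origin.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .containers import ActivationStore, StimulusSet
from .localizer import SelectivityMap
from .rsa import compute_rdm


@dataclass
class GeometryConfig:
    n_comp: int = 10        # PCA components per layer before the meta-RDM
    mds_dim: int = 2
    n_pc: int = 2           # projection components
    n_top_units: int = 25   # tuning vectors per domain
    scale: float = 2.5e4    # tuning-vector display scaling
    seed: int = 0

    def validate(self) -> None:
        if not self.n_comp >= self.mds_dim >= 1:
            raise ValueError("need n_comp >= mds_dim >= 1")
        if self.scale <= 0:
            raise ValueError("scale must be positive")


def _fix_signs(components: np.ndarray) -> np.ndarray:
    """Make the largest-magnitude loading of each component positive."""
    flip = np.sign(components[np.argmax(np.abs(components), axis=0),
                              np.arange(components.shape[1])])
    flip[flip == 0] = 1.0
    return components * flip


def classical_mds(dissimilarity: np.ndarray, n_dim: int) -> np.ndarray:
    """Torgerson (eigendecomposition) multidimensional scaling.

    Deterministic: no initialization or iteration; axes ordered by
    eigenvalue, signs fixed by the largest-magnitude coordinate.
    """
    d = np.asarray(dissimilarity, dtype=float)
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    vals, vecs = np.linalg.eigh(b)
    order = np.argsort(vals)[::-1][:n_dim]
    lam = np.maximum(vals[order], 0.0)
    coords = vecs[:, order] * np.sqrt(lam)
    return _fix_signs(coords)


def meta_rdm_trajectories(
    store: ActivationStore,
    probe: StimulusSet,
    config: GeometryConfig,
    layers: list[str] | None = None,
    stage: str = "post",
    split: str = "probe",
    categories: list[str] | None = None,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Layer-wise MDS trajectories of probe images.

    Returns ``(coords, meta_rdm)``: a tidy frame with one row per
    (image, layer) holding the embedded coordinates, and the meta-RDM
    itself. ``categories`` restricts the probe to a compact set of real
    categories (the classic trajectory figures use a handful); layers with
    fewer units than ``n_comp`` are reduced to their unit count and flagged
    with a warning.
    """
    config.validate()
    sub = store.subset(split)
    if categories is not None:
        keep = np.isin(sub.category, categories)
        if not keep.any():
            raise ValueError("no probe stimuli in the requested categories")
        sub = ActivationStore(
            activations={k: v[keep] for k, v in sub.activations.items()},
            layer_names=list(sub.layer_names),
            category=sub.category[keep],
            split=sub.split[keep],
            stimulus_id=sub.stimulus_id[keep],
        )
    layers = layers if layers is not None else list(store.layer_names)
    if len(layers) < 2:
        raise ValueError("need >= 2 layers for trajectories")
    if sub.n_stimuli < config.n_comp + 1:
        raise ValueError("probe too small for the configured n_comp")

    blocks = []
    for layer in layers:
        acts = sub.get(layer, stage)
        k = min(config.n_comp, acts.shape[1])
        if k < config.n_comp:
            warnings.warn(
                f"layer {layer!r} has {acts.shape[1]} units < n_comp="
                f"{config.n_comp}; reduced to {k}",
                stacklevel=2,
            )
        pca = PCA(n_components=k, svd_solver="full")
        scores = pca.fit_transform(acts)
        if k < config.n_comp:  # pad so rows are comparable across layers
            scores = np.pad(scores, ((0, 0), (0, config.n_comp - k)))
        blocks.append(scores)

    stacked = np.vstack(blocks)  # (n_images * n_layers, n_comp)
    meta = compute_rdm(stacked)
    coords = classical_mds(meta.values, config.mds_dim)

    rows = []
    n_img = sub.n_stimuli
    for li, layer in enumerate(layers):
        for i in range(n_img):
            rows.append(
                {
                    "stimulus_id": int(sub.stimulus_id[i]),
                    "category": sub.category[i],
                    "layer": layer,
                    **{f"dim{d + 1}": coords[li * n_img + i, d]
                       for d in range(config.mds_dim)},
                }
            )
    return pd.DataFrame(rows), meta.values


def category_separation(coords: pd.DataFrame, layer: str) -> float:
    """Between- over within-category mean embedded distance at one layer."""
    sub = coords[coords["layer"] == layer]
    dims = [c for c in sub.columns if c.startswith("dim")]
    x = sub[dims].to_numpy()
    cats = sub["category"].to_numpy()
    d = np.linalg.norm(x[:, None] - x[None, :], axis=-1)
    same = cats[:, None] == cats[None, :]
    off = ~np.eye(len(x), dtype=bool)
    within = d[same & off].mean()
    between = d[~same].mean()
    return float(between / within) if within > 0 else float("inf")


def pc_projection_map(
    ref_activations: np.ndarray,
    probe_activations: np.ndarray,
    smap: SelectivityMap,
    layer: str,
    domains: list[str],
    config: GeometryConfig,
    stage: str = "post",
    ref_ids: np.ndarray | None = None,
    probe_ids: np.ndarray | None = None,
) -> tuple[np.ndarray, dict[str, np.ndarray], dict[str, np.ndarray]]:
    """Project probes into a reference PCA basis, with unit tuning arrows.

    Returns ``(probe_scores, arrows, arrow_units)``: probe coordinates
    (n_probe, n_pc); per-domain arrow endpoints (n_units, n_pc), each the
    image of ``scale`` times a unit's one-hot vector under the component
    matrix; and the unit indices used (the ``n_top_units`` most selective by
    mean contrast t, or all available, flagged, if fewer).
    """
    config.validate()
    if ref_ids is not None and probe_ids is not None:
        if np.intersect1d(ref_ids, probe_ids).size:
            raise ValueError("reference and probe stimulus sets must be disjoint")
    pca = PCA(n_components=config.n_pc, svd_solver="full")
    pca.fit(ref_activations)
    comps = _fix_signs(pca.components_.T)  # (n_units, n_pc), sign-stable
    scores = (probe_activations - pca.mean_) @ comps

    arrows: dict[str, np.ndarray] = {}
    arrow_units: dict[str, np.ndarray] = {}
    for dom in domains:
        entry = smap.get(layer, stage, dom)
        n_take = min(config.n_top_units, len(entry.indices))
        if n_take < config.n_top_units:
            warnings.warn(
                f"domain {dom!r} has only {len(entry.indices)} selective "
                f"units (< {config.n_top_units}); using all",
                stacklevel=2,
            )
        order = np.argsort(-entry.t_mean, kind="stable")[:n_take]
        units = entry.indices[order]
        # one-hot vectors scaled then mapped through the component matrix
        arrows[dom] = config.scale * comps[units, :]
        arrow_units[dom] = units
    return scores, arrows, arrow_units
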