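"""fMRI-style localization of category-selective units.

Mirrors the classic functional-localizer logic: for each unit, contrast the
preferred category against every other contrast category with a two-sample
pooled-variance t test, threshold each contrast's p-values with
Benjamini-Hochberg FDR at level ``q``, and call a unit selective for a
domain only if it passes *every* contrast with a positive t. Because each
domain's contrast set contains the other domains' preferred categories, the
selective sets of different domains within a layer are disjoint by
construction.

A 2:1 response-ratio alternative (preferred mean at least ``ratio`` times
each non-preferred mean) is provided for post-rectification stages, where
mean responses are non-negative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import ActivationStore

RATIO_FLOOR = 1e-8


@dataclass
class LocalizerDesign:
    domains: list[str] = field(default_factory=lambda: ["face", "body", "scene", "word"])
    contrast_categories: list[str] = field(
        default_factory=lambda: ["face", "body", "scene", "word", "object", "scrambled"]
    )
    q: float = 0.05
    preferred_map: dict[str, str] | None = None  # default: domain == category
    fdr_scope: str = "contrast"  # "contrast" (per layer-contrast) | "pooled"

    def __post_init__(self) -> None:
        if not 0.0 < self.q < 1.0:
            raise ValueError("q must be in (0, 1)")
        if self.preferred_map is None:
            self.preferred_map = {d: d for d in self.domains}
        for d in self.domains:
            if self.preferred_map[d] not in self.contrast_categories:
                raise ValueError(
                    f"preferred category for domain {d!r} not in contrast_categories"
                )
        if self.fdr_scope not in ("contrast", "pooled"):
            raise ValueError("fdr_scope must be 'contrast' or 'pooled'")

    def others(self, domain: str) -> list[str]:
        pref = self.preferred_map[domain]
        return [c for c in self.contrast_categories if c != pref]


@dataclass
class SelectivityEntry:
    indices: np.ndarray           # selected unit indices, ascending
    t_per_contrast: np.ndarray    # (n_selected, n_contrasts)
    contrasts: list[str]          # non-preferred category of each contrast
    t_mean: np.ndarray            # (n_selected,) mean over contrasts


@dataclass
class SelectivityMap:
    entries: dict[tuple[str, str, str], SelectivityEntry]  # (layer, stage, domain)
    layer_names: list[str]
    domains: list[str]
    stages: tuple[str, ...]
    method: str  # "ttest_fdr" | "ratio"
    q: float | None = None
    ratio: float | None = None

    def get(self, layer: str, stage: str, domain: str) -> SelectivityEntry:
        return self.entries[(layer, stage, domain)]

    def indices(self, layer: str, domain: str, stage: str = "post") -> np.ndarray:
        return self.entries[(layer, stage, domain)].indices

    def counts(self, stage: str = "post") -> pd.DataFrame:
        rows = [
            {"layer": lay, "domain": dom, "n_selected": len(e.indices)}
            for (lay, stg, dom), e in self.entries.items()
            if stg == stage
        ]
        return pd.DataFrame(rows)


def contrast_tmap(
    activations: np.ndarray,
    labels: np.ndarray,
    preferred: str,
    other: str,
) -> tuple[np.ndarray, np.ndarray]:
    """Pooled-variance two-sample t (preferred minus other) per unit.

    Units with zero pooled variance and zero mean difference get
    ``t = 0, p = 1``; zero variance with a nonzero difference gives
    ``t = +/-inf, p = 0``.
    """
    labels = np.asarray(labels)
    for cat in (preferred, other):
        if cat not in labels:
            raise ValueError(f"category {cat!r} absent from labels")
    a = activations[labels == preferred]
    b = activations[labels == other]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 stimuli in each category")

    n1, n2 = len(a), len(b)
    diff = a.mean(axis=0) - b.mean(axis=0)
    ss = ((a - a.mean(axis=0)) ** 2).sum(axis=0) + ((b - b.mean(axis=0)) ** 2).sum(axis=0)
    dof = n1 + n2 - 2
    pooled = np.sqrt(ss / dof) * np.sqrt(1.0 / n1 + 1.0 / n2)

    t = np.zeros_like(diff)
    p = np.ones_like(diff)
    nz = pooled > 0
    t[nz] = diff[nz] / pooled[nz]
    p[nz] = 2.0 * stats.t.sf(np.abs(t[nz]), dof)
    degenerate = (~nz) & (diff != 0)
    t[degenerate] = np.where(diff[degenerate] > 0, np.inf, -np.inf)
    p[degenerate] = 0.0
    return t, p


def bh_fdr_mask(pvals: np.ndarray, q: float) -> np.ndarray:
    """Benjamini-Hochberg step-up at level ``q``: True where the null is rejected."""
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((pvals < 0) | (pvals > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(pvals, alpha=q, method="fdr_bh")[0]


def localize_selective_units(
    store: ActivationStore,
    design: LocalizerDesign,
    stages: tuple[str, ...] = ("pre", "post"),
    split: str = "localizer",
) -> SelectivityMap:
    """t-test + FDR + intersection localizer over every layer and stage."""
    loc = store.subset(split)
    labels = loc.category
    entries: dict[tuple[str, str, str], SelectivityEntry] = {}

    for layer in loc.layer_names:
        for stage in stages:
            acts = loc.get(layer, stage)
            n_units = acts.shape[1]
            for domain in design.domains:
                pref = design.preferred_map[domain]
                others = design.others(domain)
                tmat = np.empty((n_units, len(others)))
                pmat = np.empty((n_units, len(others)))
                for ci, other in enumerate(others):
                    tmat[:, ci], pmat[:, ci] = contrast_tmap(acts, labels, pref, other)
                if design.fdr_scope == "contrast":
                    passed = np.column_stack(
                        [bh_fdr_mask(pmat[:, ci], design.q) for ci in range(len(others))]
                    )
                else:  # pooled over this layer-stage-domain's contrasts
                    passed = bh_fdr_mask(pmat.ravel(), design.q).reshape(pmat.shape)
                sel = np.all(passed & (tmat > 0), axis=1)
                idx = np.flatnonzero(sel)
                entries[(layer, stage, domain)] = SelectivityEntry(
                    indices=idx,
                    t_per_contrast=tmat[idx],
                    contrasts=list(others),
                    t_mean=tmat[idx].mean(axis=1) if len(idx) else np.zeros(0),
                )

    return SelectivityMap(
        entries=entries,
        layer_names=list(loc.layer_names),
        domains=list(design.domains),
        stages=stages,
        method="ttest_fdr",
        q=design.q,
    )


def ratio_localize(
    store: ActivationStore,
    design: LocalizerDesign,
    ratio: float = 2.0,
    stages: tuple[str, ...] = ("post",),
    split: str = "localizer",
) -> SelectivityMap:
    """2:1-style localizer: preferred mean >= ratio x each non-preferred mean.

    Defined for post-rectification stages only, where mean responses are
    non-negative; denominators are floored at a small epsilon and a unit
    with zero preferred mean is never selected.
    """
    if any(s != "post" for s in stages):
        raise ValueError("ratio localizer is defined for post-nonlinearity stages only")
    loc = store.subset(split)
    labels = loc.category
    entries: dict[tuple[str, str, str], SelectivityEntry] = {}

    for layer in loc.layer_names:
        for stage in stages:
            acts = loc.get(layer, stage)
            for domain in design.domains:
                pref = design.preferred_map[domain]
                others = design.others(domain)
                pref_mean = acts[labels == pref].mean(axis=0)
                sel = pref_mean > 0
                for other in others:
                    om = np.maximum(acts[labels == other].mean(axis=0), RATIO_FLOOR)
                    sel &= pref_mean >= ratio * om
                idx = np.flatnonzero(sel)
                tmat = np.empty((len(idx), len(others)))
                for ci, other in enumerate(others):
                    t_all, _ = contrast_tmap(acts, labels, pref, other)
                    tmat[:, ci] = t_all[idx]
                entries[(layer, stage, domain)] = SelectivityEntry(
                    indices=idx,
                    t_per_contrast=tmat,
                    contrasts=list(others),
                    t_mean=tmat.mean(axis=1) if len(idx) else np.zeros(0),
                )

    return SelectivityMap(
        entries=entries,
        layer_names=list(loc.layer_names),
        domains=list(design.domains),
        stages=stages,
        method="ratio",
        ratio=ratio,
    )


def selectivity_iou(
    map_a: SelectivityMap, map_b: SelectivityMap, stage: str = "post"
) -> pd.DataFrame:
    """Intersection-over-union of two maps' selective sets, per layer and domain."""
    rows = []
    for layer in map_a.layer_names:
        for domain in map_a.domains:
            ia = set(map_a.indices(layer, domain, stage).tolist())
            ib = set(map_b.indices(layer, domain, stage).tolist())
            union = ia | ib
            iou = len(ia & ib) / len(union) if union else np.nan
            rows.append({"layer": layer, "domain": domain, "iou": iou})
    return pd.DataFrame(rows)


@dataclass
class GeneralizationSummary:
    fraction_positive: float
    t_correlation: float
    n_units: int
    defined: bool


def generalization_check(
    smap: SelectivityMap,
    probe_store: ActivationStore,
    design: LocalizerDesign,
    stage: str = "post",
    split: str = "probe",
) -> dict[str, GeneralizationSummary]:
    """Do localizer-selected units keep their preference on independent probes?

    Recomputes the contrast t statistics on the probe split, restricted to
    the previously selected units, and reports per domain the fraction with
    positive mean probe t plus the correlation between localizer t and probe
    t across units (pooled over layers).
    """
    probe = probe_store.subset(split)
    labels = probe.category
    out: dict[str, GeneralizationSummary] = {}
    for domain in design.domains:
        loc_t: list[np.ndarray] = []
        probe_t: list[np.ndarray] = []
        for layer in smap.layer_names:
            if (layer, stage, domain) not in smap.entries:
                continue
            entry = smap.get(layer, stage, domain)
            if len(entry.indices) == 0:
                continue
            acts = probe.get(layer, stage)[:, entry.indices]
            pref = design.preferred_map[domain]
            others = [c for c in entry.contrasts if c in labels]
            tmat = np.empty((len(entry.indices), len(others)))
            for ci, other in enumerate(others):
                tmat[:, ci], _ = contrast_tmap(acts, labels, pref, other)
            keep = [entry.contrasts.index(o) for o in others]
            loc_t.append(entry.t_per_contrast[:, keep].mean(axis=1))
            probe_t.append(tmat.mean(axis=1))
        if not loc_t:
            out[domain] = GeneralizationSummary(np.nan, np.nan, 0, defined=False)
            continue
        lt = np.concatenate(loc_t)
        pt = np.concatenate(probe_t)
        frac = float(np.mean(pt > 0))
        if len(lt) >= 2 and lt.std() > 0 and pt.std() > 0:
            r = float(np.corrcoef(lt, pt)[0, 1])
        else:
            r = np.nan
        out[domain] = GeneralizationSummary(frac, r, len(lt), defined=True)
    return out


@dataclass
class SelectivitySummary:
    table: pd.DataFrame                  # per layer/stage/domain proportions & mean t
    spearman_proportion: float           # layer index vs total proportion selective
    spearman_mean_t: float               # layer index vs mean t of selective units


def selectivity_summary(
    smap: SelectivityMap, stage: str = "post", n_units: dict[str, int] | None = None
) -> SelectivitySummary:
    """Depth trends: proportion selective and mean selective-unit t per layer."""
    if len(smap.layer_names) < 3:
        raise ValueError("need >= 3 layers for a depth trend")
    rows = []
    for li, layer in enumerate(smap.layer_names):
        for domain in smap.domains:
            e = smap.get(layer, stage, domain)
            width = n_units.get(layer) if n_units else None
            if width is None:
                # infer from the largest index seen; caller may pass exact widths
                width = max(
                    (int(x.indices.max()) + 1 if len(x.indices) else 0)
                    for (lay, stg, _), x in smap.entries.items()
                    if lay == layer and stg == stage
                )
                width = max(width, 1)
            rows.append(
                {
                    "layer": layer,
                    "layer_index": li,
                    "domain": domain,
                    "n_selected": len(e.indices),
                    "proportion": len(e.indices) / width,
                    "mean_t": float(e.t_mean.mean()) if len(e.indices) else np.nan,
                }
            )
    table = pd.DataFrame(rows)
    per_layer = table.groupby("layer_index").agg(
        total_prop=("proportion", "sum"), mean_t=("mean_t", "mean")
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant inputs yield nan, reported as such
        sp = stats.spearmanr(per_layer.index, per_layer["total_prop"]).statistic
        st_ = stats.spearmanr(per_layer.index, per_layer["mean_t"]).statistic
    return SelectivitySummary(
        table=table,
        spearman_proportion=float(sp),
        spearman_mean_t=float(st_),
    )
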