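"""Reproducible benchmark experiments on synthetic planted-truth data.

Each experiment regenerates its inputs from a base seed, runs the relevant
pipeline pieces end-to-end, and returns summary statistics. These are the
package's standing validation studies: FDR calibration on null models,
planted-unit recovery, the non-negative Lasso oracle comparison, encoding
weight/support recovery with matched-selectivity dominance and best-layer
selection, lesion dissociation, noise-ceiling behavior, and the deepening
of category separation across layers.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from .encoding import (
    PositiveLasso,
    average_repeats,
    evaluate_encoding,
    fit_nonneg_sparse_encoding,
    noise_ceiling_mc,
    nonneg_lasso_objective,
    select_best_layer,
    session_zscore,
)
from .geometry import GeometryConfig, category_separation, meta_rdm_trajectories
from .lesion import (
    activation_cost_correlation,
    domain_lesion_spec,
    lesion_cost_profile,
    random_lesion_null,
)
from .localizer import LocalizerDesign, localize_selective_units
from .planted import PlantedModelConfig, build_planted_model, forward_activations
from .readout import ReadoutConfig, train_sparse_readout
from .stimuli import StimulusConfig, generate_stimulus_set
from .voxels import VoxelConfig, simulate_voxel_dataset


def _spawn_seeds(base_seed: int, n: int, stream: int) -> np.ndarray:
    """n deterministic child seeds (< 2**31) from a base seed."""
    ss = np.random.SeedSequence([int(base_seed), stream])
    return (ss.generate_state(n) % (2**31)).astype(np.int64)


# ---------------------------------------------------------------------------
# FDR calibration (null models)
# ---------------------------------------------------------------------------

@dataclass
class FdrCalibrationResult:
    mean_flag_rate: float
    se: float
    n_seeds: int
    q: float

    @property
    def bound(self) -> float:
        return self.q + 3 * self.se


def fdr_calibration_experiment(
    base_seed: int = 0,
    n_seeds: int = 100,
    layer_widths: tuple[int, ...] = (1000, 1000),
    q: float = 0.05,
) -> FdrCalibrationResult:
    """Localizer flag rate on g=0 null models with exchangeable categories.

    The null uses template-free stimuli (every category drawn from the same
    distribution) so no unit has any true preference; the flag rate then
    estimates the localizer's false-positive rate at FDR level ``q``.
    """
    seeds = _spawn_seeds(base_seed, n_seeds, stream=1)
    design = LocalizerDesign(q=q)
    rates = []
    for seed in seeds:
        sc = StimulusConfig(template_scale=0.0, splits={"localizer": 16})
        stim = generate_stimulus_set(sc, int(seed))
        model = build_planted_model(
            stim,
            PlantedModelConfig(layer_widths=list(layer_widths), gain=0.0),
            int(seed) + 1,
        )
        store = forward_activations(model, stim)
        smap = localize_selective_units(store, design)
        flagged = total = 0
        for layer in model.layer_names:
            width = model.layer_sizes()[layer]
            for stage in ("pre", "post"):
                mask = np.zeros(width, bool)
                for dom in design.domains:
                    mask[smap.indices(layer, dom, stage)] = True
                flagged += int(mask.sum())
                total += width
        rates.append(flagged / total)
    rates = np.asarray(rates)
    return FdrCalibrationResult(
        mean_flag_rate=float(rates.mean()),
        se=float(rates.std(ddof=1) / np.sqrt(n_seeds)),
        n_seeds=n_seeds,
        q=q,
    )


# ---------------------------------------------------------------------------
# planted-unit recovery
# ---------------------------------------------------------------------------

@dataclass
class RecoveryResult:
    precision: dict[str, float]
    recall: dict[str, float]

    @property
    def min_precision(self) -> float:
        return min(self.precision.values())

    @property
    def min_recall(self) -> float:
        return min(self.recall.values())


def recovery_experiment(
    base_seed: int = 0,
    gain: float = 4.0,
    stages: tuple[str, ...] = ("pre", "post"),
) -> RecoveryResult:
    """Localizer precision/recall against planted masks, pooled over layers."""
    seeds = _spawn_seeds(base_seed, 2, stream=2)
    stim = generate_stimulus_set(StimulusConfig(), int(seeds[0]))
    model = build_planted_model(
        stim, PlantedModelConfig(gain=gain), int(seeds[1])
    )
    store = forward_activations(model, stim)
    smap = localize_selective_units(store, LocalizerDesign(), stages=stages)
    precision, recall = {}, {}
    for dom in model.domains:
        tp = fp = fn = 0
        for layer in model.layer_names:
            for stage in stages:
                true = set(model.planted_indices(layer, dom).tolist())
                got = set(smap.indices(layer, dom, stage).tolist())
                tp += len(true & got)
                fp += len(got - true)
                fn += len(true - got)
        precision[dom] = tp / max(tp + fp, 1)
        recall[dom] = tp / max(tp + fn, 1)
    return RecoveryResult(precision=precision, recall=recall)


# ---------------------------------------------------------------------------
# non-negative Lasso oracle
# ---------------------------------------------------------------------------

@dataclass
class LassoOracleResult:
    max_gap: float               # worst (solver - oracle) objective gap
    n_problems: int
    all_nonnegative: bool
    grid_step: float


def lasso_oracle_experiment(
    base_seed: int = 0,
    n_problems: int = 100,
    n_grid: int = 41,
    n_obs: int = 30,
) -> LassoOracleResult:
    """Compare the solver against dense grid search on 3-feature problems.

    The oracle evaluates the objective on a cubic lattice over
    [0, w_max]^3 (plus the matching closed-form intercept); the solver must
    never exceed the best lattice value by more than the lattice resolution
    allows.
    """
    rng = np.random.default_rng(_spawn_seeds(base_seed, 1, stream=3)[0])
    max_gap = -np.inf
    all_nonneg = True
    w_max = 2.0
    grid = np.linspace(0.0, w_max, n_grid)
    step = grid[1] - grid[0]
    for _ in range(n_problems):
        p = 3
        X = rng.standard_normal((n_obs, p))
        w_true = np.where(rng.random(p) < 0.7, np.abs(rng.standard_normal(p)), 0.0)
        y = X @ w_true + 0.3 * rng.standard_normal(n_obs) + rng.standard_normal()
        alpha = float(rng.choice([0.01, 0.05, 0.2]))

        est = PositiveLasso(alpha=alpha).fit(X, y)
        all_nonneg &= bool(np.all(est.coef_ >= 0))
        obj_solver = nonneg_lasso_objective(X, y, est.coef_, est.intercept_, alpha)

        # oracle: brute-force lattice; intercept closed-form per lattice point
        ww = np.stack(np.meshgrid(grid, grid, grid, indexing="ij"), axis=-1)
        ww = ww.reshape(-1, p)
        resid_mean = y.mean() - ww @ X.mean(axis=0)
        pred = X @ ww.T + resid_mean  # (n, n_grid^3)
        obj = ((y[:, None] - pred) ** 2).sum(axis=0) / (2 * n_obs) + alpha * ww.sum(
            axis=1
        )
        obj_oracle = float(obj.min())
        max_gap = max(max_gap, obj_solver - obj_oracle)
    return LassoOracleResult(
        max_gap=float(max_gap),
        n_problems=n_problems,
        all_nonnegative=all_nonneg,
        grid_step=float(step),
    )


# ---------------------------------------------------------------------------
# encoding recovery / matched selectivity / best layer
# ---------------------------------------------------------------------------

@dataclass
class EncodingRecoveryResult:
    recovery_ok_rate: float       # seeds with support >= 0.8 and weight r > 0.9
    support_recall_mean: float
    weight_corr_mean: float
    matched_univariate_rate: float
    matched_versa_rate: float
    best_layer_univariate_rate: float
    best_layer_versa_rate: float
    n_seeds: int


def _prep_voxels(store, vox):
    z = session_zscore(vox)
    ids, mat = average_repeats(z)
    id2row = {i: r for r, i in enumerate(store.stimulus_id)}
    rows = np.array([id2row[i] for i in ids])
    id2sp = dict(zip(store.stimulus_id, store.split))
    sp = np.array([id2sp[i] for i in ids])
    return ids, mat, rows, sp


def encoding_recovery_experiment(
    base_seed: int = 0,
    n_seeds: int = 50,
    noise_sd: float = 0.02,
    alphas: tuple[float, ...] = (1e-5, 1e-4, 1e-3),
    eval_alpha: float = 0.1,
) -> EncodingRecoveryResult:
    """Weight/support recovery, matched-selectivity dominance, best layer.

    Per seed: simulate face and scene ROI voxels from layer-2 planted units
    (s=5, low trial noise); (a) refit each face voxel from the true source
    units over a small alpha grid chosen on validation, scoring support
    recall and truth-weight correlation; (b) compare matched (face-unit) vs
    mismatched (scene-unit) encoding of face voxels on the test split; (c)
    select the best layer on validation and check it is the generating one.
    """
    seeds = _spawn_seeds(base_seed, n_seeds, stream=4)
    rec_ok, sups, wcs = [], [], []
    m_uni, m_versa, b_uni, b_versa = [], [], [], []
    for seed in seeds:
        seed = int(seed)
        stim = generate_stimulus_set(StimulusConfig(), seed)
        model = build_planted_model(stim, PlantedModelConfig(), seed + 1)
        store = forward_activations(model, stim)
        smap = localize_selective_units(
            store, LocalizerDesign(), stages=("post",)
        )
        vc = VoxelConfig(rois=["face", "scene"], voxels_per_roi=10,
                         noise_sd=noise_sd)
        truth = {d: model.planted_mask[vc.source_layer][d] for d in vc.rois}
        vox = simulate_voxel_dataset(store, truth, vc, seed + 2)
        ids, mat, rows, sp = _prep_voxels(store, vox)
        m_tr, m_va, m_te = sp == "enc_train", sp == "enc_val", sp == "enc_test"

        # (a) support / weight recovery from the true source units
        fv = vox.roi_domain == "face"
        src = np.flatnonzero(truth["face"])
        X = store.get(vc.source_layer, "post")[rows][:, src]
        recs, wc = [], []
        for v in np.flatnonzero(fv):
            best = None
            for a in alphas:
                em = fit_nonneg_sparse_encoding(X[m_tr], mat[m_tr][:, v], a)
                r = np.corrcoef(em.predict(X[m_va])[:, 0], mat[m_va][:, v])[0, 1]
                if best is None or r > best[0]:
                    best = (r, em)
            w = best[1].weights[0]
            tw = vox.truth_weights[v][src]
            true_sup = set(np.flatnonzero(tw > 0).tolist())
            got_sup = set(np.flatnonzero(w > 1e-8).tolist())
            recs.append(len(true_sup & got_sup) / len(true_sup))
            wc.append(np.corrcoef(w, tw)[0, 1])
        sups.append(np.mean(recs))
        wcs.append(np.mean(wc))
        rec_ok.append(np.mean(recs) >= 0.8 and np.mean(wc) > 0.9)

        # (b, c) matched vs mismatched and best layer, on localized subsets
        y_tr, y_va, y_te = mat[m_tr][:, fv], mat[m_va][:, fv], mat[m_te][:, fv]
        val_metrics, fits = {}, {}
        for layer in model.layer_names:
            idx = smap.indices(layer, "face")
            if len(idx) == 0:
                continue
            Xl = store.get(layer, "post")[rows][:, idx]
            em = fit_nonneg_sparse_encoding(
                Xl[m_tr], y_tr, eval_alpha, train_stimulus_ids=ids[m_tr])
            val_metrics[layer] = evaluate_encoding(em, Xl[m_va], y_va, ids[m_va])
            fits[layer] = (em, Xl)
        best = select_best_layer(val_metrics, model.layer_names)
        b_uni.append(best["univariate"] == vc.source_layer)
        b_versa.append(best["versa"] == vc.source_layer)

        test = {}
        for dom in ("face", "scene"):
            idx = smap.indices(vc.source_layer, dom)
            Xl = store.get(vc.source_layer, "post")[rows][:, idx]
            em = fit_nonneg_sparse_encoding(
                Xl[m_tr], y_tr, eval_alpha, train_stimulus_ids=ids[m_tr])
            test[dom] = evaluate_encoding(em, Xl[m_te], y_te, ids[m_te])
        m_uni.append(test["face"]["univariate"] > test["scene"]["univariate"])
        m_versa.append(test["face"]["versa"] > test["scene"]["versa"])

    return EncodingRecoveryResult(
        recovery_ok_rate=float(np.mean(rec_ok)),
        support_recall_mean=float(np.mean(sups)),
        weight_corr_mean=float(np.mean(wcs)),
        matched_univariate_rate=float(np.mean(m_uni)),
        matched_versa_rate=float(np.mean(m_versa)),
        best_layer_univariate_rate=float(np.mean(b_uni)),
        best_layer_versa_rate=float(np.mean(b_versa)),
        n_seeds=n_seeds,
    )


# ---------------------------------------------------------------------------
# lesion dissociation
# ---------------------------------------------------------------------------

@dataclass
class LesionDissociationResult:
    diagonal_dominance_rate: float
    domain_activation_cost_r: float      # mean over seeds and domains
    domain_r_negative_rate: float
    random_activation_cost_r: float      # mean over seeds (size-matched draws)
    n_seeds: int


def lesion_dissociation_experiment(
    base_seed: int = 0,
    n_seeds: int = 50,
    readout: ReadoutConfig | None = None,
    n_random_draws: int = 2,
) -> LesionDissociationResult:
    """Own-domain deficits, and activation-cost correlations vs random lesions."""
    seeds = _spawn_seeds(base_seed, n_seeds, stream=5)
    diag, dom_r, rand_r = [], [], []
    for seed in seeds:
        seed = int(seed)
        stim = generate_stimulus_set(StimulusConfig(), seed)
        model = build_planted_model(stim, PlantedModelConfig(), seed + 1)
        store = forward_activations(model, stim)
        design = LocalizerDesign()
        smap = localize_selective_units(store, design, stages=("post",))
        train = stim.subset("readout_train")
        evl = stim.subset("readout_eval")
        feats = forward_activations(model, train).get(
            model.layer_names[-1], "post"
        )
        rc = readout or ReadoutConfig()
        rc = dataclasses.replace(rc, seed=seed)
        head = train_sparse_readout(feats, train.category, rc)
        ev_store = forward_activations(model, evl)
        mid = model.layer_names[len(model.layer_names) // 2]

        ok = True
        rs = []
        for dom in design.domains:
            prof = lesion_cost_profile(
                model, head, evl, domain_lesion_spec(smap, dom), rc.k)
            d = prof.as_dict()
            own = d[dom]
            ok &= own > max(v for c, v in d.items() if c != dom)
            rs.append(activation_cost_correlation(
                ev_store, smap.indices(mid, dom), prof, mid))
        diag.append(ok)
        dom_r.append(np.nanmean(rs))
        null = random_lesion_null(
            model, head, evl, smap, design.domains[0], n_random_draws, seed,
            rc.k)
        rand_r.append(np.nanmean([
            activation_cost_correlation(
                ev_store, smap.indices(mid, design.domains[0]), p, mid)
            for p in null
        ]))
    dom_arr = np.asarray(dom_r)
    return LesionDissociationResult(
        diagonal_dominance_rate=float(np.mean(diag)),
        domain_activation_cost_r=float(np.nanmean(dom_arr)),
        domain_r_negative_rate=float(np.mean(dom_arr < 0)),
        random_activation_cost_r=float(np.nanmean(rand_r)),
        n_seeds=n_seeds,
    )


# ---------------------------------------------------------------------------
# noise ceiling grid
# ---------------------------------------------------------------------------

@dataclass
class NoiseCeilingGridResult:
    noise_sds: list[float]
    univariate: list[float]
    rdm: list[float]

    def monotone_decreasing(self) -> bool:
        u = np.asarray(self.univariate)
        r = np.asarray(self.rdm)
        return bool(np.all(np.diff(u) <= 1e-9) and np.all(np.diff(r) <= 1e-9))


def noise_ceiling_grid_experiment(
    base_seed: int = 0,
    noise_sds: tuple[float, ...] = (0.0, 0.25, 0.5, 1.0, 2.0, 4.0),
    n_stimuli: int = 100,
    n_voxels: int = 20,
    n_sim: int = 300,
) -> NoiseCeilingGridResult:
    """Monte-Carlo ceiling along a noise grid (1 at zero noise, decreasing)."""
    seed = int(_spawn_seeds(base_seed, 1, stream=6)[0])
    uni, rdm = [], []
    for sd in noise_sds:
        nc = noise_ceiling_mc(
            signal_sd=1.0, noise_sd=sd, n_stimuli=n_stimuli,
            n_voxels=n_voxels, n_rep=3, n_sim=n_sim, seed=seed)
        uni.append(nc.univariate)
        rdm.append(nc.rdm)
    return NoiseCeilingGridResult(
        noise_sds=list(noise_sds), univariate=uni, rdm=rdm)


# ---------------------------------------------------------------------------
# geometry separation
# ---------------------------------------------------------------------------

@dataclass
class GeometrySeparationResult:
    first_layer_ratio: float      # mean between/within distance ratio
    deepest_layer_ratio: float
    deeper_rate: float            # fraction of seeds with deepest > first
    n_seeds: int


def geometry_separation_experiment(
    base_seed: int = 0,
    n_seeds: int = 10,
    probe_per_category: int = 30,
) -> GeometrySeparationResult:
    """Between/within category separation in the MDS embedding by depth.

    Uses a 30-image-per-category probe set of the four domain categories,
    the standard size for layer-trajectory visualizations.
    """
    seeds = _spawn_seeds(base_seed, n_seeds, stream=7)
    first, deepest, deeper = [], [], []
    for seed in seeds:
        seed = int(seed)
        sc = StimulusConfig()
        sc.splits = dict(sc.splits)
        sc.splits["probe"] = probe_per_category
        stim = generate_stimulus_set(sc, seed)
        model = build_planted_model(stim, PlantedModelConfig(), seed + 1)
        store = forward_activations(model, stim)
        coords, _ = meta_rdm_trajectories(
            store, stim, GeometryConfig(), categories=list(model.domains)
        )
        r_first = category_separation(coords, model.layer_names[0])
        r_deep = category_separation(coords, model.layer_names[-1])
        first.append(r_first)
        deepest.append(r_deep)
        deeper.append(r_deep > r_first)
    return GeometrySeparationResult(
        first_layer_ratio=float(np.mean(first)),
        deepest_layer_ratio=float(np.mean(deepest)),
        deeper_rate=float(np.mean(deeper)),
        n_seeds=n_seeds,
    )
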