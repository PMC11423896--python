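"""Sparse positive-weighted voxel encoding models and their evaluation.

The linking model between feature-model units and voxels is deliberately
constrained: each voxel is fit as a non-negative, L1-regularized linear
combination of *matched-selectivity* units only (face voxels from
face-selective units, and so on), with an unpenalized, unconstrained
intercept:

    minimize  (1 / 2n) * ||y - X w - c||^2  +  alpha * sum(w),   w >= 0.

Preparation mirrors the standard fMRI workflow: per-session z-scoring of
each voxel's response profile, averaging over stimulus repeats, and a
reliability filter on the noise-ceiling signal-to-noise ratio (NCSNR).
Correspondence is scored univariately (ROI-mean response profile) and
multivariately (veRSA: Pearson correlation between predicted-pattern and
measured-pattern RDM lower triangles), with the evaluation layer chosen on
a validation split and final numbers from a held-out test split only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.linear_model import Lasso
from sklearn.utils.validation import check_is_fitted

from .containers import VoxelDataset
from .rsa import compute_rdm, rdm_correlation


@dataclass
class EncodingConfig:
    alpha: float = 0.1
    ncsnr_threshold: float = 0.3
    layers: list[str] | None = None      # None -> all layers in the store
    stage: str = "post"


# ---------------------------------------------------------------------------
# voxel data preparation
# ---------------------------------------------------------------------------

def session_zscore(data: VoxelDataset) -> VoxelDataset:
    """z-score each voxel's within-session response profile (sample SD).

    Removes per-session affine instabilities (offset + gain) exactly.
    Zero-variance voxel-sessions are left at zero and flagged.
    """
    z = data.responses.astype(float).copy()
    flags = []
    for s in data.sessions():
        m = data.session_id == s
        if m.sum() < 2:
            raise ValueError(f"session {s} has < 2 trials")
        block = z[m]
        mu = block.mean(axis=0)
        sd = block.std(axis=0, ddof=1)
        dead = sd == 0
        sd_safe = np.where(dead, 1.0, sd)
        z[m] = (block - mu) / sd_safe
        for v in np.flatnonzero(dead):
            z[m, v] = 0.0
            flags.append((int(v), int(s)))
    out = VoxelDataset(
        responses=z,
        session_id=data.session_id,
        stimulus_id=data.stimulus_id,
        repeat_index=data.repeat_index,
        roi_domain=data.roi_domain,
        source_layer=data.source_layer,
        source_units=data.source_units,
        truth_weights=data.truth_weights,
        noise_sd=data.noise_sd,
        seed=data.seed,
        zscore_flags=np.asarray(flags, dtype=int) if flags else None,
    )
    return out


def average_repeats(data: VoxelDataset) -> tuple[np.ndarray, np.ndarray]:
    """Mean response per stimulus across its repeats.

    Returns ``(stimulus_ids, matrix)`` with stimulus ids ascending and the
    matrix of shape (n_stimuli, n_voxels).
    """
    ids = np.unique(data.stimulus_id)
    out = np.empty((len(ids), data.n_voxels))
    for i, sid in enumerate(ids):
        m = data.stimulus_id == sid
        if not m.any():  # pragma: no cover - unreachable given unique()
            raise ValueError(f"stimulus id {sid} has no trials")
        out[i] = data.responses[m].mean(axis=0)
    return ids, out


def ncsnr(data: VoxelDataset) -> np.ndarray:
    """Noise-ceiling signal-to-noise ratio per voxel.

    noise SD = sqrt(mean over stimuli of the unbiased across-repeat
    variance); signal SD = sqrt(max(0, variance of single-trial responses
    minus noise variance)); ncsnr = signal SD / noise SD (infinite where the
    noise SD is zero).
    """
    ids = np.unique(data.stimulus_id)
    noise_var = np.zeros(data.n_voxels)
    for sid in ids:
        m = data.stimulus_id == sid
        if m.sum() < 2:
            raise ValueError(f"stimulus id {sid} has < 2 repeats")
        noise_var += data.responses[m].var(axis=0, ddof=1)
    noise_var /= len(ids)
    total_var = data.responses.var(axis=0, ddof=1)
    signal_var = np.maximum(total_var - noise_var, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.sqrt(signal_var) / np.sqrt(noise_var)
    out[noise_var == 0] = np.inf
    return out


def reliability_filter(data: VoxelDataset, threshold: float = 0.3) -> np.ndarray:
    """Boolean mask of voxels whose NCSNR exceeds ``threshold``."""
    return ncsnr(data) > threshold


# ---------------------------------------------------------------------------
# non-negative sparse regression
# ---------------------------------------------------------------------------

class PositiveLasso(BaseEstimator, RegressorMixin):
    """L1-regularized linear regression with non-negative coefficients.

    Objective: (1/2n) ||y - Xw - c||^2 + alpha * sum(w), w >= 0, intercept
    c unpenalized and unconstrained. With alpha > 0 this delegates to
    coordinate descent (sklearn Lasso with a positivity constraint); with
    alpha = 0 it solves the non-negative least-squares problem directly.
    """

    def __init__(self, alpha: float = 0.1, max_iter: int = 50_000,
                 tol: float = 1e-6):
        self.alpha = alpha
        self.max_iter = max_iter
        self.tol = tol

    def fit(self, X: np.ndarray, y: np.ndarray) -> "PositiveLasso":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if X.shape[0] != y.shape[0]:
            raise ValueError("X and y have misaligned rows")
        if X.shape[1] < 1:
            raise ValueError("X needs at least one feature column")
        if self.alpha == 0:
            from scipy.optimize import nnls

            xm, ym = X.mean(axis=0), y.mean()
            w, _ = nnls(X - xm, y - ym)
            self.coef_ = w
            self.intercept_ = float(ym - xm @ w)
        else:
            est = Lasso(
                alpha=self.alpha,
                positive=True,
                fit_intercept=True,
                max_iter=self.max_iter,
                tol=self.tol,
            )
            with warnings.catch_warnings():
                from sklearn.exceptions import ConvergenceWarning

                warnings.simplefilter("ignore", ConvergenceWarning)
                est.fit(X, y)
            self.coef_ = est.coef_.copy()
            self.intercept_ = float(est.intercept_)
        assert np.all(self.coef_ >= 0), "positivity violated"
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        check_is_fitted(self, "coef_")
        return np.asarray(X, dtype=float) @ self.coef_ + self.intercept_


def nonneg_lasso_objective(
    X: np.ndarray, y: np.ndarray, w: np.ndarray, c: float, alpha: float
) -> float:
    """The fit objective; used by tests and diagnostics."""
    n = X.shape[0]
    resid = y - X @ w - c
    return float(resid @ resid / (2 * n) + alpha * np.sum(w))


@dataclass
class EncodingModel:
    """Per-voxel non-negative sparse weights over a selective-unit subset."""

    weights: np.ndarray            # (n_voxels, n_subset_units), >= 0
    intercepts: np.ndarray         # (n_voxels,)
    unit_indices: np.ndarray       # global indices of the subset columns
    layer: str
    stage: str
    domain: str                    # selectivity of the source subset
    alpha: float
    train_stimulus_ids: np.ndarray
    n_nonzero: np.ndarray = field(default_factory=lambda: np.zeros(0, int))

    def predict(self, X_subset: np.ndarray) -> np.ndarray:
        return X_subset @ self.weights.T + self.intercepts


def fit_nonneg_sparse_encoding(
    X: np.ndarray,
    y: np.ndarray,
    alpha: float,
    unit_indices: np.ndarray | None = None,
    layer: str = "?",
    stage: str = "post",
    domain: str = "?",
    train_stimulus_ids: np.ndarray | None = None,
) -> EncodingModel:
    """Fit one encoding model per voxel (column of ``y``)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if y.ndim == 1:
        y = y[:, None]
    n_vox = y.shape[1]
    W = np.zeros((n_vox, X.shape[1]))
    c = np.zeros(n_vox)
    for v in range(n_vox):
        est = PositiveLasso(alpha=alpha).fit(X, y[:, v])
        W[v] = est.coef_
        c[v] = est.intercept_
    return EncodingModel(
        weights=W,
        intercepts=c,
        unit_indices=(
            np.asarray(unit_indices)
            if unit_indices is not None
            else np.arange(X.shape[1])
        ),
        layer=layer,
        stage=stage,
        domain=domain,
        alpha=alpha,
        train_stimulus_ids=(
            np.asarray(train_stimulus_ids)
            if train_stimulus_ids is not None
            else np.zeros(0, int)
        ),
        n_nonzero=(W > 0).sum(axis=1),
    )


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    if x.std() == 0 or y.std() == 0:
        warnings.warn("correlation undefined (zero variance)", stacklevel=3)
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def evaluate_encoding(
    model: EncodingModel,
    X_subset: np.ndarray,
    measured: np.ndarray,
    stimulus_ids: np.ndarray | None = None,
) -> dict[str, float]:
    """Univariate and veRSA correspondence on an evaluation split.

    ``X_subset``: activations of the model's unit subset for the split's
    stimuli; ``measured``: prepared (z-scored, repeat-averaged) voxel
    responses, same stimulus order. Refuses stimuli seen at training time.
    """
    if stimulus_ids is not None and len(model.train_stimulus_ids):
        if np.intersect1d(stimulus_ids, model.train_stimulus_ids).size:
            raise ValueError("evaluation split overlaps the training stimuli")
    pred = model.predict(X_subset)
    res: dict[str, float] = {}
    if np.allclose(pred.std(axis=0), 0.0):
        # positivity drove every weight to zero: the model predicts a
        # constant and explains no stimulus-driven structure
        warnings.warn("constant predictions; correspondence set to 0",
                      stacklevel=2)
        return {"univariate": 0.0, "versa": 0.0}
    res["univariate"] = _pearson(pred.mean(axis=1), measured.mean(axis=1))
    if pred.shape[1] >= 2:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            v = rdm_correlation(
                compute_rdm(pred, stimulus_ids), compute_rdm(measured, stimulus_ids)
            )
        res["versa"] = 0.0 if not np.isfinite(v) else v
    else:
        res["versa"] = float("nan")
    return res


def select_best_layer(
    metrics: dict[str, dict[str, float]], layer_order: list[str]
) -> dict[str, str]:
    """Argmax layer per metric on validation scores; ties -> shallower layer."""
    if not metrics:
        raise ValueError("no layers evaluated")
    names = [l for l in layer_order if l in metrics]
    out = {}
    for metric in next(iter(metrics.values())):
        best, best_v = None, -np.inf
        for layer in names:  # shallow -> deep; strict > keeps shallower on tie
            v = metrics[layer][metric]
            if np.isfinite(v) and v > best_v:
                best, best_v = layer, v
        out[metric] = best if best is not None else names[0]
    return out


# ---------------------------------------------------------------------------
# noise ceilings
# ---------------------------------------------------------------------------

@dataclass
class NoiseCeiling:
    univariate: float
    rdm: float
    univariate_spread: float
    rdm_spread: float
    n_sim: int
    seed: int


def noise_ceiling_mc(
    signal_sd: np.ndarray | float,
    noise_sd: np.ndarray | float,
    n_stimuli: int,
    n_voxels: int,
    n_rep: int = 3,
    n_sim: int = 200,
    seed: int = 0,
) -> NoiseCeiling:
    """Monte-Carlo noise ceiling for the univariate and RDM metrics.

    Each simulation draws a noiseless stimulus x voxel signal pattern from
    N(0, signal_sd^2), forms a noisy measurement by averaging ``n_rep``
    noisy repeats, and correlates noiseless with noisy summaries. The
    ceiling is the mean correlation over simulations. In the synthetic
    regime the SDs are the generator's true parameters; otherwise they are
    moment estimates from repeat data.
    """
    if n_sim < 100:
        raise ValueError("n_sim must be >= 100 for a stable ceiling")
    sig = np.broadcast_to(np.asarray(signal_sd, dtype=float), (n_voxels,))
    noi = np.broadcast_to(np.asarray(noise_sd, dtype=float), (n_voxels,))
    if np.any(sig <= 0):
        raise ValueError("signal SDs must be positive")
    if np.any(noi < 0):
        raise ValueError("noise SDs must be non-negative")
    rng = np.random.default_rng(seed)
    uni, rdm = [], []
    for _ in range(n_sim):
        clean = rng.standard_normal((n_stimuli, n_voxels)) * sig
        noisy = clean + rng.standard_normal((n_stimuli, n_voxels)) * (
            noi / np.sqrt(n_rep)
        )
        if np.all(noi == 0):
            uni.append(1.0)
            rdm.append(1.0)
            continue
        uni.append(_pearson(clean.mean(axis=1), noisy.mean(axis=1)))
        if n_voxels >= 2:
            rdm.append(rdm_correlation(compute_rdm(clean), compute_rdm(noisy)))
    rdm_arr = np.asarray(rdm if rdm else [np.nan])
    uni_arr = np.asarray(uni)
    return NoiseCeiling(
        univariate=float(np.nanmean(uni_arr)),
        rdm=float(np.nanmean(rdm_arr)),
        univariate_spread=float(np.nanstd(uni_arr)),
        rdm_spread=float(np.nanstd(rdm_arr)),
        n_sim=n_sim,
        seed=seed,
    )


def moment_noise_estimates(data: VoxelDataset) -> tuple[np.ndarray, np.ndarray]:
    """Per-voxel (signal SD, noise SD) moment estimates from repeat data."""
    ids = np.unique(data.stimulus_id)
    noise_var = np.zeros(data.n_voxels)
    for sid in ids:
        m = data.stimulus_id == sid
        noise_var += data.responses[m].var(axis=0, ddof=1)
    noise_var /= len(ids)
    total = data.responses.var(axis=0, ddof=1)
    signal_sd = np.sqrt(np.maximum(total - noise_var, 0.0))
    return signal_sd, np.sqrt(noise_var)
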