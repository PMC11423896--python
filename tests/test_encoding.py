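"""Voxel preparation, non-negative sparse encoding, and its evaluation."""

import numpy as np
import pytest

from catselect import (
    EncodingModel,
    PositiveLasso,
    VoxelConfig,
    average_repeats,
    evaluate_encoding,
    fit_nonneg_sparse_encoding,
    ncsnr,
    noise_ceiling_mc,
    select_best_layer,
    session_zscore,
    simulate_voxel_dataset,
)
from catselect.containers import VoxelDataset
from catselect.encoding import nonneg_lasso_objective, reliability_filter


def _toy_dataset(responses, session_id=None, stimulus_id=None, repeat_index=None):
    n = responses.shape[0]
    return VoxelDataset(
        responses=np.asarray(responses, float),
        session_id=np.zeros(n, int) if session_id is None else np.asarray(session_id),
        stimulus_id=np.arange(n) if stimulus_id is None else np.asarray(stimulus_id),
        repeat_index=np.zeros(n, int) if repeat_index is None else np.asarray(repeat_index),
        roi_domain=np.asarray(["face"] * responses.shape[1], dtype=object),
        source_layer="layer2",
        source_units=np.arange(3),
        truth_weights=None,
        noise_sd=0.0,
        seed=0,
    )


class TestSessionZscore:
    def test_each_session_voxel_has_zero_mean_unit_sd(self, rng):
        resp = rng.standard_normal((40, 6)) * 3 + 2
        data = _toy_dataset(resp, session_id=np.repeat([0, 1], 20))
        z = session_zscore(data)
        for s in (0, 1):
            block = z.responses[z.session_id == s]
            assert np.abs(block.mean(axis=0)).max() < 1e-12
            assert np.abs(block.std(axis=0, ddof=1) - 1).max() < 1e-12

    def test_single_session_equals_global_zscore(self, rng):
        resp = rng.standard_normal((30, 4))
        z = session_zscore(_toy_dataset(resp))
        expect = (resp - resp.mean(axis=0)) / resp.std(axis=0, ddof=1)
        assert np.allclose(z.responses, expect)

    def test_zero_variance_voxel_session_left_at_zero_and_flagged(self):
        resp = np.ones((10, 2))
        resp[:, 1] = np.arange(10)
        z = session_zscore(_toy_dataset(resp))
        assert np.all(z.responses[:, 0] == 0.0)
        assert z.zscore_flags is not None
        assert (0, 0) in {tuple(r) for r in z.zscore_flags}

    def test_tiny_session_raises(self):
        data = _toy_dataset(np.ones((3, 1)), session_id=np.array([0, 0, 1]))
        with pytest.raises(ValueError, match="< 2 trials"):
            session_zscore(data)


class TestAverageRepeats:
    def test_simple_mean(self):
        data = _toy_dataset(
            np.array([[1.0], [2.0], [3.0]]),
            stimulus_id=np.array([7, 7, 7]),
            repeat_index=np.array([0, 1, 2]),
        )
        ids, avg = average_repeats(data)
        assert ids.tolist() == [7]
        assert avg[0, 0] == pytest.approx(2.0)

    def test_identical_repeats_average_to_themselves(self, rng):
        row = rng.standard_normal(5)
        data = _toy_dataset(
            np.tile(row, (3, 1)),
            stimulus_id=np.array([1, 1, 1]),
            repeat_index=np.array([0, 1, 2]),
        )
        _, avg = average_repeats(data)
        assert np.allclose(avg[0], row)


class TestNcsnr:
    def test_zero_noise_voxel_reports_infinite_reliability(self):
        resp = np.repeat(np.arange(5.0)[:, None], 3, axis=0)
        data = _toy_dataset(
            resp, stimulus_id=np.repeat(np.arange(5), 3),
            repeat_index=np.tile(np.arange(3), 5),
        )
        assert np.isinf(ncsnr(data)[0])

    def test_pure_noise_voxel_has_near_zero_reliability(self):
        vals = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            resp = rng.standard_normal((60, 1))
            data = _toy_dataset(
                resp, stimulus_id=np.repeat(np.arange(20), 3),
                repeat_index=np.tile(np.arange(3), 20),
            )
            vals.append(ncsnr(data)[0])
        assert np.mean(vals) < 0.3

    def test_threshold_filter_is_strictly_greater(self):
        rng = np.random.default_rng(0)
        n_stim, n_rep = 40, 3
        sig_sds = np.array([0.0, 0.1, 0.5, 2.0])
        signal = rng.standard_normal((n_stim, len(sig_sds))) * sig_sds
        resp = np.repeat(signal, n_rep, axis=0) + rng.standard_normal(
            (n_stim * n_rep, len(sig_sds))
        )
        data = _toy_dataset(
            resp, stimulus_id=np.repeat(np.arange(n_stim), n_rep),
            repeat_index=np.tile(np.arange(n_rep), n_stim),
        )
        rel = ncsnr(data)
        assert np.array_equal(reliability_filter(data, 0.3), rel > 0.3)

    def test_reliability_decreases_with_trial_noise(self, store, model):
        """Mean NCSNR falls monotonically along a noise grid (many seeds)."""
        truth = {"face": model.planted_mask["layer2"]["face"]}
        grid = [0.05, 0.2, 0.8]
        means = []
        for sd in grid:
            vals = []
            for seed in range(10):
                cfg = VoxelConfig(rois=["face"], voxels_per_roi=4, noise_sd=sd)
                vox = simulate_voxel_dataset(store, truth, cfg, seed=seed)
                vals.append(ncsnr(session_zscore(vox)).mean())
            means.append(np.mean(vals))
        assert means[0] > means[1] > means[2]


class TestPositiveLasso:
    def test_alpha_zero_orthonormal_recovers_exactly(self):
        q, _ = np.linalg.qr(np.random.default_rng(1).standard_normal((40, 4)))
        w_true = np.array([1.5, 0.0, 0.7, 0.2])
        y = q @ w_true + 3.0
        est = PositiveLasso(alpha=0.0).fit(q, y)
        assert np.allclose(est.coef_, w_true, atol=1e-6)
        assert est.intercept_ == pytest.approx(3.0, abs=1e-6)

    def test_negated_tuning_forces_all_weights_to_zero(self, rng):
        x = rng.standard_normal((50, 3))
        y = -(x @ np.array([1.0, 2.0, 0.5]))  # anti-correlated with every column
        est = PositiveLasso(alpha=0.01).fit(x, y)
        assert np.all(est.coef_ == 0.0)
        assert est.intercept_ == pytest.approx(y.mean())

    def test_negative_alpha_raises(self):
        with pytest.raises(ValueError, match="alpha"):
            PositiveLasso(alpha=-0.1).fit(np.ones((4, 1)), np.ones(4))

    def test_misaligned_rows_raise(self):
        with pytest.raises(ValueError, match="misaligned"):
            PositiveLasso(alpha=0.1).fit(np.ones((4, 1)), np.ones(5))

    def test_nonzero_count_monotone_in_alpha(self, rng):
        """Stronger L1 never activates more weights on a fixed problem."""
        x = rng.standard_normal((60, 8))
        y = x[:, :4] @ np.array([1.0, 0.8, 0.5, 0.3]) + 0.1 * rng.standard_normal(60)
        counts = []
        for alpha in [1e-4, 1e-3, 1e-2, 0.1, 1.0]:
            est = PositiveLasso(alpha=alpha).fit(x, y)
            counts.append(int((est.coef_ > 0).sum()))
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_objective_helper_matches_definition(self, rng):
        x = rng.standard_normal((10, 2))
        y = rng.standard_normal(10)
        w = np.array([0.3, 0.0])
        obj = nonneg_lasso_objective(x, y, w, 0.5, alpha=0.1)
        resid = y - x @ w - 0.5
        assert obj == pytest.approx(resid @ resid / 20 + 0.1 * 0.3)


class TestEvaluate:
    def _model(self, weights, ids):
        w = np.atleast_2d(weights)
        return EncodingModel(
            weights=w, intercepts=np.zeros(w.shape[0]),
            unit_indices=np.arange(w.shape[1]), layer="layer2", stage="post",
            domain="face", alpha=0.0, train_stimulus_ids=np.asarray(ids),
        )

    def test_perfect_model_on_noiseless_voxels_scores_one(self, rng):
        x = rng.standard_normal((30, 6))
        w = np.abs(rng.standard_normal((4, 6)))
        measured = x @ w.T
        em = self._model(w, ids=[])
        res = evaluate_encoding(em, x, measured)
        assert res["univariate"] == pytest.approx(1.0)
        assert res["versa"] == pytest.approx(1.0)

    def test_shuffled_predictions_score_near_zero(self, rng):
        x = rng.standard_normal((60, 6))
        w = np.abs(rng.standard_normal((4, 6)))
        measured = x @ w.T
        rs = []
        for seed in range(10):
            perm = np.random.default_rng(seed).permutation(60)
            em = self._model(w, ids=[])
            res = evaluate_encoding(em, x[perm], measured)
            rs.append(res["univariate"])
        assert abs(np.mean(rs)) < 0.15

    def test_train_eval_overlap_raises(self, rng):
        x = rng.standard_normal((10, 3))
        em = self._model(np.ones((2, 3)), ids=[1, 2, 3])
        with pytest.raises(ValueError, match="overlaps"):
            evaluate_encoding(em, x, x @ np.ones((3, 2)),
                              stimulus_ids=np.array([3, 4]))


class TestBestLayer:
    def test_monotone_profile_selects_deepest(self):
        metrics = {
            "layer1": {"univariate": 0.1, "versa": 0.2},
            "layer2": {"univariate": 0.5, "versa": 0.6},
            "layer3": {"univariate": 0.9, "versa": 0.8},
        }
        best = select_best_layer(metrics, ["layer1", "layer2", "layer3"])
        assert best == {"univariate": "layer3", "versa": "layer3"}

    def test_ties_break_to_the_shallower_layer(self):
        metrics = {
            "layer1": {"univariate": 0.5},
            "layer2": {"univariate": 0.5},
        }
        best = select_best_layer(metrics, ["layer1", "layer2"])
        assert best["univariate"] == "layer1"

    def test_empty_metrics_raise(self):
        with pytest.raises(ValueError, match="no layers"):
            select_best_layer({}, [])


class TestNoiseCeiling:
    def test_zero_noise_ceiling_is_exactly_one(self):
        nc = noise_ceiling_mc(1.0, 0.0, n_stimuli=40, n_voxels=8, n_sim=100,
                              seed=0)
        assert nc.univariate == 1.0
        assert nc.rdm == 1.0

    def test_huge_noise_ceiling_collapses_toward_zero(self):
        nc = noise_ceiling_mc(1.0, 50.0, n_stimuli=40, n_voxels=8, n_sim=150,
                              seed=0)
        assert abs(nc.univariate) < 0.15
        assert abs(nc.rdm) < 0.15

    def test_nonpositive_signal_variance_raises(self):
        with pytest.raises(ValueError, match="signal"):
            noise_ceiling_mc(0.0, 1.0, n_stimuli=10, n_voxels=4, n_sim=100)

    def test_too_few_simulations_raise(self):
        with pytest.raises(ValueError, match="n_sim"):
            noise_ceiling_mc(1.0, 1.0, n_stimuli=10, n_voxels=4, n_sim=10)


def test_fit_nonneg_sparse_encoding_always_nonnegative(store, model, rng):
    idx = model.planted_indices("layer2", "face")
    x = store.get("layer2", "post")[:100, idx]
    y = x @ np.abs(rng.standard_normal((3, len(idx)))).T
    for alpha in (0.0, 1e-3, 0.1):
        em = fit_nonneg_sparse_encoding(x, y, alpha)
        assert np.all(em.weights >= 0)
        assert np.all(np.isfinite(em.weights))
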