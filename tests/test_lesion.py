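"""Lesion cost profiles, dissociation, and activation-cost prediction."""

import numpy as np
import pytest

from catselect import (
    CostProfile,
    LesionSpec,
    ReadoutConfig,
    activation_cost_correlation,
    compare_cost_profiles,
    crossval_top_affected,
    domain_lesion_spec,
    downstream_selectivity_change,
    forward_activations,
    lesion_cost_profile,
    random_lesion_null,
    top_fraction_lesion_spec,
    train_sparse_readout,
    topk_accuracy_per_category,
)

DOMAINS = ["face", "body", "scene", "word"]


@pytest.fixture(scope="module")
def head(model, stimulus_set, store):
    train = stimulus_set.subset("readout_train")
    feats = store.get(model.layer_names[-1], "post")[
        np.isin(store.stimulus_id, train.stimulus_id)
    ]
    return train_sparse_readout(feats, train.category, ReadoutConfig(seed=0))


@pytest.fixture(scope="module")
def eval_set(stimulus_set):
    return stimulus_set.subset("readout_eval")


def test_empty_lesion_has_zero_cost(model, head, eval_set):
    prof = lesion_cost_profile(model, head, eval_set, LesionSpec(units={}), k=1)
    assert np.all(prof.deficit == 0.0)


def test_total_lesion_drops_mean_accuracy_to_chance(model, head, eval_set):
    spec = LesionSpec(
        units={lay: np.arange(n) for lay, n in model.layer_sizes().items()}
    )
    prof = lesion_cost_profile(model, head, eval_set, spec, k=1)
    n_cat = len(prof.categories)
    # constant features: deterministic tie-broken predictions, chance on average
    assert prof.lesioned.mean() == pytest.approx(1.0 / n_cat)
    assert np.allclose(prof.deficit, 100.0 * (prof.baseline - prof.lesioned))


def test_own_domain_deficit_dominates(model, head, eval_set, smap_post):
    for dom in DOMAINS:
        prof = lesion_cost_profile(
            model, head, eval_set, domain_lesion_spec(smap_post, dom), k=1
        )
        d = prof.as_dict()
        own = d[dom]
        assert own > max(v for c, v in d.items() if c != dom)


def test_head_is_untouched_by_lesion_evaluation(model, head, eval_set, smap_post):
    w_before = head.weights.copy()
    b_before = head.bias.copy()
    lesion_cost_profile(
        model, head, eval_set, domain_lesion_spec(smap_post, "face"), k=1
    )
    assert np.array_equal(head.weights, w_before)
    assert np.array_equal(head.bias, b_before)


class TestCrossval:
    def test_destroyed_category_is_selected_and_max_on_heldout(
        self, model, head, eval_set, smap_post
    ):
        spec = domain_lesion_spec(smap_post, "face")
        selected, held = crossval_top_affected(
            model, head, eval_set, spec, n_top=1, k=1, seed=0
        )
        assert selected == ["face"]
        assert held > 0

    def test_n_top_equals_all_matches_overall_mean(
        self, model, head, eval_set, smap_post
    ):
        """With every category selected, the held-out summary is the plain mean."""
        spec = domain_lesion_spec(smap_post, "face")
        n_cat = len(np.unique(eval_set.category))
        selected, held = crossval_top_affected(
            model, head, eval_set, spec, n_top=n_cat, k=1, seed=3
        )
        assert sorted(selected) == sorted(np.unique(eval_set.category))
        # rebuild half B with the function's own (documented) split rule
        rng = np.random.default_rng(3)
        half_a = np.zeros(eval_set.n_stimuli, dtype=bool)
        for cat in np.unique(eval_set.category):
            idx = rng.permutation(np.flatnonzero(eval_set.category == cat))
            half_a[idx[: int(np.ceil(len(idx) / 2))]] = True
        from catselect.containers import StimulusSet

        half_b = StimulusSet(
            features=eval_set.features[~half_a],
            category=eval_set.category[~half_a],
            split=eval_set.split[~half_a],
            stimulus_id=eval_set.stimulus_id[~half_a],
            templates=eval_set.templates,
            category_names=eval_set.category_names,
            seed=eval_set.seed,
        )
        prof_b = lesion_cost_profile(model, head, half_b, spec, k=1)
        assert held == pytest.approx(prof_b.deficit.mean())

    def test_two_seeds_agree_on_planted_domain(
        self, model, head, eval_set, smap_post
    ):
        spec = domain_lesion_spec(smap_post, "scene")
        for seed in (0, 1):
            selected, _ = crossval_top_affected(
                model, head, eval_set, spec, n_top=2, k=1, seed=seed
            )
            assert "scene" in selected


class TestProfileComparison:
    def _prof(self, deficits):
        d = np.asarray(deficits, float)
        return CostProfile(
            categories=[f"c{i}" for i in range(len(d))],
            deficit=d,
            baseline=np.ones(len(d)),
            lesioned=np.ones(len(d)) - d / 100,
            split="readout_eval",
            k=1,
        )

    def test_self_correlation_is_one(self):
        p = self._prof([1.0, 5.0, -2.0, 0.5])
        assert compare_cost_profiles(p, p) == pytest.approx(1.0)

    def test_negated_profile_gives_minus_one(self):
        p = self._prof([1.0, 5.0, -2.0, 0.5])
        q = self._prof([-1.0, -5.0, 2.0, -0.5])
        assert compare_cost_profiles(p, q) == pytest.approx(-1.0)

    def test_zero_variance_profile_is_flagged(self):
        p = self._prof([1.0, 1.0, 1.0])
        q = self._prof([1.0, 2.0, 3.0])
        with pytest.warns(UserWarning, match="undefined"):
            assert np.isnan(compare_cost_profiles(p, q))

    def test_mismatched_categories_raise(self):
        p = self._prof([1.0, 2.0])
        q = self._prof([1.0, 2.0, 3.0])
        with pytest.raises(ValueError, match="different category"):
            compare_cost_profiles(p, q)

    def test_domain_lesions_are_dissociated(self, model, head, eval_set, smap_post):
        profs = {
            dom: lesion_cost_profile(
                model, head, eval_set, domain_lesion_spec(smap_post, dom), k=1
            )
            for dom in DOMAINS
        }
        rs = [
            compare_cost_profiles(profs[a], profs[b])
            for i, a in enumerate(DOMAINS)
            for b in DOMAINS[i + 1 :]
        ]
        assert np.nanmean(rs) < 0.3


class TestActivationCost:
    def test_domain_lesions_show_negative_relation(
        self, model, head, eval_set, smap_post
    ):
        ev_store = forward_activations(model, eval_set)
        for dom in DOMAINS:
            prof = lesion_cost_profile(
                model, head, eval_set, domain_lesion_spec(smap_post, dom), k=1
            )
            r = activation_cost_correlation(
                ev_store, smap_post.indices("layer2", dom), prof, "layer2"
            )
            assert r < 0

    def test_empty_unit_set_is_flagged(self, store, model, head, eval_set,
                                       smap_post):
        ev_store = forward_activations(model, eval_set)
        prof = lesion_cost_profile(
            model, head, eval_set, domain_lesion_spec(smap_post, "face"), k=1
        )
        with pytest.warns(UserWarning, match="empty unit set"):
            assert np.isnan(
                activation_cost_correlation(ev_store, np.array([], int), prof,
                                            "layer2")
            )


class TestRandomLesions:
    def test_draws_are_size_matched_and_reproducible(
        self, model, head, eval_set, smap_post
    ):
        p1 = random_lesion_null(model, head, eval_set, smap_post, "face",
                                n_draws=2, seed=5)
        p2 = random_lesion_null(model, head, eval_set, smap_post, "face",
                                n_draws=2, seed=5)
        for a, b in zip(p1, p2):
            assert np.array_equal(a.deficit, b.deficit)

    def test_full_layer_sized_draw_equals_full_lesion(self, model, head, eval_set):
        """When the reference count is the whole layer, the draw is forced."""
        from catselect.localizer import SelectivityEntry, SelectivityMap

        widths = model.layer_sizes()
        entries = {
            (lay, "post", "face"): SelectivityEntry(
                indices=np.arange(widths[lay]),
                t_per_contrast=np.zeros((widths[lay], 1)),
                contrasts=["object"],
                t_mean=np.zeros(widths[lay]),
            )
            for lay in model.layer_names
        }
        fake = SelectivityMap(
            entries=entries, layer_names=model.layer_names, domains=["face"],
            stages=("post",), method="ttest_fdr",
        )
        null = random_lesion_null(model, head, eval_set, fake, "face",
                                  n_draws=1, seed=0)[0]
        full = lesion_cost_profile(
            model, head, eval_set,
            LesionSpec(units={lay: np.arange(n) for lay, n in widths.items()}),
            k=1,
        )
        assert np.array_equal(null.deficit, full.deficit)


class TestTopFractionAndDownstream:
    def test_top_fraction_profile_correlates_with_full_lesion(
        self, model, head, eval_set, smap_post
    ):
        widths = model.layer_sizes()
        full = lesion_cost_profile(
            model, head, eval_set, domain_lesion_spec(smap_post, "face"), k=1
        )
        top = lesion_cost_profile(
            model, head, eval_set,
            top_fraction_lesion_spec(smap_post, "face", 0.01, widths), k=1
        )
        assert compare_cost_profiles(full, top) > 0

    def test_early_lesion_hits_preferred_category_downstream(
        self, model, stimulus_set, smap_post
    ):
        probe = stimulus_set.subset("probe")
        deltas = downstream_selectivity_change(
            model, smap_post, "face", probe,
            early_layers=["layer1", "layer2"], target_layer="layer3",
        )
        assert deltas["face"] == min(deltas.values())
        assert deltas["face"] < 0

    def test_target_layer_inside_early_layers_raises(
        self, model, stimulus_set, smap_post
    ):
        with pytest.raises(ValueError, match="target layer"):
            downstream_selectivity_change(
                model, smap_post, "face", stimulus_set.subset("probe"),
                early_layers=["layer1", "layer2"], target_layer="layer2",
            )

    def test_empty_early_lesion_changes_nothing(
        self, model, stimulus_set, smap_post
    ):
        from dataclasses import replace

        empty_entries = {
            k: replace(
                v,
                indices=np.zeros(0, int),
                t_per_contrast=np.zeros((0, len(v.contrasts))),
                t_mean=np.zeros(0),
            )
            if k[0] in ("layer1", "layer2") and k[2] == "face"
            else v
            for k, v in smap_post.entries.items()
        }
        empty_map = replace(smap_post, entries=empty_entries)
        deltas = downstream_selectivity_change(
            model, empty_map, "face", stimulus_set.subset("probe"),
            early_layers=["layer1", "layer2"], target_layer="layer3",
        )
        assert all(v == 0.0 for v in deltas.values())
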