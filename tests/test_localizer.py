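"""t-contrast + FDR localization, the ratio method, and depth summaries."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from catselect import (
    LocalizerDesign,
    PlantedModelConfig,
    StimulusConfig,
    bh_fdr_mask,
    build_planted_model,
    contrast_tmap,
    forward_activations,
    generalization_check,
    generate_stimulus_set,
    localize_selective_units,
    ratio_localize,
    selectivity_iou,
    selectivity_summary,
)

DOMAINS = ["face", "body", "scene", "word"]


class TestContrastTmap:
    def test_matches_textbook_pooled_t(self):
        """Cross-check one unit against scipy's equal-variance t test."""
        a = np.array([2.0, 2.0, 2.0, 2.1])
        b = np.array([0.0, 0.0, 0.0, 0.0])
        acts = np.concatenate([a, b])[:, None]
        labels = np.array(["p"] * 4 + ["o"] * 4)
        t, p = contrast_tmap(acts, labels, "p", "o")
        ref = stats.ttest_ind(a, b, equal_var=True)
        assert t[0] == pytest.approx(ref.statistic)
        assert p[0] == pytest.approx(ref.pvalue)

    def test_constant_identical_groups_give_t0_p1(self):
        acts = np.full((8, 3), 3.14)
        labels = np.array(["p"] * 4 + ["o"] * 4)
        t, p = contrast_tmap(acts, labels, "p", "o")
        assert np.all(t == 0.0)
        assert np.all(p == 1.0)

    def test_swapping_groups_negates_t(self, rng):
        acts = rng.standard_normal((12, 5))
        labels = np.array(["p"] * 6 + ["o"] * 6)
        t1, _ = contrast_tmap(acts, labels, "p", "o")
        t2, _ = contrast_tmap(acts, labels, "o", "p")
        assert np.allclose(t1, -t2)

    def test_absent_category_raises(self, rng):
        acts = rng.standard_normal((4, 2))
        labels = np.array(["p", "p", "o", "o"])
        with pytest.raises(ValueError, match="absent"):
            contrast_tmap(acts, labels, "p", "missing")

    def test_single_stimulus_group_raises(self, rng):
        acts = rng.standard_normal((3, 2))
        labels = np.array(["p", "o", "o"])
        with pytest.raises(ValueError, match=">= 2"):
            contrast_tmap(acts, labels, "p", "o")


class TestBhFdr:
    def test_hand_worked_step_up(self):
        # sorted p: 0.001 <= 0.05*(1/3); 0.2 > 0.05*(2/3); 0.9 > 0.05
        mask = bh_fdr_mask(np.array([0.001, 0.2, 0.9]), q=0.05)
        assert mask.tolist() == [True, False, False]

    def test_all_ones_rejects_nothing_and_all_zeros_everything(self):
        assert not bh_fdr_mask(np.ones(10), 0.05).any()
        assert bh_fdr_mask(np.zeros(10), 0.05).all()

    def test_empty_input_gives_empty_mask(self):
        assert bh_fdr_mask(np.array([]), 0.05).shape == (0,)

    def test_out_of_range_pvalues_raise(self):
        with pytest.raises(ValueError):
            bh_fdr_mask(np.array([0.5, 1.5]), 0.05)

    @settings(max_examples=50, deadline=None)
    @given(
        pvals=st.lists(
            st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=30
        ),
        q1=st.floats(min_value=0.01, max_value=0.5),
        q2=st.floats(min_value=0.01, max_value=0.5),
    )
    def test_rejections_monotone_in_q(self, pvals, q1, q2):
        """The BH rejection set can only grow as the FDR level increases."""
        lo, hi = sorted([q1, q2])
        p = np.asarray(pvals)
        m_lo, m_hi = bh_fdr_mask(p, lo), bh_fdr_mask(p, hi)
        assert np.all(m_hi[m_lo])  # everything rejected at lo also at hi


class TestLocalize:
    def test_recovers_planted_units(self, model, smap):
        for dom in DOMAINS:
            tp = fp = fn = 0
            for layer in model.layer_names:
                for stage in ("pre", "post"):
                    true = set(model.planted_indices(layer, dom).tolist())
                    got = set(smap.indices(layer, dom, stage).tolist())
                    tp += len(true & got)
                    fp += len(got - true)
                    fn += len(true - got)
            assert tp / (tp + fp) >= 0.9
            assert tp / (tp + fn) >= 0.9

    def test_domain_sets_are_disjoint_within_layer(self, smap):
        for layer in smap.layer_names:
            for stage in smap.stages:
                sets = [
                    set(smap.indices(layer, d, stage).tolist()) for d in DOMAINS
                ]
                for i in range(len(sets)):
                    for j in range(i + 1, len(sets)):
                        assert not (sets[i] & sets[j])

    def test_selected_units_have_positive_t_everywhere(self, smap):
        for entry in smap.entries.values():
            if len(entry.indices):
                assert np.all(entry.t_per_contrast > 0)

    def test_unit_failing_one_contrast_is_excluded(self):
        """Intersection rule: passing 4 of 5 contrasts is not enough."""
        rng = np.random.default_rng(0)
        n = 30
        cats = ["face", "body", "scene", "word", "object", "scrambled"]
        labels = np.repeat(cats, n)
        acts = rng.normal(0, 0.05, (len(labels), 2))
        # unit 0: face >> all others. unit 1: face >> all except object (tie)
        acts[labels == "face", 0] += 5.0
        acts[labels == "face", 1] += 5.0
        acts[labels == "object", 1] += 5.0
        store = _toy_store(acts, labels)
        smap = localize_selective_units(
            store, LocalizerDesign(domains=["face"], contrast_categories=cats),
            stages=("post",),
        )
        assert smap.indices("toy", "face").tolist() == [0]


def _toy_store(acts, labels):
    from catselect.containers import ActivationStore

    return ActivationStore(
        activations={("toy", "post"): acts, ("toy", "pre"): acts},
        layer_names=["toy"],
        category=np.asarray(labels, dtype=object),
        split=np.asarray(["localizer"] * len(labels), dtype=object),
        stimulus_id=np.arange(len(labels)),
    )


class TestRatioLocalize:
    def _store(self, pref_mean, other_mean):
        labels = np.array(["face"] * 4 + ["object"] * 4, dtype=object)
        acts = np.zeros((8, 1))
        acts[:4, 0] = pref_mean + np.array([-0.01, 0.01, -0.01, 0.01])
        acts[4:, 0] = other_mean + np.array([-0.01, 0.01, -0.01, 0.01])
        return _toy_store(acts, labels)

    def test_boundary_ratio_is_inclusive(self):
        store = self._store(4.0, 2.0)
        design = LocalizerDesign(
            domains=["face"], contrast_categories=["face", "object"]
        )
        smap = ratio_localize(store, design, ratio=2.0)
        assert smap.indices("toy", "face").tolist() == [0]

    def test_above_half_preferred_mean_excludes(self):
        store = self._store(4.0, 2.5)
        design = LocalizerDesign(
            domains=["face"], contrast_categories=["face", "object"]
        )
        smap = ratio_localize(store, design, ratio=2.0)
        assert smap.indices("toy", "face").tolist() == []

    def test_pre_stage_request_raises(self, store, design):
        with pytest.raises(ValueError, match="post-nonlinearity"):
            ratio_localize(store, design, stages=("pre",))

    def test_method_overlap_iou_positive_on_planted_model(
        self, store, design, smap_post
    ):
        rmap = ratio_localize(store, design)
        iou = selectivity_iou(smap_post, rmap)
        assert (iou["iou"].dropna() > 0).all()


class TestGeneralization:
    def test_probe_identity_reproduces_localizer_t(self, store, design, smap_post):
        out = generalization_check(smap_post, store, design, split="localizer")
        for g in out.values():
            assert g.defined
            assert g.fraction_positive == 1.0
            assert g.t_correlation == pytest.approx(1.0, abs=1e-10)

    def test_selective_units_generalize_to_shifted_probe(
        self, store, design, smap_post
    ):
        out = generalization_check(smap_post, store, design)
        for g in out.values():
            assert g.defined
            assert g.fraction_positive >= 0.9

    def test_empty_selective_set_is_flagged_undefined(self, store):
        design = LocalizerDesign(
            domains=["object"],
            contrast_categories=["face", "body", "scene", "word", "object",
                                 "scrambled"],
            q=1e-12,
        )
        smap = localize_selective_units(store, design, stages=("post",))
        if all(
            len(smap.indices(l, "object")) == 0 for l in smap.layer_names
        ):
            out = generalization_check(smap, store, design)
            assert not out["object"].defined


class TestSummary:
    def test_monotone_rho_gives_perfect_depth_trend(self):
        stim = generate_stimulus_set(StimulusConfig(), 31)
        model = build_planted_model(
            stim, PlantedModelConfig(rho=[0.02, 0.05, 0.1]), 32
        )
        store = forward_activations(model, stim)
        smap = localize_selective_units(store, LocalizerDesign(), stages=("post",))
        out = selectivity_summary(smap, n_units=model.layer_sizes())
        assert out.spearman_proportion == pytest.approx(1.0)

    def test_needs_three_layers(self, smap_post):
        from dataclasses import replace

        small = replace(
            smap_post,
            entries={
                k: v for k, v in smap_post.entries.items() if k[0] != "layer3"
            },
            layer_names=["layer1", "layer2"],
        )
        with pytest.raises(ValueError, match=">= 3 layers"):
            selectivity_summary(small)
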