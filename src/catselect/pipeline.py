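"""Config-driven orchestration of the full analysis pipeline.

Stages (dependency order): simulate -> localize -> readout -> lesion ->
voxels -> encode -> geometry. Every artifact is written with a checksum
into a manifest (config hash, per-stage seeds, wall times); re-running with
an unchanged configuration reuses cached artifacts, and changing one
section only invalidates the stages that depend on it.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as cio
from .config import STAGES, PipelineConfig
from .containers import StimulusSet
from .encoding import (
    evaluate_encoding,
    fit_nonneg_sparse_encoding,
    moment_noise_estimates,
    ncsnr,
    noise_ceiling_mc,
    select_best_layer,
    session_zscore,
    average_repeats,
)
from .geometry import meta_rdm_trajectories, pc_projection_map
from .lesion import (
    activation_cost_correlation,
    compare_cost_profiles,
    crossval_top_affected,
    domain_lesion_spec,
    lesion_cost_profile,
    random_lesion_null,
)
from .localizer import (
    generalization_check,
    localize_selective_units,
    ratio_localize,
    selectivity_iou,
    selectivity_summary,
)
from .planted import build_planted_model, forward_activations
from .readout import topk_accuracy_per_category, train_sparse_readout
from .stimuli import generate_stimulus_set
from .voxels import simulate_voxel_dataset

MANIFEST = "manifest.json"


class MissingInputError(FileNotFoundError):
    """A stage was requested without its upstream artifacts."""


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _section_hash(cfg: PipelineConfig, sections: tuple[str, ...]) -> str:
    payload = {
        s: dataclasses.asdict(getattr(cfg, s)) for s in sections if s != "seed"
    }
    payload["seed"] = cfg.seed
    return hashlib.sha256(
        json.dumps(payload, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


#: config sections each stage depends on (upstream stages are added below)
_STAGE_SECTIONS = {
    "simulate": ("stimuli", "model"),
    "localize": ("localizer",),
    "readout": ("readout",),
    "lesion": ("lesion",),
    "voxels": ("voxels",),
    "encode": ("encoding",),
    "geometry": ("geometry",),
}
_STAGE_DEPS = {
    "simulate": (),
    "localize": ("simulate",),
    "readout": ("simulate",),
    "lesion": ("simulate", "localize", "readout"),
    "voxels": ("simulate",),
    "encode": ("simulate", "localize", "voxels"),
    "geometry": ("simulate", "localize"),
}


def _stage_hash(cfg: PipelineConfig, stage: str) -> str:
    sections: list[str] = []
    seen: set[str] = set()

    def collect(s: str) -> None:
        if s in seen:
            return
        seen.add(s)
        for dep in _STAGE_DEPS[s]:
            collect(dep)
        sections.extend(_STAGE_SECTIONS[s])

    collect(stage)
    return _section_hash(cfg, tuple(sections))


class Pipeline:
    """Stateful runner binding a config to an output directory."""

    def __init__(self, config: PipelineConfig, out_dir: str | Path,
                 force: bool = False):
        self.cfg = config
        self.out = Path(out_dir)
        self.out.mkdir(parents=True, exist_ok=True)
        self.force = force
        self.manifest = self._load_manifest()

    # -- manifest -----------------------------------------------------------

    def _load_manifest(self) -> dict:
        p = self.out / MANIFEST
        if p.exists():
            try:
                return json.loads(p.read_text())
            except json.JSONDecodeError:
                pass
        return {"stages": {}, "config_hash": None}

    def _save_manifest(self) -> None:
        all_sections = tuple(
            s for secs in _STAGE_SECTIONS.values() for s in secs
        )
        self.manifest["config_hash"] = _section_hash(self.cfg, all_sections)
        (self.out / MANIFEST).write_text(json.dumps(self.manifest, indent=2))

    def _cached(self, stage: str) -> bool:
        if self.force:
            return False
        entry = self.manifest["stages"].get(stage)
        if not entry or entry["hash"] != _stage_hash(self.cfg, stage):
            return False
        for rel, digest in entry["outputs"].items():
            p = self.out / rel
            if not p.exists() or _sha256(p) != digest:
                return False
        return True

    def _record(self, stage: str, outputs: list[Path], t0: float) -> None:
        self.manifest["stages"][stage] = {
            "hash": _stage_hash(self.cfg, stage),
            "seed": self.cfg.stage_seed(stage),
            "wall_time_s": round(time.time() - t0, 3),
            "outputs": {
                str(p.relative_to(self.out)): _sha256(p) for p in outputs
            },
        }
        self._save_manifest()

    def _require(self, stage: str, *paths: str) -> None:
        for rel in paths:
            if not (self.out / rel).exists():
                raise MissingInputError(
                    f"stage {stage!r} requires missing artifact {rel!r}; "
                    "run its upstream stage first"
                )

    # -- stages -------------------------------------------------------------

    def run(self, stages: list[str] | None = None) -> dict:
        todo = list(STAGES) if stages is None else [
            s for s in STAGES if s in set(stages)
        ]
        if stages is not None:
            unknown = set(stages) - set(STAGES)
            if unknown:
                raise ValueError(f"unknown stage(s) {sorted(unknown)}")
        for stage in todo:
            if self._cached(stage):
                continue
            getattr(self, f"stage_{stage}")()
        return self.manifest

    # each stage reads its inputs from disk so stages can run independently

    def stage_simulate(self) -> None:
        t0 = time.time()
        seed = self.cfg.stage_seed("simulate")
        stim = generate_stimulus_set(self.cfg.stimuli, seed)
        model = build_planted_model(stim, self.cfg.model, seed + 1)
        store = forward_activations(model, stim)
        outs = [cio.save_activation_store(store, self.out / "activations.h5")]
        np.savez(
            self.out / "stimuli.npz",
            features=stim.features,
            category=stim.category.astype(str),
            split=stim.split.astype(str),
            stimulus_id=stim.stimulus_id,
            templates=stim.templates,
            seed=stim.seed,
        )
        outs.append(self.out / "stimuli.npz")
        masks = {
            layer: {dom: m.tolist() for dom, m in doms.items()}
            for layer, doms in model.planted_mask.items()
        }
        (self.out / "planted_masks.json").write_text(json.dumps(masks))
        outs.append(self.out / "planted_masks.json")
        np.savez(
            self.out / "model.npz",
            **{f"w{i}": l.weights for i, l in enumerate(model.layers)},
            **{f"b{i}": l.bias for i, l in enumerate(model.layers)},
            layer_names=np.asarray(model.layer_names, dtype=object),
            gain=model.gain,
            rho=model.rho,
            seed=model.seed,
        )
        outs.append(self.out / "model.npz")
        self._record("simulate", outs, t0)
        self._stim, self._model, self._store = stim, model, store

    def _load_sim(self):
        self._require("localize", "activations.h5", "stimuli.npz", "model.npz")
        if getattr(self, "_store", None) is None:
            self._store = cio.load_activation_store(self.out / "activations.h5")
            z = np.load(self.out / "stimuli.npz", allow_pickle=True)
            self._stim = StimulusSet(
                features=z["features"],
                category=z["category"].astype(object),
                split=z["split"].astype(object),
                stimulus_id=z["stimulus_id"],
                templates=z["templates"],
                category_names=sorted(set(z["category"].tolist())),
                seed=int(z["seed"]),
                config=self.cfg.stimuli,
            )
            m = np.load(self.out / "model.npz", allow_pickle=True)
            from .planted import Layer, PlantedModel

            names = [str(x) for x in m["layer_names"]]
            masks = json.loads((self.out / "planted_masks.json").read_text())
            self._model = PlantedModel(
                layers=[Layer(m[f"w{i}"], m[f"b{i}"]) for i in range(len(names))],
                layer_names=names,
                planted_mask={
                    lay: {dom: np.asarray(v, bool) for dom, v in doms.items()}
                    for lay, doms in masks.items()
                },
                gain=float(m["gain"]),
                rho=(m["rho"].tolist() if m["rho"].ndim else float(m["rho"])),
                domains=list(self.cfg.model.domains),
                seed=int(m["seed"]),
            )
        return self._stim, self._model, self._store

    def stage_localize(self) -> None:
        t0 = time.time()
        _, model, store = self._load_sim()
        design = self.cfg.localizer
        smap = localize_selective_units(store, design)
        rmap = ratio_localize(store, design)
        outs = [
            cio.save_selectivity_map(smap, self.out / "selectivity_ttest.json"),
            cio.save_selectivity_map(rmap, self.out / "selectivity_ratio.json"),
        ]
        outs.append(cio.save_table(selectivity_iou(smap, rmap),
                                   self.out / "method_iou.tsv"))
        summary = selectivity_summary(smap, n_units=model.layer_sizes())
        outs.append(cio.save_table(summary.table, self.out / "selectivity_summary.tsv"))
        gen = generalization_check(smap, store, design)
        gen_df = pd.DataFrame(
            [
                {"domain": d, "fraction_positive": g.fraction_positive,
                 "t_correlation": g.t_correlation, "n_units": g.n_units,
                 "defined": g.defined}
                for d, g in gen.items()
            ]
        )
        outs.append(cio.save_table(gen_df, self.out / "generalization.tsv"))
        trends = pd.DataFrame(
            [{"spearman_proportion": summary.spearman_proportion,
              "spearman_mean_t": summary.spearman_mean_t}]
        )
        outs.append(cio.save_table(trends, self.out / "depth_trends.tsv"))
        self._record("localize", outs, t0)
        self._smap = smap

    def _load_smap(self):
        self._require("lesion", "selectivity_ttest.json")
        if getattr(self, "_smap", None) is None:
            self._smap = cio.load_selectivity_map(
                self.out / "selectivity_ttest.json"
            )
        return self._smap

    def stage_readout(self) -> None:
        t0 = time.time()
        stim, model, store = self._load_sim()
        cfg = dataclasses.replace(
            self.cfg.readout, seed=self.cfg.stage_seed("readout")
        )
        train = stim.subset("readout_train")
        feats = store.get(model.layer_names[-1], "post")[
            np.isin(store.stimulus_id, train.stimulus_id)
        ]
        head = train_sparse_readout(feats, train.category, cfg)
        outs = [cio.save_readout_head(head, self.out / "readout_head.h5")]
        evl = stim.subset("readout_eval")
        ev_feats = store.get(model.layer_names[-1], "post")[
            np.isin(store.stimulus_id, evl.stimulus_id)
        ]
        acc = topk_accuracy_per_category(head, ev_feats, evl.category,
                                         self.cfg.lesion.k)
        df = pd.DataFrame(
            {"category": list(acc), "topk_accuracy": list(acc.values())}
        )
        df["sparsity_fraction"] = head.sparsity_fraction
        outs.append(cio.save_table(df, self.out / "readout_accuracy.tsv"))
        self._record("readout", outs, t0)
        self._head = head

    def _load_head(self):
        self._require("lesion", "readout_head.h5")
        if getattr(self, "_head", None) is None:
            self._head = cio.load_readout_head(self.out / "readout_head.h5")
        return self._head

    def stage_lesion(self) -> None:
        t0 = time.time()
        stim, model, store = self._load_sim()
        smap = self._load_smap()
        head = self._load_head()
        lc = self.cfg.lesion
        seed = self.cfg.stage_seed("lesion")
        evl = stim.subset("readout_eval")
        ev_store = forward_activations(model, evl)

        outs = []
        profiles = {}
        rows = []
        act_rows = []
        mid_layer = model.layer_names[len(model.layer_names) // 2]
        for dom in self.cfg.localizer.domains:
            spec = domain_lesion_spec(smap, dom)
            outs.append(cio.save_lesion_spec(
                spec, self.out / f"lesion_spec_{dom}.json"))
            prof = lesion_cost_profile(model, head, evl, spec, lc.k)
            profiles[dom] = prof
            outs.append(cio.save_cost_profile(
                prof, self.out / f"cost_profile_{dom}.tsv"))
            top, held = crossval_top_affected(
                model, head, evl, spec, lc.n_top, lc.k, seed)
            rows.append({"domain": dom, "top_categories": ",".join(top),
                         "heldout_mean_deficit": held})
            act_rows.append({
                "domain": dom,
                "layer": mid_layer,
                "activation_cost_r": activation_cost_correlation(
                    ev_store, smap.indices(mid_layer, dom), prof, mid_layer),
            })
        outs.append(cio.save_table(pd.DataFrame(rows),
                                   self.out / "crossval_deficits.tsv"))
        null_profiles = random_lesion_null(
            model, head, evl, smap, self.cfg.localizer.domains[0],
            lc.n_random_draws, seed, lc.k)
        null_r = [
            activation_cost_correlation(
                ev_store, smap.indices(mid_layer, self.cfg.localizer.domains[0]),
                p, mid_layer)
            for p in null_profiles
        ]
        act_df = pd.DataFrame(act_rows)
        act_df["random_lesion_mean_r"] = float(np.nanmean(null_r))
        outs.append(cio.save_table(act_df, self.out / "activation_cost.tsv"))
        pair_rows = []
        doms = list(profiles)
        for i, a in enumerate(doms):
            for b in doms[i + 1:]:
                pair_rows.append({"domain_a": a, "domain_b": b,
                                  "pearson_r": compare_cost_profiles(
                                      profiles[a], profiles[b])})
        outs.append(cio.save_table(pd.DataFrame(pair_rows),
                                   self.out / "profile_similarity.tsv"))
        self._record("lesion", outs, t0)

    def stage_voxels(self) -> None:
        t0 = time.time()
        _, model, store = self._load_sim()
        truth = {
            dom: model.planted_mask[self.cfg.voxels.source_layer][dom]
            for dom in self.cfg.voxels.rois
        }
        vox = simulate_voxel_dataset(
            store, truth, self.cfg.voxels, self.cfg.stage_seed("voxels")
        )
        outs = [cio.save_voxel_dataset(vox, self.out / "voxels.h5")]
        self._record("voxels", outs, t0)
        self._vox = vox

    def stage_encode(self) -> None:
        t0 = time.time()
        _, model, store = self._load_sim()
        smap = self._load_smap()
        self._require("encode", "voxels.h5")
        vox = getattr(self, "_vox", None) or cio.load_voxel_dataset(
            self.out / "voxels.h5"
        )
        ec = self.cfg.encoding
        seed = self.cfg.stage_seed("encode")

        z = session_zscore(vox)
        rel = ncsnr(z)
        ids, mat = average_repeats(z)
        id2row = {i: r for r, i in enumerate(store.stimulus_id)}
        rows = np.array([id2row[i] for i in ids])
        id2sp = dict(zip(store.stimulus_id, store.split))
        sp = np.array([id2sp[i] for i in ids])
        m_tr, m_va, m_te = (sp == "enc_train"), (sp == "enc_val"), (sp == "enc_test")

        layers = ec.layers or list(model.layer_names)
        out_rows = []
        ceil_rows = []
        for roi in self.cfg.voxels.rois:
            vmask = (vox.roi_domain == roi) & (rel > ec.ncsnr_threshold)
            if not vmask.any():
                out_rows.append({"roi": roi, "note": "no reliable voxels"})
                continue
            y_tr, y_va, y_te = mat[m_tr][:, vmask], mat[m_va][:, vmask], mat[m_te][:, vmask]
            val_metrics = {}
            fits = {}
            for layer in layers:
                idx = smap.indices(layer, roi)
                if len(idx) == 0:
                    continue
                X = store.get(layer, ec.stage)[rows][:, idx]
                em = fit_nonneg_sparse_encoding(
                    X[m_tr], y_tr, ec.alpha, unit_indices=idx, layer=layer,
                    stage=ec.stage, domain=roi, train_stimulus_ids=ids[m_tr])
                val_metrics[layer] = evaluate_encoding(
                    em, X[m_va], y_va, ids[m_va])
                fits[layer] = (em, X)
            if not val_metrics:
                out_rows.append({"roi": roi, "note": "no selective units"})
                continue
            best = select_best_layer(val_metrics, layers)
            for metric, layer in best.items():
                em, X = fits[layer]
                test = evaluate_encoding(em, X[m_te], y_te, ids[m_te])
                out_rows.append({
                    "roi": roi, "metric": metric, "best_layer": layer,
                    "validation_r": val_metrics[layer][metric],
                    "test_r": test[metric],
                })
            sig, noi = moment_noise_estimates(z)
            nc = noise_ceiling_mc(
                np.maximum(sig[vmask].mean(), 1e-6),
                noi[vmask].mean(),
                n_stimuli=int(m_te.sum()),
                n_voxels=int(vmask.sum()),
                n_rep=vox.n_repeats,
                n_sim=200,
                seed=seed,
            )
            ceil_rows.append({
                "roi": roi, "univariate_ceiling": nc.univariate,
                "rdm_ceiling": nc.rdm,
                "univariate_spread": nc.univariate_spread,
                "rdm_spread": nc.rdm_spread,
            })
        outs = [
            cio.save_table(pd.DataFrame(out_rows), self.out / "encoding_metrics.tsv"),
            cio.save_table(pd.DataFrame(ceil_rows), self.out / "noise_ceilings.tsv"),
            cio.save_table(
                pd.DataFrame({"voxel": np.arange(len(rel)),
                              "roi": vox.roi_domain, "ncsnr": rel}),
                self.out / "ncsnr.tsv",
            ),
        ]
        self._record("encode", outs, t0)

    def stage_geometry(self) -> None:
        t0 = time.time()
        stim, model, store = self._load_sim()
        smap = self._load_smap()
        gc = self.cfg.geometry
        coords, _ = meta_rdm_trajectories(
            store, stim, gc, categories=self.cfg.localizer.domains
        )
        outs = [cio.save_table(coords, self.out / "mds_trajectories.tsv")]

        layer = model.layer_names[-1]
        ref = store.subset("readout_train").get(layer, "post")
        probe = store.subset("probe").get(layer, "post")
        scores, arrows, arrow_units = pc_projection_map(
            ref, probe, smap, layer, self.cfg.localizer.domains, gc)
        probe_ids = store.subset("probe").stimulus_id
        probe_cat = store.subset("probe").category
        df = pd.DataFrame({
            "stimulus_id": probe_ids, "category": probe_cat,
            **{f"pc{d + 1}": scores[:, d] for d in range(gc.n_pc)},
        })
        outs.append(cio.save_table(df, self.out / "pc_projection.tsv"))
        arrow_rows = []
        for dom, arr in arrows.items():
            for u, vec in zip(arrow_units[dom], arr):
                arrow_rows.append({"domain": dom, "unit": int(u),
                                   **{f"pc{d + 1}": vec[d]
                                      for d in range(gc.n_pc)}})
        outs.append(cio.save_table(pd.DataFrame(arrow_rows),
                                   self.out / "tuning_arrows.tsv"))
        self._record("geometry", outs, t0)


def run_pipeline(config: PipelineConfig, out_dir: str | Path,
                 stages: list[str] | None = None, force: bool = False) -> dict:
    """Execute the requested stages in dependency order; returns the manifest."""
    return Pipeline(config, out_dir, force=force).run(stages)
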