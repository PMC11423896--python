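"""Serialization: HDF5 for matrices, JSON for maps/specs, TSV for tables.

Every file embeds a schema version tag; loading a mismatched or truncated
file raises instead of silently coercing.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .containers import ActivationStore, LesionSpec, VoxelDataset
from .lesion import CostProfile
from .localizer import SelectivityEntry, SelectivityMap
from .readout import ReadoutConfig, ReadoutHead

SCHEMA_VERSION = "1"


class SchemaError(IOError):
    """Version mismatch or structurally broken artifact file."""


def _check_version(found: str | None, path: Path) -> None:
    if found != SCHEMA_VERSION:
        raise SchemaError(
            f"{path}: schema version {found!r} != expected {SCHEMA_VERSION!r}"
        )


def _str_array(values) -> np.ndarray:
    return np.asarray([str(v) for v in values], dtype=object)


# ---------------------------------------------------------------------------
# HDF5 artifacts
# ---------------------------------------------------------------------------

def save_activation_store(store: ActivationStore, path: str | Path) -> Path:
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        f.attrs["kind"] = "activation_store"
        f.attrs["layer_names"] = [str(l) for l in store.layer_names]
        f.create_dataset("category", data=np.char.encode(
            store.category.astype(str), "utf-8"))
        f.create_dataset("split", data=np.char.encode(
            store.split.astype(str), "utf-8"))
        f.create_dataset("stimulus_id", data=store.stimulus_id.astype(np.int64))
        for (layer, stage), acts in store.activations.items():
            grp = f.require_group(layer)
            d = grp.create_dataset(stage, data=acts)
            d.attrs["stage"] = stage
    return path


def load_activation_store(path: str | Path) -> ActivationStore:
    path = Path(path)
    try:
        with h5py.File(path, "r") as f:
            _check_version(f.attrs.get("schema_version"), path)
            if f.attrs.get("kind") != "activation_store":
                raise SchemaError(f"{path}: not an activation store")
            layer_names = [str(l) for l in f.attrs["layer_names"]]
            acts = {}
            for layer in layer_names:
                for stage in f[layer]:
                    acts[(layer, stage)] = f[layer][stage][...]
            return ActivationStore(
                activations=acts,
                layer_names=layer_names,
                category=np.char.decode(f["category"][...], "utf-8").astype(object),
                split=np.char.decode(f["split"][...], "utf-8").astype(object),
                stimulus_id=f["stimulus_id"][...],
            )
    except (OSError, KeyError) as exc:
        if isinstance(exc, SchemaError):
            raise
        raise SchemaError(f"{path}: unreadable or truncated ({exc})") from exc


def save_voxel_dataset(data: VoxelDataset, path: str | Path) -> Path:
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        f.attrs["kind"] = "voxel_dataset"
        f.attrs["source_layer"] = data.source_layer
        f.attrs["noise_sd"] = data.noise_sd
        f.attrs["seed"] = data.seed
        f.create_dataset("responses", data=data.responses)
        f.create_dataset("session_id", data=data.session_id.astype(np.int64))
        f.create_dataset("stimulus_id", data=data.stimulus_id.astype(np.int64))
        f.create_dataset("repeat_index", data=data.repeat_index.astype(np.int64))
        f.create_dataset("roi_domain", data=np.char.encode(
            data.roi_domain.astype(str), "utf-8"))
        f.create_dataset("source_units", data=data.source_units.astype(np.int64))
        if data.truth_weights is not None:
            f.create_dataset("truth_weights", data=data.truth_weights)
    return path


def load_voxel_dataset(path: str | Path) -> VoxelDataset:
    path = Path(path)
    try:
        with h5py.File(path, "r") as f:
            _check_version(f.attrs.get("schema_version"), path)
            if f.attrs.get("kind") != "voxel_dataset":
                raise SchemaError(f"{path}: not a voxel dataset")
            return VoxelDataset(
                responses=f["responses"][...],
                session_id=f["session_id"][...],
                stimulus_id=f["stimulus_id"][...],
                repeat_index=f["repeat_index"][...],
                roi_domain=np.char.decode(f["roi_domain"][...], "utf-8").astype(object),
                source_layer=str(f.attrs["source_layer"]),
                source_units=f["source_units"][...],
                truth_weights=(f["truth_weights"][...]
                               if "truth_weights" in f else None),
                noise_sd=float(f.attrs["noise_sd"]),
                seed=int(f.attrs["seed"]),
            )
    except (OSError, KeyError) as exc:
        if isinstance(exc, SchemaError):
            raise
        raise SchemaError(f"{path}: unreadable or truncated ({exc})") from exc


def save_readout_head(head: ReadoutHead, path: str | Path) -> Path:
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        f.attrs["kind"] = "readout_head"
        f.attrs["sparsity_fraction"] = head.sparsity_fraction
        f.attrs["config"] = json.dumps(vars(head.config))
        f.create_dataset("weights", data=head.weights)
        f.create_dataset("bias", data=head.bias)
        f.create_dataset("classes", data=np.char.encode(
            head.classes.astype(str), "utf-8"))
        f.create_dataset("training_log", data=head.training_log)
    return path


def load_readout_head(path: str | Path) -> ReadoutHead:
    path = Path(path)
    try:
        with h5py.File(path, "r") as f:
            _check_version(f.attrs.get("schema_version"), path)
            if f.attrs.get("kind") != "readout_head":
                raise SchemaError(f"{path}: not a readout head")
            return ReadoutHead(
                weights=f["weights"][...],
                bias=f["bias"][...],
                classes=np.char.decode(f["classes"][...], "utf-8").astype(object),
                sparsity_fraction=float(f.attrs["sparsity_fraction"]),
                training_log=f["training_log"][...],
                config=ReadoutConfig(**json.loads(f.attrs["config"])),
            )
    except (OSError, KeyError) as exc:
        if isinstance(exc, SchemaError):
            raise
        raise SchemaError(f"{path}: unreadable or truncated ({exc})") from exc


# ---------------------------------------------------------------------------
# JSON artifacts
# ---------------------------------------------------------------------------

def save_selectivity_map(smap: SelectivityMap, path: str | Path) -> Path:
    path = Path(path)
    payload = {
        "schema_version": SCHEMA_VERSION,
        "kind": "selectivity_map",
        "method": smap.method,
        "q": smap.q,
        "ratio": smap.ratio,
        "layer_names": smap.layer_names,
        "domains": smap.domains,
        "stages": list(smap.stages),
        "entries": {
            f"{lay}|{stg}|{dom}": {
                "indices": e.indices.tolist(),
                "t_per_contrast": e.t_per_contrast.tolist(),
                "contrasts": e.contrasts,
                "t_mean": e.t_mean.tolist(),
            }
            for (lay, stg, dom), e in smap.entries.items()
        },
    }
    path.write_text(json.dumps(payload))
    return path


def load_selectivity_map(path: str | Path) -> SelectivityMap:
    path = Path(path)
    try:
        payload = json.loads(path.read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise SchemaError(f"{path}: unreadable or truncated ({exc})") from exc
    _check_version(payload.get("schema_version"), path)
    if payload.get("kind") != "selectivity_map":
        raise SchemaError(f"{path}: not a selectivity map")
    entries = {}
    for key, e in payload["entries"].items():
        lay, stg, dom = key.split("|")
        idx = np.asarray(e["indices"], dtype=np.intp)
        tpc = np.asarray(e["t_per_contrast"], dtype=float).reshape(
            len(idx), len(e["contrasts"]))
        entries[(lay, stg, dom)] = SelectivityEntry(
            indices=idx,
            t_per_contrast=tpc,
            contrasts=list(e["contrasts"]),
            t_mean=np.asarray(e["t_mean"], dtype=float),
        )
    return SelectivityMap(
        entries=entries,
        layer_names=payload["layer_names"],
        domains=payload["domains"],
        stages=tuple(payload["stages"]),
        method=payload["method"],
        q=payload["q"],
        ratio=payload["ratio"],
    )


def save_lesion_spec(spec: LesionSpec, path: str | Path) -> Path:
    path = Path(path)
    payload = {
        "schema_version": SCHEMA_VERSION,
        "kind": "lesion_spec",
        "provenance": spec.provenance,
        "units": {lay: idx.tolist() for lay, idx in spec.units.items()},
    }
    path.write_text(json.dumps(payload))
    return path


def load_lesion_spec(path: str | Path) -> LesionSpec:
    path = Path(path)
    try:
        payload = json.loads(path.read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise SchemaError(f"{path}: unreadable or truncated ({exc})") from exc
    _check_version(payload.get("schema_version"), path)
    if payload.get("kind") != "lesion_spec":
        raise SchemaError(f"{path}: not a lesion spec")
    return LesionSpec(
        units={lay: np.asarray(v, dtype=np.intp)
               for lay, v in payload["units"].items()},
        provenance=payload["provenance"],
    )


# ---------------------------------------------------------------------------
# TSV artifacts
# ---------------------------------------------------------------------------

def save_cost_profile(profile: CostProfile, path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame(
        {
            "category": profile.categories,
            "deficit_points": profile.deficit,
            "baseline": profile.baseline,
            "lesioned": profile.lesioned,
        }
    )
    with open(path, "w") as fh:
        fh.write(f"# schema_version={SCHEMA_VERSION} kind=cost_profile "
                 f"split={profile.split} k={profile.k}\n")
        df.to_csv(fh, sep="\t", index=False)
    return path


def load_cost_profile(path: str | Path) -> CostProfile:
    path = Path(path)
    try:
        with open(path) as fh:
            header = fh.readline()
            df = pd.read_csv(fh, sep="\t")
    except (OSError, pd.errors.ParserError) as exc:
        raise SchemaError(f"{path}: unreadable or truncated ({exc})") from exc
    if f"schema_version={SCHEMA_VERSION}" not in header or "cost_profile" not in header:
        raise SchemaError(f"{path}: bad cost-profile header {header!r}")
    meta = dict(tok.split("=") for tok in header[1:].split() if "=" in tok)
    return CostProfile(
        categories=df["category"].tolist(),
        deficit=df["deficit_points"].to_numpy(),
        baseline=df["baseline"].to_numpy(),
        lesioned=df["lesioned"].to_numpy(),
        split=meta.get("split", "?"),
        k=int(meta.get("k", 1)),
    )


def save_table(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    df.to_csv(path, sep="\t", index=False)
    return path
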