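"""Shared in-memory containers for the analysis pipeline.

These are deliberately thin: plain arrays plus per-row annotations, so that
every stage (localizer, lesioner, encoder, geometry) consumes the same
objects without format conversions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: split tags a stimulus may carry
SPLITS = (
    "localizer",
    "probe",
    "readout_train",
    "readout_eval",
    "enc_train",
    "enc_val",
    "enc_test",
)


@dataclass
class StimulusSet:
    """Category-structured stimuli in a feature-vector input space.

    Each stimulus is a point near its category template; splits mirror the
    roles of the localizer set, the independent color probe set, the
    recognition train/eval images, and the encoding train/val/test images.
    """

    features: np.ndarray          # (n_stimuli, input_dim)
    category: np.ndarray          # (n_stimuli,) str
    split: np.ndarray             # (n_stimuli,) str
    stimulus_id: np.ndarray       # (n_stimuli,) int, unique
    templates: np.ndarray         # (n_categories, input_dim) generator truth
    category_names: list[str]
    seed: int
    #: generating configuration (set by the generator); lets consumers draw
    #: additional stimuli from the same distribution
    config: object | None = None

    @property
    def n_stimuli(self) -> int:
        return self.features.shape[0]

    @property
    def input_dim(self) -> int:
        return self.features.shape[1]

    def subset(self, split: str) -> "StimulusSet":
        if split not in SPLITS:
            raise ValueError(f"unknown split {split!r}")
        m = self.split == split
        return StimulusSet(
            features=self.features[m],
            category=self.category[m],
            split=self.split[m],
            stimulus_id=self.stimulus_id[m],
            templates=self.templates,
            category_names=self.category_names,
            seed=self.seed,
            config=self.config,
        )


@dataclass
class ActivationStore:
    """Per-stage stimulus x unit response matrices for a layered model.

    Pre- and post-nonlinearity responses of each layer are distinct
    computational stages and are stored under separate keys.
    """

    activations: dict[tuple[str, str], np.ndarray]  # (layer, stage) -> (n, units)
    layer_names: list[str]                          # ordered, input -> output
    category: np.ndarray
    split: np.ndarray
    stimulus_id: np.ndarray

    STAGES = ("pre", "post")

    def get(self, layer: str, stage: str = "post") -> np.ndarray:
        key = (layer, stage)
        if key not in self.activations:
            raise KeyError(f"no activations for layer={layer!r} stage={stage!r}")
        return self.activations[key]

    def n_units(self, layer: str) -> int:
        return self.get(layer, "post").shape[1]

    @property
    def n_stimuli(self) -> int:
        return len(self.category)

    def subset(self, split: str) -> "ActivationStore":
        m = self.split == split
        if not m.any():
            raise ValueError(f"split {split!r} not present in store")
        return ActivationStore(
            activations={k: v[m] for k, v in self.activations.items()},
            layer_names=list(self.layer_names),
            category=self.category[m],
            split=self.split[m],
            stimulus_id=self.stimulus_id[m],
        )


@dataclass
class LesionSpec:
    """Units to silence (post-nonlinearity outputs forced to zero), per layer."""

    units: dict[str, np.ndarray] = field(default_factory=dict)  # layer -> indices
    provenance: str = "domain"  # domain | random | top_fraction

    def __post_init__(self) -> None:
        clean = {}
        for layer, idx in self.units.items():
            arr = np.asarray(idx, dtype=np.intp)
            if arr.ndim != 1:
                raise ValueError("lesion indices must be one-dimensional")
            if len(np.unique(arr)) != len(arr):
                raise ValueError(f"duplicate lesion indices for layer {layer!r}")
            clean[layer] = np.sort(arr)
        self.units = clean

    @property
    def is_empty(self) -> bool:
        return all(len(v) == 0 for v in self.units.values())

    def n_units(self) -> int:
        return int(sum(len(v) for v in self.units.values()))

    def validate(self, layer_sizes: dict[str, int]) -> None:
        for layer, idx in self.units.items():
            if layer not in layer_sizes:
                raise ValueError(f"lesion references unknown layer {layer!r}")
            if len(idx) and (idx.min() < 0 or idx.max() >= layer_sizes[layer]):
                raise ValueError(
                    f"lesion index out of range for layer {layer!r} "
                    f"(size {layer_sizes[layer]})"
                )


@dataclass
class VoxelDataset:
    """Trial-level simulated voxel responses with session/repeat structure.

    Emulates event-related fMRI betas: each encoding stimulus is measured
    ``R`` times, trials fall into contiguous sessions with per-session affine
    (offset + gain) instabilities, and every voxel is a noisy non-negative
    sparse mixture of source units. Ground-truth mixing weights are retained
    for recovery benchmarks.
    """

    responses: np.ndarray       # (n_trials, n_voxels)
    session_id: np.ndarray      # (n_trials,) int
    stimulus_id: np.ndarray     # (n_trials,) int
    repeat_index: np.ndarray    # (n_trials,) int
    roi_domain: np.ndarray      # (n_voxels,) str
    source_layer: str
    source_units: np.ndarray    # (n_sources,) global unit indices in source layer
    truth_weights: np.ndarray | None  # (n_voxels, n_sources) >= 0
    noise_sd: float
    seed: int
    zscore_flags: np.ndarray | None = None  # (voxel, session) pairs left at 0

    @property
    def n_trials(self) -> int:
        return self.responses.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.responses.shape[1]

    @property
    def n_repeats(self) -> int:
        return int(np.max(self.repeat_index)) + 1

    def sessions(self) -> np.ndarray:
        return np.unique(self.session_id)
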