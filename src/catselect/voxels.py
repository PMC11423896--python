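"""Simulated trial-level voxel datasets with known ground truth.

Emulates event-related fMRI betas from category-selective regions of
interest: each voxel is a noisy, sparse, non-negative mixture of a handful
of that domain's truly selective model units; every encoding stimulus is
measured ``R`` times (default 3); trials fall into contiguous sessions,
each with its own additive offset and multiplicative gain (the
session-instability that per-session z-scoring is meant to remove); and
i.i.d. Gaussian trial noise is added on top.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .containers import ActivationStore, VoxelDataset


@dataclass
class VoxelConfig:
    rois: list[str] = field(default_factory=lambda: ["face", "body", "scene", "word"])
    voxels_per_roi: int = 12
    support_size: int = 5          # s: source units mixed into each voxel
    n_repeats: int = 3             # R: repeats per encoding stimulus
    noise_sd: float = 0.15         # sigma_v: trial noise, response units
    session_length: int = 150      # trials per session
    session_offset_sd: float = 0.3
    session_gain_sd: float = 0.2   # gains ~ 1 + N(0, sd), floored at 0.2
    shuffle_trials: bool = True    # repeats may fall in different sessions
    source_layer: str = "layer2"
    source_stage: str = "post"

    def validate(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.support_size < 1:
            raise ValueError("support_size (s) must be >= 1")
        if self.n_repeats < 2:
            raise ValueError("need R >= 2 repeats")
        if self.voxels_per_roi < 1:
            raise ValueError("voxels_per_roi must be >= 1")


def simulate_voxel_dataset(
    activations: ActivationStore,
    truth_masks: dict[str, np.ndarray],
    config: VoxelConfig,
    seed: int,
    split: str = "enc_train",
    extra_splits: tuple[str, ...] = ("enc_val", "enc_test"),
) -> VoxelDataset:
    """Simulate an ROI voxel dataset from source-unit activations.

    ``truth_masks`` maps each requested ROI domain to a boolean mask (or
    index array) over the source layer's units; voxel supports are drawn
    from that domain's units only, so ground truth is recoverable.
    """
    config.validate()
    rng = np.random.default_rng(seed)

    splits = (split,) + tuple(extra_splits)
    keep = np.isin(activations.split, splits)
    if not keep.any():
        raise ValueError(f"no stimuli in splits {splits}")
    acts = activations.get(config.source_layer, config.source_stage)[keep]
    stim_ids = activations.stimulus_id[keep]
    n_stim, n_units = acts.shape

    # per-voxel non-negative sparse mixing weights over domain source units
    roi_domain: list[str] = []
    weights = np.zeros((config.voxels_per_roi * len(config.rois), n_units))
    for ri, roi in enumerate(config.rois):
        if roi not in truth_masks:
            raise ValueError(f"no truth mask for ROI domain {roi!r}")
        mask = np.asarray(truth_masks[roi])
        src = np.flatnonzero(mask) if mask.dtype == bool else mask.astype(np.intp)
        if len(src) < config.support_size:
            raise ValueError(
                f"ROI {roi!r} has {len(src)} source units < s={config.support_size}"
            )
        for v in range(config.voxels_per_roi):
            vi = ri * config.voxels_per_roi + v
            support = rng.choice(src, size=config.support_size, replace=False)
            w = np.abs(rng.standard_normal(config.support_size)) + 0.1
            weights[vi, support] = w / w.sum()
            roi_domain.append(roi)

    signal = acts @ weights.T  # (n_stim, n_voxels)

    # trial table: R rounds over all stimuli, optionally shuffled together so
    # repeats of a stimulus may land in different sessions
    trial_stim = np.tile(np.arange(n_stim), config.n_repeats)
    trial_rep = np.repeat(np.arange(config.n_repeats), n_stim)
    if config.shuffle_trials:
        order = rng.permutation(len(trial_stim))
        trial_stim, trial_rep = trial_stim[order], trial_rep[order]
    n_trials = len(trial_stim)
    session_id = np.arange(n_trials) // config.session_length

    offsets = rng.normal(0.0, config.session_offset_sd, session_id.max() + 1)
    gains = np.maximum(
        1.0 + rng.normal(0.0, config.session_gain_sd, session_id.max() + 1), 0.2
    )

    responses = (
        gains[session_id, None] * signal[trial_stim]
        + offsets[session_id, None]
        + rng.normal(0.0, config.noise_sd, (n_trials, weights.shape[0]))
    )

    return VoxelDataset(
        responses=responses,
        session_id=session_id,
        stimulus_id=stim_ids[trial_stim],
        repeat_index=trial_rep,
        roi_domain=np.asarray(roi_domain, dtype=object),
        source_layer=config.source_layer,
        source_units=np.arange(n_units),
        truth_weights=weights,
        noise_sd=config.noise_sd,
        seed=seed,
    )
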