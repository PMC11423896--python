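"""Synthetic category-structured stimulus generation.

Stimuli live in a ``d``-dimensional feature space. Each category ``k`` has a
unit-norm template ``t_k``; the templates form rows of a random orthonormal
frame, so categories are mutually near-orthogonal directions. A stimulus is
its template plus within-category jitter

    x = s * t_k + sigma_w * (z_perp + eta * z_par),   z ~ N(0, I_d)

where ``z_par``/``z_perp`` are the components of ``z`` inside/outside the
template span, ``eta`` (``template_mix``) shrinks exemplar variation along
the category-diagnostic directions, and ``s`` (``template_scale``) scales the
category signal (0 gives category-exchangeable stimuli -- the calibrated
null for false-positive-rate checks). An optional "scrambled" category is
template-free noise with the same covariance as the exemplar jitter -- the
analog of phase-scrambled images, which preserve low-level image statistics
while destroying category structure.

The probe split uses an independently drawn jitter realization, optionally
at a different ``sigma_w`` -- a distribution-shift analog of swapping the
localizer image set for an independent probe set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .containers import SPLITS, StimulusSet

SCRAMBLED = "scrambled"


@dataclass
class StimulusConfig:
    categories: list[str] = field(
        default_factory=lambda: ["face", "body", "scene", "word", "object"]
    )
    input_dim: int = 128
    sigma_within: float = 0.7
    probe_sigma: float | None = 0.8    # None -> same as sigma_within
    template_mix: float = 0.25         # jitter fraction inside the template span
    template_scale: float = 1.0        # 0 -> exchangeable (null) categories
    scrambled: bool = True
    scrambled_splits: tuple[str, ...] = ("localizer", "probe")
    #: stimuli per category in each split; a split absent here is not generated
    splits: dict[str, int] = field(
        default_factory=lambda: {
            "localizer": 16,
            "probe": 20,
            "readout_train": 80,
            "readout_eval": 200,
            "enc_train": 60,
            "enc_val": 40,
            "enc_test": 40,
        }
    )

    def validate(self) -> None:
        if len(self.categories) < 2:
            raise ValueError("need at least 2 categories")
        if self.input_dim < len(self.categories) + int(self.scrambled):
            raise ValueError(
                "input_dim must be >= number of categories to build "
                "near-orthogonal templates"
            )
        if not 0.0 <= self.sigma_within < 1.0:
            raise ValueError("sigma_within must be in [0, 1)")
        for split, n in self.splits.items():
            if split not in SPLITS:
                raise ValueError(f"unknown split {split!r}")
            if n < 1:
                raise ValueError(f"split {split!r} has non-positive size {n}")
        if not self.splits:
            raise ValueError("no splits configured")


def _jitter(
    rng: np.random.Generator,
    n: int,
    frame: np.ndarray,
    sigma: float,
    mix: float,
) -> np.ndarray:
    """Within-category jitter, attenuated inside the template span."""
    d = frame.shape[1]
    z = rng.standard_normal((n, d))
    par = z @ frame.T @ frame          # component in the template span
    return sigma * (z - par + mix * par)


def generate_stimulus_set(
    config: StimulusConfig, seed: int, jitter_seed: int | None = None
) -> StimulusSet:
    """Draw a deterministic, category-structured stimulus set.

    Identical ``(config, seed)`` pairs reproduce the set bitwise. The
    template frame and the exemplar jitter come from independent streams, so
    ``jitter_seed`` can draw a fresh sample from the *same* category
    distribution (same templates, new exemplars).
    """
    config.validate()
    frame_rng = np.random.default_rng(np.random.SeedSequence([seed, 1]))
    rng = np.random.default_rng(
        np.random.SeedSequence([seed if jitter_seed is None else jitter_seed, 2])
    )
    cats = list(config.categories)
    d = config.input_dim

    # random orthonormal frame; rows are unit-norm mutually orthogonal templates
    gauss = frame_rng.standard_normal((d, d))
    q, r = np.linalg.qr(gauss)
    q *= np.sign(np.diag(r))  # fix QR sign ambiguity for determinism
    frame = q[: len(cats)]
    templates = config.template_scale * frame

    feats, cat_col, split_col = [], [], []
    all_cats = cats + ([SCRAMBLED] if config.scrambled else [])
    for split, n_per in config.splits.items():
        sigma = config.sigma_within
        if split == "probe" and config.probe_sigma is not None:
            sigma = config.probe_sigma
        for k, cat in enumerate(all_cats):
            if cat == SCRAMBLED:
                if split not in config.scrambled_splits:
                    continue
                x = _jitter(rng, n_per, frame, sigma, config.template_mix)
            else:
                x = templates[k] + _jitter(rng, n_per, frame, sigma, config.template_mix)
            feats.append(x)
            cat_col.extend([cat] * n_per)
            split_col.extend([split] * n_per)

    features = np.vstack(feats)
    if not np.all(np.isfinite(features)):  # pragma: no cover - defensive
        raise FloatingPointError("non-finite stimulus features")
    return StimulusSet(
        features=features,
        category=np.asarray(cat_col, dtype=object),
        split=np.asarray(split_col, dtype=object),
        stimulus_id=np.arange(features.shape[0]),
        templates=templates,
        category_names=all_cats,
        seed=seed,
        config=config,
    )
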