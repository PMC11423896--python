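"""Representational dissimilarity matrices (Pearson dissimilarity)."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np


@dataclass
class RDMatrix:
    """Pairwise pattern dissimilarities: entry (i, j) = 1 - Pearson r."""

    values: np.ndarray                 # (n, n), symmetric, zero diagonal
    stimulus_id: np.ndarray            # (n,)
    undefined_rows: np.ndarray | None = None  # zero-variance pattern rows

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def n_pairs(self) -> int:
        return self.n * (self.n - 1) // 2

    def lower_triangle(self) -> np.ndarray:
        i, j = np.tril_indices(self.n, k=-1)
        return self.values[i, j]


def compute_rdm(
    patterns: np.ndarray, stimulus_id: np.ndarray | None = None
) -> RDMatrix:
    """RDM over stimulus response patterns (rows).

    Requires >= 2 channels per pattern; rows with zero variance get
    undefined (NaN) entries and are flagged rather than silently propagated.
    """
    patterns = np.asarray(patterns, dtype=float)
    if patterns.ndim != 2 or patterns.shape[1] < 2:
        raise ValueError("patterns must be n_stimuli x n_channels with >= 2 channels")
    n = patterns.shape[0]
    sd = patterns.std(axis=1)
    bad = np.flatnonzero(sd == 0)
    if len(bad):
        warnings.warn(
            f"{len(bad)} zero-variance pattern row(s); their dissimilarities "
            "are undefined",
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(patterns)
    d = 1.0 - corr
    np.fill_diagonal(d, 0.0)
    d = 0.5 * (d + d.T)  # enforce exact symmetry against fp noise
    ok = sd > 0
    np.clip(d, 0.0, 2.0, out=d)  # numeric guard; analytic range is [0, 2]
    d[~ok, :] = np.nan
    d[:, ~ok] = np.nan
    np.fill_diagonal(d, 0.0)
    if stimulus_id is None:
        stimulus_id = np.arange(n)
    return RDMatrix(
        values=d,
        stimulus_id=np.asarray(stimulus_id),
        undefined_rows=bad if len(bad) else None,
    )


def rdm_correlation(a: RDMatrix, b: RDMatrix) -> float:
    """Pearson r between the lower triangles of two RDMs."""
    if a.n != b.n:
        raise ValueError("RDMs differ in size")
    x, y = a.lower_triangle(), b.lower_triangle()
    m = np.isfinite(x) & np.isfinite(y)
    if m.sum() < 2 or x[m].std() == 0 or y[m].std() == 0:
        warnings.warn("rdm_correlation undefined (constant or empty triangles)",
                      stacklevel=2)
        return float("nan")
    return float(np.corrcoef(x[m], y[m])[0, 1])
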