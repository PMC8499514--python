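"""Renyi diversity profiles over clone frequency vectors.

The Renyi entropy of order alpha >= 0 of a frequency vector p is

    H_alpha = 1 / (1 - alpha) * log( sum_i p_i^alpha )

with the limits H_1 = -sum p_i log p_i (Shannon) and
H_inf = -log(max p_i).  H_0 is the log of the richness (number of
detected clones), and H_2 = log(1 / sum p_i^2), the log inverse Simpson
index.  Natural log is the default; ``base`` rescales.  Plotted against a
grid of alpha values the profile summarizes clonal diversity: a flat
profile means perfectly even clone sizes, a steeply decreasing one means
domination by few clones.  Profiles are replicate-averaged per alpha,
computed from raw sequence counts with vector-population labels pooled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_ALPHA_GRID",
    "DiversityProfile",
    "renyi_entropy",
    "diversity_profile",
    "top_clone_contribution",
]

DEFAULT_ALPHA_GRID: tuple[float, ...] = (
    0.0, 0.25, 0.5, 1.0, 2.0, 4.0, 8.0, 16.0, 32.0, 64.0, math.inf,
)


def _clean(p) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.size == 0 or np.all(p == 0):
        raise ValueError("no clones")
    if (p < 0).any():
        raise ValueError("negative frequencies")
    p = p[p > 0]
    return p / p.sum()


def renyi_entropy(p, alpha: float, base: float = math.e) -> float:
    """Renyi entropy of order ``alpha`` in units of log ``base``.

    Zero-frequency entries are excluded from the power sum; at alpha = 0
    only detected (non-zero) clones count toward richness.
    """
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    p = _clean(p)
    if alpha == 1.0:
        h = float(-(p * np.log(p)).sum())
    elif math.isinf(alpha):
        h = float(-np.log(p.max()))
    else:
        h = float(np.log((p ** alpha).sum()) / (1.0 - alpha))
    return h / math.log(base)


@dataclass
class DiversityProfile:
    """Renyi entropies over an alpha grid, per replicate and averaged."""

    alpha_grid: tuple[float, ...]
    H: pd.DataFrame  # rows: alpha, columns: replicate/sample
    averaged_H: pd.Series  # per-alpha mean over columns

    def to_tsv(self, path) -> None:
        out = self.H.copy()
        out["mean"] = self.averaged_H
        out.index.name = "alpha"
        out.reset_index().to_csv(path, sep="\t", index=False)


def diversity_profile(
    counts: pd.DataFrame,
    alpha_grid: tuple[float, ...] = DEFAULT_ALPHA_GRID,
    base: float = math.e,
) -> DiversityProfile:
    """Profile from raw per-replicate counts, averaged per alpha.

    ``counts`` is clone x replicate (columns are the replicates whose
    profiles are averaged); each column is normalized to frequencies
    independently.
    """
    H = pd.DataFrame(
        {
            col: [renyi_entropy(counts[col], a, base=base) for a in alpha_grid]
            for col in counts.columns
        },
        index=list(alpha_grid),
    )
    return DiversityProfile(tuple(alpha_grid), H, H.mean(axis=1))


def top_clone_contribution(p) -> tuple[float, float]:
    """Contribution of the highest-frequency clone.

    Returns ``(p_max, 1/p_max)``: p_max = exp(-H_inf) is the top clone's
    share of the population, and exp(H_inf) = 1/p_max its reciprocal
    (both are exposed since either transform of H_inf is in common use).
    """
    p = _clean(p)
    p_max = float(p.max())
    return p_max, 1.0 / p_max
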