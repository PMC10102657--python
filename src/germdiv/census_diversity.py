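"""Landrace census diversity indices.

Simpson's index is implemented as the Gini-Simpson complement 1 - sum(p^2)
(probability that two random individuals belong to different landraces),
Shannon's H uses the natural log, and evenness is Pielou's J = H / ln S.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from germdiv.io_formats import LandraceCensus

__all__ = [
    "DiversityIndices",
    "proportions",
    "simpson_index",
    "shannon_index",
    "evenness_index",
    "diversity_indices",
]


@dataclass
class DiversityIndices:
    site_label: str
    richness: int
    simpson: float
    shannon: float
    evenness: float


def proportions(census: LandraceCensus) -> np.ndarray:
    """Landrace shares p_i = count_i / total; zero-count entries dropped."""
    counts = census.counts
    counts = counts[counts > 0]
    if counts.size == 0:
        raise ValueError("census has no positive counts")
    return counts / counts.sum()


def _check_simplex(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("proportion vector must be 1-D and non-empty")
    if (p < 0).any():
        raise ValueError("proportions must be non-negative")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError(f"proportions sum to {p.sum()!r}, not 1")
    return p


def simpson_index(p: np.ndarray) -> float:
    """Gini-Simpson diversity 1 - sum(p_i^2)."""
    p = _check_simplex(p)
    return float(1.0 - np.sum(p**2))


def shannon_index(p: np.ndarray) -> float:
    """Shannon entropy H = -sum(p_i ln p_i); zero shares contribute 0."""
    p = _check_simplex(p)
    nz = p[p > 0]
    return float(-np.sum(nz * np.log(nz)))


def evenness_index(p: np.ndarray) -> float:
    """Pielou's evenness J = H / ln S, defined as 1 for a single category."""
    p = np.asarray(p, dtype=float)
    s = int(np.count_nonzero(p))
    if s <= 1:
        return 1.0
    return shannon_index(p) / np.log(s)


def diversity_indices(census: LandraceCensus) -> DiversityIndices:
    """Richness, Simpson, Shannon, and evenness for one census."""
    p = proportions(census)
    return DiversityIndices(
        site_label=census.site_label,
        richness=int(p.size),
        simpson=simpson_index(p),
        shannon=shannon_index(p),
        evenness=evenness_index(p),
    )
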