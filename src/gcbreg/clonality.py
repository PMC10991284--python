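"""Repertoire diversity and clonality statistics.

Hill numbers give the effective count of equally abundant clones at
order q: q=1 is the exponential of Shannon entropy, q=2 the inverse
Simpson index.  Productive Simpson Clonality is sqrt(1/D) with D the
order-2 Hill diversity — 1 for a monoclonal repertoire, 1/sqrt(S) for
a perfectly even repertoire of S clones.  Plug-in (empirical)
estimators on observed frequencies; zero-count clones are dropped
before frequencies are formed.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "clone_frequencies",
    "hill_diversity",
    "simpson_clonality",
    "clonal_fraction_curve",
    "diversity_summary",
]


def clone_frequencies(counts: Sequence[float]) -> np.ndarray:
    """Frequencies over positive clones; zero-count clones dropped."""
    c = np.asarray(counts, dtype=float)
    if np.any(c < 0):
        raise ValueError("clone counts must be nonnegative")
    c = c[c > 0]
    if c.size == 0:
        raise ValueError("need at least one positive clone count")
    return c / c.sum()


def hill_diversity(counts: Sequence[float], q: float) -> float:
    """Hill number of order q (effective number of clones)."""
    p = clone_frequencies(counts)
    if q == 1:
        return float(np.exp(-np.sum(p * np.log(p))))
    return float(np.sum(p**q) ** (1.0 / (1.0 - q)))


def simpson_clonality(counts: Sequence[float]) -> float:
    """sqrt(1/D) with D the order-2 Hill diversity; equals sqrt(sum p^2)."""
    return float(np.sqrt(1.0 / hill_diversity(counts, q=2)))


def clonal_fraction_curve(counts: Sequence[float]) -> np.ndarray:
    """Cumulative frequency against descending clone rank; ends at 1."""
    p = clone_frequencies(counts)
    return np.cumsum(np.sort(p)[::-1])


def diversity_summary(counts: Sequence[float]) -> pd.Series:
    """Shannon (q=1) and Simpson (q=2) Hill diversities plus clonality."""
    return pd.Series(
        {
            "shannon_hill1": hill_diversity(counts, q=1),
            "simpson_D": hill_diversity(counts, q=2),
            "clonality": simpson_clonality(counts),
        }
    )
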