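"""TCR repertoire diversity and clonality from clone-count tables."""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd


def _frequencies(counts) -> np.ndarray:
    if isinstance(counts, pd.DataFrame):
        counts = counts["templates"].to_numpy()
    counts = np.asarray(counts, dtype=float)
    if counts.size == 0:
        raise ValueError("empty repertoire")
    if np.any(counts <= 0):
        raise ValueError("clone counts must be positive")
    return counts / counts.sum()


def inverse_simpson(counts: Sequence[float] | pd.DataFrame) -> float:
    """Inverse Simpson diversity ``1 / sum(p_i^2)`` (1 for a single clone,
    n for n equally-sized clones)."""
    p = _frequencies(counts)
    return float(1.0 / np.sum(p * p))


def simpson_clonality(counts: Sequence[float] | pd.DataFrame) -> float:
    """Simpson clonality ``sqrt(sum(p_i^2))``, in (0, 1]; 1 for a
    monoclonal repertoire, 1/sqrt(n) for n equal clones.

    This is the immunosequencing convention; note the algebraic identity
    ``clonality**2 * inverse_simpson == 1``.
    """
    p = _frequencies(counts)
    return float(np.sqrt(np.sum(p * p)))


def shannon_clonality(counts: Sequence[float] | pd.DataFrame) -> float:
    """Alternative clonality: ``1 - H/ln(n)`` (normalised Shannon entropy
    deficit).  Distinct from :func:`simpson_clonality`; 0 for a uniform
    repertoire, defined as 1.0 when only one clone is present."""
    p = _frequencies(counts)
    n = p.size
    if n == 1:
        return 1.0
    h = -np.sum(p * np.log(p))
    return float(1.0 - h / np.log(n))
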