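"""Shared statistical primitives.

Every exact over-representation p-value in the package (key-driver
cross-checks, rare/common variant convergence, pathway ORA) flows through
:func:`hypergeom_enrichment`, and every multiple-testing adjustment through
:func:`bh_fdr`, so there is a single tested implementation of each.
"""

from __future__ import annotations

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["bh_fdr", "hypergeom_enrichment", "fold_enrichment"]


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    Equivalent to q_(i) = min_{j>=i} (p_(j) * m / j) capped at 1, applied to
    the order statistics and mapped back to the input order.

    Parameters
    ----------
    p_values : array-like of float in (0, 1]

    Returns
    -------
    numpy.ndarray of adjusted values, same length and order as the input.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.empty(0, dtype=float)
    if np.any((p <= 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def hypergeom_enrichment(overlap: int, unit_size: int, catalog_size: int,
                         background_size: int) -> float:
    """One-sided (enrichment) exact p-value for a 2x2 overlap table.

    P(X >= overlap) where X ~ Hypergeometric(background_size, catalog_size,
    unit_size).  Identical to a one-sided Fisher exact test with
    alternative="greater"; the two names in the literature denote the same
    tail.
    """
    if background_size <= 0:
        raise ValueError("background must be non-empty")
    if not (0 <= overlap <= min(unit_size, catalog_size)):
        raise ValueError("infeasible contingency table")
    if unit_size > background_size or catalog_size > background_size:
        raise ValueError("unit/catalog cannot exceed the background")
    return float(stats.hypergeom.sf(overlap - 1, background_size,
                                    catalog_size, unit_size))


def fold_enrichment(overlap: int, unit_size: int, catalog_size: int,
                    background_size: int) -> float:
    """(overlap/unit) / (catalog/background); NaN when a denominator is 0."""
    if unit_size == 0 or catalog_size == 0 or background_size == 0:
        return float("nan")
    return (overlap / unit_size) / (catalog_size / background_size)
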