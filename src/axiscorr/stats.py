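"""Secondary cohort statistics for chromosome-spread quantifications.

Covers the standard per-cell / per-chromosome measures that accompany
the correlation analysis: focus densities per micrometer of axis,
background-corrected intensity ratios between unsynapsed and synapsed
axis regions, G-tests (likelihood-ratio tests) of 2x2 cell-category
proportions, and Mann-Whitney U comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as _sps

__all__ = [
    "FocusDensityRecord",
    "RegionIntensityRecord",
    "ContingencyTable",
    "focus_density",
    "intensity_ratio",
    "likelihood_ratio_test",
    "mann_whitney",
    "ttest_means",
]


@dataclass(frozen=True)
class FocusDensityRecord:
    cell_id: str
    condition: str
    focus_count: int
    axis_length_um: float

    @property
    def density(self) -> float:
        return focus_density(self.focus_count, self.axis_length_um)


@dataclass(frozen=True)
class RegionIntensityRecord:
    chromosome_id: str
    cell_id: str
    mean_unsynapsed: float
    mean_synapsed: float
    background: float

    @property
    def ratio(self) -> float:
        return intensity_ratio(self.mean_unsynapsed, self.mean_synapsed, self.background)


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 counts, rows = condition, columns = category (e.g. positive/negative)."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.shape != (2, 2):
            raise ValueError("contingency table must be 2x2")
        if np.any(c < 0) or not np.issubdtype(c.dtype, np.integer):
            if not np.all(c == np.floor(c)) or np.any(c < 0):
                raise ValueError("counts must be non-negative integers")
            c = c.astype(int)
        object.__setattr__(self, "counts", c.astype(int))


def focus_density(focus_count: int, axis_length_um: float) -> float:
    """Foci per micrometer of axis."""
    if focus_count < 0:
        raise ValueError("focus_count must be >= 0")
    if axis_length_um <= 0:
        raise ValueError("axis_length_um must be positive")
    return focus_count / axis_length_um


def intensity_ratio(
    mean_unsynapsed: float, mean_synapsed: float, background: float = 0.0
) -> float:
    """Background-corrected unsynapsed/synapsed intensity ratio."""
    denom = mean_synapsed - background
    if denom == 0:
        raise ZeroDivisionError("corrected synapsed intensity is zero")
    return (mean_unsynapsed - background) / denom


def likelihood_ratio_test(table: ContingencyTable | np.ndarray):
    """G-test of independence on a 2x2 table.

    G = 2 * sum(O * ln(O / E)) with expected counts from the
    independence margins (0 * ln 0 taken as 0); p from chi-square with
    1 degree of freedom.  Returns ``(G, df, p)``.  A zero margin makes
    the test undefined and raises ``ValueError``.
    """
    if not isinstance(table, ContingencyTable):
        table = ContingencyTable(np.asarray(table))
    counts = table.counts
    if np.any(counts.sum(axis=0) == 0) or np.any(counts.sum(axis=1) == 0):
        raise ValueError("G-test undefined for a zero margin")
    g, p, df, _ = _sps.chi2_contingency(
        counts, correction=False, lambda_="log-likelihood"
    )
    return float(g), int(df), float(p)


def mann_whitney(group_a, group_b, method: str | None = None) -> dict:
    """Two-sided Mann-Whitney U test with midrank tie handling.

    ``U`` is reported for ``group_a`` (number of (a, b) pairs with
    a > b, plus half the ties).  By default the exact null distribution
    is used when ``min(n_a, n_b) <= 8`` and the pooled values have no
    ties, otherwise the normal approximation with tie and continuity
    correction; ``method`` (``"exact"`` | ``"asymptotic"``) overrides
    the choice.  The method actually used is recorded in the result.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    if method is None:
        pooled = np.concatenate([a, b])
        has_ties = np.unique(pooled).size < pooled.size
        method = "exact" if min(a.size, b.size) <= 8 and not has_ties else "asymptotic"
    elif method not in ("exact", "asymptotic"):
        raise ValueError(f"unknown method {method!r}")
    res = _sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return {
        "U": float(res.statistic),
        "p_value": float(res.pvalue),
        "method": method,
        "n_a": int(a.size),
        "n_b": int(b.size),
    }


def ttest_means(group_a, group_b, equal_var: bool = False) -> dict:
    """Plain two-sample t-test convenience (Welch by default)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("both groups need >= 2 values")
    res = _sps.ttest_ind(a, b, equal_var=equal_var)
    return {
        "t": float(res.statistic),
        "p_value": float(res.pvalue),
        "mean_a": float(a.mean()),
        "mean_b": float(b.mean()),
    }
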