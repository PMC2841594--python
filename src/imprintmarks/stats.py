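"""Contingency chi-square statistics with explicit validity checking.

Two test variants are provided, matching common practice in mined-chromatin
comparisons: the Yates-continuity-corrected chi-square for 2x2 tables (used
when comparing a single profile between two gene groups) and the plain
Pearson chi-square for r x c tables (used when comparing whole profile
distributions). Every result carries a validity verdict from a two-tier
Cochran-style rule on the expected counts:

* ``invalid``            — any expected count < 1 (the test is not run on
                           such data; e.g. a 0%-vs-tiny-% comparison);
* ``valid_with_warning`` — all expected counts >= 1 but some < 5;
* ``valid``              — all expected counts >= 5.

The statistics themselves are computed from the textbook formulas here;
only the chi-square tail distribution comes from scipy.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import chi2 as _chi2_dist

from .annotations_io import ValidationError

__all__ = [
    "VALID",
    "VALID_WITH_WARNING",
    "INVALID",
    "ContingencyTable",
    "Validity",
    "ContingencyResult",
    "expected_counts",
    "check_conditions",
    "yates_chi2_2x2",
    "contingency_chi2",
    "proportions_from_percentages",
    "two_group_table",
]

VALID = "valid"
VALID_WITH_WARNING = "valid_with_warning"
INVALID = "invalid"


@dataclass(frozen=True)
class ContingencyTable:
    """r x c table of non-negative integer counts with axis labels."""

    observed: np.ndarray
    row_labels: tuple[str, ...] = ()
    col_labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        obs = np.asarray(self.observed)
        if obs.ndim != 2 or obs.shape[0] < 2 or obs.shape[1] < 2:
            raise ValidationError(f"table must be at least 2x2, got shape {obs.shape}")
        if np.any(obs < 0):
            raise ValidationError("counts must be non-negative")
        if not np.allclose(obs, np.round(obs)):
            raise ValidationError("counts must be integers")
        obs = obs.astype(np.int64)
        if obs.sum() == 0:
            raise ValidationError("table total must be positive")
        object.__setattr__(self, "observed", obs)
        r, c = obs.shape
        object.__setattr__(
            self,
            "row_labels",
            tuple(self.row_labels) or tuple(f"row{i}" for i in range(r)),
        )
        object.__setattr__(
            self,
            "col_labels",
            tuple(self.col_labels) or tuple(f"col{j}" for j in range(c)),
        )

    @property
    def shape(self) -> tuple[int, int]:
        return self.observed.shape


def expected_counts(table: ContingencyTable) -> np.ndarray:
    """Independence-model expected counts E[i,j] = rowsum_i * colsum_j / total."""
    obs = table.observed
    row = obs.sum(axis=1, keepdims=True).astype(float)
    col = obs.sum(axis=0, keepdims=True).astype(float)
    total = obs.sum()
    return row @ col / total


@dataclass(frozen=True)
class Validity:
    verdict: str
    reason: str
    min_expected: float


def check_conditions(table: ContingencyTable) -> Validity:
    """Two-tier expected-count rule; see the module docstring."""
    expected = expected_counts(table)
    min_e = float(expected.min())
    if min_e < 1.0:
        return Validity(
            INVALID,
            f"smallest expected count {min_e:.3g} < 1; "
            "data does not meet the conditions of the chi-square test",
            min_e,
        )
    if min_e < 5.0:
        n_small = int((expected < 5.0).sum())
        return Validity(
            VALID_WITH_WARNING,
            f"{n_small} expected count(s) below 5 (smallest {min_e:.3g})",
            min_e,
        )
    return Validity(VALID, "all expected counts >= 5", min_e)


@dataclass(frozen=True)
class ContingencyResult:
    statistic: float | None
    df: int
    p_value: float | None
    yates_applied: bool
    expected: np.ndarray
    validity: Validity

    @property
    def is_runnable(self) -> bool:
        return self.validity.verdict != INVALID


def yates_chi2_2x2(table: ContingencyTable) -> ContingencyResult:
    """Continuity-corrected chi-square for a 2x2 table (df = 1).

    statistic = sum over cells of (max(|O - E| - 0.5, 0))^2 / E; the
    correction is clamped at zero so near-null tables cannot inflate.
    """
    if table.shape != (2, 2):
        raise ValidationError(f"Yates correction requires a 2x2 table, got {table.shape}")
    obs = table.observed
    if np.any(obs.sum(axis=1) == 0) or np.any(obs.sum(axis=0) == 0):
        return ContingencyResult(
            statistic=None,
            df=1,
            p_value=None,
            yates_applied=True,
            expected=expected_counts(table),
            validity=Validity(
                INVALID, "degenerate table: an all-zero row or column", 0.0
            ),
        )
    expected = expected_counts(table)
    validity = check_conditions(table)
    diff = np.maximum(np.abs(table.observed - expected) - 0.5, 0.0)
    statistic = float((diff**2 / expected).sum())
    p_value = float(_chi2_dist.sf(statistic, 1))
    return ContingencyResult(
        statistic=statistic,
        df=1,
        p_value=p_value,
        yates_applied=True,
        expected=expected,
        validity=validity,
    )


def contingency_chi2(table: ContingencyTable) -> ContingencyResult:
    """Pearson chi-square for an r x c table, df = (r-1)(c-1), no correction.

    A degenerate table (some all-zero row or column) yields an ``invalid``
    verdict with the statistic omitted rather than a division error.
    """
    obs = table.observed
    r, c = table.shape
    df = (r - 1) * (c - 1)
    if np.any(obs.sum(axis=1) == 0) or np.any(obs.sum(axis=0) == 0):
        expected = expected_counts(table)
        return ContingencyResult(
            statistic=None,
            df=df,
            p_value=None,
            yates_applied=False,
            expected=expected,
            validity=Validity(
                INVALID, "degenerate table: an all-zero row or column", 0.0
            ),
        )
    expected = expected_counts(table)
    validity = check_conditions(table)
    statistic = float(((obs - expected) ** 2 / expected).sum())
    p_value = float(_chi2_dist.sf(statistic, df))
    return ContingencyResult(
        statistic=statistic,
        df=df,
        p_value=p_value,
        yates_applied=False,
        expected=expected,
        validity=validity,
    )


def proportions_from_percentages(percent: float, n: int) -> int:
    """Reconstruct an integer count from a printed percentage and group size.

    Nearest-integer rounding with half away from zero, so reconstructions
    from rounded published percentages are reproducible.
    """
    if not 0 <= percent <= 100:
        raise ValidationError(f"percent must be within [0, 100], got {percent}")
    if n <= 0:
        raise ValidationError(f"group size must be positive, got {n}")
    return int(np.floor(percent / 100.0 * n + 0.5))


def two_group_table(
    k1: int,
    n1: int,
    k2: int,
    n2: int,
    row_labels: Sequence[str] = ("group1", "group2"),
    col_labels: Sequence[str] = ("with_profile", "without_profile"),
) -> ContingencyTable:
    """2x2 table from per-group counts of a profile: rows are groups,
    columns are with/without the profile."""
    if not (0 <= k1 <= n1 and 0 <= k2 <= n2):
        raise ValidationError("counts must satisfy 0 <= k <= n")
    return ContingencyTable(
        observed=np.array([[k1, n1 - k1], [k2, n2 - k2]], dtype=np.int64),
        row_labels=tuple(row_labels),
        col_labels=tuple(col_labels),
    )
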