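"""Observed-over-expected (Ro/e) tissue preference and chi-square tests.

Ro/e divides observed cell counts in a (cell subtype, tissue/condition)
cell of a contingency table by the chi-square expected counts
(rowsum x colsum / N); values above 1 indicate preference of the subtype
for that condition. The chi-square test is the raw Pearson statistic with
no continuity correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from escctme.core_io import ValidationError


class LowExpectedCountWarning(UserWarning):
    """Some expected counts fall below 5; the chi-square approximation weakens."""


@dataclass
class ContingencyTable:
    """Cluster x category counts (rows: cell subtypes; columns: conditions)."""

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.counts)
        if (df.to_numpy() < 0).any():
            raise ValidationError("contingency counts must be non-negative")
        if df.to_numpy().sum() <= 0:
            raise ValidationError("contingency table grand total must be > 0")
        self.counts = df.astype(float)

    @classmethod
    def from_labels(
        cls, rows, cols, *, crossed_with=None, sep="-"
    ) -> "ContingencyTable":
        """Cross-tabulate two per-cell label vectors.

        ``crossed_with`` optionally crosses the column labels with a second
        factor (e.g. tissue x response), the layout used when preferences
        are assessed jointly over tissue and therapeutic response.
        """
        cols = pd.Series(cols).astype(str)
        if crossed_with is not None:
            cols = cols + sep + pd.Series(crossed_with).astype(str).to_numpy()
        tab = pd.crosstab(pd.Series(rows, name="cluster"), cols.rename("condition"))
        return cls(tab)

    @property
    def values(self) -> np.ndarray:
        return self.counts.to_numpy()

    def expected(self) -> pd.DataFrame:
        """Independence-model expected counts, rowsum x colsum / N."""
        O = self.values
        rowsum = O.sum(axis=1, keepdims=True)
        colsum = O.sum(axis=0, keepdims=True)
        return pd.DataFrame(
            rowsum * colsum / O.sum(), index=self.counts.index, columns=self.counts.columns
        )


def ro_e(table: ContingencyTable, *, on_empty: str = "error") -> pd.DataFrame:
    """Ratio of observed to expected cell counts, same shape as the table.

    Every row and column sum must be positive; with ``on_empty="na"`` an
    all-zero row instead yields NaN for that row rather than an error.
    """
    O = table.values
    rowsum = O.sum(axis=1)
    colsum = O.sum(axis=0)
    zero_rows = np.flatnonzero(rowsum == 0)
    zero_cols = np.flatnonzero(colsum == 0)
    if zero_cols.size:
        raise ValidationError(
            f"zero column totals for {table.counts.columns[zero_cols].tolist()}"
        )
    if zero_rows.size and on_empty == "error":
        raise ValidationError(
            f"zero row totals for {table.counts.index[zero_rows].tolist()}"
        )
    E = table.expected().to_numpy()
    with np.errstate(invalid="ignore", divide="ignore"):
        R = np.where(E > 0, O / E, np.nan)
    return pd.DataFrame(R, index=table.counts.index, columns=table.counts.columns)


class ChiSquareResult(NamedTuple):
    statistic: float
    df: int
    p_value: float


def chi_square_test(
    table: ContingencyTable, *, continuity_correction: bool = False
) -> ChiSquareResult:
    """Pearson chi-square test of independence on the contingency table.

    No continuity correction by default (matching the Ro/e expectation
    model); a warning is emitted when any expected count is below 5.
    """
    O = table.values
    if O.shape[0] < 2 or O.shape[1] < 2:
        raise ValidationError("chi-square needs at least 2 rows and 2 columns")
    if (O.sum(axis=1) == 0).any() or (O.sum(axis=0) == 0).any():
        raise ValidationError("chi-square requires positive row and column totals")
    stat, p, dof, expected = stats.chi2_contingency(O, correction=continuity_correction)
    if (expected < 5).any():
        warnings.warn(
            "expected counts below 5; chi-square approximation may be poor",
            LowExpectedCountWarning,
            stacklevel=2,
        )
    return ChiSquareResult(statistic=float(stat), df=int(dof), p_value=float(p))
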