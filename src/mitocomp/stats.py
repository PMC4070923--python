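"""Pearson correlation with two-tailed significance for per-gene statistics.

The two-tailed P comes from ``t = r * sqrt((n-2) / (1-r^2))`` on n-2
degrees of freedom (the standard test for a Pearson coefficient under
bivariate normality). No multiple-testing correction is applied to a
battery: callers receive the raw per-pair results.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson r with two-tailed P for one named column pair."""

    x_name: str
    y_name: str
    n: int
    r: float
    p: float

    def format_p(self, ndigits: int = 3) -> str:
        """P printed at fixed precision; values below half an ulp print 0.000."""
        return f"{self.p:.{ndigits}f}"

    def __str__(self) -> str:
        return f"{self.x_name} ~ {self.y_name}: r = {self.r:.3f}, P = {self.format_p()} (n = {self.n})"


def pearson(
    x, y, names: tuple[str, str] = ("x", "y")
) -> CorrelationResult:
    """Pearson correlation of two equal-length numeric vectors (n >= 3)."""
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape or xa.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    n = xa.size
    if n < 3:
        raise ValueError(f"need at least 3 observations, got {n}")
    if np.std(xa) == 0 or np.std(ya) == 0:
        raise ValueError("zero variance in one of the variables")
    result = sps.pearsonr(xa, ya)
    return CorrelationResult(
        x_name=names[0], y_name=names[1], n=n,
        r=float(result.statistic), p=float(result.pvalue),
    )


def correlation_battery(
    table: pd.DataFrame | str | Path,
    pairs: list[tuple[str, str]],
) -> list[CorrelationResult]:
    """One Pearson test per named column pair of a per-gene statistics table.

    ``table`` is a DataFrame or a TSV path ('#' lines are comments). Rows
    with an undefined value in either column of a pair are dropped pairwise
    with a log line.
    """
    if not isinstance(table, pd.DataFrame):
        table = pd.read_csv(table, sep="\t", comment="#")
    results = []
    for x_name, y_name in pairs:
        for col in (x_name, y_name):
            if col not in table.columns:
                raise KeyError(f"unknown column {col!r}")
        columns = [x_name] if x_name == y_name else [x_name, y_name]
        sub = table[columns].dropna()
        dropped = len(table) - len(sub)
        if dropped:
            logger.info("%s ~ %s: dropped %d rows with undefined values", x_name, y_name, dropped)
        results.append(pearson(sub[x_name], sub[y_name], names=(x_name, y_name)))
    return results
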