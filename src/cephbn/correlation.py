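"""Pairwise Pearson correlation matrix and thresholded correlation network.

The correlation network is the descriptive baseline model: variables are
nodes, and an undirected edge joins every pair whose absolute Pearson
correlation exceeds a threshold (0.4 by default).  Binary Treatment/Growth
columns participate on their 0/1 coding, where Pearson correlation coincides
with the point-biserial coefficient.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Optional

import numpy as np
import pandas as pd

from .domain_data import RateTable
from .errors import UndefinedCorrelationError


def pearson(x, y) -> float:
    """Sample Pearson correlation of two equal-length sequences.

    r = sum((x_i - xbar)(y_i - ybar)) / sqrt(sum (x_i-xbar)^2 * sum (y_i-ybar)^2)

    Raises :class:`UndefinedCorrelationError` if either sequence is constant.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d sequences of equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    dx = x - x.mean()
    dy = y - y.mean()
    sxx = float(dx @ dx)
    syy = float(dy @ dy)
    if sxx == 0.0 or syy == 0.0:
        raise UndefinedCorrelationError("correlation undefined for a constant sequence")
    r = float(dx @ dy) / np.sqrt(sxx * syy)
    return float(np.clip(r, -1.0, 1.0))


@dataclasses.dataclass(frozen=True)
class CorrelationNetwork:
    variables: tuple[str, ...]
    r_matrix: np.ndarray  # symmetric, unit diagonal; NaN where undefined
    edges: frozenset[frozenset]  # unordered pairs with |r| > threshold
    threshold: float

    def has_edge(self, a: str, b: str) -> bool:
        return frozenset((a, b)) in self.edges

    def edge_list(self) -> list[tuple[str, str, float]]:
        """(var_a, var_b, r) sorted lexicographically."""
        idx = {v: i for i, v in enumerate(self.variables)}
        out = []
        for pair in self.edges:
            a, b = sorted(pair)
            out.append((a, b, float(self.r_matrix[idx[a], idx[b]])))
        return sorted(out)

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.edge_list(), columns=["var_a", "var_b", "r"]).to_csv(
            path, sep="\t", index=False
        )

    def matrix_to_csv(self, path) -> None:
        pd.DataFrame(self.r_matrix, index=self.variables, columns=self.variables).to_csv(path)


def build_correlation_network(table, threshold: float = 0.4,
                              variables: Optional[list[str]] = None) -> CorrelationNetwork:
    """Correlation network over all rate-table columns.

    Rows with a missing value in either member of a pair are excluded pairwise
    (in practice only Growth can be missing).  Constant columns yield no edges
    and are reported with a warning; the matrix entry is NaN.
    """
    frame = table.frame if isinstance(table, RateTable) else pd.DataFrame(table)
    if variables is not None:
        frame = frame[variables]
    if len(frame) < 3:
        raise ValueError("need at least 3 rows")
    names = tuple(frame.columns)
    p = len(names)
    r = np.eye(p)
    edges = set()
    constant = [c for c in names if frame[c].dropna().nunique() <= 1]
    if constant:
        warnings.warn(f"constant column(s) excluded from edges: {constant}")
    for i in range(p):
        for j in range(i + 1, p):
            a, b = names[i], names[j]
            sub = frame[[a, b]].dropna()
            if a in constant or b in constant or len(sub) < 3:
                r[i, j] = r[j, i] = np.nan
                continue
            try:
                rij = pearson(sub[a], sub[b])
            except UndefinedCorrelationError:
                # constant on the pairwise-complete rows (e.g. Treatment
                # against a Growth recorded only for untreated patients)
                warnings.warn(f"correlation undefined for pair ({a}, {b}) "
                              "on its complete rows; no edge")
                r[i, j] = r[j, i] = np.nan
                continue
            r[i, j] = r[j, i] = rij
            if abs(rij) > threshold:
                edges.add(frozenset((a, b)))
    return CorrelationNetwork(names, r, frozenset(edges), threshold)
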