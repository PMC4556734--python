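"""Functional-connectivity matrices and proportional thresholding.

Functional connectivity between nodes is the Pearson correlation of their
preprocessed time series. Weak and potentially spurious correlations are
removed by proportional thresholding: only the strongest fraction (by
default 20%) of connection weights is preserved per subject, and the
resulting weighted matrices are analysed. Equal edge density across
subjects emphasises differences in topology over differences in total
connectivity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from ._utils import round_half_away


@dataclass(frozen=True)
class FCMatrix:
    """Symmetric Pearson-correlation matrix with unit diagonal."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("FC matrix must be square")
        object.__setattr__(self, "values", v)

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class WeightedNetwork:
    """Thresholded weighted network at a fixed edge density.

    ``weights`` is symmetric with a zero diagonal; exactly
    ``retained_count`` upper-triangle entries are nonzero, and every
    retained weight is at least as large (signed) as every discarded one.
    """

    weights: np.ndarray
    density: float
    retained_count: int

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("weights must be square")
        object.__setattr__(self, "weights", w)

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    def edge_list(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Retained upper-triangle edges as (rows, cols, weights)."""
        iu = np.triu_indices(self.n_nodes, k=1)
        vals = self.weights[iu]
        keep = vals != 0
        return iu[0][keep], iu[1][keep], vals[keep]


def correlation_matrix(ts: np.ndarray) -> FCMatrix:
    """Pearson correlation between all node pairs of a T x N series."""
    ts = np.asarray(ts, dtype=float)
    if ts.ndim != 2 or ts.shape[0] < 3:
        raise ValueError("need a T x N matrix with T >= 3")
    constant = np.flatnonzero(ts.std(axis=0) == 0)
    if constant.size:
        raise ValueError(
            f"correlation undefined for constant node time series: {constant.tolist()}"
        )
    r = np.corrcoef(ts, rowvar=False)
    r = np.clip(r, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return FCMatrix(r)


def proportional_threshold(
    fc: FCMatrix | np.ndarray, density: float = 0.2
) -> WeightedNetwork:
    """Keep the strongest ``density`` fraction of connection weights.

    "Strongest" means largest signed value; the retained count is
    round-half-away-from-zero of density * N(N-1)/2, and ties at the cut are
    broken by (row, col) lexicographic order so the result is deterministic.
    A warning is issued if any retained weight is non-positive (density
    exceeding the positive-weight fraction).
    """
    values = fc.values if isinstance(fc, FCMatrix) else np.asarray(fc, dtype=float)
    if not 0 < density <= 1:
        raise ValueError("density must lie in (0, 1]")
    n = values.shape[0]
    rows, cols = np.triu_indices(n, k=1)
    vals = values[rows, cols]
    n_pairs = vals.size
    k = round_half_away(density * n_pairs)
    order = np.lexsort((cols, rows, -vals))
    keep = order[:k]
    if k and vals[keep].min() <= 0:
        warnings.warn(
            "retained non-positive weights: requested density exceeds the "
            "positive-weight fraction",
            stacklevel=2,
        )
    weights = np.zeros_like(values)
    weights[rows[keep], cols[keep]] = vals[keep]
    weights += weights.T
    return WeightedNetwork(weights=weights, density=density, retained_count=k)


def absolute_threshold_mode(fc: FCMatrix | np.ndarray, density: float = 0.2) -> WeightedNetwork:
    """Variant ranking edges by |r| instead of signed r (config flag)."""
    values = fc.values if isinstance(fc, FCMatrix) else np.asarray(fc, dtype=float)
    net = proportional_threshold(np.abs(values), density)
    signed = np.where(net.weights != 0, values, 0.0)
    return WeightedNetwork(signed, net.density, net.retained_count)


def mean_connectivity(net: WeightedNetwork, mode: str = "retained") -> float:
    """Whole-brain connectivity: mean of retained weights.

    ``mode="retained"`` (default) averages over retained edges only;
    ``mode="all_pairs"`` divides the retained sum by all N(N-1)/2 pairs.
    """
    if net.retained_count < 1:
        raise ValueError("network has no retained edges")
    if mode not in ("retained", "all_pairs"):
        raise ValueError("mode must be 'retained' or 'all_pairs'")
    iu = np.triu_indices(net.n_nodes, k=1)
    total = float(net.weights[iu].sum())
    if mode == "retained":
        return total / net.retained_count
    return total / iu[0].size


def write_matrix_tsv(path: str | Path, matrix: np.ndarray, node_ids: np.ndarray) -> None:
    """Dense matrix TSV with node-id header and index."""
    frame = pd.DataFrame(matrix, index=node_ids, columns=node_ids)
    frame.to_csv(path, sep="\t", index_label="node_id", float_format="%.12g")


def read_matrix_tsv(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    frame = pd.read_csv(path, sep="\t", index_col="node_id")
    return frame.to_numpy(float), frame.index.to_numpy(int)


def write_edge_list_tsv(
    path: str | Path, net: WeightedNetwork, node_ids: np.ndarray
) -> None:
    rows, cols, weights = net.edge_list()
    pd.DataFrame(
        {"node_i": node_ids[rows], "node_j": node_ids[cols], "weight": weights}
    ).to_csv(path, sep="\t", index=False, float_format="%.12g")
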