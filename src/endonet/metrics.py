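"""Weighted graph measures, null-model normalization, NDI, and hub topography.

The global organisation of each subject's thresholded network is summarised
by four measures:

* node strength — the total weight of a node's retained connections;
* clustering coefficient C — the Onnela weighted form, quantifying the
  density of closed triangles around nodes;
* global efficiency E — the mean inverse shortest weighted path length over
  node pairs, with edge lengths taken as reciprocal weights;
* node disruption index (NDI) — the slope of a regression of
  (individual - reference) node strengths on the reference strengths, where
  the reference is a group-average strength profile; 0 means the individual
  matches the reference topography.

C and E are normalized by their mean over an ensemble of random networks
that preserve the size, density, degree sequence and (approximately) the
strength distribution of the subject's network. Hubs are the top fraction
(default 20%) of nodes by strength, tallied per analysed functional
network.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

from ._utils import round_half_away
from .connectivity import WeightedNetwork
from .parcellation import ANALYZED_NETWORKS, Parcellation


def _weights_of(net: WeightedNetwork | np.ndarray) -> np.ndarray:
    if isinstance(net, WeightedNetwork):
        return net.weights
    w = np.asarray(net, dtype=float)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ValueError("expected a square weight matrix")
    return w


def node_strengths(net: WeightedNetwork | np.ndarray) -> np.ndarray:
    """Per-node total connection weight (row sums of the weight matrix)."""
    return _weights_of(net).sum(axis=1)


def clustering_coefficient(net: WeightedNetwork | np.ndarray) -> float:
    """Mean Onnela weighted clustering coefficient.

    Weights are scaled by the maximum weight; each node's coefficient is the
    sum of geometric means of triangle weights divided by k(k-1) possible
    triangles, where k is the binary degree. Nodes with k < 2 contribute 0.
    """
    w = _weights_of(net)
    if (w < 0).any():
        raise ValueError("negative weights: threshold to non-negative weights first")
    w_max = w.max()
    if w_max == 0:
        return 0.0
    cbrt = np.cbrt(w / w_max)
    triangles = np.diagonal(cbrt @ cbrt @ cbrt)
    degree = (w > 0).sum(axis=1)
    denom = degree * (degree - 1)
    coeff = np.zeros(w.shape[0])
    ok = denom > 0
    coeff[ok] = triangles[ok] / denom[ok]
    return float(coeff.mean())


def global_efficiency(net: WeightedNetwork | np.ndarray) -> float:
    """Mean inverse shortest weighted path length; disconnected pairs give 0.

    Edge lengths are reciprocal weights (stronger connections are shorter),
    and shortest paths are computed with Dijkstra's algorithm.
    """
    w = _weights_of(net)
    if (w < 0).any():
        raise ValueError("negative weights: threshold to non-negative weights first")
    n = w.shape[0]
    if n < 2:
        return 0.0
    rows, cols = np.nonzero(w)
    lengths = csr_matrix((1.0 / w[rows, cols], (rows, cols)), shape=w.shape)
    dist = shortest_path(lengths, method="D", directed=False)
    with np.errstate(divide="ignore"):
        inv = 1.0 / dist
    inv[~np.isfinite(inv)] = 0.0
    np.fill_diagonal(inv, 0.0)
    return float(inv.sum() / (n * (n - 1)))


# ---------------------------------------------------------------------------
# Null ensemble
# ---------------------------------------------------------------------------


def _rewire_edges(
    rows: np.ndarray, cols: np.ndarray, n_attempts: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Degree-preserving double-edge swaps on the binarized topology."""
    u = rows.copy()
    v = cols.copy()
    n_edges = u.size
    edge_set = {(int(a), int(b)) for a, b in zip(u, v)}
    pick = rng.integers(0, n_edges, size=(n_attempts, 2))
    flips = rng.random(n_attempts) < 0.5
    for (i, j), flip in zip(pick, flips):
        if i == j:
            continue
        a, b = int(u[i]), int(v[i])
        c, d = int(u[j]), int(v[j])
        if flip:
            c, d = d, c
        # propose (a, d) and (c, b)
        if a == d or c == b:
            continue
        e1 = (a, d) if a < d else (d, a)
        e2 = (c, b) if c < b else (b, c)
        if e1 in edge_set or e2 in edge_set:
            continue
        edge_set.discard((a, b) if a < b else (b, a))
        edge_set.discard((min(c, d), max(c, d)))
        edge_set.add(e1)
        edge_set.add(e2)
        u[i], v[i] = e1
        u[j], v[j] = e2
    return u, v


def _assign_weights(
    u: np.ndarray, v: np.ndarray, weights: np.ndarray, target_strengths: np.ndarray
) -> np.ndarray:
    """Greedy rank matching of the weight multiset onto rewired edges.

    Weights are placed in descending order; at each step the largest
    remaining weight goes to the unassigned edge with the largest residual
    target strength sum, and the residuals of its endpoints are decremented.
    Preserves the weight multiset exactly and the strength sequence
    approximately.
    """
    order = np.argsort(-weights, kind="stable")
    residual = target_strengths.astype(float).copy()
    eu = u.copy()
    ev = v.copy()
    out_u = np.empty_like(u)
    out_v = np.empty_like(v)
    out_w = np.empty_like(weights)
    n_left = eu.size
    for rank, wi in enumerate(order):
        w = weights[wi]
        scores = residual[eu[:n_left]] + residual[ev[:n_left]]
        j = int(np.argmax(scores))
        a, b = eu[j], ev[j]
        out_u[rank], out_v[rank], out_w[rank] = a, b, w
        residual[a] -= w
        residual[b] -= w
        n_left -= 1
        eu[j], ev[j] = eu[n_left], ev[n_left]
    return np.stack([out_u, out_v, out_w.astype(float)])


def null_ensemble(
    net: WeightedNetwork, n: int = 100, seed: int = 0, n_swap_factor: int = 10
) -> list[WeightedNetwork]:
    """Random networks preserving size, density, degrees and strengths.

    Each null network is built by (1) attempting ``n_swap_factor *
    retained_count`` degree-preserving double-edge swaps on the binarized
    topology, then (2) reassigning the original weight multiset to the
    rewired edges by greedy rank matching against the original node
    strengths. Node count, edge count, degree sequence and weight multiset
    are preserved exactly; the strength sequence approximately.
    """
    if n < 1:
        raise ValueError("ensemble size must be >= 1")
    rows, cols, weights = net.edge_list()
    if rows.size < 2:
        raise ValueError("need at least 2 edges to rewire")
    strengths = node_strengths(net)
    rng = np.random.default_rng(seed)
    nulls = []
    for _ in range(n):
        u, v = _rewire_edges(rows, cols, n_swap_factor * rows.size, rng)
        assigned = _assign_weights(u, v, weights, strengths)
        w_null = np.zeros_like(net.weights)
        ui = assigned[0].astype(int)
        vi = assigned[1].astype(int)
        w_null[ui, vi] = assigned[2]
        w_null[vi, ui] = assigned[2]
        nulls.append(
            WeightedNetwork(w_null, density=net.density, retained_count=net.retained_count)
        )
    return nulls


@dataclass(frozen=True)
class MetricResult:
    """A graph metric with its null-ensemble normalization."""

    raw: float
    null_mean: float
    normalized: float
    ensemble_size: int


def normalize_metric(
    metric_fn: Callable[[WeightedNetwork], float],
    net: WeightedNetwork,
    ensemble: Sequence[WeightedNetwork],
) -> MetricResult:
    """Divide a metric by its mean over a null ensemble."""
    if not ensemble:
        raise ValueError("ensemble must be non-empty")
    raw = float(metric_fn(net))
    null_mean = float(np.mean([metric_fn(g) for g in ensemble]))
    if null_mean == 0:
        raise ValueError("null mean is zero; normalized metric undefined")
    return MetricResult(
        raw=raw,
        null_mean=null_mean,
        normalized=raw / null_mean,
        ensemble_size=len(ensemble),
    )


# ---------------------------------------------------------------------------
# Node disruption index
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class NDIResult:
    """Slope/intercept of (individual - template) strengths on template."""

    slope: float
    intercept: float
    r_squared: float
    template_id: str | None = None


def node_disruption_index(
    subject: np.ndarray, template: np.ndarray, template_id: str | None = None
) -> NDIResult:
    """OLS fit of (subject - template) node strengths against the template.

    A slope of 0 means the subject's strength profile matches the reference
    group average; for a uniformly scaled profile k * template the slope is
    exactly k - 1.
    """
    subject = np.asarray(subject, dtype=float)
    template = np.asarray(template, dtype=float)
    if subject.shape != template.shape or subject.ndim != 1:
        raise ValueError("subject and template strengths must be equal-length vectors")
    if np.ptp(template) == 0:
        raise ValueError("template strengths are degenerate (zero variance)")
    diff = subject - template
    if np.ptp(diff) == 0:
        # exact offset (or identity): slope 0, intercept = the constant offset
        return NDIResult(0.0, float(diff[0]), 1.0 if diff[0] == 0 else 0.0, template_id)
    fit = sps.linregress(template, diff)
    return NDIResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        template_id=template_id,
    )


def group_template(
    strengths: Sequence[np.ndarray], leave_one_out: int | None = None
) -> np.ndarray:
    """Per-node mean strength over a set of subjects.

    With ``leave_one_out=i`` the i-th subject is excluded from the average,
    for evaluating members of the template group against their own group.
    """
    if len(strengths) < 2:
        raise ValueError("need at least 2 subjects to form a template")
    stack = np.asarray(strengths, dtype=float)
    if leave_one_out is None:
        return stack.mean(axis=0)
    if not 0 <= leave_one_out < stack.shape[0]:
        raise ValueError("leave_one_out index out of range")
    mask = np.ones(stack.shape[0], dtype=bool)
    mask[leave_one_out] = False
    return stack[mask].mean(axis=0)


# ---------------------------------------------------------------------------
# Hubs and network blocks
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class HubProfile:
    """Top-fraction nodes by strength and their per-network tally.

    ``hub_indices`` are positional indices into the parcellation;
    ``counts`` covers the analysed networks only, so its values sum to at
    most the hub-set size.
    """

    hub_indices: np.ndarray
    counts: dict[str, int]
    fraction: float


def identify_hubs(
    strengths: np.ndarray, parc: Parcellation, fraction: float = 0.2
) -> HubProfile:
    """The top round(fraction * N) nodes by strength, tallied per network.

    Ties are broken by node id ascending. Counts are reported for the nine
    analysed networks; hubs falling in excluded networks are in the hub set
    but not in any count.
    """
    strengths = np.asarray(strengths, dtype=float)
    if strengths.shape != (parc.n_nodes,):
        raise ValueError("strengths must have one entry per parcellation node")
    if not 0 < fraction <= 1:
        raise ValueError("fraction must lie in (0, 1]")
    k = round_half_away(fraction * parc.n_nodes)
    order = np.lexsort((parc.node_ids, -strengths))
    hubs = order[:k]
    labels = parc.labels.astype(str)
    counts = {
        net: int(np.isin(hubs, parc.network_indices(net)).sum())
        for net in ANALYZED_NETWORKS
        if net in labels
    }
    return HubProfile(hub_indices=np.sort(hubs), counts=counts, fraction=fraction)


def hub_profile(
    net: WeightedNetwork,
    parc: Parcellation,
    fraction: float = 0.2,
    method: str = "strength",
) -> HubProfile:
    """Hub identification from a network, by strength or (alternative) degree."""
    if method == "strength":
        values = node_strengths(net)
    elif method == "degree":
        values = (net.weights > 0).sum(axis=1).astype(float)
    else:
        raise ValueError("method must be 'strength' or 'degree'")
    return identify_hubs(values, parc, fraction)


def network_block_weights(
    net: WeightedNetwork, parc: Parcellation
) -> pd.DataFrame:
    """Intra-network and network-to-rest mean connection weights.

    For each analysed network A, ``intra`` is the mean weight over all node
    pairs within A (zeros included) and ``inter`` the mean over pairs with
    exactly one endpoint in A. Networks with fewer than 2 nodes have no
    intra mean (NaN).
    """
    w = net.weights
    n = parc.n_nodes
    labels = parc.labels.astype(str)
    records = []
    for network in ANALYZED_NETWORKS:
        if network not in labels:
            continue
        members = parc.network_indices(network)
        m = members.size
        if m >= 2:
            block = w[np.ix_(members, members)]
            intra = float(block.sum() / (m * (m - 1)))
        else:
            intra = float("nan")
        others = np.setdiff1d(np.arange(n), members)
        if m and others.size:
            inter = float(w[np.ix_(members, others)].mean())
        else:
            inter = float("nan")
        records.append({"network": network, "intra": intra, "inter": inter})
    return pd.DataFrame.from_records(records).set_index("network")
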