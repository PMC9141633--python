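"""Whole-brain connectivity matrices and graph-level comparisons.

Assembles region x region connectivity matrices from voxel-level data,
partitions edges into within- and between-network classes given a
region-to-network assignment (e.g., 400 regions grouped into 7
resting-state networks), and provides the graph-level statistics used to
compare connectivity measures: rank-correlation similarity between
matrices, fraction-of-maximum thresholding, spectral edge nonrandomness,
and between-subject similarity.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import stats

from .measures import RegionActivity, compute_measure

__all__ = [
    "FCMatrix",
    "NetworkAssignment",
    "EdgeClass",
    "assemble_fc",
    "partition_edges",
    "measure_similarity",
    "threshold_fc",
    "nonrandomness",
    "subject_similarity",
]


@dataclass(frozen=True)
class FCMatrix:
    """Symmetric region x region connectivity values for one measure."""

    values: np.ndarray
    measure_tag: str = ""
    subject_id: str = ""
    region_ids: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
            raise ValueError(f"FC matrix must be square, got shape {arr.shape}")
        if not np.allclose(arr, arr.T, atol=1e-10):
            raise ValueError("FC matrix must be symmetric")
        arr = arr.copy()
        np.fill_diagonal(arr, 0.0)
        object.__setattr__(self, "values", arr)
        if self.region_ids is None:
            object.__setattr__(
                self, "region_ids", tuple(f"r{i}" for i in range(arr.shape[0]))
            )
        elif len(self.region_ids) != arr.shape[0]:
            raise ValueError("region_ids length does not match matrix size")

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]

    def upper_triangle(self) -> np.ndarray:
        iu = np.triu_indices(self.n_regions, k=1)
        return self.values[iu]


@dataclass(frozen=True)
class NetworkAssignment:
    """Region -> network-label map (each region exactly one label)."""

    labels: dict[str, str]

    @property
    def n_networks(self) -> int:
        return len(set(self.labels.values()))

    @property
    def networks(self) -> tuple[str, ...]:
        return tuple(sorted(set(self.labels.values())))

    def label_of(self, region_id: str) -> str:
        try:
            return self.labels[region_id]
        except KeyError:
            raise KeyError(f"region {region_id!r} missing from network assignment") from None


@dataclass(frozen=True)
class EdgeClass:
    """Within/between classification of every edge, plus per-network-pair sets.

    ``pair_edges`` maps a sorted (network_a, network_b) tuple to the list of
    (i, j) index pairs (i < j) whose endpoints lie in those networks;
    within-network blocks have network_a == network_b.
    """

    within: tuple[tuple[int, int], ...]
    between: tuple[tuple[int, int], ...]
    pair_edges: dict[tuple[str, str], tuple[tuple[int, int], ...]]


def assemble_fc(
    regions: list[RegionActivity], measure: str, subject_id: str = "", **measure_kwargs
) -> FCMatrix:
    """Evaluate a measure on every unordered region pair."""
    r = len(regions)
    if r < 2:
        raise ValueError("need at least two regions")
    values = np.zeros((r, r))
    for i, j in itertools.combinations(range(r), 2):
        values[i, j] = values[j, i] = compute_measure(
            measure, regions[i], regions[j], **measure_kwargs
        )
    ids = tuple(reg.region_id or f"r{i}" for i, reg in enumerate(regions))
    return FCMatrix(values=values, measure_tag=measure, subject_id=subject_id, region_ids=ids)


def partition_edges(fc: FCMatrix, assign: NetworkAssignment) -> EdgeClass:
    """Split all R(R-1)/2 edges into within- and between-network classes."""
    within: list[tuple[int, int]] = []
    between: list[tuple[int, int]] = []
    pair_edges: dict[tuple[str, str], list[tuple[int, int]]] = {}
    labels = [assign.label_of(rid) for rid in fc.region_ids]
    for i, j in itertools.combinations(range(fc.n_regions), 2):
        la, lb = sorted((labels[i], labels[j]))
        pair_edges.setdefault((la, lb), []).append((i, j))
        (within if la == lb else between).append((i, j))
    return EdgeClass(
        within=tuple(within),
        between=tuple(between),
        pair_edges={k: tuple(v) for k, v in pair_edges.items()},
    )


def _scoped_entries(
    fc: FCMatrix, scope: str | tuple[str, str], assign: NetworkAssignment | None
) -> np.ndarray:
    if scope == "all":
        return fc.upper_triangle()
    if assign is None:
        raise ValueError("a NetworkAssignment is required for a network-pair scope")
    key = tuple(sorted(scope))
    edges = partition_edges(fc, assign).pair_edges.get(key)
    if not edges:
        raise ValueError(f"no edges in network pair {key}")
    idx = np.array(edges)
    return fc.values[idx[:, 0], idx[:, 1]]


def measure_similarity(
    fc_a: FCMatrix,
    fc_b: FCMatrix,
    scope: str | tuple[str, str] = "all",
    assign: NetworkAssignment | None = None,
) -> float:
    """Spearman rank correlation between two matrices' scoped upper triangles.

    ``scope`` is either "all" or a (network_a, network_b) pair restricting
    the comparison to that block's edges. Rank-based, so invariant to any
    common monotone rescaling of the matrices.
    """
    if fc_a.n_regions != fc_b.n_regions:
        raise ValueError("matrices must cover the same regions")
    a = _scoped_entries(fc_a, scope, assign)
    b = _scoped_entries(fc_b, scope, assign)
    return float(stats.spearmanr(a, b).statistic)


def threshold_fc(fc: FCMatrix, fraction: float) -> FCMatrix:
    """Zero every entry below ``fraction`` times the matrix maximum."""
    if not 0.0 <= fraction <= 1.0:
        raise ValueError(f"fraction must lie in [0, 1], got {fraction}")
    cut = fraction * fc.values.max()
    values = np.where(fc.values < cut, 0.0, fc.values)
    return FCMatrix(
        values=values,
        measure_tag=fc.measure_tag,
        subject_id=fc.subject_id,
        region_ids=fc.region_ids,
    )


def binarize_top_density(fc: FCMatrix, density: float) -> nx.Graph:
    """Keep the top ``density`` fraction of edges by weight; return the graph.

    Edge count is round(density * R(R-1)/2); ties at the cut are broken by
    (descending weight, edge index) so the result is deterministic.
    """
    if not 0.0 < density < 1.0:
        raise ValueError(f"density must lie in (0, 1), got {density}")
    r = fc.n_regions
    iu = np.triu_indices(r, k=1)
    weights = fc.values[iu]
    m = max(1, int(round(density * weights.size)))
    order = np.argsort(-weights, kind="stable")[:m]
    g = nx.Graph()
    g.add_nodes_from(range(r))
    g.add_edges_from(zip(iu[0][order], iu[1][order]))
    return g


def nonrandomness(
    fc: FCMatrix | nx.Graph, density: float = 0.10, k: int = 7
) -> tuple[float, dict[tuple[int, int], float]]:
    """Spectral edge-nonrandomness of the thresholded connectivity graph.

    The weighted matrix is binarized by keeping the top ``density`` fraction
    of edges; on the largest connected component each node is embedded with
    the k leading adjacency eigenvectors, and each edge's nonrandomness is
    the inner product of its endpoints' embedding vectors. Embeddings are
    normalised so that the per-edge values over present edges sum exactly to
    the sum of the k leading adjacency eigenvalues — the graph-level
    nonrandomness. Community-structured graphs score high; Erdos-Renyi
    graphs at the same density score low, and edges bridging two
    communities receive small per-edge values.

    Returns (total, per-edge map keyed by node-index pairs of the input).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if isinstance(fc, FCMatrix):
        g = binarize_top_density(fc, density)
    else:
        g = fc
    if g.number_of_edges() == 0:
        raise ValueError("graph has no edges after thresholding")
    component = max(nx.connected_components(g), key=len)
    g = g.subgraph(component).copy()
    nodes = sorted(g.nodes())
    a = nx.to_numpy_array(g, nodelist=nodes)
    k_eff = min(k, len(nodes))
    eigvals, eigvecs = np.linalg.eigh(a)
    lead = np.argsort(eigvals)[::-1][:k_eff]
    # sqrt(2) scaling tiles the eigenvalue sum over unordered edges:
    # sum_edges 2 v_j(u) v_j(v) = v_j^T A v_j = lambda_j
    emb = np.sqrt(2.0) * eigvecs[:, lead]
    index = {node: i for i, node in enumerate(nodes)}
    per_edge = {
        (u, v): float(emb[index[u]] @ emb[index[v]]) for u, v in g.edges()
    }
    total = float(np.sum(eigvals[lead]))
    return total, per_edge


def subject_similarity(
    fcs: list[FCMatrix],
    scope: str | tuple[str, str] = "all",
    assign: NetworkAssignment | None = None,
    leave_one_out: bool = False,
) -> np.ndarray:
    """Pearson correlation of each subject's matrix with the cohort average.

    The average is the element-wise mean over all subjects (including the
    subject itself, unless ``leave_one_out``); correlations are over the
    scoped upper-triangle entries.
    """
    if len(fcs) < 2:
        raise ValueError("need at least two subjects")
    entries = np.array([_scoped_entries(fc, scope, assign) for fc in fcs])
    out = np.empty(len(fcs))
    total = entries.sum(axis=0)
    for i in range(len(fcs)):
        if leave_one_out:
            ref = (total - entries[i]) / (len(fcs) - 1)
        else:
            ref = total / len(fcs)
        out[i] = stats.pearsonr(entries[i], ref).statistic
    return out
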