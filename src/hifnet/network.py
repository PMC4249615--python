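"""Relevance-network construction from a seed gene list.

Edge significance is calibrated against a permutation null: mutual information
is computed for random probe pairs after independently permuting one member,
and the log of the empirical survival function is fitted linearly over the top
tail, ``ln P(MI > m) ~ a + b m`` with ``b < 0``.  The fitted line is
extrapolated to map MI to p-values far below the smallest achievable
permutation frequency — this is how thresholds such as 1e-15, which exceed any
feasible permutation count, are realized.

The network itself links seed probes to every other probe whose pairwise MI is
significant at the requested threshold (``seed_restricted`` mode; an
``all_pairs`` mode is available).  Indirect edges can then be pruned with the
data-processing inequality: in every triangle the edge whose MI falls below
``(1 - tolerance) * min`` of the other two is marked, and all marks are
removed simultaneously.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .datatypes import ExpressionMatrix, SeedList
from .mi import chi2_critical, mi_from_ranks, mi_one_vs_many, rank_rows

__all__ = [
    "NullCalibration",
    "calibrate_null",
    "infer_relevance_network",
    "apply_dpi",
]


@dataclass
class NullCalibration:
    """Fitted exponential tail of the permutation-null MI distribution."""

    samples: np.ndarray
    a: float  # intercept of ln P(MI > m)
    b: float  # slope, negative
    rng_seed: int
    n_pairs: int
    tail_fraction: float = 0.1

    def p_value(self, mi):
        """Edge p-value(s) for the given MI value(s), capped at 1."""
        return np.minimum(1.0, np.exp(self.a + self.b * np.asarray(mi, dtype=float)))

    def threshold(self, p: float) -> float:
        """MI value whose fitted p-value equals ``p``."""
        if not 0 < p < 1:
            raise ValueError("p must be in (0, 1)")
        return (np.log(p) - self.a) / self.b


def calibrate_null(
    matrix: ExpressionMatrix,
    n_pairs: int = 1000,
    rng_seed: int = 0,
    tail_fraction: float = 0.1,
    min_split: int = 8,
    alpha_split: float = 0.05,
) -> NullCalibration:
    """Permutation-null MI calibration for one cohort.

    Draws ``n_pairs`` random probe pairs, permutes one member of each pair
    independently, estimates MI, and fits the log empirical survival function
    over the top ``tail_fraction`` of the samples by least squares (Hazen
    plotting positions).  The null is cohort-specific because the MI null
    scale depends on the sample count.
    """
    if n_pairs < 200:
        raise ValueError("need at least 200 permutation pairs for a stable tail fit")
    rng = np.random.default_rng(rng_seed)
    vals = matrix.values.to_numpy()
    m = vals.shape[0]
    if m < 2:
        raise ValueError("need at least 2 probes")
    crit = chi2_critical(alpha_split)
    ranks = rank_rows(vals)
    mis = np.empty(n_pairs)
    for k in range(n_pairs):
        i, j = rng.choice(m, size=2, replace=False)
        mis[k] = mi_from_ranks(ranks[i], rng.permutation(ranks[j]), min_split, crit)
    order = np.sort(mis)[::-1]
    n_tail = max(int(np.ceil(tail_fraction * n_pairs)), 10)
    m_tail = order[:n_tail]
    surv = (np.arange(1, n_tail + 1) - 0.5) / n_pairs
    # the null has a point mass at exactly 0 (cells whose uniformity test
    # never rejects); the decile fit deliberately spans that mass, which
    # anchors the intercept and stabilizes the extrapolation slope, but a
    # usable fit still needs a handful of positive samples in the tail
    if int(np.count_nonzero(m_tail > 0)) < 3:
        raise ValueError(
            "fewer than 3 positive permutation MI samples in the tail; "
            "increase n_pairs"
        )
    b, a = np.polyfit(m_tail, np.log(surv), 1)
    if b >= 0:
        raise ValueError(
            "null tail fit has non-negative slope; increase n_pairs"
        )
    return NullCalibration(
        samples=mis, a=float(a), b=float(b), rng_seed=rng_seed,
        n_pairs=n_pairs, tail_fraction=tail_fraction,
    )


def infer_relevance_network(
    matrix: ExpressionMatrix,
    seeds: SeedList,
    p_threshold: float,
    calib: NullCalibration,
    mode: str = "seed_restricted",
    min_split: int = 8,
    alpha_split: float = 0.05,
) -> nx.Graph:
    """Build the MI relevance network anchored on the seed probes.

    In ``seed_restricted`` mode (default, matching the seed-anchored usage) MI
    is computed for every (seed probe, other probe) pair; ``all_pairs``
    computes every pair.  Edges with fitted p-value below ``p_threshold`` are
    kept.  Returned as an undirected :class:`networkx.Graph` whose edges carry
    ``mi`` (nats) and ``p``, and whose nodes carry ``is_seed``.
    """
    if not 0 < p_threshold < 1:
        raise ValueError("p_threshold must be in (0, 1)")
    if mode not in ("seed_restricted", "all_pairs"):
        raise ValueError(f"unknown mode {mode!r}")
    probes = matrix.probe_ids
    probe_pos = {p: i for i, p in enumerate(probes)}
    seed_idx = [probe_pos[p] for p in seeds.probes if p in probe_pos]
    if not seed_idx:
        raise ValueError("no resolved seed probe present in the matrix")
    seed_set = set(seed_idx)

    vals = matrix.values.to_numpy()
    ranks = rank_rows(vals)
    sorted_ranks = np.sort(ranks, axis=1)
    crit = chi2_critical(alpha_split)

    graph = nx.Graph()
    graph.graph.update(
        mode=mode, p_threshold=p_threshold, mi_units="nats",
        calibration_seed=calib.rng_seed,
    )
    n = vals.shape[0]

    def _add_edges(i, rows):
        if rows.size == 0:
            return
        mis = mi_one_vs_many(ranks[i], ranks, rows, sorted_ranks, min_split, crit)
        ps = calib.p_value(mis)
        for j, mi_v, p_v in zip(rows[ps < p_threshold],
                                mis[ps < p_threshold], ps[ps < p_threshold]):
            graph.add_edge(probes[i], probes[int(j)], mi=float(mi_v), p=float(p_v))

    if mode == "seed_restricted":
        for i in seed_idx:
            rows = np.array(
                [j for j in range(n) if j != i and (j not in seed_set or j > i)],
                dtype=np.int64,
            )
            _add_edges(i, rows)
    else:
        for i in range(n - 1):
            _add_edges(i, np.arange(i + 1, n, dtype=np.int64))

    seed_probes = {probes[i] for i in seed_idx}
    for node in graph.nodes:
        graph.nodes[node]["is_seed"] = node in seed_probes
    if graph.number_of_edges() == 0:
        warnings.warn("relevance network has no significant edges", stacklevel=2)
    return graph


def apply_dpi(network: nx.Graph, tolerance: float = 0.1) -> nx.Graph:
    """Prune likely-indirect edges with the data-processing inequality.

    For every triangle (i, j, k), edge (i, j) is marked for removal when
    ``mi(i,j) < (1 - tolerance) * min(mi(i,k), mi(j,k))``.  All marks are
    evaluated on the input graph and removed simultaneously, so the result
    does not depend on edge iteration order.
    """
    if not 0 <= tolerance < 1:
        raise ValueError("tolerance must be in [0, 1)")
    factor = 1.0 - tolerance
    marks = []
    adj = network.adj
    for u, v, data in network.edges(data=True):
        mi_uv = data["mi"]
        for k in set(adj[u]) & set(adj[v]):
            if mi_uv < factor * min(adj[u][k]["mi"], adj[v][k]["mi"]):
                marks.append((u, v))
                break
    pruned = network.copy()
    pruned.remove_edges_from(marks)
    pruned.graph["dpi_tolerance"] = tolerance
    return pruned
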