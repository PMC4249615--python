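"""Dual-cohort consensus and APL-specific subnetwork extraction.

The two cohort networks are intersected edge-wise ("significant in both
adjacency matrices"), a case-vs-rest differential analysis is run per cohort,
and the consensus graph is pruned to nodes that are differential (FDR-adjusted
p < alpha) in both cohorts with concordant direction.  Connected components of
the pruned graph with at most ``min_component_genes`` distinct genes are
discarded, reflecting the removal of isolated transcripts and small circuits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .datatypes import ExpressionMatrix, ProbeAnnotation
from .stats import bh_adjust, welch_rows

__all__ = [
    "differential_expression",
    "consensus_edges",
    "Subnetwork",
    "extract_apl_subnetwork",
    "hub_table",
    "detect_modules",
]


def differential_expression(
    matrix: ExpressionMatrix,
    case_label: str,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-probe Welch t-test, case subtype vs all other samples.

    Returns a DataFrame indexed by probe with columns ``t``, ``p``, ``q``
    (BH-adjusted), ``delta`` (case mean minus rest mean) and ``direction``
    in {"up", "down", "ns"}: up iff q < alpha and delta > 0, down iff
    q < alpha and delta < 0.
    """
    labels = matrix.require_labels()
    case_mask = (labels == case_label).to_numpy()
    if case_mask.sum() < 2 or (~case_mask).sum() < 2:
        raise ValueError(f"need >=2 samples in {case_label!r} and in the rest")
    arr = matrix.values.to_numpy()
    t, p, delta = welch_rows(arr[:, case_mask], arr[:, ~case_mask])
    q = bh_adjust(p)
    direction = np.where(
        q < alpha, np.where(delta > 0, "up", np.where(delta < 0, "down", "ns")), "ns"
    )
    return pd.DataFrame(
        {"t": t, "p": p, "q": q, "delta": delta, "direction": direction},
        index=pd.Index(matrix.probe_ids, name="probe"),
    )


def consensus_edges(net_a: nx.Graph, net_b: nx.Graph) -> nx.Graph:
    """Edges present (as unordered pairs) in both cohort networks.

    Per-edge attributes from both inputs are retained as ``mi_a``/``mi_b`` and
    ``p_a``/``p_b``; nodes are the endpoints of surviving edges with
    ``is_seed`` carried over.
    """
    cons = nx.Graph()
    cons.graph["mi_units"] = "nats"
    small, large = (net_a, net_b) if net_a.number_of_edges() <= net_b.number_of_edges() else (net_b, net_a)
    for u, v in small.edges:
        if large.has_edge(u, v):
            da, db = net_a[u][v], net_b[u][v]
            cons.add_edge(
                u, v,
                mi_a=da["mi"], p_a=da["p"], mi_b=db["mi"], p_b=db["p"],
                mi=min(da["mi"], db["mi"]),
            )
    for node in cons.nodes:
        cons.nodes[node]["is_seed"] = bool(
            net_a.nodes.get(node, {}).get("is_seed")
            or net_b.nodes.get(node, {}).get("is_seed")
        )
    return cons


def _component_order(graph: nx.Graph):
    """Connected components, largest (in probes) first, ties by smallest node id."""
    comps = [sorted(c) for c in nx.connected_components(graph)]
    comps.sort(key=lambda c: (-len(c), c[0]))
    return comps


@dataclass
class Subnetwork:
    """Consensus graph restricted to concordantly differential probes.

    ``graph`` nodes carry ``gene``, ``direction`` (consensus), ``dir_a``,
    ``dir_b``, ``component`` and ``is_seed``; ``components`` summarizes each
    retained component's size in probes and in distinct genes.
    """

    graph: nx.Graph
    components: pd.DataFrame

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    def directions(self) -> pd.Series:
        return pd.Series(
            {n: d["direction"] for n, d in self.graph.nodes(data=True)}, dtype=object
        )

    def genes(self) -> set[str]:
        return {d["gene"] for _, d in self.graph.nodes(data=True)}

    def gene_directions(self) -> pd.Series:
        """Per-gene direction; genes whose probes disagree are 'ns'."""
        per_gene: dict[str, set] = {}
        for _, d in self.graph.nodes(data=True):
            per_gene.setdefault(d["gene"], set()).add(d["direction"])
        return pd.Series(
            {g: (dirs.pop() if len(dirs) == 1 else "ns") for g, dirs in per_gene.items()},
            dtype=object,
        )

    def probes_with_direction(self, direction: str) -> list[str]:
        return [n for n, d in self.graph.nodes(data=True) if d["direction"] == direction]


def extract_apl_subnetwork(
    consensus: nx.Graph,
    de_a: pd.DataFrame,
    de_b: pd.DataFrame,
    annotation: ProbeAnnotation,
    alpha: float = 0.05,
    min_component_genes: int = 10,
    concordance: str = "strict",
) -> Subnetwork:
    """Prune the consensus network to the case-specific subnetwork.

    Nodes are kept when q < ``alpha`` in *both* cohorts and, under the default
    strict concordance, when the direction of change agrees; the induced
    subgraph is then cleaned of connected components with at most
    ``min_component_genes`` distinct genes (isolated transcripts and small
    circuits).  Component ids are assigned largest-first.
    """
    if concordance not in ("strict", "any"):
        raise ValueError("concordance must be 'strict' or 'any'")
    keep = []
    directions = {}
    for node in consensus.nodes:
        if node not in de_a.index or node not in de_b.index:
            raise KeyError(f"node {node!r} missing from a differential result")
        ra, rb = de_a.loc[node], de_b.loc[node]
        if ra["q"] >= alpha or rb["q"] >= alpha:
            continue
        if concordance == "strict":
            if ra["direction"] == "ns" or ra["direction"] != rb["direction"]:
                continue
            directions[node] = ra["direction"]
        else:
            directions[node] = ra["direction"] if ra["direction"] != "ns" else rb["direction"]
        keep.append(node)

    sub = consensus.subgraph(keep).copy()
    comps = _component_order(sub)
    records = []
    comp_id = 0
    kept_nodes = []
    for comp in comps:
        n_genes = annotation.n_genes(comp)
        if n_genes <= min_component_genes:
            continue
        for node in comp:
            sub.nodes[node]["component"] = comp_id
        records.append({"component": comp_id, "n_probes": len(comp), "n_genes": n_genes})
        kept_nodes.extend(comp)
        comp_id += 1
    sub = sub.subgraph(kept_nodes).copy()
    for node in sub.nodes:
        sub.nodes[node]["gene"] = annotation.gene_of(node)
        sub.nodes[node]["direction"] = directions[node]
        sub.nodes[node]["dir_a"] = de_a.loc[node, "direction"]
        sub.nodes[node]["dir_b"] = de_b.loc[node, "direction"]
        sub.nodes[node]["is_seed"] = bool(consensus.nodes[node].get("is_seed", False))
    if sub.number_of_nodes() == 0:
        warnings.warn("extracted subnetwork is empty", stacklevel=2)
    components = pd.DataFrame(records, columns=["component", "n_probes", "n_genes"])
    return Subnetwork(graph=sub, components=components)


def hub_table(
    network: nx.Graph,
    de_a: pd.DataFrame,
    de_b: pd.DataFrame,
    annotation: ProbeAnnotation | None = None,
) -> pd.DataFrame:
    """Degree vs worst-case differential significance, one row per node.

    ``worst_p`` is the larger (least significant) of the node's two cohort raw
    p-values — the axis used to contrast hubs against strongly dysregulated
    genes.  Sorted by degree descending, ties by node id.
    """
    rows = []
    for node in network.nodes:
        if node not in de_a.index or node not in de_b.index:
            raise KeyError(f"node {node!r} missing from a differential result")
        rows.append(
            {
                "node": node,
                "gene": annotation.gene_of(node) if annotation is not None else "",
                "degree": network.degree[node],
                "worst_p": max(de_a.loc[node, "p"], de_b.loc[node, "p"]),
            }
        )
    df = pd.DataFrame(rows, columns=["node", "gene", "degree", "worst_p"])
    return df.sort_values(
        ["degree", "node"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)


def detect_modules(
    network: nx.Graph,
    annotation: ProbeAnnotation | None = None,
) -> tuple[pd.Series, pd.DataFrame]:
    """Label connected components as modules, largest first.

    Returns (node -> component id, component size table).  Sizes are reported
    in probes and — when an annotation is supplied — in distinct genes.
    """
    comps = _component_order(network)
    labels = {}
    records = []
    for cid, comp in enumerate(comps):
        for node in comp:
            labels[node] = cid
        records.append(
            {
                "component": cid,
                "n_probes": len(comp),
                "n_genes": annotation.n_genes(comp) if annotation is not None else len(
                    set(comp)
                ),
            }
        )
    return (
        pd.Series(labels, dtype=int),
        pd.DataFrame(records, columns=["component", "n_probes", "n_genes"]),
    )
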