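"""Readers and writers for the pipeline's plain-text interchange formats.

Expression matrices, label and annotation tables, seed lists, GMT gene-set
collections, miRNA target predictions, and the SIF + attribute-table network
exports compatible with standard graph viewers.
"""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .datatypes import ExpressionMatrix, ProbeAnnotation, SeedList
from .enrichment import GeneSetCollection

__all__ = [
    "read_expression", "write_expression",
    "read_labels", "write_labels",
    "read_annotation", "write_annotation",
    "read_seed_list", "write_seed_list",
    "read_gmt", "read_predictions",
    "write_network", "write_differential", "write_subnetwork_nodes",
    "write_hub_table", "write_coloring", "write_timecourse", "read_timecourse",
    "write_embedding", "write_anticorrelation", "write_calibration",
    "write_truth",
]


# -- expression --------------------------------------------------------------

def read_expression(path, labels_path=None, name=None) -> ExpressionMatrix:
    """Expression TSV: first column probe id, header row of sample ids.

    Missing values are a hard error — no imputation is attempted.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.isna().to_numpy().any():
        raise ValueError(f"{path}: expression matrix contains missing values")
    labels = read_labels(labels_path) if labels_path else None
    return ExpressionMatrix(df, labels, name=name or Path(path).stem)


def write_expression(matrix: ExpressionMatrix, path) -> None:
    matrix.values.rename_axis("probe_id").to_csv(path, sep="\t")


def read_labels(path) -> pd.Series:
    """Two-column TSV: sample id, subtype."""
    df = pd.read_csv(path, sep="\t", header=None, names=["sample_id", "subtype"],
                     dtype=str, comment="#")
    return pd.Series(df["subtype"].to_numpy(), index=df["sample_id"], dtype=object)


def write_labels(labels: pd.Series, path) -> None:
    pd.DataFrame({"sample_id": labels.index, "subtype": labels.to_numpy()}).to_csv(
        path, sep="\t", header=False, index=False
    )


# -- annotation / seeds ------------------------------------------------------

def read_annotation(path) -> ProbeAnnotation:
    """Two-column TSV: probe id, gene symbol."""
    df = pd.read_csv(path, sep="\t", header=None, names=["probe_id", "gene"],
                     dtype=str, comment="#")
    return ProbeAnnotation(pd.Series(df["gene"].to_numpy(), index=df["probe_id"]))


def write_annotation(annotation: ProbeAnnotation, path) -> None:
    annotation.mapping.rename_axis("probe_id").rename("gene").to_csv(
        path, sep="\t", header=False
    )


def read_seed_list(path) -> SeedList:
    """Plain text, one gene symbol per line; '#' starts a comment."""
    genes = []
    for line in Path(path).read_text().splitlines():
        sym = line.split("#", 1)[0].strip()
        if sym:
            genes.append(sym)
    return SeedList(genes=genes)


def write_seed_list(seeds: SeedList, path) -> None:
    Path(path).write_text("\n".join(seeds.genes) + "\n")


# -- gene sets / predictions -------------------------------------------------

def read_gmt(path) -> GeneSetCollection:
    """GMT: set name, description, then tab-separated member genes."""
    sets, desc = {}, {}
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"{path}:{ln}: GMT line needs name, description, >=1 gene")
        name = parts[0]
        if name in sets:
            raise ValueError(f"{path}:{ln}: duplicate set name {name!r}")
        sets[name] = {g for g in parts[2:] if g}
        desc[name] = parts[1]
    return GeneSetCollection(sets=sets, descriptions=desc)


def read_predictions(path) -> set[tuple[str, str]]:
    """Two-column TSV of (mirna id, target gene symbol); '#' comments allowed."""
    pairs = set()
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        stripped = line.split("#", 1)[0].rstrip()
        if not stripped.strip():
            continue
        parts = stripped.split("\t")
        if len(parts) != 2 or not parts[0].strip() or not parts[1].strip():
            raise ValueError(f"{path}:{ln}: malformed prediction row {line!r}")
        pairs.add((parts[0].strip(), parts[1].strip()))
    return pairs


# -- network exports ---------------------------------------------------------

def write_network(network: nx.Graph, prefix) -> None:
    """SIF + edge-attribute TSV + node-attribute TSV under ``prefix``.*"""
    prefix = Path(prefix)
    edges = sorted((min(u, v), max(u, v)) for u, v in network.edges)
    with open(prefix.with_suffix(".sif"), "w") as fh:
        for u, v in edges:
            fh.write(f"{u}\tmi\t{v}\n")
    rows = []
    for u, v in edges:
        d = network[u][v]
        rows.append({
            "node1": u, "node2": v,
            "mi_nats": d.get("mi", np.nan),
            "p_value": d.get("p", d.get("p_a", np.nan)),
            **{k: d[k] for k in ("mi_a", "mi_b", "p_a", "p_b") if k in d},
        })
    pd.DataFrame(rows).to_csv(prefix.parent / f"{prefix.name}_edges.tsv",
                              sep="\t", index=False)
    nrows = [
        {"node": n, "is_seed": bool(d.get("is_seed", False)), "degree": network.degree[n]}
        for n, d in sorted(network.nodes(data=True))
    ]
    pd.DataFrame(nrows).to_csv(prefix.parent / f"{prefix.name}_nodes.tsv",
                               sep="\t", index=False)


def write_subnetwork_nodes(subnetwork, path) -> None:
    rows = [
        {
            "node": n,
            "gene": d.get("gene", ""),
            "direction": d.get("direction", ""),
            "component": d.get("component", -1),
            "is_seed": bool(d.get("is_seed", False)),
        }
        for n, d in sorted(subnetwork.graph.nodes(data=True))
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# -- tabular results ---------------------------------------------------------

def write_differential(de: pd.DataFrame, path) -> None:
    de.rename_axis("probe").to_csv(path, sep="\t")


def write_hub_table(hubs: pd.DataFrame, path) -> None:
    hubs.to_csv(path, sep="\t", index=False)


def write_coloring(coloring: pd.DataFrame, path) -> None:
    coloring.rename_axis("node").to_csv(path, sep="\t")


def write_timecourse(tc: pd.DataFrame, path) -> None:
    tc.rename_axis("gene").to_csv(path, sep="\t")


def read_timecourse(path) -> pd.DataFrame:
    """Time-course TSV: first column gene, remaining columns labeled by hour."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.columns = [float(c) for c in df.columns]
    return df


def write_embedding(result, path) -> None:
    df = result.coordinates.copy()
    df.insert(0, "cluster", result.clusters)
    with open(path, "w") as fh:
        fh.write("# variance_explained\t" +
                 "\t".join(f"{v:.6g}" for v in result.variance_ratio) + "\n")
        if result.ari is not None:
            fh.write(f"# adjusted_rand_index\t{result.ari:.6g}\n")
        df.rename_axis("sample").to_csv(fh, sep="\t")


def write_anticorrelation(table, path) -> None:
    df = table.table.copy()
    df["anticorrelated_genes"] = [
        ";".join(g) for g in df.get("genes", [[]] * len(df))
    ]
    cols = ["mirna", "n_anticorrelated", "anticorrelated_genes"]
    if "predicted_fraction" in df:
        cols.append("predicted_fraction")
    df[cols].to_csv(path, sep="\t", index=False, na_rep="NA")


def write_calibration(calib, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# a\t{calib.a:.8g}\n# b\t{calib.b:.8g}\n")
        fh.write(f"# rng_seed\t{calib.rng_seed}\n# n_pairs\t{calib.n_pairs}\n")
        fh.write("mi_nats\n")
        for v in calib.samples:
            fh.write(f"{v:.8g}\n")


def write_truth(truth, outdir) -> None:
    """Planted-structure export: edge TSV, membership TSV, JSON metadata."""
    outdir = Path(outdir)
    pd.DataFrame(truth.planted_edges, columns=["anchor", "member"]).to_csv(
        outdir / "truth_edges.tsv", sep="\t", index=False
    )
    rows = [
        {"gene": g, "module": mod}
        for mod in sorted(truth.modules)
        for g in sorted(truth.modules[mod])
    ]
    pd.DataFrame(rows).to_csv(outdir / "truth_modules.tsv", sep="\t", index=False)
    meta = {
        "seed": truth.seed,
        "regulators": truth.regulators,
        "subtype_shifts": truth.subtype_shifts,
    }
    (outdir / "truth_meta.json").write_text(json.dumps(meta, indent=2, sort_keys=True))
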