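"""Subtype-wise profiling of the extracted subnetwork.

Three views of the subnetwork's behaviour:

* a per-subtype coloring (each FAB subtype vs the rest, BH-FDR within the
  subnetwork's probes) reproducing the up/down/ns state matrix;
* unsupervised separation of sample groups over the subnetwork probes
  (hierarchical clustering with 1 - Pearson correlation distance and average
  linkage, plus PCA), used for the normal-vs-leukemic promyelocyte contrast;
* a reversal score for a differentiation-treatment time-course: the fraction
  of subnetwork genes whose fold change at the final time point moves against
  their disease direction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.decomposition import PCA
from sklearn.metrics import adjusted_rand_score

from .consensus import Subnetwork, differential_expression
from .datatypes import ExpressionMatrix

__all__ = [
    "subtype_coloring",
    "EmbeddingResult",
    "promyelocyte_separation",
    "atra_reversal",
]


def subtype_coloring(
    subnetwork: Subnetwork,
    matrix: ExpressionMatrix,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-subtype up/down/ns state of every subnetwork node.

    For each subtype label F a one-vs-rest Welch t-test is run restricted to
    the subnetwork's probes, with BH-FDR within that probe set; the state is
    'up'/'down' when q < alpha, 'ns' otherwise.  Subtypes with fewer than two
    samples yield an all-'ns' column with a warning.
    """
    labels = matrix.require_labels()
    subtypes = sorted(set(labels))
    if len(subtypes) < 2:
        raise ValueError("need at least 2 subtypes")
    nodes = [n for n in subnetwork.nodes if n in matrix.values.index]
    if not nodes:
        raise ValueError("no subnetwork node present in the matrix")
    sub = matrix.subset_probes(nodes)
    out = pd.DataFrame("ns", index=pd.Index(nodes, name="node"), columns=subtypes)
    for st in subtypes:
        n_case = int((labels == st).sum())
        if n_case < 2 or (len(labels) - n_case) < 2:
            warnings.warn(f"subtype {st!r} has fewer than 2 samples; column set to ns",
                          stacklevel=2)
            continue
        de = differential_expression(sub, st, alpha=alpha)
        out[st] = de["direction"].to_numpy()
    return out


@dataclass
class EmbeddingResult:
    """PCA coordinates, hierarchical clusters, and label agreement."""

    coordinates: pd.DataFrame        # samples x principal components
    variance_ratio: np.ndarray       # non-increasing, sums to <= 1
    clusters: pd.Series              # sample -> cluster id (1..k)
    ari: float | None                # adjusted Rand index vs true labels


def promyelocyte_separation(
    matrix: ExpressionMatrix,
    node_set,
    k: int = 2,
) -> EmbeddingResult:
    """Cluster samples over the given probes and embed them with PCA.

    Distance between samples is 1 - Pearson correlation of their expression
    profiles over ``node_set``; the average-linkage tree is cut into ``k``
    clusters.  When the matrix carries labels for every sample the adjusted
    Rand index against them is reported.
    """
    node_set = list(node_set)
    if len(node_set) < 2:
        raise ValueError("need at least 2 probes for sample profiles")
    if matrix.n_samples < k:
        raise ValueError("fewer samples than requested clusters")
    sub = matrix.subset_probes(node_set)
    profiles = sub.values.to_numpy().T  # samples x probes
    corr = np.corrcoef(profiles)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = np.maximum((dist + dist.T) / 2.0, 0.0)
    tree = linkage(squareform(dist, checks=False), method="average")
    clusters = pd.Series(
        fcluster(tree, t=k, criterion="maxclust"), index=sub.sample_ids, name="cluster"
    )
    n_comp = min(len(node_set), matrix.n_samples, 10)
    pca = PCA(n_components=n_comp)
    coords = pca.fit_transform(profiles - profiles.mean(axis=0))
    coordinates = pd.DataFrame(
        coords,
        index=sub.sample_ids,
        columns=[f"PC{i + 1}" for i in range(coords.shape[1])],
    )
    ari = None
    if len(sub.labels) and all(s in sub.labels.index for s in sub.sample_ids):
        truth = sub.require_labels()
        ari = float(adjusted_rand_score(truth.to_numpy(), clusters.to_numpy()))
    return EmbeddingResult(
        coordinates=coordinates,
        variance_ratio=pca.explained_variance_ratio_,
        clusters=clusters,
        ari=ari,
    )


def atra_reversal(
    timecourse: pd.DataFrame,
    subnetwork: Subnetwork,
    final_time: float,
) -> tuple[float, pd.DataFrame]:
    """Fraction of subnetwork genes whose expression reverses under treatment.

    ``timecourse`` holds per-gene log2 fold changes relative to the first time
    point (columns are hours).  A down-regulated gene counts as reversed when
    its fold change at ``final_time`` is strictly positive, an up-regulated
    gene when strictly negative; genes without a consensus direction are
    excluded.  Returns the reversal fraction and the per-gene table.
    """
    cols = list(timecourse.columns)
    if final_time not in cols:
        raise ValueError(f"final_time {final_time!r} not in time-course columns")
    gene_dirs = subnetwork.gene_directions()
    genes = [g for g in timecourse.index if g in gene_dirs.index and gene_dirs[g] != "ns"]
    if not genes:
        raise ValueError("no subnetwork gene with a direction present in the time-course")
    fc = timecourse.loc[genes, final_time]
    dirs = gene_dirs[genes]
    reversed_mask = ((dirs == "down") & (fc > 0)) | ((dirs == "up") & (fc < 0))
    table = pd.DataFrame(
        {
            "direction": dirs,
            "fold_change": fc,
            "reversed": reversed_mask,
        },
        index=pd.Index(genes, name="gene"),
    )
    return float(reversed_mask.mean()), table
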