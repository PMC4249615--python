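"""miRNA integration: subtype-up-regulated miRNAs ranked by anti-correlation.

miRNAs significantly up-regulated in the case subtype (Welch t-test,
Bonferroni-corrected p < alpha over all tested miRNAs) are ranked by how many
of the subnetwork's down-regulated transcripts they anti-correlate with
(Pearson r strictly below -0.4 by default).  Externally produced target
predictions can then annotate each miRNA with the fraction of its
anti-correlated genes that carry a predicted binding site.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import ExpressionMatrix, MiRNAMatrix, ProbeAnnotation
from .stats import bonferroni_adjust, welch_rows

__all__ = [
    "select_upregulated_mirnas",
    "AntiCorrelationTable",
    "anticorrelation_ranking",
    "predicted_target_fraction",
]


def select_upregulated_mirnas(
    mirnas: MiRNAMatrix,
    case_label: str,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """miRNAs up-regulated in the case subtype after Bonferroni correction.

    The correction spans all miRNAs tested.  Returns a DataFrame (mirna id
    index; t, p, p_adj, delta) restricted to adjusted p < alpha with positive
    mean difference, sorted by adjusted p.
    """
    labels = mirnas.require_labels()
    case_mask = (labels == case_label).to_numpy()
    if case_mask.sum() < 2 or (~case_mask).sum() < 2:
        raise ValueError(f"need >=2 samples in {case_label!r} and in the rest")
    arr = mirnas.values.to_numpy()
    t, p, delta = welch_rows(arr[:, case_mask], arr[:, ~case_mask])
    p_adj = bonferroni_adjust(p)
    df = pd.DataFrame(
        {"t": t, "p": p, "p_adj": p_adj, "delta": delta},
        index=pd.Index(mirnas.probe_ids, name="mirna"),
    )
    return df[(df["p_adj"] < alpha) & (df["delta"] > 0)].sort_values("p_adj")


@dataclass
class AntiCorrelationTable:
    """Per-miRNA anti-correlated transcripts, ordered by count."""

    table: pd.DataFrame           # mirna, n_anticorrelated, transcripts, [genes, predicted_fraction]
    r_threshold: float

    @property
    def ranking(self) -> list[str]:
        return list(self.table["mirna"])


def anticorrelation_ranking(
    mirnas: MiRNAMatrix,
    selected: list[str],
    matrix: ExpressionMatrix,
    down_nodes,
    r_threshold: float = -0.4,
) -> AntiCorrelationTable:
    """Rank selected miRNAs by their number of anti-correlated down transcripts.

    Pearson correlation is computed for every (miRNA, down-regulated probe)
    pair over the samples shared by the two matrices; pairs with r strictly
    below ``r_threshold`` are retained (r exactly at the threshold is not).
    Ties in the count are broken by miRNA id.
    """
    selected = list(selected)
    down_nodes = list(down_nodes)
    if not selected:
        raise ValueError("no selected miRNAs to rank")
    if not down_nodes:
        raise ValueError("no down-regulated transcripts supplied")
    shared = [s for s in matrix.sample_ids if s in set(mirnas.sample_ids)]
    if len(shared) < 3:
        raise ValueError("need at least 3 shared samples for correlations")
    x = matrix.values.loc[down_nodes, shared].to_numpy()
    m = mirnas.values.loc[selected, shared].to_numpy()

    def _center_scale(a):
        a = a - a.mean(axis=1, keepdims=True)
        sd = np.sqrt((a**2).sum(axis=1, keepdims=True))
        sd[sd == 0] = np.nan
        return a / sd

    r = _center_scale(x) @ _center_scale(m).T  # probes x mirnas
    rows = []
    for j, mid in enumerate(selected):
        hits = [down_nodes[i] for i in np.flatnonzero(r[:, j] < r_threshold)]
        rows.append({"mirna": mid, "n_anticorrelated": len(hits), "transcripts": hits})
    df = pd.DataFrame(rows, columns=["mirna", "n_anticorrelated", "transcripts"])
    df = df.sort_values(
        ["n_anticorrelated", "mirna"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    return AntiCorrelationTable(table=df, r_threshold=r_threshold)


def predicted_target_fraction(
    table: AntiCorrelationTable,
    predictions: set[tuple[str, str]],
    annotation: ProbeAnnotation,
) -> AntiCorrelationTable:
    """Annotate each miRNA with its predicted-target fraction.

    The anti-correlated transcripts are collapsed to genes (a gene counts once
    if any of its probes passed); the fraction is the share of those genes
    predicted as targets of the miRNA.  miRNAs with an empty anti-correlated
    list get NA, not 0.
    """
    df = table.table.copy()
    genes_col = []
    frac_col = []
    for _, row in df.iterrows():
        genes = sorted(set(annotation.genes_of(row["transcripts"]))) if row["transcripts"] else []
        genes_col.append(genes)
        if not genes:
            frac_col.append(np.nan)
        else:
            hit = sum((row["mirna"], g) in predictions for g in genes)
            frac_col.append(hit / len(genes))
    df["genes"] = genes_col
    df["predicted_fraction"] = frac_col
    return AntiCorrelationTable(table=df, r_threshold=table.r_threshold)
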