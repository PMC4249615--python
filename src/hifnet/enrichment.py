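"""Over-representation analysis of gene lists against gene-set collections.

A generic hypergeometric upper-tail test replacing the external annotation
service: for a query of n genes drawn from a background of N, a set with K
background members and k query members scores P(X >= k) under the
hypergeometric law, equivalent to the one-sided Fisher exact test of the
2x2 table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .stats import bh_adjust, bonferroni_adjust

__all__ = ["GeneSetCollection", "ora_enrichment"]


@dataclass
class GeneSetCollection:
    """Named gene sets with optional descriptions."""

    sets: dict[str, set]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if any(not s for s in self.sets.values()):
            empty = [n for n, s in self.sets.items() if not s]
            raise ValueError(f"empty gene sets: {empty[:5]}")

    def __len__(self) -> int:
        return len(self.sets)


def ora_enrichment(
    query,
    background,
    sets: GeneSetCollection,
    correction: str = "bh",
) -> pd.DataFrame:
    """Hypergeometric over-representation of each gene set in the query.

    The query must be a subset of the background; every set is intersected
    with the background before testing.  Returns a DataFrame (one row per
    set: k, K, n, N, p, p_adj) sorted by adjusted then raw p-value.
    """
    query = set(query)
    background = set(background)
    if not query or not background:
        raise ValueError("query and background must be non-empty")
    if not query <= background:
        raise ValueError("query must be a subset of the background")
    if correction not in ("bh", "bonferroni"):
        raise ValueError("correction must be 'bh' or 'bonferroni'")
    n = len(query)
    n_bg = len(background)
    rows = []
    for name, members in sets.sets.items():
        members_bg = members & background
        k = len(members_bg & query)
        big_k = len(members_bg)
        p = float(hypergeom.sf(k - 1, n_bg, big_k, n)) if big_k else 1.0
        rows.append(
            {
                "set": name,
                "description": sets.descriptions.get(name, ""),
                "k": k,
                "K": big_k,
                "n": n,
                "N": n_bg,
                "p": min(p, 1.0),
            }
        )
    df = pd.DataFrame(rows)
    adjust = bh_adjust if correction == "bh" else bonferroni_adjust
    df["p_adj"] = adjust(df["p"].to_numpy())
    return df.sort_values(["p_adj", "p", "set"], kind="mergesort").reset_index(drop=True)
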