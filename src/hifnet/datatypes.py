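"""Shared containers for expression data, annotation, and seed lists.

Expression values are stored as a pandas DataFrame (probes x samples) inside a
thin :class:`ExpressionMatrix` wrapper that also carries the per-sample subtype
labels (FAB M0..M5, or PM/APL for the promyelocyte comparison).  All values are
on a log2-like additive scale after normalization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "ProbeAnnotation",
    "SeedList",
]


class ExpressionMatrix:
    """Probes-by-samples expression values plus per-sample subtype labels.

    Parameters
    ----------
    values : pandas.DataFrame
        Rows indexed by unique probe ids, columns by unique sample ids.
    labels : mapping or pandas.Series, optional
        sample id -> subtype label (e.g. ``"M3"``).  May cover a subset of the
        samples; operations that need labels validate coverage themselves.
    name : str, optional
        Free-form cohort name, carried through filters.
    """

    def __init__(self, values: pd.DataFrame, labels=None, name: str | None = None):
        if not isinstance(values, pd.DataFrame):
            raise TypeError("values must be a pandas DataFrame (probes x samples)")
        if values.index.has_duplicates:
            raise ValueError("duplicate probe ids in expression matrix")
        if values.columns.has_duplicates:
            raise ValueError("duplicate sample ids in expression matrix")
        arr = values.to_numpy()
        if arr.size and not np.isfinite(arr).all():
            raise ValueError("expression matrix contains missing/non-finite values")
        self.values = values.astype(float)
        if labels is None:
            self.labels = pd.Series(dtype=object)
        else:
            self.labels = pd.Series(labels, dtype=object)
        self.name = name

    # -- basic introspection -------------------------------------------------
    @property
    def probe_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_probes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def label_of(self, sample_id: str) -> str:
        return self.labels[sample_id]

    def samples_with_label(self, label: str) -> list[str]:
        return [s for s in self.sample_ids if self.labels.get(s) == label]

    def require_labels(self) -> pd.Series:
        """Labels aligned to the sample order; error if any sample is unlabeled."""
        missing = [s for s in self.sample_ids if s not in self.labels.index]
        if missing:
            raise ValueError(f"samples without subtype label: {missing[:5]}")
        return self.labels.reindex(self.sample_ids)

    def subset_probes(self, probes) -> "ExpressionMatrix":
        """Restrict to the given probes, preserving the given order."""
        probes = list(probes)
        missing = set(probes) - set(self.values.index)
        if missing:
            raise KeyError(f"probes not in matrix: {sorted(missing)[:5]}")
        return ExpressionMatrix(self.values.loc[probes], self.labels, self.name)

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.copy(), self.labels.copy(), self.name)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        nm = f" {self.name!r}" if self.name else ""
        return f"<ExpressionMatrix{nm} {self.n_probes} probes x {self.n_samples} samples>"


# MiRNAMatrix shares all behaviour with the mRNA matrix; only the row
# identifiers differ (miRNA ids instead of probe ids).
MiRNAMatrix = ExpressionMatrix


class ProbeAnnotation:
    """Many-to-one mapping from probe id to gene symbol."""

    def __init__(self, mapping):
        ser = pd.Series(mapping, dtype=object)
        if ser.index.has_duplicates:
            raise ValueError("duplicate probe ids in annotation")
        if (ser.astype(str).str.len() == 0).any():
            raise ValueError("empty gene symbols in annotation")
        self.mapping = ser

    def gene_of(self, probe: str) -> str:
        return self.mapping[probe]

    def genes_of(self, probes) -> pd.Series:
        """Gene symbol per probe (probes missing from the annotation raise)."""
        out = self.mapping.reindex(list(probes))
        if out.isna().any():
            missing = out.index[out.isna()].tolist()
            raise KeyError(f"probes without annotation: {missing[:5]}")
        return out

    def probes_of(self, gene: str) -> list[str]:
        return list(self.mapping.index[self.mapping == gene])

    def n_genes(self, probes) -> int:
        """Number of distinct genes among the given probes."""
        return int(self.genes_of(probes).nunique())

    def __len__(self) -> int:
        return len(self.mapping)

    def __contains__(self, probe) -> bool:
        return probe in self.mapping.index


@dataclass
class SeedList:
    """Seed gene symbols plus, after resolution, their probe ids."""

    genes: list[str]
    probes: list[str] = field(default_factory=list)

    def __post_init__(self):
        if not self.genes:
            raise ValueError("seed list is empty")
        self.genes = list(dict.fromkeys(self.genes))  # dedupe, keep order

    def resolve(self, annotation: ProbeAnnotation, matrix: ExpressionMatrix) -> "SeedList":
        """Return a copy whose probes are the matrix probes annotated to a seed gene."""
        geneset = set(self.genes)
        probes = [p for p in matrix.probe_ids
                  if p in annotation and annotation.gene_of(p) in geneset]
        return SeedList(genes=list(self.genes), probes=probes)
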