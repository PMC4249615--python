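"""Cross-platform harmonization, normalization, and information filters.

The two AML cohorts come from different microarray platforms, so the analysis
is restricted to the probe sets common to both.  Each surviving probe row is
log2-transformed (optional; raw intensity inputs only) and mean-centered
across that cohort's samples — equivalently, expressed as the log2 ratio to
its geometric mean.  Centering is applied after the log transform: the reverse
order is undefined for non-positive centered values and log-ratio
normalization is the standard microarray practice.

Two filters follow:

* an entropy filter removing the least informative probes — those whose value
  histogram is concentrated in few bins (near-constant probes, dead probes
  with rare spikes);
* an optional differential prefilter keeping only probes that distinguish the
  case subtype from the rest (Welch t-test, BH-FDR).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datatypes import ExpressionMatrix
from .stats import bh_adjust, welch_rows

__all__ = [
    "intersect_and_normalize",
    "probe_entropy",
    "entropy_filter",
    "prefilter_transcripts",
]


def _normalize(matrix: ExpressionMatrix, log2: bool) -> ExpressionMatrix:
    vals = matrix.values
    if log2:
        arr = vals.to_numpy()
        if (arr <= 0).any():
            i, j = np.argwhere(arr <= 0)[0]
            raise ValueError(
                "log2 transform requested but probe "
                f"{vals.index[i]!r} has non-positive value in sample {vals.columns[j]!r}"
            )
        vals = np.log2(vals)
    vals = vals.sub(vals.mean(axis=1), axis=0)
    return ExpressionMatrix(vals, matrix.labels, matrix.name)


def intersect_and_normalize(
    matrix_a: ExpressionMatrix,
    matrix_b: ExpressionMatrix,
    log2: bool = True,
) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Restrict both cohorts to their common probes and normalize each.

    The shared probes keep cohort A's row order in both outputs.  Each probe
    row is (optionally) log2-transformed and then mean-centered within its
    cohort, so every output row has mean 0.

    Set ``log2=False`` for inputs that are already on an additive log-like
    scale (e.g. the synthetic cohorts).
    """
    shared = [p for p in matrix_a.probe_ids if p in set(matrix_b.probe_ids)]
    if not shared:
        raise ValueError("no probes shared between the two cohorts")
    a = matrix_a.subset_probes(shared)
    b = matrix_b.subset_probes(shared)
    return _normalize(a, log2), _normalize(b, log2)


def probe_entropy(matrix: ExpressionMatrix, n_bins: int | None = None) -> pd.Series:
    """Histogram entropy (nats) of each probe's value distribution.

    Each probe is binned into ``ceil(sqrt(n_samples))`` equal-width bins over
    its own observed range (scale-invariant for location/scale families);
    constant probes have entropy 0.
    """
    n = matrix.n_samples
    if n < 2:
        raise ValueError("entropy undefined with fewer than 2 samples")
    if n_bins is None:
        n_bins = int(np.ceil(np.sqrt(n)))
    arr = matrix.values.to_numpy()
    out = np.zeros(arr.shape[0])
    for i, row in enumerate(arr):
        lo, hi = row.min(), row.max()
        if hi <= lo:
            continue  # constant row: all mass in one bin
        counts, _ = np.histogram(row, bins=n_bins, range=(lo, hi))
        p = counts[counts > 0] / n
        out[i] = -np.sum(p * np.log(p))
    return pd.Series(out, index=matrix.values.index, name="entropy")


def entropy_filter(
    matrix: ExpressionMatrix,
    percentile: float = 10.0,
    cutoff: float | None = None,
) -> ExpressionMatrix:
    """Drop probes whose entropy is strictly below the given percentile.

    Ties at the percentile value are kept ("strictly less than").  Probe order
    of the survivors is preserved.  Pass a previously recorded ``cutoff`` to
    reuse it instead of recomputing the percentile (a second pass with the
    recorded cutoff removes nothing).
    """
    if not 0 < percentile < 100:
        raise ValueError("percentile must be in (0, 100)")
    ent = probe_entropy(matrix)
    if cutoff is None:
        cutoff = float(np.percentile(ent.to_numpy(), percentile))
    keep = ent >= cutoff
    out = ExpressionMatrix(matrix.values.loc[keep.to_numpy()], matrix.labels, matrix.name)
    out.entropy_cutoff = cutoff
    return out


def prefilter_transcripts(
    matrix: ExpressionMatrix,
    case_label: str,
    alpha: float = 0.05,
) -> ExpressionMatrix:
    """Keep probes differentially expressed between the case subtype and the rest.

    Welch t-test per probe (case vs all other samples), BH-FDR across probes,
    survivors are those with q < ``alpha``.  Order preserved.
    """
    labels = matrix.require_labels()
    case_mask = (labels == case_label).to_numpy()
    if case_mask.sum() < 2 or (~case_mask).sum() < 2:
        raise ValueError(f"need >=2 samples in {case_label!r} and in the rest")
    arr = matrix.values.to_numpy()
    _, p, _ = welch_rows(arr[:, case_mask], arr[:, ~case_mask])
    q = bh_adjust(p)
    keep = q < alpha
    return ExpressionMatrix(matrix.values.loc[keep], matrix.labels, matrix.name)
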