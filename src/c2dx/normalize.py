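"""Per-sample ("individual") normalization of panel expression profiles.

Each sample is normalized independently of every other sample, which keeps the
scheme implementable in a clinic where samples arrive one at a time. The
three steps, applied within a single sample:

1. ``v_g = log2(raw_g + pseudocount)`` for every panel gene;
2. center against the housekeeping reference: ``c_g = v_g - mean(v_hk)`` for
   the diagnostic genes;
3. z-scale across the diagnostic genes with the sample (n-1) standard
   deviation: ``z_g = (c_g - mean(c)) / sd(c)``.

A sample whose centered diagnostic values are all identical has sd 0; it is
returned as an all-zero profile with a degenerate flag rather than NaNs.

Because step 3 re-centers across the diagnostic genes, the housekeeping
centering of step 2 is mathematically absorbed; it is retained verbatim for
fidelity to the described clinical procedure. The scheme is invariant to any
positive rescaling of the raw sample (library size cancels).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .panel_io import ExpressionMatrix, GenePanel

__all__ = ["NormalizedMatrix", "normalize_sample", "normalize_matrix"]

DEFAULT_PSEUDOCOUNT = 1.0


@dataclass
class NormalizedMatrix:
    """Diagnostic-gene z-profiles, one column per sample.

    ``z`` is a DataFrame (diagnostic genes × samples); ``degenerate`` flags
    samples whose profile had zero variance (their z column is all zeros).
    For every non-degenerate sample, the column has mean 0 and sample
    standard deviation 1 across the diagnostic genes.
    """

    z: pd.DataFrame
    degenerate: pd.Series
    labels: pd.Series | None = None

    @property
    def gene_names(self) -> list[str]:
        return self.z.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.z.columns.tolist()


def normalize_sample(
    raw: Mapping[str, float] | pd.Series,
    panel: GenePanel,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> tuple[pd.Series, bool]:
    """Normalize one sample's raw expression against the panel.

    Parameters
    ----------
    raw
        Per-gene non-negative expression (counts or FPKM-UQ); must cover every
        panel gene.
    panel
        Gene panel naming the housekeeping reference genes.
    pseudocount
        Added before the log2 transform so zero counts stay finite.

    Returns
    -------
    (z, degenerate)
        z-values indexed by diagnostic gene, and whether the sample was
        degenerate (constant centered profile → all-zero z).
    """
    raw = pd.Series(raw, dtype=float)
    missing = [g for g in panel.genes if g not in raw.index]
    if missing:
        raise KeyError(f"sample is missing panel genes: {missing}")
    hk = panel.housekeeping_genes
    diag = panel.diagnostic_genes
    if not hk:  # GenePanel already forbids this; defensive for ad-hoc panels
        raise ValueError("panel has no housekeeping gene")
    values = raw[panel.genes]
    if (values < 0).any() or not np.isfinite(values.to_numpy()).all():
        raise ValueError("raw expression must be non-negative and finite")

    v = np.log2(values + pseudocount)
    h = v[hk].mean()
    c = v[diag] - h
    sd = c.std(ddof=1) if len(diag) > 1 else 0.0
    if sd == 0.0 or not np.isfinite(sd):
        return pd.Series(0.0, index=pd.Index(diag, name="gene")), True
    z = (c - c.mean()) / sd
    z.index.name = "gene"
    return z, False


def normalize_matrix(
    matrix: ExpressionMatrix,
    panel: GenePanel,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> NormalizedMatrix:
    """Normalize every sample of a matrix independently.

    Column *j* of the result is exactly ``normalize_sample`` of column *j*;
    the presence, order, or values of other samples cannot affect it.
    """
    missing = [g for g in panel.genes if g not in matrix.values.index]
    if missing:
        raise KeyError(f"matrix is missing panel genes: {missing}")
    z_cols: dict[str, pd.Series] = {}
    flags: dict[str, bool] = {}
    for sample in matrix.sample_ids:
        try:
            z, flag = normalize_sample(matrix.values[sample], panel, pseudocount)
        except (KeyError, ValueError) as exc:
            raise type(exc)(f"sample {sample!r}: {exc}") from exc
        z_cols[sample] = z
        flags[sample] = flag
    z = pd.DataFrame(z_cols, index=pd.Index(panel.diagnostic_genes, name="gene"))
    degenerate = pd.Series(flags, name="degenerate")
    labels = matrix.labels.copy() if matrix.labels is not None else None
    return NormalizedMatrix(z=z, degenerate=degenerate, labels=labels)
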