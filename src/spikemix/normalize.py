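r"""Per-gene weighted normalization onto the spike-fraction axis.

For gene *i* with abundances :math:`A_{ij}` across libraries *j* carrying
known spike fractions :math:`Q_j`, the normalized abundance is

.. math::

    \hat A_{ij} = A_{ij} \div \frac{\sum_j Q_j A_{ij}}{\sum_j Q_j^2}.

The divisor :math:`s_i = \sum_j Q_j A_{ij} / \sum_j Q_j^2` is the
least-squares no-intercept slope of :math:`A_{ij}` on :math:`Q_j`, so the
rescaled values satisfy the projection identity
:math:`\sum_j Q_j \hat A_{ij} / \sum_j Q_j^2 = 1` exactly: a perfectly
linear gene maps onto the line :math:`\hat A = Q` with slope one and
intercept zero, regardless of its absolute expression level.  Genes whose
weighted sum is zero (no counts in any positive-Q library) have no defined
scale and are flagged ``excluded`` rather than dropped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .counts import CountTable, CountTableError
from .design import MixtureDesign


@dataclass
class NormalizedTable:
    """Result of the weighted normalization.

    ``norm_abundance`` holds :math:`\\hat A_{ij}` (NaN for excluded genes),
    ``scale`` the per-gene divisor :math:`s_i`, and ``excluded`` flags the
    genes with :math:`s_i = 0` for which normalization is undefined.
    """

    norm_abundance: pd.DataFrame
    scale: pd.Series
    excluded: pd.Series
    design: MixtureDesign

    @property
    def genes(self) -> pd.Index:
        return self.norm_abundance.index

    def defined(self) -> pd.DataFrame:
        """Normalized abundances of the non-excluded genes only."""
        return self.norm_abundance.loc[~self.excluded]


def normalize(table: CountTable, design: MixtureDesign | None = None) -> NormalizedTable:
    """Rescale each gene's abundances onto the spike-fraction axis.

    ``A_ij`` is the (post-subsampling) read count.  Raises if every Q_j is
    zero, since the divisor is then undefined for all genes.
    """
    if design is None:
        design = MixtureDesign.from_table(table)
    if list(design.library_ids) != table.library_ids:
        raise CountTableError("design libraries do not match count-table columns")
    q = np.asarray(design.q, dtype=float)
    qsq = float(np.sum(q**2))
    if qsq == 0.0:
        raise CountTableError("all spike fractions are zero: normalization undefined")
    a = table.counts.to_numpy(dtype=float)
    scale = (a @ q) / qsq
    excluded = scale == 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        norm = a / scale[:, None]
    norm[excluded, :] = np.nan
    return NormalizedTable(
        norm_abundance=pd.DataFrame(norm, index=table.genes, columns=table.library_ids),
        scale=pd.Series(scale, index=table.genes, name="scale"),
        excluded=pd.Series(excluded, index=table.genes, name="excluded"),
        design=design,
    )


def write_normalized(norm: NormalizedTable, path) -> None:
    """Write normalized abundances with scale and exclusion-flag columns (TSV)."""
    out = norm.norm_abundance.copy()
    out["scale"] = norm.scale
    out["excluded"] = norm.excluded
    out.to_csv(path, sep="\t", index_label="gene")
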