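"""Dual-run decomposition of per-gene slope variation.

Two runs of the same mixture experiment yield paired slope estimates
(m1_i, m2_i) per gene.  By analogy with dual-reporter noise studies,
variation along the diagonal of the paired scatter is "extrinsic"
(eta_ext = std(m1 + m2): shared between the runs, e.g. a common
pre-amplification batch) and variation perpendicular to it is "intrinsic"
(eta_int = std(m1 - m2): independent between the runs, e.g. separate
tagmentation reactions).  Runs that share a pre-amplification batch should
show lower intrinsic noise than runs with separate pre-amplifications.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .linearity import FitError, GeneFit

#: sample (n-1) std convention, matching the summary statistics
_DDOF = 1


@dataclass(frozen=True)
class NoiseDecomposition:
    """eta_int = std(m1 - m2), eta_ext = std(m1 + m2) over matched genes."""

    eta_int: float
    eta_ext: float
    n_genes: int
    pairing: tuple[str, str] = ("run1", "run2")

    def variance_identity_gap(self, m1: np.ndarray, m2: np.ndarray) -> float:
        """|var(m1-m2) + var(m1+m2) - 2 var(m1) - 2 var(m2)| with the
        decomposition's moment convention (diagnostic)."""
        lhs = np.var(m1 - m2, ddof=_DDOF) + np.var(m1 + m2, ddof=_DDOF)
        rhs = 2 * np.var(m1, ddof=_DDOF) + 2 * np.var(m2, ddof=_DDOF)
        return float(abs(lhs - rhs))


def matched_slopes(
    fits1: list[GeneFit], fits2: list[GeneFit]
) -> pd.DataFrame:
    """Slope pairs for genes present in both runs (matched by identifier)."""
    s1 = pd.Series({f.gene: f.slope for f in fits1}, name="m1")
    s2 = pd.Series({f.gene: f.slope for f in fits2}, name="m2")
    return pd.concat([s1, s2], axis=1, join="inner")


def decompose_noise(
    fits1: list[GeneFit],
    fits2: list[GeneFit],
    pairing: tuple[str, str] = ("run1", "run2"),
) -> NoiseDecomposition:
    """Intrinsic/extrinsic noise from two runs' per-gene slopes.

    Genes are matched by identifier after each run's own coverage filter;
    at least 2 shared genes are required.  Unmatched genes are simply not
    part of the decomposition (callers can diff the fit lists to report
    them).
    """
    pairs = matched_slopes(fits1, fits2)
    if len(pairs) < 2:
        raise FitError(
            f"need >= 2 genes passing the filter in both runs, got {len(pairs)}"
        )
    m1 = pairs["m1"].to_numpy()
    m2 = pairs["m2"].to_numpy()
    return NoiseDecomposition(
        eta_int=float(np.std(m1 - m2, ddof=_DDOF)),
        eta_ext=float(np.std(m1 + m2, ddof=_DDOF)),
        n_genes=len(pairs),
        pairing=pairing,
    )
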