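"""Per-gene dose-response fits and per-protocol summary statistics.

After normalization each spike-species gene should track the known mixing
fraction: a linear fit of normalized abundance versus Q has expected slope
1 and intercept 0.  This module filters genes by coverage in the reference
(highest-Q) library, fits ordinary least squares per gene, and aggregates
slopes/intercepts/Pearson correlations per protocol, including one-sample
t-tests of the mean slope against 1 and the mean intercept against 0, a
Welch two-sample test for comparing protocols on mean correlation, and the
interquartile range of slopes used to compare against the ideal-protocol
simulation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .counts import CountTable, CountTableError
from .design import MixtureDesign
from .normalize import NormalizedTable

logger = logging.getLogger(__name__)

DEFAULT_MIN_COUNT = 20


class FitError(ValueError):
    """Raised for undefined fits or summaries."""


@dataclass(frozen=True)
class GeneFit:
    """Ordinary least-squares fit of one gene's normalized abundance vs Q.

    ``pearson_r`` is NaN when the response is constant across libraries
    (zero variance leaves the correlation undefined; the fit is flagged).
    """

    gene: str
    slope: float
    intercept: float
    pearson_r: float
    n_points: int
    ref_count: int = -1

    @property
    def r_defined(self) -> bool:
        return not math.isnan(self.pearson_r)


@dataclass(frozen=True)
class ProtocolSummary:
    """Distribution of per-gene fit parameters for one protocol.

    Means and standard deviations (sample convention, n-1) of slopes,
    intercepts and correlations; one-sample t statistics of slopes against
    1 and intercepts against 0; interquartile range of slopes (quartiles by
    linear interpolation).  ``n_undefined_r`` counts genes whose Pearson r
    was undefined and therefore left out of the r statistics.
    """

    protocol: str
    n_genes: int
    mean_slope: float
    sd_slope: float
    mean_intercept: float
    sd_intercept: float
    mean_r: float
    sd_r: float
    t_slope_vs_1: float
    p_slope: float
    t_intercept_vs_0: float
    p_intercept: float
    iqr_slope: float
    n_undefined_r: int = 0


# ---------------------------------------------------------------------------
# Gene filtering
# ---------------------------------------------------------------------------

def filter_genes(
    table: CountTable,
    min_count: int = DEFAULT_MIN_COUNT,
    design: MixtureDesign | None = None,
) -> pd.Index:
    """Spike-species genes with at least ``min_count`` fragments in the
    highest-Q library ("at least" is inclusive: a count equal to
    ``min_count`` is retained)."""
    if design is None:
        design = MixtureDesign.from_table(table)
    ref = design.reference_library()
    spike = table.spike_genes()
    if len(spike) == 0:
        logger.warning("no spike-species genes in table; filter returns empty set")
        return spike
    keep = table.counts.loc[spike, ref] >= min_count
    return spike[keep.to_numpy()]


# ---------------------------------------------------------------------------
# Per-gene least squares
# ---------------------------------------------------------------------------

def _check_q(q: np.ndarray) -> None:
    if len(q) < 3:
        raise FitError(f"need >= 3 points for a per-gene fit, got {len(q)}")
    if np.ptp(q) == 0:
        raise FitError("spike fractions are constant; slope undefined")


def fit_gene(q, a_hat, gene: str = "", ref_count: int = -1) -> GeneFit:
    """OLS slope/intercept and Pearson r of one gene's response.

    A constant response gives slope 0 and an undefined (NaN) correlation.
    """
    q = np.asarray(q, dtype=float)
    y = np.asarray(a_hat, dtype=float)
    if q.shape != y.shape:
        raise FitError("q and a_hat must have the same length")
    _check_q(q)
    qc = q - q.mean()
    yc = y - y.mean()
    sxx = float(qc @ qc)
    sxy = float(qc @ yc)
    syy = float(yc @ yc)
    slope = sxy / sxx
    intercept = float(y.mean() - slope * q.mean())
    r = sxy / math.sqrt(sxx * syy) if syy > 0 else float("nan")
    return GeneFit(
        gene=gene, slope=slope, intercept=intercept, pearson_r=r,
        n_points=len(q), ref_count=ref_count,
    )


def fit_table(
    norm: NormalizedTable,
    genes: pd.Index,
    table: CountTable | None = None,
) -> list[GeneFit]:
    """Vectorized per-gene fits over a gene subset of a normalized table.

    Equivalent to calling :func:`fit_gene` per gene (same closed-form
    normal equations); ``table`` supplies the reference-library counts for
    bookkeeping when given.
    """
    design = norm.design
    q = np.asarray(design.q, dtype=float)
    _check_q(q)
    genes = pd.Index(genes)
    usable = genes[~norm.excluded.loc[genes].to_numpy()]
    n_excl = len(genes) - len(usable)
    if n_excl:
        logger.info("fit_table: %d of %d genes excluded by normalization", n_excl, len(genes))
    y = norm.norm_abundance.loc[usable].to_numpy(dtype=float)
    qc = q - q.mean()
    sxx = float(qc @ qc)
    yc = y - y.mean(axis=1, keepdims=True)
    sxy = yc @ qc
    syy = (yc**2).sum(axis=1)
    slopes = sxy / sxx
    intercepts = y.mean(axis=1) - slopes * q.mean()
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(syy > 0, sxy / np.sqrt(sxx * syy), np.nan)
    if table is not None:
        ref_counts = table.counts.loc[usable, design.reference_library()].to_numpy()
    else:
        ref_counts = np.full(len(usable), -1)
    return [
        GeneFit(gene=str(g), slope=float(m), intercept=float(b), pearson_r=float(rr),
                n_points=len(q), ref_count=int(c))
        for g, m, b, rr, c in zip(usable, slopes, intercepts, r, ref_counts)
    ]


def fits_frame(fits: list[GeneFit]) -> pd.DataFrame:
    """Tabular view of fits (gene, slope, intercept, pearson_r, ref_count)."""
    return pd.DataFrame(
        {
            "gene": [f.gene for f in fits],
            "slope": [f.slope for f in fits],
            "intercept": [f.intercept for f in fits],
            "pearson_r": [f.pearson_r for f in fits],
            "n_points": [f.n_points for f in fits],
            "ref_count": [f.ref_count for f in fits],
        }
    ).set_index("gene")


# ---------------------------------------------------------------------------
# Summaries and protocol comparison
# ---------------------------------------------------------------------------

def summarize_protocol(fits: list[GeneFit], protocol: str = "") -> ProtocolSummary:
    """Mean +/- sample SD of slopes/intercepts/correlations with t-tests.

    Slopes are tested against 1 and intercepts against 0 with one-sample
    t-tests.  Zero-variance inputs leave the t statistic undefined (NaN).
    Genes with undefined r are excluded from the r statistics but counted
    in ``n_undefined_r``.
    """
    if len(fits) < 2:
        raise FitError(f"need >= 2 fits to summarize, got {len(fits)}")
    slopes = np.array([f.slope for f in fits])
    intercepts = np.array([f.intercept for f in fits])
    rs = np.array([f.pearson_r for f in fits])
    r_ok = rs[~np.isnan(rs)]
    n_undef = int(np.isnan(rs).sum())
    if len(r_ok) < 2:
        raise FitError("need >= 2 fits with defined pearson_r")

    def one_sample(x: np.ndarray, popmean: float) -> tuple[float, float]:
        if x.std(ddof=1) == 0:
            return float("nan"), float("nan")
        res = stats.ttest_1samp(x, popmean)
        return float(res.statistic), float(res.pvalue)

    t_m, p_m = one_sample(slopes, 1.0)
    t_b, p_b = one_sample(intercepts, 0.0)
    q1, q3 = np.percentile(slopes, [25, 75], method="linear")
    return ProtocolSummary(
        protocol=protocol,
        n_genes=len(fits),
        mean_slope=float(slopes.mean()),
        sd_slope=float(slopes.std(ddof=1)),
        mean_intercept=float(intercepts.mean()),
        sd_intercept=float(intercepts.std(ddof=1)),
        mean_r=float(r_ok.mean()),
        sd_r=float(r_ok.std(ddof=1)),
        t_slope_vs_1=t_m,
        p_slope=p_m,
        t_intercept_vs_0=t_b,
        p_intercept=p_b,
        iqr_slope=float(q3 - q1),
        n_undefined_r=n_undef,
    )


@dataclass(frozen=True)
class ProtocolComparison:
    """Welch two-sample t-test on per-gene correlation coefficients."""

    t: float
    p: float
    n1: int
    n2: int
    degenerate: bool = False


def compare_protocols(fits1: list[GeneFit], fits2: list[GeneFit]) -> ProtocolComparison:
    """Compare two protocols on their per-gene Pearson correlations.

    Uses Welch's unequal-variance t-test.  If both samples have zero
    variance the statistic is undefined and the result is flagged
    ``degenerate``.
    """
    r1 = np.array([f.pearson_r for f in fits1 if f.r_defined])
    r2 = np.array([f.pearson_r for f in fits2 if f.r_defined])
    if len(r1) == 0 or len(r2) == 0:
        raise FitError("both protocols need at least one fit with defined r")
    if r1.std(ddof=0) == 0 and r2.std(ddof=0) == 0:
        return ProtocolComparison(
            t=float("nan"), p=float("nan"), n1=len(r1), n2=len(r2), degenerate=True
        )
    res = stats.ttest_ind(r1, r2, equal_var=False)
    return ProtocolComparison(
        t=float(res.statistic), p=float(res.pvalue), n1=len(r1), n2=len(r2)
    )


def summaries_frame(summaries: list[ProtocolSummary]) -> pd.DataFrame:
    """Per-protocol summary table (one row per protocol)."""
    return pd.DataFrame([s.__dict__ for s in summaries]).set_index("protocol")
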