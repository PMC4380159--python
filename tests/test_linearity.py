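"""Gene filtering, per-gene least squares, and protocol summaries."""

import math

import numpy as np
import pytest
from scipy import stats

from spikemix import (
    GeneFit,
    compare_protocols,
    filter_genes,
    fit_gene,
    fit_table,
    normalize,
    run_ensemble,
    summarize_protocol,
)
from spikemix.linearity import FitError
from spikemix.counts import CountTableError
from spikemix.synthetic import GeneratorConfig, simulation_config_from_profile

from conftest import make_table

Q4 = (0.0, 0.05, 0.10, 0.20)


def _fits(slopes, rs=None):
    rs = rs if rs is not None else [1.0] * len(slopes)
    return [
        GeneFit(gene=f"g{i}", slope=m, intercept=0.0, pearson_r=r, n_points=4)
        for i, (m, r) in enumerate(zip(slopes, rs))
    ]


class TestFilterGenes:
    def test_inclusive_boundary_and_enumeration(self):
        """Reference counts (3, 20, 21, 400, 19) keep exactly the three
        genes with at least 20 fragments in the highest-Q library."""
        table = make_table(
            {"L0": [0] * 5, "L20": [3, 20, 21, 400, 19]},
            species=["spike"] * 5,
            fractions=[0.0, 0.20],
            genes=[f"Dvir\\g{i}" for i in range(5)],
        )
        kept = filter_genes(table, min_count=20)
        assert list(kept) == ["Dvir\\g1", "Dvir\\g2", "Dvir\\g3"]

    def test_no_spike_genes_gives_empty_set(self):
        table = make_table({"L0": [5], "L20": [500]}, ["background"], [0.0, 0.2])
        assert len(filter_genes(table)) == 0

    def test_requires_positive_fraction(self):
        table = make_table({"L0": [5]}, ["spike"], [0.0])
        with pytest.raises(CountTableError, match="spike fraction > 0"):
            filter_genes(table)


class TestFitGene:
    def test_identity_line(self):
        fit = fit_gene(Q4, Q4)
        assert fit.slope == pytest.approx(1.0, abs=1e-12)
        assert fit.intercept == pytest.approx(0.0, abs=1e-12)
        assert fit.pearson_r == pytest.approx(1.0, abs=1e-12)

    def test_constant_response_flags_r_undefined(self):
        fit = fit_gene(Q4, [2.0, 2.0, 2.0, 2.0])
        assert fit.slope == 0.0
        assert not fit.r_defined

    def test_normal_equation_oracle(self):
        """Frozen closed-form solution (exact rational arithmetic) for
        q = (0,.05,.10,.20), y = (.01,.04,.12,.19)."""
        fit = fit_gene(Q4, [0.01, 0.04, 0.12, 0.19])
        assert fit.slope == pytest.approx(164 / 175, rel=1e-12)
        assert fit.intercept == pytest.approx(1 / 125, rel=1e-12)
        assert fit.pearson_r == pytest.approx(0.9850249592138111, rel=1e-10)

    def test_agrees_with_linregress_on_random_instances(self):
        rng = np.random.default_rng(11)
        for _ in range(200):
            y = rng.normal(size=4)
            fit = fit_gene(Q4, y)
            ref = stats.linregress(Q4, y)
            assert fit.slope == pytest.approx(ref.slope, rel=1e-9, abs=1e-9)
            assert fit.intercept == pytest.approx(ref.intercept, rel=1e-9, abs=1e-9)
            assert fit.pearson_r == pytest.approx(ref.rvalue, rel=1e-9, abs=1e-9)

    def test_rejects_degenerate_inputs(self):
        with pytest.raises(FitError, match=">= 3 points"):
            fit_gene([0.0, 0.1], [1.0, 2.0])
        with pytest.raises(FitError, match="constant"):
            fit_gene([0.1, 0.1, 0.1], [1.0, 2.0, 3.0])

    def test_vectorized_fit_matches_scalar(self, random_table):
        norm = normalize(random_table)
        genes = norm.genes[~norm.excluded]
        fits = fit_table(norm, genes, random_table)
        for f in fits[:25]:
            y = norm.norm_abundance.loc[f.gene].to_numpy()
            ref = fit_gene(random_table.spike_fractions, y, gene=f.gene)
            assert f.slope == pytest.approx(ref.slope, rel=1e-12)
            assert f.intercept == pytest.approx(ref.intercept, abs=1e-12)
            if ref.r_defined:
                assert f.pearson_r == pytest.approx(ref.pearson_r, rel=1e-12)


class TestSummarize:
    def test_zero_variance_flags_t_undefined(self):
        summary = summarize_protocol(_fits([1.0, 1.0, 1.0]))
        assert summary.mean_slope == 1.0 and summary.sd_slope == 0.0
        assert math.isnan(summary.t_slope_vs_1)

    def test_hand_arithmetic_two_fits(self):
        summary = summarize_protocol(_fits([0.9, 1.1]))
        assert summary.mean_slope == pytest.approx(1.0)
        assert summary.sd_slope == pytest.approx(0.1414213562373095, rel=1e-12)
        assert summary.t_slope_vs_1 == pytest.approx(0.0, abs=1e-12)
        assert summary.iqr_slope == pytest.approx(0.1, rel=1e-12)

    def test_requires_two_fits(self):
        with pytest.raises(FitError):
            summarize_protocol(_fits([1.0]))

    def test_undefined_r_counted_not_propagated(self):
        fits = _fits([1.0, 1.1, 0.9], rs=[0.99, float("nan"), 0.97])
        summary = summarize_protocol(fits)
        assert summary.n_undefined_r == 1
        assert summary.mean_r == pytest.approx(0.98)


class TestCompareProtocols:
    def test_identical_samples(self):
        fits = _fits([1.0] * 10, rs=list(np.linspace(0.9, 0.99, 10)))
        res = compare_protocols(fits, fits)
        assert res.t == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_zero_pooled_variance_flagged(self):
        a = _fits([1.0] * 10, rs=[1.0] * 10)
        b = _fits([1.0] * 10, rs=[0.5] * 10)
        res = compare_protocols(a, b)
        assert res.degenerate and math.isnan(res.t)

    def test_empty_input_errors(self):
        with pytest.raises(FitError):
            compare_protocols([], _fits([1.0]))

    def test_null_calibration(self):
        """When both r samples come from the same distribution the Welch
        p-values are uniform on (0, 1)."""
        rng = np.random.default_rng(5)
        pvals = []
        for _ in range(1000):
            r1 = rng.normal(0.9, 0.05, size=10)
            r2 = rng.normal(0.9, 0.05, size=10)
            pvals.append(compare_protocols(_fits([1.0] * 10, r1),
                                           _fits([1.0] * 10, r2)).p)
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01


class TestOnSyntheticData:
    def test_mean_r_increases_with_depth(self):
        """Deeper sequencing means less counting noise, hence tighter
        per-gene correlations (non-strict monotonicity within noise)."""
        means = []
        for depth in (10_000, 100_000, 1_000_000):
            vals = []
            for seed in range(5):
                gen = GeneratorConfig(n_background_genes=300, n_spike_genes=100,
                                      levels=Q4, depth=depth, seed=seed)
                cfg = simulation_config_from_profile(gen, n_reps=1, min_count=5)
                vals.append(run_ensemble(cfg).mean("mean_r"))
            means.append(np.mean(vals))
        assert means[0] < means[1] + 0.002
        assert means[1] < means[2] + 0.002
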