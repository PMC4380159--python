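"""The synthetic two-species mixture generator."""

import numpy as np
import pandas as pd
import pytest

from spikemix import (
    GeneratorConfig,
    SimulationConfig,
    analyze_experiment,
    generate_experiment,
    make_expression_profile,
    simulate_experiment,
)
from spikemix.counts import SPIKE
from spikemix.simulation import SimulationError
from spikemix.synthetic import _bias_factors


SMALL = dict(n_background_genes=300, n_spike_genes=100, depth=200_000)


class TestExpressionProfile:
    def test_probabilities_sum_to_one(self):
        profile = make_expression_profile(GeneratorConfig(**SMALL, seed=1))
        assert profile.probs.sum() == pytest.approx(1.0, abs=1e-12)
        assert (profile.probs > 0).all()

    def test_spike_mass_equals_max_level(self):
        config = GeneratorConfig(**SMALL, seed=2)
        profile = make_expression_profile(config)
        spike_mass = profile.probs[profile.species == SPIKE].sum()
        assert spike_mass == pytest.approx(max(config.levels), abs=1e-12)

    def test_dynamic_range_order_statistic(self):
        """The realized max/min expression ratio approaches the configured
        dynamic range (averaged over seeds, within 10%)."""
        ratios = []
        for seed in range(20):
            config = GeneratorConfig(n_background_genes=3000, n_spike_genes=1000,
                                     dynamic_range=1e5, seed=seed)
            profile = make_expression_profile(config)
            ratios.append(profile.expression.max() / profile.expression.min())
        assert abs(np.mean(ratios) - 1e5) / 1e5 < 0.10

    def test_rejects_degenerate_configs(self):
        with pytest.raises(SimulationError):
            GeneratorConfig(n_background_genes=0, n_spike_genes=10)
        with pytest.raises(SimulationError):
            GeneratorConfig(dynamic_range=0.5)


class TestGenerateExperiment:
    def test_ideal_protocol_matches_multinomial_null(self):
        """With no bias and no overdispersion the generator is the
        multinomial null, draw for draw."""
        config = GeneratorConfig(**SMALL, seed=5)
        table = generate_experiment(config, preamp_id="A", run=0)
        profile = make_expression_profile(config)
        sim = simulate_experiment(SimulationConfig(
            base_probs=profile.probs,
            species=profile.species,
            levels=config.levels,
            depth_per_library=config.depth,
            seed=config.draw_seed("A", 0),
            genes=profile.genes,
        ))
        np.testing.assert_array_equal(table.counts.to_numpy(),
                                      sim.counts.to_numpy())

    def test_deterministic_and_run_specific(self):
        config = GeneratorConfig(**SMALL, seed=5, bias_sd=0.2)
        a = generate_experiment(config, preamp_id="A", run=0)
        b = generate_experiment(config, preamp_id="A", run=0)
        c = generate_experiment(config, preamp_id="A", run=1)
        pd.testing.assert_frame_equal(a.counts, b.counts)
        assert not a.counts.equals(c.counts.set_axis(a.counts.columns, axis=1))

    def test_bias_shared_within_preamp_batch(self):
        config = GeneratorConfig(**SMALL, seed=5, bias_sd=0.2)
        n = 400
        same = [_bias_factors(config, "A", level_index, n) for level_index in (0, 1)]
        again = _bias_factors(config, "A", 0, n)
        other = _bias_factors(config, "B", 0, n)
        np.testing.assert_array_equal(same[0], again)
        assert not np.array_equal(same[0], same[1])  # per-level draws differ
        assert not np.array_equal(same[0], other)    # per-batch draws differ

    def test_spike_read_fraction_tracks_level(self):
        """Without bias, the expected share of spike-species reads in each
        library equals its mixture level (3 SEs over seeds)."""
        config_levels = (0.0, 0.05, 0.10, 0.20)
        fractions = []
        for seed in range(10):
            config = GeneratorConfig(**SMALL, levels=config_levels, seed=seed)
            table = generate_experiment(config, preamp_id="A")
            spike = table.counts.loc[table.spike_genes()].sum(axis=0)
            fractions.append((spike / table.depths).to_numpy())
        mean_frac = np.mean(fractions, axis=0)
        for level, observed in zip(config_levels, mean_frac):
            se = np.sqrt(max(level, 1e-12) * (1 - level) / (SMALL["depth"] * 10))
            assert abs(observed - level) <= 3 * se + 1e-12

    def test_overdispersion_inflates_variance(self):
        """Compound-multinomial draws scatter more than multinomial ones."""
        base = dict(n_background_genes=50, n_spike_genes=20, depth=50_000,
                    levels=(0.0, 0.2))
        var = {}
        for name, od in (("multinomial", None), ("overdispersed", 30.0)):
            counts = []
            for run in range(60):
                config = GeneratorConfig(**base, overdispersion=od, seed=9)
                t = generate_experiment(config, preamp_id="A", run=run)
                counts.append(t.counts.iloc[0, -1])
            var[name] = np.var(counts)
        assert var["overdispersed"] > 3 * var["multinomial"]

    def test_same_preamp_slopes_more_correlated(self):
        """Per-gene slopes from two same-batch runs correlate more strongly
        than slopes from runs with independent pre-amplifications."""
        same_r, diff_r = [], []
        for seed in range(10):
            config = GeneratorConfig(**SMALL, bias_sd=0.2, seed=seed)
            fits = {}
            for pre, run in (("A", 0), ("A", 1), ("B", 0)):
                table = generate_experiment(config, preamp_id=pre, run=run)
                frame = {f.gene: f.slope for f in analyze_experiment(table).fits}
                fits[(pre, run)] = pd.Series(frame)
            a0, a1, b0 = fits[("A", 0)], fits[("A", 1)], fits[("B", 0)]
            shared_same = a0.index.intersection(a1.index)
            shared_diff = a0.index.intersection(b0.index)
            same_r.append(np.corrcoef(a0[shared_same], a1[shared_same])[0, 1])
            diff_r.append(np.corrcoef(a0[shared_diff], b0[shared_diff])[0, 1])
        assert np.median(same_r) > np.median(diff_r)
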