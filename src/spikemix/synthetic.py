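"""Synthetic two-species mixture experiments.

Generates count tables with the statistical structure the analysis
assumes, so every pipeline stage is testable without sequencing data: a
two-species gene universe whose expression spans a configurable dynamic
range (default 1e5-fold, the typical span of RNA abundances), known
mixture levels of the spike species, multinomial read sampling at a
configurable depth, and an optional gene-specific pre-amplification bias
shared between runs that reuse the same amplified cDNA pools.

The bias model is a stand-in, not a measured mechanism: each
pre-amplification batch draws one lognormal factor per gene *per mixture
level* (each level is a separate RNA pool, hence a separate amplification
reaction), multiplies the level's sampling probabilities by those factors
and renormalizes.  Because the factors are level-specific they perturb
per-gene slopes, and because they are tied to the batch the perturbation
is shared between runs with the same ``preamp_id`` — reproducing the
same-versus-different pre-amplification contrast without asserting any
particular amplification chemistry.  With ``bias_sd = 0`` and no
overdispersion the generator is an ideal protocol and matches the
multinomial null of :mod:`spikemix.simulation` draw for draw.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .counts import BACKGROUND, SPIKE, CountTable, LibraryMeta
from .simulation import SimulationConfig, SimulationError, build_level_probs


def _subseed(seed: int, *parts) -> int:
    """Deterministic child seed for a named random stream (< 2**32)."""
    key = [int(seed)] + [zlib.crc32(str(p).encode()) for p in parts]
    return int(np.random.SeedSequence(key).generate_state(1)[0])


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for the synthetic generator.

    Defaults mirror the mixture experiment being emulated: five known
    spike fractions 0/1/5/10/20%, ~8,000 expressed genes of which a
    quarter are spike-species, expression spanning 1e5-fold, and 2.5M
    reads per library (the order of the common subsampled depth).
    ``bias_sd`` is the standard deviation of the log gene-specific
    pre-amplification bias (0 = ideal protocol); ``overdispersion`` is an
    optional Dirichlet concentration multiplier for compound-multinomial
    draws (None = pure multinomial).
    """

    n_background_genes: int = 6000
    n_spike_genes: int = 2000
    dynamic_range: float = 1e5
    levels: tuple[float, ...] = (0.0, 0.01, 0.05, 0.10, 0.20)
    depth: int = 2_500_000
    bias_sd: float = 0.0
    overdispersion: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_background_genes <= 0 or self.n_spike_genes <= 0:
            raise SimulationError("need at least one gene of each species")
        if self.dynamic_range <= 1:
            raise SimulationError("dynamic_range must be > 1")
        if self.depth < 0:
            raise SimulationError("depth must be >= 0")
        if self.bias_sd < 0:
            raise SimulationError("bias_sd must be >= 0")
        if not self.levels or max(self.levels) <= 0:
            raise SimulationError("need at least one positive level")
        if self.overdispersion is not None and self.overdispersion <= 0:
            raise SimulationError("overdispersion must be > 0 when set")

    def draw_seed(self, preamp_id: str, run: int = 0) -> int:
        """Seed of the multinomial read-sampling stream for one run."""
        return _subseed(self.seed, "draw", preamp_id, run)


@dataclass
class ExpressionProfile:
    """Base expression state of the reference (highest-level) mixture."""

    probs: np.ndarray
    species: np.ndarray
    genes: np.ndarray
    expression: np.ndarray  # raw expression values before mass allocation


def make_expression_profile(config: GeneratorConfig) -> ExpressionProfile:
    """Log-uniform expression over ``dynamic_range``, normalized so that
    spike-species genes carry total probability mass equal to the maximum
    mixture level (the reference library *is* that mixture)."""
    rng = np.random.default_rng(_subseed(config.seed, "profile"))
    n_bg, n_sp = config.n_background_genes, config.n_spike_genes
    span = np.log10(config.dynamic_range)
    expr = 10 ** rng.uniform(0.0, span, n_bg + n_sp)
    species = np.array([BACKGROUND] * n_bg + [SPIKE] * n_sp)
    max_level = max(config.levels)
    probs = np.empty_like(expr)
    bg, sp = expr[:n_bg], expr[n_bg:]
    probs[:n_bg] = (1.0 - max_level) * bg / bg.sum()
    probs[n_bg:] = max_level * sp / sp.sum()
    width = len(str(n_bg + n_sp))
    genes = np.array(
        [f"Dmel\\g{i:0{width}d}" for i in range(n_bg)]
        + [f"Dvir\\g{i:0{width}d}" for i in range(n_sp)]
    )
    return ExpressionProfile(probs=probs, species=species, genes=genes, expression=expr)


def _bias_factors(config: GeneratorConfig, preamp_id: str, level_index: int,
                  n_genes: int) -> np.ndarray:
    rng = np.random.default_rng(
        _subseed(config.seed, "bias", preamp_id, f"level{level_index}")
    )
    return rng.lognormal(mean=0.0, sigma=config.bias_sd, size=n_genes)


def generate_experiment(
    config: GeneratorConfig,
    preamp_id: str = "preamp0",
    run: int = 0,
    protocol: str = "synthetic",
) -> CountTable:
    """One synthetic mixture experiment: one library per level.

    Libraries sharing ``preamp_id`` (across calls and runs) see the
    identical per-level bias vectors; a different ``preamp_id`` draws
    independent ones.  Deterministic given ``(config.seed, preamp_id,
    run)``; with ``bias_sd = 0`` and no overdispersion the counts equal
    :func:`spikemix.simulation.simulate_experiment` run on this profile
    with seed ``config.draw_seed(preamp_id, run)``.
    """
    profile = make_expression_profile(config)
    max_level = max(config.levels)
    rng = np.random.default_rng(config.draw_seed(preamp_id, run))
    cols, metas = {}, []
    for idx, level in enumerate(config.levels):
        p = build_level_probs(profile.probs, profile.species, level, max_level)
        if config.bias_sd > 0:
            p = p * _bias_factors(config, preamp_id, idx, len(p))
            p = p / p.sum()
        if config.overdispersion is not None:
            # compound multinomial: resample probabilities per library
            pos = p > 0
            resampled = np.zeros_like(p)
            resampled[pos] = rng.dirichlet(config.overdispersion * p[pos])
            p = resampled
        lib_id = f"{protocol}-{preamp_id}-r{run}-q{level:g}"
        cols[lib_id] = rng.multinomial(config.depth, p).astype(np.int64)
        metas.append(
            LibraryMeta(
                library_id=lib_id,
                protocol=protocol,
                spike_fraction=level,
                preamp_id=preamp_id,
                seed=config.seed,
            )
        )
    idx_ = pd.Index(profile.genes, name="gene")
    return CountTable(
        counts=pd.DataFrame(cols, index=idx_),
        species=pd.Series(profile.species, index=idx_, name="species"),
        libraries=metas,
    )


def simulation_config_from_profile(
    config: GeneratorConfig,
    levels: tuple[float, ...] | None = None,
    n_reps: int = 20,
    seed: int | None = None,
    min_count: int = 20,
) -> SimulationConfig:
    """Multinomial-null configuration whose base probabilities come from
    this generator's expression profile (used when no measured reference
    library is available)."""
    profile = make_expression_profile(config)
    return SimulationConfig(
        base_probs=profile.probs,
        species=profile.species,
        levels=levels if levels is not None else config.levels,
        depth_per_library=config.depth,
        n_reps=n_reps,
        seed=config.seed if seed is None else seed,
        genes=profile.genes,
        min_count=min_count,
    )
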