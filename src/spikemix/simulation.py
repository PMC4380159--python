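"""Ideal-protocol null model: multinomial counting noise only.

An idealized RNA-seq protocol introduces no bias — the only stochasticity
is which reads get sampled.  Given a base per-gene probability vector
(representing the highest-spike-fraction reference library), libraries at
lower spike fractions are emulated by scaling the spike-species
probabilities down proportionally and redistributing the freed probability
mass evenly (equal absolute increment) over the background-species genes.
One multinomial draw per mixture level at a fixed depth then yields an
ideal count table, and repeating the draw gives null distributions of the
pipeline's quality metrics (mean correlation, slope IQR, ...) against
which an observed protocol can be ranked.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .counts import BACKGROUND, SPIKE, CountTable, LibraryMeta
from .design import MixtureDesign
from .linearity import DEFAULT_MIN_COUNT, fit_table, filter_genes, summarize_protocol
from .normalize import normalize

logger = logging.getLogger(__name__)


class SimulationError(ValueError):
    pass


@dataclass
class SimulationConfig:
    """Parameters of the multinomial null model.

    ``base_probs`` is the per-gene probability vector of the reference
    (highest-level) library; ``levels`` are the spike fractions to emulate;
    each simulated library draws ``depth_per_library`` reads.
    """

    base_probs: np.ndarray
    species: np.ndarray
    levels: tuple[float, ...] = (0.0, 0.05, 0.10, 0.20)
    depth_per_library: int = 2_500_000
    n_reps: int = 20
    seed: int = 0
    genes: np.ndarray | None = None
    min_count: int = DEFAULT_MIN_COUNT

    def __post_init__(self) -> None:
        p = np.asarray(self.base_probs, dtype=float)
        object.__setattr__(self, "base_probs", p)
        sp = np.asarray(self.species)
        object.__setattr__(self, "species", sp)
        if p.ndim != 1 or len(p) != len(sp):
            raise SimulationError("base_probs and species must be 1-D and aligned")
        if (p < 0).any():
            raise SimulationError("base_probs must be non-negative")
        if abs(p.sum() - 1.0) > 1e-12:
            raise SimulationError(f"base_probs must sum to 1 (got {p.sum()!r})")
        levels = tuple(float(l) for l in self.levels)
        object.__setattr__(self, "levels", levels)
        if not levels or max(levels) <= 0:
            raise SimulationError("need at least one positive spike level")
        if min(levels) < 0 or max(levels) > 1:
            raise SimulationError("levels must lie in [0, 1]")
        if self.genes is None:
            width = len(str(len(p)))
            names = np.array(
                [f"{'Dvir' if s == SPIKE else 'Dmel'}\\g{i:0{width}d}"
                 for i, s in enumerate(sp)]
            )
            object.__setattr__(self, "genes", names)


def build_level_probs(
    base_probs: np.ndarray,
    species: np.ndarray,
    level: float,
    max_level: float,
) -> np.ndarray:
    """Probability vector for a library at a lower spike fraction.

    Spike-species probabilities are scaled by ``level / max_level``; the
    freed mass is assigned evenly — the same absolute increment per gene —
    to the background-species genes.  The result sums to 1.
    """
    p = np.asarray(base_probs, dtype=float)
    species = np.asarray(species)
    if max_level <= 0:
        raise SimulationError("max_level must be > 0")
    if not 0 <= level <= max_level:
        raise SimulationError(f"level {level} outside [0, {max_level}]")
    is_spike = species == SPIKE
    n_background = int((~is_spike).sum())
    out = p.copy()
    out[is_spike] = p[is_spike] * (level / max_level)
    freed = p[is_spike].sum() - out[is_spike].sum()
    if freed > 0:
        if n_background == 0:
            raise SimulationError("no background genes to absorb freed probability mass")
        out[~is_spike] += freed / n_background
    return out


def simulate_experiment(config: SimulationConfig) -> CountTable:
    """One ideal experiment: a multinomial draw per level, fixed depth.

    Deterministic given ``config.seed``.  Library ids are ``sim_q<level>``;
    each library's metadata records its level as the spike fraction.
    """
    if config.depth_per_library == 0:
        logger.warning("depth_per_library is 0: all-zero count table")
    max_level = max(config.levels)
    rng = np.random.default_rng(config.seed)
    cols, metas = {}, []
    for level in config.levels:
        probs = build_level_probs(config.base_probs, config.species, level, max_level)
        lib_id = f"sim_q{level:g}"
        cols[lib_id] = rng.multinomial(config.depth_per_library, probs).astype(np.int64)
        metas.append(
            LibraryMeta(library_id=lib_id, protocol="simulated",
                        spike_fraction=level, preamp_id="ideal", seed=config.seed)
        )
    idx = pd.Index(config.genes, name="gene")
    return CountTable(
        counts=pd.DataFrame(cols, index=idx),
        species=pd.Series(config.species, index=idx, name="species"),
        libraries=metas,
    )


# ---------------------------------------------------------------------------
# Ensembles
# ---------------------------------------------------------------------------

#: quality metrics recorded per replicate
METRICS = ("mean_slope", "mean_intercept", "mean_r", "iqr_slope")


@dataclass
class SimulationEnsemble:
    """Null distributions of quality metrics over simulation replicates.

    ``metrics`` has one row per successful replicate and one column per
    metric in :data:`METRICS`.  ``percentile_rank`` reports, for an observed
    value, the percentage of replicates that *strictly exceed* it — e.g.
    "13% of simulations had a higher IQR".
    """

    metrics: pd.DataFrame
    n_failed: int = 0
    observed_ranks: dict[str, float] = field(default_factory=dict)

    @property
    def n_reps(self) -> int:
        return len(self.metrics)

    def percentile_rank(self, metric: str, observed: float) -> float:
        values = self.metrics[metric].to_numpy()
        return 100.0 * float((values > observed).sum()) / len(values)

    def mean(self, metric: str) -> float:
        return float(self.metrics[metric].mean())

    def standard_error(self, metric: str) -> float:
        x = self.metrics[metric].to_numpy()
        return float(x.std(ddof=1) / np.sqrt(len(x)))


def replicate_metrics(table: CountTable, min_count: int = DEFAULT_MIN_COUNT) -> dict[str, float]:
    """Run the analysis pipeline (normalize -> filter -> fit -> summarize)
    on one count table and return its quality metrics."""
    design = MixtureDesign.from_table(table)
    norm = normalize(table, design)
    kept = filter_genes(table, min_count=min_count, design=design)
    fits = fit_table(norm, kept, table)
    summary = summarize_protocol(fits, protocol=table.libraries[0].protocol)
    return {
        "mean_slope": summary.mean_slope,
        "mean_intercept": summary.mean_intercept,
        "mean_r": summary.mean_r,
        "iqr_slope": summary.iqr_slope,
    }


def run_ensemble(
    config: SimulationConfig,
    observed: dict[str, float] | None = None,
) -> SimulationEnsemble:
    """Replicate the ideal experiment ``config.n_reps`` times through the
    full analysis pipeline.

    Per-replicate seeds are derived deterministically from ``config.seed``.
    A replicate whose pipeline fails (e.g. no gene passes the filter at
    very low depth) is recorded as failed and the run continues.  If
    ``observed`` metric values are supplied, their strict-greater percentile
    ranks within the ensemble are attached.
    """
    if config.n_reps < 1:
        raise SimulationError("n_reps must be >= 1")
    rep_seeds = np.random.SeedSequence(config.seed).generate_state(config.n_reps)
    rows, n_failed = [], 0
    for rep, rep_seed in enumerate(rep_seeds):
        rep_config = SimulationConfig(
            base_probs=config.base_probs,
            species=config.species,
            levels=config.levels,
            depth_per_library=config.depth_per_library,
            n_reps=1,
            seed=int(rep_seed),
            genes=config.genes,
            min_count=config.min_count,
        )
        try:
            table = simulate_experiment(rep_config)
            rows.append(replicate_metrics(table, min_count=config.min_count))
        except Exception as exc:  # noqa: BLE001 - a failed replicate must not kill the run
            n_failed += 1
            logger.warning("replicate %d failed: %s", rep, exc)
    if not rows:
        raise SimulationError("every replicate failed")
    metrics = pd.DataFrame(rows, columns=list(METRICS))
    ensemble = SimulationEnsemble(metrics=metrics, n_failed=n_failed)
    if observed:
        ensemble.observed_ranks = {
            k: ensemble.percentile_rank(k, v) for k, v in observed.items() if k in metrics
        }
    return ensemble
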