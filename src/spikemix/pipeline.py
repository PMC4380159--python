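"""End-to-end orchestration: subsample -> normalize -> filter -> fit ->
summarize, plus the simulation comparison and the paired-run noise
decomposition, with all outputs written as TSV/JSON under one directory."""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .counts import CountTable, CountTableError, PrefixRule, load_experiment
from .design import MixtureDesign
from .linearity import (
    DEFAULT_MIN_COUNT,
    GeneFit,
    ProtocolSummary,
    filter_genes,
    fit_table,
    fits_frame,
    summaries_frame,
    summarize_protocol,
)
from .noise import decompose_noise
from .normalize import NormalizedTable, normalize
from .simulation import SimulationConfig, run_ensemble
from .counts import subsample_counts

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    design_path: str | Path
    out_dir: str | Path
    min_count: int = DEFAULT_MIN_COUNT
    target_depth: int | None = None  # None = minimum depth across libraries
    seed: int = 0
    spike_prefix: str = "Dvir\\"
    simulate_reps: int = 0
    simulate_reference_protocol: str | None = None
    noise_pairs: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.min_count < 0:
            raise CountTableError("min_count must be >= 0")


@dataclass
class ProtocolResult:
    protocol: str
    table: CountTable
    norm: NormalizedTable
    fits: list[GeneFit]
    summary: ProtocolSummary


def analyze_experiment(
    table: CountTable, min_count: int = DEFAULT_MIN_COUNT, protocol: str = ""
) -> ProtocolResult:
    """Normalize, filter, fit, and summarize one experiment (one library
    per mixture level, a single protocol)."""
    design = MixtureDesign.from_table(table)
    norm = normalize(table, design)
    kept = filter_genes(table, min_count=min_count, design=design)
    logger.info(
        "%s: %d spike genes pass the >=%d filter (of %d genes total)",
        protocol or "experiment", len(kept), min_count, len(table.genes),
    )
    fits = fit_table(norm, kept, table)
    summary = summarize_protocol(fits, protocol=protocol)
    return ProtocolResult(protocol=protocol, table=table, norm=norm, fits=fits,
                          summary=summary)


def run_pipeline(config: RunConfig) -> dict:
    """Run the full analysis described by a design table and write a
    report bundle (per-gene fits, protocol summaries, optional simulation
    comparison and noise decomposition, and a run manifest).

    Returns a dict with the in-memory results keyed by stage.
    """
    out_dir = Path(config.out_dir)
    rule = PrefixRule(spike_prefix=config.spike_prefix)
    table = load_experiment(config.design_path, rule)
    if not table.library_ids:
        raise CountTableError("design lists no libraries")

    protocols = sorted({m.protocol for m in table.libraries})
    for pair in config.noise_pairs:
        for p in pair:
            if p not in protocols:
                raise CountTableError(f"noise pair names unknown protocol {p!r}")
    depths = table.depths
    target = int(depths.min()) if config.target_depth is None else int(config.target_depth)
    logger.info("subsampling %d libraries to %d reads each", len(table.library_ids), target)
    table = subsample_counts(table, target, seed=config.seed)

    out_dir.mkdir(parents=True, exist_ok=True)
    results: dict[str, ProtocolResult] = {}
    for protocol in protocols:
        libs = [m.library_id for m in table.libraries if m.protocol == protocol]
        sub = table.select_libraries(libs)
        res = analyze_experiment(sub, min_count=config.min_count, protocol=protocol)
        results[protocol] = res
        fits_frame(res.fits).to_csv(out_dir / f"fits_{protocol}.tsv", sep="\t")
    summary_df = summaries_frame([r.summary for r in results.values()])
    summary_df.to_csv(out_dir / "protocol_summaries.tsv", sep="\t")

    bundle: dict = {"protocols": results, "summaries": summary_df, "target_depth": target}

    if config.simulate_reps > 0:
        ref_protocol = config.simulate_reference_protocol or protocols[0]
        ref_res = results[ref_protocol]
        ref_lib = MixtureDesign.from_table(ref_res.table).reference_library()
        counts = ref_res.table.counts[ref_lib].to_numpy(dtype=float)
        sim_config = SimulationConfig(
            base_probs=counts / counts.sum(),
            species=ref_res.table.species.to_numpy(),
            levels=tuple(m.spike_fraction for m in ref_res.table.libraries),
            depth_per_library=target,
            n_reps=config.simulate_reps,
            seed=config.seed,
            genes=ref_res.table.genes.to_numpy(),
            min_count=config.min_count,
        )
        observed = {
            "mean_r": ref_res.summary.mean_r,
            "iqr_slope": ref_res.summary.iqr_slope,
            "mean_slope": ref_res.summary.mean_slope,
            "mean_intercept": ref_res.summary.mean_intercept,
        }
        ensemble = run_ensemble(sim_config, observed=observed)
        ensemble.metrics.to_csv(out_dir / "simulation_ensemble.tsv", sep="\t",
                                index_label="replicate")
        with open(out_dir / "simulation_ranks.json", "w") as fh:
            json.dump({"reference_protocol": ref_protocol,
                       "observed": observed,
                       "percentile_rank_higher": ensemble.observed_ranks,
                       "n_failed": ensemble.n_failed}, fh, indent=2)
        bundle["ensemble"] = ensemble

    noise_rows = []
    for p1, p2 in config.noise_pairs:
        dec = decompose_noise(results[p1].fits, results[p2].fits, pairing=(p1, p2))
        noise_rows.append({"run1": p1, "run2": p2, "eta_int": dec.eta_int,
                           "eta_ext": dec.eta_ext, "n_genes": dec.n_genes})
    if noise_rows:
        pd.DataFrame(noise_rows).to_csv(out_dir / "noise_decomposition.tsv",
                                        sep="\t", index=False)
        bundle["noise"] = noise_rows

    manifest = {
        "spikemix_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "python_version": platform.python_version(),
        "seed": config.seed,
        "min_count": config.min_count,
        "target_depth": target,
        "n_genes": int(len(table.genes)),
        "libraries": table.library_ids,
        "protocols": protocols,
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    bundle["manifest"] = manifest
    return bundle
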