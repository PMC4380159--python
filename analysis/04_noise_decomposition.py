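#!/usr/bin/env python
"""Where does run-to-run slope variation come from?

Three runs of the five-level mixture experiment (0/1/5/10/20%): two share
one pre-amplified cDNA batch but use independent downstream reactions,
the third uses a separate pre-amplification.  Pairing per-gene slopes and
splitting their variation into the component perpendicular to the
diagonal (intrinsic, eta_int = std(m1 - m2)) and along it (extrinsic,
eta_ext = std(m1 + m2)) attributes the shared-batch part: if
pre-amplification matters, the same-batch pair shows lower intrinsic
noise.
"""

from pathlib import Path

import pandas as pd

from spikemix import GeneratorConfig, analyze_experiment, decompose_noise, generate_experiment
from spikemix.noise import matched_slopes

OUT = Path("results/noise")
SEED = 31

RUNS = {  # label -> (preamp batch, run index)
    "ss": ("batchW", 0),
    "ss25": ("batchX", 0),
    "ss5": ("batchX", 1),
}


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    config = GeneratorConfig(levels=(0.0, 0.01, 0.05, 0.10, 0.20),
                             bias_sd=0.2, seed=SEED)
    fits = {}
    for label, (preamp, run) in RUNS.items():
        table = generate_experiment(config, preamp_id=preamp, run=run,
                                    protocol=label)
        fits[label] = analyze_experiment(table, protocol=label).fits
        print(f"{label}: {len(fits[label])} genes pass the filter "
              f"(preamp {preamp}, run {run})")

    rows = []
    for name, (a, b) in {"same_preamp": ("ss25", "ss5"),
                         "different_preamp": ("ss", "ss25")}.items():
        dec = decompose_noise(fits[a], fits[b], pairing=(a, b))
        matched_slopes(fits[a], fits[b]).to_csv(OUT / f"slopes_{name}.tsv", sep="\t",
                                                index_label="gene")
        rows.append({"pairing": name, "run1": a, "run2": b,
                     "eta_int": dec.eta_int, "eta_ext": dec.eta_ext,
                     "n_genes": dec.n_genes})
        print(f"{name} ({a} vs {b}): eta_int = {dec.eta_int:.3f}, "
              f"eta_ext = {dec.eta_ext:.3f}, n = {dec.n_genes}")
    pd.DataFrame(rows).to_csv(OUT / "decomposition.tsv", sep="\t", index=False)

    same, diff = rows[0], rows[1]
    if same["eta_int"] < diff["eta_int"]:
        print("\nintrinsic noise is lower for the same-batch pair: the "
              "pre-amplification contributes a reproducible, batch-specific "
              "component to per-gene slope variation.")


if __name__ == "__main__":
    main()
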