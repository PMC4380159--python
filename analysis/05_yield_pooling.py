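#!/usr/bin/env python
"""Molar yields and an equimolar sequencing pool.

Converts Qubit mass concentrations and Bioanalyzer mean fragment sizes
into femtomole yields, then computes the per-library volumes that put
equal femtomoles of every library into one pool — the step that equalizes
index representation before sequencing (and the step whose failure gives
one library a wildly disproportionate share of reads).
"""

from pathlib import Path

from spikemix import LibraryYield, pooling_table

OUT = Path("results/pooling")

# representative post-enrichment measurements (concentration ng/uL,
# library volume uL, mean fragment size bp)
LIBRARIES = [
    ("trus_q20", 38.5, 25.0, 380.0),
    ("ct_q20", 0.9, 22.0, 330.0),
    ("tots_q20", 5.6, 20.0, 310.0),
    ("ss_q20", 1.8, 22.0, 450.0),
]
POOL_VOLUME_UL = 20.0


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    yields = [
        LibraryYield(library_id=lid, concentration=c, volume=v, mean_size=s)
        for lid, c, v, s in LIBRARIES
    ]
    table = pooling_table(yields, POOL_VOLUME_UL)
    table.to_csv(OUT / "pooling.tsv", sep="\t")
    print(table.round(3).to_string())
    spread = table["yield_fmol"].max() / table["yield_fmol"].min()
    print(f"\nyields span {spread:.0f}-fold; pooling by inverse molar "
          f"concentration contributes {table['pool_fmol'].iloc[0]:.2f} fmol "
          f"per library into {POOL_VOLUME_UL:.0f} uL")


if __name__ == "__main__":
    main()
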