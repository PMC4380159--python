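"""Library molar yield and equimolar pooling.

A sequencing library's molar yield Y (femtomoles) follows from its mass
concentration C (ng/uL), volume V (uL) and mean fragment size S (bp):

    Y = C * 1e-9 [g/ng] * V * 1e15 [fmol/mol] / 608.9 [g/mol/bp] / S

using 608.9 g/mol per base pair of double-stranded DNA.  Pooling libraries
at volumes inversely proportional to molar concentration equalizes the
fmol (and hence index representation) each library contributes to the
sequencing pool.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: average molar mass of one double-stranded base pair, g/mol
GRAMS_PER_MOLE_PER_BP = 608.9


class YieldError(ValueError):
    pass


@dataclass(frozen=True)
class LibraryYield:
    library_id: str
    concentration: float  # ng/uL
    volume: float  # uL
    mean_size: float  # bp

    def __post_init__(self) -> None:
        if self.mean_size <= 0:
            raise YieldError(f"{self.library_id}: mean_size must be > 0 bp")
        if self.concentration < 0 or self.volume < 0:
            raise YieldError(f"{self.library_id}: concentration and volume must be >= 0")

    @property
    def yield_fmol(self) -> float:
        return molar_yield(self.concentration, self.volume, self.mean_size)

    @property
    def molar_concentration(self) -> float:
        """fmol per uL."""
        return molar_yield(self.concentration, 1.0, self.mean_size)


def molar_yield(concentration: float, volume: float, mean_size: float) -> float:
    """Total yield in femtomoles from C (ng/uL), V (uL) and S (bp).

    Linear in C and V, inversely linear in S.
    """
    if mean_size <= 0:
        raise YieldError(f"mean_size must be > 0 bp, got {mean_size}")
    if concentration < 0 or volume < 0:
        raise YieldError("concentration and volume must be >= 0")
    return concentration * 1e-9 * volume * 1e15 / GRAMS_PER_MOLE_PER_BP / mean_size


def equimolar_pool(
    yields: list[LibraryYield], target_total_volume: float
) -> pd.Series:
    """Per-library volumes (uL) for an equimolar pool of total volume
    ``target_total_volume``.

    Volumes are inversely proportional to each library's molar
    concentration, so every library contributes the same number of
    femtomoles.  Raises (naming the library) if any molar concentration is
    zero.
    """
    if not yields:
        raise YieldError("no libraries to pool")
    if target_total_volume <= 0:
        raise YieldError("target_total_volume must be > 0")
    conc = np.array([y.molar_concentration for y in yields])
    zero = [y.library_id for y, c in zip(yields, conc) if c == 0]
    if zero:
        raise YieldError(f"zero molar concentration for libraries: {zero}")
    volumes = 1.0 / conc
    volumes *= target_total_volume / volumes.sum()
    return pd.Series(volumes, index=[y.library_id for y in yields], name="volume_uL")


def pooling_table(yields: list[LibraryYield], target_total_volume: float) -> pd.DataFrame:
    """Yields and pooling volumes as one table (fmol contributed per
    library is constant by construction)."""
    volumes = equimolar_pool(yields, target_total_volume)
    return pd.DataFrame(
        {
            "concentration_ng_per_uL": [y.concentration for y in yields],
            "volume_uL": [y.volume for y in yields],
            "mean_size_bp": [y.mean_size for y in yields],
            "yield_fmol": [y.yield_fmol for y in yields],
            "pool_volume_uL": volumes.to_numpy(),
            "pool_fmol": volumes.to_numpy() * [y.molar_concentration for y in yields],
        },
        index=pd.Index([y.library_id for y in yields], name="library_id"),
    )
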