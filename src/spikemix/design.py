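"""Mixture designs: the known spike fractions Q_j attached to libraries."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .counts import CountTable, CountTableError, LibraryMeta


@dataclass(frozen=True)
class MixtureDesign:
    """Ordered spike fractions Q_j with protocol/pre-amplification annotations.

    ``q[j]`` is the known fraction of spike-species RNA in library ``j``; it
    is the independent variable of the per-gene linearity analysis.
    """

    library_ids: tuple[str, ...]
    q: np.ndarray
    protocols: tuple[str, ...] = ()
    preamp_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        q = np.asarray(self.q, dtype=float)
        object.__setattr__(self, "q", q)
        if q.shape != (len(self.library_ids),):
            raise CountTableError("one spike fraction per library required")
        if ((q < 0) | (q > 1)).any():
            raise CountTableError("spike fractions must lie in [0, 1]")

    @classmethod
    def from_table(cls, table: CountTable) -> "MixtureDesign":
        return cls.from_libraries(table.libraries)

    @classmethod
    def from_libraries(cls, libraries: list[LibraryMeta]) -> "MixtureDesign":
        return cls(
            library_ids=tuple(m.library_id for m in libraries),
            q=np.array([m.spike_fraction for m in libraries], dtype=float),
            protocols=tuple(m.protocol for m in libraries),
            preamp_ids=tuple(m.preamp_id for m in libraries),
        )

    @property
    def max_q(self) -> float:
        return float(self.q.max()) if len(self.q) else 0.0

    def reference_library(self) -> str:
        """The library with the highest spike fraction (the filter reference)."""
        if self.max_q <= 0:
            raise CountTableError("no library with spike fraction > 0")
        return self.library_ids[int(np.argmax(self.q))]
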