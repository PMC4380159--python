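import numpy as np
import pandas as pd
import pytest

from spikemix import CountTable, LibraryMeta


def make_table(counts: dict[str, list[int]], species: list[str],
               fractions: list[float], genes: list[str] | None = None,
               protocol: str = "toy", preamp: str = "p0") -> CountTable:
    """Build a small CountTable from per-library count lists."""
    n = len(next(iter(counts.values())))
    if genes is None:
        genes = [f"g{i}" for i in range(n)]
    idx = pd.Index(genes, name="gene")
    libs = [
        LibraryMeta(library_id=lib, protocol=protocol, spike_fraction=frac,
                    preamp_id=preamp)
        for lib, frac in zip(counts, fractions)
    ]
    return CountTable(
        counts=pd.DataFrame({k: np.asarray(v, dtype=np.int64) for k, v in counts.items()},
                            index=idx),
        species=pd.Series(species, index=idx, name="species"),
        libraries=libs,
    )


@pytest.fixture
def q4():
    """The four mixture fractions of the main comparison experiment."""
    return (0.0, 0.05, 0.10, 0.20)


@pytest.fixture
def linear_table(q4):
    """Two spike genes responding perfectly linearly to the mixture fraction,
    plus one flat background gene."""
    return make_table(
        counts={
            "L0": [0, 0, 100],
            "L5": [5, 50, 100],
            "L10": [10, 100, 100],
            "L20": [20, 200, 100],
        },
        species=["spike", "spike", "background"],
        fractions=list(q4),
        genes=["Dvir\\a", "Dvir\\b", "Dmel\\c"],
    )


@pytest.fixture
def random_table():
    """A moderately sized random count table with mixed species."""
    rng = np.random.default_rng(42)
    n = 60
    counts = {
        f"L{j}": rng.integers(0, 500, size=n) for j in range(4)
    }
    species = ["spike" if i % 3 else "background" for i in range(n)]
    return make_table(counts, species, [0.0, 0.05, 0.10, 0.20])
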