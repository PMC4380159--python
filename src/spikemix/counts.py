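"""Count-table I/O in the htseq-count dialect, merging, and depth subsampling.

The on-disk unit is the two-column tab-separated file that ``htseq-count``
writes: one ``gene TAB count`` line per gene, with trailing summary counters
whose names start with ``__`` (``__no_feature``, ``__ambiguous``, ...).  In
memory, an experiment is a :class:`CountTable`: an integer gene x library
matrix plus per-gene species labels and per-library metadata (protocol,
spike fraction, pre-amplification batch).

Species are assigned from gene-name prefixes.  Two-genome references built
from FlyBase distinguish species by prefixing gene names (e.g. ``Dvir\\``
for *D. virilis* genes mapped against a *D. melanogaster* background), so
the default rule marks ``Dvir\\``-prefixed genes as the spike species and
everything else as background; both the prefix and explicit per-gene
overrides are configurable.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

SPIKE = "spike"
BACKGROUND = "background"

#: prefix htseq-count uses for its special summary counters
SPECIAL_PREFIX = "__"


class CountTableError(ValueError):
    """Raised for malformed count files or invalid count tables."""


@dataclass(frozen=True)
class PrefixRule:
    """Species assignment by gene-name prefix.

    Parameters
    ----------
    spike_prefix:
        Genes whose identifier starts with this prefix are labelled as the
        spike species; all other genes are background.
    overrides:
        Optional explicit ``gene -> species`` map taking precedence over the
        prefix match; values must be ``"spike"`` or ``"background"``.
    """

    spike_prefix: str = "Dvir\\"
    overrides: Mapping[str, str] = field(default_factory=dict)

    def species_of(self, gene: str) -> str:
        label = self.overrides.get(gene)
        if label is not None:
            if label not in (SPIKE, BACKGROUND):
                raise CountTableError(
                    f"override for {gene!r} must be {SPIKE!r} or {BACKGROUND!r}, got {label!r}"
                )
            return label
        return SPIKE if gene.startswith(self.spike_prefix) else BACKGROUND


@dataclass(frozen=True)
class LibraryMeta:
    """Per-library annotations.

    ``spike_fraction`` is the known mixing fraction Q of spike-species RNA in
    the library (0.20 for a 20% mix).  ``preamp_id`` identifies the shared
    pre-amplification batch; libraries built from the same amplified cDNA
    pool carry the same id.
    """

    library_id: str
    protocol: str = ""
    spike_fraction: float = 0.0
    preamp_id: str = ""
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= float(self.spike_fraction) <= 1.0:
            raise CountTableError(
                f"library {self.library_id!r}: spike_fraction {self.spike_fraction} "
                "outside [0, 1]"
            )


@dataclass
class CountTable:
    """Integer gene x library count matrix with species and library metadata.

    Attributes
    ----------
    counts:
        DataFrame indexed by gene identifier with one column per library id;
        non-negative integers.  Special ``__`` counters are *not* part of
        this matrix.
    species:
        Series aligned to ``counts.index`` with values ``"spike"`` or
        ``"background"``.
    libraries:
        One :class:`LibraryMeta` per column, in column order.
    specials:
        DataFrame of the ``__``-prefixed summary counters (may be empty);
        kept for reporting, excluded from depth and all analysis.
    """

    counts: pd.DataFrame
    species: pd.Series
    libraries: list[LibraryMeta]
    specials: pd.DataFrame = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.specials is None:
            self.specials = pd.DataFrame(
                index=pd.Index([], name="gene"), columns=self.counts.columns, dtype=np.int64
            )
        self.validate()

    # -- invariants -----------------------------------------------------
    def validate(self) -> None:
        cts = self.counts
        if cts.index.has_duplicates:
            dups = cts.index[cts.index.duplicated()].unique().tolist()
            raise CountTableError(f"duplicate gene identifiers: {dups[:5]}")
        if not all(np.issubdtype(d, np.integer) for d in cts.dtypes):
            raise CountTableError("counts must be integers")
        if (cts.to_numpy() < 0).any():
            raise CountTableError("counts must be >= 0")
        lib_ids = [m.library_id for m in self.libraries]
        if lib_ids != list(cts.columns):
            raise CountTableError(
                f"library metadata {lib_ids} does not match columns {list(cts.columns)}"
            )
        if not self.species.index.equals(cts.index):
            raise CountTableError("species labels must cover exactly the gene index")
        bad = set(self.species.unique()) - {SPIKE, BACKGROUND}
        if bad:
            raise CountTableError(f"unknown species labels: {sorted(bad)}")

    # -- convenience ----------------------------------------------------
    @property
    def genes(self) -> pd.Index:
        return self.counts.index

    @property
    def library_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def depths(self) -> pd.Series:
        """Per-library mapped depth: column sums, special counters excluded."""
        return self.counts.sum(axis=0)

    @property
    def spike_fractions(self) -> np.ndarray:
        return np.array([m.spike_fraction for m in self.libraries], dtype=float)

    def spike_genes(self) -> pd.Index:
        return self.genes[self.species.to_numpy() == SPIKE]

    def select_libraries(self, library_ids: Sequence[str]) -> "CountTable":
        """Column subset preserving gene order and metadata."""
        meta = {m.library_id: m for m in self.libraries}
        missing = [l for l in library_ids if l not in meta]
        if missing:
            raise CountTableError(f"unknown libraries: {missing}")
        return CountTable(
            counts=self.counts[list(library_ids)].copy(),
            species=self.species.copy(),
            libraries=[meta[l] for l in library_ids],
            specials=self.specials.reindex(columns=list(library_ids), fill_value=0),
        )


# ---------------------------------------------------------------------------
# Reading and writing the htseq-count dialect
# ---------------------------------------------------------------------------

def _parse_htseq(handle: io.TextIOBase, name: str) -> tuple[dict[str, int], dict[str, int]]:
    genes: dict[str, int] = {}
    specials: dict[str, int] = {}
    for lineno, raw in enumerate(handle, start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise CountTableError(
                f"{name}: line {lineno}: expected 'gene<TAB>count', got {line!r}"
            )
        gene, value = parts[0], parts[1].strip()
        try:
            count = int(value)
        except ValueError:
            raise CountTableError(
                f"{name}: line {lineno}: count {value!r} is not an integer"
            ) from None
        if count < 0:
            raise CountTableError(f"{name}: line {lineno}: negative count {count}")
        target = specials if gene.startswith(SPECIAL_PREFIX) else genes
        if gene in target:
            raise CountTableError(f"{name}: line {lineno}: duplicate gene {gene!r}")
        target[gene] = count
    return genes, specials


def read_counts(
    path: str | Path,
    prefix_rule: PrefixRule | None = None,
    meta: LibraryMeta | None = None,
) -> CountTable:
    """Read one htseq-count file into a single-library :class:`CountTable`.

    Lines whose gene id starts with ``__`` are stored in ``specials`` and
    excluded from the depth.  ``meta`` defaults to a bare record whose
    library id is the file stem.
    """
    prefix_rule = prefix_rule or PrefixRule()
    path = Path(path)
    if meta is None:
        meta = LibraryMeta(library_id=path.stem)
    with open(path) as handle:
        genes, specials = _parse_htseq(handle, str(path))
    idx = pd.Index(list(genes), name="gene")
    counts = pd.DataFrame({meta.library_id: np.array(list(genes.values()), dtype=np.int64)},
                          index=idx)
    species = pd.Series([prefix_rule.species_of(g) for g in idx], index=idx, name="species")
    spec_df = pd.DataFrame(
        {meta.library_id: np.array(list(specials.values()), dtype=np.int64)},
        index=pd.Index(list(specials), name="gene"),
    )
    return CountTable(counts=counts, species=species, libraries=[meta], specials=spec_df)


def write_counts(table: CountTable, directory: str | Path) -> list[Path]:
    """Write one htseq-dialect file per library (``<library_id>.tsv``).

    Special counters are appended after the genes, mirroring htseq-count
    output order.  Returns the paths written.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for lib in table.library_ids:
        p = directory / f"{lib}.tsv"
        with open(p, "w") as out:
            for gene, count in table.counts[lib].items():
                out.write(f"{gene}\t{int(count)}\n")
            if lib in table.specials.columns:
                for gene, count in table.specials[lib].dropna().items():
                    out.write(f"{gene}\t{int(count)}\n")
        paths.append(p)
    return paths


def merge_tables(tables: Sequence[CountTable]) -> CountTable:
    """Merge single- or multi-library tables on the union of genes.

    Genes absent from a library are filled with zero counts (an unobserved
    gene and a zero count are indistinguishable in count files).  Species
    labels must agree wherever genes are shared.
    """
    if not tables:
        raise CountTableError("nothing to merge")
    gene_index = tables[0].genes
    for t in tables[1:]:
        gene_index = gene_index.union(t.genes, sort=False)
    counts = pd.concat(
        [t.counts.reindex(gene_index, fill_value=0) for t in tables], axis=1
    ).astype(np.int64)
    if counts.columns.has_duplicates:
        raise CountTableError(f"duplicate library ids across tables: "
                              f"{counts.columns[counts.columns.duplicated()].tolist()}")
    species = pd.Series(index=gene_index, dtype=object, name="species")
    for t in tables:
        sub = t.species
        known = species.loc[sub.index].dropna()
        clash = known[known != sub.loc[known.index]]
        if len(clash):
            raise CountTableError(f"conflicting species labels for {clash.index.tolist()[:5]}")
        species.loc[sub.index] = sub
    specials = pd.concat(
        [t.specials.reindex(columns=t.library_ids) for t in tables], axis=1
    )
    specials = specials.fillna(0).astype(np.int64)
    libraries = [m for t in tables for m in t.libraries]
    return CountTable(counts=counts, species=species, libraries=libraries, specials=specials)


# ---------------------------------------------------------------------------
# Design tables
# ---------------------------------------------------------------------------

DESIGN_COLUMNS = ["library_id", "path", "protocol", "spike_fraction", "preamp_id"]


def read_design(path: str | Path) -> pd.DataFrame:
    """Read a design CSV with columns library_id, path, protocol, spike_fraction, preamp_id."""
    design = pd.read_csv(path, dtype={"library_id": str, "protocol": str, "preamp_id": str})
    missing = [c for c in DESIGN_COLUMNS if c not in design.columns]
    if missing:
        raise CountTableError(f"design table missing columns: {missing}")
    if design["library_id"].duplicated().any():
        raise CountTableError("design table has duplicate library_id values")
    return design


def load_experiment(design_path: str | Path, prefix_rule: PrefixRule | None = None) -> CountTable:
    """Load and merge all libraries listed in a design CSV.

    Count-file paths are resolved relative to the design file's directory.
    """
    design_path = Path(design_path)
    design = read_design(design_path)
    tables = []
    for row in design.itertuples(index=False):
        meta = LibraryMeta(
            library_id=str(row.library_id),
            protocol=str(row.protocol),
            spike_fraction=float(row.spike_fraction),
            preamp_id=str(row.preamp_id),
        )
        count_path = Path(row.path)
        if not count_path.is_absolute():
            count_path = design_path.parent / count_path
        tables.append(read_counts(count_path, prefix_rule, meta))
    return merge_tables(tables)


# ---------------------------------------------------------------------------
# Equal-depth subsampling
# ---------------------------------------------------------------------------

def subsample_counts(table: CountTable, target_depth: int, seed: int) -> CountTable:
    """Subsample every library to exactly ``target_depth`` mapped fragments.

    Reads are drawn without replacement from each library's counted
    fragments — a multivariate hypergeometric draw on the count vector,
    statistically equivalent to uniformly subsampling mapped reads before
    counting.  Column sums of the result equal ``target_depth`` exactly and
    no gene's count can exceed its original count.
    """
    if target_depth < 0:
        raise CountTableError(f"target_depth must be >= 0, got {target_depth}")
    depths = table.depths
    short = depths[depths < target_depth]
    if len(short):
        raise CountTableError(
            "target_depth %d exceeds depth of libraries: %s"
            % (target_depth, ", ".join(f"{l}={d}" for l, d in short.items()))
        )
    rng = np.random.default_rng(seed)
    out = {}
    for lib in table.library_ids:
        col = table.counts[lib].to_numpy(dtype=np.int64)
        if target_depth == int(depths[lib]):
            out[lib] = col.copy()
        else:
            out[lib] = rng.multivariate_hypergeometric(col, target_depth, method="marginals")
    counts = pd.DataFrame(out, index=table.genes).astype(np.int64)
    libraries = [replace(m, seed=seed) for m in table.libraries]
    return CountTable(
        counts=counts,
        species=table.species.copy(),
        libraries=libraries,
        specials=table.specials.copy(),
    )
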