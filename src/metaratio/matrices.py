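"""Pivoting filtered annotation records into taxon-by-function count matrices.

All downstream statistics (activity ratios, richness, rarefaction, the
co-occurrence network) are computed from :class:`TaxonFunctionMatrix`, a
count matrix of reads per (taxon at a chosen rank, function label) for one
library.  Eukaryotic records are dropped at this stage (prokaryote-targeted
gene calling makes their annotations unreliable) and the number dropped is
recorded on the matrix.

Composition tables report the relative abundance of taxa at a rank, with
rare labels grouped into an ``"other"`` bucket for presentation only; the
matrices used for statistics are never grouped.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import pandas as pd

from .annotation import Library
from .catalog import GeneCatalog

__all__ = [
    "MATRIX_RANKS",
    "TaxonFunctionMatrix",
    "CompositionTable",
    "build_matrix",
    "composition_by_rank",
    "aggregate_to_pathway",
]

logger = logging.getLogger(__name__)

MATRIX_RANKS = ("phylum", "genus", "species")

UNMAPPED = "unmapped"


@dataclass
class TaxonFunctionMatrix:
    """Read counts per (taxon, function) for one library.

    ``counts`` is a pandas DataFrame with taxa as the index and function (or
    pathway) labels as columns; integer, non-negative.
    """

    rank: str
    counts: pd.DataFrame
    library_id: str
    molecule: str
    n_dropped_eukaryota: int = 0
    axis: str = "function"  # "function" or "pathway"

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")
        if self.counts.index.has_duplicates or self.counts.columns.has_duplicates:
            raise ValueError("duplicate taxon or function labels")

    @property
    def taxa(self) -> list[str]:
        return list(self.counts.index)

    @property
    def functions(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def total(self) -> int:
        return int(self.counts.values.sum())

    def function_total(self, label: str) -> int:
        if label not in self.counts.columns:
            return 0
        return int(self.counts[label].sum())

    def to_wide_tsv(self, path) -> None:
        df = self.counts.copy()
        df.index.name = self.rank
        df.sort_index().sort_index(axis=1).to_csv(path, sep="\t")

    def to_long_tsv(self, path) -> None:
        long = (
            self.counts.stack()
            .rename("count")
            .reset_index()
            .set_axis([self.rank, self.axis, "count"], axis=1)
        )
        long = long[long["count"] > 0].sort_values([self.rank, self.axis])
        long.to_csv(path, sep="\t", index=False)


@dataclass
class CompositionTable:
    """Relative abundances at one rank, rare labels grouped into 'other'."""

    rank: str
    fractions: dict[str, float] = field(default_factory=dict)
    library_id: str = ""
    molecule: str = ""

    def __post_init__(self) -> None:
        total = sum(self.fractions.values())
        if self.fractions and abs(total - 1.0) > 1e-9:
            raise ValueError(f"fractions sum to {total}, expected 1")
        if any(not (0.0 <= f <= 1.0) for f in self.fractions.values()):
            raise ValueError("fractions must lie in [0, 1]")

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"{self.rank}\tfraction\n")
            for label, frac in sorted(self.fractions.items(), key=lambda kv: (-kv[1], kv[0])):
                fh.write(f"{label}\t{frac:.6f}\n")


def build_matrix(lib: Library, rank: str = "species") -> TaxonFunctionMatrix:
    """Tally reads per (taxon at ``rank``, function label).

    Expects a filtered, best-hit-resolved library.  Records with domain
    Eukaryota are dropped (count logged and stored on the matrix); records
    missing the rank land in their explicit ``unclassified_*`` label.
    """
    if rank not in MATRIX_RANKS:
        raise ValueError(f"rank must be one of {MATRIX_RANKS}, got {rank!r}")
    tally: Counter[tuple[str, str]] = Counter()
    n_euk = 0
    for rec in lib.records:
        if rec.lineage[0].lower() == "eukaryota":
            n_euk += 1
            continue
        tally[(rec.rank_label(rank), rec.function_label)] += 1
    if n_euk:
        logger.info("dropped %d eukaryotic records from %s", n_euk, lib.library_id)
    if tally:
        ser = pd.Series(tally, dtype="int64")
        ser.index = pd.MultiIndex.from_tuples(ser.index)
        counts = ser.unstack(fill_value=0).astype("int64")
        counts = counts.sort_index().sort_index(axis=1)
    else:
        counts = pd.DataFrame(dtype="int64")
    return TaxonFunctionMatrix(
        rank=rank,
        counts=counts,
        library_id=lib.library_id,
        molecule=lib.molecule,
        n_dropped_eukaryota=n_euk,
    )


def composition_by_rank(
    lib: Library,
    rank: str = "phylum",
    other_threshold: float = 0.01,
    *,
    drop_eukaryota: bool = True,
) -> CompositionTable:
    """Relative abundance of taxa at ``rank``; labels under ``other_threshold``
    are merged into ``"other"``."""
    labels = [
        rec.rank_label(rank)
        for rec in lib.records
        if not (drop_eukaryota and rec.lineage[0].lower() == "eukaryota")
    ]
    if not labels:
        raise ValueError(f"library {lib.library_id} has no usable records")
    n = len(labels)
    fractions: dict[str, float] = {}
    other = 0.0
    for label, count in Counter(labels).items():
        frac = count / n
        if frac < other_threshold:
            other += frac
        else:
            fractions[label] = frac
    if other > 0:
        fractions["other"] = fractions.get("other", 0.0) + other
    return CompositionTable(
        rank=rank, fractions=fractions, library_id=lib.library_id, molecule=lib.molecule
    )


def aggregate_to_pathway(
    m: TaxonFunctionMatrix, catalog: GeneCatalog
) -> TaxonFunctionMatrix:
    """Replace the function axis by the catalog's pathway axis, summing counts.

    Functions without a catalog pathway are collected under ``"unmapped"``
    (stress genes are therefore "unmapped" here by design) so total counts
    are conserved.
    """
    if m.counts.empty:
        return TaxonFunctionMatrix(
            rank=m.rank,
            counts=m.counts.copy(),
            library_id=m.library_id,
            molecule=m.molecule,
            n_dropped_eukaryota=m.n_dropped_eukaryota,
            axis="pathway",
        )
    mapping = {f: (catalog.pathway_of(f) or UNMAPPED) for f in m.counts.columns}
    agg = m.counts.T.groupby(m.counts.columns.map(mapping)).sum().T
    agg = agg.sort_index().sort_index(axis=1).astype("int64")
    return TaxonFunctionMatrix(
        rank=m.rank,
        counts=agg,
        library_id=m.library_id,
        molecule=m.molecule,
        n_dropped_eukaryota=m.n_dropped_eukaryota,
        axis="pathway",
    )
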