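"""Reading, validating, filtering and summarizing read annotation tables.

The entry point of the whole analysis is a tab-delimited table with one row
per read annotation: read identifier, library, molecule (DNA or RNA), a
seven-rank taxonomic lineage, a function label, and the alignment quality
scores (bit score, E-value, alignment length in amino acids).  Two dialects
are supported: an MG-RAST-export-like layout that carries every field
explicitly, and the 12-column BLAST tabular layout plus a sidecar mapping
from subject id to lineage and function.

Quality filtering follows the conventional annotation cut-offs for shotgun
meta-omics: bit score >= 50, E-value <= 1e-5 and alignment length >= 15
amino acids, all boundaries inclusive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import IO, Iterable, Mapping, Sequence

__all__ = [
    "RANKS",
    "MOLECULES",
    "AnnotationRecord",
    "FilterCriteria",
    "Library",
    "LibrarySummary",
    "normalize_lineage",
    "parse_annotation_table",
    "apply_quality_filters",
    "best_hit_per_read",
    "summarize_library",
    "write_library_summary",
]

#: Fixed rank order for taxonomic lineages.
RANKS = ("domain", "phylum", "class", "order", "family", "genus", "species")

#: Legal molecule labels for a library.
MOLECULES = frozenset({"DNA", "RNA"})


class AnnotationError(ValueError):
    """Raised on malformed annotation input."""


def normalize_lineage(ranks: Sequence[str]) -> tuple[str, ...]:
    """Return a full seven-rank lineage with missing ranks made explicit.

    A rank that is empty (or whitespace, or a literal ``-``) is replaced by
    ``"unclassified_<nearest resolved parent>"`` so that aggregating at any
    rank never silently drops reads.  A completely unresolved lineage hangs
    off ``unclassified_root``.
    """
    if len(ranks) > len(RANKS):
        raise AnnotationError(f"lineage has {len(ranks)} ranks, at most {len(RANKS)} allowed")
    padded = list(ranks) + [""] * (len(RANKS) - len(ranks))
    out: list[str] = []
    parent = "root"
    for label in padded:
        label = label.strip()
        if not label or label == "-":
            label = f"unclassified_{parent}"
        else:
            parent = label
        out.append(label)
    return tuple(out)


@dataclass(slots=True)
class AnnotationRecord:
    """One read's taxonomy + function assignment with quality scores."""

    read_id: str
    library_id: str
    molecule: str
    lineage: tuple[str, ...]
    function_label: str
    bit_score: float
    e_value: float
    align_len_aa: int
    read_len_bp: int | None = None

    def __post_init__(self) -> None:
        if self.molecule not in MOLECULES:
            raise AnnotationError(f"molecule must be DNA or RNA, got {self.molecule!r}")
        if len(self.lineage) != len(RANKS):
            self.lineage = normalize_lineage(self.lineage)
        if self.bit_score < 0 or self.e_value < 0 or self.align_len_aa < 0:
            raise AnnotationError(
                f"negative quality score on read {self.read_id!r}: "
                f"bit={self.bit_score}, e={self.e_value}, aln={self.align_len_aa}"
            )

    def rank_label(self, rank: str) -> str:
        """Taxon label at ``rank``; species as a binomial 'genus species' string."""
        i = RANKS.index(rank)
        if rank == "species":
            genus = self.lineage[RANKS.index("genus")]
            species = self.lineage[i]
            if species.startswith("unclassified_"):
                return f"{genus} sp."
            if species.startswith(genus + " "):
                return species
            return f"{genus} {species}"
        return self.lineage[i]


@dataclass(frozen=True)
class FilterCriteria:
    """Annotation quality cut-offs; every boundary is inclusive."""

    min_bit_score: float = 50.0
    max_e_value: float = 1e-5
    min_align_aa: int = 15

    def __post_init__(self) -> None:
        for v in (self.min_bit_score, self.max_e_value, self.min_align_aa):
            if not math.isfinite(v):
                raise AnnotationError("filter thresholds must be finite")
        if self.min_align_aa < 0:
            raise AnnotationError("min_align_aa must be >= 0")

    def passes(self, rec: AnnotationRecord) -> bool:
        return (
            rec.bit_score >= self.min_bit_score
            and rec.e_value <= self.max_e_value
            and rec.align_len_aa >= self.min_align_aa
        )


@dataclass(slots=True)
class Library:
    """An ordered collection of annotation records from one sequencing library."""

    library_id: str
    molecule: str
    records: list[AnnotationRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.molecule not in MOLECULES:
            raise AnnotationError(f"molecule must be DNA or RNA, got {self.molecule!r}")
        for rec in self.records:
            if rec.library_id != self.library_id or rec.molecule != self.molecule:
                raise AnnotationError(
                    f"record {rec.read_id!r} ({rec.library_id}, {rec.molecule}) does not "
                    f"belong to library ({self.library_id}, {self.molecule})"
                )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)


@dataclass(frozen=True)
class LibrarySummary:
    """Per-library descriptive statistics (read counts, lengths, annotation rate)."""

    library_id: str
    n_reads: int
    n_annotated: int
    pct_annotated: float
    mean_len_bp: float | None = None
    sd_len_bp: float | None = None
    total_bp: int | None = None


# ---------------------------------------------------------------------------
# Parsing

_MGRAST_COLUMNS = (
    "read_id",
    "library_id",
    "molecule",
    *RANKS,
    "function_label",
    "bit_score",
    "e_value",
    "align_len_aa",
    "read_len_bp",
)


def _parse_float(text: str, what: str, lineno: int) -> float:
    try:
        return float(text)
    except ValueError:
        raise AnnotationError(f"line {lineno}: cannot parse {what} from {text!r}") from None


def _parse_int(text: str, what: str, lineno: int) -> int:
    try:
        return int(float(text))
    except ValueError:
        raise AnnotationError(f"line {lineno}: cannot parse {what} from {text!r}") from None


def parse_annotation_table(
    stream: IO[str] | Iterable[str],
    dialect: str = "mgrast_tsv",
    *,
    library_id: str | None = None,
    molecule: str | None = None,
    sidecar: Mapping[str, tuple[Sequence[str], str]] | None = None,
) -> Library:
    """Parse a tab-delimited annotation table into a :class:`Library`.

    Parameters
    ----------
    stream
        Text stream (or iterable of lines).  A first line starting with
        ``#`` is treated as a header and skipped.
    dialect
        ``"mgrast_tsv"``: columns read_id, library_id, molecule, the seven
        lineage ranks, function_label, bit_score, e_value, align_len_aa and
        an optional read_len_bp.
        ``"blast_tab"``: the 12-column BLAST tabular layout (qseqid sseqid
        pident length mismatch gapopen qstart qend sstart send evalue
        bitscore); requires ``library_id``, ``molecule`` and ``sidecar``
        (sseqid -> (lineage ranks, function label)).  The length column is
        interpreted as amino acids.

    Raises
    ------
    AnnotationError
        On a malformed row (with its line number) or when a file mixes DNA
        and RNA rows.
    """
    if dialect not in ("mgrast_tsv", "blast_tab"):
        raise AnnotationError(f"unknown dialect {dialect!r}")
    if dialect == "blast_tab":
        if library_id is None or molecule is None or sidecar is None:
            raise AnnotationError("blast_tab dialect requires library_id, molecule and sidecar")

    records: list[AnnotationRecord] = []
    lib_id: str | None = library_id
    mol: str | None = molecule

    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n").rstrip("\r")
        if not line.strip():
            continue
        if line.startswith("#"):
            continue
        fields = line.split("\t")
        if dialect == "mgrast_tsv":
            if len(fields) not in (len(_MGRAST_COLUMNS) - 1, len(_MGRAST_COLUMNS)):
                raise AnnotationError(
                    f"line {lineno}: expected {len(_MGRAST_COLUMNS) - 1} or "
                    f"{len(_MGRAST_COLUMNS)} columns, got {len(fields)}"
                )
            row_mol = fields[2].strip()
            if row_mol not in MOLECULES:
                raise AnnotationError(f"line {lineno}: molecule must be DNA or RNA, got {row_mol!r}")
            rec = AnnotationRecord(
                read_id=fields[0],
                library_id=fields[1],
                molecule=row_mol,
                lineage=normalize_lineage(fields[3:10]),
                function_label=fields[10],
                bit_score=_parse_float(fields[11], "bit_score", lineno),
                e_value=_parse_float(fields[12], "e_value", lineno),
                align_len_aa=_parse_int(fields[13], "align_len_aa", lineno),
                read_len_bp=(
                    _parse_int(fields[14], "read_len_bp", lineno)
                    if len(fields) == len(_MGRAST_COLUMNS) and fields[14].strip()
                    else None
                ),
            )
        else:  # blast_tab
            if len(fields) != 12:
                raise AnnotationError(f"line {lineno}: expected 12 columns, got {len(fields)}")
            sseqid = fields[1]
            if sseqid not in sidecar:  # type: ignore[operator]
                raise AnnotationError(f"line {lineno}: subject {sseqid!r} missing from sidecar")
            lineage, function_label = sidecar[sseqid]  # type: ignore[index]
            rec = AnnotationRecord(
                read_id=fields[0],
                library_id=lib_id,  # type: ignore[arg-type]
                molecule=mol,  # type: ignore[arg-type]
                lineage=normalize_lineage(lineage),
                function_label=function_label,
                bit_score=_parse_float(fields[11], "bit_score", lineno),
                e_value=_parse_float(fields[10], "e_value", lineno),
                align_len_aa=_parse_int(fields[3], "align_len_aa", lineno),
            )
        if lib_id is None:
            lib_id = rec.library_id
        if mol is None:
            mol = rec.molecule
        if rec.molecule != mol:
            raise AnnotationError(
                f"line {lineno}: molecule {rec.molecule} conflicts with {mol}; "
                "files mixing DNA and RNA rows are rejected"
            )
        if rec.library_id != lib_id:
            raise AnnotationError(
                f"line {lineno}: library {rec.library_id!r} conflicts with {lib_id!r}"
            )
        records.append(rec)

    if lib_id is None:  # empty table and no override: identity unknown but legal
        lib_id = "unknown"
    return Library(library_id=lib_id, molecule=mol or "DNA", records=records)


# ---------------------------------------------------------------------------
# Filtering and best-hit resolution


def apply_quality_filters(lib: Library, crit: FilterCriteria | None = None) -> Library:
    """Retain records meeting all three quality cut-offs (boundaries inclusive).

    The input library is left unmodified and record order is preserved.
    """
    crit = crit or FilterCriteria()
    kept = [rec for rec in lib.records if crit.passes(rec)]
    return Library(lib.library_id, lib.molecule, kept)


def best_hit_per_read(lib: Library) -> Library:
    """Resolve multiple annotations per read to a single deterministic best hit.

    Highest bit score wins; ties broken by lowest E-value, then by the
    lexicographically smallest (function label, joined lineage) pair, so the
    result is independent of input row order.  Output rows are ordered by
    first appearance of each read id.
    """
    best: dict[str, AnnotationRecord] = {}
    for rec in lib.records:
        cur = best.get(rec.read_id)
        if cur is None:
            best[rec.read_id] = rec
            continue
        new_key = (-rec.bit_score, rec.e_value, rec.function_label, "|".join(rec.lineage))
        cur_key = (-cur.bit_score, cur.e_value, cur.function_label, "|".join(cur.lineage))
        if new_key < cur_key:
            best[rec.read_id] = rec
    return Library(lib.library_id, lib.molecule, list(best.values()))


# ---------------------------------------------------------------------------
# Summaries


def summarize_library(
    lib: Library,
    n_total_reads: int,
    read_lengths: Sequence[int] | None = None,
) -> LibrarySummary:
    """Descriptive statistics for one library.

    ``n_total_reads`` is the sequencing depth of the library (annotated reads
    are a subset of it); ``read_lengths`` optionally provides per-read
    lengths in bp from which mean/sd/total are computed.
    """
    if n_total_reads <= 0:
        raise AnnotationError("n_total_reads must be positive")
    n_annotated = len({rec.read_id for rec in lib.records})
    if n_annotated > n_total_reads:
        raise AnnotationError(
            f"{n_annotated} annotated reads exceed the stated total of {n_total_reads}"
        )
    mean_len = sd_len = total = None
    if read_lengths is not None and len(read_lengths) > 0:
        n = len(read_lengths)
        total = int(sum(read_lengths))
        mean_len = total / n
        sd_len = math.sqrt(sum((x - mean_len) ** 2 for x in read_lengths) / n) if n > 1 else 0.0
    return LibrarySummary(
        library_id=lib.library_id,
        n_reads=n_total_reads,
        n_annotated=n_annotated,
        pct_annotated=100.0 * n_annotated / n_total_reads,
        mean_len_bp=mean_len,
        sd_len_bp=sd_len,
        total_bp=total,
    )


def mean_length_from_totals(total_bp: float, n_reads: int) -> float:
    """Mean read length implied by a printed total-bp and read count."""
    if n_reads <= 0:
        raise AnnotationError("n_reads must be positive")
    return total_bp / n_reads


def write_library_summary(summaries: Sequence[LibrarySummary], path) -> None:
    """Write summaries as a TSV with one row per statistic, one column per library."""
    rows = [
        ("Number of reads", lambda s: s.n_reads),
        ("Mean sequence length (bp)", lambda s: _fmt(s.mean_len_bp)),
        ("SD sequence length (bp)", lambda s: _fmt(s.sd_len_bp)),
        ("Total bp", lambda s: _fmt(s.total_bp)),
        ("Annotated reads", lambda s: s.n_annotated),
        ("% annotated reads", lambda s: f"{s.pct_annotated:.1f}"),
    ]
    with open(path, "w") as fh:
        fh.write("Statistic\t" + "\t".join(s.library_id for s in summaries) + "\n")
        for label, getter in rows:
            fh.write(label + "\t" + "\t".join(str(getter(s)) for s in summaries) + "\n")


def _fmt(v) -> str:
    if v is None:
        return "NA"
    if isinstance(v, float):
        return f"{v:.1f}"
    return str(v)
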