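"""RNA:DNA activity ratios for taxa, genes and pathways.

A feature's relative transcriptional activity is estimated as the ratio of
its fraction of annotated RNA reads to its fraction of annotated DNA reads.
Fractions (not raw counts) make the ratio comparable across libraries of
very different depth.  A ratio with a zero DNA fraction is reported as
undefined rather than smoothed; optional +0.5 pseudocount smoothing exists
as an explicit flag and is always labelled in output.  Low-support features
(few reads on either side) are annotated, never filtered: a handful of reads
can swing a ratio wildly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from .catalog import GeneCatalog
from .matrices import TaxonFunctionMatrix, aggregate_to_pathway

__all__ = [
    "ActivityRatio",
    "rna_dna_ratio",
    "fold_activity",
    "pathway_activity_report",
    "write_activity_report",
]

DEFAULT_SUPPORT_THRESHOLD = 10


@dataclass(frozen=True)
class ActivityRatio:
    """Library-size-normalized RNA:DNA ratio for one feature."""

    feature: str
    rna_count: int
    dna_count: int
    rna_frac: float
    dna_frac: float
    ratio: float | None
    defined: bool
    low_support: bool
    smoothed: bool = False
    cycle: str | None = None


def _feature_counts(m: TaxonFunctionMatrix, feature: str, on: str) -> int:
    if on == "taxon":
        if feature not in m.counts.index:
            return 0
        return int(m.counts.loc[feature].sum())
    return m.function_total(feature)


def rna_dna_ratio(
    dna: TaxonFunctionMatrix,
    rna: TaxonFunctionMatrix,
    feature: str,
    *,
    on: str = "function",
    support_threshold: int = DEFAULT_SUPPORT_THRESHOLD,
    smooth: bool = False,
) -> ActivityRatio:
    """RNA:DNA ratio of one feature (a taxon, gene or pathway label).

    ``on`` selects which matrix axis the feature lives on (``"taxon"`` or
    ``"function"``).  With ``smooth=True`` a +0.5 pseudocount is added to
    both counts; the result is labelled ``smoothed``.
    """
    if on not in ("taxon", "function"):
        raise ValueError("on must be 'taxon' or 'function'")
    axis_labels = (
        set(dna.counts.index) | set(rna.counts.index)
        if on == "taxon"
        else set(dna.counts.columns) | set(rna.counts.columns)
    )
    if feature not in axis_labels:
        raise KeyError(f"feature {feature!r} absent from both matrices")
    dna_count = _feature_counts(dna, feature, on)
    rna_count = _feature_counts(rna, feature, on)
    dna_total, rna_total = dna.total, rna.total
    dc = dna_count + 0.5 if smooth else dna_count
    rc = rna_count + 0.5 if smooth else rna_count
    dna_frac = dc / dna_total if dna_total else 0.0
    rna_frac = rc / rna_total if rna_total else 0.0
    defined = dna_frac > 0
    return ActivityRatio(
        feature=feature,
        rna_count=rna_count,
        dna_count=dna_count,
        rna_frac=rna_frac,
        dna_frac=dna_frac,
        ratio=(rna_frac / dna_frac) if defined else None,
        defined=defined,
        low_support=min(rna_count, dna_count) < support_threshold,
        smoothed=smooth,
    )


def fold_activity(a: ActivityRatio, b: ActivityRatio) -> float:
    """How many fold more active feature ``a`` is than feature ``b``."""
    if not (a.defined and b.defined):
        raise ValueError("fold activity requires two defined ratios")
    if b.ratio == 0:
        raise ValueError(f"feature {b.feature!r} has ratio 0; fold activity undefined")
    return a.ratio / b.ratio


def pathway_activity_report(
    dna: TaxonFunctionMatrix,
    rna: TaxonFunctionMatrix,
    catalog: GeneCatalog,
    *,
    support_threshold: int = DEFAULT_SUPPORT_THRESHOLD,
    smooth: bool = False,
) -> list[ActivityRatio]:
    """One :class:`ActivityRatio` per catalog pathway, sorted by cycle then pathway.

    Matrices on the gene axis are aggregated to pathways first.  Pathways
    absent from both libraries appear with zero counts and an undefined
    ratio; pathways with fewer than ``support_threshold`` reads on either
    side are flagged ``low_support``.
    """
    if dna.axis != "pathway":
        dna = aggregate_to_pathway(dna, catalog)
    if rna.axis != "pathway":
        rna = aggregate_to_pathway(rna, catalog)
    out: list[ActivityRatio] = []
    for cycle, pathway in sorted(catalog.pathways):
        dna_count = dna.function_total(pathway)
        rna_count = rna.function_total(pathway)
        dc = dna_count + 0.5 if smooth else dna_count
        rc = rna_count + 0.5 if smooth else rna_count
        dna_frac = dc / dna.total if dna.total else 0.0
        rna_frac = rc / rna.total if rna.total else 0.0
        defined = dna_frac > 0
        out.append(
            ActivityRatio(
                feature=pathway,
                rna_count=rna_count,
                dna_count=dna_count,
                rna_frac=rna_frac,
                dna_frac=dna_frac,
                ratio=(rna_frac / dna_frac) if defined else None,
                defined=defined,
                low_support=min(rna_count, dna_count) < support_threshold,
                smoothed=smooth,
                cycle=cycle,
            )
        )
    return out


def write_activity_report(ratios: Iterable[ActivityRatio], path, *, site: str = "") -> None:
    """Write ratios as TSV: site, cycle, feature, dna_pct, rna_pct, ratio, flags."""
    with open(path, "w") as fh:
        fh.write(
            "site\tcycle\tfeature\tdna_count\trna_count\tdna_pct\trna_pct\t"
            "ratio\tdefined\tlow_support\tsmoothed\n"
        )
        for r in ratios:
            ratio_str = f"{r.ratio:.6g}" if r.defined else "NA"
            fh.write(
                f"{site}\t{r.cycle or ''}\t{r.feature}\t{r.dna_count}\t{r.rna_count}\t"
                f"{100 * r.dna_frac:.4f}\t{100 * r.rna_frac:.4f}\t{ratio_str}\t"
                f"{r.defined}\t{r.low_support}\t{r.smoothed}\n"
            )
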