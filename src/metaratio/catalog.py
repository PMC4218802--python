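"""Gene catalog: key functional genes mapped to pathways, plus stress markers.

The catalog is the single source of truth for which function labels count as
carbon/nitrogen-cycle genes (and which pathway each diagnoses) and which
count as stress-response genes (UV, osmotic or oxidative).  Label matching is
case-insensitive after whitespace normalization; synonyms belong in the
catalog file, not in the matcher.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import yaml

__all__ = ["FunctionalGene", "StressGene", "GeneCatalog", "load_catalog", "default_catalog"]

CYCLES = ("carbon", "nitrogen")
STRESS_CATEGORIES = ("UV", "osmotic", "oxidative")


def _norm(label: str) -> str:
    return " ".join(label.split()).lower()


@dataclass(frozen=True)
class FunctionalGene:
    name: str
    cycle: str
    pathway: str


@dataclass(frozen=True)
class StressGene:
    name: str
    category: str


@dataclass(frozen=True)
class GeneCatalog:
    """Carbon/nitrogen functional-gene catalog plus stress-gene catalog."""

    functional_genes: tuple[FunctionalGene, ...]
    stress_genes: tuple[StressGene, ...]
    _functional_by_norm: dict = field(default_factory=dict, repr=False, compare=False)
    _stress_by_norm: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        names = [g.name for g in self.functional_genes] + [s.name for s in self.stress_genes]
        norms = [_norm(n) for n in names]
        if len(set(norms)) != len(norms):
            raise ValueError("gene names must be unique across functional and stress lists")
        for g in self.functional_genes:
            if g.cycle not in CYCLES:
                raise ValueError(f"unknown cycle {g.cycle!r} for {g.name!r}")
            if not g.pathway:
                raise ValueError(f"functional gene {g.name!r} lacks a pathway")
            self._functional_by_norm[_norm(g.name)] = g
        for s in self.stress_genes:
            if s.category not in STRESS_CATEGORIES:
                raise ValueError(f"unknown stress category {s.category!r} for {s.name!r}")
            self._stress_by_norm[_norm(s.name)] = s

    # -- lookups -----------------------------------------------------------
    def functional(self, label: str) -> FunctionalGene | None:
        return self._functional_by_norm.get(_norm(label))

    def stress(self, label: str) -> StressGene | None:
        return self._stress_by_norm.get(_norm(label))

    def is_functional(self, label: str) -> bool:
        return self.functional(label) is not None

    def is_stress(self, label: str) -> bool:
        return self.stress(label) is not None

    def pathway_of(self, label: str) -> str | None:
        g = self.functional(label)
        return g.pathway if g else None

    @property
    def pathways(self) -> tuple[tuple[str, str], ...]:
        """Unique (cycle, pathway) pairs in catalog order."""
        seen: dict[tuple[str, str], None] = {}
        for g in self.functional_genes:
            seen.setdefault((g.cycle, g.pathway))
        return tuple(seen)

    @property
    def all_gene_names(self) -> tuple[str, ...]:
        return tuple(g.name for g in self.functional_genes) + tuple(
            s.name for s in self.stress_genes
        )

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("name\trole\tcycle_or_category\tpathway\n")
            for g in self.functional_genes:
                fh.write(f"{g.name}\tfunctional\t{g.cycle}\t{g.pathway}\n")
            for s in self.stress_genes:
                fh.write(f"{s.name}\tstress\t{s.category}\t\n")


def _from_mapping(doc: dict) -> GeneCatalog:
    return GeneCatalog(
        functional_genes=tuple(
            FunctionalGene(d["name"], d["cycle"], d["pathway"])
            for d in doc.get("functional_genes", [])
        ),
        stress_genes=tuple(
            StressGene(d["name"], d["category"]) for d in doc.get("stress_genes", [])
        ),
    )


def load_catalog(path) -> GeneCatalog:
    """Load a catalog from a YAML (or JSON — YAML superset) file."""
    with open(path) as fh:
        return _from_mapping(yaml.safe_load(fh))


def default_catalog() -> GeneCatalog:
    """The packaged default carbon/nitrogen + stress catalog."""
    ref = importlib.resources.files("metaratio").joinpath("data/default_catalog.yaml")
    return _from_mapping(yaml.safe_load(ref.read_text()))
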