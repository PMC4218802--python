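"""Synthetic paired DNA/RNA annotation libraries from a known community.

The generator emulates what a taxonomy+function annotation pipeline would
emit for a community whose structure we control, so every downstream stage
can be tested against ground truth.  The model:

* Taxon relative abundances ``p_t`` are drawn lognormal and normalized —
  the classic skewed species-abundance distribution.
* Each taxon carries a gene repertoire drawn by per-gene inclusion
  probabilities from the functional + stress catalog; every taxon keeps at
  least one functional gene.
* A DNA read lands on (taxon t, gene g in its repertoire) with probability
  proportional to ``p_t``; an RNA read with probability proportional to
  ``p_t * alpha_t * e_g`` where ``alpha_t`` is a per-taxon activity
  multiplier and ``e_g`` a per-gene expression weight.  Activity therefore
  factorizes into "how active the organism is" and "how expressed the gene
  is", which is what RNA:DNA ratios are meant to resolve.
* Read depths are multinomial, so requested library sizes are hit exactly.
* A ``noise`` fraction of rows receives quality scores that fail exactly one
  of the three annotation filters; all other rows pass all three.

No nucleotide sequences are generated and no read-error realism is
attempted; the unit of simulation is the annotated read.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .annotation import AnnotationRecord, Library, normalize_lineage
from .catalog import GeneCatalog, default_catalog

__all__ = [
    "CommunitySpec",
    "Taxon",
    "Community",
    "GroundTruth",
    "sample_community",
    "simulate_libraries",
    "simulate_paired_libraries",
    "write_ground_truth_json",
    "write_library_tsv",
]

DEFAULT_PHYLA = (
    "Cyanobacteria",
    "Proteobacteria",
    "Actinobacteria",
    "Bacteroidetes",
    "Planctomycetes",
    "Verrucomicrobia",
    "Firmicutes",
)

# Quality-score sampling ranges for rows meant to pass all three filters.
GOOD_BIT = (50.0, 300.0)
GOOD_LOG10_E = (-30.0, -5.0)
GOOD_ALN = (15, 80)


@dataclass(frozen=True)
class CommunitySpec:
    """Parameters of the simulated community.

    ``abundance_mu``/``abundance_sigma`` parameterize the lognormal abundance
    model; ``activity_sigma`` is the lognormal spread of the per-taxon
    activity multipliers drawn when none are given explicitly.  Per-gene
    inclusion probabilities default to ``functional_inclusion`` /
    ``stress_inclusion`` and can be overridden per gene.
    """

    n_taxa: int = 50
    abundance_mu: float = 0.0
    abundance_sigma: float = 1.0
    activity_multipliers: tuple[float, ...] | None = None
    activity_sigma: float = 0.5
    functional_inclusion: float = 0.35
    stress_inclusion: float = 0.30
    inclusion_overrides: dict[str, float] = field(default_factory=dict)
    expression_weights: dict[str, float] = field(default_factory=dict)
    noise: float = 0.05
    seed: int = 0
    phyla: tuple[str, ...] = DEFAULT_PHYLA

    def __post_init__(self) -> None:
        if self.n_taxa < 1:
            raise ValueError("n_taxa must be >= 1")
        if not (0.0 <= self.noise < 1.0):
            raise ValueError("noise must lie in [0, 1)")
        if self.activity_multipliers is not None:
            if len(self.activity_multipliers) != self.n_taxa:
                raise ValueError("need one activity multiplier per taxon")
            if any(a <= 0 for a in self.activity_multipliers):
                raise ValueError("activity multipliers must be positive")
        if any(e <= 0 for e in self.expression_weights.values()):
            raise ValueError("expression weights must be positive")

    def inclusion_probability(self, gene_name: str, is_stress: bool) -> float:
        if gene_name in self.inclusion_overrides:
            return self.inclusion_overrides[gene_name]
        return self.stress_inclusion if is_stress else self.functional_inclusion


@dataclass(frozen=True)
class Taxon:
    name: str
    lineage: tuple[str, ...]
    repertoire: tuple[str, ...]  # gene names, catalog order


@dataclass(frozen=True)
class Community:
    taxa: tuple[Taxon, ...]
    catalog: GeneCatalog
    noise: float = 0.05


@dataclass
class GroundTruth:
    """The simulator's hidden parameters plus exact sampling probabilities."""

    abundances: np.ndarray  # p_t, sums to 1
    activity: np.ndarray  # alpha_t
    expression: dict[str, float]  # e_g
    repertoires: list[tuple[str, ...]]
    taxon_names: list[str]
    # (taxon, gene) -> probability, per molecule; filled by simulate_libraries
    dna_probs: dict[tuple[str, str], float] = field(default_factory=dict)
    rna_probs: dict[tuple[str, str], float] = field(default_factory=dict)
    seed: int = 0

    def _taxon_prob(self, probs: dict[tuple[str, str], float], taxon: str) -> float:
        return sum(p for (t, _), p in probs.items() if t == taxon)

    def expected_taxon_ratio(self, taxon: str) -> float:
        """Ground-truth RNA:DNA ratio of a taxon (RNA share over DNA share)."""
        dna = self._taxon_prob(self.dna_probs, taxon)
        if dna == 0:
            raise ValueError(f"taxon {taxon!r} has zero DNA probability")
        return self._taxon_prob(self.rna_probs, taxon) / dna

    def expected_gene_ratio(self, gene: str) -> float:
        dna = sum(p for (_, g), p in self.dna_probs.items() if g == gene)
        if dna == 0:
            raise ValueError(f"gene {gene!r} has zero DNA probability")
        rna = sum(p for (_, g), p in self.rna_probs.items() if g == gene)
        return rna / dna

    def expected_taxon_counts(self, taxon: str, n_dna: int, n_rna: int) -> tuple[float, float]:
        return (
            n_dna * self._taxon_prob(self.dna_probs, taxon),
            n_rna * self._taxon_prob(self.rna_probs, taxon),
        )


def sample_community(
    spec: CommunitySpec, catalog: GeneCatalog | None = None
) -> tuple[Community, GroundTruth]:
    """Draw a community (abundances, lineages, repertoires) from ``spec``.

    Deterministic given ``spec.seed``.  Abundances are lognormal draws
    normalized to sum to one; each taxon receives a unique genus/species
    pair under a phylum cycled from ``spec.phyla``, and a gene repertoire
    drawn by per-gene inclusion probability (with at least one functional
    gene forced when the draw comes up empty).
    """
    catalog = catalog or default_catalog()
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 101]))
    n = spec.n_taxa

    if spec.abundance_sigma == 0:
        raw = np.full(n, np.exp(spec.abundance_mu))
    else:
        raw = rng.lognormal(spec.abundance_mu, spec.abundance_sigma, size=n)
    p = raw / raw.sum()

    if spec.activity_multipliers is not None:
        alpha = np.asarray(spec.activity_multipliers, dtype=float)
    elif spec.activity_sigma == 0:
        alpha = np.ones(n)
    else:
        alpha = rng.lognormal(0.0, spec.activity_sigma, size=n)

    func_names = [g.name for g in catalog.functional_genes]
    stress_names = [s.name for s in catalog.stress_genes]
    all_genes = func_names + stress_names
    incl = np.array(
        [
            spec.inclusion_probability(g, is_stress=(g in set(stress_names)))
            for g in all_genes
        ]
    )

    taxa: list[Taxon] = []
    repertoires: list[tuple[str, ...]] = []
    for i in range(n):
        phylum = spec.phyla[i % len(spec.phyla)]
        genus = f"Genus{i + 1:03d}"
        species = f"sp{i + 1:03d}"
        lineage = normalize_lineage(["Bacteria", phylum, "", "", "", genus, species])
        mask = rng.random(len(all_genes)) < incl
        repertoire = [g for g, keep in zip(all_genes, mask) if keep]
        if not any(g in set(func_names) for g in repertoire):
            repertoire.append(func_names[int(rng.integers(len(func_names)))])
            repertoire.sort(key=all_genes.index)
        name = f"{genus} {species}"
        taxa.append(Taxon(name=name, lineage=lineage, repertoire=tuple(repertoire)))
        repertoires.append(tuple(repertoire))

    expression = {g: spec.expression_weights.get(g, 1.0) for g in all_genes}
    gt = GroundTruth(
        abundances=p,
        activity=alpha,
        expression=expression,
        repertoires=repertoires,
        taxon_names=[t.name for t in taxa],
        seed=spec.seed,
    )
    return Community(taxa=tuple(taxa), catalog=catalog, noise=spec.noise), gt


def _sample_quality(rng: np.random.Generator, n: int, noise: float):
    """Quality-score columns for n rows; a ``noise`` fraction fails exactly
    one randomly chosen filter criterion, all other rows pass all three."""
    bit = rng.uniform(*GOOD_BIT, size=n)
    e_val = 10.0 ** rng.uniform(*GOOD_LOG10_E, size=n)
    aln = rng.integers(GOOD_ALN[0], GOOD_ALN[1] + 1, size=n)
    is_noise = rng.random(n) < noise
    which = rng.integers(0, 3, size=n)
    fail_bit = is_noise & (which == 0)
    fail_e = is_noise & (which == 1)
    fail_aln = is_noise & (which == 2)
    bit[fail_bit] = rng.uniform(0.0, 49.9, size=int(fail_bit.sum()))
    e_val[fail_e] = 10.0 ** rng.uniform(-4.99, 0.0, size=int(fail_e.sum()))
    aln[fail_aln] = rng.integers(0, 15, size=int(fail_aln.sum()))
    return bit, e_val, aln, is_noise


def _one_library(
    community: Community,
    probs: np.ndarray,
    cells: list[tuple[int, str]],
    n_reads: int,
    noise: float,
    library_id: str,
    molecule: str,
    rng: np.random.Generator,
) -> Library:
    counts = rng.multinomial(n_reads, probs)
    taxon_idx = np.repeat(np.arange(len(cells)), counts)
    rng.shuffle(taxon_idx)
    bit, e_val, aln, _ = _sample_quality(rng, n_reads, noise)
    read_len = rng.normal(200.0, 60.0, size=n_reads).clip(50).astype(int)
    records = []
    taxa = community.taxa
    for i in range(n_reads):
        t_i, gene = cells[taxon_idx[i]]
        records.append(
            AnnotationRecord(
                read_id=f"{library_id}_r{i:07d}",
                library_id=library_id,
                molecule=molecule,
                lineage=taxa[t_i].lineage,
                function_label=gene,
                bit_score=float(bit[i]),
                e_value=float(e_val[i]),
                align_len_aa=int(aln[i]),
                read_len_bp=int(read_len[i]),
            )
        )
    return Library(library_id=library_id, molecule=molecule, records=records)


def simulate_libraries(
    community: Community,
    ground_truth: GroundTruth,
    n_dna: int,
    n_rna: int,
    seed: int | None = None,
    *,
    library_prefix: str = "S",
) -> tuple[Library, Library, GroundTruth]:
    """Draw paired DNA and RNA annotation libraries from a sampled community.

    Each read is one annotation record; record counts equal ``n_dna`` and
    ``n_rna`` exactly.  The DNA and RNA draws use independent streams spawned
    from ``seed`` (defaulting to the community's seed), so either library is
    reproducible on its own.  ``ground_truth`` is updated in place with the
    exact per-(taxon, gene) sampling probabilities used.
    """
    if n_dna < 0 or n_rna < 0:
        raise ValueError("library sizes must be non-negative")
    if all(len(t.repertoire) == 0 for t in community.taxa):
        raise ValueError("community has no genes to sample")
    seed = ground_truth.seed if seed is None else seed
    ss_dna, ss_rna = np.random.SeedSequence([seed, 202]).spawn(2)

    p = ground_truth.abundances
    alpha = ground_truth.activity
    e_g = ground_truth.expression
    cells: list[tuple[int, str]] = []
    w_dna: list[float] = []
    w_rna: list[float] = []
    for i, taxon in enumerate(community.taxa):
        for gene in taxon.repertoire:
            cells.append((i, gene))
            w_dna.append(p[i])
            w_rna.append(p[i] * alpha[i] * e_g[gene])
    dna_probs = np.asarray(w_dna) / np.sum(w_dna)
    rna_probs = np.asarray(w_rna) / np.sum(w_rna)
    names = ground_truth.taxon_names
    ground_truth.dna_probs = {
        (names[i], g): float(pr) for (i, g), pr in zip(cells, dna_probs)
    }
    ground_truth.rna_probs = {
        (names[i], g): float(pr) for (i, g), pr in zip(cells, rna_probs)
    }

    noise = community.noise
    dna_lib = _one_library(
        community,
        dna_probs,
        cells,
        n_dna,
        noise,
        f"{library_prefix}_DNA",
        "DNA",
        np.random.default_rng(ss_dna),
    )
    rna_lib = _one_library(
        community,
        rna_probs,
        cells,
        n_rna,
        noise,
        f"{library_prefix}_RNA",
        "RNA",
        np.random.default_rng(ss_rna),
    )
    return dna_lib, rna_lib, ground_truth


def simulate_paired_libraries(
    spec: CommunitySpec,
    n_dna: int,
    n_rna: int,
    catalog: GeneCatalog | None = None,
    *,
    library_prefix: str = "S",
) -> tuple[Library, Library, GroundTruth]:
    """Convenience wrapper: sample a community, then its paired libraries."""
    community, gt = sample_community(spec, catalog)
    dna, rna, gt = simulate_libraries(
        community, gt, n_dna, n_rna, spec.seed, library_prefix=library_prefix
    )
    return dna, rna, gt


def write_library_tsv(lib: Library, path) -> None:
    """Write a library in the mgrast_tsv dialect (round-trips through the parser)."""
    with open(path, "w") as fh:
        fh.write(
            "#read_id\tlibrary_id\tmolecule\tdomain\tphylum\tclass\torder\tfamily\t"
            "genus\tspecies\tfunction_label\tbit_score\te_value\talign_len_aa\tread_len_bp\n"
        )
        for rec in lib.records:
            fh.write(
                f"{rec.read_id}\t{rec.library_id}\t{rec.molecule}\t"
                + "\t".join(rec.lineage)
                + f"\t{rec.function_label}\t{rec.bit_score!r}\t{rec.e_value!r}\t"
                f"{rec.align_len_aa}\t{rec.read_len_bp if rec.read_len_bp is not None else ''}\n"
            )


def write_ground_truth_json(gt: GroundTruth, path) -> None:
    doc = {
        "seed": gt.seed,
        "taxon_names": gt.taxon_names,
        "abundances": [float(x) for x in gt.abundances],
        "activity": [float(x) for x in gt.activity],
        "expression": gt.expression,
        "repertoires": [list(r) for r in gt.repertoires],
        "dna_probs": {f"{t}||{g}": p for (t, g), p in gt.dna_probs.items()},
        "rna_probs": {f"{t}||{g}": p for (t, g), p in gt.rna_probs.items()},
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1, sort_keys=True)
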