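"""Relating functional genes to stress-response genes.

Two analyses connect the carbon/nitrogen-cycle genes to the stress-response
repertoire of the community:

* **Accumulation** — for each functional gene f, count its species richness
  R and the number S of distinct stress gene types carried by the species
  that contain f.  S grows roughly logarithmically with R, so a least-squares
  fit of S = a*ln(R) + b summarizes the relationship.

* **Co-occurrence network** — after pruning trivially connected rows and
  columns, each (functional gene, stress gene) pair is tested for Spearman
  rank correlation of their per-species read counts; p-values are adjusted
  for multiple comparisons (Benjamini-Hochberg by default) and only
  significant pairs that actually share a species become network edges.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .catalog import GeneCatalog
from .matrices import TaxonFunctionMatrix

__all__ = [
    "StressAccumulationPoint",
    "LogFit",
    "CorrelationEdge",
    "GeneNetwork",
    "stress_accumulation",
    "fit_log_curve",
    "prune_matrix",
    "correlation_network",
    "export_network",
    "read_edge_tsv",
    "write_accumulation_tsv",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class StressAccumulationPoint:
    """(functional gene, species richness R, distinct stress gene types S)."""

    function_label: str
    molecule: str
    richness: int
    n_stress_types: int

    def __post_init__(self) -> None:
        if self.richness == 0 and self.n_stress_types != 0:
            raise ValueError("a gene found in no species cannot co-occur with stress genes")


@dataclass(frozen=True)
class LogFit:
    """Least-squares fit of S = a*ln(R) + b."""

    a: float
    b: float
    r_squared: float
    n_points: int
    n_excluded_zero_richness: int = 0

    def predict(self, richness) -> np.ndarray:
        return self.a * np.log(np.asarray(richness, dtype=float)) + self.b


@dataclass(frozen=True)
class CorrelationEdge:
    functional_gene: str
    stress_gene: str
    rho: float
    p_raw: float
    p_adj: float
    n_species: int
    shared_species: int


@dataclass
class GeneNetwork:
    """Bipartite gene co-occurrence network after significance filtering."""

    nodes: dict[str, dict] = field(default_factory=dict)  # name -> attrs
    edges: list[CorrelationEdge] = field(default_factory=list)
    n_pairs_tested: int = 0
    n_zero_variance: int = 0
    molecule: str = ""

    def __post_init__(self) -> None:
        for e in self.edges:
            if e.functional_gene == e.stress_gene:
                raise ValueError(f"self-edge on {e.functional_gene!r}")
            if e.functional_gene not in self.nodes or e.stress_gene not in self.nodes:
                raise ValueError("every edge endpoint must be a node")

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for name, attrs in self.nodes.items():
            g.add_node(name, **{k: v for k, v in attrs.items() if v is not None})
        for e in self.edges:
            g.add_edge(
                e.functional_gene,
                e.stress_gene,
                rho=e.rho,
                p_raw=e.p_raw,
                p_adj=e.p_adj,
                n_species=e.n_species,
                shared_species=e.shared_species,
            )
        return g


def stress_accumulation(
    m: TaxonFunctionMatrix, catalog: GeneCatalog
) -> list[StressAccumulationPoint]:
    """One accumulation point per catalog functional gene present in the matrix axis.

    R counts species containing the gene; S counts distinct stress gene
    labels found across those species (each label once, however many species
    carry it).
    """
    if m.rank != "species":
        raise ValueError("stress accumulation requires a species-rank matrix")
    cols = list(m.counts.columns)
    stress_cols = [c for c in cols if catalog.is_stress(c)]
    presence = m.counts.values > 0 if not m.counts.empty else np.zeros((0, 0), dtype=bool)
    col_idx = {c: i for i, c in enumerate(cols)}
    points: list[StressAccumulationPoint] = []
    for g in catalog.functional_genes:
        fcol = next(
            (c for c in cols if (fg := catalog.functional(c)) and fg.name == g.name), None
        )
        if fcol is None:
            points.append(StressAccumulationPoint(g.name, m.molecule, 0, 0))
            continue
        species_mask = presence[:, col_idx[fcol]]
        richness = int(species_mask.sum())
        if richness == 0:
            points.append(StressAccumulationPoint(g.name, m.molecule, 0, 0))
            continue
        s_types = {
            catalog.stress(sc).name
            for sc in stress_cols
            if presence[species_mask, col_idx[sc]].any()
        }
        points.append(StressAccumulationPoint(g.name, m.molecule, richness, len(s_types)))
    return points


def fit_log_curve(points) -> LogFit:
    """Least-squares fit of S = a*ln(R) + b over accumulation points.

    Points with R = 0 are excluded (their count is recorded on the fit);
    at least two points with distinct positive R are required.
    """
    pts = list(points)
    usable = [(p.richness, p.n_stress_types) for p in pts if p.richness >= 1]
    n_excluded = len(pts) - len(usable)
    if n_excluded:
        logger.info("fit_log_curve: excluded %d zero-richness points", n_excluded)
    if len(usable) < 2 or len({r for r, _ in usable}) < 2:
        raise ValueError("log fit needs >= 2 points with distinct positive richness")
    x = np.log(np.array([r for r, _ in usable], dtype=float))
    y = np.array([s for _, s in usable], dtype=float)
    a, b = np.polyfit(x, y, 1)
    resid = y - (a * x + b)
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 if ss_tot == 0 else max(0.0, 1.0 - ss_res / ss_tot)
    return LogFit(float(a), float(b), r2, len(usable), n_excluded)


def prune_matrix(
    m: TaxonFunctionMatrix,
    catalog: GeneCatalog,
    *,
    to_fixpoint: bool = False,
) -> TaxonFunctionMatrix:
    """Drop trivially connected rows/columns before network construction.

    A single ordered pass: (1) remove species carrying at most one distinct
    catalog functional gene; (2) then remove functional genes present in at
    most one remaining species.  Stress genes are never removed by rule (2).
    ``to_fixpoint=True`` iterates the pass until nothing changes (logged
    whenever that differs from the single pass).
    """
    if m.rank != "species":
        raise ValueError("pruning operates on a species-rank matrix")
    counts = m.counts
    func_cols = [c for c in counts.columns if catalog.is_functional(c)]

    def one_pass(df):
        n_func = (df[func_cols].reindex(columns=[c for c in func_cols if c in df.columns]) > 0).sum(axis=1)
        kept_rows = df.loc[n_func > 1]
        drop_cols = [
            c
            for c in kept_rows.columns
            if catalog.is_functional(c) and int((kept_rows[c] > 0).sum()) <= 1
        ]
        return kept_rows.drop(columns=drop_cols)

    pruned = one_pass(counts)
    if to_fixpoint:
        prev = None
        result = pruned
        while prev is None or result.shape != prev.shape:
            prev = result
            result = one_pass(result)
        if result.shape != pruned.shape:
            logger.info(
                "prune_matrix: fixpoint differs from single pass (%s vs %s)",
                result.shape,
                pruned.shape,
            )
        pruned = result
    logger.info(
        "prune_matrix: %d -> %d species, %d -> %d columns",
        counts.shape[0] if not counts.empty else 0,
        pruned.shape[0] if not pruned.empty else 0,
        counts.shape[1] if not counts.empty else 0,
        pruned.shape[1] if not pruned.empty else 0,
    )
    return TaxonFunctionMatrix(
        rank=m.rank,
        counts=pruned,
        library_id=m.library_id,
        molecule=m.molecule,
        n_dropped_eukaryota=m.n_dropped_eukaryota,
        axis=m.axis,
    )


def correlation_network(
    m: TaxonFunctionMatrix,
    catalog: GeneCatalog,
    alpha: float = 0.05,
    adjust: str = "fdr_bh",
    *,
    use_adjusted: bool = True,
    binary: bool = False,
) -> GeneNetwork:
    """Spearman co-occurrence network between functional and stress genes.

    For every (functional gene, stress gene) pair present in the matrix, the
    per-species count vectors are rank-correlated (mid-rank ties; p-value
    from the t-approximation on n-2 degrees of freedom).  P-values are
    adjusted across all tested pairs; an edge is retained when the
    (adjusted, by default) p-value is at most ``alpha`` and the two genes
    share at least one species.  Zero-variance vectors are counted, not
    tested.  ``binary=True`` correlates presence/absence instead of counts.
    """
    n_species = m.counts.shape[0] if not m.counts.empty else 0
    if n_species < 3:
        raise ValueError("correlation network needs at least 3 species")
    cols = list(m.counts.columns)
    func_cols = [c for c in cols if catalog.is_functional(c)]
    stress_cols = [c for c in cols if catalog.is_stress(c)]
    data = m.counts[func_cols + stress_cols].to_numpy(dtype=float)
    if binary:
        data = (data > 0).astype(float)
    col_idx = {c: i for i, c in enumerate(func_cols + stress_cols)}

    tested: list[tuple[str, str, float, float, int]] = []
    n_zero_var = 0
    for f in func_cols:
        x = data[:, col_idx[f]]
        for s in stress_cols:
            y = data[:, col_idx[s]]
            if np.all(x == x[0]) or np.all(y == y[0]):
                n_zero_var += 1
                continue
            rho, p = stats.spearmanr(x, y)
            shared = int(((m.counts[f] > 0) & (m.counts[s] > 0)).sum())
            tested.append((f, s, float(rho), float(p), shared))

    edges: list[CorrelationEdge] = []
    if tested:
        p_raw = np.array([t[3] for t in tested])
        _, p_adj, _, _ = multipletests(p_raw, method=adjust)
        for (f, s, rho, p, shared), pa in zip(tested, p_adj):
            p_gate = pa if use_adjusted else p
            if p_gate <= alpha and shared >= 1:
                edges.append(CorrelationEdge(f, s, rho, p, float(pa), n_species, shared))

    nodes: dict[str, dict] = {}
    for e in edges:
        fg = catalog.functional(e.functional_gene)
        sg = catalog.stress(e.stress_gene)
        nodes.setdefault(
            e.functional_gene,
            {"node_type": "functional", "cycle": fg.cycle if fg else None, "stress_category": None},
        )
        nodes.setdefault(
            e.stress_gene,
            {"node_type": "stress", "cycle": None, "stress_category": sg.category if sg else None},
        )
    return GeneNetwork(
        nodes=nodes,
        edges=edges,
        n_pairs_tested=len(tested),
        n_zero_variance=n_zero_var,
        molecule=m.molecule,
    )


# ---------------------------------------------------------------------------
# Export / import

EDGE_TSV_HEADER = "gene_a\tgene_b\trho\tp_raw\tp_adj\tn_species\tshared_species"


def export_network(net: GeneNetwork, path, fmt: str = "edge_tsv") -> None:
    """Write the network as ``graphml``, ``sif`` or ``edge_tsv``."""
    if fmt == "graphml":
        nx.write_graphml(net.to_networkx(), path)
    elif fmt == "sif":
        with open(path, "w") as fh:
            connected = set()
            for e in net.edges:
                fh.write(f"{e.functional_gene}\tcorr\t{e.stress_gene}\n")
                connected.update((e.functional_gene, e.stress_gene))
            for name in net.nodes:
                if name not in connected:
                    fh.write(f"{name}\n")
    elif fmt == "edge_tsv":
        with open(path, "w") as fh:
            fh.write(EDGE_TSV_HEADER + "\n")
            for e in net.edges:
                fh.write(
                    f"{e.functional_gene}\t{e.stress_gene}\t{e.rho!r}\t{e.p_raw!r}\t"
                    f"{e.p_adj!r}\t{e.n_species}\t{e.shared_species}\n"
                )
    else:
        raise ValueError(f"unknown network format {fmt!r}")


def read_edge_tsv(path) -> list[CorrelationEdge]:
    """Re-import an ``edge_tsv`` export; round-trips the edge set exactly."""
    edges: list[CorrelationEdge] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if header != EDGE_TSV_HEADER:
            raise ValueError(f"unexpected edge TSV header: {header!r}")
        for line in fh:
            f, s, rho, p_raw, p_adj, n, shared = line.rstrip("\n").split("\t")
            edges.append(
                CorrelationEdge(f, s, float(rho), float(p_raw), float(p_adj), int(n), int(shared))
            )
    return edges


def write_accumulation_tsv(points, fit: LogFit | None, path) -> None:
    """Export accumulation points (and the fitted curve parameters) as TSV."""
    with open(path, "w") as fh:
        fh.write("function\tmolecule\trichness\tn_stress_types\n")
        for p in points:
            fh.write(f"{p.function_label}\t{p.molecule}\t{p.richness}\t{p.n_stress_types}\n")
        if fit is not None:
            fh.write(
                f"# log fit: S = {fit.a:.6g}*ln(R) + {fit.b:.6g}, "
                f"r2 = {fit.r_squared:.4f}, n = {fit.n_points}\n"
            )
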