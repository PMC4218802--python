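"""End-to-end pipeline: parse -> filter -> best hit -> matrices -> statistics.

``run_pipeline`` executes the whole analysis chain for one or more sites,
each with a paired DNA and RNA annotation table (or a simulation spec that
generates them), and writes every result table plus a JSON run report with
per-stage record bookkeeping.  Outputs are deterministic given the config
and seed: running the same config twice yields byte-identical files.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import activity as activity_mod
from . import diversity as diversity_mod
from . import stress as stress_mod
from .annotation import (
    FilterCriteria,
    Library,
    apply_quality_filters,
    best_hit_per_read,
    parse_annotation_table,
    summarize_library,
    write_library_summary,
)
from .catalog import GeneCatalog, default_catalog, load_catalog
from .matrices import build_matrix, composition_by_rank
from .simulate import (
    CommunitySpec,
    simulate_paired_libraries,
    write_ground_truth_json,
    write_library_tsv,
)

__all__ = ["RunConfig", "StageCount", "RunReport", "run_pipeline", "load_config"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Exactly one of ``inputs`` (site -> {"dna": path, "rna": path}) or
    ``simulation`` (CommunitySpec fields plus n_dna/n_rna) must be given.
    """

    out_dir: str | Path = "metaratio_out"
    inputs: dict[str, dict[str, str]] = field(default_factory=dict)
    simulation: dict | None = None
    filter_criteria: FilterCriteria = field(default_factory=FilterCriteria)
    catalog_path: str | None = None
    composition_rank: str = "phylum"
    richness_rank: str = "species"
    other_threshold: float = 0.01
    alpha: float = 0.05
    adjust: str = "fdr_bh"
    support_threshold: int = 10
    seed: int = 0

    def validate(self) -> None:
        if not self.inputs and self.simulation is None:
            raise ValueError("config needs either input files or a simulation spec")
        if self.inputs and self.simulation is not None:
            raise ValueError("give input files or a simulation spec, not both")
        for site, files in self.inputs.items():
            for mol in ("dna", "rna"):
                if mol not in files:
                    raise ValueError(f"site {site!r} is missing its {mol.upper()} table")
                if not Path(files[mol]).exists():
                    raise FileNotFoundError(files[mol])

    def catalog(self) -> GeneCatalog:
        return load_catalog(self.catalog_path) if self.catalog_path else default_catalog()


@dataclass(frozen=True)
class StageCount:
    stage: str
    records_in: int
    records_out: int

    @property
    def removed(self) -> int:
        return self.records_in - self.records_out


@dataclass
class RunReport:
    out_dir: str
    outputs: list[str] = field(default_factory=list)
    stage_counts: dict[str, list[dict]] = field(default_factory=dict)
    flags: list[str] = field(default_factory=list)
    failed_stage: str | None = None

    def add_stage(self, site_mol: str, stage: str, n_in: int, n_out: int) -> None:
        self.stage_counts.setdefault(site_mol, []).append(
            {"stage": stage, "records_in": n_in, "records_out": n_out}
        )

    def write(self, path) -> None:
        # paths are recorded relative to out_dir so identical runs into
        # different directories produce byte-identical reports
        base = Path(self.out_dir)
        rel = sorted(
            str(Path(p).relative_to(base)) if Path(p).is_relative_to(base) else p
            for p in self.outputs
        )
        with open(path, "w") as fh:
            json.dump(
                {
                    "outputs": rel,
                    "stage_counts": self.stage_counts,
                    "flags": sorted(self.flags),
                    "failed_stage": self.failed_stage,
                },
                fh,
                indent=1,
                sort_keys=True,
            )


def load_config(path) -> RunConfig:
    """Load a YAML/JSON run config."""
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    crit = doc.pop("filter_criteria", None)
    cfg = RunConfig(**doc)
    if crit:
        cfg.filter_criteria = FilterCriteria(**crit)
    return cfg


def _prepare_libraries(cfg: RunConfig, out: Path, report: RunReport):
    """Yield (site, dna Library, rna Library) from files or simulation."""
    if cfg.simulation is not None:
        sim = dict(cfg.simulation)
        n_dna = int(sim.pop("n_dna", 20000))
        n_rna = int(sim.pop("n_rna", 20000))
        sim.setdefault("seed", cfg.seed)
        spec = CommunitySpec(**sim)
        dna, rna, gt = simulate_paired_libraries(
            spec, n_dna, n_rna, cfg.catalog(), library_prefix="sim"
        )
        gt_path = out / "ground_truth.json"
        write_ground_truth_json(gt, gt_path)
        report.outputs.append(str(gt_path))
        for lib in (dna, rna):
            p = out / f"{lib.library_id}.annotations.tsv"
            write_library_tsv(lib, p)
            report.outputs.append(str(p))
        yield "sim", dna, rna
        return
    for site, files in sorted(cfg.inputs.items()):
        libs = {}
        for mol in ("dna", "rna"):
            with open(files[mol]) as fh:
                libs[mol] = parse_annotation_table(fh, "mgrast_tsv")
            if libs[mol].molecule != mol.upper():
                raise ValueError(
                    f"{files[mol]} declares molecule {libs[mol].molecule}, expected {mol.upper()}"
                )
        yield site, libs["dna"], libs["rna"]


def run_pipeline(cfg: RunConfig) -> RunReport:
    """Run the full chain and write all outputs under ``cfg.out_dir``."""
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    catalog = cfg.catalog()
    report = RunReport(out_dir=str(out))

    catalog_path = out / "catalog.tsv"
    catalog.to_tsv(catalog_path)
    report.outputs.append(str(catalog_path))

    for site, dna_raw, rna_raw in _prepare_libraries(cfg, out, report):
        stage = "parse"
        try:
            summaries = []
            mats = {}
            for lib in (dna_raw, rna_raw):
                key = f"{site}_{lib.molecule}"
                stage = f"filter[{key}]"
                filtered = apply_quality_filters(lib, cfg.filter_criteria)
                report.add_stage(key, "quality_filter", len(lib), len(filtered))
                stage = f"best_hit[{key}]"
                resolved = best_hit_per_read(filtered)
                report.add_stage(key, "best_hit", len(filtered), len(resolved))
                lengths = [r.read_len_bp for r in lib.records if r.read_len_bp is not None]
                summaries.append(
                    summarize_library(resolved, max(len(lib), 1), lengths or None)
                )

                stage = f"matrices[{key}]"
                sp_matrix = build_matrix(resolved, cfg.richness_rank)
                report.add_stage(key, "species_matrix", len(resolved), sp_matrix.total)
                if sp_matrix.n_dropped_eukaryota:
                    report.flags.append(
                        f"{key}: dropped {sp_matrix.n_dropped_eukaryota} eukaryotic records"
                    )
                mats[lib.molecule] = (resolved, sp_matrix)
                wide = out / f"{key}.matrix_{cfg.richness_rank}.tsv"
                sp_matrix.to_wide_tsv(wide)
                report.outputs.append(str(wide))

                stage = f"composition[{key}]"
                comp = composition_by_rank(
                    resolved, cfg.composition_rank, cfg.other_threshold
                )
                comp_path = out / f"{key}.composition_{cfg.composition_rank}.tsv"
                comp.to_tsv(comp_path)
                report.outputs.append(str(comp_path))

            summary_path = out / f"{site}.library_summary.tsv"
            write_library_summary(summaries, summary_path)
            report.outputs.append(str(summary_path))

            stage = f"activity[{site}]"
            dna_mat = mats["DNA"][1]
            rna_mat = mats["RNA"][1]
            ratios = activity_mod.pathway_activity_report(
                dna_mat, rna_mat, catalog, support_threshold=cfg.support_threshold
            )
            act_path = out / f"{site}.pathway_activity.tsv"
            activity_mod.write_activity_report(ratios, act_path, site=site)
            report.outputs.append(str(act_path))
            for r in ratios:
                if r.defined and r.low_support:
                    report.flags.append(
                        f"{site}: pathway {r.feature!r} has low support "
                        f"(dna={r.dna_count}, rna={r.rna_count})"
                    )

            stage = f"diversity[{site}]"
            for molecule, (_, mat) in sorted(mats.items()):
                curves = []
                for g in catalog.functional_genes:
                    vec = (
                        mat.counts[g.name][mat.counts[g.name] > 0]
                        if g.name in mat.counts.columns
                        else []
                    )
                    vec = list(vec)
                    if sum(vec) >= 1:
                        curves.append(
                            diversity_mod.rarefaction_curve(vec, function_label=g.name)
                        )
                curve_path = out / f"{site}_{molecule}.rarefaction.tsv"
                diversity_mod.write_curves_tsv(curves, curve_path)
                report.outputs.append(str(curve_path))

            stage = f"stress[{site}]"
            for molecule, (_, mat) in sorted(mats.items()):
                key = f"{site}_{molecule}"
                points = stress_mod.stress_accumulation(mat, catalog)
                fit = None
                try:
                    fit = stress_mod.fit_log_curve(points)
                except ValueError as exc:
                    report.flags.append(f"{key}: log fit skipped ({exc})")
                acc_path = out / f"{key}.stress_accumulation.tsv"
                stress_mod.write_accumulation_tsv(points, fit, acc_path)
                report.outputs.append(str(acc_path))

                pruned = stress_mod.prune_matrix(mat, catalog)
                report.add_stage(key, "prune", mat.total, pruned.total)
                try:
                    net = stress_mod.correlation_network(
                        pruned, catalog, alpha=cfg.alpha, adjust=cfg.adjust
                    )
                except ValueError as exc:
                    report.flags.append(f"{key}: network skipped ({exc})")
                    continue
                if net.n_zero_variance:
                    report.flags.append(
                        f"{key}: {net.n_zero_variance} zero-variance gene pairs untested"
                    )
                for fmt, suffix in (("edge_tsv", "edges.tsv"), ("graphml", "graphml"), ("sif", "sif")):
                    net_path = out / f"{key}.network.{suffix}"
                    stress_mod.export_network(net, net_path, fmt)
                    report.outputs.append(str(net_path))
        except Exception:
            report.failed_stage = stage
            report.write(out / "run_report.json")
            raise

    report.write(out / "run_report.json")
    report.outputs.append(str(out / "run_report.json"))
    return report
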