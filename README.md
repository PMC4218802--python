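# metaratio

Comparative analysis of **paired metagenome (DNA) and metatranscriptome
(RNA) libraries** from the same sample, starting from taxonomy+function
annotated reads. For microbial ecologists asking not just *who is there and
what can they do*, but *who is doing it*: which taxa and which metabolic
pathways are transcriptionally active relative to their genomic abundance,
how taxonomically redundant each function is, and whether functions carried
by more taxa also have access to more kinds of stress-response genes.

The pipeline:

1. **Parse & filter** annotation tables (MG-RAST-export-like TSV or BLAST
   tabular + sidecar); keep reads with bit score ≥ 50, E-value ≤ 1e-5 and
   alignment ≥ 15 aa; resolve multiple hits per read deterministically.
2. **Pivot** into taxon × function count matrices at phylum / genus /
   species rank; phylum composition tables with <1% labels grouped as
   "other"; key-gene → pathway aggregation for the carbon and nitrogen
   cycles.
3. **Activity**: for a feature f, the relative activity is the RNA:DNA
   ratio of within-library read fractions,
   `ratio(f) = (n_f,RNA / N_RNA) / (n_f,DNA / N_DNA)` — e.g. a pathway at
   2% of RNA reads but 1% of DNA reads has ratio 2, i.e. transcribed twice
   as much as its genomic abundance predicts.
4. **Diversity**: per-gene taxonomic richness R and exact hypergeometric
   rarefaction, `E[R(n)] = Σ_i [1 − C(N−N_i, n)/C(N, n)]`.
5. **Stress association**: the number of distinct stress-gene types S found
   in the species carrying each functional gene, with the least-squares fit
   `S = a·ln(R) + b`; and a pruned Spearman co-occurrence network between
   functional and stress genes (BH-adjusted p ≤ 0.05).
6. **Simulation**: a generative model of annotated reads from a community
   with known abundances, activity multipliers and gene repertoires, so
   every estimator can be checked against ground truth.

See `docs/methods.md` for the statistical details and assumptions.

## Worked example

Simulate a 20-taxon community, run the core analyses:

```python
from metaratio import (
    CommunitySpec, simulate_paired_libraries, default_catalog,
    apply_quality_filters, best_hit_per_read, build_matrix,
    pathway_activity_report, stress_accumulation, fit_log_curve,
    prune_matrix, correlation_network,
)

spec = CommunitySpec(n_taxa=20, seed=42)
dna, rna, truth = simulate_paired_libraries(spec, 50_000, 50_000)
catalog = default_catalog()

md = build_matrix(best_hit_per_read(apply_quality_filters(dna)), "species")
mr = build_matrix(best_hit_per_read(apply_quality_filters(rna)), "species")

for r in pathway_activity_report(md, mr, catalog)[:6]:
    print(f"{r.cycle:8s} {r.feature:28s} dna%={100*r.dna_frac:6.3f} "
          f"rna%={100*r.rna_frac:6.3f} ratio={r.ratio:.3f}")

fit = fit_log_curve(stress_accumulation(md, catalog))
print(f"log fit: S = {fit.a:.3f} ln(R) + {fit.b:.3f}  (r2 = {fit.r_squared:.3f})")
```

prints

```
carbon   CBB                          dna%= 2.882 rna%= 2.921 ratio=1.013
carbon   TCA                          dna%= 7.142 rna%= 6.909 ratio=0.967
carbon   glycolysis                   dna%=12.253 rna%=11.975 ratio=0.977
carbon   oxidative phosphorylation    dna%= 2.347 rna%= 1.756 ratio=0.748
carbon   photoheterotrophy            dna%= 5.697 rna%= 5.858 ratio=1.028
carbon   photosystem I                dna%= 1.860 rna%= 3.243 ratio=1.744
log fit: S = 3.013 ln(R) + 0.956  (r2 = 0.668)
```

Photosystem I reads are 1.9% of the DNA library but 3.2% of the RNA
library: in this simulated community that pathway is transcribed ~1.7×
above its genomic abundance. The log fit says each e-fold increase in a
gene's species richness adds about three stress-gene types to the pool its
carriers can draw on. Estimates track the simulator's hidden parameters:
the most abundant taxon's true activity ratio here is 0.815 and the
estimate from 50k-read libraries is 0.811.

The same chain runs from the shell:

```sh
metaratio simulate --n-taxa 20 --n-dna 50000 --n-rna 50000 --seed 42 -o sim_out
metaratio activity sim_out/sim_DNA.annotations.tsv sim_out/sim_RNA.annotations.tsv -o activity.tsv
metaratio run-all config.yaml        # full pipeline from a YAML config
```

`run-all` writes matrices, composition tables, pathway activity reports,
rarefaction curves, stress-accumulation tables, and the network in GraphML
/ SIF / edge-TSV form, plus a JSON run report with per-stage record
bookkeeping. Outputs are byte-identical across runs with the same config
and seed.

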