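# Methods

`metaratio` analyzes paired shotgun metagenome (DNA) and metatranscriptome
(RNA) libraries that have already been annotated with taxonomy and function.
The unit of input is one annotated read — the package does no sequence-level
work. This note describes the statistical procedures, the simulation model
used for validation, the numerical choices, and what the tests do and do not
establish about real data.

## Input model and quality filtering

An annotation record carries a seven-rank lineage (domain … species), a
function label, and three alignment-quality scores: bit score, E-value and
alignment length in amino acids. Records are kept when

    bit_score >= 50,  E-value <= 1e-5,  alignment >= 15 aa,

all boundaries inclusive. These are the conventional cut-offs for
BLASTX-style annotation of short shotgun reads; all three are exposed as
parameters. Filtering is idempotent and order-preserving.

When a read carries several annotations, a single best hit is kept:
highest bit score, then lowest E-value, then the lexicographically smallest
(function label, joined lineage) pair. The final tie-break is arbitrary but
deterministic and independent of input row order, which matters more than
which of two equally scored hits wins.

Missing lineage ranks are rewritten as `unclassified_<nearest resolved
parent>` so that aggregating at any rank conserves read counts. Species
labels are formed as binomials (`genus species`, or `genus sp.` when the
species epithet is missing) so species-level richness is well defined.
Eukaryotic records are dropped when matrices are built (prokaryote-targeted
gene callers make those annotations unreliable); the dropped count is kept
on the matrix and surfaced in the run report.

## RNA:DNA activity ratios

For a feature f (taxon, gene, or pathway) with count `n_f` in a library of
`N` annotated reads, the within-library fraction is `n_f / N`, and the
relative activity is

    ratio(f) = (n_f_RNA / N_RNA) / (n_f_DNA / N_DNA).

Fractions, not raw counts, are used because paired libraries routinely
differ in depth by an order of magnitude; the ratio is then invariant to
library scaling (tested). A zero DNA fraction yields an *undefined* ratio,
reported as such — no silent pseudocounts. Optional `smooth=True` adds +0.5
to both counts and labels the output accordingly. Features where either
library has fewer than 10 reads (configurable) are flagged `low_support`
but never removed: a pathway seen in nine DNA reads needs only a handful of
RNA reads to double its apparent activity, so such ratios should be read
with caution rather than hidden.

The denominator is the number of *annotated* reads in the library, not the
sequencing depth; an alternative total can be supplied by rescaling the
matrices before calling, but fraction-of-annotated is the default because
annotation rates differ strongly between DNA and RNA libraries.

Key genes diagnose pathways through the catalog (RuBisCo → CBB cycle,
phosphofructokinase → glycolysis, pyruvate dehydrogenase → TCA, cytochrome
C oxidase → oxidative phosphorylation, puf operon → photoheterotrophy,
photosystems I/II, glutamine synthetase → ammonia assimilation, nitrogenase
→ N₂ fixation, nitric/nitrous oxide reductase → denitrification, amoA →
nitrification). The catalog is a YAML file and fully replaceable; label
matching is case-insensitive after whitespace normalization, and synonyms
belong in the catalog, not the matcher.

## Richness and rarefaction

The richness R of a functional gene is the number of distinct taxa (at a
chosen rank; species by default) containing at least one read of that gene.
Rarefaction asks how R would look at a smaller sequencing depth. With
per-taxon read counts `N_i` summing to `N`, the expected richness in a
uniform random subsample of n reads without replacement is the
hypergeometric expectation

    E[R(n)] = Σ_i [ 1 − C(N−N_i, n) / C(N, n) ],

evaluated through log-gamma functions so libraries of 10⁷ reads do not
overflow. This matches the semantics of vegan's `rarecurve`. The curve is
exact, monotone in n, and equals observed richness at n = N; a Monte-Carlo
subsampler (multivariate hypergeometric draws) exists purely as an
independent check and agrees within Monte-Carlo error (tested at 10⁵
replicates). The per-function count vector rarefied is "reads of that
function per taxon": rarefaction is within a function's reads, which is the
interpretation under which curves for abundant genes saturate while rare
genes keep climbing.

A saturation flag summarizes the tail: the curve is called saturated when
the mean slope over the last 10% of the depth range falls below one new
taxon per ten final depth steps. Both the tail fraction and tolerance are
parameters; the flag is descriptive, not inferential.

## Stress-gene accumulation and the logarithmic fit

For each functional gene f, S(f) is the number of *distinct* stress-gene
labels (UV, osmotic, oxidative categories in the catalog) found across all
species that contain f — each label counts once regardless of how many
species carry it. S is monotone under species addition (tested). The
relationship between S and richness R is summarized by least squares on

    S = a·ln(R) + b,

fit with `numpy.polyfit` on ln R. Points with R = 0 are excluded (their
count is recorded); at least two distinct positive R values are required.
The logarithmic form reflects saturation: each added species carries a
diminishing chance of contributing a novel stress-gene type.

## Co-occurrence network

Before correlation, the species-by-gene matrix is pruned in one ordered
pass: (1) species with at most one distinct functional gene are removed,
then (2) functional genes present in at most one remaining species are
removed. Stress genes are never column-pruned — they are the objects being
tested, not the conditioning set. An optional fixpoint mode iterates the
pass and logs when it changes the result; the default is the single pass.

For every (functional gene, stress gene) pair, Spearman's rho is computed
on per-species read counts (mid-rank ties), with the p-value from the
t-approximation on n−2 degrees of freedom (`scipy.stats.spearmanr`).
Counts rather than presence/absence are the default because a pruned
co-occurrence table is nearly saturated in presence/absence and would make
most pairs degenerate; binary mode is a flag. P-values are adjusted across
all tested pairs by Benjamini–Hochberg (configurable), and an edge is kept
when the **adjusted** p-value is ≤ 0.05 and the pair shares at least one
species. Gating on the adjusted value is the conservative reading when an
adjustment is computed at all; raw-p gating is available by flag.
Zero-variance vectors are counted and flagged, not tested. Under a null
where stress counts are independent of functional counts, the mean retained
fraction stays below the nominal 5% (tested over seeded simulations — BH
controls FDR, which is conservative for the retained-edge fraction under a
complete null).

Networks are exported as GraphML (node type, cycle and stress-category
attributes), SIF (interaction label `corr`), and a TSV edge list that
round-trips exactly; float fields are written with `repr` so re-import is
bit-faithful.

## The synthetic community generator

Ground truth for validation comes from a generative model of the annotated
read stream, not of sequences:

* **Abundances.** Taxon relative abundances are lognormal(μ=0, σ=1) draws,
  normalized — the standard skewed abundance model for microbial
  communities. σ=0 degenerates to a uniform community.
* **Repertoires.** Each taxon includes each catalog gene independently with
  probability 0.35 (functional) or 0.30 (stress), per-gene overridable;
  a taxon that draws no functional gene receives one at random, so every
  taxon participates in the carbon/nitrogen analysis.
* **Activity.** A read lands on (taxon t, gene g) with weight `p_t` for
  DNA and `p_t · α_t · e_g` for RNA, where α_t is a per-taxon activity
  multiplier (lognormal, σ=0.5 by default) and e_g a per-gene expression
  weight (1.0 unless set). The two factors mirror the two claims RNA:DNA
  ratios are used to make: organisms differ in overall activity, and genes
  differ in expression. Depths are multinomial, so requested library sizes
  are met exactly, and the exact cell probabilities are stored in the
  ground truth for recovery tests.
* **Quality noise.** A `noise` fraction (default 0.05) of rows receives
  scores failing exactly one filter criterion; all other rows pass all
  three (bit uniform on [50, 300], E-value log-uniform on [1e−30, 1e−5],
  alignment uniform on [15, 80] aa). Any distribution supported on the
  passing region would do; these are documented defaults, and the noise
  rows are by construction exactly the rows the default filter removes.
* **Streams.** DNA and RNA libraries draw from independent generators
  spawned from one seed, so either library is reproducible alone.

What the generator does **not** emulate: read lengths tied to alignment
quality, annotation errors that swap taxa or functions, rRNA carryover,
chimeras, uneven genome sizes, or correlated gene repertoires (real
repertoires follow phylogeny; simulated ones are independent across taxa).
Passing recovery tests therefore shows the estimators are correct under
multinomial sampling with known annotation quality — not that annotation
bias or RNA degradation in real libraries cancel out. Those caveats apply
to any RNA:DNA ratio analysis and are out of scope here.

## Problem sizes and numerical choices

Validation runs use 50-taxon communities at 2×10⁵ reads per library with 20
replicates for ratio recovery (taxa checked only when both expected counts
are ≥ 100, where the multinomial coefficient of variation is ≤ 10%);
rarefaction oracle checks use 10⁵ Monte-Carlo replicates; the network
false-positive control uses 40 species × 20 seeded simulations. These sizes
give stable validation statistics while keeping the whole suite fast on one
CPU. Degenerate inputs are handled explicitly: empty libraries make empty
matrices; an empty composition is an error; undefined ratios are values,
not exceptions; log fits and networks raise informative errors below their
minimum usable input (two distinct positive richness values; three
species).

## Known limitations

* The best-hit rule is a deterministic stand-in for however the upstream
  annotation server resolves multi-database hits; it is not a
  reconstruction of any particular server's behavior.
* The pipeline treats DNA and RNA libraries from one site as directly
  comparable after within-library normalization; compositional effects
  (one highly expressed gene depressing all other RNA fractions) are
  inherent to the ratio definition.
* The default stress-gene catalog is a small, documented marker set (e.g.
  orange carotenoid protein and photolyase for UV; superoxide dismutase,
  catalase, peroxiredoxin for oxidative; compatible-solute transport and
  mechanosensitive channels for osmotic), not an exhaustive ontology;
  real studies should supply their own catalog.
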