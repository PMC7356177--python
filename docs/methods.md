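# Methods

This note documents the models, parameter choices and numerical
conventions behind `lncnet`, and what the synthetic benchmark does and
does not establish about real data.

## Differential expression

Per feature, case and control log2 intensities are compared with a
Welch two-sample *t*-test (unequal variances). The vendor consoles used
for array studies of this kind do not document their exact statistic, so
the test function is isolated behind one interface (`deg.welch_tests`)
and can be swapped (e.g., for a moderated-variance test) without
touching selection logic. Welch on log2 values is the simplest
defensible two-group test for normalized array intensities.

* log2 FC = mean(case) − mean(control); the signed linear FC is
  `sign · 2^|log2FC|`, with +1.0 at exactly zero — down-regulation is a
  negative reciprocal (−4.52 means 4.52-fold down).
* Multiplicity: Benjamini–Hochberg across **all** features jointly.
  Coding genes and lncRNAs are filtered by the same rule, so one family
  is the conservative choice; `split_by_class` partitions afterwards.
* Selection: |FC| ≥ `fc_min` (default 1.5) and q ≤ `q_max` (default
  0.01), both boundaries inclusive ("at least" / "≤").
* Degenerate inputs: a group with < 2 samples is an error; features
  constant within both groups get p = 1 when group means agree and p = 0
  when they differ (the zero-noise limit), and are counted in the log.
  Note that rows built from identical floats can acquire ~1-ulp
  variance during mean subtraction, in which case the t-test returns an
  astronomically small (not exactly zero) p — selection is unaffected.

## DEG network and MCODE-style modules

The PPI edge list is undirected and simple: self-loops are dropped,
reciprocal/duplicate rows collapse keeping the maximum score, and edges
below `min_score` (default 0.4; the threshold a practitioner would apply
to a STRING experimental channel, exposed as config because no single
value is canonical) are excluded. The DEG network is the subgraph
induced on coding DEGs; "connected DEGs" counts nodes of degree ≥ 1.

Module detection follows the molecular-complex-detection (MCODE)
scheme with deterministic tie-breaks:

1. **Vertex weighting.** For node *v*, take the closed neighborhood
   graph; find its highest (largest-*k* non-empty) *k*-core by iterative
   peeling; weight(*v*) = *k* × density of that core, where density of a
   graph with *n* nodes and *m* edges is 2*m*/(*n*(*n*−1)) (0 for
   *n* < 2).
2. **Seeded growth.** Unclaimed nodes are visited in descending weight
   (ties: lexicographic id). A candidate starts at the seed and grows to
   a fixpoint, admitting an unclaimed neighbor when (a) its weight
   strictly exceeds `seed_weight × (1 − node_score_cutoff)` (default
   cutoff 0.2) and (b) it has ≥ 2 edges into the current candidate —
   the *coherence* condition; the very first addition to the
   single-node seed is exempt. Grown nodes are claimed whether or not
   the candidate survives post-processing, so modules are disjoint.
3. **Post-processing.** With `haircut` (default on, the plugin default)
   the candidate is reduced to its 2-core, guaranteeing within-module
   degree ≥ 2; candidates without a non-empty `k_core_filter`-core
   (default 4) are discarded; `fluff` (default off — fluffed nodes can
   be shared, breaking disjointness) optionally appends dense
   peripheral neighbors. Score = density × size; labels M1, M2, …
   follow descending score, ties broken by larger size then smallest
   member, so runs are reproducible and insensitive to input order.

The coherence condition is the one deliberate departure from a pure
weight-threshold expansion. When two dense regions of equal weight are
joined by a single edge, every vertex weight is identical and no weight
threshold can separate them; requiring two independent links into the
growing candidate keeps a lone bridge edge from fusing genuinely
distinct complexes (see `examples/03_module_detection.py`) while dense
regions, whose members share many edges, grow unimpeded.

`k_core` itself is computed by iterative peeling and is validated in the
suite against exhaustive subset search (≤ 12 nodes) and an independent
library implementation.

## Enrichment

One-sided over-representation only (the workflow never tests
depletion): p = P[X ≥ overlap] for X hypergeometric with the universe,
set-within-universe and query-within-universe sizes. Query and set
members outside the universe are intersected away at test time, with
dropped query genes logged. The universe defaults to all features of the
supplied annotation (standard practice when the assay interrogates a
defined feature space), or to the union of GMT members when no universe
is given. Two regimes mirror field conventions: GO biological processes
are reported at uncorrected p < 0.05 (strict), pathway collections at
Bonferroni p_adj ≤ 0.05 (inclusive); both alphas are config values.

## lncRNA prioritization cascade

Filters, in order, over the selected lncRNA DEGs: |FC| ≥ 4 (inclusive);
≥ 1 validated lncRNA→miRNA interaction; non-empty targeted-DEG set,
where targeted DEGs = (direct lncRNA→gene targets ∪ gene targets of the
lncRNA's miRNAs) ∩ coding DEGs — a set union, so a gene reached both
ways counts once, and direct targets count even for lncRNAs without a
miRNA route. Module coverage is the set of module labels whose members
intersect the targeted DEGs; *prioritized* requires covering the label
set of **all** detected modules, not a majority. Each record carries an
independent pass flag per filter, so composing the filters equals
intersecting their pass sets and the report shows where each lncRNA
fell out. Targeted-DEG counts use coding DEGs only (module genes are
proteins); the records keep the full sets so other conventions can be
derived.

## Synthetic data: what it emulates

`GeneratorConfig` defaults define a down-scaled 10 vs 10 microarray
cohort: 2000 coding features and 300 lncRNAs, 5% differentially
expressed with linear |FC| drawn in [1.8, 6], i.i.d. Gaussian log2 noise
with sd 0.3 (log-normal intensities, the standard array approximation),
baseline log2 means uniform in [5, 12] (typical intensity range, inert
to the statistics). Six modules of eight genes are planted as cliques
with ≤ 10% edge dropout constrained so every member keeps within-module
degree ≥ 4 (hence `module_size` ≥ 6); within-module edge scores lie in
[0.7, 0.99], background edges (probability 0.01 among DE genes plus an
equal margin of non-DE genes) in [0.4, 0.7]. Two driver lncRNAs get one
miRNA per module targeting ~60% of its genes plus direct gene targets;
four decoys each fail exactly one cascade stage (sub-threshold FC, no
miRNA, targets outside the DEG set, partial module coverage).

Identifiability by design: the planted lncRNA magnitudes keep a
4-standard-error guard band (SE of the measured log2 FC =
`noise_sd · sqrt(1/n_case + 1/n_control)`, ≈ 0.134 at defaults) away
from both decision boundaries (1.5 and 4), and the partial-coverage
decoy's chains omit two modules rather than one so a single spurious
module merger downstream cannot hand it full coverage. Configurations
whose noise leaves no feasible decoy interval are rejected. Under these
conditions the planted drivers are recovered, and all decoys rejected
at their designed stages, in 20/20 seeds at the suite's problem sizes.

All randomness flows from one root seed through fixed named
`SeedSequence` streams (truth, matrix, network, regulatory, gene sets),
so every artifact is byte-reproducible and independent of generation
order.

What passing recovery tests does **not** show about real data: the
generator has no probe-level effects, batch structure, sample
covariates, correlated noise, or annotation errors; its regulatory
annotation is exact (real lncRNA→miRNA→gene databases are incomplete
and noisy), its modules are planted cliques rather than organically
dense regions, and real PPI confidence scores are not uniform draws.
Recovery here demonstrates the correctness of the pipeline's logic, not
the sensitivity of the workflow on noisy annotations.

## Numerical conventions

* TSV dialect: UTF-8, tab-separated, one header row, `#` comments;
  floats written with `%.17g` and read with round-trip precision, so
  write→read is bit-exact.
* All tie-breaks (seed choice, labels, table ordering) are
  deterministic; two runs from one config produce byte-identical files,
  and manifests record config hash, seed, stage counts and SHA-256
  checksums.
* Hypergeometric tails come from `scipy.stats.hypergeom.sf`, BH from
  `statsmodels` (both cross-checked against enumeration/step-up oracles
  in the suite).

## Known limitations

* The two-group test is unmoderated; with very few samples per group an
  empirical-Bayes variance model would be more powerful.
* Enrichment ignores GO graph topology and gene–gene correlation.
* Module detection parameters (k-core 4, cutoff 0.2) follow the usual
  PPI-complex settings; very sparse networks may yield no module, in
  which case module coverage is undefined and the cascade stops with an
  explicit error.
* The headline counts of any specific published cohort (e.g., numbers
  of DEGs or connected genes) are functions of that study's raw data
  and annotation versions and are not reproducible from summary tables;
  the pipeline reproduces the published *decision logic* instead.
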