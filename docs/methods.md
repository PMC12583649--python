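# Methods

This note documents the models, numerical choices and known limitations
behind `coregflow`. Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Problem setting

A regulator's activity is often invisible at its own mRNA level: kinases
activate transcription factors post-translationally, so a two-group test
on the factor's expression misses the event even while its target genes
shift en masse. The package follows the regulon strategy: learn each
regulator's activated targets *A*ʳ and repressed targets *I*ʳ from a
reference compendium observed under diverse, unperturbed conditions, then
score the regulator's activity in new samples from the contrast between
those two gene sets.

## Network inference

### Discretization

Each gene is standardized across samples (mean, unbiased SD) and mapped to
{−1, 0, +1} at ±`z_threshold` SDs; zero-variance genes become all-0 rows.
The `discretize` primitive defaults to ±1 SD. The *inference* entry point
defaults to `z_threshold = 0.6`: at ±1 SD only about a third of samples
carry a non-zero state, and with 30 regulators the discrete fit then has
too little resolution to separate true programs from the combinatorial
background — lowering the threshold to 0.6 SD roughly doubles the
informative sample fraction and measurably improves edge recovery on
synthetic data. Both are exposed parameters.

### Candidate mining

Co-regulator sets are mined level-wise (apriori): a set is frequent when
its members are jointly +1 or jointly −1 in at least `min_support`
(default 0.1) of samples. The combined two-direction support is
anti-monotone, so the level-wise search is exact. Ordering is
deterministic (support descending, then lexicographic).

### Per-target screening and program search

Scoring every mined (*A*, *I*) pair against every target overfits badly:
with tens of thousands of pairs and a few dozen samples, the best
training-fit program is usually spurious. Each target therefore gets a
regulator shortlist first: a regulator may act as activator (repressor)
only if its discrete co-expression with the target — the mean product of
their three-state values — exceeds `min_coexpression = 0.09` (falls below
its negative) *and* ranks among the target's `max_regulators_per_target =
6` strongest in that direction. Candidate programs pair mined sets lying
inside the shortlist on each side (either side may be empty, not both);
programs are ranked by fit with deterministic tie-breaks (fit, then total
regulator count, then lexicographic members).

Up to `max_programs_per_gene = 400` programs under `fit_cutoff = 1.0` are
retained per gene. The list is deliberately deep: the discrete fit alone
cannot reliably place the true program first, but the evidence-integration
stage re-ranks the whole list, and external evidence is far more
discriminating than fit differences of a few hundredths. With the
shortlist in place the per-gene candidate space is small (a few hundred),
so the deep list costs little.

### Evidence integration

The selected program per gene maximizes
`(1 − fit/2) + λ · evidence_support` with `λ = 1` by default.
`evidence_support` averages two fractions: the program's regulator→target
edges present in the pooled TF-binding/ChIP evidence, and its cooperating
regulator pairs present in the protein-interaction evidence. Cooperating
pairs are counted *within* each side (co-activator pairs plus co-repressor
pairs): an activator and a repressor of the same gene are not a
cooperation claim, and counting cross-side pairs systematically punishes
true activator+repressor programs against their singleton sub-programs.
The pair term is dropped when no side has two regulators. Selection is
monotone in λ and reduces to fit-only selection at λ = 0.

Evidence enrichment of a finished network is a hypergeometric upper tail:
for protein interactions the universe is all unordered pairs of network
regulators and the network draws its co-regulator pairs; for TF→target
evidence the universe is all regulator×target pairs and the network draws
its program edges. Both universes are provided because either convention
is defensible; the report stage computes both.

## Influence

For regulator *r* and one sample, influence is the Welch statistic
comparing the expression of *A*ʳ against *I*ʳ within that sample, with
unbiased variances. Conventions:

- **Eligibility** — at least `min_targets = 5` regulon genes, counted over
  both halves combined by default (`per_side` mode requires each nonempty
  half to reach the threshold on its own).
- **One-sided regulons** — the formula is undefined when a half is empty.
  By default the nonempty half is contrasted against all profiled genes
  outside the regulon, flagged `one-sided-fallback`; `strict` mode excludes
  such regulators. Activator-only regulators are the majority in inferred
  networks, so silent exclusion would hide most of the network.
- **Single-gene halves** have no unbiased variance and are routed through
  the same fallback.
- **Query standardization** — the query matrix is per-gene centred and
  scaled before scoring (flag `standardize`). The reference network comes
  from a different dataset, so raw scales are not comparable; the flag
  records the choice.
- A zero denominator (both halves constant) yields an undefined value;
  regulators with undefined values in any sample are excluded from
  differential testing.

A regulator counts as *active* in a sample only when its influence is
strictly positive.

## Differential analysis

Per feature (regulator influence, or gene log2 expression), a two-sided
Welch t-test contrasts condition B against A; p-values are BH-adjusted
across features via `statsmodels`. Classification is strict: up-DIR iff
adj. p < 0.05 and Δ influence > 0.5; up-DEG iff adj. p < 0.05 and
log2 FC > log2 1.5. The influence difference is the raw condition-mean
difference, not a model coefficient. Per-feature Welch tests stand in for
a moderated linear model; at the simulated group sizes (20 per condition)
variance moderation changes rankings negligibly, and the self-contained
test keeps the pipeline dependency-light.

Note that BH adjustment is *not* idempotent in general — re-adjusting an
adjusted vector multiplies by n/j again; constant vectors are the fixed
points. The test suite asserts the step-up definition directly.

Over-representation of gene sets in a DEG list is the hypergeometric upper
tail P(X ≥ overlap); batch mode BH-adjusts across the collection and
reports gene ratios (overlap / query size). Gene-set collections arrive as
GMT files; when none is supplied the pipeline uses the inferred network's
own regulons (≥ 5 genes) as the collection, which keeps the stage
exercised and deterministic.

## Co-regulatory graph

Nodes are the up/down-classified DIRs with their regulon sizes and
influence differences. Two nodes are joined when they co-occur in at least
`min_shared_targets = 1` programs; the edge is typed `ppi_evidence` if the
pair has an interaction record, `transcriptional_evidence` if either
regulator's own gene is an evidenced target of the other (direction kept
as an edge attribute), else `inferred_only` — types are not exclusive.
The regulatory node is the largest connected component among up-DIRs,
ties broken toward the lexicographically smallest member; connected
components stand in for the visual clustering a network viewer would
perform. `mean_group_influence` is defined here as the arithmetic mean of
the members' influence differences — a deliberate interpretation, since
no closed formula exists for the quantity upstream. GraphML export keeps
all attributes on an undirected document (direction as an attribute) so
that re-import reproduces the graph exactly; SIF writes one row per edge
type, transcriptional rows per evidenced direction.

## Synthetic data

The generator emulates a two-condition perturbation study mapped onto a
reference network:

- regulator activities are iid Normal(0, 1) per sample; the
  `planted_node_size = 3` planted regulators gain `delta = 2` activity
  units in the stimulated condition (conditions beyond the second act as
  inhibitor arms with the shift zeroed);
- regulator mRNA is activity plus Normal(0, `sigma = 1`) noise; with
  `decouple_mrna` the planted regulators' mRNA omits the shift while their
  targets still respond — the influential-without-mRNA-change phenomenon;
- each target's expression is the weighted sum of its activators'
  activities minus its repressors', plus noise; weights are uniform on
  (0.8, 1.2); non-block targets draw 1–2 activators and 0–1 repressors,
  sizes chosen as typical of sparse curated regulatory maps;
- the planted regulators are joint co-activators of a dedicated 30-target
  block and carry pairwise protein-interaction evidence;
- the evidence layer keeps a `coverage = 0.8` fraction of true edges and
  adds `fpr = 0.05` spurious ones, per edge class;
- `simulate_reference` draws a 206-sample unstimulated compendium from the
  same seed-determined network and weights — the size of a typical
  cancer cell-line panel — on which the pipeline infers the reference
  network, mirroring the compendium-then-query design. Defaults use
  20 samples per condition in the query.

Seven ordered random sub-streams (activities, weights, topology, noise,
evidence, reference activities, reference noise) derive from one seed, so
outputs are byte-reproducible and a change confined to one stage leaves
the others untouched.

What the generator does **not** model: count noise and mean–variance
dependence (values are Gaussian on a log-like scale), batch effects,
correlated regulator activities beyond the planted shift, feedback, or
TF→TF regulation (regulators are not targets of other programs by
default). Passing tests therefore demonstrate correct recovery of additive
planted structure under Gaussian noise — not performance on raw RNA-seq
counts or confounded designs.

Note one identifiability consequence: in the unshifted reference
compendium the planted regulators' activities are independent, so their
triple is not a frequent itemset there; cooperative block programs are
recovered as planted *pairs*, which still connects the node and assigns
each member a large regulon.

## Problem sizes

Tests and the acceptance script use the generator's default conditions
(30 regulators, 300 targets, 20+20 query samples, 206 compendium samples)
with 20 independent seeds for recovery statistics, 50 runs for null
calibration, and 200 random instances for the influence oracle check. The
full suite runs in well under a minute; these sizes give recovery-rate
estimates with ±0.05–0.1 Monte-Carlo error, adequate for the pass/fail
bounds asserted.

## Degenerate inputs and numerical conventions

- Duplicate gene or sample identifiers, non-numeric cells and design
  mismatches raise distinct error types at read time.
- Missing expression values follow an explicit policy: `fail` (default)
  or `gene-mean` row imputation; the pipeline uses `gene-mean`. This is a
  deliberate, simple stand-in for latent-signal estimation of unobserved
  genes, which is out of scope.
- Zero-variance genes discretize to all zeros and standardize to zeros.
- All orderings (candidate sets, program ties, graph components, output
  rows) have deterministic tie-breaks; floats are serialized at 10
  significant digits; manifests carry no timestamps, making output
  directories byte-reproducible.

## Known limitations

- The discrete fit is a coarse likelihood surrogate; with strong noise the
  inferred program is often a correct sub-program (precision is favoured
  over recall). Reported F1 on synthetic data reflects this.
- Evidence integration assumes evidence errors are independent of the
  expression noise; adversarially wrong evidence will mislead selection
  in proportion to λ.
- The one-sided fallback changes the scale of influence for
  activator-only regulators relative to two-sided ones; comparisons across
  regulators should rely on the differential test, not raw values.
- Multi-factor and paired designs are out of scope; contrasts are
  explicit ordered condition pairs.
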