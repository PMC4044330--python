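# Methods

`mirlink` implements an integrated miRNA–mRNA expression analysis of the
kind used for bulk time-course injury studies — here modelled on
radiation-induced lung injury (RILI) in the rat, observed at an early
pneumonitis stage (3 weeks post-irradiation), a middle stage (12 weeks) and
a late fibrotic stage (26 weeks), each with its own sham-treated control
condition. The pipeline turns probe-level array intensities into
stage-wise differential-expression (DE) calls for mRNAs and miRNAs,
screens each DE miRNA for enrichment of its predicted targets among the
directional DE mRNA lists, extracts reciprocal (anti-correlated)
miRNA→target pairs, and exports the resulting bipartite regulatory
network. A synthetic-data generator with planted regulatory structure
makes every stage verifiable without external data.

## Preprocessing

Probe-level matrices carry per-spot quality flags (0 = fine signal). The
fixed processing order is:

1. **Flag filtering.** Cells with a nonzero flag become missing; probes
   whose fine fraction falls below `min_fine_fraction` (default 0.5) are
   dropped. Surviving values are never altered.
2. **log2 transform**, only if the matrix is still on the linear scale
   (a `scale` marker prevents double application).
3. **Quantile normalization** at probe level. Every column is mapped onto
   the cross-column mean of sorted values; within-column ranks are
   preserved; a tie group receives the mean of the reference values its
   rank range spans; missing cells are ignored (available-case ranks
   interpolated onto the reference grid) and stay missing. Normalizing
   before probe collapsing follows the convention of the standard
   array-processing stacks.
4. **Probe collapsing** to one row per feature (median by default over the
   triplicate spots; mean available). Features with no observed cell are
   dropped and logged.

Rank normalization presumes that column distributions are close to
exchangeable — i.e., that most features are unchanged between samples.
Two consequences are deliberately surfaced rather than hidden:

* the synthetic generator's default DE density is kept realistic
  (see below), because planting effects into a large fraction of the
  transcriptome would violate this assumption by construction;
* the zero-noise exactness checks run with normalization disabled
  (`quantile=False` in `preprocess_pipeline`, `quantile_normalize: false`
  in the pipeline config). With planted shifts and exactly zero residual
  noise, rank normalization converts rank displacement into value changes
  — a null feature that is overtaken in rank by shifted features acquires
  a nonzero group difference with zero variance, which is then an
  arbitrarily significant spurious call. That is a property of the method,
  not a bug, and the exactness contract is therefore defined on
  unnormalized noise-free data.

## Differential expression

For each feature at each stage, irradiated and control replicates are
compared with a Welch (unequal-variance) two-sample t-test, with
Satterthwaite degrees of freedom; the effect size is the log2 fold change
mean(irradiated) − mean(control). Degenerate inputs follow a fixed
contract: both groups constant with equal means → t = 0, p = 1; both
constant with unequal means → p = 0 with a logged warning; fewer than two
finite values in a group → feature skipped and counted.

Benjamini–Hochberg FDR is computed within each (platform, stage) family
over the features actually tested. A feature is called **up** when
log2FC ≥ `fc_threshold` (default 1, i.e. 2-fold) *and* the significance
rule holds, **down** symmetrically. The significance rule defaults to raw
p < α (α = 0.05), matching the common "≥2-fold and P < 0.05" calling
convention for this assay class; `significance_on: fdr` switches the gate
to the BH-adjusted values, and the FDR column is always reported either
way. Cross-stage Venn cells (features called in exactly a given subset of
stages, per direction) are computed by exhaustive set arithmetic and are
invariant to stage ordering.

Small-sample note: with four replicates per group, the Welch approximation
is mildly conservative — its true size at nominal α = 0.05 is ≈ 0.042
under a normal null (measured both for this pipeline and for the reference
implementation in scipy). The null-calibration check accordingly verifies
the call rate to within three binomial standard deviations of a 5,000-test
family rather than asserting 0.05 exactly.

## Target screening and reciprocal pairs

The integration universe is the set of mRNA features tested at the stage —
the DE family and the Fisher family coincide by construction. For every
DE miRNA, two 2×2 tables are built (against the up- and the down-regulated
mRNA lists): a = DE∧target, b = DE∧¬target, c = target∧¬DE, d = neither.
The two-tailed Fisher exact p sums the hypergeometric probabilities of all
tables with the observed margins that are at most as probable as the
observed table (minimum-likelihood convention — two-tailed Fisher has
competing definitions, so this one is pinned and oracle-tested). The odds
ratio is the sample estimate ad/bc, infinite when bc = 0 with ad > 0 and
undefined (NaN, with p = 1) when a margin is zero. A miRNA with no targets
inside the universe yields a marked p = 1 row rather than an exception.
No correction across screens is applied by default (each miRNA is reported
at its own p, as is conventional for this screen); a BH-across-screens
switch exists and is logged when used. miRNA families sharing seed
sequences are *not* collapsed; each miRNA is screened independently.

A **reciprocal pair** is a predicted miRNA→gene edge whose endpoints are
DE in opposite directions at the same stage. With pooled hybridizations
there is no per-sample correlation to exploit, so opposite DE direction
plus a prediction edge is the operational definition of a candidate
repressive interaction. `pair_summary` reduces the pair table to the
per-stage counts of distinct up-miRNAs / their down-targets and
down-miRNAs / their up-targets.

## Enrichment, network, qPCR

**Enrichment** replaces web-service annotation with an auditable upper-tail
hypergeometric test of a DE gene list against user-supplied GMT
collections, BH-corrected within each category. The default background is
the tested (array) features, configurable. An EASE-style variant (one
overlap gene discounted) is available but off by default: the plain tail
is exact and oracle-testable. Reports default to the top 20 sets per
category in the CLI.

**Network.** Reciprocal pairs across stages union into a directed
bipartite graph (miRNA → gene); multi-stage support is an edge attribute
(not parallel edges), along with the best supporting screen p. Exports:
SIF (`mirna represses gene`), GraphML (typed attributes), and edge-list
TSV, all in deterministic lexicographic order. An optional top-N miRNA
restriction ranks by smallest screen p, then pair count, then id — a
transparent choice for "top identified miRNAs" selections whose ranking
statistic is conventionally left unstated.

**qPCR.** Relative quantities use the pure 2^−ΔΔCt model: technical
replicates averaged on the Ct scale, ΔCt = Ct(target) − Ct(reference)
per sample, ΔΔCt referenced to the mean ΔCt of the calibrator group within
the same stage and assay, rq = 2^−ΔΔCt. The calibrator group's mean ΔΔCt
is zero by construction. No amplification-efficiency correction is
applied. The reference assay (e.g. U6 snRNA for miRNA assays) is always
explicit input — there is no default housekeeping gene. Replicate sds
above 0.5 cycles flag the affected rows.

## Synthetic data generator

The generator emulates the shape of a pooled rat irradiation study:

* three stages with stage-matched sham controls (a single reused control
  pool is available via `stage_matched_controls=False` semantics of the
  label layout); four replicate hybridizations per condition by default,
  with a `paper_faithful()` switch to two (pooled designs hybridize each
  pool twice; a 2-vs-2 Welch test is statistically fragile, so the default
  keeps the design's shape but stabilizes the tests);
* every feature printed as three replicate probes; per-spot flag failures
  at rate 0.02; intensities on the log2 scale, baseline ~ N(8, 1.5²);
* a bipartite prediction graph (30 predicted targets per miRNA), each edge
  *functional* with probability `repression_penetrance` (0.8);
* ~6% of miRNAs DE (cf. 23 of 387 assayed in the motivating study), fixed
  direction, |effect| ~ N(2, 0.25²) clipped below at 1 log2 unit so
  planted truth is detectable under the 2-fold rule; per-stage activity via
  a one-factor Gaussian copula (marginal 0.8, cross-stage correlation 0.5,
  reproducing large cross-stage overlaps); functional targets receive the
  opposite-sign effect; ~5% of unregulated genes are DE independently,
  yielding an overall DE density of roughly 10–20% of genes per stage
  (cf. ~5100 of >41000 transcripts);
* noise: per-(feature, sample) residual sd 0.25 log2 units; per-spot probe
  noise at half that, so triplicate collapsing visibly reduces variance;
* when several active miRNAs regulate one gene with conflicting signs, the
  largest-magnitude regulator wins (deterministic tie-break by id); true
  reciprocal pairs are then *derived* from the final labels and the
  functional edges, so the truth tables are self-consistent by
  construction.

Every draw comes from a child RNG keyed by `(seed, site label)`, so truth
and expression are pure functions of (seed, parameters), fixtures are
byte-identical across runs *and processes*, and adding a draw site never
reshuffles earlier streams.

What the generator does **not** model: dye chemistry, spatial artifacts,
background correction, intensity-dependent variance, probe affinity
biases, or correlated biological replicates. Passing recovery tests on
these data therefore demonstrate the correctness and calibration of the
analysis chain, not the field performance of the array platforms.

## Validation and problem sizes

The test suite checks, among others: exact agreement of the two-tailed
Fisher p with exhaustive enumeration (1,000 random tables, N ≤ 60), of BH
with the step-up definition (1,000 random vectors), and of the enrichment
tail with direct summation (N ≤ 200); distribution equality after quantile
normalization (100 random complete matrices); null calibration over 200
seeded replicates of a 5,000-gene, 4-replicate single-stage design (DE
call rate within 3 binomial sds of α for a 5,000-test family; Fisher
screen false-positive rate bounded by α + 3 sds of the pooled screen
count); planted-structure recovery at the default conditions (per-stage DE
sensitivity ≥ 0.9, observed false-discovery proportion ≤ 0.1, pair
precision and recall ≥ 0.8); the zero-noise exactness limit; the qPCR
closed forms; and byte-identical manifests for repeated `run_all`
invocations. Problem sizes were chosen so the whole suite runs in a couple
of minutes on one CPU while keeping every statistical check adequately
powered.

## Known limitations

* The per-miRNA screen tests each miRNA marginally; co-targeting by
  correlated miRNA families will produce correlated screens.
* Direction-based pairing cannot distinguish direct repression from
  co-regulation; the planted-truth evaluation quantifies exactly this
  (predicted-but-nonfunctional edges whose gene moves for other reasons
  appear as precision loss).
* Quantile normalization assumes majority-null columns; analyses of
  conditions with transcriptome-wide shifts should disable it or use
  spike-in anchored methods, which are out of scope.
* The Welch test's small-sample conservativeness (size ≈ 0.042 at nominal
  0.05 with 4+4 replicates) is inherited by design; moderated-variance
  (empirical Bayes) statistics are intentionally not provided.
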