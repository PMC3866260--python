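# Methods

## The circuit model

A *circuit* is a triple (miRNA, TF, mRNA) in which all three pairwise
regulatory relations are supported twice over: structurally, by membership
in the three typed interaction pair sets (miRNA→gene, TF→gene, miRNA→TF),
and statistically, by significant pairwise expression correlation within a
developmental stage. TFs enter the expression analysis through their coding
gene's mRNA profile; a candidate whose target gene *is* the TF's own coding
gene is excluded by default (the TF–gene edge would be a self-correlation),
with an explicit switch to allow it.

The pipeline is: read and normalize inputs → variance-filter the gene
universe → assemble candidates → segment the time axis into stages → test
every candidate in every stage → set-level context analyses → enrichment.

## Identifier handling

miRNA names are lower-cased (unifying `miR`/`mir`, retaining a species
prefix when present); gene and TF symbols keep their spelling but all
membership tests fold case. This resolves the spelling heterogeneity typical
of mixed database exports without attempting any probe-to-symbol mapping:
inputs are assumed to be keyed by symbol already. Rows with missing or
unparseable expression values are rejected at read time with a logged count,
so the correlation machinery never sees missingness; with genome-scale row
counts the loss is negligible and no imputation rule has to be invented.

## Variance filter

Per-entity sample variance (unbiased, n−1) is computed across *all* columns
— every time point and replicate. Two policies:

- `absolute_threshold v`: keep rows with variance strictly greater than v.
- `quantile q` (default, q = 0.25): drop the `floor(q·n)` lowest-variance
  rows (stable sort). The rank-based rule makes the boundaries exact:
  q = 0 keeps everything, q = 0.25 on 200 rows keeps exactly 150, and a
  constant row is always in the dropped set for any q > 0.

The default quantile is deliberately arbitrary and exposed in configuration:
the appropriate cutoff is data-dependent and should be chosen per study.

## Stage segmentation

The shipped preset encodes the published reading of murine lung
development: `early` = time points 1–3, `late` = 4–6, the final
(maturation-like) point excluded, and a derived `whole` stage equal to the
union of all non-excluded points. `whole` is always present exactly once
and is never stored as a named stage, so the named stages stay disjoint.

Alternatively the partition is suggested from the data: expression rows are
z-scored (mean 0, unit n−1 variance), columns are clustered agglomeratively
with correlation distance (1 − Pearson) and average linkage by default, the
dendrogram is cut at k groups, and replicates of a time point vote by
majority (ties to the lower group index). Ties in the minimal inter-cluster
distance break toward the lowest cluster indices, making the merge order
fully deterministic; the agglomeration is a direct Lance–Williams update so
the tie-break is under our control, and it agrees with standard library
linkage on tie-free data. Every stage must keep at least 3 time points —
with fewer, a permutation test over collapsed replicates cannot reach
conventional significance. Because the published stage choice mixes
clustering with biological judgment, automatic suggestion never silently
overrides the preset: the partition source is explicit configuration.

## The permutation test

For vectors x, y over a stage's columns the statistic is the Pearson
correlation implemented exactly as the centered cross-moment over the
product of centered norms; a zero-variance vector makes the correlation
*undefined*, which marks the edge non-significant but never raises.

Null distribution: y is permuted with x fixed (permuting both is redundant
under exchangeability). If n! ≤ `exhaustive_cap` (default 10,000, i.e.
n ≤ 7) all n! permutations are enumerated, the identity included, and
p = #{perm : stat ≥ stat_obs − tol}/n!. Otherwise B Monte-Carlo draws
(default 10,000) from a seeded generator give the add-one estimate
p = (1 + #extreme)/(B + 1), which is valid and strictly positive. The
comparison tolerance (`tie_tolerance`, 1e−12) counts exact ties as extreme.
The two-sided statistic is |R|; an optional sign-constrained mode tests
signed R against a required direction per edge kind (e.g. negative for
miRNA edges) for sensitivity analyses — the default is two-sided because
the published procedure constrains no signs.

Significance uses p ≤ α (not <): permutation p-values are discrete and ≤ is
the exact-test convention. α defaults to 0.05 with no multiple-testing
correction across edges or candidates, matching the raw-threshold
procedure; BH-adjusted reporting is available in the enrichment layer and
the results table carries all p-values for post-hoc adjustment.

Replicates are **concatenated** by default (all stage columns in (time,
replicate) order), not averaged. A 3-time-point stage with averaged
replicates has only 3! = 6 orderings, so the smallest achievable p is
1/6 > 0.05 and *no* edge could ever be significant there; concatenating two
replicates gives n = 6 and 720 orderings. This is the minimal reading under
which 3-point stages can produce circuits at α = 0.05.

Determinism: every (edge, stage) derives a stable 31-bit sub-seed from the
master seed and the edge identity, so results do not depend on candidate
order or on the edge cache. The cache (one test per distinct (pair, stage),
shared across candidates) is therefore semantically invisible and is
verified as such.

## Synthetic data

The generator emulates a two-class (miRNA/gene) time course: default 7 time
points × 2 replicates, stages early (t1–3) and late (t4–6) with t7
excluded, 50 planted circuits per stage, decoy pairs, and independent
Gaussian replicate noise (sd 0.05) around per-time means. Replicates share
the time-point mean — the two-animal reading of a two-sample design — and
the run is a pure function of the seed.

Each planted circuit owns a latent driver s(t) over its stage's time
points: i.i.d. standard-normal draws, **standardized within the stage**
(mean 0, unit sample variance). Standardization matters: with raw draws the
realized driver spread of a 3-point stage is so variable that the mean
realized edge correlation falls well short of its target (a Jensen effect),
whereas with a fixed spread the analytic signal-to-noise calibration is
exact. The three member entities load on the driver with coefficient
±a, where

    a = noise_sd · sqrt(r / (1 − r)),   r = edge_target_abs_r (default 0.95),

so each observed profile correlates sqrt(r) with the driver and the expected
pairwise within-stage correlation of any two members is exactly r. The
miRNA loads negatively by default (repression); TF and gene load
positively. Outside its stage a planted entity is pure noise, as are
background entities everywhere — their columns are exchangeable, forming an
exact permutation null; decoy pairs are drawn among background entities and
are therefore listed-but-independent by construction.

**Identifiability of planted drivers.** A short stage admits rearrangements
of a replicated profile that correlate strongly with the original: for a
2-replicate 3-point stage, every profile has a non-trivial rearrangement at
|corr| ≳ 0.91, and a driver whose best rearrangement nearly ties the
identity is indistinguishable from it by an exact permutation test — the
aliasing orderings inflate the p-value past α even at |R| ≈ 0.95. Drivers
are therefore rejection-sampled until no rearrangement of the replicated
stage profile exceeds `max_alias_correlation` (default 0.93, just above the
geometric floor) in absolute correlation with the original. The bound is
enforced only for replicated stage lengths ≤ 6: for longer stages aliases
are a vanishing fraction of n! and cannot consume the α count budget (and
close duplicated values would make an absolute bound unattainable). This
guarantees that "planted" means "recoverable in principle"; it does not
touch background or off-stage expression, so null calibration is unaffected.

A separate helper, `generate_stage_profile_matrix`, produces the structure
two-way clustering actually detects — gene groups with opposite block-wise
stage profiles — because per-circuit random drivers deliberately carry no
column-level block signal.

**What the generator does not emulate:** microarray intensity
distributions, probe effects, normalization artifacts, correlated
regulatory cascades, or shared regulators across planted circuits (planted
entity sets are disjoint). Passing recovery tests therefore demonstrates
the statistical machinery, not robustness to array-specific noise.

## Set-level analyses

Overlaps, gene-set restriction, exclusive regulators and common-node
networks are pure set algebra over the detected circuits (compared as id
triples, ignoring statistics) and are all verified against brute-force
reconstructions. The common-node network keeps circuits containing *at
least one* node (of matching class) present in both stages' circuits —
the interpretation consistent with mixed common/non-common membership in
published cross-stage examples — and merges them with per-edge stage tags.

## Enrichment

Over-representation of a circuit gene list against a GMT collection uses
the exact hypergeometric upper tail P(X ≥ k) (scipy's survival function),
or the conservative EASE variant with k replaced by max(k−1, 0).
The default background is the variance-filtered analysis universe — the
set of genes that could have appeared in circuits — not the genome;
annotation terms are intersected with that universe before testing.
Raw p-values are reported with BH adjustment alongside and a flag at the
conventional p < 0.05 threshold. Reproducing any specific annotation
database or its historical p-values is out of scope; collections are
opaque inputs.

## Problem sizes used in validation

The validation suite exercises: exhaustive-vs-brute-force permutation
agreement for all n ≤ 6 (100 instances); Monte-Carlo/exhaustive agreement
at n = 5 with B = 10⁵; type-I calibration from 2,000 independent Gaussian
pairs at n = 8 with B = 10⁴ (rejection rate within [0.04, 0.06]); a global
null of 10,000 candidate triples over three stages (circuit rate ≤ 0.002,
theoretical α³ ≈ 1.25×10⁻⁴); planted recovery at the default design
(recall ≥ 0.9 per stage, ≥ 90% stage-exclusive assignment); stage-block
recovery on 20 seeds; 50-instance set-algebra and candidate-assembly
oracles; exact combinatorial enrichment checks for all universes N ≤ 30;
and byte-level reproducibility of a full pipeline rerun.

## Known limitations

- With 3-point stages (n = 6 concatenated) the sampling noise of a
  correlation is large: a planted edge at target 0.95 occasionally realizes
  |R| < the i.i.d.-null 99th percentile (~0.92 at n = 6). Separation of
  planted from null edges is therefore probabilistic at this design and
  absolute only for longer stages; recovery operates through the
  permutation p-value, not a correlation cutoff.
- Candidate counts and circuit counts from any real study depend on the
  interaction databases and their versions; they are descriptive context,
  not reproducible targets of this implementation.
- The permutation test assumes exchangeability of columns within a stage
  under the null; replicate concatenation treats replicates as independent
  draws, which is the weakest workable assumption but understates
  within-animal correlation if replicates are not biological.
- Identifier normalization is string-based; no ortholog or alias resolution
  is attempted.
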