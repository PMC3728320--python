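# Methods

`plastid-delim` implements a single-locus species-delimitation workflow for
low-divergence plant groups: descriptive alignment statistics per marker,
DNA-barcode discrimination, tree-based classification of species as mono-,
para- or polyphyletic, and general mixed Yule-coalescent (GMYC) lineage
delimitation on an ultrametric chronogram, together with a
multispecies-coalescent simulator that generates data with known truth.

## Alignment statistics

**Character conventions.** Sequences are upper-cased, `?` is normalised to
`N`, and IUPAC ambiguity codes are retained in the data but treated as
missing by every statistic — one consistent rule, stated in the reports.
Partitions are stored 1-based inclusive (the NEXUS `charset` convention
users edit); all internal site arithmetic is 0-based half-open.

**Site classes.** A column is *variable* when two or more distinct
unambiguous bases occur, and *parsimony-informative* when at least two bases
each occur in at least two sequences. The default gap policy (`missing`)
simply ignores non-ACGT states at each site, matching the behaviour of
parsimony software from which published informative-site counts come; the
alternative `exclude_site` policy counts any column containing a gap or
missing state as excluded. The four class counts always sum to the region
length.

**Diversity.** Watterson's `theta_w = S / (a_n * L_eff)` per site and mean
pairwise diversity `pi` per site are computed, by default, under *complete
deletion* (every column containing any gap/missing state is dropped first),
matching the convention of the population-genetics software such statistics
are usually reported from. *Pairwise deletion* is available: each sequence
pair is compared over its own mutually unambiguous columns and normalised
by that pair's column count. Both modes are checked against an independent
all-pairs/all-sites brute-force oracle on random alignments.

**Haplotypes.** `strict` identity is byte equality. `distance_zero`
identity merges two sequences whenever no column shows two differing
unambiguous bases — the "pairwise distance zero" de-duplication used when
collapsing sequences with missing data — closed transitively by single
linkage, which makes the partition deterministic. Strict classes always
refine distance-zero classes.

**Indels.** Each maximal gap run per row is a candidate event; candidates
with identical (start, end) merge into one event, and runs touching the row
ends are treated as missing data (partial reads), never as indels. Simple
indel coding emits one binary character per event: `1` for rows gapped
exactly over the span, `0` for rows fully nucleotide across it, and `-`
(inapplicable) for rows whose gap strictly contains the event, partially
overlaps it, or whose span contains missing data. An optional column
exclusion mask in the run config handles features such as small inversions
that should not be scored as substitutions; no automatic inversion
detection is attempted.

## Barcode discrimination and species status

A species is *discriminated* (diagnosable) by a marker iff **every**
haplotype class containing one of its sequences contains only its
sequences; a single private haplotype is not enough. Outgroups are excluded
from classes and denominators. A marker is *group-diagnostic* (e.g. for
taxonomic subsections) iff no haplotype class spans two groups.

On a rooted tree, a species is monophyletic iff the clade under the MRCA of
its tips is pure (singletons are monophyletic by definition). Otherwise we
compute the minimum number of *origins* of the binary character "belongs to
the species" over all most-parsimonious reconstructions, counting a
root-state origin as one; one origin = paraphyletic, two or more =
polyphyletic. The minimisation is a two-field dynamic programme (minimum
changes, then minimum origins among change-optimal reconstructions),
verified against exhaustive enumeration of all internal state assignments
on small trees. Note that a root-state reconstruction with several losses
can be most parsimonious, so species whose tips fall in two clades are not
automatically polyphyletic; polyphyly requires that every
minimum-change reconstruction uses at least two origins. Classification is
purely topological — branch lengths are ignored, zero-length branches do
not merge tips, and identical haplotypes appear as separate tips unless
collapsed first (both workflows are supported and reports state which was
used).

## GMYC

**Model.** On an ultrametric, binary, outgroup-pruned tree with `n` tips,
the `n-1` waiting intervals between successive branching ages (root to
present; their durations sum to the root age) compete against the combined
rate

    b_i = lambda1 * n_Y,i^p1 + lambda2 * sum_k [n_k,i (n_k,i - 1)]^p2

with `logL = sum_i [log b_i - b_i x_i]`. A lineage belongs to the
coalescent process of cluster *k* when its parent node lies inside that
cluster's subtree; all other lineages (including cluster stems and
singleton lineages below the threshold) count toward the diversification
process. The exponent of the coalescent term is applied to the product
`n(n-1)`, symmetric with the null model. Simultaneous node ages (common in
consensus chronograms) are separated by a deterministic epsilon below
1e-9 x root age, and the report records that this happened.

**Models fitted.**

* *Null*: one coalescent-type process `lambda [n(n-1)]^p` over the whole
  tree, k = 2.
* *Single threshold*: every branching age (plus the all-coalescent and
  all-diversification extremes) is a candidate threshold T; nodes strictly
  younger than T are coalescent. Each candidate's four rate/exponent
  parameters are optimised; k = 5 (four parameters plus the threshold).
* *Multiple threshold*: hill climbing over per-lineage assignments starting
  from the single-threshold optimum; one move either promotes a cluster
  root to the diversification process or demotes a lowest diversification
  node, with rates re-optimised per proposal and proposal order shuffled by
  the seed. k = 4 + the number of distinct thresholds, where that number is
  the minimum set of age values generating the assignment (a greedy minimum
  interval-piercing over the switch edges; a single-threshold assignment
  yields exactly 1, keeping k continuous across methods).

**Optimisation.** Bounded quasi-Newton (L-BFGS-B) on
(log lambda1, log lambda2, p1, p2), exponents bounded to [0, 3], rate
bounds set 14 log-units around a moment estimate (expected events ~
observed intervals), with a fixed multistart grid (default 10 starts) and
nested seeding: the null optimum seeds the all-coalescent single-threshold
candidate and the single-threshold optimum seeds the multiple-threshold
search. This seeding makes the nesting inequality
`logL(null) <= logL(single) <= logL(multiple)` hold by construction, and an
exhaustive grid oracle on small trees confirms the optimiser attains the
global region. A zero combined rate in any interval returns `-inf` rather
than raising.

**Tests and averaging.** Likelihood-ratio tests use a chi-square with
df = 2 by default for both single-vs-null and multiple-vs-single — the df
that reproduces the published p-values for the printed statistics
(3.17 -> 0.21, 10.08 -> 0.0065) — with a `--df` override. AICc uses the tip
count as the sample size (flagged in reports; the model count makes
`n - k - 1 <= 0` an error on very small trees). Multimodel averaging
retains models within a delta-AICc cutoff (default 7) of the best,
weights them by `exp(-dAICc/2)` normalised, and reports weighted means and
*between-model* variances of cluster and entity counts (within-model
uncertainty is not included) plus per-pair cluster co-membership
probabilities. The default candidate set is the null model plus every
single-threshold model; the set composition is printed in the output
because adding multiple-threshold variants is a legitimate alternative.
Probability-threshold entities are formed greedily from maximal clades
whose internal tip pairs all reach the probability threshold, which makes
the entity count non-increasing as the threshold drops. The entity
confidence interval is the range over models within 2 log-likelihood units
of the maximum.

## Synthetic data

The generator emulates the structure the analysis assumes for a recently
diversified conifer section sampled at one plastid locus:

* **Species tree**: Yule process conditioned on S tips — forward simulation
  with Exp(k * birth_rate) waiting times and one final Exp(S * birth_rate)
  interval, so the S = 2 split age has mean 1/(2 birth_rate). Defaults:
  S = 10, birth rate 1 per tree unit (time units are arbitrary; the
  delimitation model is time-scale invariant, so no absolute calibration is
  simulated).
* **Gene tree**: multispecies coalescent via msprime (haploid samples, so a
  lineage pair within a population coalesces at rate `1/Ne_time`); no
  recombination, matching uniparental plastid inheritance. Default 2-14
  samples per species, drawn uniformly, emulating uneven field sampling.
* **Sequences**: HKY with four discrete-gamma rate categories (median
  method, mean 1), the generator scaled to `mu` substitutions/site/unit
  time, root drawn from equilibrium frequencies (default A/T-rich,
  G+C = 0.37, as in conifer plastid markers). Defaults mu = 0.002/site/unit
  and L = 1200 put simulated per-site diversity in the low-10^-3 range
  typical of such data. kappa defaults to 2, alpha to 1.
* **Degradation**: shared internal gap events with geometric lengths
  (mean 3) at distinct non-adjacent spans away from row ends — so each is
  recoverable exactly as one indel event — and per-row terminal missing
  blocks (default `N`, emulating unidirectional reads).

`recovery_fixture` produces the regime where delimitation should work:
Ne_time is scaled so the expected within-species T_MRCA is a small fraction
(default 7.5%) of the **shallowest** species divergence. Scaling against
the mean node age instead leaves a large chance that the youngest Yule
split is inside the coalescent cloud (the last inter-speciation interval is
Exp(S * birth_rate)), making exact recovery of S impossible no matter the
method; the per-divergence scaling isolates the estimator's behaviour from
that identifiability ceiling.

What the simulations do **not** emulate: introgression/plastid capture,
recombination, selection, substitution-model misspecification (GTR data
analysed as HKY), sequencing error, or realistic indel evolution. Passing
tests therefore demonstrate correctness of the statistics and the
delimitation machinery under the model's own assumptions, not robustness of
GMYC to the biological processes that confound it in real groups.

## Validation experiments and problem sizes

The experiment module runs three calibration studies (sizes chosen to keep
a full validation run in the minutes range on one CPU):

* *Recovery*: 100 replicates, S = 10 species, 4 tips each, coalescent depth
  7.5% of the shallowest divergence; single-threshold GMYC should delimit
  exactly 10 entities in >= 80% and the 2-log-likelihood support set should
  cover 10 in >= 90%.
* *Power collapse*: 100 replicates, S = 5, 3 tips each, Ne_time ten times
  the species-tree root age; the single-vs-null LR test rejects in roughly
  a fifth of replicates, down from essentially always in the favourable
  regime — the regime where large effective population sizes defeat
  single-locus delimitation. Note that the residual rejections reflect the
  test's mild anticonservativeness, not real signal: the alternative
  maximises over every candidate threshold plus two extra exponent
  parameters, while 2 dlogL is referred to a fixed chi-square(2), so the
  rejection rate under a structureless coalescent sits near 20% rather
  than the nominal 5%. Significance from this test should be read
  accordingly.
* *Nesting*: 500 random Yule/coalescent trees; zero violations of the
  likelihood ordering of the nested model hierarchy.

## Degenerate inputs and numerical choices

Trees must be rooted; polytomies are rejected unless resolved (zero-length,
seeded order). Non-ultrametric trees are rejected unless a tolerance is
given, in which case tip ages within tolerance x root age are clamped to 0.
GMYC needs >= 3 tips and a binary tree; AICc additionally needs
`n > k + 1`. Empty regions, alignments with no analyzable sites after
deletion, and unmapped tips raise typed input errors (CLI exit code 2);
optimiser failure raises a numerical error (exit code 3). All randomness is
driven by explicit integer seeds; identical configuration gives
byte-identical outputs.

## Known limitations

* Single-locus delimitation only; no bGMYC, PTP or multilocus methods.
* The single-vs-null likelihood-ratio test is mildly anticonservative (see
  above); its p-values are comparative guides, not calibrated error rates.
* The multiple-threshold search is a local hill climb: it guarantees
  improvement over the single-threshold solution but not the global
  multiple-threshold optimum.
* Between-model variance only in multimodel averages.
* The haplotype-collapse distance-zero rule is single-linkage: with heavy
  missing data, chains of compatible sequences can merge haplotypes that
  differ at unobserved sites — inherent to the convention, not a bug.
* Chronogram estimation is out of scope: the GMYC stage consumes an
  existing ultrametric tree and inherits its errors.
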