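# Methods

## Premating isolation from multiple-choice counts

A two-strain multiple-choice test is summarised by four mating counts
(n11, n12, n21, n22), the first index naming the female's strain.  The
statistics are:

* joint isolation index `I = (n11 + n22 − n12 − n21) / n` with
  `n = n11 + n12 + n21 + n22`: the homotypic excess as a fraction of all
  matings, 0 under random mating, ±1 under complete assortative /
  disassortative mating;
* female-side indices `I1 = (n11 − n12)/(n11 + n12)` and
  `I2 = (n22 − n21)/(n22 + n21)`, each conditioning on one strain's
  females.  When a female class produced no matings the index is *undefined*
  (`None`), not zero;
* standard error `SE = sqrt((1 − I²)/n)`.  All three indices use the pair's
  total mating count `n`, not the index-specific denominators: this is the
  convention under which the published SEs reproduce, and under the
  multinomial model it is exact for `I` (with c ∈ {±1} weights,
  `Var(I) = (Σ pᵢcᵢ² − (Σ pᵢcᵢ)²)/n = (1 − E[I]²)/n`);
* significance: `|index| ≥ 2·SE`, evaluated on unrounded values; the rule is
  inclusive at the boundary (a published row sits exactly at 2·SE and is
  flagged significant there);
* random-mating test: Pearson χ² of the four counts against equal expected
  `n/4` per class, df = 3, no continuity correction, upper-tail p.  The
  uncorrected form is used throughout because it reproduces the published
  χ² values on every internally consistent row; the published tables do not
  state a χ² significance criterion, so p-values are printed and the caller
  chooses α.

`n` is always recomputed from the counts.  A published total that disagrees
(two of the fifteen bundled rows) is kept in the row and surfaced as a
data-quality warning, never silently corrected.

## Postzygotic isolation from reciprocal crosses

Per directed cross, replicates pooled: a Pearson χ² of the offspring sex
counts against 1:1 (df = 1, no continuity correction), and the fraction of
dissected F1 males with at least one motile sperm.  The motile fraction
carries an exact (Clopper–Pearson) two-sided 95% CI — chosen over Wald
because dissection counts are small (tens of males).  Categories:

* **sterile** — zero motile among >0 dissected;
* **fertile** — CP lower bound ≥ 0.85.  The threshold is set so that a
  fully motile cross qualifies at every dissection size from ~25 males up
  (the experiments dissect 28–70): at 35/35 the bound is 0.8999 and at
  28/28 it is 0.8766, while the strongest "reduced" regime observed
  (~76% motile of 70) reaches only ~0.64, leaving a wide margin;
* **reduced** — anything else; **unknown** — nothing dissected.

## Sequence divergence and haplotype networks

Distances are uncorrected p-distances in percent with **pairwise deletion**:
a site is compared only when both sequences carry A/C/G/T; N and gaps drop
out per pair.  Pairwise deletion (rather than complete deletion) preserves
per-pair information and yields the full-alignment denominator whenever the
data are complete.  On read, IUPAC ambiguity codes other than N are
collapsed to N (missing) with a warning — the conservative choice absent a
stated ambiguity policy — and U is read as T.

Group divergence is the arithmetic mean of all inter-group pairwise percent
distances; the diagonal is 0 by convention (within-group polymorphism is
reported only through the haplotype structure).

Records with zero mismatches over their comparable sites collapse into
haplotypes greedily in input order, each record joining the first haplotype
whose representative it matches; the representative is the member with the
fewest N's (ties by lexicographic id).  The network is a minimum spanning
tree over haplotypes with edge weight equal to the number of differing
comparable sites, built by Kruskal's algorithm with candidate edges
pre-sorted by (steps, id, id) so ties resolve deterministically for a given
input order.  Where several MSTs exist, the total weight and the multiset of
edge weights are invariant; the specific tie-broken edge set is only
guaranteed stable for a fixed input order.  An optional `connection_limit`
removes edges above a step threshold after construction — the analogue of a
statistical-parsimony connection limit.  The probability-of-parsimony
computation that would justify a particular 95% limit is deliberately not
reimplemented; the limit is a user parameter, default unlimited, because the
published network is fully connected and a limit never binds there.
Unsampled intermediate haplotypes are not inferred: an edge of k steps
renders as k tick marks, not k−1 hidden nodes.

## Synthetic data

* **Mating trials**: each replicate draws (n11, n12, n21, n22) from a
  multinomial over propensities (p11, p12, p21, p22) at fixed total
  `n_matings`.  Conditioning on the total matches how the statistics are
  used (all condition on n); latency, courtship sequence and per-pair
  heterogeneity are not modelled, so passing calibration checks validates
  the estimators under the multinomial idealisation, not under behavioural
  dynamics.  Defaults used in the checks: n = 80 matings and 200 replicates,
  matching the published trial scale (N = 59–83 per pair), with propensity
  (0.35, 0.15, 0.15, 0.35) for the "true I = 0.4" regime seen in the
  strongest published pair.
* **Crosses**: offspring sex ~ binomial(n_offspring, prop_female); each
  dissected male lacks motile sperm independently with probability
  `sterility_p`.  No litter effects or replicate heterogeneity.
* **Alignments**: a uniform-random ancestral sequence of the target length
  (1,159 sites in the analyses, the concatenated COI+COII scale) evolves
  along a user-given group tree with a *fixed* substitution count per
  branch; all substitution sites are drawn without replacement from one
  global pool (infinite-sites at this scale), so realized Hamming distances
  equal path sums exactly and network-recovery tests can assert exact edge
  weights.  Within-group polymorphism defaults to zero and can be requested
  per group.  Real mtDNA violates all of this (multiple hits, rate
  heterogeneity, codon structure), which is why only model-free statistics
  (p-distance, MST) are computed downstream.

All generators are reproducible from an integer seed via numpy's
`default_rng`.

## Numerical and reporting conventions

* Report rounding: half away from zero (the convention of the published
  tables), default 2 decimals; internal values stay at full precision.
  The rounding is float-based, so values within ~1e-15 of a half may fall
  either way — comparisons against printed values never rely on it.
* Printed-value comparisons accept one unit in the last printed digit,
  because the published tables mix rounding (2.1) and truncation
  (0.86 for 0.868) conventions.
* Degenerate inputs: zero total matings / zero offspring raise an
  undefined-statistic error; `|I| = 1` gives SE = 0 and counts as
  significant; a pair of sequences with no comparable sites has undefined
  distance (an error when a group matrix needs it).
* Pipeline runs are deterministic: the run log records input SHA-256
  hashes, the seed and the package version, and a rerun with the same
  config is byte-identical.

## Scope and limitations

The analyses cover the choice-test, cross and mtDNA-distance/network
stages.  Bayesian tree inference, substitution-model selection, SNP/RADseq
processing and sequence assembly/alignment are out of scope; alignments are
taken as given.  The deposited mtDNA sequences are not bundled because no
published mapping ties accession ids to strain labels; the
divergence/network stage therefore demonstrates on synthetic alignments
whose branch substitution counts mirror the published between-lineage
scales, and accepts a user-supplied `group_map` for real data.  Problem
sizes in the simulation checks (200 replicates at n = 80; 500 seeds for the
type-I-error check) were chosen to estimate rates to within a few percent,
comfortably tight for the 3σ acceptance bands used in the tests.
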