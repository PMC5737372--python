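# Methods

This note documents the model, the statistical machinery, the synthetic
data generator, and the numerical and design choices made where the design
was genuinely open.  It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Inputs and preprocessing

**Network.** An undirected PPI network from a two-column edge list or a
BioGRID tab export (interactor official-symbol columns, configurable).
Directionality is an artifact of assay design and is discarded; duplicate
pairs and self-loops are dropped.  Cleaning: proteins with degree above
`max_degree` (default 1000) are removed *simultaneously* (degrees measured
on the input network) because promiscuous hubs connect mostly unrelated
proteins; then the largest connected component (LCC) is extracted.  We fix
the order hubs-then-LCC so the final network is guaranteed connected and
all distances finite; the reverse order can yield a different network, and
both the threshold and the order are configuration.  Component-size ties
break by the lexicographically smallest member, for determinism.

**Distances.** All-pairs shortest-path hop counts, computed by repeated
BFS (`scipy.sparse.csgraph`), which on unit-weight graphs equals
Floyd–Warshall entry for entry (asserted against an O(n³) reference in the
tests) and is much faster on sparse networks.  Stored dense as `int16`
with an explicit node ordering; TSV-cacheable, keyed by a network hash.

**UTRs.** FASTA records are uppercased, T→U converted, and truncated to
the first `truncate_to` (default 500) bases downstream of the TSS — this
sidesteps uncertain start-codon annotation.  Multiple variants of one
protein are kept as separate segments whose union is associated with the
protein; the scanner concatenates them with a non-matchable separator, so
no match can span a variant join, while occurrence positions stay
per-variant (needed for conservation mapping).  Characters outside
{A,C,G,U} — including N — get an empty match mask: they can never satisfy
any motif symbol.  The spec for the input format only demands that
ambiguous bases not produce spurious matches; treating sequence-N as
unmatchable is the conservative reading.

## Motif space and matching

Motifs are fixed-length (default 8) strings over Σ = {A,C,G,U,R,Y,N} with
R = purine, Y = pyrimidine, N = any base; the space has |Σ|⁸ = 5,764,801
patterns, enumerated in a fixed lexicographic order (A,C,G,U,R,Y,N).  The
full IUPAC set (S,W,K,M,B,D,H,V) is deliberately excluded by default — the
three degeneracy classes cover purine/pyrimidine structure without blowing
up the space — but the alphabet is a parameter.

Matching compiles a motif to per-position 4-bit masks over a 2-bit-style
base encoding; a position matches when masks intersect.  All (overlapping)
offsets count toward occurrence totals, but a protein enters the carrier
set V_m at most once ("at least one match", forward strand only).  The
bitmask engine's contract is exact equality with a naive character-class
scan, property-tested over random sequences and patterns.

Motifs with |V_m| > `max_proteins` (default 1500) are flagged excluded
from significance assessment — they are dominated by degenerate symbols
and their null calibration would be disproportionately expensive — but
their occurrence counts are retained.  Zero-carrier motifs are dropped.
Desk-scale runs score either a full enumeration of a small space or a
seeded uniform sample of the 8-mer space plus explicitly supplied
patterns (`n_motif_sample`, `extra_motifs`); counts per exclusion reason
are reported in the run manifest rather than targeting any fixed total.

## The TPPD statistic

For carrier set V of size n, core size l = ⌊0.1·n + 0.5⌋ (round half-up),
floored at 1 and capped at n−1 so the statistic is defined for every
n ≥ 2.  The rounding rule is a package choice — "top 10%" admits floor,
round, or ceil — and both the fraction and the rule are configuration.
D(u) is the sum of the l smallest distances from u to other members;
the core is the l members with smallest D; TPPD is the sum of D over the
core.  Tie-breaks (equal D at the core boundary) are deterministic:
sort by (D, identifier).  The minimum possible value is l² (a core at
pairwise distance 1).  The total pairwise distance (TPD, sum over all
pairs) is retained as a legacy cross-check; with l = n−1,
Σ_u D(u) = 2·TPD.

Three exact evaluators back the Monte Carlo null: a numba counting-sort
kernel (hop distances are small integers, so the l smallest distances per
member come from a histogram in one pass — the default, and the fastest
at every k), a gather-and-partition backend, and a bitset backend that,
for each hop level t, counts members within distance t by popcounts over
packed per-node reachability bitmasks and reconstructs the sum of the l
smallest distances as Σ_t (l − min(count_t, l)).  All three are asserted
equal to each other and to the naive definition on random instances.

## Null model and p-values

A motif's null is the TPPD of k proteins drawn without replacement with
probability proportional to UTR length — longer UTRs accumulate more
chance matches, so a uniform null would overstate clustering for
long-UTR-biased motifs.  Sampling uses exponential sort keys
(Efraimidis–Spirakis), distributionally identical to sequential
draw-and-remove with renormalization; the tests verify empirical inclusion
frequencies against exactly enumerated sequential probabilities on tiny
populations.  Proteins without a UTR have weight 0 and are never drawn
(they also cannot carry motifs); they remain in the network for distance
purposes.

Regimes: empirical for k ≤ `k_switch` (default 300) with
`mc_samples_small` draws (default 10⁶, giving p-value resolution ~10⁻⁶);
normal N(μ_k, σ_k²) for `k_switch` < k ≤ `k_max` (default 1500) with
moments fitted on `mc_samples_large` draws (default 10⁵).  The empirical
p-value is the plain left-tail proportion with ties counted in (the
defining event is S_k ≤ TPPD); no pseudocount is added, so the stated
resolution is exact.  When the observed value undercuts every draw, the
package falls back to the normal tail fitted on the same draws, *capped at
1/n_samples* — the cap is a package addition that keeps p monotone in the
observed statistic across the empirical/fallback boundary.  Per-k sample
sets are seeded by (seed, k) and shared across motifs of equal k: results
are independent of evaluation order, and each k is calibrated once, as in
a genome-scale run where each k in 301..1500 is fitted once and cached.
A degenerate null (σ = 0, e.g. a motif carried by the entire sampleable
population, whose only possible draw is the population itself) yields
p = 1.

**Accuracy envelope of the normal regime.**  The normal approximation
targets large carrier sets on large networks (real PPI scale: ~12k
proteins, mean degree ~16, k/|V| ≤ 0.12).  At desk scale the regime
boundary k = 301 on a 500-node network is a stress test: with an extreme
planted-density contrast the S_k distribution is left-skewed (the rare
module-heavy draws) and on a very sparse homogeneous network (mean degree
5) it is right-skewed, and in both cases the normal left tail is off by
more than 2× at p = 10⁻³.  On a homogeneous network with realistic mean
degree (~16) the approximation is accurate (measured normal/empirical
ratios 0.8–1.0 down to p = 10⁻³); the regime-consistency check therefore
uses that configuration, and runs with small dense-module networks should
treat normal-regime tails below ~10⁻² as approximate.

## FDR by local scrambling

Bonferroni-style correction is inappropriate: the motif space is a web of
near-duplicate hypotheses.  Instead the entire pipeline is re-run on decoy
UTRs in which each variant's bases are permuted within non-overlapping
10-nt windows (final partial window permuted within itself), preserving
local composition (GC content, CpG-ish structure at window scale).
FDR(p) = N(p)/M(p), decoy/real counts of motifs at or below p, capped at
1 and reported as 1 where M(p) = 0; thresholds default to the observed
real p-values.  The decoy pass reuses the real run's null model — the
network and UTR lengths (hence sampling weights) are unchanged by
scrambling; only the carrier sets move.

## Families, conservation, strand, enrichment

**Families.** Similarity s = |V₁∩V₂|/min(|V₁|,|V₂|), distance d = 1/s − 1;
disjoint sets (s = 0) get a large finite sentinel distance (10⁶) so
average linkage stays finite.  The dendrogram is scipy's average-linkage
(UPGMA), verified against a textbook O(n³) agglomeration.  The cut to the
target family count (default 200) *stops the agglomeration* n−K merges in,
which always yields exactly min(K, #motifs) families; a height threshold
cannot do this when merge heights tie (identical carrier sets all merge at
height 0).  Representatives: smallest clustering p-value, ties broken
lexicographically.

**Conservation.** An occurrence of a length-L motif at offset o has middle
position o + ⌊L/2⌋ (0-based; base 5 of 8 in 1-based terms — the tie for an
even-length midpoint is broken downstream).  Cons(m) is the fraction of
core occurrences whose midpoint lies in a conserved element (BED3,
half-open); the fold-enrichment divides by the background fraction of UTR
bases in elements, computed from the track with overlapping intervals
merged.  In synthetic mode coordinates are sequence-local; genome lift-over
is out of scope.

**Strand specificity.** ss = forward/reverse-complement occurrence counts
over *all* UTRs (not just the core — the measure is a global hint of
RNA-level function, where ss ≫ 1 is expected for post-transcriptional
elements).  The test is one-sided: the upper tail of Binomial(n, ½) at the
forward count, via the normal approximation N(n/2, √n/2) *with continuity
correction* — without it the approximation misses the exact tail by ~17%
at n = 200, with it ~3%, inside the 10% contract asserted in the tests.  A
reverse-biased motif (ss < 1) thus gets p ≈ 1.  BH-adjusted across motifs.

**Term enrichment.** Flat term→gene table; per term, the one-sided
Fisher's exact (hypergeometric upper tail) of the core against the network
background, BH-adjusted across terms; terms with no background members are
skipped.  Ontology-aware (parent–child) corrections are out of scope.

## Synthetic data generator

The generator emulates the statistical structure the method assumes, not
the biology of real UTRs:

- **Network**: Erdős–Rényi background (default n = 500, edge p = 0.01)
  with one planted dense module (30 proteins, internal edge p = 0.5);
  stray components are re-attached by a seeded random edge to the main
  component.  No scale-free degree structure.
- **UTRs**: one variant per protein, length uniform on [200, 500],
  iid uniform base composition.  No codon structure, GC isochores, or
  length/degree correlation.
- **Planting**: the planted motif (default `NNCGCYAU`) is inserted once,
  at a uniform offset, in module members with rate 0.8 and others with
  rate 0.02; each insertion independently resolves the degenerate
  positions uniformly within their base classes, so the signal matches the
  pattern without being one literal string — as real degenerate motifs
  behave.  A truth record stores every planted (protein, offset, instance).
- **Conservation**: a 9-nt element covers each planted midpoint with
  probability 0.9; background elements of 20 nt are placed at a Poisson
  rate targeting ~10% base coverage.
- **Terms**: module membership as one term, plus random background terms.

The default motif degeneracy (two N, one Y) is chosen so the carrier set
is ~100 proteins — module carriers plus length-weighted chance carriers —
matching the scale of real significant motif sets (tens to hundreds of
carriers) and giving a core size (l ≈ 10) that only a genuinely dense
module can realize; a nearly literal planted motif would shrink the
carrier set to a size where minimal-TPPD cores also arise by chance, and
an extremely degenerate one would make random draws include most of the
module.  Everything is deterministic per seed and all outputs round-trip
through the package's own readers.

What passing tests on these fixtures do *not* show: robustness to
scale-free hubs, correlated UTR length/composition, overlapping real
modules, or genome-coordinate conservation tracks.

## Problem sizes used in the checks

The test suite and the acceptance script run the method end to end at
desk scale, as the package's own study design: Monte Carlo depth 10⁴ per
set size for empirical small-k p-values (10⁶ only for the regime-boundary
comparison, which is reported at 2×10⁵ draws in the acceptance script)
and 3×10³ for large-k moment fits — moment estimation converges far
faster than tail counting — candidate
samples of 120–3000 motifs from the 8-mer space, 20 replicates for the
power check in the suite and 5 in the script, and 200–250 random sets for
calibration.  Null calibration draws sets with k varied over 30–120: the
TPPD is integer-valued, so at a single fixed k the p-value distribution
has large atoms and a KS test against U(0,1) measures discreteness rather
than miscalibration; mixing k smooths the atoms while testing exactly the
same uniformity property.

## Known limitations

- Hop distances ignore edge confidence and interaction type; dense
  networks (STRING-like) compress the distance range and weaken the
  statistic.
- The normal regime's extreme tails are approximate (see the accuracy
  envelope above); at paper scale this matters only for p ≪ 10⁻⁶.
- The FDR is global (one curve for all motifs), not per-motif-class.
- Family cutting by count reproduces the intended "reasonable number of
  families" behavior but the count itself (200) is a presentation choice,
  not an inferred quantity.
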