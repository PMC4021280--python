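# Methods

This note documents the models, parameter choices and known limitations of
`foldcons`, in the spirit of the methods documentation of simulation and
statistics packages.  It states no empirical number that the test suite or
`scripts/acceptance.py` does not itself compute.

## Scope and data model

The unit of analysis is the 4-fold degenerate site: a third codon position
whose codon family encodes one amino acid for all four nucleotides (the
eight families GCN, CGN, GGN, CTN, CCN, TCN, ACN, GTN; the 6-fold amino
acids Leu/Arg/Ser contribute only their 4-fold subfamilies CTN/CGN/TCN).
Sites are defined by the reference species' codons alone; orthologs may
differ at the column — that difference is exactly what the conservation
measure quantifies.  CDS coordinates are 1-based (position 1 = A of ATG),
alignment columns 0-based.

Input filters follow common ortholog-set practice: every species must have
its ortholog present, and a gene is dropped when any reference/ortholog
pair has less than 80% of either sequence aligned (the boundary is
inclusive — exactly 80% is kept, since the exclusion rule is "less than
80%").

## Conservation: equal-split weights and weighted entropy

Column conservation is E_w = −Σ p_i log2 p_i (bits), where p_i is the
weighted fraction of sequences carrying nucleotide i.  Weights are the
equal-split measure: each branch's length is divided equally among its
descendant leaves and a leaf's weight is the (normalised) sum of its
shares.  Equal-split was chosen because it is fully reproducible from
topology and branch lengths alone and is the standard phylogenetic
down-weighting of correlated taxa.  Entropy uses log base 2 so the maximum
(four equiprobable nucleotides) is 2 bits, which makes the conservation
cutoff of 0.5 bits a quarter of the range; the cutoff is strict (E_w < 0.5).

Gap handling: gap/N rows are excluded from a column and the remaining
weights renormalised, keeping Σ p_i = 1 and E_w in [0, 2].  Treating gaps
as a fifth symbol is available nowhere downstream because an all-gap column
is undefined and dropped.  A tree with all branch lengths zero falls back
to uniform weights with a warning.

## Folding engine and structural sensitivity

Base-pair probabilities come from an exact inside–outside dynamic program
over all nested secondary structures with canonical pairs (AU/AT, GC,
GU/GT) and hairpin loops of at least 3 unpaired bases.  The energy model is
deliberately simple — a fixed stabilising energy per pair (defaults
GC −2.1, AU −1.3, GU −0.9 kcal/mol) plus a stacking bonus (−1.1 kcal/mol)
for directly stacked pairs, Boltzmann-weighted at RT = 0.0019872·T with
T = 310.15 K by default.  Full nearest-neighbour parameter sets add realism
to absolute structure prediction, but every statistic downstream depends on
*differences* between wild-type and mutant probability matrices, for which
the simple ensemble suffices and remains exactly testable: the DP is
verified against brute-force enumeration of all structures with Boltzmann
weighting on short sequences (agreement to ~1e-10 or better).  All energies
are configurable.

Numerics: the partition function is rescaled by a per-nucleotide factor
(with automatic retry on overflow/underflow), so windows of several hundred
nucleotides stay within float64 range; probabilities are exact ratios in
which the scale cancels.

A mutation's impact is d_max: over every subinterval [a, b] of the folded
window with b−a+1 ≥ 10, the Euclidean norm of the base-pair probability
differences restricted to that interval, divided by the interval length,
maximised over intervals.  This renders the "local region of maximal
change" idea concretely; it is computed exactly by 2-D prefix sums and
verified against a naive all-intervals scan.  A site's structural
sensitivity is the arithmetic mean of d_max over its three possible point
mutations, each folded in the same local window (default ±200 nt of
context for real-data analysis; the simulation studies and tests use ±40
for speed, stated below).  A site is sensitive when the mean strictly
exceeds 0.1.

Because this d_max scale is not the scale of any external folding tool, the
0.1 cutoff is treated as calibratable: `calibrate_sensitivity_cutoff`
chooses the cutoff reproducing a target sensitive-site fraction.  The
literal 0.1 default was retained after observing that on synthetic coding
sequences it yields roughly an eighth of sites sensitive — comfortably
inside the "below 25% of sites" range that follows from single-mutation
disruption rates of a few percent — so no recalibration was needed.

## Codon-usage bias: ENC′

ENC′ corrects Wright's effective number of codons for background nucleotide
composition.  Per synonymous family (k codons, n counted): X² =
n·Σ(p_i−e_i)²/e_i against background-expected frequencies e_i, F′ =
(X²+n−k)/(k(n−1)), class averages weighted by family counts, ENC′ = 2 +
9/F̄′₂ + 1/F̄′₃ + 5/F̄′₄ + 3/F̄′₆, missing 3-fold class interpolated as the
mean of the 2- and 4-fold classes, clipped to [20, 61].  The background is
the gene's own overall nucleotide frequencies (the simplest reading of
"background composition"); e_i are products of background frequencies over
the positions at which the family's codons vary, renormalised within the
family.  Families with fewer than 2 observations are excluded from their
class; a class with no usable family falls back to the neutral 1/k.  With a
flat background the correction vanishes and ENC′ equals classic Wright ENC
— this identity is exercised as a cross-check against an independent
homozygosity-based implementation.  Genes under 10 codons are undefined and
excluded from stratification.

## Association statistics

Categorical: per-gene 2×2 tables (sensitive × conserved, both cutoffs
strict) pooled by Mantel-Haenszel.  The χ² uses the 0.5 continuity
correction and a two-sided χ²₁ p-value; the 95% CI uses the
Robins–Breslow–Greenland variance, the standard interval for the pooled
odds ratio.  Strata with fewer than two observations are skipped and
counted; an all-zero cross-product denominator reports an infinite OR with
the χ² p-value retained.  The implementation is verified against R's
`mantelhaen.test` and an independently coded textbook formula.

Stratification splits genes at the median of a covariate (expression, or
ENC′ with the orientation that "top" = strongest bias = lowest ENC′); exact
median ties go to the bottom half by stable gene-id order, and with an odd
count the bottom half takes the extra gene.

Windows: [1, 36], [13, 48], … with starts through nucleotide 109 (10
windows; the alternate 45/15/121 scheme gives 9).  A site belongs to every
window containing its position — the overlapping design implies
multi-membership — and each window pools per-gene tables across all genes.

Continuous: the statistic is the mean over genes of the per-gene Pearson
correlation between sensitivity and E_w (genes need ≥ 3 usable sites and
variance in both variables; exclusions are counted, never silent).  The
null distribution reshuffles E_w only among sites sharing the same
*reference-species* nucleotide within each gene — the reference nucleotide
is also what drives folding, making it the natural exchangeability class;
classes with fewer than 2 sites cannot move.  p-values are left-tailed with
the add-one estimator (1 + #{null ≤ observed})/(1 + n_perm), so p = 0 is
impossible and the test is valid at finite n_perm.  Per-gene permutation
streams are split deterministically from the master seed.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes:

- **Tree**: rooted binary topology, balanced or Yule (random tip
  splitting); every branch length drawn Exp(mean = `branch_scale`).
- **Root CDS**: ATG followed by random stop-free codons with a GC-bias
  parameter.
- **Evolution**: only 4-fold third positions evolve; per branch and site a
  single change/no-change draw with P(change) = 1 − exp(−rate·t), then a
  uniform choice among the three alternatives.  Non-synonymous positions
  are frozen (rate 0) because the analysis reads only 4-fold sites — a
  slow-but-nonzero protein rate would add a nuisance dimension without
  touching any statistic.  The single-draw model ignores multiple hits per
  branch; at the default branch scale (0.2) this is a small distortion and
  buys closed-form oracles (two-leaf divergence probability, exact
  saturation at P(change) = 3/4).
- **Planted effect**: sensitive sites' rates divided by (1 + β), optionally
  only within a CDS region; β maps monotonically to the expected log-odds
  ratio, and β = 0 gives exactly exchangeable rates, so the permutation
  null holds by construction.
- **Expression**: log-normal per gene.

Defaults (200 genes × 8 species × 150 codons, branch_scale 0.2,
syn_rate_mean 0.3, GC 0.5, lognormal(0, 1) expression) were chosen once as
a realistic mid-sized ortholog study: ~0.8 expected substitutions per
4-fold site across the tree yields a balanced conserved/variable mix
around the 0.5-bit cutoff.  Seeding is counter-based per gene, so any gene
is reproducible in isolation and folding can be reused across evolution
replicates.

What the generator does *not* emulate: indels and alignment error, codon
models with nonsynonymous change (GY94/MG94), selection heterogeneity
beyond the planted effect, compositional heterogeneity across lineages,
and any realistic linkage between expression and codon bias.  Passing
calibration and power tests on this generator therefore demonstrates the
statistics' correctness and sensitivity under the stated model — not that
real genomes will show the effect.

## Study sizes used in validation

The calibration studies run at 50 genes × 8 species × 100 codons with
folding flank 40 nt: 1,000 evolution replicates for the type-I error of
the Mantel-Haenszel test (nominal α = 0.05; note the continuity correction
makes the test mildly conservative), 200 datasets × 200 permutations for
the uniformity of the permutation null, 100 replicates for β = 4 effect
recovery, and 20 replicates for the 5′-restricted variant (windows and
regional tests).  These sizes keep the full validation suite to a few
minutes while leaving the binomial/KS checks well-powered.

## Known limitations

- The folding ensemble has no loop-length penalties beyond the minimum
  hairpin, no dangles, no pseudoknots; absolute pair probabilities are not
  comparable to full thermodynamic folders, and the d_max scale (hence the
  0.1 cutoff) is specific to this engine.
- Whether full mRNAs or local windows should be folded per mutation is a
  modelling choice; local windows are used, consistent with the locality
  rationale of the d_max statistic itself.
- The permutation constraint uses the reference nucleotide; a consensus
  nucleotide is a defensible alternative the API could grow.
- E_w treats columns independently; no site-rate autocorrelation is
  modelled or exploited.
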