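# Methods

This note records the models behind `bsakit`, the defaults and why they were
chosen, what the simulator does and does not emulate, and the numerical
conventions a maintainer needs.

## The cross and the simulator

The simulated experiment is a temperate × tropical advanced intercross: one
F0 TEMP female and one F0 TROP male found two lines, each maintained by
random within-line mating (census 100 per generation) to F4, where females
are phenotyped and bulked; one line is notionally continued to F7 for
mapping. Both lines descend from the *same* F0 pair (two independent F1
broods). Real experiments of this kind typically mate a separate pair per
line; sharing the pair keeps exactly four founder haplotypes in play, which
makes the parental-genotype contingency of the bulk comparisons (below)
well defined for both lines from a single pair of genotype columns. The
statistical structure of each line is unchanged by this choice.

**Meiosis.** Crossovers per chromosome per meiosis are Poisson with mean
cM/100 under a linear genetic↔physical map — no interference, no obligate
chiasma. This is the simplest model consistent with chromosome-scale cM
arithmetic; it slightly over-disperses crossover counts relative to
interference models but leaves every chromosome-scale expectation (map
expansion, ancestry fractions) exact. Each haplotype is an ordered partition
of [1, L] into founder-origin segments (founders 0/1 = TEMP female, 2/3 =
TROP male); the partition invariant is asserted in tests after every
meiosis.

**Map expansion.** Each haplotype carries the expected crossover count
accumulated along its meiotic lineage (the meiosis' own draw plus the mean
of its two parents' counters). Counting starts at the F1 meiosis: crossovers
inside an F0 parent recombine that founder's own two haplotypes and are
invisible to the TEMP×TROP map. An F_k transmitted gamete therefore
accumulates k−1 mapped meioses, giving the 6× apparent map expansion of an
F7 intercross relative to an F2, and `liftover.map_expansion_factor(k) =
k−1` with corrected genetic lengths flagged as lower bounds (undetected
double crossovers between markers can only shrink the apparent map).

**Genome and sites.** Default layout: three chromosomes of 587, 491 and
372 Mb, 50 cM each. Default 50,000 SNPs placed uniformly (a desk-scale
stand-in for the ~957,000 sites such a study yields; every statistic scales
with site count only through stratum sizes). 10% of sites are strongly
differentiated between source populations (reference-allele frequencies
0.95/0.05, random orientation), the rest share one Uniform(0.05, 0.95)
frequency — so roughly one SNP in ten can pass the |AFD_pop| > 0.5
"segregating in nature" rule, echoing the up-to-one-in-ten divergence of
temperate vs tropical samples.

**Phenotype.** A female's diapause incidence is
DI = logistic(intercept + Σ effect·d + ε), observed as a binomial over her
egg count (line 1: 60 females, 20–64 eggs; line 2: 78 females, 22–69 eggs),
where d is her TEMP-ancestry dosage at each QTL. The Gaussian liability
noise ε (sd 2.0 by default) represents unmodelled polygenic and
environmental variance. It is essential: with binomial egg noise alone a
QTL-free line would have every DI pinned near logistic(intercept) and the
extreme bulks could never fill, whereas real intercross females span the
full DI range. sd 2.0 spreads null DIs over roughly (0.02, 0.98) and fills
all four bulks at the study's thresholds. Bulk rules: low bulk DI ≤ 10%
(line 1) / ≤ 5% (line 2), high bulk DI ≥ 50%, boundary inclusive, truncated
to the most extreme 11/11 (line 1) and 12/8 (line 2) females.

**Read counts.** RNA is pooled in equal amounts, so a bulk's expected
reference read fraction is its mean dosage/2. Depth is negative binomial
(mean 60, shape 5 — overdispersed, as pooled RNAseq depths are), reads
split binomially. Expression-level variation among pooled females is not
modelled (a per-individual weight would multiply dosages before averaging;
equal pooling is the stated experimental intent). No sequencing error,
alignment artifacts, or allele-specific expression: passing tests show the
*statistics* behave as designed, not that they are robust to such
artifacts.

**Randomness.** One master seed; `numpy` `SeedSequence.spawn` gives each
stage (founder model, founder alleles, per-line breeding, per-line
phenotyping, counts, panels) an independent child stream, so identical
seeds reproduce byte-identical outputs and stages do not perturb each
other.

## The screen

**Filters.** Completeness: ≥ 1 read in each of the four bulks (the
"genotyped in all bulks" rule, with a configurable depth floor since a
stricter reading is defensible) and ≥ 5 non-missing genotypes in each
panel. Concordance: all three AFDs non-zero with one sign. Segregation:
candidates need |AFD_pop| strictly > 0.5, matching the printed ">".

**Percentile p-values.** Within a stratum,
p_i = #{j: |AFD_j| ≥ |AFD_i|}/n — the inclusive upper-tail proportion. This
guarantees p ∈ (0, 1] (products never hit zero) and is conservative under
ties; ties share one p with no randomized breaking. Under an exchangeable
null the p-values are the tie-adjusted ranks {r_i/n}, i.e. uniform on a
grid, verified by KS test in the suite.

**Strata.** Population comparison: MAF bins of width 0.05 over the pooled
TEMP+TROP panel allele counts, adjacent bins merged left-to-right until
each stratum holds ≥ 200 SNPs (exact bin widths in such analyses are a
judgment call; both width and minimum are configurable, and the MAF pool
can be restricted to either panel). Bulk comparisons: the unordered pair of
F0 parental genotypes {hom-ref, het, hom-alt}. Sites with a missing
parental genotype keep their AFDs but are not scored; sites whose parents
are identical homozygotes are monomorphic in the cross and get line
p-values of 1 rather than competing in a stratum whose |AFD|s are pure
noise.

**Combination and calibration.** The combined score is the product of the
three p-values. Under independence and uniformity the product of k uniforms
has CDF F_k(t) = t·Σ_{i<k}(−ln t)^i/i!; the tier threshold solves
N·F_k(t) = m by Brent's method on (0, 1), with N the number of *scored
same-sign* SNPs — thresholds are relative to the set actually tested.
Because the same-sign pre-filter and the discreteness of rank p-values make
exact uniformity approximate (both push the realized false-positive count
*below* nominal — the suite measures ≈ 0.5 realized at the m = 5 tier on
fully null simulations), an empirical-null calibration
(`fdr_threshold_empirical`) is provided: the threshold is the pooled order
statistic of simulated null combined scores at rank m·replicates.

**What the tiers mean.** m is an expected false-positive *count* among N,
not an FDR: with real signal present the same thresholds pass more SNPs,
and the expected number of those that are null stays ≤ m.

**Caveat, not modelled.** The two bulk comparisons share founders with the
panel comparison and with each other through linkage, so the three
p-values are not exactly independent at linked sites; the product is used
as a score and the calibration treats sites marginally. Linkage
disequilibrium *between* SNPs is likewise unmodelled — candidate SNPs come
in linked clusters and are not independent discoveries.

## Mapping resolution

With bulks formed at F4, each bulk haplotype carries only ~3 mapped
meioses; at 50 cM per chromosome the expected crossover spacing among the
~40 haplotypes of a bulk is several megabases, and the AFD signal around a
QTL is a plateau tens of megabases wide within which read-sampling noise
(depth ~60) shuffles ranks freely. Candidate SNPs therefore localize a
large-effect QTL to the right chromosomal region but not to a few
megabases: across seeded replicates the median candidate-to-QTL distance is
typically 5–50 Mb, and pushing the effect size to 3× the liability SD does
not change this, because the limit is crossover density, not phenotyping
accuracy. Sharper localization requires later generations, larger bulks, or
denser effective recombination — not a different statistic.

## Annotation proximity and liftover

Feature-to-SNP distance is from the SNP point to the nearest interval edge,
boundary-inclusive (≤ 50 kb counts; 0 inside a feature) — interval-edge
conventions differ between tools, so this one is fixed and tested against a
brute-force scan. Summary classes follow the usual candidate-table rows
(protein-coding genes, lncRNA, pseudogenes, other = tRNA + misc RNA), with
features deduplicated by id within a tier and tiers cumulative.

Liftover transfers a feature only when it lies entirely within one placed
contig's source interval; features spanning contig boundaries, sitting on
unplaced contigs, or straddling a chimeric-scaffold cut are rejected with
machine-readable reasons (`split` / `unplaced` / `cut`) rather than
silently dropped or truncated. Interchange coordinates are 1-based
inclusive (GFF3/AGP convention) throughout; reverse-orientation placements
reflect coordinates within the target interval and flip strand, and
lift ∘ inverse-lift is the identity on accepted features. AGP `?`
orientations are treated as `+` with a warning. Reciprocal-best-hit
filtering keeps hits with e-value ≤ 1e−20, identity ≥ 85%, query coverage
≥ 50%, takes the best hit per query by bit-score (ties broken by
lexicographic subject id, for determinism), and pairs mutual bests.

## Problem sizes in the test suite

The suite runs the full screen at the design's 50,000 sites for the
end-to-end checks (50 planted-QTL and 100 null replicates), 10,000-draw
crossover and map-expansion statistics, 400-replicate threshold
calibrations at N = 46,736, and brute-force oracle comparisons at a few
hundred to a few thousand items — sizes chosen so each statistical
tolerance (3·SE, or a χ²/KS test at α = 0.01) is meaningful while the whole
suite stays interactive.
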