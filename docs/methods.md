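# Methods

`invfinder` detects polymorphic chromosomal inversions de novo from
unphased SNP genotypes sampled across a hybrid zone, and characterizes
them through karyotype calling, diversity statistics, family
recombination patterns and geographic clines. This note documents the
models, the numerical choices, and what the synthetic benchmarks do and
do not demonstrate.

## Why LD networks find inversions

Recombination is suppressed in inversion heterokaryotypes, so the two
arrangements of an inverted region diverge in allele frequency at many
sites. In a sample spanning a hybrid zone, those sites form a
genomically clustered block of SNPs in strong mutual LD that stands out
against the genome-wide background (admixture LD from dispersal is
spread across the genome, not gathered in blocks). The pipeline
exploits exactly this signature.

## Pairwise LD (r²)

For each pair of SNPs within a linkage group, haplotype frequencies are
estimated from unphased diploid genotypes by EM over the 9-cell
two-locus genotype table (the only latent quantity is the phase of
double heterozygotes). r² = D²/(p_A(1−p_A)p_B(1−p_B)) with D taken from
the EM solution; the EM is run from three initializations of the
double-heterozygote split and the solution with the highest multinomial
likelihood is kept (the likelihood can have two local maxima for weakly
informative tables). Pairs with fewer than 10 pairwise-complete
individuals, or with a monomorphic member, are undefined and treated as
r² = 0 by the clustering. A genotypic (Burrows-style composite)
estimator is available behind `composite_r2` for data where the random
union-of-gametes assumption is doubtful.

## Cluster tree and single-outlier clusters

Single-linkage agglomeration runs over descending r² thresholds (grid
step 0.01; ties in merge order broken by smaller SNP index). Each merge
records, for both child clusters, the statistic

    λ = (median intra-cluster r² before merge − median after) × n_child,

which is large when a tight cluster is absorbed into a weakly linked
background, and the child's edge count |E| (pairs with r² ≥ the merge
threshold). A cluster is *extracted* at stringency φ when λ×10 > φ and
|E| ≥ |E|min = 30; extraction marks the node, and any qualifying
ancestor that contains an extracted node is a compound cluster and is
never emitted. Extracted single-outlier clusters (SOCs) are retained if
they have ≥ 32 SNPs and median intracluster r² ≥ 0.3.

φ is swept over 0, 1, 2, … until no cluster is extracted at all (not
merely none retained — at lenient φ small noise clusters are extracted
and discarded by the size filter, and the informative extractions occur
at moderate φ). Among retained SOCs sharing SNPs across φ, the one with
the fewest SNPs (highest median LD) wins, except when two SNP-disjoint
overlapping SOCs fuse into one larger cluster at higher φ, in which
case the fused cluster replaces both (two overlapping inversions
sharing one source of LD). The λ scale and sweep are this package's
own formalization of network-based outlier extraction; the benchmark
surface is recovery of planted rearrangements, not equality with any
other implementation. SOC intervals are the extreme cM positions of
member SNPs; they bound the region influenced by the rearrangement and
are not breakpoint estimates.

## Karyotype calling

For each SOC, PCA runs on ALL SNPs inside its interval (not only the
high-LD members): genotype codes are mean-imputed per SNP and
column-centred, not variance-scaled (scaling would let rare SNPs
dominate; a `scale_pca` switch exists). k-means (scikit-learn, best of
10 restarts by the between-cluster share of the total sum of squares —
the same objective the classical Hartigan–Wong updates optimize) groups
individuals on PC1 into homokaryotypes and heterokaryotypes, or on
PC1/PC2 into six groups when two SOCs overlap (three arrangements).
A manual-override path accepts PC1 cut points for regions where no
k-means run reflects the visible structure.

Candidates are kept when PC1 explains ≥ 10% of the variance and
intermediate individuals are rare. "Intermediate" is made operational
as: score farther than 3 robust standard deviations (1.4826×MAD of
within-group residuals, pooled) from the group's median centre, in the
direction of an adjacent centre, with tolerated fraction 0.05. Robust
statistics are used because the intermediates themselves would inflate
a plain pooled SD and mask the rule. Both the multiplier and the
fraction are configuration, since no numeric rule is canonical.

Orientation: the heterokaryotype group must lie between its
homokaryotype groups (strictly ordered PC1 means, else an error with
diagnostics); for six groups the homokaryotypes are the vertices of the
largest PC1/PC2 triangle and each heterokaryotype pairs the two
vertices whose midpoint its centroid is nearest. R is the arrangement
most frequent among individuals within the first 10 m of the transect
(the Crab-end window; configurable).

## Diversity and divergence

H_obs per SNP is the heterozygote fraction among called individuals of
a group. Nucleotide diversity per probe region is the sum of per-site
π (computed from allele counts: 2a(n−a)/(n(n−1)) with n haplotypes)
over the region's SNPs divided by the effective region length
(default 120 bp, the probe length; invariant sites contribute zero).
Divergence between homokaryotype groups uses the mixture identity

    N(N−1)π_t = 2 n_x n_y d_XY + n_x(n_x−1)π_x + n_y(n_y−1)π_y,

with n_x, n_y counted in haplotypes (2 × diploids) — the convention
that makes the identity exact; a negative numerator (possible with
missing-data noise) is floored at zero and flagged. Group comparisons
use two-sided Wilcoxon rank-sum tests with Holm (sequential
Bonferroni) adjustment within each reported table. π and d_XY are
reported for validation of candidates, not interpreted as inversion
ages.

## Family recombination analysis

Markers heterozygous in exactly one parent are informative for that
parent. QC removes sites with Mendelian-impossible offspring genotypes
and sites failing an exact binomial test of 1:1 transmission at
p < 10⁻³ ("extreme" distortion is not numerically defined anywhere
authoritative; the threshold is configuration and logged). When the
second parent is ungenotyped, its homozygous genotype is imputed from
the offspring when they segregate only one of its alleles.

Parental phase is inferred by a greedy minimal-switch rule: markers are
processed in map order and each marker's orientation is chosen to
minimize the number of offspring switching haplotype, seeded at the
first informative marker. Each remaining switch between consecutive
runs is one crossover; runs supported by a single SNP, or only by
consecutive SNPs within one contig, are removed (genotyping artefacts
cannot be excluded there), making event counts conservative. Event
intervals are reported in cM and contig coordinates; an event spanning
a candidate boundary counts as collinear (conservative), and gaps
> 20 cM between informative markers are flagged.

Orientation parsimony: for a homokaryotypic parent, crossover counts
are recomputed with the candidate block's marker order reversed; each
offspring haplotype is called R or A by whichever order needs fewer
crossovers (ties are uninformative). A single crossover inside an
inverted block surfaces as two extra switches under the wrong order,
so informative meioses discriminate sharply.

## Cline fitting

Arrangement copy numbers (0/1/2) along the 1-D transect are modelled as
Binomial(2, p(x)) — local Hardy–Weinberg. The symmetric cline is

    p(x) = p_C + (p_W − p_C) / (1 + exp(−4 (x − c) / w)),

where w is the inverse of the maximum slope (the 4/w scaling); the
asymmetric model uses separate widths on the two sides of the centre,
continuous at c; the constant model is the null. Widths are fitted on
the log scale and end frequencies on the logit scale to avoid boundary
effects. Optimization is derivative-free (Nelder-Mead), multi-start
(8 starts: two quartile centres × two width scales × both end-frequency
orientations, with data-driven end-frequency guesses), tolerance 1e-8
on the log-likelihood. Constrained fits (pinned frequency, centre or
width) warm-start from the unconstrained solution and vice versa, so
nesting inequalities hold to optimizer tolerance.

Model selection: clinal requires ΔAIC(constant − cline) > 10 AND
binomial deviance explained > 10%; asymmetric replaces symmetric only
under the same ΔAIC rule; ties keep the simpler model.

Fixation test: the end frequency nearer 0/1 is pinned there and the
models compared by likelihood ratio. Because the pinned value lies on
the boundary of the parameter space, the p-value uses the
boundary-corrected mixture ½χ²₀ + ½χ²₁ (the plain χ²₁ p is reported
alongside, as is ΔAIC ≤ 2 for comparability). Known limitation: when
the cline is steep and the tail of the transect is long, the data near
the end are essentially fixed and the LRT null collapses onto zero —
the test is then strongly conservative (measured type-I error ~1% at
w = 10 m on a 152-m transect). The calibration benchmark therefore uses
a wide cline (c = 95 m, w = 36 m, the upper end of widths the pipeline
reports), where the end-frequency information is regular and the
measured size is ~5%.

Profile analysis: shared centre (grid 85–100 m by 1 m) or shared width
(log-scale grid 0–4 by 0.2, i.e. 1–54.6 m) across clinal inversions;
2ΔLL between the summed unconstrained log-likelihoods and the best
constrained sum is referred to χ² with (number of inversions − 1)
degrees of freedom. A diagnostic reports whether a forced-fixation
cline with the estimated centre and width predicts frequencies within
1% of fixation at the transect ends (it does for all steep mid-transect
clines) — observed polymorphic ends then indicate that divergent
selection alone is an insufficient explanation.

## Synthetic data generator

The generator plants known structure rather than simulating a
coalescent: the benchmark surface is recovery of planted truth, and
explicit per-arrangement allele-frequency vectors produce the LD, PCA,
heterozygosity and cline signatures the pipeline consumes at a tiny
fraction of the cost. Specifics:

- Individuals are uniform on [0, L] (default L = 152 m, n = 373).
- Per inversion, each of an individual's two haplotypes draws an
  arrangement from the true cline p(x) (karyotype ~ Binomial(2, p(x));
  three-arrangement regions use two derived clines with the reference
  taking the remainder).
- A `divergence` fraction of inside SNPs is arrangement-diagnostic
  (frequency < 0.05 in one arrangement and > 0.95 in another), so the
  mean |f_R − f_A| over inside SNPs ≈ divergence. This mirrors the
  biology the scan exploits: suppressed recombination preserves
  near-fixed differences between arrangements. The default divergence
  (0.6) reproduces median intracluster r² in the 0.8–0.9 range, within
  the span observed for real candidate inversions.
- Each derived arrangement descends from one seeding haplotype: a
  (1 − diversity_ratio) share of its SNPs is fixed at the seed allele,
  so diversity_ratio = 0 gives exactly π = 0 within that arrangement
  (pre-error) and diversity_ratio scales its reduced diversity.
- Background SNPs are constant-frequency, with a 5% clinal fraction
  (smooth sigmoid frequency change) emulating the hybrid zone's
  clinal-SNP background; genotype missingness (2%) and symmetric
  miscalls (0.2%) are applied last.
- Families: meioses draw crossover counts Poisson(map length in
  Morgans) with uniform positions on the cM scale (Haldane, no
  interference). Crossovers inside an inversion are rejected when the
  parent is heterokaryotypic, with double-crossover leakage at 1e-4 and
  gene conversion at 1e-5 per locus per meiosis (defaults;
  configurable). Parents homozygous for a derived arrangement
  recombine freely but in the reversed gene order — phase is evaluated
  in reflected coordinates inside the block — which is what makes the
  orientation-parsimony signal reproducible in simulation.
- `emulate_paper_design` assembles the study-shaped fixture: 373
  transect individuals, 17 linkage groups (~40k SNPs at scale 1,
  scalable), inversions on 11 linkage groups including two overlapping
  three-arrangement pairs, and four families of 8, 21, 12 and 11
  offspring, the first three sharing a father and one mother
  ungenotyped.

What the generator does not emulate: linkage disequilibrium from shared
ancestry along the transect beyond the clinal-SNP fraction
(isolation-by-distance LD), selection, crossover interference, and
read-level error structure. Passing benchmarks therefore demonstrate
the pipeline's correctness and calibration under the planted model, not
its false-positive rate under every real-data background; the
sensitivity of the spurious-SOC rate to the background clinal fraction
is reported by the benchmarks, not resolved.

## Benchmark problem sizes

The reported benchmarks use: detection on 2,000 SNPs × 400 individuals
(11 planted inversions, ≥ 32 diagnostic-capable SNPs each) plus a
50-linkage-group collinear genome for the false-positive rate; cline
recovery and null-model selection over 100 replicates at n = 373;
fixation-test calibration over 600–1,000 replicates; 200 heterokaryotype
meioses for suppression; ~10 single-inversion families for orientation;
10,000 random cases for the d_XY identity. The end-to-end pipeline
fixture runs at a reduced marker density (scale 0.05, ~2,000 SNPs) with
all stages enabled.

## Degenerate inputs and tie-breaks

Monomorphic or undefined LD pairs are flagged, never silently dropped;
a linkage group whose LD matrix is entirely undefined raises. k-means
requires at least k distinct score points. Orientation raises on
non-monotone group means rather than guessing. Negative d_XY floors at
0 with a flag. Cline fits clip probabilities at 1e-9 for likelihood
evaluation; width underflow in the optimizer is floored rather than
allowed to reach zero. Filtering order is fixed (individuals → site
call rate → MAF) and idempotent.
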