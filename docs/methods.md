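# Methods

This note records the models implemented in `ployssr`, the defaults that
matter, the choices made where the design was genuinely open, and what the
synthetic panels do and do not establish about real data.

## Data model

Genotypes are allele-presence records: an SSR cell is the multiset of
distinct fragment sizes (bp) observed for one accession at one locus, with
at most `ploidy` (default 4) entries; the S-locus cell is a set of allele
labels. Cells with fewer than `ploidy` distinct alleles are stored as-is —
allele dosage and null alleles cannot be separated in routine tetraploid
electropherogram scoring, so no copy numbers are imputed at the data level.
Validation flags such cells as possible dosage/null cases and reports
observed size ranges against the declared per-locus ranges; these are
warnings, never errors. A wholly missing locus is an absent cell, and every
downstream operation states its handling (pairwise deletion in the distance
builders, per-locus typed counts in the diversity statistics).

## Presence-based frequencies and diversity indices

With dosage unknown, allele frequencies are computed from presence: each
typed accession carries weight 1 at a locus, split equally over its distinct
alleles (`presence_split`, the default; `presence_unit` gives unnormalized
carrier counts for band-informativeness uses). All indices are functions of
these frequencies: Ne = 1/Σp², H′ = −Σp ln p (natural logarithm), PIC by the
Botstein formula 1 − Σp² − Σ_{i<j} 2p_i²p_j², and Rp = Σ(1 − 2|0.5 − c|)
over carrier proportions c. Classical expected/observed heterozygosity and
Hardy–Weinberg machinery are deliberately absent: they presuppose dosage.

Two different "private allele" universes coexist and are never conflated:
per-locus PA counts alleles carried by exactly one accession; per-group
PA counts alleles observed in exactly one group. Within-group polymorphism
is the share of loci showing ≥ 2 alleles in the group — note a clonal group
of heterozygous plants is still polymorphic by this definition; only a
single-allele locus is monomorphic.

The probability of identity is a phenotype-match probability: per locus,
PI = Σ f_g² over the frequencies of the observed unordered allele-set
phenotypes, multiplied across loci (log-additive, monotonically
non-increasing as loci are added). Allele-level diploid PI formulas do not
transfer to tetraploid phenotypes, so this definition — the empirical
probability that two accessions drawn with replacement match — is the
package's PI and is tested against exhaustive pair enumeration.

## Distances

**Bruvo.** Per allele pair, d = 1 − 2^(−x) with x = |a − b|/u for repeat
unit u. x is *not* rounded to whole repeat counts: off-ladder sizes are
legitimate and the formula is defined for real x. Multisets of equal size
are matched by exact minimization over all ≤ 4! = 24 matchings (brute force
is cheap at ploidy 4; the Hungarian assignment is used as an independent
oracle in the tests, never as the implementation). Unequal sizes are
reconciled by a fill model: `genome_addition` fills the smaller genotype
from its own alleles, `genome_loss` from the other genotype's, each
averaging the matching distance over every possible fill; the default
`addition_loss_average` averages the two models, treating copy-number gain
and loss as equally likely; `infinite` scores each unmatched slot 1 (the
upper bound), and therefore dominates the averaged model on nested
genotypes.

**Jaccard.** S-allele sets are compared as 1 − |A∩B|/|A∪B|; the S-locus
evolves by point mutation and recombination rather than stepwise repeat
changes, so a stepwise distance would be meaningless there.

**Combined matrix.** The mean of the 10 per-locus Bruvo distances and the
one Jaccard distance, each locus weighted exactly 1/11. Pairs missing a
locus average over the loci both members are typed at; a pair with no
shared typed locus is an error, not a silent zero. Per-locus matrices are
retained for provenance.

**Nei.** Each accession is treated as a one-member population with
presence-split frequencies; D = −ln(J_xy / √(J_x J_y)) with the J identity
sums accumulated over loci. Pairs sharing no allele anywhere have infinite
D and are capped at `NEI_MAX_DISTANCE = 30` (identity e⁻³⁰ ≈ 10⁻¹³ — far
below anything resolvable with 11 loci). The same Nei matrix feeds both the
dendrogram and the pairwise-differentiation heatmap output; no separate
F_ST estimator is implemented, since presence-based one-member "populations"
leave the distinction without content.

## Trees, networks, support

UPGMA is average-linkage agglomeration with node height = half the merge
distance; ties merge the pair whose (lexicographically smallest member id
per cluster) sorts first, making every tree — including the degenerate
all-equal-distances case — bit-reproducible. Branch support resamples the
11 loci with replacement (the S-locus is one resampling unit, matching the
one-locus weight it has in the distance), rebuilds the Nei matrix and tree
per replicate from precomputed per-locus identity components, and reports
the percentage of replicates containing each reference clade. The bootstrap
unit is the locus, not alleles within loci: with 27 accessions and 11 loci
the locus is the exchangeable sampling unit for multilocus support. Clades
under the threshold (default 40%) are collapsed into polytomies; surviving
edges keep their support, exported as internal node labels in Newick with
heights as branch lengths.

The minimum spanning network is a Kruskal MST under the deterministic
(weight, endpoint-pair) edge ordering; with ties enabled, every non-tree
edge whose weight equals (within 1e-12) the heaviest edge on the tree path
between its endpoints is added flagged `tie_alternate` — by the cycle
property these are exactly the edges that could replace a tree edge in
another valid MST.

## Ordination and permutation tests

PCoA is classical scaling: Gower double-centering of the squared distances,
symmetric eigen-decomposition, coordinates = eigenvectors × √eigenvalue for
positive eigenvalues. The combined Bruvo/Jaccard distance is not Euclidean,
so negative eigenvalues occur; they are reported but excluded from the
coordinates and from the explained-variance denominator (the common
classical-scaling convention). A Cailliez additive correction is available
(`correction="cailliez"`) but off by default, since it rescales all
distances to fix a property the downstream analyses do not need. Axis signs
follow a fixed convention (first nonzero loading positive) so outputs are
reproducible.

Group structure is tested directly on the distance matrix with two
one-sided permutation schemes, both annotated per cell of the group-mean
distance matrix: between(g, h) permutes labels within g ∪ h and counts
permutations whose mean cross-group distance reaches the observed one;
within(g) draws random size-|g| subsets of all accessions and counts
subsets as compact as the observed group. p = (1 + hits)/(1 + N) with
N = 1999 by default, so the attainable minimum is 1/(N+1). Ties are counted
with a scale-relative tolerance (1e-9), which makes p-values invariant to
rescaling the matrix and means that permutations recreating a perfectly
separated partition count as hits — for small pooled groups the attainable
minimum p can therefore sit slightly above 1/(N+1); the test results expose
the null statistics so this floor can be verified. Significance stars
follow p ≤ 0.001 / 0.01 / 0.05.

## Cluster-number criteria

The Bayesian clustering itself is external; the package consumes a long
table of per-run ln P(D|K) (and optionally per-run Q matrices). ΔK uses
sample standard deviations (ddof = 1): L′(K) = mean(K) − mean(K−1),
L″(K) = |L′(K+1) − L′(K)|, ΔK = L″/sd(K), undefined at the range ends and
wherever sd = 0 (reported as missing, never as infinity). The plateau
criterion is one-sided: the smallest K such that no larger K improves the
mean likelihood by more than `plateau_tol_sd` (default 1) × sd(K). A
symmetric band was rejected because likelihood curves that keep creeping
upward would never satisfy it, yet are exactly what a plateau looks like in
practice. ΔK resolves the uppermost hierarchical split while the plateau
can reveal finer substructure; the package always reports both and leaves
the choice to the analyst.

Q-matrix replicates are aligned to the first replicate by greedy
maximum-correlation column pairing before averaging — an approximation to
full label-switching search that is adequate for K ≤ 10 desk-scale
summaries. Accessions whose maximum mean membership falls below 0.8
(configurable) are flagged admixed.

## Synthetic panels

The generator emulates the structure the analyses assume: 27 tetraploid
accessions in 5 groups of 5/7/5/5/5; 10 SSR loci whose ladders (base size,
repeat unit 2–3 bp, 5–14 alleles within ~102–213 bp) are drawn per seed;
one 17-allele S-locus drawn without replacement per accession (a genotype
cannot carry duplicate self-incompatibility alleles) from group-biased
pools. Per group and locus, allele frequencies are Dirichlet(α) over the
ladder; accessions draw `ploidy` allele copies i.i.d. and record the
distinct alleles (presence collapsing — the same information loss as real
dosage-ambiguous scoring). The default α = 0.5 was chosen so that observed
per-locus allele counts across the panel stay within the 5–14 design range
in ≥ 95% of seeds while still producing clear group structure. The default
panel also contains an exact-clone complex plus single-allele mutants
(one allele shifted by one repeat unit — the signature difference between
clonal selections) and two admixed accessions drawing from mixtures of
group frequencies. Optional per-copy dropout (default 0) produces missing
cells.

Synthetic likelihood tables are piecewise-linear mean curves (gain 300 per
cluster up to the true K, 1 beyond) with Gaussian replicate noise (sd 15,
20 replicates, K = 1..10). The post-plateau slope is kept well below one
replicate standard deviation so the curve is a genuine plateau under the
package's own plateau rule.

What passing tests on these panels shows: the statistics, distances, and
inference machinery behave correctly under dosage-ambiguous tetraploid
scoring with clones, mutants, and admixture present. What it does not show:
robustness to allele-calling error, size homoplasy, null-allele bias, or
linkage between loci — none of which the generator models; the panels are
i.i.d. draws per locus given group, with no pedigree or mutation process
across generations.

## Numerical conventions

Distance matrices are validated on construction (symmetry, zero diagonal,
finiteness). Display rounding is 3 decimals in CSV outputs; all internal
arithmetic is full precision. Per-metric "Mean" rows in the stats output
are true arithmetic means of the computed columns. MST tie detection and
permutation tie counting use the tolerances given above; all stochastic
operations (bootstrap, permutation, simulation) take explicit integer
seeds and are bit-reproducible under a fixed seed. Problem sizes used in
the shipped checks (500 null replicates × 199 permutations; 200 likelihood
tables; 1000 bootstrap replicates; 1000 oracle pairs) were chosen to make
the Monte-Carlo bands tight at single-core desk scale.

## Known limitations

- Frequencies are presence-based throughout; if dosage-resolved genotypes
  become available, every index here underuses them.
- The Nei distance on one-member "populations" is a relatedness summary,
  not an F-statistic with sampling theory behind it.
- Greedy Q-column alignment can mis-pair columns when replicate runs find
  genuinely different local optima.
- The MSN lists tied alternative edges only, not all near-minimal edges;
  there is no edge-weight uncertainty measure.
- PI assumes unrelated accessions; in panels full of clones it understates
  the sharing probability among relatives by construction.
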