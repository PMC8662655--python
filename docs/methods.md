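# Methods

This note documents the models, decision rules and numerical choices
behind `neosexpipe`, and what its synthetic-data tests do and do not
demonstrate about real data.

## Background and scope

In birds, females are the heterogametic sex (ZW).  In the Sylvioidea
songbirds, a fusion between the ancestral sex chromosome and part of an
autosome (~24 Ma) created a *neo-sex chromosome*: an old, heavily
differentiated *ancestral* region and a young *added* region in which
Z-W recombination shut down gradually after the fusion.  The package
implements the downstream analyses such a study needs once reads are
aligned and genotypes called: identifying sex-linked scaffolds, phasing
gametologs, dating recombination suppression per gene, measuring
purifying selection (dN/dS), and quantifying diversity loss and repeat
accumulation.  Assembly, annotation, read alignment, orthology
inference and ML tree building are out of scope; their outputs
(profiles, VCFs, alignments, Newick trees, repeat BEDs) are inputs.

## Sex-linkage classification (`sexlink`)

Per scaffold, evidence is the per-sex median (configurable to mean) of
per-sample median coverage and of per-sample heterozygosity, computed
upstream from mismatch-free alignments.  Rules, applied with strict
inequalities and precedence W > Z > autosome:

- **W**: female median > 25x and male median exactly 0 (an epsilon for
  noisy inputs is available, default 0).
- **Z**: female/male ratio < 0.55; or ratio < 0.65 together with an
  absolute male-female heterozygosity difference > 0.1 (females are
  hemizygous on Z, so heterozygous calls there are male-biased).
- A scaffold with zero male coverage that misses the W cut is left
  unassigned: no coverage ratio can be formed.

Region assignment from dual-reference homology requires both reference
targets to agree on Z (or Z_random) for the ancestral region, or on
4A (or 4A_random) for the added region; one named target plus an
unplaced scaffold also counts; conflicts are unassigned; ranges under
10 kb are ignored.  The pseudoautosomal region is not inferred — it is
supplied as an explicit scaffold list when known from a linkage map.

## Gametolog phasing (`phasing`)

Phasing assumes mapping against a W-depleted reference, so female W
reads co-map to the homologous Z scaffold.  At a biallelic site, if
every ZZ male is homozygous for allele *a* and every ZW female carries
one and the same second allele *b* (heterozygous *a/b*, or homozygous
*b* where her Z copy also carries *b* is not distinguishable and is
treated as a carrier), then *a* is the Z allele and *b* the W allele.
Everything else — heterozygous males (Z polymorphism), male-male
polymorphism, several female-specific alleles, a female lacking the
candidate W allele, missing genotypes — is masked to N, as are sites
with quality < 20 or any used sample depth < 20 (the strictest reading
of the quality/coverage rule: the minimum depth over all samples used
in the decision; both thresholds configurable).

The W-deletion screen uses per-exon, per-sex coverage normalized to
each sex's autosomal median, plus female-private allele counts.  A true
hemizygous deletion leaves females with only the Z dose (ratio ~0.5)
and no W-specific variation; an exon is therefore *deleted* when the
female/male normalized ratio < 0.75 **and** female-private alleles < 1.
A coverage drop contradicted by ample female-private variation is
*ambiguous*; a gene is excluded from gametolog sets if any exon is
deleted.  The 0.75 / 1 defaults are not published values; they are
chosen so the expectation for a real deletion (0.5, 0) is always
caught, and both are configuration knobs.

## Dating recombination suppression (`timing`)

After suppression at time t, a gene's W copy evolves independently of
Z.  In a gene tree this leaves two readable signals, interpreted only
on nodes with bootstrap support >= tau (default 70; weaker nodes are
treated as absent, polytomy semantics, never as evidence against):

- a supported {Z, W} pair of species *s* means recombination outlived
  the split of *s* — suppression cannot sit on branches older than
  that split;
- a supported clade of only W sequences containing the focal species
  means suppression predates the radiation of those species — no
  branch younger than the clade's crown age (read off the *dated
  species tree*, never off gene-tree branch lengths) is possible.

Candidates start as all focal-lineage branches between the fusion age
and the present; constraints only remove branches, so candidate sets
shrink monotonically and always form a contiguous path segment.
Boundary ties keep the boundary branch (closed-interval semantics).
One remaining branch is RESOLVED, several are an INTERVAL, an empty
set is INCONCLUSIVE and reported, not dropped.  When deletion
screening leaves only part of the W clade, the constraint degrades to
the largest supported W clade present.

For the ancestral region all ingroup W sequences are expected to be
monophyletic, attaching deep in the avian backbone.  The candidate
interval runs between the closest supported flanking nodes: supported
all-Z clades containing the focal Z bound the time from below (their
crown age), supported clades joining the W clade with its nearest Z
relatives bound it from above (the split age of the closest Z lineage
left outside).  Unsupported flanks honestly widen the interval, to
W-crown-age..root in the worst case.

Preprocessing: columns containing gaps or ambiguity codes in any row
are removed; trimmed alignments shorter than 700 bp are dropped.  The
gene-conversion screen is a deliberately simplified Sawyer-style test,
not a GENECONV reimplementation: per within-species Z/W pair, maximal
runs of identical columns are scored by length against a null that
permutes the positions of that pair's mismatch columns (default
10,000 seeded permutations); runs with p < 0.05 are masked before tree
building.  Tree building is neighbor joining (scikit-bio) on
Jukes-Cantor distances with seeded column-resampling bootstrap
(support = % of replicates containing each clade of the point tree,
rooted on the outgroup); saturated distances (p >= 0.75) are capped
(default 5.0) with a warning.  NJ is a desk-scale stand-in — any
externally built Newick tree with support labels is accepted as
first-class input, keeping the ML step pluggable.

## Substitution rates (`rates`)

Nei-Gojobori (1986) counting: per codon, each position contributes the
fraction of its three point mutations that are synonymous (mutations
to stop codons count as nonsynonymous); observed differences average
over all orderings of the single-step pathway, excluding orderings
through stop codons; pS = Sd/S and pN = Nd/N are corrected with
d = -3/4 ln(1 - 4p/3).  Codons containing N (or a stop) in either
sequence are dropped pairwise and `aligned_bp` counts only retained
codons.  p >= 3/4 or dS above the saturation cutoff flags the estimate
saturated.  Filters keep aligned_bp >= 500 (inclusive) and dS < 3.
omega = dN/dS is undefined (and excluded from summaries) when dS = 0.
A counting method was chosen over ML codon models deliberately: it is
deterministic, fast, and exactly checkable against brute-force
enumeration; no branch/site or positive-selection models are offered.

Contrasts are two-sided throughout: Mann-Whitney U (U reported for the
first group), Wilcoxon signed-rank (statistic is the sum of positive
ranks, R's V), Spearman rank correlation, and Kruskal-Wallis with
Dunn's pairwise z tests (shared tie correction) under
Benjamini-Hochberg adjustment.

## Diversity and repeats (`popgen`)

Variant filters, in order: repeat overlap; mean site depth at least
twice the median of per-site mean depths (inclusive cut, computed per
context); site quality > 20; SAF > 0 and SAR > 0; RPL > 0 and RPR > 0;
per-genotype depth (genotypes below 10x are set missing — 5x for
females on sex-linked scaffolds, where they are hemizygous); site call
rate >= 80%; biallelic SNPs only.  The cascade is idempotent and logs
every removal with its reason.  Inputs are expected pre-decomposed
into SNPs; complex records are rejected, not decomposed.

A site is *callable* when >= 80% of samples meet the same depth
thresholds, the mean depth is under the coverage cap, and it lies
outside repeats.  Per segregating site with j alternate copies among k
observed allele copies (k = n samples in haploid contexts, 2n in
diploid), pi_site = 2j(k-j) / (k(k-1)) — the unbiased pairwise
estimator, assumed to match the convention of the original study's
diversity tool (not printed there; documented assumption).  A window's
estimate divides the per-site sum by its callable bp, not its length;
windows are half-open 100 kb multiples from scaffold start, and a
window with zero callable bp is flagged undefined rather than zero.
Repeat fractions merge overlapping annotation records before counting
and are length-weighted when aggregated over regions.

## Synthetic data (`synthetic_data`)

The default dated species tree mirrors a Sylvioidea-like design:
focal-lineage splits at 3, 5, 7, 17 and 21 Ma, the fusion at 24 Ma, an
outgroup at 44 Ma; the ancestral backbone extends it with Z-bearing
outgroups at 33, 41, 60, 75 and 93 Ma and a reptile rooting outgroup
at 280 Ma (the 33/60/75/93/280 Ma values are simulator choices placed
to span the avian backbone realistically).

Gametologs evolve under Jukes-Cantor at mu = 0.002 substitutions per
site per My (a realistic passerine nuclear rate) on 3 kb genes.  Before
the gene's suppression time t the Z and W histories are identical;
at t the shared W lineage detaches from the focal Z and follows the
species topology of all species that diverged after t, while each
species that diverged before t detaches its own W from its own Z at
the same time — so every simulated gene tree carries both constraint
types the dating rules read.  The expected focal Z-W p-distance is
3/4 (1 - exp(-8 mu t / 3)).  Optional gene conversion pastes a Z
segment onto the focal W at a random position.  No indels or rate
heterogeneity are simulated; alignment trimming is exercised with
explicitly injected gap/N columns instead.

Coverage profiles: per-sample medians are medians over 201 per-site
negative-binomial draws (dispersion r = 10), around class means at a
default autosomal diploid depth of 60x — a realistic resequencing
depth for this design, since the >25x W rule presupposes haploid
(c/2) coverage clearing 25x.  Autosomes and PAR get c in both sexes,
Z gets c/2 in females and c in males, W gets c/2 in females and
exactly 0 in males.  Heterozygosity is 0.20 for diploid contexts and
0.01 for hemizygous ones (sd 0.02) — rates over assayed variant
windows, not genome-wide.  A noise-free degenerate mode returns exact
class means.

Genotype tables project known Z/W haplotypes onto ZZ males (two Z
draws) and ZW females; optional male Z polymorphism and targeted
low-depth injection exercise the masking rules.  Diversity tables
place Poisson(theta x a_k x L) segregating sites (a_k the Watterson
harmonic number for k copies) with derived counts from the neutral SFS
P(j) proportional to 1/j, which makes the expected per-site diversity equal
theta exactly.

What passing these tests shows — and does not.  The simulations are
idealized: error-free genotypes, iid sites, no selection, no
rate variation, no mapping bias, no indels, a correct species tree.
Perfect classifier/phasing recovery and >= 90% branch recovery under
these conditions validate the *logic* of the rules and the calibration
of the estimators; they do not bound error rates on real data, where
mismapping, annotation errors and model misspecification dominate.

## Problem sizes and determinism

Everything is seeded and byte-reproducible for a fixed seed.  The
shipped analyses use problem sizes a single CPU handles in minutes:
200 scaffolds x 10 samples for classification; 100 genes x 3 kb x 13
sequences x 100 bootstrap replicates per suppression scenario; a 10 Mb
x 5-sample neutral simulation for diversity.  These are the sizes the
package's own reproduction script (`scripts/acceptance.py`) uses.

## Known limitations

- The phasing truth table is reconstructed from the hemizygosity
  model's main-text description; supplementary per-condition rules of
  the original study may differ in edge cases.
- NG86 underestimates rates relative to ML codon models at high
  divergence; the dS < 3 filter removes the worst of it.
- The gene-conversion screen detects long identical tracts only; short
  or old conversion tracts with accumulated post-conversion mutations
  escape it.
- The NJ bootstrap stand-in is less accurate than ML on short or
  saturated alignments; supply external trees where that matters.
- Mann-Whitney U's group convention (first group) is documented but
  the original study's convention is not printed; compare |U| against
  n1*n2 - U when matching published tables.
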