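# Methods

## The compartmentalization statistic

All coordinates are 0-based half-open internally; conversion to GFF3/VCF
1-based conventions happens only at I/O boundaries, which removes the usual
bedtools off-by-one ambiguity from the analysis itself.

For each gene the flanks are the `flank_len` (default 50,000 bp) windows on
either side of the gene span, truncated at chromosome ends. From these windows
the union of **all** genes' CDS intervals is subtracted — not only the focal
gene's — so a neighbor's coding exon never counts as flank sequence, while
neighbors' introns and UTRs deliberately remain (only CDS is subtracted).
Flanks of adjacent genes may overlap; each gene is scored independently and no
deduplication is attempted.

Repeat annotations are first resolved to a non-overlapping set: records are
ranked by descending score (ties: leftmost start, then longer record) and a
record is kept iff it overlaps no already-kept record — the lower-scoring
record of any overlapping pair is dropped whole, not trimmed. Because the
resolved set is disjoint, per-class covered lengths partition the total and
`covered[ALL] = Σ_class covered[class]` is asserted rather than assumed.
Simple repeats and low-complexity annotations are carried through I/O but never
count toward TE density.

TE density is covered bp / noncoding flank bp. Genes with zero noncoding flank
are excluded from the distribution (0/0 is undefined; assigning 0 would bias
the percentile). The call cutoff is the linear-interpolation percentile
(numpy's default) of the eligible-gene density vector; genes exactly at the
cutoff are called, so a fully degenerate distribution saturates to "all
called" with a logged warning. Fewer than 10 eligible genes is a hard error —
a percentile of so few values is meaningless.

## Enrichment stages

GO terms are flat labels; no DAG ancestor propagation is performed, which keeps
the test reproducible but means results are only comparable across annotation
sets of similar granularity. The population is the species' GO-annotated gene
set; the study set is its intersection with the calls. Two-sided Fisher exact
p-values (scipy) are BH-adjusted (statsmodels `fdr_bh`); direction (enriched vs
purified) comes from the fold sign of the same two-sided test. Species with
under 20% annotated genes are refused; study sets under 4 annotated genes
produce an empty result. If no term reaches q < 0.05 at τ = 90 the calls are
recomputed at τ = 95 and retested; this fallback fires only on a fully
non-significant first pass.

The multigene-family fold is the ratio of the fraction of called genes in
families of size ≥ 10 to the same fraction among background genes, with +inf
returned when the background fraction is zero. The threshold 10 is also used
to gate families in the selection stage; the alternative "more than 9
homologs excluding self" reading (≥ 11) is exposed as a parameter.

TE-class profile comparisons pool, across species, annotated called genes per
class, and test each GO term's representation between two classes with Fisher +
BH; the headline number is the fraction of terms with q < 0.05 per class pair.

## Chromosomal context

A gene is subtelomeric iff its midpoint lies in the first or last 10% of its
chromosome (midpoint because partial-overlap semantics are otherwise
ambiguous). The null distribution resamples |called| genes without replacement
from the chromosome's genes 1000 times; the implementation draws the
subtelomeric count per permutation from the hypergeometric distribution, which
is distributionally identical to explicit label resampling but vectorizes. The
two-sided p doubles the smaller tail with a +1 pseudocount in numerator and
denominator and caps at 1, so p ∈ [1/(N+1), 1] and the test is valid but
slightly conservative under the null (measured type-I rate ≈ 0.046 at α =
0.05 over 500 replicates).

GC and recombination tracks are averaged per gene over the gene span plus its
flanks, bp-weighted by overlap with the bedGraph intervals; groups are compared
with a two-sided Mann–Whitney U test and only the sign of the median difference
feeds the cross-species exact binomial test (ties dropped).

## Population genetics

Samples are haploid genomes (assembly-based calls), so n is the number of
genomes. Per-sample SV calls merge by single linkage when both breakpoints lie
within 500 bp; the cluster representative is the leftmost (then longest) call
and its allele count is the number of contributing samples. TE-associated SVs
require length strictly > 50 bp and TE coverage ≥ 0.5 (read literally:
"longer than" is strict, "at least" is inclusive). TE SVs are assigned to
noncoding flanks and SNVs to CDS; a variant hitting both a called and an other
gene is credited to the called group, and multiple hits within one group count
once.

The folded AFS bins minor-allele counts 1..⌊n/2⌋, excluding monomorphic
records. The χ² homogeneity test drops empty columns, then pools adjacent
bins from the high-frequency tail until every expected cell is ≥ 5 (df =
K_pooled − 1); the choice of raw counts (not proportions) and tail-first
pooling is this package's convention and is stated here because the binning
convention materially affects the statistic. Pooling below two columns is an
error rather than a silent degenerate test.

## Selection summary

Families with ≥ 10 genes enter the stage. A family is "compartmentalized"
when at least one member gene is called (`--family-rule any`; `majority`
requires a strict majority) — the permissive reading, chosen because a single
TE-compartmentalized member is already evidence the family occupies a TE-rich
neighborhood. Sites are pooled within each group; pooled proportions equal the
site-weighted average of per-family proportions (asserted in tests). A site
with both posteriors above 0.95 is treated as an inconsistent input and
rejected. The cross-species test operates on per-species signs of the group
difference, not on pooled site counts, so one large species cannot dominate.

## Synthetic data generator

The generator emulates the *structure* of real inputs without nucleotide
sequence. One species is: `n_chroms` × `chrom_length` chromosomes (defaults
5 × 25 Mb), `n_genes` genes (default 1,000) placed one per slot on an even
grid with a flank-sized margin inside each slot, so each gene's flank signal
stays local — a deliberate simplification; real genomes have overlapping
flanks, which the analysis handles but the planted-truth evaluation avoids.
Family sizes follow a truncated zipf law (exponent 2.2, cap 60), putting
roughly a quarter of genes in multigene families, in the range seen in
well-annotated metazoan genomes. "Labile" families are selected — preferring
multigene families, mirroring the observation that TE-compartmentalized genes
are predominantly multigene — until about `frac_labile` (default 5%) of genes
are covered, never overshooting the gene budget.

TE placement is a Boolean (Poisson-interval) process per flank and class:
insertion count ~ Poisson, lengths ~ exponential with class-specific means
(LINE 900, SINE 250, LTR 1500, DNA 600 bp — fragment-scale, as RepeatMasker
annotations are fragment-dominated), intensity λ = −ln(1 − r)/mean_len so the
expected union coverage equals the target rate r despite self-overlap. Labile
flanks use `te_rate_labile` (default 0.50) vs `te_rate_background` (0.05) and
a LINE/LTR-heavy class mix. Overlapping placements are left in the output so
the resolution step is genuinely exercised; resolution discards some coverage,
so realized labile densities sit below the nominal rate while preserving the
planted contrast (≈ 6-fold realized for the 10-fold rate ratio).

Population variants: allele counts follow the neutral 1/i spectrum over
1..n−1, except TE variants in labile-gene flanks which, with probability
`afs_skew` (default 0.5), draw uniformly from counts > n/2. SNV counts are
neutral in both groups. This is a stand-in for a coalescent model — it has no
linkage, demography or sequence context — so passing tests show the AFS
machinery and test calibration are correct, not that the pipeline detects any
particular biological demography. Posterior tables draw each site into
{positive, constrained, neither} with rates (`selection_base` + effect for
labile families), then place the corresponding posterior above 0.95; no site
carries both signals, matching the semantics of mutually exclusive per-site
selection regimes.

Determinism: each stage derives an independent `default_rng([seed, stage_key])`
stream, so fixtures are byte-identical across runs and platforms and any stage
can be re-drawn independently.

## Problem sizes used in validation

The planted-recovery study uses the default 1,000-gene species. Recovery
(sensitivity/precision, subtelomeric enrichment) is evaluated on the top-5%
call set because the planted fraction is 5% of genes — at τ = 90 the call set
is necessarily half non-planted and precision cannot exceed ~0.5. The AFS
power/calibration studies use 100-gene single-chromosome species with half the
genes labile, giving ~500 variants per group at n = 50 genomes, over 100
(power) and 200 (null) replicates. The selection studies use 50 families × 200
sites per species, 20 species for the trend test and 200 single-species
replicates for the null sign balance. These sizes make the full validation
suite run in well under a minute while keeping every Monte-Carlo estimate's
standard error small relative to its acceptance band.

## Known limitations

- No GO DAG propagation; terms are compared as flat labels.
- The VCF dialect (INFO keys `SVLEN`, `TECOV`, `EFF`) is this package's own;
  real SV callers and annotators need a thin conversion step.
- Recombination/GC "regions" are gene-plus-flank averages; windowed
  alternatives would need a different aggregation.
- The χ² AFS comparison's pooling rule is a convention; conclusions near the
  significance boundary can depend on it.
- The generator plants signals independently; correlated real-world
  confounders (assembly quality, annotation density gradients) are out of its
  scope, and results on real genomes should be read with those in mind.
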