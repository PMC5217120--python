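# Methods

This note documents the models, algorithms, parameter choices, and known
limitations behind `exorna`.

## Study design being modelled

Paired small-RNA libraries from the lymphoblastoid cell lines and secreted
exosomes of a three-generation family: four grandparents, two parents, and
11 children (17 individuals, 34 libraries). The children's shared parents
make the family a powerful eQTL design despite its small size: every child
inherits one of exactly two paternal and one of exactly two maternal
haplotypes in each genomic segment, so a transcript's expression can be
regressed directly on those two binary inheritance codes.

## miRNA clusters

A cluster is a set of hairpins in which every member lies within
`max_gap` (default 10,000 bp) of at least one other member — the connected
components of the proximity graph. "Within 10 kb" is interpreted as the
inter-interval gap, `max(0, later_start − earlier_end)` on 0-based
half-open coordinates: the most permissive reading consistent with
spanning hairpin loci, and configurable. Strand is ignored by default
(`use_strand` flag available); whether the distance should instead be
measured between mature coordinates is not settled, so the clustering
accepts any interval table. Because proximity is one-dimensional, a sorted
sweep tracking the running maximum end recovers the components exactly;
the test suite proves equivalence against a brute-force union-find on
random annotations. Cluster counts are the per-sample sums of member
mature counts, excluding matures whose parent hairpins span more than one
cluster (their reads cannot be attributed). Singleton hairpins form
singleton clusters, so their mature and cluster counts are identical.

## Biotype composition

Proportions are computed over the six analysed classes only (lincRNA,
miRNA, misc, piRNA, rRNA, snoRNA); other annotations are dropped before
normalisation, so the composition is closed and per-sample proportions sum
to exactly 1. Compartments are compared per class with a paired two-sided
t-test (paired on individual) and Bonferroni correction with m = 6.
Zero-variance paired differences are reported as p = NA with a
`degenerate` flag rather than a fabricated zero — the t statistic is
undefined there.

## Differential expression

A deliberately simple negative-binomial Wald engine:

* **Size factors**: median-of-ratios over transcripts with a positive
  geometric mean, renormalised to geometric mean 1. Verified against
  pyDESeq2's size factors (proportionality) in the tests.
* **Dispersion**: per-transcript method of moments on normalized counts,
  `α = (s² − μ)/μ²` pooled across condition groups by degrees of freedom,
  floored at 1e-8. No empirical-Bayes shrinkage — this is the main
  deviation from the DESeq2 family of engines and will change exact DE
  counts on real data; the engine is validated by simulation instead
  (null rejection rate 0.05 ± 0.02 at the study's sample size).
* **Test**: log-link NB GLM with log-size-factor offsets; Wald test on the
  compartment coefficient; BH adjustment over tested transcripts.
  All-zero transcripts are excluded from testing and from the BH
  denominator. No independent filtering is applied: all nonzero
  transcripts are tested, which is the conservative choice.
* **Orientation**: fold changes are exosome over cell; positive log2FC
  means relatively more abundant in exosomes.
* The paired (per-individual) design is not used by default — the model is
  `~ compartment`, as an unpaired contrast; a categorical covariate (e.g.
  sequencing run) can be added, and a covariate confounded with the
  compartment is rejected with an error.

## Variability

Spearman correlations (average ranks for ties) between samples on the
per-biotype normalized expression matrix; agglomerative clustering on
1 − ρ with average linkage. The within-cell and within-exosome pairwise
correlations (n(n−1)/2 = 136 values per compartment at n = 17) are
compared with a two-sided Wilcoxon rank-sum test: exact null distribution
for tie-free groups of ≤ 12 values, tie-corrected normal approximation
otherwise. The pairwise values share samples and are therefore dependent;
the p-value is reported as-is for comparability, with that caveat attached
to the result object.

## Pedigree haplotypes

* **Mendelian filter**: a marker is dropped when any (child, father,
  mother) trio has a child dosage impossible under Mendelian transmission;
  missing genotypes are unconstrained.
* **Phasing**: at markers where a parent is heterozygous and the
  grandparental genotypes admit exactly one assignment, each parental
  allele is anchored to the grandpaternal (code 0) or grandmaternal
  (code 1) haplotype. Markers where both grandparents are heterozygous are
  uninformative. The anchoring is arbitrary but fixed; eQTL results are
  invariant to flipping any block's encoding (tested).
* **Transmissions**: at each marker informative for a parent, the child's
  transmitted allele is deduced from the child's and the other parent's
  genotypes (skipped when both alleles are consistent), then mapped to an
  origin code. Raw calls are smoothed by a sliding-window majority vote,
  default width w = 5 (odd, ≥ 3), to absorb genotyping error. Missing
  genotypes are treated as uninformative, never imputed.
* **Blocks**: every origin switch in any child on either side contributes
  a breakpoint at the midpoint between the flanking informative markers;
  blocks are the intervals between consecutive breakpoints and tile each
  chromosome's covered extent. Per-child codes are constant within a block
  by construction.

The smoothing window sets a resolution limit: an origin segment spanning
fewer than ⌈w/2⌉ of a child's deducible calls is absorbed by the vote, so
a pair of crossovers closer together than roughly three informative-marker
spacings is invisible. Recovery statistics are therefore quoted over
*detectable* crossovers — those with at least three deducible calls in the
flanking segments on both sides. On default synthetic pedigrees, >99.9% of
per-marker origins and ~100% of detectable breakpoints (localised to the
flanking-call interval) are recovered.

## eQTL mapping

Per transcript and compartment, OLS of `log(Y+1)` (natural log; switching
to log2 rescales β by 1/ln 2 and leaves R² and p unchanged — tested) on
the paternal and maternal codes of the block containing the transcript's
hairpin midpoint (configurable to hairpin overlap). The p-value comes from
the overall F-test, `F = (R²/k) / ((1−R²)/(n−k−1))` with k the number of
non-degenerate regressors — the standard mapping from R² to a p-value for
OLS, which for k = 2 and n = 11 has the closed form
`p = (1 + 2F/8)^(−4)`. Constant regressors are dropped (k reduced); if
both are constant the transcript is untestable and flagged.

Eligibility: median normalized expression ≥ 10 over the children's samples
in the given compartment (size factors computed from all 17 of the
compartment's samples, children subset afterwards); transcripts mapping to
multiple loci and transcripts whose interval overlaps a retained variant
are excluded. BH q-values are computed within compartment; sharing is
assessed by the Pearson correlation of effect sizes across compartments
and by intersecting hits at 20% FDR.

Confounder QC:

* **Haplotype ranking**: a genome-wide scan of every block against every
  tested transcript; blocks are ranked by the number of transcripts
  associated at nominal p ≤ 0.05. A top-ranked block is suspect of
  tracking a technical factor.
* **k-mer mapping bias**: 10-mers in each child's unmapped reads,
  normalized by total reads, compared between haplotype groups with a
  one-sided Wilcoxon rank-sum in the direction *opposing* the eQTL effect
  (an excess in the low-expression group would indicate haplotype-specific
  mapping failure). Only k-mers present in at least half the children are
  tested — rank tests on all-zero vectors are meaningless; the floor is
  configurable.
* **Sex confounding**: Fisher's exact association between block codes and
  child sex (the method is unspecified upstream; Fisher's exact is the
  natural choice for a 2×2 inheritance-by-sex table).

## NTA profiling

Hairpin-local alignments encode nontemplated additions as CIGAR soft
clips: a leading clip is a 5′ NTA, a trailing clip a 3′ NTA (labels
`"XY-"` and `"-XY"`, uppercased). Reads with fewer than 16 matched bases
are skipped; reverse-strand records are excluded (hairpin references are
single-stranded); a read clipped on both ends contributes one event per
side (events, not reads, are counted by default). Frequencies are
percentages of all hairpin-aligned reads, with clips longer than 2 nt
pooled into "other" and the NTA-free fraction closing the composition to
100%. Per-hairpin contribution tables (percent of a given NTA's reads per
hairpin) expose effects driven by a few highly abundant miRNAs. The 5′
and 3′ streams are kept separate end-to-end; headline comparisons use 3′.
The local realignment itself is out of scope — the profiler consumes its
output, and the generator emits compatible SAM.

## Synthetic-study generator

The generator is first-class, tested code; its defaults are the study
conditions.

* **Pedigree/genotypes**: 2 chromosomes × 300 biallelic autosomal markers
  (positions uniform over 100 Mb), minor-allele frequency ~ Uniform(0.2,
  0.5) to guarantee informative, heterozygous parents. Gametes are formed
  with Poisson(1) crossovers per meiosis per chromosome, placed uniformly
  and independently per meiosis. Sex chromosomes are not simulated; the
  sex-confounding check is a covariate check, not X genetics.
* **Counts**: 34 libraries with target depths Uniform(0.8M, 1.2M);
  per-transcript NB counts via a gamma–Poisson mixture with
  Var = μ + αμ², α = 0.1 (cell) and 0.3 (exosome) — the exosome side is
  deliberately more dispersed to reproduce the higher between-exosome
  variability. Compartment log2 fold changes are drawn around
  biotype-specific shifts (piRNA/rRNA up in exosomes, miRNA/snoRNA down,
  sd 0.8); a 5-hairpin cluster (10 matures) carries LFC = 10 with a low
  cellular baseline (~20 reads/M), making it nearly undetectable in cells
  and massively exported; 3 mature miRNAs carry a planted cis effect
  e^(β·p_i) with β = 1.5 on the natural-log scale, applied to children in
  both compartments (a shared eQTL). The NB family for exosome noise is an
  assumption made for testing — the real noise family is unknown.
* **Alignments/reads**: 22-nt substrings of random 70-nt hairpins, tails
  planted at per-read rates (default −A 8%, −T 4%, −TT 2%, 5′ A 1%) and
  encoded as soft clips; unmapped 36-nt reads carry a planted 10-mer at a
  configurable rate for the mapping-bias QC.
* **Reproducibility**: one RNG stream per output artifact, derived from
  the single seed via a stable (CRC-32) stream key, so every fixture is
  independently reproducible across processes.

What the generator does *not* emulate: sequencing error, adapter artifacts,
multimapping ambiguity, GC/length biases, batch effects, relatedness
beyond the single family, and piRNA genomic coordinates (synthetic piRNAs
are quantified but not eQTL-mapped, having no locus). Passing tests
therefore demonstrate correctness of the algorithms under the stated
statistical model, not robustness to every artifact of real libraries.

## Problem sizes and numerical choices

Tests and the acceptance script run at the generator's default scale
(600 markers, ~150 transcripts, 34 samples; 2,000 null model fits, 200
recovery replicates, 20–50 seed sweeps for the recovery suites), chosen to
exercise every code path at desk scale. Dispersion estimates are floored
at 1e-8; perfect model fits (R² = 1) report the smallest positive float as
their p-value with a `perfect_fit` flag; BH uses a stable mergesort;
Wilcoxon switches between exact and asymptotic forms as described above.

## Known limitations

* The NB engine's DE counts will not numerically match shrinkage-based
  engines (DESeq2/edgeR) on real data; direction and strong effects agree.
* The haplotype-block inference is a stated-behaviour-equivalent
  simplification of pedigree phasing pipelines; it assumes genotyped
  grandparents and biallelic autosomal markers.
* The eQTL F-test assumes approximately normal log-expression residuals;
  calibration was verified by simulation at n = 11 (rejection rate
  0.044–0.057 at nominal 0.05), not derived analytically for NB noise.
* The rank-sum variability contrast treats dependent correlation pairs as
  exchangeable, mirroring standard practice; its p-values are comparative,
  not strictly calibrated.
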