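# Methods

This note documents the models and procedures behind each stage, the
parameters that matter, the numerical choices made where the design was
genuinely open, and what the synthetic-data tests do and do not show.

## Expression quantification and depth diagnostics

FPKM is the plain definition, FPKM[g,s] = count[g,s]·10⁹ / (length[g] ·
total[s]), using full transcript length (no effective-length
correction) and the per-sample total fragment count. A sample with zero
total is a hard error naming the sample.

The saturation diagnostic models reduced sequencing depth as binomial
thinning of per-gene counts at rate p/100. For gene-level counts this
is distributionally identical to uniform subsampling of mapped reads,
so no alignments are needed. For each depth percentage the fraction of
genes whose thinned FPKM lies within `tolerance` (default 0.10) of the
full-depth FPKM is averaged over `n_reps` replicates (default 50; the
pipeline uses 20). At p = 100 the subsample is the library itself, so
the fraction is exactly 1. Genes below an optional FPKM floor
(`fpkm_threshold`, e.g. 3) are excluded when the floor is positive —
low-expression genes never saturate, and the floor asks the question
"is depth sufficient for the genes one would actually analyse?". The
percentage grid and replicate count are exposed as flags because no
canonical values exist.

Density summaries use the per-group **mean** FPKM per gene (groups here
have few samples; pooling per-sample densities was the alternative and
is recoverable by passing a one-sample-per-group design), log10 after
excluding zeros, on a fixed histogram grid (default 80 bins over
log10 FPKM ∈ [−3, 5]) normalised to unit area.

2^−ΔΔCq: ΔCq = Cq_target − Cq_reference within a sample; ΔΔCq subtracts
the mean ΔCq of that gene over calibrator-condition samples. Missing
reference or calibrator rows are errors, not NaNs.

## Differential expression

The DE engine is deliberately simple; the scientifically load-bearing
part is the downstream consistency filter, and any external engine's
per-comparison tables can be substituted (`deresult_from_table`).

Size factors are median-of-ratios to the gene-wise geometric-mean
reference, rescaled to geometric mean 1. When no gene is expressed in
every sample, a pseudo-reference over positive counts only is available
behind a flag (and is what `test_pairwise` uses internally).

The test compares group count sums on normalized data. Per-gene
dispersion α is estimated by method of moments from within-group
variances, a trend α(μ) = a₀ + a₁/μ is fitted by trimmed least squares,
and the gene estimate is shrunk toward the trend with 10 prior degrees
of freedom (clipped to [1e−8, 10]). With fewer than two replicates in
both groups — the motivating studies often have 1–2 samples per
temperature group — the trend alone is used and a warning logged. Group
sums are modelled negative-binomial with matching mean and variance
(Var K_A = μ_A + α q̄² Σ s_j²), and the two-sided p-value is the
conditional probability, given the total, of all splits no more likely
than the observed one. The conditional law is enumerated on a window of
±12 conditional standard deviations around the mode (always containing
the observation); mass outside is far below double precision. All-zero
genes get p = 1 and are excluded from the BH denominator. BH is applied
within each pairwise comparison separately, significance at adjusted
p < 0.05.

Direction convention: log2FC is computed low-over-high with a 0.5
pseudocount per group sum, so "up at low temperature" means lfc > 0.

`consistent_degs` intersects the significant sets of all low-vs-high
comparisons and records the per-comparison direction; a gene is flagged
`consistent_direction` only when the sign agrees everywhere. The
overlap report gives the two consistent sets, their intersection, their
per-high-group Venn membership counts, and how many members are also
significant in the direct low1-vs-low2 comparison.

## Resampling GO-group enrichment

The unit of testing is a *functional group* taken as given in the
annotation map (a fixed classification such as a GO slim); no DAG
propagation is performed. For a DEG set of size k and an expressed-gene
background, the null is 10000 draws of k genes **without replacement**
from the background (a with-replacement mode exists behind a flag). The
empirical two-sided p is 2·min(P̂(X ≤ obs), P̂(X ≥ obs)) with add-one
smoothing ((#extreme + 1)/(n_iter + 1)), capped at 1, so p = 0 is
impossible. Both directions are reported ("higher"/"lower") because
under-representation is as informative as over-representation here.
Significance uses Bonferroni α/m with m = number of groups having at
least one background gene.

Sampling exploits exchangeability: genes with identical
group-membership patterns are interchangeable, so per-pattern counts of
a draw follow a multivariate hypergeometric (sampled directly with
numpy) and group counts are a linear map of them. This is exactly the
same distribution as naive gene-index sampling, several times faster,
and makes the single-group marginal exactly hypergeometric — which is
why `hypergeom_oracle` (exact tail sums, two-sided as twice the smaller
tail) is a valid independent check of the whole machinery.

## Variants and genetic structure

Quality filtering removes a record when **either** QUAL < 30 or
QD < 5 fails (the stricter reading of a remove-if-low rule; both
thresholds are flags, and records lacking the scores pass with a
warning). Site selection keeps positions with at most 2 observed
alleles (alleles with nonzero total depth) where **every** sample has
total depth ≥ 6; a `min_samples_covered` flag relaxes the every-sample
requirement. Requiring every sample is what makes every tip of the
downstream tree genotypable.

IUPAC calling: a sample is heterozygous when both alleles reach
`het_min_fraction` (default 0.2) of its site depth, coded with the
two-base ambiguity letter; otherwise the majority base. The fraction is
a flag because no principled universal value exists; 0.2 at ~20 reads
keeps both allele-dropout and error-driven false hets below 1% per
call, while at ~12 reads the binomial cost of the same threshold rises
to a few percent per heterozygote (this is a property of any fixed
fraction at low depth, not of the implementation).

The matrix builder optionally subsamples sites uniformly without
replacement (mirroring the practice of thinning very large SNP sets
before phylogenetic inference), orders columns by (gene, position), and
exports FASTA, relaxed PHYLIP and a NEXUS DATA block so the matrix can
feed external Bayesian inference. Zero-depth cells are coded `?`.

Coding effects substitute the alternate base into its codon (CDS given
as 1-based transcript coordinates with strand and frame; minus-strand
CDS are reverse-complemented first) and translate with the standard
code; a trailing partial codon is ignored with a warning. Per-gene
non-synonymous/synonymous ratios report +inf when syn = 0 < nonsyn and
NaN when both are 0.

The built-in structure check is a desk-scale substitute for full
Bayesian inference: pairwise distances score 0 for identical codes, 0.5
when a two-base ambiguity faces a plain base it contains, 1 otherwise
(two different ambiguities score 1 even when they share a base — the
rule is kept deliberately literal and symmetric), missing data skipped
pairwise; neighbor joining is scikit-bio's standard Q-criterion
implementation. On continuous distances Q-ties have measure zero, so no
bespoke tie-breaking was added.

## SSR detection and markers

A perfect SSR is a maximal tandem run of a primitive 1–6 base unit
meeting the per-unit-size minimum repeat number (defaults 10, 6, 5, 5,
5, 5); trailing partial units are not counted; N breaks runs. Runs
whose unit is a power of a shorter unit are reported at the shortest
period. Overlapping candidates of different unit sizes are resolved by
longest span, ties to the smaller unit, then leftmost start. Adjacent
SSRs separated by at most `compound_max_gap` bases (default 100, the
conventional scanner default; the value is a flag because small
interruptions like "(CT)8tatct(TC)6" must merge) become one compound
record. Detection is implemented with vectorised self-match arrays
(seq[i] == seq[i+k]) rather than regexes; the regex formulation is kept
in the test suite as an independent oracle.

Marker filters: SSR candidates are perfect repeats with unit size ≥ 2
(mononucleotide runs and compound repeats genotype poorly); InDel
candidates are genes containing exactly one biallelic InDel. Primer
design is delegated — the marker tables carry target and flank
coordinates for external tools.

## Synthetic data generator

The generator emulates an eight-to-ten-sample design across five
temperature groups (T2/T5/T10/T14/T18 at 2–18 °C) and writes every
input the analysis consumes plus a truth set.

Counts: gene baselines are log-normal relative abundances; library
sizes are log-normal around 10⁶ (CV 0.2) to force non-trivial
normalization; counts are NB with dispersion 0.05. A fraction (default
10%) of genes is responsive below the 10 °C chilling cutoff with
log2FC ~ N(2, 0.5); 5% of responsive genes are down-regulated (most
cold-acclimation DEGs go up, but direction logic needs exercise) and
35% respond only in the coldest group, reproducing the observed pattern
that the coldest comparison yields roughly twice as many consistent
DEGs. Expected counts are normalized against the *baseline* total, so
a responsive gene's low/high mean ratio is exactly 2^lfc — which is
what the law-of-large-numbers recovery test checks.

Annotation: 25 groups, marginal membership probability uniform in
[0.03, 0.15] per group, independent across genes; planted groups
multiply the membership *odds* of responsive genes (default: one group
at odds 10, standing in for "transmembrane transporter activity").

Pileups: 500 biallelic sites over two populations (samples split into
contiguous blocks); 20% of sites are fixed for different alleles
between populations, the rest share an alternate frequency uniform in
[0.05, 0.95]. Genotypes are Hardy-Weinberg draws; coverage is
Poisson(20) per sample per site; alternate reads are binomial at the
genotype allele fraction perturbed by a 1% per-read error.

Transcripts: 2 kb random background in which accidental SSR runs are
mutated below threshold, so the scanner recovers exactly the planted
records; planted CDS are ATG..stop frames with no internal stop, placed
clear of the planted SSR.

One top-level seed fans out to fixed per-stage child streams
(SeedSequence with stage tags), so each stage is independently
reproducible and byte-identical under rerun.

What the generator does **not** emulate — GC/length biases, multimapping,
library-prep batch effects, linkage between SNP sites, a realistic
U-shaped allele-frequency spectrum, GO DAG structure, imperfect SSRs —
bounds what passing tests show: they validate the statistical machinery
under its own assumptions, not robustness to real-data artefacts.

## Problem sizes used in checks

The test suite and `scripts/acceptance.py` run at the sizes the methods
are meant for while staying desk-scale: oracle grids over backgrounds of
10–30 genes at 10000 resamples; enrichment calibration at 10000 genes ×
25 groups × 10000 iterations over 10–20 replicates; DE calibration at
5000 genes, 3 vs 3; genotyping at 500 sites × 10 samples over 10–20
seeds; SSR oracle equivalence on 300–1000 random 2-kb sequences. The
pipeline's default synthetic run uses 2000 genes so an end-to-end
determinism check stays cheap.

## Known limitations

- The NB exact-style test is calibrated but conservative near zero
  counts; it is a stand-in where a dedicated DE engine is unavailable,
  and external tables are first-class inputs.
- Enrichment treats groups independently; overlapping groups are tested
  marginally (matching the bar-chart classification use case), and
  Bonferroni is conservative under that overlap.
- The heterozygote fraction rule degrades predictably below ~15 reads
  (see above); depth-aware genotype likelihoods are out of scope.
- NJ on ambiguity-aware distances is a structure *check*, not a
  substitute for model-based phylogenetics; the NEXUS export exists
  precisely so the full inference can be run externally.
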