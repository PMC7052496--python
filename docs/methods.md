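# Methods

## Scope and data model

`seedimprint` analyses bulk RNA-seq of developing seeds from a
reciprocal cross between two inbred lines, A and B. The cross direction
`AxB` means A is the maternal line. Inbreeding matters twice: it makes
diagnostic SNPs (sites homozygous-divergent between the lines) reliable
allele-of-origin markers, and it bounds the residual heterozygosity a
line retains — each selfing generation halves heterozygosity, so five
generations leave 2⁻⁵ ≈ 3% (`pseudoref.expected_residual_heterozygosity`).

All genomic coordinates are 0-based half-open internally; VCF and GFF3
readers/writers convert at the file boundary.

## Tissue dosage model

Whole-seed RNA mixes seed coat (maternal sporophyte), embryo (1 maternal
: 1 paternal genome) and endosperm (2:1). The expected maternal read
fraction of a gene is the expression-weighted average of the per-tissue
fractions (1, 1/2, 2/3 for an unimprinted gene), with the mixture
proportions `p(t)` varying over the series. Imprinting modifies only the
endosperm term: a PEG's maternal endosperm fraction collapses to the
leakage ε (default 0.02, which keeps ratio statistics finite — complete
silencing is the ε → 0 limit), a MEG's rises to 1−ε. cis-ASE multiplies
the favoured line's allele activity by a factor (default 4) in embryo
and endosperm; the seed coat carries only maternal alleles, so ASE
cannot move its fraction.

The default mixture trajectory — (1,0,0) at 0 DAP through (0.45, 0.15,
0.40) at 8 DAP — encodes endosperm proliferation accelerating late in
the series. Real per-stage tissue proportions are not measured
quantities here; the trajectory is a declared assumption, configurable
per time point, constrained only by the requirement that the ovule stage
is all-maternal.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes,
with one master seed feeding independent named substreams (so enlarging
one component never perturbs another, and a seed reproduces a dataset
byte for byte):

* **Genome/variants.** Random chromosomes; non-overlapping gene models
  of gamma-distributed length (mean 1 kb) with 1–3 exons. Per gene,
  Poisson(π × coding length) diagnostic SNPs, each a homozygous
  substitution in exactly one line (default π = 0.028). Deliberately
  failing variant calls (one bad annotation each) and a few intergenic
  indels per chromosome exercise hard filtering and liftover.
* **Counts.** NB(mean, φ) with φ = 0.1; the mean is library size ×
  baseline (lognormal, SD 1 log-unit) × temporal archetype multiplier ×
  tissue-mixture weight × lognormal maternal-plant batch factor (SD 0.1
  per gene×batch). Five time points with 5/4/3/4/4 replicates; ovule
  replicates beyond the shared maternal plants receive their own pooled
  batches, yielding seven batches. Scaling is by one grand constant
  rather than per-sample, so a flat gene's expected count is flat and
  realized library sizes drift mildly with composition, as in real
  libraries.
* **Allele counts.** SNP coverage is a binomial thinning of the gene's
  count by 2·read_length/gene_length (floor 1 when expressed); the
  maternal count is beta-binomial around the dosage-model fraction with
  overdispersion ρ = 0.02. Whole-seed tables cover 2–8 DAP; isolated
  tissues draw dedicated NB counts at 8 DAP (4 replicates/direction).
* **Truth.** Temporal archetypes (flat, ovule-peak, 6-DAP-peak,
  8-DAP-rise by default; flat fraction 0.4) define DE truth; allelic
  statuses are planted at 5% PEG / 3% MEG / 6% cis-ASE. Imprinted and
  ASE genes are simulated endosperm-dominant (tissue weights
  0.05/0.05/0.90): imprinting is an endosperm phenomenon, and this is
  also what makes such genes visible in whole-seed data at all — an
  endosperm-minor PEG is swamped by seed-coat reads. A consequence is
  that endosperm-dominant genes drift with the tissue mixture even under
  a flat archetype; the truth table therefore carries both `is_de`
  (archetype) and `is_temporally_changing` (archetype or
  mixture-driven).

What the generator does **not** emulate: read-level FASTQ with error
models, isoform structure, GC/length biases, mapping ambiguity from
paralogs, or partial imprinting gradients. Passing tests demonstrate
correct recovery under the stated generative model, not robustness to
every artefact of real libraries.

## Pseudo-reference and liftover

Variants are hard-filtered (QD ≥ 2, FS ≤ 60, MQ ≥ 20, MQRankSum ≥
−12.5, ReadPosRankSum ≥ −8, DP ≥ 4 and ≤ mean+2SD of the input set;
missing annotations never reject; each rejected variant is tallied under
the first rule it fails). The printed convention for the mapping-quality
rank-sum cut is ambiguous about sign in parts of the literature; the
threshold is configurable and defaults to −12.5. The depth ceiling may
be fixed (`dp_max`) — the adaptive ceiling is, strictly, only
approximately idempotent because the mean and SD shrink on refiltering.

Homozygous-alt variants are substituted per chromosome in descending
coordinate order (earlier edits cannot invalidate later coordinates);
heterozygous calls are skipped with a warning since a pseudo-reference
is a single haplotype. The coordinate map is a chain of gapless blocks;
`lift` is exact outside indel gaps and returns the nearest preceding
conserved base with a `deleted_adjacent` flag inside them. Coding
divergence π counts SNV sites whose alleles differ between the lines
over covered coding sites.

## Read arbitration

"Mapping quality" is operationalized strictly as the mismatch count
(MAPQ is ignored): after retaining properly-paired, uniquely mapped
alignments with mismatches ≤ 0.04 × read length (boundary inclusive),
each read goes to the parent with fewer mismatches; single-parent reads
are kept as-is. Tie policy defaults to seeded uniform random
(deterministic-maternal and drop-ties are offered); ties cannot occur at
diagnostic SNPs by construction, so the policy only touches
non-informative reads. Chosen coordinates are lifted to the reference
through the parent's chain.

## Quantification

Counting is annotation-level: a read increments the single gene whose
exon union contains its position; multi-gene positions are discarded and
tallied. Gene length is the union-exon length. The expression filter
keeps genes with CPM > 1 in ≥ 3 samples. TMM follows the
trimmed-mean-of-M-values definition — reference sample by
upper-quartile proximity to the mean, 30%/5% two-sided rank trims on M
and A, inverse asymptotic-variance weights, geometric-mean rescaling —
and reproduces edgeR's `calcNormFactors` to ~1e-15 on shared input (a
unit test keeps that equivalence honest). FPKM uses raw library sizes;
TMM-adjusted effective sizes enter only the DE offsets, and both
behaviours are arguments, not hard-coded.

## Time-course differential expression

Both stages share an in-package IRLS fitter for log-link NB2 GLMs with
fixed per-gene dispersion (cross-checked against statsmodels in the
tests). Dispersion is estimated per gene by method of moments within
time-point groups and shrunk 70% toward the median common value —
deliberately simpler than empirical-Bayes tagwise machinery; the
acceptance bar is error-rate behaviour, not numerical equality with any
specific DE package.

* **GLM-LRT stage**: categorical time factor vs intercept-only null,
  LRT on #timepoints−1 df, BH, flag at q ≤ 0.01. Time is categorical
  here and numeric below, mirroring the two tools this two-stage design
  reflects.
* **Polynomial stage**: orthonormal polynomial time basis (degree 4 =
  #timepoints−1 by default) plus batch dummies; global LRT of the time
  terms against a batch-only null with BH at 0.01; backward elimination
  of time terms at α = 0.05 (drop-one LRTs, worst first); deviance
  pseudo-R² = 1 − dev(selected)/dev(batch-only), gate at 0.6. The
  batch-only null makes R² measure time-explained deviance
  specifically.

The DEG set is the intersection of the two flags, which can only shrink
the GLM set — the property the null-calibration tests pin down. Sample
PCA runs on log2(CPM+1) of the 500 most variable genes.

## Clustering and enrichment

Profiles are z-scored log2(mean FPKM + 1) over time points — shapes,
not magnitudes; z-scoring is an option since raw-scale clustering is
defensible too. K-means uses scikit-learn's Lloyd algorithm with 100
random starts and 25 iterations (Hartigan–Wong is an R-side
implementation detail; with 100 starts the objective difference is
immaterial, and determinism comes from the seed). The gap statistic
draws B = 50 uniform reference sets in the PCA-aligned bounding box and
picks the smallest k with Gap(k) ≥ Gap(k+1) − s_{k+1}. Hierarchical
clustering is scipy average-linkage/Euclidean. Enrichment is a one-sided
hypergeometric upper tail per (cluster, term) with BH across all pairs;
an optional Jaccard ≥ 0.7 greedy collapse merges near-duplicate term
gene-sets (no ontology-graph semantics are attempted).

## Expression classes

Expressed: mean FPKM ≥ 1 at some time point. Stage-specific: ≥ 5 at one
stage and ≤ 1 at all others (mutually exclusive by construction since
5 > 1). Ovule/seed-exclusive: every external tissue < 1 while ovules (≥
5) or some 2–8 DAP stage (≥ 5) is expressed; ovule precedence in the
single label, both flags retained. All boundaries inclusive per the
symbols; means are unweighted over replicates within a time point.

## Allelic-bias calling

Whole-seed candidates per time point and direction, two rules:

* **zero-maternal** — maternal count 0 at every SNP in every replicate;
  genes with mean per-replicate total < 2 or per-replicate SD > mean are
  removed.
* **paternal ratio** — per SNP, paternal/maternal ratio per replicate,
  averaged across replicates; called when strictly more than half the
  SNPs have mean ratio > 2, the SD of SNP means is below their mean, and
  allelic counts are nonzero in ≥ 2 replicates. Replicate ratios with a
  zero maternal count are excluded from the mean by default (that signal
  belongs to the zero-maternal rule); a (x+0.5)/(y+0.5) pseudocount mode
  is available. Single-SNP genes satisfy "majority" with their one SNP.

These are threshold rules, not calibrated tests — deliberately: a
whole-seed sample gives no a-priori expected ratio for a gene of unknown
tissue composition, so candidate calling is a screen to be validated,
not an imprinting survey.

**Reciprocal classification.** In isolated endosperm the biallelic
expectation of the line-count ratio is fixed by genome dosage (2 when
the line is maternal, 1/2 when paternal). The classifier therefore uses
the dosage-corrected allele-*activity* ratio — pooled line ratio divided
by that expectation, pseudocount 0.5 — rather than the raw line ratio: a
raw-ratio rule puts a 4:1 cis-ASE gene exactly at the threshold in the
direction where the favoured line is paternal (observed ratio 4/2 = 2),
making the boundary case undecidable in expectation, while the activity
ratio is direction-invariant (4.0 both ways, 1.0 for biallelic, ~1/ε for
a PEG). Paternal activity > 2 in both directions ⇒ `imprinted_PEG`
(maternal ⇒ `imprinted_MEG`); same line > 2 in both ⇒ `allele_specific`;
discordant ⇒ `inconsistent`; neither ⇒ `unbiased`; a missing direction ⇒
`unvalidated`. The statistic is symmetric under relabelling the lines,
which a test asserts.

MEG discovery from *whole-seed* data is out of scope by design —
maternal seed-coat RNA confounds it; MEGs are only classified from
isolated endosperm.

## Pipeline and problem sizes

`pipeline.run_pipeline` chains every stage on a simulated dataset and
writes per-stage TSVs plus a truth-scored JSON report; every stage is a
pure function of (inputs, config, seed). Default thresholds are the
collected stage defaults above (FDR 0.01, R² 0.6, CPM > 1 in ≥ 3,
FPKM 1/5, ratio > 2, mismatch 0.04, k-means 100×25).

Simulation sizes used by the test suite and `scripts/acceptance.py` are
desk-scale choices: 800-gene datasets for allelic recovery, 2000-gene
null series (three seeds) and a 1500-gene planted series for DE
calibration, 4 archetypes × 100 genes × 10 seeds for clustering, 15–20k
reads for arbitration. At these sizes the full suite runs in about a
minute and the acceptance script in about one minute on one CPU.

## Known limitations

* The DE stages are calibrated, not replicas; gene lists from edgeR /
  maSigPro on real data will differ in detail.
* The arbitration fixture models mismatch counts generatively; it does
  not re-implement alignment, so mapping-rate values are directional
  signatures, not predictions of real aligner output.
* Coding divergence counts SNVs only; indel divergence is excluded.
* The adaptive depth ceiling is only approximately idempotent (see
  above); supply `dp_max` when exact idempotence matters.
* The hypergeometric enrichment treats terms as flat gene sets; no GO
  graph reasoning.
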