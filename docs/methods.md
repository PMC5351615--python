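# Methods

## The analysis model

`epidriver` implements a fragment-based differential methylation analysis
for reduced representation bisulfite sequencing (RRBS) of paired tumor
samples, together with a screen for candidate epigenetic drivers of
progression.

**Unit of analysis.** RRBS libraries are built from MspI-digested DNA, so
the natural analysis unit is the in-silico MspI restriction fragment
rather than the single CpG or a tiled window. MspI recognises CCGG and
cuts C^CGG; on the forward strand a site at offset *i* induces a cut at
*i + 1*, which keeps each site's CpG attached to the downstream fragment.
Fragments are the intervals between consecutive cuts; chromosome-terminal
pieces (one enzymatic end only) are excluded, and the analysis retains
fragments of 40–220 bp inclusive. CpGs are indexed by the forward-strand
C offset; counts reported on the reverse-strand G are collapsed onto the C
at read time, the usual practice that doubles effective coverage. N bases
never match CCGG or CG.

**Fragment methylation.** A fragment is *analysable* in a sample when at
least `min_cpgs` (default 2) of its CpGs carry at least `cov_min`
(default 10) reads. Once that evidence gate passes, the fragment level is
the pooled-read fraction over **all** covered CpGs of the fragment —
sub-threshold CpGs still contribute reads. Pooling (rather than averaging
per-CpG fractions) weights CpGs by their coverage and yields the 2×2
count table the exact test needs. The same pooled fractions define the
methylation difference Δ used for calling, consistently across modules.

**DMF calling.** For each fragment analysable in both samples of a
comparison, the 2×2 table (methylated/unmethylated × sample A/B) is
tested with a two-sided Fisher's exact test: the p-value sums
hypergeometric probabilities of all tables with the observed margins whose
probability does not exceed the observed table's (relative tolerance
1 + 1e−7 for floating-point ties; no mid-p). P-values are
Bonferroni-corrected with *m* = number of fragments tested in that pair
comparison — each pair is analysed independently, so correction is
per-pair, not global. A differentially methylated fragment (DMF) requires
`p_adj < alpha` (default 0.05) **and** |Δ| ≥ `delta_min` (default 0.25,
inclusive). Direction is *hyper* when the second sample is more
methylated.

**Driver screen.** Candidate epi-drivers are fragments called in every
primary/metastatic pair with a consistent direction: a change recurring
independently across pairs, always in the same direction, is more
plausibly causal than a private passenger event. The screen reports the
shared-in-all set, hyper-in-all and hypo-in-all subsets (mixed-direction
fragments excluded from both), pairwise overlap percentages
(100·|A∩B| / min(|A|,|B|); the denominator is configurable since
conventions differ) and per-pair-pair direction agreement. When a normal
reference sample exists, fragments significant in both the normal→primary
and primary→metastatic step are classified into the four two-step
progression patterns (hyper-hyper, hyper-hypo, hypo-hyper, hypo-hypo).

**Annotation.** Shared DMFs are annotated by any-overlap (≥ 1 bp) against
gene models with precedence promoter > exon > intron > intergenic.
Promoters are strand-aware windows of −2000..+500 around the TSS — wide
enough to contain a promoter DMF ~1 kb upstream of the TSS, the
situation of primary interest in promoter-driven expression changes. TSS
distance is the signed, strand-aware offset of the fragment midpoint
(negative = upstream). CpG-island context is island_core / shore /
open_sea with a 2 kb shore, the common convention. Arbitrary BED tracks
(repeats, regulatory features) are scored as the fraction of a DMF set
overlapping each track. Gene association caps the intergenic assignment
distance at 50 kb (configurable).

**Validation statistics.** Cross-platform agreement uses Pearson r over
matched per-CpG fractions and over per-amplicon means (averaging
independent per-CpG noise, so amplicon-level r is expected to be the
larger), plus Bland–Altman bias and 95% limits of agreement
(bias ± 1.96·SD of differences, SD with n−1). Cohort validation matches
array probes to DMFs when the probe coordinate lies inside the fragment
or within 500 bp of either edge (ties to several DMFs go to the nearest
midpoint), then runs a two-sided Mann–Whitney U test of metastatic vs
primary betas per matched probe: exact null distribution when the
combined n ≤ 20 without ties, normal approximation with tie correction
otherwise. Direction concordance compares the sign of the median beta
difference with the RRBS consensus direction. Raw p-values drive nothing
but reporting; a Bonferroni column is emitted for transparency. A
Shapiro–Wilk gate annotates whether a t-test would have been defensible;
the rank test is computed regardless. Methylation–expression association
uses Spearman's rho, with an exact permutation p-value for n ≤ 9 (full
enumeration, vectorised) and the t approximation otherwise.

## The synthetic-data generator

Every downstream stage is tested against studies with known ground truth.
The generator emulates the *structure* of a paired cell-line study — one
normal reference, N primary/metastatic pairs, duplicate libraries for the
normal and the first primary — not the biology of any particular tumor.

* **Genome** — random sequence (2 × 200 kb by default) with CCGG sites
  injected at a per-base rate of 0.008, giving ~1800 fragments in the
  40–220 bp range with a realistic length spread; natural CCGG
  occurrences are disrupted so the site rate is fully controlled
  (`ccgg_rate=0` therefore yields a fragment-free genome and errors).
  CpG-dense "islands" (5 blocks of 1 kb per chromosome, ~3× the CCGG
  rate) are recorded as a BED track.
* **Methylation truth** — per-fragment background levels from an equal
  mixture of Beta(2, 38) and Beta(38, 2), reproducing the bimodal
  (hypo/hyper) pattern of somatic methylomes. Each pair adds a
  per-fragment baseline offset (sd 0.05) *shared by that pair's primary
  and metastatic sample*, so pairs cluster together and planted deltas
  are exact. Planted DMFs shift all metastatic samples (shared) or one
  pair (private) by ±Δ; progression fragments additionally shift all
  primaries relative to the normal. Planted baselines are drawn from the
  mixture component compatible with the first shift (hypermethylation
  starts low, hypomethylation starts high), clamped so every cumulative
  shift stays within [0.02, 0.98]: designed effect sizes survive without
  clipping, as they must for recovery experiments to measure the
  statistics rather than clipping artifacts. Levels are clipped to [0, 1]
  at the end.
* **Counts** — per-CpG coverage is negative-binomial with mean 30 and
  dispersion 0.1 (variance μ + 0.1μ²; 0 dials back to Poisson);
  methylated counts are beta-binomial around the fragment's true level
  with intra-class correlation 0.05 (0 dials back to binomial). The
  overdispersion defaults expose the exact test to realistic extra-count
  variation while the dials keep idealised regimes testable. Replicate
  libraries are independent draws from identical truth. Output is
  Bismark-style coverage text (1-based, percent, meth count, unmeth
  count); zero-coverage positions are omitted as in real output.
* **Cohort** — an array-style beta matrix with 99 primary and 359
  metastatic samples (the group-size structure of a large public melanoma
  cohort), one probe per selected DMF at a configurable offset (rejected
  beyond 500 bp, matching the probe-matching window), betas = group truth
  + Gaussian noise (sd 0.1) clipped to [0, 1], plus decoy probes > 10 kb
  from any DMF with identical group levels. Expression tables are
  sign·beta + noise, a monotone link that Spearman recovers exactly at
  zero noise.
* **Determinism** — every random draw flows from a master seed through
  tagged `numpy` generator streams; reruns are byte-identical, including
  FASTA, coverage files, truth tables and the pipeline summary.

What the generator does **not** emulate: read-level artifacts (mapping
bias, bisulfite conversion failure, SNPs), non-CpG methylation,
fragment-length–coverage coupling, CpG-density–methylation coupling, or
any melanoma-specific noise magnitudes (no public quantitative noise model
exists for the motivating data). Passing recovery tests therefore
demonstrates correctness of the statistics and bookkeeping under a
plausible count model — not calibrated performance on real tumors.

## Numerical and design choices

* Coordinates are 0-based half-open internally; Bismark coverage
  (1-based) and GTF convert at the I/O boundary.
* Fragment size bounds are inclusive on both ends.
* Hierarchical clustering uses 1 − Pearson r over CpGs covered ≥ 10× in
  *all* samples, average linkage, samples pre-sorted by id for
  deterministic ties; a constant profile raises an error rather than
  producing NaN distances. The tree is exported as Newick.
* `bonferroni` clamps at 1; direction is hyper iff Δ > 0 (a zero delta
  reports hypo but can never be significant).
* The Fisher implementation normalises the hypergeometric pmf in
  log-space; agreement with integer-arithmetic enumeration is ~1e−14
  relative over all tables with total ≤ 60 (tested exhaustively).
* The Mann–Whitney exact/asymptotic switch is at combined n = 20; ties
  always force the asymptotic path.
* Coverage-file rows whose percent column disagrees with the counts by
  > 0.1 are rejected as corrupt; duplicate positions (strand-split
  output) merge by summing; zero-coverage rows are rejected.
* Config hashes cover thresholds, simulator parameters and the content of
  referenced input files, and appear in every output TSV header with the
  tool version and master seed.

## Problem sizes in the test suite

The packaged studies are scaled for quick, deterministic runs: test
genomes of 60–400 kb (≈ 300–2000 fragments), 2–3 pairs, coverage 30–500,
10–50 seeds per Monte-Carlo property. At these sizes the full suite runs
in about a minute and the acceptance script in well under a minute. The
family-wise error and threshold-boundary properties are asserted under
the binomial count dial, where they are exact guarantees of the
Fisher/Bonferroni construction; under the default overdispersion a
|Δ̂| ≥ 0.25 observation for a true 10% effect is only a ~2.7σ event per
fragment, so occasional boundary crossings there are expected count-noise
behaviour, not a defect of the inclusive threshold.

## Known limitations

* Pooled-count Fisher testing treats reads as independent; overdispersed
  data make it anti-conservative at the single-fragment level (the screen
  mitigates this by requiring recurrence across pairs; beta-binomial
  callers are deliberately out of scope).
* Pairwise overlap percentages depend on a denominator convention; the
  smaller-set denominator is the default and configurable.
* Gene annotation assigns one gene per fragment by precedence and
  alphabetical tie-break; overlapping gene models may therefore be
  summarised under either gene.
* The per-CpG unweighted global mean is one of several defensible global
  methylation summaries (fragment-weighted means differ).
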