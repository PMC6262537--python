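# Methods

## The procedure

`cnasig` implements a copy-number-alteration (CNA) signature discovery and
survival-stratification procedure for colorectal-cancer liver-metastasis
(CRCLM) cohorts profiled by array CGH. The pipeline has five computational
stages:

1. **Elementary-block aggregation.** Per-probe log2 tumor/reference ratios
   are grouped into "elementary blocks" of k = 10 consecutively located
   probes per chromosome, and each block is summarized by the arithmetic
   mean of its member probes. Averaging across ~10 probes (~60 kb at ~6 kb
   spacing) suppresses probe-level noise by roughly √10 while preserving
   the expected log2 ratio of a segmental event. Blocks never span
   chromosomes. A trailing run of fewer than k probes is retained as one
   partial block by default (`keep_partial=False` drops it); the
   aggregation statistic is the mean because it is unbiased for the
   segment-level log2 ratio (a median would be as defensible at this block
   size but mixes poorly with missing-value exclusion). Missing probe
   values are excluded from the block mean; an all-missing block propagates
   missingness.

2. **Differential-CNA testing.** Each block is tested for a mean log2-ratio
   difference between the two levels of a binary clinical variable —
   recurrence (relapsed vs not) and synchronous metastasis (present at
   diagnosis vs metachronous) — with the pooled-variance two-sample
   Student's t-test, two-sided, df = n₁+n₂−2, at α = 0.05. No
   multiple-testing correction is applied at this stage by default: the
   per-block calls are *inputs to a chromosome-level enrichment test*, not
   end results, and inflating the per-block threshold would starve the
   enrichment stage. A Benjamini–Hochberg option (`bh_correct=True`) exists
   for standalone reanalysis. Zero-variance degeneracies are surfaced
   explicitly: equal constant groups give (t = 0, p = 1); unequal constant
   groups are flagged `degenerate` with p = 0 rather than hidden.

3. **Hotspot enrichment.** For each chromosome a 2×2 table — significant
   vs non-significant × on-chromosome vs rest-of-genome — is tested with
   the two-sided Fisher's exact test (sum of hypergeometric point
   probabilities no larger than the observed table's). A chromosome is a
   *hotspot* when its Bonferroni-corrected p (across chromosomes) is below
   0.05 **and** its significant-block density exceeds the genome-wide
   density. The density condition makes the call one-sided: enrichment is a
   hotspot, significant depletion is not. The on-chromosome vs
   rest-of-genome construction is one of two plausible 2×2 layouts (the
   alternative conditions on gene-harboring blocks); it is isolated behind
   `enrich_by_chromosome` so the alternative is a local change.

4. **Signature selection.** The funnel intersects, in order: (i) blocks
   significant for recurrence, (ii) restricted to hotspot chromosomes,
   (iii) overlapping an annotated gene region by ≥ 1 bp (0-based half-open
   intervals throughout, BED convention), (iv) also significant for
   synchronous metastasis. Genes supported by ≥ 1 surviving block form the
   signature — no minimum block count, since at aCGH scale single blocks
   legitimately drive genes. The funnel order only affects intermediate
   counts, never the final set; all four intermediate sets are reported (in
   blocks and probes) as a JSON audit trail. A gene's direction (loss/gain)
   is the sign of the mean copy-number difference of its supporting blocks
   in the *recurrence* contrast.

5. **Risk stratification.** The per-patient risk score is the mean
   gene-level copy-number value over signature genes (each gene the mean of
   its supporting blocks). The mean is preferred over the sum for
   cross-cohort comparability; for a fixed gene count the two give
   identical median splits. Patients at or below the cohort median are
   **high-risk** — copy-number *loss* of the signature genes is the
   risk-conferring state — with exact-median ties sent to high-risk
   (switchable). Prognosis is evaluated by per-group Kaplan–Meier curves,
   the two-group log-rank test (1-df chi-square; an exact label-permutation
   p is available for small cohorts), and Cox proportional hazards with
   Efron tie handling (Breslow optional), Wald CIs. The multivariate model
   uses the encodings: low-risk-signature indicator, age ≥ 60, TNM stage II
   vs III/IV, male vs female (female reference — an assumption, as the
   reference level is conventionally unstated). Non-convergence and
   monotone likelihood raise an explicit error; at n ≈ 21 the multivariate
   model can legitimately fail, in which case stratification proceeds and
   the Cox slot is empty.

External application (`apply_signature_external`) re-uses the same scoring
and median-split path; signature genes are matched into the external matrix
by supporting-block id first (identity on the discovery cohort), then by
gene symbol, then by interval overlap against a probe annotation. Fewer
than two matchable genes is an error.

## The synthetic cohort generator

`cnasig.simulate` generates aCGH-like cohorts that make every stage
testable against known ground truth. What it emulates:

- **Array geometry:** probes tiled at 6 kb spacing (50 bp oligo
  footprint), 10-probe blocks — on a miniature genome of eight 1.2 Mb
  chromosomes (1600 probes, 160 blocks). Eight chromosomes keep the two
  lesion-bearing ones a modest fraction of the genome, so the
  rest-of-genome background of the enrichment test is not dominated by the
  other planted chromosome, as in a real karyotype.
- **Cohort composition:** 21 patients, 13 relapsed, 13 synchronous
  (independent random assignment, so the relapse∧synchronous overlap is
  hypergeometric around 8, matching the discovery cohort's structure).
- **Lesions:** Gaussian probe noise (σ = 0.3 log2 units) around 0;
  segmental losses (−1.0, single-copy scale) on chr1 and chr5 in *relapsed*
  patients (these create the hotspots); three planted signature loci — two
  on chr1, one on chr5, each spanning one block, carrying the loss in
  relapse∧synchronous patients only (the intersection the funnel must
  find). `lesion_scope="relapse"` plants gene lesions in all relapsed
  patients to test the hotspot stage in isolation. Eight decoy genes, two
  of them inside the relapse segments, make signature *precision* a real
  measurement: a decoy inside a segment passes the recurrence and hotspot
  filters and must be rejected by the synchronous filter.
- **Survival:** relapse-free times in months, exponential with hazard
  0.023/month (median ≈ 30 months) times `risk_hazard_ratio` for carriers
  of the planted gene lesions. Exponential is the minimal
  proportional-hazards choice; no survival-time model is implied by the
  underlying study. The default hazard ratio is 6: the reported adjusted
  HR of 0.13 for the low-risk group corresponds to a high/low contrast
  near 7.7, so 6 is the cohort-realistic scale. Censoring is administrative
  at 55.7 months plus uniform dropout over the 14.5–55.7-month follow-up
  window for a `censor_rate` fraction (default 0.2) of patients. Overall
  survival is generated with the same baseline scale and an attenuated
  (√HR) effect, mirroring the weaker OS association.
- **Determinism:** one integer seed; per-stage sub-streams derived with
  `numpy.random.SeedSequence.spawn`, so identical seeds give bit-identical
  cohorts.

What it does **not** emulate: genome-wide waviness, GC bias, tumor purity
and subclonality, allele-specific copy number, probe-specific variance, or
correlated (segmentation-induced) noise. Passing tests therefore
demonstrate that the pipeline recovers planted truth under idealized
additive-Gaussian conditions at realistic effect sizes — not that it would
recover biology from raw arrays, where normalization artifacts dominate.

Effect sizes (loss depth, noise, hazard ratio) are free simulation
parameters, not estimates from the real cohort, which published only test
results, not effect magnitudes.

## Numerical and design choices

- Coordinates 0-based half-open everywhere; overlap = ≥ 1 bp.
- t-test: pooled variance (not Welch), matching the named "Student's
  t-test"; switchable by using `scipy` directly if Welch is wanted.
- Fisher's exact two-sided p via `scipy.stats.fisher_exact`, validated in
  the test suite against exhaustive hypergeometric enumeration for every
  2×2 table with total ≤ 30.
- KM / log-rank / Cox delegate to `lifelines`; the exact permutation
  log-rank (enumeration over all group assignments) is limited to ≤ 5×10⁵
  assignments. Cox convergence tolerance is lifelines' default (1e-7 target
  on the Newton decrement); failures raise `CoxConvergenceError`.
- Median split uses `numpy.median` (mean of middle two at even n).
- The packaged clinical fixture carries the printed 21-patient cohort
  table; its survival columns are blank because they live in the GEO
  archive (GSE103088), not the printed table, so cohort-level survival
  claims are never recomputed from the fixture. "Rectosigmoid" is
  summarized as colon, matching the printed colon/rectum split.
- The genome build of the array design is not pinned anywhere; gene
  annotations are caller-supplied BED and build-agnostic.

## Problem sizes used in tests and the acceptance script

Desk-scale replicate counts were chosen to keep Monte-Carlo error well
inside each assertion's band: 50 seeds for funnel precision/recall, 10
replicates of n = 400 for Cox recovery (the replicate-mean log-HR has
s.e. ≈ 0.035, against a ±15% band), 2000/500–1000 null simulations for
t-test/log-rank type-I error (band [0.03, 0.07]), 10⁵ Monte-Carlo draws
against the exact 70-atom permutation null at n = 8.

## Known limitations

- Per-block α = 0.05 without correction means genome-wide significant-block
  counts are threshold-dependent and annotation-dependent; they are
  reported for audit, not treated as reproducible quantities.
- At n = 21 the multivariate Cox model is fragile (4 covariates, ~13–16
  events); wide CIs and occasional non-convergence are expected and
  surfaced, not suppressed.
- The log-rank asymptotic p is anticonservative-to-approximate at very
  small n; the permutation option exists for that regime.
- No segmentation (CBS/GLAD): block means are the only smoothing, by
  design.
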