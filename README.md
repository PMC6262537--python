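# cnasig

Copy-number-alteration (CNA) signature discovery and survival
stratification for colorectal-cancer liver-metastasis (CRCLM) cohorts
profiled by array CGH.

## The problem

After hepatectomy for colorectal liver metastases, most patients relapse,
and clinical/pathologic scores separate risk groups poorly. DNA copy-number
profiles offer a more stable substrate than RNA for a prognostic signature.
Given a probes × patients matrix of log2 tumor/reference ratios, a gene
annotation, and a clinical table with recurrence status, synchronous-
metastasis status and survival follow-up, `cnasig` derives a small gene
signature and a per-patient risk score that stratifies relapse-free
survival (RFS).

## The method

1. **Elementary blocks** — k = 10 consecutive probes per chromosome,
   averaged per block (signal enhancement: noise shrinks by ~√k).
2. **Differential CNA** — per-block pooled-variance Student's t-tests of
   log2 ratios between relapsed/non-relapsed and between synchronous/
   metachronous patients (two-sided, α = 0.05).
3. **Hotspot enrichment** — per chromosome, a 2×2 Fisher's exact test of
   significant vs other blocks, on-chromosome vs rest of genome; hotspot =
   Bonferroni p < 0.05 **and** above-genome significant-block density.
4. **Signature** — genes overlapped (≥1 bp, half-open) by blocks that are
   recurrence-significant, on a hotspot chromosome, *and*
   synchronous-significant; direction from the recurrence contrast.
5. **Risk score** — per patient, the mean signature-gene copy-number level;
   the cohort median splits high-risk (score ≤ median: copy-number loss
   confers risk) from low-risk. Evaluated by Kaplan–Meier, log-rank, and
   univariate/multivariate Cox (Efron ties; age ≥ 60, stage II vs III/IV,
   sex as co-covariates). The signature can be applied unchanged to an
   external cohort (`apply_signature_external`).

A synthetic-cohort generator (`cnasig.simulate`) plants segmental chr1/chr5
losses in relapsed patients, three signature loci in relapse∧synchronous
patients, decoy genes, and exponential RFS tied to the planted lesions —
ground truth for every stage. See `docs/methods.md` for the model and its
assumptions.

## Worked example

The numbered scripts under `analysis/` run the whole study shape on
simulated cohorts:

```bash
python analysis/01_simulate_cohorts.py --seed 0   # discovery n=21, external n=45
python analysis/02_cohort_summary.py              # packaged clinical table
python analysis/03_discover_signature.py          # funnel -> signature -> risk
python analysis/04_validate_signature.py          # external application
python analysis/05_calibration_and_recovery.py    # type-I error, HR recovery
```

Output of the discovery and validation steps (seed 0):

```
hotspot chromosomes: ['chr1', 'chr5']
signature: ['CSMD2', 'S100PBP', 'TGFBI'] (directions: ['loss', 'loss', 'loss'])
risk groups: {'high_risk': 11, 'low_risk': 10}; log-rank chi2=2.043, p=0.1529
adjusted HR (low-risk signature) = 0.081 [0.014, 0.475], p=0.0054
external cohort: 45 patients, median threshold -0.0769
log-rank chi2=7.760, p=0.0053 (significant at 0.05)
```

Reading this: the funnel recovered exactly the three planted loss genes and
both planted hotspot chromosomes; the 21-patient discovery cohort is split
11/10 at the median risk score; the adjusted Cox model finds the low-risk
group strongly protective (HR 0.081); and the signature transfers to the
independent 45-patient cohort, where the log-rank test separates the risk
groups (p = 0.005). At n = 21 the unadjusted discovery log-rank is noisy
across seeds (here p = 0.15) — expected at that cohort size.

The clinical summary step prints, from the packaged 21-patient CRCLM table:

```
n=21 patients; mean age 60.9 (range 39-83); 13 relapsed / 8 not; 12M/9F;
13 synchronous; 12 colon / 9 rectal primaries
```

There is also a CLI (`cnasig simulate|discover|validate|summarize`) over
the same library, configured by YAML; run `cnasig --help`.

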