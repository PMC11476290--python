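# isomirome

IsomiR calling and biomarker evaluation for small RNA sequencing, with a
fully synthetic, ground-truthed three-cohort benchmark.

Most miRNA loci produce not just one canonical mature miRNA but a family
of variants — **isomiRs** — created during or after biogenesis:

- **5′ isomiRs**: alternative Drosha/Dicer cleavage shifts the 5′ end
  (re-framing the seed, nucleotides 2–8, and hence the mRNA targets);
- **3′ adenylated / uridylated isomiRs**: terminal
  nucleotidyltransferases add non-templated A or U tails;
- **A-to-I edited isomiRs**: ADAR-family enzymes deaminate adenosine to
  inosine, which sequencers read as G.

In lung adenocarcinoma these modification rates shift relative to
non-malignant lung, making isomiRs candidate early-detection biomarkers.
The hard part is telling a genuine low-frequency isomiR from a
sequencing error, and doing so consistently across cohorts sequenced on
different plates and platforms. This package implements that analysis
end to end and ships a synthetic-data generator that plants known
modification frequencies so every stage can be validated exactly.

## The model

For a candidate isomiR observed *k* times in a sample, alongside *n − k*
otherwise identical reads lacking its characteristic variant, the
sequencing-error hypothesis is scored with a binomial tail

&nbsp;&nbsp;&nbsp;&nbsp;p = P(X ≥ k),&nbsp; X ~ Binomial(n, e),

where *e* is the baseline error rate: for substitutions, the larger of
the Phred-25 expectation (10<sup>−2.5</sup> ≈ 0.32%) and the observed
rate of the same substitution at the same read position on the same
sequencing plate; a conservative 2% for 5′ shifts and 3′ tails. The
hypothesis is rejected at Benjamini–Hochberg FDR < 0.05 (per sample and
isomiR type) with at least three supporting reads. An isomiR is
*expressed* in a sample group when it reaches ≥ 1 RPM **and** survives
the error test, each in ≥ 10% of the group's samples; it is
*high-confidence* when expressed in at least one group in at least two
of the three cohorts, after discarding variants matching a SNP/somatic
blacklist and sequences that cross-map elsewhere in the genome
(including tRNA 3′-CCA artifacts).

Downstream, an isomiR's **frequency** is its expression divided by its
miRNA family total; frequencies are z-scored across all samples of all
cohorts, and a sample's **modification rate** per type is the mean of
its defined z-scores. Rates and per-isomiR frequencies feed paired
tumor-vs-normal t-tests (BH-FDR per cohort), Spearman correlations with
editing-enzyme expression in tumors, median-split log-rank survival
analysis, and SVM / random-forest classifiers evaluated within and
across cohorts (10-fold CV / out-of-bag error; cross-cohort AUC with
feature selection and random-search hyperparameter tuning confined to
the training cohort).

## Worked example

`examples/04_modification_rates.py` simulates a small paired benchmark
(3 cohorts × 10 pairs, 8,000 reads/sample), runs the pipeline and tests
the planted group effects:

```
paired ANL-vs-LUAD tests per cohort:
       rate cohort  n_pairs      p      direction  sign_correct
    editing   BCCA       10 0.0271  lower_in_LUAD          True
    editing   TCGA       10 0.0324  lower_in_LUAD          True
    editing    EWU       10 0.0970  lower_in_LUAD          True
adenylation   BCCA       10 0.0000  lower_in_LUAD          True
adenylation   TCGA       10 0.0003  lower_in_LUAD          True
adenylation    EWU       10 0.0003  lower_in_LUAD          True
uridylation   BCCA       10 0.0001 higher_in_LUAD          True
uridylation   TCGA       10 0.0000 higher_in_LUAD          True
uridylation    EWU       10 0.0001 higher_in_LUAD          True

published lung editing catalog: 16 sites, 13 (81%) in the seed region,
12 (75%) with 5'-adjacent U
```

The generator planted lower editing and adenylation and higher
uridylation in tumors; every direction is recovered, and the planted
deficits are significant in most cohorts already at this reduced size.
The last lines summarize the bundled published catalog of sixteen
high-confidence lung A-to-I editing sites: the seed-region concentration
and the 5′-uracil preference of the editing enzymes.

The other scripts in `examples/` walk through simulation
(`01`), read preprocessing (`02`), isomiR calling and filtering (`03`),
enzyme correlations and survival (`05`), and cross-cohort classifiers
(`06`). A thin CLI covers the shell workflow:

```bash
isomirome simulate --out bench --seed 1      # FASTQ + truth tables
isomirome run bench --out calls --min-reads 1000
```

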