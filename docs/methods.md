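# Methods

This note documents the models, procedures, parameter choices and known
limitations of `isomirome`, in the spirit of a methods appendix: what is
computed, under which assumptions, and what the synthetic benchmarks do
and do not demonstrate.

## 1. Read preprocessing

Reads are 3′-adapter-trimmed by locating the earliest occurrence of the
adapter (one mismatch tolerated within its first ten bases, so a
sequencing error at the insert/adapter junction cannot leave the adapter
in place) and removing everything from that point on. Inserts shorter
than 15 nt are discarded; reads with any base below Phred 25 are
removed; samples below a coverage threshold (five million reads for
production data; a scaled value, default 1,000, for synthetic runs —
the same code path with one parameter) are excluded. Trimming is
idempotent and all filters are pure functions of the read.

## 2. Alignment and isomiR decomposition

The toy genome is small (~50 kb), so alignment is an exact seeded
search rather than an external aligner: candidate positions come from
two disjoint seed k-mers over the first bases of the read (pigeonhole:
any alignment with ≤ 1 internal mismatch leaves one seed exact; k = 8,
or 7 for 15-nt reads), verified on both strands allowing one internal
mismatch plus a trailing non-templated overhang of up to 3 nt. Hits are
ranked by (mismatches, overhang).

A read assigned to a miRNA locus is decomposed into: the 5′ shift
(aligned start minus mature start, mature-sense coordinates; negative =
extension into the precursor), the templated 3′ end offset (discarded
beyond ±2), the non-templated tail (the maximal 3′ suffix not matching
the genomic continuation, capped at 3 nt), and internal substitutions
(reads with ≥ 2 discarded). Minus-strand loci are reverse-complemented
on load; all offsets live on the mature sense strand.

Collapsing into the four isomiR identities ignores type-irrelevant
positions: 5′ keys ignore all 3′ variation; tail keys (homopolymer A/U/
C/G tails of length 1–2 ending at position 1 or 2 past the mature 3′
end) ignore 5′ variation; edited keys (single A→G, keyed by 5′ shift
and edited position in isomiR coordinates) ignore each read's final two
bases — a read whose only substitution lies there counts as unedited.
Names follow the `<miRNA> <shift>`, `<miRNA> <pos><base>`,
`<miRNA> <shift> <pos> AI` convention and round-trip through the parser.

*Degenerate cases.* A tail whose first base equals the genomic
continuation is indistinguishable from a templated 3′ extension and is
(correctly) not called an NTA; a substitution in the last read base is
likewise absorbed as a 1-nt overhang. These ambiguities exist in real
data too; the generator's reference fixes the two bases past each
mature 3′ end to C/G (order alternating across loci) so that the
biologically dominant A/U tails never alias and C/G tails are
observable at half the loci each.

## 3. Error model and confidence filtering

Substitution error rates are estimated per (plate, read position,
substitution type) from reads matching canonical sequences (canonical
5′ end, no tail, ≤ 1 substitution — avoiding circularity with the
isomiRs under test) and floored at the Phred-25 expectation
10^(−2.5) ≈ 0.32%; strata without coverage fall back to the floor. 5′
shifts and tails use a flat, deliberately conservative 2% (not
plate-adjusted; the observed-rate machinery only applies naturally to
substitutions).

The binomial error test uses as denominator the "otherwise identical"
reads: for a 5′ key, reads with the canonical 5′ end; for a tail key,
untailed reads of the miRNA; for an edited key, reads with the same 5′
shift unedited at the site. BH correction is applied per sample and per
isomiR type (the most conservative reading that keeps types
independent); rejection additionally requires ≥ 3 reads. Expression
calls per (isomiR, cohort, group) require ≥ 1 RPM and error-test
survival each in ≥ 10% of the group's samples (miRNAs: the RPM
criterion only). Expressed isomiRs are then screened against the
SNP/somatic blacklist (characteristic substitution or tail matching a
known variant at the same mature-coordinate offset) and the
cross-mapping filter: the key's most highly expressed raw sequence is
re-searched, and the key is discarded if any site outside its home
hairpin matches with no more mismatches (ties on mismatches are broken
by overhang length, equal-or-shorter overhang discarding — the
conservative choice); CCA-terminated sequences are re-searched after
CCA removal and discarded if they land in a tRNA region. Finally, the
high-confidence catalog requires expression in ≥ 1 group in ≥ 2 of the
3 cohorts.

## 4. Statistics

Frequency = isomiR RPM / family RPM (undefined when the family is
unexpressed; computed from RPM but identical to the count ratio within
a sample, shared denominator). Frequencies are z-scored per isomiR
across all samples of all cohorts (sample sd, n − 1; zero-spread
columns are set to 0 with a warning; undefined entries propagate), and
a sample's modification rate per type is the mean of its defined
z-scores. Paired ANL/LUAD comparisons use paired t-tests per cohort —
α = 0.05 for rates, BH-FDR < 0.05 across the type's high-confidence
isomiRs for per-isomiR tables (pairs with an undefined side are
dropped; fewer than three remaining pairs yields a flagged no-test).
Multi-cohort claims are a reporting aggregation over per-cohort flags,
not a combined test.

Enzyme correlations (tumor samples only) use Spearman's ρ with
tie-corrected ranks; p-values use the t-approximation for n > 20 and a
seeded permutation for n ≤ 20 (exhaustive enumeration is infeasible and
the approximation is poor at small n). Each edited isomiR is grouped by
the enzyme with which it has a significant (BH-FDR < 0.05) positive
correlation; significance with both assigns the larger ρ and flags the
row; otherwise "Neither". Survival analysis splits tumor patients at
the median of the analyzed quantity (ties to the below-median arm — a
documented choice where convention is silent) and applies a log-rank
test; arms without events are computed but flagged. Probe-level
expression collapses to genes by keeping the highest-mean probe
(ties: lowest probe identifier).

The catalog summary classifies an edited site as seed-internal when its
0-based position is 1–7 (nucleotides 2–8) and reads the bases adjacent
to the edited adenosine from the hairpin, so neighbours outside the
mature sequence come from the precursor. The bundled
`data/lung_editing_sites.tsv` is the published 16-site human-lung
catalog used by the worked examples.

## 5. Classifiers

Feature tables contain ANL and stage I/II LUAD samples only; frequency
tables drop any feature undefined in an included sample. Single-cohort
evaluation uses all features of the type expressed in that cohort
(high confidence not required): SVMs (RBF kernel) report the mean
error over stratified 10-fold cross-validation with per-fold
standardization; random forests (300 trees) report out-of-bag error.
Cross-cohort evaluation trains on the largest cohort using only
features differential there (Welch t-test, BH-FDR < 0.05; an empty set
is a rejection, not an error to paper over), standardizes with
training-set statistics, and tunes hyperparameters by seeded random
search — SVM box constraint (log-uniform 10⁻²–10³) and kernel scale
against 5-fold CV error; forest minimum leaf size (≤ 20) and per-node
feature fraction (≤ 70%) against OOB error — before reporting ROC AUC
(midrank ties) per held-out cohort from raw SVM scores / voting
fractions. Random search replaces Bayesian optimization with the same
objectives and bounds; the RBF kernel is the default because a tuned
kernel scale implies a scaled kernel family, with the budget and kernel
exposed as knobs. Stratified folds and seeded draws make every
evaluation reproducible bit-for-bit given a seed.

## 6. The synthetic benchmark

`synthetic_data` builds a single-contig ~50 kb genome with 12 embedded
hairpins (70 nt, mature 22 nt at offset 20; one minus-strand locus),
one tRNA region, one decoy locus whose mature sequence is planted at a
second genomic site (to exercise cross-mapping), and one locus carrying
a heterozygous-like A→G variant at 50% frequency that is listed on the
blacklist (to exercise variant screening and the plate error model's
observed-rate branch). Nine A-to-I sites span seed and non-seed
positions, most with a 5′-adjacent U, matching the known enzyme
preference.

Reads are mature sequences with independently drawn events — 5′ shifts,
templated 3′ offsets ({−2…+2}, mode 0), homopolymer A/U (rarely C/G)
tails of length 1–2 (tails attach to the canonical templated end, so
they are unambiguously non-templated), A→G edits — followed by the full
adapter, constant Phred-30 qualities with a 0.2% per-read chance of one
sub-25 base (to exercise the quality filter), and per-base substitution
errors at the plate's rate (at most one per read, applied to the
insert; at the simulated rates multi-error reads are ~0.1% and errors
in the adapter would only perturb trimming). Reads whose edit plus a
tail-aliasing substitution would stack to two mismatches are discarded
by the annotator, exactly as in real data.

The default study design is three paired cohorts — 18 + 24 + 18
tumor/normal pairs (a largest cohort must exist for cross-cohort
training), 50,000 reads per sample, two plates per cohort with error
rates 0.002–0.005, the third cohort using a different 3′ adapter.
Baseline ANL frequencies are 0.10–0.18 (editing), 0.06–0.12
(adenylation), 0.04–0.10 (uridylation); tumor samples shift editing
−0.04…−0.05 at ADARB1-coupled sites, +0.03…+0.04 at the two
ADAR-coupled sites, adenylation −0.03…−0.05 and uridylation
+0.025…+0.05 on subsets of loci. Per-sample editing is modulated
multiplicatively by two latent factors (log-scale slope 0.35) shared
with the simulated ADAR/ADARB1 expression (ADAR up and ADARB1 down in
tumors), plus patient- and sample-level lognormal noise (σ = 0.12 /
0.08); pairs share the patient latent, which is also coupled to
overall survival (log-hazard −0.8 per latent unit, exponential times,
uniform censoring at 6–72 months). An enzyme probe table (1–3 noisy
probes per gene, one informative) feeds the probe-collapsing step.
Stage I/II makes up 80% of tumors.

Two named variants: `null_config` removes every group effect and the
survival coupling (for calibration checks), and `separable_config`
doubles the group effects and weakens the enzyme coupling to 0.15 —
the strong-effect regime in which biomarker classifiers are expected to
approach perfect cross-cohort AUC. These are distinct study conditions,
not tuning knobs: the default design measures parameter recovery under
realistic biological variance (where the editing-rate t-test in the
smallest cohort hovers near the significance boundary precisely because
the enzyme latent dominates editing variance), while the separable
design measures classifier behaviour when a strong signal exists.

What the generator does **not** emulate: realistic base-caller error
spectra (errors are uniform substitutions), PCR duplicates and UMIs,
multi-error reads, read-length and quality distributions of real
instruments, secondary-structure-dependent expression, and
genome-scale mapping ambiguity beyond the planted decoy. Green
benchmarks therefore demonstrate the correctness and calibration of the
statistical machinery on its stated model, not performance on real
libraries.

## 7. Benchmark problem sizes

The validation suite scales depth down while preserving the quantities
that drive power: the null-calibration run uses 200 event-free
libraries of 3,000 reads (~2,000 artifact candidates); the power run
uses 60 samples of 5,000 reads and scores planted events with effective
frequency ≥ 5% on families with ≥ 250 reads — the absolute count that
the production-scale "family RPM ≥ 50 at five million reads" adequacy
condition corresponds to, since binomial power depends on counts, not
rates; the classifier null uses three cohorts of 12 pairs at 8,000
reads with a 300-draw label-permutation band. Parameter recovery and
the separable classifier benchmark run the full default design. The
end-to-end default run (120 samples × 50,000 reads) completes in about
half a minute on one CPU because reads are collapsed to unique inserts
before alignment and alignments are cached across samples.

## 8. Numerical and implementation notes

Binomial tails come from `scipy.stats.binom.sf` (checked against exact
rational-arithmetic summation to 10⁻¹⁰ for n ≤ 200), BH from
`statsmodels` (checked against an independent textbook step-up),
log-rank from `lifelines`, and model fitting from `scikit-learn`; the
domain logic — decomposition, collapsing, the error model, the
confidence rules, the generator — is implemented here. Zero-spread
z-score columns use a 10⁻¹² sd tolerance (frequency vectors constant to
rounding). All randomness flows from explicit seeds; per-sample
generator streams derive from the master seed so samples can be
regenerated independently and lazily.
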