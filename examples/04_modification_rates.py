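"""Sample-wide modification rates and tumor-vs-normal differences.

An isomiR's frequency is its expression over its miRNA family's total;
z-scoring each high-confidence isomiR across all samples and averaging
per type gives each sample an editing / adenylation / uridylation rate.
The benchmark plants lower editing and adenylation and higher
uridylation in tumors; paired t-tests per cohort recover this.
"""

import isomirome as iso
from isomirome import benchmark as bm
from isomirome.pipeline import run_pipeline

data = iso.simulate_cohorts(iso.small_config(n_pairs=10, n_reads=8000), seed=4)
result = run_pipeline(data, min_sample_reads=500)

print("per-sample modification rates (mean frequency z-score, first rows):")
print(result.rates.head(4).round(3).to_string())
print()
print("paired ANL-vs-LUAD tests per cohort:")
table = bm.rate_tests(result)
print(table[["rate", "cohort", "n_pairs", "p", "direction", "sign_correct"]]
      .round(4).to_string(index=False))
print()
print("'sign_correct' compares each direction with what the generator")
print("planted; p < 0.05 marks a recovered group difference.")
print()
summary = iso.summarize_catalog(iso.load_lung_editing_sites())
print(f"published lung editing catalog: {summary.n_sites} sites, "
      f"{summary.n_seed} ({100 * summary.seed_fraction:.0f}%) in the seed region, "
      f"{summary.adj5_counts['U']} ({100 * summary.adj5_fraction('U'):.0f}%) with 5'-adjacent U —")
print("the seed bias means editing typically re-targets the miRNA.")
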