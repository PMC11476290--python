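"""Editing-enzyme correlations and survival stratification.

Per-sample editing frequencies are correlated (Spearman, tumor samples
only) with the expression of the two editing enzymes; each edited
isomiR is grouped by which enzyme it tracks.  Patients are then split
at the median editing rate and compared by a log-rank test — the
generator couples low editing to worse outcomes.
"""

import pandas as pd

import isomirome as iso
from isomirome.isomir_annotation import IsomirKind
from isomirome.modification_stats import correlate_enzymes, median_split_survival, collapse_probes
from isomirome.pipeline import run_pipeline

data = iso.simulate_cohorts(iso.small_config(n_pairs=12, n_reads=8000), seed=5)
result = run_pipeline(data, min_sample_reads=500)

enzymes = collapse_probes(data.probes, data.probe_map)  # probe -> gene level
edit_names = result.hc_keys(IsomirKind.EDIT_AI)
corr = correlate_enzymes(result.freq[edit_names], enzymes, result.sheet, seed=0)
print("isomiR editing vs enzyme expression (tumor samples):")
print(corr[["isomir", "rho_a", "fdr_a", "rho_b", "fdr_b", "group"]]
      .round(3).to_string(index=False))
print()
print("'group' = which enzyme's expression the editing frequency tracks;")
print("the generator coupled most sites to the second enzyme (ADARB1-like).")

luad = result.sheet[result.sheet["group"] == "LUAD"].set_index("sample_id")
rates = result.rates.loc[luad.index, "editing"]
res = median_split_survival(rates, luad["os_time"], luad["os_event"])
print()
print(f"median-split survival on the editing rate: log-rank p = {res['p']:.3g} "
      f"({res['n']} patients, {res['n_high']} above median)")
print("low editing was planted as a hazard; small cohorts may not reach p < 0.05.")
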