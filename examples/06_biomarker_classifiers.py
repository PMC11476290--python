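"""Cross-cohort biomarker evaluation with SVMs and random forests.

Classifiers separating normal lung from stage I/II tumors are trained
on the largest cohort using features that are differential there, with
hyperparameters tuned by seeded random search, and tested on the two
held-out cohorts.  On the strong-effect benchmark the edited-isomiR
features generalize with near-perfect AUC.
"""

import isomirome as iso
from isomirome import benchmark as bm

config = iso.separable_config()
for cohort in config.cohorts:
    cohort.n_pairs = max(12, cohort.n_pairs // 2)
config.n_reads = 10_000

data, result = bm.run_benchmark_pipeline(config, seed=6, min_sample_reads=500)
for kind, mode in (("EDIT_AI", "rpm"), ("EDIT_AI", "frequency"),
                   ("NTA_A", "frequency"), ("MIRNA", "rpm")):
    try:
        out = bm.cross_cohort_benchmark(result, "TCGA", kind, mode, seed=6)
    except ValueError as exc:
        print(f"{kind:8s} {mode:9s}  rejected: {exc}")
        print("          (the benchmark plants modification changes, not miRNA-")
        print("           abundance changes, so miRNA-only features carry no signal)")
        continue
    print(f"{kind:8s} {mode:9s}  features={out['n_features']:3d}  "
          f"SVM mean AUC={out['svm']['mean_auc']:.3f}  "
          f"RF mean AUC={out['rf']['mean_auc']:.3f}")
print()
print("AUC is computed per held-out cohort from raw SVM scores / RF voting")
print("fractions; 0.5 is chance, 1.0 perfect ANL-vs-LUAD separation.")
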