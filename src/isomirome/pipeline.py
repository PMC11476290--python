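"""End-to-end orchestration: reads -> annotations -> confident catalog
-> statistics-ready matrices.

``run_pipeline`` consumes a cohort source (simulated in memory or read
from FASTQ on disk), processes one sample at a time (adapter trimming,
quality filtering, alignment, isomiR decomposition and collapsing),
fits the plate error model, applies the per-sample binomial error test
and the expression / blacklist / cross-mapping / high-confidence rules,
and returns expression, frequency, z-score and modification-rate
matrices ready for the statistical and classifier layers.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from . import confidence_filter as cf
from . import isomir_annotation as ann
from . import modification_stats as ms
from . import read_prep as rp
from .isomir_annotation import GenomeIndex, IsomirKind, IsomiRKey
from .synthetic_data import CohortData, ReferenceBundle

__all__ = ["PipelineResult", "run_pipeline", "FastqCohortSource", "classifier_matrix"]

ISOMIR_KINDS = (IsomirKind.FIVE_PRIME, IsomirKind.NTA_A, IsomirKind.NTA_U,
                IsomirKind.NTA_C, IsomirKind.NTA_G, IsomirKind.EDIT_AI)


@dataclass
class SampleCalls:
    sample_id: str
    n_raw: int
    n_retained: int
    n_mapped: int
    key_counts: dict
    counterparts: dict
    family_counts: dict
    error_pass: dict = field(default_factory=dict)  # key -> bool


@dataclass
class PipelineResult:
    """Everything downstream analyses need, in matrix form.

    ``isomir_rpm``/``isomir_counts`` are samples x isomiR-name frames
    (zeros where unobserved), ``family_rpm`` samples x miRNA, ``flags``
    the per-(isomiR, cohort, group) expression calls, ``hc_isomirs`` /
    ``hc_mirnas`` the high-confidence catalog, ``freq``/``z``/``rates``
    the frequency, z-score and per-sample modification-rate matrices
    over the high-confidence catalog, and ``audit`` the discard log.
    """

    sheet: pd.DataFrame
    bundle: ReferenceBundle
    isomir_counts: pd.DataFrame
    isomir_rpm: pd.DataFrame
    family_rpm: pd.DataFrame
    flags: pd.DataFrame
    hc_isomirs: list
    hc_mirnas: list
    freq: pd.DataFrame
    z: pd.DataFrame
    rates: pd.DataFrame
    error_model: cf.ErrorRateModel
    audit: Counter
    kind_of: dict
    family_of: dict
    dropped_samples: list
    calls: dict = field(default_factory=dict)  # sample_id -> SampleCalls

    def hc_keys(self, kind: IsomirKind) -> list:
        return [n for n in self.hc_isomirs if self.kind_of[n] == kind]

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.isomir_counts.to_csv(outdir / "isomir_counts.tsv", sep="\t")
        self.isomir_rpm.to_csv(outdir / "isomir_rpm.tsv", sep="\t")
        self.family_rpm.to_csv(outdir / "family_rpm.tsv", sep="\t")
        self.flags.to_csv(outdir / "expression_flags.tsv", sep="\t", index=False)
        self.freq.to_csv(outdir / "hc_frequencies.tsv", sep="\t")
        self.rates.to_csv(outdir / "modification_rates.tsv", sep="\t")
        pd.Series(dict(self.audit)).rename("count").to_csv(
            outdir / "filter_audit.tsv", sep="\t")
        pd.Series(self.hc_isomirs).to_csv(
            outdir / "high_confidence_isomirs.tsv", sep="\t", index=False, header=False)


class FastqCohortSource:
    """Cohort source backed by FASTQ files written by the simulator (or
    arranged in the same layout: <cohort>/<sample_id>.fastq plus
    sample_sheet.tsv with an adapter column and a reference/ directory)."""

    def __init__(self, root):
        self.root = Path(root)
        self.bundle = ReferenceBundle.load_dir(self.root / "reference")
        self.sheet = pd.read_csv(self.root / "sample_sheet.tsv", sep="\t")

    def sample_ids(self):
        return list(self.sheet["sample_id"])

    def adapter_for(self, sid: str) -> str:
        return self.sheet.set_index("sample_id").loc[sid, "adapter"]

    def reads(self, sid: str):
        cohort = self.sheet.set_index("sample_id").loc[sid, "cohort"]
        return list(rp.read_fastq(self.root / cohort / f"{sid}.fastq")), None


def _process_sample(
    sid: str,
    records,
    adapter: str,
    index: GenomeIndex,
    align_cache: dict,
    audit: Counter,
    top_seqs: dict,
    min_len: int = 15,
    min_q: int = 25,
) -> tuple[Optional[SampleCalls], dict, dict]:
    """Trim, filter, align and annotate one sample's reads.

    Returns (calls, mismatch tallies, coverage tallies); reads are
    collapsed to unique insert sequences before alignment, and
    alignments are cached across samples.
    """
    genome_len = len(index.genome)
    inserts: Counter = Counter()
    n_raw = 0
    n_retained = 0
    for read in records:
        n_raw += 1
        trimmed = rp.trim_adapter(read, adapter, min_len=min_len)
        if trimmed is None:
            audit["trim_rejected"] += 1
            continue
        if not rp.quality_filter(trimmed, min_q=min_q):
            audit["quality_rejected"] += 1
            continue
        n_retained += 1
        inserts[trimmed.seq] += 1

    ann_counts = []
    mismatch_tally: Counter = Counter()
    coverage_tally: Counter = Counter()
    family_counts: Counter = Counter()
    for seq, count in inserts.items():
        cached = align_cache.get(seq)
        if cached is None:
            hits = index.search(seq) if len(seq) >= 2 * GenomeIndex.K_SHORT else []
            if not hits:
                cached = (None, None)
            else:
                best_rank = (hits[0].mismatches, hits[0].overhang)
                best = [h for h in hits if (h.mismatches, h.overhang) == best_rank]
                chosen = next((h for h in best if h.locus is not None), None)
                if chosen is None:
                    cached = (None, "unassigned")
                else:
                    a = ann.annotate_read(seq, chosen, genome_len)
                    cached = (a, "annotation_discard" if a is None else None)
            align_cache[seq] = cached
        a, reason = cached
        if a is None:
            audit[reason or "unaligned"] += count
            continue
        ann_counts.append((a, count))
        family_counts[a.mirna_name] += count
        # error-model tallies from canonical-end reads with <=1 substitution
        if a.five_prime_shift == 0 and a.nta == "":
            templated = a.length - len(a.nta)
            for pos in range(templated):
                coverage_tally[pos] += count
            for pos, ref, alt in a.substitutions:
                mismatch_tally[(pos, f"{ref}>{alt}")] += count

    if not ann_counts:
        return None, {}, {}
    n_mapped = sum(c for _, c in ann_counts)
    key_counts = ann.collapse(ann_counts)
    counterparts = ann.counterpart_counts(ann_counts, key_counts)
    # most expressed raw sequence per key (for the cross-mapping filter)
    for seq, count in inserts.items():
        cached = align_cache.get(seq)
        if cached and cached[0] is not None:
            for key in ann.keys_for_annotation(cached[0]):
                top_seqs.setdefault(key, Counter())[seq] += count
    calls = SampleCalls(sid, n_raw, n_retained, n_mapped, key_counts,
                        counterparts, dict(family_counts))
    return calls, dict(mismatch_tally), dict(coverage_tally)


def run_pipeline(
    source: CohortData | FastqCohortSource,
    min_sample_reads: int = 1000,
    rpm_threshold: float = 1.0,
    min_group_fraction: float = 0.10,
    alpha: float = 0.05,
    min_reads: int = 3,
    min_hc_cohorts: int = 2,
) -> PipelineResult:
    """Run the full isomiR pipeline over a cohort source."""
    bundle = source.bundle
    sheet = source.sheet.copy()
    index = GenomeIndex(bundle.genome, bundle.loci)
    audit: Counter = Counter()
    align_cache: dict = {}
    top_seqs: dict = {}
    calls: dict[str, SampleCalls] = {}
    dropped = []
    mismatches: Counter = Counter()
    coverage: Counter = Counter()
    plate_of = dict(zip(sheet["sample_id"], sheet["plate"]))

    for sid in source.sample_ids():
        records, _ = source.reads(sid)
        if not rp.coverage_filter(len(records), threshold=min_sample_reads):
            dropped.append(sid)
            audit["sample_low_coverage"] += 1
            continue
        sample_calls, mism, cov = _process_sample(
            sid, records, source.adapter_for(sid), index, align_cache, audit, top_seqs)
        if sample_calls is None:
            dropped.append(sid)
            audit["sample_no_mapped_reads"] += 1
            continue
        calls[sid] = sample_calls
        plate = plate_of[sid]
        for (pos, subtype), k in mism.items():
            mismatches[(plate, pos, subtype)] += k
        for pos, k in cov.items():
            coverage[(plate, pos)] += k

    if not calls:
        raise ValueError("no samples survived preprocessing")
    sheet = sheet[sheet["sample_id"].isin(calls)].reset_index(drop=True)
    model = cf.estimate_error_rates(mismatches, coverage)

    # per-sample binomial error test, BH within (sample, isomiR type)
    for sid, sc in calls.items():
        plate = plate_of[sid]
        for kind in ISOMIR_KINDS:
            keys = [k for k in sc.key_counts if k.kind == kind]
            if not keys:
                continue
            pvals = []
            counts = []
            for key in keys:
                k_iso = sc.key_counts[key]
                k_ctr = sc.counterparts.get(key, 0)
                if kind == IsomirKind.EDIT_AI:
                    e = model.substitution_rate(plate, key.coords[1], "A>G")
                else:
                    e = model.nta_five_prime_rate
                pvals.append(cf.binomial_error_test(k_iso, k_ctr, e))
                counts.append(k_iso)
            passed = cf.reject_error_hypothesis(pvals, counts, alpha=alpha,
                                                min_reads=min_reads)
            for key, ok in zip(keys, passed):
                sc.error_pass[key] = bool(ok)

    # expression matrices
    all_keys = sorted({k for sc in calls.values() for k in sc.key_counts},
                      key=lambda k: k.name)
    names = [k.name for k in all_keys]
    sids = list(calls)
    count_mat = pd.DataFrame(0, index=sids, columns=names, dtype=float)
    rpm_mat = pd.DataFrame(0.0, index=sids, columns=names)
    for sid, sc in calls.items():
        rpm = ann.quantify(sc.key_counts, sc.n_mapped)
        for key, c in sc.key_counts.items():
            count_mat.at[sid, key.name] = c
            rpm_mat.at[sid, key.name] = rpm[key]
    mirnas = sorted({m for sc in calls.values() for m in sc.family_counts})
    family_rpm = pd.DataFrame(0.0, index=sids, columns=mirnas)
    for sid, sc in calls.items():
        for m, c in sc.family_counts.items():
            family_rpm.at[sid, m] = c * 1e6 / sc.n_mapped

    # group-level expression calls
    groups = sheet.groupby(["cohort", "group"])["sample_id"].apply(list)
    flag_rows = []
    key_by_name = {k.name: k for k in all_keys}
    for (cohort, group), members in groups.items():
        members = [s for s in members if s in calls]
        rpm_sub = rpm_mat.loc[members]
        for key in all_keys:
            rpm_pass = (rpm_sub[key.name] >= rpm_threshold).tolist()
            err_pass = [calls[s].error_pass.get(key, False) for s in members]
            expressed = cf.expressed_in_group(rpm_pass, err_pass,
                                              min_fraction=min_group_fraction)
            flag_rows.append({"isomir": key.name, "kind": key.kind.value,
                              "cohort": cohort, "group": group,
                              "expressed": expressed})
        for m in mirnas:
            rpm_pass = (family_rpm.loc[members, m] >= rpm_threshold).tolist()
            expressed = cf.expressed_in_group(rpm_pass, None,
                                              min_fraction=min_group_fraction)
            flag_rows.append({"isomir": m, "kind": IsomirKind.MIRNA.value,
                              "cohort": cohort, "group": group,
                              "expressed": expressed})
    flags = pd.DataFrame(flag_rows)

    # blacklist + cross-mapping on expressed isomiRs
    mature_len_of = {l.mirna_name: l.mature_len for l in bundle.loci}
    expressed_any = set(flags.loc[flags["expressed"] &
                                  (flags["kind"] != IsomirKind.MIRNA.value), "isomir"])
    kept = set()
    for name in expressed_any:
        key = key_by_name[name]
        if not cf.blacklist_filter(key, bundle.blacklist,
                                   mature_len_of.get(key.mirna_name, 22)):
            audit["blacklist_discard"] += 1
            continue
        top_seq = top_seqs[key].most_common(1)[0][0]
        if not cf.cross_map_filter(key, top_seq, index, bundle.trna_regions):
            audit["cross_map_discard"] += 1
            continue
        kept.add(name)
    flags.loc[(flags["kind"] != IsomirKind.MIRNA.value)
              & ~flags["isomir"].isin(kept), "expressed"] = False

    # high-confidence: expressed in >=1 group in >= min_hc_cohorts cohorts
    hc_isomirs, hc_mirnas = [], []
    for name, sub in flags.groupby("isomir"):
        by_cohort = {c: dict(zip(g["group"], g["expressed"]))
                     for c, g in sub.groupby("cohort")}
        if cf.high_confidence(by_cohort, min_cohorts=min_hc_cohorts):
            if sub["kind"].iloc[0] == IsomirKind.MIRNA.value:
                hc_mirnas.append(name)
            else:
                hc_isomirs.append(name)
    hc_isomirs.sort()
    hc_mirnas.sort()

    kind_of = {k.name: k.kind for k in all_keys}
    family_of = {k.name: k.mirna_name for k in all_keys}
    freq = ms.frequency_matrix(rpm_mat[hc_isomirs], family_rpm,
                               {n: family_of[n] for n in hc_isomirs}) \
        if hc_isomirs else pd.DataFrame(index=sids)
    import warnings as _w
    with _w.catch_warnings():
        _w.simplefilter("ignore")
        z = ms.zscore_matrix(freq) if hc_isomirs else freq
    rates = ms.modification_rates(z, {n: kind_of[n] for n in hc_isomirs})

    return PipelineResult(
        sheet=sheet, bundle=bundle, isomir_counts=count_mat, isomir_rpm=rpm_mat,
        family_rpm=family_rpm, flags=flags, hc_isomirs=hc_isomirs,
        hc_mirnas=hc_mirnas, freq=freq, z=z, rates=rates, error_model=model,
        audit=audit, kind_of=kind_of, family_of=family_of, dropped_samples=dropped,
        calls=calls,
    )


def classifier_matrix(result: PipelineResult, kind: str, mode: str) -> pd.DataFrame:
    """Samples x features values for the classifier layer.

    ``kind`` is an isomiR type name ("EDIT_AI", "NTA_A", "NTA_U",
    "FIVE_PRIME") or "MIRNA"; ``mode`` "rpm" or "frequency" (frequencies
    are isomiR/family ratios and exist for isomiR kinds only).
    """
    if kind == "MIRNA":
        if mode != "rpm":
            raise ValueError("miRNA features are RPM-based")
        return result.family_rpm
    names = [n for n, k in result.kind_of.items() if k.value == kind]
    if mode == "rpm":
        return result.isomir_rpm[names]
    if mode == "frequency":
        return ms.frequency_matrix(
            result.isomir_rpm[names], result.family_rpm,
            {n: result.family_of[n] for n in names})
    raise ValueError(f"unknown mode {mode!r}")


def expressed_in_cohort(result: PipelineResult, cohort: str, kind: str) -> list:
    """Names of the given type expressed in either group of a cohort
    (high-confidence not required, matching single-cohort classifiers)."""
    f = result.flags
    sub = f[(f["cohort"] == cohort) & (f["kind"] == kind) & f["expressed"]]
    return sorted(sub["isomir"].unique())
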