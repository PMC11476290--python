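"""IsomiR frequencies, modification rates, and cohort-level statistics.

The frequency of an isomiR in a sample is its expression divided by the
combined expression of its canonical miRNA and all of that miRNA's
isomiRs; it is undefined where the family has no expression.  Each
high-confidence isomiR's frequencies are z-scored across all samples of
all cohorts, and a sample's modification rate for one isomiR type
(editing, adenylation, uridylation, 5' shifting) is the mean of the
defined z-scores of that type's high-confidence isomiRs in the sample.

On top of those quantities this module provides paired ANL-vs-LUAD
tests (per-cohort t-tests for rates; BH-FDR per-isomiR differential
tables), Spearman correlations of editing with modifier-enzyme
expression in tumor samples (with ADAR-like / ADARB1-like / Neither
grouping), median-split log-rank survival analysis, probe collapsing
for array-style expression, and catalog summaries of editing-site
position and sequence context.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from lifelines.statistics import logrank_test
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .isomir_annotation import SEED_RANGE, IsomirKind, IsomiRKey, MiRNALocus

__all__ = [
    "isomir_frequency",
    "frequency_matrix",
    "zscore_matrix",
    "modification_rate",
    "modification_rates",
    "paired_rate_test",
    "paired_differential",
    "correlate_enzymes",
    "median_split_survival",
    "CatalogSummary",
    "summarize_catalog",
    "edit_site_context",
    "nta_spectrum",
    "collapse_probes",
]


def isomir_frequency(isomir_rpm: float, family_rpm: float) -> float:
    """Ratio of isomiR to family expression; NaN where the family has
    no expression (the isomiR's z-score is then undefined)."""
    if isomir_rpm < 0 or family_rpm < 0:
        raise ValueError("RPM values must be non-negative")
    if isomir_rpm > family_rpm + 1e-9:
        raise ValueError("isomiR RPM exceeds its family RPM")
    if family_rpm == 0:
        return float("nan")
    return isomir_rpm / family_rpm


def frequency_matrix(isomir_rpm: pd.DataFrame, family_rpm: pd.DataFrame,
                     family_of: dict) -> pd.DataFrame:
    """Samples x isomiRs frequency matrix.

    ``isomir_rpm`` is samples x isomiR names, ``family_rpm`` samples x
    miRNA names, and ``family_of`` maps each isomiR name to its miRNA.
    Zero-family entries become NaN (undefined).
    """
    fam = pd.DataFrame(
        {name: family_rpm[family_of[name]] for name in isomir_rpm.columns}
    )
    freq = isomir_rpm / fam.replace(0.0, np.nan)
    freq[fam == 0] = np.nan
    return freq


def zscore_matrix(freq: pd.DataFrame) -> pd.DataFrame:
    """Column-wise z-scores over defined entries (sample sd, n-1).

    Undefined frequencies stay undefined; isomiRs with zero spread give
    an all-zero column with a warning.
    """
    mean = freq.mean(axis=0, skipna=True)
    sd = freq.std(axis=0, ddof=1, skipna=True)
    degenerate = (sd <= 1e-12) | sd.isna()  # constant up to rounding
    if degenerate.any():
        cols = list(freq.columns[degenerate])
        warnings.warn(f"zero spread for {len(cols)} isomiR(s); z set to 0: {cols[:5]}")
    z = (freq - mean) / sd.where(~degenerate, np.nan)
    z.loc[:, degenerate] = freq.loc[:, degenerate].notna().astype(float) * 0.0
    z[freq.isna()] = np.nan
    return z


def modification_rate(z: pd.DataFrame, keys: Sequence[str], sample: str) -> float:
    """Mean defined z-score over ``keys`` for one sample (NaN if none)."""
    vals = z.loc[sample, [k for k in keys if k in z.columns]]
    return float(vals.mean(skipna=True))


def modification_rates(z: pd.DataFrame, kind_of: dict) -> pd.DataFrame:
    """Samples x isomiR-type matrix of modification rates.

    ``kind_of`` maps isomiR names to their :class:`IsomirKind`; NTA_A
    and NTA_U map to adenylation and uridylation rates, EDIT_AI to the
    editing rate, FIVE_PRIME to the 5'-shift rate.
    """
    groups = {
        "editing": [n for n, k in kind_of.items() if k == IsomirKind.EDIT_AI],
        "adenylation": [n for n, k in kind_of.items() if k == IsomirKind.NTA_A],
        "uridylation": [n for n, k in kind_of.items() if k == IsomirKind.NTA_U],
        "five_prime": [n for n, k in kind_of.items() if k == IsomirKind.FIVE_PRIME],
    }
    out = {}
    for rate_name, names in groups.items():
        cols = [n for n in names if n in z.columns]
        if cols:
            out[rate_name] = z[cols].mean(axis=1, skipna=True)
        else:
            out[rate_name] = pd.Series(np.nan, index=z.index)
    return pd.DataFrame(out)


def _paired_vectors(values: pd.Series, sheet: pd.DataFrame, cohort: str):
    sub = sheet[sheet["cohort"] == cohort]
    anl = sub[sub["group"] == "ANL"].set_index("patient_id")["sample_id"]
    luad = sub[sub["group"] == "LUAD"].set_index("patient_id")["sample_id"]
    patients = anl.index.intersection(luad.index)
    a = values.reindex(anl.loc[patients].values).to_numpy(dtype=float)
    b = values.reindex(luad.loc[patients].values).to_numpy(dtype=float)
    ok = ~(np.isnan(a) | np.isnan(b))
    return a[ok], b[ok]


def paired_rate_test(rates: pd.Series, sheet: pd.DataFrame, cohort: str) -> dict:
    """Paired t-test of a per-sample quantity between ANL and LUAD in
    one cohort.  Pairs with an undefined value on either side are
    dropped; fewer than three remaining pairs yields a flagged no-test."""
    a, b = _paired_vectors(rates, sheet, cohort)
    if len(a) < 3:
        return {"cohort": cohort, "n_pairs": len(a), "t": np.nan, "p": np.nan,
                "direction": "", "tested": False}
    if np.allclose(a, b):
        t, p = 0.0, 1.0
    else:
        t, p = stats.ttest_rel(b, a)
    direction = "higher_in_LUAD" if np.mean(b - a) > 0 else "lower_in_LUAD"
    return {"cohort": cohort, "n_pairs": len(a), "t": float(t), "p": float(p),
            "direction": direction, "tested": True}


def paired_differential(
    freq: pd.DataFrame,
    sheet: pd.DataFrame,
    names: Sequence[str],
    cohort: str,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-isomiR paired ANL-vs-LUAD frequency tests within one cohort,
    BH-corrected across the given isomiRs (FDR < ``alpha``)."""
    rows = []
    for name in names:
        if name not in freq.columns:
            rows.append({"isomir": name, "n_pairs": 0, "t": np.nan, "p": np.nan,
                         "direction": "", "tested": False})
            continue
        res = paired_rate_test(freq[name], sheet, cohort)
        rows.append({"isomir": name, "n_pairs": res["n_pairs"], "t": res["t"],
                     "p": res["p"], "direction": res["direction"],
                     "tested": res["tested"]})
    table = pd.DataFrame(rows)
    table["fdr"] = np.nan
    tested = table["tested"] & table["p"].notna()
    if tested.any():
        _, fdr, _, _ = multipletests(table.loc[tested, "p"], alpha=alpha, method="fdr_bh")
        table.loc[tested, "fdr"] = fdr
    table["significant"] = table["fdr"] < alpha
    table["cohort"] = cohort
    return table


def _spearman(x: np.ndarray, y: np.ndarray, rng: Optional[np.random.Generator],
              n_perm: int = 10_000) -> tuple[float, float]:
    """Spearman rho with tie-corrected ranks; permutation p for n <= 20,
    t-approximation otherwise."""
    rho = stats.spearmanr(x, y).statistic
    n = len(x)
    if n <= 20:
        if rng is None:
            rng = np.random.default_rng(0)
        count = 0
        for _ in range(n_perm):
            perm_rho = stats.spearmanr(x, rng.permutation(y)).statistic
            if abs(perm_rho) >= abs(rho) - 1e-12:
                count += 1
        return float(rho), (count + 1) / (n_perm + 1)
    return float(rho), float(stats.spearmanr(x, y).pvalue)


def correlate_enzymes(
    values: pd.DataFrame,
    enzymes: pd.DataFrame,
    sheet: pd.DataFrame,
    enzyme_a: str = "ADAR",
    enzyme_b: str = "ADARB1",
    alpha: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Spearman correlation of per-sample values (columns = isomiRs or
    rates) with two modifier enzymes, tumor samples only.

    Each isomiR is grouped by which enzyme it correlates with: a
    significant (BH-FDR < alpha) positive correlation assigns it to that
    enzyme's group; significance with both assigns the larger rho (the
    row is flagged); otherwise "Neither".
    """
    luad = sheet.loc[sheet["group"] == "LUAD", "sample_id"]
    luad = [s for s in luad if s in values.index and s in enzymes.columns]
    if len(luad) < 5:
        raise ValueError("need >= 5 LUAD samples with both measurements")
    rng = np.random.default_rng(seed)
    rows = []
    for name in values.columns:
        v = values.loc[luad, name].to_numpy(dtype=float)
        ok = ~np.isnan(v)
        row = {"isomir": name, "n": int(ok.sum())}
        for label, enzyme in (("a", enzyme_a), ("b", enzyme_b)):
            e = enzymes.loc[enzyme, luad].to_numpy(dtype=float)[ok]
            vv = v[ok]
            if len(vv) < 5 or np.all(vv == vv[0]) or np.all(e == e[0]):
                row[f"rho_{label}"], row[f"p_{label}"] = np.nan, np.nan
                row["flagged"] = True
            else:
                row[f"rho_{label}"], row[f"p_{label}"] = _spearman(vv, e, rng)
        rows.append(row)
    table = pd.DataFrame(rows)
    for label in ("a", "b"):
        ok = table[f"p_{label}"].notna()
        table[f"fdr_{label}"] = np.nan
        if ok.any():
            _, fdr, _, _ = multipletests(table.loc[ok, f"p_{label}"], alpha=alpha,
                                         method="fdr_bh")
            table.loc[ok, f"fdr_{label}"] = fdr
    groups, flags = [], []
    for _, r in table.iterrows():
        sig_a = r["fdr_a"] < alpha and r["rho_a"] > 0
        sig_b = r["fdr_b"] < alpha and r["rho_b"] > 0
        if sig_a and sig_b:
            groups.append(enzyme_a if r["rho_a"] >= r["rho_b"] else enzyme_b)
            flags.append(True)
        elif sig_a:
            groups.append(enzyme_a)
            flags.append(False)
        elif sig_b:
            groups.append(enzyme_b)
            flags.append(False)
        else:
            groups.append("Neither")
            flags.append(False)
    table["group"] = groups
    table["both_significant"] = flags
    return table


def median_split_survival(
    values: pd.Series,
    os_time: pd.Series,
    os_event: pd.Series,
    min_patients: int = 10,
) -> dict:
    """Log-rank test between above-median and at-or-below-median groups.

    Median ties go to the below-median arm.  Arms without events are
    computed but flagged; identical values yield no split.
    """
    df = pd.DataFrame({"v": values, "t": os_time, "e": os_event}).dropna()
    if len(df) < min_patients:
        return {"p": np.nan, "n": len(df), "flag": "too_few_patients"}
    med = df["v"].median()
    hi = df["v"] > med
    if hi.sum() == 0 or (~hi).sum() == 0:
        return {"p": np.nan, "n": len(df), "flag": "no_split"}
    res = logrank_test(df.loc[hi, "t"], df.loc[~hi, "t"],
                       event_observed_A=df.loc[hi, "e"], event_observed_B=df.loc[~hi, "e"])
    flag = ""
    if df.loc[hi, "e"].sum() == 0 or df.loc[~hi, "e"].sum() == 0:
        flag = "arm_without_events"
    return {"p": float(res.p_value), "statistic": float(res.test_statistic),
            "n": len(df), "n_high": int(hi.sum()), "flag": flag}


@dataclass
class CatalogSummary:
    """Seed-position and sequence-context statistics of an editing-site
    catalog."""

    sites: pd.DataFrame  # mirna, five_prime_shift, edited_position, seed, adj5, adj3
    n_sites: int
    n_seed: int
    adj5_counts: Counter
    adj3_counts: Counter

    @property
    def seed_fraction(self) -> float:
        return self.n_seed / self.n_sites if self.n_sites else float("nan")

    def adj5_fraction(self, base: str) -> float:
        return self.adj5_counts.get(base, 0) / self.n_sites if self.n_sites else float("nan")


def summarize_catalog(sites: pd.DataFrame) -> CatalogSummary:
    """Summarize an editing-site table.

    ``sites`` needs columns ``mirna``, ``five_prime_shift``,
    ``edited_position`` (isomiR coordinates, 0 = first nucleotide) and
    ``adj5``/``adj3`` (RNA bases adjacent to the edited A; when the
    adjacent base lies outside the mature sequence it is drawn from the
    precursor).  A site lies in the seed when its 0-based position is
    within 1-7 (nucleotides 2-8).
    """
    if (sites["edited_position"] < 0).any():
        raise ValueError("edited position outside the isomiR")
    out = sites.copy()
    out["seed"] = out["edited_position"].isin(list(SEED_RANGE))
    return CatalogSummary(
        sites=out,
        n_sites=len(out),
        n_seed=int(out["seed"].sum()),
        adj5_counts=Counter(out["adj5"]),
        adj3_counts=Counter(out["adj3"]),
    )


_TO_RNA = str.maketrans("ACGT", "ACGU")


def edit_site_context(key: IsomiRKey, locus: MiRNALocus) -> dict:
    """Sequence context of one edited site, for catalog summaries.

    The neighbours immediately 5' and 3' of the edited adenosine are
    read from the hairpin, so positions outside the mature sequence fall
    back to the precursor.
    """
    if key.kind != IsomirKind.EDIT_AI:
        raise ValueError("context is defined for edited isomiRs only")
    shift, pos = key.coords
    moff = locus.hairpin_seq.find(locus.mature_seq)
    hp_pos = moff + shift + pos
    if not 0 < hp_pos < len(locus.hairpin_seq) - 1:
        raise ValueError(f"{key.name}: edited position outside the hairpin")
    return {
        "mirna": key.mirna_name,
        "five_prime_shift": shift,
        "edited_position": pos,
        "adj5": locus.hairpin_seq[hp_pos - 1].translate(_TO_RNA),
        "adj3": locus.hairpin_seq[hp_pos + 1].translate(_TO_RNA),
    }


def nta_spectrum(flags: pd.DataFrame) -> pd.DataFrame:
    """Counts of expressed tailed isomiRs per tail base, cohort and
    group (the C/G tails are rare but real).  ``flags`` needs columns
    kind, cohort, group, expressed."""
    tails = flags[flags["kind"].isin([k.value for k in
                                      (IsomirKind.NTA_A, IsomirKind.NTA_U,
                                       IsomirKind.NTA_C, IsomirKind.NTA_G)])]
    tails = tails[tails["expressed"]]
    out = (tails.groupby(["cohort", "group", "kind"]).size()
           .rename("n_isomirs").reset_index())
    out["base"] = out["kind"].str.replace("NTA_", "", regex=False)
    return out


def collapse_probes(probes: pd.DataFrame, probe_map: pd.DataFrame) -> pd.DataFrame:
    """Gene-level expression: per gene keep the probe with the highest
    mean across samples (ties: lexicographically smallest probe id)."""
    rows = {}
    for gene, sub in probe_map.groupby("gene"):
        ids = [p for p in sorted(sub["probe"]) if p in probes.index]
        if not ids:
            warnings.warn(f"gene {gene} has no probes in the expression table")
            continue
        means = probes.loc[ids].mean(axis=1)
        best = means.sort_index().idxmax()  # idxmax takes the first (lowest id) on ties
        rows[gene] = probes.loc[best]
    return pd.DataFrame(rows).T
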