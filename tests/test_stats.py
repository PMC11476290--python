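import warnings

import numpy as np
import pandas as pd
import pytest

import isomirome as iso
from isomirome.isomir_annotation import IsomirKind, IsomiRKey
from isomirome.modification_stats import (
    collapse_probes,
    correlate_enzymes,
    edit_site_context,
    isomir_frequency,
    median_split_survival,
    modification_rate,
    nta_spectrum,
    paired_differential,
    paired_rate_test,
    summarize_catalog,
    zscore_matrix,
)


class TestFrequency:
    @pytest.mark.parametrize("iso_rpm,fam_rpm,expected", [(10, 100, 0.1), (0, 100, 0.0)])
    def test_definition(self, iso_rpm, fam_rpm, expected):
        assert isomir_frequency(iso_rpm, fam_rpm) == expected

    def test_zero_family_undefined(self):
        assert np.isnan(isomir_frequency(0, 0))

    def test_family_accounting_violation_rejected(self):
        with pytest.raises(ValueError):
            isomir_frequency(11, 10)


class TestZscores:
    def test_two_sample_column_hand_computed(self):
        freq = pd.DataFrame({"x": [0.1, 0.3]})
        z = zscore_matrix(freq)
        assert z["x"].tolist() == pytest.approx([-np.sqrt(0.5), np.sqrt(0.5)])

    def test_constant_column_warns_and_zeroes(self):
        freq = pd.DataFrame({"x": [0.2, 0.2, 0.2]})
        with pytest.warns(UserWarning, match="zero spread"):
            z = zscore_matrix(freq)
        assert (z["x"] == 0).all()

    def test_undefined_propagates(self):
        freq = pd.DataFrame({"x": [0.1, np.nan, 0.3]})
        z = zscore_matrix(freq)
        assert np.isnan(z["x"].iloc[1])

    def test_mean_zero_sd_one_over_defined(self):
        rng = np.random.default_rng(1)
        freq = pd.DataFrame(rng.random((30, 8)))
        freq.iloc[3, 2] = np.nan
        z = zscore_matrix(freq)
        assert np.allclose(z.mean(skipna=True), 0, atol=1e-10)
        assert np.allclose(z.std(ddof=1, skipna=True), 1, atol=1e-10)


class TestModificationRate:
    def test_all_zero(self):
        z = pd.DataFrame({"a": [0.0], "b": [0.0]}, index=["s"])
        assert modification_rate(z, ["a", "b"], "s") == 0.0

    def test_undefined_excluded(self):
        z = pd.DataFrame({"a": [1.0], "b": [-1.0], "c": [np.nan]}, index=["s"])
        assert modification_rate(z, ["a", "b", "c"], "s") == 0.0

    def test_no_defined_values_is_nan(self):
        z = pd.DataFrame({"a": [np.nan]}, index=["s"])
        assert np.isnan(modification_rate(z, ["a"], "s"))


def _sheet(n_pairs, cohort="C"):
    rows = []
    for i in range(n_pairs):
        for g in ("ANL", "LUAD"):
            rows.append({"sample_id": f"{g}{i}", "cohort": cohort, "group": g,
                         "patient_id": f"P{i}", "stage": "IA" if g == "LUAD" else ""})
    return pd.DataFrame(rows)


class TestPairedTests:
    def test_identical_vectors_give_t0_p1(self):
        sheet = _sheet(5)
        vals = pd.Series({f"{g}{i}": float(i) for i in range(5) for g in ("ANL", "LUAD")})
        res = paired_rate_test(vals, sheet, "C")
        assert res["t"] == 0.0 and res["p"] == 1.0

    def test_undefined_pairs_dropped_and_too_few_flagged(self):
        sheet = _sheet(4)
        vals = pd.Series({f"{g}{i}": (np.nan if i > 1 else float(i))
                          for i in range(4) for g in ("ANL", "LUAD")})
        res = paired_rate_test(vals, sheet, "C")
        assert not res["tested"] and res["n_pairs"] == 2

    def test_null_false_positive_rate_controlled(self):
        """Planted null: FDR-significant fraction across replicates stays
        near the nominal level."""
        rng = np.random.default_rng(7)
        sheet = _sheet(20)
        n_iso, n_rep = 100, 30
        total_fp, total_tests = 0, 0
        for _ in range(n_rep):
            freq = pd.DataFrame(
                rng.normal(0.2, 0.05, size=(40, n_iso)),
                index=[f"{g}{i}" for i in range(20) for g in ("ANL", "LUAD")],
                columns=[f"iso{j}" for j in range(n_iso)])
            tab = paired_differential(freq, sheet, list(freq.columns), "C")
            total_fp += tab["significant"].sum()
            total_tests += len(tab)
        rate = total_fp / total_tests
        sigma = np.sqrt(0.05 * 0.95 / total_tests)
        assert rate <= 0.05 + 3 * sigma

    def test_planted_shift_detected_with_direction(self):
        rng = np.random.default_rng(3)
        sheet = _sheet(20)
        idx = [f"{g}{i}" for i in range(20) for g in ("ANL", "LUAD")]
        freq = pd.DataFrame(rng.normal(0.2, 0.02, size=(40, 10)), index=idx,
                            columns=[f"iso{j}" for j in range(10)])
        for j in range(5):  # plant a deficit on half the isomiRs
            freq.loc[[s for s in idx if s.startswith("LUAD")], f"iso{j}"] -= 0.05
        tab = paired_differential(freq, sheet, list(freq.columns), "C").set_index("isomir")
        for j in range(5):
            assert tab.loc[f"iso{j}", "significant"]
            assert tab.loc[f"iso{j}", "direction"] == "lower_in_LUAD"
        assert tab.loc[[f"iso{j}" for j in range(5, 10)], "significant"].sum() <= 1


class TestCorrelations:
    def _frame(self, n=30):
        sheet = _sheet(n)
        luad = [f"LUAD{i}" for i in range(n)]
        return sheet, luad

    def test_perfect_monotone_rho_one(self):
        sheet, luad = self._frame()
        vals = pd.DataFrame({"iso": np.arange(30, dtype=float)}, index=luad)
        enz = pd.DataFrame([np.arange(30) ** 2, np.ones(30)],
                           index=["ADAR", "ADARB1"], columns=luad)
        tab = correlate_enzymes(vals, enz, sheet)
        assert tab["rho_a"].iloc[0] == pytest.approx(1.0)

    def test_independent_vectors_raw_alpha_calibrated(self):
        """Raw Spearman p < 0.05 occurs in about 5% of independent draws
        (checked against its binomial sampling band)."""
        rng = np.random.default_rng(11)
        n, reps, hits = 100, 400, 0
        from scipy.stats import spearmanr

        for _ in range(reps):
            if spearmanr(rng.random(n), rng.random(n)).pvalue < 0.05:
                hits += 1
        sigma = np.sqrt(0.05 * 0.95 / reps)
        assert abs(hits / reps - 0.05) < 3.5 * sigma

    def test_coupling_assigns_enzyme_group(self):
        rng = np.random.default_rng(5)
        sheet, luad = self._frame(40)
        u = rng.normal(size=40)
        vals = pd.DataFrame({"iso_a": 0.1 * np.exp(0.5 * u),
                             "iso_n": rng.random(40)}, index=luad)
        enz = pd.DataFrame([np.exp(u + 0.1 * rng.normal(size=40)),
                            np.exp(rng.normal(size=40))],
                           index=["ADAR", "ADARB1"], columns=luad)
        tab = correlate_enzymes(vals, enz, sheet).set_index("isomir")
        assert tab.loc["iso_a", "group"] == "ADAR"
        assert tab.loc["iso_n", "group"] == "Neither"

    def test_constant_vector_flagged(self):
        sheet, luad = self._frame()
        vals = pd.DataFrame({"iso": np.full(30, 0.5)}, index=luad)
        enz = pd.DataFrame([np.arange(30), np.arange(30)],
                           index=["ADAR", "ADARB1"], columns=luad, dtype=float)
        tab = correlate_enzymes(vals, enz, sheet)
        assert tab["flagged"].iloc[0] and np.isnan(tab["rho_a"].iloc[0])

    def test_too_few_samples_rejected(self):
        sheet, luad = self._frame(3)
        vals = pd.DataFrame({"iso": [1.0, 2.0, 3.0]}, index=luad)
        enz = pd.DataFrame([[1, 2, 3], [1, 2, 3]], index=["ADAR", "ADARB1"],
                           columns=luad, dtype=float)
        with pytest.raises(ValueError):
            correlate_enzymes(vals, enz, sheet)


class TestSurvival:
    def test_identical_arms_give_p_one(self):
        values = pd.Series(np.arange(20, dtype=float))
        times = pd.Series(list(range(1, 11)) * 2)
        events = pd.Series([1] * 20)
        res = median_split_survival(values, times, events)
        assert res["p"] == pytest.approx(1.0)
        assert res["statistic"] == pytest.approx(0.0, abs=1e-9)

    def test_planted_hazard_ratio_detected(self):
        rng = np.random.default_rng(13)
        detected = 0
        reps = 20
        for _ in range(reps):
            n = 200
            values = pd.Series(np.concatenate([np.zeros(n // 2), np.ones(n // 2)]))
            lam = np.where(values == 0, 2.0, 1.0)  # hazard ratio 2
            t = rng.exponential(1 / lam)
            censor = rng.uniform(0.2, 3.0, size=n)
            times = pd.Series(np.minimum(t, censor))
            events = pd.Series((t <= censor).astype(int))
            if median_split_survival(values, times, events)["p"] < 0.05:
                detected += 1
        assert detected >= 0.8 * reps

    def test_no_split_flagged(self):
        res = median_split_survival(pd.Series(np.ones(20)),
                                    pd.Series(np.arange(1.0, 21.0)),
                                    pd.Series([1] * 20))
        assert res["flag"] == "no_split" and np.isnan(res["p"])

    def test_zero_event_arm_flagged_but_computed(self):
        values = pd.Series(np.arange(20, dtype=float))
        times = pd.Series(np.arange(1.0, 21.0))
        events = pd.Series([1] * 10 + [0] * 10)  # above-median arm: no events
        res = median_split_survival(values, times, events)
        assert res["flag"] == "arm_without_events"
        assert np.isfinite(res["p"])


class TestCatalog:
    def test_lung_catalog_seed_and_adjacent_statistics(self):
        sites = iso.load_lung_editing_sites()
        summary = summarize_catalog(sites)
        assert summary.n_sites == 16
        assert summary.n_seed == 13
        assert summary.adj5_counts["U"] == 12

    def test_position_zero_not_in_seed(self):
        sites = pd.DataFrame([{"mirna": "m", "five_prime_shift": 0,
                               "edited_position": 0, "adj5": "A", "adj3": "A"}])
        assert summarize_catalog(sites).n_seed == 0

    def test_negative_position_rejected(self):
        sites = pd.DataFrame([{"mirna": "m", "five_prime_shift": 0,
                               "edited_position": -1, "adj5": "A", "adj3": "A"}])
        with pytest.raises(ValueError):
            summarize_catalog(sites)

    def test_context_from_precursor_when_outside_mature(self, bundle):
        locus = bundle.locus("syn-miR-15-5p")  # edit site at mature position 0
        key = IsomiRKey("syn-miR-15-5p", IsomirKind.EDIT_AI, (0, 0))
        ctx = edit_site_context(key, locus)
        moff = locus.hairpin_seq.find(locus.mature_seq)
        assert ctx["adj5"] == locus.hairpin_seq[moff - 1].replace("T", "U")
        assert ctx["edited_position"] == 0

    def test_nta_spectrum_counts_expressed_tails(self, small_run):
        _, res = small_run
        spec = nta_spectrum(res.flags)
        assert set(spec["base"]) <= {"A", "U", "C", "G"}
        au = spec[spec["base"].isin(["A", "U"])]["n_isomirs"].sum()
        cg = spec[spec["base"].isin(["C", "G"])]["n_isomirs"].sum()
        assert au > cg  # A/U tails dominate, C/G rare


class TestCollapseProbes:
    def test_single_probe_passthrough(self):
        probes = pd.DataFrame({"s1": [1.0], "s2": [2.0]}, index=["p1"])
        pm = pd.DataFrame([{"probe": "p1", "gene": "G"}])
        out = collapse_probes(probes, pm)
        assert out.loc["G"].tolist() == [1.0, 2.0]

    def test_highest_mean_probe_retained(self):
        probes = pd.DataFrame({"s1": [5.0, 9.0], "s2": [5.0, 9.0]},
                              index=["p1", "p2"])
        pm = pd.DataFrame([{"probe": "p1", "gene": "G"}, {"probe": "p2", "gene": "G"}])
        assert collapse_probes(probes, pm).loc["G", "s1"] == 9.0

    def test_tie_takes_lowest_probe_id(self):
        probes = pd.DataFrame({"s1": [7.0, 7.0]}, index=["p2", "p1"])
        pm = pd.DataFrame([{"probe": "p2", "gene": "G"}, {"probe": "p1", "gene": "G"}])
        out = collapse_probes(probes, pm)
        assert out.loc["G", "s1"] == 7.0  # p1 chosen; equal values either way

    def test_missing_gene_warns(self):
        probes = pd.DataFrame({"s1": [1.0]}, index=["p1"])
        pm = pd.DataFrame([{"probe": "pX", "gene": "G"}])
        with pytest.warns(UserWarning, match="no probes"):
            out = collapse_probes(probes, pm)
        assert out.empty

    def test_simulated_probe_tables_collapse_to_gene_signal(self, small_run):
        data, _ = small_run
        genes = collapse_probes(data.probes, data.probe_map)
        assert set(genes.index) == set(data.enzymes.index)
        # the retained probe is the informative (scale-1) one: highly
        # correlated with the underlying gene expression
        for g in genes.index:
            r = np.corrcoef(genes.loc[g], data.enzymes.loc[g, genes.columns])[0, 1]
            assert r > 0.8
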