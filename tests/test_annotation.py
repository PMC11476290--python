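import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import isomirome as iso
from isomirome.isomir_annotation import (
    IsomirKind,
    IsomiRKey,
    ReadAnnotation,
    annotate_read,
    collapse,
    counterpart_counts,
    keys_for_annotation,
    name_isomir,
    parse_name,
    quantify,
    revcomp,
)


def _mature(bundle, name):
    return bundle.locus(name).mature_seq


def _brute_force_hits(genome, seq):
    """Oracle: exact occurrences of seq on either strand of the genome."""
    hits = []
    for strand, ref in (("+", genome), ("-", revcomp(genome))):
        start = 0
        while (i := ref.find(seq, start)) >= 0:
            hits.append((strand, i))
            start = i + 1
    return hits


class TestAlign:
    def test_exact_mature_single_hit_zero_mismatches(self, bundle, index):
        for name in ("syn-miR-11-5p", "syn-miR-19-5p"):  # plus and minus strand
            hits = iso.align_read(_mature(bundle, name), index)
            best = [h for h in hits if (h.mismatches, h.overhang) == (0, 0)]
            assert len(best) == 1
            assert best[0].locus.mirna_name == name

    def test_two_nt_overhang_detected(self, bundle, index):
        seq = _mature(bundle, "syn-miR-12-3p") + "AA"
        hits = iso.align_read(seq, index)
        assert hits[0].locus.mirna_name == "syn-miR-12-3p"
        assert hits[0].overhang == 2 and hits[0].mismatches == 0

    def test_decoy_has_two_equally_ranked_hits(self, bundle, index):
        seq = _mature(bundle, "syn-miR-dup-5p")
        hits = iso.align_read(seq, index)
        exact = [h for h in hits if h.mismatches == 0 and h.overhang == 0]
        assert len(exact) == len(_brute_force_hits(bundle.genome, seq)) == 2

    def test_search_agrees_with_brute_force_on_single_mismatch(self, bundle, index):
        mature = _mature(bundle, "syn-miR-13-5p")
        mutated = mature[:10] + ("A" if mature[10] != "A" else "C") + mature[11:]
        hits = iso.align_read(mutated, index)
        assert hits[0].locus.mirna_name == "syn-miR-13-5p"
        assert hits[0].mismatches == 1

    def test_unalignable_read_returns_empty(self, index):
        assert iso.align_read("ACGT" * 6, index) == [] or all(
            h.mismatches <= 1 for h in iso.align_read("ACGT" * 6, index))


class TestAnnotate:
    def _annotate(self, bundle, index, seq):
        hits = iso.align_read(seq, index)
        best = next(h for h in hits if h.locus is not None)
        return annotate_read(seq, best, len(bundle.genome))

    def test_single_planted_edit(self, bundle, index):
        mature = _mature(bundle, "syn-miR-11-5p")
        assert mature[4] == "A"
        seq = mature[:4] + "G" + mature[5:]
        ann = self._annotate(bundle, index, seq)
        assert ann.substitutions == ((4, "A", "G"),)
        assert ann.five_prime_shift == 0 and ann.three_prime_shift == 0
        assert ann.nta == ""

    def test_trimmed_first_base_gives_positive_shift(self, bundle, index):
        seq = _mature(bundle, "syn-miR-11-5p")[1:]
        ann = self._annotate(bundle, index, seq)
        assert ann.five_prime_shift == 1

    def test_five_prime_extension_negative_shift(self, bundle, index):
        locus = bundle.locus("syn-miR-14-3p")
        moff = locus.hairpin_seq.find(locus.mature_seq)
        seq = locus.hairpin_seq[moff - 2 : moff + locus.mature_len]
        ann = self._annotate(bundle, index, seq)
        assert ann.five_prime_shift == -2

    def test_minus_strand_coordinates(self, bundle, index):
        seq = _mature(bundle, "syn-miR-19-5p")[1:]
        ann = self._annotate(bundle, index, seq)
        assert ann.mirna_name == "syn-miR-19-5p"
        assert ann.five_prime_shift == 1

    def test_two_internal_mismatches_discarded(self, bundle, index):
        mature = _mature(bundle, "syn-miR-11-5p")
        seq = list(mature)
        seq[3] = "A" if mature[3] != "A" else "C"
        seq[9] = "A" if mature[9] != "A" else "C"
        seq = "".join(seq)
        hits = [h for h in iso.align_read(seq, index) if h.locus is not None]
        assert not hits or annotate_read(seq, hits[0], len(bundle.genome)) is None

    def test_nta_is_nontemplated_suffix(self, bundle, index):
        seq = _mature(bundle, "syn-miR-12-3p") + "TT"
        ann = self._annotate(bundle, index, seq)
        assert ann.nta == "TT" and ann.three_prime_shift == 0


def A(mirna="m", s5=0, s3=0, nta="", subs=(), length=22):
    return ReadAnnotation(mirna, s5, s3, nta, tuple(subs), length)


class TestCollapse:
    def test_same_edit_different_three_prime_ends_combined(self):
        anns = [(A(subs=[(4, "A", "G")], s3=0, length=22), 1),
                (A(subs=[(4, "A", "G")], s3=-1, length=21), 1)]
        keys = collapse(anns, IsomirKind.EDIT_AI)
        assert keys == {IsomiRKey("m", IsomirKind.EDIT_AI, (0, 4)): 2}

    def test_read_contributes_to_both_five_prime_and_nta_views(self):
        ann = A(s5=-2, nta="A", length=25)
        keys = {k.kind for k in keys_for_annotation(ann)}
        assert keys == {IsomirKind.FIVE_PRIME, IsomirKind.NTA_A}
        assert collapse([(ann, 1)], IsomirKind.FIVE_PRIME) == {
            IsomiRKey("m", IsomirKind.FIVE_PRIME, (-2,)): 1}

    def test_edit_in_final_two_bases_not_a_key(self):
        ann = A(subs=[(21, "A", "G")], length=22)
        assert collapse([(ann, 1)], IsomirKind.EDIT_AI) == {}
        ann20 = A(subs=[(20, "A", "G")], length=22)
        assert collapse([(ann20, 1)], IsomirKind.EDIT_AI) == {}
        ann19 = A(subs=[(19, "A", "G")], length=22)
        assert collapse([(ann19, 1)], IsomirKind.EDIT_AI) != {}

    def test_uridine_tail_maps_to_nta_u(self):
        ann = A(nta="T", length=23)
        (key,) = collapse([(ann, 3)], IsomirKind.NTA_U)
        assert key == IsomiRKey("m", IsomirKind.NTA_U, (1,))

    def test_long_or_mixed_tails_excluded_from_nta_keys(self):
        assert collapse([(A(nta="AAA", length=25), 1)]) == {}
        assert collapse([(A(nta="AT", length=24), 1)]) == {}

    def test_counterparts(self):
        anns = [
            (A(subs=[(4, "A", "G")]), 5),   # edited
            (A(), 90),                       # canonical
            (A(s5=1, length=21), 10),        # 5' isomiR
            (A(nta="A", length=23), 7),      # adenylated
        ]
        keys = collapse(anns)
        ctr = counterpart_counts(anns, keys)
        edit_key = IsomiRKey("m", IsomirKind.EDIT_AI, (0, 4))
        five_key = IsomiRKey("m", IsomirKind.FIVE_PRIME, (1,))
        nta_key = IsomiRKey("m", IsomirKind.NTA_A, (1,))
        assert ctr[edit_key] == 90 + 7  # same shift, unedited at site
        assert ctr[five_key] == 5 + 90 + 7  # canonical 5' end
        assert ctr[nta_key] == 5 + 90 + 10  # untailed reads


class TestNaming:
    @pytest.mark.parametrize("key,expected", [
        (IsomiRKey("hsa-miR-200b-3p", IsomirKind.EDIT_AI, (0, 4)), "hsa-miR-200b-3p 0 4 AI"),
        (IsomiRKey("hsa-miR-140-3p", IsomirKind.FIVE_PRIME, (1,)), "hsa-miR-140-3p 1"),
        (IsomiRKey("hsa-miR-99a-5p", IsomirKind.NTA_A, (1,)), "hsa-miR-99a-5p 1A"),
        (IsomiRKey("hsa-miR-99a-5p", IsomirKind.NTA_U, (2,)), "hsa-miR-99a-5p 2U"),
        (IsomiRKey("hsa-miR-151a-3p", IsomirKind.EDIT_AI, (-2, 2)), "hsa-miR-151a-3p -2 2 AI"),
    ])
    def test_examples(self, key, expected):
        assert name_isomir(key) == expected
        assert parse_name(expected) == key

    @given(
        mirna=st.sampled_from(["hsa-miR-1-5p", "hsa-let-7d-3p", "syn-miR-11-5p"]),
        kind=st.sampled_from([IsomirKind.FIVE_PRIME, IsomirKind.NTA_A, IsomirKind.NTA_U,
                              IsomirKind.NTA_C, IsomirKind.NTA_G, IsomirKind.EDIT_AI]),
        a=st.integers(-3, 3), b=st.integers(0, 20), pos=st.integers(1, 2),
    )
    @settings(max_examples=200, deadline=None, derandomize=True, database=None)
    def test_round_trip(self, mirna, kind, a, b, pos):
        if kind == IsomirKind.EDIT_AI:
            key = IsomiRKey(mirna, kind, (a, b))
        elif kind == IsomirKind.FIVE_PRIME:
            key = IsomiRKey(mirna, kind, (a if a != 0 else 1,))
        else:
            key = IsomiRKey(mirna, kind, (pos,))
        assert parse_name(name_isomir(key)) == key


class TestQuantify:
    def test_rpm_definition(self):
        key = IsomiRKey("m", IsomirKind.FIVE_PRIME, (1,))
        assert quantify({key: 10}, 1_000_000) == {key: 10.0}

    def test_zero_mapped_rejected(self):
        with pytest.raises(ValueError):
            quantify({}, 0)


class TestConservation:
    def test_family_counts_bound_isomir_counts(self, small_run):
        _, res = small_run
        for sid, sc in res.calls.items():
            fam = sc.family_counts
            assert sum(fam.values()) == sc.n_mapped
            for key, c in sc.key_counts.items():
                assert c <= fam[key.mirna_name]

    def test_family_rpm_sums_to_one_million(self, small_run):
        _, res = small_run
        sums = res.family_rpm.sum(axis=1)
        assert (abs(sums - 1e6) < 1e-3).all()


def test_error_free_reads_recover_all_planted_events():
    """With zero error, zero low-quality reads and no SNP, the pipeline's
    per-key counts equal the generator's truth-table counts exactly."""
    from collections import Counter

    import isomirome as iso
    from isomirome import pipeline as pl

    cfg = iso.small_config(n_pairs=1, n_reads=6000)
    cfg.low_q_read_frac = 0.0
    for lc in cfg.loci:
        lc.snp_freq = 0.0
        lc.decoy_copies = 1  # keep the decoy locus uniquely mapped here
    for cc in cfg.cohorts:
        cc.plates = [("P", 0.0)]
    data = iso.simulate_cohorts(cfg, seed=8)
    res = pl.run_pipeline(data, min_sample_reads=100)

    def tail_outcome(tail, cont):
        """How a homopolymer tail reads against its genomic continuation:
        ('nta', position) for a clean non-templated call, 'templated' when
        it aliases with the continuation, 'sub' when partial aliasing
        turns it into an internal substitution."""
        if tail == "":
            return ("none",)
        if len(tail) == 1:
            return ("templated",) if tail[0] == cont[0] else ("nta", 1)
        if tail[0] == cont[0]:
            return ("templated",) if tail[1] == cont[1] else ("nta", 2)
        return ("sub",) if tail[1] == cont[1] else ("nta", 2)

    for sid in data.sample_ids():
        _, truth = data.reads(sid)
        sc = res.calls[sid]
        expected_edit = Counter()
        expected_nta = Counter()
        for _, row in truth.iterrows():
            locus = data.bundle.locus(row["locus"])
            moff = locus.hairpin_seq.find(locus.mature_seq)
            cont = locus.hairpin_seq[moff + locus.mature_len : moff + locus.mature_len + 2]
            outcome = tail_outcome(row["tail"], cont)
            if row["edited"] and outcome[0] != "sub":  # edit + tail-sub = 2 subs, discarded
                lt = data.profiles[sid].loci[row["locus"]]
                key = IsomiRKey(row["locus"], IsomirKind.EDIT_AI,
                                (row["shift5"], lt.edit_site - row["shift5"]))
                expected_edit[key] += row["count"]
            if outcome[0] == "nta":
                base = {"A": "A", "T": "U", "C": "C", "G": "G"}[row["tail"][0]]
                key = IsomiRKey(row["locus"], IsomirKind[f"NTA_{base}"], (outcome[1],))
                expected_nta[key] += row["count"]
        observed_edit = {k: c for k, c in sc.key_counts.items()
                         if k.kind == IsomirKind.EDIT_AI}
        assert observed_edit == dict(expected_edit)
        observed_nta = {k: c for k, c in sc.key_counts.items() if "NTA" in k.kind.value}
        assert observed_nta == dict(expected_nta)
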