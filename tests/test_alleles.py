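"""Major/minor ranking, edit summaries, minor-SV classification."""

import numpy as np
import pandas as pd
from hypothesis import given, settings, strategies as st

from nemabar.alleles import (
    AMBIGUOUS,
    POLYMORPHIC,
    SECOND_NEMATODE,
    build_isolate_profiles,
    classify_minor,
    edit_distance_and_summary,
    flag_ambiguous_isolates,
    rank_svs,
)

from oracles import levenshtein_dp


def sv_row(sample="s1", sv="svX", region=1, count=100, seq="ACGT",
           phylum="Nematoda", order="Dorylaimida"):
    return pd.Series({"sample_id": sample, "sv_id": sv, "region": region,
                      "count": count, "sequence": seq, "phylum": phylum,
                      "order": order})


class TestEditSummary:
    def test_single_substitution(self):
        d, s = edit_distance_and_summary("AAAA", "AAGA")
        assert (d, s) == (1, "A/G")

    def test_grouped_substitutions(self):
        d, s = edit_distance_and_summary("ATATATAT", "ACACACAC")
        assert (d, s) == (4, "T/C (4 sites)")

    def test_insertion(self):
        d, s = edit_distance_and_summary("AACCTTAA", "AACCGGTTAA")
        assert d == 2 and "GG insertion" in s

    def test_deletion(self):
        d, s = edit_distance_and_summary("AACCTT", "AACTT")
        assert (d, s) == (1, "C deletion")

    def test_substitution_plus_insertion(self):
        # one substitution plus a two-base insertion: distance 3, with both
        # event kinds named (the exact alignment decomposition may vary)
        d, s = edit_distance_and_summary("TTTTCCCCAAAA", "TTTTCCCCAAGGAT")
        assert d == 3
        assert "insertion" in s and "/" in s

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_distance_matches_dp_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a = "".join("ACGT"[i] for i in rng.integers(0, 4, size=60))
        b = list(a)
        for _ in range(rng.integers(0, 6)):
            op = rng.integers(3)
            pos = rng.integers(len(b))
            if op == 0:
                b[pos] = "ACGT"[rng.integers(4)]
            elif op == 1:
                b.insert(pos, "ACGT"[rng.integers(4)])
            elif len(b) > 1:
                b.pop(pos)
        b = "".join(b)
        assert edit_distance_and_summary(a, b)[0] == levenshtein_dp(a, b)


class TestRankSvs:
    def _table(self):
        return pd.DataFrame([
            ("s1", "svA", 1, 7000, "AAAA", "Nematoda", "Dorylaimida"),
            ("s1", "svB", 1, 2500, "CCCC", "Nematoda", "Dorylaimida"),
            ("s1", "svC", 1, 40, "GGGG", "Nematoda", "Dorylaimida"),
            ("s1", "svD", 1, 460, "TTTT", "Ascomycota", "NA"),
        ], columns=["sample_id", "sv_id", "region", "count",
                    "sequence", "phylum", "order"])

    def test_major_and_floor(self):
        major, minors = rank_svs(self._table(), "s1")
        assert major["sv_id"] == "svA"
        # svB is 2500/9540 of the nematode fraction (> 7%); svC is below
        assert minors["sv_id"].tolist() == ["svB"]

    def test_single_sv_no_minors(self):
        t = self._table().iloc[[0]]
        major, minors = rank_svs(t, "s1")
        assert major["sv_id"] == "svA" and minors.empty

    def test_no_nematode_sv_absent(self):
        t = self._table().iloc[[3]]
        major, minors = rank_svs(t, "s1")
        assert major is None

    def test_count_tie_broken_by_sequence(self):
        t = self._table().copy()
        t.loc[t.sv_id == "svB", "count"] = 7000
        major, _ = rank_svs(t, "s1")
        assert major["sv_id"] == "svA"  # "AAAA" < "CCCC"


class TestClassifyMinor:
    def test_one_mismatch_same_order_is_allele(self):
        major = sv_row(sv="R1_SV_3", seq="GGATACGGA")
        minor = sv_row(sv="R1_SV_12", seq="GGATGCGGA")
        call = classify_minor(major, minor, n_cooccurring=11)
        assert call.classification == POLYMORPHIC
        assert call.edit_distance == 1 and call.edit_summary == "A/G"
        assert call.n_cooccurring_samples == 11

    def test_substitution_plus_insertion_still_allele(self):
        major = sv_row(seq="TTTTCCCCAAAA")
        minor = sv_row(sv="svM", seq="TTTTCCCCAAGGAT")
        call = classify_minor(major, minor)
        assert call.classification == POLYMORPHIC and call.edit_distance == 3

    def test_order_mismatch_is_second_nematode(self):
        major = sv_row(order="Dorylaimida", seq="AAAA")
        minor = sv_row(sv="svM", order="Rhabditida", seq="AAAT")
        assert classify_minor(major, minor).classification == SECOND_NEMATODE

    def test_distant_same_order_is_ambiguous(self):
        major = sv_row(seq="A" * 30)
        minor = sv_row(sv="svM", seq="G" * 30)
        assert classify_minor(major, minor).classification == AMBIGUOUS

    def test_single_sample_allele_allowed(self):
        major = sv_row(seq="AAAA")
        minor = sv_row(sv="svM", seq="AATA")
        call = classify_minor(major, minor, n_cooccurring=1)
        assert call.classification == POLYMORPHIC

    def test_symmetric_consistency(self):
        # swapping which of an allele pair is major never yields second_nematode
        a, b = "GGATACGGA", "GGATGCGGA"
        first = classify_minor(sv_row(sv="x", seq=a), sv_row(sv="y", seq=b))
        second = classify_minor(sv_row(sv="y", seq=b), sv_row(sv="x", seq=a))
        assert first.classification == second.classification == POLYMORPHIC


def _profile_tables(rows):
    df = pd.DataFrame(rows, columns=["sample_id", "sv_id", "region", "count",
                                     "sequence", "phylum", "order"])
    return {1: df}, {1: sorted(set(df["sample_id"]))}


class TestFlagAmbiguous:
    def test_three_distant_same_order_svs_excluded(self):
        base = "A" * 20
        far1 = "C" * 10 + "A" * 10
        far2 = "G" * 10 + "A" * 10
        tables, retained = _profile_tables([
            ("id14", "sv1", 1, 5000, base, "Nematoda", "Rhabditida"),
            ("id14", "sv2", 1, 3000, far1, "Nematoda", "Rhabditida"),
            ("id14", "sv3", 1, 2000, far2, "Nematoda", "Rhabditida"),
        ])
        profiles = build_isolate_profiles(tables, retained)
        assert flag_ambiguous_isolates(profiles) == ["id14"]

    def test_clean_allele_pair_retained(self):
        tables, retained = _profile_tables([
            ("s1", "sv1", 1, 7000, "AAAAAAAA", "Nematoda", "Rhabditida"),
            ("s1", "sv2", 1, 3000, "AAAATAAA", "Nematoda", "Rhabditida"),
        ])
        profiles = build_isolate_profiles(tables, retained)
        assert flag_ambiguous_isolates(profiles) == []
        assert profiles[0].calls[0].classification == POLYMORPHIC

    def test_two_order_sample_kept_with_flag(self):
        tables, retained = _profile_tables([
            ("s1", "sv1", 1, 7000, "A" * 20, "Nematoda", "Dorylaimida"),
            ("s1", "sv2", 1, 3000, "C" * 20, "Nematoda", "Rhabditida"),
        ])
        profiles = build_isolate_profiles(tables, retained)
        assert flag_ambiguous_isolates(profiles) == []
        assert profiles[0].multi_nematode


class TestSyntheticRecovery:
    def test_allele_sensitivity_and_specificity(self, pipeline_bundle):
        _, _, bundle = pipeline_bundle
        truth = bundle["truth"]
        retained = {p.sample_id for p in bundle["profiles"]}
        tp = truth.allele_pairs
        tp = tp[tp["sample_id"].isin(retained)]
        truth_set = set(map(tuple, tp[["sample_id", "region", "major_sv",
                                       "minor_sv"]].values))
        calls = bundle["allele_calls"]
        poly = calls[calls["classification"] == POLYMORPHIC]
        call_set = set(map(tuple, poly[["sample_id", "region", "major_sv",
                                        "minor_sv"]].values))
        assert truth_set, "expected polymorphic specimens at study scale"
        assert call_set == truth_set  # sensitivity = specificity = 1.0

    def test_second_nematode_count_matches_truth(self, pipeline_bundle):
        _, _, bundle = pipeline_bundle
        truth = bundle["truth"]
        retained = {p.sample_id for p in bundle["profiles"]}
        truth_multi = {s for s, c in truth.sample_class.items()
                       if c == "predation"} & retained
        called_multi = {p.sample_id for p in bundle["profiles"]
                        if p.multi_nematode}
        assert called_multi == truth_multi

    def test_major_sv_is_specimen_sequence(self, pipeline_bundle):
        _, _, bundle = pipeline_bundle
        truth = bundle["truth"]
        seqs = {rid: dict(zip(t["sv_id"], t["sequence"]))
                for rid, t in bundle["tables"].items()}
        for prof in bundle["profiles"]:
            species = truth.sample_species[prof.sample_id]
            hap = truth.specimen_seqs[species]
            for rid, sv in prof.majors.items():
                s, e = truth.region_coords[species][rid]
                assert seqs[rid][sv] == hap[s:e]
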