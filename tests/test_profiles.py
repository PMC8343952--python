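import pytest
from hypothesis import given, settings, strategies as st

from lineakit.profiles import (
    CoverageError,
    MtProfile,
    ProfileError,
    SeqRange,
    Variant,
    build_alignment_rows,
    parse_profile,
    parse_range_spec,
    parse_variant,
    profile_diff,
    profile_to_sequence,
    read_profile_table,
    restrict_profile,
    write_profile_table,
)

HV1 = SeqRange(16024, 16365)
HV2 = SeqRange(73, 340)


class TestParseVariant:
    @pytest.mark.parametrize(
        "token,kind,position,insert_index,base",
        [
            ("73G", "substitution", 73, None, "G"),
            ("73g", "substitution", 73, None, "G"),
            ("315.1C", "insertion", 315, 1, "C"),
            ("315.2c", "insertion", 315, 2, "C"),
            ("249DEL", "deletion", 249, None, None),
            ("249del", "deletion", 249, None, None),
            ("249-", "deletion", 249, None, None),
            ("16365N", "substitution", 16365, None, "N"),
        ],
    )
    def test_grammar(self, token, kind, position, insert_index, base):
        v = parse_variant(token)
        assert (v.kind, v.position, v.insert_index, v.base) == (
            kind,
            position,
            insert_index,
            base,
        )

    @pytest.mark.parametrize(
        "token", ["", "G73", "73", "73GG", "0A", "16570A", "315.0C", "73X", "7 3G", "-73"]
    )
    def test_rejects_malformed(self, token):
        with pytest.raises(ProfileError):
            parse_variant(token)

    def test_error_names_token(self):
        with pytest.raises(ProfileError, match="73XX"):
            parse_variant("73XX")

    @given(
        st.integers(min_value=1, max_value=16569),
        st.sampled_from("ACGT"),
        st.one_of(st.none(), st.integers(min_value=1, max_value=5)),
    )
    @settings(max_examples=100, derandomize=True)
    def test_token_round_trip(self, pos, base, ins):
        tok = f"{pos}{base}" if ins is None else f"{pos}.{ins}{base}"
        assert parse_variant(tok).token() == tok

    @given(st.text(max_size=8))
    @settings(max_examples=300, derandomize=True)
    def test_random_text_parses_or_rejects_cleanly(self, text):
        """The parser accepts exactly the token grammar, raising cleanly otherwise."""
        try:
            v = parse_variant(text)
        except ProfileError:
            return
        assert v.position >= 1
        # anything accepted must regenerate an equivalent canonical token
        assert parse_variant(v.token()) == v


class TestParseProfile:
    def test_empty_profile_is_reference(self):
        p = parse_profile("S1 16024-16365;73-340")
        assert p.variants == ()
        assert p.coverage == (HV2, HV1)

    def test_two_variant_profile(self):
        p = parse_profile("S2 73-340 73G 263G")
        assert [v.token() for v in p.variants] == ["73G", "263G"]

    def test_variant_outside_range_rejected(self):
        with pytest.raises(ProfileError, match="16126C"):
            parse_profile("S3 73-340 16126C")

    def test_duplicate_position_rejected(self):
        with pytest.raises(ProfileError, match="263"):
            parse_profile("S4 73-340 263G 263DEL")

    def test_variants_sorted_regardless_of_input_order(self):
        p = parse_profile("S5 73-340 263G 73G 150.1T 150.2A")
        assert [v.token() for v in p.variants] == ["73G", "150.1T", "150.2A", "263G"]

    def test_range_spec_requires_start_le_end(self):
        with pytest.raises(ProfileError):
            parse_range_spec("340-73")


class TestProfileToSequence:
    def test_empty_profile_gives_reference_substring(self, reference):
        p = parse_profile("S1 73-340")
        assert profile_to_sequence(p, reference, SeqRange(73, 340)) == reference[72:340]

    def test_substitution_applied(self, reference):
        p = parse_profile("S2 73-340 73G")
        out = profile_to_sequence(p, reference, SeqRange(73, 75))
        assert out == "G" + reference[73:75]

    def test_deletion_becomes_gap(self, reference):
        p = parse_profile("S3 73-340 249DEL")
        out = profile_to_sequence(p, reference, SeqRange(248, 250))
        assert out == reference[247] + "-" + reference[249]

    def test_insertions_appended_in_index_order(self, reference):
        p = parse_profile("S4 73-340 315.2A 315.1C")
        out = profile_to_sequence(p, reference, SeqRange(315, 316))
        assert out == reference[314] + "CA" + reference[315]

    def test_window_outside_coverage_raises(self, reference):
        p = parse_profile("S5 73-340")
        with pytest.raises(CoverageError):
            profile_to_sequence(p, reference, SeqRange(16024, 16100))


class TestRestrict:
    def test_restrict_to_hv1_keeps_hv1_variants(self):
        p = parse_profile("S1 16024-16365;73-340 73G 263G 16126C")
        r = restrict_profile(p, [HV1])
        assert r.coverage == (HV1,)
        assert [v.token() for v in r.variants] == ["16126C"]

    def test_disjoint_window_flags_empty_coverage(self):
        p = parse_profile("S1 73-340 73G")
        r = restrict_profile(p, [SeqRange(16024, 16365)])
        assert r.is_empty
        assert r.variants == ()

    def test_idempotent(self):
        p = parse_profile("S1 16024-16365;73-340 73G 16126C")
        once = restrict_profile(p, [HV1])
        assert restrict_profile(once, [HV1]) == once

    def test_restriction_never_differs_from_original_inside_window(self):
        p = parse_profile("S1 16024-16365;73-340 73G 263G 16126C 16189DEL")
        r = restrict_profile(p, [HV1])
        _, count = profile_diff(p, r, [HV1])
        assert count == 0


class TestProfileDiff:
    def test_identity(self):
        p = parse_profile("S1 73-340 73G 263G")
        assert profile_diff(p, p, [HV2])[1] == 0

    def test_single_extra_variant(self):
        a = parse_profile("A 73-340 263G")
        b = parse_profile("B 73-340 263G 73G")
        diff, count = profile_diff(a, b, [HV2])
        assert count == 1
        assert {v.token() for v in diff} == {"73G"}

    def test_symmetric(self):
        a = parse_profile("A 73-340 263G 150.1C")
        b = parse_profile("B 73-340 73G 249DEL")
        assert profile_diff(a, b, [HV2]) == profile_diff(b, a, [HV2])

    def test_n_calls_are_not_differences(self):
        a = parse_profile("A 73-340 100N")
        b = parse_profile("B 73-340")
        assert profile_diff(a, b, [HV2])[1] == 0

    def test_uncovered_window_raises(self):
        a = parse_profile("A 73-340")
        b = parse_profile("B 16024-16365")
        with pytest.raises(CoverageError):
            profile_diff(a, b, [HV2])


class TestAlignmentRows:
    def test_shared_insertion_columns(self, reference):
        a = parse_profile("A 73-340 315.1C")
        b = parse_profile("B 73-340 73G")
        rows = dict(build_alignment_rows([a, b], reference, [SeqRange(73, 340)]))
        assert len(rows["A"]) == len(rows["B"]) == (340 - 73 + 1) + 1
        # the insertion column is gap-filled for the profile lacking it
        idx = 315 - 73 + 1  # column position of the inserted base
        assert rows["A"][idx] == "C"
        assert rows["B"][idx] == "-"


def test_profile_table_round_trip(tmp_path):
    profiles = [
        parse_profile("S1 16024-16365;73-340 73G 263G 315.1C"),
        parse_profile("S2 73-340"),
        parse_profile("S3 16024-16365 16189DEL"),
    ]
    path = tmp_path / "profiles.tsv"
    write_profile_table(path, profiles)
    assert read_profile_table(path) == profiles
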