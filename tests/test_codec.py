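"""Decode/encode/validate semantics, round trips, error locality, and
file decoding under the four scopes."""

import io

import pytest

import tfsl
from tfsl import codec
from tfsl.errors import DecodingError, EncodingError


class TestDecodeEncodeExamples:
    def test_roman_numeral_transformation(self, make_spec):
        dt = make_spec({"x": {"regexes": {"I": 1, "II": 2, "III": 3}}})["x"]
        assert dt.decode("III") == 3
        assert dt.encode(3) == "III"

    def test_symbol_to_word_map(self, make_spec):
        dt = make_spec({"x": {"values": ["D", "I"],
                              "decoded": {"D": "deletion",
                                          "I": "insertion"}}})["x"]
        assert dt.decode("D") == "deletion"
        assert dt.encode("insertion") == "I"

    def test_boolean_flags(self, make_spec):
        dt = make_spec({"x": {"values": ["T", "F"],
                              "decoded": {"T": True, "F": False}}})["x"]
        assert dt.decode("T") is True
        assert dt.encode(False) == "F"

    def test_ncbi_identifier_shapes(self, builtins):
        dt = builtins["ncbi_id"]["ncbi_id"]
        assert dt.decode("gi|21434723") == {"db_tag": "gi",
                                            "fields": ["21434723"]}
        value = dt.decode("sp|P01013|OVAX_CHICK")
        assert value["db_tag"] == "sp" and len(value["fields"]) == 2

    def test_empty_sequence_with_empty_text_rule(self, make_spec):
        dt = make_spec({"x": {"list_of": {"regex": "[a-z]+"},
                              "splitted_by": "\t", "min_length": 0}})["x"]
        assert dt.encode([]) == ""
        assert dt.decode("") == []

    def test_non_injective_map_encodes_first_listed_text(self, make_spec):
        dt = make_spec({"x": {"values": ["yes", "y"],
                              "decoded": {"yes": True, "y": True}}})["x"]
        assert dt.encode(True) == "yes"

    def test_canonical_rule_overrides_first_listed(self, make_spec):
        dt = make_spec({"x": {"values": ["yes", "y"],
                              "decoded": {"yes": True, "y": True},
                              "canonical": ["y"]}})["x"]
        assert dt.encode(True) == "y"

    def test_prefix_suffix_formatting(self, make_spec):
        dt = make_spec({"x": {"integer": {}, "prefix": "n=",
                              "suffix": ";"}})["x"]
        assert dt.decode("n=42;") == 42
        assert dt.encode(-3) == "n=-3;"

    def test_composed_trailing_optional_fields(self, make_spec):
        dt = make_spec({"x": {"composed_of": [
            {"a": {"regex": "[a-z]+"}}, {"b": {"integer": {}}}],
            "splitted_by": ":", "n_required": 1}})["x"]
        assert dt.decode("ab:3") == {"a": "ab", "b": 3}
        assert dt.decode("ab") == {"a": "ab"}
        assert dt.encode({"a": "ab"}) == "ab"
        with pytest.raises(EncodingError, match="absent"):
            dt.encode({"b": 3})

    def test_labeled_list(self, make_spec):
        dt = make_spec({"x": {"labeled_list": {"n": {"integer": {}},
                                               "s": {"regex": "[a-z]+"}},
                              "required": ["n"], "splitted_by": ";"}})["x"]
        assert dt.decode("n:3;s:ab") == {"n": 3, "s": "ab"}
        assert dt.decode("s:ab;n:3") == {"n": 3, "s": "ab"}
        assert not dt.is_valid_encoded("s:ab")          # required n missing
        assert dt.encode({"n": 1}) == "n:1"


class TestValidationConsistency:
    """is_valid_encoded must equal decode success, and is_valid_decoded
    encode success, over generated corpora of every builtin datatype."""

    def test_encoded_validation_equals_decode_success(self, builtins):
        checked = 0
        for name, spec in builtins.items():
            for dt_name in spec.datatype_names():
                dt = spec[dt_name]
                tests = dt.generate_examples(n_valid=5, n_invalid=3, seed=11)
                corpus = [t for t, _ in tests.valid] + tests.invalid_encoded
                for text in corpus:
                    try:
                        dt.decode(text)
                        decodes = True
                    except DecodingError:
                        decodes = False
                    assert dt.is_valid_encoded(text) == decodes, (dt_name, text)
                    checked += 1
        assert checked > 500

    def test_decoded_validation_equals_encode_success(self, builtins):
        for name, spec in builtins.items():
            for dt_name in spec.datatype_names():
                dt = spec[dt_name]
                tests = dt.generate_examples(n_valid=5, n_invalid=0, seed=13)
                for _, value in tests.valid:
                    try:
                        dt.encode(value)
                        encodes = True
                    except EncodingError:
                        encodes = False
                    assert dt.is_valid_decoded(value) == encodes, (dt_name, value)
                    assert encodes


class TestRoundTrips:
    def test_value_round_trip_is_exact(self, builtins):
        # decode(encode(v)) == v for generated valid values
        for name, spec in builtins.items():
            for dt_name in spec.datatype_names():
                dt = spec[dt_name]
                for text, value in dt.generate_examples(8, 0, seed=3).valid:
                    assert dt.decode(dt.encode(value)) == value, (dt_name, value)

    def test_text_round_trip_is_semantic(self, builtins):
        # encode(decode(t)) re-decodes to the same value as t
        for name, spec in builtins.items():
            for dt_name in spec.datatype_names():
                dt = spec[dt_name]
                for text, value in dt.generate_examples(8, 0, seed=5).valid:
                    assert dt.decode(dt.encode(dt.decode(text))) == value


class TestErrorLocality:
    @pytest.mark.parametrize("tree,text,offset", [
        ({"constant": "ACGT"}, "ACGA", 3),
        ({"constant": "ACGT"}, "XCGT", 0),
        ({"values": ["alpha", "beta"]}, "alZha", 2),
        ({"regex": "[a-z]+[0-9]+"}, "abc?", 3),
        ({"integer": {}, "prefix": "n="}, "m=4", 0),
        ({"list_of": {"regex": "[a-z]+"}, "splitted_by": ","}, "ab,C", 3),
    ])
    def test_reported_offset_is_the_first_impossible_character(
            self, make_spec, tree, text, offset):
        dt = make_spec({"x": tree})["x"]
        with pytest.raises(DecodingError) as exc:
            dt.decode(text)
        assert exc.value.offset == offset
        assert 0 <= exc.value.offset <= len(text)

    def test_error_names_the_failing_sub_definition(self, builtins):
        dt = builtins["egc"]["expectation_record"]
        with pytest.raises(DecodingError) as exc:
            dt.decode("E\ttax1\tattr\t~\t5")
        assert "operator" in exc.value.path


EGC_THREE_A_LINES = (
    "A\tgc_content\tGC content\tsequence_statistic\n"
    "A\tsize\tgenome size\t.\n"
    "A\ttrna\ttRNA count\tfeature_count\n")


class TestFileDecoding:
    def test_line_scope_yields_one_record_per_line(self, builtins):
        records = list(builtins["egc"]["line"].decode_file(
            io.StringIO(EGC_THREE_A_LINES)))
        assert len(records) == 3
        assert [r.value["id"] for r in records] == ["gc_content", "size",
                                                    "trna"]
        assert [r.source_span for r in records] == [(1, 1), (2, 2), (3, 3)]

    def test_comment_lines_decode_via_the_comment_alternative(self, builtins):
        text = "#x\n" + EGC_THREE_A_LINES
        records = list(builtins["egc"]["line"].decode_file(io.StringIO(text)))
        assert records[0].value == "#x"
        assert len(records) == 4

    def test_line_scope_error_carries_the_line_number(self, builtins):
        text = EGC_THREE_A_LINES + "Z\tbad\n"
        with pytest.raises(DecodingError) as exc:
            list(builtins["egc"]["line"].decode_file(io.StringIO(text)))
        assert exc.value.lineno == 4

    def test_unit_scope_groups_fixed_line_blocks(self, builtins):
        text = tfsl.generate_fixture("fastq", 5, seed=2)
        records = list(builtins["fastq"]["read"].decode_file(
            io.StringIO(text)))
        assert len(records) == 5
        assert records[0].source_span == (1, 4)

    def test_unit_scope_rejects_a_partial_trailing_unit(self, builtins):
        text = tfsl.generate_fixture("fastq", 2, seed=2)
        text += "@orphan\n"
        with pytest.raises(DecodingError, match="multiple"):
            list(builtins["fastq"]["read"].decode_file(io.StringIO(text)))

    def test_section_scope_spans_maximal_runs(self, make_spec):
        spec = make_spec({
            "hline": {"regex": "#[ -~]*"},
            "header": {"list_of": "$hline", "splitted_by": "\n",
                       "scope": "section"},
        })
        records = list(spec["header"].decode_file(
            io.StringIO("#a\n#b\n#c\n")))
        assert len(records) == 1
        assert records[0].value == ["#a", "#b", "#c"]

    def test_file_scope_requires_header_before_body(self, make_spec):
        spec = make_spec({
            "hline": {"regex": "@[ -~]*"},
            "bline": {"regex": "[a-z]+\\t[0-9]+"},
            "doc": {"composed_of": [
                {"header": {"list_of": "$hline", "splitted_by": "\n"}},
                {"body": {"list_of": "$bline", "splitted_by": "\n"}}],
                "splitted_by": "\n", "scope": "file"},
        })
        good = "@h1\n@h2\nab\t1\ncd\t2\n"
        (record,) = spec["doc"].decode_file(io.StringIO(good))
        assert record.value == {"header": ["@h1", "@h2"],
                                "body": ["ab\t1", "cd\t2"]}
        bad = "ab\t1\n@h1\n"
        with pytest.raises(DecodingError):
            list(spec["doc"].decode_file(io.StringIO(bad)))

    def test_streaming_matches_whole_file_decoding(self, builtins):
        text = tfsl.generate_fixture("egc", 300, seed=9)
        dt = builtins["egc"]["file"]
        (whole,) = dt.decode_file(io.StringIO(text))
        streamed = list(dt.decode_file(io.StringIO(text), streaming=True))
        assert [r.value for r in streamed] == whole.value
        spans = [r.source_span for r in streamed]
        assert spans == sorted(spans)

    def test_trailing_newline_is_optional(self, builtins):
        dt = builtins["egc"]["line"]
        with_nl = list(dt.decode_file(io.StringIO("#x\n")))
        without = list(dt.decode_file(io.StringIO("#x")))
        assert [r.value for r in with_nl] == [r.value for r in without]

    def test_windows_newlines_are_normalized(self, builtins, tmp_path):
        path = tmp_path / "crlf.egc"
        path.write_bytes(b"#a\r\n#b\r\n")
        records = list(builtins["egc"]["line"].decode_file(str(path)))
        assert [r.value for r in records] == ["#a", "#b"]

    def test_empty_file_decodes_to_zero_records(self, builtins):
        assert list(builtins["egc"]["line"].decode_file(io.StringIO(""))) == []
        (record,) = builtins["egc"]["file"].decode_file(io.StringIO(""))
        assert record.value == []


class TestScopeObject:
    def test_unit_size_is_tied_to_unit_scope(self):
        with pytest.raises(ValueError):
            codec.Scope("line", 4)
        with pytest.raises(ValueError):
            codec.Scope("unit")
        with pytest.raises(ValueError):
            codec.Scope("banana")
        assert codec.Scope("unit", 4).unit_size == 4
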