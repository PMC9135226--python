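"""Builtin specifications and the deterministic fixture generator."""

import io

import pytest

import tfsl
from tfsl import generate_fixture


class TestBuiltinSpecs:
    @pytest.mark.parametrize("name", tfsl.BUILTIN_NAMES)
    def test_loads_and_passes_its_embedded_testdata(self, builtins, name):
        spec = builtins[name]
        assert spec.datatype_names()
        report = spec.test()
        assert report.total > 0
        assert report.ok(), [str(f) for f in report.failures]

    def test_unknown_builtin_name(self):
        with pytest.raises(KeyError):
            tfsl.load_builtin("nonesuch")


# the printed example identifier of every NCBI database tag
NCBI_EXAMPLES = [
    "ref|NM_010450.1", "gb|M73307|AGMA13GT", "tpg|BK003456|",
    "emb|CAM43271.1|", "tpe|BN000123|", "dbj|BAC85684.1", "tpd|FAA00017|",
    "sp|P01013|OVAX_CHICK", "tr|Q90RT2|Q90RT2_9HIV1", "pir||G36364",
    "pdb|1I4L|D", "prf||0806162C", "pat|US|RE33188|1", "pgp|EP|0238993|7",
    "gnl|taxon|9606", "lcl|hnm271", "bbs|316342", "bbm|464147",
    "gim|442187", "gi|21434723", "gpp|GPC_123456789", "nat|AT_123456789.1|",
]


class TestNcbiIdentifiers:
    @pytest.mark.parametrize("example", NCBI_EXAMPLES)
    def test_every_documented_example_decodes(self, builtins, example):
        value = builtins["ncbi_id"]["ncbi_id"].decode(example)
        assert value["db_tag"] == example.split("|", 1)[0]
        assert isinstance(value["fields"], list)

    @pytest.mark.parametrize("example", NCBI_EXAMPLES)
    def test_mutated_identifiers_are_rejected(self, builtins, example):
        dt = builtins["ncbi_id"]["ncbi_id"]
        unknown_tag = "q" + example        # tag outside the documented set
        broken_pipe = example.replace("|", ";", 1)
        assert not dt.is_valid_encoded(unknown_tag)
        assert not dt.is_valid_encoded(broken_pipe)

    def test_decode_encode_round_trip_preserves_every_example(self, builtins):
        dt = builtins["ncbi_id"]["ncbi_id"]
        for example in NCBI_EXAMPLES:
            assert dt.encode(dt.decode(example)) == example


class TestEgcStructuralRules:
    def test_comment_lines(self, builtins):
        dt = builtins["egc"]["line"]
        assert dt.decode("# free text") == "# free text"
        assert not dt.is_valid_encoded("no comment")

    def test_tab_separation_is_mandatory(self, builtins):
        dt = builtins["egc"]["line"]
        assert dt.is_valid_encoded("P\tp1\tthermophilic")
        assert not dt.is_valid_encoded("P p1 thermophilic")

    def test_exactly_four_record_types(self, builtins):
        dt = builtins["egc"]["line"]
        for rt in "ATPE":
            assert any(dt.is_valid_encoded(line) for line in [
                f"{rt}\tid1\tname x\t.",
                f"{rt}\tid1\tname x",
                f"{rt}\tid1\tid2\t>\t5",
            ]), rt
        assert not dt.is_valid_encoded("X\tid1\tname x\t.")

    def test_missing_value_marker_decodes_to_null(self, builtins):
        dt = builtins["egc"]["line"]
        value = dt.decode("T\ttax1\tBacteria\t.")
        assert value["rank"] is None
        assert dt.encode(value).endswith("\t.")

    def test_positional_fields_cannot_be_empty(self, builtins):
        dt = builtins["egc"]["line"]
        assert not dt.is_valid_encoded("A\t\tname\t.")
        assert not dt.is_valid_encoded("A\tid\t\t.")

    def test_numeric_expected_values_decode_as_numbers(self, builtins):
        dt = builtins["egc"]["line"]
        assert dt.decode("E\ts\ta\t>\t40")["value"] == 40
        assert dt.decode("E\ts\ta\t>=\t0.4")["value"] == 0.4
        assert dt.decode("E\ts\ta\t=\thigh")["value"] == "high"


class TestFixtureGenerator:
    def test_zero_records_is_an_empty_file(self):
        assert generate_fixture("egc", 0, 0) == ""
        records = list(tfsl.Specification.builtin("egc")["line"]
                       .decode_file(io.StringIO("")))
        assert records == []

    def test_unknown_format_name(self):
        with pytest.raises(ValueError, match="unknown fixture format"):
            generate_fixture("genbank", 1, 0)

    def test_generation_is_deterministic(self):
        assert generate_fixture("egc", 30, 5) == generate_fixture("egc", 30, 5)
        assert generate_fixture("egc", 30, 5) != generate_fixture("egc", 30, 6)

    def test_egc_decode_counts_match_the_internal_tally(self, builtins):
        text, counts = generate_fixture("egc", 100, 1, return_counts=True)
        records = list(builtins["egc"]["line"].decode_file(io.StringIO(text)))
        observed = {"A": 0, "T": 0, "P": 0, "E": 0, "comment": 0}
        for record in records:
            if isinstance(record.value, str):
                observed["comment"] += 1
            else:
                observed[record.value["record_type"]] += 1
        assert observed == counts
        assert sum(v for k, v in counts.items() if k != "comment") == 100

    def test_fastq_fixture_structure(self, builtins):
        text = generate_fixture("fastq", 10, 2)
        lines = text.splitlines()
        assert len(lines) == 40
        records = list(builtins["fastq"]["read"].decode_file(
            io.StringIO(text)))
        assert len(records) == 10
        for record in records:
            assert len(record.value["quality"]) \
                == len(record.value["sequence"])

    def test_fasta_fixture_decodes_entry_by_entry(self, builtins):
        text, counts = generate_fixture("fasta", 12, 3, return_counts=True)
        (whole,) = builtins["fasta"]["file"].decode_file(io.StringIO(text))
        assert len(whole.value) == counts["entries"] == 12
        for entry in whole.value:
            assert entry["header"]["id"].startswith("seq_")
            assert entry["sequence"]

    def test_gfa_fixture_decodes_fully(self, builtins):
        text, counts = generate_fixture("gfa", 40, 4, return_counts=True)
        records = list(builtins["gfa"]["line"].decode_file(io.StringIO(text)))
        observed = {"H": 0, "S": 0, "L": 0}
        for record in records:
            observed[record.value["record_type"]] += 1
        assert observed == counts


class TestOverrideRepair:
    """Import-with-override: accept a corrupted file, re-emit it corrected."""

    def test_patched_spec_accepts_and_original_reencodes(self, builtins):
        patched = tfsl.Specification({
            "include": [{"path": tfsl.builtin_spec_path("gfa"),
                         "override": {"tags": {"code_aliases": {"z": "Z"}}}}],
            "datatypes": {}})
        bad = "S\ts1\t*\txx:z:hello world"
        assert not builtins["gfa"]["line"].is_valid_encoded(bad)
        value = patched["gfa::line"].decode(bad)
        assert value["tags"]["xx"] == {"type": "Z", "value": "hello world"}
        fixed = builtins["gfa"]["line"].encode(value)
        assert fixed == "S\ts1\t*\txx:Z:hello world"
        assert builtins["gfa"]["line"].is_valid_encoded(fixed)

    def test_literal_code_map_extension_also_accepts(self, builtins):
        patched = tfsl.Specification({
            "include": [{"path": tfsl.builtin_spec_path("gfa"),
                         "override": {"tags": {"tagged_list.z":
                                               "$tag_value_Z"}}}],
            "datatypes": {}})
        bad = "S\ts1\t*\txx:z:hello"
        value = patched["gfa::line"].decode(bad)
        assert value["tags"]["xx"]["type"] == "z"

    def test_sequence_override_accepts_empty_sequences(self, builtins):
        patched = tfsl.Specification({
            "include": [{"path": tfsl.builtin_spec_path("gfa"),
                         "override": {"sequence":
                                      {"one_of.1": {"regex":
                                                    "[A-Za-z=.]*"}}}}],
            "datatypes": {}})
        bad = "S\ts1\t"
        assert patched["gfa::line"].is_valid_encoded(bad)
        assert not builtins["gfa"]["line"].is_valid_encoded(bad)
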