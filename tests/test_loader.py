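"""Specification loading: includes, namespaces, overrides, reference
resolution, and precompiled archives."""

import json

import pytest

import tfsl
from tfsl import load_compiled, load_specification, save_compiled
from tfsl.errors import (CircularReferenceError, CorruptArchiveError,
                        IncludeCycleError, IncludeError, SpecSyntaxError,
                        UnresolvedReferenceError, VersionMismatchError)


class TestBasicLoading:
    def test_minimal_document(self):
        spec = load_specification({"datatypes": {"x": {"constant": "A"}}})
        assert spec.datatype_names() == ["x"]

    def test_yaml_text_and_json_text(self):
        yaml_text = "datatypes:\n  x:\n    constant: A\n"
        json_text = '{"datatypes": {"x": {"constant": "A"}}}'
        assert load_specification(yaml_text).datatype_names() == ["x"]
        assert load_specification(json_text).datatype_names() == ["x"]

    def test_unknown_section_is_rejected(self):
        with pytest.raises(SpecSyntaxError, match="unknown section"):
            load_specification({"datatypez": {}})

    def test_invalid_datatype_name_is_rejected(self):
        with pytest.raises(SpecSyntaxError, match="invalid datatype name"):
            load_specification({"datatypes": {"3x": "A"}})

    def test_unresolved_reference(self):
        with pytest.raises(UnresolvedReferenceError, match="ghost"):
            load_specification({"datatypes": {"x": {"list_of": "$ghost"}}})

    def test_circular_reference_names_the_cycle(self):
        with pytest.raises(CircularReferenceError) as exc:
            load_specification({"datatypes": {
                "a": {"list_of": "$b", "splitted_by": ","},
                "b": {"list_of": "$a", "splitted_by": ";"}}})
        cycle = exc.value.cycle
        assert cycle[0] == cycle[-1] and set(cycle) == {"a", "b"}

    def test_spec_errors_report_each_bad_datatype(self):
        with pytest.raises(SpecSyntaxError) as exc:
            load_specification({"datatypes": {
                "good": "A",
                "bad1": {"integer": {"min": 2, "max": 1}},
                "bad2": {"one_of": ["$good"]}}})
        paths = {d.path[0] for d in exc.value.diagnostics}
        assert paths == {"bad1", "bad2"}


class TestIncludes:
    def _write(self, tmp_path, name, doc):
        import yaml
        path = tmp_path / name
        path.write_text(yaml.safe_dump(doc))
        return str(path)

    def test_namespace_prefixes_imported_names(self, tmp_path):
        self._write(tmp_path, "inner.yaml", {
            "namespace": "gfa",
            "datatypes": {"tag": {"regex": "[A-Z]+"},
                          "taglist": {"list_of": "$tag",
                                      "splitted_by": ","}}})
        spec = load_specification(self._write(tmp_path, "outer.yaml", {
            "include": ["inner.yaml"],
            "datatypes": {"mine": {"list_of": "$gfa::tag",
                                   "splitted_by": ";"}}}))
        assert "gfa::tag" in spec.table and "gfa::taglist" in spec.table
        # references inside the imported file were re-qualified
        eng = spec.engine
        from tfsl import codec
        assert codec.decode("AB,CD", spec["gfa::taglist"], eng) == ["AB", "CD"]
        assert codec.decode("AB;CD", spec["mine"], eng) == ["AB", "CD"]

    def test_whitelist_imports_only_named_datatypes(self, tmp_path):
        self._write(tmp_path, "inner.yaml", {
            "datatypes": {"x": {"constant": "X"}, "y": {"constant": "Y"}}})
        spec = load_specification(self._write(tmp_path, "outer.yaml", {
            "include": [{"path": "inner.yaml", "names": ["x"]}],
            "datatypes": {}}))
        assert "x" in spec.table and "y" not in spec.table

    def test_whitelist_pulls_dependencies(self, tmp_path):
        self._write(tmp_path, "inner.yaml", {
            "datatypes": {"x": {"list_of": "$dep", "splitted_by": ","},
                          "dep": {"constant": "D"},
                          "unrelated": {"constant": "U"}}})
        spec = load_specification(self._write(tmp_path, "outer.yaml", {
            "include": [{"path": "inner.yaml", "names": ["x"]}],
            "datatypes": {}}))
        assert set(spec.table) == {"x", "dep"}

    def test_include_cycle_is_detected(self, tmp_path):
        self._write(tmp_path, "a.yaml", {"include": ["b.yaml"],
                                         "datatypes": {}})
        self._write(tmp_path, "b.yaml", {"include": ["a.yaml"],
                                         "datatypes": {}})
        with pytest.raises(IncludeCycleError):
            load_specification(str(tmp_path / "a.yaml"))

    def test_include_is_idempotent_through_a_diamond(self, tmp_path):
        self._write(tmp_path, "base.yaml", {
            "namespace": "base", "datatypes": {"t": {"constant": "T"}}})
        self._write(tmp_path, "left.yaml", {"include": ["base.yaml"],
                                            "datatypes": {}})
        self._write(tmp_path, "right.yaml", {"include": ["base.yaml"],
                                             "datatypes": {}})
        spec = load_specification(self._write(tmp_path, "top.yaml", {
            "include": ["left.yaml", "right.yaml"], "datatypes": {}}))
        assert spec.datatype_names() == ["base::t"]

    def test_name_collision_without_namespace_is_an_error(self, tmp_path):
        self._write(tmp_path, "inner.yaml", {
            "datatypes": {"x": {"constant": "X"}}})
        with pytest.raises(IncludeError, match="collision"):
            load_specification(self._write(tmp_path, "outer.yaml", {
                "include": ["inner.yaml"],
                "datatypes": {"x": {"constant": "DIFFERENT"}}}))

    def test_missing_include_file(self, tmp_path):
        with pytest.raises(IncludeError, match="cannot read"):
            load_specification(self._write(tmp_path, "outer.yaml", {
                "include": ["nothing.yaml"], "datatypes": {}}))

    def test_override_replaces_an_addressed_subtree(self, tmp_path):
        self._write(tmp_path, "inner.yaml", {
            "datatypes": {"num": {"integer": {"min": 0, "max": 10}}}})
        spec = load_specification(self._write(tmp_path, "outer.yaml", {
            "include": [{"path": "inner.yaml",
                         "override": {"num": {"integer.max": 99}}}],
            "datatypes": {}}))
        from tfsl import codec
        assert codec.is_valid_encoded("42", spec["num"], spec.engine)

    def test_override_can_extend_a_mapping(self, tmp_path):
        # the repair idiom: add a type code that the original spec lacks
        self._write(tmp_path, "inner.yaml", {
            "datatypes": {"tags": {"tagged_list": {"Z": {"regex": "[a-z]+"}},
                                   "splitted_by": "\t"}}})
        spec = load_specification(self._write(tmp_path, "outer.yaml", {
            "include": [{"path": "inner.yaml",
                         "override": {"tags": {"tagged_list.z":
                                               {"regex": "[a-z]+"}}}}],
            "datatypes": {}}))
        from tfsl import codec
        assert codec.is_valid_encoded("ab:z:xy", spec["tags"], spec.engine)

    def test_override_with_a_dangling_path_is_an_error(self, tmp_path):
        self._write(tmp_path, "inner.yaml", {
            "datatypes": {"num": {"integer": {}}}})
        with pytest.raises(IncludeError, match="override path"):
            load_specification(self._write(tmp_path, "outer.yaml", {
                "include": [{"path": "inner.yaml",
                             "override": {"num": {"float.max.x": 1}}}],
                "datatypes": {}}))

    def test_override_of_an_unknown_datatype_is_an_error(self, tmp_path):
        self._write(tmp_path, "inner.yaml", {"datatypes": {}})
        with pytest.raises(IncludeError, match="override target"):
            load_specification(self._write(tmp_path, "outer.yaml", {
                "include": [{"path": "inner.yaml",
                             "override": {"ghost": {"integer.max": 1}}}],
                "datatypes": {}}))


class TestPrecompiledArchives:
    def test_round_trip_preserves_the_datatype_list(self, builtins, tmp_path):
        path = tmp_path / "egc.tfc"
        save_compiled(builtins["egc"].compiled, path)
        loaded = load_compiled(path)
        assert loaded.datatype_names() == builtins["egc"].datatype_names()

    def test_round_trip_preserves_decode_behaviour(self, builtins, tmp_path):
        from tfsl import codec
        path = tmp_path / "egc.tfc"
        save_compiled(builtins["egc"].compiled, path)
        loaded = load_compiled(path)
        line = "E\ttax1\tgc_content\t>=\t0.4"
        assert (codec.decode(line, loaded["line"], loaded.engine)
                == builtins["egc"]["line"].decode(line))

    def test_round_trip_preserves_scopes_and_testdata(self, builtins,
                                                      tmp_path):
        path = tmp_path / "fastq.tfc"
        save_compiled(builtins["fastq"].compiled, path)
        loaded = load_compiled(path)
        assert loaded["read"].scope == "unit"
        assert loaded["read"].unit_size == 4
        report = tfsl.run_testdata(loaded, loaded.testdata)
        assert report.ok() and report.total > 0

    def test_truncated_archive_is_reported_corrupt(self, builtins, tmp_path):
        path = tmp_path / "x.tfc"
        save_compiled(builtins["egc"].compiled, path)
        data = path.read_text()
        path.write_text(data[:len(data) // 2])
        with pytest.raises(CorruptArchiveError):
            load_compiled(path)

    def test_json_that_is_not_an_archive_is_reported_corrupt(self, tmp_path):
        path = tmp_path / "x.tfc"
        path.write_text('{"unrelated": true}')
        with pytest.raises(CorruptArchiveError):
            load_compiled(path)

    def test_dialect_version_mismatch(self, builtins, tmp_path):
        path = tmp_path / "x.tfc"
        save_compiled(builtins["egc"].compiled, path)
        payload = json.loads(path.read_text())
        payload["dialect_version"] = "999"
        path.write_text(json.dumps(payload))
        with pytest.raises(VersionMismatchError):
            load_compiled(path)

    def test_load_specification_autodetects_archives(self, builtins,
                                                     tmp_path):
        path = tmp_path / "egc.tfc"
        save_compiled(builtins["egc"].compiled, path)
        spec = load_specification(str(path))
        assert spec.datatype_names() == builtins["egc"].datatype_names()

    def test_archived_and_source_specs_agree_on_random_inputs(self, builtins,
                                                              tmp_path):
        from tfsl import codec, testkit
        path = tmp_path / "ncbi.tfc"
        save_compiled(builtins["ncbi_id"].compiled, path)
        loaded = load_compiled(path)
        src = builtins["ncbi_id"].compiled
        checked = 0
        for name in src.datatype_names():
            tests = tfsl.generate_examples(src.table[name], 5, 5, 41,
                                           src.engine)
            corpus = [t for t, _ in tests.valid] + tests.invalid_encoded
            for text in corpus:
                a = codec.is_valid_encoded(text, src.table[name], src.engine)
                b = codec.is_valid_encoded(text, loaded.table[name],
                                           loaded.engine)
                assert a == b
                if a:
                    assert (codec.decode(text, src.table[name], src.engine)
                            == codec.decode(text, loaded.table[name],
                                            loaded.engine))
                checked += 1
        assert checked >= 200
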