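"""Loading of specification documents.

A specification document (YAML 1.2 or JSON) has up to four sections:

``datatypes``
    name -> datatype definition tree (the only mandatory section);
``testdata``
    name -> valid/invalid examples, executed by the test kit;
``include``
    imports from other specification files — a list of entries, each a
    path or a mapping ``{path, names, override}`` where ``names`` restricts
    the import to the listed datatypes (plus their dependencies) and
    ``override`` rewrites addressed sub-components of imported definitions;
``namespace``
    a prefix (joined with ``::``) applied to this file's datatype names
    when they are exported to an including specification.

Loading resolves includes recursively, validates and normalizes every
definition, builds the dependency graph of datatype references, rejects
cycles, and compiles a matcher for every datatype.  The result — the
resolved name -> definition hash table with attached matchers — can be
serialized to a versioned archive and reloaded without re-resolution.
"""

from __future__ import annotations

import copy
import json
import os
from dataclasses import dataclass, field

import yaml

from .compiler import Engine
from .errors import (CorruptArchiveError, DocumentSyntaxError, IncludeCycleError,
                     IncludeError, SpecSyntaxError, UnresolvedReferenceError,
                     VersionMismatchError)
from .graph import DependencyGraph, check_acyclic
from .model import (NAME_RE, REFERENCE_SIGIL, DatatypeDefinition,
                    normalize_definition, validate_definition_tree)

DIALECT_VERSION = "1"
ARCHIVE_TAG = "tfsl-compiled"

_SECTIONS = {"datatypes", "testdata", "include", "namespace"}


@dataclass
class IncludeItem:
    path: str
    names: list | None = None
    override: dict | None = None


@dataclass
class SpecSource:
    """A parsed but unresolved specification document."""

    datatypes: dict = field(default_factory=dict)
    testdata: dict = field(default_factory=dict)
    includes: list = field(default_factory=list)
    namespace: str | None = None
    origin: str | None = None


class CompiledSpecification:
    """The resolved datatype table with compiled matchers.

    ``table`` maps every datatype name to its normalized definition; every
    reference in every definition resolves to a key of the table, and the
    dependency graph is acyclic.  ``engine`` holds the compiled expressions.
    """

    def __init__(self, table: dict[str, DatatypeDefinition], engine: Engine,
                 provenance: list[str], testdata: dict | None = None,
                 dialect_version: str = DIALECT_VERSION):
        self.table = table
        self.engine = engine
        self.provenance = provenance
        self.testdata = testdata or {}
        self.dialect_version = dialect_version

    def datatype_names(self) -> list[str]:
        return sorted(self.table)

    def __contains__(self, name: str) -> bool:
        return name in self.table

    def __getitem__(self, name: str) -> DatatypeDefinition:
        return self.table[name]


# ---------------------------------------------------------------------------
# document parsing
# ---------------------------------------------------------------------------

def parse_document(text: str, origin: str | None = None):
    """Parse YAML or JSON text into a document tree.

    JSON is attempted first when the extension or the leading character
    suggests it; YAML 1.2 is the general case.
    """
    prefer_json = (origin is not None and origin.endswith(".json")) \
        or text.lstrip()[:1] in ("{", "[")
    if prefer_json:
        try:
            return json.loads(text)
        except json.JSONDecodeError:
            pass  # fall through to YAML (a superset for most documents)
    try:
        return yaml.safe_load(text)
    except yaml.YAMLError as exc:
        where = f" in {origin}" if origin else ""
        raise DocumentSyntaxError(f"document syntax error{where}: {exc}") \
            from exc


def parse_spec_source(tree, origin: str | None = None) -> SpecSource:
    """Validate the section structure of a document tree."""
    if tree is None:
        tree = {}
    if not isinstance(tree, dict):
        raise SpecSyntaxError("a specification document must be a mapping")
    unknown = set(tree) - _SECTIONS
    if unknown:
        raise SpecSyntaxError(
            "unknown section(s): " + ", ".join(sorted(unknown))
            + "; valid sections are " + ", ".join(sorted(_SECTIONS)))
    datatypes = tree.get("datatypes", {})
    if not isinstance(datatypes, dict):
        raise SpecSyntaxError("the datatypes section must be a mapping")
    for name in datatypes:
        if not isinstance(name, str) or not NAME_RE.fullmatch(name):
            raise SpecSyntaxError(f"invalid datatype name {name!r}")
    testdata = tree.get("testdata", {}) or {}
    if not isinstance(testdata, dict):
        raise SpecSyntaxError("the testdata section must be a mapping")
    namespace = tree.get("namespace")
    if namespace is not None and (not isinstance(namespace, str)
                                  or not NAME_RE.fullmatch(namespace)):
        raise SpecSyntaxError(f"invalid namespace {namespace!r}")
    includes = []
    for item in tree.get("include", []) or []:
        if isinstance(item, str):
            includes.append(IncludeItem(path=item))
        elif isinstance(item, dict):
            path = item.get("path") or item.get("file")
            if not isinstance(path, str):
                raise SpecSyntaxError("include entries need a 'path'")
            extra = set(item) - {"path", "file", "names", "override"}
            if extra:
                raise SpecSyntaxError(
                    "unknown include key(s): " + ", ".join(sorted(extra)))
            includes.append(IncludeItem(path=path,
                                        names=item.get("names"),
                                        override=item.get("override")))
        else:
            raise SpecSyntaxError("include entries must be paths or mappings")
    return SpecSource(datatypes=dict(datatypes), testdata=dict(testdata),
                      includes=includes, namespace=namespace, origin=origin)


# ---------------------------------------------------------------------------
# include resolution
# ---------------------------------------------------------------------------

def _tree_references(node):
    """All reference names occurring in a raw definition tree."""
    if isinstance(node, str):
        if node.startswith(REFERENCE_SIGIL):
            yield node[1:]
    elif isinstance(node, list):
        for item in node:
            yield from _tree_references(item)
    elif isinstance(node, dict):
        for v in node.values():
            yield from _tree_references(v)


def _rename_references(node, mapping: dict[str, str]):
    if isinstance(node, str) and node.startswith(REFERENCE_SIGIL):
        target = node[1:]
        return REFERENCE_SIGIL + mapping.get(target, target)
    if isinstance(node, list):
        return [_rename_references(v, mapping) for v in node]
    if isinstance(node, dict):
        return {k: _rename_references(v, mapping) for k, v in node.items()}
    return node


def _apply_override(tree, keypath: str, replacement, context: str):
    """Replace the sub-tree addressed by the dot-separated *keypath*.

    All components but the last must exist; the last may be new (so that an
    override can extend a mapping, e.g. add a type code)."""
    keys = keypath.split(".")
    node = tree
    for key in keys[:-1]:
        if isinstance(node, list):
            try:
                key = int(key)
                node = node[key]
                continue
            except (ValueError, IndexError):
                pass
        if not isinstance(node, dict) or key not in node:
            raise IncludeError(
                f"override path {keypath!r} not found in {context}")
        node = node[key]
    last = keys[-1]
    if isinstance(node, list):
        try:
            node[int(last)] = replacement
            return
        except (ValueError, IndexError):
            raise IncludeError(
                f"override path {keypath!r} not found in {context}") from None
    if not isinstance(node, dict):
        raise IncludeError(f"override path {keypath!r} not found in {context}")
    node[last] = replacement


def _dependency_closure(names, datatypes, context):
    wanted = list(names)
    seen = set()
    while wanted:
        name = wanted.pop()
        if name in seen:
            continue
        seen.add(name)
        if name not in datatypes:
            raise IncludeError(
                f"include list names unknown datatype {name!r} in {context}")
        wanted.extend(ref for ref in _tree_references(datatypes[name])
                      if ref not in seen)
    return seen


def _merge_datatypes(acc: dict, new: dict, context: str):
    for name, tree in new.items():
        if name in acc and acc[name] != tree:
            raise IncludeError(
                f"name collision for datatype {name!r} while including "
                f"{context}; use a namespace or an explicit override")
        acc.setdefault(name, tree)


def resolve_includes(source: SpecSource, loaded_stack: list[str] | None = None,
                     reader=None) -> SpecSource:
    """Merge all included specifications into *source*.

    Include paths are resolved relative to the including file's directory.
    Recursion follows nested includes; a file appearing twice on the loading
    stack is an include cycle.  Overrides are applied to the imported trees
    before namespacing; a declared namespace of the included file prefixes
    its datatype names (``ns::name``) and the references among them.
    """
    loaded_stack = list(loaded_stack or [])
    if source.origin:
        here = os.path.abspath(source.origin)
        if here not in loaded_stack:
            loaded_stack.append(here)
    merged: dict = {}
    for item in source.includes:
        base = os.path.dirname(os.path.abspath(source.origin)) \
            if source.origin else os.getcwd()
        inc_path = os.path.normpath(os.path.join(base, item.path))
        if inc_path in loaded_stack:
            raise IncludeCycleError(loaded_stack + [inc_path])
        if reader is not None:
            text = reader(inc_path)
        else:
            try:
                with open(inc_path, "r", encoding="utf-8") as fh:
                    text = fh.read()
            except OSError as exc:
                raise IncludeError(
                    f"cannot read included file {item.path!r}: {exc}") \
                    from exc
        inc_source = parse_spec_source(parse_document(text, inc_path),
                                       inc_path)
        inc_resolved = resolve_includes(inc_source,
                                        loaded_stack + [inc_path], reader)
        datatypes = {k: v for k, v in inc_resolved.datatypes.items()}
        for name, patches in (item.override or {}).items():
            if name not in datatypes:
                raise IncludeError(
                    f"override target {name!r} is not defined in {item.path}")
            if not isinstance(patches, dict):
                raise IncludeError("an override must map key paths to "
                                   "replacement trees")
            tree = copy.deepcopy(datatypes[name])
            for keypath, replacement in patches.items():
                _apply_override(tree, keypath, replacement,
                                f"datatype {name!r} of {item.path}")
            datatypes[name] = tree
        if item.names is not None:
            keep = _dependency_closure(item.names, datatypes, item.path)
            datatypes = {k: v for k, v in datatypes.items() if k in keep}
        if inc_resolved.namespace:
            ns = inc_resolved.namespace
            renames = {name: f"{ns}::{name}" for name in datatypes
                       if "::" not in name}
            datatypes = {renames.get(name, name):
                         _rename_references(tree, renames)
                         for name, tree in datatypes.items()}
        _merge_datatypes(merged, datatypes, item.path)
    _merge_datatypes(merged, source.datatypes, source.origin or "<inline>")
    return SpecSource(datatypes=merged, testdata=source.testdata,
                      includes=[], namespace=source.namespace,
                      origin=source.origin)


# ---------------------------------------------------------------------------
# building & archives
# ---------------------------------------------------------------------------

def build_specification(resolved: SpecSource) -> CompiledSpecification:
    diagnostics = []
    table: dict[str, DatatypeDefinition] = {}
    for name, tree in resolved.datatypes.items():
        diags = validate_definition_tree(tree, (name,))
        if diags:
            diagnostics.extend(diags)
        else:
            table[name] = normalize_definition(tree, name)
    if diagnostics:
        raise SpecSyntaxError("invalid specification", diagnostics)
    for name, defn in table.items():
        for ref in defn.references():
            if ref not in table:
                raise UnresolvedReferenceError(ref, name)
    check_acyclic(DependencyGraph.from_table(table))
    engine = Engine(table)
    for name in table:
        engine.matcher(table[name], name)   # compile eagerly, fail early
    return CompiledSpecification(
        table=table, engine=engine,
        provenance=[resolved.origin] if resolved.origin else [],
        testdata=resolved.testdata)


def load_specification(path_or_text) -> CompiledSpecification:
    """Load a specification from a file path, document text, or document
    tree; precompiled archives are recognized and loaded without
    re-resolution."""
    if isinstance(path_or_text, dict):
        return build_specification(
            resolve_includes(parse_spec_source(path_or_text)))
    if not isinstance(path_or_text, (str, os.PathLike)):
        raise TypeError("expected a path, document text, or document tree")
    text, origin = str(path_or_text), None
    if "\n" not in text and os.path.exists(text):
        origin = text
        with open(text, "r", encoding="utf-8") as fh:
            text = fh.read()
    stripped = text.lstrip()
    if stripped.startswith("{") and f'"{ARCHIVE_TAG}"' in stripped[:200]:
        return _load_compiled_text(text)
    source = parse_spec_source(parse_document(text, origin), origin)
    return build_specification(resolve_includes(source))


def save_compiled(spec: CompiledSpecification, path) -> None:
    """Serialize the resolved table to a versioned archive (JSON).

    Matchers are re-derived from the stored definition trees on load, which
    keeps the archive independent of the regular-expression engine."""
    payload = {
        ARCHIVE_TAG: True,
        "dialect_version": spec.dialect_version,
        "provenance": spec.provenance,
        "datatypes": {name: defn.to_tree()
                      for name, defn in spec.table.items()},
        "testdata": spec.testdata,
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, ensure_ascii=False)


def _load_compiled_text(text: str,
                        origin: str | None = None) -> CompiledSpecification:
    try:
        payload = json.loads(text)
    except json.JSONDecodeError as exc:
        raise CorruptArchiveError(f"corrupt archive: {exc}") from exc
    if not isinstance(payload, dict) or not payload.get(ARCHIVE_TAG) \
            or "datatypes" not in payload or "dialect_version" not in payload:
        raise CorruptArchiveError("corrupt archive: missing required keys")
    if payload["dialect_version"] != DIALECT_VERSION:
        raise VersionMismatchError(
            f"archive dialect version {payload['dialect_version']!r} does "
            f"not match this library's {DIALECT_VERSION!r}")
    source = SpecSource(datatypes=payload["datatypes"],
                        testdata=payload.get("testdata", {}),
                        origin=origin)
    spec = build_specification(source)
    spec.provenance = payload.get("provenance", [])
    return spec


def load_compiled(path) -> CompiledSpecification:
    """Load an archive written by :func:`save_compiled`."""
    try:
        with open(path, "r", encoding="utf-8") as fh:
            text = fh.read()
    except OSError as exc:
        raise CorruptArchiveError(f"cannot read archive: {exc}") from exc
    return _load_compiled_text(text, str(path))
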