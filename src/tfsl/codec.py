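"""Core operations: decode, encode, validate — on strings and files.

Decoding converts a text representation into the data it represents
(applying transformation rules); encoding writes a text representation for
suitable data, emitting the canonical form when several texts are valid.
Validation is available on both sides: ``is_valid_encoded`` asks whether a
text follows the definition, ``is_valid_decoded`` whether a value is
representable.  The two validations are by construction equivalent to
decode/encode success.

File decoding applies a definition to a whole file under one of four
scopes: one record per *line*, per fixed-size *unit* of lines, per maximal
*section* of matching lines, or one record for the entire *file*.  With
file scope, *streaming* emits the elements of the outermost compound one at
a time while the structural constraints (section order, required sections,
length bounds) are still enforced across the stream.
"""

from __future__ import annotations

import io
import json
import os
import re
from dataclasses import dataclass

from .compiler import (Engine, format_unsigned, parse_unsigned,
                       partial_match_prefix)
from .errors import DecodingError, EncodingError
from .model import DatatypeDefinition, Reference

_STRING_KINDS = ("constant", "values", "regex", "regexes")


@dataclass(frozen=True)
class Scope:
    """Which part of a file one record of the definition covers."""

    kind: str                    # line | unit | section | file
    unit_size: int | None = None

    def __post_init__(self):
        if self.kind not in ("line", "unit", "section", "file"):
            raise ValueError(f"unknown scope {self.kind!r}")
        if (self.kind == "unit") != (self.unit_size is not None):
            raise ValueError("unit_size is required iff scope is 'unit'")
        if self.unit_size is not None and self.unit_size < 1:
            raise ValueError("unit_size must be positive")


@dataclass
class DecodedRecord:
    """One decoded record of a file: the value, the (1-based, inclusive)
    span of source lines it covers, and the datatype that produced it."""

    value: object
    source_span: tuple
    datatype: str


def _vkey(value) -> str:
    """Hashable identity of a data value (mappings key-sorted)."""
    return json.dumps(value, sort_keys=True, ensure_ascii=False)


# ---------------------------------------------------------------------------
# string decoding
# ---------------------------------------------------------------------------

def decode(text: str, defn, engine: Engine, path: str = "", base: int = 0):
    """Decode *text* under *defn*, returning the represented data value.

    Raises :class:`DecodingError` (with the failing sub-definition path and
    a best-effort character offset) if the text is invalid.  *base* is the
    character offset of *text* within the enclosing representation, so that
    reported offsets are absolute.
    """
    defn = engine.resolve(defn, path or "?")
    path = path or defn.name
    if defn.has_empty and text == "":
        return _copy_value(defn.empty_value)
    core, base = _strip_affixes(text, defn, path, base)
    if defn.also_matches is not None \
            and re.fullmatch(defn.also_matches, core) is None:
        raise DecodingError(
            f"text does not satisfy the additional pattern "
            f"{defn.also_matches!r}", path=path, offset=base)
    value = _decode_core(core, defn, engine, path, base)
    return value


def _strip_affixes(text: str, defn, path: str, base: int):
    core = text
    if defn.prefix:
        if not text.startswith(defn.prefix):
            off = _common_prefix_len(text, defn.prefix)
            raise DecodingError(f"expected prefix {defn.prefix!r}",
                                path=path, offset=base + off)
        core, base = core[len(defn.prefix):], base + len(defn.prefix)
    if defn.suffix:
        if not core.endswith(defn.suffix) or len(core) < len(defn.suffix):
            raise DecodingError(f"expected suffix {defn.suffix!r}",
                                path=path, offset=base + len(core))
        core = core[:len(core) - len(defn.suffix)]
    return core, base


def _common_prefix_len(a: str, b: str) -> int:
    n = 0
    for x, y in zip(a, b):
        if x != y:
            break
        n += 1
    return n


def _copy_value(v):
    if isinstance(v, dict):
        return {k: _copy_value(x) for k, x in v.items()}
    if isinstance(v, list):
        return [_copy_value(x) for x in v]
    return v


def _apply_decoded_map(core: str, defn, default):
    if defn.decoded is not None and core in defn.decoded:
        return _copy_value(defn.decoded[core])
    return default


def _decode_core(core: str, defn, engine: Engine, path: str, base: int):
    kind, p = defn.kind, defn.params

    if kind == "constant":
        if core != p["text"]:
            raise DecodingError(
                f"expected the constant {p['text']!r}", path=path,
                offset=base + _common_prefix_len(core, p["text"]))
        return _apply_decoded_map(core, defn, core)

    if kind == "values":
        if core not in p["values"]:
            off = max((_common_prefix_len(core, v) for v in p["values"]),
                      default=0)
            raise DecodingError(
                f"{core!r} is not one of the permitted values",
                path=path, offset=base + off)
        return _apply_decoded_map(core, defn, core)

    if kind == "regex":
        if re.fullmatch(p["pattern"], core) is None:
            raise DecodingError(
                f"text does not match the pattern {p['pattern']!r}",
                path=path,
                offset=base + partial_match_prefix(p["pattern"], core))
        return _apply_decoded_map(core, defn, core)

    if kind == "regexes":
        for pat, mapped in zip(p["patterns"], p["decoded_by_pattern"]):
            if re.fullmatch(pat, core) is not None:
                if defn.decoded is not None and core in defn.decoded:
                    return _copy_value(defn.decoded[core])
                return _copy_value(mapped) if mapped is not None else core
        raise DecodingError(
            "text matches none of the patterns", path=path,
            offset=base + max((partial_match_prefix(pat, core)
                               for pat in p["patterns"]), default=0))

    if kind == "integer":
        if re.fullmatch(r"[-+]?[0-9]+", core) is None:
            raise DecodingError("not a base-10 integer numeral",
                                path=path, offset=base)
        v = int(core)
        _check_range(v, p.get("min"), p.get("max"), False, False, path)
        return v

    if kind == "unsigned_integer":
        from .compiler import UNSIGNED_SRC
        if re.fullmatch(UNSIGNED_SRC[p["base"]], core) is None:
            raise DecodingError(
                f"not a base-{p['base']} unsigned numeral",
                path=path, offset=base)
        v = parse_unsigned(core, p["base"])
        _check_range(v, p.get("min"), p.get("max"), False, False, path)
        return v

    if kind == "float":
        from .compiler import FLOAT_SRC
        if re.fullmatch(FLOAT_SRC, core) is None:
            raise DecodingError("not a floating-point numeral",
                                path=path, offset=base)
        v = float(core)
        _check_range(v, p.get("min"), p.get("max"),
                     p["min_excluded"], p["max_excluded"], path)
        return v

    if kind == "list_of":
        return _decode_list(core, defn, engine, path, base)

    if kind == "labeled_list":
        return _decode_labeled(core, defn, engine, path, base)

    if kind == "tagged_list":
        return _decode_tagged(core, defn, engine, path, base)

    if kind == "composed_of":
        return _decode_composed(core, defn, engine, path, base)

    if kind == "one_of":
        last_error = None
        for i, alt in enumerate(p["alternatives"]):
            alt_r = engine.resolve(alt, path)
            if engine.matcher(alt_r).regex.fullmatch(core) is None:
                continue
            try:
                return decode(core, alt_r, engine, f"{path}|{i}", base)
            except DecodingError as exc:
                last_error = exc
        if last_error is not None:
            raise last_error
        raise DecodingError("text matches none of the alternatives",
                            path=path, offset=base)

    raise AssertionError(kind)


def _check_range(v, lo, hi, lo_open, hi_open, path):
    if lo is not None and (v < lo or (lo_open and v == lo)):
        raise DecodingError(f"{v} is below the permitted interval", path=path)
    if hi is not None and (v > hi or (hi_open and v == hi)):
        raise DecodingError(f"{v} is above the permitted interval", path=path)


def _split_parts(core: str, sep: str, base: int):
    """Split on an exclusive delimiter, keeping character offsets."""
    parts, pos = [], 0
    for piece in core.split(sep):
        parts.append((base + pos, piece))
        pos += len(piece) + len(sep)
    return parts


def _scan_parts(core: str, elem, sep: str, engine: Engine, path: str,
                base: int):
    """Greedy left-to-right element scan for non-exclusive separators.

    Each element match is maximal at its position; there is no backtracking
    across elements (see the methods documentation for the consequences).
    """
    scanner = engine.scanner(elem, path)
    parts, pos = [], 0
    while True:
        m = scanner.match(core, pos)
        if m is None:
            raise DecodingError("cannot match a list element",
                                path=path, offset=base + pos)
        if m.end() == pos and not sep:
            raise DecodingError(
                "list element matches the empty string with no separator; "
                "cannot make progress", path=path, offset=base + pos)
        parts.append((base + pos, core[pos:m.end()]))
        pos = m.end()
        if pos == len(core):
            return parts
        if sep:
            if not core.startswith(sep, pos):
                raise DecodingError(f"expected separator {sep!r}",
                                    path=path, offset=base + pos)
            pos += len(sep)


def _list_parts(core: str, defn, engine, path, base):
    p = defn.params
    if p["splitted"]:
        if not p["separator"]:
            raise DecodingError("splitted_by requires a non-empty delimiter",
                                path=path)
        return _split_parts(core, p["separator"], base)
    return _scan_parts(core, p["element"], p["separator"], engine, path, base)


def _decode_list(core, defn, engine, path, base):
    p = defn.params
    if core == "":
        if p["min_length"] == 0:
            return []
        raise DecodingError(
            f"at least {p['min_length']} element(s) required", path=path,
            offset=base)
    parts = _list_parts(core, defn, engine, path, base)
    n = len(parts)
    if n < p["min_length"] or (p["max_length"] is not None
                               and n > p["max_length"]):
        raise DecodingError(
            f"{n} element(s), but between {p['min_length']} and "
            f"{p['max_length'] if p['max_length'] is not None else 'inf'} "
            "are required", path=path, offset=base)
    return [decode(piece, p["element"], engine, f"{path}[{i}]", off)
            for i, (off, piece) in enumerate(parts)]


def _elements(core, defn, engine, path, base):
    """Element texts of a labeled/tagged list, with offsets."""
    p = defn.params
    if p["splitted"]:
        if core == "":
            return []
        return _split_parts(core, p["separator"], base)
    if core == "":
        return []
    # fall back to matching the whole element alternation iteratively
    raise DecodingError(
        "labeled/tagged lists require an exclusive delimiter (splitted_by)",
        path=path)


def _decode_labeled(core, defn, engine, path, base):
    p = defn.params
    isep = p["internal_separator"]
    result = {}
    for off, el in _elements(core, defn, engine, path, base):
        if isep not in el:
            raise DecodingError(
                f"expected label{isep}value element", path=path, offset=off)
        label, rest = el.split(isep, 1)
        if label not in p["labels"]:
            raise DecodingError(f"unknown label {label!r}", path=path,
                                offset=off)
        result[label] = decode(rest, p["labels"][label], engine,
                               f"{path}.{label}",
                               off + len(label) + len(isep))
    missing = [r for r in p["required"] if r not in result]
    if missing:
        raise DecodingError(
            "required label(s) missing: " + ", ".join(missing),
            path=path, offset=base)
    return result


def _decode_tagged(core, defn, engine, path, base):
    p = defn.params
    isep = p["internal_separator"]
    name_re = re.compile(p["tagname"])
    result = {}
    for off, el in _elements(core, defn, engine, path, base):
        pieces = el.split(isep, 2)
        if len(pieces) != 3:
            raise DecodingError(
                f"expected name{isep}code{isep}value element",
                path=path, offset=off)
        name, code, rest = pieces
        if name_re.fullmatch(name) is None:
            raise DecodingError(f"invalid tag name {name!r}", path=path,
                                offset=off)
        code = p["code_aliases"].get(code, code)
        if code not in p["codes"]:
            raise DecodingError(f"unknown type code {code!r}", path=path,
                                offset=off + len(name) + len(isep))
        value = decode(rest, p["codes"][code], engine, f"{path}.{name}",
                       off + len(el) - len(rest))
        result[name] = {"type": code, "value": value}
    return result


def _decode_composed(core, defn, engine, path, base):
    p = defn.params
    fields = p["fields"]
    if p["splitted"]:
        if core == "" and p["n_required"] == 0:
            return {}
        parts = _split_parts(core, p["separator"], base)
        if not p["n_required"] <= len(parts) <= len(fields):
            raise DecodingError(
                f"{len(parts)} field(s), but between {p['n_required']} and "
                f"{len(fields)} are required", path=path, offset=base)
        return {fname: decode(piece, sub, engine, f"{path}.{fname}", off)
                for (fname, sub), (off, piece) in zip(fields, parts)}
    # regex strategy: one named group per field captures a raw slice,
    # then each slice is decoded recursively (hierarchical parsing)
    m = engine.struct_regex(defn, path).fullmatch(core)
    if m is None:
        off = partial_match_prefix(engine.pattern_source(defn), core)
        raise DecodingError("text does not match the composition",
                            path=path, offset=base + off)
    out = {}
    for i, (fname, sub) in enumerate(fields):
        piece = m.group(f"_f{i}")
        if piece is None:
            continue
        out[fname] = decode(piece, sub, engine, f"{path}.{fname}",
                            base + m.start(f"_f{i}"))
    return out


# ---------------------------------------------------------------------------
# encoding
# ---------------------------------------------------------------------------

def encode(value, defn, engine: Engine, path: str = "") -> str:
    """Write the canonical text representation of *value* under *defn*.

    Raises :class:`EncodingError` naming the first violated constraint.
    """
    defn = engine.resolve(defn, path or "?")
    path = path or defn.name
    if defn.has_empty and _vkey(value) == _vkey(defn.empty_value):
        return ""
    core = _encode_core(value, defn, engine, path)
    if defn.also_matches is not None \
            and re.fullmatch(defn.also_matches, core) is None:
        raise EncodingError(
            f"encoded text does not satisfy the additional pattern "
            f"{defn.also_matches!r}", path=path)
    return defn.prefix + core + defn.suffix


def _reverse_map(defn):
    """value-key -> text map for string kinds, honouring ``canonical`` and
    first-listed order otherwise."""
    rev: dict[str, str] = {}
    decoded = defn.decoded or {}
    pairs = []  # (text, decoded value), in listed order
    if defn.kind == "constant":
        text = defn.params["text"]
        pairs.append((text, decoded.get(text, text)))
    elif defn.kind == "values":
        pairs.extend((v, decoded.get(v, v)) for v in defn.params["values"])
    elif defn.kind == "regexes":
        # only literal patterns name a unique text for their mapped value
        for pat, mapped in zip(defn.params["patterns"],
                               defn.params["decoded_by_pattern"]):
            if mapped is not None and re.escape(pat) == pat:
                pairs.append((pat, decoded.get(pat, mapped)))
    pairs = [(t, v) for t, v in decoded.items()] + pairs
    for text, value in pairs:
        rev.setdefault(_vkey(value), text)
    for text in defn.canonical:
        value = decoded.get(text, text)
        rev[_vkey(value)] = text
    return rev


def _encode_core(value, defn, engine: Engine, path: str) -> str:
    kind, p = defn.kind, defn.params

    if kind in _STRING_KINDS:
        rev = _reverse_map(defn)
        key = _vkey(value)
        if key in rev:
            return rev[key]
        if isinstance(value, str):
            if kind == "regex" and re.fullmatch(p["pattern"], value):
                return value
            if kind == "regexes":
                for pat, mapped in zip(p["patterns"], p["decoded_by_pattern"]):
                    if mapped is None and re.fullmatch(pat, value):
                        return value
            if kind == "values" and value in p["values"]:
                return value
            if kind == "constant" and value == p["text"]:
                return value
        raise EncodingError(f"value {value!r} has no text representation",
                            path=path)

    if kind == "integer":
        if not isinstance(value, int) or isinstance(value, bool):
            raise EncodingError("an integer is required", path=path)
        _check_range_enc(value, p.get("min"), p.get("max"), False, False, path)
        return str(value)

    if kind == "unsigned_integer":
        if not isinstance(value, int) or isinstance(value, bool) or value < 0:
            raise EncodingError("a non-negative integer is required", path=path)
        _check_range_enc(value, p.get("min"), p.get("max"), False, False, path)
        return format_unsigned(value, p["base"], p["with_prefix"])

    if kind == "float":
        if isinstance(value, bool) or not isinstance(value, (int, float)):
            raise EncodingError("a number is required", path=path)
        _check_range_enc(value, p.get("min"), p.get("max"),
                         p["min_excluded"], p["max_excluded"], path)
        return str(value) if isinstance(value, int) else repr(float(value))

    if kind == "list_of":
        if not isinstance(value, (list, tuple)):
            raise EncodingError("a sequence is required", path=path)
        n = len(value)
        if n < p["min_length"] or (p["max_length"] is not None
                                   and n > p["max_length"]):
            raise EncodingError(
                f"sequence of {n} element(s) violates the length constraints",
                path=path)
        texts = [encode(v, p["element"], engine, f"{path}[{i}]")
                 for i, v in enumerate(value)]
        return p["separator"].join(texts)

    if kind == "labeled_list":
        if not isinstance(value, dict):
            raise EncodingError("a mapping is required", path=path)
        unknown = [k for k in value if k not in p["labels"]]
        if unknown:
            raise EncodingError("unknown label(s): " + ", ".join(unknown),
                                path=path)
        missing = [r for r in p["required"] if r not in value]
        if missing:
            raise EncodingError(
                "required label(s) missing: " + ", ".join(missing), path=path)
        isep = p["internal_separator"]
        texts = [label + isep
                 + encode(value[label], p["labels"][label], engine,
                          f"{path}.{label}")
                 for label in p["labels"] if label in value]
        return p["separator"].join(texts)

    if kind == "tagged_list":
        if not isinstance(value, dict):
            raise EncodingError("a mapping is required", path=path)
        isep = p["internal_separator"]
        name_re = re.compile(p["tagname"])
        texts = []
        for name, item in value.items():
            if name_re.fullmatch(name) is None:
                raise EncodingError(f"invalid tag name {name!r}", path=path)
            if not (isinstance(item, dict) and "type" in item
                    and "value" in item):
                raise EncodingError(
                    f"tag {name!r} must be a mapping with 'type' and 'value'",
                    path=path)
            code = p["code_aliases"].get(item["type"], item["type"])
            if code not in p["codes"]:
                raise EncodingError(f"unknown type code {item['type']!r}",
                                    path=path)
            texts.append(name + isep + code + isep
                         + encode(item["value"], p["codes"][code], engine,
                                  f"{path}.{name}"))
        return p["separator"].join(texts)

    if kind == "composed_of":
        if not isinstance(value, dict):
            raise EncodingError("a mapping is required", path=path)
        fields = p["fields"]
        names = [f for f, _ in fields]
        unknown = [k for k in value if k not in names]
        if unknown:
            raise EncodingError("unknown field(s): " + ", ".join(unknown),
                                path=path)
        present = [f in value for f in names]
        n_present = sum(present)
        if n_present < p["n_required"]:
            missing = [f for f, here in zip(names, present)
                       if not here][:p["n_required"] - n_present]
            raise EncodingError(
                "required field(s) missing: " + ", ".join(missing), path=path)
        if not all(present[:n_present]):
            absent = names[present.index(False)]
            raise EncodingError(
                f"field {absent!r} is absent but a later field is present "
                "(only trailing fields may be omitted)", path=path)
        texts = [encode(value[fname], sub, engine, f"{path}.{fname}")
                 for (fname, sub), here in zip(fields, present) if here]
        return p["separator"].join(texts)

    if kind == "one_of":
        for i, alt in enumerate(p["alternatives"]):
            try:
                return encode(value, alt, engine, f"{path}|{i}")
            except EncodingError:
                continue
        raise EncodingError(
            "value is representable by none of the alternatives", path=path)

    raise AssertionError(kind)


def _check_range_enc(v, lo, hi, lo_open, hi_open, path):
    if lo is not None and (v < lo or (lo_open and v == lo)):
        raise EncodingError(f"{v} is below the permitted interval", path=path)
    if hi is not None and (v > hi or (hi_open and v == hi)):
        raise EncodingError(f"{v} is above the permitted interval", path=path)


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

def is_valid_encoded(text: str, defn, engine: Engine) -> bool:
    """True iff *text* follows the definition (iff :func:`decode` succeeds).

    The compiled expression is used as a fast rejection path; accepted
    texts are confirmed by decoding, so the answer is always exact.
    """
    defn = engine.resolve(defn)
    if engine.matcher(defn).regex.fullmatch(text) is None:
        return False
    try:
        decode(text, defn, engine)
        return True
    except DecodingError:
        return False


def is_valid_decoded(value, defn, engine: Engine) -> bool:
    """True iff *value* can be represented (iff :func:`encode` succeeds)."""
    try:
        encode(value, defn, engine)
        return True
    except EncodingError:
        return False


# ---------------------------------------------------------------------------
# file decoding
# ---------------------------------------------------------------------------

class _StructureMiss(Exception):
    """Internal: a sub-structure did not match at the current line; the
    caller may recover (end of a section, optional field, alternative)."""

    def __init__(self, lineno: int, message: str):
        self.lineno = lineno
        self.message = message
        super().__init__(f"line {lineno}: {message}")


def _read_lines(source) -> list[str]:
    if isinstance(source, (str, os.PathLike)) and not isinstance(source, io.IOBase):
        with open(source, "r", encoding="utf-8") as fh:
            text = fh.read()
    elif hasattr(source, "read"):
        text = source.read()
    else:
        raise TypeError("decode_file expects a path or a readable file object")
    lines = text.split("\n")
    if lines and lines[-1] == "":
        lines.pop()
    return lines


def _effective_scope(defn, scope) -> Scope:
    if scope is not None:
        if isinstance(scope, str):
            return Scope(scope, defn.unit_size if scope == "unit" else None)
        return scope
    if defn.scope is not None:
        return Scope(defn.scope, defn.unit_size)
    return Scope("line")


def decode_file(source, defn, engine: Engine, scope: "Scope | str | None" = None,
                streaming: bool = False):
    """Decode a file under *defn*, yielding :class:`DecodedRecord` objects.

    *scope* defaults to the definition's declared scope, else line scope.
    With file scope, ``streaming=True`` yields the elements of the outermost
    compound one at a time instead of one whole-file record.
    """
    defn = engine.resolve(defn)
    scope = _effective_scope(defn, scope)
    lines = _read_lines(source)
    if scope.kind == "line":
        return _decode_lines_scope(lines, defn, engine)
    if scope.kind == "unit":
        return _decode_unit_scope(lines, defn, engine, scope.unit_size)
    if scope.kind == "section":
        return _decode_section_scope(lines, defn, engine)
    if streaming:
        return _stream_file_scope(lines, defn, engine)
    return _decode_whole_file(lines, defn, engine)


def _decode_lines_scope(lines, defn, engine):
    for i, line in enumerate(lines):
        try:
            value = decode(line, defn, engine)
        except DecodingError as exc:
            raise DecodingError(str(exc), lineno=i + 1) from exc
        yield DecodedRecord(value, (i + 1, i + 1), defn.name)


def _decode_unit_scope(lines, defn, engine, unit_size):
    if len(lines) % unit_size != 0:
        raise DecodingError(
            f"file has {len(lines)} line(s), not a multiple of the unit "
            f"size {unit_size}", lineno=len(lines))
    for start in range(0, len(lines), unit_size):
        chunk = "\n".join(lines[start:start + unit_size])
        try:
            value = decode(chunk, defn, engine)
        except DecodingError as exc:
            raise DecodingError(str(exc), lineno=start + 1) from exc
        yield DecodedRecord(value, (start + 1, start + unit_size), defn.name)


def _is_line_repeat(defn, engine):
    """A list over whole lines: list_of with the newline as exclusive
    delimiter."""
    return (defn.kind == "list_of" and defn.params["splitted"]
            and defn.params["separator"] == "\n")


def _is_line_composition(defn, engine):
    return (defn.kind == "composed_of" and defn.params["splitted"]
            and defn.params["separator"] == "\n")


def _decode_section_scope(lines, defn, engine):
    if not _is_line_repeat(defn, engine):
        raise DecodingError(
            "section scope requires a list over lines "
            "(list_of with splitted_by newline)")
    elem = defn.params["element"]
    i = 0
    while i < len(lines):
        start = i
        values = []
        while i < len(lines):
            try:
                value, j = _consume(elem, lines, i, engine)
            except _StructureMiss:
                break
            values.append(value)
            i = j
            if defn.params["max_length"] is not None \
                    and len(values) >= defn.params["max_length"]:
                break
        if not values:
            raise DecodingError("line does not belong to any section",
                                lineno=i + 1)
        if len(values) < defn.params["min_length"]:
            raise DecodingError(
                f"section has {len(values)} record(s); at least "
                f"{defn.params['min_length']} required", lineno=start + 1)
        yield DecodedRecord(values, (start + 1, i), defn.name)


def _consume(defn, lines, i, engine, path: str = ""):
    """Greedy structural consumption of lines[i:] by a (possibly multi-line)
    definition; returns (value, next index).  Raises :class:`_StructureMiss`
    when the structure does not match at line i."""
    defn = engine.resolve(defn, path or "?")
    path = path or defn.name

    if _is_line_repeat(defn, engine):
        p = defn.params
        values = []
        j = i
        while j < len(lines) and (p["max_length"] is None
                                  or len(values) < p["max_length"]):
            try:
                value, k = _consume(p["element"], lines, j, engine,
                                    f"{path}[{len(values)}]")
            except _StructureMiss:
                break
            values.append(value)
            j = k
        if len(values) < p["min_length"]:
            raise _StructureMiss(j + 1,
                                 f"{path}: at least {p['min_length']} "
                                 f"record(s) required, found {len(values)}")
        return values, j

    if _is_line_composition(defn, engine):
        p = defn.params
        out = {}
        j = i
        for idx, (fname, sub) in enumerate(p["fields"]):
            optional = idx >= p["n_required"]
            try:
                value, j2 = _consume(sub, lines, j, engine, f"{path}.{fname}")
            except _StructureMiss:
                if optional:
                    continue
                raise
            out[fname] = value
            j = j2
        return out, j

    if defn.kind == "one_of":
        last = None
        for k, alt in enumerate(defn.params["alternatives"]):
            try:
                return _consume(alt, lines, i, engine, f"{path}|{k}")
            except _StructureMiss as miss:
                last = miss
        raise last if last is not None else _StructureMiss(i + 1, path)

    # single-line definition
    if i >= len(lines):
        raise _StructureMiss(i + 1, f"{path}: unexpected end of file")
    try:
        value = decode(lines[i], defn, engine, path)
    except DecodingError as exc:
        raise _StructureMiss(i + 1, str(exc)) from exc
    return value, i + 1


def _decode_whole_file(lines, defn, engine):
    try:
        value, j = _consume(defn, lines, 0, engine)
    except _StructureMiss as miss:
        raise DecodingError(miss.message, lineno=miss.lineno) from miss
    if j != len(lines):
        raise DecodingError("unexpected content after the end of the "
                            "file structure", lineno=j + 1)
    yield DecodedRecord(value, (1, max(j, 1)), defn.name)


def _stream_file_scope(lines, defn, engine):
    """Emit the elements of the outermost compound one at a time while still
    enforcing the whole-file structure (section order, length bounds)."""
    if _is_line_repeat(defn, engine):
        yield from _stream_repeat(lines, 0, defn, engine, defn.name,
                                  must_end=True)
        return
    if _is_line_composition(defn, engine):
        p = defn.params
        i = 0
        for idx, (fname, sub) in enumerate(p["fields"]):
            sub_r = engine.resolve(sub, defn.name)
            optional = idx >= p["n_required"]
            record_name = f"{defn.name}.{fname}"
            if _is_line_repeat(sub_r, engine):
                i = yield from _stream_repeat(
                    lines, i, sub_r, engine, record_name,
                    must_end=False, optional=optional)
            else:
                try:
                    value, j = _consume(sub_r, lines, i, engine, record_name)
                except _StructureMiss as miss:
                    if optional:
                        continue
                    raise DecodingError(miss.message,
                                        lineno=miss.lineno) from miss
                yield DecodedRecord(value, (i + 1, j), record_name)
                i = j
        if i != len(lines):
            raise DecodingError("unexpected content after the end of the "
                                "file structure", lineno=i + 1)
        return
    # not a line-structured compound: stream degenerates to the whole record
    yield from _decode_whole_file(lines, defn, engine)


def _stream_repeat(lines, i, defn, engine, record_name, must_end,
                   optional=False):
    p = defn.params
    count = 0
    while i < len(lines) and (p["max_length"] is None
                              or count < p["max_length"]):
        try:
            value, j = _consume(p["element"], lines, i, engine,
                                f"{record_name}[{count}]")
        except _StructureMiss as miss:
            if must_end:
                raise DecodingError(miss.message, lineno=miss.lineno) from miss
            break
        yield DecodedRecord(value, (i + 1, j), record_name)
        i = j
        count += 1
    if must_end and i != len(lines):
        raise DecodingError("unexpected content after the end of the "
                            "file structure", lineno=i + 1)
    if count < p["min_length"] and not (optional and count == 0):
        raise DecodingError(
            f"{record_name}: at least {p['min_length']} record(s) required, "
            f"found {count}", lineno=i + 1)
    return i
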