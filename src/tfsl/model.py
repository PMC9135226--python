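"""Data model of the specification language.

A *datatype definition* describes the text representation of one piece of
information in a line-oriented format.  Definitions come in twelve kinds:

scalar
    ``constant`` (one valid text), ``values`` (a closed set of texts),
    ``regex`` / ``regexes`` (pattern matching), ``integer`` /
    ``unsigned_integer`` / ``float`` (numbers in an interval);
compound
    ``list_of`` (homogeneous sequence), ``labeled_list`` (label:value
    elements), ``tagged_list`` (name:typecode:value elements),
    ``composed_of`` (ordered, named fields), ``one_of`` (alternatives).

A definition is written as a mapping with exactly one *kind key* (one of the
twelve above) whose value is the kind-specific payload, plus optional
sibling *rule keys*:

formatting rules
    ``prefix``, ``suffix`` (constant literals around the representation),
    ``splitted_by`` (element delimiter guaranteed never to occur inside
    elements; enables split-based parsing), ``separator`` (delimiter that may
    also occur inside elements; forces regex-based parsing),
    ``internal_separator`` (between label/tag components, default ``:``);
validation rules
    interval bounds inside numeric payloads, ``length`` / ``min_length`` /
    ``max_length`` (list sizes), ``required`` (labels that must be present),
    ``n_required`` (number of leading mandatory fields of a composition),
    ``tagname`` (pattern for tag names), ``also_matches`` (an additional
    pattern the text must satisfy);
transformation rules
    ``decoded`` (text -> data value map applied after matching), ``empty``
    (the data value represented by the empty string), ``canonical`` (which
    text form to emit when a decoded value has several representations),
    ``code_aliases`` (alias -> canonical type-code map of a tagged list).

Two shorthands keep specifications concise: a bare string is a ``constant``
definition, a bare list is a ``values`` definition.  A string starting with
``$`` is a *reference* to another named datatype.

File-scope behaviour is controlled by ``scope`` (``line``, ``unit``,
``section`` or ``file``) and ``unit_size`` (required iff scope is ``unit``).
"""

from __future__ import annotations

import numbers
import re
from dataclasses import dataclass

from .errors import SpecSyntaxError

KINDS = (
    "constant", "values", "regex", "regexes", "integer", "unsigned_integer",
    "float", "list_of", "labeled_list", "tagged_list", "composed_of", "one_of",
)

SCOPES = ("line", "unit", "section", "file")

#: rule keys accepted next to each kind key
_COMMON_KEYS = ("prefix", "suffix", "scope", "unit_size", "empty")
_RULE_KEYS: dict[str, tuple[str, ...]] = {
    "constant": ("decoded", "canonical", "also_matches"),
    "values": ("decoded", "canonical", "also_matches"),
    "regex": ("decoded", "canonical", "also_matches"),
    "regexes": ("decoded", "canonical", "also_matches"),
    "integer": (),
    "unsigned_integer": (),
    "float": (),
    "list_of": ("splitted_by", "separator", "length", "min_length", "max_length"),
    "labeled_list": ("splitted_by", "separator", "internal_separator", "required"),
    "tagged_list": ("splitted_by", "separator", "internal_separator", "tagname",
                    "code_aliases"),
    "composed_of": ("splitted_by", "separator", "n_required"),
    "one_of": (),
}

IDENTIFIER_RE = re.compile(r"[A-Za-z_][A-Za-z0-9_]*")
NAME_RE = re.compile(r"(?:[A-Za-z_][A-Za-z0-9_]*::)?[A-Za-z_][A-Za-z0-9_]*")

REFERENCE_SIGIL = "$"


def is_reference(node) -> bool:
    """True if *node* is a reference shorthand (``"$name"``)."""
    return isinstance(node, str) and node.startswith(REFERENCE_SIGIL)


@dataclass(frozen=True)
class Reference:
    """An unresolved pointer to a named datatype of the same specification."""

    target: str

    def __repr__(self) -> str:
        return f"${self.target}"


@dataclass(frozen=True)
class Diagnostic:
    """One problem found in a definition tree.

    ``path`` locates the offending node, ``message`` describes the problem
    and ``valid_keys`` lists the keys that would be acceptable in that
    context (the context-sensitive help shown to spec authors).
    """

    path: tuple
    message: str
    valid_keys: tuple = ()

    def __str__(self) -> str:
        loc = "/".join(str(p) for p in self.path) or "<root>"
        msg = f"{loc}: {self.message}"
        if self.valid_keys:
            msg += " (valid keys here: " + ", ".join(sorted(self.valid_keys)) + ")"
        return msg


@dataclass
class DatatypeDefinition:
    """A normalized datatype definition.

    ``params`` holds the kind-specific payload with defaults filled in;
    nested definitions are themselves ``DatatypeDefinition`` objects and
    references are :class:`Reference` objects.  Instances are plain data:
    matchers are attached separately at compilation time.
    """

    name: str
    kind: str
    params: dict
    prefix: str = ""
    suffix: str = ""
    decoded: dict | None = None        # text -> data value
    canonical: tuple = ()              # preferred texts for encoding
    empty_value = None                 # set via has_empty/empty_value pair
    has_empty: bool = False
    also_matches: str | None = None
    scope: str | None = None
    unit_size: int | None = None

    def __post_init__(self):
        if self.kind not in KINDS:
            raise ValueError(f"unknown kind {self.kind!r}")

    # -- equality helpers -------------------------------------------------
    def __eq__(self, other):
        if not isinstance(other, DatatypeDefinition):
            return NotImplemented
        return self.to_tree() == other.to_tree() and self.name == other.name

    def __hash__(self):  # pragma: no cover - rarely used
        return hash((self.name, self.kind))

    # -- serialization ----------------------------------------------------
    def to_tree(self):
        """Canonical document tree of this definition.

        ``normalize_definition(to_tree(d), d.name)`` reproduces ``d``; this
        is the form stored in precompiled archives.
        """
        tree = {self.kind: _params_to_tree(self.kind, self.params)}
        if self.kind == "list_of":
            if self.params.get("length") is not None:
                tree["length"] = self.params["length"]
            else:
                if self.params["min_length"] != 1:
                    tree["min_length"] = self.params["min_length"]
                if self.params["max_length"] is not None:
                    tree["max_length"] = self.params["max_length"]
        for key in ("n_required",
                    "required", "internal_separator", "tagname", "code_aliases"):
            if key in self.params and self.params[key] is not None:
                value = self.params[key]
                if key == "required":
                    value = list(value)
                tree[key] = value
        if self.kind in ("list_of", "labeled_list", "tagged_list", "composed_of"):
            sep_key = "splitted_by" if self.params.get("splitted") else "separator"
            tree[sep_key] = self.params.get("separator", "")
        if self.prefix:
            tree["prefix"] = self.prefix
        if self.suffix:
            tree["suffix"] = self.suffix
        if self.decoded is not None:
            tree["decoded"] = dict(self.decoded)
        if self.canonical:
            tree["canonical"] = list(self.canonical)
        if self.has_empty:
            tree["empty"] = self.empty_value
        if self.also_matches is not None:
            tree["also_matches"] = self.also_matches
        if self.scope is not None:
            tree["scope"] = self.scope
        if self.unit_size is not None:
            tree["unit_size"] = self.unit_size
        return tree

    def references(self):
        """Yield the names of all datatypes this definition refers to,
        recursively through inline sub-definitions."""
        yield from _collect_references(self)


def _params_to_tree(kind: str, params: dict):
    def sub(node):
        if isinstance(node, Reference):
            return REFERENCE_SIGIL + node.target
        return node.to_tree()

    if kind == "constant":
        return params["text"]
    if kind == "values":
        return list(params["values"])
    if kind == "regex":
        return params["pattern"]
    if kind == "regexes":
        if any(v is not None for v in params["decoded_by_pattern"]):
            return [
                {p: v} if v is not None else p
                for p, v in zip(params["patterns"], params["decoded_by_pattern"])
            ]
        return list(params["patterns"])
    if kind == "integer":
        out = {}
        if params["min"] is not None:
            out["min"] = params["min"]
        if params["max"] is not None:
            out["max"] = params["max"]
        return out
    if kind == "unsigned_integer":
        out = {}
        if params["min"] is not None:
            out["min"] = params["min"]
        if params["max"] is not None:
            out["max"] = params["max"]
        if params["base"] != 10:
            out["base"] = params["base"]
        if params["with_prefix"]:
            out["with_prefix"] = True
        return out
    if kind == "float":
        out = {}
        if params["min"] is not None:
            out["min"] = params["min"]
        if params["max"] is not None:
            out["max"] = params["max"]
        if params["min_excluded"]:
            out["min_excluded"] = True
        if params["max_excluded"]:
            out["max_excluded"] = True
        return out
    if kind == "list_of":
        return sub(params["element"])
    if kind == "labeled_list":
        return {label: sub(d) for label, d in params["labels"].items()}
    if kind == "tagged_list":
        return {code: sub(d) for code, d in params["codes"].items()}
    if kind == "composed_of":
        return [{name: sub(d)} for name, d in params["fields"]]
    if kind == "one_of":
        return [sub(d) for d in params["alternatives"]]
    raise AssertionError(kind)


def _collect_references(defn: DatatypeDefinition):
    def walk(node):
        if isinstance(node, Reference):
            yield node.target
        elif isinstance(node, DatatypeDefinition):
            yield from _collect_references(node)

    p = defn.params
    if defn.kind == "list_of":
        yield from walk(p["element"])
    elif defn.kind == "labeled_list":
        for d in p["labels"].values():
            yield from walk(d)
    elif defn.kind == "tagged_list":
        for d in p["codes"].values():
            yield from walk(d)
    elif defn.kind == "composed_of":
        for _, d in p["fields"]:
            yield from walk(d)
    elif defn.kind == "one_of":
        for d in p["alternatives"]:
            yield from walk(d)


# ---------------------------------------------------------------------------
# structural validation
# ---------------------------------------------------------------------------

def _is_scalar_text(v) -> bool:
    return isinstance(v, str) or (isinstance(v, numbers.Number)
                                  and not isinstance(v, bool))


def _check_pattern(pattern, path, key, out):
    if not isinstance(pattern, str):
        out.append(Diagnostic(path, f"{key} pattern must be a string"))
        return
    try:
        re.compile(pattern)
    except re.error as exc:
        out.append(Diagnostic(path, f"invalid regular expression: {exc}"))


def validate_definition_tree(tree, path=()) -> list[Diagnostic]:
    """Check that *tree* is a syntactically valid datatype definition.

    Returns an empty list on success; otherwise a list of
    :class:`Diagnostic`, each locating the problem and listing the keys
    valid in its context.  Never raises on malformed input.
    """
    out: list[Diagnostic] = []
    path = tuple(path)

    # shorthand forms
    if isinstance(tree, str):
        if tree.startswith(REFERENCE_SIGIL):
            name = tree[1:]
            if not NAME_RE.fullmatch(name):
                out.append(Diagnostic(path, f"invalid reference name {name!r}"))
        return out
    if _is_scalar_text(tree):
        return out
    if isinstance(tree, list):
        if not tree:
            out.append(Diagnostic(path, "empty list cannot define a value set"))
        for i, v in enumerate(tree):
            if not _is_scalar_text(v):
                out.append(Diagnostic(path + (i,),
                                      "value-set members must be strings or numbers"))
        return out
    if not isinstance(tree, dict):
        out.append(Diagnostic(path, "a definition must be a mapping, string or list",
                              KINDS))
        return out

    kind_keys = [k for k in tree if k in KINDS]
    if not kind_keys:
        out.append(Diagnostic(path, "no kind key found; exactly one is required",
                              KINDS))
        return out
    if len(kind_keys) > 1:
        out.append(Diagnostic(path,
                              "multiple kind keys: " + ", ".join(sorted(kind_keys)),
                              KINDS))
        return out
    kind = kind_keys[0]
    allowed = set(_COMMON_KEYS) | set(_RULE_KEYS[kind]) | {kind}
    for key in tree:
        if key not in allowed:
            out.append(Diagnostic(path + (key,), f"unknown key {key!r} for kind {kind}",
                                  tuple(sorted(allowed))))

    payload = tree[kind]
    ppath = path + (kind,)
    if kind == "constant":
        if not _is_scalar_text(payload):
            out.append(Diagnostic(ppath, "constant must be a string or number"))
    elif kind == "values":
        if not isinstance(payload, list) or not payload:
            out.append(Diagnostic(ppath, "values requires a non-empty list"))
        else:
            texts = []
            for i, v in enumerate(payload):
                if not _is_scalar_text(v):
                    out.append(Diagnostic(ppath + (i,),
                                          "value-set members must be strings or numbers"))
                else:
                    texts.append(str(v))
            if len(set(texts)) != len(texts):
                out.append(Diagnostic(ppath, "duplicate members in value set"))
    elif kind == "regex":
        _check_pattern(payload, ppath, "regex", out)
    elif kind == "regexes":
        items = None
        if isinstance(payload, list) and payload:
            items = payload
        elif isinstance(payload, dict) and payload:
            items = [{k: v} for k, v in payload.items()]
        if items is None:
            out.append(Diagnostic(ppath, "regexes requires a non-empty list or mapping"))
        else:
            for i, item in enumerate(items):
                if isinstance(item, dict):
                    if len(item) != 1:
                        out.append(Diagnostic(ppath + (i,),
                                              "each pattern entry maps one pattern "
                                              "to its decoded value"))
                        continue
                    item = next(iter(item))
                _check_pattern(item, ppath + (i,), "regexes", out)
    elif kind in ("integer", "unsigned_integer"):
        extra = ("base", "with_prefix") if kind == "unsigned_integer" else ()
        if payload is None:
            payload = {}
        if not isinstance(payload, dict):
            out.append(Diagnostic(ppath, f"{kind} requires a mapping of bounds",
                                  ("min", "max") + extra))
        else:
            for key in payload:
                if key not in ("min", "max") + extra:
                    out.append(Diagnostic(ppath + (key,), f"unknown key {key!r}",
                                          ("min", "max") + extra))
            for b in ("min", "max"):
                v = payload.get(b)
                if v is not None and (not isinstance(v, int) or isinstance(v, bool)):
                    out.append(Diagnostic(ppath + (b,), f"{b} must be an integer"))
                elif kind == "unsigned_integer" and isinstance(v, int) and v < 0:
                    out.append(Diagnostic(ppath + (b,), f"{b} must be non-negative"))
            lo, hi = payload.get("min"), payload.get("max")
            if isinstance(lo, int) and isinstance(hi, int) and lo > hi:
                out.append(Diagnostic(ppath, f"empty interval: min {lo} > max {hi}"))
            base = payload.get("base", 10)
            if kind == "unsigned_integer" and base not in (2, 8, 10, 16):
                out.append(Diagnostic(ppath + ("base",),
                                      "base must be one of 2, 8, 10, 16"))
    elif kind == "float":
        if payload is None:
            payload = {}
        keys = ("min", "max", "min_excluded", "max_excluded")
        if not isinstance(payload, dict):
            out.append(Diagnostic(ppath, "float requires a mapping of bounds", keys))
        else:
            for key in payload:
                if key not in keys:
                    out.append(Diagnostic(ppath + (key,), f"unknown key {key!r}", keys))
            for b in ("min", "max"):
                v = payload.get(b)
                if v is not None and not isinstance(v, numbers.Real):
                    out.append(Diagnostic(ppath + (b,), f"{b} must be a number"))
            for b in ("min_excluded", "max_excluded"):
                v = payload.get(b, False)
                if not isinstance(v, bool):
                    out.append(Diagnostic(ppath + (b,), f"{b} must be boolean"))
            lo, hi = payload.get("min"), payload.get("max")
            if (isinstance(lo, numbers.Real) and isinstance(hi, numbers.Real)):
                if lo > hi:
                    out.append(Diagnostic(ppath, f"empty interval: min {lo} > max {hi}"))
                elif lo == hi and (payload.get("min_excluded")
                                   or payload.get("max_excluded")):
                    out.append(Diagnostic(ppath, "empty interval: single point excluded"))
    elif kind == "list_of":
        out.extend(validate_definition_tree(payload, ppath))
        length = tree.get("length")
        has_minmax = "min_length" in tree or "max_length" in tree
        if length is not None and has_minmax:
            out.append(Diagnostic(path, "length excludes min_length/max_length"))
        for key in ("length", "min_length", "max_length"):
            v = tree.get(key)
            if v is not None and (not isinstance(v, int) or isinstance(v, bool)
                                  or v < 0):
                out.append(Diagnostic(path + (key,),
                                      f"{key} must be a non-negative integer"))
        lo, hi = tree.get("min_length"), tree.get("max_length")
        if isinstance(lo, int) and isinstance(hi, int) and lo > hi:
            out.append(Diagnostic(path, "min_length greater than max_length"))
    elif kind in ("labeled_list", "tagged_list"):
        if not isinstance(payload, dict) or not payload:
            what = "label" if kind == "labeled_list" else "type-code"
            out.append(Diagnostic(ppath, f"requires a non-empty {what} -> "
                                         "definition mapping"))
        else:
            for label, sub in payload.items():
                out.extend(validate_definition_tree(sub, ppath + (label,)))
        if kind == "labeled_list":
            req = tree.get("required")
            if req is not None:
                if not isinstance(req, list):
                    out.append(Diagnostic(path + ("required",),
                                          "required must be a list of labels"))
                elif isinstance(payload, dict):
                    for label in req:
                        if label not in payload:
                            out.append(Diagnostic(path + ("required",),
                                                  f"required label {label!r} "
                                                  "is not defined"))
        else:
            if "tagname" in tree:
                _check_pattern(tree["tagname"], path + ("tagname",), "tagname", out)
            aliases = tree.get("code_aliases")
            if aliases is not None:
                if not isinstance(aliases, dict):
                    out.append(Diagnostic(path + ("code_aliases",),
                                          "code_aliases must map alias -> code"))
                elif isinstance(payload, dict):
                    for alias, target in aliases.items():
                        if target not in payload:
                            out.append(Diagnostic(path + ("code_aliases", alias),
                                                  f"alias target {target!r} is not "
                                                  "a defined type code"))
    elif kind == "composed_of":
        pairs = _composed_pairs(payload)
        if pairs is None:
            out.append(Diagnostic(ppath, "composed_of requires an ordered "
                                         "field-name -> definition mapping"))
        else:
            seen = set()
            for fname, sub in pairs:
                if not isinstance(fname, str) or not IDENTIFIER_RE.fullmatch(fname):
                    out.append(Diagnostic(ppath + (fname,),
                                          f"invalid field name {fname!r}"))
                if fname in seen:
                    out.append(Diagnostic(ppath + (fname,),
                                          f"duplicate field name {fname!r}"))
                seen.add(fname)
                out.extend(validate_definition_tree(sub, ppath + (fname,)))
            nreq = tree.get("n_required")
            if nreq is not None and (not isinstance(nreq, int) or isinstance(nreq, bool)
                                     or not 0 <= nreq <= len(pairs)):
                out.append(Diagnostic(path + ("n_required",),
                                      "n_required must be an integer between 0 "
                                      "and the number of fields"))
    elif kind == "one_of":
        if not isinstance(payload, list) or len(payload) < 2:
            out.append(Diagnostic(ppath, "one_of requires at least two alternatives"))
        else:
            for i, sub in enumerate(payload):
                out.extend(validate_definition_tree(sub, ppath + (i,)))

    # rule keys
    if "splitted_by" in tree and "separator" in tree:
        out.append(Diagnostic(path, "splitted_by and separator are mutually exclusive"))
    for key in ("prefix", "suffix", "splitted_by", "separator", "internal_separator"):
        v = tree.get(key)
        if v is not None and not isinstance(v, str):
            out.append(Diagnostic(path + (key,), f"{key} must be a string"))
    if "also_matches" in tree:
        _check_pattern(tree["also_matches"], path + ("also_matches",),
                       "also_matches", out)
    decoded = tree.get("decoded")
    if decoded is not None and not isinstance(decoded, dict):
        out.append(Diagnostic(path + ("decoded",),
                              "decoded must map texts to data values"))
    canonical = tree.get("canonical")
    if canonical is not None and not (isinstance(canonical, str)
                                      or (isinstance(canonical, list)
                                          and all(isinstance(c, str)
                                                  for c in canonical))):
        out.append(Diagnostic(path + ("canonical",),
                              "canonical must be a text or list of texts"))
    scope = tree.get("scope")
    if scope is not None and scope not in SCOPES:
        out.append(Diagnostic(path + ("scope",),
                              f"scope must be one of {', '.join(SCOPES)}"))
    unit_size = tree.get("unit_size")
    if scope == "unit":
        if not isinstance(unit_size, int) or isinstance(unit_size, bool) \
                or unit_size < 1:
            out.append(Diagnostic(path + ("unit_size",),
                                  "unit scope requires a positive unit_size"))
    elif unit_size is not None:
        out.append(Diagnostic(path + ("unit_size",),
                              "unit_size is only allowed with scope: unit"))
    return out


def _composed_pairs(payload):
    """Accept either an ordered mapping or a list of single-key mappings."""
    if isinstance(payload, dict) and payload:
        return list(payload.items())
    if isinstance(payload, list) and payload:
        pairs = []
        for item in payload:
            if not isinstance(item, dict) or len(item) != 1:
                return None
            pairs.append(next(iter(item.items())))
        return pairs
    return None


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def normalize_definition(tree, name: str) -> DatatypeDefinition:
    """Expand shorthands and fill defaults, returning the canonical in-memory
    definition.  Raises :class:`SpecSyntaxError` if the tree is invalid."""
    diagnostics = validate_definition_tree(tree)
    if diagnostics:
        raise SpecSyntaxError(f"invalid definition for datatype {name!r}",
                              diagnostics)
    return _normalize(tree, name)


def _sub_def(node, name: str):
    """Normalize a subordinate definition node (reference or inline tree)."""
    if is_reference(node):
        return Reference(node[1:])
    return _normalize(node, name)


def _normalize(tree, name: str) -> DatatypeDefinition:
    if isinstance(tree, str) and not tree.startswith(REFERENCE_SIGIL):
        tree = {"constant": tree}
    elif _is_scalar_text(tree):
        tree = {"constant": tree}
    elif isinstance(tree, list):
        tree = {"values": tree}
    kind = next(k for k in tree if k in KINDS)
    payload = tree[kind]

    params: dict = {}
    if kind == "constant":
        params["text"] = str(payload)
    elif kind == "values":
        params["values"] = [str(v) for v in payload]
    elif kind == "regex":
        params["pattern"] = payload
    elif kind == "regexes":
        patterns, by_pattern = [], []
        items = ([{k: v} for k, v in payload.items()]
                 if isinstance(payload, dict) else payload)
        for item in items:
            if isinstance(item, dict):
                (pat, val), = item.items()
                patterns.append(pat)
                by_pattern.append(val)
            else:
                patterns.append(item)
                by_pattern.append(None)
        params["patterns"] = patterns
        params["decoded_by_pattern"] = by_pattern
    elif kind == "integer":
        payload = payload or {}
        params["min"] = payload.get("min")
        params["max"] = payload.get("max")
    elif kind == "unsigned_integer":
        payload = payload or {}
        params["min"] = payload.get("min")
        params["max"] = payload.get("max")
        params["base"] = payload.get("base", 10)
        params["with_prefix"] = bool(payload.get("with_prefix", False))
    elif kind == "float":
        payload = payload or {}
        params["min"] = payload.get("min")
        params["max"] = payload.get("max")
        params["min_excluded"] = bool(payload.get("min_excluded", False))
        params["max_excluded"] = bool(payload.get("max_excluded", False))
    elif kind == "list_of":
        params["element"] = _sub_def(payload, f"{name}[element]")
        params["length"] = tree.get("length")
        if params["length"] is not None:
            params["min_length"] = params["max_length"] = params["length"]
        else:
            params["min_length"] = tree.get("min_length", 1)
            params["max_length"] = tree.get("max_length")
    elif kind == "labeled_list":
        params["labels"] = {label: _sub_def(sub, f"{name}[{label}]")
                            for label, sub in payload.items()}
        params["required"] = tuple(tree.get("required", ()))
        params["internal_separator"] = tree.get("internal_separator", ":")
    elif kind == "tagged_list":
        params["codes"] = {str(code): _sub_def(sub, f"{name}[{code}]")
                           for code, sub in payload.items()}
        params["tagname"] = tree.get("tagname", r"[A-Za-z_][A-Za-z0-9_]*")
        params["internal_separator"] = tree.get("internal_separator", ":")
        params["code_aliases"] = dict(tree.get("code_aliases", {}))
    elif kind == "composed_of":
        pairs = _composed_pairs(payload)
        params["fields"] = [(fname, _sub_def(sub, f"{name}.{fname}"))
                            for fname, sub in pairs]
        params["n_required"] = tree.get("n_required", len(pairs))
    elif kind == "one_of":
        params["alternatives"] = [_sub_def(sub, f"{name}|{i}")
                                  for i, sub in enumerate(payload)]

    if kind in ("list_of", "labeled_list", "tagged_list", "composed_of"):
        if "splitted_by" in tree:
            params["splitted"] = True
            params["separator"] = tree["splitted_by"]
        else:
            params["splitted"] = False
            params["separator"] = tree.get("separator", "")

    canonical = tree.get("canonical", ())
    if isinstance(canonical, str):
        canonical = (canonical,)
    defn = DatatypeDefinition(
        name=name,
        kind=kind,
        params=params,
        prefix=tree.get("prefix", ""),
        suffix=tree.get("suffix", ""),
        decoded=dict(tree["decoded"]) if tree.get("decoded") is not None else None,
        canonical=tuple(canonical),
        also_matches=tree.get("also_matches"),
        scope=tree.get("scope"),
        unit_size=tree.get("unit_size"),
    )
    if "empty" in tree:
        defn.has_empty = True
        defn.empty_value = tree["empty"]
    return defn


def is_data_value(v) -> bool:
    """True if *v* belongs to the decoded data domain: None, bool, int,
    float, str, sequences thereof, or string-keyed mappings thereof."""
    if v is None or isinstance(v, (bool, int, float, str)):
        return True
    if isinstance(v, (list, tuple)):
        return all(is_data_value(x) for x in v)
    if isinstance(v, dict):
        return all(isinstance(k, str) and is_data_value(x) for k, x in v.items())
    return False
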