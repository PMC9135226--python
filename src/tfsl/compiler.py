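"""Translation of datatype definitions into anchored regular expressions.

Every resolved definition compiles to a regular expression accepting its
valid text representations.  Compound definitions embed the patterns of
their components; literal prefixes, suffixes and delimiters are escaped.
Where an exclusive delimiter is declared (``splitted_by``) the decoder uses
a split-based plan instead of capturing groups; compositions with
non-exclusive separators are parsed with one named group per field, and
nested compounds are parsed hierarchically (the outer expression captures a
raw slice, the inner expression parses the slice).

Numeric interval kinds compile to a digit-envelope pattern plus a
post-match range check (an exact interval-to-regex expansion would explode
for wide intervals and the range check is part of validation in any case);
:meth:`CompiledMatcher.accepts` applies both.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field as dc_field

from .errors import PatternError, UnresolvedReferenceError
from .model import DatatypeDefinition, Reference

#: envelope patterns for numbers; ranges are checked after matching
INTEGER_SRC = r"[-+]?[0-9]+"
FLOAT_SRC = r"[-+]?(?:[0-9]+(?:\.[0-9]*)?|\.[0-9]+)(?:[eE][-+]?[0-9]+)?"
UNSIGNED_SRC = {
    2: r"(?:0[bB])?[01]+",
    8: r"(?:0[oO])?[0-7]+",
    10: r"[0-9]+",
    16: r"(?:0[xX])?[0-9A-Fa-f]+",
}

_NAMED_GROUP_RE = re.compile(r"\(\?P<[^>]+>")


def sanitize_user_pattern(pattern: str) -> str:
    """Prepare a user regex for embedding: named groups become non-capturing
    so that the same pattern can occur several times in one expression.
    Backreferences to named groups cannot survive this and are rejected."""
    if "(?P=" in pattern:
        raise PatternError(
            f"pattern {pattern!r} uses named backreferences, which cannot be "
            "embedded in a composite expression")
    return _NAMED_GROUP_RE.sub("(?:", pattern)


@dataclass
class CompiledMatcher:
    """An anchored expression for one datatype plus its post-match checks.

    ``accepts`` is the fast validation path: the anchored pattern plus the
    numeric range / additional-pattern checks of this datatype.  It is exact
    for scalar datatypes; for compounds containing bounded numeric
    components the definitive answer is given by decoding (the library's
    ``is_valid_encoded`` uses the decoder and is always exact).
    """

    pattern: str                       # anchored source
    regex: "re.Pattern"
    strategy: str                      # regex | split | hybrid
    group_map: dict = dc_field(default_factory=dict)
    post_checks: list = dc_field(default_factory=list)

    def accepts(self, text: str) -> bool:
        if self.regex.fullmatch(text) is None:
            return False
        return all(check(text) for check in self.post_checks)


class Engine:
    """Compiles and caches matchers for all definitions of one resolved
    specification table.  The table must already be reference-closed and
    acyclic."""

    def __init__(self, table: dict[str, DatatypeDefinition], group_cap: int = 500):
        self.table = table
        self.group_cap = group_cap
        self._sources: dict[int, str] = {}
        self._matchers: dict[int, CompiledMatcher] = {}
        self._scanners: dict[int, "re.Pattern"] = {}
        self._struct: dict[int, "re.Pattern"] = {}

    # -- resolution -------------------------------------------------------
    def resolve(self, node, referrer: str = "?") -> DatatypeDefinition:
        while isinstance(node, Reference):
            try:
                node = self.table[node.target]
            except KeyError:
                raise UnresolvedReferenceError(node.target, referrer) from None
        return node

    # -- pattern sources --------------------------------------------------
    def pattern_source(self, node, referrer: str = "?") -> str:
        """Unanchored source (self-contained, non-capturing) for *node*."""
        defn = self.resolve(node, referrer)
        key = id(defn)
        if key not in self._sources:
            # placeholder guards against accidental recursion; the cycle
            # check makes this unreachable for loaded specifications
            self._sources[key] = "(?!)"
            self._sources[key] = self._wrap(defn, self._core_source(defn))
        return self._sources[key]

    def _wrap(self, defn: DatatypeDefinition, inner: str) -> str:
        src = f"(?:{inner})"
        if defn.prefix or defn.suffix:
            src = re.escape(defn.prefix) + src + re.escape(defn.suffix)
            src = f"(?:{src})"
        if defn.has_empty:
            src = f"(?:{src}|)"
        return src

    def _core_source(self, defn: DatatypeDefinition) -> str:
        kind, p = defn.kind, defn.params
        if kind == "constant":
            return re.escape(p["text"])
        if kind == "values":
            return "|".join(re.escape(v) for v in p["values"])
        if kind == "regex":
            return sanitize_user_pattern(p["pattern"])
        if kind == "regexes":
            return "|".join(f"(?:{sanitize_user_pattern(pat)})"
                            for pat in p["patterns"])
        if kind == "integer":
            return INTEGER_SRC
        if kind == "unsigned_integer":
            return UNSIGNED_SRC[p["base"]]
        if kind == "float":
            return FLOAT_SRC
        if kind == "list_of":
            elem = self.pattern_source(p["element"], defn.name)
            return self._repeat(elem, p["separator"],
                                p["min_length"], p["max_length"])
        if kind == "labeled_list":
            isep = re.escape(p["internal_separator"])
            elem = "|".join(
                re.escape(label) + isep
                + f"(?:{self.pattern_source(sub, defn.name)})"
                for label, sub in p["labels"].items())
            n_min = len(p["required"])
            return self._repeat(f"(?:{elem})", p["separator"], n_min, None)
        if kind == "tagged_list":
            isep = re.escape(p["internal_separator"])
            alts = [re.escape(code) + isep
                    + f"(?:{self.pattern_source(sub, defn.name)})"
                    for code, sub in p["codes"].items()]
            for alias, target in p["code_aliases"].items():
                alts.append(re.escape(alias) + isep
                            + f"(?:{self.pattern_source(p['codes'][target], defn.name)})")
            name_src = sanitize_user_pattern(p["tagname"])
            elem = f"(?:{name_src}){isep}(?:{'|'.join(alts)})"
            return self._repeat(f"(?:{elem})", p["separator"], 0, None)
        if kind == "composed_of":
            return self._composed_source(defn, capture=False)
        if kind == "one_of":
            return "|".join(f"(?:{self.pattern_source(sub, defn.name)})"
                            for sub in p["alternatives"])
        raise AssertionError(kind)

    def _repeat(self, elem: str, separator: str, n_min: int,
                n_max: int | None) -> str:
        """Pattern for *n_min*..*n_max* elements joined by *separator*."""
        sep = re.escape(separator)
        e = f"(?:{elem})"
        if n_max == 0:
            return "(?:)"
        if not sep:
            hi = "" if n_max is None else n_max
            return f"{e}{{{n_min},{hi}}}"
        hi = "" if n_max is None else n_max - 1
        more = f"(?:{sep}{e}){{{max(n_min - 1, 0)},{hi}}}"
        body = f"{e}{more}"
        if n_min == 0:
            return f"(?:{body})?"
        return body

    def _composed_source(self, defn: DatatypeDefinition, capture: bool) -> str:
        p = defn.params
        sep = re.escape(p["separator"])
        n_req = p["n_required"]
        parts = []
        for i, (fname, sub) in enumerate(p["fields"]):
            src = f"(?:{self.pattern_source(sub, defn.name)})"
            if capture:
                src = f"(?P<_f{i}>{src})"
            parts.append(src)
        required, optional = parts[:n_req], parts[n_req:]
        if not required:
            return self._all_optional_source(parts, sep)
        # trailing optional fields nest so that separators pair with fields
        tail = ""
        for part in reversed(optional):
            tail = f"(?:{sep}{part}{tail})?"
        return sep.join(required) + tail

    def _all_optional_source(self, parts: list[str], sep: str) -> str:
        # f1 (sep f2 (sep f3 ...)?)? , whole thing optional
        inner = ""
        for part in reversed(parts[1:]):
            inner = f"(?:{sep}{part}{inner})?"
        return f"(?:{parts[0]}{inner})?"

    # -- compiled objects -------------------------------------------------
    def matcher(self, node, referrer: str = "?") -> CompiledMatcher:
        defn = self.resolve(node, referrer)
        key = id(defn)
        if key in self._matchers:
            return self._matchers[key]
        src = self.pattern_source(defn)
        anchored = rf"\A(?:{src})\Z"
        try:
            regex = re.compile(anchored)
        except re.error as exc:
            raise PatternError(
                f"cannot compile pattern for datatype {defn.name!r}: {exc}") from None
        if regex.groups > self.group_cap:
            raise PatternError(
                f"datatype {defn.name!r} compiles to {regex.groups} capturing "
                f"groups, exceeding the cap of {self.group_cap}")
        post = self._post_checks(defn)
        strategy = self._strategy(defn)
        m = CompiledMatcher(pattern=anchored, regex=regex, strategy=strategy,
                            post_checks=post)
        self._matchers[key] = m
        return m

    def _strategy(self, defn: DatatypeDefinition) -> str:
        if defn.kind in ("list_of", "labeled_list", "tagged_list", "composed_of"):
            if defn.params.get("splitted"):
                return "split"
            return "hybrid" if defn.kind == "composed_of" else "regex"
        return "regex"

    def _post_checks(self, defn: DatatypeDefinition) -> list:
        checks = []
        p = defn.params

        def stripped(text: str) -> str:
            if defn.prefix and text.startswith(defn.prefix):
                text = text[len(defn.prefix):]
            if defn.suffix and text.endswith(defn.suffix):
                text = text[:len(text) - len(defn.suffix)]
            return text

        if defn.kind == "integer" and (p["min"] is not None or p["max"] is not None):
            def int_range(text, _p=p):
                if defn.has_empty and text == "":
                    return True
                v = int(stripped(text))
                return ((_p["min"] is None or v >= _p["min"])
                        and (_p["max"] is None or v <= _p["max"]))
            checks.append(int_range)
        elif defn.kind == "unsigned_integer" and (p["min"] is not None
                                                  or p["max"] is not None):
            def uint_range(text, _p=p):
                if defn.has_empty and text == "":
                    return True
                v = parse_unsigned(stripped(text), _p["base"])
                return ((_p["min"] is None or v >= _p["min"])
                        and (_p["max"] is None or v <= _p["max"]))
            checks.append(uint_range)
        elif defn.kind == "float" and (p["min"] is not None or p["max"] is not None):
            def float_range(text, _p=p):
                if defn.has_empty and text == "":
                    return True
                v = float(stripped(text))
                lo, hi = _p["min"], _p["max"]
                if lo is not None and (v < lo or (v == lo and _p["min_excluded"])):
                    return False
                if hi is not None and (v > hi or (v == hi and _p["max_excluded"])):
                    return False
                return True
            checks.append(float_range)
        if defn.also_matches is not None:
            extra = re.compile(defn.also_matches)
            checks.append(lambda text: (defn.has_empty and text == "")
                          or extra.fullmatch(stripped(text)) is not None)
        if defn.kind == "labeled_list" and p["required"] and p.get("splitted"):
            sep, isep = p["separator"], p["internal_separator"]
            required = set(p["required"])

            def labels_present(text):
                core = stripped(text)
                if core == "":
                    return not required or defn.has_empty
                found = {el.split(isep, 1)[0] for el in core.split(sep)}
                return required <= found
            checks.append(labels_present)
        return checks

    def scanner(self, node, referrer: str = "?") -> "re.Pattern":
        """Unanchored compiled pattern, for scanning elements inside a list
        with a non-exclusive separator."""
        defn = self.resolve(node, referrer)
        key = id(defn)
        if key not in self._scanners:
            self._scanners[key] = re.compile(f"(?:{self.pattern_source(defn)})")
        return self._scanners[key]

    def struct_regex(self, node, referrer: str = "?") -> "re.Pattern":
        """Anchored pattern of a composition with one named group per field
        (``_f0`` ..), used by the regex parsing strategy."""
        defn = self.resolve(node, referrer)
        key = id(defn)
        if key not in self._struct:
            src = self._composed_source(defn, capture=True)
            self._struct[key] = re.compile(rf"\A(?:{src})\Z")
        return self._struct[key]


def partial_match_prefix(pattern: str, text: str) -> int:
    """Longest ``i`` such that ``text[:i]`` is a prefix of some string
    matching *pattern* — the first character at which no continuation can
    match is ``text[i]``.

    Best effort: a bounded backtracking walk over the parsed expression;
    exotic constructs (backreferences, lookarounds) end the walk early and
    the largest position reached so far is returned.
    """
    try:
        import re._parser as sre_parse
        import re._constants as sre
    except ImportError:  # pragma: no cover - older interpreters
        import sre_parse
        import sre_constants as sre
    try:
        parsed = list(sre_parse.parse(pattern))
    except re.error:
        return 0
    best = 0
    budget = [50000]

    def in_match(items, ch):
        negate = False
        hit = False
        for op, arg in items:
            if op is sre.NEGATE:
                negate = True
            elif op is sre.LITERAL:
                hit = hit or ord(ch) == arg
            elif op is sre.RANGE:
                hit = hit or arg[0] <= ord(ch) <= arg[1]
            elif op is sre.CATEGORY:
                if arg is sre.CATEGORY_DIGIT:
                    hit = hit or ch.isdigit()
                elif arg is sre.CATEGORY_WORD:
                    hit = hit or ch.isalnum() or ch == "_"
                elif arg is sre.CATEGORY_SPACE:
                    hit = hit or ch.isspace()
                elif arg is sre.CATEGORY_NOT_DIGIT:
                    hit = hit or not ch.isdigit()
                elif arg is sre.CATEGORY_NOT_WORD:
                    hit = hit or not (ch.isalnum() or ch == "_")
                elif arg is sre.CATEGORY_NOT_SPACE:
                    hit = hit or not ch.isspace()
        return hit != negate

    def item(node, pos):
        nonlocal best
        if budget[0] <= 0:
            return
        budget[0] -= 1
        op, arg = node
        if op is sre.LITERAL:
            if pos < len(text) and ord(text[pos]) == arg:
                yield pos + 1
        elif op is sre.NOT_LITERAL:
            if pos < len(text) and ord(text[pos]) != arg:
                yield pos + 1
        elif op is sre.ANY:
            if pos < len(text) and text[pos] != "\n":
                yield pos + 1
        elif op is sre.IN:
            if pos < len(text) and in_match(arg, text[pos]):
                yield pos + 1
        elif op is sre.SUBPATTERN:
            yield from seq(list(arg[3]), 0, pos)
        elif op is sre.ATOMIC_GROUP:
            yield from seq(list(arg), 0, pos)
        elif op is sre.BRANCH:
            for branch in arg[1]:
                yield from seq(list(branch), 0, pos)
        elif op in (sre.MAX_REPEAT, sre.MIN_REPEAT):
            lo, hi, sub = arg
            sub = list(sub)

            def rep(k, p):
                if budget[0] <= 0:
                    return
                if k >= lo:
                    yield p
                if k < hi:
                    for p2 in seq(sub, 0, p):
                        if p2 == p:
                            if k + 1 >= lo:
                                yield p2
                            break
                        yield from rep(k + 1, p2)
            yield from rep(0, pos)
        elif op is sre.AT:
            yield pos
        # anything else (backreferences, lookarounds): give up silently

    def seq(items, i, pos):
        nonlocal best
        best = max(best, pos)
        if budget[0] <= 0:
            return
        if i == len(items):
            yield pos
            return
        for p in item(items[i], pos):
            yield from seq(items, i + 1, p)

    for _ in seq(parsed, 0, 0):
        pass
    return min(best, len(text))


def parse_unsigned(text: str, base: int) -> int:
    """Parse an unsigned numeral, stripping the conventional radix prefix."""
    prefixes = {2: ("0b", "0B"), 8: ("0o", "0O"), 16: ("0x", "0X")}
    for pref in prefixes.get(base, ()):
        if text.startswith(pref) and len(text) > len(pref):
            text = text[len(pref):]
            break
    return int(text, base)


def format_unsigned(value: int, base: int, with_prefix: bool = False) -> str:
    """Canonical numeral of *value* in *base* (upper-case hex digits)."""
    digits = {2: "01", 8: "01234567", 10: "0123456789",
              16: "0123456789ABCDEF"}[base]
    if value == 0:
        text = "0"
    else:
        out = []
        v = value
        while v:
            v, r = divmod(v, base)
            out.append(digits[r])
        text = "".join(reversed(out))
    if with_prefix:
        text = {2: "0b", 8: "0o", 10: "", 16: "0x"}[base] + text
    return text
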