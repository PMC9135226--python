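"""Specification testing: embedded test data and automatic examples.

A specification may carry a ``testdata`` section with, per datatype,
valid (text -> expected value) pairs and invalid texts / values.
:func:`run_testdata` executes these expectations against the compiled
specification: valid texts must decode to the expected value and survive
an encode/re-decode round trip; invalid texts must fail validation;
invalid values must be rejected by encoding.

:func:`generate_examples` produces such test data automatically: valid
examples are built constructively per kind (a constant's text, value-set
members, interval boundary and interior points, recursive composition for
compounds, pattern-directed synthesis for regular-expression kinds) and
invalid examples by mutation (boundary violation, member corruption,
separator damage, prefix/suffix removal).  Generation is deterministic
given the seed.
"""

from __future__ import annotations

import random
import re
import string
from dataclasses import dataclass, field

from . import codec
from .compiler import Engine, format_unsigned
from .errors import TfslError, UnsatisfiableExampleError
from .model import DatatypeDefinition

try:  # Python >= 3.11
    import re._parser as _sre_parse
    import re._constants as _sre
except ImportError:  # pragma: no cover - older interpreters
    import sre_parse as _sre_parse
    import sre_constants as _sre


# ---------------------------------------------------------------------------
# test data containers
# ---------------------------------------------------------------------------

@dataclass
class DatatypeTests:
    """Examples for one datatype."""

    valid: list = field(default_factory=list)            # (text, value) pairs
    invalid_encoded: list = field(default_factory=list)  # texts
    invalid_decoded: list = field(default_factory=list)  # values


@dataclass
class Failure:
    datatype: str
    direction: str      # decode | reencode | invalid_encoded | invalid_decoded
    case: object
    expected: object
    observed: object

    def __str__(self):
        return (f"[{self.datatype}/{self.direction}] case {self.case!r}: "
                f"expected {self.expected!r}, observed {self.observed!r}")


@dataclass
class TestReport:
    passed: int = 0
    failed: int = 0
    failures: list = field(default_factory=list)

    @property
    def total(self):
        return self.passed + self.failed

    def ok(self) -> bool:
        return self.failed == 0

    def record(self, failure: Failure | None):
        if failure is None:
            self.passed += 1
        else:
            self.failed += 1
            self.failures.append(failure)


def parse_testdata(tree: dict) -> dict[str, DatatypeTests]:
    """Parse a ``testdata`` section tree into per-datatype examples."""
    out: dict[str, DatatypeTests] = {}
    for name, entry in (tree or {}).items():
        tests = DatatypeTests()
        if not isinstance(entry, dict):
            raise TfslError(f"testdata for {name!r} must be a mapping")
        valid = entry.get("valid", {})
        if isinstance(valid, dict):
            tests.valid = list(valid.items())
        else:
            tests.valid = [tuple(pair) for pair in valid]
        invalid = entry.get("invalid", {}) or {}
        tests.invalid_encoded = list(invalid.get("encoded", []))
        tests.invalid_decoded = list(invalid.get("decoded", []))
        out[name] = tests
    return out


def run_testdata(spec, tests) -> TestReport:
    """Execute test expectations against a compiled specification.

    *tests* is either a raw ``testdata`` tree or a name ->
    :class:`DatatypeTests` mapping.  Unknown datatype names are an error.
    """
    if tests and not isinstance(next(iter(tests.values())), DatatypeTests):
        tests = parse_testdata(tests)
    report = TestReport()
    engine = spec.engine
    for name, data in tests.items():
        if name not in spec.table:
            raise TfslError(f"testdata references unknown datatype {name!r}")
        defn = spec.table[name]
        for text, expected in data.valid:
            try:
                observed = codec.decode(text, defn, engine)
            except TfslError as exc:
                report.record(Failure(name, "decode", text, expected, str(exc)))
                continue
            if observed != expected:
                report.record(Failure(name, "decode", text, expected, observed))
                continue
            report.record(None)
            try:
                again = codec.decode(codec.encode(expected, defn, engine),
                                     defn, engine)
            except TfslError as exc:
                report.record(Failure(name, "reencode", text, expected,
                                      str(exc)))
                continue
            report.record(None if again == expected
                          else Failure(name, "reencode", text, expected, again))
        for text in data.invalid_encoded:
            ok = not codec.is_valid_encoded(text, defn, engine)
            report.record(None if ok else
                          Failure(name, "invalid_encoded", text,
                                  "rejection", "accepted"))
        for value in data.invalid_decoded:
            ok = not codec.is_valid_decoded(value, defn, engine)
            report.record(None if ok else
                          Failure(name, "invalid_decoded", value,
                                  "rejection", "accepted"))
    return report


# ---------------------------------------------------------------------------
# pattern-directed string synthesis
# ---------------------------------------------------------------------------

_PRINTABLE = [chr(c) for c in range(32, 127)]
_REPEAT_CAP = 3  # keep generated examples short and readable


def synthesize_from_pattern(pattern: str, rng: random.Random) -> str:
    """Generate a string matching *pattern* (bounded repetition)."""
    parsed = _sre_parse.parse(pattern)
    return _synth_seq(parsed, rng)


def _synth_seq(items, rng) -> str:
    return "".join(_synth_item(op, arg, rng) for op, arg in items)


def _synth_item(op, arg, rng) -> str:
    if op is _sre.LITERAL:
        return chr(arg)
    if op is _sre.NOT_LITERAL:
        pool = [c for c in _PRINTABLE if ord(c) != arg]
        return rng.choice(pool)
    if op is _sre.ANY:
        return rng.choice(_PRINTABLE)
    if op is _sre.IN:
        return rng.choice(_in_pool(arg))
    if op in (_sre.MAX_REPEAT, _sre.MIN_REPEAT):
        lo, hi, items = arg
        hi = min(hi, lo + _REPEAT_CAP)
        n = rng.randint(lo, hi)
        return "".join(_synth_seq(items, rng) for _ in range(n))
    if op is _sre.SUBPATTERN:
        return _synth_seq(arg[3], rng)
    if op is _sre.BRANCH:
        return _synth_seq(rng.choice(arg[1]), rng)
    if op is _sre.AT:
        return ""
    if op is _sre.CATEGORY:  # pragma: no cover - reached via IN normally
        return rng.choice(_category_pool(arg))
    if op is _sre.ATOMIC_GROUP:
        return _synth_seq(arg, rng)
    raise UnsatisfiableExampleError(
        f"cannot synthesize strings for regex construct {op}")


def _category_pool(cat):
    if cat is _sre.CATEGORY_DIGIT:
        return string.digits
    if cat is _sre.CATEGORY_NOT_DIGIT:
        return [c for c in _PRINTABLE if not c.isdigit()]
    if cat is _sre.CATEGORY_WORD:
        return string.ascii_letters + string.digits + "_"
    if cat is _sre.CATEGORY_NOT_WORD:
        return [c for c in _PRINTABLE
                if not (c.isalnum() or c == "_")]
    if cat is _sre.CATEGORY_SPACE:
        return " \t"
    if cat is _sre.CATEGORY_NOT_SPACE:
        return [c for c in _PRINTABLE if not c.isspace()]
    raise UnsatisfiableExampleError(f"unsupported category {cat}")


def _in_pool(items):
    negate = False
    pool: list[str] = []
    for op, arg in items:
        if op is _sre.NEGATE:
            negate = True
        elif op is _sre.LITERAL:
            pool.append(chr(arg))
        elif op is _sre.RANGE:
            pool.extend(chr(c) for c in range(arg[0], min(arg[1], 0x10FFF) + 1))
        elif op is _sre.CATEGORY:
            pool.extend(_category_pool(arg))
    if negate:
        excluded = set(pool)
        pool = [c for c in _PRINTABLE if c not in excluded]
    pool = [c for c in pool if c.isprintable() or c in "\t"]
    if not pool:
        raise UnsatisfiableExampleError("empty character class")
    return pool


# ---------------------------------------------------------------------------
# example generation
# ---------------------------------------------------------------------------

def generate_examples(defn: DatatypeDefinition, n_valid: int, n_invalid: int,
                      seed: int, engine: Engine) -> DatatypeTests:
    """Deterministically generate valid/invalid examples for *defn*.

    Valid examples are constructed per kind and returned as (text, value)
    pairs; invalid examples are mutations verified to fail validation.
    Raises :class:`UnsatisfiableExampleError` when the request cannot be
    met (e.g. invalid examples of a definition accepting every string).
    """
    if n_valid < 0 or n_invalid < 0:
        raise ValueError("counts must be non-negative")
    rng = random.Random(seed)
    tests = DatatypeTests()

    texts: list[str] = []
    seen: set[str] = set()
    attempts = 0
    while len(texts) < n_valid and attempts < 50 * max(n_valid, 1):
        attempts += 1
        force_fresh = len(seen) < n_valid and attempts < 20 * max(n_valid, 1)
        text = _valid_text(defn, engine, rng, len(texts))
        if text is None:
            continue
        if not codec.is_valid_encoded(text, defn, engine):
            continue
        if force_fresh and text in seen:
            continue
        texts.append(text)
        seen.add(text)
    if len(texts) < n_valid:
        raise UnsatisfiableExampleError(
            f"could not generate {n_valid} valid example(s) for "
            f"datatype {defn.name!r}")
    tests.valid = [(t, codec.decode(t, defn, engine)) for t in texts]

    if n_invalid:
        tests.invalid_encoded = _invalid_texts(defn, engine, rng, n_invalid,
                                               texts or [""])
    return tests


def _valid_text(defn, engine, rng, index):
    defn = engine.resolve(defn)
    kind, p = defn.kind, defn.params
    if defn.has_empty and rng.random() < 0.1:
        return ""

    if kind == "constant":
        core = p["text"]
    elif kind == "values":
        members = p["values"]
        core = members[index % len(members)] if rng.random() < 0.7 \
            else rng.choice(members)
    elif kind == "regex":
        core = synthesize_from_pattern(p["pattern"], rng)
    elif kind == "regexes":
        core = synthesize_from_pattern(rng.choice(p["patterns"]), rng)
    elif kind == "integer":
        core = str(_interval_point(p["min"], p["max"], rng, index))
    elif kind == "unsigned_integer":
        lo = p["min"] if p["min"] is not None else 0
        v = _interval_point(lo, p["max"], rng, index)
        core = format_unsigned(v, p["base"], p["with_prefix"])
        if not p["with_prefix"] and p["base"] != 10 and rng.random() < 0.25:
            core = {2: "0b", 8: "0o", 16: "0x"}[p["base"]] + core
    elif kind == "float":
        core = _float_point(p, rng, index)
    elif kind == "list_of":
        hi = p["max_length"] if p["max_length"] is not None \
            else p["min_length"] + 2
        n = p["min_length"] if index == 0 else rng.randint(p["min_length"], hi)
        parts = [_valid_text(p["element"], engine, rng, i) for i in range(n)]
        if any(part is None for part in parts):
            return None
        core = p["separator"].join(parts)
    elif kind == "labeled_list":
        labels = list(p["labels"])
        chosen = [lab for lab in labels
                  if lab in p["required"] or rng.random() < 0.5]
        rng.shuffle(chosen)
        isep = p["internal_separator"]
        parts = []
        for lab in chosen:
            t = _valid_text(p["labels"][lab], engine, rng, index)
            if t is None:
                return None
            parts.append(lab + isep + t)
        core = p["separator"].join(parts)
    elif kind == "tagged_list":
        isep = p["internal_separator"]
        n = rng.randint(0, 2)
        parts, used = [], set()
        for _ in range(n):
            name = synthesize_from_pattern(p["tagname"], rng)
            if name in used:
                continue
            used.add(name)
            code = rng.choice(list(p["codes"]))
            t = _valid_text(p["codes"][code], engine, rng, index)
            if t is None:
                return None
            parts.append(name + isep + code + isep + t)
        core = p["separator"].join(parts)
    elif kind == "composed_of":
        n_fields = len(p["fields"])
        n = n_fields if index == 0 else rng.randint(p["n_required"], n_fields)
        parts = []
        for fname, sub in p["fields"][:n]:
            t = _valid_text(sub, engine, rng, index)
            if t is None:
                return None
            parts.append(t)
        core = p["separator"].join(parts)
    elif kind == "one_of":
        alts = p["alternatives"]
        core_text = _valid_text(alts[index % len(alts)], engine, rng, index)
        if core_text is None:
            return None
        core = core_text
    else:  # pragma: no cover
        raise AssertionError(kind)
    return defn.prefix + core + defn.suffix


def _interval_point(lo, hi, rng, index):
    if lo is None and hi is None:
        lo, hi = -100, 100
    elif lo is None:
        lo = hi - 200
    elif hi is None:
        hi = lo + 200
    if index == 0:
        return lo
    if index == 1:
        return hi
    return rng.randint(lo, hi)


def _float_point(p, rng, index):
    lo, hi = p["min"], p["max"]
    if lo is None and hi is None:
        lo, hi = -100.0, 100.0
    elif lo is None:
        lo = hi - 200.0
    elif hi is None:
        hi = lo + 200.0
    if index == 0 and not p["min_excluded"]:
        return repr(float(lo))
    if index == 1 and not p["max_excluded"]:
        return repr(float(hi))
    span = hi - lo
    v = lo + span * (0.25 + 0.5 * rng.random())
    if span == 0:
        v = lo
    return repr(float(v))


_JUNK = "\x01"


def _invalid_texts(defn, engine, rng, n_invalid, valid_texts):
    defn = engine.resolve(defn)
    candidates: list[str] = []

    def boundary_violations():
        p = defn.params
        if defn.kind in ("integer", "unsigned_integer"):
            if p["min"] is not None:
                yield defn.prefix + str(p["min"] - 1) + defn.suffix
            if p["max"] is not None:
                yield defn.prefix + str(p["max"] + 1) + defn.suffix
        if defn.kind == "float":
            if p["min"] is not None:
                yield defn.prefix + repr(float(p["min"]) - 1.0) + defn.suffix
                if p["min_excluded"]:
                    yield defn.prefix + repr(float(p["min"])) + defn.suffix
            if p["max"] is not None:
                yield defn.prefix + repr(float(p["max"]) + 1.0) + defn.suffix
                if p["max_excluded"]:
                    yield defn.prefix + repr(float(p["max"])) + defn.suffix

    candidates.extend(boundary_violations())
    junk_chars = (_JUNK, "\t", "\n", " ")
    for text in list(valid_texts)[:10]:
        for junk in junk_chars:
            candidates.append(text + junk)
            candidates.append(junk + text)
        if text:
            candidates.append(text[1:])
            candidates.append(text[:-1])
            pos = rng.randrange(len(text))
            for junk in junk_chars:
                candidates.append(text[:pos] + junk + text[pos + 1:])
        if defn.prefix and text.startswith(defn.prefix):
            candidates.append(text[len(defn.prefix):])
        if defn.suffix and text.endswith(defn.suffix):
            candidates.append(text[:len(text) - len(defn.suffix)] or _JUNK)
        sep = defn.params.get("separator")
        if sep and sep in text:
            candidates.append(text.replace(sep, _JUNK, 1))
    if "" not in valid_texts:
        candidates.append("")

    out, seen = [], set()
    for cand in candidates:
        if cand in seen:
            continue
        seen.add(cand)
        if not codec.is_valid_encoded(cand, defn, engine):
            out.append(cand)
            if len(out) == n_invalid:
                return out
    raise UnsatisfiableExampleError(
        f"could not construct {n_invalid} invalid example(s) for "
        f"datatype {defn.name!r} (only {len(out)} found); the definition "
        "may accept every candidate mutation")


def generate_spec_examples(spec, n_valid: int, n_invalid: int, seed: int,
                           names=None) -> dict[str, DatatypeTests]:
    """Generate examples for every (or the named) datatype of a compiled
    specification; per-datatype seeds are derived deterministically."""
    out = {}
    for i, name in enumerate(sorted(names or spec.table)):
        out[name] = generate_examples(spec.table[name], n_valid, n_invalid,
                                      seed + 7919 * i, spec.engine)
    return out


def testdata_to_tree(tests: dict[str, DatatypeTests]) -> dict:
    """Serialize generated examples back to a ``testdata`` section tree."""
    tree = {}
    for name, data in tests.items():
        entry: dict = {}
        if data.valid:
            entry["valid"] = {text: value for text, value in data.valid}
        invalid = {}
        if data.invalid_encoded:
            invalid["encoded"] = list(data.invalid_encoded)
        if data.invalid_decoded:
            invalid["decoded"] = list(data.invalid_decoded)
        if invalid:
            entry["invalid"] = invalid
        tree[name] = entry
    return tree
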