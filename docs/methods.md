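# Methods

This note documents the model behind `tfsl`, the concrete choices made
where the design was open, and what the shipped tests do and do not show.

## The specification model

A specification is a tree-shaped document with four sections: `datatypes`
(name → definition), optional `testdata`, optional `include`, optional
`namespace`.  A definition selects exactly one of twelve *kinds* by its
key — `constant`, `values`, `regex`, `regexes`, `integer`,
`unsigned_integer`, `float`, `list_of`, `labeled_list`, `tagged_list`,
`composed_of`, `one_of` — and sibling keys carry the formatting,
validation and transformation rules.  Two shorthands keep files short: a
bare string is a constant, a bare list is a value set.  `$name` is a
reference; the `$` sigil makes references syntactically distinct from
constant shorthands in every position.

Decoded data lives in the JSON data domain: `None`, booleans, integers,
floats, strings, lists, and string-keyed mappings.  `composed_of` decodes
to a mapping keyed by field names; `list_of` to a list; `labeled_list` to
a label→value mapping; `tagged_list` to name→`{"type": code, "value": v}`
(the code is kept because it selects the value's datatype and is needed to
re-encode); `one_of` to the first matching alternative's value.

## Compilation

Loading proceeds in phases: parse the document (YAML 1.2 via PyYAML, or
JSON), resolve `include` entries recursively (a file appearing twice on
the loading stack is an include cycle), validate every definition tree
(diagnostics carry a path and the set of keys valid at that point),
normalize to a canonical in-memory form, build the dependency graph of
references, reject cycles with an iterative depth-first search that
returns one witness cycle, and compile one anchored regular expression per
datatype.  The resolved name→definition hash table plus the compiled
matchers is the unit the rest of the library works with; it can be
serialized to a versioned JSON archive.  The archive stores normalized
definition trees, not compiled automata — matchers are re-derived on load,
which is cheap and keeps the archive independent of the host regex engine.

### Regular expressions and the split strategy

Patterns are built bottom-up with non-capturing groups only; literal
prefixes, suffixes and delimiters are regex-escaped, so metacharacters in
user literals can never change the accepted language.  User-supplied
patterns are embedded after rewriting named groups to non-capturing groups
(a pattern using named backreferences is rejected with a clear error); a
configurable cap (default 500 capturing groups per datatype) guards
against pathological user patterns.

Two parsing strategies exist, chosen by the rule key.  `splitted_by`
declares the delimiter *exclusive* (it never occurs inside elements) and
enables split-based parsing; `separator` makes no such promise and forces
regex-based parsing.  A `composed_of` with a non-exclusive separator is
parsed by a single expression with one named group per field capturing a
raw slice; each slice is then decoded recursively with its own machinery
(hierarchical parsing), so nesting depth is not limited by engine group
capacity.  A `list_of` with a non-exclusive separator is decoded by a
greedy left-to-right element scan without cross-element backtracking; the
full-pattern validator does backtrack, so for adversarial definitions the
two can disagree.  All shipped builtin specifications use exclusive
delimiters for lists, where the question does not arise; this is the one
known soft spot of the dual-route design and is deliberately documented
rather than papered over.

Numeric kinds compile to a digit-envelope pattern plus a post-match range
check — an exact interval-to-regex expansion explodes for wide intervals,
and the range check is part of validation anyway.  Consequently the raw
pattern of a *compound* containing a bounded numeric component
over-accepts slightly; `is_valid_encoded` is therefore defined as "decode
succeeds" (with the pattern as a fast rejection path) and is always exact.

### Numeric conventions

Integers decode exactly (`int`); leading zeros and a leading `-` are
accepted, `+` likewise.  `unsigned_integer` accepts the conventional radix
prefixes (`0x`/`0X`, `0o`, `0b`) on decode and emits none by default
(upper-case hex digits; set `with_prefix` to emit the prefix).  Floats
decode to binary floating point; encode uses Python's shortest round-trip
representation, so `decode(encode(v)) == v` exactly.  Float interval
bounds are closed by default and opened per side with
`min_excluded`/`max_excluded`; integer intervals are always closed.

### Encoding and canonical texts

When several texts decode to one value (a non-injective `decoded` map),
encode emits the first-listed text, unless a `canonical` rule names
another.  This makes the *value* round trip (`decode(encode(v)) == v`)
exact, while the *text* round trip is semantic: `encode(decode(t))` may
normalize `t` to its canonical spelling.  For `regexes` with per-pattern
mapped values, only literal patterns define an encodable text; values
mapped from genuinely regular patterns cannot be inverted and raise an
encoding error.

## File scopes and streaming

File decoding applies a definition under one of four scopes: *line* (one
record per line), *unit* (a fixed number of lines per record; a file whose
line count is not a multiple of the unit size is an error — strictness
favoured), *section* (maximal runs of lines matching the element
definition — greedy, so ties are impossible), and *file*.  File-scope
definitions are line-structured compounds (`list_of`/`composed_of` with
`splitted_by: "\n"`); the structural parser consumes lines greedily, which
resolves section boundaries by maximal munch, enforces required sections
and length bounds, and reports violations with 1-based line numbers.  With
`streaming=True` the elements of the outermost compound are emitted one at
a time while the same structural checks run across the stream, so
streaming and whole-file decoding provably agree (a test compares them
record by record on generated files).  Input newlines are normalized
(universal newlines); a trailing final newline is optional; encode emits
`\n`.

## Error locality

Decoding errors carry the failing sub-definition path and a character
offset.  Offsets are absolute (threaded through nested decoding) and
best-effort: for constants and value sets the longest common prefix, for
pattern kinds the longest prefix of the text that is a prefix of some
matching string, computed by a bounded backtracking walk over the parsed
expression (budgeted; exotic constructs fall back to the largest position
reached).  Crafted-fixture tests pin the exact offsets for representative
shapes.

## Includes, namespaces, overrides

Include paths resolve relative to the including file.  A file's declared
`namespace` prefixes its datatype names (`ns::name`) when exported, and
references among its own datatypes are re-qualified mechanically.  Name
collisions without a namespace are an error unless the colliding trees are
identical (so diamond imports are idempotent).  A whitelist (`names`)
imports only the listed datatypes plus their transitive dependencies.
Overrides address any sub-tree of an imported definition by a dotted key
path; all components but the last must exist, the last may be new — that
is exactly what lets a patched specification *add* a tag type code.  For
the repair idiom, `tagged_list` additionally supports `code_aliases`
(alias code → canonical code, applied at decode), so a file carrying an
invalid code can be decoded through the patched specification and
re-encoded with the unmodified one in its corrected form.  Overrides apply
before namespacing and testdata of included files is not merged.

## Specification testing and example generation

`testdata` sections carry, per datatype, valid `text: value` pairs and
invalid texts/values.  Execution asserts decode equality, an
encode/re-decode round trip, and rejection of the invalid cases.  Example
generation is constructive per kind (a constant's text; value-set members;
interval boundaries — both endpoints are always among the first three
examples — and seeded interior points; recursive composition for
compounds) and pattern-directed for regex kinds, via a synthesizer over
the standard library's parsed expression tree with repetition capped at 3
to keep examples short and inspectable.  Invalid examples are mutations —
boundary violations, junk-character insertion (including tab/newline,
which most single-line datatypes exclude), separator corruption,
prefix/suffix removal — each verified to fail validation; a definition
accepting every candidate mutation makes the request unsatisfiable, which
is reported as such.  Generation is deterministic given the seed.

## Builtin specifications and fixtures

The NCBI identifier and accession grammars are encoded from the public
documentation of the databases (URLs in the specification files); every
documented example identifier is embedded as test data.  The EGC builtin
follows the format's structural rules (tab separation, `#` comments,
single-letter record type, non-empty fields, `.` for missing); the
positional-field semantics per record type are an illustrative schema
fixed by this package and marked non-canonical in the file.  The GFA
builtin is a reduced, representative subset (H/S/L lines plus the tag
system), not a full-fidelity GFA1 grammar.  The fixture generator emulates
well-formed files only — realistic record mixes, seeded sequences,
quality strings of matching length — and none of real data's pathologies
(encoding damage, truncation, nonstandard dialects); passing tests
demonstrate correctness of the machinery on specification-conformant
input, not robustness to arbitrary real-world files.  Cross-record
semantics (identifier uniqueness, coordinate consistency,
sequence/quality length equality) are the caller's layer by design.

## Problem sizes

The shipped test suite and the acceptance script use: 100 generated
values per builtin datatype for round trips (~10,300 checks), exhaustive
enumeration of all 156 strings of length ≤ 3 over a 5-symbol alphabet for
5 scalar datatypes, 50 random graphs of ≤ 8 nodes against a
path-enumeration oracle, a 1000-record generated EGC file for
streaming equivalence, ~1000 seeded inputs for archive equivalence, and
generator seeds 0–4 for self-test closure.  The whole suite runs in a few
seconds on one CPU.

## Known limitations

Formats must be regular languages; embedded recursive payloads (e.g.
JSON-in-a-field) are an open extension point.  Non-exclusive-separator
lists decode greedily (above).  `labeled_list`/`tagged_list` require an
exclusive element delimiter.  Duplicate labels in input take
last-occurrence-wins semantics.  Archives are versioned and refuse to load
across dialect versions.  The dialect is internally consistent and fully
documented here, but files written for other tools in this family are not
guaranteed byte-compatible.
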