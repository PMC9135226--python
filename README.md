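# tfsl — declarative specifications for line-oriented text formats

Much of bioinformatics data lives in flat text files — FASTA, FASTQ, SAM,
GFA, GFF3, accession lists — and for every new or niche format someone ends
up hand-writing yet another parser.  `tfsl` takes the opposite approach: you
*describe* the format once, declaratively, in a small YAML/JSON dialect (the
Text Formats Specification Language), and the library compiles that
description into working machinery for

- **decoding** — turning format text into structured data (dicts, lists,
  numbers, booleans, `None`),
- **encoding** — writing such data back as canonical format text,
- **validation** — of a text against the format, or of data against
  representability,
- **file decoding** — with *line*, fixed-size *unit*, maximal *section* and
  whole-*file* scopes, including element-at-a-time streaming that still
  enforces the global file structure (e.g. "header section before body"),
- **specification testing** — embedded valid/invalid examples are executed
  automatically, and new examples (valid and invalid) can be generated from
  the definitions themselves.

It is aimed at people who need a working, validating parser+writer for a
format in minutes — tool authors, pipeline builders, and anyone defining a
new format who wants the format description to *be* the implementation.

## The specification language

A format is a set of named **datatypes**.  Scalar kinds: `constant`,
`values` (closed set), `regex` / `regexes`, `integer`, `unsigned_integer`
(base 2/8/10/16), `float` (open or closed interval bounds).  Compound
kinds: `list_of`, `labeled_list` (label:value), `tagged_list`
(name:typecode:value, as in SAM/GFA tags), `composed_of` (ordered named
fields), `one_of` (alternatives, first match wins).  Rules attach to any
definition: formatting (`prefix`, `suffix`, `splitted_by` / `separator`),
validation (interval bounds, lengths, required labels), and transformation
(`decoded` maps like `{"T": true, "F": false}` or roman numerals to
integers, `empty` for empty-string values, `canonical` to pick the emitted
text when several are valid).  `$name` references another datatype;
specifications can `include` other files, with namespaces (`ns::name`) and
surgical overrides of imported definitions.

Internally, each datatype compiles to an anchored regular expression (or a
split-based plan where a delimiter is exclusive); references are resolved
through a dependency graph with depth-first cycle detection, and the
resolved table can be saved as a versioned archive and reloaded without
recompilation.  Formats must be regular languages — arbitrarily nested
grammars such as Newick are out of scope by design.

Builtin specifications ship for: NCBI FASTA sequence identifiers (all 22
database-tag classes, e.g. `sp|P01013|OVAX_CHICK`), sequence-database
accessions (SRA/ERA/DRA, UniProt, RefSeq, Ensembl, BioProject/BioSample,
INSD, Trace), FASTA, FASTQ, a GFA1-like subset with the tag system, and
EGC ("expected genomic content"), a tab-separated rule format with four
record types (A attribute, T taxon, P phenotype group, E expectation) and
`.` as missing-value marker.

## Worked example

```python
>>> from tfsl import Specification, generate_fixture
>>> spec = Specification.builtin("ncbi_id")
>>> spec["ncbi_id"].decode("sp|P01013|OVAX_CHICK")
{'db_tag': 'sp', 'fields': ['P01013', 'OVAX_CHICK']}
>>> spec["ncbi_id"].encode({'db_tag': 'gi', 'fields': ['21434723']})
'gi|21434723'
```

The identifier was parsed into its database tag (`sp`, SWISS-Prot) and its
pipe-separated fields; encoding is the exact inverse.  File decoding with
the EGC builtin (fixture generated deterministically, seed 4):

```python
>>> import io
>>> egc = Specification.builtin("egc")
>>> text = generate_fixture("egc", 6, seed=4)
>>> for record in egc["line"].decode_file(io.StringIO(text)):
...     print(record.source_span, record.value)
(1, 1) {'record_type': 'A', 'id': 'gc_content_0', 'name': 'gc content 0', 'computation': None}
(2, 2) {'record_type': 'T', 'id': 'tax0', 'taxon_name': 'Escherichia coli', 'rank': 'species'}
(3, 3) {'record_type': 'E', 'subject_id': 'tax0', 'attribute_id': 'gc_content_0', 'operator': '=', 'value': 'motile'}
...
```

Each line became a typed record; the `.` in the attribute line decoded to
`None` (the missing-value rule).  The same operations are available from
the shell, pipe-friendly:

```sh
$ tf_decode string -s ncbi_id -t ncbi_id "lcl|hnm271"
{"db_tag": "lcl", "fields": ["hnm271"]}
$ tf_validate encoded -s ncbi_id -t ncbi_id "gim|442187"; echo $?
0
$ tf_spec test -s egc
25 passed, 0 failed
```

`tf_decode file` emits newline-delimited JSON, `tf_encode json` turns it
back into format text, `tf_spec gentest` generates example test data, and
`tf_spec compile` writes a precompiled archive.

A practical repair idiom: when a tool emits files with an invalid GFA tag
type code `z`, import the builtin specification with an override
(`code_aliases: {z: Z}`), decode the broken file with the patched
specification, and re-encode with the original one — the output is valid
again.

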