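# EGC ("expected genomic content"): rules describing the expected content
# of a microbial genome under a given condition (phenotype, lifestyle or
# taxonomic membership).
#
# Line-oriented, GFA-style: each line not starting with '#' is a record of
# tab-separated fields; the first field is a single letter giving the
# record type; positional fields are never empty and never contain tabs or
# newlines; a point '.' marks missing information where allowed.
#
# Record types:
#   A  attribute definition: id, human-readable name, computation
#   T  taxon subject group:  id, taxon name, rank
#   P  phenotype subject group: id, description
#   E  expectation: subject id, attribute id, operator, expected value
#
# The positional-field semantics beyond the structural rules above are an
# illustrative schema fixed by this package, not an upstream-canonical one.
datatypes:
  identifier:
    regex: "[A-Za-z_][A-Za-z0-9_]*"

  # any non-empty tab-free text that is not the missing-value marker
  text_field:
    regex: "(?:[^\\t\\n.][^\\t\\n]*|\\.[^\\t\\n]+)"

  missing:
    constant: "."
    decoded: {".": null}

  maybe_text:
    one_of: ["$missing", "$text_field"]

  rank:
    one_of:
      - "$missing"
      - values: [domain, phylum, class, order, family, genus, species, strain]

  operator:
    values: ["=", "!=", "<", "<=", ">", ">="]

  expected_value:
    one_of:
      - "$missing"
      - integer: {}
      - float: {}
      - "$text_field"

  attribute_record:
    composed_of:
      - record_type: "A"
      - id: "$identifier"
      - name: "$text_field"
      - computation: "$maybe_text"
    splitted_by: "\t"

  taxon_record:
    composed_of:
      - record_type: "T"
      - id: "$identifier"
      - taxon_name: "$text_field"
      - rank: "$rank"
    splitted_by: "\t"

  phenotype_record:
    composed_of:
      - record_type: "P"
      - id: "$identifier"
      - description: "$text_field"
    splitted_by: "\t"

  expectation_record:
    composed_of:
      - record_type: "E"
      - subject_id: "$identifier"
      - attribute_id: "$identifier"
      - operator: "$operator"
      - value: "$expected_value"
    splitted_by: "\t"

  comment:
    regex: "#[^\\n]*"

  line:
    one_of:
      - "$comment"
      - "$attribute_record"
      - "$taxon_record"
      - "$phenotype_record"
      - "$expectation_record"
    scope: line

  file:
    list_of: "$line"
    splitted_by: "\n"
    min_length: 0
    scope: file

testdata:
  line:
    valid:
      "# expected genomic content": "# expected genomic content"
      "A\tgc_content\tGC content\tsequence_statistic":
        {record_type: A, id: gc_content, name: "GC content",
         computation: sequence_statistic}
      "A\ttrna_count\ttRNA gene count\t.":
        {record_type: A, id: trna_count, name: "tRNA gene count",
         computation: null}
      "T\ttax1\tEscherichia coli\tspecies":
        {record_type: T, id: tax1, taxon_name: "Escherichia coli",
         rank: species}
      "T\ttax2\tBacteria\t.":
        {record_type: T, id: tax2, taxon_name: Bacteria, rank: null}
      "P\tpheno1\tthermophilic":
        {record_type: P, id: pheno1, description: thermophilic}
      "E\ttax1\tgc_content\t>=\t0.4":
        {record_type: E, subject_id: tax1, attribute_id: gc_content,
         operator: ">=", value: 0.4}
      "E\ttax1\ttrna_count\t>\t40":
        {record_type: E, subject_id: tax1, attribute_id: trna_count,
         operator: ">", value: 40}
    invalid:
      encoded:
        - "A\tgc_content"
        - "X\ta\tb\tc"
        - "A\t\tGC content\t."
        - "A gc_content GC content ."
        - "E\ttax1\tgc_content\t~\t0.4"
        - ""
      decoded:
        - {record_type: A, id: gc_content}
        - {record_type: Q, id: a, name: b, computation: c}
        - 42
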