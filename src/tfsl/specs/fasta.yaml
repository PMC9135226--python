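# FASTA sequence files: entries of one '>' header line followed by one or
# more sequence lines.  Header identifiers may follow the NCBI FASTA
# identifier grammar (imported) or be simple free-form identifiers.
include:
  - path: ncbi_id.yaml

datatypes:
  simple_id:
    regex: "[A-Za-z0-9_.:#+/-]+"

  header:
    composed_of:
      - id:
          one_of: ["$ncbi::ncbi_id", "$simple_id"]
      - description: {regex: "[ -~]*", prefix: " "}
    n_required: 1
    prefix: ">"

  sequence_line:
    regex: "[A-Za-z*-]+"

  entry:
    composed_of:
      - header: "$header"
      - sequence: {list_of: "$sequence_line", splitted_by: "\n", min_length: 1}
    splitted_by: "\n"

  file:
    list_of: "$entry"
    splitted_by: "\n"
    min_length: 0
    scope: file

testdata:
  header:
    valid:
      ">seq1 first test sequence":
        {id: seq1, description: "first test sequence"}
      ">sp|P01013|OVAX_CHICK GENE X PROTEIN":
        {id: {db_tag: sp, fields: ["P01013", "OVAX_CHICK"]},
         description: "GENE X PROTEIN"}
      ">contig_4":
        {id: contig_4}
    invalid:
      encoded: ["seq1", "> seq1", ">"]
  sequence_line:
    valid:
      "ACGTACGT": "ACGTACGT"
      "MKVLA*": "MKVLA*"
    invalid:
      encoded: ["ACGT ACGT", ""]
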