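# A representative subset of the GFA1 assembly-graph format: header (H),
# segment (S) and link (L) lines plus comments, with the optional-tag
# system (name:typecode:value).  Reduced to the structure needed for
# section/override testing; not a full-fidelity GFA1 grammar.
namespace: gfa

datatypes:
  segment_name:
    regex: "[A-Za-z0-9_.+-]+"

  orientation:
    values: ["+", "-"]

  # '*' means: sequence not stored; decoded as null
  sequence:
    one_of:
      - constant: "*"
        decoded: {"*": null}
      - regex: "[A-Za-z=.]+"

  cigar:
    one_of:
      - constant: "*"
        decoded: {"*": null}
      - regex: "(?:[0-9]+[MIDNSHPX=])+"

  tag_value_A: {regex: "[!-~]"}
  tag_value_i: {integer: {}}
  tag_value_f: {float: {}}
  tag_value_Z: {regex: "[ !-~]*"}
  tag_value_H: {regex: "(?:[0-9A-F][0-9A-F])*"}

  tags:
    tagged_list:
      A: "$tag_value_A"
      i: "$tag_value_i"
      f: "$tag_value_f"
      Z: "$tag_value_Z"
      H: "$tag_value_H"
    tagname: "[A-Za-z][A-Za-z0-9]"
    splitted_by: "\t"

  header_line:
    composed_of:
      - record_type: "H"
      - tags: "$tags"
    separator: "\t"
    n_required: 1

  segment_line:
    composed_of:
      - record_type: "S"
      - name: "$segment_name"
      - sequence: "$sequence"
      - tags: "$tags"
    separator: "\t"
    n_required: 3

  link_line:
    composed_of:
      - record_type: "L"
      - from_segment: "$segment_name"
      - from_orient: "$orientation"
      - to_segment: "$segment_name"
      - to_orient: "$orientation"
      - overlap: "$cigar"
      - tags: "$tags"
    separator: "\t"
    n_required: 6

  comment:
    regex: "#[^\\n]*"

  line:
    one_of:
      - "$comment"
      - "$header_line"
      - "$segment_line"
      - "$link_line"
    scope: line

  file:
    list_of: "$line"
    splitted_by: "\n"
    min_length: 0
    scope: file

testdata:
  line:
    valid:
      "H\tVN:Z:1.0":
        {record_type: H, tags: {VN: {type: Z, value: "1.0"}}}
      "S\ts1\tACGTACGT":
        {record_type: S, name: s1, sequence: ACGTACGT}
      "S\ts2\t*\tLN:i:4721\tRC:i:123":
        {record_type: S, name: s2, sequence: null,
         tags: {LN: {type: i, value: 4721}, RC: {type: i, value: 123}}}
      "L\ts1\t+\ts2\t-\t12M":
        {record_type: L, from_segment: s1, from_orient: "+",
         to_segment: s2, to_orient: "-", overlap: "12M"}
      "# assembly graph": "# assembly graph"
    invalid:
      encoded:
        - "S\ts1"
        - "S\ts1\tACGT\txx:z:hello"
        - "Q\ts1\tACGT"
        - "L\ts1\t?\ts2\t-\t12M"
        - "S\ts1\tACGT\tGCJ:i:1"
      decoded:
        - {record_type: S, name: s1}
        - {record_type: S, name: s1, sequence: ACGT,
           tags: {xx: {type: z, value: hello}}}
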