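# FASTQ sequencing reads: four-line records (title, sequence, separator,
# quality).  The equal-length constraint between sequence and quality is a
# cross-field check left to the caller.
datatypes:
  title:
    composed_of:
      - id: {regex: "[!-~]+"}
      - description: {regex: "[ -~]*", prefix: " "}
    n_required: 1
    prefix: "@"

  sequence:
    regex: "[A-Za-z]+"

  separator_line:
    regex: "\\+[ -~]*"

  quality:
    regex: "[!-~]+"

  read:
    composed_of:
      - title: "$title"
      - sequence: "$sequence"
      - separator: "$separator_line"
      - quality: "$quality"
    splitted_by: "\n"
    scope: unit
    unit_size: 4

  file:
    list_of: "$read"
    splitted_by: "\n"
    min_length: 0
    scope: file

testdata:
  read:
    valid:
      "@r1 sample\nACGT\n+\nIIII":
        {title: {id: r1, description: sample}, sequence: ACGT,
         separator: "+", quality: IIII}
      "@r2\nACGTA\n+r2\nII#I!":
        {title: {id: r2}, sequence: ACGTA, separator: "+r2",
         quality: "II#I!"}
    invalid:
      encoded:
        - "r1\nACGT\n+\nIIII"
        - "@r1\nACGT\nIIII"
        - "@r1\nAC GT\n+\nIIII"
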