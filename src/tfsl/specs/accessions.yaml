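# Accession identifiers of the NCBI, DDBJ, ENA/EBI and UniProt sequence
# databases.  Grammar per the public documentation of the databases:
#   https://www.ncbi.nlm.nih.gov/Sequin/acc.html
#   https://www.ddbj.nig.ac.jp/acc_def-e.html
#   https://www.ddbj.nig.ac.jp/prefix-e.html#dra
#   https://www.ncbi.nlm.nih.gov/books/NBK21091/
#   https://www.uniprot.org/help/accession_numbers
#   https://www.ensembl.org/info/genome/stable_ids/prefixes.html
namespace: acc

datatypes:
  accession:
    one_of:
      - "$insd_read_archive"
      - "$uniprot"
      - "$trace_archive"
      - "$insd_metadata"
      - "$refseq"
      - "$ensembl"
      - "$insd_sequence"

  # INSD read archives (SRA/ERA/DRA): institution, data type, entry number
  insd_read_archive:
    composed_of:
      - institution:
          values: ["S", "E", "D"]
          decoded: {"S": "NCBI", "E": "ENA/EBI", "D": "DDBJ"}
      - archive: "R"
      - record_type:
          values: ["P", "R", "S", "X", "Z", "A"]
          decoded:
            "P": study
            "R": run
            "S": sample
            "X": experiment
            "Z": analysis
            "A": submission
      - entry: {regex: "[0-9]{6,}"}

  # UniProtKB entry accession
  uniprot:
    regex: "(?:[OPQ][0-9][A-Z0-9]{3}[0-9]|[A-NR-Z][0-9](?:[A-Z][A-Z0-9]{2}[0-9]){1,2})"

  # Trace Archive: database name, entry number
  trace_archive:
    composed_of:
      - database: "TI"
      - entry: {regex: "[0-9]+"}

  # INSD assembled sequences: nucleotide, protein, bulk (WGS) and MGA
  insd_sequence:
    one_of:
      - "$insd_nucleotide"
      - "$insd_protein"
      - "$insd_bulk"
      - "$insd_mga"
  insd_nucleotide:
    regex: "(?:[A-Z][0-9]{5}|[A-Z]{2}[0-9]{6,8})(?:\\.[0-9]+)?"
  insd_protein:
    regex: "[A-Z]{3}[0-9]{5,7}(?:\\.[0-9]+)?"
  insd_bulk:
    regex: "[A-Z]{4,6}[0-9]{8,11}(?:\\.[0-9]+)?"
  insd_mga:
    regex: "[A-Z]{5}[0-9]{7}"

  # INSD metadata: BioProject / BioSample records
  insd_metadata:
    composed_of:
      - record_type:
          values: ["PRJ", "SAM"]
          decoded: {"PRJ": "BioProject", "SAM": "BioSample"}
      - institution:
          values: ["N", "E", "D"]
          decoded: {"N": "NCBI", "E": "ENA/EBI", "D": "DDBJ"}
      - subcode: {regex: "[A-Z]?"}
      - entry: {regex: "[0-9]+"}

  # RefSeq: molecule/annotation class, entry number, optional version
  refseq:
    composed_of:
      - molecule:
          values: ["AC", "NC", "NG", "NT", "NW", "NZ", "NM", "NR", "XM",
                   "XR", "AP", "NP", "YP", "XP", "WP"]
          decoded:
            "AC": "genomic, alternate assembly"
            "NC": "genomic, reference assembly"
            "NG": "genomic region, curated"
            "NT": "genomic contig, predicted"
            "NW": "genomic contig, predicted"
            "NZ": "genomic, unfinished WGS"
            "NM": "mRNA, curated"
            "NR": "RNA, curated"
            "XM": "mRNA, predicted model"
            "XR": "RNA, predicted model"
            "AP": "protein, alternate assembly"
            "NP": "protein, curated"
            "YP": "protein, predicted"
            "XP": "protein, predicted model"
            "WP": "protein, non-redundant"
      - entry: {regex: "[0-9]{6,9}", prefix: "_"}
      - version: {unsigned_integer: {}, prefix: "."}
    n_required: 2

  # Ensembl stable IDs: species code, feature type, 11-digit entry, version
  ensembl:
    composed_of:
      - project: "ENS"
      - species: {regex: "[A-Z]{0,4}"}
      - feature:
          values: ["E", "FM", "GT", "G", "P", "R", "T"]
          decoded:
            "E": exon
            "FM": "protein family"
            "GT": "gene tree"
            "G": gene
            "P": protein
            "R": "regulatory feature"
            "T": transcript
      - entry: {regex: "[0-9]{11}"}
      - version: {unsigned_integer: {}, prefix: "."}
    n_required: 4

testdata:
  insd_read_archive:
    valid:
      "SRR123456":
        {institution: NCBI, archive: R, record_type: run, entry: "123456"}
      "ERX0000017":
        {institution: "ENA/EBI", archive: R, record_type: experiment, entry: "0000017"}
      "DRP000001":
        {institution: DDBJ, archive: R, record_type: study, entry: "000001"}
    invalid:
      encoded: ["XRR123456", "SRR12", "SRQ123456"]
  uniprot:
    valid:
      "P01013": "P01013"
      "Q90RT2": "Q90RT2"
      "A0A023GPI8": "A0A023GPI8"
    invalid:
      encoded: ["P0101", "p01013", "ZZZZZZ"]
  trace_archive:
    valid:
      "TI102938": {database: TI, entry: "102938"}
    invalid:
      encoded: ["TI", "TX102938"]
  insd_sequence:
    valid:
      "M73307": "M73307"
      "BK003456": "BK003456"
      "CAM43271.1": "CAM43271.1"
      "CAAA01000001": "CAAA01000001"
      "BAAAA0100001": "BAAAA0100001"
    invalid:
      encoded: ["M7330", "m73307"]
  insd_metadata:
    valid:
      "PRJNA123456":
        {record_type: BioProject, institution: NCBI, subcode: A, entry: "123456"}
      "SAMEA1234567":
        {record_type: BioSample, institution: "ENA/EBI", subcode: A, entry: "1234567"}
      "SAMN12345678":
        {record_type: BioSample, institution: NCBI, subcode: "", entry: "12345678"}
    invalid:
      encoded: ["PRJXA123456", "SAM123456"]
  refseq:
    valid:
      "NM_010450.1":
        {molecule: "mRNA, curated", entry: "010450", version: 1}
      "NC_000913.3":
        {molecule: "genomic, reference assembly", entry: "000913", version: 3}
      "WP_123456789":
        {molecule: "protein, non-redundant", entry: "123456789"}
    invalid:
      encoded: ["NM010450.1", "QQ_010450.1", "NM_01."]
  ensembl:
    valid:
      "ENSG00000139618":
        {project: ENS, species: "", feature: gene, entry: "00000139618"}
      "ENSMUSG00000064370.14":
        {project: ENS, species: MUS, feature: gene, entry: "00000064370", version: 14}
      "ENSDART00000033574":
        {project: ENS, species: DAR, feature: transcript, entry: "00000033574"}
    invalid:
      encoded: ["ENSG0000013961", "ENSQ00000139618"]
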