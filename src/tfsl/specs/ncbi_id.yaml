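# Sequence identifiers used by NCBI in FASTA headers: a database tag,
# then pipe-separated fields whose number depends on the tag.
# Some positions may be empty (e.g. "pir||G36364", "tpg|BK003456|").
# Decoded form: {db_tag: <tag>, fields: [<field>, ...]}.
namespace: ncbi

datatypes:
  field:
    regex: "[A-Za-z0-9_.]+"
  opt_field:
    regex: "[A-Za-z0-9_.]*"

  ncbi_id:
    one_of:
      - "$id_ref"
      - "$id_gb"
      - "$id_tpg"
      - "$id_emb"
      - "$id_tpe"
      - "$id_dbj"
      - "$id_tpd"
      - "$id_sp"
      - "$id_tr"
      - "$id_pir"
      - "$id_pdb"
      - "$id_prf"
      - "$id_pat"
      - "$id_pgp"
      - "$id_gnl"
      - "$id_lcl"
      - "$id_bbs"
      - "$id_bbm"
      - "$id_gim"
      - "$id_gi"
      - "$id_gpp"
      - "$id_nat"

  # NCBI RefSeq database
  id_ref:
    composed_of:
      - db_tag: ref
      - fields: {list_of: "$opt_field", splitted_by: "|", min_length: 1, max_length: 2}
    separator: "|"
  # NCBI GenBank database
  id_gb:
    composed_of:
      - db_tag: gb
      - fields: {list_of: "$field", splitted_by: "|", length: 2}
    separator: "|"
  # GenBank third-party annotation
  id_tpg:
    composed_of:
      - db_tag: tpg
      - fields: {list_of: "$opt_field", splitted_by: "|", length: 2}
    separator: "|"
  # EMBL sequence database
  id_emb:
    composed_of:
      - db_tag: emb
      - fields: {list_of: "$opt_field", splitted_by: "|", length: 2}
    separator: "|"
  # EMBL third-party annotation
  id_tpe:
    composed_of:
      - db_tag: tpe
      - fields: {list_of: "$opt_field", splitted_by: "|", length: 2}
    separator: "|"
  # DDBJ sequence database
  id_dbj:
    composed_of:
      - db_tag: dbj
      - fields: {list_of: "$opt_field", splitted_by: "|", min_length: 1, max_length: 2}
    separator: "|"
  # DDBJ third-party annotation
  id_tpd:
    composed_of:
      - db_tag: tpd
      - fields: {list_of: "$opt_field", splitted_by: "|", length: 2}
    separator: "|"
  # SWISS-Prot: accession, entry name
  id_sp:
    composed_of:
      - db_tag: sp
      - fields: {list_of: "$field", splitted_by: "|", length: 2}
    separator: "|"
  # TrEMBL: accession, entry name
  id_tr:
    composed_of:
      - db_tag: tr
      - fields: {list_of: "$field", splitted_by: "|", length: 2}
    separator: "|"
  # PIR: (empty), entry
  id_pir:
    composed_of:
      - db_tag: pir
      - fields: {list_of: "$opt_field", splitted_by: "|", length: 2}
    separator: "|"
  # PDB: entry, chain
  id_pdb:
    composed_of:
      - db_tag: pdb
      - fields: {list_of: "$field", splitted_by: "|", length: 2}
    separator: "|"
  # PRF: (empty), entry
  id_prf:
    composed_of:
      - db_tag: prf
      - fields: {list_of: "$opt_field", splitted_by: "|", length: 2}
    separator: "|"
  # patent sequence: country, patent, sequence number
  id_pat:
    composed_of:
      - db_tag: pat
      - fields: {list_of: "$field", splitted_by: "|", length: 3}
    separator: "|"
  # pre-grant patent sequence: country, application, sequence number
  id_pgp:
    composed_of:
      - db_tag: pgp
      - fields: {list_of: "$field", splitted_by: "|", length: 3}
    separator: "|"
  # general database reference: database, tag
  id_gnl:
    composed_of:
      - db_tag: gnl
      - fields: {list_of: "$field", splitted_by: "|", length: 2}
    separator: "|"
  # local sequence
  id_lcl:
    composed_of:
      - db_tag: lcl
      - fields: {list_of: "$field", splitted_by: "|", length: 1}
    separator: "|"
  # GenInfo backbone sequence ID
  id_bbs:
    composed_of:
      - db_tag: bbs
      - fields: {list_of: "$field", splitted_by: "|", length: 1}
    separator: "|"
  # GenInfo backbone molecule type
  id_bbm:
    composed_of:
      - db_tag: bbm
      - fields: {list_of: "$field", splitted_by: "|", length: 1}
    separator: "|"
  # GenInfo import ID
  id_gim:
    composed_of:
      - db_tag: gim
      - fields: {list_of: "$field", splitted_by: "|", length: 1}
    separator: "|"
  # GenInfo integrated database
  id_gi:
    composed_of:
      - db_tag: gi
      - fields: {list_of: "$field", splitted_by: "|", length: 1}
    separator: "|"
  # NCBI internal, genome pipeline
  id_gpp:
    composed_of:
      - db_tag: gpp
      - fields: {list_of: "$opt_field", splitted_by: "|", min_length: 1, max_length: 2}
    separator: "|"
  # NCBI internal, named annotation track
  id_nat:
    composed_of:
      - db_tag: nat
      - fields: {list_of: "$opt_field", splitted_by: "|", min_length: 1, max_length: 2}
    separator: "|"

testdata:
  ncbi_id:
    valid:
      "ref|NM_010450.1": {db_tag: ref, fields: ["NM_010450.1"]}
      "gb|M73307|AGMA13GT": {db_tag: gb, fields: ["M73307", "AGMA13GT"]}
      "tpg|BK003456|": {db_tag: tpg, fields: ["BK003456", ""]}
      "emb|CAM43271.1|": {db_tag: emb, fields: ["CAM43271.1", ""]}
      "tpe|BN000123|": {db_tag: tpe, fields: ["BN000123", ""]}
      "dbj|BAC85684.1": {db_tag: dbj, fields: ["BAC85684.1"]}
      "tpd|FAA00017|": {db_tag: tpd, fields: ["FAA00017", ""]}
      "sp|P01013|OVAX_CHICK": {db_tag: sp, fields: ["P01013", "OVAX_CHICK"]}
      "tr|Q90RT2|Q90RT2_9HIV1": {db_tag: tr, fields: ["Q90RT2", "Q90RT2_9HIV1"]}
      "pir||G36364": {db_tag: pir, fields: ["", "G36364"]}
      "pdb|1I4L|D": {db_tag: pdb, fields: ["1I4L", "D"]}
      "prf||0806162C": {db_tag: prf, fields: ["", "0806162C"]}
      "pat|US|RE33188|1": {db_tag: pat, fields: ["US", "RE33188", "1"]}
      "pgp|EP|0238993|7": {db_tag: pgp, fields: ["EP", "0238993", "7"]}
      "gnl|taxon|9606": {db_tag: gnl, fields: ["taxon", "9606"]}
      "lcl|hnm271": {db_tag: lcl, fields: ["hnm271"]}
      "bbs|316342": {db_tag: bbs, fields: ["316342"]}
      "bbm|464147": {db_tag: bbm, fields: ["464147"]}
      "gim|442187": {db_tag: gim, fields: ["442187"]}
      "gi|21434723": {db_tag: gi, fields: ["21434723"]}
      "gpp|GPC_123456789": {db_tag: gpp, fields: ["GPC_123456789"]}
      "nat|AT_123456789.1|": {db_tag: nat, fields: ["AT_123456789.1", ""]}
    invalid:
      encoded:
        - "xy|123"
        - "q|123"
        - "ref"
        - "gi|21434723|9606"
        - "sp|P01013"
        - "pat|US|RE33188"
        - "gb,M73307,AGMA13GT"
        - "lcl|"
      decoded:
        - {db_tag: xyz, fields: ["1"]}
        - {db_tag: gi, fields: ["1", "2"]}
        - "plain string"
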