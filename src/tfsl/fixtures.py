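"""Deterministic fixture-file generation for the builtin formats.

``generate_fixture(format, n_records, seed)`` produces the content of a
valid file of the requested format; identical seeds give identical files.
Every generated file fully decodes under its builtin specification (the
test suite asserts this).  The generator also reports its internal tally
(record counts by type) so that decode results can be cross-checked
against an independent source.
"""

from __future__ import annotations

import random

FIXTURE_FORMATS = ("egc", "fasta", "fastq", "gfa")

_WORDS = ("thermophilic", "halophilic", "acidophilic", "marine", "soil",
          "gut", "anaerobic", "aerobic", "motile", "sporulating")
_TAXA = ("Escherichia coli", "Bacillus subtilis", "Haloferax volcanii",
         "Sulfolobus solfataricus", "Prochlorococcus marinus")
_RANKS = ("species", "genus", "family", "order", "phylum")
_ATTRS = ("gc_content", "genome_size", "trna_count", "rrna_operons",
          "crispr_arrays", "secretion_systems")
_OPS = ("=", "!=", "<", "<=", ">", ">=")


def generate_fixture(format: str, n_records: int, seed: int,
                     return_counts: bool = False):
    """Return the text of a valid *format* file with *n_records* records.

    With ``return_counts=True`` also return the generator's own tally of
    records by type (comment lines are not records).
    """
    if format not in FIXTURE_FORMATS:
        raise ValueError(f"unknown fixture format {format!r}; "
                         f"available: {', '.join(FIXTURE_FORMATS)}")
    if n_records < 0:
        raise ValueError("n_records must be non-negative")
    rng = random.Random(seed)
    make = {"egc": _egc, "fasta": _fasta, "fastq": _fastq, "gfa": _gfa}[format]
    text, counts = make(n_records, rng)
    if return_counts:
        return text, counts
    return text


def _egc(n: int, rng: random.Random):
    lines = []
    counts = {"A": 0, "T": 0, "P": 0, "E": 0, "comment": 0}
    attributes: list[str] = []
    subjects: list[str] = []

    def attr():
        name = f"{rng.choice(_ATTRS)}_{len(attributes)}"
        attributes.append(name)
        counts["A"] += 1
        computation = rng.choice(("sequence_statistic", "feature_count", "."))
        return f"A\t{name}\t{name.replace('_', ' ')}\t{computation}"

    def taxon():
        name = f"tax{len(subjects)}"
        subjects.append(name)
        counts["T"] += 1
        rank = rng.choice(_RANKS + (".",))
        return f"T\t{name}\t{rng.choice(_TAXA)}\t{rank}"

    def pheno():
        name = f"pheno{len(subjects)}"
        subjects.append(name)
        counts["P"] += 1
        return f"P\t{name}\t{rng.choice(_WORDS)}"

    def expect():
        counts["E"] += 1
        value = rng.choice((
            str(rng.randint(0, 5000)),
            f"{rng.uniform(0.2, 0.8):.3f}",
            rng.choice(_WORDS),
            ".",
        ))
        return (f"E\t{rng.choice(subjects)}\t{rng.choice(attributes)}"
                f"\t{rng.choice(_OPS)}\t{value}")

    for i in range(n):
        if rng.random() < 0.08:
            lines.append(f"# comment {counts['comment']}")
            counts["comment"] += 1
        if not attributes:
            lines.append(attr())
        elif not subjects:
            lines.append(taxon() if rng.random() < 0.5 else pheno())
        else:
            kind = rng.choices("ATPE", weights=(1, 1, 1, 3))[0]
            lines.append({"A": attr, "T": taxon, "P": pheno,
                          "E": expect}[kind]())
    return _join(lines), counts


def _random_seq(rng, lo, hi, alphabet="ACGT"):
    return "".join(rng.choice(alphabet) for _ in range(rng.randint(lo, hi)))


def _fasta(n: int, rng: random.Random):
    lines = []
    for i in range(n):
        desc = f" {rng.choice(_WORDS)} isolate {i}" if rng.random() < 0.7 else ""
        lines.append(f">seq_{i}{desc}")
        seq = _random_seq(rng, 40, 180)
        for start in range(0, len(seq), 60):
            lines.append(seq[start:start + 60])
    return _join(lines), {"entries": n}


def _fastq(n: int, rng: random.Random):
    lines = []
    for i in range(n):
        seq = _random_seq(rng, 20, 80)
        qual = "".join(chr(rng.randint(33, 74)) for _ in seq)
        lines.append(f"@read_{i} len={len(seq)}")
        lines.append(seq)
        lines.append("+")
        lines.append(qual)
    return _join(lines), {"reads": n}


def _gfa(n: int, rng: random.Random):
    lines = ["H\tVN:Z:1.0"]
    counts = {"H": 1, "S": 0, "L": 0}
    segments: list[str] = []
    for i in range(n):
        if segments and rng.random() < 0.4:
            a, b = rng.choice(segments), rng.choice(segments)
            counts["L"] += 1
            lines.append(f"L\t{a}\t{rng.choice('+-')}\t{b}"
                         f"\t{rng.choice('+-')}\t{rng.randint(1, 40)}M")
        else:
            name = f"s{len(segments)}"
            segments.append(name)
            counts["S"] += 1
            seq = _random_seq(rng, 10, 60) if rng.random() < 0.8 else "*"
            tags = ""
            if rng.random() < 0.5:
                tags = f"\tLN:i:{len(seq) if seq != '*' else rng.randint(10, 60)}"
            lines.append(f"S\t{name}\t{seq}{tags}")
    return _join(lines), counts


def _join(lines):
    return "\n".join(lines) + ("\n" if lines else "")
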