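"""Builtin format specifications shipped with the package.

Each builtin is a specification document installed under ``tfsl/specs``:

``ncbi_id``
    NCBI FASTA sequence identifiers (22 database-tag classes);
``accessions``
    accession identifiers of the NCBI/DDBJ/ENA-EBI/UniProt databases;
``egc``
    the "expected genomic content" rule format (4 record types);
``fasta`` / ``fastq``
    sequence files (FASTA entries; FASTQ four-line reads);
``gfa``
    a representative GFA1-like subset with the name:typecode:value tag
    system.
"""

from __future__ import annotations

from importlib import resources

from .loader import CompiledSpecification, load_specification

BUILTIN_NAMES = ("accessions", "egc", "fasta", "fastq", "gfa", "ncbi_id")

_cache: dict[str, CompiledSpecification] = {}


def builtin_spec_path(name: str) -> str:
    """Filesystem path of the builtin specification document *name*."""
    if name not in BUILTIN_NAMES:
        raise KeyError(f"unknown builtin specification {name!r}; "
                       f"available: {', '.join(BUILTIN_NAMES)}")
    return str(resources.files("tfsl") / "specs" / f"{name}.yaml")


def load_builtin(name: str, cache: bool = True) -> CompiledSpecification:
    """Load (and memoize) a builtin specification."""
    if cache and name in _cache:
        return _cache[name]
    spec = load_specification(builtin_spec_path(name))
    if cache:
        _cache[name] = spec
    return spec
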