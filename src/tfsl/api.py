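"""Object-oriented facade: ``Specification`` and ``Datatype``.

>>> from tfsl import Specification
>>> spec = Specification.builtin("ncbi_id")
>>> spec["ncbi_id"].decode("sp|P01013|OVAX_CHICK")
{'db_tag': 'sp', 'fields': ['P01013', 'OVAX_CHICK']}
"""

from __future__ import annotations

from . import codec, loader, testkit
from .builtin_specs import load_builtin
from .model import DatatypeDefinition


class Datatype:
    """One datatype of a loaded specification, bound to its engine."""

    def __init__(self, spec: "Specification", name: str):
        self._spec = spec
        self.name = name

    @property
    def definition(self) -> DatatypeDefinition:
        return self._spec.compiled.table[self.name]

    @property
    def pattern(self) -> str:
        """The anchored regular expression of this datatype."""
        return self._spec.compiled.engine.matcher(self.definition).pattern

    def decode(self, text: str):
        return codec.decode(text, self.definition, self._spec.compiled.engine)

    def encode(self, value) -> str:
        return codec.encode(value, self.definition, self._spec.compiled.engine)

    def is_valid_encoded(self, text: str) -> bool:
        return codec.is_valid_encoded(text, self.definition,
                                      self._spec.compiled.engine)

    def is_valid_decoded(self, value) -> bool:
        return codec.is_valid_decoded(value, self.definition,
                                      self._spec.compiled.engine)

    def decode_file(self, source, scope=None, streaming: bool = False):
        """Iterate :class:`~tfsl.codec.DecodedRecord` objects of a file."""
        return codec.decode_file(source, self.definition,
                                 self._spec.compiled.engine,
                                 scope=scope, streaming=streaming)

    def generate_examples(self, n_valid: int = 5, n_invalid: int = 5,
                          seed: int = 0) -> testkit.DatatypeTests:
        return testkit.generate_examples(self.definition, n_valid, n_invalid,
                                         seed, self._spec.compiled.engine)

    def __repr__(self):  # pragma: no cover - cosmetic
        return f"<Datatype {self.name} ({self.definition.kind})>"


class Specification:
    """A loaded (compiled) specification.

    Accepts a file path, document text, a document tree, or an already
    compiled specification object.
    """

    def __init__(self, source):
        if isinstance(source, loader.CompiledSpecification):
            self.compiled = source
        else:
            self.compiled = loader.load_specification(source)

    @classmethod
    def builtin(cls, name: str) -> "Specification":
        """One of the shipped builtin specifications (see
        :mod:`tfsl.builtin_specs`)."""
        return cls(load_builtin(name))

    def datatype_names(self) -> list[str]:
        return self.compiled.datatype_names()

    def __contains__(self, name: str) -> bool:
        return name in self.compiled

    def __getitem__(self, name: str) -> Datatype:
        if name not in self.compiled:
            raise KeyError(f"specification defines no datatype {name!r}")
        return Datatype(self, name)

    def test(self, testdata=None) -> testkit.TestReport:
        """Run the embedded (or the given) test data."""
        return testkit.run_testdata(self.compiled,
                                    testdata if testdata is not None
                                    else self.compiled.testdata)

    def save_compiled(self, path) -> None:
        loader.save_compiled(self.compiled, path)

    def __repr__(self):  # pragma: no cover - cosmetic
        return (f"<Specification of {len(self.compiled.table)} datatype(s): "
                + ", ".join(self.datatype_names()[:6])
                + ("..." if len(self.compiled.table) > 6 else "") + ">")
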