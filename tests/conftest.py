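import pytest

import tfsl


@pytest.fixture(scope="session")
def builtins():
    """All builtin specifications, loaded once per session."""
    return {name: tfsl.Specification.builtin(name)
            for name in tfsl.BUILTIN_NAMES}


@pytest.fixture()
def make_spec():
    """Build a specification from a datatypes mapping (or full document)."""
    def _make(tree):
        if "datatypes" not in tree:
            tree = {"datatypes": tree}
        return tfsl.Specification(tree)
    return _make
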