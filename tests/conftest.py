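import pytest

from myofractal import load_reference_dataset


@pytest.fixture(scope="session")
def reference():
    """(expression table, phenotype records, rank-window map)."""
    return load_reference_dataset()


@pytest.fixture(scope="session")
def expression(reference):
    return reference[0]


@pytest.fixture(scope="session")
def phenotypes(reference):
    return reference[1]


@pytest.fixture(scope="session")
def windows(reference):
    return reference[2]
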