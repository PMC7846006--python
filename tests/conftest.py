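import pytest

from mtduplex import fixtures as fx
from mtduplex.reference_panel import design_panel, load_packaged_reference
from mtduplex.variant_classification import load_packaged_tree


@pytest.fixture(scope="session")
def reference():
    return load_packaged_reference()


@pytest.fixture(scope="session")
def panel(reference):
    return design_panel(reference)


@pytest.fixture(scope="session")
def tree():
    return load_packaged_tree()


@pytest.fixture(scope="session")
def het_table():
    """Long-format heteroplasmy fixture (one row per SNP x subject x tissue)."""
    return fx.heteroplasmy_table()


@pytest.fixture(scope="session")
def homoplasmy_sets():
    return fx.homoplasmy_sets()


@pytest.fixture(scope="session")
def annotation_db():
    return fx.annotation_db()


@pytest.fixture(scope="session")
def cohort():
    return fx.cohort_presence()
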