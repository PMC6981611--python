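import pytest

from iqsp.aaindex_io import load_bundled_scales
from iqsp.ruleforest import load_irqsp_rules
from iqsp.synthetic import generate_two_class_set


@pytest.fixture(scope="session")
def scales18():
    """The bundled 18-scale fixture (synthetic stand-in values)."""
    return load_bundled_scales()


@pytest.fixture(scope="session")
def irqsp_rules():
    """The published 8-rule IR-QSP set with its printed statistics."""
    return load_irqsp_rules()


@pytest.fixture(scope="session")
def small_pool():
    """A small two-class composition-model peptide pool (60 + 60)."""
    return generate_two_class_set(60, 60, seed=7)
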