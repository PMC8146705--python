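import numpy as np
import pytest

from mrmkit import mrm, quant
from mrmkit.digestion import DigestParams, digest_proteomes
from mrmkit.simulate import make_proteomes


@pytest.fixture(scope="session")
def panel():
    """The shipped nine-legume reference method (27 markers, 81 transitions)."""
    return mrm.load_reference_panel()


@pytest.fixture(scope="session")
def extraction_screens():
    """Published normalized peak areas: (buffer screen, time screen)."""
    return quant.load_extraction_screen()


@pytest.fixture(scope="session")
def synthetic_panel():
    """Nine synthetic proteomes with planted markers, plus indexes.

    Returns (proteomes, backgrounds, manifest, index, background_index).
    """
    proteomes, backgrounds, manifest = make_proteomes(seed=42)
    index = digest_proteomes(proteomes, DigestParams())
    bg_index = digest_proteomes(backgrounds, DigestParams())
    return proteomes, backgrounds, manifest, index, bg_index


@pytest.fixture()
def rng():
    return np.random.default_rng(20240947)
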