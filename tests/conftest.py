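import numpy as np
import pytest

from paracis import synth
from paracis.msa import MultipleAlignment


@pytest.fixture(scope="session")
def small_family():
    """8 diverged paralogs, substitutions only, no indels."""
    cfg = synth.SimulationConfig(
        seed=11, n_paralogs=8, ancestor_length=800,
        substitution_rate=0.03, indel_rate=0.0,
    )
    return synth.generate_paralog_family(cfg)


@pytest.fixture(scope="session")
def indel_family():
    """Family with substitutions and indels for projection tests."""
    cfg = synth.SimulationConfig(
        seed=7, n_paralogs=6, ancestor_length=600,
        substitution_rate=0.04, indel_rate=0.01,
    )
    return synth.generate_paralog_family(cfg)


@pytest.fixture
def tiny_msa():
    return MultipleAlignment(
        (
            ("p1", "ACG-T"),
            ("p2", "ACG-T"),
            ("p3", "ACGAT"),
        )
    )


@pytest.fixture
def rng():
    return np.random.default_rng(123)
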