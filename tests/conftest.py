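"""Shared fixtures: all inputs are generated programmatically at test time."""

from __future__ import annotations

import numpy as np
import pytest

from motifshift import synthetic_data as sd

AA = "ACDEFGHIKLMNPQRSTVWY"


@pytest.fixture(scope="session")
def vertebrate_family():
    """30-species IRF5-like family (NES + SRR + signature windows), with indels."""
    config = sd.default_vertebrate_config(seed=11)
    records, truth = sd.simulate_family(config)
    return config, records, truth


@pytest.fixture(scope="session")
def vertebrate_family_no_indel():
    config = sd.default_vertebrate_config(seed=11, indel_rate=0.0)
    records, truth = sd.simulate_family(config)
    return config, records, truth


@pytest.fixture(scope="session")
def bird_families():
    """58-species bird IRF5 (planted Y->F->L->V) and IRF6 (all YDG) families."""
    irf5 = sd.default_bird_config(seed=13, subfamily="IRF5")
    irf6 = sd.default_bird_config(seed=14, subfamily="IRF6")
    return {
        "IRF5": sd.simulate_family(irf5) + (irf5,),
        "IRF6": sd.simulate_family(irf6) + (irf6,),
    }


@pytest.fixture(scope="session")
def interface_panel():
    return sd.synthetic_interface_records(seed=17)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


def _random_protein(rng: np.random.Generator, length: int, alphabet: str = AA) -> str:
    return "".join(rng.choice(list(alphabet), size=length))


@pytest.fixture()
def random_protein():
    return _random_protein
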