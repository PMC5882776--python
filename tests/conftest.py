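import numpy as np
import pytest

from pcpredox.chain import ChainModel
from pcpredox.congeners import Congener
from pcpredox.kinetics import LogisticParams, TimeSeries, logistic_value
from pcpredox.microcosm import CHAIN_SPECIES, MicrocosmConfig, generate_microcosm

SAMPLING_DAYS = np.array([0.0, 3.0, 7.0, 12.0, 17.0, 22.0, 40.0])


@pytest.fixture
def control_pcp_params():
    """Control PCP-decrement logistic parameters (µM scale)."""
    return LogisticParams(a=149.61, b=170.26, k=0.52)


@pytest.fixture
def noiseless_series(control_pcp_params):
    """Exact logistic decrement sampled on the standard day grid."""
    values = logistic_value(control_pcp_params, SAMPLING_DAYS)
    return TimeSeries("control", "pcp", SAMPLING_DAYS, values, unit="uM")


@pytest.fixture
def five_species_chain():
    """PCP -> ... -> 3-CP chain with distinct rates and a 3 d lag."""
    initial = np.zeros(len(CHAIN_SPECIES))
    initial[0] = 150.0
    return ChainModel(
        CHAIN_SPECIES,
        np.array([0.5, 0.4, 0.3, 0.2]),
        initial,
        lag_d=3.0,
    )


@pytest.fixture
def control_dataset():
    """Synthetic control microcosm, triplicate, 3% noise, seed 1."""
    return generate_microcosm(MicrocosmConfig(seed=1))


@pytest.fixture
def paper_chain():
    """The observed congener chain, parent to terminus."""
    return [
        Congener.from_name(n)
        for n in ("PCP", "2,3,4,5-TeCP", "3,4,5-TCP", "3,5-DCP", "3-CP")
    ]
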