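import numpy as np
import pytest

import stgcoupling as sc


@pytest.fixture(scope="session")
def protocol():
    return sc.TemperatureProtocol.uniform([7.0, 11.0, 15.0, 19.0, 21.0], 600.0)


@pytest.fixture(scope="session")
def noiseless_cfg():
    """Deterministic preparation: no period jitter, no phase jitter, fixed k."""
    return sc.GeneratorConfig(period_jitter_cv=0.0, lock_jitter_sd=0.0,
                              cycles_per_slow_burst=10, seed=7)


@pytest.fixture(scope="session")
def default_prep(protocol):
    """One default-jitter preparation shared across tests."""
    cfg = sc.GeneratorConfig(seed=11)
    trains, truth = sc.generate_preparation(cfg, protocol)
    return cfg, trains, truth


def make_train(times, neuron="LG", temperature=11.0, prep="p0", epoch="e0"):
    return sc.SpikeTrain(prep, neuron, temperature, np.asarray(times, float), epoch)


def make_burst_seq(starts, period, neuron="PD", temperature=11.0,
                   duty=0.3, n_spikes=2):
    """BurstSequence with prescribed burst starts and a common final period."""
    from stgcoupling.types import Burst, BurstSequence

    starts = np.asarray(starts, float)
    bursts = []
    for i, s in enumerate(starts):
        per = (starts[i + 1] - s) if i + 1 < starts.size else period
        if i + 1 == starts.size:
            per = float("nan")
        bursts.append(Burst(start=float(s), stop=float(s + duty * period),
                            n_spikes=n_spikes, period=per))
    train = make_train(starts, neuron=neuron, temperature=temperature)
    return BurstSequence(bursts, train)
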