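import numpy as np
import pytest

import emgsim as es


@pytest.fixture(scope="session")
def model():
    return es.ElbowModelParams()


@pytest.fixture(scope="session")
def synth_spec():
    return es.SyntheticProfileSpec(seed=1)


@pytest.fixture(scope="session")
def baseline(synth_spec):
    """Healthy baseline activations from the full synthetic-EMG chain."""
    return es.baseline_from_synthetic(synth_spec)


@pytest.fixture(scope="session")
def healthy_result(baseline, model):
    return es.forward_simulate(baseline, model)


@pytest.fixture(scope="session")
def scenario_battery(baseline, model, healthy_result):
    """Outcome metrics for the healthy condition and every severity ladder.

    Computed once per session; the severity ladders of all four
    impairment families on the same baseline are the workhorse for the
    directional and MQI tests.
    """
    healthy = es.compute_outcomes(healthy_result, label="healthy")
    battery = {"healthy": healthy}
    for family, specs in es.FAMILY_SPECS.items():
        ms = []
        for spec in specs:
            acts = es.build_scenario_set(baseline, spec)
            ms.append(es.compute_outcomes(es.forward_simulate(acts, model),
                                          label=spec.label()))
        battery[family] = ms
    return battery
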