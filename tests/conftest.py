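"""Shared fixtures: the reduced toy model and synthetic datasets."""

import numpy as np
import pytest

from cholode.objective_fit import ObjectiveConfig
from cholode.synthdata import (
    SynthConfig,
    generate_ground_truth,
    simulate_dataset,
    toy_network,
)


@pytest.fixture(scope="session")
def toy_net():
    return toy_network()


@pytest.fixture(scope="session")
def toy_truth(toy_net):
    return generate_ground_truth(toy_net, seed=7)


@pytest.fixture(scope="session")
def noisefree_dataset(toy_net, toy_truth):
    _, dataset = simulate_dataset(toy_net, toy_truth, SynthConfig(cv=0.0))
    return dataset


@pytest.fixture(scope="session")
def noisy_dataset(toy_net, toy_truth):
    _, dataset = simulate_dataset(
        toy_net, toy_truth, SynthConfig(cv=0.05, measurement_seed=11)
    )
    return dataset


@pytest.fixture(scope="session")
def recovery_config():
    """Objective for ground-truth recovery: the pseudo-timepoint
    regularizer is off because its anchors are heuristic interpolations,
    not values the generating model passes through."""
    return ObjectiveConfig(pseudo_weight=0.0)


def euler_oracle(model, values, clamps, end_time, dt=1e-4):
    """Fixed-step explicit Euler on the same derivative the solver uses.

    A brute-force integrator independent of LSODA's step-size control and
    error estimation; the grid is fine enough for first-order accuracy
    below the comparison tolerance.
    """
    from cholode.logic_ode import _rhs_kernel

    n = int(round(end_time / dt))
    x = model.x0.copy()
    args = model._kernel_args
    for _ in range(n):
        x = x + dt * _rhs_kernel(x, clamps, values, *args)
    return x
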