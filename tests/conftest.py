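"""Shared fixtures.

The two trained networks (SSVEP and motor imagery) dominate the suite's
runtime, so they are built once per session and shared between the unit,
property and acceptance tests.  Everything is generated programmatically
from fixed seeds; nothing is read from disk.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pytest

import snnaug as sa


@dataclass
class PipelineBundle:
    """A trained reconstruction pipeline on one fixture modality."""

    epochs: sa.EpochSet
    template: sa.Template
    net: sa.NetworkState
    record: sa.TrainingRecord
    inputs: dict[str, sa.SpikeRaster]


SCALED_LAYERS = (50, 150, 40)


@pytest.fixture(scope="session")
def ssvep_epochs() -> sa.EpochSet:
    return sa.make_ssvep_fixture(sa.FixtureSpec.ssvep(seed=5))


@pytest.fixture(scope="session")
def ssvep_bundle(ssvep_epochs) -> PipelineBundle:
    template = sa.extract_template_average(ssvep_epochs)
    spec = sa.NetworkSpec(layer_sizes=SCALED_LAYERS, n_channels=1, seed=2)
    net = sa.build_network(spec)
    n_steps = template.signals.shape[-1] * spec.readout_stride
    inputs = sa.fixed_class_inputs(net, template.class_names, n_steps, seed=5)
    trained, record = sa.train(net, inputs, template.as_dict())
    return PipelineBundle(ssvep_epochs, template, trained, record, inputs)


@pytest.fixture(scope="session")
def mi_epochs() -> sa.EpochSet:
    return sa.make_mi_fixture(sa.FixtureSpec.mi(seed=11))


@pytest.fixture(scope="session")
def mi_bundle(mi_epochs) -> PipelineBundle:
    template = sa.select_best_trial(mi_epochs, seed=0)
    spec = sa.NetworkSpec(layer_sizes=SCALED_LAYERS, n_channels=2, seed=2)
    net = sa.build_network(spec)
    n_steps = template.signals.shape[-1] * spec.readout_stride
    inputs = sa.fixed_class_inputs(net, template.class_names, n_steps, seed=5)
    trained, record = sa.train(net, inputs, template.as_dict())
    return PipelineBundle(mi_epochs, template, trained, record, inputs)


@pytest.fixture(scope="session")
def mild_cfg() -> sa.PerturbationConfig:
    """The low-noise corner of the sweep grids: 10 neurons at 20 Hz."""
    return sa.PerturbationConfig(n_noise_neurons=10, noise_rate_hz=20.0, seed=1)


@pytest.fixture(scope="session")
def mi_mild_synth(mi_bundle, mild_cfg) -> sa.EpochSet:
    return sa.generate_samples(
        mi_bundle.net,
        mi_bundle.inputs,
        mild_cfg,
        n_samples=100,
        seed=9,
        channel_names=mi_bundle.template.channel_names,
    )


@pytest.fixture(scope="session")
def ssvep_mild_synth(ssvep_bundle, mild_cfg) -> sa.EpochSet:
    return sa.generate_samples(
        ssvep_bundle.net,
        ssvep_bundle.inputs,
        mild_cfg,
        n_samples=100,
        seed=9,
        channel_names=ssvep_bundle.template.channel_names,
    )


@pytest.fixture(scope="session")
def mi_sweep(mi_bundle):
    """3x3 perturbation sweep used by the correlation-trend checks."""
    return sa.perturbation_sweep(
        mi_bundle.net,
        mi_bundle.inputs,
        [10, 60, 220],
        [20.0, 200.0, 800.0],
        n_samples=100,
        seed=9,
        channel_names=mi_bundle.template.channel_names,
    )


@pytest.fixture()
def tiny_net() -> sa.NetworkState:
    """A 5-neuron-per-layer network for cheap structural tests."""
    spec = sa.NetworkSpec(layer_sizes=(5, 5, 5), n_channels=2, seed=7)
    return sa.build_network(spec)
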