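"""The three-layer feedforward spiking network and its perturbation layer.

A fixed Poisson raster drives an input -> hidden -> output chain of LIF
layers; output spikes are smoothed by the double-exponential filter and a
linear readout ``EEG_c = sum_j W_read[c, j] * r_j`` maps them to EEG
channels, strided down from the simulation step (1 ms) to the EEG rate
(250 Hz by default, i.e. every 4th step).

The optional perturbation layer is a population of Poisson noise neurons
coupled into the *synaptic current* of the output layer through fixed,
never-trained weights.  The weights are drawn once when the layer is
attached; every generated sample redraws only the noise spike raster.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace

import numpy as np

from . import _engine
from .dynamics import FilterParams, NeuronParams, SpikeRaster, poisson_spikes

__all__ = [
    "NetworkSpec",
    "NetworkState",
    "PerturbationConfig",
    "PerturbationStateError",
    "build_network",
    "attach_perturbation",
    "detach_perturbation",
    "forward",
    "clip_synapses",
]


class PerturbationStateError(RuntimeError):
    """Perturbation layer attached/absent in a way the operation forbids."""


@dataclass(frozen=True)
class NetworkSpec:
    """Architecture and initialization of the generator network.

    ``layer_sizes`` is (n_input, n_hidden, n_output); the reference
    configurations are [500, 1500, 100] for motor imagery and
    [100, 500, 200] for SSVEP.  ``init_scale`` sets the fan-in-scaled
    Gaussian std for the spiking weights and ``readout_scale`` for the
    readout (kept smaller so early EEG output stays moderate).
    """

    layer_sizes: tuple[int, int, int]
    n_channels: int
    neuron_params: NeuronParams = field(default_factory=NeuronParams)
    filter_params: FilterParams = field(default_factory=FilterParams)
    init_scale: float = 1.0
    readout_scale: float = 0.1
    eeg_fs: float = 250.0
    seed: int = 0

    def __post_init__(self) -> None:
        sizes = tuple(int(s) for s in self.layer_sizes)
        object.__setattr__(self, "layer_sizes", sizes)
        if len(sizes) != 3 or any(s < 1 for s in sizes):
            raise ValueError("layer_sizes must be three positive counts")
        if not 1 <= self.n_channels <= sizes[2]:
            raise ValueError("need 1 <= n_channels <= n_output")
        if self.eeg_fs <= 0:
            raise ValueError("eeg_fs must be positive")
        stride = 1000.0 / (self.neuron_params.dt * self.eeg_fs)
        if abs(stride - round(stride)) > 1e-9 or round(stride) < 1:
            raise ValueError(
                "1000/(dt*eeg_fs) must be a positive integer readout stride"
            )

    @property
    def n_input(self) -> int:
        return self.layer_sizes[0]

    @property
    def n_hidden(self) -> int:
        return self.layer_sizes[1]

    @property
    def n_output(self) -> int:
        return self.layer_sizes[2]

    @property
    def readout_stride(self) -> int:
        return round(1000.0 / (self.neuron_params.dt * self.eeg_fs))


@dataclass(frozen=True)
class PerturbationConfig:
    """Poisson noise population: size, rate and coupling magnitude."""

    n_noise_neurons: int
    noise_rate_hz: float
    weight_scale: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_noise_neurons < 0:
            raise ValueError("n_noise_neurons must be >= 0")
        if self.noise_rate_hz < 0:
            raise ValueError("noise_rate_hz must be >= 0")


@dataclass
class NetworkState:
    """Weights of the network; ``W_pert`` exists only while attached."""

    W_ih: np.ndarray  # (n_hidden, n_input)
    W_ho: np.ndarray  # (n_output, n_hidden)
    W_read: np.ndarray  # (n_channels, n_output)
    spec: NetworkSpec
    W_pert: np.ndarray | None = None  # (n_output, n_noise), fixed
    pert_cfg: PerturbationConfig | None = None
    training_record: object | None = None

    @property
    def trained(self) -> bool:
        return self.training_record is not None

    def copy(self) -> "NetworkState":
        return copy.deepcopy(self)


def build_network(spec: NetworkSpec) -> NetworkState:
    """Initialize weights: zero-mean Gaussians with std scale/sqrt(fan_in)."""
    rng = np.random.default_rng(spec.seed)
    n_in, n_h, n_out = spec.layer_sizes
    W_ih = rng.normal(0.0, spec.init_scale / np.sqrt(n_in), size=(n_h, n_in))
    W_ho = rng.normal(0.0, spec.init_scale / np.sqrt(n_h), size=(n_out, n_h))
    W_read = rng.normal(
        0.0, spec.readout_scale / np.sqrt(n_out), size=(spec.n_channels, n_out)
    )
    return NetworkState(W_ih=W_ih, W_ho=W_ho, W_read=W_read, spec=spec)


def attach_perturbation(net: NetworkState, cfg: PerturbationConfig) -> NetworkState:
    """Return a copy of ``net`` with a frozen noise-coupling matrix attached."""
    if net.W_pert is not None:
        raise PerturbationStateError("perturbation layer already attached; detach first")
    out = net.copy()
    rng = np.random.default_rng(cfg.seed)
    n_noise = cfg.n_noise_neurons
    # per-synapse std is NOT divided by sqrt(n_noise): the injected current
    # variance must grow with the noise-population size, which is what makes
    # sample fidelity fall monotonically along the neuron-count axis
    out.W_pert = rng.normal(0.0, cfg.weight_scale, size=(net.spec.n_output, n_noise))
    out.pert_cfg = cfg
    return out


def detach_perturbation(net: NetworkState) -> NetworkState:
    """Return a copy of ``net`` without the perturbation layer."""
    if net.W_pert is None:
        raise PerturbationStateError("no perturbation layer attached")
    out = net.copy()
    out.W_pert = None
    out.pert_cfg = None
    return out


def _noise_drive(net: NetworkState, n_steps: int, noise_seed: int) -> np.ndarray | None:
    """Per-step perturbation current into the output layer, or None."""
    cfg = net.pert_cfg
    if cfg is None or cfg.n_noise_neurons == 0 or cfg.noise_rate_hz == 0:
        return None
    raster = poisson_spikes(
        cfg.n_noise_neurons,
        cfg.noise_rate_hz,
        n_steps,
        net.spec.neuron_params.dt,
        seed=noise_seed,
    )
    return raster.spikes.T @ net.W_pert.T  # (T, n_output)


def simulate(
    net: NetworkState,
    input_spikes: np.ndarray,
    noise_drive: np.ndarray | None = None,
) -> dict:
    """Batched forward pass.  input_spikes: (B, T, n_input).

    Returns the layer traces plus the filtered output ``rr`` and the readout
    ``eeg`` of shape (B, n_channels, T // stride).
    """
    spec = net.spec
    params, fp = spec.neuron_params, spec.filter_params
    drive_h = input_spikes @ net.W_ih.T
    hid = _engine.layer_forward(drive_h, params)
    drive_o = hid["S"] @ net.W_ho.T
    if noise_drive is not None:
        drive_o = drive_o + noise_drive
    out = _engine.layer_forward(drive_o, params)
    rr = _engine.filter_forward(out["S"], fp, params.dt)
    idx = np.arange(0, rr.shape[1], spec.readout_stride)
    eeg = np.einsum("btj,cj->bct", rr[:, idx], net.W_read)
    return {"hidden": hid, "output": out, "rr": rr, "eeg": eeg, "sample_idx": idx}


def forward(
    net: NetworkState,
    input_raster: SpikeRaster,
    noise_seed: int | None = None,
) -> tuple[np.ndarray, SpikeRaster, SpikeRaster]:
    """Map one input raster to (eeg, hidden raster, output raster).

    With a perturbation layer attached (and non-trivial), ``noise_seed`` is
    required so each generated sample explicitly states its fresh noise
    raster; the coupling weights ``W_pert`` never change between calls.
    """
    spec = net.spec
    if input_raster.n_neurons != spec.n_input:
        raise ValueError(
            f"input raster has {input_raster.n_neurons} neurons, expected {spec.n_input}"
        )
    if input_raster.dt != spec.neuron_params.dt:
        raise ValueError("input raster dt must match the neuron dt")
    T = input_raster.n_steps
    active = (
        net.pert_cfg is not None
        and net.pert_cfg.n_noise_neurons > 0
        and net.pert_cfg.noise_rate_hz > 0
    )
    if active and noise_seed is None:
        raise PerturbationStateError(
            "perturbation layer attached: a noise_seed is required per call"
        )
    nd = _noise_drive(net, T, noise_seed) if active else None
    res = simulate(net, input_raster.spikes.T[None], None if nd is None else nd[None])
    dt = spec.neuron_params.dt
    hidden = SpikeRaster(res["hidden"]["S"][0].T, dt)
    output = SpikeRaster(res["output"]["S"][0].T, dt)
    return res["eeg"][0], hidden, output


def clip_synapses(net: NetworkState, fraction: float, seed: int = 0) -> NetworkState:
    """Zero a uniformly random fraction of the spiking-weight entries.

    Exactly ``round(fraction * size)`` entries are zeroed in each of W_ih and
    W_ho; the readout and perturbation weights are untouched and the input
    network is not modified.
    """
    if not 0 <= fraction < 1:
        raise ValueError("fraction must lie in [0, 1)")
    out = net.copy()
    rng = np.random.default_rng(seed)
    for W in (out.W_ih, out.W_ho):
        k = round(fraction * W.size)
        if k:
            idx = rng.choice(W.size, size=k, replace=False)
            W.reshape(-1)[idx] = 0.0
    return out
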