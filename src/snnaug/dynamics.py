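"""Discrete-time spiking neuron dynamics and the double-exponential synaptic filter.

The simulation is clock-driven at a fixed step ``dt`` (1 ms by default).  A
leaky integrate-and-fire (LIF) neuron follows the exact-decay discrete map

    I[n+1] = alpha * I[n] + drive[n]          alpha = exp(-dt / tau_s)
    u[n+1] = beta  * u[n] + I[n] - theta*S[n]  beta  = exp(-dt / tau_m)

where ``S[n] = Heaviside(u[n] - theta)`` is evaluated on the *pre-update*
potential and the reset subtracts the threshold (reset-by-subtraction).
Quadratic (QIF) and exponential (EIF) variants advance the membrane by
explicit Euler on their continuous equations with the same reset convention.

Spike trains are smoothed by a two-stage exponential cascade (rise time
``tau_r``, decay time ``tau_d``) whose impulse response is the normalized
difference of exponentials; the cascade is linear, so it is integrated with
the exact one-step discretization rather than forward Euler.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import exp

import numpy as np
from scipy.signal import lfilter

__all__ = [
    "NeuronParams",
    "SpikeRaster",
    "LayerState",
    "FilterParams",
    "InvalidRateError",
    "PotentialOverflowError",
    "poisson_spikes",
    "neuron_step",
    "double_exp_filter",
]


class InvalidRateError(ValueError):
    """Firing rate and time step imply a per-step spike probability > 1."""


class PotentialOverflowError(FloatingPointError):
    """A membrane potential became non-finite during integration."""


@dataclass(frozen=True)
class NeuronParams:
    """Integrate-and-fire neuron parameters (times in ms, potentials in mV).

    ``R`` and ``u_rest`` default to the dimensionless substitutions 1 and 0,
    so synaptic currents are unitless.  ``a0``/``u_c`` apply to QIF only,
    ``delta_T`` to EIF only; ``u_ceiling`` clamps the EIF potential before
    its exponential can overflow.
    """

    dt: float = 1.0
    tau_m: float = 10.0
    tau_s: float = 5.0
    u_rest: float = 0.0
    R: float = 1.0
    theta: float = 1.0
    model_kind: str = "LIF"
    a0: float | None = None
    u_c: float | None = None
    delta_T: float | None = None
    u_ceiling: float = 30.0

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.tau_m <= 0 or self.tau_s <= 0:
            raise ValueError("dt, tau_m and tau_s must be positive")
        if self.theta <= self.u_rest:
            raise ValueError("spike threshold must exceed the resting potential")
        if self.model_kind not in ("LIF", "QIF", "EIF"):
            raise ValueError(f"unknown model_kind {self.model_kind!r}")
        if self.model_kind == "QIF":
            if self.a0 is None or self.u_c is None:
                raise ValueError("QIF requires a0 and u_c")
            if self.a0 <= 0:
                raise ValueError("QIF curvature a0 must be positive")
            if self.u_c <= self.u_rest:
                raise ValueError("QIF critical potential must exceed u_rest")
        elif self.a0 is not None or self.u_c is not None:
            raise ValueError("a0/u_c only apply to the QIF model")
        if self.model_kind == "EIF":
            if self.delta_T is None:
                raise ValueError("EIF requires the sharpness delta_T")
            if self.delta_T <= 0:
                raise ValueError("EIF sharpness delta_T must be positive")
        elif self.delta_T is not None:
            raise ValueError("delta_T only applies to the EIF model")

    @property
    def alpha(self) -> float:
        """Synaptic current decay factor exp(-dt/tau_s)."""
        return exp(-self.dt / self.tau_s)

    @property
    def beta(self) -> float:
        """Membrane potential decay factor exp(-dt/tau_m)."""
        return exp(-self.dt / self.tau_m)


@dataclass(frozen=True)
class SpikeRaster:
    """Binary spike matrix, neurons x timesteps, at a fixed step ``dt`` (ms)."""

    spikes: np.ndarray
    dt: float = 1.0

    def __post_init__(self) -> None:
        spikes = np.asarray(self.spikes)
        if spikes.ndim != 2:
            raise ValueError("spikes must be a 2-D neurons x timesteps array")
        if not np.isin(spikes, (0, 1)).all():
            raise ValueError("spike raster entries must be 0 or 1")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        object.__setattr__(self, "spikes", spikes.astype(np.float64))

    @property
    def n_neurons(self) -> int:
        return self.spikes.shape[0]

    @property
    def n_steps(self) -> int:
        return self.spikes.shape[1]

    def rate_hz(self) -> float:
        """Empirical mean firing rate across all neurons, in Hz."""
        return float(self.spikes.mean() * 1000.0 / self.dt)


@dataclass
class LayerState:
    """Per-neuron membrane potentials ``u`` (mV) and synaptic currents ``I``."""

    u: np.ndarray
    I: np.ndarray

    def __post_init__(self) -> None:
        self.u = np.asarray(self.u, dtype=np.float64)
        self.I = np.asarray(self.I, dtype=np.float64)
        if self.u.shape != self.I.shape:
            raise ValueError("u and I must have the same shape")
        if not (np.isfinite(self.u).all() and np.isfinite(self.I).all()):
            raise ValueError("layer state must be finite")

    @classmethod
    def zeros(cls, n: int) -> "LayerState":
        return cls(np.zeros(n), np.zeros(n))


@dataclass(frozen=True)
class FilterParams:
    """Double-exponential synaptic filter times (ms): rise tau_r, decay tau_d."""

    tau_r: float = 3.0
    tau_d: float = 2.0

    def __post_init__(self) -> None:
        if self.tau_r <= 0 or self.tau_d <= 0:
            raise ValueError("filter time constants must be positive")
        if self.tau_r == self.tau_d:
            raise ValueError("tau_r and tau_d must differ (double exponential)")


def poisson_spikes(
    n_neurons: int, rate_hz: float, n_steps: int, dt: float = 1.0, seed: int = 0
) -> SpikeRaster:
    """Draw a Bernoulli-approximated Poisson raster.

    Each entry is an independent Bernoulli draw with p = rate_hz * dt / 1000;
    the same seed always yields the identical raster.
    """
    if n_neurons < 1 or n_steps < 1:
        raise ValueError("n_neurons and n_steps must be >= 1")
    if rate_hz < 0:
        raise InvalidRateError("firing rate must be non-negative")
    p = rate_hz * dt / 1000.0
    if p > 1.0:
        raise InvalidRateError(
            f"rate {rate_hz} Hz at dt={dt} ms implies spike probability {p} > 1"
        )
    rng = np.random.default_rng(seed)
    spikes = (rng.random((n_neurons, n_steps)) < p).astype(np.float64)
    return SpikeRaster(spikes, dt)


def _membrane_update(u, I, S, params: NeuronParams):
    """One-step membrane advance common to all model kinds (reset included)."""
    kind = params.model_kind
    reset = params.theta * S
    if kind == "LIF":
        return params.beta * u + I - reset
    h = params.dt / params.tau_m
    if kind == "QIF":
        # overflow here is deliberate: callers detect the resulting
        # non-finite potential and raise PotentialOverflowError
        with np.errstate(over="ignore", invalid="ignore"):
            dv = params.a0 * (u - params.u_rest) * (u - params.u_c) + params.R * I
            return u + h * dv - reset
    # EIF: clamp the exponential argument via the potential ceiling
    u_safe = np.minimum(u, params.u_ceiling)
    dv = (
        -(u_safe - params.u_rest)
        + params.delta_T * np.exp((u_safe - params.theta) / params.delta_T)
        + params.R * I
    )
    return np.minimum(u + h * dv - reset, params.u_ceiling)


def neuron_step(
    state: LayerState,
    input_current: np.ndarray,
    params: NeuronParams,
    step_index: int | None = None,
) -> tuple[LayerState, np.ndarray]:
    """Advance a layer by one time step; returns the new state and spike vector.

    Spikes are detected on the current-step potential (``u >= theta``, tie
    counts as a spike) before the update consumes it; the reset subtracts
    ``theta`` so non-unit thresholds remain correct.
    """
    u, I = state.u, state.I
    drive = np.asarray(input_current, dtype=np.float64)
    if drive.shape != u.shape:
        raise ValueError("input_current must match the layer size")
    S = (u >= params.theta).astype(np.float64)
    u_next = _membrane_update(u, I, S, params)
    I_next = params.alpha * I + drive
    if not np.isfinite(u_next).all():
        where = f" at step {step_index}" if step_index is not None else ""
        raise PotentialOverflowError(f"membrane potential diverged{where}")
    return LayerState(u_next, I_next), S


def filter_coefficients(fp: FilterParams, dt: float) -> tuple[float, float, float, float]:
    """Exact one-step discretization coefficients (a_r, a_d, g0, c).

    A spike increments the intermediate state ``h`` by g0 = 1/(tau_r*tau_d);
    the output obeys r' = a_d r + c h with the cross-coupling gain ``c`` chosen
    so the discrete impulse response equals the continuous kernel
    g0 * (exp(-t/tau_r) - exp(-t/tau_d)) / (1/tau_d - 1/tau_r)
    at every sample point.
    """
    a_r = exp(-dt / fp.tau_r)
    a_d = exp(-dt / fp.tau_d)
    g0 = 1.0 / (fp.tau_r * fp.tau_d)
    c = (a_d - a_r) / (1.0 / fp.tau_r - 1.0 / fp.tau_d)
    return a_r, a_d, g0, c


def double_exp_filter(raster: SpikeRaster, fp: FilterParams) -> np.ndarray:
    """Smooth each neuron's spike train into a continuous rate signal.

    Returns a (neurons x timesteps) array; entry ``[j, n]`` is the filter
    output at time ``(n + 1) * dt`` given spikes up to and including step n.
    Starting from rest the output is non-negative, and the map is linear in
    the raster.
    """
    a_r, a_d, g0, c = filter_coefficients(fp, raster.dt)
    h = lfilter([g0], [1.0, -a_r], raster.spikes, axis=-1)
    return lfilter([c], [1.0, -a_d], h, axis=-1)
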