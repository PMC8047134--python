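"""Vectorized forward simulation and adjoint (backward) passes.

All arrays here are batch-major, time-second: (B, T, n).  Linear recurrences
(synaptic currents, the output filter and their adjoints) run through
``scipy.signal.lfilter``; only the threshold nonlinearity of the membrane
loop and, in relaxed mode, the time-varying adjoint recursion are explicit
Python loops over time.

The backward pass implements backpropagation through time with the surrogate
spike derivative: the hard forward spike ``Heaviside(u - theta)`` is given
the pseudo-derivative ``slope * sigmoid'(slope * (u - theta))``.  In relaxed
mode the forward pass itself uses the sigmoid (every operation smooth), which
is what the finite-difference gradient check exercises; there the reset path
is differentiated too, while the hard training mode treats the reset term as
constant for stability.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import lfilter

from .dynamics import FilterParams, NeuronParams, filter_coefficients


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def surrogate_factor(u: np.ndarray, theta: float, slope: float) -> np.ndarray:
    """slope * sigmoid'(slope * (u - theta)) — the spike pseudo-derivative."""
    s = sigmoid(slope * (u - theta))
    return slope * s * (1.0 - s)


def _causal(x: np.ndarray, rho: float) -> np.ndarray:
    """y[n] = rho*y[n-1] + x[n] along axis 1."""
    return lfilter([1.0], [1.0, -rho], x, axis=1)


def _anticausal(x: np.ndarray, rho: float) -> np.ndarray:
    """y[n] = x[n] + rho*y[n+1] along axis 1 (adjoint of _causal)."""
    return _causal(x[:, ::-1], rho)[:, ::-1]


def _shift_left(x: np.ndarray) -> np.ndarray:
    """out[n] = x[n+1], zero-padded at the end."""
    out = np.zeros_like(x)
    out[:, :-1] = x[:, 1:]
    return out


def layer_forward(
    drive: np.ndarray,
    params: NeuronParams,
    *,
    relaxed: bool = False,
    slope: float = 10.0,
) -> dict:
    """Simulate a LIF layer for all steps.  drive: (B, T, n) synaptic input.

    Returns S (spikes), U (pre-update potentials) and I (currents), each
    (B, T, n).  Relaxed mode replaces the Heaviside with a sigmoid of the
    given steepness (used by the gradient check only).
    """
    B, T, n = drive.shape
    alpha, beta, theta = params.alpha, params.beta, params.theta
    I = np.empty_like(drive)
    I[:, 0] = 0.0
    if T > 1:
        I[:, 1:] = _causal(drive, alpha)[:, :-1]
    S = np.empty_like(drive)
    U = np.empty_like(drive)
    u = np.zeros((B, n))
    for t in range(T):
        U[:, t] = u
        if relaxed:
            s = sigmoid(slope * (u - theta))
        else:
            s = (u >= theta).astype(np.float64)
        S[:, t] = s
        u = beta * u + I[:, t] - theta * s
    return {"S": S, "U": U, "I": I}


def layer_adjoint(
    dS_down: np.ndarray,
    U: np.ndarray,
    params: NeuronParams,
    *,
    slope: float = 10.0,
    include_reset: bool = False,
) -> np.ndarray:
    """Backpropagate through one spiking layer.

    ``dS_down``: loss gradient w.r.t. this layer's spikes (B, T, n).
    Returns d_drive, the gradient w.r.t. the per-step synaptic drive, from
    which weight and upstream-spike gradients follow by linearity.
    """
    alpha, beta, theta = params.alpha, params.beta, params.theta
    g = surrogate_factor(U, theta, slope)
    B, T, n = dS_down.shape
    P = np.empty_like(dS_down)
    p = np.zeros((B, n))
    if include_reset:
        for t in range(T - 1, -1, -1):
            p = (beta - theta * g[:, t]) * p + g[:, t] * dS_down[:, t]
            P[:, t] = p
    else:
        # constant-coefficient recursion: p[t] = beta*p[t+1] + g[t]*dS[t]
        P = _anticausal(g * dS_down, beta)
    # q[t] = dL/dI[t] = alpha*q[t+1] + p[t+1]; d_drive[t] = q[t+1]
    q = _anticausal(_shift_left(P), alpha)
    return _shift_left(q)


def filter_forward(S: np.ndarray, fp: FilterParams, dt: float) -> np.ndarray:
    """Batched double-exponential filter; S: (B, T, n) -> rr: (B, T, n)."""
    a_r, a_d, g0, c = filter_coefficients(fp, dt)
    h = _causal(g0 * S, a_r)
    return _causal(c * h, a_d)


def filter_adjoint(d_rr: np.ndarray, fp: FilterParams, dt: float) -> np.ndarray:
    """Adjoint of :func:`filter_forward`: gradient w.r.t. the spike input."""
    a_r, a_d, g0, c = filter_coefficients(fp, dt)
    x = _anticausal(d_rr, a_d)
    return g0 * _anticausal(c * x, a_r)
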