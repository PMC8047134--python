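"""Surrogate-gradient training of the network against per-class EEG templates.

One fixed Poisson raster per class drives the network; every epoch runs all
classes, accumulates the squared reconstruction error against each class
template, backpropagates through time with the surrogate spike derivative
(the Heaviside forward pass is untouched; its pseudo-derivative is
``slope * sigmoid'(slope * (u - theta))``) and applies one Adam update to
W_ih, W_ho and W_read.  Perturbation weights are never trained and training
refuses to run while a perturbation layer is attached.

Gradients use the summed squared error over channels, samples and classes —
with the reference Adam hyperparameters (lr 5e-4, eps 0.8) the epsilon term
would swamp mean-reduced gradients entirely.  The *recorded* loss remains
the per-class mean squared error, matching :func:`mse_loss`.

The reset term of the membrane update is treated as a constant in the hard
(spiking) backward pass, a standard stabilization; the fully relaxed mode
used by the finite-difference gradient check differentiates it exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import _engine
from .dynamics import SpikeRaster
from .network import NetworkState, PerturbationStateError

__all__ = [
    "TrainConfig",
    "TrainingRecord",
    "DivergenceError",
    "surrogate_spike",
    "mse_loss",
    "train",
    "relaxed_loss_and_grads",
]

log = logging.getLogger(__name__)


class DivergenceError(FloatingPointError):
    """The training loss became non-finite."""


@dataclass(frozen=True)
class TrainConfig:
    """Adam hyperparameters and training control.

    Defaults follow the reference configuration: learning rate 5e-4,
    betas (0.9, 0.999), epsilon 0.8 (atypically large: it damps update
    magnitude for weakly-driven parameters, acting as a trust region under
    sum-reduced gradients), zero weight decay.  ``loss_tolerance`` is the
    early-stop threshold on the summed per-class mean MSE; None derives
    1e-3 x the mean template variance per class.
    """

    learning_rate: float = 5e-4
    betas: tuple[float, float] = (0.9, 0.999)
    epsilon: float = 0.8
    weight_decay: float = 0.0
    max_epochs: int = 1000
    loss_tolerance: float | None = None
    surrogate_slope: float = 10.0
    alternate_classes: bool = False

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        b1, b2 = self.betas
        if not (0 <= b1 < 1 and 0 <= b2 < 1):
            raise ValueError("betas must lie in [0, 1)")
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")
        if self.surrogate_slope <= 0:
            raise ValueError("surrogate_slope must be positive")


@dataclass
class TrainingRecord:
    """Per-epoch, per-class mean-MSE history and final template correlations."""

    loss_history: np.ndarray  # (epochs_run, n_classes)
    epochs_run: int
    final_correlation: np.ndarray  # (n_classes, n_channels) Pearson r
    class_names: list[str]
    channel_names: list[str] | None = None  # carried for downstream labeling


def surrogate_spike(
    u_minus_theta: np.ndarray | float, slope: float = 10.0
) -> tuple[np.ndarray, np.ndarray]:
    """Hard forward spike and the backward gradient factor.

    Forward: Heaviside(u - theta) with a tie at threshold counting as a
    spike.  Backward factor: slope * sigmoid'(slope * (u - theta)), which
    is 0.25 at threshold for slope 1.
    """
    x = np.asarray(u_minus_theta, dtype=np.float64)
    fwd = (x >= 0).astype(np.float64)
    s = _engine.sigmoid(slope * x)
    return fwd, slope * s * (1.0 - s)


def mse_loss(predicted: np.ndarray, template: np.ndarray) -> float:
    """Mean of squared elementwise differences over all channels and samples."""
    predicted = np.asarray(predicted, dtype=np.float64)
    template = np.asarray(template, dtype=np.float64)
    if predicted.shape != template.shape:
        raise ValueError(
            f"shape mismatch: {predicted.shape} vs {template.shape}"
        )
    return float(np.mean((predicted - template) ** 2))


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.linalg.norm(a) * np.linalg.norm(b)
    if denom == 0:
        return float("nan")
    return float(a @ b / denom)


def _forward_backward(net: NetworkState, S_in: np.ndarray, targets: np.ndarray, slope: float):
    """One pass over a batch of classes; returns (per-class mean MSE, grads, eeg).

    S_in: (B, T, n_input); targets: (B, C, Nt).  Gradients use sum reduction.
    """
    from .network import simulate

    spec = net.spec
    params, fp = spec.neuron_params, spec.filter_params
    res = simulate(net, S_in)
    eeg = res["eeg"]
    err = eeg - targets
    per_class_mse = (err**2).mean(axis=(1, 2))
    d_eeg = 2.0 * err  # sum-reduced gradient
    idx = res["sample_idx"]
    rr = res["rr"]
    dW_read = np.einsum("bct,btj->cj", d_eeg, rr[:, idx])
    d_rr = np.zeros_like(rr)
    d_rr[:, idx] = np.einsum("bct,cj->btj", d_eeg, net.W_read)
    dS_out = _engine.filter_adjoint(d_rr, fp, params.dt)
    d_drive_o = _engine.layer_adjoint(
        dS_out, res["output"]["U"], params, slope=slope, include_reset=False
    )
    dW_ho = np.einsum("bto,bth->oh", d_drive_o, res["hidden"]["S"])
    dS_hid = d_drive_o @ net.W_ho
    d_drive_h = _engine.layer_adjoint(
        dS_hid, res["hidden"]["U"], params, slope=slope, include_reset=False
    )
    dW_ih = np.einsum("bth,bti->hi", d_drive_h, S_in)
    grads = {"W_ih": dW_ih, "W_ho": dW_ho, "W_read": dW_read}
    return per_class_mse, grads, eeg


class _Adam:
    def __init__(self, shapes: dict, cfg: TrainConfig):
        self.m = {k: np.zeros(s) for k, s in shapes.items()}
        self.v = {k: np.zeros(s) for k, s in shapes.items()}
        self.t = 0
        self.cfg = cfg

    def step(self, weights: dict, grads: dict) -> None:
        cfg = self.cfg
        b1, b2 = cfg.betas
        self.t += 1
        for k, W in weights.items():
            g = grads[k]
            if cfg.weight_decay:
                g = g + cfg.weight_decay * W
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1**self.t)
            vhat = self.v[k] / (1 - b2**self.t)
            W -= cfg.learning_rate * mhat / (np.sqrt(vhat) + cfg.epsilon)


def train(
    net: NetworkState,
    class_inputs: dict[str, SpikeRaster],
    templates: dict[str, np.ndarray],
    cfg: TrainConfig | None = None,
) -> tuple[NetworkState, TrainingRecord]:
    """Train a copy of ``net`` to reconstruct all class templates simultaneously.

    ``class_inputs`` maps class name -> fixed input raster; ``templates`` maps
    class name -> (n_channels, n_samples) target EEG at the readout rate.
    Returns the trained network (with its TrainingRecord attached) and the
    record.  Inputs and any perturbation weights are left bit-identical.
    """
    cfg = cfg or TrainConfig()
    if net.W_pert is not None:
        raise PerturbationStateError("detach the perturbation layer before training")
    names = list(class_inputs)
    if set(names) != set(templates):
        raise ValueError("class_inputs and templates must share the same classes")
    spec = net.spec
    T = {class_inputs[k].n_steps for k in names}
    if len(T) != 1:
        raise ValueError("all class inputs must share one step count")
    T = T.pop()
    n_t = T // spec.readout_stride + (1 if T % spec.readout_stride else 0)
    S_in = np.stack([class_inputs[k].spikes.T for k in names])
    tgt = np.stack([np.asarray(templates[k], dtype=np.float64) for k in names])
    if tgt.shape[1:] != (spec.n_channels, n_t):
        raise ValueError(
            f"templates must be (n_channels={spec.n_channels}, {n_t}); got {tgt.shape[1:]}"
        )
    for k in names:
        if class_inputs[k].n_neurons != spec.n_input:
            raise ValueError(f"input raster for class {k!r} does not match n_input")

    tol = cfg.loss_tolerance
    if tol is None:
        tol = 1e-3 * float(tgt.var(axis=-1).mean()) * len(names)

    out = net.copy()
    weights = {"W_ih": out.W_ih, "W_ho": out.W_ho, "W_read": out.W_read}
    opt = _Adam({k: w.shape for k, w in weights.items()}, cfg)
    history = []
    eeg = None
    for epoch in range(cfg.max_epochs):
        if cfg.alternate_classes:
            per_class = np.empty(len(names))
            eeg = np.empty_like(tgt)
            for b in range(len(names)):
                mse_b, grads, eeg_b = _forward_backward(
                    out, S_in[b : b + 1], tgt[b : b + 1], cfg.surrogate_slope
                )
                per_class[b] = mse_b[0]
                eeg[b] = eeg_b[0]
                opt.step(weights, grads)
        else:
            per_class, grads, eeg = _forward_backward(
                out, S_in, tgt, cfg.surrogate_slope
            )
            opt.step(weights, grads)
        total = float(per_class.sum())
        if not np.isfinite(total):
            raise DivergenceError(f"non-finite loss at epoch {epoch}")
        history.append(per_class.copy())
        log.info(
            "epoch %d: %s",
            epoch,
            ", ".join(f"{k}={v:.5g}" for k, v in zip(names, per_class)),
        )
        if total <= tol:
            break
    corr = np.empty((len(names), spec.n_channels))
    for b in range(len(names)):
        for c in range(spec.n_channels):
            corr[b, c] = _pearson(eeg[b, c], tgt[b, c])
    record = TrainingRecord(
        loss_history=np.asarray(history),
        epochs_run=len(history),
        final_correlation=corr,
        class_names=names,
    )
    out.training_record = record
    return out, record


def relaxed_loss_and_grads(
    net: NetworkState,
    S_in: np.ndarray,
    targets: np.ndarray,
    slope: float = 10.0,
) -> tuple[float, dict[str, np.ndarray]]:
    """Loss and exact gradients of the fully sigmoid-relaxed network.

    Every spike nonlinearity (including the reset path) is replaced by the
    sigmoid, so the network is smooth end-to-end and the returned gradients
    are checkable against central finite differences.  Loss is the summed
    squared error, the same reduction the training gradients use.
    """
    spec = net.spec
    params, fp = spec.neuron_params, spec.filter_params
    drive_h = S_in @ net.W_ih.T
    hid = _engine.layer_forward(drive_h, params, relaxed=True, slope=slope)
    drive_o = hid["S"] @ net.W_ho.T
    outp = _engine.layer_forward(drive_o, params, relaxed=True, slope=slope)
    rr = _engine.filter_forward(outp["S"], fp, params.dt)
    idx = np.arange(0, rr.shape[1], spec.readout_stride)
    eeg = np.einsum("btj,cj->bct", rr[:, idx], net.W_read)
    err = eeg - targets
    loss = float((err**2).sum())
    d_eeg = 2.0 * err
    dW_read = np.einsum("bct,btj->cj", d_eeg, rr[:, idx])
    d_rr = np.zeros_like(rr)
    d_rr[:, idx] = np.einsum("bct,cj->btj", d_eeg, net.W_read)
    dS_out = _engine.filter_adjoint(d_rr, fp, params.dt)
    d_drive_o = _engine.layer_adjoint(
        dS_out, outp["U"], params, slope=slope, include_reset=True
    )
    dW_ho = np.einsum("bto,bth->oh", d_drive_o, hid["S"])
    dS_hid = d_drive_o @ net.W_ho
    d_drive_h = _engine.layer_adjoint(
        dS_hid, hid["U"], params, slope=slope, include_reset=True
    )
    dW_ih = np.einsum("bth,bti->hi", d_drive_h, S_in)
    return loss, {"W_ih": dW_ih, "W_ho": dW_ho, "W_read": dW_read}
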