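"""Template extraction and synthetic-sample generation.

Stage 1 extracts one clean template per class, either by trial averaging
(SSVEP, where the response is phase-locked to the stimulus) or by picking
the trial the classifier is most confident about (motor imagery, where
averaging washes out the broadband mu/beta modulation).  Stage 3 activates
the perturbation layer of a trained network and draws a fresh noise raster
per sample, yielding arbitrarily many labeled synthetic trials; sweeps over
the noise-population size and rate map out how far the samples drift from
the template (Pearson correlation of the per-cell average against the
template).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import pearsonr

from . import _engine
from .dynamics import SpikeRaster, poisson_spikes
from .network import (
    NetworkState,
    PerturbationConfig,
    attach_perturbation,
)

__all__ = [
    "EpochSet",
    "Template",
    "CorrelationGrid",
    "UntrainedNetworkError",
    "UndefinedCorrelationError",
    "extract_template_average",
    "select_best_trial",
    "fixed_class_inputs",
    "generate_samples",
    "perturbation_sweep",
    "correlation_grid",
]

log = logging.getLogger(__name__)


class UntrainedNetworkError(RuntimeError):
    """Sample generation requested from a network with no training record."""


class UndefinedCorrelationError(ValueError):
    """Pearson correlation requested against a zero-variance signal."""


@dataclass
class EpochSet:
    """Labeled EEG trials: data is (trials, channels, samples) in microvolts."""

    data: np.ndarray
    labels: np.ndarray  # integer index into class_names, one per trial
    fs: float
    channel_names: list[str]
    class_names: list[str]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.data.ndim != 3:
            raise ValueError("data must be (trials, channels, samples)")
        if self.labels.shape != (self.data.shape[0],):
            raise ValueError("one label per trial required")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.data.shape[1] != len(self.channel_names):
            raise ValueError("channel_names must match the channel count")
        for k in range(len(self.class_names)):
            if not (self.labels == k).any():
                raise ValueError(
                    f"class {self.class_names[k]!r} has no trials"
                )
        if self.labels.min() < 0 or self.labels.max() >= len(self.class_names):
            raise ValueError("labels must index class_names")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    def class_trials(self, name_or_index: str | int) -> np.ndarray:
        """Data of all trials of one class, (trials, channels, samples)."""
        k = (
            name_or_index
            if isinstance(name_or_index, (int, np.integer))
            else self.class_names.index(name_or_index)
        )
        return self.data[self.labels == k]

    def subset(self, indices: np.ndarray) -> "EpochSet":
        return EpochSet(
            self.data[indices],
            self.labels[indices],
            self.fs,
            list(self.channel_names),
            list(self.class_names),
        )


@dataclass
class Template:
    """One signal per class, (n_classes, channels, samples), plus provenance."""

    signals: np.ndarray
    class_names: list[str]
    channel_names: list[str]
    fs: float
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.signals = np.asarray(self.signals, dtype=np.float64)
        if self.signals.ndim != 3 or self.signals.shape[0] != len(self.class_names):
            raise ValueError("signals must be (n_classes, channels, samples)")

    def as_dict(self) -> dict[str, np.ndarray]:
        return {k: self.signals[i] for i, k in enumerate(self.class_names)}


@dataclass
class CorrelationGrid:
    """Pearson r of averaged synthetic samples vs the template on a noise grid."""

    axis_neurons: list[int]
    axis_rates: list[float]
    r: np.ndarray  # (len(axis_neurons), len(axis_rates))
    channel: str
    class_name: str
    method: str = "averaged"

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=np.float64)
        if self.r.shape != (len(self.axis_neurons), len(self.axis_rates)):
            raise ValueError("r must be |axis_neurons| x |axis_rates|")
        if np.nanmax(np.abs(self.r)) > 1 + 1e-12:
            raise ValueError("correlations must lie in [-1, 1]")


def extract_template_average(
    epochs: EpochSet, n_trials: int | None = None, seed: int = 0
) -> Template:
    """Per-class elementwise mean across trials (optionally a random subset)."""
    rng = np.random.default_rng(seed)
    signals = []
    for k in range(len(epochs.class_names)):
        trials = epochs.class_trials(k)
        if n_trials is not None and n_trials < len(trials):
            pick = rng.choice(len(trials), size=n_trials, replace=False)
            trials = trials[pick]
        signals.append(trials.mean(axis=0))
    return Template(
        np.stack(signals),
        list(epochs.class_names),
        list(epochs.channel_names),
        epochs.fs,
        provenance={"method": "averaged", "n_trials": n_trials},
    )


def select_best_trial(epochs: EpochSet, seed: int = 0) -> Template:
    """Pick, per class, the trial the classifier assigns the highest posterior.

    CSP + LDA are fitted on the full set (training and scoring on the same
    data, deliberately: the goal is a confidence ranking of the trials, not
    a generalization estimate); ties break toward the lowest trial index.
    """
    from .evaluation import csp_features, csp_fit, fit_classifier

    counts = [int((epochs.labels == k).sum()) for k in range(len(epochs.class_names))]
    if all(c == 1 for c in counts):
        order = [int(np.flatnonzero(epochs.labels == k)[0]) for k in range(len(counts))]
        return Template(
            epochs.data[order],
            list(epochs.class_names),
            list(epochs.channel_names),
            epochs.fs,
            provenance={
                "method": "best_trial",
                "trial_index": order,
                "posterior": [1.0] * len(order),
            },
        )
    model = csp_fit(epochs)
    feats = csp_features(model, epochs)
    clf = fit_classifier(feats, epochs.labels, kind="LDA")
    proba = clf.predict_proba(feats)
    class_order = list(clf.classes_)
    signals, indices, posteriors = [], [], []
    for k in range(len(epochs.class_names)):
        trial_idx = np.flatnonzero(epochs.labels == k)
        own = proba[trial_idx, class_order.index(k)]
        best = trial_idx[int(np.argmax(own))]  # argmax keeps the lowest index on ties
        signals.append(epochs.data[best])
        indices.append(int(best))
        posteriors.append(float(own.max()))
    return Template(
        np.stack(signals),
        list(epochs.class_names),
        list(epochs.channel_names),
        epochs.fs,
        provenance={
            "method": "best_trial",
            "trial_index": indices,
            "posterior": posteriors,
        },
    )


def fixed_class_inputs(
    net: NetworkState | "NetworkSpec",
    class_names: list[str],
    n_steps: int,
    rate_hz: float = 10.0,
    seed: int = 0,
) -> dict[str, SpikeRaster]:
    """One frozen Poisson input raster per class (default 10 Hz)."""
    spec = getattr(net, "spec", net)
    out = {}
    for i, name in enumerate(class_names):
        child = int(np.random.SeedSequence(seed, spawn_key=(i,)).generate_state(1)[0])
        out[name] = poisson_spikes(
            spec.n_input, rate_hz, n_steps, spec.neuron_params.dt, seed=child
        )
    return out


def _sample_seed(seed: int, class_index: int, sample_index: int) -> int:
    """Deterministic per-sample noise seed so any trial is reproducible alone."""
    ss = np.random.SeedSequence(seed, spawn_key=(class_index, sample_index))
    return int(ss.generate_state(1)[0])


def generate_samples(
    net: NetworkState,
    class_inputs: dict[str, SpikeRaster],
    cfg: PerturbationConfig,
    n_samples: int,
    seed: int = 0,
    channel_names: list[str] | None = None,
    force: bool = False,
    _chunk: int = 50,
) -> EpochSet:
    """Generate ``n_samples`` synthetic trials per class.

    Attaches the perturbation layer described by ``cfg`` to a copy of the
    trained network and runs one forward pass per (class, sample) with a
    fresh noise raster whose seed derives deterministically from
    ``(seed, class, sample)``.  The hidden layer is simulated once per class
    (its input is fixed) and samples are processed in batches.
    """
    if not net.trained:
        if not force:
            raise UntrainedNetworkError(
                "network has no training record; pass force=True to generate anyway"
            )
        log.warning("generating samples from an untrained network (forced)")
    pert = attach_perturbation(net, cfg)
    spec = pert.spec
    params, fp = spec.neuron_params, spec.filter_params
    names = list(class_inputs)
    T = class_inputs[names[0]].n_steps
    idx = np.arange(0, T, spec.readout_stride)
    active = cfg.n_noise_neurons > 0 and cfg.noise_rate_hz > 0
    data = np.empty((len(names) * n_samples, spec.n_channels, len(idx)))
    labels = np.empty(len(names) * n_samples, dtype=np.int64)
    row = 0
    for ci, name in enumerate(names):
        S_in = class_inputs[name].spikes.T[None]
        hid = _engine.layer_forward(S_in @ pert.W_ih.T, params)
        base = (hid["S"] @ pert.W_ho.T)[0]  # (T, n_output)
        for start in range(0, n_samples, _chunk):
            m = min(_chunk, n_samples - start)
            if active:
                noise = np.stack(
                    [
                        poisson_spikes(
                            cfg.n_noise_neurons,
                            cfg.noise_rate_hz,
                            T,
                            params.dt,
                            seed=_sample_seed(seed, ci, start + si),
                        ).spikes.T
                        for si in range(m)
                    ]
                )
                drive = base[None] + noise @ pert.W_pert.T
            else:
                drive = np.broadcast_to(base, (m, T, spec.n_output)).copy()
            out = _engine.layer_forward(drive, params)
            rr = _engine.filter_forward(out["S"], fp, params.dt)
            data[row : row + m] = np.einsum("btj,cj->bct", rr[:, idx], pert.W_read)
            labels[row : row + m] = ci
            row += m
    return EpochSet(
        data,
        labels,
        spec.eeg_fs,
        channel_names or [f"ch{c}" for c in range(spec.n_channels)],
        names,
    )


def perturbation_sweep(
    net: NetworkState,
    class_inputs: dict[str, SpikeRaster],
    neuron_counts: list[int],
    rates: list[float],
    n_samples: int = 100,
    seed: int = 0,
    weight_scale: float = 1.0,
    weight_seed: int = 0,
    channel_names: list[str] | None = None,
) -> dict[tuple[int, float], EpochSet]:
    """Independent generation for every (noise-neuron count, rate) grid cell."""
    if not neuron_counts or not rates:
        raise ValueError("sweep grid must be non-empty")
    out = {}
    for n in neuron_counts:
        for rate in rates:
            cfg = PerturbationConfig(
                n_noise_neurons=n,
                noise_rate_hz=rate,
                weight_scale=weight_scale,
                seed=weight_seed,
            )
            log.info("sweep cell: %d noise neurons at %g Hz", n, rate)
            out[(n, float(rate))] = generate_samples(
                net, class_inputs, cfg, n_samples, seed=seed,
                channel_names=channel_names,
            )
    return out


def _pearson_checked(a: np.ndarray, b: np.ndarray) -> float:
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise UndefinedCorrelationError("zero-variance signal in correlation")
    return float(pearsonr(a, b).statistic)


def correlation_grid(
    sweep: dict[tuple[int, float], EpochSet],
    template: Template,
    class_name: str,
    channel: str,
    method: str = "averaged",
) -> CorrelationGrid:
    """Pearson r between synthetic samples and the template per grid cell.

    ``method='averaged'`` correlates the mean of the cell's samples with the
    template (the default reading); ``'per_sample'`` averages per-sample
    correlations instead.
    """
    if method not in ("averaged", "per_sample"):
        raise ValueError("method must be 'averaged' or 'per_sample'")
    neurons = sorted({k[0] for k in sweep})
    rates = sorted({k[1] for k in sweep})
    ci = template.class_names.index(class_name)
    ch = template.channel_names.index(channel)
    tmpl = template.signals[ci, ch]
    r = np.full((len(neurons), len(rates)), np.nan)
    for i, n in enumerate(neurons):
        for j, rate in enumerate(rates):
            cell = sweep.get((n, rate))
            if cell is None:
                continue
            trials = cell.class_trials(class_name)[:, ch]
            if trials.shape[1] != tmpl.shape[0]:
                raise ValueError("sweep sample length does not match the template")
            if method == "averaged":
                r[i, j] = _pearson_checked(trials.mean(axis=0), tmpl)
            else:
                r[i, j] = float(
                    np.mean([_pearson_checked(tr, tmpl) for tr in trials])
                )
    return CorrelationGrid(neurons, rates, r, channel, class_name, method)
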