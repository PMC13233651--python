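"""Validation analyses: instantaneous phase, phase-locked spike histograms,
vector strength and seizure-propagation latency maps.

The seizure carrier signal is x2 - x1 (spike-and-wave minus fast discharge);
its instantaneous phase comes from the analytic signal (Hilbert transform).
Spikes of each vertex's subpopulation are binned at the phase of that
vertex's signal at the spike time; tight cross-scale synchronization shows
up as histogram mass concentrated near the phases of maximal transmitted
spike probability, quantified by the vector strength (modulus of the mean
unit phasor, 1 = perfect locking, 0 = uniform).
"""

from __future__ import annotations

import dataclasses

import numpy as np
import scipy.signal

from .field import FieldRecording
from .snn import SpikeRecord

__all__ = [
    "PhaseSeries",
    "PhaseLockHistogram",
    "hilbert_phase",
    "phase_locked_histogram",
    "vector_strength",
    "onset_latency_map",
]


@dataclasses.dataclass
class PhaseSeries:
    """Instantaneous phase in [-pi, pi) per signal over time."""

    phases: np.ndarray  # (n_signals, n_times)
    source: str = "x2-x1"

    def __post_init__(self) -> None:
        self.phases = np.atleast_2d(np.asarray(self.phases, dtype=float))
        if ((self.phases < -np.pi) | (self.phases >= np.pi)).any():
            raise ValueError("phases must lie in [-pi, pi)")

    @property
    def n_times(self) -> int:
        return self.phases.shape[1]


@dataclasses.dataclass
class PhaseLockHistogram:
    """Phase histograms of spike counts over [-pi, pi)."""

    bin_edges: np.ndarray
    per_vertex: np.ndarray  # (n_devices, n_bins)
    average: np.ndarray  # mean across devices with spikes
    pooled: np.ndarray  # summed across devices
    vector_strength: float
    n_spikes: int

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


def hilbert_phase(signal: np.ndarray, source: str = "x2-x1") -> PhaseSeries:
    """Phase of the analytic signal, mean removed first.

    ``signal`` is one time series or a (n_signals, n_times) stack.  Constant
    rows are rejected (their phase is undefined).
    """
    sig = np.atleast_2d(np.asarray(signal, dtype=float))
    if sig.shape[1] < 16:
        raise ValueError("signal must contain at least 16 samples")
    if not np.isfinite(sig).all():
        raise ValueError("signal must be finite")
    span = sig.max(axis=1) - sig.min(axis=1)
    if (span == 0).any():
        raise ValueError(
            f"constant signal(s) at rows {np.flatnonzero(span == 0)[:10]}: "
            "phase undefined"
        )
    centered = sig - sig.mean(axis=1, keepdims=True)
    analytic = scipy.signal.hilbert(centered, axis=1)
    ph = np.angle(analytic)
    ph = np.mod(ph + np.pi, 2.0 * np.pi) - np.pi  # [-pi, pi)
    return PhaseSeries(phases=ph, source=source)


def vector_strength(phases, weights=None) -> float:
    """Modulus of the weighted mean unit phasor of the spike phases."""
    phases = np.asarray(phases, dtype=float).ravel()
    if weights is not None:
        weights = np.asarray(weights, dtype=float).ravel()
        total = weights.sum()
    else:
        weights = np.ones_like(phases)
        total = len(phases)
    if total <= 0:
        raise ValueError("vector strength requires at least one spike")
    return float(np.abs(np.sum(weights * np.exp(1j * phases)) / total))


def phase_locked_histogram(
    phases: PhaseSeries,
    spikes: SpikeRecord,
    n_bins: int = 20,
    edge_exclude: float = 0.05,
) -> PhaseLockHistogram:
    """Bin each vertex's spikes at that vertex's signal phase at spike time.

    ``phases`` must carry one row per device (in ``spikes.device_order``
    order) sampled on the same step grid as ``spikes.counts``.  The first
    and last ``edge_exclude`` fraction of samples are excluded to avoid
    Hilbert edge artifacts.  Half-open, left-inclusive bins over [-pi, pi).
    """
    counts = spikes.counts
    n_steps, n_dev = counts.shape
    if phases.phases.shape != (n_dev, n_steps):
        raise ValueError(
            f"phases must have shape ({n_dev}, {n_steps}), got {phases.phases.shape}"
        )
    lo = int(np.floor(edge_exclude * n_steps))
    hi = n_steps - lo
    edges = np.linspace(-np.pi, np.pi, n_bins + 1)
    per_vertex = np.zeros((n_dev, n_bins))
    phasor = 0.0 + 0.0j
    total = 0
    for d in range(n_dev):
        w = counts[lo:hi, d].astype(float)
        ph = phases.phases[d, lo:hi]
        h, _ = np.histogram(ph, bins=edges, weights=w)
        per_vertex[d] = h
        phasor += np.sum(w * np.exp(1j * ph))
        total += int(w.sum())
    with_spikes = per_vertex.sum(axis=1) > 0
    average = (
        per_vertex[with_spikes].mean(axis=0)
        if with_spikes.any()
        else np.zeros(n_bins)
    )
    vs = float(np.abs(phasor) / total) if total else 0.0
    return PhaseLockHistogram(
        bin_edges=edges,
        per_vertex=per_vertex,
        average=average,
        pooled=per_vertex.sum(axis=0),
        vector_strength=vs,
        n_spikes=total,
    )


def onset_latency_map(
    recording: FieldRecording,
    threshold: float = 0.3,
    hysteresis: float = 0.3,
) -> np.ndarray:
    """First seizure-onset time of x2 - x1 per node; NaN where none occurs.

    The resting value of x2 - x1 is 0.6 (= -0.9 - (-1.5)); seizure onset is
    detected as the first sample where the signal leaves the resting band
    downward (drops below ``threshold``, default half the resting value, with
    rest sitting ``hysteresis`` above it).  The downward direction is robust
    to the SWE local coupling, which drives x2 upward in recruited tissue so
    that x2 - x1 need not cross zero.  Onset-zone nodes, initialized inside
    the ictal regime, cross first.
    """
    s = recording.x2 - recording.x1  # (n_times, n_nodes)
    below = s < threshold
    latency = np.full(recording.n_nodes, np.nan)
    any_cross = below.any(axis=0)
    first = below.argmax(axis=0)
    latency[any_cross] = recording.times[first[any_cross]]
    return latency
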