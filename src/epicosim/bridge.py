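"""Rate conversion and the lockstep exchange between the two simulators.

At every shared time step the field state of each CA1 vertex is converted to
a per-step Poisson spike-generation parameter through a rectified linear
map of the fast-discharge variable x1 and the spike-and-wave variable x2:

    p_x1 = max(0, (x1 + o_x1) * g_x1 * dt)
    p_x2 = max(0, (x2 + o_x2) * g_x2 * dt)
    lambda = p_x1 + p_x2

with calibrated offsets o_x1 = 2, o_x2 = 0.5 and gains g_x1 = 0.375,
g_x2 = 1.25 at dt = 0.1 ms.  At the resting state the x2 channel is rectified
to exactly zero (x2 = -0.9 < -o_x2) while the x1 channel transmits a small
baseline ((-1.5 + 2) * 0.375 * dt = 0.01875 per step); both channels reach
zero only when the fast discharge dips below -2 during the ictal wave.
The rate vector is ordered by the device-creation order
(``VertexAssignment.device_order``); the spiking side answers with a
per-vertex spike-count vector.  The count channel is implemented, logged and
covered by tests, but feedback into the field is disabled by default: the
field drives CA1 spiking activity, not vice versa.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from . import field as fieldmod
from .field import (
    HistoryBuffer,
    LocalKernel,
    SEMParameters,
    SEMState,
    SparseConnectome,
    FieldRecording,
    initialize_states,
)
from .geometry import VertexAssignment
from .snn import SNNSimulator, SpikeRecord, SpikingNetwork, poisson_device_step

__all__ = [
    "ConversionParams",
    "RateMessage",
    "SpikeCountMessage",
    "InProcessTransport",
    "SerializedTransport",
    "rate_from_x1",
    "rate_from_x2",
    "spike_parameter",
    "make_rate_message",
    "encode_message",
    "decode_message",
    "run_cosimulation",
    "CosimResult",
]


@dataclasses.dataclass
class ConversionParams:
    """Calibrated constants of the state-to-rate conversion."""

    o_x1: float = 2.0
    o_x2: float = 0.5
    g_x1: float = 0.375
    g_x2: float = 1.25
    dt: float = 0.1
    bernoulli: bool = False  # clip lambda at one spike per step if set

    def __post_init__(self) -> None:
        if self.g_x1 < 0 or self.g_x2 < 0:
            raise ValueError("conversion gains must be non-negative")
        if self.dt <= 0:
            raise ValueError("dt must be positive")


@dataclasses.dataclass
class RateMessage:
    """Per-step vector of per-vertex Poisson parameters, in device order."""

    step_index: int
    rates: np.ndarray

    def __post_init__(self) -> None:
        self.rates = np.asarray(self.rates, dtype=float)
        if (self.rates < 0).any():
            raise ValueError("rates must be non-negative")


@dataclasses.dataclass
class SpikeCountMessage:
    """Per-step vector of per-vertex spike counts (the feedback channel)."""

    step_index: int
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")


def rate_from_x1(x1, conv: ConversionParams):
    """Rectified x1 conversion: max(0, (x1 + o_x1) * g_x1 * dt)."""
    x1 = np.asarray(x1, dtype=float)
    if not np.isfinite(x1).all():
        raise ValueError("x1 must be finite")
    return np.maximum(0.0, (x1 + conv.o_x1) * conv.g_x1 * conv.dt)


def rate_from_x2(x2, conv: ConversionParams):
    """Rectified x2 conversion: max(0, (x2 + o_x2) * g_x2 * dt)."""
    x2 = np.asarray(x2, dtype=float)
    if not np.isfinite(x2).all():
        raise ValueError("x2 must be finite")
    return np.maximum(0.0, (x2 + conv.o_x2) * conv.g_x2 * conv.dt)


def spike_parameter(p_x1, p_x2):
    """Per-step Poisson parameter: lambda = p_x1 + p_x2."""
    p_x1 = np.asarray(p_x1, dtype=float)
    p_x2 = np.asarray(p_x2, dtype=float)
    if (p_x1 < 0).any() or (p_x2 < 0).any():
        raise ValueError("spike parameters must be non-negative")
    return p_x1 + p_x2


def make_rate_message(
    x1: np.ndarray,
    x2: np.ndarray,
    device_order: np.ndarray,
    conv: ConversionParams,
    step_index: int = 0,
) -> RateMessage:
    """Convert the field state of the CA1 vertices to one rate vector.

    ``x1`` and ``x2`` are indexed by mesh vertex id; the message is ordered
    by ``device_order`` regardless of any internal storage permutation.
    """
    device_order = np.asarray(device_order, dtype=np.int64)
    if device_order.size and device_order.max() >= len(x1):
        raise ValueError("device_order references vertices beyond the state")
    lam = spike_parameter(
        rate_from_x1(x1[device_order], conv), rate_from_x2(x2[device_order], conv)
    )
    if conv.bernoulli:
        lam = np.minimum(lam, 1.0)
    return RateMessage(step_index=step_index, rates=lam)


_MSG_VERSION = 1


def encode_message(msg) -> bytes:
    """Newline-delimited numeric-row encoding with a versioned header."""
    if isinstance(msg, RateMessage):
        kind, values = "rate", msg.rates
        payload = " ".join(repr(float(v)) for v in values)
    elif isinstance(msg, SpikeCountMessage):
        kind, values = "count", msg.counts
        payload = " ".join(str(int(v)) for v in values)
    else:
        raise TypeError(f"cannot encode {type(msg).__name__}")
    header = f"epicosim-msg {_MSG_VERSION} {kind} {msg.step_index} {len(values)}"
    return (header + "\n" + payload + "\n").encode()


def decode_message(raw: bytes):
    lines = raw.decode().splitlines()
    tag, version, kind, step, n = lines[0].split()
    if tag != "epicosim-msg" or int(version) != _MSG_VERSION:
        raise ValueError("unrecognized message header")
    fields = lines[1].split() if len(lines) > 1 else []
    if len(fields) != int(n):
        raise ValueError("message length does not match header")
    if kind == "rate":
        return RateMessage(int(step), np.array([float(v) for v in fields]))
    if kind == "count":
        return SpikeCountMessage(int(step), np.array([int(v) for v in fields]))
    raise ValueError(f"unknown message kind {kind!r}")


class InProcessTransport:
    """Hands message objects across unchanged."""

    def send(self, msg):
        return msg


class SerializedTransport:
    """Round-trips every message through its byte encoding.

    Stands in for an out-of-process channel; under a fixed seed it must
    produce results identical to the in-process transport.
    """

    def send(self, msg):
        return decode_message(encode_message(msg))


@dataclasses.dataclass
class CosimResult:
    field_recording: FieldRecording
    spike_record: SpikeRecord | None
    rate_log: list
    count_log: list
    #: per-step Poisson draws of the input devices (the bridge's own spikes)
    device_counts: np.ndarray | None = None


def run_cosimulation(
    n_nodes: int,
    conn: SparseConnectome,
    kernel: LocalKernel,
    params: SEMParameters,
    onset_nodes,
    assignment: VertexAssignment,
    conv: ConversionParams,
    duration: float,
    seed: int = 0,
    net: SpikingNetwork | None = None,
    dt: float = 0.1,
    monitor_stride: int = 1,
    static_weight: float = 4.0,
    static_delay: float = 1.0,
    connectivity_enabled: bool = True,
    feedback_enabled: bool = False,
    feedback_gain: float = 0.0,
    transport=None,
) -> CosimResult:
    """Lockstep one-directional co-simulation.

    Per step: the field advances one Heun step; a :class:`RateMessage` is
    built from the CA1 vertices and crosses the transport; the per-vertex
    devices draw Poisson counts which are relayed to their subpopulations;
    the spiking network advances one step; a :class:`SpikeCountMessage` is
    logged.  The count channel feeds back into the field only when
    ``feedback_enabled`` is set (off by default), so the field trajectory is
    identical with and without the spiking side attached.

    ``net=None`` runs the field side of the same loop alone (used to verify
    one-directionality).
    """
    if abs(dt - conv.dt) > 1e-12:
        raise ValueError("field and conversion dt must agree")
    transport = InProcessTransport() if transport is None else transport
    n_steps = int(np.floor(duration / dt + 1e-9))
    state = initialize_states(n_nodes, onset_nodes)
    w_steps = conn.delay_steps(dt)
    depth = max(int(w_steps.max()) + 1 if w_steps.size else 1, 1)
    history = HistoryBuffer(n_nodes, depth, state.x1)
    devices = assignment.device_order

    rng = np.random.default_rng(seed)
    sim = None
    subpops = None
    n2c = None
    if net is not None:
        sim = SNNSimulator(
            net,
            dt=dt,
            connectivity_enabled=connectivity_enabled,
            max_external_delay=static_delay,
        )
        subpops = [assignment.vertex_to_neurons[int(v)] for v in devices]
        n2v = assignment.neuron_to_vertex(net.n_neurons)
        vertex_col = {int(v): c for c, v in enumerate(devices)}
        n2c = np.array([vertex_col.get(int(v), -1) for v in n2v], dtype=np.int64)
    dsteps_relay = int(np.floor(static_delay / dt + 0.5))

    n_rec = n_steps // monitor_stride + 1
    rec = np.empty((n_rec, 6, n_nodes))
    rec[0] = state.as_array()
    irec = 1
    rate_log: list[RateMessage] = []
    count_log: list[SpikeCountMessage] = []
    counts = np.zeros((n_steps, len(devices)), dtype=np.int64)
    device_counts = np.zeros((n_steps, len(devices)), dtype=np.int64)
    ev_ids, ev_times = [], []
    exogenous = None

    for step in range(n_steps):
        state = fieldmod.heun_step(
            state, params, conn, kernel, history, dt, exogenous=exogenous
        )
        msg = transport.send(
            make_rate_message(state.x1, state.x2, devices, conv, step)
        )
        rate_log.append(msg)
        if sim is not None:
            dev_counts = poisson_device_step(msg.rates, rng)
            device_counts[step] = dev_counts
            for c in np.flatnonzero(dev_counts):
                if len(subpops[c]):
                    sim.schedule_external(
                        subpops[c], dsteps_relay, float(dev_counts[c]) * static_weight
                    )
            spiked = sim.step()
            if len(spiked):
                ev_ids.append(spiked)
                ev_times.append(np.full(len(spiked), step * dt))
                cols = n2c[spiked]
                np.add.at(counts[step], cols[cols >= 0], 1)
            cmsg = transport.send(SpikeCountMessage(step, counts[step]))
            count_log.append(cmsg)
            if feedback_enabled:
                exogenous = np.zeros(n_nodes)
                exogenous[devices] = feedback_gain * cmsg.counts
        if (step + 1) % monitor_stride == 0:
            rec[irec] = state.as_array()
            irec += 1

    recording = FieldRecording(
        times=np.arange(n_rec) * dt * monitor_stride,
        states=rec,
        node_ids=np.arange(n_nodes),
        dt=dt,
        stride=monitor_stride,
    )
    spike_record = None
    if sim is not None:
        ids = np.concatenate(ev_ids) if ev_ids else np.empty(0, dtype=np.int64)
        times = np.concatenate(ev_times) if ev_times else np.empty(0)
        spike_record = SpikeRecord(
            ids=ids,
            times=times,
            counts=counts,
            device_order=devices,
            dt=dt,
            duration=duration,
        )
    return CosimResult(
        recording,
        spike_record,
        rate_log,
        count_log,
        device_counts if sim is not None else None,
    )
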