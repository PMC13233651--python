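"""CA1 point-neuron network: bursting neurons, short-term-plasticity synapses,
per-vertex Poisson input devices, and the downscaling procedure.

Neurons follow a Hill-Tononi-style conductance model: a leaky membrane with
separate Na/K leaks, an adaptive spike threshold, and intrinsic currents --
persistent sodium (I_NaP, fast positive feedback), a depolarization-activated
potassium current driven by a slow activity variable D (I_KNa, slow negative
feedback), a low-threshold calcium-like current (I_T) and a hyperpolarization-
activated cation current (I_h).  The NaP/KNa pair produces the recurrent
burst-silence firing typical of CA1 pyramidal cells under sustained drive.
Synapses implement the Tsodyks-Markram short-term plasticity model with
per-connection resource and utilization states, delivering exponential
conductance transients after a fixed transmission delay.

The spike mechanism is explicit: when V crosses the dynamic threshold theta
outside the refractory period, a spike is emitted, V is clamped to E_Na and
theta to the same value; during the t_ref window V repolarizes toward E_K
with time constant tau_spike while theta relaxes back to theta_eq.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .geometry import NeuronCloud, VertexAssignment

__all__ = [
    "NeuronModelParams",
    "SynapseParams",
    "SpikingNetwork",
    "SpikeRecord",
    "NetworkStats",
    "SNNSimulator",
    "build_synthetic_connectivity",
    "downscale",
    "integrity_stats",
    "poisson_device_step",
    "relay_spikes",
    "step_network",
    "run_snn",
]


@dataclasses.dataclass
class NeuronModelParams:
    """Constants of the bursting point-neuron model (mV, ms, relative nS)."""

    tau_m: float = 16.0
    g_NaL: float = 0.2
    g_KL: float = 1.0
    E_Na: float = 30.0
    E_K: float = -90.0
    theta_eq: float = -51.0
    tau_theta: float = 2.0
    t_ref: float = 2.0
    tau_spike: float = 1.75
    # persistent sodium
    g_NaP: float = 1.0
    # sodium-activated potassium (burst-terminating adaptation)
    g_KNa: float = 4.0
    tau_D: float = 400.0
    D_influx: float = 0.03
    D_eq: float = 0.001
    D_half: float = 0.25
    D_thresh: float = -10.0
    D_slope: float = 5.0
    # low-threshold Ca-like and h currents
    g_T: float = 1.0
    tau_hT: float = 50.0
    E_T: float = 0.0
    g_h: float = 1.0
    tau_mh: float = 100.0
    E_h: float = -40.0
    # synaptic receptor kinetics
    tau_ampa: float = 2.4
    E_ampa: float = 0.0
    tau_gaba: float = 5.0
    E_gaba: float = -70.0

    def __post_init__(self) -> None:
        for name in (
            "tau_m",
            "tau_theta",
            "tau_spike",
            "tau_D",
            "tau_hT",
            "tau_mh",
            "tau_ampa",
            "tau_gaba",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclasses.dataclass
class SynapseParams:
    """Tsodyks-Markram constants for one connection class."""

    U: float = 0.5
    tau_rec: float = 800.0
    tau_fac: float = 0.0
    weight: float = 2.0
    delay: float = 1.0
    receptor: str = "AMPA"

    def __post_init__(self) -> None:
        if not 0 < self.U <= 1:
            raise ValueError("U must lie in (0, 1]")
        if self.tau_rec < 0 or self.tau_fac < 0:
            raise ValueError("time constants must be non-negative")
        if self.delay <= 0:
            raise ValueError("delay must be positive")
        if self.receptor not in ("AMPA", "GABA"):
            raise ValueError("receptor must be AMPA or GABA")


@dataclasses.dataclass
class SpikingNetwork:
    """Neuron cloud plus a flat connection table.

    Connections are stored column-wise (pre, post, TM constants, weight,
    delay, Euclidean length); all arrays share one length.
    """

    cloud: NeuronCloud
    neuron_params: NeuronModelParams
    pre: np.ndarray
    post: np.ndarray
    U: np.ndarray
    tau_rec: np.ndarray
    tau_fac: np.ndarray
    weight: np.ndarray
    delay: np.ndarray
    length: np.ndarray
    receptor: np.ndarray  # 0 = AMPA, 1 = GABA

    def __post_init__(self) -> None:
        n = self.cloud.n_neurons
        self.pre = np.asarray(self.pre, dtype=np.int64)
        self.post = np.asarray(self.post, dtype=np.int64)
        for name in ("U", "tau_rec", "tau_fac", "weight", "delay", "length"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        self.receptor = np.asarray(self.receptor, dtype=np.int64)
        if self.pre.size:
            if self.pre.min() < 0 or self.pre.max() >= n:
                raise ValueError("pre ids out of range")
            if self.post.min() < 0 or self.post.max() >= n:
                raise ValueError("post ids out of range")
            if (self.pre == self.post).any():
                raise ValueError("self-connections are not allowed")

    @property
    def n_neurons(self) -> int:
        return self.cloud.n_neurons

    @property
    def n_connections(self) -> int:
        return len(self.pre)

    def outgoing_csr(self):
        """Connections grouped by presynaptic neuron: (order, indptr)."""
        order = np.argsort(self.pre, kind="stable")
        indptr = np.searchsorted(self.pre[order], np.arange(self.n_neurons + 1))
        return order, indptr


@dataclasses.dataclass
class SpikeRecord:
    """Spike events plus per-vertex per-step counts in device order."""

    ids: np.ndarray
    times: np.ndarray
    counts: np.ndarray  # (n_steps, n_devices)
    device_order: np.ndarray
    dt: float
    duration: float

    def __post_init__(self) -> None:
        if len(self.times) and (
            self.times.min() < 0 or self.times.max() > self.duration
        ):
            raise ValueError("spike times outside [0, duration]")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def n_events(self) -> int:
        return len(self.ids)


@dataclasses.dataclass
class NetworkStats:
    """Integrity statistics of a (possibly downscaled) network."""

    density_counts: np.ndarray  # (3, n_bins) per-axis position histograms
    density_edges: np.ndarray  # (3, n_bins + 1)
    indegree_counts: np.ndarray
    indegree_edges: np.ndarray
    outdegree_counts: np.ndarray
    outdegree_edges: np.ndarray
    length_counts: np.ndarray
    length_edges: np.ndarray
    moments: dict


def build_synthetic_connectivity(
    cloud: NeuronCloud,
    mean_degree: float = 20.0,
    length_scale: float = 2.0,
    seed: int = 0,
    synapse: SynapseParams | None = None,
) -> SpikingNetwork:
    """Distance-dependent random connectivity, p_ij ∝ exp(-d_ij / length_scale).

    The proportionality constant is set so the expected outdegree equals
    ``mean_degree`` (probabilities capped at 1).  No self-connections.
    """
    if mean_degree < 0:
        raise ValueError("mean_degree must be non-negative")
    synapse = SynapseParams() if synapse is None else synapse
    n = cloud.n_neurons
    rng = np.random.default_rng(seed)
    if mean_degree == 0 or n < 2:
        empty = np.empty(0)
        return SpikingNetwork(
            cloud,
            NeuronModelParams(),
            np.empty(0, dtype=np.int64),
            np.empty(0, dtype=np.int64),
            empty,
            empty.copy(),
            empty.copy(),
            empty.copy(),
            empty.copy(),
            empty.copy(),
            np.empty(0, dtype=np.int64),
        )
    # two passes over row blocks keep memory O(block * n) for large clouds
    block = 512
    kernel_sum = 0.0
    for lo in range(0, n, block):
        hi = min(lo + block, n)
        diff = cloud.positions[lo:hi, None, :] - cloud.positions[None, :, :]
        d = np.sqrt((diff**2).sum(-1))
        k = np.exp(-d / length_scale)
        k[np.arange(lo, hi) - lo, np.arange(lo, hi)] = 0.0
        kernel_sum += k.sum()
    scale = mean_degree * n / kernel_sum
    pres, posts, lens = [], [], []
    for lo in range(0, n, block):
        hi = min(lo + block, n)
        diff = cloud.positions[lo:hi, None, :] - cloud.positions[None, :, :]
        d = np.sqrt((diff**2).sum(-1))
        prob = np.minimum(scale * np.exp(-d / length_scale), 1.0)
        prob[np.arange(lo, hi) - lo, np.arange(lo, hi)] = 0.0
        edges = rng.uniform(size=prob.shape) < prob
        r, c = np.nonzero(edges)
        pres.append(r + lo)
        posts.append(c)
        lens.append(d[r, c])
    pre = np.concatenate(pres)
    post = np.concatenate(posts)
    lengths = np.concatenate(lens)
    m = len(pre)
    rec = 0 if synapse.receptor == "AMPA" else 1
    return SpikingNetwork(
        cloud,
        NeuronModelParams(),
        pre,
        post,
        np.full(m, synapse.U),
        np.full(m, synapse.tau_rec),
        np.full(m, synapse.tau_fac),
        np.full(m, synapse.weight),
        np.full(m, synapse.delay),
        lengths,
        np.full(m, rec, dtype=np.int64),
    )


def downscale(
    net: SpikingNetwork, n_target: int, seed: int = 0
) -> tuple[SpikingNetwork, np.ndarray]:
    """Random neuron sampling preserving only consistent connections.

    Uniformly samples ``n_target`` neurons without replacement and keeps
    exactly the connections with both endpoints retained (the induced
    subgraph).  Ids are re-indexed by order-preserving compaction; the
    returned mapping has ``mapping[old_id] = new_id`` (or -1 if dropped).
    """
    n = net.n_neurons
    if not 1 <= n_target <= n:
        raise ValueError("n_target out of range")
    rng = np.random.default_rng(seed)
    keep = np.sort(rng.choice(n, size=n_target, replace=False))
    mapping = np.full(n, -1, dtype=np.int64)
    mapping[keep] = np.arange(n_target)
    mask = (mapping[net.pre] >= 0) & (mapping[net.post] >= 0)
    cloud = NeuronCloud(
        positions=net.cloud.positions[keep],
        apd_coords=net.cloud.apd_coords[keep],
        neuron_ids=np.arange(n_target),
    )
    sub = SpikingNetwork(
        cloud,
        net.neuron_params,
        mapping[net.pre[mask]],
        mapping[net.post[mask]],
        net.U[mask],
        net.tau_rec[mask],
        net.tau_fac[mask],
        net.weight[mask],
        net.delay[mask],
        net.length[mask],
        net.receptor[mask],
    )
    return sub, mapping


def integrity_stats(net: SpikingNetwork, bins: int = 10) -> NetworkStats:
    """Density, in/outdegree and connection-length histograms plus moments."""
    if net.n_neurons == 0:
        raise ValueError("empty network")
    pos = net.cloud.positions
    density_counts = np.empty((3, bins))
    density_edges = np.empty((3, bins + 1))
    for ax in range(3):
        c, e = np.histogram(pos[:, ax], bins=bins)
        density_counts[ax], density_edges[ax] = c, e
    indeg = np.bincount(net.post, minlength=net.n_neurons)
    outdeg = np.bincount(net.pre, minlength=net.n_neurons)
    dmax = max(indeg.max(initial=0), outdeg.max(initial=0), 1)
    edges = np.arange(dmax + 2) - 0.5
    in_c, in_e = np.histogram(indeg, bins=edges)
    out_c, out_e = np.histogram(outdeg, bins=edges)
    if net.n_connections:
        len_c, len_e = np.histogram(net.length, bins=bins)
    else:
        len_c, len_e = np.zeros(bins), np.linspace(0, 1, bins + 1)
    moments = {
        "mean_indegree": float(indeg.mean()),
        "mean_outdegree": float(outdeg.mean()),
        "mean_length": float(net.length.mean()) if net.n_connections else 0.0,
        "n_neurons": net.n_neurons,
        "n_connections": net.n_connections,
    }
    return NetworkStats(
        density_counts,
        density_edges,
        in_c,
        in_e,
        out_c,
        out_e,
        len_c,
        len_e,
        moments,
    )


def poisson_device_step(p, rng: np.random.Generator):
    """Spike count(s) of the per-vertex device for one step: Poisson(p)."""
    p = np.asarray(p, dtype=float)
    if (p < 0).any():
        raise ValueError("Poisson parameter must be non-negative")
    return rng.poisson(p)


def relay_spikes(
    count: int,
    subpop: np.ndarray,
    t: float,
    static_weight: float = 4.0,
    static_delay: float = 1.0,
):
    """Fan a device's spikes out to its whole subpopulation.

    Each of the ``count`` device spikes is delivered identically to every
    neuron of the subpopulation through a static (non-plastic) synapse,
    giving ``count * len(subpop)`` synaptic events at time ``t + delay``.
    Returns (targets, times, weights).
    """
    if count < 0:
        raise ValueError("count must be non-negative")
    subpop = np.asarray(subpop, dtype=np.int64)
    targets = np.tile(subpop, count)
    times = np.full(len(targets), t + static_delay)
    weights = np.full(len(targets), static_weight)
    return targets, times, weights


class SNNSimulator:
    """Synchronous fixed-step simulator of a :class:`SpikingNetwork`.

    External (device) input is injected as AMPA conductance increments
    scheduled through a ring buffer; recurrent spikes pass through the
    Tsodyks-Markram machinery.  Entirely deterministic given its inputs.
    """

    def __init__(
        self,
        net: SpikingNetwork,
        dt: float = 0.1,
        connectivity_enabled: bool = True,
        max_external_delay: float = 2.0,
    ):
        if dt <= 0:
            raise ValueError("dt must be positive")
        self.net = net
        self.dt = dt
        self.connectivity_enabled = connectivity_enabled
        p = net.neuron_params
        n = net.n_neurons
        self.V = np.full(n, -70.0)
        self.theta = np.full(n, p.theta_eq)
        self.D = np.full(n, p.D_eq)
        self.hT = np.full(n, 0.1)
        self.mh = np.full(n, 0.05)
        self.refrac = np.zeros(n, dtype=np.int64)
        self.g = np.zeros((2, n))  # AMPA, GABA conductances
        self.time = 0.0
        self.step_index = 0
        # TM per-connection state
        self.tm_u = net.U.copy()
        self.tm_x = np.ones(net.n_connections)
        self.tm_last = np.full(net.n_connections, -np.inf)
        self.order, self.indptr = net.outgoing_csr()
        # synaptic delays rounded to steps (nearest, ties up)
        self.delay_steps = np.floor(net.delay / dt + 0.5).astype(np.int64)
        self.delay_steps = np.maximum(self.delay_steps, 1)
        max_delay = int(self.delay_steps.max(initial=1))
        max_delay = max(max_delay, int(np.floor(max_external_delay / dt + 0.5)) + 1)
        self.buflen = max_delay + 1
        self.pending = np.zeros((self.buflen, 2, n))
        self._decay = np.exp(-dt / np.array([p.tau_ampa, p.tau_gaba]))[:, None]

    def schedule_external(self, targets: np.ndarray, delay_steps: int, weight):
        """Queue static AMPA increments ``delay_steps`` steps ahead."""
        if delay_steps >= self.buflen:
            raise ValueError("external delay exceeds buffer")
        slot = (self.step_index + delay_steps) % self.buflen
        np.add.at(self.pending[slot, 0], targets, weight)

    def step(self, external_current: float | np.ndarray = 0.0) -> np.ndarray:
        """Advance one dt; returns the ids of neurons that spiked."""
        p = self.net.neuron_params
        slot = self.step_index % self.buflen
        self.g += self.pending[slot]
        self.pending[slot] = 0.0
        self.g *= self._decay

        V = self.V
        if not np.isfinite(V).all():
            raise FloatingPointError("non-finite membrane state")
        mNaP = 1.0 / (1.0 + np.exp(-(V + 55.7) / 7.7))
        i_nap = p.g_NaP * mNaP**3 * (p.E_Na - V)
        mKNa = 1.0 / (1.0 + (p.D_half / np.maximum(self.D, 1e-9)) ** 3.5)
        i_kna = p.g_KNa * mKNa * (p.E_K - V)
        mT = 1.0 / (1.0 + np.exp(-(V + 59.0) / 6.2))
        i_t = p.g_T * mT**2 * self.hT * (p.E_T - V)
        i_h = p.g_h * self.mh * (p.E_h - V)
        i_syn = self.g[0] * (p.E_ampa - V) + self.g[1] * (p.E_gaba - V)

        dt = self.dt
        self.hT += dt * (1.0 / (1.0 + np.exp((V + 83.0) / 4.0)) - self.hT) / p.tau_hT
        self.mh += dt * (1.0 / (1.0 + np.exp((V + 75.0) / 5.5)) - self.mh) / p.tau_mh
        influx = p.D_influx / (1.0 + np.exp(-(V - p.D_thresh) / p.D_slope))
        self.D += dt * (influx - (self.D - p.D_eq) / p.tau_D)
        self.theta += dt * (-(self.theta - p.theta_eq) / p.tau_theta)

        active = self.refrac == 0
        dv = (
            p.g_NaL * (p.E_Na - V)
            + p.g_KL * (p.E_K - V)
            + i_nap
            + i_kna
            + i_t
            + i_h
            + i_syn
            + external_current
        ) / p.tau_m
        V[active] += dt * dv[active]
        V[~active] += dt * (-(V[~active] - p.E_K) / p.tau_spike)
        self.refrac[~active] -= 1

        spiked = np.flatnonzero(active & (V >= self.theta))
        if len(spiked):
            V[spiked] = p.E_Na
            self.theta[spiked] = p.E_Na
            self.refrac[spiked] = int(round(p.t_ref / dt))
            if self.connectivity_enabled and self.net.n_connections:
                self._deliver_recurrent(spiked)
        self.step_index += 1
        self.time += dt
        return spiked

    def _deliver_recurrent(self, spiked: np.ndarray) -> None:
        net = self.net
        t = self.time
        for i in spiked:
            sl = self.order[self.indptr[i] : self.indptr[i + 1]]
            if not len(sl):
                continue
            dt_last = t - self.tm_last[sl]
            finite = np.isfinite(dt_last)
            # recover resources / decay facilitation since last release
            x = np.where(
                finite,
                1.0 - (1.0 - self.tm_x[sl]) * np.exp(-dt_last / net.tau_rec[sl]),
                self.tm_x[sl],
            )
            u = np.where(
                (net.tau_fac[sl] > 0) & finite,
                net.U[sl]
                + (self.tm_u[sl] - net.U[sl])
                * np.exp(
                    -dt_last / np.where(net.tau_fac[sl] > 0, net.tau_fac[sl], 1.0)
                ),
                net.U[sl],
            )
            u_plus = u + net.U[sl] * (1.0 - u) * (net.tau_fac[sl] > 0)
            release = u_plus * x
            self.tm_x[sl] = x - release
            self.tm_u[sl] = u_plus
            self.tm_last[sl] = t
            eff = net.weight[sl] * release
            slots = (self.step_index + self.delay_steps[sl]) % self.buflen
            np.add.at(self.pending, (slots, net.receptor[sl], net.post[sl]), eff)


def step_network(sim: SNNSimulator, external_current: float = 0.0) -> np.ndarray:
    """One synchronous update of membranes and synapses; returns spiker ids."""
    return sim.step(external_current)


def run_snn(
    net: SpikingNetwork,
    assignment: VertexAssignment,
    rate_streams: np.ndarray,
    duration: float,
    seed: int = 0,
    dt: float = 0.1,
    static_weight: float = 4.0,
    static_delay: float = 1.0,
    connectivity_enabled: bool = True,
) -> SpikeRecord:
    """Drive the network with per-vertex Poisson devices and count spikes.

    ``rate_streams`` has one column per ``assignment.device_order`` entry and
    one row per time step: the per-step Poisson parameter of that vertex's
    input device.  Device spikes are fanned out to the vertex's subpopulation
    through static synapses; emitted network spikes are tallied per vertex.
    """
    n_steps = int(np.floor(duration / dt + 1e-9))
    devices = assignment.device_order
    rate_streams = np.asarray(rate_streams, dtype=float)
    if rate_streams.shape != (n_steps, len(devices)):
        raise ValueError(
            f"rate_streams must have shape ({n_steps}, {len(devices)}), "
            f"got {rate_streams.shape}"
        )
    rng = np.random.default_rng(seed)
    sim = SNNSimulator(
        net, dt=dt, connectivity_enabled=connectivity_enabled,
        max_external_delay=static_delay,
    )
    subpops = [assignment.vertex_to_neurons[int(v)] for v in devices]
    n2v = assignment.neuron_to_vertex(net.n_neurons)
    vertex_col = {int(v): c for c, v in enumerate(devices)}
    n2c = np.array([vertex_col.get(int(v), -1) for v in n2v], dtype=np.int64)
    dsteps = int(np.floor(static_delay / dt + 0.5))

    counts = np.zeros((n_steps, len(devices)), dtype=np.int64)
    ev_ids, ev_times = [], []
    for step in range(n_steps):
        dev_counts = poisson_device_step(rate_streams[step], rng)
        for c in np.flatnonzero(dev_counts):
            if len(subpops[c]):
                sim.schedule_external(
                    subpops[c], dsteps, float(dev_counts[c]) * static_weight
                )
        spiked = sim.step()
        if len(spiked):
            t = step * dt
            ev_ids.append(spiked)
            ev_times.append(np.full(len(spiked), t))
            cols = n2c[spiked]
            np.add.at(counts[step], cols[cols >= 0], 1)
    ids = np.concatenate(ev_ids) if ev_ids else np.empty(0, dtype=np.int64)
    times = np.concatenate(ev_times) if ev_times else np.empty(0)
    return SpikeRecord(
        ids=ids,
        times=times,
        counts=counts,
        device_order=devices,
        dt=dt,
        duration=duration,
    )
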