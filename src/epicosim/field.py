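"""Spatial Epileptor neural field on a surface mesh.

Each mesh node carries a six-state phenomenological neural mass: a fast
discharge pair (x1, y1), a slower spike-and-wave-event (SWE) pair (x2, y2), a
slow permittivity variable z that gates transitions between interictal and
ictal regimes, and an integral coupling state g that low-passes past fast
activity into the SWE subsystem.  Nodes interact through (i) delayed global
difference coupling on x1, weighted by a sparse tractography connectome, and
(ii) Heaviside-gated local coupling over geodesic neighborhoods with three
channels: fast->fast (gamma11 into x1), fast->integral (gamma12 into g) and
SWE->SWE (gamma22 into x2).

The per-node excitability x0 sets the resting equilibrium: the epileptogenic
zone (x0 = -1.6) seizes autonomously and recurrently, while propagation-zone
tissue (x0 = -1.9) is stable at the resting point (x1 = -1.5, y1 = -11,
z = 3, x2 = -0.9, y2 = 0.3, g = -0.1) yet sits close enough to the fold that
local coupling from ictal neighbors recruits it.  The permittivity drive
slope (``z_slope``, default 7.5) is calibrated so that this resting point is
an exact equilibrium of the propagation zone; see docs/methods.md.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import scipy.optimize
import scipy.sparse as sp

from ._kernels import _run_loop

__all__ = [
    "SEMParameters",
    "SEMState",
    "SparseConnectome",
    "HistoryBuffer",
    "LocalKernel",
    "FieldRecording",
    "STABLE_POINT",
    "ONSET_POINT",
    "initialize_states",
    "compute_global_coupling",
    "compute_local_coupling",
    "sem_derivatives",
    "heun_step",
    "run_field",
    "find_fixed_point",
    "build_local_kernel",
    "random_connectome",
]

#: Resting initialization of non-onset nodes.
STABLE_POINT = np.array([-1.5, -11.0, 3.0, -0.9, 0.3, -0.1])
#: Ictal initialization of the seizure-onset zone.
ONSET_POINT = np.array([0.0, -5.0, 3.0, 0.0, 0.0, 0.0])

STATE_NAMES = ("x1", "y1", "z", "x2", "y2", "g")


@dataclasses.dataclass
class SEMParameters:
    """All constants of the spatial Epileptor.

    ``x0`` may be a scalar or a per-node array.  Defaults are the calibrated
    values used throughout: bias currents Iext = 3.1 and Iext2 = 0.45, global
    coupling scale k = 0.636 (times gamma_glob = 1), local coupling strengths
    gamma11/gamma12/gamma22 = 0.34/0.064/0.032 with Heaviside thresholds
    theta11/theta12/theta22 = -1/-1/-0.5, time scales tau0 = 2857 (permittivity),
    tau1 = 1 (fast recovery), tau2 = 10 (SWE recovery), and a global time-scale
    tt = 0.17 multiplying every derivative.  ``m`` shapes the ictal branch of
    the fast nullcline (default 0).  ``z_slope`` is the permittivity drive
    slope (default 7.5; see module docstring).
    """

    x0: float | np.ndarray = -2.2
    Iext: float = 3.1
    Iext2: float = 0.45
    m: float = 0.0
    k: float = 0.636
    gamma11: float = 0.34
    gamma12: float = 0.064
    gamma22: float = 0.032
    gamma_glob: float = 1.0
    theta11: float = -1.0
    theta12: float = -1.0
    theta22: float = -0.5
    tau0: float = 2857.0
    tau1: float = 1.0
    tau2: float = 10.0
    tt: float = 0.17
    z_slope: float = 7.5

    def __post_init__(self) -> None:
        for name in ("tau0", "tau1", "tau2", "tt"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("gamma11", "gamma12", "gamma22", "gamma_glob"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def x0_array(self, n_nodes: int) -> np.ndarray:
        x0 = np.asarray(self.x0, dtype=float)
        if x0.ndim == 0:
            return np.full(n_nodes, float(x0))
        if x0.shape != (n_nodes,):
            raise ValueError("per-node x0 must have one entry per node")
        return x0


@dataclasses.dataclass
class SEMState:
    """Per-node state fields of the six Epileptor variables."""

    x1: np.ndarray
    y1: np.ndarray
    z: np.ndarray
    x2: np.ndarray
    y2: np.ndarray
    g: np.ndarray
    time: float = 0.0

    def __post_init__(self) -> None:
        arrays = self.as_array()
        if not np.isfinite(arrays).all():
            raise ValueError("state contains non-finite values")

    @property
    def n_nodes(self) -> int:
        return len(self.x1)

    def as_array(self) -> np.ndarray:
        """Stack to a (6, n) array ordered (x1, y1, z, x2, y2, g)."""
        return np.stack([self.x1, self.y1, self.z, self.x2, self.y2, self.g])

    @classmethod
    def from_array(cls, arr: np.ndarray, time: float = 0.0) -> "SEMState":
        return cls(*(np.array(a) for a in arr), time=time)


@dataclasses.dataclass
class SparseConnectome:
    """Global connectivity: sparse weights, tract lengths and derived delays."""

    weights: sp.csr_matrix
    tract_lengths: sp.csr_matrix
    conduction_speed: float = 3.0  # mm/ms

    def __post_init__(self) -> None:
        self.weights = sp.csr_matrix(self.weights)
        self.tract_lengths = sp.csr_matrix(self.tract_lengths)
        if self.conduction_speed <= 0:
            raise ValueError("conduction speed must be positive")
        if (self.weights.data < 0).any():
            raise ValueError("weights must be non-negative")
        if self.weights.diagonal().any() or self.tract_lengths.diagonal().any():
            raise ValueError("connectome diagonal must be zero")
        w = self.weights.copy()
        w.data = np.ones_like(w.data)
        l = self.tract_lengths.copy()
        l.data = np.ones_like(l.data)
        if (w != l).nnz:
            raise ValueError("weights and tract lengths must share sparsity pattern")

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    @property
    def delays(self) -> sp.csr_matrix:
        d = self.tract_lengths.copy()
        d.data = d.data / self.conduction_speed
        return d

    def delay_steps(self, dt: float) -> np.ndarray:
        """Per-nonzero delays in integration steps (nearest, ties up)."""
        return np.floor(self.delays.data / dt + 0.5).astype(np.int64)

    @classmethod
    def empty(cls, n_nodes: int) -> "SparseConnectome":
        z = sp.csr_matrix((n_nodes, n_nodes))
        return cls(weights=z, tract_lengths=z.copy())


class HistoryBuffer:
    """Ring buffer of past x1 values used for delayed global coupling.

    ``read(cols, delay_steps)`` at delay 0 returns the most recently pushed
    value; reads beyond the buffer depth raise.
    """

    def __init__(self, n_nodes: int, depth: int, initial_x1: np.ndarray):
        if depth < 1:
            raise ValueError("depth must be >= 1")
        self.depth = depth
        self.buffer = np.tile(np.asarray(initial_x1, dtype=float), (depth, 1))
        self.index = 0

    def push(self, x1: np.ndarray) -> None:
        self.index = (self.index + 1) % self.depth
        self.buffer[self.index] = x1

    def read(self, cols: np.ndarray, delay_steps: np.ndarray) -> np.ndarray:
        if np.any(delay_steps >= self.depth):
            raise ValueError("delay exceeds history buffer depth")
        if np.any(delay_steps < 0):
            raise ValueError("delays must be non-negative")
        return self.buffer[(self.index - delay_steps) % self.depth, cols]


@dataclasses.dataclass
class LocalKernel:
    """Laplace (exponential) kernel over geodesic neighborhoods."""

    matrix: sp.csr_matrix
    sigma: float
    cutoff: float

    def __post_init__(self) -> None:
        self.matrix = sp.csr_matrix(self.matrix)
        if not np.isfinite(self.matrix.data).all():
            raise ValueError("kernel entries must be finite")
        if (self.matrix.data < 0).any():
            raise ValueError("kernel entries must be non-negative")

    @property
    def n_nodes(self) -> int:
        return self.matrix.shape[0]

    @classmethod
    def empty(cls, n_nodes: int, sigma: float = 2.0, cutoff: float = 6.0):
        return cls(sp.csr_matrix((n_nodes, n_nodes)), sigma, cutoff)


def build_local_kernel(
    geodesic: sp.spmatrix,
    sigma: float = 2.0,
    cutoff: float = 6.0,
    normalize: bool = False,
) -> LocalKernel:
    """K_ij = exp(-d_ij / sigma) for geodesic d_ij <= cutoff (self excluded)."""
    if sigma <= 0 or cutoff <= 0:
        raise ValueError("sigma and cutoff must be positive")
    d = sp.coo_matrix(geodesic)
    keep = (d.data > 0) & (d.data <= cutoff)
    k = sp.coo_matrix(
        (np.exp(-d.data[keep] / sigma), (d.row[keep], d.col[keep])), shape=d.shape
    ).tocsr()
    if normalize:
        rows = np.asarray(k.sum(axis=1)).ravel()
        rows[rows == 0] = 1.0
        k = sp.diags(1.0 / rows) @ k
    return LocalKernel(matrix=k, sigma=sigma, cutoff=cutoff)


def random_connectome(
    positions: np.ndarray,
    mean_degree: float = 5.0,
    weight_scale: float = 0.05,
    conduction_speed: float = 3.0,
    seed: int = 0,
) -> SparseConnectome:
    """Synthetic sparse global connectome between mesh nodes.

    Random directed edges (expected out-degree ``mean_degree``) with
    exponentially distributed weights scaled by ``weight_scale`` and tract
    lengths equal to the Euclidean inter-node distance.
    """
    n = len(positions)
    rng = np.random.default_rng(seed)
    p = min(mean_degree / max(n - 1, 1), 1.0)
    mask = rng.uniform(size=(n, n)) < p
    np.fill_diagonal(mask, False)
    row, col = np.nonzero(mask)
    w = weight_scale * rng.exponential(size=len(row))
    # guard against sampled zeros, which would break the shared-pattern invariant
    w = np.maximum(w, 1e-12)
    lengths = np.linalg.norm(positions[row] - positions[col], axis=1)
    lengths = np.maximum(lengths, 1e-6)
    shape = (n, n)
    return SparseConnectome(
        weights=sp.coo_matrix((w, (row, col)), shape=shape).tocsr(),
        tract_lengths=sp.coo_matrix((lengths, (row, col)), shape=shape).tocsr(),
        conduction_speed=conduction_speed,
    )


def initialize_states(n_nodes: int, onset_nodes) -> SEMState:
    """Stable-point initialization with an ictal override on the onset zone."""
    if n_nodes < 1:
        raise ValueError("n_nodes must be >= 1")
    onset = np.asarray(list(onset_nodes), dtype=np.int64)
    if onset.size and (onset.min() < 0 or onset.max() >= n_nodes):
        raise ValueError("onset node ids out of range")
    arr = np.tile(STABLE_POINT[:, None], (1, n_nodes))
    arr[:, onset] = ONSET_POINT[:, None]
    return SEMState.from_array(arr)


def compute_global_coupling(
    history: HistoryBuffer,
    conn: SparseConnectome,
    x1_now: np.ndarray,
    k: float,
    gamma_glob: float = 1.0,
    dt: float = 0.1,
) -> np.ndarray:
    """Delayed difference coupling: k * sum_j w_ij (x1_j(t - d_ij) - x1_i(t)).

    The difference form vanishes at consensus, so homogeneous equilibria of
    the uncoupled node remain equilibria of the network.
    """
    w = conn.weights.tocoo()
    if w.nnz == 0:
        return np.zeros_like(x1_now)
    dsteps = conn.delay_steps(dt)
    delayed = history.read(w.col, dsteps)
    acc = np.bincount(w.row, weights=w.data * delayed, minlength=conn.n_nodes)
    row_sum = np.asarray(conn.weights.sum(axis=1)).ravel()
    return k * gamma_glob * (acc - row_sum * x1_now)


def compute_local_coupling(
    x1: np.ndarray, x2: np.ndarray, kernel: LocalKernel, params: SEMParameters
):
    """Heaviside-gated kernel sums (lc11, lc12, lc22).

    lc11_i = gamma11 * sum_j K_ij H(x1_j - theta11), and analogously for lc12
    (threshold theta12 on x1) and lc22 (threshold theta22 on x2).  H is the
    strict Heaviside step (H(0) = 0).
    """
    if kernel.n_nodes != len(x1) or len(x1) != len(x2):
        raise ValueError("kernel/state shape mismatch")
    k = kernel.matrix
    h11 = (x1 > params.theta11).astype(float)
    h12 = (x1 > params.theta12).astype(float)
    h22 = (x2 > params.theta22).astype(float)
    return (
        params.gamma11 * (k @ h11),
        params.gamma12 * (k @ h12),
        params.gamma22 * (k @ h22),
    )


def sem_derivatives(
    state: SEMState,
    params: SEMParameters,
    glob: np.ndarray | None = None,
    lc11: np.ndarray | None = None,
    lc12: np.ndarray | None = None,
    lc22: np.ndarray | None = None,
) -> np.ndarray:
    """Right-hand sides of the six state equations, scaled by tt.

    Fast subsystem: dx1 = tt (y1 - f1(x1, x2, z) - z + Iext + glob + lc11)
    with the cubic interictal branch f1 = x1^3 - 3 x1^2 for x1 < 0 and the
    ictal branch f1 = (x2 - m - 0.6 (z - 4)^2) x1 otherwise;
    dy1 = tt (1 - 5 x1^2 - y1) / tau1.  Permittivity:
    dz = tt (z_slope (x1 - x0) - z) / tau0.  SWE subsystem:
    dx2 = tt (-y2 + x2 - x2^3 + Iext2 + 2 g - 0.3 (z - 3.5) + lc22);
    dy2 = tt (-y2 + f2(x2)) / tau2 with f2 = 6 (x2 + 0.25) above -0.25, else 0.
    Integral coupling (low-pass of x1): dg = tt (-0.01 (g - 0.1 x1) + lc12).
    """
    arr = state.as_array()
    if not np.isfinite(arr).all():
        raise ValueError("non-finite state")
    x1, y1, z, x2, y2, g = arr
    n = state.n_nodes
    zero = np.zeros(n)
    glob = zero if glob is None else glob
    lc11 = zero if lc11 is None else lc11
    lc12 = zero if lc12 is None else lc12
    lc22 = zero if lc22 is None else lc22
    if not (len(glob) == len(lc11) == len(lc12) == len(lc22) == n):
        raise ValueError("coupling arrays must match node count")
    p = params
    x0 = p.x0_array(n)

    f1 = np.where(
        x1 < 0,
        -(x1**3) + 3.0 * x1**2,
        (p.m - x2 + 0.6 * (z - 4.0) ** 2) * x1,
    )
    dx1 = p.tt * (y1 - z + p.Iext + f1 + glob + lc11)
    dy1 = p.tt * (1.0 - 5.0 * x1**2 - y1) / p.tau1
    dz = p.tt * (p.z_slope * (x1 - x0) - z) / p.tau0
    dx2 = p.tt * (-y2 + x2 - x2**3 + p.Iext2 + 2.0 * g - 0.3 * (z - 3.5) + lc22)
    f2 = np.where(x2 < -0.25, 0.0, 6.0 * (x2 + 0.25))
    dy2 = p.tt * (-y2 + f2) / p.tau2
    dg = p.tt * (-0.01 * (g - 0.1 * x1) + lc12)
    return np.stack([dx1, dy1, dz, dx2, dy2, dg])


def heun_step(
    state: SEMState,
    params: SEMParameters,
    conn: SparseConnectome,
    kernel: LocalKernel,
    history: HistoryBuffer,
    dt: float,
    exogenous: np.ndarray | None = None,
) -> SEMState:
    """One deterministic Heun (predictor-corrector) step.

    The delayed global coupling is evaluated once per step from the history
    buffer; local coupling is re-evaluated at the predictor state.  The
    history buffer is advanced exactly once, after the corrector.
    ``exogenous`` is an optional per-node input added to the x1 equation
    alongside the global coupling (the feedback hook of the co-simulation).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    glob = compute_global_coupling(
        history, conn, state.x1, params.k, params.gamma_glob, dt
    )
    if exogenous is not None:
        glob = glob + exogenous
    lc11, lc12, lc22 = compute_local_coupling(state.x1, state.x2, kernel, params)
    d1 = sem_derivatives(state, params, glob, lc11, lc12, lc22)
    arr = state.as_array()
    pred = SEMState.from_array(arr + dt * d1, time=state.time + dt)
    lc11p, lc12p, lc22p = compute_local_coupling(pred.x1, pred.x2, kernel, params)
    d2 = sem_derivatives(pred, params, glob, lc11p, lc12p, lc22p)
    new = arr + 0.5 * dt * (d1 + d2)
    if not np.isfinite(new).all():
        raise FloatingPointError(
            f"field integration diverged at t = {state.time:.3f} ms"
        )
    out = SEMState.from_array(new, time=state.time + dt)
    history.push(out.x1)
    return out


@dataclasses.dataclass
class FieldRecording:
    """Subsampled per-node time series of all six state fields."""

    times: np.ndarray
    states: np.ndarray  # (n_samples, 6, n_nodes)
    node_ids: np.ndarray
    dt: float
    stride: int

    def __getattr__(self, name):
        if name in STATE_NAMES:
            return self.states[:, STATE_NAMES.index(name), :]
        raise AttributeError(name)

    @property
    def n_nodes(self) -> int:
        return self.states.shape[2]

    @property
    def sample_dt(self) -> float:
        return self.dt * self.stride


def _prepare_sparse(conn: SparseConnectome, kernel: LocalKernel, dt: float):
    w = conn.weights.tocsr()
    w.sort_indices()
    dsteps_csr = conn.tract_lengths.tocsr()
    dsteps_csr.sort_indices()
    dsteps = np.floor(dsteps_csr.data / conn.conduction_speed / dt + 0.5).astype(
        np.int64
    )
    km = kernel.matrix.tocsr()
    km.sort_indices()
    return w, dsteps, km


def run_field(
    n_nodes: int,
    conn: SparseConnectome,
    kernel: LocalKernel,
    params: SEMParameters,
    onset_nodes,
    duration: float,
    dt: float = 0.1,
    monitor_stride: int = 1,
    initial_state: SEMState | None = None,
) -> FieldRecording:
    """Integrate the field for ``duration`` ms and record every ``stride`` steps.

    Fully deterministic: identical inputs give bit-identical recordings.  The
    inner loop is compiled (numba) over CSR connectivity and a ring history
    buffer; it reproduces :func:`heun_step` semantics.
    """
    if duration < 0:
        raise ValueError("duration must be non-negative")
    if monitor_stride < 1:
        raise ValueError("monitor stride must be >= 1")
    if conn.n_nodes != n_nodes or kernel.n_nodes != n_nodes:
        raise ValueError("connectome/kernel node count mismatch")
    state = (
        initialize_states(n_nodes, onset_nodes)
        if initial_state is None
        else initial_state
    )
    n_steps = int(np.floor(duration / dt + 1e-9))
    w, dsteps, km = _prepare_sparse(conn, kernel, dt)
    depth = max(int(dsteps.max()) + 1 if dsteps.size else 1, 1)
    hist = np.tile(state.x1, (depth, 1))
    row_sum = np.asarray(conn.weights.sum(axis=1)).ravel()

    n_rec = n_steps // monitor_stride + 1
    rec = np.empty((n_rec, 6, n_nodes))
    arr = state.as_array().copy()
    p = params
    ok = _run_loop(
        arr,
        p.x0_array(n_nodes),
        p.Iext,
        p.Iext2,
        p.m,
        p.k * p.gamma_glob,
        p.gamma11,
        p.gamma12,
        p.gamma22,
        p.theta11,
        p.theta12,
        p.theta22,
        p.tau0,
        p.tau1,
        p.tau2,
        p.tt,
        p.z_slope,
        w.data,
        w.indices,
        w.indptr,
        dsteps,
        row_sum,
        km.data,
        km.indices,
        km.indptr,
        hist,
        dt,
        n_steps,
        monitor_stride,
        rec,
    )
    if not ok:
        raise FloatingPointError("field integration diverged (non-finite state)")
    times = np.arange(n_rec) * dt * monitor_stride
    return FieldRecording(
        times=times,
        states=rec,
        node_ids=np.arange(n_nodes),
        dt=dt,
        stride=monitor_stride,
    )


def find_fixed_point(
    params: SEMParameters, x0: float, guess: np.ndarray | None = None
) -> np.ndarray:
    """Equilibrium of one uncoupled node, |residual| < 1e-10.

    Root-finds the six-dimensional derivative field from ``guess`` (default:
    the resting initialization).  Raises if the residual norm is not driven
    below tolerance.
    """
    guess = STABLE_POINT if guess is None else np.asarray(guess, dtype=float)
    p = dataclasses.replace(params, x0=float(x0))

    def f(v):
        st = SEMState.from_array(v[:, None])
        return sem_derivatives(st, p).ravel()

    sol = scipy.optimize.root(f, guess, method="hybr", tol=1e-14)
    res = np.linalg.norm(f(sol.x))
    if res >= 1e-10:
        raise RuntimeError(
            f"fixed-point search did not converge (residual {res:.2e})"
        )
    return sol.x
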