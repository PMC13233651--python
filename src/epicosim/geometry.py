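"""Synthetic hippocampal geometry and the vertex-to-neuron assignment.

This module generates a curved, CA1-centred sheet mesh that stands in for an
MRI-derived hippocampal surface, samples a point-neuron soma cloud in a shell
around it, and maps neurons onto mesh vertices in the unfolded
anterior-posterior / proximal-distal (AP-PD) coordinate frame.  The AP-PD
coordinates of the synthetic surface are its generating parameters, so the
flat map is exact by construction and every downstream registration step can
be validated against ground truth.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.csgraph import dijkstra
from scipy.spatial import cKDTree

__all__ = [
    "SurfaceModel",
    "NeuronCloud",
    "VertexAssignment",
    "generate_synthetic_hippocampus",
    "generate_neuron_cloud",
    "geodesic_distances",
    "flatmap_ap_pd",
    "assign_neurons_to_vertices",
    "relabel_vertices",
    "select_onset_patch",
]

#: Region labels eligible for neuron assignment (hippocampal output subfields).
ASSIGNABLE_LABELS = ("CA1", "CA2", "subiculum")

KNOWN_LABELS = (
    "CA1",
    "CA2",
    "CA3",
    "CA4",
    "DG",
    "subiculum",
    "entorhinal",
    "parahippocampal",
    "fusiform",
    "other",
)


@dataclasses.dataclass
class SurfaceModel:
    """Triangulated surface with per-vertex region labels and AP-PD coordinates.

    Attributes
    ----------
    vertices : (n, 3) float array
        Vertex positions in mm.
    triangles : (m, 3) int array
        Vertex index triples.
    labels : (n,) str array
        Region tag per vertex (e.g. ``"CA1"``, ``"subiculum"``).
    cortical_flag : (n,) bool array
        Whether the vertex belongs to cortical grey matter.
    apd_coords : (n, 2) float array or None
        Intrinsic (AP, PD) coordinates, arbitrary units.
    """

    vertices: np.ndarray
    triangles: np.ndarray
    labels: np.ndarray
    cortical_flag: np.ndarray
    apd_coords: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.triangles = np.asarray(self.triangles, dtype=np.int64)
        self.labels = np.asarray(self.labels, dtype=object)
        self.cortical_flag = np.asarray(self.cortical_flag, dtype=bool)
        if self.apd_coords is not None:
            self.apd_coords = np.asarray(self.apd_coords, dtype=float)
        self.validate()

    @property
    def n_vertices(self) -> int:
        return self.vertices.shape[0]

    def validate(self) -> None:
        n = self.n_vertices
        if self.triangles.size and (
            self.triangles.min() < 0 or self.triangles.max() >= n
        ):
            raise ValueError("triangle indices out of range")
        referenced = np.zeros(n, dtype=bool)
        referenced[self.triangles.ravel()] = True
        if not referenced.all():
            orphans = np.flatnonzero(~referenced)
            raise ValueError(f"vertices not referenced by any triangle: {orphans[:10]}")
        if len(self.labels) != n or len(self.cortical_flag) != n:
            raise ValueError("per-vertex arrays must match vertex count")
        if self.apd_coords is not None:
            if self.apd_coords.shape != (n, 2):
                raise ValueError("apd_coords must have shape (n_vertices, 2)")
            if not np.isfinite(self.apd_coords).all():
                raise ValueError("apd_coords must be finite")


@dataclasses.dataclass
class NeuronCloud:
    """Point-neuron soma positions with intrinsic AP-PD coordinates."""

    positions: np.ndarray
    apd_coords: np.ndarray
    neuron_ids: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.apd_coords = np.asarray(self.apd_coords, dtype=float)
        self.neuron_ids = np.asarray(self.neuron_ids, dtype=np.int64)
        n = len(self.positions)
        if not np.array_equal(self.neuron_ids, np.arange(n)):
            raise ValueError("neuron ids must be contiguous from 0")
        if not (
            np.isfinite(self.positions).all() and np.isfinite(self.apd_coords).all()
        ):
            raise ValueError("neuron coordinates must be finite")

    @property
    def n_neurons(self) -> int:
        return len(self.neuron_ids)


@dataclasses.dataclass
class VertexAssignment:
    """Partition of the neuron cloud into per-vertex subpopulations.

    ``device_order`` fixes the ordering contract for every rate / spike-count
    vector exchanged between the two simulators: one entry per CA1 vertex, in
    the order the per-vertex devices are created (ascending vertex id).
    """

    vertex_to_neurons: dict[int, np.ndarray]
    device_order: np.ndarray

    def __post_init__(self) -> None:
        self.device_order = np.asarray(self.device_order, dtype=np.int64)
        all_ids = (
            np.concatenate([v for v in self.vertex_to_neurons.values()])
            if self.vertex_to_neurons
            else np.empty(0, dtype=np.int64)
        )
        if len(np.unique(all_ids)) != len(all_ids):
            raise ValueError("neuron lists must be pairwise disjoint")
        if len(np.unique(self.device_order)) != len(self.device_order):
            raise ValueError("device_order entries must be unique")

    @property
    def n_assigned(self) -> int:
        return sum(len(v) for v in self.vertex_to_neurons.values())

    def neuron_to_vertex(self, n_neurons: int) -> np.ndarray:
        """Inverse map; -1 for unassigned neurons."""
        out = np.full(n_neurons, -1, dtype=np.int64)
        for v, ids in self.vertex_to_neurons.items():
            out[ids] = v
        return out


def _sheet_embedding(ap: np.ndarray, pd_: np.ndarray, curvature: float) -> np.ndarray:
    """Isometric embedding of the (AP, PD) sheet, rolled along the PD axis.

    Constant-curvature extrusion: PD coordinate is arc length along the rolled
    profile, so intrinsic distances on the surface equal AP-PD distances and
    the flat map is exact.  Zero curvature degenerates to the plane z = 0.
    """
    if abs(curvature) < 1e-12:
        return np.column_stack([ap, pd_, np.zeros_like(ap)])
    c = curvature
    return np.column_stack([ap, np.sin(c * pd_) / c, (1.0 - np.cos(c * pd_)) / c])


def generate_synthetic_hippocampus(
    n_ap: int,
    n_pd: int,
    curvature: float = 0.15,
    seed: int = 0,
    ap_extent: float = 20.0,
    pd_extent: float = 10.0,
    jitter: float = 0.25,
) -> SurfaceModel:
    """Generate a curved rectangular sheet mesh mimicking the CA1 environs.

    The sheet is parameterised analytically by (AP, PD); those parameters are
    stored as ``apd_coords`` and serve as ground truth for flat-mapping.  PD
    bands are labeled subiculum / CA1 / CA2 in order, mimicking hippocampal
    lamination so the relabeling rule is exercised at band boundaries.

    Parameters
    ----------
    n_ap, n_pd : int
        Grid resolution along each axis (>= 4).
    curvature : float
        Rolling curvature of the sheet in rad/mm; 0 gives a planar sheet.
    seed : int
        Seeds the grid-line jitter that breaks lattice degeneracies.
    ap_extent, pd_extent : float
        Physical sheet extents in mm.
    jitter : float
        Interior grid-line displacement as a fraction of grid spacing (< 0.5
        keeps the grid ordering intact).
    """
    if n_ap < 4 or n_pd < 4:
        raise ValueError("n_ap and n_pd must both be >= 4")
    if not 0 <= jitter < 0.5:
        raise ValueError("jitter must lie in [0, 0.5)")
    rng = np.random.default_rng(seed)
    ap_lines = np.linspace(0.0, ap_extent, n_ap)
    pd_lines = np.linspace(0.0, pd_extent, n_pd)
    dap = ap_extent / (n_ap - 1)
    dpd = pd_extent / (n_pd - 1)
    ap_lines[1:-1] += rng.uniform(-jitter, jitter, n_ap - 2) * dap
    pd_lines[1:-1] += rng.uniform(-jitter, jitter, n_pd - 2) * dpd

    ap, pd_ = np.meshgrid(ap_lines, pd_lines, indexing="ij")
    ap, pd_ = ap.ravel(), pd_.ravel()
    vertices = _sheet_embedding(ap, pd_, curvature)
    apd = np.column_stack([ap, pd_])

    tris = []
    for i in range(n_ap - 1):
        for j in range(n_pd - 1):
            v00 = i * n_pd + j
            v01 = v00 + 1
            v10 = v00 + n_pd
            v11 = v10 + 1
            tris.append((v00, v10, v11))
            tris.append((v00, v11, v01))
    triangles = np.array(tris, dtype=np.int64)

    # PD bands: subiculum (proximal third) / CA1 (middle) / CA2 (distal).
    labels = np.empty(len(ap), dtype=object)
    band = pd_ / pd_extent
    labels[band < 1.0 / 3.0] = "subiculum"
    labels[(band >= 1.0 / 3.0) & (band < 2.0 / 3.0)] = "CA1"
    labels[band >= 2.0 / 3.0] = "CA2"

    return SurfaceModel(
        vertices=vertices,
        triangles=triangles,
        labels=labels,
        cortical_flag=np.ones(len(ap), dtype=bool),
        apd_coords=apd,
    )


def generate_neuron_cloud(
    mesh: SurfaceModel,
    n_neurons: int,
    thickness: float = 0.5,
    seed: int = 0,
) -> NeuronCloud:
    """Sample neuron somata in a shell around the assignable surface.

    Each neuron is placed at an area-weighted random point of a triangle whose
    three vertices are all labeled CA1/CA2/subiculum, then displaced along the
    triangle normal by a uniform offset in ``[-thickness/2, thickness/2]``.
    The neuron inherits the AP-PD coordinate of its generating surface point
    (barycentric interpolation), which is exact ground truth for the flat map.
    """
    if n_neurons < 1:
        raise ValueError("n_neurons must be >= 1")
    if thickness < 0:
        raise ValueError("thickness must be non-negative")
    if mesh.apd_coords is None:
        raise ValueError("mesh must carry AP-PD coordinates")
    rng = np.random.default_rng(seed)

    tri_labels = mesh.labels[mesh.triangles]
    eligible = np.all(np.isin(tri_labels, ASSIGNABLE_LABELS), axis=1)
    tri = mesh.triangles[eligible]
    if len(tri) == 0:
        raise ValueError("mesh has no fully assignable triangles")
    p0, p1, p2 = (mesh.vertices[tri[:, k]] for k in range(3))
    cross = np.cross(p1 - p0, p2 - p0)
    area = 0.5 * np.linalg.norm(cross, axis=1)
    pick = rng.choice(len(tri), size=n_neurons, p=area / area.sum())

    # uniform barycentric sampling
    r1 = np.sqrt(rng.uniform(size=n_neurons))
    r2 = rng.uniform(size=n_neurons)
    w0, w1, w2 = 1.0 - r1, r1 * (1.0 - r2), r1 * r2
    base = (
        w0[:, None] * p0[pick] + w1[:, None] * p1[pick] + w2[:, None] * p2[pick]
    )
    normals = cross[pick] / np.linalg.norm(cross[pick], axis=1, keepdims=True)
    offset = rng.uniform(-0.5 * thickness, 0.5 * thickness, size=n_neurons)
    positions = base + offset[:, None] * normals

    apd_v = mesh.apd_coords[tri]
    apd = (
        w0[:, None] * apd_v[pick, 0]
        + w1[:, None] * apd_v[pick, 1]
        + w2[:, None] * apd_v[pick, 2]
    )
    return NeuronCloud(
        positions=positions, apd_coords=apd, neuron_ids=np.arange(n_neurons)
    )


def mesh_edge_graph(mesh: SurfaceModel) -> sp.csr_matrix:
    """Undirected edge graph of the mesh weighted by 3D edge length."""
    t = mesh.triangles
    edges = np.concatenate([t[:, [0, 1]], t[:, [1, 2]], t[:, [2, 0]]])
    lengths = np.linalg.norm(
        mesh.vertices[edges[:, 0]] - mesh.vertices[edges[:, 1]], axis=1
    )
    n = mesh.n_vertices
    g = sp.coo_matrix((lengths, (edges[:, 0], edges[:, 1])), shape=(n, n)).tocsr()
    g = g.maximum(g.T)
    return g


def geodesic_distances(mesh: SurfaceModel, cutoff: float) -> sp.csr_matrix:
    """Sparse symmetric matrix of edge-graph shortest-path distances <= cutoff.

    Distances are measured along mesh edges (Dijkstra on the edge graph), a
    standard approximation to exact polyhedral geodesics that converges with
    mesh resolution.  The diagonal is (implicitly) zero; disconnected pairs are
    simply absent.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    g = mesh_edge_graph(mesh)
    d = dijkstra(g, directed=False, limit=cutoff)
    d[~np.isfinite(d)] = 0.0
    np.fill_diagonal(d, 0.0)
    out = sp.csr_matrix(d)
    out.eliminate_zeros()
    return out


def flatmap_ap_pd(model, source=None) -> np.ndarray:
    """Return the common AP-PD coordinates used for assignment.

    Parameters
    ----------
    model : SurfaceModel or NeuronCloud
        Object whose points are to be mapped.
    source : None or pandas.DataFrame
        ``None`` selects the synthetic ground-truth coordinates carried by the
        model (the analytic parameterisation; no registration is computed).  A
        DataFrame must have columns ``id``, ``ap``, ``pd`` covering every
        point; missing points raise an error naming them.
    """
    n = model.n_vertices if isinstance(model, SurfaceModel) else model.n_neurons
    if source is None:
        coords = model.apd_coords
        if coords is None:
            raise ValueError("model carries no intrinsic AP-PD coordinates")
    else:
        table = pd.DataFrame(source)
        missing = set(range(n)) - set(table["id"].astype(int))
        if missing:
            raise ValueError(
                f"AP-PD table is missing coordinates for points {sorted(missing)[:20]}"
            )
        table = table.set_index("id").loc[np.arange(n)]
        coords = table[["ap", "pd"]].to_numpy(dtype=float)
    if not np.isfinite(coords).all():
        raise ValueError("AP-PD coordinates must be finite")
    return coords


def assign_neurons_to_vertices(
    mesh: SurfaceModel,
    cloud: NeuronCloud,
    mesh_apd: np.ndarray | None = None,
    cloud_apd: np.ndarray | None = None,
) -> VertexAssignment:
    """Attach every neuron to its nearest assignable vertex in AP-PD space.

    Eligible vertices are those labeled CA1, CA2 or subiculum.  The result is
    a strict partition: each neuron belongs to exactly one vertex, so each
    per-vertex device drives a disjoint subpopulation and per-vertex spike
    counts are unambiguous.  Distance ties go to the lowest vertex id; neuron
    lists are sorted ascending.
    """
    mesh_apd = flatmap_ap_pd(mesh) if mesh_apd is None else np.asarray(mesh_apd)
    cloud_apd = flatmap_ap_pd(cloud) if cloud_apd is None else np.asarray(cloud_apd)
    eligible = np.flatnonzero(np.isin(mesh.labels, ASSIGNABLE_LABELS))
    if len(eligible) == 0:
        raise ValueError("no vertices labeled CA1/CA2/subiculum")

    tree = cKDTree(mesh_apd[eligible])
    k = min(4, len(eligible))
    dist, idx = tree.query(cloud_apd, k=k)
    if k == 1:
        dist, idx = dist[:, None], idx[:, None]
    # resolve ties toward the lowest vertex id
    tied = dist <= dist[:, :1] * (1.0 + 1e-12) + 1e-300
    cand = np.where(tied, eligible[idx], np.iinfo(np.int64).max)
    nearest = cand.min(axis=1)

    v2n: dict[int, np.ndarray] = {int(v): np.empty(0, dtype=np.int64) for v in eligible}
    order = np.argsort(nearest, kind="stable")
    split_at = np.flatnonzero(np.diff(nearest[order])) + 1
    for grp in np.split(order, split_at):
        v2n[int(nearest[grp[0]])] = np.sort(cloud.neuron_ids[grp])

    device_order = np.sort([v for v, ids in v2n.items() if len(ids) > 0])
    return VertexAssignment(vertex_to_neurons=v2n, device_order=device_order)


def select_onset_patch(mesh: SurfaceModel, n_patch: int = 5) -> np.ndarray:
    """Pick a compact patch of adjacent CA1 vertices as the seizure-onset zone.

    Returns the ``n_patch`` CA1 vertices nearest (in AP-PD space) to the CA1
    vertex closest to the CA1 centroid.
    """
    ca1 = np.flatnonzero(mesh.labels == "CA1")
    if len(ca1) == 0:
        raise ValueError("mesh has no CA1 vertices")
    n_patch = min(n_patch, len(ca1))
    apd = flatmap_ap_pd(mesh)[ca1]
    center = apd.mean(axis=0)
    seed_vertex = np.argmin(((apd - center) ** 2).sum(axis=1))
    d = ((apd - apd[seed_vertex]) ** 2).sum(axis=1)
    return np.sort(ca1[np.argsort(d, kind="stable")[:n_patch]])


def relabel_vertices(
    mesh: SurfaceModel, assignment: VertexAssignment
) -> SurfaceModel:
    """Reconcile region labels with the neuron assignment.

    CA2/subiculum vertices holding at least one neuron become CA1; CA1
    vertices left empty take the label of the nearest CA2/subiculum vertex in
    AP-PD space.  After one application every CA1 vertex owns neurons and
    every populated vertex is CA1, so the operation is idempotent.
    """
    labels = mesh.labels.copy()
    apd = flatmap_ap_pd(mesh)
    populated = {
        v for v, ids in assignment.vertex_to_neurons.items() if len(ids) > 0
    }

    donors = np.flatnonzero(
        (np.isin(mesh.labels, ("CA2", "subiculum")))
        & ~np.isin(np.arange(mesh.n_vertices), list(populated) or [-1])
    )
    for v in range(mesh.n_vertices):
        if v in populated and labels[v] in ("CA2", "subiculum"):
            labels[v] = "CA1"
    empty_ca1 = [
        v
        for v in range(mesh.n_vertices)
        if mesh.labels[v] == "CA1" and v not in populated
    ]
    if empty_ca1:
        if len(donors) == 0:
            raise ValueError(
                "unassigned CA1 vertices but no CA2/subiculum vertex to inherit from"
            )
        tree = cKDTree(apd[donors])
        dist, j = tree.query(apd[empty_ca1], k=min(2, len(donors)))
        dist = np.atleast_2d(dist.T).T
        j = np.atleast_2d(j.T).T
        tied = dist <= dist[:, :1] * (1.0 + 1e-12) + 1e-300
        cand = np.where(tied, donors[j], np.iinfo(np.int64).max)
        for v, donor in zip(empty_ca1, cand.min(axis=1)):
            labels[v] = mesh.labels[donor]

    return SurfaceModel(
        vertices=mesh.vertices,
        triangles=mesh.triangles,
        labels=labels,
        cortical_flag=mesh.cortical_flag,
        apd_coords=mesh.apd_coords,
    )
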