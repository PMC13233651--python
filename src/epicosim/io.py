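"""Readers/writers for the artifact formats and the run configuration.

Conventions: coordinates in mm, times in ms, vertex and neuron ids 0-based.
Tables are CSV with a header row; connectome matrices are Matrix Market
coordinate files (1-based indices per that format); recordings are HDF5.
All writes are atomic (write to a temp name, then rename).
"""

from __future__ import annotations

import dataclasses
import logging
import os
import tempfile
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
import yaml

from .bridge import ConversionParams
from .field import FieldRecording, SEMParameters, SparseConnectome
from .geometry import NeuronCloud, SurfaceModel, VertexAssignment
from .snn import NeuronModelParams, SpikeRecord, SpikingNetwork, SynapseParams

logger = logging.getLogger("epicosim")

__all__ = [
    "RunConfig",
    "read_mesh",
    "write_mesh",
    "read_mesh_off",
    "write_mesh_off",
    "read_apd_table",
    "write_apd_table",
    "read_connectome",
    "write_connectome",
    "read_network",
    "write_network",
    "read_assignment",
    "write_assignment",
    "read_spikes",
    "write_spikes",
    "read_recording",
    "write_recording",
    "split_seed",
]


def _atomic_write(path: Path, writer) -> None:
    path = Path(path)
    # keep the suffix: some writers (Matrix Market) key their format on it
    fd, tmp = tempfile.mkstemp(
        dir=path.parent, prefix=path.stem + ".", suffix=path.suffix
    )
    os.close(fd)
    try:
        writer(Path(tmp))
        os.replace(tmp, path)
    except BaseException:
        os.unlink(tmp)
        raise


def split_seed(seed: int, n: int = 4) -> list[int]:
    """Expand one global seed into independent per-module stream seeds.

    Uses numpy's SeedSequence spawning; stream order is fixed:
    geometry, network, spiking, bridge[, ...].
    """
    children = np.random.SeedSequence(seed).spawn(n)
    return [int(c.generate_state(1)[0] % (2**31)) for c in children]


# ---------------------------------------------------------------- meshes


def write_mesh(mesh: SurfaceModel, outdir: str | Path) -> None:
    """Plain-table mesh dialect: vertices/triangles/labels/apd CSVs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    vdf = pd.DataFrame(
        {
            "id": np.arange(mesh.n_vertices),
            "x": mesh.vertices[:, 0],
            "y": mesh.vertices[:, 1],
            "z": mesh.vertices[:, 2],
            "cortical": mesh.cortical_flag.astype(int),
        }
    )
    _atomic_write(outdir / "vertices.csv", lambda p: vdf.to_csv(p, index=False, float_format="%.17g"))
    tdf = pd.DataFrame(mesh.triangles, columns=["v0", "v1", "v2"])
    _atomic_write(outdir / "triangles.csv", lambda p: tdf.to_csv(p, index=False))
    ldf = pd.DataFrame(
        {"vertex_id": np.arange(mesh.n_vertices), "label": mesh.labels}
    )
    _atomic_write(outdir / "labels.csv", lambda p: ldf.to_csv(p, index=False))
    if mesh.apd_coords is not None:
        write_apd_table(
            np.arange(mesh.n_vertices), mesh.apd_coords, outdir / "apd.csv"
        )


def read_mesh(indir: str | Path) -> SurfaceModel:
    indir = Path(indir)
    vdf = pd.read_csv(indir / "vertices.csv", float_precision="round_trip")
    tdf = pd.read_csv(indir / "triangles.csv")
    ldf = pd.read_csv(indir / "labels.csv").set_index("vertex_id")
    apd = None
    if (indir / "apd.csv").exists():
        table = pd.read_csv(indir / "apd.csv", float_precision="round_trip")
        apd = table.sort_values("id")[["ap", "pd"]].to_numpy()
    order = vdf.sort_values("id")
    return SurfaceModel(
        vertices=order[["x", "y", "z"]].to_numpy(),
        triangles=tdf[["v0", "v1", "v2"]].to_numpy(),
        labels=ldf.loc[order["id"], "label"].to_numpy(dtype=object),
        cortical_flag=order["cortical"].to_numpy(dtype=bool),
        apd_coords=apd,
    )


def write_mesh_off(mesh: SurfaceModel, path: str | Path) -> None:
    """Standard OFF surface format (geometry only)."""
    def w(p: Path):
        with open(p, "w") as fh:
            fh.write("OFF\n")
            fh.write(f"{mesh.n_vertices} {len(mesh.triangles)} 0\n")
            for v in mesh.vertices:
                fh.write(f"{float(v[0])!r} {float(v[1])!r} {float(v[2])!r}\n")
            for t in mesh.triangles:
                fh.write(f"3 {t[0]} {t[1]} {t[2]}\n")

    _atomic_write(Path(path), w)


def read_mesh_off(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read an OFF file; returns (vertices, triangles)."""
    with open(path) as fh:
        lines = [
            ln.strip()
            for ln in fh
            if ln.strip() and not ln.startswith("#")
        ]
    if lines[0] != "OFF":
        raise ValueError(f"{path}: not an OFF file (line 1)")
    nv, nf, _ = (int(v) for v in lines[1].split())
    verts = np.array([[float(x) for x in ln.split()] for ln in lines[2 : 2 + nv]])
    tris = []
    for i, ln in enumerate(lines[2 + nv : 2 + nv + nf]):
        parts = ln.split()
        if int(parts[0]) != 3:
            raise ValueError(f"{path}: non-triangular face at line {3 + nv + i}")
        tris.append([int(v) for v in parts[1:4]])
    return verts, np.array(tris, dtype=np.int64)


def write_apd_table(ids: np.ndarray, apd: np.ndarray, path: str | Path) -> None:
    df = pd.DataFrame({"id": ids, "ap": apd[:, 0], "pd": apd[:, 1]})
    _atomic_write(Path(path), lambda p: df.to_csv(p, index=False, float_format="%.17g"))


def read_apd_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = {"id", "ap", "pd"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


# ------------------------------------------------------------ connectome


def write_connectome(conn: SparseConnectome, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _atomic_write(
        outdir / "weights.mtx", lambda p: scipy.io.mmwrite(str(p), conn.weights.tocoo())
    )
    _atomic_write(
        outdir / "tract_lengths.mtx",
        lambda p: scipy.io.mmwrite(str(p), conn.tract_lengths.tocoo()),
    )


def read_connectome(
    indir: str | Path, conduction_speed: float = 3.0
) -> SparseConnectome:
    indir = Path(indir)
    w = sp.csr_matrix(scipy.io.mmread(indir / "weights.mtx"))
    l = sp.csr_matrix(scipy.io.mmread(indir / "tract_lengths.mtx"))
    for name, mat in (("weights", w), ("tract_lengths", l)):
        n_explicit = int((mat.data == 0).sum())
        if n_explicit:
            logger.warning(
                "%s: dropped %d explicitly stored zeros in %s",
                indir,
                n_explicit,
                name,
            )
            mat.eliminate_zeros()
    return SparseConnectome(
        weights=w, tract_lengths=l, conduction_speed=conduction_speed
    )


# --------------------------------------------------------------- network


def write_network(net: SpikingNetwork, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ndf = pd.DataFrame(
        {
            "id": net.cloud.neuron_ids,
            "x": net.cloud.positions[:, 0],
            "y": net.cloud.positions[:, 1],
            "z": net.cloud.positions[:, 2],
            "ap": net.cloud.apd_coords[:, 0],
            "pd": net.cloud.apd_coords[:, 1],
        }
    )
    _atomic_write(outdir / "neurons.csv", lambda p: ndf.to_csv(p, index=False, float_format="%.17g"))
    cdf = pd.DataFrame(
        {
            "pre": net.pre,
            "post": net.post,
            "U": net.U,
            "tau_rec": net.tau_rec,
            "tau_fac": net.tau_fac,
            "weight": net.weight,
            "delay": net.delay,
            "length": net.length,
            "receptor": net.receptor,
        }
    )
    _atomic_write(outdir / "connections.csv", lambda p: cdf.to_csv(p, index=False, float_format="%.17g"))


def read_network(
    indir: str | Path, neuron_params: NeuronModelParams | None = None
) -> SpikingNetwork:
    indir = Path(indir)
    ndf = pd.read_csv(indir / "neurons.csv", float_precision="round_trip").sort_values("id")
    cdf = pd.read_csv(indir / "connections.csv", float_precision="round_trip")
    cloud = NeuronCloud(
        positions=ndf[["x", "y", "z"]].to_numpy(),
        apd_coords=ndf[["ap", "pd"]].to_numpy(),
        neuron_ids=ndf["id"].to_numpy(),
    )
    return SpikingNetwork(
        cloud,
        neuron_params or NeuronModelParams(),
        cdf["pre"].to_numpy(),
        cdf["post"].to_numpy(),
        cdf["U"].to_numpy(),
        cdf["tau_rec"].to_numpy(),
        cdf["tau_fac"].to_numpy(),
        cdf["weight"].to_numpy(),
        cdf["delay"].to_numpy(),
        cdf["length"].to_numpy(),
        cdf["receptor"].to_numpy(),
    )


def write_assignment(assignment: VertexAssignment, path: str | Path) -> None:
    rows = []
    for v, ids in sorted(assignment.vertex_to_neurons.items()):
        for nid in ids:
            rows.append((v, nid))
    df = pd.DataFrame(rows, columns=["vertex_id", "neuron_id"])
    devdf = pd.DataFrame({"vertex_id": assignment.device_order})
    path = Path(path)
    _atomic_write(path, lambda p: df.to_csv(p, index=False, float_format="%.17g"))
    _atomic_write(
        path.with_name(path.stem + "_devices.csv"),
        lambda p: devdf.to_csv(p, index=False),
    )


def read_assignment(path: str | Path) -> VertexAssignment:
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    devdf = pd.read_csv(path.with_name(path.stem + "_devices.csv"))
    v2n = {
        int(v): np.sort(grp["neuron_id"].to_numpy(dtype=np.int64))
        for v, grp in df.groupby("vertex_id")
    }
    return VertexAssignment(
        vertex_to_neurons=v2n,
        device_order=devdf["vertex_id"].to_numpy(dtype=np.int64),
    )


# ---------------------------------------------------------------- spikes


def write_spikes(record: SpikeRecord, outdir: str | Path) -> None:
    """Two-column text event list plus the per-vertex count matrix."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    def w(p: Path):
        with open(p, "w") as fh:
            fh.write("# neuron_id time_ms\n")
            for nid, t in zip(record.ids, record.times):
                fh.write(f"{int(nid)} {float(t)!r}\n")

    _atomic_write(outdir / "spikes.txt", w)
    cdf = pd.DataFrame(
        record.counts, columns=[f"v{int(v)}" for v in record.device_order]
    )
    _atomic_write(outdir / "vertex_counts.csv", lambda p: cdf.to_csv(p, index=False, float_format="%.17g"))
    meta = {"dt": record.dt, "duration": record.duration}
    _atomic_write(
        outdir / "spikes_meta.yaml", lambda p: p.write_text(yaml.safe_dump(meta))
    )


def read_spikes(indir: str | Path) -> SpikeRecord:
    indir = Path(indir)
    meta = yaml.safe_load((indir / "spikes_meta.yaml").read_text())
    ids, times = [], []
    with open(indir / "spikes.txt") as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("#") or not line.strip():
                continue
            parts = line.split()
            try:
                nid, t = int(parts[0]), float(parts[1])
            except (IndexError, ValueError) as exc:
                raise ValueError(
                    f"{indir / 'spikes.txt'}: malformed row at line {lineno}"
                ) from exc
            if not 0 <= t <= meta["duration"]:
                raise ValueError(
                    f"{indir / 'spikes.txt'}: time out of range at line {lineno}"
                )
            ids.append(nid)
            times.append(t)
    cdf = pd.read_csv(indir / "vertex_counts.csv", float_precision="round_trip")
    device_order = np.array([int(c[1:]) for c in cdf.columns], dtype=np.int64)
    return SpikeRecord(
        ids=np.array(ids, dtype=np.int64),
        times=np.array(times),
        counts=cdf.to_numpy(dtype=np.int64),
        device_order=device_order,
        dt=float(meta["dt"]),
        duration=float(meta["duration"]),
    )


# ------------------------------------------------------------- recording


def write_recording(rec: FieldRecording, path: str | Path) -> None:
    def w(p: Path):
        with h5py.File(p, "w") as fh:
            # track_times off keeps identical runs byte-identical
            fh.create_dataset("times", data=rec.times, track_times=False)
            fh.create_dataset("node_ids", data=rec.node_ids, track_times=False)
            fh.create_dataset("states", data=rec.states, track_times=False)
            fh.attrs["dt"] = rec.dt
            fh.attrs["stride"] = rec.stride
            fh.attrs["state_order"] = "x1,y1,z,x2,y2,g"

    _atomic_write(Path(path), w)


def read_recording(path: str | Path) -> FieldRecording:
    with h5py.File(path, "r") as fh:
        return FieldRecording(
            times=fh["times"][...],
            states=fh["states"][...],
            node_ids=fh["node_ids"][...],
            dt=float(fh.attrs["dt"]),
            stride=int(fh.attrs["stride"]),
        )


# ---------------------------------------------------------------- config


_CONFIG_SCHEMA_VERSION = 1

_SECTION_TYPES = {
    "sem": SEMParameters,
    "conversion": ConversionParams,
    "neuron": NeuronModelParams,
    "synapse": SynapseParams,
}

_TOP_KEYS = {
    "schema_version",
    "include",
    "seed",
    "dt",
    "duration",
    "monitor_stride",
    "onset_vertices",
    "x0_map",
    "conduction_speed",
    "kernel_sigma",
    "kernel_cutoff",
    "kernel_normalize",
    "static_weight",
    "static_delay",
    "feedback_enabled",
    "feedback_gain",
    "n_ap",
    "n_pd",
    "n_neurons",
    "curvature",
    "thickness",
    "mean_degree",
    "length_scale",
    "sem",
    "conversion",
    "neuron",
    "synapse",
}


@dataclasses.dataclass
class RunConfig:
    """Resolved configuration of one pipeline run.

    Unknown keys are rejected; every run writes the resolved config next to
    its outputs so results are reproducible from the output directory alone.
    """

    seed: int = 0
    dt: float = 0.1
    duration: float = 1000.0
    monitor_stride: int = 10
    onset_vertices: list = dataclasses.field(default_factory=list)
    x0_map: dict = dataclasses.field(default_factory=dict)  # label -> x0
    conduction_speed: float = 3.0
    kernel_sigma: float = 2.0
    kernel_cutoff: float = 6.0
    kernel_normalize: bool = False
    static_weight: float = 4.0
    static_delay: float = 1.0
    feedback_enabled: bool = False
    feedback_gain: float = 0.0
    n_ap: int = 24
    n_pd: int = 12
    n_neurons: int = 800
    curvature: float = 0.15
    thickness: float = 0.5
    mean_degree: float = 20.0
    length_scale: float = 2.0
    sem: SEMParameters = dataclasses.field(default_factory=SEMParameters)
    conversion: ConversionParams = dataclasses.field(
        default_factory=ConversionParams
    )
    neuron: NeuronModelParams = dataclasses.field(
        default_factory=NeuronModelParams
    )
    synapse: SynapseParams = dataclasses.field(default_factory=SynapseParams)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = _load_yaml_with_includes(Path(path))
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        version = data.pop("schema_version", _CONFIG_SCHEMA_VERSION)
        if version != _CONFIG_SCHEMA_VERSION:
            raise ValueError(f"unsupported config schema version {version}")
        unknown = set(data) - _TOP_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs = {}
        for key, value in data.items():
            if key in _SECTION_TYPES:
                cls_ = _SECTION_TYPES[key]
                known = {f.name for f in dataclasses.fields(cls_)}
                bad = set(value) - known
                if bad:
                    raise ValueError(f"unknown keys in '{key}': {sorted(bad)}")
                kwargs[key] = cls_(**value)
            else:
                kwargs[key] = value
        return cls(**kwargs)

    def to_dict(self) -> dict:
        out = {"schema_version": _CONFIG_SCHEMA_VERSION}
        for f in dataclasses.fields(self):
            value = getattr(self, f.name)
            if dataclasses.is_dataclass(value):
                value = dataclasses.asdict(value)
            out[f.name] = value
        return out

    def write_resolved(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        _atomic_write(
            outdir / "resolved_config.yaml",
            lambda p: p.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True)),
        )


def _load_yaml_with_includes(path: Path, _depth: int = 0) -> dict:
    if _depth > 8:
        raise ValueError("config include depth exceeded")
    data = yaml.safe_load(path.read_text()) or {}
    includes = data.pop("include", [])
    if isinstance(includes, str):
        includes = [includes]
    merged: dict = {}
    for inc in includes:
        inc_path = (path.parent / inc) if not Path(inc).is_absolute() else Path(inc)
        merged.update(_load_yaml_with_includes(inc_path, _depth + 1))
    merged.update(data)
    return merged
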