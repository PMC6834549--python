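"""Readers/writers and run configuration.

HDF5 is the canonical interchange format (complex arrays stored as
separate real/imag float64 datasets); CSV for small tables.  NIfTI and
CIFTI-2 dense timeseries can be ingested read-only via nibabel.  Every
artifact embeds the parameters that produced it.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .clustering import ClusterParams, ClusterSet
from .dmd import DataMatrix, DMDMode, ModeSet, WindowSpec
from .simulator import MarkovSpec, SimulationResult

__all__ = [
    "RunConfig",
    "read_timeseries",
    "save_timeseries",
    "save_simulation",
    "load_simulation",
    "save_modeset",
    "load_modeset",
    "save_clusters",
    "load_clusters",
]


@dataclass
class RunConfig:
    """Everything needed to reproduce a pipeline run."""

    # windowing
    T: int = 32
    dT: int = 4
    r: int = 8
    # binning
    bins_per_axis: int = 40
    neighborhood: int = 8
    # clustering
    z_t: float = 2.5
    t: float = 0.955
    c_min: int = 25
    min_cluster_size: int = 5
    n_clusters: int | None = None
    linkage: str = "average"
    # dynamics
    lag_seconds: float = 30.0
    # run
    seed: int = 0
    input_path: str | None = None
    output_dir: str = "."
    dt: float | None = None
    log_level: str = "INFO"

    def window_spec(self) -> WindowSpec:
        return WindowSpec(T=self.T, dT=self.dT, r=self.r)

    def cluster_params(self) -> ClusterParams:
        return ClusterParams(
            z_t=self.z_t,
            t=self.t,
            c_min=self.c_min,
            min_cluster_size=self.min_cluster_size,
            n_clusters=self.n_clusters,
            linkage_method=self.linkage,
        )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        names = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - names
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def _stamp(group: h5py.Group, config: RunConfig | None = None) -> None:
    import sklearn
    import scipy

    group.attrs["numpy_version"] = np.__version__
    group.attrs["scipy_version"] = scipy.__version__
    group.attrs["sklearn_version"] = sklearn.__version__
    if config is not None:
        group.attrs["config_json"] = json.dumps(config.to_dict())
        group.attrs["config_hash"] = config.digest()


# ---------------------------------------------------------------- timeseries


def save_timeseries(data: DataMatrix, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=data.values)
        f.attrs["dt"] = data.dt
        f.attrs["scan_id"] = data.scan_id
        if data.coords is not None:
            f.create_dataset("coords", data=data.coords)
        if data.groups is not None:
            f.create_dataset("groups", data=np.asarray(data.groups, dtype=int))


def _read_hdf5(path: Path, dt: float | None) -> DataMatrix:
    with h5py.File(path, "r") as f:
        values = f["data"][()]
        file_dt = float(f.attrs["dt"]) if "dt" in f.attrs else None
        coords = f["coords"][()] if "coords" in f else None
        groups = f["groups"][()] if "groups" in f else None
        scan_id = str(f.attrs.get("scan_id", ""))
    dt = dt if dt is not None else file_dt
    if dt is None:
        raise ValueError(f"{path}: no frame interval in file and none supplied")
    return DataMatrix(values, dt, coords=coords, groups=groups, scan_id=scan_id)


def _read_csv(path: Path, dt: float | None) -> DataMatrix:
    if dt is None:
        raise ValueError(f"{path}: CSV carries no frame interval; pass dt")
    values = pd.read_csv(path, header=None).to_numpy(dtype=float)
    return DataMatrix(values, dt, scan_id=path.stem)


def _read_nifti(path: Path, dt: float | None) -> DataMatrix:
    import nibabel as nib

    img = nib.load(str(path))
    if isinstance(img, nib.Cifti2Image):
        # dense timeseries: rows are frames, columns grayordinates
        values = np.asarray(img.get_fdata()).T
        ax0 = img.header.get_axis(0)
        file_dt = getattr(ax0, "step", None)
        coords = None
    else:
        arr = np.asarray(img.get_fdata())
        if arr.ndim != 4:
            raise ValueError(f"{path}: expected a 4-D NIfTI timeseries")
        n_frames = arr.shape[3]
        values = arr.reshape(-1, n_frames)
        zooms = img.header.get_zooms()
        file_dt = float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0 else None
        ii, jj, kk = np.unravel_index(np.arange(values.shape[0]), arr.shape[:3])
        coords = np.column_stack([ii, jj, kk]).astype(float)
    dt = dt if dt is not None else (float(file_dt) if file_dt else None)
    if dt is None:
        raise ValueError(f"{path}: no frame interval in header and none supplied")
    if np.isnan(values).any():
        bad = np.flatnonzero(np.isnan(values).any(axis=1))
        raise ValueError(f"{path}: NaNs at locations {bad[:10].tolist()}")
    return DataMatrix(values, dt, coords=coords, scan_id=path.name)


def read_timeseries(
    path: str | Path, format: str | None = None, dt: float | None = None
) -> DataMatrix:
    """Load a space x time matrix from HDF5, CSV, NIfTI or CIFTI-2.

    The format is inferred from the extension unless given explicitly.
    ``dt`` overrides (or supplies, when the file has none) the frame
    interval in seconds.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        name = path.name.lower()
        if name.endswith((".h5", ".hdf5")):
            format = "hdf5"
        elif name.endswith(".csv"):
            format = "csv"
        elif name.endswith((".nii", ".nii.gz", ".dtseries.nii")):
            format = "nifti"
        else:
            raise ValueError(f"cannot infer format of {path}")
    readers = {"hdf5": _read_hdf5, "csv": _read_csv, "nifti": _read_nifti, "cifti2": _read_nifti}
    if format not in readers:
        raise ValueError(f"unknown format {format!r}")
    return readers[format](path, dt)


# ---------------------------------------------------------------- simulation


def save_simulation(sim: SimulationResult, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=sim.data.values)
        f.create_dataset("states", data=sim.state_sequence.astype(np.int8))
        f.create_dataset("coords", data=sim.data.coords)
        f.create_dataset("transition_probs", data=sim.markov.transition_probs)
        shapes = f.create_group("shapes")
        for name, img in sim.shapes.all_patterns().items():
            shapes.create_dataset(name, data=img)
        for key, val in sim.params.items():
            f.attrs[key] = val
        f.attrs["scan_id"] = sim.data.scan_id
        f.attrs["initial_state"] = sim.markov.initial_state
        _stamp(f)


def load_simulation(path: str | Path) -> SimulationResult:
    from .simulator import ShapeModes, synthesize

    with h5py.File(path, "r") as f:
        states = f["states"][()].astype(int)
        shapes = ShapeModes(**{k: f["shapes"][k][()] for k in f["shapes"]})
        markov = MarkovSpec(
            transition_probs=f["transition_probs"][()],
            initial_state=int(f.attrs["initial_state"]),
        )
        params = {k: f.attrs[k] for k in f.attrs}
    return synthesize(
        shapes,
        str(params["cat_choice"]),
        str(params["chicken_choice"]),
        states,
        markov=markov,
        f_c=float(params["f_c"]),
        f_k=float(params["f_k"]),
        phi_c=float(params["phi_c"]),
        phi_k=float(params["phi_k"]),
        noise_amp=float(params["noise_amp"]),
        centered_noise=bool(params["centered_noise"]),
        dt=float(params["dt"]),
        seed=int(params["seed"]),
        scan_id=str(params.get("scan_id", "")),
    )


# ------------------------------------------------------------------ modesets


def save_modeset(ms: ModeSet, path: str | Path, config: RunConfig | None = None) -> None:
    with h5py.File(path, "w") as f:
        phi = np.array([m.phi for m in ms.modes])
        f.create_dataset("phi_real", data=phi.real)
        f.create_dataset("phi_imag", data=phi.imag)
        ev = np.array([m.eigval for m in ms.modes])
        f.create_dataset("eigval_real", data=ev.real)
        f.create_dataset("eigval_imag", data=ev.imag)
        amp = np.array([m.amplitude for m in ms.modes])
        f.create_dataset("amplitude_real", data=amp.real)
        f.create_dataset("amplitude_imag", data=amp.imag)
        f.create_dataset("window_index", data=ms.window_index())
        f.create_dataset(
            "window_start", data=np.array([m.window_start for m in ms.modes])
        )
        f.create_dataset("window_starts", data=ms.window_starts)
        f.attrs["T"] = ms.spec.T
        f.attrs["dT"] = ms.spec.dT
        f.attrs["r"] = ms.spec.r
        f.attrs["dt"] = ms.dt
        f.attrs["scan_id"] = ms.scan_id
        _stamp(f, config)


def load_modeset(path: str | Path) -> ModeSet:
    from .dmd import eigen_to_rates

    with h5py.File(path, "r") as f:
        phi = f["phi_real"][()] + 1j * f["phi_imag"][()]
        ev = f["eigval_real"][()] + 1j * f["eigval_imag"][()]
        amp = f["amplitude_real"][()] + 1j * f["amplitude_imag"][()]
        w_idx = f["window_index"][()]
        w_start = f["window_start"][()]
        window_starts = f["window_starts"][()]
        spec = WindowSpec(int(f.attrs["T"]), int(f.attrs["dT"]), int(f.attrs["r"]))
        dt = float(f.attrs["dt"])
        scan_id = str(f.attrs["scan_id"])
    modes = []
    for j in range(len(ev)):
        growth, freq_hz = eigen_to_rates(complex(ev[j]), dt)
        modes.append(
            DMDMode(
                phi=phi[j],
                eigval=complex(ev[j]),
                growth=growth,
                freq_hz=freq_hz,
                freq_per_step=freq_hz * dt,
                amplitude=complex(amp[j]),
                window_index=int(w_idx[j]),
                window_start=int(w_start[j]),
                scan_id=scan_id,
            )
        )
    return ModeSet(modes, window_starts, spec, dt, scan_id)


# ------------------------------------------------------------------ clusters


def save_clusters(
    cs: ClusterSet,
    summary: dict[int, dict],
    path: str | Path,
    config: RunConfig | None = None,
) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("labels", data=cs.labels)
        f.create_dataset("linkage", data=cs.linkage_matrix)
        f.create_dataset("masks", data=cs.masks.astype(np.int8))
        if cs.mode_windows is not None:
            f.create_dataset("mode_windows", data=cs.mode_windows)
        g = f.create_group("averages")
        for cid, entry in summary.items():
            sub = g.create_group(str(cid))
            sub.create_dataset("average", data=entry["average"])
            if "average_full" in entry:
                sub.create_dataset("average_full", data=entry["average_full"])
            sub.attrs["size"] = entry["size"]
            sub.attrs["freq_mean_hz"] = entry["freq_mean_hz"]
            sub.attrs["freq_std_hz"] = entry["freq_std_hz"]
        for key, val in dataclasses.asdict(cs.params).items():
            f.attrs[f"param_{key}"] = "null" if val is None else val
        _stamp(f, config)


def load_clusters(path: str | Path) -> tuple[ClusterSet, dict[int, dict]]:
    with h5py.File(path, "r") as f:
        raw = {k[len("param_"):]: f.attrs[k] for k in f.attrs if k.startswith("param_")}
        kwargs = {}
        for key in ("z_t", "t", "c_min", "min_cluster_size", "n_clusters", "linkage_method"):
            if key in raw:
                v = raw[key]
                if isinstance(v, bytes):
                    v = v.decode()
                if isinstance(v, str) and v == "null":
                    v = None
                elif key in ("c_min", "min_cluster_size", "n_clusters"):
                    v = int(v)
                elif key in ("z_t", "t"):
                    v = float(v)
                kwargs[key] = v
        params = ClusterParams(**kwargs)
        cs = ClusterSet(
            labels=f["labels"][()],
            linkage_matrix=f["linkage"][()],
            params=params,
            masks=f["masks"][()].astype(bool),
            mode_windows=f["mode_windows"][()] if "mode_windows" in f else None,
        )
        summary = {}
        for cid in f["averages"]:
            sub = f["averages"][cid]
            entry = {
                "average": sub["average"][()],
                "size": int(sub.attrs["size"]),
                "freq_mean_hz": float(sub.attrs["freq_mean_hz"]),
                "freq_std_hz": float(sub.attrs["freq_std_hz"]),
            }
            if "average_full" in sub:
                entry["average_full"] = sub["average_full"][()]
            summary[int(cid)] = entry
    return cs, summary
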