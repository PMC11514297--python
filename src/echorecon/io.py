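"""File I/O: spectra, schedules, datasets, model checkpoints, run configs.

Real 2D spectra travel in two formats: an NMRPipe-style 2D binary (512
float32 header words followed by row-major float32 intensities — precise to
single precision) and an HDF5 container (lossless, also used for
hypercomplex FIDs, virtual-echo arrays, sigma maps, training datasets and
network checkpoints).  NUS schedules are plain text, one zero-based integer
per line, compatible with common NUS tooling.
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import yaml

from .simulate import PairDataset, SimConfig

__all__ = [
    "write_spectrum", "read_spectrum", "write_schedule", "read_schedule",
    "save_dataset", "load_dataset", "save_checkpoint", "load_checkpoint",
    "RunConfig",
]

_HDR_WORDS = 512
# NMRPipe header word indices used here
_FDFLTORDER = 2      # byte-order sentinel, 2.345 when native
_FDDIMCOUNT = 9
_FDSIZE = 99         # points along the row (direct) axis
_FDQUADFLAG = 106    # 1 = real data
_FDSPECNUM = 219     # number of rows (indirect axis)
_FDF2FTFLAG = 220
_FDTRANSPOSED = 221
_FDF1FTFLAG = 222
_ORDER_SENTINEL = np.float32(2.345)


def write_spectrum(spectrum: np.ndarray, path: str | Path) -> None:
    """Write a real 2D spectrum.

    ``.h5``/``.hdf5`` suffix selects the lossless HDF5 container; anything
    else writes the NMRPipe-style float32 binary.
    """
    path = Path(path)
    spectrum = np.asarray(spectrum, float)
    if spectrum.ndim != 2:
        raise ValueError("expected a 2D real spectrum")
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "w") as fh:
            fh.create_dataset("spectrum", data=spectrum)
            fh.attrs["axis_order"] = "indirect x direct"
        return
    header = np.zeros(_HDR_WORDS, dtype=np.float32)
    header[_FDFLTORDER] = _ORDER_SENTINEL
    header[_FDDIMCOUNT] = 2
    header[_FDSIZE] = spectrum.shape[1]
    header[_FDSPECNUM] = spectrum.shape[0]
    header[_FDQUADFLAG] = 1
    header[_FDF2FTFLAG] = 1
    header[_FDF1FTFLAG] = 1
    header[_FDTRANSPOSED] = 0
    with open(path, "wb") as fh:
        header.tofile(fh)
        spectrum.astype(np.float32).tofile(fh)


def read_spectrum(path: str | Path) -> np.ndarray:
    """Read a spectrum written by :func:`write_spectrum`."""
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "r") as fh:
            return fh["spectrum"][()]
    raw = np.fromfile(path, dtype=np.float32)
    if raw.size < _HDR_WORDS:
        raise ValueError(f"{path}: truncated file, no header")
    header, data = raw[:_HDR_WORDS], raw[_HDR_WORDS:]
    if not np.isclose(header[_FDFLTORDER], _ORDER_SENTINEL):
        raise ValueError(f"{path}: bad byte-order sentinel, not a spectrum "
                         "file (or foreign byte order)")
    if int(header[_FDDIMCOUNT]) != 2:
        raise ValueError(f"{path}: expected 2D data")
    rows, cols = int(header[_FDSPECNUM]), int(header[_FDSIZE])
    if rows * cols != data.size:
        raise ValueError(f"{path}: header claims {rows}x{cols} points but "
                         f"file holds {data.size}")
    return data.astype(float).reshape(rows, cols)


def write_schedule(schedule, path: str | Path) -> None:
    """Plain-text NUS schedule: one zero-based integer per line, sorted."""
    sched = np.sort(np.asarray(schedule, dtype=np.int64))
    Path(path).write_text("\n".join(str(int(i)) for i in sched) + "\n")


def read_schedule(path: str | Path) -> np.ndarray:
    lines = [ln.strip() for ln in Path(path).read_text().splitlines()
             if ln.strip()]
    try:
        idx = np.asarray([int(ln) for ln in lines], dtype=np.int64)
    except ValueError as exc:
        raise ValueError(f"{path}: non-integer schedule line") from exc
    if idx.size == 0:
        raise ValueError(f"{path}: empty schedule")
    if np.unique(idx).size != idx.size:
        raise ValueError(f"{path}: duplicate schedule indices")
    if idx.min() < 0:
        raise ValueError(f"{path}: negative schedule index")
    return np.sort(idx)


def save_dataset(dataset: PairDataset, path: str | Path) -> None:
    """Persist a training dataset with its generating config (provenance)."""
    with h5py.File(path, "w") as fh:
        fh.create_dataset("inputs", data=dataset.inputs)
        fh.create_dataset("references", data=dataset.references)
        fh.create_dataset("seeds", data=dataset.seeds)
        fh.attrs["mode"] = dataset.mode
        fh.attrs["config_yaml"] = yaml.safe_dump(
            dataclasses.asdict(dataset.config))


def load_dataset(path: str | Path) -> PairDataset:
    with h5py.File(path, "r") as fh:
        raw = yaml.safe_load(fh.attrs["config_yaml"])
        cfg = SimConfig(**{k: (tuple(v) if isinstance(v, list) else v)
                           for k, v in raw.items()})
        return PairDataset(inputs=fh["inputs"][()],
                           references=fh["references"][()],
                           seeds=fh["seeds"][()],
                           mode=str(fh.attrs["mode"]), config=cfg)


def save_checkpoint(estimator, path: str | Path) -> None:
    """Save a fitted WNN-based estimator (cascade or sigma predictor)."""
    from .cascade import CascadeReconstructor
    from .uncertainty import SigmaPredictor

    def dump_model(group, model):
        for i, p in enumerate(model.get_weights()):
            group.create_dataset(f"param_{i:03d}", data=p)

    with h5py.File(path, "w") as fh:
        fh.attrs["params_yaml"] = yaml.safe_dump(
            {k: (list(v) if isinstance(v, tuple) else v)
             for k, v in estimator.get_params().items()
             if k != "spec"})
        spec = estimator.spec
        if spec is not None:
            fh.attrs["spec_yaml"] = yaml.safe_dump(dataclasses.asdict(spec))
        if isinstance(estimator, CascadeReconstructor):
            fh.attrs["kind"] = "cascade"
            fh.attrs["spectrum_extent"] = estimator.stages_[0].scheme_.spectrum_extent
            for s, reg in enumerate(estimator.stages_):
                dump_model(fh.create_group(f"stage_{s}"), reg.model_)
        elif isinstance(estimator, SigmaPredictor):
            fh.attrs["kind"] = "sigma"
            fh.attrs["spectrum_extent"] = estimator.scheme_.spectrum_extent
            dump_model(fh.create_group("model"), estimator.model_)
        else:
            raise TypeError(f"cannot checkpoint {type(estimator).__name__}")


def load_checkpoint(path: str | Path):
    """Rebuild a fitted estimator from :func:`save_checkpoint` output."""
    from .cascade import CascadeReconstructor, WNNRegressor
    from .uncertainty import SigmaPredictor
    from .wnn import TileScheme, WNNSpec, build_wnn

    def load_model(group, spec):
        model = build_wnn(spec)
        model.set_weights([group[k][()] for k in sorted(group)])
        return model

    with h5py.File(path, "r") as fh:
        params = yaml.safe_load(fh.attrs["params_yaml"])
        params = {k: (tuple(v) if isinstance(v, list) else v)
                  for k, v in params.items()}
        spec = (WNNSpec(**yaml.safe_load(fh.attrs["spec_yaml"]))
                if "spec_yaml" in fh.attrs else WNNSpec())
        extent = tuple(int(v) for v in fh.attrs["spectrum_extent"])
        scheme = TileScheme(extent, tuple(params["output_extent"]),
                            spec.receptive_field)
        kind = fh.attrs["kind"]
        if kind == "cascade":
            est = CascadeReconstructor(spec=spec, **params)
            est.stages_ = []
            for s in range(est.n_stages):
                reg = WNNRegressor(spec=spec,
                                   output_extent=tuple(params["output_extent"]))
                reg.scheme_ = scheme
                reg.model_ = load_model(fh[f"stage_{s}"], spec)
                est.stages_.append(reg)
            est.histories_ = []
            return est
        est = SigmaPredictor(spec=spec, **params)
        est.scheme_ = scheme
        est.model_ = load_model(fh["model"], spec)
        return est


@dataclass
class RunConfig:
    """End-to-end pipeline configuration with lossless YAML round-trip.

    Unknown keys (top level or inside ``simulation``) are rejected so typos
    fail loudly.  The seed is mandatory: every random choice in a run is
    derived from it.
    """

    seed: int
    output_dir: str = "."
    verbosity: int = 1
    simulation: dict = field(default_factory=dict)
    processing: dict = field(default_factory=dict)
    reconstruction: dict = field(default_factory=dict)
    training: dict = field(default_factory=dict)
    metrics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        valid_sim = {f.name for f in dataclasses.fields(SimConfig)}
        unknown = set(self.simulation) - valid_sim
        if unknown:
            raise ValueError(f"unknown simulation keys: {sorted(unknown)}")

    def sim_config(self, **overrides) -> SimConfig:
        kwargs = dict(self.simulation)
        kwargs.update(overrides)
        kwargs.setdefault("rng_seed", self.seed)
        return SimConfig(**{k: (tuple(v) if isinstance(v, list) else v)
                            for k, v in kwargs.items()})

    def to_yaml(self, path: str | Path | None = None) -> str:
        text = yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source: str | Path) -> "RunConfig":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        data = yaml.safe_load(text)
        if not isinstance(data, dict):
            raise ValueError("config must be a YAML mapping")
        valid = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - valid
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "seed" not in data:
            raise ValueError("config must declare a seed")
        return cls(**data)

    def digest(self) -> str:
        """Short hash identifying the configuration (for run logs)."""
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:12]
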