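"""Reading raw frames and metadata, writing reduced outputs, and the
on-disk background library.

Raw frames come from single-page integer TIFF files or rank-2/rank-3
HDF5 datasets (a rank-3 stack yields one frame per slice, all sharing
one metadata sidecar).  Scalar measurement metadata lives in a YAML
sidecar, one file per measurement; HDF5-internal attributes with the
same keys are honored, but the sidecar wins on conflict.  Reduced 2D
outputs are written as HDF5 with NeXus-flavored attributes; 1D curves
as 3-column ASCII and as an HDF5 group following NXcanSAS naming
(``Q``, ``I``, ``Idev``).

All HDF5 objects are written with timestamp tracking disabled so that
re-running a reduction with the same inputs reproduces the output files
byte for byte.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import tifffile
import yaml

from .averaging import Curve1D
from .errors import ConfigurationError, FormatError, MetadataError
from .frames import CorrectionMap, DetectorFrame, MeasurementMeta
from .geometry import Geometry
from .pipeline import BackgroundEntry

#: Sidecar keys mapped onto MeasurementMeta fields.
SIDECAR_KEYS = {
    "time_s": "time_s",
    "flux_incident": "flux_incident",
    "flux_emergent": "flux_emergent",
    "transmission": "transmission",
    "deadtime_s": "deadtime_s",
    "thickness_m": "thickness_m",
    "volume_fraction": "volume_fraction",
    "role": "role",
    "container_id": "container_id",
    "time_s_sigma": "time_sigma",
    "flux_incident_sigma": "flux_incident_sigma",
    "flux_emergent_sigma": "flux_emergent_sigma",
    "transmission_sigma": "transmission_sigma",
    "thickness_m_sigma": "thickness_sigma",
    "volume_fraction_sigma": "volume_fraction_sigma",
}

_UNITS_LABEL = {
    "raw_counts": "counts",
    "rate": "counts/s",
    "normalized": "dimensionless",
    "absolute": "1/(m sr)",
}


def _meta_from_mapping(mapping: dict) -> MeasurementMeta:
    kwargs = {}
    for key, value in mapping.items():
        if key in SIDECAR_KEYS and value is not None:
            field_name = SIDECAR_KEYS[key]
            kwargs[field_name] = value if field_name in ("role", "container_id") \
                else float(value)
    return MeasurementMeta(**kwargs)


def read_sidecar(path) -> dict:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise MetadataError(f"sidecar {path} is not a mapping")
    return data


def _find_dataset(h5: h5py.File, name: str | None):
    if name is not None:
        if name not in h5:
            raise FormatError(f"dataset {name!r} not found")
        return h5[name]
    found = []

    def visit(_, obj):
        if isinstance(obj, h5py.Dataset) and obj.ndim in (2, 3):
            found.append(obj)

    h5.visititems(visit)
    if not found:
        raise FormatError("no rank-2 or rank-3 dataset found in HDF5 file")
    return found[0]


def read_frame(path, sidecar_path=None, dataset: str | None = None,
               required: tuple[str, ...] = ()):
    """DS: read raw detector counts plus metadata.

    Returns a single :class:`DetectorFrame` for a 2D input, or a list
    of frames for a rank-3 HDF5 stack (all sharing one sidecar).
    Counts must be non-negative; *required* lists sidecar keys that
    must be present for the configured corrections.
    """
    path = Path(path)
    attrs_meta: dict = {}
    if path.suffix.lower() in (".tif", ".tiff"):
        data = tifffile.imread(path)
        if data.ndim != 2:
            raise FormatError(f"{path}: expected a single 2D TIFF page")
        stack = None
    else:
        with h5py.File(path, "r") as h5:
            ds = _find_dataset(h5, dataset)
            data = ds[()]
            attrs_meta = {k: v for k, v in ds.attrs.items() if k in SIDECAR_KEYS}
            attrs_meta.update(
                {k: v for k, v in h5.attrs.items() if k in SIDECAR_KEYS}
            )
        if data.ndim == 3:
            stack = [np.asarray(s) for s in data]
        elif data.ndim == 2:
            stack = None
        else:
            raise FormatError(f"{path}: dataset rank {data.ndim} unsupported")

    sidecar: dict = {}
    if sidecar_path is not None:
        sidecar = read_sidecar(sidecar_path)
        clash = {
            k for k in sidecar
            if k in attrs_meta and not np.isclose(
                float(sidecar[k]), float(attrs_meta[k])
            )
        } if attrs_meta else set()
        if clash:
            warnings.warn(
                f"sidecar overrides HDF5 attributes for keys {sorted(clash)}"
            )
    merged = {**attrs_meta, **sidecar}
    missing = [k for k in required if k not in merged or merged[k] is None]
    if missing:
        raise MetadataError(
            f"sidecar for {path} is missing required keys: {', '.join(missing)}"
        )
    meta = _meta_from_mapping(merged)

    def build(arr) -> DetectorFrame:
        arr = np.asarray(arr)
        if np.any(arr < 0):
            i, j = np.argwhere(arr < 0)[0]
            raise FormatError(
                f"{path}: negative counts at pixel ({i}, {j}); raw frames "
                "must be non-negative"
            )
        return DetectorFrame(
            signal=arr.astype(float), uncertainty=np.zeros(arr.shape),
            meta=meta, units_state="raw_counts", provenance=("DS",),
        )

    if stack is not None:
        return [build(a) for a in stack]
    return build(data)


def read_mask(path) -> np.ndarray:
    """Read a mask image: 2D uint8, nonzero = masked."""
    arr = tifffile.imread(path) if str(path).lower().endswith((".tif", ".tiff")) \
        else _read_h5_array(path)
    if arr.ndim != 2:
        raise FormatError("mask must be a 2D image")
    return np.asarray(arr) != 0


def read_flatfield(path) -> CorrectionMap:
    """Read a flatfield correction matrix (float image, mean ~ 1)."""
    arr = tifffile.imread(path) if str(path).lower().endswith((".tif", ".tiff")) \
        else _read_h5_array(path)
    if arr.ndim != 2:
        raise FormatError("flatfield must be a 2D image")
    return CorrectionMap(values=np.asarray(arr, dtype=float), name="FF",
                         apply="multiply")


def _read_h5_array(path) -> np.ndarray:
    with h5py.File(path, "r") as h5:
        return _find_dataset(h5, None)[()]


def _dset(group, name, data):
    return group.create_dataset(name, data=data, track_times=False)


def write_frame(frame: DetectorFrame, path, final: bool = False) -> None:
    """Write a frame as HDF5: signal/uncertainty/mask + provenance.

    The read-back round trip (:func:`read_frame_output`) is lossless.
    """
    if final and frame.units_state != "absolute":
        warnings.warn(
            f"writing a final output in units_state {frame.units_state!r}, "
            "not absolute"
        )
    with h5py.File(path, "w") as h5:
        d = _dset(h5, "signal", frame.signal)
        d.attrs["units"] = _UNITS_LABEL[frame.units_state]
        _dset(h5, "uncertainty", frame.uncertainty)
        _dset(h5, "mask", frame.mask.astype(np.uint8))
        h5.attrs["units_state"] = frame.units_state
        h5.attrs["provenance"] = list(frame.provenance)
        meta = {
            k: getattr(frame.meta, v) for k, v in SIDECAR_KEYS.items()
            if getattr(frame.meta, v) is not None
        }
        h5.attrs["meta"] = yaml.safe_dump(meta, sort_keys=True)


def read_frame_output(path) -> DetectorFrame:
    """Read back a frame written by :func:`write_frame`."""
    with h5py.File(path, "r") as h5:
        meta = _meta_from_mapping(yaml.safe_load(h5.attrs["meta"]))
        return DetectorFrame(
            signal=h5["signal"][()],
            uncertainty=h5["uncertainty"][()],
            mask=h5["mask"][()].astype(bool),
            meta=meta,
            units_state=str(h5.attrs["units_state"]),
            provenance=tuple(str(p) for p in h5.attrs["provenance"]),
        )


def write_curve_ascii(curve: Curve1D, path) -> None:
    """3-column ASCII export: abscissa, intensity, sigma.

    The reported sigma is the larger of the propagated and the
    scatter-based estimator per bin; both are kept in the HDF5 export.
    Exactly one non-comment row per bin.
    """
    label = "Q (1/nm)" if curve.mode == "azimuthal" else "chi (rad)"
    header = (
        f"# saxsred reduced curve ({curve.mode})\n"
        f"# columns: {label}\tI ({curve.units})\tsigma (max of propagated, SEM)\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        sig = curve.sigma
        for x, i, s in zip(curve.abscissa, curve.intensity, sig):
            fh.write(f"{x:.9e}\t{i:.9e}\t{s:.9e}\n")


def write_curve_h5(curve: Curve1D, path) -> None:
    """NXcanSAS-style HDF5 export of a 1D curve."""
    with h5py.File(path, "w") as h5:
        entry = h5.create_group("sasentry1")
        entry.attrs["NX_class"] = "NXentry"
        data = entry.create_group("sasdata1")
        data.attrs["NX_class"] = "NXdata"
        data.attrs["signal"] = "I"
        data.attrs["I_axes"] = "Q" if curve.mode == "azimuthal" else "chi"
        q = _dset(data, "Q" if curve.mode == "azimuthal" else "chi",
                  curve.abscissa)
        q.attrs["units"] = "1/nm" if curve.mode == "azimuthal" else "rad"
        i = _dset(data, "I", curve.intensity)
        i.attrs["units"] = curve.units
        _dset(data, "Idev", curve.sigma)
        _dset(data, "Idev_propagated", curve.sigma_prop)
        _dset(data, "Idev_sem", curve.sigma_sem)
        _dset(data, "n_pix", curve.n_pix)
        _dset(data, "edges", curve.edges)


def read_curve_h5(path) -> Curve1D:
    with h5py.File(path, "r") as h5:
        data = h5["sasentry1/sasdata1"]
        mode = "azimuthal" if "Q" in data else "radial"
        return Curve1D(
            abscissa=data["Q" if mode == "azimuthal" else "chi"][()],
            edges=data["edges"][()],
            intensity=data["I"][()],
            sigma_prop=data["Idev_propagated"][()],
            sigma_sem=data["Idev_sem"][()],
            n_pix=data["n_pix"][()],
            mode=mode,
            units=str(data["I"].attrs.get("units", "")),
        )


def write_output(obj, path, format: str | None = None,
                 final: bool = False) -> None:
    """Write a frame or curve, dispatching on type and *format*."""
    if isinstance(obj, DetectorFrame):
        write_frame(obj, path, final=final)
    elif isinstance(obj, Curve1D):
        if format == "ascii" or str(path).endswith((".dat", ".txt", ".csv")):
            write_curve_ascii(obj, path)
        else:
            write_curve_h5(obj, path)
    else:
        raise TypeError(f"cannot write object of type {type(obj).__name__}")


# -- background library ---------------------------------------------------


def library_add(directory, entry: BackgroundEntry, name: str) -> Path:
    """Store a background entry as one HDF5 file in the library directory."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    path = directory / f"{name}.h5"
    with h5py.File(path, "w") as h5:
        h5.attrs["energy_kev"] = entry.energy_kev
        h5.attrs["container_id"] = entry.container_id
        h5.attrs["provenance"] = list(entry.provenance)
        if isinstance(entry.payload, DetectorFrame):
            h5.attrs["kind"] = "frame"
            grp = h5.create_group("payload")
            _dset(grp, "signal", entry.payload.signal)
            _dset(grp, "uncertainty", entry.payload.uncertainty)
            _dset(grp, "mask", entry.payload.mask.astype(np.uint8))
            grp.attrs["units_state"] = entry.payload.units_state
            grp.attrs["provenance"] = list(entry.payload.provenance)
        else:
            h5.attrs["kind"] = "curve"
            grp = h5.create_group("payload")
            _dset(grp, "Q", entry.payload.abscissa)
            _dset(grp, "edges", entry.payload.edges)
            _dset(grp, "I", entry.payload.intensity)
            _dset(grp, "Idev_propagated", entry.payload.sigma_prop)
            _dset(grp, "Idev_sem", entry.payload.sigma_sem)
            _dset(grp, "n_pix", entry.payload.n_pix)
            grp.attrs["units"] = entry.payload.units
    return path


def library_load(path) -> BackgroundEntry:
    with h5py.File(path, "r") as h5:
        kind = str(h5.attrs["kind"])
        grp = h5["payload"]
        if kind == "frame":
            payload = DetectorFrame(
                signal=grp["signal"][()],
                uncertainty=grp["uncertainty"][()],
                mask=grp["mask"][()].astype(bool),
                units_state=str(grp.attrs["units_state"]),
                provenance=tuple(str(p) for p in grp.attrs["provenance"]),
            )
        else:
            payload = Curve1D(
                abscissa=grp["Q"][()], edges=grp["edges"][()],
                intensity=grp["I"][()],
                sigma_prop=grp["Idev_propagated"][()],
                sigma_sem=grp["Idev_sem"][()], n_pix=grp["n_pix"][()],
                mode="azimuthal", units=str(grp.attrs.get("units", "")),
            )
        return BackgroundEntry(
            payload=payload,
            energy_kev=float(h5.attrs["energy_kev"]),
            container_id=str(h5.attrs["container_id"]),
            provenance=tuple(str(p) for p in h5.attrs["provenance"]),
        )


def library_list(directory) -> list[dict]:
    """Summaries of every entry in a library directory."""
    out = []
    for path in sorted(Path(directory).glob("*.h5")):
        with h5py.File(path, "r") as h5:
            out.append({
                "name": path.stem,
                "kind": str(h5.attrs["kind"]),
                "energy_kev": float(h5.attrs["energy_kev"]),
                "container_id": str(h5.attrs["container_id"]),
            })
    return out


# -- run configuration -----------------------------------------------------


@dataclass
class RunConfig:
    """A full reduction run description, loaded from YAML."""

    geometry: Geometry
    measurements: dict            # role -> list of {"frames": [...], "sidecar": ...}
    output_dir: Path
    mask_path: Path | None = None
    flatfield_path: Path | None = None
    dark_path: Path | None = None
    dark_sidecar: Path | None = None
    steps: dict = field(default_factory=dict)       # role -> list of codes
    cal_factor: float = 1.0
    cal_sigma: float = 0.0
    use_emergent_flux: bool = False
    enable_self_absorption: bool = False
    strict: bool = False
    seed: int = 0
    energy_kev: float | None = None
    nbins: int = 100


def load_run_config(path) -> RunConfig:
    """Parse and validate a YAML run configuration."""
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigurationError(f"{path} is not a YAML mapping")
    base = path.parent

    def resolve(p):
        p = Path(p)
        return p if p.is_absolute() else base / p

    try:
        g = raw["geometry"]
        geometry = Geometry(
            distance_m=float(g["distance_m"]),
            pixel_pitch_m=tuple(float(v) for v in g["pixel_pitch_m"]),
            beam_center=tuple(float(v) for v in g["beam_center"]),
            wavelength_nm=float(g["wavelength_nm"]),
            sensor_optical_depth=float(g.get("sensor_optical_depth", 0.0)),
            polarization_fraction=float(g.get("polarization_fraction", 0.5)),
        )
        measurements = raw["measurements"]
    except KeyError as exc:
        raise ConfigurationError(f"run config missing key {exc}") from exc

    for role, entries in measurements.items():
        if role not in ("A", "B", "C"):
            raise ConfigurationError(f"unknown role {role!r} in measurements")
        if not entries:
            raise ConfigurationError(f"role {role} maps to no measurements")
        for entry in entries:
            for p in list(np.atleast_1d(entry["frames"])) + [entry.get("sidecar")]:
                if p is not None and not resolve(p).exists():
                    raise ConfigurationError(f"referenced file missing: {p}")

    def opt_path(key):
        p = raw.get(key)
        if p is None:
            return None
        p = resolve(p)
        if not p.exists():
            raise ConfigurationError(f"referenced file missing: {p}")
        return p

    return RunConfig(
        geometry=geometry,
        measurements={
            role: [
                {
                    "frames": [resolve(p) for p in np.atleast_1d(e["frames"])],
                    "sidecar": resolve(e["sidecar"]) if e.get("sidecar") else None,
                }
                for e in entries
            ]
            for role, entries in measurements.items()
        },
        output_dir=resolve(raw.get("output_dir", "reduced")),
        mask_path=opt_path("mask"),
        flatfield_path=opt_path("flatfield"),
        dark_path=opt_path("dark"),
        dark_sidecar=opt_path("dark_sidecar"),
        steps=raw.get("steps", {}),
        cal_factor=float(raw.get("cal_factor", 1.0)),
        cal_sigma=float(raw.get("cal_sigma", 0.0)),
        use_emergent_flux=bool(raw.get("use_emergent_flux", False)),
        enable_self_absorption=bool(raw.get("enable_self_absorption", False)),
        strict=bool(raw.get("strict", False)),
        seed=int(raw.get("seed", 0)),
        energy_kev=(float(raw["energy_kev"]) if "energy_kev" in raw else None),
        nbins=int(raw.get("nbins", 100)),
    )
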