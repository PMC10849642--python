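"""On-disk formats and run configuration.

Volumes live in multipage TIFF or HDF5 (one rank-3 dataset per channel);
object tables and result tables are plain CSV; run configuration is YAML.
No numerics here beyond exact voxel↔μm unit conversion.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import tifffile
import yaml

from .objects import OBJECT_CLASSES, ObjectRecord
from .volumes import ImageVolume, LayerVolume

__all__ = [
    "RunConfig",
    "read_volume",
    "write_volume",
    "read_layer_volume",
    "read_object_table",
    "write_object_table",
    "read_anchor_table",
    "write_anchor_table",
    "write_results",
    "load_config",
    "save_config",
]

log = logging.getLogger(__name__)

_TIFF_SUFFIXES = {".tif", ".tiff"}
_HDF5_SUFFIXES = {".h5", ".hdf5", ".he5"}


@dataclass
class RunConfig:
    """Geometry/binning parameters of a quantification run.

    Defaults encode the analysis bands: a 3-μm vessel-surface band for
    surface tau, 10-μm along-vessel bins, a 30-μm neighborhood for object
    densities, and a 100-μm export radius around each vessel.
    """

    surface_band_um: float = 3.0
    bin_length_um: float = 10.0
    density_radius_um: float = 30.0
    export_radius_um: float = 100.0
    radial_step_um: float = 2.0
    n_deciles: int = 10
    decile_population: str = "donor"  # "donor" | "vessel" | "global"
    seed: int = 0
    min_object_size: int = 5
    max_object_size: int | None = None
    overlap_fraction: float = 0.5
    connectivity: int = 26

    def violations(self) -> list[str]:
        """Validate; returns a list of human-readable violations (empty = ok)."""
        out = []
        if not 0 < self.surface_band_um <= self.density_radius_um:
            out.append(
                f"need 0 < surface_band_um ({self.surface_band_um}) <= "
                f"density_radius_um ({self.density_radius_um})"
            )
        if not self.density_radius_um <= self.export_radius_um:
            out.append(
                f"need density_radius_um ({self.density_radius_um}) <= "
                f"export_radius_um ({self.export_radius_um})"
            )
        if self.bin_length_um <= 0:
            out.append(f"bin_length_um must be > 0, got {self.bin_length_um}")
        if self.radial_step_um <= 0:
            out.append(f"radial_step_um must be > 0, got {self.radial_step_um}")
        if self.n_deciles < 2:
            out.append(f"n_deciles must be >= 2, got {self.n_deciles}")
        if self.decile_population not in ("donor", "vessel", "global"):
            out.append(f"unknown decile_population {self.decile_population!r}")
        if self.connectivity not in (6, 26):
            out.append(f"connectivity must be 6 or 26, got {self.connectivity}")
        if not 0 < self.overlap_fraction <= 1:
            out.append(f"overlap_fraction must be in (0, 1], got {self.overlap_fraction}")
        return out

    def validate(self) -> None:
        v = self.violations()
        if v:
            raise ValueError("invalid configuration: " + "; ".join(v))


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**raw)


def save_config(config: RunConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dataclasses.asdict(config), fh, sort_keys=True)


# ---------------------------------------------------------------------------
# volumes


def _check_voxel_size(voxel_size) -> tuple[float, float, float]:
    vs = tuple(float(v) for v in voxel_size)
    if len(vs) != 3 or any(v <= 0 for v in vs):
        raise ValueError(f"voxel_size must be three positive μm values, got {voxel_size}")
    return vs


def read_volume(
    path: str | Path,
    channel: str = "",
    voxel_size=(1.0, 1.0, 1.0),
    dataset: str | None = None,
) -> ImageVolume:
    """Read a rank-3 volume from multipage TIFF or HDF5.

    ``voxel_size`` is ``(z, y, x)`` μm and must be supplied explicitly —
    it is metadata the raw formats do not reliably carry. Integer data is
    widened losslessly to float64.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    vs = _check_voxel_size(voxel_size)
    if path.suffix.lower() in _TIFF_SUFFIXES:
        data = tifffile.imread(path)
    elif path.suffix.lower() in _HDF5_SUFFIXES:
        with h5py.File(path, "r") as fh:
            if dataset is None:
                keys = sorted(k for k in fh.keys() if isinstance(fh[k], h5py.Dataset))
                if not keys:
                    raise ValueError(f"no dataset found in {path}")
                dataset = keys[0]
            data = fh[dataset][()]
            if "voxel_size_um" in fh[dataset].attrs:
                vs = _check_voxel_size(fh[dataset].attrs["voxel_size_um"])
    else:
        raise ValueError(f"unsupported volume format: {path.suffix!r}")
    data = np.asarray(data)
    if data.ndim != 3:
        raise ValueError(f"volume rank != 3 in {path}: rank {data.ndim}")
    if np.issubdtype(data.dtype, np.integer):
        data = data.astype(np.float64)
    return ImageVolume(data, vs, channel)


def write_volume(volume: ImageVolume, path: str | Path, dataset: str = "data") -> Path:
    """Write a volume to TIFF or HDF5 (by suffix); round-trips bit-identically."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.suffix.lower() in _TIFF_SUFFIXES:
        tifffile.imwrite(path, volume.data, photometric="minisblack")
    elif path.suffix.lower() in _HDF5_SUFFIXES:
        with h5py.File(path, "w") as fh:
            # track_times=False keeps file bytes reproducible across runs
            ds = fh.create_dataset(dataset, data=volume.data, track_times=False)
            ds.attrs["voxel_size_um"] = volume.voxel_size
            ds.attrs["channel"] = volume.channel
    else:
        raise ValueError(f"unsupported volume format: {path.suffix!r}")
    return path


def read_layer_volume(path: str | Path, voxel_size=(1.0, 1.0, 1.0)) -> LayerVolume:
    vol = read_volume(path, channel="layers", voxel_size=voxel_size)
    return LayerVolume(vol.data.astype(np.int64), vol.voxel_size)


# ---------------------------------------------------------------------------
# object tables

_UM_COLS = ["centroid_z_um", "centroid_y_um", "centroid_x_um"]
_VOX_COLS = ["centroid_z_vox", "centroid_y_vox", "centroid_x_vox"]


def read_object_table(
    path: str | Path,
    voxel_size: tuple[float, float, float] | None = None,
) -> list[ObjectRecord]:
    """Read an object table CSV into records, dropping ``noise`` rows.

    Centroid units are declared by the header: ``centroid_{z,y,x}_um``
    (used as-is) or ``centroid_{z,y,x}_vox`` (multiplied exactly by
    ``voxel_size``, which is then required).
    """
    df = pd.read_csv(path)
    if all(c in df.columns for c in _UM_COLS):
        cent = df[_UM_COLS].to_numpy(dtype=float)
    elif all(c in df.columns for c in _VOX_COLS):
        if voxel_size is None:
            raise ValueError("voxel-unit centroids require voxel_size")
        cent = df[_VOX_COLS].to_numpy(dtype=float) * np.asarray(
            _check_voxel_size(voxel_size)
        )
    else:
        raise ValueError(
            f"object table must declare centroid columns {_UM_COLS} or {_VOX_COLS}"
        )
    bad = set(df["object_class"].astype(str)) - set(OBJECT_CLASSES)
    if bad:
        raise ValueError(f"unknown object class label(s): {sorted(bad)}")
    records: list[ObjectRecord] = []
    n_noise = 0
    for i, row in enumerate(df.itertuples(index=False)):
        if row.object_class == "noise":
            n_noise += 1
            continue
        def _opt(name, cast):
            v = getattr(row, name, None)
            return None if v is None or (isinstance(v, float) and np.isnan(v)) else cast(v)

        records.append(
            ObjectRecord(
                object_id=int(getattr(row, "object_id", len(records) + 1)),
                object_class=str(row.object_class),
                centroid_um=cent[i],
                voxel_count=int(row.voxel_count),
                layer=int(getattr(row, "layer", 0)),
                vessel_id=_opt("vessel_id", lambda v: int(float(v))),
                distance_um=_opt("distance_um", float),
                arc_um=_opt("arc_um", float),
                nft_positive=_opt("nft_positive", lambda v: bool(v) if not isinstance(v, str) else v == "True"),
            )
        )
    if n_noise:
        log.info("dropped %d noise objects from %s", n_noise, path)
    return records


def write_object_table(records: list[ObjectRecord], path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    rows = [
        {
            "object_id": r.object_id,
            "object_class": r.object_class,
            "centroid_z_um": r.centroid_um[0],
            "centroid_y_um": r.centroid_um[1],
            "centroid_x_um": r.centroid_um[2],
            "voxel_count": r.voxel_count,
            "layer": r.layer,
            "vessel_id": r.vessel_id,
            "distance_um": r.distance_um,
            "arc_um": r.arc_um,
            "nft_positive": r.nft_positive,
        }
        for r in records
    ]
    cols = [
        "object_id", "object_class", "centroid_z_um", "centroid_y_um",
        "centroid_x_um", "voxel_count", "layer", "vessel_id",
        "distance_um", "arc_um", "nft_positive",
    ]
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)
    return path


# ---------------------------------------------------------------------------
# anchors and result tables


def write_anchor_table(readings: dict[str, np.ndarray], path: str | Path) -> Path:
    """Write anchor readings as (category, depth, reading) rows.

    ``readings`` maps category → array of shape (n_depths, n_per_depth).
    """
    rows = []
    for cat in ("background", "autofluorescence", "positive"):
        arr = np.asarray(readings[cat], dtype=float)
        for d in range(arr.shape[0]):
            for v in arr[d]:
                rows.append({"category": cat, "depth": d, "reading": v})
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows, columns=["category", "depth", "reading"]).to_csv(path, index=False)
    return path


def read_anchor_table(path: str | Path) -> dict[str, np.ndarray]:
    df = pd.read_csv(path)
    out = {}
    for cat, grp in df.groupby("category"):
        depths = sorted(grp["depth"].unique())
        out[cat] = np.stack(
            [grp.loc[grp["depth"] == d, "reading"].to_numpy(dtype=float) for d in depths]
        )
    return out


def write_results(tables: dict[str, pd.DataFrame], outdir: str | Path) -> dict[str, Path]:
    """Write each result table to ``<outdir>/<name>.csv`` with stable columns.

    Deterministic: two writes of equal tables produce identical bytes.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = {}
    for name, df in tables.items():
        p = outdir / f"{name}.csv"
        df.to_csv(p, index=False, float_format="%.10g")
        written[name] = p
    return written
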