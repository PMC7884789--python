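"""Readers and writers for the pipeline's on-disk formats, plus run config.

Contracts (vendor-neutral, since microscope exports vary):

* spectral cube — multi-page TIFF, one page per wavelength, with a JSON
  sidecar ``{"excitation_nm": ..., "wavelengths_nm": [...]}`` next to it;
* FLIM cube — HDF5 with dataset ``/decays`` of shape (ny, nx, L) and
  attributes ``Ts_ns``, ``L`` and ``channel``;
* single spectrum — CSV with columns ``wavelength_nm,intensity`` and the
  excitation recorded on a leading comment line.

All round-trips are lossless for integer data and validated on read.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import tifffile
import yaml

from .flim import FLIMImage
from .presets import FlimChannel
from .spectra import EmissionSpectrum, SpectralImage

__all__ = [
    "RunConfig",
    "read_spectral_cube",
    "write_spectral_cube",
    "read_flim_cube",
    "write_flim_cube",
    "read_spectrum_csv",
    "write_spectrum_csv",
]


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_spectral_cube(img: SpectralImage, path) -> Path:
    """Write a cube as multi-page TIFF (one page per wavelength) + sidecar."""
    path = Path(path)
    tifffile.imwrite(path, np.moveaxis(img.cube, 2, 0), photometric="minisblack")
    sidecar = _sidecar_path(path)
    sidecar.write_text(json.dumps({
        "excitation_nm": img.excitation,
        "wavelengths_nm": img.wavelengths.tolist(),
    }))
    return path


def read_spectral_cube(path) -> SpectralImage:
    path = Path(path)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FileNotFoundError(f"missing sidecar {sidecar} for spectral cube")
    meta = json.loads(sidecar.read_text())
    try:
        wavelengths = np.asarray(meta["wavelengths_nm"], dtype=float)
        excitation = float(meta["excitation_nm"])
    except KeyError as exc:
        raise KeyError(f"sidecar {sidecar} lacks required key {exc}") from exc
    pages = tifffile.imread(path)
    if pages.ndim == 2:
        pages = pages[None]
    if pages.shape[0] != wavelengths.size:
        raise ValueError(
            f"cube has {pages.shape[0]} pages but sidecar lists "
            f"{wavelengths.size} wavelengths"
        )
    return SpectralImage(np.moveaxis(pages, 0, 2), wavelengths, excitation)


def write_flim_cube(img: FLIMImage, path) -> Path:
    path = Path(path)
    with h5py.File(path, "w") as h5:
        ds = h5.create_dataset("decays", data=img.decays)
        ds.attrs["Ts_ns"] = img.ts
        ds.attrs["L"] = img.L
        ds.attrs["channel"] = img.channel.value
    return path


def read_flim_cube(path) -> FLIMImage:
    path = Path(path)
    with h5py.File(path, "r") as h5:
        if "decays" not in h5:
            raise KeyError(f"{path} has no /decays dataset")
        ds = h5["decays"]
        for attr in ("Ts_ns", "L", "channel"):
            if attr not in ds.attrs:
                raise KeyError(f"{path}:/decays lacks attribute {attr!r}")
        decays = ds[()]
        ts = float(ds.attrs["Ts_ns"])
        L = int(ds.attrs["L"])
        channel = FlimChannel(str(ds.attrs["channel"]))
    if ts <= 0:
        raise ValueError(f"{path}: Ts_ns must be positive, got {ts}")
    if decays.ndim != 3 or decays.shape[2] != L:
        raise ValueError(
            f"{path}: L attribute {L} does not match decay axis "
            f"{decays.shape[-1] if decays.ndim == 3 else decays.shape}"
        )
    if np.any(decays < 0):
        raise ValueError(f"{path}: negative photon counts")
    return FLIMImage(decays, ts, channel)


def write_spectrum_csv(spectrum: EmissionSpectrum, path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# excitation_nm: {spectrum.excitation}\n")
        pd.DataFrame({
            "wavelength_nm": spectrum.wavelengths,
            "intensity": spectrum.intensities,
        }).to_csv(fh, index=False)
    return path


def read_spectrum_csv(path, excitation: float | None = None) -> EmissionSpectrum:
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("# excitation_nm:"):
            excitation = float(first.split(":", 1)[1])
            df = pd.read_csv(fh)
        else:
            fh.seek(0)
            df = pd.read_csv(fh)
    if excitation is None:
        raise ValueError(f"{path}: excitation not recorded; pass excitation=")
    return EmissionSpectrum(df["wavelength_nm"].to_numpy(),
                            df["intensity"].to_numpy(), excitation)


# ---------------------------------------------------------------------------
# run configuration

@dataclass
class RunConfig:
    """Configuration of a full synthetic-cohort pipeline run.

    Defaults are the pipeline's canonical constants: chi-squared window
    0.8-1.2, residual bound 4, ellipsoid mass 0.60, SHG-Int thresholds
    2.5 / 22, Coll-Int threshold 28 and 32x FLIM pixel binning.
    """

    seed: int = 0
    n_control: int = 10
    n_grade1: int = 7
    n_grade2: int = 8
    # FLIM
    flim_L: int = 256
    flim_Ts_ns: float = 12.5 / 256
    flim_bin_factor: int = 32
    chi2_window: tuple[float, float] = (0.8, 1.2)
    residual_bound: float = 4.0
    # discrimination
    ellipsoid_mass: float = 0.60
    shg_thresholds: tuple[float, float] = (2.5, 22.0)
    coll_int_threshold: float = 28.0
    indeterminate: str = "exclude"
    # generation scale
    image_shape: tuple[int, int] = (8, 8)
    flim_shape: tuple[int, int] = (16, 16)
    photons_per_pixel: float = 1e5
    fit_restarts: int = 2
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if not 0 < self.ellipsoid_mass < 1:
            raise ValueError("ellipsoid_mass must lie in (0, 1)")
        if self.chi2_window[0] >= self.chi2_window[1]:
            raise ValueError("chi2 window must be an increasing interval")
        if self.flim_Ts_ns <= 0 or self.flim_L < 64:
            raise ValueError("invalid FLIM timing parameters")
        if self.indeterminate not in ("exclude", "error"):
            raise ValueError("indeterminate must be 'exclude' or 'error'")
        if min(self.n_control, self.n_grade1, self.n_grade2) < 0:
            raise ValueError("cohort counts must be non-negative")

    def to_yaml(self, path) -> Path:
        path = Path(path)
        d = dataclasses.asdict(self)
        d["chi2_window"] = list(self.chi2_window)
        d["shg_thresholds"] = list(self.shg_thresholds)
        d["image_shape"] = list(self.image_shape)
        d["flim_shape"] = list(self.flim_shape)
        path.write_text(yaml.safe_dump(d, sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("chi2_window", "shg_thresholds", "image_shape", "flim_shape"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)
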