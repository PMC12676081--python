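"""File formats: TIFF cubes + JSON sidecars, label images, CSV spectra.

* FLIM cube: multi-page TIFF, one page per time bin, 16-bit counts, with a
  JSON sidecar carrying bin width, period, pixel size, excitation and seed.
* Masks: single-page TIFF/PNG label image plus a JSON class map.
* Spectra: CSV with header ``wavenumber_cm1,intensity``, ascending axis.
* Ground truth and reports: JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile

from .flim import FLIMCube
from .raman import RamanSpectrum

__all__ = [
    "save_cube", "load_cube",
    "save_mask", "load_mask",
    "save_spectrum", "load_spectrum",
    "save_json", "load_json",
]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def save_cube(path: str | Path, cube: FLIMCube, seed: int | None = None) -> None:
    path = Path(path)
    counts = np.asarray(cube.counts)
    if counts.max(initial=0) > np.iinfo(np.uint16).max:
        raise ValueError("counts exceed 16-bit range")
    tifffile.imwrite(path, counts.astype(np.uint16))
    meta = {
        "bin_width_ns": cube.bin_width_ns,
        "period_ns": cube.period_ns,
        "pixel_size_um": cube.pixel_size_um,
        "excitation_nm": cube.excitation_nm,
        "seed": seed,
    }
    _sidecar(path).write_text(json.dumps(meta, indent=2, sort_keys=True))


def load_cube(path: str | Path) -> FLIMCube:
    path = Path(path)
    counts = tifffile.imread(path)
    meta = json.loads(_sidecar(path).read_text())
    return FLIMCube(
        counts=counts,
        bin_width_ns=meta["bin_width_ns"],
        period_ns=meta["period_ns"],
        pixel_size_um=meta.get("pixel_size_um", 1.0),
        excitation_nm=meta.get("excitation_nm", 440.0),
    )


def save_mask(path: str | Path, mask: np.ndarray, pixel_size_um: float,
              class_map: dict[str, int] | None = None) -> None:
    path = Path(path)
    arr = np.asarray(mask).astype(np.uint8)
    if path.suffix.lower() == ".png":
        iio.imwrite(path, arr)
    else:
        tifffile.imwrite(path, arr)
    meta = {"pixel_size_um": pixel_size_um, "class_map": class_map or {}}
    _sidecar(path).write_text(json.dumps(meta, indent=2, sort_keys=True))


def load_mask(path: str | Path) -> tuple[np.ndarray, float, dict[str, int]]:
    path = Path(path)
    if path.suffix.lower() == ".png":
        arr = np.asarray(iio.imread(path))
    else:
        arr = tifffile.imread(path)
    meta = json.loads(_sidecar(path).read_text())
    return arr, float(meta["pixel_size_um"]), dict(meta.get("class_map", {}))


def save_spectrum(path: str | Path, spectrum: RamanSpectrum) -> None:
    path = Path(path)
    lines = ["wavenumber_cm1,intensity"]
    for w, y in zip(spectrum.wavenumber_cm1, spectrum.intensity):
        lines.append(f"{w:.6g},{y:.8g}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    _sidecar(path).write_text(json.dumps(
        {"excitation_nm": spectrum.excitation_nm, "calibrated": spectrum.calibrated},
        indent=2, sort_keys=True))


def load_spectrum(path: str | Path, excitation_nm: float | None = None) -> RamanSpectrum:
    path = Path(path)
    data = np.loadtxt(path, delimiter=",", skiprows=1)
    meta = {}
    if _sidecar(path).exists():
        meta = json.loads(_sidecar(path).read_text())
    wl = excitation_nm if excitation_nm is not None else meta.get("excitation_nm")
    if wl is None:
        raise ValueError("excitation wavelength neither passed nor in sidecar")
    return RamanSpectrum(
        wavenumber_cm1=data[:, 0], intensity=data[:, 1],
        excitation_nm=float(wl), calibrated=bool(meta.get("calibrated", False)),
    )


class _NumpyEncoder(json.JSONEncoder):
    def default(self, obj):
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (np.bool_,)):
            return bool(obj)
        return super().default(obj)


def save_json(path: str | Path, obj) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, cls=_NumpyEncoder))


def load_json(path: str | Path):
    return json.loads(Path(path).read_text())
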