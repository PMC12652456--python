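"""Spectra containers and I/O: delimited spectra tables, ENVI hypercubes,
edge trimming and ROI mean-reflectance extraction.

A spectra table is a CSV with a ``sample_id`` column followed by one column
per band, headed by the wavelength in nm printed to three decimals. This
dialect is fixed so round trips are bit-exact.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SensorGrid",
    "SpectraMatrix",
    "HyperCube",
    "ROIMask",
    "vnir_grid",
    "swir_grid",
    "read_spectra_table",
    "write_spectra_table",
    "read_envi",
    "write_envi",
    "mean_reflectance",
    "trim_to_range",
]


@dataclass(frozen=True)
class SensorGrid:
    """A sensor's wavelength grid (nm), strictly increasing."""

    sensor_id: str  # "VNIR" or "SWIR"
    wavelengths: np.ndarray

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        if wl.ndim != 1 or wl.size < 1:
            raise ValueError("wavelengths must be a non-empty 1-D vector")
        if not np.all(np.diff(wl) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        object.__setattr__(self, "wavelengths", wl)

    @property
    def n_bands(self) -> int:
        return self.wavelengths.size


def vnir_grid() -> SensorGrid:
    """Default VNIR grid: 646 bands spanning 430-900 nm."""
    return SensorGrid("VNIR", np.linspace(430.0, 900.0, 646))


def swir_grid() -> SensorGrid:
    """Default SWIR grid: 148 bands spanning 950-1650 nm."""
    return SensorGrid("SWIR", np.linspace(950.0, 1650.0, 148))


@dataclass
class SpectraMatrix:
    """samples x bands reflectance bound to a wavelength grid."""

    grid: SensorGrid
    values: np.ndarray
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (samples x bands)")
        if self.values.shape[1] != self.grid.n_bands:
            raise ValueError(
                f"column count {self.values.shape[1]} != grid bands {self.grid.n_bands}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values must be finite with no missing entries")
        if not self.sample_ids:
            self.sample_ids = [f"S{i:04d}" for i in range(self.values.shape[0])]
        if len(self.sample_ids) != self.values.shape[0]:
            raise ValueError("sample_ids length must match row count")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]


@dataclass
class HyperCube:
    """lines x samples x bands reflectance cube."""

    values: np.ndarray
    grid: SensorGrid
    interleave: str = "bsq"  # bsq | bil | bip

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("cube must be 3-D (lines x samples x bands)")
        if self.values.shape[2] != self.grid.n_bands:
            raise ValueError("cube band count must equal grid band count")
        if self.interleave.lower() not in ("bsq", "bil", "bip"):
            raise ValueError(f"unknown interleave {self.interleave!r}")


@dataclass
class ROIMask:
    """Boolean pixel mask over a cube's spatial plane."""

    mask: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("mask must be 2-D")
        if not self.mask.any():
            raise ValueError("ROI mask selects no pixels")

    @property
    def pixel_count(self) -> int:
        return int(self.mask.sum())


# ---------------------------------------------------------------- tables

def write_spectra_table(matrix: SpectraMatrix, path: str | Path) -> None:
    cols = [f"{w:.3f}" for w in matrix.grid.wavelengths]
    df = pd.DataFrame(matrix.values, columns=cols)
    df.insert(0, "sample_id", matrix.sample_ids)
    df.to_csv(path, index=False, float_format="%.10g")


def read_spectra_table(path: str | Path, sensor_id: str = "VNIR") -> SpectraMatrix:
    path = Path(path)
    df = pd.read_csv(path, dtype={0: str})
    if df.columns[0] != "sample_id":
        raise ValueError(f"{path}: first column must be 'sample_id', got {df.columns[0]!r}")
    try:
        wl = np.array([float(c) for c in df.columns[1:]])
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric wavelength header: {exc}") from exc
    if not np.all(np.diff(wl) > 0):
        bad = int(np.argmin(np.diff(wl)))
        raise ValueError(f"{path}: wavelengths not strictly increasing near column {bad + 1}")
    body = df.iloc[:, 1:]
    numeric = body.apply(pd.to_numeric, errors="coerce")
    if numeric.isna().any().any():
        r, c = np.argwhere(numeric.isna().to_numpy())[0]
        raise ValueError(f"{path}: non-numeric cell at row {r}, column {df.columns[c + 1]!r}")
    return SpectraMatrix(
        SensorGrid(sensor_id, wl), numeric.to_numpy(float), list(df["sample_id"])
    )


# ---------------------------------------------------------------- ENVI

_ENVI_DTYPES = {4: np.float32, 5: np.float64, 12: np.uint16}
_ENVI_CODES = {np.dtype(np.float32): 4, np.dtype(np.float64): 5, np.dtype(np.uint16): 12}


def _parse_envi_header(text: str) -> dict:
    if not text.lstrip().upper().startswith("ENVI"):
        raise ValueError("not an ENVI header (missing ENVI magic)")
    # fold brace-delimited lists onto one line before splitting on '='
    text = re.sub(r"\{[^}]*\}", lambda m: m.group(0).replace("\n", " "), text)
    fields: dict = {}
    for line in text.splitlines()[1:]:
        if "=" not in line:
            continue
        key, _, val = line.partition("=")
        fields[key.strip().lower()] = val.strip()
    return fields


def read_envi(header_path: str | Path, data_path: str | Path | None = None) -> HyperCube:
    """Read an ENVI cube (data types 4/5 float, 12 uint16 with a
    ``reflectance scale factor``); BSQ/BIL/BIP dialects give identical arrays.
    """
    header_path = Path(header_path)
    if data_path is None:
        data_path = header_path.with_suffix(".dat")
    fields = _parse_envi_header(header_path.read_text())
    try:
        samples = int(fields["samples"])
        lines = int(fields["lines"])
        bands = int(fields["bands"])
        dtype_code = int(fields["data type"])
        interleave = fields["interleave"].lower()
    except KeyError as exc:
        raise ValueError(f"ENVI header missing required field {exc}") from exc
    if dtype_code not in _ENVI_DTYPES:
        raise ValueError(f"unsupported ENVI data type {dtype_code} (supported: 4, 5, 12)")
    dtype = np.dtype(_ENVI_DTYPES[dtype_code])
    if int(fields.get("byte order", "0")) == 1:
        dtype = dtype.newbyteorder(">")
    offset = int(fields.get("header offset", "0"))
    raw = np.fromfile(data_path, dtype=dtype, offset=offset)
    expected = lines * samples * bands
    if raw.size != expected:
        raise ValueError(
            f"payload has {raw.size} values, header implies {expected} "
            f"({lines}x{samples}x{bands})"
        )
    if interleave == "bsq":
        cube = raw.reshape(bands, lines, samples).transpose(1, 2, 0)
    elif interleave == "bil":
        cube = raw.reshape(lines, bands, samples).transpose(0, 2, 1)
    elif interleave == "bip":
        cube = raw.reshape(lines, samples, bands)
    else:
        raise ValueError(f"unknown interleave {interleave!r}")
    cube = cube.astype(float)
    if dtype_code == 12:
        scale = float(fields.get("reflectance scale factor", "10000"))
        cube = cube / scale
    if "wavelength" in fields:
        wl = np.array([float(v) for v in fields["wavelength"].strip("{} ").split(",") if v.strip()])
        if wl.size != bands:
            raise ValueError("wavelength list length does not match band count")
    else:
        wl = np.arange(bands, dtype=float)
    sensor = fields.get("sensor type", "VNIR").strip() or "VNIR"
    return HyperCube(cube, SensorGrid(sensor, wl), interleave)


def write_envi(
    cube: HyperCube,
    header_path: str | Path,
    data_path: str | Path | None = None,
    dtype_code: int = 4,
    scale: float = 10000.0,
) -> None:
    header_path = Path(header_path)
    if data_path is None:
        data_path = header_path.with_suffix(".dat")
    if dtype_code not in _ENVI_DTYPES:
        raise ValueError(f"unsupported ENVI data type {dtype_code}")
    lines, samples, bands = cube.values.shape
    arr = cube.values
    if dtype_code == 12:
        arr = np.clip(np.round(arr * scale), 0, np.iinfo(np.uint16).max)
    arr = arr.astype(_ENVI_DTYPES[dtype_code])
    il = cube.interleave.lower()
    if il == "bsq":
        out = arr.transpose(2, 0, 1)
    elif il == "bil":
        out = arr.transpose(0, 2, 1)
    else:
        out = arr
    out.tofile(data_path)
    wl = ", ".join(f"{w:.6f}" for w in cube.grid.wavelengths)
    hdr = (
        "ENVI\n"
        f"samples = {samples}\n"
        f"lines = {lines}\n"
        f"bands = {bands}\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        f"data type = {dtype_code}\n"
        f"interleave = {il}\n"
        f"sensor type = {cube.grid.sensor_id}\n"
        "byte order = 0\n"
        + (f"reflectance scale factor = {scale:g}\n" if dtype_code == 12 else "")
        + "wavelength = {" + wl + "}\n"
    )
    header_path.write_text(hdr)


# ---------------------------------------------------------------- ops

def mean_reflectance(cube: HyperCube, roi: ROIMask) -> np.ndarray:
    """Per-band arithmetic mean reflectance over the ROI pixels,
    R = (1/n) * sum_i R_i."""
    if roi.mask.shape != cube.values.shape[:2]:
        raise ValueError(
            f"mask shape {roi.mask.shape} does not match cube plane {cube.values.shape[:2]}"
        )
    return cube.values[roi.mask].mean(axis=0)


def trim_to_range(matrix: SpectraMatrix, min_nm: float, max_nm: float) -> SpectraMatrix:
    """Keep bands with min_nm <= lambda <= max_nm (boundaries inclusive).

    The retained original band indices are recorded on the result as
    ``retained_indices`` for provenance.
    """
    wl = matrix.grid.wavelengths
    keep = np.flatnonzero((wl >= min_nm) & (wl <= max_nm))
    if keep.size == 0:
        raise ValueError(f"no bands inside [{min_nm}, {max_nm}] nm")
    prior = getattr(matrix, "retained_indices", None)
    out = SpectraMatrix(
        SensorGrid(matrix.grid.sensor_id, wl[keep]),
        matrix.values[:, keep],
        list(matrix.sample_ids),
    )
    out.retained_indices = keep if prior is None else np.asarray(prior)[keep]
    return out
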