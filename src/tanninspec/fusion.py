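"""Data-layer and feature-layer fusion of dual-sensor spectra.

Both strategies concatenate along the wavelength/feature axis, VNIR block
first, with per-column provenance (sensor, original band index, wavelength)
so fusion is lossless and auditable.  No per-sensor rescaling is applied by
default — modeling operates on raw reflectance — but optional per-block
standardization is available.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cars import CARSResult
from .spectra_io import SpectraMatrix

__all__ = ["FusedMatrix", "concat_data_layer", "concat_feature_layer", "defuse"]


@dataclass
class FusedMatrix:
    values: np.ndarray
    provenance: pd.DataFrame  # columns: sensor_id, band_index, wavelength_nm
    layer: str                # "data" | "feature"
    sample_ids: list[str]

    def __post_init__(self) -> None:
        if self.values.shape[1] != len(self.provenance):
            raise ValueError("provenance must have one row per fused column")
        if self.layer not in ("data", "feature"):
            raise ValueError("layer must be 'data' or 'feature'")

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


def _check_alignment(a: SpectraMatrix, b: SpectraMatrix) -> None:
    if a.n_samples != b.n_samples:
        raise ValueError(f"sample counts differ: {a.n_samples} vs {b.n_samples}")
    mismatched = [
        (i, x, y) for i, (x, y) in enumerate(zip(a.sample_ids, b.sample_ids)) if x != y
    ]
    if mismatched:
        listing = ", ".join(f"row {i}: {x!r} vs {y!r}" for i, x, y in mismatched[:5])
        raise ValueError(f"sample ids mismatch ({listing}{'...' if len(mismatched) > 5 else ''})")


def concat_data_layer(
    vnir: SpectraMatrix, swir: SpectraMatrix, standardize_blocks: bool = False
) -> FusedMatrix:
    """Splice full spectra along the wavelength axis (VNIR then SWIR)."""
    _check_alignment(vnir, swir)
    blocks, prov = [], []
    for m in (vnir, swir):
        v = m.values
        if standardize_blocks:
            v = (v - v.mean(0)) / np.where(v.std(0) > 0, v.std(0), 1.0)
        blocks.append(v)
        prov.append(pd.DataFrame({
            "sensor_id": m.grid.sensor_id,
            "band_index": np.arange(m.grid.n_bands),
            "wavelength_nm": m.grid.wavelengths,
        }))
    return FusedMatrix(
        np.hstack(blocks), pd.concat(prov, ignore_index=True), "data", list(vnir.sample_ids)
    )


def restrict(matrix: SpectraMatrix, result: CARSResult | np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(values, original band indices) for a CARS-selected subset."""
    idx = result.selected if isinstance(result, CARSResult) else np.asarray(result, int)
    if idx.size == 0:
        raise ValueError("empty feature subset")
    if idx.min() < 0 or idx.max() >= matrix.grid.n_bands:
        raise ValueError("selected indices outside band range")
    return matrix.values[:, idx], idx


def concat_feature_layer(
    vnir: SpectraMatrix,
    vnir_sel: CARSResult | np.ndarray,
    swir: SpectraMatrix,
    swir_sel: CARSResult | np.ndarray,
) -> FusedMatrix:
    """Concatenate the two CARS feature subsets on the feature axis.

    Provenance records the original (pre-selection) band indices, so the
    fusion is losslessly invertible by :func:`defuse`.
    """
    _check_alignment(vnir, swir)
    v_vals, v_idx = restrict(vnir, vnir_sel)
    s_vals, s_idx = restrict(swir, swir_sel)
    prov = pd.concat([
        pd.DataFrame({"sensor_id": vnir.grid.sensor_id, "band_index": v_idx,
                      "wavelength_nm": vnir.grid.wavelengths[v_idx]}),
        pd.DataFrame({"sensor_id": swir.grid.sensor_id, "band_index": s_idx,
                      "wavelength_nm": swir.grid.wavelengths[s_idx]}),
    ], ignore_index=True)
    return FusedMatrix(np.hstack([v_vals, s_vals]), prov, "feature", list(vnir.sample_ids))


def defuse(fused: FusedMatrix) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Invert fusion: per sensor, (values, original band indices)."""
    out = {}
    for sensor, sub in fused.provenance.groupby("sensor_id", sort=False):
        cols = sub.index.to_numpy()
        out[str(sensor)] = (fused.values[:, cols], sub["band_index"].to_numpy())
    return out
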