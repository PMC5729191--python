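"""Readers/writers for per-vertex overlays and packed vertex series.

Overlays travel as CSV (one row per vertex). Vertex time series can be
round-tripped through NIfTI with vertices packed on the first axis (for
interoperability with volumetric tooling) when nibabel is available.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic_cohort import VertexSeries

__all__ = [
    "save_overlay_csv",
    "load_overlay_csv",
    "save_vertex_series_nifti",
    "load_vertex_series_nifti",
]


def save_overlay_csv(path, **columns) -> None:
    """Write named per-vertex arrays as a CSV overlay table."""
    pd.DataFrame({k: np.asarray(v) for k, v in columns.items()}).to_csv(
        path, index=False
    )


def load_overlay_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def save_vertex_series_nifti(ts: VertexSeries, path) -> None:
    """Pack a (V, T) series into a NIfTI volume of shape (V, 1, 1, T)."""
    import nibabel as nib

    img = nib.Nifti1Image(
        ts.data[:, None, None, :].astype(np.float32), affine=np.eye(4)
    )
    img.header.set_zooms((1.0, 1.0, 1.0, ts.tr_s))
    nib.save(img, str(path))


def load_vertex_series_nifti(path, tr_s: float | None = None) -> VertexSeries:
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise ValueError("expected a 4D packed series")
    if tr_s is None:
        tr_s = float(img.header.get_zooms()[3])
    return VertexSeries(data=data.reshape(data.shape[0], data.shape[3]), tr_s=tr_s)
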