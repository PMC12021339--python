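"""NIfTI-1 reading and writing for volumes, maps and label images."""

from __future__ import annotations

import warnings
from pathlib import Path

import nibabel as nib
import numpy as np

from .core import (
    ContrastVolume,
    FormatError,
    LabelVolume,
    QuantMap,
    ROIMask,
    _GridVolume,
)

__all__ = ["read_volume", "write_volume"]


def _load(path: str | Path) -> tuple[np.ndarray, tuple, np.ndarray]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        img = nib.load(str(path))
        data = np.asarray(img.dataobj)
        spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
        affine = np.asarray(img.affine, dtype=float)
    except Exception as exc:  # nibabel raises various error types
        raise FormatError(f"cannot read {path} as NIfTI: {exc}") from exc
    if data.ndim != 3:
        raise FormatError(f"{path}: expected a 3D volume, got ndim={data.ndim}")
    return data, spacing, affine


def read_volume(
    path: str | Path,
    kind: str = "auto",
    weighting: str = "T1w",
    quantity: str = "R1",
    region_table: dict | None = None,
):
    """Load a NIfTI volume as a ContrastVolume, QuantMap or LabelVolume.

    ``kind`` is ``contrast``, ``quant``, ``label`` or ``auto`` (label for
    integer-typed storage, contrast otherwise).  Requesting ``label`` for a
    float-stored file succeeds with a warning when all values are integral.
    """
    data, spacing, affine = _load(path)
    is_int = np.issubdtype(data.dtype, np.integer)
    if kind == "auto":
        kind = "label" if is_int else "contrast"
    if kind == "label":
        if not is_int:
            if not np.allclose(data, np.rint(data), atol=0):
                raise FormatError(f"{path}: non-integral values in a label volume")
            warnings.warn(f"{path}: float-stored label volume; casting to int")
            data = np.rint(data).astype(np.int32)
        table = region_table
        if table is None:
            table = {int(i): str(int(i)) for i in np.unique(data) if i != 0}
        return LabelVolume(data, spacing=spacing, affine=affine, region_table=table)
    if kind == "quant":
        return QuantMap(np.asarray(data, float), spacing=spacing, affine=affine, quantity=quantity)
    if kind == "contrast":
        return ContrastVolume(
            np.asarray(data, float), spacing=spacing, affine=affine, weighting=weighting
        )
    raise ValueError(f"unknown kind {kind!r}")


def write_volume(volume: _GridVolume, path: str | Path) -> Path:
    """Write a volume as NIfTI-1.

    Images and quantitative maps are stored as float32; label volumes and
    masks as the smallest sufficient integer type.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if isinstance(volume, LabelVolume):
        maxid = int(np.abs(volume.data).max()) if volume.data.size else 0
        dtype = np.int16 if maxid < 2**15 else np.int32
        data = volume.data.astype(dtype)
    elif isinstance(volume, ROIMask):
        data = volume.data.astype(np.int16)
    else:
        data = volume.data.astype(np.float32)
    img = nib.Nifti1Image(data, np.asarray(volume.affine))
    img.header.set_zooms(volume.spacing)
    nib.save(img, str(path))
    return path
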