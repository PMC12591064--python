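"""Image-stack I/O: multi-page TIFF and HDF5, 32-bit float, lossless.

Stages of the pipeline exchange stacks through fixed HDF5 dataset names
(``/holograms/d0`` …, ``/phase``, ``/volume``, ``/angles``, ``/truth/*``)
so they compose without extra flags; multi-page TIFF is the
interoperability fallback.
"""

from __future__ import annotations

import os
from pathlib import Path

import h5py
import numpy as np
import tifffile

__all__ = ["read_stack", "write_stack", "FormatError"]


class FormatError(ValueError):
    pass


def _is_hdf5(path: Path) -> bool:
    return path.suffix.lower() in (".h5", ".hdf5", ".hdf")


def write_stack(stack: np.ndarray, path, dataset: str = "data") -> None:
    """Write an image stack as multi-page TIFF or an HDF5 dataset
    (by extension), stored as 32-bit float; round trips bit-exactly."""
    path = Path(path)
    if not path.parent.is_dir():
        raise FileNotFoundError(f"parent directory {path.parent} does not exist")
    data = np.asarray(stack, dtype=np.float32)
    if _is_hdf5(path):
        mode = "a" if path.exists() else "w"
        with h5py.File(path, mode) as fh:
            if dataset in fh:
                del fh[dataset]
            fh.create_dataset(dataset, data=data)
    else:
        tmp = path.with_suffix(path.suffix + ".part")
        try:
            tifffile.imwrite(tmp, data, photometric="minisblack")
            os.replace(tmp, path)
        finally:
            tmp.unlink(missing_ok=True)


def read_stack(path, dataset: str = "data") -> np.ndarray:
    """Read a stack written by :func:`write_stack` (float32)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if _is_hdf5(path):
        with h5py.File(path, "r") as fh:
            if dataset not in fh:
                raise FormatError(f"dataset {dataset!r} not found in {path}")
            return fh[dataset][()]
    try:
        pages = tifffile.TiffFile(path).pages
        shapes = {p.shape for p in pages}
        if len(shapes) > 1:
            bad = [i for i, p in enumerate(pages) if p.shape != pages[0].shape]
            raise FormatError(
                f"TIFF pages have inconsistent shapes in {path}: first offending page {bad[0]}"
            )
        return tifffile.imread(path)
    except tifffile.TiffFileError as exc:
        raise FormatError(f"cannot read {path} as TIFF: {exc}") from exc
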