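"""TIFF stack and sidecar-metadata IO.

Volumes are multi-page greyscale TIFFs read into ``(z, y, x)`` arrays
(slice-major, 0-based).  The voxel size comes from a sidecar JSON
(``<stack>.meta.json``) when present, otherwise from the caller, otherwise
the package default of 1.625 µm.  Label masks are written as 8-bit TIFFs with
values 0/255.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile

from .core import DEFAULT_VOXEL_SIZE_UM, Volume, as_bool_mask

__all__ = ["read_volume", "write_volume", "read_mask", "write_mask", "sidecar_path"]


def sidecar_path(path: str | Path) -> Path:
    return Path(str(path) + ".meta.json")


def write_volume(
    path: str | Path,
    vol: Volume,
    dtype: str = "uint8",
    write_sidecar: bool = True,
) -> Path:
    """Write a volume as a multi-page greyscale TIFF (+ metadata sidecar)."""
    path = Path(path)
    data = vol.data
    if dtype in ("uint8", "uint16"):
        info = np.iinfo(dtype)
        data = np.clip(np.rint(data), info.min, info.max).astype(dtype)
    elif dtype == "float32":
        data = data.astype(np.float32)
    else:
        raise ValueError(f"unsupported dtype {dtype!r}")
    tifffile.imwrite(path, data, photometric="minisblack")
    if write_sidecar:
        meta = {"voxel_size_um": vol.voxel_size_um, **vol.meta}
        sidecar_path(path).write_text(json.dumps(meta, sort_keys=True) + "\n")
    return path


def read_volume(path: str | Path, voxel_size_um: float | None = None) -> Volume:
    """Read a multi-page (or single-file 3D) greyscale TIFF as a Volume.

    Rejects RGB input; 2D images are promoted to single-slice stacks.  Voxel
    size resolution order: sidecar JSON, explicit argument, package default.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        if page.samplesperpixel and page.samplesperpixel > 1:
            raise ValueError(
                f"{path} is RGB/multi-sample; expected greyscale tomography data"
            )
        data = tif.asarray()
    if data.ndim == 2:
        data = data[None]
    if data.ndim != 3:
        raise ValueError(f"{path}: expected 2D or 3D greyscale data, got {data.shape}")

    meta: dict = {}
    sp = sidecar_path(path)
    if sp.exists():
        meta = json.loads(sp.read_text())
    vs = meta.pop("voxel_size_um", None) or voxel_size_um or DEFAULT_VOXEL_SIZE_UM
    return Volume(data, float(vs), meta)


def write_mask(path: str | Path, mask: np.ndarray) -> Path:
    """Write a binary mask as an 8-bit TIFF with values 0/255."""
    path = Path(path)
    m = as_bool_mask(mask)
    tifffile.imwrite(path, (m.astype(np.uint8) * 255), photometric="minisblack")
    return path


def read_mask(path: str | Path) -> np.ndarray:
    arr = tifffile.imread(path)
    return as_bool_mask(arr, str(path))
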