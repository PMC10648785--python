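"""Readers and writers for scintigram images, masks and tables.

Count images travel as 16-bit grayscale PNG (lossless, integer) or
single-frame grayscale DICOM; masks as 0/255 8-bit PNG.  The view is
inferred from the filename (``*_anterior.*`` / ``*_posterior.*``, with
``ant``/``front`` and ``post``/``back`` accepted) or from the DICOM
ViewPosition tag.
"""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pydicom
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, SecondaryCaptureImageStorage, generate_uid

from .segmentation import RawScintigram

__all__ = [
    "FormatError",
    "read_image",
    "read_mask_png",
    "write_image_png",
    "write_mask_png",
    "write_dicom",
]


class FormatError(ValueError):
    """Unsupported or malformed image input."""


_VIEW_TOKENS = {
    "anterior": "anterior",
    "ant": "anterior",
    "front": "anterior",
    "ap": "anterior",
    "posterior": "posterior",
    "post": "posterior",
    "back": "posterior",
    "pa": "posterior",
}


def _infer_view(path: Path) -> str | None:
    stem = path.stem.lower()
    for token in sorted(_VIEW_TOKENS, key=len, reverse=True):
        if stem.endswith(token) or f"_{token}_" in f"_{stem}_":
            return _VIEW_TOKENS[token]
    return None


def read_image(path: str | Path, view: str | None = None) -> RawScintigram:
    """Read a single-frame grayscale count image (PNG, TIFF or DICOM)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in (".dcm", ".dicom"):
        ds = pydicom.dcmread(path)
        if int(getattr(ds, "NumberOfFrames", 1)) > 1:
            raise FormatError(f"{path}: multi-frame DICOM not supported")
        if int(getattr(ds, "SamplesPerPixel", 1)) != 1:
            raise FormatError(f"{path}: color DICOM not supported")
        pixels = ds.pixel_array
        if view is None:
            vp = str(getattr(ds, "ViewPosition", "")).lower()
            view = _VIEW_TOKENS.get(vp)
    else:
        pixels = iio.imread(path)
        if pixels.ndim != 2:
            raise FormatError(f"{path}: expected single-channel grayscale image")
    if view is None:
        view = _infer_view(path)
    if view is None:
        raise FormatError(f"{path}: cannot infer view; pass view= explicitly")
    return RawScintigram(np.asarray(pixels).astype(np.int64), view=view)


def write_image_png(pixels: np.ndarray, path: str | Path) -> None:
    """Write nonnegative integer counts as 16-bit grayscale PNG."""
    pixels = np.asarray(pixels)
    if pixels.min() < 0 or pixels.max() > np.iinfo(np.uint16).max:
        raise FormatError("counts outside the 16-bit range")
    iio.imwrite(Path(path), pixels.astype(np.uint16))


def read_mask_png(path: str | Path) -> np.ndarray:
    return iio.imread(Path(path)) > 0


def write_mask_png(mask: np.ndarray, path: str | Path) -> None:
    iio.imwrite(Path(path), (np.asarray(mask, bool) * 255).astype(np.uint8))


def write_dicom(pixels: np.ndarray, path: str | Path, view: str = "anterior") -> None:
    """Write counts as a minimal secondary-capture grayscale DICOM."""
    pixels = np.asarray(pixels)
    if pixels.min() < 0 or pixels.max() > np.iinfo(np.uint16).max:
        raise FormatError("counts outside the 16-bit range")
    arr = pixels.astype(np.uint16)

    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = SecondaryCaptureImageStorage
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian

    ds = Dataset()
    ds.file_meta = meta
    ds.SOPClassUID = SecondaryCaptureImageStorage
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "NM"
    ds.ViewPosition = "AP" if view == "anterior" else "PA"
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.Rows, ds.Columns = arr.shape
    ds.BitsAllocated = 16
    ds.BitsStored = 16
    ds.HighBit = 15
    ds.PixelRepresentation = 0
    ds.PixelData = arr.tobytes()
    ds.save_as(Path(path), enforce_file_format=True)
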