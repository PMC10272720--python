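"""Reading and writing angiographic frame sequences.

Two on-disk layouts are supported:

* **DICOM** — either a single multi-frame file (secondary capture) or a
  directory of single-frame files sorted by ``InstanceNumber``.  The frame
  rate is derived with the priority ``override > FrameTime (0018,1063) >
  CineRate (0018,0040)`` and the spatial resolution with ``override >
  PixelSpacing > ImagerPixelSpacing``.
* **image stack** — a directory of per-frame TIFF/PNG images plus a small
  key-value sidecar ``metadata.txt`` holding ``fps`` and ``resolution``,
  so phantom fixtures stay self-describing.

Pixel values are never rescaled or inverted on read: whatever intensity
convention is stored is the analysis signal.  The pipeline-wide convention
is that contrast medium *decreases* intensity.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pydicom
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid

__all__ = ["AngioSequence", "read_sequence", "write_sequence"]

SIDECAR_NAME = "metadata.txt"

#: Multi-frame Grayscale Word Secondary Capture Image Storage
_MF_SC_SOP_CLASS = "1.2.840.10008.5.1.4.1.1.7.2"

#: Frame rates derived from DICOM frame times are rounded to this many
#: decimals, so that e.g. a frame time of 66.67 ms maps to 15.0 fps.
FPS_DECIMALS = 2

_IMAGE_EXTENSIONS = {".tif", ".tiff", ".png"}


@dataclass(frozen=True)
class AngioSequence:
    """An ordered stack of grayscale angiography frames plus acquisition metadata.

    Parameters
    ----------
    frames
        3D array indexed ``(time, row, col)``; arbitrary monotone grayscale
        units, kept in the native (integer) dtype of the source.
    fps
        Temporal resolution in frames per second.
    resolution
        Spatial resolution in mm per pixel (isotropic).
    """

    frames: np.ndarray
    fps: float
    resolution: float

    def __post_init__(self) -> None:
        frames = np.asarray(self.frames)
        if frames.ndim != 3:
            raise ValueError(
                f"frames must be a (time, row, col) array, got ndim={frames.ndim}"
            )
        if frames.shape[0] < 2:
            raise ValueError("a sequence needs at least 2 frames")
        if not self.fps > 0:
            raise ValueError(f"fps must be positive, got {self.fps}")
        if not self.resolution > 0:
            raise ValueError(f"resolution must be positive, got {self.resolution}")
        object.__setattr__(self, "frames", frames)

    @property
    def frame_count(self) -> int:
        return int(self.frames.shape[0])

    @property
    def shape(self) -> tuple[int, int]:
        """(rows, cols) of a single frame."""
        return (int(self.frames.shape[1]), int(self.frames.shape[2]))

    @property
    def frame_interval_s(self) -> float:
        return 1.0 / self.fps


def _fps_from_dataset(ds: Dataset) -> float | None:
    frame_time = getattr(ds, "FrameTime", None)  # (0018,1063), ms per frame
    if frame_time is not None and float(frame_time) > 0:
        return round(1000.0 / float(frame_time), FPS_DECIMALS)
    cine_rate = getattr(ds, "CineRate", None)  # (0018,0040), frames/s
    if cine_rate is not None and float(cine_rate) > 0:
        return float(cine_rate)
    return None


def _resolution_from_dataset(ds: Dataset) -> float | None:
    for attr in ("PixelSpacing", "ImagerPixelSpacing"):
        spacing = getattr(ds, attr, None)
        if spacing is not None:
            return float(spacing[0])
    return None


def _read_dicom_file(path: Path) -> tuple[np.ndarray, float | None, float | None]:
    ds = pydicom.dcmread(path)
    frames = ds.pixel_array
    if frames.ndim == 2:
        frames = frames[np.newaxis]
    return frames, _fps_from_dataset(ds), _resolution_from_dataset(ds)


def _read_dicom_series(paths: list[Path]) -> tuple[np.ndarray, float | None, float | None]:
    datasets = [pydicom.dcmread(p) for p in paths]
    datasets.sort(key=lambda d: int(getattr(d, "InstanceNumber", 0)))
    arrays = [d.pixel_array for d in datasets]
    shapes = {a.shape for a in arrays}
    if len(shapes) != 1:
        raise ValueError(f"inconsistent frame shapes in DICOM series: {sorted(shapes)}")
    return np.stack(arrays), _fps_from_dataset(datasets[0]), _resolution_from_dataset(datasets[0])


def _parse_sidecar(path: Path) -> dict[str, float]:
    meta: dict[str, float] = {}
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#") or "=" not in line:
            continue
        key, value = (part.strip() for part in line.split("=", 1))
        meta[key] = float(value)
    return meta


def _read_image_stack(directory: Path) -> tuple[np.ndarray, float | None, float | None]:
    frame_paths = sorted(
        p for p in directory.iterdir() if p.suffix.lower() in _IMAGE_EXTENSIONS
    )
    arrays = [iio.imread(p) for p in frame_paths]
    shapes = {a.shape for a in arrays}
    if len(shapes) != 1:
        raise ValueError(f"inconsistent frame shapes in image stack: {sorted(shapes)}")
    fps = resolution = None
    sidecar = directory / SIDECAR_NAME
    if sidecar.exists():
        meta = _parse_sidecar(sidecar)
        fps = meta.get("fps")
        resolution = meta.get("resolution")
    return np.stack(arrays), fps, resolution


def read_sequence(
    path: str | os.PathLike,
    override_fps: float | None = None,
    override_resolution: float | None = None,
) -> AngioSequence:
    """Read an angiographic sequence from DICOM or an image stack.

    ``path`` may be a multi-frame DICOM file, a directory of single-frame
    DICOM files, or a directory of TIFF/PNG frames with a ``metadata.txt``
    sidecar.  Explicit overrides take precedence over stored metadata;
    metadata that is neither stored nor overridden is an error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such sequence: {path}")

    if path.is_file():
        frames, fps, resolution = _read_dicom_file(path)
    else:
        dicom_paths = sorted(path.glob("*.dcm"))
        if dicom_paths:
            frames, fps, resolution = _read_dicom_series(dicom_paths)
        else:
            frames, fps, resolution = _read_image_stack(path)

    if frames.shape[0] < 2:
        raise ValueError("a sequence needs at least 2 frames")
    if override_fps is not None:
        fps = float(override_fps)
    if override_resolution is not None:
        resolution = float(override_resolution)
    if fps is None:
        raise ValueError(f"missing fps for {path} and no override given")
    if resolution is None:
        raise ValueError(f"missing resolution for {path} and no override given")
    return AngioSequence(frames=frames, fps=fps, resolution=resolution)


def _write_dicom(seq: AngioSequence, path: Path) -> Path:
    frames = seq.frames
    if not np.issubdtype(frames.dtype, np.integer):
        raise ValueError("DICOM output requires integer pixel data")
    itemsize = frames.dtype.itemsize
    if itemsize > 2:
        raise ValueError(f"unsupported pixel dtype for DICOM: {frames.dtype}")
    signed = np.issubdtype(frames.dtype, np.signedinteger)

    file_meta = FileMetaDataset()
    file_meta.MediaStorageSOPClassUID = _MF_SC_SOP_CLASS
    file_meta.MediaStorageSOPInstanceUID = generate_uid()
    file_meta.TransferSyntaxUID = ExplicitVRLittleEndian

    ds = Dataset()
    ds.file_meta = file_meta
    ds.SOPClassUID = _MF_SC_SOP_CLASS
    ds.SOPInstanceUID = file_meta.MediaStorageSOPInstanceUID
    ds.Modality = "XA"
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.NumberOfFrames = seq.frame_count
    ds.Rows, ds.Columns = seq.shape
    ds.BitsAllocated = 8 * itemsize
    ds.BitsStored = 8 * itemsize
    ds.HighBit = 8 * itemsize - 1
    ds.PixelRepresentation = 1 if signed else 0
    # DS is limited to 16 characters; this keeps ~13 significant digits,
    # far inside the 1e-6 metadata round-trip tolerance.
    ds.FrameTime = f"{1000.0 / seq.fps:.10g}"
    ds.PixelSpacing = [f"{seq.resolution:.10g}"] * 2
    ds.PixelData = np.ascontiguousarray(frames).tobytes()
    ds.save_as(path, enforce_file_format=True)
    return path


def _write_image_stack(seq: AngioSequence, directory: Path) -> Path:
    directory.mkdir(parents=True, exist_ok=True)
    digits = max(4, len(str(seq.frame_count - 1)))
    for i, frame in enumerate(seq.frames):
        iio.imwrite(directory / f"frame_{i:0{digits}d}.tif", frame)
    (directory / SIDECAR_NAME).write_text(
        f"fps = {seq.fps:.10g}\nresolution = {seq.resolution:.10g}\n"
    )
    return directory


def write_sequence(
    seq: AngioSequence,
    path: str | os.PathLike,
    format: str = "dicom",
) -> Path:
    """Write a sequence so that :func:`read_sequence` restores it bit-exactly.

    ``format`` is ``"dicom"`` (one multi-frame file) or ``"image_stack"``
    (a directory of TIFF frames plus a metadata sidecar).
    """
    path = Path(path)
    if format == "dicom":
        return _write_dicom(seq, path)
    if format == "image_stack":
        return _write_image_stack(seq, path)
    raise ValueError(f"unsupported format: {format!r} (expected 'dicom' or 'image_stack')")
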