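"""Reading CT volumes into the canonical in-memory representation.

A :class:`CTVolume` is an ordered rank-3 intensity grid with the slice axis
first (``(n_slices, height, width)``), in-slice coordinates ``(row, col)``,
0-based.  Supported sources are DICOM series directories (via pydicom),
NIfTI files (via nibabel) and lexicographically ordered grayscale image
stacks (PNG/TIFF via Pillow).  Loading passes raw intensities through
unchanged; :func:`normalize_volume` maps them to [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .errors import DegenerateVolumeError, EmptyVolumeError, FormatError

__all__ = ["CTVolume", "load_volume", "save_image_stack", "normalize_volume",
           "quality_filter"]

_IMAGE_SUFFIXES = {".png", ".tif", ".tiff"}


@dataclass
class CTVolume:
    """An ordered stack of grayscale CT slices for one scan."""

    slices: np.ndarray  # (n_slices, height, width)
    patient_id: str = ""
    scan_id: str = ""
    source_format: str = "array"
    spacing: tuple[float, float, float] | None = None  # (z, row, col), mm

    def __post_init__(self):
        self.slices = np.asarray(self.slices)
        if self.slices.ndim != 3 or self.slices.shape[0] < 1:
            raise FormatError(
                f"volume must be (n_slices, H, W) with n_slices >= 1, "
                f"got shape {self.slices.shape}")

    @property
    def n_slices(self) -> int:
        return self.slices.shape[0]

    @property
    def slice_shape(self) -> tuple[int, int]:
        return self.slices.shape[1], self.slices.shape[2]


def load_volume(path: str | Path, format: str | None = None, *,
                patient_id: str = "", scan_id: str = "") -> CTVolume:
    """Load one scan from ``path``.

    ``format`` is one of ``"dicom"``, ``"nifti"``, ``"image_stack"``; when
    omitted it is inferred (a file ending .nii/.nii.gz -> nifti; a directory
    containing .dcm files -> dicom; otherwise image_stack).  Slices are
    ordered by acquisition position for DICOM (ImagePositionPatient z, with
    InstanceNumber as fallback) and by filename for stacks.  Intensities are
    returned raw, as stored.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"{path} does not exist")
    if format is None:
        if path.is_file() and (path.name.endswith(".nii") or path.name.endswith(".nii.gz")):
            format = "nifti"
        elif path.is_dir() and any(path.glob("*.dcm")):
            format = "dicom"
        else:
            format = "image_stack"
    pid = patient_id or path.stem.replace(".nii", "")
    sid = scan_id or pid
    if format == "image_stack":
        slices = _load_image_stack(path)
    elif format == "nifti":
        slices = _load_nifti(path)
    elif format == "dicom":
        slices = _load_dicom(path)
    else:
        raise FormatError(f"unknown format {format!r}")
    return CTVolume(slices=slices, patient_id=pid, scan_id=sid, source_format=format)


def _load_image_stack(path: Path) -> np.ndarray:
    from PIL import Image

    if not path.is_dir():
        raise FormatError(f"image_stack expects a directory, got {path}")
    files = sorted(p for p in path.iterdir() if p.suffix.lower() in _IMAGE_SUFFIXES)
    if not files:
        raise FileNotFoundError(f"no image files in {path}")
    arrays = []
    for f in files:
        with Image.open(f) as im:
            arrays.append(np.asarray(im.convert("F"), dtype=np.float64))
    shapes = {a.shape for a in arrays}
    if len(shapes) > 1:
        raise FormatError(f"mixed slice shapes in {path}: {sorted(shapes)}")
    return np.stack(arrays, axis=0)


def _load_nifti(path: Path) -> np.ndarray:
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj).astype(np.float64)
    if data.ndim != 3:
        raise FormatError(f"expected a 3-D NIfTI volume, got shape {data.shape}")
    # stored (H, W, D); canonical order puts the slice axis first
    return np.moveaxis(data, 2, 0)


def _load_dicom(path: Path) -> np.ndarray:
    import pydicom

    if not path.is_dir():
        raise FormatError(f"dicom expects a series directory, got {path}")
    files = sorted(path.glob("*.dcm"))
    if not files:
        raise FileNotFoundError(f"no DICOM files in {path}")
    dsets = [pydicom.dcmread(str(f)) for f in files]

    def sort_key(ds):
        ipp = getattr(ds, "ImagePositionPatient", None)
        if ipp is not None and len(ipp) == 3:
            return (0, float(ipp[2]))
        return (1, int(getattr(ds, "InstanceNumber", 0)))

    dsets.sort(key=sort_key)
    arrays = []
    for ds in dsets:
        a = ds.pixel_array.astype(np.float64)
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        arrays.append(a * slope + intercept)
    shapes = {a.shape for a in arrays}
    if len(shapes) > 1:
        raise FormatError(f"mixed slice shapes in {path}: {sorted(shapes)}")
    return np.stack(arrays, axis=0)


def save_image_stack(volume: CTVolume, directory: str | Path) -> list[Path]:
    """Write a volume as 8-bit grayscale PNGs ``slice_0000.png`` ...

    Intensities are assumed normalized to [0, 1] and are quantized to
    0..255; the round trip through :func:`load_volume` therefore agrees
    within 1/255 per pixel.
    """
    from PIL import Image

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    data = np.clip(volume.slices, 0.0, 1.0)
    for i, sl in enumerate(data):
        p = directory / f"slice_{i:04d}.png"
        Image.fromarray(np.round(sl * 255.0).astype(np.uint8), mode="L").save(p)
        paths.append(p)
    return paths


def normalize_volume(v: CTVolume, mode: str = "minmax_volume", *,
                     level: float | None = None,
                     width: float | None = None) -> CTVolume:
    """Map intensities into [0, 1].

    ``minmax_volume`` maps the volume minimum to 0 and maximum to 1; a
    constant volume is degenerate and raises.  ``fixed_window`` clips to
    ``[level - width/2, level + width/2]`` (e.g. a mediastinal window of
    level 40 HU, width 400 HU) and scales that range linearly.
    """
    x = v.slices.astype(np.float64)
    if mode == "minmax_volume":
        lo, hi = float(x.min()), float(x.max())
        if hi <= lo:
            raise DegenerateVolumeError(
                f"volume {v.scan_id or '<unnamed>'} has constant intensity "
                f"({lo}); min-max normalization is undefined — use a fixed "
                f"window instead")
        y = (x - lo) / (hi - lo)
    elif mode == "fixed_window":
        if level is None or width is None or width <= 0:
            raise DegenerateVolumeError("fixed_window requires level and width > 0")
        lo, hi = level - width / 2.0, level + width / 2.0
        y = (np.clip(x, lo, hi) - lo) / (hi - lo)
    else:
        raise FormatError(f"unknown normalization mode {mode!r}")
    return replace(v, slices=y)


def quality_filter(v: CTVolume, min_std: float = 0.01
                   ) -> tuple[CTVolume, list[int]]:
    """Drop near-uniform slices.

    Keeps slices whose intensity standard deviation is >= ``min_std``
    (default 0.01 on the [0, 1] scale — an explicit, configurable stand-in
    for low-quality-frame removal).  Returns the filtered volume plus the
    indices of the dropped slices; slice order is preserved.
    """
    stds = v.slices.std(axis=(1, 2))
    keep = stds >= min_std
    dropped = [int(i) for i in np.nonzero(~keep)[0]]
    if not keep.any():
        raise EmptyVolumeError(
            f"all {v.n_slices} slices of {v.scan_id or '<unnamed>'} fell below "
            f"min_std={min_std}")
    return replace(v, slices=v.slices[keep]), dropped
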