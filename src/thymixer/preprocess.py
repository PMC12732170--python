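"""Anatomically guided cropping, slice-triplet fusion and resizing.

The preprocessing stage turns a normalized CT volume into the model's
inputs:

* **grid crop** — each slice is divided into a 3x3 grid and the upper two
  cells of the middle column (the anterior mediastinum, where thymomas
  arise) are kept as one stacked 2:1 region: rows ``[0, 2*floor(H/3))``,
  cols ``[floor(W/3), 2*floor(W/3))``.  Remainder rows/columns fall in the
  discarded third band, so the geometry is deterministic for any H, W.
* **triplet fusion** — three consecutive cropped slices become the three
  channels of one RGB-like image, in non-overlapping stride-3 windows
  (fusion is meant to *reduce* the sample count ~3x; a sliding window would
  not).  A remainder of one or two slices is dropped.
* **resize** — bilinear resampling to the model input size 224x112, whose
  2:1 aspect matches the two stacked grid cells.

Config flags reproduce the ablation variants: ``mode="entire"`` skips the
crop, ``channels="single"`` replicates each slice across all three channels
instead of fusing triplets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.transform import resize as _sk_resize

from .ct_io import CTVolume, quality_filter
from .errors import InsufficientSlicesError, SizeError

__all__ = ["CropSpec", "FusedPatch", "PreprocessConfig", "grid_crop",
           "fuse_triplets", "resize_patch", "preprocess_scan", "project_mask"]


@dataclass(frozen=True)
class CropSpec:
    """Geometry of the mediastinal crop for a slice of shape (H, W)."""

    height: int
    width: int

    @property
    def row_stop(self) -> int:
        return 2 * (self.height // 3)

    @property
    def col_lo(self) -> int:
        return self.width // 3

    @property
    def col_hi(self) -> int:
        return 2 * (self.width // 3)

    @property
    def crop_shape(self) -> tuple[int, int]:
        return self.row_stop, self.col_hi - self.col_lo


@dataclass
class FusedPatch:
    """One three-channel model input with provenance.

    ``source_slices`` are the indices (into the *filtered* volume) of the
    three slices occupying the channels, in order; the label is inherited
    from the source patient (every slice of a thymoma patient counts as
    thymoma in stage 1).
    """

    pixels: np.ndarray  # (224, 112, 3), values in [0, 1]
    scan_id: str = ""
    patient_id: str = ""
    source_slices: tuple[int, ...] = ()
    label: str = ""


@dataclass
class PreprocessConfig:
    mode: str = "cropped"          # "cropped" | "entire"
    channels: str = "rgb_fused"    # "rgb_fused" | "single"
    min_std: float = 0.01
    target: tuple[int, int] = (224, 112)

    def __post_init__(self):
        if self.mode not in ("cropped", "entire"):
            raise ValueError(f"mode must be 'cropped' or 'entire', got {self.mode!r}")
        if self.channels not in ("rgb_fused", "single"):
            raise ValueError(
                f"channels must be 'rgb_fused' or 'single', got {self.channels!r}")


def grid_crop(sl: np.ndarray) -> np.ndarray:
    """Return the stacked upper-middle 2:1 region of a 2-D slice."""
    if sl.ndim != 2:
        raise SizeError(f"grid_crop expects a 2-D slice, got shape {sl.shape}")
    h, w = sl.shape
    if h < 3 or w < 3:
        raise SizeError(f"slice {h}x{w} is too small for a 3x3 grid")
    spec = CropSpec(h, w)
    return sl[0:spec.row_stop, spec.col_lo:spec.col_hi]


def fuse_triplets(slices: np.ndarray | list[np.ndarray]) -> np.ndarray:
    """Stack consecutive slice triplets as channels.

    Input: ``n`` 2-D slices (as a list or an ``(n, h, w)`` array), n >= 3.
    Output: ``(n // 3, h, w, 3)`` with channel ``k`` of output ``j`` being
    input slice ``3j + k``; the remainder of one or two slices is dropped.
    """
    arr = np.asarray(slices)
    n = arr.shape[0]
    if n < 3:
        raise InsufficientSlicesError(f"triplet fusion needs >= 3 slices, got {n}")
    m = n // 3
    return arr[:3 * m].reshape(m, 3, *arr.shape[1:]).transpose(0, 2, 3, 1)


def resize_patch(image: np.ndarray, target: tuple[int, int] = (224, 112)
                 ) -> np.ndarray:
    """Bilinear resize of a 2-D or (h, w, 3) image to ``target``; values are
    clipped back into [0, 1]."""
    if image.size == 0:
        raise SizeError("cannot resize an empty image")
    shape = target if image.ndim == 2 else (*target, image.shape[2])
    out = _sk_resize(image.astype(np.float64), shape, order=1, mode="edge",
                     anti_aliasing=False, preserve_range=True)
    return np.clip(out, 0.0, 1.0)


def preprocess_scan(v: CTVolume, cfg: PreprocessConfig | None = None,
                    label: str = "") -> list[FusedPatch]:
    """Full stage: quality filter -> (crop) -> fuse -> resize.

    With ``channels="single"`` every kept slice yields one patch whose three
    channels are identical copies of that slice.
    """
    cfg = cfg or PreprocessConfig()
    filtered, _dropped = quality_filter(v, cfg.min_std)
    if cfg.mode == "cropped":
        planes = np.stack([grid_crop(s) for s in filtered.slices])
    else:
        planes = filtered.slices
    if cfg.channels == "rgb_fused":
        fused = fuse_triplets(planes)
        sources = [(3 * j, 3 * j + 1, 3 * j + 2) for j in range(fused.shape[0])]
    else:
        fused = np.repeat(planes[:, :, :, None], 3, axis=3)
        sources = [(j, j, j) for j in range(fused.shape[0])]
    patches = []
    for img, src in zip(fused, sources):
        patches.append(FusedPatch(
            pixels=resize_patch(img, cfg.target).astype(np.float32),
            scan_id=v.scan_id, patient_id=v.patient_id,
            source_slices=src, label=label))
    return patches


def project_mask(mask_volume: np.ndarray, v: CTVolume,
                 cfg: PreprocessConfig | None = None) -> list[np.ndarray]:
    """Project a boolean lesion-mask volume through the same pipeline.

    Returns one boolean ``target``-shaped mask per produced patch (the union
    over the three fused slices), using the same quality filter, crop and
    fusion bookkeeping as :func:`preprocess_scan` applied to ``v``.  Used to
    check lesion retention and Grad-CAM localization on phantoms.
    """
    cfg = cfg or PreprocessConfig()
    stds = v.slices.std(axis=(1, 2))
    kept = mask_volume[stds >= cfg.min_std]
    if cfg.mode == "cropped":
        planes = np.stack([grid_crop(m) for m in kept])
    else:
        planes = kept
    if cfg.channels == "rgb_fused":
        fused = fuse_triplets(planes.astype(float))
        combined = fused.max(axis=3)
    else:
        combined = planes.astype(float)
    out = []
    for m in combined:
        resized = _sk_resize(m, cfg.target, order=0, mode="edge",
                             anti_aliasing=False, preserve_range=True)
        out.append(resized > 0.5)
    return out
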