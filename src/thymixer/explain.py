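"""Grad-CAM saliency for the patch classifier.

The class score used is the *pre-softmax logit* of the target class
(standard Grad-CAM); its gradient on the final convolutional feature map is
averaged spatially to weight the channels, the weighted sum is rectified,
bilinearly upsampled to the patch size and min-max normalized.  Because the
gradient is taken before the softmax, adding a constant to all logits
leaves the heatmap unchanged — a property the test suite asserts.

Heatmaps are computed on the cropped patch and can be re-projected onto the
full slice through the inverse of the grid crop (rows ``[0, 2H/3)``, cols
``[W/3, 2W/3)``), transparent outside that region.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import resize as _sk_resize

from .errors import ParameterError
from .mixer import MixerNet
from .preprocess import CropSpec

__all__ = ["Heatmap", "gradcam", "peak_cell_hit", "project_to_full",
           "overlay_full"]


@dataclass
class Heatmap:
    values: np.ndarray        # (H_patch, W_patch) in [0, 1]
    target_class: int
    all_zero: bool = False    # True when the class-score gradient vanished
    coarse: np.ndarray | None = None  # raw rectified CAM on the conv grid


def gradcam(model: MixerNet, patch: np.ndarray, target_class: int) -> Heatmap:
    """Compute a Grad-CAM heatmap for one ``(H, W, 3)`` patch."""
    n_classes = model.config.n_classes
    if not 0 <= target_class < n_classes:
        raise ParameterError(
            f"target_class {target_class} out of range [0, {n_classes})")
    if patch.ndim != 3:
        raise ParameterError(f"expected one (H, W, 3) patch, got {patch.shape}")
    model.train(True)  # forward must cache activations for the backward pass
    logits = model.forward(patch[None].astype(np.float32))
    dlogits = np.zeros_like(logits)
    dlogits[0, target_class] = 1.0
    model.backward(dlogits, through_backbone=False)
    f = model.feature_map[0]          # (h, w, C)
    df = model.d_feature_map[0]
    weights = df.mean(axis=(0, 1))    # spatial mean of the logit gradient
    coarse = np.maximum((f * weights).sum(axis=-1), 0.0)
    h, w = model.config.input_size
    cam = _sk_resize(coarse.astype(np.float64), (h, w), order=1, mode="edge",
                     anti_aliasing=False, preserve_range=True)
    lo, hi = float(cam.min()), float(cam.max())
    if hi <= 0.0:
        return Heatmap(values=np.zeros((h, w)), target_class=target_class,
                       all_zero=True, coarse=coarse)
    cam = (cam - lo) / (hi - lo) if hi > lo else np.ones_like(cam)
    return Heatmap(values=cam, target_class=target_class, coarse=coarse)


def peak_cell_hit(heatmap: Heatmap, lesion_mask: np.ndarray,
                  dilation_px: int = 12) -> bool:
    """Does the peak CAM cell fall on the (dilated) lesion?

    The CAM lives on the coarse convolutional grid (7x3 for a 224x112
    patch), so localization is judged at that native resolution: the
    footprint of the argmax cell, mapped back onto the patch, must
    intersect the lesion mask after dilating it by ``dilation_px`` pixels
    (default 12, roughly a third of a feature cell — the quantization slack
    of the grid).  An all-zero heatmap never hits.
    """
    from scipy.ndimage import binary_dilation

    if heatmap.all_zero or heatmap.coarse is None:
        return False
    mask = np.asarray(lesion_mask, dtype=bool)
    if not mask.any():
        return False
    gh, gw = heatmap.coarse.shape
    h, w = mask.shape
    r, c = np.unravel_index(int(heatmap.coarse.argmax()), (gh, gw))
    ch, cw = h // gh, w // gw
    rs, re = r * ch, h if r == gh - 1 else (r + 1) * ch
    cs, ce = c * cw, w if c == gw - 1 else (c + 1) * cw
    dilated = binary_dilation(mask, iterations=dilation_px)
    return bool(dilated[rs:re, cs:ce].any())


def project_to_full(heatmap: Heatmap, slice_shape: tuple[int, int]) -> np.ndarray:
    """Map a patch heatmap back into the crop region of a full slice.

    Returns an ``slice_shape`` array that is zero outside the crop region
    and the (bilinearly resampled) heatmap inside it.
    """
    spec = CropSpec(*slice_shape)
    ch, cw = spec.crop_shape
    inner = _sk_resize(heatmap.values, (ch, cw), order=1, mode="edge",
                       anti_aliasing=False, preserve_range=True)
    out = np.zeros(slice_shape)
    out[0:spec.row_stop, spec.col_lo:spec.col_hi] = inner
    return out


def overlay_full(heatmap: Heatmap, full_slice: np.ndarray,
                 alpha: float = 0.5, cmap: str = "jet") -> np.ndarray:
    """RGBA composite of the heatmap over the full slice.

    The slice is rendered in grayscale; the heatmap is colored blue-to-red
    and blended only inside the crop region (fully transparent heatmap
    outside it).
    """
    from matplotlib import colormaps

    gray = np.clip(full_slice.astype(np.float64), 0.0, 1.0)
    base = np.stack([gray, gray, gray, np.ones_like(gray)], axis=-1)
    projected = project_to_full(heatmap, full_slice.shape)
    colors = colormaps[cmap](projected)
    spec = CropSpec(*full_slice.shape)
    region = np.zeros(full_slice.shape, dtype=bool)
    region[0:spec.row_stop, spec.col_lo:spec.col_hi] = True
    blend = base.copy()
    blend[region, :3] = (1 - alpha) * base[region, :3] + alpha * colors[region, :3]
    return blend
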