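"""Four-stage MRI-slice preprocessing: resize, Gaussian filter, normalize, augment.

The pipeline order is resize -> Gaussian filter -> normalize -> (training
only) augment. Images and masks always travel as a pair through geometric
transforms so the annotation stays pixel-locked to the anatomy: images use
bilinear interpolation, masks nearest-neighbour so labels stay binary.

Normalization is a plain division by 255 (8-bit intensities to the unit
interval); 16-bit inputs are rescaled to 8-bit range first. A
``value_domain`` flag on :class:`GrayscaleSlice` guards against applying it
twice.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage
from skimage.transform import resize as _sk_resize


class ShapeConsistencyError(ValueError):
    """Image and mask shapes disagree."""


class DoubleNormalizationError(ValueError):
    """normalize() applied to an already unit-interval slice."""


@dataclass
class GrayscaleSlice:
    """A single-channel 2-D slice with identity and value-domain metadata.

    ``value_domain`` is ``"raw"`` for integer intensities (0..255 after any
    bit-depth rescale) and ``"unit"`` once normalized to [0, 1].
    """

    pixels: np.ndarray
    slice_id: str = ""
    value_domain: str = "raw"


@dataclass(frozen=True)
class AugmentationPolicy:
    """Stochastic label-preserving transforms applied to training pairs.

    Defaults follow the study protocol: horizontal flip, rotation drawn
    uniformly from ±120 degrees, zoom by ±0.2 (scale in [0.8, 1.2]).
    """

    horizontal_flip_prob: float = 0.5
    rotation_limit: float = 120.0
    zoom_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.horizontal_flip_prob <= 1.0:
            raise ValueError("horizontal_flip_prob must be in [0, 1]")
        if self.rotation_limit < 0 or self.zoom_fraction < 0:
            raise ValueError("rotation_limit and zoom_fraction must be >= 0")
        if self.zoom_fraction >= 1.0:
            raise ValueError("zoom_fraction must be < 1")


def resize_pair(
    image: np.ndarray, mask: np.ndarray, target: tuple[int, int]
) -> tuple[np.ndarray, np.ndarray]:
    """Resize an image/mask pair to ``target`` (H, W).

    Bilinear for the image, nearest-neighbour for the mask (stays binary).
    An identity target returns verbatim copies.
    """
    image = np.asarray(image)
    mask = np.asarray(mask)
    th, tw = target
    if th <= 0 or tw <= 0:
        raise ValueError(f"target size must be positive, got {target}")
    if image.shape[:2] != mask.shape[:2]:
        raise ShapeConsistencyError(
            f"image {image.shape[:2]} and mask {mask.shape[:2]} sizes differ"
        )
    if image.shape[:2] == (th, tw):
        return image.copy(), mask.copy()
    out_img = _sk_resize(
        image.astype(np.float64),
        (th, tw),
        order=1,
        preserve_range=True,
        anti_aliasing=image.shape[0] > th or image.shape[1] > tw,
    )
    mask_shape = (th, tw) + mask.shape[2:]
    out_mask = _sk_resize(
        mask.astype(np.float64),
        mask_shape,
        order=0,
        preserve_range=True,
        anti_aliasing=False,
    )
    return out_img.astype(image.dtype, copy=False), (out_mask > 0.5).astype(mask.dtype)


def gaussian_filter_slice(
    image: np.ndarray, sigma: float = 1.0, truncate: float = 2.0
) -> np.ndarray:
    """Low-pass Gaussian blur with a normalized kernel (reflect boundary).

    The kernel weights sum to one, so constants pass through unchanged and
    total intensity is conserved away from boundary effects.
    """
    if sigma <= 0:
        raise ValueError(f"sigma must be > 0, got {sigma}")
    return ndimage.gaussian_filter(
        np.asarray(image, dtype=np.float64), sigma=sigma, truncate=truncate, mode="reflect"
    )


def normalize(slc: GrayscaleSlice) -> GrayscaleSlice:
    """Map raw intensities to [0, 1] by dividing each pixel by 255.

    16-bit inputs are first rescaled into 8-bit range so the /255 step is
    well defined regardless of acquisition bit depth.

    Raises
    ------
    DoubleNormalizationError
        If the slice is already in the unit domain.
    """
    if slc.value_domain == "unit":
        raise DoubleNormalizationError(
            f"slice {slc.slice_id!r} is already normalized; refusing to divide by 255 twice"
        )
    pixels = np.asarray(slc.pixels, dtype=np.float64)
    if pixels.max(initial=0.0) > 255.0:  # 16-bit source
        pixels = pixels * (255.0 / 65535.0)
    return replace(slc, pixels=pixels / 255.0, value_domain="unit")


def normalize_array(image: np.ndarray) -> np.ndarray:
    """Array-level /255 normalization (guard lives on :func:`normalize`)."""
    return normalize(GrayscaleSlice(np.asarray(image))).pixels


def _zoom_to_size(arr: np.ndarray, scale: float, order: int) -> np.ndarray:
    """Scale a 2-D (or 2-D+channels) array about its center, then crop/pad
    back to the original size."""
    h, w = arr.shape[:2]
    zoom = [scale, scale] + [1.0] * (arr.ndim - 2)
    out = ndimage.zoom(arr.astype(np.float64), zoom, order=order, mode="constant", cval=0.0)
    zh, zw = out.shape[:2]
    if zh >= h:
        top, left = (zh - h) // 2, (zw - w) // 2
        out = out[top : top + h, left : left + w]
    else:
        pad_h, pad_w = h - zh, w - zw
        pad = [(pad_h // 2, pad_h - pad_h // 2), (pad_w // 2, pad_w - pad_w // 2)]
        pad += [(0, 0)] * (arr.ndim - 2)
        out = np.pad(out, pad, mode="constant")
    return out


def augment_pair(
    image: np.ndarray,
    mask: np.ndarray,
    policy: AugmentationPolicy,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Apply one random flip/rotate/zoom draw identically to image and mask.

    The same geometric transform is applied to both arrays; the mask uses
    nearest-neighbour interpolation and is re-binarized, the image bilinear.
    Output sizes equal input sizes. Deterministic given the generator state.
    """
    image = np.asarray(image)
    mask = np.asarray(mask)
    if image.shape[:2] != mask.shape[:2]:
        raise ShapeConsistencyError(
            f"image {image.shape[:2]} and mask {mask.shape[:2]} sizes differ"
        )
    do_flip = rng.random() < policy.horizontal_flip_prob
    angle = rng.uniform(-policy.rotation_limit, policy.rotation_limit)
    scale = rng.uniform(1.0 - policy.zoom_fraction, 1.0 + policy.zoom_fraction)

    img = image.astype(np.float64)
    msk = mask.astype(np.float64)
    if do_flip:
        img = img[:, ::-1]
        msk = msk[:, ::-1]
    if policy.rotation_limit > 0:
        img = ndimage.rotate(img, angle, reshape=False, order=1, mode="constant", cval=0.0)
        msk = ndimage.rotate(msk, angle, reshape=False, order=0, mode="constant", cval=0.0)
    if policy.zoom_fraction > 0:
        img = _zoom_to_size(img, scale, order=1)
        msk = _zoom_to_size(msk, scale, order=0)
    return img, (msk > 0.5).astype(mask.dtype)


def preprocess_slice(
    slc: GrayscaleSlice,
    mask: np.ndarray,
    target: tuple[int, int],
    sigma: float = 1.0,
) -> tuple[GrayscaleSlice, np.ndarray]:
    """Run the deterministic pipeline stages: resize -> filter -> normalize.

    Augmentation is train-only and applied separately, after this.
    """
    img, msk = resize_pair(slc.pixels, mask, target)
    img = gaussian_filter_slice(img, sigma=sigma)
    out = normalize(replace(slc, pixels=img))
    return out, msk
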