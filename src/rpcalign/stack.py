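"""Image collections as data matrices.

A batch of n same-size images is stored as a matrix ``N`` of shape
``(m, n)`` with ``m = width * height * channels`` and intensities
normalised to [0, 1].  Column i is the vectorisation of image i.

Vectorisation convention (fixed, required for bit-exact round trips):
channel-planar, row-major raster — all of channel 0 first (rows
concatenated left-to-right), then channel 1, then channel 2.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np
from scipy import ndimage

__all__ = ["ImageStack", "load_stack", "unstack", "save_images", "stack_images"]


@dataclass
class ImageStack:
    """Matrix of vectorized images plus the geometry needed to un-stack them.

    Attributes
    ----------
    data : ndarray, shape (m, n)
        Intensities in [0, 1]; column i is image i.
    width, height, channels : int
        Geometry; ``m == width * height * channels``; channels is 1 or 3.
    source_ids : list of str
        Ordered labels, one per column.
    """

    data: np.ndarray
    width: int
    height: int
    channels: int
    source_ids: list = field(default_factory=list)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("stack data must be a 2-D matrix")
        m = self.width * self.height * self.channels
        if self.data.shape[0] != m:
            raise ValueError(
                f"row count {self.data.shape[0]} != width*height*channels = {m}"
            )
        if self.channels not in (1, 3):
            raise ValueError("channels must be 1 or 3")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("stack contains non-finite values")
        if not self.source_ids:
            self.source_ids = [f"img_{i:03d}" for i in range(self.data.shape[1])]
        if len(self.source_ids) != self.data.shape[1]:
            raise ValueError("source_ids length must match column count")

    @property
    def m(self) -> int:
        return self.data.shape[0]

    @property
    def n(self) -> int:
        return self.data.shape[1]

    @property
    def shape(self):
        return self.data.shape

    def unstack(self, index: int) -> np.ndarray:
        return unstack(self, index)

    def images(self) -> list:
        """All columns as image arrays, in column order."""
        return [unstack(self, i) for i in range(self.n)]

    def copy_with(self, data: np.ndarray) -> "ImageStack":
        """New stack with identical geometry but different data."""
        return ImageStack(
            data=np.asarray(data, float),
            width=self.width,
            height=self.height,
            channels=self.channels,
            source_ids=list(self.source_ids),
        )


def vectorize(img: np.ndarray) -> np.ndarray:
    """Vectorize an image (h, w) or (h, w, c) channel-planar, row-major."""
    img = np.asarray(img, dtype=float)
    if img.ndim == 2:
        return img.reshape(-1).copy()
    return np.moveaxis(img, 2, 0).reshape(-1).copy()


def unvectorize(v: np.ndarray, height: int, width: int, channels: int) -> np.ndarray:
    """Inverse of :func:`vectorize`; returns (h, w) for 1 channel, else (h, w, c)."""
    planes = np.asarray(v, dtype=float).reshape(channels, height, width)
    if channels == 1:
        return planes[0].copy()
    return np.moveaxis(planes, 0, 2).copy()


def stack_images(images: Sequence[np.ndarray], source_ids=None) -> ImageStack:
    """Stack same-geometry in-memory image arrays into an ImageStack."""
    if len(images) == 0:
        raise ValueError("no images to stack")
    first = np.asarray(images[0])
    h, w = first.shape[:2]
    c = 1 if first.ndim == 2 else first.shape[2]
    cols = []
    for img in images:
        a = np.asarray(img, float)
        if a.shape[:2] != (h, w) or (1 if a.ndim == 2 else a.shape[2]) != c:
            raise ValueError("all images must share the same geometry")
        cols.append(vectorize(a))
    return ImageStack(
        data=np.stack(cols, axis=1),
        width=w,
        height=h,
        channels=c,
        source_ids=list(source_ids) if source_ids else [],
    )


def _to_unit_range(img: np.ndarray) -> np.ndarray:
    """Rescale a decoded image to float64 in [0, 1] based on its dtype."""
    if img.dtype == np.uint8:
        return img.astype(float) / 255.0
    if img.dtype == np.uint16:
        return img.astype(float) / 65535.0
    if img.dtype == bool:
        return img.astype(float)
    out = img.astype(float)
    return np.clip(out, 0.0, 1.0)


def _resize_bilinear(img: np.ndarray, target_wh) -> np.ndarray:
    """Bilinear resize with half-pixel centre alignment."""
    tw, th = target_wh
    h, w = img.shape[:2]
    xs = (np.arange(tw) + 0.5) * (w / tw) - 0.5
    ys = (np.arange(th) + 0.5) * (h / th) - 0.5
    gx, gy = np.meshgrid(np.clip(xs, 0, w - 1), np.clip(ys, 0, h - 1))
    if img.ndim == 2:
        return ndimage.map_coordinates(img, [gy, gx], order=1, mode="nearest")
    chans = [
        ndimage.map_coordinates(img[:, :, k], [gy, gx], order=1, mode="nearest")
        for k in range(img.shape[2])
    ]
    return np.stack(chans, axis=2)


def load_stack(paths, target_size=None, grayscale: bool = False) -> ImageStack:
    """Load an ordered list of image files into an ImageStack.

    Parameters
    ----------
    paths : sequence of path-like
        At least 2 for decomposition work (a single path is accepted for
        plumbing, e.g. round-trip checks).
    target_size : (width, height), optional
        Resize every image (bilinear).  Required if the input sizes differ.
    grayscale : bool
        Reduce colour images to one channel by channel mean.
    """
    paths = [Path(p) for p in paths]
    if len(paths) == 0:
        raise ValueError("no input paths given")
    imgs = []
    for p in paths:
        try:
            raw = iio.imread(p)
        except FileNotFoundError:
            raise FileNotFoundError(f"unreadable image file: {p}")
        except Exception as exc:  # codec errors
            raise ValueError(f"unreadable image file: {p}: {exc}") from exc
        if raw.ndim == 3 and raw.shape[2] == 4:  # drop alpha
            raw = raw[:, :, :3]
        img = _to_unit_range(raw)
        if grayscale and img.ndim == 3:
            img = img.mean(axis=2)
        imgs.append(img)

    chans = {1 if im.ndim == 2 else im.shape[2] for im in imgs}
    if len(chans) > 1:
        raise ValueError(
            "mixed channel counts across inputs; pass grayscale=True to unify"
        )
    sizes = {im.shape[:2] for im in imgs}
    if len(sizes) > 1 and target_size is None:
        raise ValueError("input sizes differ; a target_size is required")
    if target_size is not None:
        imgs = [
            im
            if im.shape[:2] == (target_size[1], target_size[0])
            else _resize_bilinear(im, target_size)
            for im in imgs
        ]
    return stack_images(imgs, source_ids=[p.stem for p in paths])


def unstack(stack: ImageStack, index: int) -> np.ndarray:
    """Column ``index`` as an image array; exact inverse of the vectorisation."""
    if not (0 <= index < stack.n):
        raise IndexError(f"column index {index} out of range [0, {stack.n})")
    return unvectorize(stack.data[:, index], stack.height, stack.width, stack.channels)


def save_images(stack: ImageStack, directory, fmt: str = "png") -> list:
    """Write one file per column; returns the written paths.

    Values are clipped to [0, 1] then quantised: png/jpeg to 8 bits,
    tiff to 16 bits.
    """
    if fmt not in ("png", "tiff", "jpeg"):
        raise ValueError(f"unsupported format: {fmt}")
    if not str(directory):
        raise OSError("empty output directory")
    directory = Path(directory)
    try:
        os.makedirs(directory, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create output directory {directory}: {exc}") from exc
    ext = {"png": "png", "tiff": "tif", "jpeg": "jpg"}[fmt]
    out = []
    for i in range(stack.n):
        img = np.clip(unstack(stack, i), 0.0, 1.0)
        if fmt == "tiff":
            q = np.round(img * 65535.0).astype(np.uint16)
        else:
            q = np.round(img * 255.0).astype(np.uint8)
        path = directory / f"{stack.source_ids[i]}.{ext}"
        iio.imwrite(path, q)
        out.append(path)
    return out
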