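"""Per-image affine warps, their Jacobians, and the alignment update.

Convention: each image i carries 6 parameters theta = (t1..t6) forming

    A(theta) = [[t1, t2, t3],
                [t4, t5, t6]]

which maps *output* pixel coordinates (x, y, 1)^T (0-based, x = column,
y = row) to *input* coordinates — inverse warping, so every output pixel
is defined and no holes appear.  Identity is (1, 0, 0, 0, 1, 0).
Sampling is bilinear with edge-clamped (replicate-border) coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .stack import ImageStack, stack_images

__all__ = [
    "TransformSet",
    "JacobianSet",
    "identity_params",
    "warp_image",
    "warp_stack",
    "jacobian",
    "delta_tau_update",
    "accumulate",
    "transforms_to_csv",
    "transforms_from_csv",
]

P_AFFINE = 6
IDENTITY = np.array([1.0, 0.0, 0.0, 0.0, 1.0, 0.0])


def identity_params(n: int) -> np.ndarray:
    """(6, n) parameter matrix of identity transforms."""
    return np.tile(IDENTITY[:, None], (1, n))


@dataclass
class TransformSet:
    """Affine parameters for a batch of images: one 6-vector per column."""

    params: np.ndarray  # (6, n)

    def __post_init__(self):
        self.params = np.asarray(self.params, float)
        if self.params.ndim != 2 or self.params.shape[0] != P_AFFINE:
            raise ValueError("params must have shape (6, n)")
        if not np.all(np.isfinite(self.params)):
            raise ValueError("transform parameters must be finite")

    @classmethod
    def identity(cls, n: int) -> "TransformSet":
        return cls(identity_params(n))

    @property
    def n(self) -> int:
        return self.params.shape[1]

    def theta(self, i: int) -> np.ndarray:
        return self.params[:, i]

    def translations(self) -> np.ndarray:
        """(2, n) array of (tx, ty) translation components."""
        return self.params[[2, 5], :]


@dataclass
class JacobianSet:
    """Per-image m x 6 Jacobians of vec(warped image) w.r.t. the parameters."""

    jacobians: list = field(default_factory=list)
    masks: list = field(default_factory=list)  # per-image valid-pixel masks, len m

    @property
    def n(self) -> int:
        return len(self.jacobians)


def _affine_matrix(theta) -> np.ndarray:
    theta = np.asarray(theta, float)
    if theta.shape != (P_AFFINE,):
        raise ValueError("theta must be a 6-vector")
    return theta.reshape(2, 3)


def _source_coords(theta, out_shape):
    """Source (sx, sy) grids and the in-bounds mask for an output grid."""
    h, w = out_shape
    A = _affine_matrix(theta)
    det = A[0, 0] * A[1, 1] - A[0, 1] * A[1, 0]
    if abs(det) < 1e-12:
        raise ValueError("degenerate affine transform (|det| < 1e-12)")
    gx, gy = np.meshgrid(np.arange(w, dtype=float), np.arange(h, dtype=float))
    sx = A[0, 0] * gx + A[0, 1] * gy + A[0, 2]
    sy = A[1, 0] * gx + A[1, 1] * gy + A[1, 2]
    return sx, sy, gx, gy


def _valid_mask(sx, sy, in_shape):
    h, w = in_shape
    return (sx >= 0) & (sx <= w - 1) & (sy >= 0) & (sy <= h - 1)


def _sample(plane, sx, sy):
    return ndimage.map_coordinates(plane, [sy, sx], order=1, mode="nearest")


def warp_image(image: np.ndarray, theta, out_shape=None) -> np.ndarray:
    """Inverse-warp an image by A(theta) with bilinear sampling.

    Identity parameters reproduce the input exactly (bit-level): the sample
    coordinates are then exact integers and bilinear interpolation reduces
    to a lookup.
    """
    image = np.asarray(image, float)
    if not np.all(np.isfinite(image)):
        raise ValueError("image must be finite")
    in_shape = image.shape[:2]
    if out_shape is None:
        out_shape = in_shape
    sx, sy, _, _ = _source_coords(theta, out_shape)
    if image.ndim == 2:
        return _sample(image, sx, sy)
    return np.stack(
        [_sample(image[:, :, k], sx, sy) for k in range(image.shape[2])], axis=2
    )


def warp_stack(images, transforms: TransformSet) -> ImageStack:
    """Stack per-image warps: column i is vec(warp_image(images[i], tau_i)).

    This is the transformed data matrix used in all solver residuals.
    """
    if len(images) != transforms.n:
        raise ValueError(
            f"{len(images)} images but {transforms.n} transform columns"
        )
    warped = [warp_image(img, transforms.theta(i)) for i, img in enumerate(images)]
    return stack_images(warped)


def jacobian(image: np.ndarray, theta) -> np.ndarray:
    """m x 6 Jacobian of vec(warped image) with respect to theta.

    Central-difference spatial gradients of the warped image are combined
    with the derivative of the source coordinates, giving columns
    [Ix*x, Ix*y, Ix, Iy*x, Iy*y, Iy] over the output grid.  Rows whose
    source coordinates fall outside the input domain (edge-clamped samples)
    are zeroed.
    """
    image = np.asarray(image, float)
    if not np.all(np.isfinite(image)):
        raise ValueError("image must be finite")
    in_shape = image.shape[:2]
    sx, sy, gx, gy = _source_coords(theta, in_shape)
    mask = _valid_mask(sx, sy, in_shape)

    planes = [image] if image.ndim == 2 else [image[:, :, k] for k in range(image.shape[2])]
    cols = []
    for plane in planes:
        warped = _sample(plane, sx, sy)
        iy, ix = np.gradient(warped)
        J = np.stack(
            [ix * gx, ix * gy, ix, iy * gx, iy * gy, iy], axis=-1
        )  # (h, w, 6)
        J[~mask] = 0.0
        cols.append(J.reshape(-1, P_AFFINE))
    return np.concatenate(cols, axis=0)


def jacobian_set(images, transforms: TransformSet) -> JacobianSet:
    """Jacobians and valid-pixel masks for every image at its transform."""
    jacs, masks = [], []
    for i, img in enumerate(images):
        theta = transforms.theta(i)
        jacs.append(jacobian(img, theta))
        arr = np.asarray(img, float)
        sx, sy, _, _ = _source_coords(theta, arr.shape[:2])
        mask2d = _valid_mask(sx, sy, arr.shape[:2])
        c = 1 if arr.ndim == 2 else arr.shape[2]
        masks.append(np.tile(mask2d.reshape(-1), c))
    return JacobianSet(jacobians=jacs, masks=masks)


def delta_tau_update(residual: np.ndarray, jacobians: JacobianSet) -> np.ndarray:
    """Per-image least-squares alignment step.

    Column i of the output is the minimum-norm solution of
    ``J_i @ dtau_i ~= residual[:, i]`` — the Moore-Penrose pseudoinverse
    applied to the residual, image by image.
    """
    residual = np.asarray(residual, float)
    if residual.ndim != 2 or residual.shape[1] != jacobians.n:
        raise ValueError("residual column count must match jacobian count")
    delta = np.zeros((P_AFFINE, residual.shape[1]))
    for i, J in enumerate(jacobians.jacobians):
        if J.shape[0] != residual.shape[0]:
            raise ValueError("jacobian row count must match residual rows")
        delta[:, i] = np.linalg.lstsq(J, residual[:, i], rcond=None)[0]
    return delta


def accumulate(transforms: TransformSet, delta: np.ndarray) -> TransformSet:
    """Additive parameter update ``tau <- tau + delta`` (the linearised rule)."""
    delta = np.asarray(delta, float)
    if delta.shape != transforms.params.shape:
        raise ValueError("delta shape must match transform parameters")
    if not np.all(np.isfinite(delta)):
        raise ValueError("delta must be finite")
    return TransformSet(transforms.params + delta)


_CSV_COLS = [f"theta{k}" for k in range(1, 7)]


def transforms_to_csv(transforms: TransformSet, path) -> None:
    """One row per image, columns theta1..theta6, with header."""
    pd.DataFrame(transforms.params.T, columns=_CSV_COLS).to_csv(path, index=False)


def transforms_from_csv(path) -> TransformSet:
    df = pd.read_csv(path)
    return TransformSet(df[_CSV_COLS].to_numpy().T)
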