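"""Ground-truth-bearing synthetic fixtures.

The generator emulates the statistical structure the decomposition
assumes: stacks of highly correlated (exactly low-rank) smooth images,
column- or entry-sparse corruption, small affine misalignments, and the
dense photometric degradations seen in low-quality fundus photography
(blur, uneven illumination, circular artifacts).  Every fixture carries
its exact ground truth and is bit-reproducible from (recipe, seed).

Bookkeeping contract: for a bundle with clean images X_i, true per-image
warps g_i, dense photometric residual D and sparse matrix E*,

    degraded_column_i = vec(warp(X_i, g_i)) + D[:, i] + E*[:, i]

holds to numerical precision.  Dense degradations are deliberately NOT
folded into E*: the model treats them only implicitly, so fixtures that
include them are for metric/direction tests, not exact-recovery claims.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from math import ceil, cos, radians, sin
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

from .align import TransformSet, transforms_from_csv, transforms_to_csv, warp_image
from .stack import ImageStack, save_images, stack_images, vectorize

__all__ = [
    "FixtureBundle",
    "make_lowrank_stack",
    "add_sparse_corruption",
    "add_misalignment",
    "add_photometric_degradations",
    "make_fixture",
    "export_fixture",
    "load_fixture",
    "SCENARIOS",
]


@dataclass
class FixtureBundle:
    """A degraded stack together with its exact generating ground truth."""

    clean_stack: ImageStack
    degraded_images: list
    true_sparse: np.ndarray
    true_transforms: TransformSet
    dense_residual: np.ndarray
    recipe: dict = field(default_factory=dict)

    @property
    def degraded_stack(self) -> ImageStack:
        return stack_images(self.degraded_images,
                            source_ids=list(self.clean_stack.source_ids))

    def bookkeeping_error(self) -> float:
        """Max abs deviation of the stated decomposition from the degraded data."""
        n = self.clean_stack.n
        recon = np.stack(
            [
                vectorize(
                    warp_image(self.clean_stack.unstack(i),
                               self.true_transforms.theta(i))
                )
                for i in range(n)
            ],
            axis=1,
        )
        recon = recon + self.dense_residual + self.true_sparse
        return float(np.max(np.abs(recon - self.degraded_stack.data)))


def make_lowrank_stack(width, height, channels, n, rank, seed,
                       smooth_sigma: float = 3.0) -> ImageStack:
    """Exactly rank-`rank` stack of smooth images with entries in [0, 1].

    Factor images are seeded uniform noise, low-pass filtered (so spatial
    gradients exist for alignment), contrast-normalised to [0, 1], and
    combined as A @ B.T / rank with B uniform in [0, 1].
    """
    m = width * height * channels
    if rank < 1 or rank > min(m, n):
        raise ValueError(f"rank {rank} infeasible for {m}x{n}")
    rng = np.random.default_rng(seed)
    cols = []
    for _ in range(rank):
        planes = []
        for _c in range(channels):
            f = rng.uniform(size=(height, width))
            if smooth_sigma > 0:
                f = gaussian_filter(f, smooth_sigma, mode="reflect")
            lo, hi = f.min(), f.max()
            f = (f - lo) / (hi - lo) if hi > lo else np.zeros_like(f)
            planes.append(f.reshape(-1))
        cols.append(np.concatenate(planes))
    A = np.stack(cols, axis=1)  # (m, rank)
    B = rng.uniform(size=(n, rank))
    data = A @ B.T / rank
    return ImageStack(data=data, width=width, height=height, channels=channels)


def add_sparse_corruption(stack: ImageStack, fraction: float, magnitude: float,
                          mode: str = "uniform_entries", seed: int = 0):
    """Corrupt a stack sparsely; returns (corrupted stack, exact E).

    uniform_entries: each entry independently hit with probability
    `fraction` by +-magnitude (seeded signs).  whole_columns:
    ceil(fraction * n) columns receive dense uniform noise, emulating
    outlier images (the regime the L2,1 penalty targets).  The result is
    clipped to [0, 1] and E is recorded *post-clipping*, so
    corrupted = clean + E holds exactly.
    """
    if not (0 <= fraction <= 0.5):
        raise ValueError("fraction must lie in [0, 0.5]")
    if mode not in ("uniform_entries", "whole_columns"):
        raise ValueError(f"unknown corruption mode: {mode}")
    rng = np.random.default_rng(seed)
    clean = stack.data
    m, n = clean.shape
    raw = clean.copy()
    if fraction > 0:
        if mode == "uniform_entries":
            hit = rng.random((m, n)) < fraction
            signs = rng.choice([-1.0, 1.0], size=(m, n))
            raw = clean + hit * signs * magnitude
        else:
            k = ceil(fraction * n)
            cols = rng.choice(n, size=k, replace=False)
            noise = rng.uniform(-magnitude, magnitude, size=(m, k))
            raw[:, cols] = clean[:, cols] + noise
    E = np.clip(raw, 0.0, 1.0) - clean
    # re-materialise so that corrupted == clean + E holds bitwise
    corrupted = clean + E
    return stack.copy_with(corrupted), E


def add_misalignment(images, max_shift_px: float, max_rot_deg: float, seed: int = 0):
    """Apply seeded small affine perturbations; returns (images, TransformSet).

    Each image is warped by a rotation in [-max_rot, max_rot] degrees about
    the image centre composed with a translation in [-max_shift,
    max_shift] pixels per axis; the exact parameters used are returned.
    """
    if max_shift_px < 0 or max_rot_deg < 0:
        raise ValueError("perturbation bounds must be nonnegative")
    if max_rot_deg > 5:
        raise ValueError("rotations above 5 degrees violate the small-warp regime")
    rng = np.random.default_rng(seed)
    params = np.zeros((6, len(images)))
    out = []
    for i, img in enumerate(images):
        h, w = np.asarray(img).shape[:2]
        ang = radians(rng.uniform(-max_rot_deg, max_rot_deg))
        tx, ty = rng.uniform(-max_shift_px, max_shift_px, size=2)
        ca, sa = cos(ang), sin(ang)
        # rotate about the image centre, then translate
        cx, cy = (w - 1) / 2.0, (h - 1) / 2.0
        theta = np.array([
            ca, -sa, cx - ca * cx + sa * cy + tx,
            sa, ca, cy - sa * cx - ca * cy + ty,
        ])
        params[:, i] = theta
        out.append(warp_image(img, theta))
    return out, TransformSet(params)


def add_photometric_degradations(images, blur_sigma: float = 0.0,
                                 illum_strength: float = 0.0,
                                 artifact_count: int = 0,
                                 artifact_radius: float = 3.0,
                                 seed: int = 0):
    """Dense fundus-style degradations: blur, illumination ramp, spot artifacts.

    Blur uses a normalised Gaussian kernel with mirror boundary (the image
    mean is preserved exactly).  Illumination multiplies by a linear ramp
    1 + s*u with u in [-1, 1] along a seeded random direction.  Artifacts
    are seeded circular discs of intensity offset +-0.3.  All parameters
    zero returns the input unchanged.
    """
    if blur_sigma < 0 or illum_strength < 0 or artifact_count < 0:
        raise ValueError("degradation parameters must be nonnegative")
    rng = np.random.default_rng(seed)
    out = []
    for img in images:
        a = np.asarray(img, float).copy()
        h, w = a.shape[:2]
        if blur_sigma > 0:
            if a.ndim == 2:
                a = gaussian_filter(a, blur_sigma, mode="reflect")
            else:
                for k in range(a.shape[2]):
                    a[:, :, k] = gaussian_filter(a[:, :, k], blur_sigma,
                                                 mode="reflect")
        if illum_strength > 0:
            phi = rng.uniform(0, 2 * np.pi)
            gx, gy = np.meshgrid(np.linspace(-1, 1, w), np.linspace(-1, 1, h))
            u = gx * np.cos(phi) + gy * np.sin(phi)
            u = u / max(np.abs(u).max(), 1e-12)
            fieldm = 1.0 + illum_strength * u
            a = a * (fieldm if a.ndim == 2 else fieldm[:, :, None])
        if artifact_count > 0:
            gx, gy = np.meshgrid(np.arange(w, dtype=float),
                                 np.arange(h, dtype=float))
            r = artifact_radius
            for _ in range(artifact_count):
                cx = rng.uniform(r, w - 1 - r)
                cy = rng.uniform(r, h - 1 - r)
                off = rng.choice([-0.3, 0.3])
                disc = (gx - cx) ** 2 + (gy - cy) ** 2 <= r**2
                if a.ndim == 2:
                    a[disc] += off
                else:
                    a[disc, :] += off
        out.append(np.clip(a, 0.0, 1.0))
    return out


SCENARIOS = {
    # classical convex-recovery regime: incoherent rank-2, 5% entry corruption
    "rpca_convex": dict(width=50, height=50, channels=1, n=20, rank=2,
                        smooth_sigma=0.0,
                        sparse_fraction=0.05, sparse_magnitude=0.5,
                        sparse_mode="uniform_entries",
                        max_shift_px=0.0, max_rot_deg=0.0,
                        blur_sigma=0.0, illum_strength=0.0,
                        artifact_count=0, artifact_radius=0.0),
    # outlier-image regime for the weighted + L2,1 path
    "wnnm_stack": dict(width=40, height=40, channels=1, n=12, rank=3,
                       smooth_sigma=2.0,
                       sparse_fraction=0.15, sparse_magnitude=0.3,
                       sparse_mode="whole_columns",
                       max_shift_px=0.0, max_rot_deg=0.0,
                       blur_sigma=0.0, illum_strength=0.0,
                       artifact_count=0, artifact_radius=0.0),
    # smooth rank-1 stack with known sub-2-pixel translations
    "misaligned": dict(width=50, height=50, channels=1, n=10, rank=1,
                       smooth_sigma=5.0,
                       sparse_fraction=0.0, sparse_magnitude=0.0,
                       sparse_mode="uniform_entries",
                       max_shift_px=2.0, max_rot_deg=0.0,
                       blur_sigma=0.0, illum_strength=0.0,
                       artifact_count=0, artifact_radius=0.0),
    # the full degradation cocktail: misalignment + blur + illumination
    # + artifacts + sparse corruption
    "full_degraded": dict(width=64, height=64, channels=1, n=12, rank=2,
                          smooth_sigma=3.0,
                          sparse_fraction=0.02, sparse_magnitude=0.4,
                          sparse_mode="uniform_entries",
                          max_shift_px=1.0, max_rot_deg=0.5,
                          blur_sigma=0.8, illum_strength=0.2,
                          artifact_count=3, artifact_radius=4.0),
}


def make_fixture(scenario, seed: int = 0, **overrides) -> FixtureBundle:
    """Compose a named scenario (or explicit recipe dict) into a bundle."""
    if isinstance(scenario, dict):
        recipe = dict(scenario)
        name = recipe.pop("name", "custom")
    else:
        name = scenario
        if name not in SCENARIOS:
            raise ValueError(
                f"unknown scenario {name!r}; choose from {sorted(SCENARIOS)}"
            )
        recipe = dict(SCENARIOS[name])
    recipe.update(overrides)
    r = recipe

    clean = make_lowrank_stack(r["width"], r["height"], r["channels"], r["n"],
                               r["rank"], seed=seed,
                               smooth_sigma=r["smooth_sigma"])
    images = clean.images()

    if r["max_shift_px"] > 0 or r["max_rot_deg"] > 0:
        warped, true_tf = add_misalignment(images, r["max_shift_px"],
                                           r["max_rot_deg"], seed=seed + 1)
    else:
        warped, true_tf = images, TransformSet.identity(clean.n)

    dense = add_photometric_degradations(
        warped, blur_sigma=r["blur_sigma"], illum_strength=r["illum_strength"],
        artifact_count=r["artifact_count"], artifact_radius=r["artifact_radius"],
        seed=seed + 2,
    )
    warped_mat = np.stack([vectorize(im) for im in warped], axis=1)
    dense_mat = np.stack([vectorize(im) for im in dense], axis=1)
    dense_residual = dense_mat - warped_mat

    pre_sparse = stack_images(dense, source_ids=list(clean.source_ids))
    corrupted, E = add_sparse_corruption(
        pre_sparse, r["sparse_fraction"], r["sparse_magnitude"],
        mode=r["sparse_mode"], seed=seed + 3,
    )
    return FixtureBundle(
        clean_stack=clean,
        degraded_images=corrupted.images(),
        true_sparse=E,
        true_transforms=true_tf,
        dense_residual=dense_residual,
        recipe={"name": name, "seed": int(seed), **r},
    )


def export_fixture(bundle: FixtureBundle, directory) -> dict:
    """Write a fixture as PNG directories + transform CSV + recipe JSON."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "degraded": directory / "degraded",
        "clean": directory / "clean",
        "transforms": directory / "true_transforms.csv",
        "recipe": directory / "recipe.json",
    }
    save_images(bundle.degraded_stack, paths["degraded"], fmt="png")
    save_images(bundle.clean_stack, paths["clean"], fmt="png")
    transforms_to_csv(bundle.true_transforms, paths["transforms"])
    with open(paths["recipe"], "w") as fh:
        json.dump(bundle.recipe, fh, indent=2, sort_keys=True)
    return paths


def load_fixture(directory) -> FixtureBundle:
    """Rebuild a bundle from an exported directory.

    The exact float-valued ground truth is regenerated deterministically
    from the recipe manifest (PNGs are 8-bit quantised); the exported
    transforms CSV is cross-checked against the regenerated one.
    """
    directory = Path(directory)
    with open(directory / "recipe.json") as fh:
        recipe = json.load(fh)
    seed = recipe.pop("seed")
    recipe.pop("name", None)
    bundle = make_fixture(recipe, seed=seed)
    saved_tf = transforms_from_csv(directory / "true_transforms.csv")
    if not np.allclose(saved_tf.params, bundle.true_transforms.params,
                       atol=1e-12):
        raise ValueError("exported transforms disagree with the recipe manifest")
    return bundle
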