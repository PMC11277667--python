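"""Full-reference image-quality metrics: PSNR, SSIM, PCC, VIF.

All metrics take a ground-truth image ``f`` and a test image ``f_hat`` on
the same [0, max_val] scale.  SSIM exists in two modes:

* ``windowed`` (default) — the standard local form: Gaussian-weighted
  (sigma 1.5, 11x11) local means/variances and the *covariance* cross
  term, averaged over the image with the filter border cropped.
* ``global`` — a single global evaluation with the product of standard
  deviations ``2*sigma_f*sigma_fhat`` as the middle factor.  This form
  equals 1 for any pair with matching means and variances, so it is kept
  for fidelity with formulations that print it, not as the default.

VIF here is the block-variance form: images are tiled into non-overlapping
blocks and the ratio of summed ``log2(1 + blockvar/sigma_v^2)`` terms is
returned (reference blocks in the numerator, difference blocks in the
denominator).  It is unbounded as f_hat -> f; identical inputs return the
+inf sentinel with a "perfect" flag in reports.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

__all__ = [
    "MetricsConfig",
    "MetricsReport",
    "psnr",
    "ssim",
    "pcc",
    "vif",
    "evaluate_stack",
]


@dataclass
class MetricsConfig:
    """Constants of the quality metrics.

    sigma_v2 is the VIF noise variance quoted on the 0-255 intensity scale
    (default 2.0) and rescaled internally to the working max_val.
    """

    max_val: float = 1.0
    ssim_mode: str = "windowed"  # or "global"
    C1: float | None = None  # default (0.01 * max_val)^2
    C2: float | None = None  # default (0.03 * max_val)^2
    window: int = 11
    window_sigma: float = 1.5
    vif_block: int = 8
    sigma_v2: float = 2.0

    def __post_init__(self):
        if self.C1 is None:
            self.C1 = (0.01 * self.max_val) ** 2
        if self.C2 is None:
            self.C2 = (0.03 * self.max_val) ** 2
        if self.C1 <= 0 or self.C2 <= 0:
            raise ValueError("C1 and C2 must be positive")
        if self.vif_block < 2:
            raise ValueError("vif_block must be >= 2")
        if self.sigma_v2 <= 0:
            raise ValueError("sigma_v2 must be positive")
        if self.window % 2 != 1 or self.window < 3:
            raise ValueError("window must be an odd size >= 3")
        if self.ssim_mode not in ("windowed", "global"):
            raise ValueError("ssim_mode must be 'windowed' or 'global'")


def _check_shapes(f, f_hat):
    f = np.asarray(f, float)
    f_hat = np.asarray(f_hat, float)
    if f.shape != f_hat.shape:
        raise ValueError(f"shape mismatch: {f.shape} vs {f_hat.shape}")
    return f, f_hat


def _to_gray(img: np.ndarray) -> np.ndarray:
    return img.mean(axis=2) if img.ndim == 3 else img


def psnr(f, f_hat, config: MetricsConfig | None = None) -> float:
    """Peak signal-to-noise ratio, 10*log10(max_val^2 / MSE), in dB.

    Identical images return the +inf sentinel.  All pixels and channels
    enter the MSE.
    """
    cfg = config or MetricsConfig()
    f, f_hat = _check_shapes(f, f_hat)
    mse = float(np.mean((f - f_hat) ** 2))
    if mse == 0.0:
        return math.inf
    return 10.0 * math.log10(cfg.max_val**2 / mse)


def _ssim_windowed(f, f_hat, cfg: MetricsConfig) -> float:
    win = cfg.window
    pad = (win - 1) // 2
    if min(f.shape) < win:
        raise ValueError(
            f"image smaller than the {win}x{win} window; use ssim_mode='global'"
        )
    filt = dict(sigma=cfg.window_sigma, radius=pad, mode="reflect")
    ux = gaussian_filter(f, **filt)
    uy = gaussian_filter(f_hat, **filt)
    uxx = gaussian_filter(f * f, **filt)
    uyy = gaussian_filter(f_hat * f_hat, **filt)
    uxy = gaussian_filter(f * f_hat, **filt)
    NP = win * win
    cov_norm = NP / (NP - 1)  # sample-covariance correction
    vx = cov_norm * (uxx - ux * ux)
    vy = cov_norm * (uyy - uy * uy)
    vxy = cov_norm * (uxy - ux * uy)
    S = ((2 * ux * uy + cfg.C1) * (2 * vxy + cfg.C2)) / (
        (ux**2 + uy**2 + cfg.C1) * (vx + vy + cfg.C2)
    )
    return float(S[pad:-pad, pad:-pad].mean())


def _ssim_global(f, f_hat, cfg: MetricsConfig) -> float:
    mf, mfh = float(f.mean()), float(f_hat.mean())
    sf, sfh = float(f.std()), float(f_hat.std())
    num = (2 * mf * mfh + cfg.C1) * (2 * sf * sfh + cfg.C2)
    den = (mf**2 + mfh**2 + cfg.C1) * (sf**2 + sfh**2 + cfg.C2)
    return num / den


def ssim(f, f_hat, config: MetricsConfig | None = None) -> float:
    """Structural similarity; 1.0 for identical images in both modes.

    Colour inputs are reduced to grayscale by channel mean first.
    """
    cfg = config or MetricsConfig()
    f, f_hat = _check_shapes(f, f_hat)
    f, f_hat = _to_gray(f), _to_gray(f_hat)
    if cfg.ssim_mode == "global":
        return _ssim_global(f, f_hat, cfg)
    return _ssim_windowed(f, f_hat, cfg)


def pcc(f, f_hat) -> float:
    """Pearson correlation of the vectorised pixel intensities."""
    f, f_hat = _check_shapes(f, f_hat)
    x = _to_gray(f).reshape(-1)
    y = _to_gray(f_hat).reshape(-1)
    if x.std() == 0.0 or y.std() == 0.0:
        raise ValueError("PCC undefined: at least one image is constant (0/0)")
    return float(np.corrcoef(x, y)[0, 1])


def _block_vars(img, B):
    h, w = img.shape
    hb, wb = h // B, w // B
    if hb < 1 or wb < 1:
        raise ValueError(f"block size {B} larger than image {img.shape}")
    crop = img[: hb * B, : wb * B]
    blocks = crop.reshape(hb, B, wb, B)
    return blocks.var(axis=(1, 3)).reshape(-1)  # population variance


def vif(f, f_hat, config: MetricsConfig | None = None) -> float:
    """Block-variance visual information fidelity ratio.

    sum_i log2(1 + var(f_i)/sigma_v^2) over sum_i log2(1 + var(f_i -
    fhat_i)/sigma_v^2), non-overlapping blocks (incomplete border blocks
    dropped).  Returns +inf when the denominator vanishes (f_hat ~= f).
    """
    cfg = config or MetricsConfig()
    f, f_hat = _check_shapes(f, f_hat)
    f, f_hat = _to_gray(f), _to_gray(f_hat)
    sv2 = cfg.sigma_v2 * (cfg.max_val / 255.0) ** 2
    num = float(np.log2(1.0 + _block_vars(f, cfg.vif_block) / sv2).sum())
    den = float(np.log2(1.0 + _block_vars(f - f_hat, cfg.vif_block) / sv2).sum())
    if den < 1e-12:
        return math.inf
    return num / den


@dataclass
class MetricsReport:
    """Per-image quality metrics plus aggregate means.

    ``table`` has one row per image (id, psnr, ssim, pcc, vif); infinite
    sentinels stay as +inf in memory, print as "inf" in CSV, and serialise
    as null with a boolean perfect-flag column in JSON.
    """

    table: pd.DataFrame
    metrics: list = field(default_factory=lambda: ["psnr", "ssim", "pcc", "vif"])

    def means(self) -> dict:
        return {m: float(self.table[m].mean()) for m in self.metrics}

    def _full_table(self) -> pd.DataFrame:
        mean_row = {"id": "mean", **self.means()}
        return pd.concat(
            [self.table, pd.DataFrame([mean_row])], ignore_index=True
        )

    def to_csv(self, path) -> None:
        self._full_table().to_csv(path, index=False)

    def to_json(self, path=None):
        rows = []
        for _, row in self._full_table().iterrows():
            rec = {"id": row["id"]}
            for m in self.metrics:
                v = float(row[m])
                rec[m] = None if math.isinf(v) else v
                rec[f"{m}_perfect"] = bool(math.isinf(v))
            rows.append(rec)
        if path is None:
            return rows
        with open(path, "w") as fh:
            json.dump(rows, fh, indent=2)
        return rows


def evaluate_stack(enhanced, reference, config: MetricsConfig | None = None,
                   metrics=None) -> MetricsReport:
    """Per-column metrics of an enhanced stack against a reference stack."""
    cfg = config or MetricsConfig()
    metrics = list(metrics) if metrics else ["psnr", "ssim", "pcc", "vif"]
    if enhanced.shape != reference.shape or (
        enhanced.width,
        enhanced.height,
        enhanced.channels,
    ) != (reference.width, reference.height, reference.channels):
        raise ValueError("enhanced and reference stacks have mismatched geometry")
    funcs = {
        "psnr": lambda a, b: psnr(b, a, cfg),
        "ssim": lambda a, b: ssim(b, a, cfg),
        "pcc": lambda a, b: pcc(b, a),
        "vif": lambda a, b: vif(b, a, cfg),
    }
    rows = []
    for i in range(enhanced.n):
        a = enhanced.unstack(i)
        b = reference.unstack(i)
        row = {"id": reference.source_ids[i]}
        for mname in metrics:
            row[mname] = funcs[mname](a, b)
        rows.append(row)
    return MetricsReport(table=pd.DataFrame(rows), metrics=metrics)
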