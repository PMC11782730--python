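"""Quality metrics for predicted vs. ground-truth B1+ maps.

Relative magnitude error, circular absolute phase difference, RMSE
(magnitude and complex), SSIM (magnitude, unwrapped phase, complex = mean
of real/imaginary SSIM), masked Pearson correlation, and a deterministic
brain-mask recipe (Otsu threshold + largest connected component + hole
fill).

All voxelwise metrics are mask-restricted. SSIM is computed in-package
with a 7x7 uniform window and the standard constants (k1=0.01, k2=0.03);
the data range defaults to the joint max of both images.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.stats import pearsonr
from scipy.ndimage import uniform_filter
from skimage.filters import threshold_otsu
from skimage.restoration import unwrap_phase


# ---------------------------------------------------------------------------
# Brain mask
# ---------------------------------------------------------------------------


def brain_mask(image) -> np.ndarray:
    """Binary tissue mask from a (H, W) or (n, H, W) combined-magnitude
    image or a multi-channel complex stack (last axis = channels).

    Otsu threshold on the log-compressed magnitude (robust to the strong
    receive-profile shading inside the object), then largest connected
    component and hole filling, per slice. Deterministic.
    """
    img = np.asarray(image)
    if np.iscomplexobj(img) and img.ndim >= 3:
        img = np.sqrt((np.abs(img) ** 2).sum(axis=-1))
    else:
        img = np.abs(img)
    squeeze = img.ndim == 2
    if squeeze:
        img = img[None]
    if not img.any():
        raise ValueError("all-zero image: cannot build a mask")
    out = np.zeros(img.shape, dtype=bool)
    for i, sl in enumerate(img):
        if not sl.any():
            continue
        logsl = np.log(sl + 1e-6 * sl.max())
        m = logsl > threshold_otsu(logsl)
        labels, n = ndimage.label(m)
        if n > 1:
            sizes = ndimage.sum(m, labels, index=np.arange(1, n + 1))
            m = labels == (1 + int(np.argmax(sizes)))
        out[i] = ndimage.binary_fill_holes(m)
    return out[0] if squeeze else out


# ---------------------------------------------------------------------------
# Voxelwise error metrics
# ---------------------------------------------------------------------------


def _check(pred, gt, mask):
    pred = np.asarray(pred)
    gt = np.asarray(gt)
    if pred.shape != gt.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {gt.shape}")
    if mask is None:
        mask = np.ones(pred.shape, dtype=bool)
    mask = np.broadcast_to(np.asarray(mask, dtype=bool), pred.shape)
    if not mask.any():
        raise ValueError("empty mask")
    return pred, gt, mask


def magnitude_rel_error(pred, gt, mask=None, per_voxel_denominator=False) -> float:
    """Mean relative magnitude error in percent.

    Default denominator is the mask-mean ground-truth magnitude (bounded
    near field nulls); ``per_voxel_denominator=True`` divides voxelwise by
    |gt| instead.
    """
    pred, gt, mask = _check(pred, gt, mask)
    diff = np.abs(np.abs(pred) - np.abs(gt))
    if per_voxel_denominator:
        g = np.abs(gt)
        valid = mask & (g > 0)
        if not valid.any():
            raise ValueError("no masked voxels with nonzero ground truth")
        return float(100.0 * np.mean(diff[valid] / g[valid]))
    denom = np.abs(gt)[mask].mean()
    return float(100.0 * np.mean(diff[mask]) / denom)


def phase_abs_diff(pred, gt, mask=None) -> float:
    """Mean absolute circular phase difference in degrees:
    mean |angle(pred * conj(gt))|; voxels with zero ground truth are
    excluded."""
    pred, gt, mask = _check(pred, gt, mask)
    valid = mask & (np.abs(gt) > 0) & (np.abs(pred) > 0)
    if not valid.any():
        raise ValueError("no masked voxels with nonzero fields")
    d = np.angle(pred[valid] * np.conj(gt[valid]))
    return float(np.rad2deg(np.mean(np.abs(d))))


def rmse(pred, gt, mask=None, mode="magnitude") -> float:
    """RMSE of the magnitudes (mode="magnitude") or of the complex
    difference |pred - gt| (mode="complex")."""
    pred, gt, mask = _check(pred, gt, mask)
    if mode == "magnitude":
        d = np.abs(pred) - np.abs(gt)
        return float(np.sqrt(np.mean(d[mask] ** 2)))
    if mode == "complex":
        d = np.abs(pred - gt)
        return float(np.sqrt(np.mean(d[mask] ** 2)))
    raise ValueError(f"unknown rmse mode {mode!r}")


# ---------------------------------------------------------------------------
# SSIM
# ---------------------------------------------------------------------------


def _ssim_real(x, y, win=7, k1=0.01, k2=0.03, data_range=None):
    """Standard SSIM with a uniform win x win window on real 2D images."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if min(x.shape) < win:
        raise ValueError(f"image smaller than the {win}x{win} SSIM window")
    if data_range is None:
        data_range = max(x.max() - x.min(), y.max() - y.min())
        if data_range == 0:
            data_range = 1.0
    c1, c2 = (k1 * data_range) ** 2, (k2 * data_range) ** 2
    mode = "constant"
    # crop to valid (fully inside) windows, matching the reference convention
    pad = win // 2
    ux = uniform_filter(x, win, mode=mode)
    uy = uniform_filter(y, win, mode=mode)
    uxx = uniform_filter(x * x, win, mode=mode)
    uyy = uniform_filter(y * y, win, mode=mode)
    uxy = uniform_filter(x * y, win, mode=mode)
    # unbiased (N-1) normalisation over the N = win^2 window samples
    n = win * win
    cov_norm = n / (n - 1)
    vx = cov_norm * (uxx - ux * ux)
    vy = cov_norm * (uyy - uy * uy)
    vxy = cov_norm * (uxy - ux * uy)
    s = ((2 * ux * uy + c1) * (2 * vxy + c2)) / (
        (ux ** 2 + uy ** 2 + c1) * (vx + vy + c2)
    )
    return float(s[pad:-pad, pad:-pad].mean())


def ssim(pred, gt, mode="magnitude", win=7, data_range=None) -> float:
    """SSIM between two complex 2D images (or stacks, averaged per slice).

    mode="magnitude": SSIM of |.|; mode="phase": SSIM of the unwrapped
    phase maps; mode="complex": mean of SSIM(Re) and SSIM(Im).
    """
    pred = np.asarray(pred)
    gt = np.asarray(gt)
    if pred.shape != gt.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {gt.shape}")
    if pred.ndim > 2:
        lead = pred.shape[:-2]
        vals = [
            ssim(pred[idx], gt[idx], mode=mode, win=win, data_range=data_range)
            for idx in np.ndindex(lead)
        ]
        return float(np.mean(vals))
    if mode == "magnitude":
        return _ssim_real(np.abs(pred), np.abs(gt), win, data_range=data_range)
    if mode == "phase":
        pu = unwrap_phase(np.angle(pred))
        gu = unwrap_phase(np.angle(gt))
        return _ssim_real(pu, gu, win, data_range=data_range)
    if mode == "complex":
        dr = data_range
        if dr is None:
            dr = max(
                np.abs(pred.real).max(),
                np.abs(gt.real).max(),
                np.abs(pred.imag).max(),
                np.abs(gt.imag).max(),
            ) * 2
        return 0.5 * (
            _ssim_real(pred.real, gt.real, win, data_range=dr)
            + _ssim_real(pred.imag, gt.imag, win, data_range=dr)
        )
    raise ValueError(f"unknown ssim mode {mode!r}")


# ---------------------------------------------------------------------------
# Pearson correlation
# ---------------------------------------------------------------------------


def pixelwise_correlation(pred, gt, mask=None, mode="magnitude") -> float:
    """Masked Pearson correlation of magnitudes or unwrapped phases.

    Phase mode unwraps both 2D maps before masking. Returns NaN for
    zero-variance inputs.
    """
    pred, gt, mask = _check(pred, gt, mask)
    if mode == "magnitude":
        a, b = np.abs(pred)[mask], np.abs(gt)[mask]
    elif mode == "phase":
        if pred.ndim != 2:
            raise ValueError("phase-mode correlation expects single 2D maps")
        a = np.asarray(unwrap_phase(np.angle(pred)))[mask]
        b = np.asarray(unwrap_phase(np.angle(gt)))[mask]
    else:
        raise ValueError(f"unknown correlation mode {mode!r}")
    if a.size < 3:
        raise ValueError("need at least 3 masked voxels")
    if np.std(a) == 0 or np.std(b) == 0:
        return float("nan")
    return float(pearsonr(a, b)[0])


# ---------------------------------------------------------------------------
# Report
# ---------------------------------------------------------------------------


def metrics_report(pred, gt, mask, subject="", orientation="") -> pd.DataFrame:
    """Flat per-slice metric table for a (n, H, W, C) prediction/target pair.

    Columns: subject, slice, orientation, metric, mode, value.
    """
    pred = np.asarray(pred)
    gt = np.asarray(gt)
    mask = np.asarray(mask, dtype=bool)
    rows = []
    for i in range(pred.shape[0]):
        m = mask[i][..., None]
        entries = {
            ("rel_error", "magnitude"): magnitude_rel_error(pred[i], gt[i], m),
            ("phase_diff", "phase"): phase_abs_diff(pred[i], gt[i], m),
            ("rmse", "magnitude"): rmse(pred[i], gt[i], m, "magnitude"),
            ("rmse", "complex"): rmse(pred[i], gt[i], m, "complex"),
            ("ssim", "magnitude"): ssim(pred[i], gt[i], "magnitude"),
            ("ssim", "complex"): ssim(pred[i], gt[i], "complex"),
            ("mask_voxels", ""): int(mask[i].sum()),
        }
        for (metric, mode), value in entries.items():
            rows.append(
                dict(
                    subject=subject,
                    slice=i,
                    orientation=orientation,
                    metric=metric,
                    mode=mode,
                    value=value,
                )
            )
    return pd.DataFrame(rows)
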