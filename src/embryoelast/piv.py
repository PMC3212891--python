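"""Particle image velocimetry by windowed cross-correlation.

A reference image (no force) and a deformed image (force applied) are
divided into square interrogation windows; each pair of windows is
mean-subtracted and cross-correlated in the frequency domain, and the
correlation peak is located to sub-pixel precision with a three-point
Gaussian fit (parabolic fallback when a neighbour is non-positive).  With
the defaults — 16 px windows, no overlap — a 640 x 512 image yields the
standard 40 x 32 displacement lattice.

The embryo's intrinsic optical texture provides the correlation signal;
no tracer particles are assumed.  Displacements are returned in um via
the pixel scale; grids are produced in the image frame (y down) and can
be moved to the model frame with
:meth:`~embryoelast.fields.DisplacementGrid.to_model_frame`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from .fields import DisplacementGrid

__all__ = ["ImagePair", "PivConfig", "PivError", "compute_piv_field", "subpixel_peak"]


class PivError(RuntimeError):
    """PIV could not produce a displacement field."""


@dataclass
class ImagePair:
    """Reference and deformed grayscale images with a common pixel scale."""

    reference: np.ndarray
    deformed: np.ndarray
    pixel_scale_um: float = 1.5

    def __post_init__(self):
        self.reference = np.asarray(self.reference, dtype=float)
        self.deformed = np.asarray(self.deformed, dtype=float)
        if self.reference.ndim != 2 or self.deformed.ndim != 2:
            raise ValueError("images must be 2D grayscale arrays")
        if self.reference.shape != self.deformed.shape:
            raise ValueError(
                f"image shapes differ: {self.reference.shape} vs {self.deformed.shape}"
            )
        if not self.pixel_scale_um > 0:
            raise ValueError("pixel_scale_um must be positive")


@dataclass
class PivConfig:
    """Interrogation parameters.

    ``min_contrast`` is the minimum window standard deviation relative to
    the whole-image standard deviation for a window to count as textured;
    ``outlier_filter='median'`` replaces vectors deviating from their 3x3
    neighbourhood median by more than ``median_threshold_px``.
    """

    window_size: int = 16
    overlap: int = 0
    subpixel_method: str = "gaussian3"
    min_contrast: float = 0.05
    outlier_filter: str = "none"
    median_threshold_px: float = 2.0

    def __post_init__(self):
        if self.window_size < 8:
            raise ValueError("window_size must be at least 8 px")
        if not 0 <= self.overlap < self.window_size:
            raise ValueError("overlap must satisfy 0 <= overlap < window_size")
        if self.subpixel_method not in ("gaussian3", "parabolic", "none"):
            raise ValueError("subpixel_method must be gaussian3|parabolic|none")
        if self.outlier_filter not in ("none", "median"):
            raise ValueError("outlier_filter must be none|median")


def _axis_fraction(cm: float, c0: float, cp: float, method: str) -> float:
    """Sub-pixel offset from a 3-point stencil (neighbour, peak, neighbour)."""
    if method == "none":
        return 0.0
    if method == "gaussian3" and cm > 0 and c0 > 0 and cp > 0:
        lm, l0, lp = np.log(cm), np.log(c0), np.log(cp)
        den = 2.0 * (lm + lp - 2.0 * l0)
        if den < 0:
            return float((lm - lp) / den)
    den = 2.0 * (cm + cp - 2.0 * c0)
    if den < 0:
        return float((cm - cp) / den)
    return 0.0


def subpixel_peak(
    corr_map: np.ndarray, method: str = "gaussian3"
) -> Optional[Tuple[float, float]]:
    """Fractional (dx, dy) offset of the correlation peak from its pixel.

    Fits a three-point Gaussian along each axis through the integer maximum
    (parabolic fallback when a neighbour is non-positive).  Returns None —
    flagged invalid — when the maximum sits on the map border or the map is
    flat.
    """
    c = np.asarray(corr_map, dtype=float)
    if c.ndim != 2:
        raise ValueError("corr_map must be 2D")
    if np.ptp(c) == 0:
        return None
    iy, ix = np.unravel_index(np.argmax(c), c.shape)
    if iy == 0 or ix == 0 or iy == c.shape[0] - 1 or ix == c.shape[1] - 1:
        return None
    dx = _axis_fraction(c[iy, ix - 1], c[iy, ix], c[iy, ix + 1], method)
    dy = _axis_fraction(c[iy - 1, ix], c[iy, ix], c[iy + 1, ix], method)
    return float(np.clip(dx, -1, 1)), float(np.clip(dy, -1, 1))


def _axis_fraction_vec(cm, c0, cp, method: str) -> np.ndarray:
    """Vectorised :func:`_axis_fraction` over stacks of stencils."""
    out = np.zeros(len(np.atleast_1d(c0)))
    cm, c0, cp = map(np.atleast_1d, (cm, c0, cp))
    if method == "none":
        return out
    pos = (cm > 0) & (c0 > 0) & (cp > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        lm = np.log(np.where(pos, cm, 1.0))
        l0 = np.log(np.where(pos, c0, 1.0))
        lp = np.log(np.where(pos, cp, 1.0))
        den_g = 2.0 * (lm + lp - 2.0 * l0)
        gauss = (method == "gaussian3") & pos & (den_g < 0)
        out = np.where(gauss, (lm - lp) / np.where(den_g != 0, den_g, 1.0), out)
        den_p = 2.0 * (cm + cp - 2.0 * c0)
        para = (~gauss) & (den_p < 0)
        out = np.where(para, (cm - cp) / np.where(den_p != 0, den_p, 1.0), out)
    return out


def _normalized_correlation_stack(
    ref_w: np.ndarray, def_w: np.ndarray, w: int
) -> np.ndarray:
    """Local NCC maps for stacks of window pairs.

    For each shift s within +-(w//2 - 1) px the correlation coefficient is
    computed over the actual overlap region with that region's own means
    and variances, so the coefficient lies in [-1, 1], is free of the
    triangular bias of plain zero-padded correlation, and equals 1 exactly
    for a perfect integer-shift match.  Returns (n_windows, K, K) with
    K = 2*(w//2 - 1) + 1 centred on zero shift.
    """
    n = 2 * w
    ones = np.ones((w, w))
    F1 = np.fft.rfft2(ones, s=(n, n))
    FA = np.fft.rfft2(ref_w, s=(n, n))
    FB = np.fft.rfft2(def_w, s=(n, n))
    FA2 = np.fft.rfft2(ref_w**2, s=(n, n))
    FB2 = np.fft.rfft2(def_w**2, s=(n, n))

    def corr(Fx, Fy):
        c = np.fft.irfft2(Fx * np.conj(Fy), s=(n, n))
        return np.roll(c, (w, w), axis=(-2, -1))

    m = w // 2 - 1
    sl = slice(w - m, w + m + 1)

    Cab = corr(FB, FA)[:, sl, sl]       # sum a*b over overlap
    Sa1 = corr(F1[None], FA)[:, sl, sl]   # sum a
    Sb1 = corr(FB, F1[None])[:, sl, sl]   # sum b
    Sa2 = corr(F1[None], FA2)[:, sl, sl]  # sum a^2
    Sb2 = corr(FB2, F1[None])[:, sl, sl]  # sum b^2
    s1 = np.abs(np.arange(-m, m + 1)).astype(float)
    N = (w - s1)[None, :, None] * (w - s1)[None, None, :]

    num = Cab - Sa1 * Sb1 / N
    va = np.clip(Sa2 - Sa1**2 / N, 0.0, None)
    vb = np.clip(Sb2 - Sb1**2 / N, 0.0, None)
    den = np.sqrt(va * vb)
    tiny = den <= 1e-12 * np.maximum(va.max(), 1e-30)
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = np.where(tiny, 0.0, num / np.where(tiny, 1.0, den))
    return np.clip(rho, -1.0, 1.0)


def _window_stack(img: np.ndarray, w: int, step: int, ny: int, nx: int) -> np.ndarray:
    """Stack of interrogation windows, shape (ny*nx, w, w)."""
    rows = np.arange(ny) * step
    cols = np.arange(nx) * step
    out = np.empty((ny * nx, w, w), dtype=float)
    k = 0
    for r in rows:
        for c in cols:
            out[k] = img[r : r + w, c : c + w]
            k += 1
    return out


def compute_piv_field(pair: ImagePair, config: Optional[PivConfig] = None) -> DisplacementGrid:
    """Displacement field between an image pair by windowed cross-correlation.

    One vector per window position; the correlation of mean-subtracted
    windows is computed via zero-padded FFTs and its peak located to
    sub-pixel precision.  Displacements are in um (image frame, y down);
    windows whose texture contrast is below ``min_contrast`` or whose
    correlation peak is degenerate are flagged invalid.
    """
    config = config or PivConfig()
    w = config.window_size
    step = w - config.overlap
    H, W = pair.reference.shape
    ny = (H - w) // step + 1
    nx = (W - w) // step + 1
    if ny < 2 or nx < 2:
        raise ValueError("images must span at least 2 windows per dimension")

    ref_w = _window_stack(pair.reference, w, step, ny, nx)
    def_w = _window_stack(pair.deformed, w, step, ny, nx)
    img_sd = float(np.std(pair.reference))
    contrast_ok = np.ones(ny * nx, dtype=bool)
    if img_sd > 0:
        sd_ref = ref_w.std(axis=(1, 2))
        sd_def = def_w.std(axis=(1, 2))
        contrast_ok = (sd_ref > config.min_contrast * img_sd) & (
            sd_def > config.min_contrast * img_sd
        )

    # normalised cross-correlation with per-shift local statistics
    # (zero-padded linear correlation; means and variances taken over the
    # actual overlap region for each shift).  Peak at shift s means
    # deformed(x) ~ reference(x - s), and a perfect match gives rho = 1.
    sub = _normalized_correlation_stack(ref_w, def_w, w)
    K = sub.shape[1]
    m = K // 2  # search radius in px
    flat = sub.reshape(len(sub), -1)
    peak = np.argmax(flat, axis=1)
    py, px = np.unravel_index(peak, (K, K))
    interior = (py > 0) & (px > 0) & (py < K - 1) & (px < K - 1)
    nonflat = np.ptp(flat, axis=1) > 0
    valid = contrast_ok & interior & nonflat

    u = np.zeros((ny * nx, 2))
    idx = np.arange(len(sub))
    pyc = np.clip(py, 1, K - 2)
    pxc = np.clip(px, 1, K - 2)
    c0 = sub[idx, pyc, pxc]
    frac_x = _axis_fraction_vec(
        sub[idx, pyc, pxc - 1], c0, sub[idx, pyc, pxc + 1], config.subpixel_method
    )
    frac_y = _axis_fraction_vec(
        sub[idx, pyc - 1, pxc], c0, sub[idx, pyc + 1, pxc], config.subpixel_method
    )
    # a numerically perfect match is an exact integer shift: the data carry
    # no evidence of a sub-pixel offset, so none is estimated
    exact = c0 >= 1.0 - 1e-7
    frac_x[exact] = 0.0
    frac_y[exact] = 0.0
    u[:, 0] = (px - m) + np.clip(frac_x, -1, 1)
    u[:, 1] = (py - m) + np.clip(frac_y, -1, 1)
    u[~valid] = np.nan

    if not np.any(valid):
        raise PivError("all interrogation windows are invalid; empty field")

    u = u.reshape(ny, nx, 2)
    valid = valid.reshape(ny, nx)

    if config.outlier_filter == "median":
        u, valid = _median_filter_vectors(u, valid, config.median_threshold_px)

    # window-centre coordinates, mm, image frame (y down)
    scale = pair.pixel_scale_um
    x = (np.arange(nx) * step + (w - 1) / 2.0) * scale / 1000.0
    y = (np.arange(ny) * step + (w - 1) / 2.0) * scale / 1000.0
    return DisplacementGrid(
        x=x,
        y=y,
        u=u * scale,
        valid=valid,
        frame="image",
        meta={"window_size": w, "overlap": config.overlap,
              "pixel_scale_um": scale},
    )


def _median_filter_vectors(u: np.ndarray, valid: np.ndarray, threshold_px: float):
    """Replace vectors far from their 3x3 neighbourhood median."""
    from scipy.ndimage import generic_filter

    out = u.copy()
    med = np.empty_like(u)
    for k in range(2):
        comp = np.where(valid, u[..., k], np.nan)
        med[..., k] = generic_filter(comp, np.nanmedian, size=3, mode="nearest")
    dev = np.sqrt(np.sum((u - med) ** 2, axis=-1))
    bad = valid & (dev > threshold_px)
    out[bad] = med[bad]
    return out, valid
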