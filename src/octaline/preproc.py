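"""Polar-frame preprocessing: lumen detection, guidewire zeroing, pixel
shifting, 200-sample cropping, log compression, and Gaussian smoothing.

The lumen boundary is found by dynamic programming over an edge-strength
image: the positive part of the radial derivative of the Gaussian-smoothed
frame.  The contour maximises the cumulative edge strength subject to a
per-step smoothness bound, with circular closure across the theta seam.

All indices are 0-based; r increases away from the catheter.  The detected
contour value is the radial index of the boundary itself; pixel shifting
moves each column up by contour+1 so index 0 is the first sample beyond the
boundary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .sim import GUIDEWIRE, Pullback

__all__ = [
    "LumenContour",
    "ProcessedALine",
    "detect_lumen",
    "detect_guidewire",
    "zero_guidewire",
    "pixel_shift",
    "crop_log_smooth",
    "preprocess_pullback",
    "preprocess_pullback_arrays",
]

N_KEEP = 200  # samples retained per A-line (~1 mm at 5 um/px)


@dataclass
class LumenContour:
    radius_px: np.ndarray  # (n_alines,) int

    def __post_init__(self) -> None:
        self.radius_px = np.asarray(self.radius_px, dtype=int)


@dataclass
class ProcessedALine:
    values: np.ndarray  # (200,) float
    frame_index: int
    aline_index: int
    label: int | None = None
    pullback_id: str = ""


def edge_strength(frame: np.ndarray, sigma: float = 1.0) -> np.ndarray:
    """Positive part of the radial derivative of the smoothed frame.

    Smoothing is replicate along r and circular along theta so the operator
    commutes with rotations of the frame."""
    frame = np.asarray(frame, dtype=float)
    sm = ndimage.gaussian_filter1d(frame, sigma=sigma, axis=0, mode="nearest")
    sm = ndimage.gaussian_filter1d(sm, sigma=sigma, axis=1, mode="wrap")
    d = np.diff(sm, axis=0, prepend=sm[:1])
    return np.maximum(d, 0.0)


def _window_max_and_arg(prev: np.ndarray, dmax: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-row max of prev over index window [r-dmax, r+dmax]."""
    depth = prev.shape[0]
    pad = np.full(dmax, -np.inf)
    padded = np.concatenate([pad, prev, pad])
    win = np.lib.stride_tricks.sliding_window_view(padded, 2 * dmax + 1)
    arg = np.argmax(win, axis=1)
    best = win[np.arange(depth), arg]
    return best, arg + np.arange(depth) - dmax


def detect_lumen(frame: np.ndarray, dmax: int = 2, sigma: float = 1.0) -> LumenContour:
    """Globally optimal circular contour by dynamic programming.

    Maximises sum_theta E[r(theta), theta] subject to |r(t+1)-r(t)| <= dmax
    for all steps including the wrap step from the last column to the first.
    Exact: the DP is evaluated once per candidate start row (vectorised), and
    the winning start's path is recovered with backpointers.
    """
    frame = np.asarray(frame, dtype=float)
    if frame.ndim != 2:
        raise ValueError("frame must be 2-D (depth x n_alines)")
    if np.all(frame == 0):
        warnings.warn("all-zero frame; returning contour at r=0", RuntimeWarning)
        return LumenContour(np.zeros(frame.shape[1], dtype=int))
    E = edge_strength(frame, sigma=sigma)
    depth, n = E.shape
    if n == 1:
        return LumenContour(np.array([int(np.argmax(E[:, 0]))]))

    # Score pass, vectorised over start rows: D[s, r] = best score of a path
    # starting at row s in column 0 and ending at row r in the current column.
    D = np.full((depth, depth), -np.inf)
    idx = np.arange(depth)
    D[idx, idx] = E[idx, 0]
    size = 2 * dmax + 1
    for t in range(1, n):
        D = ndimage.maximum_filter1d(D, size=size, axis=1, mode="constant", cval=-np.inf)
        D += E[None, :, t]
    # circular closure: end row within dmax of start row
    closed = ndimage.maximum_filter1d(D, size=size, axis=1, mode="constant", cval=-np.inf)
    start = int(np.argmax(closed[idx, idx]))

    # Backpointer pass for the winning start row.
    prev = np.full(depth, -np.inf)
    prev[start] = E[start, 0]
    back = np.empty((n, depth), dtype=np.int64)
    for t in range(1, n):
        best, arg = _window_max_and_arg(prev, dmax)
        back[t] = arg
        prev = best + E[:, t]
    # pick the end row closest in score subject to closure
    allowed = np.abs(idx - start) <= dmax
    end_scores = np.where(allowed, prev, -np.inf)
    r = int(np.argmax(end_scores))
    path = np.empty(n, dtype=int)
    for t in range(n - 1, 0, -1):
        path[t] = r
        r = int(back[t, r])
    path[0] = r
    return LumenContour(path)


def detect_guidewire(
    frame: np.ndarray,
    contour: LumenContour,
    fraction: float = 0.1,
    dilate: int = 2,
) -> np.ndarray:
    """Stand-in shadow detector: flag columns whose summed intensity beyond
    the lumen falls below ``fraction`` of the median column sum, then dilate
    by ``dilate`` columns (circularly)."""
    frame = np.asarray(frame, dtype=float)
    depth, n = frame.shape
    r = np.arange(depth)[:, None]
    beyond = np.where(r > contour.radius_px[None, :], frame, 0.0)
    sums = beyond.sum(axis=0)
    flagged = sums < fraction * np.median(sums)
    if dilate > 0 and flagged.any():
        flagged = _wrap_dilate(flagged, dilate)
    return np.flatnonzero(flagged)


def _wrap_dilate(flagged: np.ndarray, dilate: int) -> np.ndarray:
    out = flagged.copy()
    for s in range(1, dilate + 1):
        out |= np.roll(flagged, s) | np.roll(flagged, -s)
    return out


def zero_guidewire(frame: np.ndarray, guidewire_cols: np.ndarray) -> np.ndarray:
    """Zero the occluded columns; all others untouched."""
    frame = np.array(frame, dtype=float, copy=True)
    cols = np.asarray(guidewire_cols, dtype=int)
    if cols.size and (cols.min() < 0 or cols.max() >= frame.shape[1]):
        raise ValueError("guidewire column index out of range")
    frame[:, cols] = 0.0
    return frame


def pixel_shift(frame: np.ndarray, contour: LumenContour) -> np.ndarray:
    """Shift each column up by radius+1 so index 0 is the first sample after
    the lumen boundary; vacated deep samples are zero-filled (no wrap)."""
    frame = np.asarray(frame, dtype=float)
    depth, n = frame.shape
    radii = contour.radius_px
    if radii.shape[0] != n:
        raise ValueError("contour length does not match frame width")
    if np.any(radii + 1 > depth) or np.any(radii < -1):
        raise ValueError("contour deeper than frame")
    out = np.zeros_like(frame)
    for j in range(n):
        s = int(radii[j]) + 1
        if s < depth:
            out[: depth - s, j] = frame[s:, j]
    return out


def _gaussian_kernel_1d(size: int, sigma: float) -> np.ndarray:
    half = size // 2
    x = np.arange(-half, half + 1, dtype=float)
    k = np.exp(-(x**2) / (2 * sigma**2))
    return k / k.sum()


def crop_log_smooth(
    shifted: np.ndarray, n_keep: int = N_KEEP, size: int = 7, sigma: float = 1.0
) -> np.ndarray:
    """Keep the first ``n_keep`` rows, apply log(1+x), smooth with the
    unit-sum ``size`` x ``size`` Gaussian (sigma), circular along theta and
    replicate along r."""
    shifted = np.asarray(shifted, dtype=float)
    if np.any(shifted < 0):
        raise ValueError("shifted frame must be non-negative")
    cropped = np.log1p(shifted[:n_keep])
    k = _gaussian_kernel_1d(size, sigma)
    sm = ndimage.convolve1d(cropped, k, axis=0, mode="nearest")
    sm = ndimage.convolve1d(sm, k, axis=1, mode="wrap")
    return sm


def preprocess_pullback_arrays(
    pullback: Pullback,
    contours: list[LumenContour] | None = None,
    guidewire_masks: list[np.ndarray] | None = None,
    labels: np.ndarray | None = None,
    dmax: int = 2,
):
    """Run the full chain; return flat arrays for efficiency.

    Returns (X, frame_idx, aline_idx, y) where X is (n, 200) float32 over all
    non-guidewire A-lines and y is None when labels were not supplied.
    Contours/masks are computed by the built-in detectors when absent.
    """
    n_frames, depth, n_alines = pullback.frames.shape
    xs, fidx, aidx, ys = [], [], [], []
    for iz in range(n_frames):
        frame = pullback.frames[iz].astype(float)
        contour = contours[iz] if contours is not None else detect_lumen(frame, dmax=dmax)
        if guidewire_masks is not None:
            gw_cols = np.flatnonzero(np.asarray(guidewire_masks[iz]))
        else:
            gw_cols = detect_guidewire(frame, contour)
        frame = zero_guidewire(frame, gw_cols)
        shifted = pixel_shift(frame, contour)
        processed = crop_log_smooth(shifted)
        keep = np.ones(n_alines, dtype=bool)
        keep[gw_cols] = False
        if labels is not None:
            keep &= np.asarray(labels)[:, iz] != GUIDEWIRE
        cols = np.flatnonzero(keep)
        xs.append(processed[:, cols].T.astype(np.float32))
        fidx.append(np.full(cols.size, iz, dtype=np.int64))
        aidx.append(cols.astype(np.int64))
        if labels is not None:
            ys.append(np.asarray(labels)[cols, iz])
    X = np.concatenate(xs, axis=0) if xs else np.empty((0, N_KEEP), dtype=np.float32)
    f = np.concatenate(fidx) if fidx else np.empty(0, dtype=np.int64)
    a = np.concatenate(aidx) if aidx else np.empty(0, dtype=np.int64)
    y = np.concatenate(ys) if ys else None
    return X, f, a, y


def preprocess_pullback(
    pullback: Pullback,
    contours: list[LumenContour] | None = None,
    guidewire_masks: list[np.ndarray] | None = None,
    labels: np.ndarray | None = None,
    dmax: int = 2,
) -> list[ProcessedALine]:
    """Full preprocessing chain producing one ProcessedALine per
    non-guidewire A-line (guidewire columns carry no tissue signal)."""
    X, f, a, y = preprocess_pullback_arrays(pullback, contours, guidewire_masks, labels, dmax)
    out = []
    for i in range(X.shape[0]):
        out.append(
            ProcessedALine(
                values=X[i],
                frame_index=int(f[i]),
                aline_index=int(a[i]),
                label=None if y is None else int(y[i]),
                pullback_id=pullback.pullback_id,
            )
        )
    return out
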