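"""En-face (theta, z) classification noise cleaning.

A fully connected CRF with the appearance kernel dropped (w1 = 0) leaves a
single Gaussian smoothness kernel; mean-field inference then reduces to
iterated Gaussian filtering of the class marginals.  Theta is treated as
circular (the vessel is a closed tube); z is not.  Guidewire pixels are
removed from the graph entirely and re-inserted as guidewire labels.

After inference, three serial passes of a morphological area opening (area
threshold 10, 8-connected, theta-wrap-aware) remove small islands / close
small holes, each pass treating one class as background.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy import ndimage

from .sim import GUIDEWIRE, FIBROCALCIFIC, FIBROLIPIDIC, OTHER

__all__ = [
    "EnFaceProbMap",
    "CRFParams",
    "build_enface",
    "unary",
    "energy",
    "mean_field_infer",
    "area_open_cleanup",
    "clean",
]

EPS = 1e-12
N_CLASSES = 3


@dataclass
class EnFaceProbMap:
    """Grid of per-A-line class probabilities; rows = theta, cols = z."""

    probs: np.ndarray  # (n_alines, n_frames, 3)
    valid: np.ndarray  # (n_alines, n_frames) bool; False at guidewire
    theta_circular: bool = True

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.probs.ndim != 3 or self.probs.shape[2] != N_CLASSES:
            raise ValueError("probs must be (n_alines, n_frames, 3)")
        if self.valid.shape != self.probs.shape[:2]:
            raise ValueError("valid mask shape mismatch")
        sums = self.probs[self.valid].sum(axis=1)
        if sums.size and not np.allclose(sums, 1.0, atol=1e-5):
            raise ValueError("probabilities must sum to 1 on valid pixels")


@dataclass
class CRFParams:
    w2: float = 0.25
    sigma_theta: float = 4.75  # (19, 5) window extent at +/- 2 sigma
    sigma_z: float = 1.25
    n_iter: int = 5
    truncate_sigmas: float = 2.0  # kernel halfwidth = round(truncate * sigma)

    def __post_init__(self) -> None:
        if self.w2 < 0:
            raise ValueError("w2 must be >= 0")
        if self.sigma_theta <= 0 or self.sigma_z <= 0:
            raise ValueError("kernel sigmas must be > 0")
        if self.n_iter < 1:
            raise ValueError("n_iter must be >= 1")

    @classmethod
    def from_window_extent(cls, extent_theta: int, extent_z: int, **kw) -> "CRFParams":
        """Interpret an odd (theta, z) window extent as +/- 2 sigma."""
        return cls(sigma_theta=extent_theta / 4.0, sigma_z=extent_z / 4.0, **kw)


def build_enface(
    probs: np.ndarray,
    aline_idx: np.ndarray,
    frame_idx: np.ndarray,
    n_alines: int,
    frame_range: tuple[int, int] | None = None,
    guidewire_mask: np.ndarray | None = None,
    theta_circular: bool = True,
) -> EnFaceProbMap:
    """Scatter per-A-line probabilities into the (theta, z) grid.

    ``frame_range`` is [first, last] inclusive and must be gap-free: every
    frame in the range must receive at least one A-line.
    """
    probs = np.asarray(probs, dtype=float)
    aline_idx = np.asarray(aline_idx, dtype=int)
    frame_idx = np.asarray(frame_idx, dtype=int)
    if frame_range is None:
        frame_range = (int(frame_idx.min()), int(frame_idx.max()))
    f0, f1 = frame_range
    present = np.unique(frame_idx)
    expected = np.arange(f0, f1 + 1)
    if not np.array_equal(present, expected):
        missing = sorted(set(expected) - set(present))
        raise ValueError(f"gap in frame range: missing frames {missing}")
    n_frames = f1 - f0 + 1
    grid = np.zeros((n_alines, n_frames, N_CLASSES))
    valid = np.zeros((n_alines, n_frames), dtype=bool)
    grid[aline_idx, frame_idx - f0] = probs
    valid[aline_idx, frame_idx - f0] = True
    if guidewire_mask is not None:
        valid &= ~np.asarray(guidewire_mask, dtype=bool)
        grid[~valid] = 0.0
    return EnFaceProbMap(probs=grid, valid=valid, theta_circular=theta_circular)


def unary(pmap: EnFaceProbMap) -> np.ndarray:
    """Per-pixel unary potentials -log(max(P, eps)); invalid pixels are not
    part of the graph (their values are irrelevant downstream)."""
    return -np.log(np.clip(pmap.probs, EPS, None))


def _theta_kernel(n_theta: int, sigma: float, truncate: float, circular: bool) -> np.ndarray:
    """Circular (length-n) or linear truncated Gaussian kernel along theta.

    Entry d holds the affinity at angular offset d; each unordered neighbour
    appears exactly once in the circulant (offset n/2 included once for even
    n)."""
    half = int(round(truncate * sigma))
    if circular:
        d = np.arange(n_theta)
        dist = np.minimum(d, n_theta - d)
        k = np.exp(-(dist.astype(float) ** 2) / (2 * sigma**2))
        k[dist > min(half, n_theta // 2)] = 0.0
        return k
    d = np.arange(-half, half + 1, dtype=float)
    return np.exp(-(d**2) / (2 * sigma**2))


def _z_kernel(sigma: float, truncate: float) -> np.ndarray:
    half = int(round(truncate * sigma))
    d = np.arange(-half, half + 1, dtype=float)
    return np.exp(-(d**2) / (2 * sigma**2))


def _filter_marginals(Q: np.ndarray, params: CRFParams, theta_circular: bool) -> np.ndarray:
    """Separable Gaussian filtering of (n_theta, n_z, C) marginals, excluding
    the self term; invalid pixels must already be zeroed in Q."""
    n_theta = Q.shape[0]
    kz = _z_kernel(params.sigma_z, params.truncate_sigmas)
    filt = ndimage.convolve1d(Q, kz, axis=1, mode="constant", cval=0.0)
    if theta_circular:
        kt = _theta_kernel(n_theta, params.sigma_theta, params.truncate_sigmas, True)
        # circulant application: out[i] = sum_j kt[(i-j) mod n] filt[j]
        C = _circulant(kt)
        filt = np.tensordot(C, filt, axes=(1, 0))
    else:
        kt = _theta_kernel(n_theta, params.sigma_theta, params.truncate_sigmas, False)
        filt = ndimage.convolve1d(filt, kt, axis=0, mode="constant", cval=0.0)
    return filt - Q  # remove self-contribution (kernel centre weight is 1)


def _circulant(k: np.ndarray) -> np.ndarray:
    n = k.shape[0]
    i = np.arange(n)
    return k[(i[:, None] - i[None, :]) % n]


def mean_field_infer(
    pmap: EnFaceProbMap, params: CRFParams
) -> tuple[np.ndarray, np.ndarray]:
    """Synchronous mean-field inference.

    Returns (labels, marginals): labels is (n_alines, n_frames) with
    GUIDEWIRE at invalid pixels; marginals is (n_alines, n_frames, 3) with
    zeros at invalid pixels.  Argmax ties break toward the lowest class
    index.
    """
    u = unary(pmap)
    valid = pmap.valid
    Q = np.clip(pmap.probs, EPS, None)
    Q /= Q.sum(axis=2, keepdims=True)
    Q[~valid] = 0.0
    for _ in range(params.n_iter):
        M = _filter_marginals(Q, params, pmap.theta_circular)
        S = M.sum(axis=2, keepdims=True)
        pairwise = params.w2 * (S - M)  # penalty mass from differing labels
        logits = -u - pairwise
        logits -= logits.max(axis=2, keepdims=True)
        Q = np.exp(logits)
        Q /= Q.sum(axis=2, keepdims=True)
        Q[~valid] = 0.0
        if not np.all(np.isfinite(Q)):
            raise FloatingPointError("non-finite mean-field marginals")
    labels = np.argmax(Q, axis=2)
    labels[~valid] = GUIDEWIRE
    return labels, Q


def energy(
    labeling: np.ndarray,
    unaries: np.ndarray,
    params: CRFParams,
    valid: np.ndarray | None = None,
    theta_circular: bool = True,
) -> float:
    """Exact CRF energy: unary sum plus w2-weighted Gaussian affinity over
    unordered pairs of differently labeled valid pixels.  O(P^2); intended
    for small grids and oracle checks."""
    labeling = np.asarray(labeling)
    n_theta, n_z = labeling.shape
    if valid is None:
        valid = np.ones((n_theta, n_z), dtype=bool)
    ti, zi = np.nonzero(valid)
    lab = labeling[ti, zi]
    total = float(unaries[ti, zi, lab].sum())
    half_t = int(round(params.truncate_sigmas * params.sigma_theta))
    half_z = int(round(params.truncate_sigmas * params.sigma_z))
    P = ti.size
    for a in range(P):
        dt = np.abs(ti[a + 1 :] - ti[a])
        if theta_circular:
            dt = np.minimum(dt, n_theta - dt)
            dt_max = min(half_t, n_theta // 2)
        else:
            dt_max = half_t
        dz = np.abs(zi[a + 1 :] - zi[a])
        diff = lab[a + 1 :] != lab[a]
        mask = diff & (dt <= dt_max) & (dz <= half_z)
        if not mask.any():
            continue
        k = np.exp(
            -(dt[mask].astype(float) ** 2) / (2 * params.sigma_theta**2)
            - (dz[mask].astype(float) ** 2) / (2 * params.sigma_z**2)
        )
        total += params.w2 * float(k.sum())
    return total


# ---------------------------------------------------------------------------
# Morphological cleanup.


def _wrap_components(fg: np.ndarray, theta_circular: bool) -> tuple[np.ndarray, int]:
    """8-connected components of a boolean grid, merging across the theta
    seam when circular.  Returns (component id grid, n components)."""
    structure = np.ones((3, 3), dtype=bool)
    comp, n = ndimage.label(fg, structure=structure)
    if not theta_circular or n == 0 or fg.shape[0] < 2:
        return comp, n
    parent = np.arange(n + 1)

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra

    top, bottom = comp[0], comp[-1]
    n_z = fg.shape[1]
    for dz in (-1, 0, 1):
        a = top
        b = np.roll(bottom, -dz) if dz else bottom
        # pair columns j (top) with j+dz (bottom)
        for j in range(n_z):
            jj = j + dz
            if 0 <= jj < n_z and top[j] and bottom[jj]:
                union(top[j], bottom[jj])
    roots = np.array([find(i) for i in range(n + 1)])
    _, relabeled = np.unique(roots, return_inverse=True)
    comp = relabeled[comp]
    return comp, int(comp.max())


def area_open_cleanup(
    labels: np.ndarray,
    area_threshold: int = 10,
    background_order: tuple[int, int, int] = (OTHER, FIBROCALCIFIC, FIBROLIPIDIC),
    theta_circular: bool = True,
) -> np.ndarray:
    """Three serial area-opening passes on the hard label map.

    In each pass one class is background; 8-connected components of the
    union of the other two classes with area < ``area_threshold`` are
    relabeled to the pass's background class.  Guidewire pixels are never
    touched.
    """
    out = np.asarray(labels).copy()
    for bg in background_order:
        fg = (out != bg) & (out != GUIDEWIRE)
        comp, n = _wrap_components(fg, theta_circular)
        if n == 0:
            continue
        areas = np.bincount(comp.ravel(), minlength=n + 1)
        small = np.flatnonzero(areas < area_threshold)
        small = small[small > 0]
        if small.size:
            out[np.isin(comp, small)] = bg
    return out


def clean(
    pmap: EnFaceProbMap,
    params: CRFParams,
    area_threshold: int = 10,
    background_order: tuple[int, int, int] = (OTHER, FIBROCALCIFIC, FIBROLIPIDIC),
) -> np.ndarray:
    """CRF mean-field inference followed by 3-pass area opening."""
    labels, _ = mean_field_infer(pmap, params)
    return area_open_cleanup(
        labels, area_threshold, background_order, theta_circular=pmap.theta_circular
    )


def params_to_dict(p: CRFParams) -> dict:
    return asdict(p)
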