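"""Synthetic polar-domain OCT pullback generator with exact A-line ground truth.

Produces (r, theta) intensity stacks that mimic the qualitative appearance of
intravascular OCT plaque classes -- a bright fibrous surface layer followed by
either a signal-poor, sharp-bordered calcific pocket (fibrocalcific), a fast
diffuse exponential drop-off (fibrolipidic), or a slow decay with optional
layered banding (other) -- plus an eccentric lumen, a drifting guidewire
shadow, and multiplicative gamma speckle.  Lesions are contiguous jittered
rectangles in the en-face (theta, z) plane so downstream spatial cleaning has
realistic structure to exploit.

Labels, lumen contours, and guidewire masks are generated directly (not
inferred from rendered pixels), so the ground truth is exact by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

__all__ = [
    "CLASS_NAMES",
    "LABEL_NAMES",
    "FIBROCALCIFIC",
    "FIBROLIPIDIC",
    "OTHER",
    "GUIDEWIRE",
    "ProfileParams",
    "SimConfig",
    "Pullback",
    "GroundTruth",
    "generate_aline_profile",
    "apply_speckle",
    "generate_pullback",
]

# Integer label codes used everywhere downstream.
FIBROCALCIFIC = 0
FIBROLIPIDIC = 1
OTHER = 2
GUIDEWIRE = 3

CLASS_NAMES = ("fibrocalcific", "fibrolipidic", "other")
LABEL_NAMES = CLASS_NAMES + ("guidewire",)

_MAX_UINT16 = 65535


@dataclass
class ProfileParams:
    """Class-conditional radial profile parameters (raw 16-bit-scale units)."""

    fibrous_level: float = 12000.0
    calcium_level: float = 1500.0
    deep_level: float = 5000.0
    deep_decay_px: float = 120.0
    lipid_decay_px: float = 25.0
    lipid_border_scale_px: float = 4.0  # softplus scale; border width ~4x this
    other_level: float = 9000.0
    other_decay_px: float = 150.0
    other_banding: bool = False
    media_factor: float = 0.55
    media_start_px: int = 60
    media_thickness_px: int = 25
    lumen_level: float = 100.0
    calcium_thickness_range_px: tuple[int, int] = (60, 140)


@dataclass
class SimConfig:
    n_frames: int = 40
    n_alines: int = 448
    depth_px: int = 968
    axial_um_per_px: float = 5.0  # 200 px ~ 1 mm
    frame_pitch_mm: float = 0.2
    lumen_radius_base_px: int = 120
    lumen_eccentricity_px: int = 30
    guidewire_width_alines: int = 28
    cap_thickness_range_px: tuple[int, int] = (10, 60)
    # target fraction of non-guidewire A-lines per lesion class
    coverage_fibrocalcific: float = 1.0 / 6.0
    coverage_fibrolipidic: float = 1.0 / 6.0
    lesion_arc_range_alines: tuple[int, int] = (30, 110)
    lesion_len_range_frames: tuple[int, int] = (6, 20)
    lesion_edge_jitter_alines: int = 1
    guidewire_attenuation: float = 0.02
    speckle_shape: float = 1.0
    profile: ProfileParams = field(default_factory=ProfileParams)
    seed: int = 0
    pullback_id: str = "sim"

    def __post_init__(self) -> None:
        for name in ("n_frames", "n_alines", "depth_px", "guidewire_width_alines"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1, got {getattr(self, name)}")
        lo, hi = self.cap_thickness_range_px
        if not (0 <= lo <= hi < self.depth_px):
            raise ValueError(
                f"cap_thickness_range_px must lie within [0, depth_px), got {(lo, hi)}"
            )
        for name in ("coverage_fibrocalcific", "coverage_fibrolipidic"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.speckle_shape <= 0 and not np.isinf(self.speckle_shape):
            raise ValueError("speckle_shape must be positive (inf disables noise)")
        if self.lesion_arc_range_alines[1] > self.n_alines:
            raise ValueError("lesion arc range exceeds n_alines")
        if self.lesion_len_range_frames[1] > self.n_frames:
            raise ValueError("lesion frame extent exceeds n_frames")
        if self.lumen_radius_base_px + self.lumen_eccentricity_px + 200 >= self.depth_px:
            raise ValueError("lumen geometry leaves less than 200 px of tissue depth")


@dataclass
class Pullback:
    """Ordered stack of polar frames (rows = r, columns = theta)."""

    frames: np.ndarray  # (n_frames, depth_px, n_alines), uint16
    pullback_id: str
    axial_um_per_px: float
    frame_pitch_mm: float

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (n_frames, depth, n_alines) stack")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def depth_px(self) -> int:
        return self.frames.shape[1]

    @property
    def n_alines(self) -> int:
        return self.frames.shape[2]


@dataclass
class GroundTruth:
    """Per-A-line labels, lumen contours, and guidewire occlusion masks."""

    labels: np.ndarray  # (n_alines, n_frames) int codes incl. GUIDEWIRE
    lumen: np.ndarray  # (n_alines, n_frames) last lumen-interior radial index
    guidewire_mask: np.ndarray  # (n_alines, n_frames) bool
    cap_thickness: np.ndarray | None = None  # (n_alines, n_frames), px
    calcium_thickness: np.ndarray | None = None


def _softplus(x: np.ndarray, scale: float) -> np.ndarray:
    # numerically stable scale*log(1+exp(x/scale))
    z = np.asarray(x, dtype=float) / scale
    return scale * (np.logaddexp(0.0, z))


def _profile_fibrocalcific(k, cap, cal, p: ProfileParams):
    """Plateau, sharp step down to calcium, sharp step up to decaying deep tissue."""
    k = np.asarray(k, dtype=float)
    back = cap + cal
    deep = p.deep_level * np.exp(-np.maximum(k - back, 0.0) / p.deep_decay_px)
    out = np.where(k < cap, p.fibrous_level, np.where(k < back, p.calcium_level, deep))
    return out


def _profile_fibrolipidic(k, cap, p: ProfileParams):
    """Plateau followed by a fast exponential drop with a diffuse border.

    The border is realised analytically with a softplus-rectified depth so the
    transition width is ~4 * lipid_border_scale_px without any filtering.
    """
    k = np.asarray(k, dtype=float)
    eff = _softplus(k - cap, p.lipid_border_scale_px)
    return p.fibrous_level * np.exp(-eff / p.lipid_decay_px)


def _profile_other(k, p: ProfileParams):
    k = np.asarray(k, dtype=float)
    out = p.other_level * np.exp(-k / p.other_decay_px)
    if p.other_banding:
        band = (k >= p.media_start_px) & (k < p.media_start_px + p.media_thickness_px)
        out = np.where(band, out * p.media_factor, out)
    return out


def generate_aline_profile(
    class_label: int | str,
    depth_from_lumen_px: int,
    params: ProfileParams | None = None,
    rng: np.random.Generator | None = None,
    *,
    cap_thickness_px: int | None = None,
    calcium_thickness_px: int | None = None,
    cap_thickness_range_px: tuple[int, int] = (10, 60),
) -> np.ndarray:
    """Clean (noise-free) radial intensity profile for one tissue class.

    ``depth_from_lumen_px`` counts samples starting at the first tissue pixel
    beyond the lumen boundary. Thickness parameters are drawn from ``rng``
    when not given explicitly.
    """
    if params is None:
        params = ProfileParams()
    if isinstance(class_label, str):
        try:
            class_label = CLASS_NAMES.index(class_label)
        except ValueError:
            raise ValueError(f"unknown class label {class_label!r}") from None
    if class_label not in (FIBROCALCIFIC, FIBROLIPIDIC, OTHER):
        raise ValueError(f"unknown class label {class_label!r}")
    if depth_from_lumen_px < 200:
        raise ValueError("profiles must span at least 200 samples")
    k = np.arange(depth_from_lumen_px)
    if class_label == OTHER:
        return _profile_other(k, params)
    if rng is None:
        rng = np.random.default_rng()
    if cap_thickness_px is None:
        lo, hi = cap_thickness_range_px
        cap_thickness_px = int(rng.integers(lo, hi + 1))
    if class_label == FIBROCALCIFIC:
        if calcium_thickness_px is None:
            lo, hi = params.calcium_thickness_range_px
            calcium_thickness_px = int(rng.integers(lo, hi + 1))
        return _profile_fibrocalcific(k, cap_thickness_px, calcium_thickness_px, params)
    return _profile_fibrolipidic(k, cap_thickness_px, params)


def apply_speckle(
    clean_profile: np.ndarray, speckle_shape: float, rng: np.random.Generator
) -> np.ndarray:
    """Multiply by i.i.d. unit-mean gamma noise (expectation-preserving).

    ``speckle_shape = inf`` is the noise-free limit and returns the input.
    """
    clean_profile = np.asarray(clean_profile, dtype=float)
    if np.any(clean_profile < 0):
        raise ValueError("clean profile must be non-negative")
    if np.isinf(speckle_shape):
        return clean_profile.copy()
    if speckle_shape <= 0:
        raise ValueError(f"speckle_shape must be > 0, got {speckle_shape}")
    m = rng.gamma(shape=speckle_shape, scale=1.0 / speckle_shape, size=clean_profile.shape)
    return clean_profile * m


def _paint_lesions(
    labels: np.ndarray,
    caps: np.ndarray,
    cals: np.ndarray,
    cls: int,
    target: float,
    eligible: np.ndarray,
    cfg: SimConfig,
    rng: np.random.Generator,
) -> None:
    """Paint jittered rectangular lesions until the class covers ``target`` of
    the eligible (non-guidewire) cells. Overwrites previous paint."""
    if target <= 0:
        return
    n_theta, n_z = labels.shape
    n_eligible = int(eligible.sum())
    lo_a, hi_a = cfg.lesion_arc_range_alines
    lo_f, hi_f = cfg.lesion_len_range_frames
    cap_lo, cap_hi = cfg.cap_thickness_range_px
    cal_lo, cal_hi = cfg.profile.calcium_thickness_range_px
    for _ in range(10000):
        frac = np.count_nonzero((labels == cls) & eligible) / max(n_eligible, 1)
        if frac >= target:
            return
        arc = int(rng.integers(lo_a, hi_a + 1))
        length = int(rng.integers(lo_f, hi_f + 1))
        theta0 = int(rng.integers(0, n_theta))
        z0 = int(rng.integers(0, max(n_z - length, 0) + 1))
        cap = int(rng.integers(cap_lo, max(cap_lo, cap_hi - 4) + 1))
        cal = int(rng.integers(cal_lo, cal_hi + 1))
        jit = cfg.lesion_edge_jitter_alines
        for dz in range(length):
            j0 = theta0 + (int(rng.integers(-jit, jit + 1)) if jit else 0)
            cols = (j0 + np.arange(arc)) % n_theta
            labels[cols, z0 + dz] = cls
            caps[cols, z0 + dz] = np.clip(
                cap + rng.integers(-2, 3, size=arc), cap_lo, cap_hi
            )
            cals[cols, z0 + dz] = cal
    raise RuntimeError("lesion painting did not converge; lower coverage targets")


def _render_frame(
    lumen_col: np.ndarray,
    labels_col: np.ndarray,
    caps_col: np.ndarray,
    cals_col: np.ndarray,
    cfg: SimConfig,
) -> np.ndarray:
    """Vectorised clean rendering of one polar frame (depth x n_alines)."""
    p = cfg.profile
    depth, n = cfg.depth_px, cfg.n_alines
    r = np.arange(depth)[:, None]  # (depth, 1)
    k = r - lumen_col[None, :] - 1  # tissue depth per pixel; <0 inside lumen
    frame = np.full((depth, n), p.lumen_level)
    for cls in (FIBROCALCIFIC, FIBROLIPIDIC, OTHER):
        cols = np.flatnonzero((labels_col == cls) | ((labels_col == GUIDEWIRE) & (cls == OTHER)))
        if cols.size == 0:
            continue
        kk = np.maximum(k[:, cols], 0.0)
        if cls == FIBROCALCIFIC:
            prof = _profile_fibrocalcific(kk, caps_col[None, cols], cals_col[None, cols], p)
        elif cls == FIBROLIPIDIC:
            prof = _profile_fibrolipidic(kk, caps_col[None, cols], p)
        else:
            prof = _profile_other(kk, p)
        tissue = k[:, cols] >= 0
        frame[:, cols] = np.where(tissue, prof, p.lumen_level)
    return frame


def generate_pullback(cfg: SimConfig) -> tuple[Pullback, GroundTruth]:
    """Deterministically generate a synthetic pullback and its ground truth."""
    rng = np.random.default_rng(cfg.seed)
    n_theta, n_z, depth = cfg.n_alines, cfg.n_frames, cfg.depth_px

    # Lumen radius: eccentric cosine in theta, phase and size drifting in z.
    theta = 2 * np.pi * np.arange(n_theta) / n_theta
    phase0 = rng.uniform(0, 2 * np.pi)
    dphase = rng.uniform(-0.05, 0.05)
    base_amp = rng.uniform(0.85, 1.0) * cfg.lumen_radius_base_px
    z = np.arange(n_z)
    base_z = base_amp * (1.0 + 0.08 * np.sin(2 * np.pi * z / max(n_z, 2) + rng.uniform(0, 2 * np.pi)))
    lumen = base_z[None, :] + cfg.lumen_eccentricity_px * np.cos(
        theta[:, None] - (phase0 + dphase * z)[None, :]
    )
    lumen = np.clip(np.round(lumen).astype(int), 2, depth - 201 - 1)

    # Guidewire: contiguous arc drifting slowly, wrapping across theta seam.
    gw_center = rng.integers(0, n_theta) + np.cumsum(rng.normal(0, 0.6, size=n_z))
    half = cfg.guidewire_width_alines // 2
    offs = np.arange(cfg.guidewire_width_alines) - half
    gw_cols = (np.round(gw_center).astype(int)[None, :] + offs[:, None]) % n_theta
    gw_mask = np.zeros((n_theta, n_z), dtype=bool)
    gw_mask[gw_cols, np.broadcast_to(np.arange(n_z), gw_cols.shape)] = True

    labels = np.full((n_theta, n_z), OTHER, dtype=np.int64)
    caps = np.zeros((n_theta, n_z), dtype=np.int64)
    cals = np.zeros((n_theta, n_z), dtype=np.int64)
    eligible = ~gw_mask
    _paint_lesions(labels, caps, cals, FIBROCALCIFIC, cfg.coverage_fibrocalcific, eligible, cfg, rng)
    _paint_lesions(labels, caps, cals, FIBROLIPIDIC, cfg.coverage_fibrolipidic, eligible, cfg, rng)

    frames = np.empty((n_z, depth, n_theta), dtype=np.uint16)
    for iz in range(n_z):
        clean = _render_frame(lumen[:, iz], labels[:, iz], caps[:, iz], cals[:, iz], cfg)
        noisy = apply_speckle(clean, cfg.speckle_shape, rng)
        noisy[:, gw_mask[:, iz]] *= cfg.guidewire_attenuation
        frames[iz] = np.clip(np.round(noisy), 0, _MAX_UINT16).astype(np.uint16)

    final_labels = labels.copy()
    final_labels[gw_mask] = GUIDEWIRE
    pb = Pullback(
        frames=frames,
        pullback_id=cfg.pullback_id,
        axial_um_per_px=cfg.axial_um_per_px,
        frame_pitch_mm=cfg.frame_pitch_mm,
    )
    gt = GroundTruth(
        labels=final_labels,
        lumen=lumen,
        guidewire_mask=gw_mask,
        cap_thickness=caps,
        calcium_thickness=cals,
    )
    return pb, gt


def scaled_config(
    n_frames: int = 40,
    n_alines: int = 448,
    depth_px: int = 968,
    seed: int = 0,
    pullback_id: str = "sim",
    speckle_shape: float = 1.0,
    **overrides,
) -> SimConfig:
    """SimConfig with guidewire/lesion/lumen geometry scaled to the grid so
    that small test-sized pullbacks remain valid and realistic."""
    depth_margin = depth_px - 230
    kw = dict(
        n_frames=n_frames,
        n_alines=n_alines,
        depth_px=depth_px,
        lumen_radius_base_px=min(120, depth_margin),
        lumen_eccentricity_px=min(30, max(4, depth_margin // 5)),
        guidewire_width_alines=max(4, int(round(28 * n_alines / 448))),
        lesion_arc_range_alines=(
            max(4, int(round(30 * n_alines / 448))),
            max(6, int(round(110 * n_alines / 448))),
        ),
        lesion_len_range_frames=(
            max(1, min(6, n_frames // 3)),
            max(1, min(n_frames, min(20, max(3, (2 * n_frames) // 3)))),
        ),
        speckle_shape=speckle_shape,
        seed=seed,
        pullback_id=pullback_id,
    )
    kw.update(overrides)
    return SimConfig(**kw)


def config_to_dict(cfg: SimConfig) -> dict:
    return asdict(cfg)
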