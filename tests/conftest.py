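"""Shared fixtures: synthetic A-line datasets and small trained models."""

from __future__ import annotations

import numpy as np
import pytest
from scipy import ndimage

from octaline import nets, sim


def make_aline_dataset(
    n_per_class: int,
    rng: np.random.Generator,
    cap_range: tuple[int, int] = (10, 60),
    cal_range: tuple[int, int] = (60, 140),
    speckle_shape: float = 8.0,
    smooth: bool = True,
    caps_fixed: dict | None = None,
):
    """Processed-style A-lines built directly from class profiles: speckle,
    log(1+x), and a 7-tap sigma-1 Gaussian along r (mirroring the radial part
    of the preprocessing chain)."""
    params = sim.ProfileParams()
    X, y, caps = [], [], []
    for cls in (sim.FIBROCALCIFIC, sim.FIBROLIPIDIC, sim.OTHER):
        for _ in range(n_per_class):
            if caps_fixed and cls in caps_fixed:
                cap = caps_fixed[cls]
            else:
                cap = int(rng.integers(cap_range[0], cap_range[1] + 1))
            cal = int(rng.integers(cal_range[0], cal_range[1] + 1))
            prof = sim.generate_aline_profile(
                cls, 200, params, rng, cap_thickness_px=cap, calcium_thickness_px=cal
            )
            noisy = sim.apply_speckle(prof, speckle_shape, rng)
            v = np.log1p(noisy)
            if smooth:
                v = ndimage.convolve1d(v, _g7(), mode="nearest")
            X.append(v)
            y.append(cls)
            caps.append(cap)
    X = np.asarray(X, dtype=np.float32)
    y = np.asarray(y, dtype=np.int64)
    caps = np.asarray(caps)
    order = rng.permutation(len(y))
    return X[order], y[order], caps[order]


def _g7():
    x = np.arange(-3, 4, dtype=float)
    k = np.exp(-(x**2) / 2)
    return k / k.sum()


@pytest.fixture(scope="session")
def aline_data():
    rng = np.random.default_rng(42)
    X, y, caps = make_aline_dataset(1200, rng)
    return X, y, caps


@pytest.fixture(scope="session")
def trained_cnn(aline_data):
    X, y, _ = aline_data
    n = len(y)
    cut = int(0.85 * n)
    cfg = nets.NetConfig(arch="cnn", max_epochs=8, seed=0, batch_size=256)
    model = nets.build_cnn(cfg)
    return nets.train(model, X[:cut], y[:cut], X[cut:], y[cut:], cfg)


@pytest.fixture(scope="session")
def trained_ann(aline_data):
    X, y, _ = aline_data
    n = len(y)
    cut = int(0.85 * n)
    cfg = nets.NetConfig(arch="ann", max_epochs=10, seed=0, batch_size=256)
    model = nets.build_ann(cfg)
    return nets.train(model, X[:cut], y[:cut], X[cut:], y[cut:], cfg)
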