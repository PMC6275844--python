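"""Guided-backpropagation class saliency maps.

The backward pass starts from the chosen class's pre-softmax activation.
At every ReLU the gradient is zeroed where the forward input was negative
(plain backprop) or where the flowing gradient is negative (the guided
rule).  Max-pool routes gradient to the forward argmax (ties to the first
index).  For models without ReLUs the guided pass equals the plain input
gradient.
"""

from __future__ import annotations

import numpy as np

from .nets import TrainedModel, apply_standardization

__all__ = ["guided_backprop", "frame_saliency"]


def _input_gradient(trained: TrainedModel, X: np.ndarray, class_index: int, guided: bool) -> np.ndarray:
    cfg = trained.config
    if not 0 <= class_index < cfg.n_classes:
        raise ValueError(f"class index {class_index} out of range [0, {cfg.n_classes})")
    X = np.asarray(X, dtype=float)
    single = X.ndim == 1
    if single:
        X = X[None, :]
    if X.shape[1] != cfg.input_len:
        raise ValueError(f"A-lines must have length {cfg.input_len}")
    Xs = apply_standardization(X, cfg.standardization, trained.stand_stats)
    trained.model.forward(Xs)
    g = np.zeros((X.shape[0], cfg.n_classes), dtype=np.float32)
    g[:, class_index] = 1.0
    grad = trained.model.backward(g, guided=guided)
    return grad[0] if single else grad


def guided_backprop(
    trained: TrainedModel,
    aline: np.ndarray,
    class_index: int,
    signed: bool = False,
) -> np.ndarray:
    """Per-sample relevance of one (or a batch of) processed A-line(s) for
    ``class_index``; rectified to magnitudes unless ``signed``."""
    grad = _input_gradient(trained, aline, class_index, guided=True)
    return grad if signed else np.abs(grad)


def input_gradient(trained: TrainedModel, aline: np.ndarray, class_index: int) -> np.ndarray:
    """Plain (unguided) gradient of the class activation w.r.t. the input."""
    return _input_gradient(trained, aline, class_index, guided=False)


def frame_saliency(
    trained: TrainedModel,
    frame: np.ndarray,
    class_index: int,
    guidewire_cols: np.ndarray | None = None,
    signed: bool = False,
) -> np.ndarray:
    """Column-stacked saliency over a processed frame (200 x n_alines).

    ``frame`` holds processed A-lines as columns; guidewire columns (if
    given) are zeroed in the output.
    """
    frame = np.asarray(frame, dtype=float)
    maps = guided_backprop(trained, frame.T, class_index, signed=signed)
    grid = maps.T
    if guidewire_cols is not None:
        grid = grid.copy()
        grid[:, np.asarray(guidewire_cols, dtype=int)] = 0.0
    return grid
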