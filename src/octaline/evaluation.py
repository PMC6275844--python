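"""Pullback-held-out cross-validation, confusion matrices, class metrics,
and the cross-fold paired comparison."""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from . import crf as crf_mod
from . import nets as nets_mod
from .sim import GUIDEWIRE

__all__ = [
    "FoldPlan",
    "FoldResults",
    "PullbackData",
    "make_folds",
    "confusion",
    "metrics",
    "paired_fold_test",
    "run_crossval",
]

N_CLASSES = 3


@dataclass
class FoldPlan:
    folds: list[tuple[list, list, list]]  # (train_ids, val_ids, test_ids)
    seed: int = 0

    def validate(self) -> None:
        all_test = [pid for _, _, test in self.folds for pid in test]
        if len(all_test) != len(set(all_test)):
            raise ValueError("a pullback appears in more than one test set")
        for train, val, test in self.folds:
            sets = [set(train), set(val), set(test)]
            if sets[0] & sets[1] or sets[0] & sets[2] or sets[1] & sets[2]:
                raise ValueError("train/val/test sets overlap within a fold")


def make_folds(ids, n_folds: int = 10, n_val: int | None = None, seed: int = 0) -> FoldPlan:
    """Assign each pullback to exactly one test set.

    Test sizes follow the greedy ceil(n / n_folds) pattern (48 ids and 10
    folds give nine test sets of 5 and one of 3); if that would leave an
    empty fold, near-equal partitioning is used instead.  Validation ids are
    drawn from the remaining ids after the seeded shuffle.
    """
    ids = list(ids)
    n = len(ids)
    if n < n_folds:
        raise ValueError(f"need at least {n_folds} ids, got {n}")
    if n_val is None:
        n_val = max(1, round(n / 10))  # 48 ids -> 5, matching the 38/5/5 split
    rng = np.random.default_rng(seed)
    order = [ids[i] for i in rng.permutation(n)]
    per = math.ceil(n / n_folds)
    sizes = []
    remaining = n
    for _ in range(n_folds):
        take = min(per, remaining)
        sizes.append(take)
        remaining -= take
    if min(sizes) == 0:  # fall back to near-equal partition
        base, extra = divmod(n, n_folds)
        sizes = [base + (1 if i < extra else 0) for i in range(n_folds)]
    folds = []
    start = 0
    for size in sizes:
        test = order[start : start + size]
        rest = order[:start] + order[start + size :]
        val = rest[:n_val]
        train = rest[n_val:]
        folds.append((train, val, test))
        start += size
    plan = FoldPlan(folds=folds, seed=seed)
    plan.validate()
    return plan


def confusion(y_true, y_pred, valid=None) -> np.ndarray:
    """3x3 counts, rows = true class, columns = predicted class."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ValueError("label arrays must have equal length")
    if valid is not None:
        valid = np.asarray(valid, dtype=bool)
        y_true = y_true[valid]
        y_pred = y_pred[valid]
    for name, arr in (("true", y_true), ("predicted", y_pred)):
        if arr.size and (arr.min() < 0 or arr.max() >= N_CLASSES):
            raise ValueError(f"{name} label outside the 3-class set on a valid pixel")
    cm = np.zeros((N_CLASSES, N_CLASSES), dtype=np.int64)
    np.add.at(cm, (y_true, y_pred), 1)
    return cm


def metrics(cm: np.ndarray) -> dict:
    """One-vs-rest per-class sensitivity, specificity, F1, class-wise
    accuracy (row-normalised diagonal = recall), and overall accuracy.
    Zero-support metrics are reported as NaN, not 0."""
    cm = np.asarray(cm, dtype=float)
    total = cm.sum()
    out = {"overall_accuracy": float(np.trace(cm) / total) if total else float("nan")}
    per = []
    for c in range(N_CLASSES):
        tp = cm[c, c]
        fn = cm[c].sum() - tp
        fp = cm[:, c].sum() - tp
        tn = total - tp - fn - fp
        support = tp + fn
        per.append(
            {
                "sensitivity": float(tp / support) if support else float("nan"),
                "specificity": float(tn / (tn + fp)) if (tn + fp) else float("nan"),
                "f1": float(2 * tp / (2 * tp + fp + fn)) if (2 * tp + fp + fn) else float("nan"),
                "accuracy": float(tp / support) if support else float("nan"),
                "support": int(support),
            }
        )
    out["per_class"] = per
    return out


def paired_fold_test(errors_a, errors_b) -> tuple[float, float]:
    """Classical paired two-tailed t-test on per-fold error rates."""
    a = np.asarray(errors_a, dtype=float)
    b = np.asarray(errors_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise ValueError("need equal-length paired vectors of length >= 2")
    d = a - b
    n = d.size
    sd = d.std(ddof=1)
    if sd == 0:
        import warnings

        warnings.warn("zero variance of paired differences", RuntimeWarning)
        return (0.0, 1.0) if np.allclose(d, 0) else (math.inf * np.sign(d.mean()), 0.0)
    t = d.mean() / (sd / math.sqrt(n))
    p = 2 * sps.t.sf(abs(t), df=n - 1)
    return float(t), float(p)


@dataclass
class PullbackData:
    """Preprocessed A-lines of one pullback plus en-face geometry."""

    pullback_id: str
    X: np.ndarray  # (n_valid, 200)
    y: np.ndarray  # (n_valid,)
    aline_idx: np.ndarray
    frame_idx: np.ndarray
    n_alines: int
    n_frames: int
    guidewire_mask: np.ndarray  # (n_alines, n_frames)
    labels_grid: np.ndarray  # (n_alines, n_frames) incl. GUIDEWIRE


@dataclass
class FoldResults:
    fold_confusions_pre: list = field(default_factory=list)
    fold_confusions_post: list = field(default_factory=list)
    fold_accuracy_pre: list = field(default_factory=list)
    fold_accuracy_post: list = field(default_factory=list)
    pooled_pre: np.ndarray | None = None
    pooled_post: np.ndarray | None = None

    def summary(self) -> dict:
        pre = np.asarray(self.fold_accuracy_pre, dtype=float)
        post = np.asarray(self.fold_accuracy_post, dtype=float)
        n = max(pre.size, 1)
        return {
            "n_folds": int(pre.size),
            "mean_accuracy_pre": float(pre.mean()) if pre.size else float("nan"),
            "mean_accuracy_post": float(post.mean()) if post.size else float("nan"),
            "stderr_accuracy_pre": float(pre.std(ddof=1) / math.sqrt(n)) if pre.size > 1 else float("nan"),
            "stderr_accuracy_post": float(post.std(ddof=1) / math.sqrt(n)) if post.size > 1 else float("nan"),
            "metrics_pooled_pre": metrics(self.pooled_pre) if self.pooled_pre is not None else None,
            "metrics_pooled_post": metrics(self.pooled_post) if self.pooled_post is not None else None,
        }


def _gather(dataset: dict[str, PullbackData], ids, subsample: int = 1):
    xs, ys = [], []
    for pid in ids:
        d = dataset[pid]
        xs.append(d.X[::subsample])
        ys.append(d.y[::subsample])
    return np.concatenate(xs, axis=0), np.concatenate(ys, axis=0)


def run_crossval(
    dataset: dict[str, PullbackData],
    net_config: nets_mod.NetConfig,
    crf_params: crf_mod.CRFParams,
    n_folds: int = 10,
    seed: int = 0,
    train_subsample: int = 1,
    area_threshold: int = 10,
    verbose: bool = False,
) -> FoldResults:
    """Train/evaluate per fold; tally confusions before and after cleaning.

    Leakage is structurally impossible: the fold plan partitions pullback
    ids and is validated at construction and again here.
    """
    plan = make_folds(sorted(dataset.keys()), n_folds=n_folds, seed=seed)
    plan.validate()
    results = FoldResults()
    pooled_pre = np.zeros((N_CLASSES, N_CLASSES), dtype=np.int64)
    pooled_post = np.zeros((N_CLASSES, N_CLASSES), dtype=np.int64)
    for fold_i, (train_ids, val_ids, test_ids) in enumerate(plan.folds):
        assert not (set(train_ids) & set(val_ids) | set(train_ids) & set(test_ids) | set(val_ids) & set(test_ids))
        X_tr, y_tr = _gather(dataset, train_ids, train_subsample)
        X_va, y_va = _gather(dataset, val_ids, train_subsample)
        counts = np.bincount(y_tr, minlength=N_CLASSES)
        if np.any(counts == 0):
            raise RuntimeError(
                f"fold {fold_i}: class {int(np.argmin(counts))} missing from training set"
            )
        model = nets_mod.build_model(net_config)
        trained = nets_mod.train(model, X_tr, y_tr, X_va, y_va, net_config, verbose=verbose)
        cm_pre = np.zeros((N_CLASSES, N_CLASSES), dtype=np.int64)
        cm_post = np.zeros((N_CLASSES, N_CLASSES), dtype=np.int64)
        for pid in test_ids:
            d = dataset[pid]
            probs = nets_mod.predict(trained, d.X)
            pmap = crf_mod.build_enface(
                probs,
                d.aline_idx,
                d.frame_idx,
                n_alines=d.n_alines,
                frame_range=(0, d.n_frames - 1),
                guidewire_mask=d.guidewire_mask,
            )
            cleaned = crf_mod.clean(pmap, crf_params, area_threshold=area_threshold)
            pred_pre = np.argmax(probs, axis=1)
            pred_post = cleaned[d.aline_idx, d.frame_idx]
            ok = pred_post != GUIDEWIRE
            cm_pre += confusion(d.y, pred_pre)
            cm_post += confusion(d.y[ok], pred_post[ok])
        results.fold_confusions_pre.append(cm_pre)
        results.fold_confusions_post.append(cm_post)
        results.fold_accuracy_pre.append(float(np.trace(cm_pre) / cm_pre.sum()))
        results.fold_accuracy_post.append(float(np.trace(cm_post) / cm_post.sum()))
        pooled_pre += cm_pre
        pooled_post += cm_post
        if verbose:
            print(
                f"fold {fold_i}: pre {results.fold_accuracy_pre[-1]:.3f} "
                f"post {results.fold_accuracy_post[-1]:.3f}"
            )
    results.pooled_pre = pooled_pre
    results.pooled_post = pooled_post
    return results
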