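"""Feature-based neural estimation of systolic and diastolic BP.

A small fully connected network (ReLU hidden layers, linear output) maps the
seven window-level inputs — mean dC, PWV, HR, LF HRV, I-J interval, age and
a one-time baseline cuff BP for calibration — to SBP or DBP (separate models
per target). Training minimises a composite loss

    L = MSE(pred, ref)
      + lambda_grad * mean[(d pred - d ref)^2]          (temporal gradient)
      + lambda_mono * mean[relu(-(p_i - p_j)(v_i - v_j))]  (PWV monotonicity)
      + lambda_l2   * ||W||^2

where the gradient term runs over consecutive same-subject windows and the
monotonicity hinge over within-batch pairs, penalising predictions that
decrease while pulse wave velocity increases. Evaluation uses seeded 10-fold
cross-validation with per-fold re-initialisation and per-fold input scaling,
so out-of-fold predictions never see their own fold's statistics.

The network, its analytic gradients and the Adam optimiser are implemented
directly on numpy arrays: the composite loss is not expressible in stock
regressors, and the architectures are small enough (16-8-4 or 128-32-16
neurons) that full-batch training takes seconds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import GroupKFold, KFold

logger = logging.getLogger(__name__)

__all__ = [
    "FEATURE_NAMES",
    "ModelConfig",
    "Scaler",
    "TrainedModel",
    "CVResult",
    "assemble_inputs",
    "composite_loss",
    "train_model",
    "train_cv",
    "predict",
    "permutation_importance",
]

FEATURE_NAMES = ("mean_dc", "pwv", "hr", "lf_hrv", "ij_interval", "age", "baseline_bp")
PWV_COLUMN = FEATURE_NAMES.index("pwv")

HIDDEN_SIZES = {"intermittent": (16, 8, 4), "continuous": (128, 32, 16)}


@dataclass(frozen=True)
class ModelConfig:
    """Hyperparameters for one SBP or DBP model."""

    mode: str = "continuous"
    hidden_sizes: tuple[int, ...] | None = None  # None -> per-mode default
    loss_weights: tuple[float, float, float] = (0.5, 0.1, 1e-4)  # grad, mono, l2
    lr: float = 1e-3
    epochs: int = 500
    batch_size: int = 0  # 0 = full batch
    seed: int = 0
    val_fraction: float = 0.1  # early-stopping split of the training folds
    patience: int = 50
    split: str = "window"  # random over windows, or "subject" (grouped folds)

    def __post_init__(self) -> None:
        if self.mode not in HIDDEN_SIZES:
            raise ValueError("mode must be 'intermittent' or 'continuous'")
        if any(w < 0 for w in self.loss_weights):
            raise ValueError("loss weights must be non-negative")
        if self.hidden_sizes is None:
            object.__setattr__(self, "hidden_sizes", HIDDEN_SIZES[self.mode])


@dataclass
class Scaler:
    """Per-feature standardisation fitted on training data only."""

    mean: np.ndarray
    sd: np.ndarray

    @classmethod
    def fit(cls, x: np.ndarray) -> "Scaler":
        mean = x.mean(axis=0)
        sd = x.std(axis=0)
        sd[sd == 0] = 1.0  # degenerate constant column
        return cls(mean=mean, sd=sd)

    def transform(self, x: np.ndarray) -> np.ndarray:
        return (x - self.mean) / self.sd


# ---------------------------------------------------------------------------
# Input assembly
# ---------------------------------------------------------------------------


def assemble_inputs(features, meta: dict, target: str = "sbp") -> np.ndarray:
    """Design matrix (n_windows x 7) for one subject, unscaled.

    ``features`` is a DataFrame from :func:`padbp.features.features_to_frame`
    (or a list of FeatureWindow); only rows with ``valid`` true are used.
    ``meta`` must supply ``age`` and the baseline cuff reading for the target
    (``baseline_sbp`` or ``baseline_dbp``) — the one-time calibration is
    mandatory.
    """
    from .features import features_to_frame

    if not isinstance(features, __import__("pandas").DataFrame):
        features = features_to_frame(features)
    if target not in ("sbp", "dbp"):
        raise ValueError("target must be 'sbp' or 'dbp'")
    key = f"baseline_{target}"
    if "age" not in meta or key not in meta or meta[key] is None:
        raise ValueError(f"meta must include 'age' and '{key}' (calibration is mandatory)")
    rows = features[features["valid"].astype(bool)]
    n = len(rows)
    x = np.empty((n, len(FEATURE_NAMES)))
    for j, name in enumerate(FEATURE_NAMES):
        if name == "age":
            x[:, j] = float(meta["age"])
        elif name == "baseline_bp":
            x[:, j] = float(meta[key])
        else:
            x[:, j] = rows[name].to_numpy(float)
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite values in the assembled design matrix")
    return x


# ---------------------------------------------------------------------------
# Network internals
# ---------------------------------------------------------------------------


class _MLP:
    """Minimal ReLU MLP with analytic backprop and Adam."""

    def __init__(self, n_in: int, hidden: tuple[int, ...], rng: np.random.Generator):
        sizes = (n_in, *hidden, 1)
        self.W = [
            rng.normal(0.0, np.sqrt(2.0 / sizes[i]), size=(sizes[i], sizes[i + 1]))
            for i in range(len(sizes) - 1)
        ]
        self.b = [np.zeros(sizes[i + 1]) for i in range(len(sizes) - 1)]

    def forward(self, x: np.ndarray, cache: list | None = None) -> np.ndarray:
        a = x
        if cache is not None:
            cache.append(a)
        for i, (W, b) in enumerate(zip(self.W, self.b)):
            z = a @ W + b
            a = np.maximum(z, 0.0) if i < len(self.W) - 1 else z
            if cache is not None:
                cache.append(a)
        return a[:, 0]

    def backward(self, cache: list, dpred: np.ndarray):
        """Gradients of sum(dpred * pred) wrt weights/biases."""
        gW = [None] * len(self.W)
        gb = [None] * len(self.b)
        delta = dpred[:, None]  # (n, 1)
        for i in range(len(self.W) - 1, -1, -1):
            a_prev = cache[i]
            gW[i] = a_prev.T @ delta
            gb[i] = delta.sum(axis=0)
            if i > 0:
                delta = (delta @ self.W[i].T) * (cache[i] > 0)
        return gW, gb

    def l2_norm(self) -> float:
        return float(sum((W**2).sum() for W in self.W))

    def params(self):
        return [W.copy() for W in self.W], [b.copy() for b in self.b]

    def set_params(self, W, b):
        self.W = [w.copy() for w in W]
        self.b = [x.copy() for x in b]


@dataclass
class TrainedModel:
    """Fitted network plus everything needed to reproduce its predictions."""

    net: _MLP
    scaler: Scaler
    y_mean: float
    y_sd: float
    target: str
    config: ModelConfig


@dataclass
class CVResult:
    """Out-of-fold cross-validation record."""

    fold_assignments: np.ndarray  # fold index per window
    oof_pred: np.ndarray  # mmHg, one prediction per window
    train_rmse: np.ndarray  # per fold, mmHg
    test_rmse: np.ndarray  # per fold, mmHg
    models: list


# ---------------------------------------------------------------------------
# Composite loss
# ---------------------------------------------------------------------------


def _grad_pairs(subjects: np.ndarray | None, n: int) -> tuple[np.ndarray, np.ndarray]:
    """Index pairs of consecutive windows within each subject (time order)."""
    i = np.arange(n - 1)
    j = i + 1
    if subjects is not None:
        same = np.asarray(subjects)[i] == np.asarray(subjects)[j]
        i, j = i[same], j[same]
    return i, j


def _mono_pairs(n: int, rng: np.random.Generator | None = None, cap: int = 200_000):
    i, j = np.triu_indices(n, k=1)
    if len(i) > cap:
        rng = rng or np.random.default_rng(0)
        sel = rng.choice(len(i), size=cap, replace=False)
        i, j = i[sel], j[sel]
    return i, j


def composite_loss(
    pred,
    ref,
    pwv,
    weights: tuple[float, float, float] = (0.5, 0.1, 1e-4),
    subjects=None,
    l2_norm: float = 0.0,
) -> float:
    """Scalar composite loss (see module docstring for the four terms).

    ``pred``/``ref`` must be aligned in time order within each subject;
    ``pwv`` is the pulse-wave-velocity input for the monotonicity hinge and
    ``l2_norm`` the squared weight norm of the network being penalised.
    """
    pred = np.asarray(pred, float)
    ref = np.asarray(ref, float)
    pwv = np.asarray(pwv, float)
    if not (len(pred) == len(ref) == len(pwv)):
        raise ValueError("pred, ref and pwv must have equal length")
    lg, lm, l2 = weights
    loss = float(np.mean((pred - ref) ** 2))
    gi, gj = _grad_pairs(subjects, len(pred))
    if lg > 0 and len(gi):
        d = (pred[gj] - pred[gi]) - (ref[gj] - ref[gi])
        loss += lg * float(np.mean(d**2))
    mi, mj = _mono_pairs(len(pred))
    if lm > 0 and len(mi):
        hinge = np.maximum(-(pred[mi] - pred[mj]) * (pwv[mi] - pwv[mj]), 0.0)
        loss += lm * float(np.mean(hinge))
    loss += l2 * l2_norm
    return loss


def _loss_grad_wrt_pred(pred, ref, pwv, weights, subjects, mono_idx):
    """d(composite loss)/d(pred), network-weight terms excluded."""
    n = len(pred)
    lg, lm, _ = weights
    g = 2.0 * (pred - ref) / n
    gi, gj = _grad_pairs(subjects, n)
    if lg > 0 and len(gi):
        d = (pred[gj] - pred[gi]) - (ref[gj] - ref[gi])
        coeff = 2.0 * lg / len(gi)
        np.add.at(g, gj, coeff * d)
        np.add.at(g, gi, -coeff * d)
    mi, mj = mono_idx
    if lm > 0 and len(mi):
        s = -(pred[mi] - pred[mj]) * (pwv[mi] - pwv[mj])
        act = s > 0
        coeff = lm / len(mi)
        dv = pwv[mi[act]] - pwv[mj[act]]
        np.add.at(g, mi[act], -coeff * dv)
        np.add.at(g, mj[act], coeff * dv)
    return g


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------


def train_model(
    x: np.ndarray,
    y: np.ndarray,
    config: ModelConfig,
    subjects: np.ndarray | None = None,
    pwv_raw: np.ndarray | None = None,
    target: str = "sbp",
    seed_offset: int = 0,
) -> TrainedModel:
    """Fit one network on (x, y) with Adam and early stopping.

    Inputs are standardised with statistics of ``x`` (training data only);
    targets are standardised internally and mapped back to mmHg at predict
    time. A seeded 10% validation split of the training data drives early
    stopping on plain MSE.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    rng = np.random.default_rng((config.seed + 7919 * seed_offset) % (2**31))
    scaler = Scaler.fit(x)
    xs = scaler.transform(x)
    y_mean, y_sd = float(y.mean()), float(y.std()) or 1.0
    if y_sd == 0:
        y_sd = 1.0
    ys = (y - y_mean) / y_sd
    pwv = pwv_raw if pwv_raw is not None else x[:, PWV_COLUMN]

    n = len(xs)
    n_val = max(1, int(round(config.val_fraction * n))) if n >= 10 else 0
    perm = rng.permutation(n)
    val_idx, tr_idx = perm[:n_val], perm[n_val:]
    # keep training rows in time order so the gradient term sees real
    # consecutive-window differences
    tr_idx = np.sort(tr_idx)

    net = _MLP(xs.shape[1], config.hidden_sizes, rng)
    mW = [np.zeros_like(W) for W in net.W]
    vW = [np.zeros_like(W) for W in net.W]
    mb = [np.zeros_like(b) for b in net.b]
    vb = [np.zeros_like(b) for b in net.b]
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    lg, lm, l2 = config.loss_weights

    x_tr, y_tr = xs[tr_idx], ys[tr_idx]
    pwv_tr = pwv[tr_idx]
    subj_tr = np.asarray(subjects)[tr_idx] if subjects is not None else None
    mono_idx = _mono_pairs(len(tr_idx), rng)

    best_val = np.inf
    best = net.params()
    stale = 0
    t_adam = 0
    weights = (lg, lm, l2)
    for epoch in range(config.epochs):
        cache: list = []
        pred = net.forward(x_tr, cache)
        dpred = _loss_grad_wrt_pred(pred, y_tr, pwv_tr, weights, subj_tr, mono_idx)
        gW, gb = net.backward(cache, dpred)
        t_adam += 1
        for i in range(len(net.W)):
            gW[i] = gW[i] + 2.0 * l2 * net.W[i]
            mW[i] = beta1 * mW[i] + (1 - beta1) * gW[i]
            vW[i] = beta2 * vW[i] + (1 - beta2) * gW[i] ** 2
            mb[i] = beta1 * mb[i] + (1 - beta1) * gb[i]
            vb[i] = beta2 * vb[i] + (1 - beta2) * gb[i] ** 2
            mhW = mW[i] / (1 - beta1**t_adam)
            vhW = vW[i] / (1 - beta2**t_adam)
            mhb = mb[i] / (1 - beta1**t_adam)
            vhb = vb[i] / (1 - beta2**t_adam)
            net.W[i] -= config.lr * mhW / (np.sqrt(vhW) + eps)
            net.b[i] -= config.lr * mhb / (np.sqrt(vhb) + eps)
        if n_val:
            val_pred = net.forward(xs[val_idx])
            val_loss = float(np.mean((val_pred - ys[val_idx]) ** 2))
            if val_loss < best_val - 1e-7:
                best_val = val_loss
                best = net.params()
                stale = 0
            else:
                stale += 1
                if stale >= config.patience:
                    break
    if n_val:
        net.set_params(*best)
    return TrainedModel(
        net=net, scaler=scaler, y_mean=y_mean, y_sd=y_sd, target=target, config=config
    )


def predict(model: TrainedModel, x: np.ndarray) -> np.ndarray:
    """Per-window BP predictions in mmHg for raw (unscaled) features."""
    x = np.asarray(x, float)
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite features passed to predict")
    xs = model.scaler.transform(x)
    return model.net.forward(xs) * model.y_sd + model.y_mean


def train_cv(
    x: np.ndarray,
    y: np.ndarray,
    config: ModelConfig,
    subjects: np.ndarray | None = None,
    target: str = "sbp",
    n_folds: int = 10,
) -> CVResult:
    """Seeded k-fold cross-validation with per-fold re-initialisation.

    Every window is predicted exactly once out-of-fold; the scaler and the
    network of each fold are fitted on that fold's training rows only. With
    fewer than 10 windows the split degrades to leave-one-out (warned).
    ``config.split='subject'`` groups folds by subject instead of splitting
    windows at random.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    if n < 10:
        logger.warning("only %d windows: falling back to leave-one-out", n)
        n_folds = n
    if config.split == "subject" and subjects is not None:
        groups = np.asarray(subjects)
        k = min(n_folds, len(np.unique(groups)))
        splitter = GroupKFold(n_splits=k)
        split_iter = splitter.split(x, y, groups)
    else:
        splitter = KFold(n_splits=min(n_folds, n), shuffle=True, random_state=config.seed)
        split_iter = splitter.split(x)

    folds = np.full(n, -1, int)
    oof = np.full(n, np.nan)
    train_rmse, test_rmse, models = [], [], []
    for f, (tr, te) in enumerate(split_iter):
        subj_tr = np.asarray(subjects)[tr] if subjects is not None else None
        model = train_model(
            x[tr], y[tr], config, subjects=subj_tr, target=target, seed_offset=f + 1
        )
        p_tr = predict(model, x[tr])
        p_te = predict(model, x[te])
        folds[te] = f
        oof[te] = p_te
        train_rmse.append(float(np.sqrt(np.mean((p_tr - y[tr]) ** 2))))
        test_rmse.append(float(np.sqrt(np.mean((p_te - y[te]) ** 2))))
        models.append(model)
    assert not np.isnan(oof).any(), "every window must be predicted once out-of-fold"
    return CVResult(
        fold_assignments=folds,
        oof_pred=oof,
        train_rmse=np.asarray(train_rmse),
        test_rmse=np.asarray(test_rmse),
        models=models,
    )


# ---------------------------------------------------------------------------
# Permutation importance
# ---------------------------------------------------------------------------


def permutation_importance(
    model: TrainedModel,
    x: np.ndarray,
    y: np.ndarray,
    seed: int = 0,
    n_shuffles: int = 20,
    feature_names: tuple[str, ...] = FEATURE_NAMES,
) -> dict[str, float]:
    """Shuffle-based feature importance, normalised so the top score is 1.

    For each feature, the column is shuffled ``n_shuffles`` times (seeded)
    and the mean RMSE increase over the unshuffled baseline is recorded;
    scores are divided by the maximum increase.
    """
    rng = np.random.default_rng(seed)
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    base = float(np.sqrt(np.mean((predict(model, x) - y) ** 2)))
    deltas = np.zeros(x.shape[1])
    for j in range(x.shape[1]):
        accum = 0.0
        for _ in range(n_shuffles):
            xp = x.copy()
            xp[:, j] = rng.permutation(xp[:, j])
            rmse = float(np.sqrt(np.mean((predict(model, xp) - y) ** 2)))
            accum += rmse - base
        deltas[j] = accum / n_shuffles
    top = deltas.max()
    if top <= 0:
        logger.warning("no feature raised the RMSE when shuffled; scores set to 0")
        return {name: 0.0 for name in feature_names}
    return {name: float(d / top) for name, d in zip(feature_names, deltas)}
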