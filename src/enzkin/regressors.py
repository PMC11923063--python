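"""Shallow regressors and the attention-corrected two-stage kcat/Km model.

The base predictor is deliberately small: one hidden layer (default width
256, rectified-linear) and one linear output, trained with the Adam
optimizer against an RMSE loss on log10 labels.  Wide feature vectors with
few samples overfit quickly; a single hidden layer is the regularizing
choice.

Catalytic efficiency (log10 kcat/Km) gets a two-stage treatment.  Stage 1
pre-trains a kcat and a Km regressor on the parent labels of the
efficiency dataset; their weights are then frozen.  The initial efficiency
estimate is the difference of their predictions in log10 space.  Stage 2
trains a correction network — dense layer to 256 dims, a feature-wise
attention gate

    A = softmax(W · h),     h_A = A ⊙ h,

then a linear output — and two learnable blend scalars (a, b), so the
final prediction is

    a · (f_kcat(x) − f_Km(x)) + b · g(x).

An Extra-Trees backend with the same predict contract is provided for the
tree-ensemble variant of the workflow.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from typing import Callable, Hashable, Mapping, Sequence

import numpy as np
import pandas as pd

from enzkin.evaluation import pcc, rmse, scc
from enzkin.splits import FoldAssignment

__all__ = [
    "RegressorConfig", "MLPRegressor", "TreeEnsembleRegressor",
    "CorrectionNet", "TwoStageRatioModel", "CrossValResults",
    "attention_gate", "train_regressor", "train_tree_ensemble",
    "train_two_stage", "crossval", "grid_search", "ensemble_predict",
]


@dataclass(frozen=True)
class RegressorConfig:
    """Hyperparameters of the one-hidden-layer regressor.

    All randomness (weight init, minibatch shuffling) flows from ``seed``.
    """

    hidden_dim: int = 256
    activation: str = "relu"
    learning_rate: float = 1e-3
    weight_decay: float = 1e-5
    epochs: int = 30
    batch_size: int = 64
    seed: int = 0
    # tree-ensemble backend only
    n_estimators: int = 200

    def with_seed(self, seed: int) -> "RegressorConfig":
        return replace(self, seed=seed)


def _softmax(scores: np.ndarray) -> np.ndarray:
    shifted = scores - scores.max(axis=-1, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=-1, keepdims=True)


def attention_gate(W: np.ndarray, h: np.ndarray) -> tuple[np.ndarray,
                                                          np.ndarray]:
    """Feature-wise attention: A = softmax(W·h), h_A = A ⊙ h.

    ``W`` may be a (d, d) matrix (scores = W·h) or a (d,) vector
    (elementwise scores W ⊙ h).  ``h`` may be a single vector (d,) or a
    batch (n, d); the softmax normalizes over the feature axis, so each
    attention vector sums to 1.
    """
    W = np.asarray(W, dtype=np.float64)
    h = np.asarray(h, dtype=np.float64)
    d = h.shape[-1]
    if W.ndim == 2:
        if W.shape != (d, d):
            raise ValueError(f"W shape {W.shape} incompatible with h dim {d}")
        scores = h @ W.T
    elif W.ndim == 1:
        if W.shape != (d,):
            raise ValueError(f"W shape {W.shape} incompatible with h dim {d}")
        scores = W * h
    else:
        raise ValueError(f"W must be 1-D or 2-D, got ndim {W.ndim}")
    A = _softmax(scores)
    return A, A * h


class _Adam:
    """Adam optimizer over a list of parameter arrays (updated in place)."""

    def __init__(self, params: list[np.ndarray], lr: float,
                 weight_decay: float = 0.0,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.weight_decay = weight_decay
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            if self.weight_decay:
                g = g + self.weight_decay * p
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            m_hat = m / (1 - b1 ** self.t)
            v_hat = v / (1 - b2 ** self.t)
            p -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


def _rmse_grad(pred: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """RMSE loss and its gradient w.r.t. predictions."""
    resid = pred - y
    loss = float(np.sqrt(np.mean(resid ** 2)))
    if loss == 0.0:
        return 0.0, np.zeros_like(resid)
    return loss, resid / (resid.size * loss)


class MLPRegressor:
    """One-hidden-layer neural regressor (ReLU, Adam, RMSE loss).

    Deterministic given data and config; exposes ``fit``, ``predict`` and a
    ``param_digest`` used to assert the two-stage freeze contract.
    """

    def __init__(self, input_dim: int, config: RegressorConfig | None = None):
        self.config = config or RegressorConfig()
        if self.config.activation != "relu":
            raise ValueError(
                f"unsupported activation {self.config.activation!r}"
            )
        self.input_dim = input_dim
        h = self.config.hidden_dim
        rng = np.random.default_rng(self.config.seed)
        self.W1 = rng.standard_normal((input_dim, h)) * np.sqrt(2 / input_dim)
        self.b1 = np.zeros(h)
        # zero-init readout: fit() sets b2 to the label mean, so training
        # starts at the best constant predictor
        self.W2 = np.zeros(h)
        self.b2 = np.zeros(1)
        self.loss_history: list[float] = []

    # -- forward ---------------------------------------------------------
    def _forward(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        z1 = X @ self.W1 + self.b1
        hidden = np.maximum(z1, 0.0)
        return z1, hidden @ self.W2 + self.b2[0]

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != self.input_dim:
            raise ValueError(
                f"input dim {X.shape[1]} != model dim {self.input_dim}"
            )
        return self._forward(X)[1]

    # -- training --------------------------------------------------------
    def fit(self, X: np.ndarray, y: np.ndarray) -> "MLPRegressor":
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y, dtype=np.float64)
        if X.ndim != 2 or X.shape[0] != y.shape[0]:
            raise ValueError(
                f"X shape {X.shape} incompatible with y shape {y.shape}"
            )
        if not (np.isfinite(X).all() and np.isfinite(y).all()):
            raise ValueError("non-finite values in training data")
        cfg = self.config
        rng = np.random.default_rng(cfg.seed + 1)
        self.b2[0] = y.mean()
        opt = _Adam([self.W1, self.b1, self.W2, self.b2],
                    lr=cfg.learning_rate, weight_decay=cfg.weight_decay)
        n = X.shape[0]
        batch = min(cfg.batch_size, n)
        for _epoch in range(cfg.epochs):
            order = rng.permutation(n)
            for start in range(0, n, batch):
                idx = order[start:start + batch]
                xb, yb = X[idx], y[idx]
                z1 = xb @ self.W1 + self.b1
                hidden = np.maximum(z1, 0.0)
                pred = hidden @ self.W2 + self.b2[0]
                _loss, dpred = _rmse_grad(pred, yb)
                dW2 = hidden.T @ dpred
                db2 = np.array([dpred.sum()])
                dhidden = np.outer(dpred, self.W2)
                dz1 = dhidden * (z1 > 0)
                dW1 = xb.T @ dz1
                db1 = dz1.sum(axis=0)
                opt.step([dW1, db1, dW2, db2])
            epoch_loss, _ = _rmse_grad(self._forward(X)[1], y)
            self.loss_history.append(epoch_loss)
        return self

    def parameters(self) -> list[np.ndarray]:
        return [self.W1, self.b1, self.W2, self.b2]

    def param_digest(self) -> str:
        md = hashlib.sha256()
        for p in self.parameters():
            md.update(np.ascontiguousarray(p).tobytes())
        return md.hexdigest()


class TreeEnsembleRegressor:
    """Extra-Trees backend satisfying the same predict contract."""

    def __init__(self, input_dim: int, config: RegressorConfig | None = None):
        from sklearn.ensemble import ExtraTreesRegressor

        self.config = config or RegressorConfig()
        self.input_dim = input_dim
        self._model = ExtraTreesRegressor(
            n_estimators=self.config.n_estimators,
            random_state=self.config.seed,
        )
        self.loss_history: list[float] = []

    def fit(self, X: np.ndarray, y: np.ndarray) -> "TreeEnsembleRegressor":
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y, dtype=np.float64)
        if X.ndim != 2 or X.shape[0] != y.shape[0]:
            raise ValueError(
                f"X shape {X.shape} incompatible with y shape {y.shape}"
            )
        if not (np.isfinite(X).all() and np.isfinite(y).all()):
            raise ValueError("non-finite values in training data")
        self._model.fit(X, y)
        self.loss_history.append(rmse(self._model.predict(X), y))
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != self.input_dim:
            raise ValueError(
                f"input dim {X.shape[1]} != model dim {self.input_dim}"
            )
        return self._model.predict(X)


def train_regressor(
    X: np.ndarray, y: np.ndarray, config: RegressorConfig | None = None
) -> tuple[MLPRegressor, list[float]]:
    """Train the one-hidden-layer regressor; returns (model, per-epoch RMSE)."""
    X = np.asarray(X, dtype=np.float64)
    model = MLPRegressor(X.shape[1], config).fit(X, y)
    return model, model.loss_history


def train_tree_ensemble(
    X: np.ndarray, y: np.ndarray, config: RegressorConfig | None = None
) -> TreeEnsembleRegressor:
    """Train the Extra-Trees backend (library-provided algorithm)."""
    X = np.asarray(X, dtype=np.float64)
    return TreeEnsembleRegressor(X.shape[1], config).fit(X, y)


class CorrectionNet:
    """Dense (d→256) + feature-wise attention gate + linear output.

    The attention matrix is square over the dense output, so the gate can
    re-weight the 256 learned features per sample before the final scalar
    readout.
    """

    def __init__(self, input_dim: int, hidden_dim: int = 256, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.input_dim = input_dim
        self.hidden_dim = hidden_dim
        self.W1 = rng.standard_normal((input_dim, hidden_dim)) * np.sqrt(
            2 / input_dim)
        self.b1 = np.zeros(hidden_dim)
        self.Wa = rng.standard_normal((hidden_dim, hidden_dim)) * np.sqrt(
            1 / hidden_dim)
        # zero-init readout: the correction term starts at exactly 0, so
        # the untrained two-stage prediction equals the raw log-difference
        self.W2 = np.zeros(hidden_dim)
        self.b2 = np.zeros(1)

    def parameters(self) -> list[np.ndarray]:
        return [self.W1, self.b1, self.Wa, self.W2, self.b2]

    def zero_output(self) -> None:
        """Zero the readout so the correction term is exactly 0 everywhere."""
        self.W2[:] = 0.0
        self.b2[:] = 0.0

    def _forward(self, X: np.ndarray):
        z1 = X @ self.W1 + self.b1
        hidden = np.maximum(z1, 0.0)
        A, gated = attention_gate(self.Wa, hidden)
        out = gated @ self.W2 + self.b2[0]
        return z1, hidden, A, gated, out

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        if X.ndim == 1:
            X = X[None, :]
        return self._forward(X)[4]

    def backward(self, X: np.ndarray, cache, dout: np.ndarray
                 ) -> list[np.ndarray]:
        z1, hidden, A, gated, _out = cache
        dW2 = gated.T @ dout
        db2 = np.array([dout.sum()])
        dgated = np.outer(dout, self.W2)
        # gated = A * hidden; A = softmax(hidden @ Wa.T) row-wise
        dA = dgated * hidden
        dhidden_direct = dgated * A
        ds = A * (dA - (dA * A).sum(axis=1, keepdims=True))
        dWa = ds.T @ hidden
        dhidden = dhidden_direct + ds @ self.Wa
        dz1 = dhidden * (z1 > 0)
        dW1 = X.T @ dz1
        db1 = dz1.sum(axis=0)
        return [dW1, db1, dWa, dW2, db2]


class TwoStageRatioModel:
    """Frozen kcat/Km submodels + attention correction net + blend weights.

    ``predict(x) = a · (f_kcat(x) − f_Km(x)) + b · g(x)`` where g is the
    correction net and (a, b) are learnable scalars initialized to 1.
    Stage-2 training (``fit_correction``) touches only g, a and b; the
    submodels' parameter digests are bit-identical before and after.
    """

    def __init__(self, kcat_submodel: MLPRegressor, km_submodel: MLPRegressor,
                 correction_config: RegressorConfig | None = None):
        if kcat_submodel.input_dim != km_submodel.input_dim:
            raise ValueError("submodels disagree on input dim")
        self.kcat_submodel = kcat_submodel
        self.km_submodel = km_submodel
        self.config = correction_config or RegressorConfig()
        self.correction_net = CorrectionNet(
            kcat_submodel.input_dim, hidden_dim=self.config.hidden_dim,
            seed=self.config.seed)
        self.blend = np.array([1.0, 1.0])  # (a, b)
        self.loss_history: list[float] = []

    @property
    def input_dim(self) -> int:
        return self.kcat_submodel.input_dim

    def raw_difference(self, X: np.ndarray) -> np.ndarray:
        """Initial efficiency estimate: f_kcat(x) − f_Km(x), uncorrected."""
        return self.kcat_submodel.predict(X) - self.km_submodel.predict(X)

    def predict(self, X: np.ndarray) -> np.ndarray:
        a, b = self.blend
        return a * self.raw_difference(X) + b * self.correction_net.predict(X)

    def submodel_digests(self) -> tuple[str, str]:
        return (self.kcat_submodel.param_digest(),
                self.km_submodel.param_digest())

    def fit_correction(self, X: np.ndarray, y: np.ndarray
                       ) -> "TwoStageRatioModel":
        """Stage 2: train correction net + blend on efficiency labels.

        Submodels are used only through their (frozen) predictions.
        """
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y, dtype=np.float64)
        cfg = self.config
        diff = self.raw_difference(X)  # frozen; precompute once
        net = self.correction_net
        params = net.parameters() + [self.blend]
        opt = _Adam(params, lr=cfg.learning_rate,
                    weight_decay=cfg.weight_decay)
        rng = np.random.default_rng(cfg.seed + 2)
        n = X.shape[0]
        batch = min(cfg.batch_size, n)
        for _epoch in range(cfg.epochs):
            order = rng.permutation(n)
            for start in range(0, n, batch):
                idx = order[start:start + batch]
                xb, yb, diffb = X[idx], y[idx], diff[idx]
                cache = net._forward(xb)
                corr = cache[4]
                a, b = self.blend
                pred = a * diffb + b * corr
                _loss, dpred = _rmse_grad(pred, yb)
                grads = net.backward(xb, cache, dpred * b)
                dblend = np.array([float(dpred @ diffb),
                                   float(dpred @ corr)])
                opt.step(grads + [dblend])
            a, b = self.blend
            full_pred = a * diff + b * net.predict(X)
            loss, _ = _rmse_grad(full_pred, y)
            self.loss_history.append(loss)
        return self


@dataclass
class CrossValResults:
    """Out-of-fold predictions and per-fold metrics of a cross-validation.

    ``summary()`` renders a compact per-fold table with pooled metrics,
    in the spirit of a fitted-model results object.
    """

    task: str
    assignment: FoldAssignment
    keys: list[Hashable]
    y_true: np.ndarray
    oof_pred: np.ndarray
    fold_metrics: pd.DataFrame
    models: list = field(default_factory=list, repr=False)

    @property
    def pooled_pcc(self) -> float:
        return pcc(self.oof_pred, self.y_true)

    @property
    def pooled_scc(self) -> float:
        return scc(self.oof_pred, self.y_true)

    @property
    def pooled_rmse(self) -> float:
        return rmse(self.oof_pred, self.y_true)

    def summary(self) -> str:
        lines = [
            f"Cross-validation results — task: {self.task}, "
            f"mode: {self.assignment.mode}, k={self.assignment.k}, "
            f"seed={self.assignment.seed}",
            f"n = {len(self.keys)} records",
            "",
            self.fold_metrics.to_string(index=False,
                                        float_format=lambda v: f"{v:.4f}"),
            "",
            f"pooled OOF:  PCC {self.pooled_pcc:.4f}   "
            f"SCC {self.pooled_scc:.4f}   RMSE {self.pooled_rmse:.4f}",
        ]
        return "\n".join(lines)


def crossval(
    X: np.ndarray,
    y: np.ndarray,
    keys: Sequence[Hashable],
    assignment: FoldAssignment,
    config: RegressorConfig | None = None,
    task: str = "kcat",
    model_factory: Callable[[int, RegressorConfig], object] | None = None,
) -> CrossValResults:
    """k-fold cross-validation: each record is predicted exactly once by the
    model not trained on its fold.

    Per-fold model seeds derive from the config seed plus the fold index,
    so the whole run is reproducible from one seed.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    keys = list(keys)
    cfg = config or RegressorConfig()
    missing = [k for k in keys if k not in assignment.fold_of]
    if missing:
        raise ValueError(
            f"{len(missing)} record keys missing from the fold assignment, "
            f"e.g. {missing[0]!r}"
        )
    fold_idx = np.array([assignment.fold_of[k] for k in keys])
    factory = model_factory or (lambda d, c: MLPRegressor(d, c))
    oof = np.full(len(keys), np.nan)
    rows = []
    models = []
    for fold in range(assignment.k):
        test_mask = fold_idx == fold
        if not test_mask.any():
            continue
        train_mask = ~test_mask
        model = factory(X.shape[1], cfg.with_seed(cfg.seed + fold))
        model.fit(X[train_mask], y[train_mask])
        pred = model.predict(X[test_mask])
        oof[test_mask] = pred
        n_test = int(test_mask.sum())
        row = {"fold": fold, "n_test": n_test}
        if n_test >= 2:
            row.update(pcc=pcc(pred, y[test_mask]),
                       scc=scc(pred, y[test_mask]),
                       rmse=rmse(pred, y[test_mask]))
        else:  # correlation metrics undefined on < 2 records
            row.update(pcc=np.nan, scc=np.nan,
                       rmse=rmse(pred, y[test_mask]))
        rows.append(row)
        models.append(model)
    return CrossValResults(
        task=task, assignment=assignment, keys=keys, y_true=y,
        oof_pred=oof, fold_metrics=pd.DataFrame(rows), models=models,
    )


def grid_search(
    X: np.ndarray,
    y: np.ndarray,
    keys: Sequence[Hashable],
    assignment: FoldAssignment,
    grid: Sequence[RegressorConfig],
    task: str = "kcat",
) -> tuple[RegressorConfig, pd.DataFrame]:
    """Exhaustive grid search by mean OOF RMSE; ties keep the earlier config."""
    if len(grid) == 0:
        raise ValueError("empty grid")
    rows = []
    best_idx, best_rmse = 0, np.inf
    for i, cfg in enumerate(grid):
        res = crossval(X, y, keys, assignment, cfg, task=task)
        mean_rmse = float(res.fold_metrics["rmse"].mean())
        rows.append({
            "grid_index": i, "hidden_dim": cfg.hidden_dim,
            "learning_rate": cfg.learning_rate,
            "weight_decay": cfg.weight_decay, "epochs": cfg.epochs,
            "batch_size": cfg.batch_size, "mean_oof_rmse": mean_rmse,
            "pooled_pcc": res.pooled_pcc,
        })
        if mean_rmse < best_rmse:
            best_idx, best_rmse = i, mean_rmse
    return grid[best_idx], pd.DataFrame(rows)


@dataclass
class TwoStageCVResults:
    """Per-fold two-stage models with OOF predictions for both the corrected
    and the uncorrected (raw log-difference) estimate."""

    assignment: FoldAssignment
    keys: list[Hashable]
    y_true: np.ndarray
    oof_two_stage: np.ndarray
    oof_raw_difference: np.ndarray
    models: list[TwoStageRatioModel] = field(default_factory=list, repr=False)

    @property
    def two_stage_rmse(self) -> float:
        return rmse(self.oof_two_stage, self.y_true)

    @property
    def raw_difference_rmse(self) -> float:
        return rmse(self.oof_raw_difference, self.y_true)

    @property
    def two_stage_pcc(self) -> float:
        return pcc(self.oof_two_stage, self.y_true)

    def summary(self) -> str:
        return "\n".join([
            f"Two-stage kcat/Km cross-validation — k={self.assignment.k}, "
            f"mode: {self.assignment.mode}",
            f"n = {len(self.keys)} records",
            f"raw difference OOF:  PCC "
            f"{pcc(self.oof_raw_difference, self.y_true):.4f}   "
            f"RMSE {self.raw_difference_rmse:.4f}",
            f"two-stage OOF:       PCC {self.two_stage_pcc:.4f}   "
            f"RMSE {self.two_stage_rmse:.4f}",
        ])


def train_two_stage(
    X: np.ndarray,
    y_ratio: np.ndarray,
    y_kcat: np.ndarray,
    y_km: np.ndarray,
    keys: Sequence[Hashable],
    assignment: FoldAssignment,
    submodel_config: RegressorConfig | None = None,
    correction_config: RegressorConfig | None = None,
) -> TwoStageCVResults:
    """Cross-validated two-stage training on the efficiency dataset.

    Stage 1 trains kcat and Km submodels per fold on the parent labels of
    the training records; stage 2 trains the correction net and blend with
    the submodels frozen (asserted by parameter digest).
    """
    X = np.asarray(X, dtype=np.float64)
    y_ratio = np.asarray(y_ratio, dtype=np.float64)
    y_kcat = np.asarray(y_kcat, dtype=np.float64)
    y_km = np.asarray(y_km, dtype=np.float64)
    if np.isnan(y_kcat).any() or np.isnan(y_km).any():
        raise ValueError("efficiency entries are missing parent labels")
    keys = list(keys)
    sub_cfg = submodel_config or RegressorConfig()
    cor_cfg = correction_config or RegressorConfig()
    fold_idx = np.array([assignment.fold_of[k] for k in keys])
    oof_two = np.full(len(keys), np.nan)
    oof_raw = np.full(len(keys), np.nan)
    models: list[TwoStageRatioModel] = []
    for fold in range(assignment.k):
        test_mask = fold_idx == fold
        if not test_mask.any():
            continue
        train_mask = ~test_mask
        fold_sub = sub_cfg.with_seed(sub_cfg.seed + fold)
        kcat_model = MLPRegressor(X.shape[1], fold_sub)
        kcat_model.fit(X[train_mask], y_kcat[train_mask])
        km_model = MLPRegressor(
            X.shape[1], fold_sub.with_seed(fold_sub.seed + 1000))
        km_model.fit(X[train_mask], y_km[train_mask])
        model = TwoStageRatioModel(
            kcat_model, km_model, cor_cfg.with_seed(cor_cfg.seed + fold))
        digests_before = model.submodel_digests()
        model.fit_correction(X[train_mask], y_ratio[train_mask])
        if model.submodel_digests() != digests_before:
            raise RuntimeError(
                "freeze contract violated: submodel parameters changed "
                "during correction training"
            )
        oof_two[test_mask] = model.predict(X[test_mask])
        oof_raw[test_mask] = model.raw_difference(X[test_mask])
        models.append(model)
    return TwoStageCVResults(
        assignment=assignment, keys=keys, y_true=y_ratio,
        oof_two_stage=oof_two, oof_raw_difference=oof_raw, models=models,
    )


def ensemble_predict(models: Sequence, X: np.ndarray) -> np.ndarray:
    """Arithmetic mean of member predictions (fold-model ensembling)."""
    if len(models) == 0:
        raise ValueError("ensemble_predict requires ≥ 1 model")
    return np.mean([m.predict(X) for m in models], axis=0)


def predict_multi_substrate(
    model,
    sequence: str,
    smiles_list: Sequence[str],
    protein_provider,
    molecule_provider,
) -> float:
    """Multi-substrate reaction: mean of per-substrate predictions."""
    from enzkin.featurization import feature_matrix

    if len(smiles_list) == 0:
        raise ValueError("at least one substrate is required")
    X = feature_matrix([(sequence, s) for s in smiles_list],
                       protein_provider, molecule_provider)
    return float(np.mean(model.predict(X)))
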