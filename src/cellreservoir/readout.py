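"""Trainable decision-making (readout) layers.

The reservoir is fixed; only the readout learns.  Four regression layers
map organelle-surface memory states (optionally concatenated with
replicated auxiliary scalars) to cell responses:

* ``linear`` — ordinary least squares;
* ``lasso``  — L1-penalized least squares;
* ``ridge``  — L2-penalized least squares;
* ``ann``    — a single-hidden-layer tanh network trained by full-batch
  adaptive gradient descent, with both L1 and L2 weight penalties
  (elastic net), the only layer able to learn threshold-like responses.

Training minimizes mean squared error plus the layer's penalties.  The
split is temporal — the first fraction of the rows trains, the remainder
tests — because the rows are a time series.  Feature columns (and, for the
ANN, the target) are standardized on the training partition only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.linear_model import Lasso, LinearRegression, Ridge

READOUT_KINDS = ("linear", "lasso", "ridge", "ann")


def rmse(y: np.ndarray, y_hat: np.ndarray) -> float:
    """Root-mean-square error between a target and a prediction."""
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if y.shape != y_hat.shape:
        raise ValueError(f"shape mismatch: {y.shape} vs {y_hat.shape}")
    if y.size == 0:
        raise ValueError("rmse of empty vectors is undefined")
    return float(np.sqrt(np.mean((y - y_hat) ** 2)))


def concat_aux(surface_states: np.ndarray, aux: float) -> np.ndarray:
    """Concatenate m memory states with m copies of an auxiliary scalar.

    The auxiliary channel (e.g. a ligand concentration) is replicated to
    the organelle-surface width so both halves carry equal weight in the
    feature vector; output length is exactly 2m.
    """
    s = np.asarray(surface_states, dtype=float)
    if s.ndim != 1 or s.size < 1:
        raise ValueError("surface_states must be a nonempty 1-D vector")
    return np.concatenate([s, np.full(s.size, float(aux))])


class _Scaler:
    """Column standardizer fit on the training partition only."""

    def fit(self, X: np.ndarray) -> "_Scaler":
        self.mean_ = X.mean(axis=0)
        sd = X.std(axis=0)
        # columns constant up to float rounding carry no information and
        # must not be amplified by standardization
        tol = 1e-9 * (1.0 + np.abs(self.mean_))
        self.sd_ = np.where(sd > tol, sd, 1.0)
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (X - self.mean_) / self.sd_


@dataclass
class ReadoutModel:
    """One trainable decision layer.

    ``l1``/``l2`` are the penalty strengths (a lasso has ``l2 = 0``, a
    ridge ``l1 = 0``, the ANN may carry both).  ``hidden_width`` applies to
    the ANN only.  ``seed`` fixes the ANN weight initialization; the three
    linear layers are deterministic.
    """

    kind: str
    l1: float = 1e-4
    l2: float = 1e-4
    hidden_width: int = 64
    epochs: int = 3000
    learning_rate: float = 0.01
    seed: int = 0
    trained: bool = False

    def __post_init__(self):
        if self.kind not in READOUT_KINDS:
            raise ValueError(f"unknown readout kind {self.kind!r}; choose from {READOUT_KINDS}")
        if self.l1 < 0 or self.l2 < 0:
            raise ValueError("regularization strengths must be >= 0")
        if self.kind == "lasso":
            self.l2 = 0.0
        elif self.kind == "ridge":
            self.l1 = 0.0
        elif self.kind == "linear":
            self.l1 = self.l2 = 0.0

    # -- fitting ---------------------------------------------------------
    def fit(self, X: np.ndarray, y: np.ndarray) -> "ReadoutModel":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if X.shape[0] != y.shape[0]:
            raise ValueError("X and y row counts differ")
        if X.shape[0] < 2:
            raise ValueError("need at least 2 training rows")
        if not (np.isfinite(X).all() and np.isfinite(y).all()):
            raise ValueError("non-finite values in training data")
        self._scaler = _Scaler().fit(X)
        Xs = self._scaler.transform(X)
        self._n_features = X.shape[1]
        if self.kind == "linear":
            self._est = LinearRegression().fit(Xs, y)
        elif self.kind == "lasso":
            self._est = Lasso(alpha=self.l1, max_iter=50_000, tol=1e-3).fit(Xs, y)
        elif self.kind == "ridge":
            self._est = Ridge(alpha=self.l2).fit(Xs, y)
        else:
            self._fit_ann(Xs, y)
        self.trained = True
        return self

    def _fit_ann(self, Xs: np.ndarray, y: np.ndarray) -> None:
        # full-batch Adam on MSE + l1*|W| + l2*W^2; target standardized
        rng = np.random.default_rng(self.seed)
        d, h = Xs.shape[1], self.hidden_width
        self._y_mean = float(y.mean())
        self._y_sd = float(y.std()) or 1.0
        ys = (y - self._y_mean) / self._y_sd
        params = {
            "W1": rng.normal(0.0, 1.0 / np.sqrt(d), size=(d, h)),
            "b1": np.zeros(h),
            "W2": rng.normal(0.0, 1.0 / np.sqrt(h), size=(h, 1)),
            "b2": np.zeros(1),
        }
        m = {k: np.zeros_like(v) for k, v in params.items()}
        v = {k: np.zeros_like(val) for k, val in params.items()}
        b1a, b2a, eps = 0.9, 0.999, 1e-8
        n = Xs.shape[0]
        for t in range(1, self.epochs + 1):
            # cosine-annealed step size: full-batch Adam at a fixed rate
            # orbits the optimum instead of settling into it
            lr_t = self.learning_rate * 0.5 * (1.0 + np.cos(np.pi * t / self.epochs))
            hid = np.tanh(Xs @ params["W1"] + params["b1"])
            out = (hid @ params["W2"] + params["b2"]).ravel()
            err = out - ys
            g_out = (2.0 / n) * err[:, None]
            grads = {
                "W2": hid.T @ g_out,
                "b2": g_out.sum(axis=0),
            }
            g_hid = (g_out @ params["W2"].T) * (1.0 - hid**2)
            grads["W1"] = Xs.T @ g_hid
            grads["b1"] = g_hid.sum(axis=0)
            for key in ("W1", "W2"):
                grads[key] = grads[key] + 2.0 * self.l2 * params[key]
            for key, g in grads.items():
                m[key] = b1a * m[key] + (1 - b1a) * g
                v[key] = b2a * v[key] + (1 - b2a) * g * g
                mh = m[key] / (1 - b1a**t)
                vh = v[key] / (1 - b2a**t)
                params[key] = params[key] - lr_t * mh / (np.sqrt(vh) + eps)
            if self.l1 > 0:
                # proximal step for the L1 penalty: soft-threshold the
                # weights instead of following its subgradient, which
                # oscillates under adaptive step sizes
                thr = lr_t * self.l1
                for key in ("W1", "W2"):
                    w = params[key]
                    params[key] = np.sign(w) * np.maximum(np.abs(w) - thr, 0.0)
        self._ann_params = params

    # -- prediction ------------------------------------------------------
    def predict(self, X: np.ndarray) -> np.ndarray:
        if not self.trained:
            raise RuntimeError("model is not trained")
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self._n_features:
            raise ValueError(
                f"feature dimension mismatch: trained on {self._n_features}, got {X.shape[1]}"
            )
        Xs = self._scaler.transform(X)
        if self.kind == "ann":
            p = self._ann_params
            hid = np.tanh(Xs @ p["W1"] + p["b1"])
            out = (hid @ p["W2"] + p["b2"]).ravel()
            return out * self._y_sd + self._y_mean
        return self._est.predict(Xs)

    @property
    def coef_(self) -> np.ndarray:
        """Weights of a fitted linear-family layer (not defined for ANN)."""
        if self.kind == "ann":
            raise AttributeError("ANN readout has no single coefficient vector")
        return self._est.coef_


@dataclass
class TrainResult:
    model: ReadoutModel
    train_rmse: float
    test_rmse: float
    n_train: int
    n_test: int

    @property
    def diverged(self) -> bool:
        """True when either RMSE is non-finite (readout instability)."""
        return not (np.isfinite(self.train_rmse) and np.isfinite(self.test_rmse))


def train(
    model: ReadoutModel,
    X: np.ndarray,
    y: np.ndarray,
    split: float = 0.25,
    y_eval: np.ndarray | None = None,
) -> TrainResult:
    """Fit on the first ``split`` fraction of the rows, test on the rest.

    No shuffling — the rows are a time series.  ``y_eval`` (default ``y``)
    is the target used for the error report, so a model trained on a noisy
    target can be scored against the clean one.  ``split = 1`` trains on
    everything and reports the training error twice.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if not 0.0 < split <= 1.0:
        raise ValueError("split must lie in (0, 1]")
    y_eval = y if y_eval is None else np.asarray(y_eval, dtype=float).ravel()
    n = X.shape[0]
    n_train = max(int(round(split * n)), 2)
    model.fit(X[:n_train], y[:n_train])
    with np.errstate(over="ignore", invalid="ignore"):
        pred_train = model.predict(X[:n_train])
        train_err = rmse(y_eval[:n_train], pred_train)
        if n_train < n:
            test_err = rmse(y_eval[n_train:], model.predict(X[n_train:]))
        else:
            test_err = train_err
    return TrainResult(model, train_err, test_err, n_train, n - n_train)


@dataclass
class EnsemblePrediction:
    mean: np.ndarray
    sd: np.ndarray
    predictions: np.ndarray  # (n_trials, n_points)
    train_rmses: np.ndarray


def ensemble_predict(
    model_factory,
    X: np.ndarray,
    y: np.ndarray,
    X_query: np.ndarray | None = None,
    n_trials: int = 20,
    base_seed: int = 0,
    split: float = 1.0,
) -> EnsemblePrediction:
    """Statistical ensemble over independently seeded readouts.

    ``model_factory(seed)`` must return an untrained :class:`ReadoutModel`.
    Each trial trains on the same data with its own seed; the per-point
    mean and standard deviation of the predictions on ``X_query`` (default:
    the training rows) quantify model uncertainty.  Deterministic layers
    give sd = 0.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    X_query = X if X_query is None else X_query
    seeds = np.random.SeedSequence(base_seed).generate_state(n_trials) % (2**31)
    preds, errs = [], []
    for s in seeds:
        res = train(model_factory(int(s)), X, y, split=split)
        preds.append(res.model.predict(X_query))
        errs.append(res.train_rmse)
    preds = np.asarray(preds)
    return EnsemblePrediction(
        mean=preds.mean(axis=0),
        sd=preds.std(axis=0),
        predictions=preds,
        train_rmses=np.asarray(errs),
    )
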