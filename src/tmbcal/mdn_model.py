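"""Mixture-of-log-normals density regression for panel-to-exome TMB calibration.

The regressor is a fully connected network (hidden layers 128/64/32, softplus
activations) mapping the panel-derived input vector to the parameters of a
K-component log-normal mixture over exomic TMB: mixture weights via a
normalized exponential over K logits, log-scale means unconstrained, log-scale
SDs via softplus with a small floor.  Training minimizes the mean negative
log-likelihood

    NLL(y) = -log Σ_k w_k · (1 / (y σ_k √(2π))) · exp(-(ln y - μ_k)² / 2σ_k²)

computed in log-space with a max-shift.  The median of the predictive
distribution is the point estimate; quantiles come from bisection on the
mixture CDF  Σ_k w_k Φ((ln t - μ_k)/σ_k).

Per-Mb count inputs are log1p-transformed before the network and the label is
offset by a small δ (default 0.01) so zero-TMB samples stay inside log-normal
support.  The network, its initialization, batching and optimizer (Adam) are
implemented directly on numpy arrays with analytic gradients; a fixed seed
fully determines initialization and batch order, so training is bit-for-bit
reproducible.

A fixed-variance normal linear baseline (ordinary least squares mean, single
global residual variance) provides the reference model: it is effectively
linear regression under squared loss, re-read as a predictive distribution.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import norm

from .tmb_core import InputConfig, InputVector, ancestry_onehot
from .variant_io import ANCESTRIES

_LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)


# ---------------------------------------------------------------------------
# mixture parameter container and pure mixture math
# ---------------------------------------------------------------------------

@dataclass
class MixtureParams:
    """Weights, log-scale means and log-scale SDs of K log-normal components."""

    weights: np.ndarray
    mu: np.ndarray
    sigma: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.mu = np.asarray(self.mu, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if not (self.weights.shape == self.mu.shape == self.sigma.shape):
            raise ValueError("weights, mu, sigma must share a shape (K,)")
        if abs(self.weights.sum() - 1.0) > 1e-6:
            raise ValueError("mixture weights must sum to 1 within 1e-6")
        if np.any(self.sigma <= 0):
            raise ValueError("all sigma must be positive")

    @property
    def n_components(self) -> int:
        return self.weights.size

    @property
    def mean(self) -> float:
        """Closed-form mixture mean Σ w_k exp(μ_k + σ_k²/2)."""
        return float(np.sum(
            self.weights * np.exp(self.mu + 0.5 * self.sigma ** 2)
        ))


def lognormal_mixture_nll(params: MixtureParams, y: float) -> float:
    """Negative log density of the log-normal mixture at y > 0."""
    if y <= 0:
        raise ValueError(f"y must be positive, got {y}")
    z = np.log(y)
    log_terms = (
        np.log(params.weights)
        - z
        - np.log(params.sigma)
        - _LOG_SQRT_2PI
        - (z - params.mu) ** 2 / (2.0 * params.sigma ** 2)
    )
    return float(-logsumexp(log_terms))


def mixture_pdf(params: MixtureParams, y: float) -> float:
    """Density of the mixture at y (0 for y <= 0)."""
    if y <= 0:
        return 0.0
    return float(np.exp(-lognormal_mixture_nll(params, y)))


def mixture_cdf(params: MixtureParams, t: float) -> float:
    """Σ_k w_k Φ((ln t - μ_k)/σ_k); 0 for t <= 0."""
    if t <= 0:
        return 0.0
    z = np.log(t)
    return float(np.sum(
        params.weights * norm.cdf((z - params.mu) / params.sigma)
    ))


def prob_above(params: MixtureParams, t: float) -> float:
    """P(Y > t) = 1 - CDF(t)."""
    return 1.0 - mixture_cdf(params, t)


def mixture_quantile(params: MixtureParams, q: float) -> float:
    """Quantile by bisection on the mixture CDF (relative tolerance 1e-8).

    The bracket [min_k exp(μ_k - 8σ_k), max_k exp(μ_k + 8σ_k)] contains all
    but ~1e-15 of the mixture mass.  ``quantile(0.5)`` is the model's point
    estimate.
    """
    if not (0.0 < q < 1.0):
        raise ValueError(f"q must be in (0,1), got {q}")
    lo = float(np.exp(np.min(params.mu - 8.0 * params.sigma)))
    hi = float(np.exp(np.max(params.mu + 8.0 * params.sigma)))
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if mixture_cdf(params, mid) < q:
            lo = mid
        else:
            hi = mid
        if hi - lo <= 1e-8 * max(abs(lo), abs(hi), 1e-12):
            break
    return 0.5 * (lo + hi)


# batched variants (arrays of shape (n, K)); used by the model internally ----

def _batch_nll(W: np.ndarray, MU: np.ndarray, SIG: np.ndarray,
               z: np.ndarray) -> np.ndarray:
    """Per-sample NLL of z = ln y under per-sample mixtures; returns (n,)."""
    log_terms = (
        np.log(W)
        - z[:, None]
        - np.log(SIG)
        - _LOG_SQRT_2PI
        - (z[:, None] - MU) ** 2 / (2.0 * SIG ** 2)
    )
    return -logsumexp(log_terms, axis=1)


def _batch_cdf(W: np.ndarray, MU: np.ndarray, SIG: np.ndarray,
               t: np.ndarray) -> np.ndarray:
    """Mixture CDF at per-sample thresholds t (n,); t must be positive."""
    z = np.log(t)
    return np.sum(W * norm.cdf((z[:, None] - MU) / SIG), axis=1)


def _batch_quantile(W: np.ndarray, MU: np.ndarray, SIG: np.ndarray,
                    q: float) -> np.ndarray:
    """Vectorized bisection for the q-quantile of each sample's mixture."""
    lo = np.exp(np.min(MU - 8.0 * SIG, axis=1))
    hi = np.exp(np.max(MU + 8.0 * SIG, axis=1))
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        below = _batch_cdf(W, MU, SIG, mid) < q
        lo = np.where(below, mid, lo)
        hi = np.where(below, hi, mid)
    return 0.5 * (lo + hi)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class ModelConfig:
    """Architecture and parameterization of the mixture density network.

    ``label_offset`` (δ) shifts exomic TMB into log-normal support; quantile
    and exceedance queries on the fitted model undo the shift, so all public
    outputs stay on the TMB scale.
    """

    hidden_sizes: tuple[int, ...] = (128, 64, 32)
    n_components: int = 3
    input_config: InputConfig = field(default_factory=InputConfig)
    label_offset: float = 0.01
    sigma_floor: float = 1e-3


@dataclass
class TrainConfig:
    """Optimizer and reproducibility settings.

    The seed fully determines weight initialization, the train/validation
    split and batch order.
    """

    learning_rate: float = 1e-3
    batch_size: int = 512
    max_epochs: int = 1000
    patience: int = 20
    seed: int = 0
    val_fraction: float = 0.1


def design_matrix(table: pd.DataFrame, config: InputConfig) -> np.ndarray:
    """Assemble the network input from the tidy training table.

    Per-Mb counts are log1p-transformed; ancestry is one-hot appended raw.
    """
    cols = []
    if config.use_nonsyn:
        cols.append(np.log1p(table["nonsyn_per_mb"].to_numpy(dtype=float)))
    if config.use_all:
        cols.append(np.log1p(table["all_per_mb"].to_numpy(dtype=float)))
    if config.use_hotspot:
        cols.append(np.log1p(table["hotspot_per_mb"].to_numpy(dtype=float)))
    X = np.column_stack(cols) if cols else np.zeros((len(table), 0))
    if config.use_ancestry:
        onehot = np.stack([
            ancestry_onehot(a) for a in table["ancestry"].astype(str)
        ])
        X = np.column_stack([X, onehot])
    return X


# ---------------------------------------------------------------------------
# the network
# ---------------------------------------------------------------------------

def _softplus(x: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, x)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -500, 500)))


class MixtureDensityNetwork:
    """Fully connected net emitting log-normal mixture parameters.

    Use :func:`train` to fit from a tidy table, or :meth:`fit` on arrays.
    """

    def __init__(self, n_features: int, model_config: ModelConfig | None = None):
        self.config = model_config or ModelConfig()
        self.n_features = n_features
        self.weights_: list[np.ndarray] | None = None
        self.biases_: list[np.ndarray] | None = None
        self.training_log_: list[dict] | None = None

    # -- plumbing ----------------------------------------------------------

    def _init_params(self, rng: np.random.Generator) -> None:
        sizes = [self.n_features, *self.config.hidden_sizes,
                 3 * self.config.n_components]
        self.weights_ = []
        self.biases_ = []
        for n_in, n_out in zip(sizes[:-1], sizes[1:]):
            bound = np.sqrt(6.0 / (n_in + n_out))  # Glorot uniform
            self.weights_.append(rng.uniform(-bound, bound, size=(n_in, n_out)))
            self.biases_.append(np.zeros(n_out))

    def _forward_raw(self, X: np.ndarray) -> tuple[list[np.ndarray], np.ndarray]:
        """Hidden pre-activations and the raw output layer (B, 3K)."""
        pre: list[np.ndarray] = []
        h = X
        n_hidden = len(self.config.hidden_sizes)
        for i in range(n_hidden):
            a = h @ self.weights_[i] + self.biases_[i]
            pre.append(a)
            h = _softplus(a)
        out = h @ self.weights_[n_hidden] + self.biases_[n_hidden]
        return pre, out

    def _split_output(
        self, out: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        K = self.config.n_components
        logits, MU, s = out[:, :K], out[:, K:2 * K], out[:, 2 * K:]
        logits = logits - logits.max(axis=1, keepdims=True)
        W = np.exp(logits)
        W /= W.sum(axis=1, keepdims=True)
        SIG = _softplus(s) + self.config.sigma_floor
        return W, MU, SIG, s

    def predict_params(
        self, X: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-sample mixture parameter arrays (each of shape (n, K))."""
        if X.ndim != 2 or X.shape[1] != self.n_features:
            raise ValueError(
                f"expected input of shape (n, {self.n_features}), "
                f"got {X.shape}"
            )
        _, out = self._forward_raw(X)
        W, MU, SIG, _ = self._split_output(out)
        return W, MU, SIG

    def forward(self, x: InputVector | np.ndarray) -> MixtureParams:
        """Mixture parameters for a single input vector."""
        arr = x.to_array() if isinstance(x, InputVector) else np.asarray(x, float)
        if isinstance(x, InputVector):
            arr = np.concatenate([
                np.log1p(arr[: arr.size - (len(ANCESTRIES) if x.config.use_ancestry else 0)]),
                arr[arr.size - (len(ANCESTRIES) if x.config.use_ancestry else 0):],
            ])
        W, MU, SIG = self.predict_params(arr[None, :])
        return MixtureParams(weights=W[0], mu=MU[0], sigma=SIG[0])

    # -- training ----------------------------------------------------------

    def fit(
        self,
        X: np.ndarray,
        y: np.ndarray,
        train_config: TrainConfig | None = None,
    ) -> "MixtureDensityNetwork":
        """Minimize mean mixture NLL of ln(y + δ) by minibatch Adam with
        early stopping on validation NLL."""
        tc = train_config or TrainConfig()
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        shifted = y + self.config.label_offset
        if not np.all(shifted > 0):
            raise ValueError("labels must satisfy y + label_offset > 0")
        z = np.log(shifted)

        rng = np.random.default_rng(tc.seed)
        self._init_params(rng)

        n = X.shape[0]
        perm = rng.permutation(n)
        n_val = max(1, int(round(tc.val_fraction * n)))
        val_idx, tr_idx = perm[:n_val], perm[n_val:]
        Xtr, ztr = X[tr_idx], z[tr_idx]
        Xval, zval = X[val_idx], z[val_idx]

        params = self.weights_ + self.biases_
        m = [np.zeros_like(p) for p in params]
        v = [np.zeros_like(p) for p in params]
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        step = 0

        best_val = np.inf
        best_state = None
        since_best = 0
        self.training_log_ = []

        n_tr = Xtr.shape[0]
        batch = min(tc.batch_size, n_tr)
        for epoch in range(tc.max_epochs):
            order = rng.permutation(n_tr)
            for b_start in range(0, n_tr, batch):
                idx = order[b_start:b_start + batch]
                grads, loss = self._backward(Xtr[idx], ztr[idx])
                if not np.isfinite(loss):
                    raise RuntimeError(
                        f"non-finite training loss at epoch {epoch}, batch "
                        f"starting at {b_start} (batch size {idx.size})"
                    )
                step += 1
                for i, g in enumerate(grads):
                    m[i] = beta1 * m[i] + (1 - beta1) * g
                    v[i] = beta2 * v[i] + (1 - beta2) * g * g
                    mhat = m[i] / (1 - beta1 ** step)
                    vhat = v[i] / (1 - beta2 ** step)
                    params[i] -= tc.learning_rate * mhat / (np.sqrt(vhat) + eps)

            train_nll = float(np.mean(self._nll_z(Xtr, ztr)))
            val_nll = float(np.mean(self._nll_z(Xval, zval)))
            self.training_log_.append(
                {"epoch": epoch, "train_nll": train_nll, "val_nll": val_nll}
            )
            if val_nll < best_val - 1e-7:
                best_val = val_nll
                best_state = ([w.copy() for w in self.weights_],
                              [b.copy() for b in self.biases_])
                since_best = 0
            else:
                since_best += 1
                if since_best >= tc.patience:
                    break

        if best_state is not None:
            self.weights_, self.biases_ = best_state
        return self

    def _nll_z(self, X: np.ndarray, z: np.ndarray) -> np.ndarray:
        _, out = self._forward_raw(X)
        W, MU, SIG, _ = self._split_output(out)
        return _batch_nll(W, MU, SIG, z)

    def _backward(
        self, X: np.ndarray, z: np.ndarray
    ) -> tuple[list[np.ndarray], float]:
        """Analytic gradient of the mean mixture NLL wrt all parameters."""
        n_hidden = len(self.config.hidden_sizes)
        pre, out = self._forward_raw(X)
        hs = [X]
        for a in pre:
            hs.append(_softplus(a))
        W, MU, SIG, s_raw = self._split_output(out)

        B = X.shape[0]
        zc = z[:, None]
        log_terms = (
            np.log(W) - zc - np.log(SIG) - _LOG_SQRT_2PI
            - (zc - MU) ** 2 / (2.0 * SIG ** 2)
        )
        lse = logsumexp(log_terms, axis=1, keepdims=True)
        loss = float(np.mean(-lse))
        R = np.exp(log_terms - lse)  # responsibilities, rows sum to 1

        # gradients of the per-sample NLL wrt (logits, mu, raw sigma)
        d_logits = (W - R) / B
        d_mu = -R * (zc - MU) / SIG ** 2 / B
        d_sig = -R * ((zc - MU) ** 2 / SIG ** 3 - 1.0 / SIG) / B
        d_s = d_sig * _sigmoid(s_raw)  # softplus' = sigmoid
        d_out = np.concatenate([d_logits, d_mu, d_s], axis=1)

        gW = [np.zeros_like(w) for w in self.weights_]
        gB = [np.zeros_like(b) for b in self.biases_]
        delta = d_out
        gW[n_hidden] = hs[n_hidden].T @ delta
        gB[n_hidden] = delta.sum(axis=0)
        for i in range(n_hidden - 1, -1, -1):
            delta = (delta @ self.weights_[i + 1].T) * _sigmoid(pre[i])
            gW[i] = hs[i].T @ delta
            gB[i] = delta.sum(axis=0)
        return gW + gB, loss

    # -- prediction on the TMB scale --------------------------------------

    def predict_median(self, X: np.ndarray) -> np.ndarray:
        """Median of the predictive distribution — the point estimate."""
        return self.predict_quantile(X, 0.5)

    def predict_quantile(self, X: np.ndarray, q: float) -> np.ndarray:
        if not (0.0 < q < 1.0):
            raise ValueError(f"q must be in (0,1), got {q}")
        W, MU, SIG = self.predict_params(X)
        raw = _batch_quantile(W, MU, SIG, q)
        return np.maximum(raw - self.config.label_offset, 0.0)

    def predict_prob_above(self, X: np.ndarray, t: float) -> np.ndarray:
        """P(exomic TMB > t) per sample."""
        W, MU, SIG = self.predict_params(X)
        tt = np.full(X.shape[0], t + self.config.label_offset)
        return 1.0 - _batch_cdf(W, MU, SIG, tt)

    def predict_mean(self, X: np.ndarray) -> np.ndarray:
        W, MU, SIG = self.predict_params(X)
        return np.sum(W * np.exp(MU + 0.5 * SIG ** 2), axis=1) \
            - self.config.label_offset

    def nll(self, X: np.ndarray, y: np.ndarray) -> float:
        """Mean NLL of labels under the fitted predictive distributions."""
        z = np.log(np.asarray(y, float) + self.config.label_offset)
        return float(np.mean(self._nll_z(np.asarray(X, float), z)))

    def pit(self, X: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Probability integral transform CDF_i(y_i) of the labels."""
        W, MU, SIG = self.predict_params(X)
        yy = np.asarray(y, float) + self.config.label_offset
        return _batch_cdf(W, MU, SIG, yy)

    # -- persistence -------------------------------------------------------

    def save(self, path_prefix: str) -> None:
        """Write a JSON header (config + training log) and an .npz of weights."""
        header = {
            "n_features": self.n_features,
            "model_config": {
                **asdict(self.config),
                "input_config": asdict(self.config.input_config),
            },
            "training_log": self.training_log_,
        }
        with open(path_prefix + ".json", "w") as fh:
            json.dump(header, fh, indent=2)
        arrays = {f"W{i}": w for i, w in enumerate(self.weights_)}
        arrays.update({f"b{i}": b for i, b in enumerate(self.biases_)})
        np.savez(path_prefix + ".npz", **arrays)

    @classmethod
    def load(cls, path_prefix: str) -> "MixtureDensityNetwork":
        with open(path_prefix + ".json") as fh:
            header = json.load(fh)
        mc = dict(header["model_config"])
        mc["hidden_sizes"] = tuple(mc["hidden_sizes"])
        mc["input_config"] = InputConfig(**mc["input_config"])
        model = cls(header["n_features"], ModelConfig(**mc))
        data = np.load(path_prefix + ".npz")
        n_layers = len(model.config.hidden_sizes) + 1
        model.weights_ = [data[f"W{i}"] for i in range(n_layers)]
        model.biases_ = [data[f"b{i}"] for i in range(n_layers)]
        model.training_log_ = header["training_log"]
        return model


def train(
    table: pd.DataFrame,
    model_config: ModelConfig | None = None,
    train_config: TrainConfig | None = None,
) -> MixtureDensityNetwork:
    """Fit a mixture density network from the tidy training table.

    The 98th-percentile input cap is applied upstream
    (:func:`tmbcal.tmb_core.cap_training_set`); this function takes the table
    as given.
    """
    model_config = model_config or ModelConfig()
    X = design_matrix(table, model_config.input_config)
    y = table["exomic_tmb"].to_numpy(dtype=float)
    model = MixtureDensityNetwork(X.shape[1], model_config)
    return model.fit(X, y, train_config)


# ---------------------------------------------------------------------------
# fixed-variance normal linear baseline
# ---------------------------------------------------------------------------

class LinearBaseline:
    """OLS mean with a single global residual variance.

    Minimizing the NLL of a fixed-variance normal linear in X is equivalent
    to linear regression under squared loss; the residual MSE supplies the
    (homoscedastic) predictive variance, so the baseline's exceedance
    probabilities and quantiles come from Normal(mean(x), MSE).
    """

    def __init__(self) -> None:
        self.coef_: np.ndarray | None = None
        self.sigma_: float | None = None

    def fit(self, X: np.ndarray, y: np.ndarray) -> "LinearBaseline":
        X = np.asarray(X, float)
        y = np.asarray(y, float)
        A = np.column_stack([np.ones(X.shape[0]), X])
        rank = np.linalg.matrix_rank(A)
        if rank < A.shape[1]:
            raise ValueError(
                f"rank-deficient design: rank {rank} < {A.shape[1]} columns"
            )
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        self.coef_ = coef
        resid = y - A @ coef
        self.sigma_ = float(np.sqrt(np.mean(resid ** 2)))
        return self

    def predict_mean(self, X: np.ndarray) -> np.ndarray:
        A = np.column_stack([np.ones(np.asarray(X).shape[0]), X])
        return A @ self.coef_

    # the normal is symmetric: median == mean
    predict_median = predict_mean

    def predict_quantile(self, X: np.ndarray, q: float) -> np.ndarray:
        if not (0.0 < q < 1.0):
            raise ValueError(f"q must be in (0,1), got {q}")
        return self.predict_mean(X) + self.sigma_ * norm.ppf(q)

    def predict_prob_above(self, X: np.ndarray, t: float) -> np.ndarray:
        sd = max(self.sigma_, 1e-12)
        return 1.0 - norm.cdf((t - self.predict_mean(X)) / sd)

    def nll(self, X: np.ndarray, y: np.ndarray) -> float:
        sd = max(self.sigma_, 1e-12)
        resid = np.asarray(y, float) - self.predict_mean(X)
        return float(np.mean(
            0.5 * np.log(2 * np.pi) + np.log(sd) + resid ** 2 / (2 * sd ** 2)
        ))

    def pit(self, X: np.ndarray, y: np.ndarray) -> np.ndarray:
        sd = max(self.sigma_, 1e-12)
        return norm.cdf((np.asarray(y, float) - self.predict_mean(X)) / sd)


def linear_baseline_fit(
    table: pd.DataFrame, input_config: InputConfig | None = None
) -> LinearBaseline:
    """Fit the fixed-variance normal baseline from the tidy training table."""
    input_config = input_config or InputConfig()
    X = design_matrix(table, input_config)
    y = table["exomic_tmb"].to_numpy(dtype=float)
    return LinearBaseline().fit(X, y)
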