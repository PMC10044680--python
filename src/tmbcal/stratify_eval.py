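"""Cross-validated evaluation and uncertainty-aware stratification.

Point-estimate quality is summarized by mean absolute error and Spearman rank
correlation over samples whose panel-derived input is at least 5 mutations/Mb
(low-input samples dominate cohorts and would swamp the metrics).  Threshold
utility is summarized by detection rates (how often true exomic TMB exceeds
the threshold within each panel-TMB group) and by a confidence-gated
tripartite stratification: a sample is *confident-above* a threshold t when
the predictive distribution puts at least the confidence level (default 95%)
of its mass above t, *confident-below* symmetrically, and *indeterminate*
otherwise.  PPV is scored over the confident-above stratum and NPV over the
confident-below stratum only.

Distribution calibration is checked by empirical coverage of central
predictive intervals and by the probability integral transform (PIT), which
is uniform for a perfectly specified model.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .mdn_model import (
    MixtureDensityNetwork,
    ModelConfig,
    TrainConfig,
    _batch_cdf,
    _batch_quantile,
    design_matrix,
)

DEFAULT_COVERAGE_LEVELS = (0.50, 0.80, 0.90, 0.95)


@dataclass
class StratumAssignment:
    """Tripartite call for one sample at a TMB threshold."""

    sample_id: str
    threshold: float
    p_above: float
    stratum: str  # confident_above | confident_below | indeterminate
    confidence_level: float = 0.95


@dataclass
class StratificationReport:
    """Counts and predictive values of the tripartite stratification."""

    n_confident_above: int
    n_confident_below: int
    n_indeterminate: int
    ppv: float | None
    npv: float | None

    @property
    def n_total(self) -> int:
        return (self.n_confident_above + self.n_confident_below
                + self.n_indeterminate)

    @property
    def confident_fraction(self) -> float:
        if self.n_total == 0:
            return 0.0
        return 1.0 - self.n_indeterminate / self.n_total

    def as_dict(self) -> dict:
        return {
            "n_confident_above": self.n_confident_above,
            "n_confident_below": self.n_confident_below,
            "n_indeterminate": self.n_indeterminate,
            "ppv": self.ppv,
            "npv": self.npv,
            "confident_fraction": self.confident_fraction,
        }


def mae_spearman(
    pred_median: Sequence[float],
    truth: Sequence[float],
    panel_input: Sequence[float],
    min_input: float = 5.0,
) -> tuple[float, float]:
    """MAE and Spearman rho over samples with panel input >= ``min_input``."""
    pred = np.asarray(pred_median, float)
    y = np.asarray(truth, float)
    x = np.asarray(panel_input, float)
    if not (pred.size == y.size == x.size):
        raise ValueError("input vectors must have equal length")
    mask = x >= min_input
    if not mask.any():
        raise ValueError(
            f"no samples with panel input >= {min_input}; metrics undefined"
        )
    mae = float(np.mean(np.abs(pred[mask] - y[mask])))
    rho = float(stats.spearmanr(pred[mask], y[mask]).statistic)
    return mae, rho


def kfold_predict(
    table: pd.DataFrame,
    model_config: ModelConfig | None = None,
    train_config: TrainConfig | None = None,
    k: int = 5,
) -> dict:
    """Out-of-fold mixture parameters for every sample of the table.

    Folds come from a seeded uniform shuffle (no stratification); each sample
    is predicted exactly once, by the model trained without its fold.
    Returns arrays aligned to the table rows: weights/mu/sigma of shape
    (n, K), the fold index and the fitted per-fold models.
    """
    model_config = model_config or ModelConfig()
    train_config = train_config or TrainConfig()
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    n = len(table)
    rng = np.random.default_rng(train_config.seed)
    fold = np.empty(n, dtype=int)
    perm = rng.permutation(n)
    for i, idx in enumerate(np.array_split(perm, k)):
        if idx.size < 2 * model_config.n_components:
            raise ValueError(
                f"fold {i} has {idx.size} samples, fewer than "
                f"2*K={2 * model_config.n_components}"
            )
        fold[idx] = i

    X = design_matrix(table, model_config.input_config)
    y = table["exomic_tmb"].to_numpy(dtype=float)
    K = model_config.n_components
    W = np.empty((n, K))
    MU = np.empty((n, K))
    SIG = np.empty((n, K))
    models = []
    for i in range(k):
        test = fold == i
        model = MixtureDensityNetwork(X.shape[1], model_config)
        model.fit(X[~test], y[~test], train_config)
        w, mu, sig = model.predict_params(X[test])
        W[test], MU[test], SIG[test] = w, mu, sig
        models.append(model)
    return {
        "weights": W, "mu": MU, "sigma": SIG, "fold": fold,
        "models": models, "label_offset": model_config.label_offset,
    }


def detection_rates(
    panel_tmb: Sequence[float], truth: Sequence[float], t: float
) -> dict:
    """Fraction with true exomic TMB > t within each panel-TMB group.

    Groups are {panel > t} and {panel <= t}; an empty group reports n=0 and a
    null rate.
    """
    x = np.asarray(panel_tmb, float)
    y = np.asarray(truth, float)
    if x.size != y.size:
        raise ValueError("input vectors must have equal length")
    above = x > t
    out = {}
    for label, mask in (("panel_above", above), ("panel_below", ~above)):
        n = int(mask.sum())
        rate = float(np.mean(y[mask] > t)) if n else None
        out[label] = {"n": n, "rate_true_above": rate}
    return out


def tripartite(
    p_above: Sequence[float],
    sample_ids: Sequence[str] | None = None,
    t: float = 10.0,
    confidence: float = 0.95,
) -> list[StratumAssignment]:
    """Confidence-gated tripartite stratification at threshold t."""
    if not (0.5 < confidence < 1.0):
        raise ValueError(f"confidence must be in (0.5, 1), got {confidence}")
    p = np.asarray(p_above, float)
    ids = (list(sample_ids) if sample_ids is not None
           else [str(i) for i in range(p.size)])
    out = []
    for sid, pa in zip(ids, p):
        if pa >= confidence:
            stratum = "confident_above"
        elif (1.0 - pa) >= confidence:
            stratum = "confident_below"
        else:
            stratum = "indeterminate"
        out.append(StratumAssignment(
            sample_id=sid, threshold=t, p_above=float(pa),
            stratum=stratum, confidence_level=confidence,
        ))
    return out


def stratification_report(
    assignments: Sequence[StratumAssignment],
    truth: Sequence[float],
    t: float,
) -> StratificationReport:
    """PPV over confident-above, NPV over confident-below.

    PPV: fraction of confident-above samples whose true exomic TMB exceeds t.
    NPV: fraction of confident-below samples with true exomic TMB <= t.
    An empty confident stratum reports a null metric with count 0.
    """
    y = np.asarray(truth, float)
    if len(assignments) != y.size:
        raise ValueError("assignments and truth must have equal length")
    strata = np.array([a.stratum for a in assignments])
    above = strata == "confident_above"
    below = strata == "confident_below"
    ppv = float(np.mean(y[above] > t)) if above.any() else None
    npv = float(np.mean(y[below] <= t)) if below.any() else None
    return StratificationReport(
        n_confident_above=int(above.sum()),
        n_confident_below=int(below.sum()),
        n_indeterminate=int((~above & ~below).sum()),
        ppv=ppv,
        npv=npv,
    )


def calibration_diagnostics(
    weights: np.ndarray,
    mu: np.ndarray,
    sigma: np.ndarray,
    truth: Sequence[float],
    label_offset: float = 0.0,
    levels: Sequence[float] = DEFAULT_COVERAGE_LEVELS,
) -> dict:
    """Coverage of central predictive intervals and PIT uniformity.

    ``weights/mu/sigma`` are per-sample mixture parameter arrays (n, K), e.g.
    out-of-fold output of :func:`kfold_predict`.  For each nominal level c the
    empirical coverage is the fraction of samples whose true value falls in
    the central c-interval, computed via the PIT: truth is inside iff
    |PIT - 1/2| <= c/2.  PIT uniformity is scored with a one-sample
    Kolmogorov-Smirnov statistic.
    """
    y = np.asarray(truth, float) + label_offset
    pit = _batch_cdf(weights, mu, sigma, y)
    coverage = {
        float(c): float(np.mean(np.abs(pit - 0.5) <= c / 2.0))
        for c in levels
    }
    ks = stats.kstest(pit, "uniform")
    return {
        "coverage": coverage,
        "pit": pit,
        "ks_statistic": float(ks.statistic),
        "ks_pvalue": float(ks.pvalue),
    }


def predictive_intervals(
    weights: np.ndarray,
    mu: np.ndarray,
    sigma: np.ndarray,
    level: float = 0.90,
    label_offset: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Central predictive interval bounds on the TMB scale."""
    alpha = (1.0 - level) / 2.0
    lo = _batch_quantile(weights, mu, sigma, alpha) - label_offset
    hi = _batch_quantile(weights, mu, sigma, 1.0 - alpha) - label_offset
    return np.maximum(lo, 0.0), np.maximum(hi, 0.0)
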