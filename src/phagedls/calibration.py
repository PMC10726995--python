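"""Calibration of lytic-titer loss against the AUC-delta divergence.

Two model families link spectral drift to bioactivity:

* a **linear calibration** (ordinary least squares of titer loss, in log10
  PFU/mL, on AUC-delta) with Pearson correlation inference and standard
  regression prediction intervals, used to predict the titer loss of a new
  sample from its spectrum alone;
* **threshold logistic classifiers** P(titer loss > L | AUC-delta) for a
  ladder of loss thresholds L (0.5 ... 3 log10), summarized by the percent
  change in odds per AUC-delta unit with a Wald 95% CI, Tjur's pseudo-R2,
  and the ROC-AUC computed from the rank (Mann-Whitney) statistic.

A Wald-Wolfowitz runs test on the residual signs checks for departure from
linearity (exact null distribution for n <= 30, normal approximation above).

Sign convention: ``titer_loss_log10`` is positive for a loss (the magnitude
of the log10 PFU/mL decrease), so a damaged sample has large AUC-delta and
large positive loss and the fitted slope is positive.
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit
from sklearn.metrics import roc_curve as _sk_roc_curve

__all__ = [
    "PairedObservation",
    "LinearCalibration",
    "PredictionResult",
    "RunsTestResult",
    "ThresholdClassifier",
    "ThresholdSweepEntry",
    "DEFAULT_THRESHOLDS",
    "fit_linear",
    "predict_titer_loss",
    "runs_test_linearity",
    "runs_test_pvalue",
    "fit_logistic",
    "threshold_sweep",
    "roc_curve",
    "tjur_r2",
    "rank_roc_auc",
    "read_pairs_csv",
    "write_pairs_csv",
    "model_to_dict",
    "model_from_dict",
    "save_model",
    "load_model",
]

#: Titer-loss thresholds (log10 PFU/mL) used for the logistic ladder.
DEFAULT_THRESHOLDS = (0.5, 1.0, 1.5, 2.0, 2.5, 3.0)

_SEPARATION_BETA = 50.0  # |beta1| beyond this flags quasi-complete separation
_IRLS_TOL = 1e-10
_IRLS_MAXITER = 100

MODEL_SCHEMA_VERSION = 1


@dataclasses.dataclass(frozen=True)
class PairedObservation:
    """One (AUC-delta, titer loss) pair from matched DLS and plaque assays."""

    auc_delta: float
    titer_loss_log10: float
    phage_id: str = ""
    condition: str = ""
    #: True when the plaque assay bottomed out at its detection limit
    #: ("complete titer loss"); the recorded loss is then baseline - limit.
    censored: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.auc_delta <= 200.0):
            raise ValueError(f"auc_delta must lie in [0, 200], got {self.auc_delta}")
        if not math.isfinite(self.titer_loss_log10):
            raise ValueError("titer_loss_log10 must be finite")


def _xy(
    pairs: Sequence[PairedObservation], include_censored: bool = True
) -> tuple[np.ndarray, np.ndarray]:
    used = [p for p in pairs if include_censored or not p.censored]
    x = np.array([p.auc_delta for p in used], dtype=float)
    y = np.array([p.titer_loss_log10 for p in used], dtype=float)
    return x, y


# ---------------------------------------------------------------------------
# Linear calibration
# ---------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class LinearCalibration:
    """OLS fit of titer loss on AUC-delta, with the design summaries needed
    for prediction intervals (residual SD on n-2 df, predictor mean and
    centered sum of squares, training range)."""

    slope: float
    intercept: float
    r: float
    p_value: float
    n: int
    residual_sd: float
    x_mean: float
    sxx: float
    x_min: float
    x_max: float

    @property
    def r_squared(self) -> float:
        return self.r * self.r

    def predict_point(self, x: float) -> float:
        return self.slope * x + self.intercept

    def residuals(self, pairs: Sequence[PairedObservation]) -> np.ndarray:
        x, y = _xy(pairs)
        return y - (self.slope * x + self.intercept)

    def summary(self) -> str:
        return (
            f"Linear calibration: loss = {self.slope:.6g} * AUCdelta + {self.intercept:.6g}\n"
            f"  n = {self.n}, r = {self.r:.4f}, r^2 = {self.r_squared:.4f}, "
            f"p (two-tailed Pearson) = {self.p_value:.3g}\n"
            f"  residual SD = {self.residual_sd:.4g} log10 PFU/mL, "
            f"AUCdelta training range = [{self.x_min:.3g}, {self.x_max:.3g}]"
        )


def fit_linear(
    pairs: Sequence[PairedObservation], include_censored: bool = True
) -> LinearCalibration:
    """Ordinary least squares of titer loss on AUC-delta.

    Reports the Pearson correlation and its two-tailed t-test p-value, and
    the residual SD on n-2 degrees of freedom.  Censored (detection-limit)
    pairs are included by default; set ``include_censored=False`` to drop
    them.
    """
    x, y = _xy(pairs, include_censored)
    n = x.size
    if n < 3:
        raise ValueError(f"need at least 3 pairs to fit, got {n}")
    if np.ptp(x) == 0:
        raise ValueError("no variation in predictor: all auc_delta values identical")
    res = stats.linregress(x, y)
    resid = y - (res.slope * x + res.intercept)
    residual_sd = float(np.sqrt(np.sum(resid**2) / (n - 2)))
    return LinearCalibration(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r=float(res.rvalue),
        p_value=float(res.pvalue),
        n=int(n),
        residual_sd=residual_sd,
        x_mean=float(x.mean()),
        sxx=float(np.sum((x - x.mean()) ** 2)),
        x_min=float(x.min()),
        x_max=float(x.max()),
    )


@dataclasses.dataclass(frozen=True)
class PredictionResult:
    """Point prediction of titer loss with its prediction interval."""

    predicted_loss_log10: float
    interval_log10: tuple[float, float]
    level: float
    model_ref: str = "linear"
    #: True when the queried AUC-delta lies outside the fitted range;
    #: predictions from poorly sampled regions may be less accurate.
    extrapolated: bool = False

    def __post_init__(self) -> None:
        lo, hi = self.interval_log10
        if not (lo <= self.predicted_loss_log10 <= hi):
            raise ValueError("prediction interval must contain the point prediction")


def predict_titer_loss(
    model: LinearCalibration, new_auc_delta: float, level: float = 0.95
) -> PredictionResult:
    """Predict titer loss for a new AUC-delta with a regression prediction interval.

    The interval is the standard OLS prediction interval for a single new
    observation, half-width t_{1-(1-level)/2, n-2} * s * sqrt(1 + 1/n +
    (x - x_bar)^2 / Sxx).  Queries outside the fitted AUC-delta range are
    flagged as extrapolated.
    """
    if not (0.0 <= new_auc_delta <= 200.0):
        raise ValueError("new_auc_delta must lie in [0, 200]")
    if not (0.0 < level < 1.0):
        raise ValueError("level must lie in (0, 1)")
    pred = model.predict_point(new_auc_delta)
    se = model.residual_sd * math.sqrt(
        1.0 + 1.0 / model.n + (new_auc_delta - model.x_mean) ** 2 / model.sxx
    )
    tcrit = float(stats.t.ppf(0.5 + level / 2.0, model.n - 2))
    half = tcrit * se
    return PredictionResult(
        predicted_loss_log10=pred,
        interval_log10=(pred - half, pred + half),
        level=level,
        model_ref="linear",
        extrapolated=not (model.x_min <= new_auc_delta <= model.x_max),
    )


# ---------------------------------------------------------------------------
# Runs test for departure from linearity
# ---------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class RunsTestResult:
    p_value: float
    n_runs: int
    n_positive: int
    n_negative: int
    note: str = ""


def _runs_pmf(n1: int, n2: int) -> dict[int, float]:
    """Exact null distribution of the number of runs in a binary sequence
    with n1 symbols of one kind and n2 of the other (all arrangements
    equally likely)."""
    total = math.comb(n1 + n2, n1)
    pmf: dict[int, float] = {}
    for r in range(2, n1 + n2 + 1):
        if r % 2 == 0:
            k = r // 2
            ways = 2 * math.comb(n1 - 1, k - 1) * math.comb(n2 - 1, k - 1)
        else:
            k = (r - 1) // 2
            ways = math.comb(n1 - 1, k - 1) * math.comb(n2 - 1, k) + math.comb(
                n1 - 1, k
            ) * math.comb(n2 - 1, k - 1)
        if ways:
            pmf[r] = ways / total
    return pmf


def runs_test_pvalue(signs: Sequence[int]) -> RunsTestResult:
    """Two-sided Wald-Wolfowitz runs test on a sequence of +/-1 signs.

    Exact null distribution for n <= 30; normal approximation (no
    continuity correction) above.  With only one sign present there is no
    alternation to test and p = 1 is returned.
    """
    s = np.asarray(signs, dtype=int)
    if s.size == 0:
        return RunsTestResult(1.0, 0, 0, 0, note="no nonzero residuals")
    n1 = int(np.sum(s > 0))
    n2 = int(np.sum(s < 0))
    runs = int(1 + np.sum(s[1:] != s[:-1]))
    if n1 == 0 or n2 == 0:
        return RunsTestResult(1.0, runs, n1, n2, note="all residuals share one sign")
    n = n1 + n2
    if n <= 30:
        pmf = _runs_pmf(n1, n2)
        lo = sum(p for r, p in pmf.items() if r <= runs)
        hi = sum(p for r, p in pmf.items() if r >= runs)
        p = min(1.0, 2.0 * min(lo, hi))
    else:
        mu = 1.0 + 2.0 * n1 * n2 / n
        var = 2.0 * n1 * n2 * (2.0 * n1 * n2 - n) / (n**2 * (n - 1.0))
        z = (runs - mu) / math.sqrt(var)
        p = float(2.0 * stats.norm.sf(abs(z)))
    return RunsTestResult(float(p), runs, n1, n2)


def runs_test_linearity(
    model: LinearCalibration, pairs: Sequence[PairedObservation]
) -> RunsTestResult:
    """Runs test on the signs of residuals ordered by AUC-delta.

    A nonsignificant result is consistent with a linear AUC-delta /
    titer-loss relation; clustering of same-sign residuals along the
    predictor (few runs) indicates curvature.  Zero residuals are dropped.
    """
    x, _ = _xy(pairs)
    if x.size < 4:
        raise ValueError("runs test needs at least 4 pairs")
    resid = model.residuals(pairs)
    order = np.argsort(x, kind="stable")
    resid = resid[order]
    scale = max(1.0, float(np.max(np.abs(resid))) if resid.size else 1.0)
    keep = np.abs(resid) > 1e-12 * scale
    if not keep.any():
        return RunsTestResult(1.0, 0, 0, 0, note="all residuals zero (exact fit)")
    return runs_test_pvalue(np.sign(resid[keep]).astype(int))


# ---------------------------------------------------------------------------
# Threshold logistic classifiers
# ---------------------------------------------------------------------------


def tjur_r2(y: Sequence[int], probabilities: Sequence[float]) -> float:
    """Tjur's coefficient of discrimination: mean fitted probability among
    positives minus mean among negatives."""
    y = np.asarray(y, dtype=int)
    p = np.asarray(probabilities, dtype=float)
    if not (np.any(y == 1) and np.any(y == 0)):
        raise ValueError("Tjur R2 needs both outcome classes")
    return float(p[y == 1].mean() - p[y == 0].mean())


def rank_roc_auc(y: Sequence[int], scores: Sequence[float]) -> float:
    """ROC-AUC via the Mann-Whitney rank statistic (ties get half credit)."""
    y = np.asarray(y, dtype=int)
    s = np.asarray(scores, dtype=float)
    n1 = int(np.sum(y == 1))
    n0 = int(np.sum(y == 0))
    if n1 == 0 or n0 == 0:
        raise ValueError("ROC-AUC needs both outcome classes")
    ranks = stats.rankdata(s)
    u = float(ranks[y == 1].sum()) - n1 * (n1 + 1) / 2.0
    return u / (n1 * n0)


def _logistic_irls(
    x: np.ndarray, y: np.ndarray
) -> tuple[np.ndarray, np.ndarray, bool, bool]:
    """Single-predictor logistic MLE by iteratively reweighted least squares.

    Returns (beta, covariance, converged, separated).  Separation is
    detected as a diverging slope (|beta1| > 50 on the AUC-delta scale) or
    a vanishing deviance (the fit reproduces the labels exactly, so the
    MLE diverges in the limit) rather than raising, so callers can return
    a flagged result.
    """
    X = np.column_stack([np.ones_like(x), x])
    ybar = min(max(y.mean(), 1e-6), 1 - 1e-6)
    beta = np.array([math.log(ybar / (1 - ybar)), 0.0])
    dev = dev_old = np.inf
    converged = separated = False
    xtwx = np.eye(2)
    for _ in range(_IRLS_MAXITER):
        eta = X @ beta
        p = expit(eta)
        w = np.clip(p * (1 - p), 1e-12, None)
        z = eta + (y - p) / w
        xtwx = X.T @ (w[:, None] * X)
        beta = np.linalg.solve(xtwx, X.T @ (w * z))
        if abs(beta[1]) > _SEPARATION_BETA:
            separated = True
            break
        p = np.clip(expit(X @ beta), 1e-300, 1 - 1e-16)
        dev = -2.0 * float(np.sum(y * np.log(p) + (1 - y) * np.log1p(-p)))
        if abs(dev - dev_old) < _IRLS_TOL:
            converged = True
            break
        dev_old = dev
    if dev < 1e-6:
        separated = True
    cov = np.linalg.inv(xtwx)
    return beta, cov, converged, separated


@dataclasses.dataclass(frozen=True)
class ThresholdClassifier:
    """Logistic model P(titer loss > threshold | AUC-delta).

    ``or_pct_per_unit`` is the percent increase in the odds of exceeding
    the threshold per 1-unit increase in AUC-delta, 100*(exp(beta1)-1),
    with a Wald 95% CI on the same scale.
    """

    threshold_log10: float
    beta0: float
    beta1: float
    or_pct_per_unit: float
    or_ci95: tuple[float, float]
    p_value: float
    tjur_r2: float
    roc_auc: float
    n: int
    separation_flag: bool = False

    def __post_init__(self) -> None:
        lo, hi = self.or_ci95
        if not (lo <= self.or_pct_per_unit <= hi):
            raise ValueError("odds-ratio CI must bracket the point estimate")

    def predict_probability(self, auc_delta: float | np.ndarray) -> np.ndarray:
        return expit(self.beta0 + self.beta1 * np.asarray(auc_delta, dtype=float))

    def summary(self) -> str:
        flag = "  [WARNING: separated data; slope diverges]" if self.separation_flag else ""
        return (
            f"Logistic classifier, loss > {self.threshold_log10:g} log10:{flag}\n"
            f"  odds change per AUCdelta unit = {self.or_pct_per_unit:.3g}% "
            f"(95% CI {self.or_ci95[0]:.3g}% to {self.or_ci95[1]:.3g}%), "
            f"Wald p = {self.p_value:.3g}\n"
            f"  Tjur R2 = {self.tjur_r2:.3f}, ROC-AUC = {self.roc_auc:.3f}, n = {self.n}"
        )


def fit_logistic(
    pairs: Sequence[PairedObservation], threshold_log10: float
) -> ThresholdClassifier:
    """Fit P(titer loss > threshold | AUC-delta) by maximum likelihood.

    The outcome is 1 iff the loss strictly exceeds the threshold; censored
    (detection-limit) pairs are included since their outcome class is
    unambiguous.  Perfectly separated data yield a flagged result (the
    slope estimate stops at the divergence guard) instead of an error.
    """
    x, loss = _xy(pairs)
    y = (loss > threshold_log10).astype(float)
    if y.sum() == 0 or y.sum() == y.size:
        raise ValueError(
            f"degenerate outcome: all losses on one side of threshold {threshold_log10:g}"
        )
    beta, cov, _converged, separated = _logistic_irls(x, y)
    se1 = float(np.sqrt(cov[1, 1]))
    zcrit = float(stats.norm.ppf(0.975))

    def _pct(v: float) -> float:
        # exp overflows for huge Wald bounds near separation; report +inf
        return 100.0 * (math.exp(v) - 1.0) if v < 700.0 else math.inf

    or_pct = _pct(beta[1])
    ci = (_pct(beta[1] - zcrit * se1), _pct(beta[1] + zcrit * se1))
    p_wald = float(2.0 * stats.norm.sf(abs(beta[1]) / se1)) if se1 > 0 else 0.0
    probs = expit(beta[0] + beta[1] * x)
    return ThresholdClassifier(
        threshold_log10=float(threshold_log10),
        beta0=float(beta[0]),
        beta1=float(beta[1]),
        or_pct_per_unit=or_pct,
        or_ci95=ci,
        p_value=p_wald,
        tjur_r2=tjur_r2(y.astype(int), probs),
        roc_auc=rank_roc_auc(y.astype(int), probs),
        n=int(x.size),
        separation_flag=separated,
    )


@dataclasses.dataclass(frozen=True)
class ThresholdSweepEntry:
    threshold_log10: float
    classifier: ThresholdClassifier | None
    skipped_reason: str | None = None


def threshold_sweep(
    pairs: Sequence[PairedObservation],
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
) -> list[ThresholdSweepEntry]:
    """Fit the logistic ladder over a list of loss thresholds.

    Thresholds for which one outcome class is empty are reported as
    skipped rather than raising.
    """
    if len(thresholds) == 0:
        raise ValueError("empty threshold list")
    entries = []
    for thr in thresholds:
        try:
            clf = fit_logistic(pairs, thr)
        except ValueError as exc:
            entries.append(ThresholdSweepEntry(float(thr), None, str(exc)))
        else:
            entries.append(ThresholdSweepEntry(float(thr), clf))
    return entries


def roc_curve(
    classifier: ThresholdClassifier, pairs: Sequence[PairedObservation]
) -> list[tuple[float, float]]:
    """ROC points (FPR, TPR) of a fitted classifier on a paired dataset.

    Points are ordered by decreasing probability cutoff with tied scores
    grouped; the trapezoidal area under the returned polyline equals the
    classifier's rank-statistic ROC-AUC.
    """
    x, loss = _xy(pairs)
    y = (loss > classifier.threshold_log10).astype(int)
    if y.sum() == 0 or y.sum() == y.size:
        raise ValueError("ROC needs both outcome classes")
    scores = classifier.predict_probability(x)
    fpr, tpr, _ = _sk_roc_curve(y, scores, drop_intermediate=False)
    return list(zip(fpr.tolist(), tpr.tolist()))


# ---------------------------------------------------------------------------
# Pairs CSV and model serialization
# ---------------------------------------------------------------------------

_PAIRS_COLUMNS = ("phage_id", "condition", "auc_delta", "titer_loss_log10", "censored")


def read_pairs_csv(path: str | Path) -> list[PairedObservation]:
    """Read paired (AUC-delta, titer loss) observations from long-format CSV."""
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in ("auc_delta", "titer_loss_log10") if c not in df.columns]
    if missing:
        raise ValueError(f"pairs CSV missing required columns {missing}")
    def _text(row, col):
        val = row.get(col, "")
        return "" if pd.isna(val) else str(val)

    def _flag(row):
        val = row.get("censored", False)
        if isinstance(val, str):
            return val.strip().lower() in ("true", "1", "yes")
        return bool(val) and not pd.isna(val)

    pairs = []
    for _, row in df.iterrows():
        pairs.append(
            PairedObservation(
                auc_delta=float(row["auc_delta"]),
                titer_loss_log10=float(row["titer_loss_log10"]),
                phage_id=_text(row, "phage_id"),
                condition=_text(row, "condition"),
                censored=_flag(row),
            )
        )
    if not pairs:
        raise ValueError("empty pairs CSV")
    return pairs


def write_pairs_csv(pairs: Sequence[PairedObservation], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "phage_id": p.phage_id,
                "condition": p.condition,
                "auc_delta": p.auc_delta,
                "titer_loss_log10": p.titer_loss_log10,
                "censored": p.censored,
            }
            for p in pairs
        ],
        columns=list(_PAIRS_COLUMNS),
    ).to_csv(path, index=False, float_format="%.17g")


def model_to_dict(model: LinearCalibration | ThresholdClassifier) -> dict:
    d = dataclasses.asdict(model)
    if isinstance(model, LinearCalibration):
        d["model_type"] = "linear"
    elif isinstance(model, ThresholdClassifier):
        d["model_type"] = "logistic"
        d["or_ci95"] = list(model.or_ci95)
    else:  # pragma: no cover - guarded by type hints
        raise TypeError(type(model))
    d["schema_version"] = MODEL_SCHEMA_VERSION
    return d


def model_from_dict(d: dict) -> LinearCalibration | ThresholdClassifier:
    d = dict(d)
    version = d.pop("schema_version", None)
    if version != MODEL_SCHEMA_VERSION:
        raise ValueError(f"unsupported model schema version {version!r}")
    kind = d.pop("model_type", None)
    if kind == "linear":
        return LinearCalibration(**d)
    if kind == "logistic":
        d["or_ci95"] = tuple(d["or_ci95"])
        return ThresholdClassifier(**d)
    raise ValueError(f"unknown model_type {kind!r}")


def save_model(model: LinearCalibration | ThresholdClassifier, path: str | Path) -> None:
    Path(path).write_text(json.dumps(model_to_dict(model), indent=2))


def load_model(path: str | Path) -> LinearCalibration | ThresholdClassifier:
    return model_from_dict(json.loads(Path(path).read_text()))
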