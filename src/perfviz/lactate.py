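"""Exponential lactate-prediction models and supporting statistics.

Local capillary lactate (LCL, mmol/L) rises as tissue perfusion falls. After
subtracting systemic lactatemia, the residual local excess is modeled as an
exponential function of a perfusion metric x (tissue oxygen saturation in
percent, or the fluorescence time-to-peak slope):

    predicted LCL = exp(-a*x + b) + systemic lactate

with a > 0 for the physiologically decreasing relationship. The module fits
(a, b) by least squares, cross-validates by leaving one subject (all of its
ROIs) out at a time, summarizes held-out absolute errors, compares two
models with a paired Wilcoxon signed-rank test, and provides the Fisher-z
sample-size formula for correlation studies.
"""
from __future__ import annotations

from dataclasses import dataclass
from math import ceil, log, sqrt

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import DimensionError, FitError, ParameterError

__all__ = [
    "ExponentialModel",
    "ErrorSummary",
    "normalize_lcl",
    "fit_exponential",
    "predict_lcl",
    "loo_cv",
    "error_summary",
    "compare_models_wilcoxon",
    "spearman_correlation",
    "sample_size_correlation",
]

#: Published model for StO2 (percent) as the predictor.
STO2_MODEL_COEFFS = (0.0343, 2.72)
#: Published model for the fluorescence slope as the predictor.
FLER_MODEL_COEFFS = (0.403, 2.32)

COHORT_COLUMNS = [
    "subject_id",
    "roi_label",
    "sto2_pct",
    "fler_slope",
    "lcl_mmol_l",
    "systemic_lactate_mmol_l",
]

_PREDICTOR_COLUMN = {"sto2": "sto2_pct", "fler_slope": "fler_slope"}


@dataclass(frozen=True)
class ExponentialModel:
    """Coefficients of ``exp(-a*x + b)`` for one predictor.

    ``a`` is stored positive for a decreasing lactate-vs-perfusion
    relationship; ``b`` is the log-scale intercept.
    """

    a: float
    b: float
    predictor: str = "sto2"

    def __post_init__(self) -> None:
        if not (np.isfinite(self.a) and np.isfinite(self.b)):
            raise ParameterError("model coefficients must be finite")
        if self.predictor not in _PREDICTOR_COLUMN:
            raise ParameterError(f"unknown predictor {self.predictor!r}")

    def local_excess(self, x) -> np.ndarray:
        """exp(-a*x + b): predicted normalized (local-minus-systemic) LCL."""
        return np.exp(-self.a * np.asarray(x, dtype=float) + self.b)


@dataclass(frozen=True)
class ErrorSummary:
    """Summary of absolute prediction errors (all in mmol/L)."""

    mean: float
    sd: float
    median: float
    q95_threshold: float  # observed-LCL level below which 95% of errors fall


def normalize_lcl(lcl, systemic) -> np.ndarray:
    """Local-minus-systemic lactate, elementwise; may be <= 0 and is kept so."""
    lcl = np.asarray(lcl, dtype=float)
    systemic = np.asarray(systemic, dtype=float)
    if lcl.size == 0:
        raise ParameterError("no records to normalize")
    return lcl - systemic


def predict_lcl(model: ExponentialModel, x, systemic) -> np.ndarray:
    """Predicted LCL = exp(-a*x + b) + systemic; strictly > systemic."""
    systemic = np.asarray(systemic, dtype=float)
    if np.any(systemic < 0):
        raise ParameterError("systemic lactate must be >= 0")
    return model.local_excess(x) + systemic


def _log_linear_init(x: np.ndarray, y: np.ndarray, floor: float = 1e-3):
    # log-linear fit on floored y seeds the raw-scale optimizer
    ly = np.log(np.maximum(y, floor))
    slope, intercept = np.polyfit(x, ly, 1)
    return -slope, intercept


def fit_exponential(x, y, predictor: str = "sto2", scale: str = "linear",
                    max_restarts: int = 5) -> ExponentialModel:
    """Least-squares fit of y ~ exp(-a*x + b).

    Parameters
    ----------
    x, y : array-like
        Predictor values and normalized LCL (mmol/L). Non-positive y values
        are legal: the objective exp(-a*x+b) is positive, so raw-scale least
        squares stays well defined; they are only excluded (floored) from the
        log-linear initialization.
    scale : {"linear", "log"}
        Minimize squared residuals on the raw scale (default) or on
        log(y) after flooring y at 1e-3.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise DimensionError("x and y lengths differ")
    if x.size < 3:
        raise ParameterError("need at least 3 points")
    if np.ptp(x) == 0:
        raise ParameterError("x values are all equal")
    if scale not in ("linear", "log"):
        raise ParameterError("scale must be 'linear' or 'log'")

    a0, b0 = _log_linear_init(x, y)
    if scale == "log":
        return ExponentialModel(a=float(a0), b=float(b0), predictor=predictor)

    def residuals(p):
        return np.exp(-p[0] * x + p[1]) - y

    rng = np.random.default_rng(0)
    p0 = np.array([a0, b0])
    last_msg = ""
    for attempt in range(max_restarts):
        try:
            sol = optimize.least_squares(residuals, p0, method="lm", max_nfev=10_000)
        except Exception as exc:  # noqa: BLE001 - converted to FitError below
            last_msg = str(exc)
            sol = None
        if sol is not None and sol.success and np.all(np.isfinite(sol.x)):
            return ExponentialModel(a=float(sol.x[0]), b=float(sol.x[1]),
                                    predictor=predictor)
        if sol is not None:
            last_msg = sol.message
        p0 = np.array([a0, b0]) * (1 + 0.3 * rng.standard_normal(2))
    raise FitError("exponential fit did not converge",
                   {"message": last_msg, "n": int(x.size), "init": (a0, b0)})


def loo_cv(records: pd.DataFrame, predictor: str = "sto2",
           scale: str = "linear") -> pd.DataFrame:
    """Leave-one-subject-out cross-validation of the exponential model.

    All ROIs of a subject are held out together; the model is refit on the
    remaining subjects' normalized LCL and used to predict the held-out
    records. Returns one row per record with the held-out absolute error.
    """
    col = _PREDICTOR_COLUMN.get(predictor)
    if col is None:
        raise ParameterError(f"unknown predictor {predictor!r}")
    subjects = sorted(records["subject_id"].unique())
    if len(subjects) < 3:
        raise ParameterError("need at least 3 subjects for cross-validation")

    rows = []
    for subject in subjects:
        held = records[records["subject_id"] == subject]
        train = records[records["subject_id"] != subject]
        y_train = normalize_lcl(train["lcl_mmol_l"], train["systemic_lactate_mmol_l"])
        try:
            model = fit_exponential(train[col], y_train, predictor=predictor,
                                    scale=scale)
        except FitError as exc:
            raise FitError(f"fold holding out subject {subject!r} failed",
                           exc.diagnostics) from exc
        pred = predict_lcl(model, held[col], held["systemic_lactate_mmol_l"])
        for (_, rec), p in zip(held.iterrows(), pred):
            rows.append({
                "subject_id": subject,
                "roi_label": rec["roi_label"],
                "observed_lcl": rec["lcl_mmol_l"],
                "predicted_lcl": p,
                "abs_error": abs(rec["lcl_mmol_l"] - p),
            })
    return pd.DataFrame(rows)


def error_summary(errors, lcls) -> ErrorSummary:
    """Mean/SD/median of absolute errors plus the 95% LCL threshold.

    ``q95_threshold`` is the 95th percentile (linear interpolation) of the
    observed LCL values carrying the errors: the LCL level below which 95%
    of the prediction errors occur.
    """
    errors = np.asarray(errors, dtype=float)
    lcls = np.asarray(lcls, dtype=float)
    if errors.size == 0:
        raise ParameterError("no errors to summarize")
    if errors.shape != lcls.shape:
        raise DimensionError("errors and lcls lengths differ")
    sd = float(np.std(errors, ddof=1)) if errors.size > 1 else 0.0
    return ErrorSummary(
        mean=float(np.mean(errors)),
        sd=sd,
        median=float(np.median(errors)),
        q95_threshold=float(np.percentile(lcls, 95)),
    )


def _signed_rank_statistic(diff: np.ndarray):
    """Drop zero differences, rank |d| with average ranks, return (W+, ranks)."""
    diff = diff[diff != 0]
    ranks = stats.rankdata(np.abs(diff))
    w_plus = float(ranks[diff > 0].sum())
    return w_plus, ranks


def _exact_signed_rank_cdf(ranks: np.ndarray) -> np.ndarray:
    """Exact null pmf of W+ over 2^n sign assignments, via convolution.

    Average ranks are half-integers at worst; doubling makes every rank an
    integer so the pmf lives on an integer grid of 2*W+.
    """
    scaled = np.rint(2 * ranks).astype(int)
    pmf = np.ones(1)
    for r in scaled:
        new = np.zeros(len(pmf) + r)
        new[: len(pmf)] += pmf
        new[r:] += pmf
        pmf = new
    return pmf / pmf.sum()


def compare_models_wilcoxon(errors_a, errors_b):
    """Paired Wilcoxon signed-rank test between two models' absolute errors.

    Zero differences are dropped. The null distribution is exact (full
    enumeration over sign assignments, computed by convolution) for n <= 25
    non-zero pairs; beyond that a normal approximation with tie correction
    is used. Returns ``(w_plus, p_value)``; if every difference is zero the
    result is degenerate with p = 1.
    """
    a = np.asarray(errors_a, dtype=float)
    b = np.asarray(errors_b, dtype=float)
    if a.shape != b.shape:
        raise DimensionError("paired error vectors differ in length")
    if a.size < 5:
        raise ParameterError("need at least 5 pairs")
    diff = a - b
    nz = diff[diff != 0]
    if nz.size == 0:
        return 0.0, 1.0
    w_plus, ranks = _signed_rank_statistic(diff)
    n = ranks.size
    if n <= 25:
        pmf = _exact_signed_rank_cdf(ranks)
        grid = np.arange(len(pmf)) / 2.0
        p_low = pmf[grid <= w_plus + 1e-9].sum()
        p_high = pmf[grid >= w_plus - 1e-9].sum()
        p = min(1.0, 2 * min(p_low, p_high))
        return w_plus, float(p)
    mean = n * (n + 1) / 4
    _, counts = np.unique(ranks, return_counts=True)
    tie_term = (counts**3 - counts).sum() / 48
    var = n * (n + 1) * (2 * n + 1) / 24 - tie_term
    z = (w_plus - mean) / sqrt(var)
    p = 2 * stats.norm.sf(abs(z))
    return w_plus, float(min(1.0, p))


def spearman_correlation(x, y):
    """Spearman rank correlation with average ranks; two-sided t-approx p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise DimensionError("x and y lengths differ")
    if x.size < 4:
        raise ParameterError("need at least 4 observations")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ParameterError("non-finite values")
    if np.ptp(stats.rankdata(x)) == 0 or np.ptp(stats.rankdata(y)) == 0:
        raise ParameterError("zero variance in ranks: correlation undefined")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def sample_size_correlation(r: float, alpha: float = 0.05,
                            power: float = 0.90) -> int:
    """Required number of pairs to detect correlation magnitude r.

    Fisher-z method: n = ceil(((z_{1-alpha/2} + z_power) / C)^2 + 3) with
    C = 0.5*ln((1+r)/(1-r)). Monotone decreasing in r, increasing in power.
    """
    r = abs(float(r))
    if not 0 < r < 1:
        raise ParameterError("r must satisfy 0 < |r| < 1")
    if not 0 < alpha < 1 or not 0 < power < 1:
        raise ParameterError("alpha and power must lie in (0, 1)")
    z_a = stats.norm.ppf(1 - alpha / 2)
    z_b = stats.norm.ppf(power)
    c = 0.5 * log((1 + r) / (1 - r))
    return int(ceil(((z_a + z_b) / c) ** 2 + 3))
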