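"""Multivariate inline-OD600 calibration (the soft sensor).

The model regresses offline OD600 reference measurements on probe-derived
predictors (inverse smoothed transmission, smoothed reflection, antifoam
%vol, and a transmission-reflection interaction). Fitting follows the
classical recipe for this kind of process-analytical calibration:

* z-score the predictors (so coefficients and their magnitudes are
  comparable across channels with wildly different units),
* solve ordinary least squares, or ridge with an unpenalized intercept,
  in closed form from the (penalized) normal equations,
* hold out a random test split and report RMSE / R^2 / residual mean and SD
  on it.

The residual mean +/- SD doubles as the model's practical prediction
interval: for an offline reading ``y`` the inline sensor is expected to
read within ``y + residual_mean +/- residual_sd``.

Organisation follows the familiar Model/Results pattern:
``InlineODModel(data).fit(...)`` returns an :class:`InlineODResults` that
carries the fitted :class:`ODModelSpec`, standard errors where defined,
train/test/pooled metrics and a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.linalg

from .exceptions import InvalidInputError, SchemaError, SingularDesignError
from .signals import FEATURE_NAMES

MODEL_SCHEMA_VERSION = 1

__all__ = [
    "ModelMetrics",
    "ODModelSpec",
    "InlineODModel",
    "InlineODResults",
    "split_train_test",
    "regression_metrics",
    "feature_importance",
    "predict_od",
    "prediction_interval",
    "interval_width",
    "percent_deviation",
]


# ---------------------------------------------------------------------------
# domain types


@dataclass
class ModelMetrics:
    """Goodness-of-fit summary for one evaluation split.

    rmse, residual_mean and residual_sd are in OD600 units; residuals are
    ``predicted - observed`` and residual_sd uses the unbiased (n-1)
    denominator. ``importance`` maps feature name to a non-negative weight
    summing to 1 (absolute standardized coefficient, normalized).
    """

    rmse: float
    r2: float
    residual_mean: float
    residual_sd: float
    importance: dict[str, float] | None = None

    def __post_init__(self):
        if self.rmse < 0:
            raise InvalidInputError("rmse must be >= 0")
        if self.r2 > 1 + 1e-12:
            raise InvalidInputError("r2 cannot exceed 1")
        if self.importance is not None:
            total = sum(self.importance.values())
            if abs(total - 1.0) > 1e-9 or any(w < 0 for w in self.importance.values()):
                raise InvalidInputError("importance weights must be >= 0 and sum to 1")


@dataclass
class ODModelSpec:
    """A fitted, portable calibration: everything needed to predict.

    Coefficients are on the standardized (z-score) feature scale;
    ``feature_means``/``feature_sds`` are the training-split standardization
    constants. ``ridge_lambda = 0`` means ordinary least squares. The stored
    ``metrics`` are computed on the held-out test split.
    """

    feature_names: tuple[str, ...]
    coefficients: np.ndarray
    intercept: float
    ridge_lambda: float
    feature_means: np.ndarray
    feature_sds: np.ndarray
    metrics: ModelMetrics | None = None
    schema_version: int = MODEL_SCHEMA_VERSION

    def __post_init__(self):
        self.feature_names = tuple(self.feature_names)
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        self.feature_means = np.asarray(self.feature_means, dtype=float)
        self.feature_sds = np.asarray(self.feature_sds, dtype=float)
        p = len(self.feature_names)
        if not (self.coefficients.shape == self.feature_means.shape
                == self.feature_sds.shape == (p,)):
            raise InvalidInputError("feature_names/coefficients/means/sds lengths differ")
        if self.ridge_lambda < 0:
            raise InvalidInputError("ridge_lambda must be >= 0")
        if np.any(self.feature_sds <= 0):
            raise InvalidInputError("feature_sds must be > 0")

    # dict round-trip used by the JSON persistence layer
    def to_dict(self) -> dict:
        return {
            "schema_version": self.schema_version,
            "feature_names": list(self.feature_names),
            "coefficients": [float(c) for c in self.coefficients],
            "intercept": float(self.intercept),
            "ridge_lambda": float(self.ridge_lambda),
            "feature_means": [float(m) for m in self.feature_means],
            "feature_sds": [float(s) for s in self.feature_sds],
            "metrics": None if self.metrics is None else {
                "rmse": self.metrics.rmse,
                "r2": self.metrics.r2,
                "residual_mean": self.metrics.residual_mean,
                "residual_sd": self.metrics.residual_sd,
                "importance": self.metrics.importance,
            },
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ODModelSpec":
        metrics = d.get("metrics")
        return cls(
            feature_names=tuple(d["feature_names"]),
            coefficients=np.array(d["coefficients"], dtype=float),
            intercept=float(d["intercept"]),
            ridge_lambda=float(d["ridge_lambda"]),
            feature_means=np.array(d["feature_means"], dtype=float),
            feature_sds=np.array(d["feature_sds"], dtype=float),
            metrics=None if metrics is None else ModelMetrics(**metrics),
            schema_version=int(d.get("schema_version", MODEL_SCHEMA_VERSION)),
        )


# ---------------------------------------------------------------------------
# free functions (evaluation arithmetic and helpers)


def split_train_test(data: pd.DataFrame, train_frac: float = 0.8, seed: int = 0):
    """Uniform random train/test partition, reproducible under ``seed``.

    Train size is ``floor(train_frac * n)``; the two frames are disjoint and
    exhaustive.
    """
    if not 0 < train_frac < 1:
        raise InvalidInputError("train_frac must be in (0, 1)")
    n = len(data)
    if n < 5:
        raise InvalidInputError("too few samples to split (need >= 5)")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_train = int(np.floor(train_frac * n))
    return data.iloc[perm[:n_train]], data.iloc[perm[n_train:]]


def regression_metrics(predicted, observed) -> ModelMetrics:
    """RMSE, R^2 and residual mean/SD for paired predictions.

    Residuals are ``predicted - observed``; ``r2 = 1 - SSE/SST``;
    residual_sd uses the n-1 denominator.
    """
    p = np.asarray(predicted, dtype=float)
    o = np.asarray(observed, dtype=float)
    if p.shape != o.shape or p.ndim != 1 or p.size < 2:
        raise InvalidInputError("predicted/observed must be equal-length 1-d, n >= 2")
    resid = p - o
    sst = float(np.sum((o - o.mean()) ** 2))
    if sst == 0.0:
        raise InvalidInputError("observed values have zero variance; r2 undefined")
    sse = float(np.sum(resid**2))
    return ModelMetrics(
        rmse=float(np.sqrt(np.mean(resid**2))),
        r2=1.0 - sse / sst,
        residual_mean=float(resid.mean()),
        residual_sd=float(resid.std(ddof=1)),
    )


def feature_importance(spec: "ODModelSpec | np.ndarray",
                       feature_names: Sequence[str] | None = None) -> dict[str, float]:
    """Normalized absolute standardized coefficients (sum to 1)."""
    if isinstance(spec, ODModelSpec):
        coefs, names = spec.coefficients, spec.feature_names
    else:
        coefs = np.asarray(spec, dtype=float)
        names = tuple(feature_names) if feature_names is not None else tuple(
            f"x{i}" for i in range(coefs.size))
    absc = np.abs(coefs)
    total = absc.sum()
    if total == 0:
        # all-zero model: spread the weight evenly
        w = np.full(absc.size, 1.0 / absc.size)
    else:
        w = absc / total
    return {n: float(x) for n, x in zip(names, w)}


def predict_od(spec: ODModelSpec, features) -> float | np.ndarray:
    """Apply a fitted calibration to one or many feature vectors.

    ``features`` may be a mapping, a pandas Series/DataFrame, or a 1-d/2-d
    array already in model feature order. The standardized dot product plus
    intercept is clamped below at 0 — an equilibrating, uninoculated
    fermenter reads inline OD exactly zero rather than slightly negative.
    """
    if isinstance(features, Mapping):
        try:
            x = np.array([features[n] for n in spec.feature_names], dtype=float)
        except KeyError as e:
            raise SchemaError(f"feature vector missing {e.args[0]!r}") from e
    elif isinstance(features, pd.Series):
        return predict_od(spec, features.to_dict())
    elif isinstance(features, pd.DataFrame):
        missing = [n for n in spec.feature_names if n not in features.columns]
        if missing:
            raise SchemaError(f"feature frame missing columns {missing}")
        x = features.loc[:, list(spec.feature_names)].to_numpy(dtype=float)
    else:
        x = np.asarray(features, dtype=float)
        if x.shape[-1] != len(spec.feature_names):
            raise SchemaError(
                f"expected {len(spec.feature_names)} features, got {x.shape[-1]}")
    z = (x - spec.feature_means) / spec.feature_sds
    y = z @ spec.coefficients + spec.intercept
    y = np.maximum(y, 0.0)
    return float(y) if np.ndim(y) == 0 else y


def prediction_interval(offline_od: float, residual_mean: float,
                        residual_sd: float) -> tuple[float, float]:
    """Expected inline-OD band for a given offline reading.

    Center is ``offline_od + residual_mean``; the band is one residual SD
    either side of the center.
    """
    if residual_sd < 0:
        raise InvalidInputError("residual_sd must be >= 0")
    center = offline_od + residual_mean
    return center - residual_sd, center + residual_sd


def interval_width(lower: float, upper: float) -> float:
    """Width of an interval in OD600 units."""
    if upper < lower:
        raise InvalidInputError("upper must be >= lower")
    return upper - lower


def percent_deviation(measurements) -> float:
    """Pooled coefficient of variation of repeated OD600 measurements, in %.

    ``measurements`` is either a flat sequence of readings or a DataFrame
    with an ``od600`` column (e.g. operator x sample tables); the statistic
    is 100 * sample SD (n-1) / grand mean over all readings. This is the
    operator-variability floor against which the inline model's accuracy is
    judged.
    """
    if isinstance(measurements, pd.DataFrame):
        if "od600" not in measurements.columns:
            raise SchemaError("measurement table must have an 'od600' column")
        vals = measurements["od600"].to_numpy(dtype=float)
    else:
        vals = np.asarray(measurements, dtype=float).ravel()
    if vals.size < 2:
        raise InvalidInputError("need at least 2 measurements")
    mean = vals.mean()
    if mean <= 0:
        raise InvalidInputError("grand mean must be > 0")
    return float(100.0 * vals.std(ddof=1) / mean)


# ---------------------------------------------------------------------------
# model / results


class InlineODModel:
    """Calibration model for the inline-OD soft sensor.

    Parameters
    ----------
    data : pandas.DataFrame
        One row per offline reference point, holding the predictor columns
        (default: the four canonical features) and the target column
        ``offline_od`` (OD600, >= 0). Extra columns (run_id, probe_id,
        time_h, ...) ride along untouched.
    feature_names : sequence of str, optional
        Predictors to use, in order.
    target : str
        Target column name.
    """

    def __init__(self, data: pd.DataFrame, feature_names: Sequence[str] = FEATURE_NAMES,
                 target: str = "offline_od"):
        self.feature_names = tuple(feature_names)
        self.target = target
        missing = [c for c in (*self.feature_names, target) if c not in data.columns]
        if missing:
            raise SchemaError(f"calibration data missing columns {missing}")
        sub = data.loc[:, [*self.feature_names, target]]
        if sub.isna().any().any():
            raise InvalidInputError("calibration data contains missing values")
        if (data[target] < 0).any():
            raise InvalidInputError("offline OD must be >= 0")
        self.data = data.reset_index(drop=True)

    # -- fitting ---------------------------------------------------------

    def fit(self, method: str = "olsr", ridge_lambda: float | None = None,
            train_frac: float = 0.8, seed: int = 0) -> "InlineODResults":
        """Split, standardize, solve, and evaluate.

        ``method`` is ``"olsr"`` (ordinary least squares; ``ridge_lambda``
        forced to 0) or ``"ridge"`` (L2 penalty ``ridge_lambda`` on the
        standardized coefficients, intercept unpenalized; default penalty
        1.0). Metrics are computed on train, held-out test, and pooled data;
        the test metrics are stored in the portable spec.
        """
        method = method.lower()
        if method not in ("olsr", "ridge"):
            raise InvalidInputError(f"unknown method {method!r}")
        if method == "olsr":
            lam = 0.0
        else:
            lam = 1.0 if ridge_lambda is None else float(ridge_lambda)
            if lam < 0:
                raise InvalidInputError("ridge_lambda must be >= 0")

        train, test = split_train_test(self.data, train_frac=train_frac, seed=seed)
        p = len(self.feature_names)
        if len(train) <= p + 1:
            raise InvalidInputError("need more training rows than features + 1")

        X = train.loc[:, list(self.feature_names)].to_numpy(dtype=float)
        y = train[self.target].to_numpy(dtype=float)
        mu = X.mean(axis=0)
        sd = X.std(axis=0, ddof=1)
        zero_var = [n for n, s in zip(self.feature_names, sd) if s <= 0]
        if zero_var:
            raise SingularDesignError(zero_var)
        Z = (X - mu) / sd

        if lam == 0.0:
            self._check_rank(Z)
        # Z is column-centered, so the intercept decouples and equals the
        # training mean of y. The (penalized) normal equations are solved
        # via (augmented) least squares: identical solution, but without
        # squaring the condition number of the near-collinear channels.
        yc = y - y.mean()
        if lam == 0.0:
            beta, *_ = np.linalg.lstsq(Z, yc, rcond=None)
        else:
            A = np.vstack([Z, np.sqrt(lam) * np.eye(p)])
            b = np.concatenate([yc, np.zeros(p)])
            beta, *_ = np.linalg.lstsq(A, b, rcond=None)
        intercept = float(y.mean())

        spec = ODModelSpec(
            feature_names=self.feature_names,
            coefficients=beta,
            intercept=intercept,
            ridge_lambda=lam,
            feature_means=mu,
            feature_sds=sd,
        )
        importance = feature_importance(spec)

        def _metrics(frame):
            pred = predict_od(spec, frame.loc[:, list(self.feature_names)])
            m = regression_metrics(pred, frame[self.target].to_numpy(dtype=float))
            m.importance = importance
            return m

        metrics_train = _metrics(train)
        metrics_test = _metrics(test)
        metrics_pooled = _metrics(self.data)
        spec.metrics = metrics_test

        bse = None
        if lam == 0.0:
            resid = Z @ beta + intercept - y
            dof = len(train) - p - 1
            if dof > 0:
                sigma2 = float(resid @ resid) / dof
                bse = np.sqrt(np.diag(sigma2 * np.linalg.inv(Z.T @ Z)))

        return InlineODResults(
            model=self, spec=spec, method=method,
            train_index=train.index.to_numpy(), test_index=test.index.to_numpy(),
            metrics_train=metrics_train, metrics_test=metrics_test,
            metrics_pooled=metrics_pooled, bse=bse, seed=seed,
        )

    def _check_rank(self, Z: np.ndarray) -> None:
        # pivoted QR: diagonal decay of R identifies which columns are
        # linear combinations of the earlier (pivoted) ones
        _, R, piv = scipy.linalg.qr(Z, mode="economic", pivoting=True)
        diag = np.abs(np.diag(R))
        tol = diag.max() * max(Z.shape) * np.finfo(float).eps if diag.size else 0.0
        rank = int(np.sum(diag > tol))
        if rank < Z.shape[1]:
            bad = [self.feature_names[i] for i in piv[rank:]]
            raise SingularDesignError(bad)


@dataclass
class InlineODResults:
    """Fitted calibration with its uncertainties and diagnostics.

    ``spec`` is the portable artifact (save with
    :func:`fermsense.io.write_model`); ``bse`` holds classical OLS standard
    errors of the standardized coefficients (None for ridge fits).
    """

    model: InlineODModel
    spec: ODModelSpec
    method: str
    train_index: np.ndarray
    test_index: np.ndarray
    metrics_train: ModelMetrics
    metrics_test: ModelMetrics
    metrics_pooled: ModelMetrics
    bse: np.ndarray | None = None
    seed: int = 0

    @property
    def params(self) -> pd.Series:
        """Standardized coefficients, indexed by feature name."""
        return pd.Series(self.spec.coefficients, index=list(self.spec.feature_names))

    @property
    def intercept(self) -> float:
        return self.spec.intercept

    @property
    def importance(self) -> dict[str, float]:
        return feature_importance(self.spec)

    def predict(self, features):
        """Inline OD600 for new feature vectors (clamped below at 0)."""
        return predict_od(self.spec, features)

    def prediction_interval(self, offline_od: float) -> tuple[float, float]:
        """Expected inline-OD band for an offline reading, from the
        held-out residual mean and SD of this fit."""
        m = self.metrics_test
        return prediction_interval(offline_od, m.residual_mean, m.residual_sd)

    def save(self, path) -> None:
        from . import io  # local import: io depends on this module

        io.write_model(self.spec, path)

    def summary(self) -> str:
        """Plain-text summary table in the spirit of statsmodels."""
        m_tr, m_te, m_po = self.metrics_train, self.metrics_test, self.metrics_pooled
        lines = [
            "Inline OD600 calibration results",
            "=" * 64,
            f"method: {self.method.upper():<10} ridge lambda: {self.spec.ridge_lambda:g}",
            f"n train: {len(self.train_index):<8} n test: {len(self.test_index):<8} "
            f"split seed: {self.seed}",
            f"intercept (OD600): {self.spec.intercept:.4f}",
            "-" * 64,
            f"{'feature':<16}{'coef(std)':>12}{'std err':>12}{'importance':>12}",
        ]
        imp = self.importance
        for i, name in enumerate(self.spec.feature_names):
            se = f"{self.bse[i]:.4f}" if self.bse is not None else "--"
            lines.append(
                f"{name:<16}{self.spec.coefficients[i]:>12.4f}{se:>12}"
                f"{imp[name]:>12.3f}"
            )
        lines += [
            "-" * 64,
            f"{'split':<10}{'RMSE':>10}{'R2':>10}{'resid mean':>12}{'resid SD':>12}",
        ]
        for label, m in (("train", m_tr), ("test", m_te), ("pooled", m_po)):
            lines.append(
                f"{label:<10}{m.rmse:>10.3f}{m.r2:>10.4f}"
                f"{m.residual_mean:>12.3f}{m.residual_sd:>12.3f}"
            )
        lines.append("=" * 64)
        return "\n".join(lines)
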