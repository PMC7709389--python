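"""PLS1 calibration engine.

Single-response partial least squares (Wold's PLS1, NIPALS algorithm, mean
centering only, no per-variable scaling), with:

* leave-one-out cross-validation (LOOCV) over the number of latent variables,
* RMSE_CV-minimizing latent-variable selection,
* DFFITS influence diagnostics in score space for outlier removal,
* the full training pipeline that chains these steps, and
* versioned JSON model serialization.

The LOOCV fast path fits one NIPALS decomposition per left-out sample and
reads off predictions for every component count from that single nested
model; because NIPALS components are nested by construction this is exactly
equivalent to refitting at each component count (a property the test suite
asserts against a brute-force oracle).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ANALYTES",
    "TrainingSet",
    "PlsModel",
    "CrossValCurve",
    "DffitsDiagnostics",
    "DegenerateModelError",
    "TrainingError",
    "fit_pls1",
    "predict",
    "rmse_cv",
    "loocv_curve",
    "select_latent_variables",
    "dffits_diagnostics",
    "default_dffits_threshold",
    "train_calibration",
    "model_to_json",
    "model_from_json",
]

logger = logging.getLogger(__name__)

ANALYTES = ("TC", "TG", "HDLC", "APOB")

_MODEL_FORMAT_VERSION = 1
_EPS = 1e-12


class DegenerateModelError(ValueError):
    """Raised when the response has no variance or the data admit no model."""


class TrainingError(RuntimeError):
    """Raised when the calibration pipeline cannot complete."""


@dataclass
class TrainingSet:
    """Paired spectra (rows of X) and reference concentrations y (mg/dL)."""

    X: np.ndarray
    y: np.ndarray
    analyte: str
    sample_ids: list[str] | None = None

    def __post_init__(self) -> None:
        X = np.asarray(self.X, dtype=float)
        y = np.asarray(self.y, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (n_samples x n_variables)")
        if y.shape != (X.shape[0],):
            raise ValueError("y length must match the number of rows of X")
        if X.shape[0] < 3:
            raise ValueError("need at least 3 training samples")
        if not np.all(np.isfinite(X)) or not np.all(np.isfinite(y)):
            raise ValueError("non-finite entries in training data")
        if np.any(y < 0):
            raise ValueError("reference concentrations must be >= 0")
        if self.analyte not in ANALYTES:
            raise ValueError(f"unknown analyte {self.analyte!r}")
        if self.sample_ids is None:
            self.sample_ids = [f"s{i}" for i in range(X.shape[0])]
        elif len(self.sample_ids) != X.shape[0]:
            raise ValueError("sample_ids length mismatch")
        self.X = X
        self.y = y

    @property
    def n(self) -> int:
        return int(self.X.shape[0])

    @property
    def p(self) -> int:
        return int(self.X.shape[1])

    def subset(self, keep: np.ndarray) -> "TrainingSet":
        keep = np.asarray(keep)
        idx = np.flatnonzero(keep) if keep.dtype == bool else keep
        return TrainingSet(
            X=self.X[idx],
            y=self.y[idx],
            analyte=self.analyte,
            sample_ids=[self.sample_ids[i] for i in idx],
        )


@dataclass
class PlsModel:
    """One trained PLS1 calibration.

    ``b`` is the regression vector on centered data: prediction is
    ``y_mean + (x - x_mean) @ b``. ``weights``/``loadings``/``score_norms``
    (and training ``scores``) are kept for leverage computations; they are
    not serialized.
    """

    analyte: str
    A: int
    x_mean: np.ndarray
    y_mean: float
    b: np.ndarray
    weights: np.ndarray | None = None      # p x A
    loadings: np.ndarray | None = None     # p x A
    q: np.ndarray | None = None            # A
    score_norms: np.ndarray | None = None  # t_a^T t_a per component
    scores: np.ndarray | None = None       # n x A training scores
    n_used: int = 0
    n_outliers_removed: int = 0
    rmse_cv_curve: list[float] | None = None
    rmse_cv: float | None = None
    r_train: float | None = None

    def __post_init__(self) -> None:
        if self.A < 1:
            raise ValueError("A must be >= 1")
        self.x_mean = np.asarray(self.x_mean, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        if self.b.shape != self.x_mean.shape:
            raise ValueError("b and x_mean must have the same length")


@dataclass
class CrossValCurve:
    """RMSE_CV per candidate number of latent variables (A = 1..A_max)."""

    values: np.ndarray
    n: int
    analyte: str

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or v.size == 0:
            raise ValueError("curve must be a non-empty 1-D array")
        if np.any(v < 0):
            raise ValueError("RMSE_CV values must be >= 0")
        self.values = v

    @property
    def A_max(self) -> int:
        return int(self.values.size)


@dataclass
class DffitsDiagnostics:
    """Per-sample DFFITS influence values at a fixed component count."""

    dffits: np.ndarray
    leverage: np.ndarray
    deletion_scale: np.ndarray
    threshold: float
    flags: np.ndarray
    A: int

    def __post_init__(self) -> None:
        if self.threshold <= 0:
            raise ValueError("threshold must be > 0")
        n = self.dffits.size
        if not (self.leverage.size == self.deletion_scale.size == self.flags.size == n):
            raise ValueError("diagnostic arrays must share one length")

    @property
    def n_flagged(self) -> int:
        return int(np.count_nonzero(self.flags))


# ---------------------------------------------------------------------------
# NIPALS core
# ---------------------------------------------------------------------------

def _nipals(X0: np.ndarray, y0: np.ndarray, A: int):
    """Mean-centered NIPALS PLS1 decomposition.

    Returns (W, P, q, T, score_norms, A_eff). Stops early (A_eff < A) if the
    residual X or y carries no further usable covariance.
    """
    n, p = X0.shape
    W = np.zeros((p, A))
    P = np.zeros((p, A))
    q = np.zeros(A)
    T = np.zeros((n, A))
    tt_all = np.zeros(A)
    Xd = X0.copy()
    yd = y0.copy()
    scale = max(float(np.abs(X0).max(initial=0.0)), _EPS)
    a_eff = 0
    for a in range(A):
        w = Xd.T @ yd
        wnorm = np.linalg.norm(w)
        if wnorm <= _EPS * scale * max(np.linalg.norm(yd), _EPS):
            break
        w /= wnorm
        t = Xd @ w
        tt = float(t @ t)
        if tt <= (_EPS * scale) ** 2 * n:
            break
        pl = Xd.T @ t / tt
        qa = float(yd @ t) / tt
        Xd -= np.outer(t, pl)
        yd -= qa * t
        W[:, a] = w
        P[:, a] = pl
        q[a] = qa
        T[:, a] = t
        tt_all[a] = tt
        a_eff = a + 1
    if a_eff == 0:
        raise DegenerateModelError("no usable covariance between X and y")
    return W[:, :a_eff], P[:, :a_eff], q[:a_eff], T[:, :a_eff], tt_all[:a_eff], a_eff


def _regression_vector(W: np.ndarray, P: np.ndarray, q: np.ndarray) -> np.ndarray:
    # b = W (P^T W)^{-1} q ; P^T W is upper triangular with unit-ish diagonal
    return W @ np.linalg.solve(P.T @ W, q)


def fit_pls1(ts: TrainingSet, A: int) -> PlsModel:
    """Fit a PLS1 model with ``A`` latent variables.

    Raises ``DegenerateModelError`` for a constant response and ``ValueError``
    for A outside [1, min(n-1, p)]. If the data run out of rank before ``A``
    components the model keeps the components actually extracted (logged).
    """
    n, p = ts.n, ts.p
    if not 1 <= A <= min(n - 1, p):
        raise ValueError(f"A={A} outside [1, {min(n - 1, p)}] for n={n}, p={p}")
    if np.ptp(ts.y) <= 0:
        raise DegenerateModelError("response y has zero variance")
    x_mean = ts.X.mean(axis=0)
    y_mean = float(ts.y.mean())
    W, P, q, T, tt, a_eff = _nipals(ts.X - x_mean, ts.y - y_mean, A)
    if a_eff < A:
        logger.warning(
            "%s: rank exhausted after %d of %d requested latent variables",
            ts.analyte, a_eff, A,
        )
    b = _regression_vector(W, P, q)
    fitted = y_mean + (ts.X - x_mean) @ b
    r = _pearson(ts.y, fitted)
    return PlsModel(
        analyte=ts.analyte,
        A=a_eff,
        x_mean=x_mean,
        y_mean=y_mean,
        b=b,
        weights=W,
        loadings=P,
        q=q,
        score_norms=tt,
        scores=T,
        n_used=n,
        r_train=r,
    )


def predict(model: PlsModel, x: np.ndarray) -> float:
    """Predict one concentration (mg/dL) from a feature vector."""
    x = np.asarray(getattr(x, "values", x), dtype=float)
    if x.shape != model.x_mean.shape:
        raise ValueError(
            f"feature length {x.shape} does not match model {model.x_mean.shape}"
        )
    return float(model.y_mean + (x - model.x_mean) @ model.b)


def predict_many(model: PlsModel, X: np.ndarray) -> np.ndarray:
    """Vectorized prediction over rows of ``X``."""
    X = np.asarray(X, dtype=float)
    return model.y_mean + (X - model.x_mean) @ model.b


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    if np.ptp(a) <= 0 or np.ptp(b) <= 0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------

def rmse_cv(e, p) -> float:
    """Root mean square error between measured ``e`` and predicted ``p``."""
    e = np.asarray(e, dtype=float)
    p = np.asarray(p, dtype=float)
    if e.size == 0 or e.shape != p.shape:
        raise ValueError("e and p must be non-empty arrays of equal length")
    return float(np.sqrt(np.mean((e - p) ** 2)))


def _loo_predictions(X: np.ndarray, y: np.ndarray, A_max: int) -> np.ndarray:
    """n x A_max matrix of leave-one-out predictions.

    One nested NIPALS decomposition per fold serves every component count;
    if a fold's data exhaust their rank early, the last available prediction
    carries forward to higher component counts.
    """
    n = X.shape[0]
    preds = np.empty((n, A_max))
    idx = np.arange(n)
    for i in range(n):
        keep = idx != i
        Xi = X[keep]
        yi = y[keep]
        x_mean = Xi.mean(axis=0)
        y_mean = yi.mean()
        Xd = Xi - x_mean
        yd = yi - y_mean
        xc = X[i] - x_mean
        scale = max(float(np.abs(Xd).max(initial=0.0)), _EPS)
        pred = y_mean
        for a in range(A_max):
            w = Xd.T @ yd
            wnorm = np.linalg.norm(w)
            if wnorm <= _EPS * scale * max(np.linalg.norm(yd), _EPS):
                preds[i, a:] = pred
                break
            w /= wnorm
            t = Xd @ w
            tt = float(t @ t)
            if tt <= (_EPS * scale) ** 2 * n:
                preds[i, a:] = pred
                break
            pl = Xd.T @ t / tt
            qa = float(yd @ t) / tt
            Xd -= np.outer(t, pl)
            yd -= qa * t
            t_new = float(xc @ w)
            xc = xc - t_new * pl
            pred = pred + qa * t_new
            preds[i, a] = pred
    return preds


def loocv_curve(ts: TrainingSet, A_max: int) -> CrossValCurve:
    """Leave-one-out RMSE_CV for every component count 1..A_max."""
    if not 1 <= A_max <= ts.n - 2:
        raise ValueError(f"A_max={A_max} outside [1, n-2] for n={ts.n}")
    preds = _loo_predictions(ts.X, ts.y, A_max)
    values = np.array([rmse_cv(ts.y, preds[:, a]) for a in range(A_max)])
    return CrossValCurve(values=values, n=ts.n, analyte=ts.analyte)


def select_latent_variables(curve: CrossValCurve) -> int:
    """Number of latent variables minimizing RMSE_CV (ties -> smaller A)."""
    a_star = int(np.argmin(curve.values)) + 1
    if a_star == curve.A_max:
        logger.warning(
            "%s: RMSE_CV minimum sits at the search bound A_max=%d; "
            "the bound may be too small", curve.analyte, curve.A_max,
        )
    return a_star


# ---------------------------------------------------------------------------
# DFFITS
# ---------------------------------------------------------------------------

def default_dffits_threshold(A: int, n: int) -> float:
    """Conventional size-adjusted DFFITS cutoff 2*sqrt((A+1)/n)."""
    return 2.0 * np.sqrt((A + 1) / n)


def dffits_diagnostics(
    ts: TrainingSet, A: int, threshold: float | None = None
) -> DffitsDiagnostics:
    """DFFITS influence of each training sample on its own fitted value.

    Computed in the fixed score space of the A-component model: leverage
    h_ii = 1/n + t_i (T^T T)^{-1} t_i^T, deletion residual scale s_(i) from
    the usual leave-one-out variance identity, and
    dffits_i = (yhat_i - yhat_(i),i) / (s_(i) sqrt(h_ii)).
    """
    model = fit_pls1(ts, A)
    A_eff = model.A
    n = ts.n
    if n <= A_eff + 2:
        raise ValueError(f"n={n} too small for deletion estimates at A={A_eff}")
    T = model.scores
    tt = model.score_norms
    h = 1.0 / n + np.sum(T**2 / tt, axis=1)
    fitted = predict_many(model, ts.X)
    e = ts.y - fitted
    dof = n - A_eff - 1
    sse = float(e @ e)
    yscale = max(float(np.abs(ts.y).max(initial=0.0)), 1.0)
    thr = float(threshold) if threshold is not None else default_dffits_threshold(A_eff, n)
    if sse <= (1e-8 * yscale) ** 2 * n:
        # the model interpolates to numerical precision: deletion influence
        # is pure roundoff, not evidence of an outlier
        zeros = np.zeros(n)
        return DffitsDiagnostics(
            dffits=zeros, leverage=h, deletion_scale=zeros.copy(),
            threshold=thr, flags=np.zeros(n, dtype=bool), A=A_eff,
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        s_i_sq = (sse - e**2 / (1.0 - h)) / (dof - 1)
    s_i_sq = np.clip(s_i_sq, 0.0, None)
    s_i = np.sqrt(s_i_sq)
    dff = np.zeros(n)
    for i in range(n):
        denom = s_i[i] * (1.0 - h[i])
        if denom <= _EPS * yscale:
            # zero-residual (or saturated) fit: no deletion influence unless
            # the residual itself is non-negligible
            dff[i] = 0.0 if abs(e[i]) <= 1e-8 * yscale else np.inf
        else:
            dff[i] = e[i] * np.sqrt(h[i]) / denom
    flags = np.abs(dff) > thr
    return DffitsDiagnostics(
        dffits=dff, leverage=h, deletion_scale=s_i, threshold=thr, flags=flags, A=A_eff
    )


# ---------------------------------------------------------------------------
# Training pipeline
# ---------------------------------------------------------------------------

def train_calibration(
    ts: TrainingSet, A_max: int = 40, dffits_threshold: float | None = None
) -> PlsModel:
    """Full calibration pipeline.

    LOOCV curve -> select A* -> DFFITS screen at A* (single pass) -> drop
    flagged samples -> re-run LOOCV and latent-variable selection on the
    reduced set -> final fit, with diagnostics recorded on the model.
    """
    A_max = min(A_max, ts.n - 2, ts.p)
    curve = loocv_curve(ts, A_max)
    a_star = select_latent_variables(curve)
    diag = dffits_diagnostics(ts, a_star, threshold=dffits_threshold)
    keep = ~diag.flags
    n_removed = int(np.count_nonzero(diag.flags))
    if n_removed:
        logger.info(
            "%s: removing %d influential training sample(s) (|DFFITS| > %.3f)",
            ts.analyte, n_removed, diag.threshold,
        )
    reduced = ts.subset(keep) if n_removed else ts
    if reduced.n < a_star + 3:
        raise TrainingError(
            f"outlier removal left n={reduced.n} < A*+3={a_star + 3} samples"
        )
    A_max2 = min(A_max, reduced.n - 2)
    curve2 = loocv_curve(reduced, A_max2)
    a_final = select_latent_variables(curve2)
    model = fit_pls1(reduced, a_final)
    model.n_outliers_removed = n_removed
    model.rmse_cv_curve = [float(v) for v in curve2.values]
    model.rmse_cv = float(curve2.values[a_final - 1])
    return model


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def model_to_json(model: PlsModel) -> str:
    """Versioned JSON with explicit arrays; no opaque binary."""
    payload = {
        "format_version": _MODEL_FORMAT_VERSION,
        "analyte": model.analyte,
        "A": model.A,
        "x_mean": model.x_mean.tolist(),
        "y_mean": model.y_mean,
        "b": model.b.tolist(),
        "diagnostics": {
            "n_used": model.n_used,
            "n_outliers_removed": model.n_outliers_removed,
            "rmse_cv_curve": model.rmse_cv_curve,
            "rmse_cv": model.rmse_cv,
            "r_train": model.r_train,
        },
    }
    return json.dumps(payload)


def model_from_json(text: str) -> PlsModel:
    payload = json.loads(text)
    version = payload.get("format_version")
    if version != _MODEL_FORMAT_VERSION:
        raise ValueError(f"unsupported model format version {version!r}")
    diag = payload.get("diagnostics", {})
    return PlsModel(
        analyte=payload["analyte"],
        A=int(payload["A"]),
        x_mean=np.asarray(payload["x_mean"], dtype=float),
        y_mean=float(payload["y_mean"]),
        b=np.asarray(payload["b"], dtype=float),
        n_used=int(diag.get("n_used", 0)),
        n_outliers_removed=int(diag.get("n_outliers_removed", 0)),
        rmse_cv_curve=diag.get("rmse_cv_curve"),
        rmse_cv=diag.get("rmse_cv"),
        r_train=diag.get("r_train"),
    )
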