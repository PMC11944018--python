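"""Two-class PLS-DA with NIPALS component extraction, VIP scoring, and
cross-validated predictive ability (Q²).

The model is fit on autoscaled predictors (each hormone mean-centered and
scaled to unit variance, ddof=1) against a centered 0/1-coded class response
— the standard setup for targeted metabolomics, where concentrations span
orders of magnitude and comparable variable importances require unit-variance
columns.

For a single response column NIPALS reduces to the classical PLS1 recursion:

    w_a = X_a' y / ||X_a' y||      (unit-norm weight)
    t_a = X_a w_a                  (score)
    q_a = t_a' y / t_a' t_a        (response loading)
    p_a = X_a' t_a / t_a' t_a      (predictor loading)
    X_{a+1} = X_a - t_a p_a'       (deflation)

The iterative NIPALS loop is retained (it converges in one pass for a single
response) so the component count, tolerance, and iteration cap are explicit.

Model quality metrics:

* R²X — cumulative fraction of predictor variance captured by the scores;
* R²Y — cumulative fraction of response variance explained;
* Q²  — 1 − PRESS/TSS under cross-validation (leave-one-out by default),
  with PRESS accumulated over held-out predictions and TSS taken against
  each training fold's response mean, so that predicting the training mean
  gives exactly Q² = 0.

A model is considered valid when R²X, R²Y, and Q² all strictly exceed 0.5.

VIP (variable importance in projection) for variable j over A components:

    VIP_j = sqrt( p * sum_a [ SSY_a * w_aj² ] / sum_a SSY_a )

where SSY_a = q_a² t_a't_a is the response variance explained by component a
and the weights are unit-norm. Mean squared VIP equals 1 by construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import (
    ConvergenceError,
    DegenerateModelError,
    DesignError,
    FoldSchemeError,
)

CONTROL_LABEL = "control"
TREATED_LABEL = "treated"

_NIPALS_MAX_ITER = 500
_NIPALS_TOL = 1e-10


@dataclass
class ValidityVerdict:
    """Outcome of the >0.5 gate on (R²X, R²Y, Q²)."""

    passed: bool
    r2x_ok: bool
    r2y_ok: bool
    q2_ok: bool
    threshold: float

    @property
    def flags(self) -> dict[str, bool]:
        return {"r2x": self.r2x_ok, "r2y": self.r2y_ok, "q2": self.q2_ok}


@dataclass
class PlsdaModel:
    """A fitted two-class PLS-DA model.

    Matrices follow the usual conventions: ``weights`` (p × A, unit-norm
    columns), ``x_loadings`` (p × A), ``y_loadings`` (length A), ``scores``
    (n × A, mutually orthogonal columns). ``ssy_per_component`` records the
    response variance captured by each component and feeds the VIP formula.
    ``kept_columns`` maps model variables back to the original predictor
    indices when zero-variance columns were dropped.
    """

    n_components: int
    weights: np.ndarray
    x_loadings: np.ndarray
    y_loadings: np.ndarray
    scores: np.ndarray
    x_mean: np.ndarray
    x_scale: np.ndarray
    y_mean: float
    r2x: float
    r2y: float
    ssx_per_component: np.ndarray
    ssy_per_component: np.ndarray
    kept_columns: np.ndarray
    n_variables: int
    q2: float | None = None
    r2x_cumulative: np.ndarray = field(default=None)  # type: ignore[assignment]
    r2y_cumulative: np.ndarray = field(default=None)  # type: ignore[assignment]

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Predict the continuous class response for new concentration rows."""
        X = np.asarray(X, dtype=float)[:, self.kept_columns]
        Xs = (X - self.x_mean) / self.x_scale
        # B = W (P'W)^{-1} q maps autoscaled predictors to the centered response
        W, P, q = self.weights, self.x_loadings, self.y_loadings
        coef = W @ np.linalg.solve(P.T @ W, q)
        return Xs @ coef + self.y_mean


def encode_labels(y: np.ndarray | list) -> np.ndarray:
    """Map {control, treated} labels to 0/1; both classes must be present."""
    arr = np.asarray(y)
    if arr.dtype.kind in "ifb":
        coded = arr.astype(float)
        classes = np.unique(coded)
    else:
        coded = np.where(arr == TREATED_LABEL, 1.0, 0.0)
        classes = np.unique(arr)
        unknown = set(classes) - {CONTROL_LABEL, TREATED_LABEL}
        if unknown:
            raise DesignError(f"unknown class label(s): {sorted(unknown)}")
    if len(np.unique(coded)) < 2:
        raise DesignError("both classes (control and treated) must be present")
    return coded


def _nipals_component(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """One NIPALS component for a single-column response: returns (w, t)."""
    u = y.astype(float)
    w = X.T @ u
    nw = np.linalg.norm(w)
    if nw == 0:
        raise DegenerateModelError("predictors are orthogonal to the response; no component")
    w = w / nw
    t = X @ w
    for _ in range(_NIPALS_MAX_ITER):
        w_new = X.T @ u
        w_new /= np.linalg.norm(w_new)
        t_new = X @ w_new
        if np.linalg.norm(w_new - w) < _NIPALS_TOL:
            return w_new, t_new
        w, t = w_new, t_new
        # single response: u never changes, so the loop exits on pass 2
    raise ConvergenceError(
        f"NIPALS did not converge within {_NIPALS_MAX_ITER} iterations"
    )


def fit_plsda(
    X: np.ndarray,
    y: np.ndarray | list,
    n_components: int = 2,
) -> PlsdaModel:
    """Fit a two-class PLS-DA model on autoscaled X and a centered 0/1 response.

    Zero-variance predictor columns are dropped with a warning (autoscaling is
    undefined for them); their VIP is reported as 0. A component count
    exceeding the predictor rank is truncated with a warning.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be a 2-D samples x variables matrix")
    n, p_all = X.shape
    if n < 4:
        raise DesignError(f"need at least 4 samples to fit PLS-DA, got {n}")
    if not np.isfinite(X).all():
        raise ValueError("X contains non-finite values")
    y01 = encode_labels(y)
    if len(y01) != n:
        raise ValueError("X and y have different lengths")
    if n_components < 1:
        raise ValueError("n_components must be positive")

    scale_all = X.std(axis=0, ddof=1)
    kept = np.flatnonzero(scale_all > 0)
    if len(kept) < p_all:
        warnings.warn(
            f"dropping {p_all - len(kept)} zero-variance column(s); VIP reported as 0",
            stacklevel=2,
        )
    if len(kept) == 0:
        raise DegenerateModelError("all predictor columns have zero variance")
    Xk = X[:, kept]
    p = len(kept)

    x_mean = Xk.mean(axis=0)
    x_scale = Xk.std(axis=0, ddof=1)
    Xs = (Xk - x_mean) / x_scale
    y_mean = float(y01.mean())
    yc = y01 - y_mean

    ssx_total = float((Xs**2).sum())
    ssy_total = float((yc**2).sum())
    rank = int(np.linalg.matrix_rank(Xs))
    A = min(n_components, rank)
    if A < n_components:
        warnings.warn(
            f"requested {n_components} components but rank is {rank}; truncating to {A}",
            stacklevel=2,
        )

    W = np.zeros((p, A))
    P = np.zeros((p, A))
    q = np.zeros(A)
    T = np.zeros((n, A))
    ssx_comp = np.zeros(A)
    ssy_comp = np.zeros(A)

    Xd = Xs.copy()
    extracted = 0
    for a in range(A):
        try:
            w, t = _nipals_component(Xd, yc)
        except DegenerateModelError:
            break
        tt = float(t @ t)
        if tt <= 1e-14:
            break
        # reproducible sign: first nonzero weight entry made non-negative
        pivot = np.flatnonzero(np.abs(w) > 1e-12)
        if len(pivot) and w[pivot[0]] < 0:
            w, t = -w, -t
        p_a = Xd.T @ t / tt
        q_a = float(t @ yc) / tt
        Xd = Xd - np.outer(t, p_a)
        W[:, a], P[:, a], q[a], T[:, a] = w, p_a, q_a, t
        ssx_comp[a] = tt * float(p_a @ p_a)
        ssy_comp[a] = q_a**2 * tt
        extracted = a + 1

    if extracted == 0:
        raise DegenerateModelError("no PLS component could be extracted")
    if extracted < A:
        W, P, q, T = W[:, :extracted], P[:, :extracted], q[:extracted], T[:, :extracted]
        ssx_comp, ssy_comp = ssx_comp[:extracted], ssy_comp[:extracted]

    r2x_cum = np.cumsum(ssx_comp) / ssx_total
    r2y_cum = np.cumsum(ssy_comp) / ssy_total if ssy_total > 0 else np.zeros(extracted)

    return PlsdaModel(
        n_components=extracted,
        weights=W,
        x_loadings=P,
        y_loadings=q,
        scores=T,
        x_mean=x_mean,
        x_scale=x_scale,
        y_mean=y_mean,
        r2x=float(r2x_cum[-1]),
        r2y=float(r2y_cum[-1]),
        ssx_per_component=ssx_comp,
        ssy_per_component=ssy_comp,
        kept_columns=kept,
        n_variables=p_all,
        r2x_cumulative=r2x_cum,
        r2y_cumulative=r2y_cum,
    )


def loo_folds(n: int) -> list[np.ndarray]:
    """Leave-one-out fold assignment: fold i holds out sample i."""
    return [np.array([i]) for i in range(n)]


def kfold_folds(n: int, k: int, seed: int | None = None) -> list[np.ndarray]:
    """Seeded k-fold partition of n samples."""
    idx = np.arange(n)
    if seed is not None:
        idx = np.random.default_rng(seed).permutation(n)
    return [np.sort(part) for part in np.array_split(idx, k)]


def compute_q2(
    X: np.ndarray,
    y: np.ndarray | list,
    n_components: int = 2,
    folds: list[np.ndarray] | None = None,
) -> float:
    """Cross-validated predictive ability Q² = 1 − PRESS/TSS.

    PRESS sums squared held-out prediction errors; TSS sums squared
    deviations of held-out responses from their training-fold mean, so a
    model no better than the training mean scores exactly 0.
    """
    X = np.asarray(X, dtype=float)
    y01 = encode_labels(y)
    n = len(y01)
    if folds is None:
        folds = loo_folds(n)
    press = 0.0
    tss = 0.0
    for held in folds:
        train = np.setdiff1d(np.arange(n), held)
        if len(np.unique(y01[train])) < 2:
            raise FoldSchemeError(
                "a cross-validation fold leaves only one class in training"
            )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = fit_plsda(X[train], y01[train], n_components)
        pred = model.predict(X[held])
        press += float(((y01[held] - pred) ** 2).sum())
        tss += float(((y01[held] - y01[train].mean()) ** 2).sum())
    if tss == 0:
        raise DegenerateModelError("response has no variance across folds")
    return 1.0 - press / tss


def compute_vip(model: PlsdaModel) -> np.ndarray:
    """Variable importance in projection for every original predictor column.

    Dropped (zero-variance) columns get VIP 0; over the fitted variables the
    mean squared VIP is exactly 1.
    """
    ssy = model.ssy_per_component
    total = float(ssy.sum())
    if total <= 0:
        raise DegenerateModelError("all components explain zero response variance")
    p = model.weights.shape[0]
    wnorm2 = (model.weights**2) / (model.weights**2).sum(axis=0)
    vip_kept = np.sqrt(p * (wnorm2 @ ssy) / total)
    vip = np.zeros(model.n_variables)
    vip[model.kept_columns] = vip_kept
    return vip


def validate_model(
    r2x: float, r2y: float, q2: float, threshold: float = 0.5
) -> ValidityVerdict:
    """Gate a fitted model on its three quality metrics, all strictly > threshold."""
    flags = (r2x > threshold, r2y > threshold, q2 > threshold)
    return ValidityVerdict(
        passed=all(flags),
        r2x_ok=flags[0],
        r2y_ok=flags[1],
        q2_ok=flags[2],
        threshold=threshold,
    )
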