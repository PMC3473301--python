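"""Canonical Powered Partial Least Squares (CPPLS) discriminant.

Word-frequency classification is a 'large p, small n' problem: the feature
dimension (e.g. 3782 codon words at K=1) exceeds the number of training
ORFs, so ordinary least squares for E(y) = X beta has no unique solution.
PLS methods resolve this by extracting a few latent components.  CPPLS
generalizes the classical PLS loading weights with a power parameter
gamma in [0, 1] that re-balances the influence of column standard
deviations against column-response correlations:

    w_j(gamma)  ~  sign(rho_j) * |rho_j|^(gamma/(1-gamma))
                               * sigma_j^((1-gamma)/gamma)

At gamma = 0.5 both exponents are 1 and w ~ rho*sigma ~ cov(x_j, y): the
classical PLS loading weights.  gamma -> 1 selects the single most
correlated variable, gamma -> 0 the single most variable one.  For each
component, gamma is chosen from a grid by maximizing the canonical
correlation between the candidate score t = X w(gamma) and the response.

The two-class response is coded +1 (Positive) / -1 (Negative); a test ORF
with word-frequency row x receives the score y_hat = intercept + x . beta_hat
and is classified by its sign (threshold 0, the midpoint of the coding).
The number of components A is selected by an inner cross-validation on the
training data.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import KFold, StratifiedKFold

__all__ = [
    "CpplsModel",
    "fit",
    "predict_score",
    "classify",
    "default_gamma_grid",
    "DEFAULT_A_MAX",
]

log = logging.getLogger(__name__)

DEFAULT_A_MAX = 10
INNER_CV_FOLDS = 5


def default_gamma_grid() -> np.ndarray:
    """{0.5} plus 10 evenly spaced interior points of (0, 1)."""
    pts = np.arange(1, 11) / 11.0
    return np.unique(np.concatenate([[0.5], pts]))


@dataclass
class CpplsModel:
    """Fitted CPPLS discriminant in regression-coefficient form."""

    column_means: np.ndarray
    coefficients: np.ndarray
    intercept: float
    n_components: int
    power_parameters: list[float]
    response_coding: tuple[int, int] = (+1, -1)

    @property
    def p(self) -> int:
        return len(self.coefficients)

    def to_json(self) -> str:
        return json.dumps(
            {
                "format": "codingseq-cppls-v1",
                "column_means": self.column_means.tolist(),
                "coefficients": self.coefficients.tolist(),
                "intercept": self.intercept,
                "n_components": self.n_components,
                "power_parameters": self.power_parameters,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "CpplsModel":
        d = json.loads(text)
        if d.get("format") != "codingseq-cppls-v1":
            raise ValueError("unrecognized CPPLS model format")
        return cls(
            column_means=np.asarray(d["column_means"]),
            coefficients=np.asarray(d["coefficients"]),
            intercept=float(d["intercept"]),
            n_components=int(d["n_components"]),
            power_parameters=list(d["power_parameters"]),
        )


def _powered_weights(rho: np.ndarray, sd: np.ndarray, gamma: float) -> np.ndarray:
    """Loading-weight direction for one power parameter (unnormalized).

    sd and |rho| are scaled to a maximum of 1 before powering, which leaves
    the direction unchanged but avoids overflow at extreme exponents.
    """
    if not 0.0 <= gamma <= 1.0:
        raise ValueError("gamma must lie in [0, 1]")
    w = np.zeros_like(rho)
    active = sd > 0
    if gamma == 0.0:
        j = int(np.argmax(sd))
        w[j] = 1.0
        return w
    if gamma == 1.0:
        j = int(np.argmax(np.abs(rho)))
        w[j] = np.sign(rho[j]) if rho[j] != 0 else 1.0
        return w
    rmax = np.abs(rho[active]).max(initial=0.0)
    smax = sd[active].max(initial=0.0)
    if smax == 0:
        raise ValueError("all columns constant")
    r_exp = gamma / (1.0 - gamma)
    s_exp = (1.0 - gamma) / gamma
    r_part = (np.abs(rho[active]) / rmax) ** r_exp if rmax > 0 else np.zeros(active.sum())
    s_part = (sd[active] / smax) ** s_exp
    w[active] = np.sign(rho[active]) * r_part * s_part
    return w


def _fit_components(
    Xc: np.ndarray, yc: np.ndarray, A_max: int, gamma_grid: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[float]]:
    """Extract up to A_max components from centered data.

    Returns loading weights W (p x A), X-loadings P (p x A), y-loadings q
    (A,), and the chosen gamma per component.  Stops early if the deflated
    predictors carry no remaining signal.
    """
    n, p = Xc.shape
    Xd = Xc.copy()
    sy = float(np.sqrt(yc @ yc))
    W, P, q, gammas = [], [], [], []
    for _ in range(A_max):
        sd = Xd.std(axis=0, ddof=1)
        cov = Xd.T @ yc / (n - 1)
        with np.errstate(invalid="ignore", divide="ignore"):
            rho = np.where(sd > 0, cov / np.where(sd > 0, sd, 1.0), 0.0)
        best = None
        for gamma in gamma_grid:
            w = _powered_weights(rho, sd, float(gamma))
            norm = np.linalg.norm(w)
            if norm == 0:
                continue
            w = w / norm
            t = Xd @ w
            tt = float(t @ t)
            if tt <= 1e-12 * n:
                continue
            cancor = abs(float(t @ yc)) / (np.sqrt(tt) * sy)
            if best is None or cancor > best[0] + 1e-12:
                best = (cancor, float(gamma), w, t, tt)
        if best is None:
            break
        _, gamma, w, t, tt = best
        p_load = Xd.T @ t / tt
        q_a = float(yc @ t / tt)
        Xd -= np.outer(t, p_load)
        W.append(w)
        P.append(p_load)
        q.append(q_a)
        gammas.append(gamma)
    if not W:
        raise ValueError("no component could be extracted (constant predictors?)")
    return (np.column_stack(W), np.column_stack(P), np.asarray(q), gammas)


def _beta_path(W: np.ndarray, P: np.ndarray, q: np.ndarray) -> list[np.ndarray]:
    """Regression coefficients for every truncation A = 1..A_fitted."""
    betas = []
    for a in range(1, W.shape[1] + 1):
        Wa, Pa, qa = W[:, :a], P[:, :a], q[:a]
        betas.append(Wa @ np.linalg.solve(Pa.T @ Wa, qa))
    return betas


def fit(
    X: np.ndarray,
    y: np.ndarray,
    A_max: int = DEFAULT_A_MAX,
    gamma_grid: np.ndarray | None = None,
    inner_cv: int = INNER_CV_FOLDS,
    seed: int = 0,
    A: int | None = None,
) -> CpplsModel:
    """Fit the CPPLS discriminant.

    ``y`` is the +1/-1 class coding (a continuous response is also accepted,
    in which case the inner cross-validation minimizes squared error instead
    of misclassification).  ``A`` fixes the number of components and skips
    the inner CV.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n != len(y):
        raise ValueError("X and y disagree on n")
    if n < 4:
        raise ValueError("need at least 4 training rows")
    is_classed = set(np.unique(y)) <= {-1.0, 1.0}
    if is_classed and len(np.unique(y)) < 2:
        raise ValueError("both classes must be present in y")
    if (X.std(axis=0) == 0).all():
        raise ValueError("all predictor columns are constant")
    if gamma_grid is None:
        gamma_grid = default_gamma_grid()
    A_max = int(min(A_max, n - 1, p))

    if A is None:
        A = _select_A(X, y, A_max, gamma_grid, inner_cv, seed, is_classed)
    A = int(min(A, A_max))

    xbar = X.mean(axis=0)
    ybar = float(y.mean())
    W, P, q, gammas = _fit_components(X - xbar, y - ybar, A, gamma_grid)
    A_eff = W.shape[1]
    beta = _beta_path(W, P, q)[A_eff - 1]
    return CpplsModel(
        column_means=xbar,
        coefficients=beta,
        intercept=ybar - float(xbar @ beta),
        n_components=A_eff,
        power_parameters=gammas,
    )


def _select_A(
    X: np.ndarray,
    y: np.ndarray,
    A_max: int,
    gamma_grid: np.ndarray,
    inner_cv: int,
    seed: int,
    is_classed: bool,
) -> int:
    """Inner cross-validated choice of the number of components.

    Minimizes misclassification count (squared error for continuous y);
    ties resolve to the smallest A.
    """
    if is_classed:
        splitter = StratifiedKFold(n_splits=inner_cv, shuffle=True, random_state=seed)
        splits = splitter.split(X, y)
    else:
        splitter = KFold(n_splits=inner_cv, shuffle=True, random_state=seed)
        splits = splitter.split(X)
    loss = np.zeros(A_max)
    counts = np.zeros(A_max)
    for train_idx, val_idx in splits:
        Xtr, ytr = X[train_idx], y[train_idx]
        xbar, ybar = Xtr.mean(axis=0), float(ytr.mean())
        a_cap = int(min(A_max, len(train_idx) - 1))
        W, P, q, _ = _fit_components(Xtr - xbar, ytr - ybar, a_cap, gamma_grid)
        for a, beta in enumerate(_beta_path(W, P, q)):
            pred = ybar + (X[val_idx] - xbar) @ beta
            if is_classed:
                lab = np.where(pred > 0, 1.0, -1.0)
                loss[a] += float((lab != y[val_idx]).sum())
            else:
                loss[a] += float(((pred - y[val_idx]) ** 2).sum())
            counts[a] += len(val_idx)
    valid = counts == counts.max()
    loss = np.where(valid, loss, np.inf)
    return int(np.argmin(loss)) + 1


def predict_score(model: CpplsModel, x: np.ndarray) -> float | np.ndarray:
    """Predicted response y_hat = intercept + x . beta_hat (affine in x)."""
    x = np.asarray(x, dtype=float)
    if x.shape[-1] != model.p:
        raise ValueError(f"feature row has {x.shape[-1]} columns, model expects {model.p}")
    out = model.intercept + x @ model.coefficients
    return float(out) if np.ndim(out) == 0 else out


def classify(model: CpplsModel, x: np.ndarray) -> int | np.ndarray:
    """+1 (Positive) if the predicted score is > 0, else -1 (Negative)."""
    s = predict_score(model, x)
    if np.ndim(s) == 0:
        return +1 if s > 0 else -1
    return np.where(np.asarray(s) > 0, 1, -1)
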