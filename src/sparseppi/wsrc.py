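"""Weighted sparse representation based classification (WSRC).

A test vector y is reconstructed as a sparse linear combination of the
training columns by solving the weighted stable l1 problem

    minimize ||W a||_1  subject to  ||y - X a||_2 <= eps,

where the diagonal of W holds Gaussian locality weights
w_i = exp(-||y - x_i||^2 / (2 sigma^2)) between y and each training column.
The sample is assigned to the class whose columns reconstruct it with the
smallest Euclidean residual r_c = ||y - X d_c(a)||, d_c keeping only the
coefficients of class c.

The constrained problem is solved through its penalized Lagrangian form
(a weighted lasso) with the penalty found by bisection until the residual
constraint is met; when eps is smaller than the best attainable residual
(the usual case when y lies outside the span of the training columns) the
minimum-residual penalized solution is used instead, with a warning.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.linear_model import Lasso

from . import seq_io

#: Relative floor for locality weights: the penalty ratio between the most
#: and least favoured training column is capped at 1/WEIGHT_FLOOR so the
#: substituted lasso stays well conditioned.  When every similarity
#: underflows to zero the weights degrade gracefully to uniform (plain SRC).
WEIGHT_FLOOR = 1e-6

WEIGHT_MODES = ("similarity", "inverse_similarity")


class InfeasibleEpsilonError(ValueError):
    """eps is below the best residual attainable within the column span."""

    def __init__(self, epsilon: float, best_residual: float):
        self.epsilon = epsilon
        self.best_residual = best_residual
        super().__init__(
            f"epsilon={epsilon:g} is infeasible: minimum attainable "
            f"residual is {best_residual:g}"
        )


class SolverError(RuntimeError):
    """The inner coordinate-descent solve failed to converge."""


@dataclass
class SparseCoefficients:
    """Solution of one weighted l1 solve, with solve diagnostics."""

    alpha: np.ndarray
    residual: float
    objective: float          # ||W alpha||_1
    feasible: bool            # residual <= epsilon (+ solver slack)
    fallback: bool = False    # minimum-residual fallback was taken
    penalty: float = 0.0      # lasso penalty at the returned solution


@dataclass
class PredictionResult:
    """Outcome of classifying one sample."""

    predicted_class: int
    residuals: dict[int, float]
    score: float              # r_negative - r_positive; larger => class 1
    coefficients: SparseCoefficients | None = None


def gaussian_weights(y: np.ndarray, X: np.ndarray, sigma: float) -> np.ndarray:
    """Gaussian similarity between y and every column of X.

    w_i = exp(-||y - x_i||^2 / (2 sigma^2)), in (0, 1], equal to 1 exactly
    when y coincides with the column.
    """
    if sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    y = np.asarray(y, dtype=float).ravel()
    X = np.asarray(X, dtype=float)
    if X.shape[0] != y.shape[0]:
        raise ValueError(
            f"dimension mismatch: y has {y.shape[0]} features, "
            f"X columns have {X.shape[0]}"
        )
    sq = np.sum((X - y[:, None]) ** 2, axis=0)
    return np.exp(-sq / (2.0 * sigma**2))


def _effective_weights(weights: np.ndarray) -> np.ndarray:
    """Scale weights to max 1 and clamp at the relative floor.

    The weighted l1 solution is invariant to a common scaling of the
    weights, so only the clamping can alter it, and it only binds for
    columns whose similarity is < WEIGHT_FLOOR of the best one.
    """
    w = np.asarray(weights, dtype=float).copy()
    if np.any(w < 0):
        raise ValueError("weights must be non-negative")
    top = w.max()
    if top <= 0:
        return np.ones_like(w)
    w /= top
    return np.clip(w, WEIGHT_FLOOR, None)


def solve_weighted_l1(
    X: np.ndarray,
    y: np.ndarray,
    weights: np.ndarray,
    epsilon: float,
    on_infeasible: str = "raise",
    solver_tol: float = 1e-8,
    max_bisect: int = 50,
    max_iter: int = 20_000,
    fallback_penalty: float = 1e-4,
) -> SparseCoefficients:
    """Solve min ||W a||_1 s.t. ||y - X a|| <= eps (columns of X = samples).

    The weight substitution b = W a turns the problem into a plain l1
    minimization over X W^{-1}; that is solved through its penalized lasso
    form, bisecting on the penalty (at most ``max_bisect`` steps) for the
    largest penalty whose residual still meets eps — the point where the
    lasso path and the constrained optimum coincide.

    on_infeasible: "raise" (InfeasibleEpsilonError) or "fallback" (return
    the penalized solution at ``fallback_penalty`` times the zero-solution
    penalty, with a warning).  The fallback is the usual path on real
    data, where y lies outside the span of the training columns and the
    eps constraint cannot be met by any coefficient vector.
    """
    if epsilon <= 0:
        raise ValueError(f"epsilon must be positive, got {epsilon}")
    if on_infeasible not in ("raise", "fallback"):
        raise ValueError("on_infeasible must be 'raise' or 'fallback'")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    m, n = X.shape
    if y.shape[0] != m:
        raise ValueError(f"y has {y.shape[0]} entries, X has {m} rows")
    if len(weights) != n:
        raise ValueError("one weight per training column is required")
    w = _effective_weights(weights)

    # Trivial feasibility: the zero vector already satisfies the constraint.
    ynorm = float(np.linalg.norm(y))
    if ynorm <= epsilon:
        return SparseCoefficients(
            alpha=np.zeros(n), residual=ynorm, objective=0.0,
            feasible=True, penalty=np.inf,
        )

    Xt = X / w  # column i scaled by 1/w_i; b = w * a

    # Best attainable residual within the column span.
    beta_ls, *_ = np.linalg.lstsq(Xt, y, rcond=None)
    r_min = float(np.linalg.norm(y - Xt @ beta_ls))
    slack = solver_tol * max(1.0, ynorm)
    infeasible = r_min > epsilon + slack

    lasso = Lasso(
        alpha=1.0, fit_intercept=False, warm_start=True,
        max_iter=max_iter, tol=solver_tol, precompute=True,
    )

    def solve_at(lam: float) -> tuple[np.ndarray, float]:
        lasso.set_params(alpha=max(lam, np.finfo(float).tiny))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # convergence chatter at tiny lam
            lasso.fit(Xt, y)
        beta = lasso.coef_.copy()
        return beta, float(np.linalg.norm(y - Xt @ beta))

    def polish(beta: np.ndarray) -> tuple[np.ndarray, float]:
        """Debias: refit the support by least squares, keeping sparsity.

        Coordinate descent stops on a duality-gap tolerance that cannot
        push the residual down to a tiny eps at large data scales; the
        support it finds is reliable much earlier than the coefficients.
        """
        support = np.flatnonzero(beta)
        if support.size == 0:
            return beta, float(np.linalg.norm(y))
        out = np.zeros_like(beta)
        sol, *_ = np.linalg.lstsq(Xt[:, support], y, rcond=None)
        out[support] = sol
        return out, float(np.linalg.norm(y - Xt @ out))

    # sklearn's lasso objective is (1/2m)||y - Xt b||^2 + lam ||b||_1;
    # above lam_max the solution is identically zero.
    lam_max = float(np.max(np.abs(Xt.T @ y))) / m

    if infeasible:
        if on_infeasible == "raise":
            raise InfeasibleEpsilonError(epsilon, r_min)
        lam_fb = lam_max * fallback_penalty
        beta, res = solve_at(lam_fb)
        alpha = beta / w
        warnings.warn(
            f"epsilon={epsilon:g} infeasible (best residual {r_min:g}); "
            "using minimum-residual penalized solution",
            stacklevel=2,
        )
        return SparseCoefficients(
            alpha=alpha, residual=res,
            objective=float(np.sum(w * np.abs(alpha))),
            feasible=False, fallback=True, penalty=lam_fb,
        )

    # Bisection for the largest penalty that still meets the constraint.
    # The smallest probed penalty shrinks adaptively until the penalized
    # solve actually attains the constraint the least-squares check
    # promised is attainable.
    def weighted_l1(beta: np.ndarray) -> float:
        # beta is in substituted coordinates: ||W alpha||_1 == ||beta||_1
        return float(np.sum(np.abs(beta)))

    best: list = [None]

    def consider(beta: np.ndarray, res: float, lam: float) -> None:
        if res <= epsilon + slack:
            obj = weighted_l1(beta)
            if best[0] is None or obj < best[0][0]:
                best[0] = (obj, beta, res, lam)

    lam_lo = lam_max * 1e-8
    beta, res0 = solve_at(lam_lo)
    consider(beta, res0, lam_lo)
    if res0 > epsilon + slack:
        # Coordinate descent cannot certify a tiny eps at large data
        # scales; repair by least squares on its support, else the dense
        # least-squares point (feasible here by the r_min check).
        consider(*polish(beta), lam_lo)
        consider(beta_ls, r_min, lam_lo)
    # Bisection on the raw penalized-path residual, which is monotone in
    # the penalty; polished points enter only as solution candidates,
    # never as bracketing decisions.
    lo, hi = lam_lo, lam_max
    for _ in range(max_bisect):
        mid = 0.5 * (lo + hi)
        beta, res = solve_at(mid)
        consider(beta, res, mid)
        if res <= epsilon + slack:
            lo = mid
        else:
            consider(*polish(beta), mid)
            hi = mid
    objective, best_beta, best_res, best_lam = best[0]
    alpha = best_beta / w
    return SparseCoefficients(
        alpha=alpha, residual=best_res,
        objective=objective,
        feasible=True, penalty=best_lam,
    )


def class_residuals(
    X: np.ndarray,
    labels: np.ndarray,
    alpha: np.ndarray,
    y: np.ndarray,
    classes: Sequence[int] | None = None,
) -> dict[int, float]:
    """Per-class reconstruction residuals r_c = ||y - X d_c(alpha)||."""
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    alpha = np.asarray(alpha, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if alpha.shape[0] != X.shape[1]:
        raise ValueError("alpha length must match number of training columns")
    if classes is None:
        classes = np.unique(labels)
    out: dict[int, float] = {}
    for c in classes:
        mask = labels == c
        recon = X[:, mask] @ alpha[mask]
        out[int(c)] = float(np.linalg.norm(y - recon))
    return out


class WSRC:
    """Weighted sparse representation classifier (scikit-learn style).

    Parameters
    ----------
    sigma : Gaussian kernel width of the locality weights (default 1.5).
    epsilon : reconstruction-error tolerance of the stable l1 problem
        (default 5e-5).
    weight_mode : "inverse_similarity" (default) penalizes each training
        column by the reciprocal of its Gaussian similarity to the test
        sample, so distant samples are the expensive ones and the
        reconstruction prefers near neighbours — the locality behaviour
        the weighting exists for.  "similarity" places the similarities
        themselves on the penalty diagonal; this is the literal form of
        the weighting rule as usually printed, but it penalizes *near*
        samples more and degrades toward unweighted SRC whenever the
        similarities underflow.
    normalize_columns : scale every training column to unit l2 norm
        (off by default; common in the sparse-representation literature).
    solver_tol : duality-gap tolerance of the inner coordinate-descent
        solve.  The prediction default (1e-4) is loose: classification
        only compares per-class residuals, whose differences are orders
        of magnitude above the solve error; pass a tighter value when the
        coefficients themselves are of interest.
    penalty : relative strength (fraction of the smallest penalty that
        zeroes all coefficients) of the weighted-lasso solve used for
        prediction.  Classification residuals are computed from this
        penalized locality-weighted reconstruction rather than from the
        eps-constrained solution: global-encoding pair vectors satisfy
        exact linear constraints (the two composition entries of every
        block sum to 1, and all ten mode compositions are linear in six
        class fractions), so once the training set outgrows that subspace
        dimension a near-exact reconstruction (eps = 5e-5) exists but is
        dense and class-mixed, and its residuals carry no class signal.
        The penalized solution stays sparse and local; predictions are
        insensitive to this parameter over several orders of magnitude.
    """

    def __init__(
        self,
        sigma: float = 1.5,
        epsilon: float = 5e-5,
        weight_mode: str = "inverse_similarity",
        normalize_columns: bool = False,
        solver_tol: float = 1e-4,
        max_bisect: int = 50,
        penalty: float = 1e-3,
    ):
        if sigma <= 0 or epsilon <= 0:
            raise ValueError("sigma and epsilon must be positive")
        if weight_mode not in WEIGHT_MODES:
            raise ValueError(f"weight_mode must be one of {WEIGHT_MODES}")
        if penalty <= 0:
            raise ValueError("penalty must be positive")
        self.sigma = sigma
        self.epsilon = epsilon
        self.weight_mode = weight_mode
        self.normalize_columns = normalize_columns
        self.solver_tol = solver_tol
        self.max_bisect = max_bisect
        self.penalty = penalty

    # -- fitting ---------------------------------------------------------

    def fit(self, X: np.ndarray, y: Sequence[int]) -> "WSRC":
        """Store the training set (rows = samples) as the dictionary.

        WSRC is instance based: fitting validates and stores the samples as
        the columns of the reconstruction dictionary.
        """
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        if X.ndim != 2 or X.shape[0] != y.shape[0]:
            raise ValueError("X must be 2-D with one label per row")
        classes, counts = np.unique(y, return_counts=True)
        if classes.size < 2:
            raise ValueError("training data must contain at least 2 classes")
        self.classes_ = classes
        self.X_ = X.T.copy()  # columns are samples
        if self.normalize_columns:
            norms = np.linalg.norm(self.X_, axis=0)
            norms[norms == 0] = 1.0
            self.X_ /= norms
        self.labels_ = y.copy()
        return self

    def _check_fitted(self) -> None:
        if not hasattr(self, "X_"):
            raise RuntimeError("this WSRC instance is not fitted yet")

    # -- prediction ------------------------------------------------------

    def predict_one(self, y_vec: np.ndarray) -> PredictionResult:
        """Classify a single feature vector; returns the full result."""
        self._check_fitted()
        y_vec = np.asarray(y_vec, dtype=float).ravel()
        if self.weight_mode == "similarity":
            w = gaussian_weights(y_vec, self.X_, self.sigma)
        else:
            # Locality weighting: the l1 penalty of a training column grows
            # with its Gaussian distance from y (reciprocal similarities),
            # so near samples are the cheap ones.  Exponents are taken
            # relative to the nearest column and capped so the penalty
            # ratio stays within the conditioning limit.
            sq = np.sum((self.X_ - y_vec[:, None]) ** 2, axis=0)
            expo = (sq - sq.min()) / (2.0 * self.sigma**2)
            w = np.exp(np.minimum(expo, -np.log(WEIGHT_FLOOR)))
        coef = self._penalized_solve(y_vec, w)
        residuals = class_residuals(
            self.X_, self.labels_, coef.alpha, y_vec, classes=self.classes_
        )
        # argmin residual; ties go to the lowest class index
        predicted = min(residuals, key=lambda c: (residuals[c], c))
        score = self._score_from_residuals(residuals)
        return PredictionResult(
            predicted_class=predicted, residuals=residuals,
            score=score, coefficients=coef,
        )

    def _penalized_solve(self, y_vec: np.ndarray, weights: np.ndarray) -> SparseCoefficients:
        """Weighted lasso at the fixed relative penalty (see ``penalty``)."""
        w = _effective_weights(weights)
        Xt = self.X_ / w
        m = y_vec.shape[0]
        lam_max = float(np.max(np.abs(Xt.T @ y_vec))) / m
        if lam_max == 0.0:
            return SparseCoefficients(
                alpha=np.zeros(Xt.shape[1]),
                residual=float(np.linalg.norm(y_vec)),
                objective=0.0, feasible=False, penalty=0.0,
            )
        lam = lam_max * self.penalty
        lasso = Lasso(
            alpha=lam, fit_intercept=False, precompute=True,
            max_iter=20_000, tol=self.solver_tol,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            lasso.fit(Xt, y_vec)
        alpha = lasso.coef_ / w
        res = float(np.linalg.norm(y_vec - self.X_ @ alpha))
        return SparseCoefficients(
            alpha=alpha, residual=res,
            objective=float(np.sum(w * np.abs(alpha))),
            feasible=res <= self.epsilon, penalty=lam,
        )

    def _score_from_residuals(self, residuals: dict[int, float]) -> float:
        """Residual margin r_0 - r_1 for the binary task; otherwise the
        negated minimum residual (a generic confidence)."""
        if set(residuals) == {0, 1}:
            return residuals[0] - residuals[1]
        return -min(residuals.values())

    def predict_batch(self, Y: np.ndarray) -> list[PredictionResult]:
        """Classify each row of Y; order preserved, samples independent."""
        Y = np.asarray(Y, dtype=float)
        if Y.size == 0:
            return []
        if Y.ndim != 2:
            raise ValueError("Y must be 2-D (rows = samples)")
        return [self.predict_one(row) for row in Y]

    def predict(self, Y: np.ndarray) -> np.ndarray:
        """Predicted class label per row of Y."""
        return np.array([r.predicted_class for r in self.predict_batch(Y)])

    def decision_function(self, Y: np.ndarray) -> np.ndarray:
        """Continuous score per row (larger => more likely class 1)."""
        return np.array([r.score for r in self.predict_batch(Y)])

    # -- persistence -----------------------------------------------------

    def save(self, directory: str | Path) -> None:
        """Persist as a flat archive: features CSV, labels CSV, JSON params."""
        self._check_fitted()
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        seq_io.write_feature_matrix(self.X_.T, d / "train_features.csv")
        np.savetxt(d / "train_labels.csv", self.labels_, fmt="%d")
        params = {
            "sigma": self.sigma, "epsilon": self.epsilon,
            "weight_mode": self.weight_mode,
            "normalize_columns": self.normalize_columns,
            "solver_tol": self.solver_tol, "max_bisect": self.max_bisect,
            "penalty": self.penalty,
        }
        (d / "hyperparameters.json").write_text(json.dumps(params, indent=2))

    @classmethod
    def load(cls, directory: str | Path) -> "WSRC":
        d = Path(directory)
        params = json.loads((d / "hyperparameters.json").read_text())
        model = cls(**params)
        X, _ = seq_io.read_feature_matrix(d / "train_features.csv")
        labels = np.loadtxt(d / "train_labels.csv", dtype=int, ndmin=1)
        # bypass normalize_columns re-application: saved X_ is post-scaling
        norm = model.normalize_columns
        model.normalize_columns = False
        model.fit(X, labels)
        model.normalize_columns = norm
        return model
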