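"""Gaussian graphical model estimation: regularized partial correlations.

The network is the standardized negated inverse of the correlation matrix.
Sparsity comes from the graphical lasso: the L1-penalized precision matrix
is estimated over a log-spaced path of penalty values, and the extended
Bayesian information criterion

    EBIC = -2 l(Theta) + E log n + 4 gamma E log p,
    l(Theta) = (n/2) (log det Theta - tr(S Theta))    (constant dropped)

selects the model, where E is the number of nonzero upper-triangle partial
correlations.  gamma = 0 recovers BIC; larger gamma prefers sparser graphs.
The solver is scikit-learn's coordinate-descent graphical lasso.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.covariance import graphical_lasso as _sk_glasso
from sklearn.exceptions import ConvergenceWarning

from .corr import LabeledCorrelationMatrix
from .exceptions import EstimationError

EDGE_EPS = 1e-8  # |partial| below this counts as a structural zero


@dataclass(frozen=True)
class EstimationSettings:
    """Hyperparameters of the regularization path and model selection.

    gamma : EBIC sparsity hyperparameter (>= 0); 0.50 by default.
    n_lambda : number of penalty values on the path (default 100).
    lambda_min_ratio : smallest penalty as a fraction of lambda_max, the
        largest absolute off-diagonal correlation (default 0.01).
    tol, max_iter : coordinate-descent stopping rule.  The defaults are
        loose enough to keep bootstrap runs fast; they reproduce the edge
        sets of much tighter settings on problems of this size.
    """

    gamma: float = 0.50
    n_lambda: int = 100
    lambda_min_ratio: float = 0.01
    tol: float = 1e-3
    max_iter: int = 50

    def __post_init__(self) -> None:
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")
        if self.n_lambda < 2:
            raise ValueError("n_lambda must be >= 2")
        if not 0 < self.lambda_min_ratio < 1:
            raise ValueError("lambda_min_ratio must be in (0, 1)")

    def lambda_grid(self, lambda_max: float) -> np.ndarray:
        """Log-spaced path from lambda_max down to lambda_max * ratio."""
        return np.exp(
            np.linspace(
                np.log(lambda_max),
                np.log(lambda_max * self.lambda_min_ratio),
                self.n_lambda,
            )
        )


@dataclass(frozen=True)
class GgmNetwork:
    """A regularized partial-correlation network.

    ``weights`` holds signed partial correlations with an exactly zero
    diagonal; ``lam``/``gamma``/``ebic`` record the penalty, EBIC
    hyperparameter and criterion value of the selected model (NaN for
    networks not produced by model selection, e.g. bootstrap medians).
    """

    labels: tuple[str, ...]
    weights: np.ndarray = field(repr=False)
    lam: float = float("nan")
    gamma: float = float("nan")
    ebic: float = float("nan")
    precision: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if np.max(np.abs(w - w.T)) > 1e-8:
            raise ValueError("network weights must be symmetric")
        w = (w + w.T) / 2.0
        np.fill_diagonal(w, 0.0)
        if np.any(np.abs(w) >= 1.0):
            raise ValueError("partial correlations must lie strictly inside (-1, 1)")
        w.setflags(write=False)
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "labels", tuple(str(x) for x in self.labels))

    @property
    def p(self) -> int:
        return self.weights.shape[0]

    @property
    def edge_count(self) -> int:
        iu = np.triu_indices(self.p, 1)
        return int(np.sum(np.abs(self.weights[iu]) > EDGE_EPS))

    def edge_list(self) -> pd.DataFrame:
        """Nonzero edges as a (node_a, node_b, weight) table."""
        rows = []
        for i in range(self.p):
            for j in range(i + 1, self.p):
                if abs(self.weights[i, j]) > EDGE_EPS:
                    rows.append((self.labels[i], self.labels[j], self.weights[i, j]))
        return pd.DataFrame(rows, columns=["node_a", "node_b", "weight"])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.weights, index=list(self.labels), columns=list(self.labels))

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, float_format="%.15g")


def _precision_to_partials(theta: np.ndarray) -> np.ndarray:
    d = np.sqrt(np.diag(theta))
    rho = -theta / np.outer(d, d)
    np.fill_diagonal(rho, 0.0)
    return (rho + rho.T) / 2.0


def partial_correlations(corr: LabeledCorrelationMatrix) -> np.ndarray:
    """Unregularized partial correlations from the precision matrix.

    rho_ij = -theta_ij / sqrt(theta_ii theta_jj) with Theta = Sigma^-1;
    the diagonal is set to zero by convention.
    """
    vals = corr.values
    w = np.linalg.eigvalsh(vals)
    if w.min() <= 1e-10:
        raise EstimationError(
            f"correlation matrix is numerically singular "
            f"(smallest eigenvalue {w.min():.3e}); repair or regularize first"
        )
    theta = np.linalg.inv(vals)
    return _precision_to_partials(theta)


def glasso_fit(
    corr: LabeledCorrelationMatrix,
    lam: float,
    settings: EstimationSettings | None = None,
) -> GgmNetwork:
    """L1-penalized precision estimate at a single penalty value.

    Returns the network of regularized partial correlations; the EBIC field
    is filled when the matrix carries a sample size.  At lam = 0 this is the
    (unpenalized) maximum-likelihood fit.
    """
    if lam < 0:
        raise ValueError("penalty lambda must be >= 0")
    settings = settings or EstimationSettings()
    try:
        with warnings.catch_warnings():
            # Small-lambda fits routinely stop at max_iter with a tiny dual
            # gap; those models are dense and never win EBIC selection.
            warnings.simplefilter("ignore", ConvergenceWarning)
            _, theta = _sk_glasso(
                np.array(corr.values),
                alpha=float(lam),
                tol=settings.tol,
                max_iter=settings.max_iter,
            )
    except FloatingPointError as exc:  # pragma: no cover - solver blowup
        raise EstimationError(f"graphical lasso failed at lambda={lam:.6g}: {exc}") from exc
    if not np.all(np.isfinite(theta)):
        raise EstimationError(f"graphical lasso returned non-finite precision at lambda={lam:.6g}")
    weights = _precision_to_partials(theta)
    # exact zeros below solver resolution
    weights[np.abs(weights) < EDGE_EPS] = 0.0
    net = GgmNetwork(corr.labels, weights, lam=float(lam), gamma=settings.gamma,
                     precision=theta)
    if corr.n is not None:
        net = GgmNetwork(corr.labels, weights, lam=float(lam), gamma=settings.gamma,
                         ebic=ebic_score(net, corr, settings.gamma), precision=theta)
    return net


def ebic_score(
    network: GgmNetwork,
    corr: LabeledCorrelationMatrix,
    gamma: float | None = None,
) -> float:
    """Extended BIC of a fitted precision matrix against the sample matrix.

    Uses the Gaussian log-likelihood (n/2)(log det Theta - tr(S Theta)); the
    additive constant -(n/2) p log(2 pi) is identical across candidate
    models and dropped.
    """
    n = corr.require_n()
    if network.precision is None:
        raise EstimationError("network carries no precision matrix; refit with glasso_fit")
    theta = network.precision
    gamma = network.gamma if gamma is None else gamma
    sign, logdet = np.linalg.slogdet(theta)
    if sign <= 0:
        raise EstimationError("precision matrix is not positive definite")
    ll = (n / 2.0) * (logdet - float(np.sum(corr.values * theta)))
    e = network.edge_count
    p = network.p
    return float(-2.0 * ll + e * np.log(n) + 4.0 * gamma * e * np.log(p))


def estimate_network(
    corr: LabeledCorrelationMatrix,
    settings: EstimationSettings | None = None,
) -> GgmNetwork:
    """EBIC-selected graphical lasso network over the penalty path.

    Fits ``settings.n_lambda`` penalties log-spaced from lambda_max (the
    largest absolute off-diagonal correlation) down to
    lambda_max * lambda_min_ratio and returns the minimum-EBIC model.  Ties
    are broken toward the sparser model (larger penalty).  Inputs that are
    not positive definite are repaired by eigenvalue clipping first.
    """
    settings = settings or EstimationSettings()
    corr.require_n()
    if corr.p < 3:
        raise EstimationError(f"network estimation needs p >= 3 variables, got p={corr.p}")
    corr = corr.repaired()
    lambda_max = float(np.max(np.abs(corr.values - np.eye(corr.p))))
    if lambda_max <= EDGE_EPS:
        # no dependence at all: the empty network, fitted unpenalized
        return glasso_fit(corr, 0.0, settings)
    best: GgmNetwork | None = None
    failures: list[str] = []
    for lam in settings.lambda_grid(lambda_max):
        try:
            net = glasso_fit(corr, float(lam), settings)
        except EstimationError as exc:
            failures.append(str(exc))
            continue
        # strict inequality: earlier (larger) lambda wins ties -> sparser
        if best is None or net.ebic < best.ebic - 1e-12:
            best = net
    if best is None:
        raise EstimationError(
            "every fit along the regularization path failed: " + "; ".join(failures[:3])
        )
    return best
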