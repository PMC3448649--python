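"""Raw edge weights from per-pair polynomial regression and correlation.

The network inference problem over ``n`` genes is decomposed into n(n-1)
single-regressor problems: the steady-state level of a target gene is
predicted from the level of one candidate regulator at a time, via a
polynomial (Taylor-expansion) least-squares fit of order 1 or 3.  Two
complementary quantities score each ordered pair:

* the sum of squared residuals SSR of the fit — the smaller, the more of
  the target's variation the candidate explains;
* the Pearson correlation r — the larger |r|, the more defensible the
  linear-regression treatment of the pair.

Both are combined into a single nonnegative weight

    w = (|r| * SST / max(SSR, floor * SST)) ** c

which is strictly decreasing in SSR, strictly increasing in |r|, invariant
under rescaling of either gene (SST/SSR is a ratio), and indifferent to
the sign of the correlation (activation and repression both count as
regulation).  The exponent ``c`` sharpens the ranking; c = 4 with a
third-order fit is the variant used for heterogeneous compendia such as
DREAM5, and leaves every within-target ranking unchanged because it is a
monotone transform.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Sequence

import numpy as np

from .data_io import ExpressionData
from .errors import (
    DegenerateRegressorError,
    UndefinedCorrelationError,
    UnderdeterminedFitError,
)

__all__ = [
    "RegressionFit",
    "WeightConfig",
    "polynomial_design",
    "least_squares_fit",
    "pearson",
    "pairwise_weight",
    "weight_matrix",
]

logger = logging.getLogger(__name__)

#: designs with condition number above this are treated as rank-deficient
_COND_LIMIT = 1e10


@dataclasses.dataclass(frozen=True)
class RegressionFit:
    """Result of an intercept-including least-squares fit.

    ``ssr`` is the sum of squared residuals, ``sst`` the sum of squared
    deviations of the response about its mean; with an intercept in the
    design, ``ssr <= sst`` up to rounding.  ``dof_model`` counts the
    non-intercept regressor columns actually identified by the fit.
    """

    coefficients: np.ndarray
    ssr: float
    sst: float
    dof_model: int


@dataclasses.dataclass(frozen=True)
class WeightConfig:
    """Tunable parameters of the pairwise weight construction.

    taylor_order:
        Order of the per-pair polynomial fit; 1 (default) or 3.  A
        fourth-order fit makes the normal equations ill-conditioned on
        expression data and is not supported.
    exponent_c:
        Ranking-sharpening exponent, >= 1.  Default 1; 4 is the variant
        used for real compendia.
    ssr_floor:
        Relative floor on SSR (as a fraction of SST) so that exactly
        collinear pairs get a large finite weight instead of infinity.
    candidate_regulators:
        Optional restriction of regulator rows, e.g. a transcription-factor
        list; ``None`` means every gene may regulate.
    """

    taylor_order: int = 1
    exponent_c: float = 1.0
    ssr_floor: float = 1e-12
    candidate_regulators: Sequence[int] | None = None

    def __post_init__(self) -> None:
        if self.taylor_order not in (1, 3):
            raise ValueError("taylor_order must be 1 or 3")
        if self.exponent_c < 1:
            raise ValueError("exponent_c must be >= 1")
        if self.ssr_floor <= 0:
            raise ValueError("ssr_floor must be positive")


def polynomial_design(x: np.ndarray, order: int) -> np.ndarray:
    """Design matrix ``[1, x, x**2, ..., x**order]`` for a polynomial fit.

    Requires at least ``order + 2`` observations so the fit has a residual
    degree of freedom.
    """
    x = np.asarray(x, dtype=float).ravel()
    if x.size <= order + 1:
        raise UnderdeterminedFitError(
            f"underdetermined fit: {x.size} observations for order {order}"
        )
    return np.vander(x, N=order + 1, increasing=True)


def least_squares_fit(X: np.ndarray, y: np.ndarray) -> RegressionFit:
    """Ordinary least squares of ``y`` on design ``X`` (intercept included in X).

    Raises DegenerateRegressorError when the design is (near-)singular,
    e.g. a constant regressor duplicating the intercept column.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.shape[0] != y.size:
        raise ValueError("design and response lengths differ")
    if np.linalg.matrix_rank(X, tol=None) < X.shape[1] or np.linalg.cond(X) > _COND_LIMIT:
        raise DegenerateRegressorError("degenerate regressor: design is near rank-deficient")
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    ssr = float(resid @ resid)
    dev = y - y.mean()
    sst = float(dev @ dev)
    return RegressionFit(coefficients=beta, ssr=ssr, sst=sst, dof_model=X.shape[1] - 1)


def pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Product-moment correlation coefficient in [-1, 1].

    Raises UndefinedCorrelationError when either input is constant.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size or x.size < 2:
        raise ValueError("inputs must have equal length >= 2")
    xd, yd = x - x.mean(), y - y.mean()
    sx, sy = float(xd @ xd), float(yd @ yd)
    if sx == 0.0 or sy == 0.0:
        raise UndefinedCorrelationError("undefined correlation: zero-variance input")
    r = float((xd @ yd) / np.sqrt(sx * sy))
    return min(1.0, max(-1.0, r))


def pairwise_weight(
    x_regulator: np.ndarray, y_target: np.ndarray, cfg: WeightConfig = WeightConfig()
) -> float:
    """Confidence weight for the directed regulation x_regulator -> y_target.

    Degenerate pairs (constant regulator or target, near-singular design)
    carry no evidence and score 0.
    """
    try:
        X = polynomial_design(x_regulator, cfg.taylor_order)
        fit = least_squares_fit(X, np.asarray(y_target, dtype=float))
        r = pearson(x_regulator, y_target)
    except (DegenerateRegressorError, UndefinedCorrelationError):
        return 0.0
    if fit.sst == 0.0:  # constant target; pearson above already rejects this
        return 0.0
    ssr = max(fit.ssr, cfg.ssr_floor * fit.sst)
    return float((abs(r) * fit.sst / ssr) ** cfg.exponent_c)


def weight_matrix(data: ExpressionData, cfg: WeightConfig = WeightConfig()) -> np.ndarray:
    """Raw n-by-n weight matrix; entry (j, i) scores the regulation j -> i.

    The diagonal is zero (no auto-regulation) and rows outside
    ``cfg.candidate_regulators`` (when given) are zero.  Per-pair
    degeneracies become zero entries; their count is logged.
    """
    n = data.n
    if data.m <= cfg.taylor_order + 1:
        raise UnderdeterminedFitError(
            f"underdetermined fit: m={data.m} experiments for order {cfg.taylor_order}"
        )
    if cfg.candidate_regulators is None:
        regulators = range(n)
    else:
        regulators = sorted(set(int(j) for j in cfg.candidate_regulators))
        if regulators and not (0 <= regulators[0] and regulators[-1] < n):
            raise ValueError("candidate regulator index out of range")
    W = np.zeros((n, n))
    degenerate = 0
    for j in regulators:
        xj = data.column(j)
        for i in range(n):
            if i == j:
                continue
            w = pairwise_weight(xj, data.column(i), cfg)
            if w == 0.0:
                degenerate += 1
            W[j, i] = w
    if degenerate:
        logger.info("weight_matrix: %d gene pairs scored zero (degenerate or r = 0)", degenerate)
    return W
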