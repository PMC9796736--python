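"""Item response functions, item-parameter priors, and shared containers.

The package works with binary logistic item response models in the
slope--intercept parameterization,

    P(Y_ij = 1 | theta_i) = c_j + (1 - c_j) / (1 + exp(-(a_j * theta_i + d_j))),

where ``a_j > 0`` is a discrimination (slope), ``d_j`` an easiness
(intercept, in logits) and ``c_j`` in [0, 1) a pseudo-guessing lower
asymptote.  The 2PL model is the ``c_j = 0`` restriction.  No conversion to
the difficulty parameterization ``a (theta - b)`` is exposed anywhere.

All modules stack item parameters item-major: ``(a_1, d_1[, c_1], a_2, ...)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

ModelTag = Literal["2PL", "3PL"]

__all__ = [
    "ItemParameters",
    "DIFDeltas",
    "PriorSpec",
    "GroupParameters",
    "response_probability",
    "log_prior_density",
    "log_prior_gradient",
    "stack_parameters",
    "unstack_parameters",
    "n_item_parameters",
]


class InvalidParameterError(ValueError):
    """Raised when item parameters leave their admissible region."""


class BoundaryError(ValueError):
    """Raised when a parameter sits on the boundary of its prior support."""


@dataclass(frozen=True)
class ItemParameters:
    """Natural-scale parameters of one logistic item.

    Attributes
    ----------
    slope : float
        Discrimination ``a_j``; must be positive.
    intercept : float
        Easiness ``d_j`` in logit units.
    guess : float
        Pseudo-guessing ``c_j`` in ``[0, 1)``; identically 0 under the 2PL
        tag and then excluded from the stacked parameter vector.
    model : {"2PL", "3PL"}
    """

    slope: float
    intercept: float
    guess: float = 0.0
    model: ModelTag = "2PL"

    def __post_init__(self) -> None:
        if not np.isfinite(self.slope) or self.slope <= 0:
            raise InvalidParameterError(f"slope must be > 0, got {self.slope}")
        if not (0.0 <= self.guess < 1.0):
            raise InvalidParameterError(f"guess must lie in [0, 1), got {self.guess}")
        if self.model == "2PL" and self.guess != 0.0:
            raise InvalidParameterError("2PL items must have guess == 0")

    @property
    def n_params(self) -> int:
        return 2 if self.model == "2PL" else 3


@dataclass(frozen=True)
class DIFDeltas:
    """Additive parameter shifts used only when *generating* data.

    A delta moves the item parameters of the focal subpopulation; fitting
    never sees these shifts.
    """

    slope: float = 0.0
    intercept: float = 0.0
    guess: float = 0.0

    @staticmethod
    def zero() -> "DIFDeltas":
        return DIFDeltas()


@dataclass(frozen=True)
class GroupParameters:
    """Ability distribution N(mean, var) of one person group.

    The reference group is fixed at (0, 1) for identification; only the
    non-reference groups' parameters are estimated.
    """

    mean: float = 0.0
    var: float = 1.0
    reference: bool = False

    def __post_init__(self) -> None:
        if self.var <= 0:
            raise InvalidParameterError(f"group variance must be > 0, got {self.var}")


# --------------------------------------------------------------------------
# Priors
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PriorSpec:
    """Independent per-parameter-class priors for MAP estimation.

    ``slope_dist`` is either ``"lognormal"`` (parameters are the mean and
    **variance** on the log scale) or ``"normal"`` (mean and **variance** on
    the natural scale).  The intercept prior is normal (mean, variance); the
    guessing prior is Beta(alpha, beta).

    Two named presets cover the configurations used in the simulation study:

    * ``agreeing`` -- slope LN(0, 0.0625), intercept N(0, 1), guess
      Beta(5, 45) by default (matching the generating distribution; pass
      ``guess=(4, 45)`` for the alternative elicitation).
    * ``non_informative`` -- slope N(1, 10), intercept N(0, 10), guess
      Beta(1, 1) (flat).
    """

    slope_dist: Literal["lognormal", "normal"]
    slope_params: tuple[float, float]  # (mu, variance) on the relevant scale
    intercept_params: tuple[float, float]  # (mu, variance)
    guess_params: tuple[float, float] = (1.0, 1.0)  # Beta(alpha, beta)
    name: str = "custom"

    def __post_init__(self) -> None:
        if self.slope_params[1] <= 0 or self.intercept_params[1] <= 0:
            raise InvalidParameterError("prior variances must be > 0")
        if self.guess_params[0] <= 0 or self.guess_params[1] <= 0:
            raise InvalidParameterError("beta prior parameters must be > 0")

    @staticmethod
    def agreeing(guess: tuple[float, float] = (5.0, 45.0)) -> "PriorSpec":
        return PriorSpec("lognormal", (0.0, 0.0625), (0.0, 1.0), guess, "agreeing")

    @staticmethod
    def non_informative() -> "PriorSpec":
        return PriorSpec("normal", (1.0, 10.0), (0.0, 10.0), (1.0, 1.0), "non_informative")

    @staticmethod
    def from_name(name: str) -> "PriorSpec":
        if name == "agreeing":
            return PriorSpec.agreeing()
        if name == "non_informative":
            return PriorSpec.non_informative()
        raise KeyError(f"unknown prior preset {name!r}")

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "slope_dist": self.slope_dist,
            "slope_params": list(self.slope_params),
            "intercept_params": list(self.intercept_params),
            "guess_params": list(self.guess_params),
        }

    @staticmethod
    def from_dict(d: dict) -> "PriorSpec":
        return PriorSpec(
            d["slope_dist"],
            tuple(d["slope_params"]),
            tuple(d["intercept_params"]),
            tuple(d.get("guess_params", (1.0, 1.0))),
            d.get("name", "custom"),
        )


# --------------------------------------------------------------------------
# Response function
# --------------------------------------------------------------------------

def response_probability(
    theta,
    params: ItemParameters,
    deltas: DIFDeltas | None = None,
):
    """Probability of a correct response under the (possibly shifted) item.

    Evaluates ``(c+Dc) + (1-c-Dc) * logistic((a+Da)*theta + (d+Dd))``; deltas
    default to zero.  Vectorized over ``theta``.
    """
    if deltas is None:
        deltas = DIFDeltas.zero()
    a = params.slope + deltas.slope
    d = params.intercept + deltas.intercept
    c = params.guess + deltas.guess
    if a <= 0:
        raise InvalidParameterError(f"shifted slope must be > 0, got {a}")
    if not (0.0 <= c < 1.0):
        raise InvalidParameterError(f"shifted guess must lie in [0, 1), got {c}")
    theta = np.asarray(theta, dtype=float)
    with np.errstate(over="ignore"):
        p = c + (1.0 - c) / (1.0 + np.exp(-(a * theta + d)))
    return p if p.ndim else float(p)


# --------------------------------------------------------------------------
# Parameter stacking
# --------------------------------------------------------------------------

def n_item_parameters(model: ModelTag, n_items: int) -> int:
    return (2 if model == "2PL" else 3) * n_items


def stack_parameters(items: Sequence[ItemParameters]) -> np.ndarray:
    """Flatten item parameters item-major: (a_1, d_1[, c_1], a_2, ...)."""
    out: list[float] = []
    for it in items:
        out.extend([it.slope, it.intercept])
        if it.model == "3PL":
            out.append(it.guess)
    return np.asarray(out, dtype=float)


def unstack_parameters(vec: np.ndarray, model: ModelTag) -> list[ItemParameters]:
    per = 2 if model == "2PL" else 3
    vec = np.asarray(vec, dtype=float)
    if vec.size % per:
        raise ValueError(f"length {vec.size} not divisible by {per}")
    items = []
    for j in range(vec.size // per):
        chunk = vec[j * per : (j + 1) * per]
        if model == "2PL":
            items.append(ItemParameters(chunk[0], chunk[1], 0.0, "2PL"))
        else:
            items.append(ItemParameters(chunk[0], chunk[1], chunk[2], "3PL"))
    return items


def parameter_labels(model: ModelTag, n_items: int) -> list[str]:
    """Column labels for the stacked vector, e.g. ``a1, d1, c1, a2, ...``."""
    names = ("a", "d") if model == "2PL" else ("a", "d", "c")
    return [f"{n}{j + 1}" for j in range(n_items) for n in names]


# --------------------------------------------------------------------------
# Log prior density and gradient
# --------------------------------------------------------------------------

def _slope_logpdf_and_grad(a: float, prior: PriorSpec) -> tuple[float, float]:
    mu, var = prior.slope_params
    if prior.slope_dist == "lognormal":
        if a <= 0:
            raise BoundaryError("slope must be > 0 under a log-normal prior")
        la = np.log(a)
        lp = -la - 0.5 * np.log(2 * np.pi * var) - (la - mu) ** 2 / (2 * var)
        g = -1.0 / a - (la - mu) / (var * a)
    else:
        lp = -0.5 * np.log(2 * np.pi * var) - (a - mu) ** 2 / (2 * var)
        g = -(a - mu) / var
    return lp, g


def _guess_logpdf_and_grad(c: float, prior: PriorSpec) -> tuple[float, float]:
    from scipy.stats import beta as beta_dist

    alpha, beta = prior.guess_params
    if alpha == 1.0 and beta == 1.0:
        return 0.0, 0.0  # flat on (0, 1): exact zeros
    if not (0.0 < c < 1.0):
        raise BoundaryError(
            f"guess {c} on the boundary of the Beta({alpha},{beta}) support"
        )
    lp = beta_dist.logpdf(c, alpha, beta)
    g = (alpha - 1.0) / c - (beta - 1.0) / (1.0 - c)
    return float(lp), float(g)


def log_prior_density(items: Sequence[ItemParameters], prior: PriorSpec) -> float:
    """Summed log prior density over all items' parameters."""
    total = 0.0
    for it in items:
        lp_a, _ = _slope_logpdf_and_grad(it.slope, prior)
        mu, var = prior.intercept_params
        lp_d = -0.5 * np.log(2 * np.pi * var) - (it.intercept - mu) ** 2 / (2 * var)
        total += lp_a + lp_d
        if it.model == "3PL":
            lp_c, _ = _guess_logpdf_and_grad(it.guess, prior)
            total += lp_c
    return float(total)


def log_prior_gradient(items: Sequence[ItemParameters], prior: PriorSpec) -> np.ndarray:
    """Gradient ``u_prior`` of the summed log prior w.r.t. the stacked vector.

    Ordered identically to the score-matrix columns (item-major).  At a MAP
    optimum the casewise scores satisfy ``sum_i psi(Y_i) = -u_prior``.
    """
    out: list[float] = []
    mu_d, var_d = prior.intercept_params
    for it in items:
        _, g_a = _slope_logpdf_and_grad(it.slope, prior)
        g_d = -(it.intercept - mu_d) / var_d
        out.extend([g_a, g_d])
        if it.model == "3PL":
            _, g_c = _guess_logpdf_and_grad(it.guess, prior)
            out.append(g_c)
    return np.asarray(out, dtype=float)
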