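"""Marginal ML and Bayesian MAP fitting of 2PL/3PL models.

The marginal likelihood integrates the person ability out over a fixed
quadrature grid (61 equally spaced points on [-6, 6]; normal-density weights
per group, renormalized to sum to 1).  Fitting proceeds in two stages:

1. an EM loop (Bock--Aitkin style) with per-item bounded quasi-Newton
   M-steps and group-parameter updates from expected sufficient statistics,
   run to a coarse parameter-change tolerance for robustness;
2. a joint L-BFGS-B polish of the full marginal objective (item parameters
   plus the non-reference group parameters, with the log prior added under
   MAP) using the analytic score gradient.

The polish makes the estimator an exact stationary point of the
quadrature-approximated objective, so the casewise scores computed on the
same grid satisfy the defining identities ``sum_i psi(Y_i; b) = 0`` (MML)
and ``sum_i psi(Y_i; b) = -u_prior(b)`` (MAP) to tight tolerance.

Multiple-group ("impact") fits share all item parameters across groups; the
first group's ability distribution is fixed at N(0, 1) for identification
and the remaining groups' (mean, variance) are estimated by ML — also under
MAP, where no prior is placed on group parameters.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.special import logit

from .irt_core import (
    GroupParameters,
    ItemParameters,
    ModelTag,
    PriorSpec,
    log_prior_density,
    log_prior_gradient,
    stack_parameters,
    unstack_parameters,
)

__all__ = [
    "ResponseData",
    "FittedModel",
    "QuadratureSpec",
    "fit",
    "posterior_ability_weights",
    "marginal_loglik",
    "DataError",
    "ConvergenceError",
]


class DataError(ValueError):
    """Raised for invalid response data (missing values, degenerate items)."""


class ConvergenceError(RuntimeError):
    """Raised when estimation fails to converge; carries the objective trace."""

    def __init__(self, message: str, trace: list[float]):
        super().__init__(message)
        self.trace = trace


# --------------------------------------------------------------------------
# Data container
# --------------------------------------------------------------------------

@dataclass
class ResponseData:
    """Binary response matrix with optional group labels and person covariate.

    ``responses`` is (N persons x J items) with entries in {0, 1}; ``groups``
    holds 0-based group indices (group 0 is the reference); ``covariate`` is
    a length-N vector (numeric or categorical labels) used only by the
    invariance tests, never by fitting.
    """

    responses: np.ndarray
    groups: np.ndarray | None = None
    covariate: np.ndarray | None = None

    def __post_init__(self) -> None:
        Y = np.asarray(self.responses)
        if Y.ndim != 2 or Y.shape[0] < 2:
            raise DataError("responses must be an N x J matrix with N >= 2")
        if np.any(np.isnan(Y.astype(float))):
            raise DataError("missing responses are not supported")
        if not np.isin(Y, [0, 1]).all():
            raise DataError("responses must be binary 0/1")
        self.responses = Y.astype(np.int8)
        means = self.responses.mean(axis=0)
        bad = np.where((means == 0.0) | (means == 1.0))[0]
        if bad.size:
            raise DataError(
                f"degenerate item(s) {list(bad + 1)}: all responses identical"
            )
        if self.groups is not None:
            g = np.asarray(self.groups)
            if g.shape != (Y.shape[0],):
                raise DataError("group labels must cover all persons")
            uniq = np.unique(g)
            if not np.array_equal(uniq, np.arange(uniq.size)):
                raise DataError("groups must be 0-based consecutive integers")
            self.groups = g.astype(np.int64)
        if self.covariate is not None:
            cov = np.asarray(self.covariate)
            if cov.shape != (Y.shape[0],):
                raise DataError("covariate length mismatch")
            self.covariate = cov

    @property
    def n_persons(self) -> int:
        return self.responses.shape[0]

    @property
    def n_items(self) -> int:
        return self.responses.shape[1]

    @property
    def n_groups(self) -> int:
        if self.groups is None:
            return 1
        return int(self.groups.max()) + 1

    def group_index(self) -> np.ndarray:
        if self.groups is None:
            return np.zeros(self.n_persons, dtype=np.int64)
        return self.groups


@dataclass(frozen=True)
class QuadratureSpec:
    """Equally spaced grid with per-group normal weights renormalized to 1."""

    n_points: int = 61
    lo: float = -6.0
    hi: float = 6.0

    @property
    def nodes(self) -> np.ndarray:
        return np.linspace(self.lo, self.hi, self.n_points)


@dataclass
class ConvergenceRecord:
    em_cycles: int
    polish_iterations: int
    final_change: float
    grad_inf_norm: float
    trace: list[float] = field(default_factory=list, repr=False)


@dataclass
class FittedModel:
    """Converged item and group parameter estimates plus metadata."""

    items: list[ItemParameters]
    group_params: list[GroupParameters]
    method: Literal["MML", "MAP"]
    prior: PriorSpec | None
    quadrature: QuadratureSpec
    convergence: ConvergenceRecord
    loglik: float
    logpost: float | None = None

    @property
    def model(self) -> ModelTag:
        return self.items[0].model

    @property
    def n_item_params(self) -> int:
        return sum(it.n_params for it in self.items)

    def stacked(self) -> np.ndarray:
        return stack_parameters(self.items)

    def to_json(self, path=None) -> str:
        d = {
            "model": self.model,
            "method": self.method,
            "items": [
                {"slope": it.slope, "intercept": it.intercept, "guess": it.guess}
                for it in self.items
            ],
            "groups": [
                {"mean": g.mean, "var": g.var, "reference": g.reference}
                for g in self.group_params
            ],
            "prior": self.prior.to_dict() if self.prior else None,
            "quadrature": {
                "n_points": self.quadrature.n_points,
                "lo": self.quadrature.lo,
                "hi": self.quadrature.hi,
            },
            "loglik": self.loglik,
            "logpost": self.logpost,
            "convergence": {
                "em_cycles": self.convergence.em_cycles,
                "polish_iterations": self.convergence.polish_iterations,
                "final_change": self.convergence.final_change,
                "grad_inf_norm": self.convergence.grad_inf_norm,
            },
        }
        s = json.dumps(d, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s)
        return s

    @staticmethod
    def from_json(source: str) -> "FittedModel":
        d = json.loads(source)
        model = d["model"]
        items = [
            ItemParameters(it["slope"], it["intercept"], it["guess"], model)
            for it in d["items"]
        ]
        groups = [
            GroupParameters(g["mean"], g["var"], g["reference"]) for g in d["groups"]
        ]
        prior = PriorSpec.from_dict(d["prior"]) if d["prior"] else None
        q = QuadratureSpec(**d["quadrature"])
        conv = ConvergenceRecord(
            d["convergence"]["em_cycles"],
            d["convergence"]["polish_iterations"],
            d["convergence"]["final_change"],
            d["convergence"]["grad_inf_norm"],
        )
        return FittedModel(items, groups, d["method"], prior, q, conv,
                           d["loglik"], d["logpost"])


# --------------------------------------------------------------------------
# Vectorized building blocks
# --------------------------------------------------------------------------

_PCLIP = 1e-10


def _split(vec: np.ndarray, model: ModelTag, J: int):
    per = 2 if model == "2PL" else 3
    m = vec.reshape(J, per)
    a, d = m[:, 0], m[:, 1]
    c = m[:, 2] if model == "3PL" else np.zeros(J)
    return a, d, c


def _prob_matrix(a, d, c, nodes):
    """(J, Q) response probabilities and the logistic kernel sigma."""
    z = a[:, None] * nodes[None, :] + d[:, None]
    sig = 1.0 / (1.0 + np.exp(-z))
    P = c[:, None] + (1.0 - c)[:, None] * sig
    return np.clip(P, _PCLIP, 1.0 - _PCLIP), sig


def _group_log_weights(nodes, group_params):
    """(G, Q) log quadrature weights, each row normalized to sum to 1."""
    out = np.empty((len(group_params), nodes.size))
    for g, gp in enumerate(group_params):
        logw = -0.5 * (nodes - gp.mean) ** 2 / gp.var
        logw -= logw.max()
        w = np.exp(logw)
        out[g] = np.log(w / w.sum())
    return out


def _estep(Y, gidx, P, log_wg):
    """Posterior quadrature weights (N, Q) and the marginal log-likelihood."""
    logP = np.log(P)
    log1mP = np.log1p(-P)
    # (N, Q): sum_j [ y_ij log P_jq + (1 - y_ij) log(1 - P_jq) ]
    logL = Y @ logP + (1 - Y) @ log1mP
    Z = logL + log_wg[gidx]
    m = Z.max(axis=1)
    W = np.exp(Z - m[:, None])
    s = W.sum(axis=1)
    loglik = float(np.sum(m + np.log(s)))
    W /= s[:, None]
    return W, loglik


def _item_grad_terms(P, sig, c, nodes):
    """dP/da, dP/dd, dP/dc as (J, Q) arrays."""
    core = (1.0 - c)[:, None] * sig * (1.0 - sig)
    return core * nodes[None, :], core, 1.0 - sig


def _expected_item_neg(vec_j, model, r_j, n, nodes, prior):
    """Per-item expected complete-data negative objective and gradient."""
    if model == "2PL":
        a, d = vec_j
        c = 0.0
    else:
        a, d, c = vec_j
    z = a * nodes + d
    sig = 1.0 / (1.0 + np.exp(-z))
    P = np.clip(c + (1.0 - c) * sig, _PCLIP, 1.0 - _PCLIP)
    f = -float(r_j @ np.log(P) + (n - r_j) @ np.log1p(-P))
    resid = r_j / P - (n - r_j) / (1.0 - P)
    core = (1.0 - c) * sig * (1.0 - sig)
    g = [-float(resid @ (core * nodes)), -float(resid @ core)]
    if model == "3PL":
        g.append(-float(resid @ (1.0 - sig)))
    if prior is not None:
        item = ItemParameters(a, d, c if model == "3PL" else 0.0, model)
        f -= log_prior_density([item], prior)
        g = list(np.asarray(g) - log_prior_gradient([item], prior))
    return f, np.asarray(g)


_BOUNDS = {"a": (1e-4, 50.0), "d": (None, None), "c": (1e-4, 1.0 - 1e-4)}


def _item_bounds(model: ModelTag):
    b = [_BOUNDS["a"], _BOUNDS["d"]]
    if model == "3PL":
        b.append(_BOUNDS["c"])
    return b


# --------------------------------------------------------------------------
# Full-objective evaluation (shared by polish and the score module)
# --------------------------------------------------------------------------

def _full_objective(x, model, J, Y, gidx, nodes, prior, n_free_groups,
                    group_counts):
    """Negative (penalized) marginal log-likelihood and its gradient.

    ``x`` stacks the item parameters item-major followed by (mean, var) for
    each non-reference group.  The gradient of the marginal log-likelihood
    w.r.t. the item parameters is evaluated through the EM identity: it
    equals the gradient of the expected complete-data log-likelihood at the
    same point.
    """
    k_items = (2 if model == "2PL" else 3) * J
    a, d, c = _split(x[:k_items], model, J)
    gp = [GroupParameters(reference=True)]
    for g in range(n_free_groups):
        gp.append(GroupParameters(x[k_items + 2 * g], x[k_items + 2 * g + 1]))
    P, sig = _prob_matrix(a, d, c, nodes)
    log_wg = _group_log_weights(nodes, gp)
    W, loglik = _estep(Y, gidx, P, log_wg)
    r = Y.T @ W            # (J, Q)
    n = W.sum(axis=0)      # (Q,)
    resid = r / P - (n[None, :] - r) / (1.0 - P)
    dPa, dPd, dPc = _item_grad_terms(P, sig, c, nodes)
    ga = np.sum(resid * dPa, axis=1)
    gd = np.sum(resid * dPd, axis=1)
    if model == "3PL":
        gitem = np.column_stack([ga, gd, np.sum(resid * dPc, axis=1)]).ravel()
    else:
        gitem = np.column_stack([ga, gd]).ravel()

    obj = loglik
    grad = [gitem]
    if prior is not None:
        items = unstack_parameters(x[:k_items], model)
        obj += log_prior_density(items, prior)
        grad[0] = gitem + log_prior_gradient(items, prior)

    for g in range(n_free_groups):
        gpar = gp[g + 1]
        members = gidx == (g + 1)
        S = W[members].sum(axis=0)  # (Q,)
        wq = np.exp(log_wg[g + 1])
        t1 = (nodes - gpar.mean) / gpar.var
        t2 = 0.5 * ((nodes - gpar.mean) ** 2 / gpar.var**2 - 1.0 / gpar.var)
        t1c = t1 - wq @ t1
        t2c = t2 - wq @ t2
        grad.append(np.array([S @ t1c, S @ t2c]))
    return -obj, -np.concatenate(grad), loglik


# --------------------------------------------------------------------------
# Public operations
# --------------------------------------------------------------------------

def fit(
    data: ResponseData,
    model: ModelTag = "2PL",
    method: Literal["MML", "MAP"] = "MML",
    prior: PriorSpec | None = None,
    groups: bool = False,
    quadrature: QuadratureSpec = QuadratureSpec(),
    em_tol: float = 1e-3,
    em_max_cycles: int = 500,
    grad_tol: float = 1e-3,
) -> FittedModel:
    """Fit a 2PL/3PL model by MML or MAP, optionally with impact groups.

    Parameters follow the module contract: ``prior`` is required iff
    ``method == "MAP"``; with ``groups=True`` the data must carry group
    labels and the reference group's ability distribution is fixed at
    N(0, 1).  Raises :class:`ConvergenceError` (carrying the objective
    trace) if the gradient identity cannot be met.
    """
    if method == "MAP" and prior is None:
        raise ValueError("MAP estimation requires a prior")
    if method == "MML":
        prior = None
    if groups and data.groups is None:
        raise DataError("groups=True requires group labels")

    Y = data.responses.astype(float)
    N, J = Y.shape
    gidx = data.group_index() if groups else np.zeros(N, dtype=np.int64)
    G = int(gidx.max()) + 1
    nodes = quadrature.nodes

    # deterministic starting values
    pbar = Y.mean(axis=0)
    a0 = np.ones(J)
    d0 = np.clip(logit(pbar), -3.0, 3.0)
    if model == "3PL":
        x_items = np.column_stack([a0, d0, np.full(J, 0.1)]).ravel()
    else:
        x_items = np.column_stack([a0, d0]).ravel()
    group_params = [GroupParameters(reference=True)] + [
        GroupParameters(0.0, 1.0) for _ in range(G - 1)
    ]
    bounds_item = _item_bounds(model)
    per = 2 if model == "2PL" else 3
    trace: list[float] = []

    # ---- EM stage -------------------------------------------------------
    em_cycles = 0
    change = np.inf
    for cycle in range(em_max_cycles):
        a, d, c = _split(x_items, model, J)
        P, _ = _prob_matrix(a, d, c, nodes)
        log_wg = _group_log_weights(nodes, group_params)
        W, loglik = _estep(Y, gidx, P, log_wg)
        obj = loglik
        if prior is not None:
            obj += log_prior_density(unstack_parameters(x_items, model), prior)
        trace.append(obj)
        r = Y.T @ W
        n = W.sum(axis=0)
        new_items = x_items.copy()
        for j in range(J):
            res = minimize(
                _expected_item_neg,
                x_items[j * per : (j + 1) * per],
                args=(model, r[j], n, nodes, prior),
                jac=True,
                method="L-BFGS-B",
                bounds=bounds_item,
                options={"maxiter": 100},
            )
            new_items[j * per : (j + 1) * per] = res.x
        new_groups = [GroupParameters(reference=True)]
        gchange = 0.0
        if G > 1:
            Etheta = W @ nodes
            Etheta2 = W @ nodes**2
            for g in range(1, G):
                members = gidx == g
                mu = float(Etheta[members].mean())
                var = float(max(Etheta2[members].mean() - mu**2, 0.05))
                gchange = max(
                    gchange,
                    abs(mu - group_params[g].mean),
                    abs(var - group_params[g].var),
                )
                new_groups.append(GroupParameters(mu, var))
        change = max(float(np.abs(new_items - x_items).max()), gchange)
        x_items = new_items
        group_params = new_groups if G > 1 else group_params
        em_cycles = cycle + 1
        if change < em_tol:
            break

    # ---- Joint polish ---------------------------------------------------
    n_free_groups = G - 1
    x_full = np.concatenate(
        [x_items]
        + [[gp.mean, gp.var] for gp in group_params[1:]]
    ) if n_free_groups else x_items
    bounds_full = bounds_item * J + [(-6.0, 6.0), (0.05, 25.0)] * n_free_groups
    counts = np.bincount(gidx, minlength=G)

    def f(x):
        nf, ng, _ = _full_objective(x, model, J, Y, gidx, nodes, prior,
                                    n_free_groups, counts)
        return nf, ng

    res = minimize(
        f, x_full, jac=True, method="L-BFGS-B", bounds=bounds_full,
        options={"maxiter": 1000, "ftol": 1e-14, "gtol": 1e-7},
    )
    x_full = res.x
    neg_obj, neg_grad, loglik = _full_objective(
        x_full, model, J, Y, gidx, nodes, prior, n_free_groups, counts
    )
    # KKT-projected gradient: components pinned at a bound may carry an
    # outward-pointing gradient without violating convergence.
    proj = -neg_grad.copy()
    for i, (lo, hi) in enumerate(bounds_full):
        if lo is not None and x_full[i] <= lo + 1e-9 and proj[i] < 0:
            proj[i] = 0.0
        if hi is not None and x_full[i] >= hi - 1e-9 and proj[i] > 0:
            proj[i] = 0.0
    gnorm = float(np.abs(proj).max())
    if gnorm > grad_tol:
        # one restart from the current point often clears a flat stretch
        res = minimize(
            f, x_full, jac=True, method="L-BFGS-B", bounds=bounds_full,
            options={"maxiter": 2000, "ftol": 1e-16, "gtol": 1e-9},
        )
        x_full = res.x
        neg_obj, neg_grad, loglik = _full_objective(
            x_full, model, J, Y, gidx, nodes, prior, n_free_groups, counts
        )
        proj = -neg_grad.copy()
        for i, (lo, hi) in enumerate(bounds_full):
            if lo is not None and x_full[i] <= lo + 1e-9 and proj[i] < 0:
                proj[i] = 0.0
            if hi is not None and x_full[i] >= hi - 1e-9 and proj[i] > 0:
                proj[i] = 0.0
        gnorm = float(np.abs(proj).max())
    if gnorm > grad_tol:
        raise ConvergenceError(
            f"estimation did not converge: projected gradient {gnorm:.2e} "
            f"exceeds {grad_tol:.0e} after {em_cycles} EM cycles + polish",
            trace,
        )
    trace.append(-neg_obj)

    k_items = per * J
    items = unstack_parameters(x_full[:k_items], model)
    final_groups = [GroupParameters(reference=True)]
    for g in range(n_free_groups):
        final_groups.append(
            GroupParameters(float(x_full[k_items + 2 * g]),
                            float(x_full[k_items + 2 * g + 1]))
        )
    logpost = None
    if method == "MAP":
        logpost = loglik + log_prior_density(items, prior)
    conv = ConvergenceRecord(
        em_cycles=em_cycles,
        polish_iterations=int(res.nit),
        final_change=float(change),
        grad_inf_norm=gnorm,
        trace=trace,
    )
    return FittedModel(items, final_groups, method, prior, quadrature, conv,
                       float(loglik), logpost)


def posterior_ability_weights(data: ResponseData, fitted: FittedModel) -> np.ndarray:
    """N x Q posterior quadrature weights; rows are nonnegative and sum to 1.

    Person i's row is proportional to the likelihood of their responses at
    each node times their group's prior node weight.
    """
    Y = data.responses.astype(float)
    gidx = data.group_index() if len(fitted.group_params) > 1 else np.zeros(
        data.n_persons, dtype=np.int64
    )
    a = np.array([it.slope for it in fitted.items])
    d = np.array([it.intercept for it in fitted.items])
    c = np.array([it.guess for it in fitted.items])
    P, _ = _prob_matrix(a, d, c, fitted.quadrature.nodes)
    log_wg = _group_log_weights(fitted.quadrature.nodes, fitted.group_params)
    W, _ = _estep(Y, gidx, P, log_wg)
    return W


def marginal_loglik(
    data: ResponseData,
    items: Sequence[ItemParameters],
    group_params: Sequence[GroupParameters] | None = None,
    quadrature: QuadratureSpec = QuadratureSpec(),
) -> float:
    """Quadrature-approximated marginal log-likelihood at given parameters."""
    if group_params is None:
        group_params = [GroupParameters(reference=True)]
    Y = data.responses.astype(float)
    gidx = (
        data.group_index()
        if len(group_params) > 1
        else np.zeros(data.n_persons, dtype=np.int64)
    )
    a = np.array([it.slope for it in items])
    d = np.array([it.intercept for it in items])
    c = np.array([it.guess for it in items])
    P, _ = _prob_matrix(a, d, c, quadrature.nodes)
    log_wg = _group_log_weights(quadrature.nodes, group_params)
    _, loglik = _estep(Y, gidx, P, log_wg)
    return loglik
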