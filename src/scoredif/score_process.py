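"""Casewise score contributions and the cumulative score (fluctuation) process.

Person i's score contribution is the gradient of their log marginal
likelihood with respect to the stacked item parameters, evaluated at the
fitted estimate.  At an MML optimum the contributions sum to the zero
vector; at a MAP optimum they sum to minus the log-prior gradient.  After
subtracting the column means ("centering", harmless under MML, required
under MAP) and decorrelating by an inverse square root of the score
covariance, the partial-sum process of the covariate-ordered rows,

    Psi(t) = N^{-1/2} * sum_{i <= floor(N t)} Vhat_{g(i)}^{-1/2} psi~_i,

converges to a k-dimensional standard Brownian bridge when the item
parameters are invariant.  With a single pooled covariance the finite-sample
path ends exactly at zero; with group-wise covariances it generally does
not, which motivates the simulation-based p-value engine.

Group-parameter scores (impact mean/variance) are available separately for
diagnostics but are never part of the test process.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .estimation import (
    FittedModel,
    ResponseData,
    _estep,
    _group_log_weights,
    _item_grad_terms,
    _prob_matrix,
)

__all__ = [
    "ScoreMatrix",
    "CovarianceEstimate",
    "CumulativeScoreProcess",
    "score_contributions",
    "group_score_contributions",
    "center",
    "covariance",
    "inverse_sqrt",
    "build_process",
    "process_to_frame",
    "plot_process",
    "SingularCovarianceError",
]

ScoreState = Literal["raw", "centered", "decorrelated"]


class SingularCovarianceError(np.linalg.LinAlgError):
    """Raised when the score covariance is numerically singular."""


@dataclass
class ScoreMatrix:
    """N x k casewise score contributions for the item parameters.

    ``state`` tracks the pipeline stage: raw psi, centered psi~, or
    decorrelated gamma.  Columns are item-major (a_1, d_1[, c_1], ...).
    """

    values: np.ndarray
    state: ScoreState = "raw"
    labels: list[str] | None = None

    @property
    def n_persons(self) -> int:
        return self.values.shape[0]

    @property
    def n_params(self) -> int:
        return self.values.shape[1]


@dataclass
class CovarianceEstimate:
    """Pooled (single k x k) or group-wise score covariance, divisor N.

    Inverse square roots are computed once and cached; group-wise mode maps
    group index -> matrix.
    """

    mode: Literal["pooled", "groupwise"]
    matrices: dict[int, np.ndarray]
    inv_sqrts: dict[int, np.ndarray]

    @property
    def pooled_matrix(self) -> np.ndarray:
        if self.mode != "pooled":
            raise ValueError("not a pooled estimate")
        return self.matrices[0]


@dataclass
class CumulativeScoreProcess:
    """(N+1) x k partial sums Psi(i/N), i = 0..N, with Psi(0) = 0.

    Rows follow ascending covariate order; ``covariate_sorted`` and
    ``groups_sorted`` give the covariate value and group label at each
    sorted position.  ``path[i]`` is Psi(i/N) including the N^{-1/2} scale.
    """

    path: np.ndarray
    covariate_sorted: np.ndarray
    groups_sorted: np.ndarray
    mode: Literal["pooled", "groupwise"]
    labels: list[str] | None = None

    @property
    def n_persons(self) -> int:
        return self.path.shape[0] - 1

    @property
    def n_params(self) -> int:
        return self.path.shape[1]


# --------------------------------------------------------------------------
# Score computation
# --------------------------------------------------------------------------

def _score_pieces(data: ResponseData, fitted: FittedModel):
    Y = data.responses.astype(float)
    multi = len(fitted.group_params) > 1
    gidx = data.group_index() if multi else np.zeros(data.n_persons, dtype=np.int64)
    nodes = fitted.quadrature.nodes
    a = np.array([it.slope for it in fitted.items])
    d = np.array([it.intercept for it in fitted.items])
    c = np.array([it.guess for it in fitted.items])
    P, sig = _prob_matrix(a, d, c, nodes)
    log_wg = _group_log_weights(nodes, fitted.group_params)
    W, _ = _estep(Y, gidx, P, log_wg)
    return Y, gidx, nodes, P, sig, c, log_wg, W


def score_contributions(data: ResponseData, fitted: FittedModel) -> ScoreMatrix:
    """Raw casewise scores: row i = d log L_i / d (item parameters) at the fit.

    Computed through the posterior quadrature weights,
    ``sum_q W_iq * dlog f(y_ij | theta_q) / d beta``; identical formula for
    MML and MAP fits (the prior enters only through the estimate and the
    later centering step).
    """
    Y, gidx, nodes, P, sig, c, _, W = _score_pieces(data, fitted)
    N, J = Y.shape
    dPa, dPd, dPc = _item_grad_terms(P, sig, c, nodes)
    model = fitted.model
    per = 2 if model == "2PL" else 3
    k = per * J
    S = np.empty((N, k))
    # dlog f/d beta = dP * (y/P - (1-y)/(1-P)); split into the y=1 and y=0
    # parts so each parameter class is two matrix products.
    for comp, dP in enumerate((dPa, dPd, dPc)[: per]):
        A = W @ (dP / P).T          # (N, J): E_q[dP/P]
        B = W @ (dP / (1.0 - P)).T  # (N, J): E_q[dP/(1-P)]
        S[:, comp::per] = Y * A - (1.0 - Y) * B
    if not np.isfinite(S).all():
        bad = np.where(~np.isfinite(S).all(axis=0))[0]
        raise FloatingPointError(
            f"non-finite score contributions in column(s) {bad.tolist()}"
        )
    from .irt_core import parameter_labels

    return ScoreMatrix(S, "raw", parameter_labels(model, J))


def group_score_contributions(data: ResponseData, fitted: FittedModel) -> np.ndarray:
    """Casewise scores for the non-reference group (mean, var) parameters.

    Diagnostic only: these columns are computed for the optimality checks
    but excluded from covariance estimation and the test process.  Returns
    an N x 2(G-1) array (zero rows for members of other groups).
    """
    Y, gidx, nodes, _, _, _, log_wg, W = _score_pieces(data, fitted)
    G = len(fitted.group_params)
    out = np.zeros((data.n_persons, 2 * (G - 1)))
    for g in range(1, G):
        gp = fitted.group_params[g]
        wq = np.exp(log_wg[g])
        t1 = (nodes - gp.mean) / gp.var
        t2 = 0.5 * ((nodes - gp.mean) ** 2 / gp.var**2 - 1.0 / gp.var)
        t1c = t1 - wq @ t1
        t2c = t2 - wq @ t2
        members = gidx == g
        out[members, 2 * (g - 1)] = W[members] @ t1c
        out[members, 2 * (g - 1) + 1] = W[members] @ t2c
    return out


def center(scores: ScoreMatrix) -> ScoreMatrix:
    """Subtract column means; idempotent; applied under both MML and MAP."""
    v = scores.values - scores.values.mean(axis=0, keepdims=True)
    return ScoreMatrix(v, "centered", scores.labels)


def covariance(
    scores: ScoreMatrix,
    mode: Literal["pooled", "groupwise"] = "pooled",
    groups: np.ndarray | None = None,
    tol: float = 1e-10,
) -> CovarianceEstimate:
    """Outer-product covariance of the centered scores, divisor N (not N-1).

    ``pooled``: a single Vhat = (1/N) sum_i psi~_i psi~_i'.  ``groupwise``:
    Vhat_g over each group's rows, still centered by the global mean (the
    null model asserts a common expectation; group-specific centering would
    absorb DIF signal).
    """
    if scores.state != "centered":
        raise ValueError("covariance expects centered scores")
    V = scores.values
    mats: dict[int, np.ndarray] = {}
    if mode == "pooled":
        mats[0] = V.T @ V / V.shape[0]
    else:
        if groups is None:
            raise ValueError("groupwise covariance requires group labels")
        groups = np.asarray(groups)
        for g in np.unique(groups):
            Vg = V[groups == g]
            mats[int(g)] = Vg.T @ Vg / Vg.shape[0]
    inv_sqrts = {g: inverse_sqrt(m, tol=tol, labels=scores.labels)
                 for g, m in mats.items()}
    return CovarianceEstimate(mode, mats, inv_sqrts)


def inverse_sqrt(V: np.ndarray, tol: float = 1e-10,
                 labels: list[str] | None = None) -> np.ndarray:
    """Symmetric inverse square root via eigendecomposition: S V S = I."""
    V = np.asarray(V, dtype=float)
    Vs = 0.5 * (V + V.T)
    vals, vecs = np.linalg.eigh(Vs)
    if vals.min() < tol:
        offender = int(np.argmin(np.abs(np.diag(Vs))))
        name = labels[offender] if labels else f"column {offender}"
        raise SingularCovarianceError(
            f"score covariance is singular (min eigenvalue {vals.min():.2e}); "
            f"smallest-variance parameter: {name}"
        )
    return (vecs * (1.0 / np.sqrt(vals))) @ vecs.T


def build_process(
    scores: ScoreMatrix,
    cov: CovarianceEstimate,
    covariate: np.ndarray,
    groups: np.ndarray | None = None,
) -> CumulativeScoreProcess:
    """Decorrelate, order by the covariate, and accumulate partial sums.

    Persons are sorted ascending by covariate (stable, original order breaks
    ties); row i becomes ``Vhat_{g(i)}^{-1/2} psi~_i``; the path is the
    N^{-1/2}-scaled cumulative sum prefixed with Psi(0) = 0.
    """
    if scores.state != "centered":
        raise ValueError("build_process expects centered scores")
    V = scores.values
    N, k = V.shape
    covariate = np.asarray(covariate)
    if covariate.shape[0] != N:
        raise ValueError("covariate length mismatch")
    order = np.argsort(covariate, kind="stable")
    if groups is None:
        groups = np.zeros(N, dtype=np.int64)
    groups = np.asarray(groups)
    Vs = V[order]
    gs = groups[order]
    if cov.mode == "pooled":
        D = Vs @ cov.inv_sqrts[0].T
    else:
        D = np.empty_like(Vs)
        for g, S in cov.inv_sqrts.items():
            mask = gs == g
            D[mask] = Vs[mask] @ S.T
    path = np.vstack([np.zeros((1, k)), np.cumsum(D, axis=0)]) / np.sqrt(N)
    return CumulativeScoreProcess(path, covariate[order], gs, cov.mode,
                                  scores.labels)


# --------------------------------------------------------------------------
# Export / plotting
# --------------------------------------------------------------------------

def process_to_frame(process: CumulativeScoreProcess):
    """Tidy long-format frame (t, component, value, group) for export."""
    import pandas as pd

    N, k = process.n_persons, process.n_params
    t = np.arange(N + 1) / N
    labels = process.labels or [f"p{j}" for j in range(k)]
    groups = np.concatenate([[process.groups_sorted[0]], process.groups_sorted])
    frames = [
        pd.DataFrame(
            {"t": t, "component": lab, "value": process.path[:, j],
             "group": groups}
        )
        for j, lab in enumerate(labels)
    ]
    return pd.concat(frames, ignore_index=True)


def plot_process(process: CumulativeScoreProcess, path=None, max_components=None):
    """Fluctuation chart of the cumulative score process components."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    N, k = process.n_persons, process.n_params
    t = np.arange(N + 1) / N
    labels = process.labels or [f"p{j}" for j in range(k)]
    kshow = min(k, max_components) if max_components else k
    fig, ax = plt.subplots(figsize=(7, 4))
    for j in range(kshow):
        ax.plot(t, process.path[:, j], lw=0.8, label=labels[j])
    ax.axhline(0.0, color="black", lw=0.5)
    ax.set_xlabel("t (covariate order, fraction of sample)")
    ax.set_ylabel("cumulative score process")
    if kshow <= 12:
        ax.legend(fontsize=7, ncol=3)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
        return None
    return fig
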