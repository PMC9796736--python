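"""Synthetic data with the simulation study's generating structure.

Datasets follow the study design the package is evaluated under: item
slopes drawn log-normal LN(0, 0.0625), intercepts N(0, 1), 3PL guessing
parameters Beta(5, 45); person covariates either a Bernoulli(.5) two-group
label or uniform(20, 70) (an age-like variable split at 35); an optional
impact effect N(-0.5, 1) / N(+0.5, 1) between the two sides; and DIF as
additive parameter shifts (slope +-0.3, intercept +-0.6, guessing +-0.1) on
a random one-fifth of the items, applied only to the focal side's response
function.  ``run_study`` drives Monte Carlo grids of Type I error and power
at configurable scale.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, replace
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .estimation import ConvergenceError, DataError, ResponseData, fit
from .invariance_tests import CategoricalBins, score_test
from .irt_core import DIFDeltas, ItemParameters, ModelTag, PriorSpec
from .score_process import (
    SingularCovarianceError,
    build_process,
    center,
    covariance,
    score_contributions,
)

__all__ = [
    "StudyConfig",
    "GeneratedDataset",
    "draw_item_parameters",
    "draw_persons",
    "apply_dif",
    "generate_dataset",
    "run_replicate",
    "run_study",
]

DIF_SIZES = {"slope": 0.3, "intercept": 0.6, "guess": 0.1}
_GRID_N = (500, 1000, 2000, 5000)
_GRID_ITEMS = (10, 30)


@dataclass(frozen=True)
class StudyConfig:
    """One cell of the simulation-study design grid.

    ``strict=True`` (default) restricts N and the item count to the study
    grid; pass ``strict=False`` for exploratory sizes.  ``sim_draws`` is the
    R of the simulation engine (the study's reference value is 1000; scaled
    runs may reduce it).
    """

    model: ModelTag = "2PL"
    n_persons: int = 1000
    n_items: int = 10
    covariate: Literal["categorical", "continuous"] = "categorical"
    impact: bool = False
    dif: Literal["none", "slope", "intercept", "guess"] = "none"
    direction: Literal["balanced", "unbalanced"] = "unbalanced"
    estimation: Literal["MML", "MAP-agreeing", "MAP-noninformative"] = "MML"
    engine: Literal["pooled", "simulation"] = "pooled"
    replications: int = 1000
    seed: int = 0
    sim_draws: int = 1000
    strict: bool = True

    def __post_init__(self) -> None:
        if self.strict:
            if self.n_persons not in _GRID_N:
                raise ValueError(f"N must be one of {_GRID_N} (or strict=False)")
            if self.n_items not in _GRID_ITEMS:
                raise ValueError(f"items must be one of {_GRID_ITEMS} (or strict=False)")
        if self.dif == "guess" and self.model != "3PL":
            raise ValueError("guessing DIF requires the 3PL model")

    @property
    def cell_id(self) -> str:
        return (
            f"{self.model}-N{self.n_persons}-J{self.n_items}-{self.covariate}"
            f"-impact{int(self.impact)}-dif_{self.dif}-{self.direction}"
            f"-{self.estimation}-{self.engine}"
        )

    def prior(self) -> PriorSpec | None:
        if self.estimation == "MAP-agreeing":
            return PriorSpec.agreeing()
        if self.estimation == "MAP-noninformative":
            return PriorSpec.non_informative()
        return None

    @property
    def method(self) -> str:
        return "MML" if self.estimation == "MML" else "MAP"


@dataclass
class GeneratedDataset:
    """A simulated dataset with its generating truth attached."""

    data: ResponseData
    items: list[ItemParameters]
    deltas: list[DIFDeltas]
    dif_items: np.ndarray
    covariate: np.ndarray
    side: np.ndarray  # focal-side indicator (0 reference, 1 focal)
    abilities: np.ndarray
    config: StudyConfig
    replicate: int

    def to_frame(self) -> pd.DataFrame:
        J = self.data.n_items
        df = pd.DataFrame(
            self.data.responses, columns=[f"item{j + 1}" for j in range(J)]
        )
        df["covariate"] = self.covariate
        df["group"] = self.side
        return df


def _cell_rng(seed: int, cell_id: str, replicate: int,
              stream: int = 0) -> np.random.Generator:
    """Independent, reproducible stream per (seed, cell, replicate, stream)."""
    tag = zlib.crc32(cell_id.encode()) & 0x7FFFFFFF
    return np.random.default_rng(
        np.random.SeedSequence([seed & 0x7FFFFFFF, tag, replicate, stream])
    )


# --------------------------------------------------------------------------
# Generating-process pieces
# --------------------------------------------------------------------------

def draw_item_parameters(
    J: int, model: ModelTag, rng: np.random.Generator
) -> list[ItemParameters]:
    """Draw a ~ LN(0, 0.0625), d ~ N(0, 1), c ~ Beta(5, 45) (3PL only)."""
    if J < 1:
        raise ValueError("need at least one item")
    a = np.exp(rng.normal(0.0, np.sqrt(0.0625), size=J))
    d = rng.normal(0.0, 1.0, size=J)
    if model == "3PL":
        c = rng.beta(5.0, 45.0, size=J)
        return [ItemParameters(a[j], d[j], c[j], "3PL") for j in range(J)]
    return [ItemParameters(a[j], d[j], 0.0, "2PL") for j in range(J)]


def draw_persons(
    N: int,
    covariate: Literal["categorical", "continuous"],
    impact: bool,
    rng: np.random.Generator,
):
    """Covariate values, abilities, and focal-side labels for N persons.

    Categorical: Bernoulli(.5) group membership, the covariate is the group
    label itself.  Continuous: covariate ~ U(20, 70), side split at 35.
    With impact, side 0 abilities are N(-0.5, 1) and side 1 N(+0.5, 1);
    without, all abilities are N(0, 1).
    """
    if N < 2:
        raise ValueError("need at least two persons")
    if covariate == "categorical":
        # P(first group) = .5; label 0 = first group, 1 = second (focal)
        side = (rng.random(N) >= 0.5).astype(np.int64)
        cov = side.copy()
    else:
        cov = rng.uniform(20.0, 70.0, size=N)
        side = (cov >= 35.0).astype(np.int64)
    if impact:
        theta = rng.normal(np.where(side == 0, -0.5, 0.5), 1.0)
    else:
        theta = rng.normal(0.0, 1.0, size=N)
    return cov, theta, side


def apply_dif(
    params: Sequence[ItemParameters],
    target: Literal["slope", "intercept", "guess"],
    direction: Literal["balanced", "unbalanced"],
    rng: np.random.Generator,
) -> tuple[list[DIFDeltas], np.ndarray]:
    """Select one-fifth of the items and attach DIF deltas.

    Unbalanced: all selected items get +delta (favouring the focal side for
    slope/intercept/guessing increases).  Balanced: half +delta, half
    -delta, sign assignment random over the selected items; for an odd
    count the extra item gets +delta.  A negative guessing delta is
    truncated so the shifted asymptote stays in [0.005, 1).
    """
    J = len(params)
    n_dif = J // 5
    if n_dif < 1:
        raise ValueError("item set too small for the one-fifth DIF rule")
    if target == "guess" and params[0].model != "3PL":
        raise ValueError("guessing DIF requires 3PL items")
    chosen = rng.choice(J, size=n_dif, replace=False)
    size = DIF_SIZES[target]
    signs = np.ones(n_dif)
    if direction == "balanced":
        n_neg = n_dif // 2
        order = rng.permutation(n_dif)
        signs[order[:n_neg]] = -1.0
    deltas = [DIFDeltas() for _ in range(J)]
    for idx, s in zip(chosen, signs):
        dval = s * size
        if target == "slope":
            deltas[idx] = DIFDeltas(slope=dval)
        elif target == "intercept":
            deltas[idx] = DIFDeltas(intercept=dval)
        else:
            if dval < 0:
                dval = -min(size, params[idx].guess - 0.005)
            deltas[idx] = DIFDeltas(guess=dval)
    return deltas, np.sort(chosen)


def generate_dataset(config: StudyConfig, replicate: int = 0) -> GeneratedDataset:
    """One fully reproducible dataset for a study cell.

    The response of person i to item j is Bernoulli with the item's
    response function; persons on the focal side see the DIF-shifted
    parameters on the affected items.
    """
    rng = _cell_rng(config.seed, config.cell_id, replicate)
    items = draw_item_parameters(config.n_items, config.model, rng)
    cov, theta, side = draw_persons(
        config.n_persons, config.covariate, config.impact, rng
    )
    if config.dif != "none":
        deltas, dif_items = apply_dif(items, config.dif, config.direction, rng)
    else:
        deltas = [DIFDeltas() for _ in items]
        dif_items = np.array([], dtype=np.int64)

    J = config.n_items
    a0 = np.array([it.slope for it in items])
    d0 = np.array([it.intercept for it in items])
    c0 = np.array([it.guess for it in items])
    da = np.array([dl.slope for dl in deltas])
    dd = np.array([dl.intercept for dl in deltas])
    dc = np.array([dl.guess for dl in deltas])
    # side-specific parameter rows: reference sees base, focal sees base+delta
    a = np.where(side[:, None] == 1, a0 + da, a0)
    d = np.where(side[:, None] == 1, d0 + dd, d0)
    c = np.where(side[:, None] == 1, c0 + dc, c0)
    P = c + (1.0 - c) / (1.0 + np.exp(-(a * theta[:, None] + d)))
    Y = (rng.random((config.n_persons, J)) < P).astype(np.int8)

    data = ResponseData(
        Y,
        groups=side.copy() if config.impact else None,
        covariate=cov,
    )
    return GeneratedDataset(
        data, items, deltas, dif_items, cov, side, theta, config, replicate
    )


# --------------------------------------------------------------------------
# Study driver
# --------------------------------------------------------------------------

def run_replicate(config: StudyConfig, replicate: int) -> float:
    """Generate one dataset, fit it, and return the test p-value.

    Impact cells are fitted as two-group models (reference side fixed at
    N(0,1)); the statistic is DM for continuous covariates and LM_uo for
    categorical ones, per the study design.  The simulation engine uses
    group-wise decorrelation under impact and pooled decorrelation in the
    single-group case; the pooled engine always uses the pooled covariance
    with the asymptotic reference distribution.
    """
    ds = generate_dataset(config, replicate)
    fitted = fit(
        ds.data,
        model=config.model,
        method=config.method,
        prior=config.prior(),
        groups=config.impact,
    )
    raw = score_contributions(ds.data, fitted)
    centered = center(raw)
    groupwise = config.engine == "simulation" and config.impact
    cov = covariance(
        centered,
        mode="groupwise" if groupwise else "pooled",
        groups=ds.side if groupwise else None,
    )
    process = build_process(centered, cov, ds.covariate,
                            groups=ds.side if groupwise else None)
    statistic = "DM" if config.covariate == "continuous" else "LM_uo"
    bins = (
        CategoricalBins.from_sorted_covariate(process.covariate_sorted)
        if statistic == "LM_uo"
        else None
    )
    sim_seed = int(
        _cell_rng(config.seed, config.cell_id, replicate, stream=1).integers(2**31)
    )
    result = score_test(
        process,
        statistic=statistic,
        engine="asymptotic" if config.engine == "pooled" else "simulation",
        bins=bins,
        R=config.sim_draws,
        seed=sim_seed,
        cov=cov,
    )
    return result.pvalue


def _replicate_safe(config: StudyConfig, rep: int):
    try:
        return run_replicate(config, rep)
    except (ConvergenceError, DataError, SingularCovarianceError):
        return None


def run_study(
    configs: Sequence[StudyConfig],
    reps: int | None = None,
    seed: int | None = None,
    alpha: float = 0.05,
    n_jobs: int = 1,
    drop_failures: bool = False,
    progress: bool = False,
) -> pd.DataFrame:
    """Monte Carlo rejection-rate table over a grid of study cells.

    Per cell: the fraction of replicates with p < ``alpha`` plus a binomial
    Monte Carlo standard error.  Failed fits are counted in ``failures``;
    they enter the denominator as non-rejections unless
    ``drop_failures=True``.  Results are bit-reproducible for a given
    (grid, reps, seed) and independent of ``n_jobs``.
    """
    from joblib import Parallel, delayed

    rows = []
    for config in configs:
        if reps is not None or seed is not None:
            config = replace(
                config,
                replications=reps or config.replications,
                seed=seed if seed is not None else config.seed,
            )
        R = config.replications
        if R < 1:
            raise ValueError("need at least one replicate")
        if n_jobs == 1:
            pvals = [_replicate_safe(config, r) for r in range(R)]
        else:
            pvals = Parallel(n_jobs=n_jobs)(
                delayed(_replicate_safe)(config, r) for r in range(R)
            )
        failures = sum(p is None for p in pvals)
        ok = [p for p in pvals if p is not None]
        rejections = sum(p < alpha for p in ok)
        denom = len(ok) if drop_failures else R
        rate = rejections / denom if denom else np.nan
        mc_se = np.sqrt(rate * (1.0 - rate) / denom) if denom else np.nan
        rows.append(
            {
                "model": config.model,
                "n_persons": config.n_persons,
                "n_items": config.n_items,
                "covariate": config.covariate,
                "impact": config.impact,
                "dif": config.dif,
                "direction": config.direction,
                "estimation": config.estimation,
                "engine": config.engine,
                "reps": R,
                "failures": failures,
                "rejections": rejections,
                "rate": rate,
                "mc_se": mc_se,
                "alpha": alpha,
                "seed": config.seed,
            }
        )
        if progress:
            print(f"[run_study] {config.cell_id}: rate={rate:.3f}", flush=True)
    return pd.DataFrame(rows)
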