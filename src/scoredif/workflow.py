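"""End-to-end pipeline: fit -> scores -> process -> statistic -> p-value."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .estimation import FittedModel, ResponseData, fit
from .invariance_tests import CategoricalBins, TestResult, score_test
from .irt_core import ModelTag, PriorSpec
from .score_process import (
    CovarianceEstimate,
    CumulativeScoreProcess,
    build_process,
    center,
    covariance,
    score_contributions,
)

__all__ = ["InvarianceRun", "run_invariance_test"]


@dataclass
class InvarianceRun:
    """All artifacts of one invariance-test run."""

    result: TestResult
    fitted: FittedModel
    process: CumulativeScoreProcess
    cov: CovarianceEstimate


def run_invariance_test(
    data: ResponseData,
    model: ModelTag = "2PL",
    method: Literal["MML", "MAP"] = "MML",
    prior: PriorSpec | None = None,
    groups: bool = False,
    engine: Literal["asymptotic", "simulation"] = "asymptotic",
    statistic: Literal["DM", "LM_uo"] | None = None,
    weighted: bool = True,
    R: int = 1000,
    seed: int | None = None,
) -> InvarianceRun:
    """Run the full score-based invariance test on a response dataset.

    ``data.covariate`` supplies the ordering variable.  When ``statistic``
    is None it is chosen from the covariate type: DM for numeric
    (continuous) covariates, LM_uo for non-numeric (categorical) ones.
    Decorrelation is pooled for the asymptotic engine and group-wise (when
    the fit has multiple groups) for the simulation engine.
    """
    if data.covariate is None:
        raise ValueError("invariance testing requires a person covariate")
    fitted = fit(data, model=model, method=method, prior=prior, groups=groups)
    raw = score_contributions(data, fitted)
    centered = center(raw)

    cov_vals = np.asarray(data.covariate)
    if statistic is None:
        continuous = np.issubdtype(cov_vals.dtype, np.number) and (
            np.unique(cov_vals).size > min(10, max(2, data.n_persons // 10))
        )
        statistic = "DM" if continuous else "LM_uo"

    groupwise = engine == "simulation" and groups and data.groups is not None
    cov = covariance(
        centered,
        mode="groupwise" if groupwise else "pooled",
        groups=data.groups if groupwise else None,
    )
    process = build_process(
        centered, cov, cov_vals, groups=data.groups if groupwise else None
    )
    bins = (
        CategoricalBins.from_sorted_covariate(process.covariate_sorted)
        if statistic == "LM_uo"
        else None
    )
    result = score_test(
        process, statistic=statistic, engine=engine, bins=bins,
        weighted=weighted, R=R, seed=seed, cov=cov,
    )
    return InvarianceRun(result, fitted, process, cov)
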