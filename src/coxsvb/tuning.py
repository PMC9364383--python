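"""Cross-validation hyperparameter tuning.

Grid search over the Laplace rate lambda and the Beta a0 parameter (b0
fixed), scoring each cell by goodness-of-fit measures evaluated on
training and validation folds: Monte-Carlo ELBO, expected log partial
likelihood (ELL) and Harrell's c-index.  Centering statistics are always
computed on the training folds and applied to the held-out fold, never
the reverse.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import cavi, inference
from .cavi import PriorSpec
from .data import SurvivalDataset, build_risk_sets, center_covariates
from .likelihood import expected_log_partial_likelihood_mc

logger = logging.getLogger("coxsvb")

__all__ = ["TuningGrid", "kfold_split", "default_prior", "cv_grid_search"]

CRITERIA = ("elbo", "ell", "cindex")


@dataclass(frozen=True)
class TuningGrid:
    lambda_values: tuple[float, ...]
    a0_values: tuple[float, ...]
    b0: float
    n_folds: int = 10
    criterion: str = "ell"
    seed: int = 0
    n_draws: int = 2_000  # Monte-Carlo draws for ELBO/ELL per evaluation

    def __post_init__(self):
        if not self.lambda_values or not self.a0_values:
            raise ValueError("lambda and a0 grids must be nonempty")
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if self.criterion not in CRITERIA:
            raise ValueError(f"criterion must be one of {CRITERIA}")


def kfold_split(data: SurvivalDataset, n_folds: int, seed: int = 0) -> np.ndarray:
    """Deterministic partition of subjects into near-equal folds.

    Returns a length-n array of fold labels in 0..n_folds-1; sizes differ
    by at most one.
    """
    if data.n < n_folds:
        raise ValueError("more folds than subjects")
    rng = np.random.default_rng(seed)
    labels = np.arange(data.n) % n_folds
    return labels[rng.permutation(data.n)]


def default_prior(p: int, profile: str = "simulation") -> PriorSpec:
    """Conventional prior profiles.

    ``simulation``: lam=1, a0=1, b0=p (the configuration used when
    benchmarking against MCMC).  ``omics``: lam=1, a0=p/100 (floored at
    0.01), b0=p — a-priori ~1% of features are relevant.
    """
    if p < 1:
        raise ValueError("p must be >= 1")
    if profile == "simulation":
        return PriorSpec(lam=1.0, a0=1.0, b0=float(p))
    if profile == "omics":
        return PriorSpec(lam=1.0, a0=max(p / 100.0, 0.01), b0=float(p))
    raise ValueError(f"unknown profile {profile!r}; choose 'simulation' or 'omics'")


def _subset(data: SurvivalDataset, mask: np.ndarray) -> SurvivalDataset:
    return SurvivalDataset(
        times=data.times[mask],
        events=data.events[mask],
        design=data.design[mask],
        feature_names=data.feature_names,
    )


def cv_grid_search(
    data: SurvivalDataset,
    grid: TuningGrid,
    center: bool = True,
    fit_kwargs: dict | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Evaluate every (lambda, a0) cell by k-fold cross-validation.

    Returns the long-format report (one row per cell, fold, split and
    criterion) and the best cell by mean validation value of the grid's
    criterion; ties break toward larger lambda (the sparser model).
    """
    fit_kwargs = dict(fit_kwargs or {})
    folds = kfold_split(data, grid.n_folds, grid.seed)
    for f in range(grid.n_folds):
        if data.events[folds != f].sum() == 0:
            raise ValueError(f"training split for fold {f} has zero events")
    rows = []
    for lam in grid.lambda_values:
        for a0 in grid.a0_values:
            prior = PriorSpec(lam=lam, a0=a0, b0=grid.b0)
            for f in range(grid.n_folds):
                train_mask = folds != f
                train = _subset(data, train_mask)
                valid = _subset(data, ~train_mask)
                if center:
                    train, means = center_covariates(train)
                    valid, _ = center_covariates(valid, means=means)
                fit_seed = grid.seed * 10_000 + f
                try:
                    result = cavi.fit(train, prior, seed=fit_seed, **fit_kwargs)
                except Exception as exc:  # noqa: BLE001
                    logger.warning(
                        "fit failed for lambda=%g a0=%g fold %d: %s", lam, a0, f, exc
                    )
                    rows.append({"lambda": lam, "a0": a0, "fold": f,
                                 "incomplete": True})
                    continue
                row = {"lambda": lam, "a0": a0, "fold": f, "incomplete": False,
                       "fit_seed": fit_seed}
                beta_hat = inference.posterior_mean(result.params)
                for split, ds in (("train", train), ("validation", valid)):
                    risk = build_risk_sets(ds)
                    elbo, _ = inference.elbo_mc(
                        ds, risk, result.params, prior,
                        n_draws=grid.n_draws, seed=fit_seed,
                    )
                    ell, _ = expected_log_partial_likelihood_mc(
                        ds, risk, result.params, grid.n_draws, fit_seed
                    )
                    eta = inference.prognostic_index(ds, beta_hat)
                    try:
                        cindex = inference.concordance_index(ds.times, ds.events, eta)
                    except ValueError:
                        cindex = float("nan")
                    row[f"{split}_elbo"] = elbo
                    row[f"{split}_ell"] = ell
                    row[f"{split}_cindex"] = cindex
                rows.append(row)
    report = pd.DataFrame(rows)
    col = f"validation_{grid.criterion}"
    cells = (
        report[~report["incomplete"]]
        .groupby(["lambda", "a0"])[col]
        .agg(["mean", "std"])
        .reset_index()
    )
    # best by validation criterion; ties toward larger lambda (sparser fit)
    cells = cells.sort_values(["mean", "lambda"], ascending=[False, False])
    best_row = cells.iloc[0]
    best = {
        "lambda": float(best_row["lambda"]),
        "a0": float(best_row["a0"]),
        "b0": grid.b0,
        "criterion": grid.criterion,
        "value": float(best_row["mean"]),
    }
    logger.info("best cell: lambda=%g a0=%g (%s=%.4f)",
                best["lambda"], best["a0"], grid.criterion, best["value"])
    return report, best
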