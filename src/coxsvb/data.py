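"""Right-censored survival data with high-dimensional covariates.

Data model, delimited-file I/O, preprocessing (coefficient-of-variation
filtering, centering) and risk-set construction for the Cox partial
likelihood.  A dataset is ``{(t_i, delta_i, x_i)}`` with strictly positive
times ``t_i``, binary event indicators ``delta_i`` (1 = event observed,
0 = right-censored) and covariate rows ``x_i``.  Subject order is always
the input row order; nothing here re-sorts the stored dataset.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger("coxsvb")

__all__ = [
    "SurvivalDataset",
    "RiskSetIndex",
    "NoEventsError",
    "load_dataset",
    "save_dataset",
    "build_risk_sets",
    "center_covariates",
    "cv_filter",
]


class NoEventsError(ValueError):
    """Raised when a dataset contains no uncensored subjects.

    The partial likelihood is a product over event times only, so it is
    undefined (an empty product with no information about beta) when every
    subject is censored.
    """


@dataclass
class SurvivalDataset:
    """One row per subject: observed time, event indicator, covariates.

    Attributes
    ----------
    times : (n,) array of strictly positive floats
    events : (n,) array of 0/1 indicators (1 = event observed)
    design : (n, p) covariate matrix
    feature_names : optional list of p identifiers
    """

    times: np.ndarray
    events: np.ndarray
    design: np.ndarray
    feature_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.events = np.asarray(self.events)
        self.design = np.atleast_2d(np.asarray(self.design, dtype=float))
        if self.times.ndim != 1:
            raise ValueError("times must be one-dimensional")
        n = self.times.shape[0]
        if self.events.shape != (n,):
            raise ValueError("events length does not match times")
        if self.design.shape[0] != n:
            raise ValueError(
                f"design has {self.design.shape[0]} rows for {n} subjects"
            )
        if np.isnan(self.times).any():
            bad = int(np.flatnonzero(np.isnan(self.times))[0])
            raise ValueError(f"NaN time at row {bad}")
        if not np.all(self.times > 0):
            bad = int(np.flatnonzero(~(self.times > 0))[0])
            raise ValueError(f"nonpositive time at row {bad}: {self.times[bad]}")
        ev = np.asarray(self.events, dtype=float)
        if np.isnan(ev).any():
            bad = int(np.flatnonzero(np.isnan(ev))[0])
            raise ValueError(f"NaN event indicator at row {bad}")
        if not np.isin(ev, (0.0, 1.0)).all():
            bad = int(np.flatnonzero(~np.isin(ev, (0.0, 1.0)))[0])
            raise ValueError(
                f"event indicator must be 0 or 1; row {bad} has {self.events[bad]}"
            )
        self.events = ev.astype(np.int8)
        if np.isnan(self.design).any():
            bad = int(np.flatnonzero(np.isnan(self.design).any(axis=1))[0])
            raise ValueError(f"NaN covariate at row {bad}")
        if self.feature_names is not None:
            self.feature_names = list(self.feature_names)
            if len(self.feature_names) != self.design.shape[1]:
                raise ValueError("feature_names length does not match design")

    @property
    def n(self) -> int:
        return self.times.shape[0]

    @property
    def p(self) -> int:
        return self.design.shape[1]

    @property
    def n_events(self) -> int:
        return int(self.events.sum())

    def names(self) -> list[str]:
        """Feature names, defaulting to x1..xp."""
        if self.feature_names is not None:
            return list(self.feature_names)
        return [f"x{j + 1}" for j in range(self.p)]


@dataclass
class RiskSetIndex:
    """Risk sets R(t_i) = {r : t_r >= t_i} for each uncensored subject.

    ``event_order`` lists the uncensored subjects in input-row order and
    ``risk_members[k]`` holds the member indices of R(t_{event_order[k]}).
    Every risk set contains its own event subject; ties in time are handled
    by the literal definition t_r >= t_i (Breslow-style), so tied subjects
    appear in each other's risk sets.
    """

    event_order: np.ndarray
    risk_members: list[np.ndarray]

    def __post_init__(self) -> None:
        self.event_order = np.asarray(self.event_order, dtype=np.intp)
        self.risk_members = [np.asarray(m, dtype=np.intp) for m in self.risk_members]
        if len(self.risk_members) != len(self.event_order):
            raise ValueError("one risk set required per event subject")

    @property
    def n_events(self) -> int:
        return len(self.event_order)


def build_risk_sets(data: SurvivalDataset) -> RiskSetIndex:
    """Construct the risk set of every uncensored subject.

    Raises
    ------
    NoEventsError
        If no subject has an observed event.
    """
    event_idx = np.flatnonzero(data.events == 1)
    if event_idx.size == 0:
        raise NoEventsError("no uncensored subjects: partial likelihood undefined")
    members = [np.flatnonzero(data.times >= data.times[i]) for i in event_idx]
    return RiskSetIndex(event_order=event_idx, risk_members=members)


def center_covariates(
    data: SurvivalDataset, means: np.ndarray | None = None
) -> tuple[SurvivalDataset, np.ndarray]:
    """Subtract column means from the design matrix.

    If ``means`` is given (e.g. computed on training folds) it is applied
    as-is, so held-out folds can reuse the training transformation.
    Returns the centered dataset and the means that were subtracted.
    """
    if means is None:
        means = data.design.mean(axis=0)
    means = np.asarray(means, dtype=float)
    if means.shape != (data.p,):
        raise ValueError("means length does not match number of features")
    centered = SurvivalDataset(
        times=data.times.copy(),
        events=data.events.copy(),
        design=data.design - means,
        feature_names=data.feature_names,
    )
    return centered, means


def coefficient_of_variation(design: np.ndarray) -> np.ndarray:
    """Per-column sd/mean; zero-mean columns get +inf (always retained).

    Intended for nonnegative-scale feature matrices (e.g. expression
    values) before centering.
    """
    design = np.atleast_2d(np.asarray(design, dtype=float))
    mean = design.mean(axis=0)
    sd = design.std(axis=0, ddof=1) if design.shape[0] > 1 else np.zeros(design.shape[1])
    cv = np.full(design.shape[1], np.inf)
    nz = mean != 0
    cv[nz] = sd[nz] / mean[nz]
    if (~nz).any():
        logger.warning(
            "%d zero-mean column(s) assigned CV = +inf and retained", int((~nz).sum())
        )
    return cv


def cv_filter(data: SurvivalDataset) -> tuple[SurvivalDataset, list[str]]:
    """Drop features whose coefficient of variation is below the median.

    Features with CV exactly equal to the median are retained, so an
    all-identical-CV matrix is returned unchanged.  Returns the filtered
    dataset and the retained feature names.
    """
    cv = coefficient_of_variation(data.design)
    keep = cv >= np.median(cv)
    names = data.names()
    retained = [nm for nm, k in zip(names, keep) if k]
    filtered = SurvivalDataset(
        times=data.times.copy(),
        events=data.events.copy(),
        design=data.design[:, keep],
        feature_names=retained if data.feature_names is not None else None,
    )
    logger.info("cv_filter retained %d of %d features", filtered.p, data.p)
    return filtered, retained


def load_dataset(
    path: str | Path,
    time_col: str = "time",
    event_col: str = "status",
    sep: str | None = None,
) -> SurvivalDataset:
    """Read a delimited table (CSV/TSV with header) into a dataset.

    The table must contain ``time_col`` and ``event_col``; every remaining
    column is treated as a covariate.  The delimiter is inferred from the
    file extension (.tsv/.txt -> tab) unless given.
    """
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    df = pd.read_csv(path, sep=sep)
    for col in (time_col, event_col):
        if col not in df.columns:
            raise KeyError(f"required column {col!r} not found in {path.name}")
    feat_cols = [c for c in df.columns if c not in (time_col, event_col)]
    if not feat_cols:
        raise KeyError(f"no covariate columns found in {path.name}")
    return SurvivalDataset(
        times=df[time_col].to_numpy(),
        events=df[event_col].to_numpy(),
        design=df[feat_cols].to_numpy(dtype=float),
        feature_names=feat_cols,
    )


def save_dataset(
    data: SurvivalDataset,
    path: str | Path,
    time_col: str = "time",
    event_col: str = "status",
    sidecar: dict | None = None,
) -> None:
    """Write a dataset back to a delimited table (dialect from extension).

    ``sidecar`` (e.g. centering means, retained features) is written as
    JSON next to the table.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    df = pd.DataFrame(data.design, columns=data.names())
    df.insert(0, event_col, data.events)
    df.insert(0, time_col, data.times)
    df.to_csv(path, sep=sep, index=False)
    if sidecar is not None:
        path.with_suffix(path.suffix + ".json").write_text(
            json.dumps(sidecar, indent=2, default=_json_default)
        )


def _json_default(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    raise TypeError(f"not JSON serializable: {type(obj)}")
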