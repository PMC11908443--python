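"""Height prediction from local and published models, and error metrics.

Two published height-diameter equations are bundled with their printed
coefficients: the regional Guyana-shield model (a Weibull form,
H = 42.845·(1 − exp(−0.0433·D^0.9372))) and the pantropical climate model
(H = exp(0.893 − E + 0.760·lnD − 0.0340·ln²D)), where E is a scalar
environmental-stress index supplied by the caller.

Estimated-vs-measured comparisons are summarized by the total (TE,
root-mean-square), systematic (SE, mean) and random (RE, sample SD) error
components, and by their per-tree proportional analogues CVTE/CVSE/CVRE
computed on (est − meas)/meas.  The algebraic identity
TE² = SE² + ((n−1)/n)·RE² holds exactly for every summary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data_model_io import DataError, ForestDataset
from .hd_allometry import HDFit, get_model, rank_models

__all__ = [
    "PublishedHeightModel",
    "GUYANA_SHIELD",
    "PANTROPICAL",
    "published_models",
    "predict_height",
    "ErrorSummary",
    "error_summary",
    "stratified_errors",
    "compare_height_models",
]


@dataclass(frozen=True)
class PublishedHeightModel:
    """A literature height model with immutable printed coefficients."""

    name: str
    requires_E: bool

    def predict(self, dbh, E: float | None = None) -> np.ndarray:
        D = np.asarray(dbh, dtype=float)
        if np.any(D <= 0):
            raise DataError("dbh must be positive")
        if self.name == "guyana_shield":
            # identical to the registry Weibull form at (42.845, 0.0433, 0.9372)
            return get_model("weibull")((42.845, 0.0433, 0.9372), D)
        if self.name == "pantropical":
            if E is None:
                raise DataError("the pantropical model requires the stress index E")
            lnD = np.log(D)
            return np.exp(0.893 - E + 0.760 * lnD - 0.0340 * lnD**2)
        raise ValueError(f"unknown published model {self.name!r}")


GUYANA_SHIELD = PublishedHeightModel("guyana_shield", requires_E=False)
PANTROPICAL = PublishedHeightModel("pantropical", requires_E=True)


def published_models() -> tuple[PublishedHeightModel, PublishedHeightModel]:
    return GUYANA_SHIELD, PANTROPICAL


def predict_height(model, dbh, E: float | None = None) -> np.ndarray:
    """Evaluate a fitted local model (HDFit) or a published model at dbh."""
    if isinstance(model, PublishedHeightModel):
        return model.predict(dbh, E)
    if isinstance(model, HDFit):
        D = np.asarray(dbh, dtype=float)
        if np.any(D <= 0):
            raise DataError("dbh must be positive")
        return model.predict(D)
    raise TypeError(f"cannot predict heights with {type(model).__name__}")


@dataclass
class ErrorSummary:
    """TE/SE/RE and proportional CVTE/CVSE/CVRE for (est, meas) pairs.

    RE and CVRE are NaN ("undefined markers") when n < 2; every metric is
    NaN when n = 0.
    """

    n: int
    te: float
    se: float
    re: float
    cvte: float
    cvse: float
    cvre: float
    size_class: str = "all"

    def as_dict(self) -> dict:
        return {"size_class": self.size_class, "n": self.n,
                "te": self.te, "se": self.se, "re": self.re,
                "cvte": self.cvte, "cvse": self.cvse, "cvre": self.cvre}


def error_summary(est, meas, size_class: str = "all") -> ErrorSummary:
    """TE, SE, RE and their proportional analogues for paired values."""
    est = np.asarray(est, dtype=float)
    meas = np.asarray(meas, dtype=float)
    if est.shape != meas.shape:
        raise DataError("est and meas must have equal length")
    n = est.size
    nan = float("nan")
    if n == 0:
        return ErrorSummary(0, nan, nan, nan, nan, nan, nan, size_class)
    err = est - meas
    te = math.sqrt(float(np.mean(err**2)))
    se = float(np.mean(err))
    re = math.sqrt(float(np.sum((err - se) ** 2) / (n - 1))) if n >= 2 else nan
    if np.any(meas <= 0):
        raise DataError("proportional error metrics need strictly positive meas")
    p = err / meas
    cvte = math.sqrt(float(np.mean(p**2)))
    cvse = float(np.mean(p))
    cvre = math.sqrt(float(np.sum((p - cvse) ** 2) / (n - 1))) if n >= 2 else nan
    return ErrorSummary(n, te, se, re, cvte, cvse, cvre, size_class)


def _class_label(lo: float, hi: float) -> str:
    if math.isinf(hi):
        return f"[{lo:g}, inf)"
    return f"[{lo:g}, {hi:g})"


def stratified_errors(dbh, est, meas,
                      breakpoints: Sequence[float] = ()) -> list[ErrorSummary]:
    """One error summary per half-open DBH class [low, high), plus "all".

    Empty classes yield summaries with n = 0 and NaN metrics.
    """
    dbh = np.asarray(dbh, dtype=float)
    est = np.asarray(est, dtype=float)
    meas = np.asarray(meas, dtype=float)
    bps = list(breakpoints)
    if any(b2 <= b1 for b1, b2 in zip(bps, bps[1:])):
        raise DataError("breakpoints must be strictly increasing")
    edges = [-math.inf] + bps + [math.inf]
    out = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        if not bps:
            break
        mask = (dbh >= lo) & (dbh < hi)
        label = _class_label(max(lo, 0.0), hi)
        out.append(error_summary(est[mask], meas[mask], label))
    out.append(error_summary(est, meas, "all"))
    return out


def compare_height_models(
    ds: ForestDataset,
    fits: Sequence[HDFit] = (),
    published: Sequence[PublishedHeightModel] = (),
    E: float | None = None,
    breakpoints: Sequence[float] = (30.0,),
) -> pd.DataFrame:
    """Stratified error summaries of every model against measured heights.

    Returns a long-format table (model, size_class, n, te, se, re, cvte,
    cvse, cvre); the best local model per the ranking rules is flagged.
    """
    sub = ds.with_heights()
    if not len(sub):
        raise DataError("no measured heights to compare against")
    dbh = np.array([r.dbh for r in sub.records])
    meas = np.array([r.height for r in sub.records])
    best_name = rank_models(fits)[0].name if fits else None
    rows = []
    for model in list(fits) + list(published):
        name = model.name
        est = predict_height(model, dbh, E)
        for summ in stratified_errors(dbh, est, meas, breakpoints):
            row = summ.as_dict()
            row["model"] = name
            row["is_best_local"] = name == best_name
            rows.append(row)
    cols = ["model", "size_class", "n", "te", "se", "re",
            "cvte", "cvse", "cvre", "is_best_local"]
    return pd.DataFrame(rows)[cols]
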