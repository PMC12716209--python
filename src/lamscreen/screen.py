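"""Regression-band senescence screening.

A control (proliferating) population defines a linear law between per-cell
lamin B1 and lamin A mean intensities. A cell is called senescent when its
lamin A exceeds the control mean + 2 SD, its lamin B1 exceeds the control
mean + 2 SD, or its B1 falls outside the two-sided 95% prediction band of
the control regression at its A value. Cells inside all three bounds are
non-senescent.

The "deviation from the linear correlation" criterion is implemented as a
*prediction* interval for a single new observation (not a mean-response
confidence band): by construction ~95% of control-like cells fall inside it
regardless of control sample size.

When the control fit has R^2 below ``r2_min`` (heterogeneous control, e.g. a
spontaneously senescent subpopulation), the model is corrected by iterative
trimming: points with |internally studentized residual| > 2 are removed and
the model refit, up to ``max_iter`` rounds or until R^2 >= r2_min. Channel
thresholds are recomputed from the post-trim subset.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    ConfigurationError,
    DegenerateInputError,
    InputError,
    InsufficientControlError,
    LamscreenError,
)
from .synth import NON_SENESCENT, SENESCENT

MIN_CONTROL_CELLS = 10


@dataclass(frozen=True)
class ControlModel:
    """Fitted control statistics used by the classifier."""

    slope: float
    intercept: float
    n_control: int
    r_squared: float
    resid_sd: float
    x_mean: float
    sxx: float
    alpha: float
    mean_a: float
    sd_a: float
    mean_b1: float
    sd_b1: float
    correction_applied: bool = False
    correction_iterations: int = 0

    @property
    def thr_a(self) -> float:
        return self.mean_a + 2.0 * self.sd_a

    @property
    def thr_b1(self) -> float:
        return self.mean_b1 + 2.0 * self.sd_b1

    def to_json(self, path: str | Path | None = None) -> str:
        payload = dataclasses.asdict(self)
        payload["thr_a"] = self.thr_a
        payload["thr_b1"] = self.thr_b1
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "ControlModel":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        payload = json.loads(text)
        payload.pop("thr_a", None)
        payload.pop("thr_b1", None)
        return cls(**payload)


@dataclass
class ScreenResult:
    """Per-cell labels with reason flags plus per-group summaries."""

    cells: pd.DataFrame  # input columns + screen_label, high_a, high_b1, off_line, off_line_side
    summary: pd.DataFrame  # group keys + n_cells, n_senescent, fraction_senescent
    model: ControlModel


def _ols(a: np.ndarray, b1: np.ndarray) -> tuple[float, float, float, float, float, float]:
    """OLS of b1 on a; returns slope, intercept, r2, resid_sd, x_mean, sxx."""
    n = len(a)
    x_mean = float(a.mean())
    y_mean = float(b1.mean())
    dx = a - x_mean
    sxx = float(dx @ dx)
    if sxx == 0:
        raise DegenerateInputError("zero variance in lamin_a: degenerate control fit")
    slope = float(dx @ (b1 - y_mean) / sxx)
    intercept = y_mean - slope * x_mean
    resid = b1 - (slope * a + intercept)
    sse = float(resid @ resid)
    sst = float((b1 - y_mean) @ (b1 - y_mean))
    r2 = 1.0 if sst == 0 else 1.0 - sse / sst
    resid_sd = float(np.sqrt(sse / (n - 2))) if n > 2 else 0.0
    return slope, intercept, r2, resid_sd, x_mean, sxx


def _studentized_residuals(
    a: np.ndarray, b1: np.ndarray, slope: float, intercept: float,
    resid_sd: float, x_mean: float, sxx: float,
) -> np.ndarray:
    n = len(a)
    leverage = 1.0 / n + (a - x_mean) ** 2 / sxx
    denom = resid_sd * np.sqrt(np.clip(1.0 - leverage, 1e-12, None))
    resid = b1 - (slope * a + intercept)
    if resid_sd == 0:
        return np.zeros_like(resid)
    return resid / denom


def fit_control_model(
    control: pd.DataFrame,
    alpha: float = 0.05,
    r2_min: float = 0.95,
    max_iter: int = 5,
) -> ControlModel:
    """Fit the lamin B1 ~ lamin A control model with heterogeneity correction.

    Raises :class:`InsufficientControlError` for fewer than 10 control cells.
    """
    for col in ("lamin_a", "lamin_b1"):
        if col not in control.columns:
            raise InputError(f"control table missing column {col!r}")
    a = control["lamin_a"].to_numpy(dtype=float)
    b1 = control["lamin_b1"].to_numpy(dtype=float)
    finite = np.isfinite(a) & np.isfinite(b1)
    a, b1 = a[finite], b1[finite]
    if len(a) < MIN_CONTROL_CELLS:
        raise InsufficientControlError(
            f"need >= {MIN_CONTROL_CELLS} control cells, got {len(a)}"
        )

    slope, intercept, r2, resid_sd, x_mean, sxx = _ols(a, b1)
    corrected = False
    iterations = 0
    while r2 < r2_min and iterations < max_iter:
        t = _studentized_residuals(a, b1, slope, intercept, resid_sd, x_mean, sxx)
        keep = np.abs(t) <= 2.0
        if keep.all() or keep.sum() < MIN_CONTROL_CELLS:
            break
        a, b1 = a[keep], b1[keep]
        slope, intercept, r2, resid_sd, x_mean, sxx = _ols(a, b1)
        corrected = True
        iterations += 1

    return ControlModel(
        slope=slope,
        intercept=intercept,
        n_control=len(a),
        r_squared=r2,
        resid_sd=resid_sd,
        x_mean=x_mean,
        sxx=sxx,
        alpha=alpha,
        mean_a=float(a.mean()),
        sd_a=float(a.std(ddof=1)),
        mean_b1=float(b1.mean()),
        sd_b1=float(b1.std(ddof=1)),
        correction_applied=corrected,
        correction_iterations=iterations,
    )


def prediction_band(model: ControlModel, a: float | np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two-sided (1 - alpha) prediction interval for B1 of a new cell at A=a.

    half-width = t_{1-alpha/2, n-2} * s * sqrt(1 + 1/n + (a - x_mean)^2 / Sxx)
    """
    if model.n_control < 3:
        raise LamscreenError("model must be fitted on >= 3 cells")
    a = np.asarray(a, dtype=float)
    y_hat = model.slope * a + model.intercept
    tcrit = stats.t.ppf(1.0 - model.alpha / 2.0, df=model.n_control - 2)
    half = tcrit * model.resid_sd * np.sqrt(
        1.0 + 1.0 / model.n_control + (a - model.x_mean) ** 2 / model.sxx
    )
    return y_hat - half, y_hat + half


def classify_cells(cells: pd.DataFrame, model: ControlModel) -> ScreenResult:
    """Label each cell senescent/non-senescent with reason flags.

    senescent iff lamin_a > thr_a OR lamin_b1 > thr_b1 OR lamin_b1 outside
    the prediction band at its lamin_a.
    """
    for col in ("lamin_a", "lamin_b1"):
        if col not in cells.columns:
            raise InputError(f"cells table missing column {col!r}")
    a = cells["lamin_a"].to_numpy(dtype=float)
    b1 = cells["lamin_b1"].to_numpy(dtype=float)
    lower, upper = prediction_band(model, a)

    high_a = a > model.thr_a
    high_b1 = b1 > model.thr_b1
    below = b1 < lower
    above = b1 > upper
    off_line = below | above
    senescent = high_a | high_b1 | off_line

    out = cells.copy()
    out["screen_label"] = np.where(senescent, SENESCENT, NON_SENESCENT)
    out["high_a"] = high_a
    out["high_b1"] = high_b1
    out["off_line"] = off_line
    out["off_line_side"] = np.select([above, below], ["above", "below"], default="")

    group_keys = [k for k in ("condition", "well", "timepoint_h") if k in out.columns]
    if group_keys:
        grouped = out.groupby(group_keys, sort=True, dropna=False)
        summary = grouped.agg(
            n_cells=("screen_label", "size"),
            n_senescent=("screen_label", lambda s: int((s == SENESCENT).sum())),
        ).reset_index()
    else:
        summary = pd.DataFrame(
            {"n_cells": [len(out)], "n_senescent": [int(senescent.sum())]}
        )
    summary["fraction_senescent"] = summary["n_senescent"] / summary["n_cells"]
    return ScreenResult(cells=out, summary=summary, model=model)


def screen_experiment(
    tables: Mapping[str, pd.DataFrame] | pd.DataFrame,
    control_key: str,
    alpha: float = 0.05,
    r2_min: float = 0.95,
) -> ScreenResult:
    """Fit one control model on ``control_key`` and classify every condition.

    ``tables`` is either a mapping condition -> cell table or a single table
    with a ``condition`` column.
    """
    if isinstance(tables, pd.DataFrame):
        if "condition" not in tables.columns:
            raise ConfigurationError("single-table input requires a 'condition' column")
        cells = tables
        control = tables[tables["condition"] == control_key]
        if control.empty:
            raise ConfigurationError(f"control condition {control_key!r} not found")
    else:
        if control_key not in tables:
            raise ConfigurationError(f"control condition {control_key!r} not found")
        control = tables[control_key]
        parts = []
        for cond, df in tables.items():
            part = df.copy()
            part["condition"] = cond
            parts.append(part)
        cells = pd.concat(parts, ignore_index=True)

    model = fit_control_model(control, alpha=alpha, r2_min=r2_min)
    return classify_cells(cells, model)


def screen_timecourse(
    wells: pd.DataFrame,
    alpha: float = 0.05,
    r2_min: float = 0.95,
    t0: float = 0.0,
) -> ScreenResult:
    """Per-well screening: each well's t = ``t0`` table is its own control.

    Returns a pooled :class:`ScreenResult`; ``summary`` has one row per
    (well, timepoint) and the attached model is the first well's (per-well
    models are stored in ``cells['well']``-wise classification). A
    per-condition mean trajectory is available via
    :func:`timecourse_condition_means`.
    """
    for col in ("well", "timepoint_h"):
        if col not in wells.columns:
            raise ConfigurationError(f"timecourse table missing column {col!r}")
    parts = []
    first_model: ControlModel | None = None
    for well, df in wells.groupby("well", sort=True):
        control = df[df["timepoint_h"] == t0]
        if control.empty:
            raise ConfigurationError(f"well {well!r} has no t = {t0} control table")
        model = fit_control_model(control, alpha=alpha, r2_min=r2_min)
        if first_model is None:
            first_model = model
        parts.append(classify_cells(df, model).cells)
    cells = pd.concat(parts, ignore_index=True)

    grouped = cells.groupby(["well", "timepoint_h"], sort=True)
    summary = grouped.agg(
        n_cells=("screen_label", "size"),
        n_senescent=("screen_label", lambda s: int((s == SENESCENT).sum())),
    ).reset_index()
    summary["fraction_senescent"] = summary["n_senescent"] / summary["n_cells"]
    assert first_model is not None
    return ScreenResult(cells=cells, summary=summary, model=first_model)


def timecourse_condition_means(result: ScreenResult) -> pd.DataFrame:
    """Mean senescent fraction over wells, per (condition, timepoint)."""
    cells = result.cells
    if "condition" not in cells.columns:
        raise InputError("cells lack a 'condition' column")
    per_well = (
        cells.assign(is_sen=cells["screen_label"] == SENESCENT)
        .groupby(["condition", "well", "timepoint_h"], sort=True)["is_sen"]
        .mean()
        .reset_index(name="fraction_senescent")
    )
    return (
        per_well.groupby(["condition", "timepoint_h"], sort=True)["fraction_senescent"]
        .mean()
        .reset_index()
    )


def lamin_ratio(cells: pd.DataFrame) -> pd.Series:
    """Per-cell lamin B1 / lamin A intensity ratio."""
    for col in ("lamin_a", "lamin_b1"):
        if col not in cells.columns:
            raise InputError(f"cells table missing column {col!r}")
    a = cells["lamin_a"].to_numpy(dtype=float)
    if np.any(a <= 0):
        raise InputError("lamin_a must be strictly positive to form the ratio")
    return pd.Series(cells["lamin_b1"].to_numpy(dtype=float) / a,
                     index=cells.index, name="lamin_ratio")
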