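"""Validation metrics, growth metrics and machine-readable run reports.

Confusion counts treat "senescent" as the positive class. Accuracy is
(TN + TP) / (TN + TP + FP + FN).

Growth rates come from an OLS fit of ln(count) versus time; the slope is
multiplied by 100 to give a percent-per-unit-time rate so the rule-of-70
doubling time (70 / rate) applies. The exact value 100 * ln(2) / rate is
reported alongside; for rates <= 10 %/unit the two differ by < 1.1%.
"""

from __future__ import annotations

import dataclasses
import json
import platform
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import InputError, LamscreenError
from .markers import MarkerThreshold
from .screen import ScreenResult
from .synth import LABELS, SENESCENT


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class GrowthSeries:
    timepoints: tuple[float, ...]
    counts: tuple[float, ...]
    growth_rate: float  # percent per unit time (100 * ln-slope)
    doubling_time: float  # rule-of-70: 70 / growth_rate
    doubling_time_exact: float  # 100 * ln(2) / growth_rate


def confusion_counts(
    truth: Sequence[str] | pd.Series, predicted: Sequence[str] | pd.Series
) -> ConfusionCounts:
    """Exact 2x2 tabulation with 'senescent' as the positive class."""
    t = np.asarray(truth, dtype=object)
    p = np.asarray(predicted, dtype=object)
    if t.shape != p.shape:
        raise InputError(f"label sets have different lengths: {t.shape} vs {p.shape}")
    for arr, name in ((t, "truth"), (p, "predicted")):
        bad = set(arr) - set(LABELS)
        if bad:
            raise InputError(f"unknown {name} label values: {sorted(map(str, bad))}")
    t_pos = t == SENESCENT
    p_pos = p == SENESCENT
    return ConfusionCounts(
        tp=int((t_pos & p_pos).sum()),
        tn=int((~t_pos & ~p_pos).sum()),
        fp=int((~t_pos & p_pos).sum()),
        fn=int((t_pos & ~p_pos).sum()),
    )


def accuracy(c: ConfusionCounts) -> float:
    """(TN + TP) / (TN + TP + FP + FN)."""
    if c.total <= 0:
        raise InputError("accuracy undefined for zero total count")
    return (c.tn + c.tp) / c.total


def sensitivity(c: ConfusionCounts) -> float:
    if c.tp + c.fn == 0:
        raise InputError("sensitivity undefined with no true positives or false negatives")
    return c.tp / (c.tp + c.fn)


def specificity(c: ConfusionCounts) -> float:
    if c.tn + c.fp == 0:
        raise InputError("specificity undefined with no true negatives or false positives")
    return c.tn / (c.tn + c.fp)


def doubling_time(growth_rate: float) -> float:
    """Rule-of-70 doubling time for a percent-per-unit-time growth rate."""
    if growth_rate <= 0:
        raise InputError(f"growth_rate must be > 0, got {growth_rate}")
    return 70.0 / growth_rate


def fit_growth(timepoints: Sequence[float], counts: Sequence[float]) -> GrowthSeries:
    """OLS of ln(count) on time; rate in percent per unit time."""
    t = np.asarray(timepoints, dtype=float)
    c = np.asarray(counts, dtype=float)
    if t.shape != c.shape:
        raise InputError("timepoints and counts must have equal length")
    if len(t) < 3:
        raise InputError("need >= 3 timepoints to fit a growth curve")
    if np.any(c <= 0):
        raise InputError("all counts must be > 0 for a semi-log fit")
    slope, _ = np.polyfit(t, np.log(c), 1)
    rate = 100.0 * float(slope)
    return GrowthSeries(
        timepoints=tuple(t),
        counts=tuple(c),
        growth_rate=rate,
        doubling_time=doubling_time(rate),
        doubling_time_exact=100.0 * np.log(2.0) / rate,
    )


def report(
    out_dir: str | Path,
    screen_result: ScreenResult,
    marker_thresholds: Sequence[MarkerThreshold] = (),
    truth_labels: pd.Series | None = None,
    config: Mapping[str, object] | None = None,
    seed: int | None = None,
) -> dict:
    """Write JSON + CSV run summaries; returns the JSON payload as a dict.

    Emits ``summary.csv`` (per-group fractions), ``cells.csv`` (per-cell
    labels) and ``report.json`` (control-model audit, marker thresholds,
    confusion counts and accuracy when ground truth is supplied, plus the
    run config/seed/version log).
    """
    if screen_result is None:
        raise LamscreenError("report requires a completed screen result")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    model = screen_result.model
    payload: dict = {
        "control_model": {
            "slope": model.slope,
            "intercept": model.intercept,
            "r_squared": model.r_squared,
            "resid_sd": model.resid_sd,
            "n_control": model.n_control,
            "thr_a": model.thr_a,
            "thr_b1": model.thr_b1,
            "correction_applied": model.correction_applied,
            "correction_iterations": model.correction_iterations,
        },
        "conditions": screen_result.summary.to_dict(orient="records"),
        "marker_thresholds": [
            {**dataclasses.asdict(m), "threshold": m.threshold} for m in marker_thresholds
        ],
        "log": {
            "seed": seed,
            "config": dict(config) if config else {},
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    if truth_labels is not None:
        counts = confusion_counts(truth_labels, screen_result.cells["screen_label"])
        payload["evaluation"] = {
            "tp": counts.tp,
            "tn": counts.tn,
            "fp": counts.fp,
            "fn": counts.fn,
            "accuracy": accuracy(counts),
        }

    screen_result.summary.to_csv(out / "summary.csv", index=False)
    screen_result.cells.to_csv(out / "cells.csv", index=False)
    (out / "report.json").write_text(json.dumps(payload, indent=2, sort_keys=True))
    return payload
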