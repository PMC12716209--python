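"""Marker positivity against a control mean + 2 SD threshold.

A cell is marker-positive iff its mean intensity is *strictly greater* than
the control mean plus twice the control sample SD (n-1 denominator). A cell
exactly at the threshold is negative. Fractions are reported both pooled
over cells and per field of view (FOV), mirroring dot-per-FOV plots.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InputError, InsufficientControlError
from .synth import NON_SENESCENT, SENESCENT

MIN_CONTROL_VALUES = 10


@dataclass(frozen=True)
class MarkerThreshold:
    channel: str
    control_mean: float
    control_sd: float
    n_control: int

    @property
    def threshold(self) -> float:
        return self.control_mean + 2.0 * self.control_sd

    def to_json(self, path: str | Path | None = None) -> str:
        payload = dataclasses.asdict(self)
        payload["threshold"] = self.threshold
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text


def marker_threshold(control_values, channel: str) -> MarkerThreshold:
    """Mean + 2 SD threshold from finite control values (sample SD, ddof=1)."""
    values = np.asarray(control_values, dtype=float)
    values = values[np.isfinite(values)]
    if len(values) < MIN_CONTROL_VALUES:
        raise InsufficientControlError(
            f"need >= {MIN_CONTROL_VALUES} finite control values for channel "
            f"{channel!r}, got {len(values)}"
        )
    return MarkerThreshold(
        channel=channel,
        control_mean=float(values.mean()),
        control_sd=float(values.std(ddof=1)),
        n_control=int(len(values)),
    )


def score_positivity(
    cells: pd.DataFrame, thr: MarkerThreshold
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-cell positivity (strict >) plus per-FOV and pooled fractions.

    Returns ``(scored_cells, fractions)`` where ``scored_cells`` adds a
    ``<channel>_positive`` boolean column and ``fractions`` has one row per
    (condition, fov) plus one pooled row per condition (fov = '__pooled__').
    """
    if thr.channel not in cells.columns:
        raise InputError(f"cells table missing marker channel {thr.channel!r}")
    out = cells.copy()
    flag = f"{thr.channel}_positive"
    out[flag] = out[thr.channel].to_numpy(dtype=float) > thr.threshold

    cond = out["condition"] if "condition" in out.columns else pd.Series("na", index=out.index)
    fov = out["fov_id"] if "fov_id" in out.columns else pd.Series("fov0", index=out.index)
    base = pd.DataFrame({"condition": cond, "fov_id": fov, "positive": out[flag]})

    per_fov = (
        base.groupby(["condition", "fov_id"], sort=True)["positive"]
        .agg(n_cells="size", n_positive="sum")
        .reset_index()
    )
    pooled = (
        base.groupby("condition", sort=True)["positive"]
        .agg(n_cells="size", n_positive="sum")
        .reset_index()
    )
    pooled["fov_id"] = "__pooled__"
    fractions = pd.concat([per_fov, pooled], ignore_index=True)
    fractions["n_positive"] = fractions["n_positive"].astype(int)
    fractions["fraction_positive"] = fractions["n_positive"] / fractions["n_cells"]
    return out, fractions


def stratify(
    marker_positive: pd.Series,
    screen_labels: pd.Series,
    groups: pd.Series | None = None,
) -> pd.DataFrame:
    """Cross-tabulate marker status within screened sub-populations.

    All three inputs must share an index (cell ids). Returns one row per
    group with the overall positive fraction and the positive fraction
    within the senescent and non-senescent sub-populations (NaN for an
    empty sub-population).
    """
    if not marker_positive.index.equals(screen_labels.index):
        raise InputError("marker and screen labels have mismatched cell ids")
    if groups is None:
        groups = pd.Series("all", index=marker_positive.index)
    elif not groups.index.equals(marker_positive.index):
        raise InputError("group keys have mismatched cell ids")

    df = pd.DataFrame(
        {"positive": marker_positive.astype(bool), "label": screen_labels, "group": groups}
    )
    rows = []
    for group, sub in df.groupby("group", sort=True):
        sen = sub[sub["label"] == SENESCENT]
        nsen = sub[sub["label"] == NON_SENESCENT]
        rows.append(
            {
                "group": group,
                "n_cells": len(sub),
                "n_senescent": len(sen),
                "fraction_positive": sub["positive"].mean(),
                "fraction_positive_in_senescent": sen["positive"].mean() if len(sen) else np.nan,
                "fraction_positive_in_non_senescent": nsen["positive"].mean() if len(nsen) else np.nan,
            }
        )
    return pd.DataFrame(rows)
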