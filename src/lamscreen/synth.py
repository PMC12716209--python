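"""Synthetic single-cell populations, rendered scenes, time courses and sorts.

Everything here produces data with *known* ground truth so the screening
classifier, segmentation and marker scoring can be validated end to end.
The generative model is deliberately simple:

* proliferating ("control") cells: lamin A ~ N(mean, sd) truncated > 0 and
  lamin B1 = slope * A + intercept + N(0, resid_sd);
* senescent cells: both channels of a control draw multiplied by
  ``senescent_fold``; a configurable subset additionally has B1 re-drawn
  from the (scaled) marginal control B1 distribution, breaking the
  A-B1 correlation.

Counts of senescent / decorrelated / marker-positive cells follow a
deterministic floor(n * frac) policy with the remainder assigned by a
seeded shuffle, so count-based tests are exact rather than binomial.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import CapacityError, ParameterError

SENESCENT = "senescent"
NON_SENESCENT = "non_senescent"
LABELS = (SENESCENT, NON_SENESCENT)

#: columns every truth table carries, in export order (marker columns follow)
TRUTH_COLUMNS = [
    "cell_id",
    "condition",
    "well",
    "timepoint_h",
    "true_label",
    "lamin_a",
    "lamin_b1",
]

_REDRAW_CAP = 100  # attempts to redraw a nonpositive intensity before erroring


@dataclass(frozen=True)
class PopulationSpec:
    """Parameters of one simulated cell population.

    Default control-law parameters are calibration choices of this package,
    not measured values.
    """

    n_cells: int = 1000
    frac_senescent: float = 0.0
    lamin_a_mean: float = 100.0
    lamin_a_sd: float = 20.0
    slope: float = 0.8
    intercept: float = 5.0
    resid_sd: float = 4.0
    senescent_fold: float = 3.0
    decorrelate_prob: float = 0.0
    seed: int = 0
    condition: str = "control"
    well: str = "A1"
    timepoint_h: float = 0.0

    def __post_init__(self) -> None:
        if self.n_cells < 0:
            raise ParameterError(f"n_cells must be >= 0, got {self.n_cells}")
        if not 0.0 <= self.frac_senescent <= 1.0:
            raise ParameterError(
                f"frac_senescent must lie in [0, 1], got {self.frac_senescent}"
            )
        if not 0.0 <= self.decorrelate_prob <= 1.0:
            raise ParameterError(
                f"decorrelate_prob must lie in [0, 1], got {self.decorrelate_prob}"
            )
        if self.lamin_a_sd <= 0:
            raise ParameterError(f"lamin_a_sd must be > 0, got {self.lamin_a_sd}")
        if self.resid_sd < 0:
            raise ParameterError(f"resid_sd must be >= 0, got {self.resid_sd}")
        if self.senescent_fold < 1:
            raise ParameterError(
                f"senescent_fold must be >= 1, got {self.senescent_fold}"
            )


@dataclass(frozen=True)
class SceneSpec:
    """Geometry and acquisition parameters for rendering a synthetic image."""

    image_shape: tuple[int, int] = (512, 512)
    nucleus_radius_range: tuple[float, float] = (8.0, 12.0)
    min_center_distance: float = 0.0
    background_level: float = 20.0
    noise_sd: float = 0.0
    channels: tuple[str, ...] = ("lamin_a", "lamin_b1")
    seed: int = 0
    max_attempts_per_nucleus: int = 1000
    #: clearance between a nucleus edge and the image border, so downstream
    #: blurring does not push foreground onto the border
    border_margin: float = 8.0

    def __post_init__(self) -> None:
        lo, hi = self.nucleus_radius_range
        if lo < 3 or hi < lo:
            raise ParameterError(
                "nucleus_radius_range must satisfy 3 <= lo <= hi, got "
                f"{self.nucleus_radius_range}"
            )
        if self.min_center_distance < 0:
            raise ParameterError("min_center_distance must be >= 0")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be >= 0")
        if min(self.image_shape) <= 2 * (hi + self.border_margin):
            raise ParameterError(
                f"image_shape {self.image_shape} cannot contain a nucleus of "
                f"radius {hi}"
            )


@dataclass(frozen=True)
class LogisticKinetics:
    """Logistic induction of the senescent fraction over time (hours)."""

    base: float
    plateau: float
    rate_per_h: float
    t50_h: float

    def __post_init__(self) -> None:
        for name in ("base", "plateau"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ParameterError(f"{name} must lie in [0, 1], got {v}")

    def fraction(self, t_h: float) -> float:
        """Senescent fraction base + (plateau-base) / (1 + exp(-k (t - t50)))."""
        z = -self.rate_per_h * (t_h - self.t50_h)
        return self.base + (self.plateau - self.base) / (1.0 + np.exp(z))


@dataclass
class SyntheticScene:
    """A rendered multi-channel image plus its ground truth."""

    image: np.ndarray  # (n_channels, H, W) float
    mask: np.ndarray  # (H, W) integer labels, 0 = background
    truth: pd.DataFrame
    channels: tuple[str, ...]


def _positive_normal(
    rng: np.random.Generator, mean, sd: float, size: int
) -> np.ndarray:
    """Normal draws truncated to be strictly positive by redrawing.

    Redraws each offending value up to ``_REDRAW_CAP`` times; beyond that the
    requested distribution is essentially nonpositive and we refuse to bend it.
    """
    mean = np.broadcast_to(np.asarray(mean, dtype=float), (size,))
    values = rng.normal(mean, sd)
    if sd == 0:
        if np.any(values <= 0):
            raise ParameterError("degenerate draw: nonpositive value with sd=0")
        return values
    for _ in range(_REDRAW_CAP):
        bad = values <= 0
        if not bad.any():
            return values
        values = np.where(bad, rng.normal(mean, sd), values)
    raise ParameterError(
        f"could not draw strictly positive intensities within {_REDRAW_CAP} "
        "redraws; mean/sd are incompatible with positivity"
    )


def _deterministic_flags(n: int, frac: float, rng: np.random.Generator) -> np.ndarray:
    """Boolean vector with exactly floor(n * frac) True, placed by seeded shuffle."""
    k = int(np.floor(n * frac))
    flags = np.zeros(n, dtype=bool)
    flags[:k] = True
    rng.shuffle(flags)
    return flags


def simulate_population(spec: PopulationSpec) -> pd.DataFrame:
    """Simulate one population as a truth table.

    Returns a DataFrame with :data:`TRUTH_COLUMNS`. Exactly
    ``floor(n_cells * frac_senescent)`` rows are senescent; of those, exactly
    ``floor(n_sen * decorrelate_prob)`` have B1 drawn independently of A
    (from the fold-scaled marginal control B1 distribution).
    """
    n = spec.n_cells
    rng = np.random.default_rng(spec.seed)

    sen = _deterministic_flags(n, spec.frac_senescent, rng)
    a = _positive_normal(rng, spec.lamin_a_mean, spec.lamin_a_sd, n)
    b1 = _positive_normal(rng, spec.slope * a + spec.intercept, spec.resid_sd, n)

    a = np.where(sen, a * spec.senescent_fold, a)
    b1 = np.where(sen, b1 * spec.senescent_fold, b1)

    n_sen = int(sen.sum())
    if n_sen and spec.decorrelate_prob > 0:
        deco_local = _deterministic_flags(n_sen, spec.decorrelate_prob, rng)
        n_deco = int(deco_local.sum())
        if n_deco:
            a_indep = _positive_normal(rng, spec.lamin_a_mean, spec.lamin_a_sd, n_deco)
            b1_indep = _positive_normal(
                rng, spec.slope * a_indep + spec.intercept, spec.resid_sd, n_deco
            )
            deco = np.zeros(n, dtype=bool)
            deco[np.flatnonzero(sen)[deco_local]] = True
            b1[deco] = b1_indep * spec.senescent_fold

    return pd.DataFrame(
        {
            "cell_id": np.arange(n),
            "condition": spec.condition,
            "well": spec.well,
            "timepoint_h": float(spec.timepoint_h),
            "true_label": np.where(sen, SENESCENT, NON_SENESCENT),
            "lamin_a": a,
            "lamin_b1": b1,
        }
    )


def _place_nuclei(
    n: int, spec: SceneSpec, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Rejection-sample non-overlapping ellipse centers and radii.

    Returns (centers (n, 2) float, radii (n, 2) float). Overlap is forbidden:
    accepted centers are at least ``r_i + r_j + 2`` apart (and at least
    ``min_center_distance``).
    """
    lo, hi = spec.nucleus_radius_range
    h, w = spec.image_shape
    centers = np.empty((n, 2))
    radii = np.empty((n, 2))
    for i in range(n):
        ry, rx = rng.uniform(lo, hi, size=2)
        r = max(ry, rx)
        placed = False
        margin = r + spec.border_margin
        for _ in range(spec.max_attempts_per_nucleus):
            cy = rng.uniform(margin, h - margin)
            cx = rng.uniform(margin, w - margin)
            if i:
                d = np.hypot(centers[:i, 0] - cy, centers[:i, 1] - cx)
                min_required = np.maximum(
                    spec.min_center_distance,
                    np.max(radii[:i], axis=1) + r + 2.0,
                )
                if np.any(d < min_required):
                    continue
            centers[i] = (cy, cx)
            radii[i] = (ry, rx)
            placed = True
            break
        if not placed:
            raise CapacityError(
                f"could not place nucleus {i + 1}/{n} after "
                f"{spec.max_attempts_per_nucleus} attempts; image_shape="
                f"{spec.image_shape} with min_center_distance="
                f"{spec.min_center_distance} is too crowded"
            )
    return centers, radii


def render_scene(truth: pd.DataFrame, spec: SceneSpec) -> SyntheticScene:
    """Render one nucleus per truth row as a filled ellipse over background.

    Foreground pixels are set *to* the cell's channel intensity (not added to
    background), so with ``noise_sd=0`` the per-nucleus mean over its mask
    equals the truth-table value exactly. Additive Gaussian noise of
    ``noise_sd`` is applied to every pixel afterwards.
    """
    for name in spec.channels:
        if name not in truth.columns:
            raise ParameterError(f"channel {name!r} missing from truth table")
    n = len(truth)
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_shape
    image = np.full((len(spec.channels), h, w), spec.background_level, dtype=float)
    mask = np.zeros((h, w), dtype=np.int32)

    if n:
        centers, radii = _place_nuclei(n, spec, rng)
        yy, xx = np.mgrid[0:h, 0:w]
        for k in range(n):
            cy, cx = centers[k]
            ry, rx = radii[k]
            inside = ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0
            mask[inside] = k + 1
            for ci, name in enumerate(spec.channels):
                image[ci][inside] = float(truth[name].iloc[k])

    if spec.noise_sd > 0:
        image = image + rng.normal(0.0, spec.noise_sd, size=image.shape)

    return SyntheticScene(
        image=image, mask=mask, truth=truth.reset_index(drop=True),
        channels=tuple(spec.channels),
    )


def _child_seed(seed: int, *key: int) -> int:
    ss = np.random.SeedSequence(entropy=seed, spawn_key=tuple(key))
    return int(ss.generate_state(1)[0])


def simulate_timecourse(
    doses: Sequence[float],
    timepoints_h: Sequence[float],
    kinetics: Mapping[float, LogisticKinetics],
    spec: PopulationSpec,
    wells_per_dose: int = 1,
) -> pd.DataFrame:
    """Simulate a dose/time series; each well gets an independent population
    per timepoint whose true senescent fraction follows the dose's logistic.

    Conditions are named ``dose_<d>``; wells ``<condition>_w<j>``.
    """
    if 0 not in [float(t) for t in timepoints_h]:
        raise ParameterError("timepoints_h must include 0 (the per-well control)")
    for d in doses:
        if d not in kinetics:
            raise ParameterError(f"no kinetics supplied for dose {d}")
    tables = []
    for di, dose in enumerate(doses):
        kin = kinetics[dose]
        for wj in range(wells_per_dose):
            for ti, t in enumerate(timepoints_h):
                frac = float(np.clip(kin.fraction(float(t)), 0.0, 1.0))
                sub = dataclasses.replace(
                    spec,
                    frac_senescent=frac,
                    seed=_child_seed(spec.seed, di, wj, ti),
                    condition=f"dose_{dose:g}",
                    well=f"dose_{dose:g}_w{wj}",
                    timepoint_h=float(t),
                )
                tables.append(simulate_population(sub))
    out = pd.concat(tables, ignore_index=True)
    out["cell_id"] = np.arange(len(out))
    return out


def simulate_sorted_populations(
    truth: pd.DataFrame,
    purity_sen: float,
    purity_nsen: float,
    sizes: tuple[int, int],
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Emulate sorting a population into 'senescent' and 'non-senescent' gates.

    The sorted-senescent table contains exactly ``floor(purity_sen * size)``
    truly senescent cells (impurity drawn from the other label) and likewise
    for the non-senescent gate. Sampling is without replacement across both
    outputs.
    """
    for name, p in (("purity_sen", purity_sen), ("purity_nsen", purity_nsen)):
        if not 0.0 <= p <= 1.0:
            raise ParameterError(f"{name} must lie in [0, 1], got {p}")
    size_sen, size_nsen = sizes
    n_true_sen = int(np.floor(purity_sen * size_sen))
    n_true_nsen = int(np.floor(purity_nsen * size_nsen))
    need_sen = n_true_sen + (size_nsen - n_true_nsen)
    need_nsen = (size_sen - n_true_sen) + n_true_nsen

    rng = np.random.default_rng(seed)
    idx_sen = truth.index[truth["true_label"] == SENESCENT].to_numpy()
    idx_nsen = truth.index[truth["true_label"] == NON_SENESCENT].to_numpy()
    if need_sen > len(idx_sen):
        raise CapacityError(
            f"need {need_sen} senescent cells but source has {len(idx_sen)}"
        )
    if need_nsen > len(idx_nsen):
        raise CapacityError(
            f"need {need_nsen} non-senescent cells but source has {len(idx_nsen)}"
        )
    pick_sen = rng.choice(idx_sen, size=need_sen, replace=False)
    pick_nsen = rng.choice(idx_nsen, size=need_nsen, replace=False)

    gate_sen_idx = np.concatenate(
        [pick_sen[:n_true_sen], pick_nsen[: size_sen - n_true_sen]]
    )
    gate_nsen_idx = np.concatenate(
        [pick_nsen[size_sen - n_true_sen:], pick_sen[n_true_sen:]]
    )
    gate_sen = truth.loc[gate_sen_idx].sample(frac=1.0, random_state=rng.integers(2**31)).reset_index(drop=True)
    gate_nsen = truth.loc[gate_nsen_idx].sample(frac=1.0, random_state=rng.integers(2**31)).reset_index(drop=True)
    gate_sen = gate_sen.assign(condition="sorted_senescent")
    gate_nsen = gate_nsen.assign(condition="sorted_non_senescent")
    return gate_sen, gate_nsen


def attach_marker(
    truth: pd.DataFrame,
    channel: str,
    pos_frac_by_label: Mapping[str, float],
    neg_mean: float,
    neg_sd: float,
    pos_fold: float,
    seed: int = 0,
) -> pd.DataFrame:
    """Add a marker channel with label-specific positive fractions.

    Negative cells draw N(neg_mean, neg_sd); positive cells
    N(pos_fold * neg_mean, neg_sd). The true state is recorded in a
    ``<channel>_pos`` boolean column. Positive counts per label are exactly
    ``floor(n_label * pos_frac)``.
    """
    for key, frac in pos_frac_by_label.items():
        if key not in LABELS:
            raise ParameterError(f"unknown label key {key!r}; expected one of {LABELS}")
        if not 0.0 <= frac <= 1.0:
            raise ParameterError(f"pos_frac for {key!r} must lie in [0, 1], got {frac}")
    if pos_fold <= 1:
        raise ParameterError(f"pos_fold must be > 1, got {pos_fold}")
    if neg_sd < 0:
        raise ParameterError("neg_sd must be >= 0")

    rng = np.random.default_rng(seed)
    out = truth.copy()
    n = len(out)
    pos = np.zeros(n, dtype=bool)
    for label in LABELS:
        in_label = (out["true_label"] == label).to_numpy()
        n_label = int(in_label.sum())
        if n_label == 0:
            continue
        frac = float(pos_frac_by_label.get(label, 0.0))
        pos[np.flatnonzero(in_label)[_deterministic_flags(n_label, frac, rng)]] = True

    means = np.where(pos, pos_fold * neg_mean, neg_mean)
    if neg_sd > 0:
        values = _positive_normal(rng, means, neg_sd, n)
    else:
        values = means.astype(float)
    out[channel] = values
    out[f"{channel}_pos"] = pos
    return out


# ---------------------------------------------------------------------------
# Plain-text I/O


def write_truth_csv(truth: pd.DataFrame, path: str | Path) -> None:
    truth.to_csv(path, index=False)


def read_truth_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in TRUTH_COLUMNS if c not in df.columns]
    if missing:
        raise ParameterError(f"truth CSV missing required columns: {missing}")
    return df


def write_scene(scene: SyntheticScene, out_dir: str | Path) -> None:
    """Write image (multi-page TIFF), 16-bit mask TIFF, truth CSV and a
    channel-order sidecar into ``out_dir``."""
    import tifffile

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(out / "image.tif", scene.image.astype(np.float32))
    if scene.mask.max() > np.iinfo(np.uint16).max:
        raise CapacityError("more than 65535 labels cannot be stored as uint16")
    tifffile.imwrite(out / "mask.tif", scene.mask.astype(np.uint16))
    write_truth_csv(scene.truth, out / "truth.csv")
    (out / "channels.json").write_text(json.dumps({"channels": list(scene.channels)}))
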