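"""Nucleus detection on the lamin A channel and per-ROI measurement.

Pipeline: Gaussian blur -> Li minimum-cross-entropy threshold -> foreground
mask -> Laplacian-of-Gaussian blob response -> local-maximum seeds ->
seeded watershed on the inverted blurred image restricted to the foreground
-> area filter -> border policy. All steps are deterministic; tie-breaking
for equal-height maxima is lexicographic (row, column) order.

Default parameters (blur_sigma=2, log_sigma=8, min_seed_distance=10,
area in [50, 10000] px^2) are package calibration choices and are
overridable via :class:`SegmentationConfig`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.segmentation import watershed

from .errors import DegenerateInputError, InputError, ParameterError


@dataclass(frozen=True)
class SegmentationConfig:
    blur_sigma: float = 2.0
    log_sigma: float = 8.0
    min_seed_distance: float = 10.0
    min_area: int = 50
    max_area: int = 10000
    border_policy: str = "drop"  # or "keep"
    #: blank-field guard: foreground is accepted only when the blurred
    #: foreground/background mean separation exceeds this many image SDs;
    #: any split of a unimodal (pure-noise) field separates by < ~1.6 SD
    min_contrast_snr: float = 2.5

    def __post_init__(self) -> None:
        if self.blur_sigma <= 0 or self.log_sigma <= 0:
            raise ParameterError("blur_sigma and log_sigma must be > 0")
        if self.min_seed_distance < 1:
            raise ParameterError("min_seed_distance must be >= 1")
        if not self.min_area < self.max_area:
            raise ParameterError("min_area must be < max_area")
        if self.border_policy not in ("keep", "drop"):
            raise ParameterError("border_policy must be 'keep' or 'drop'")


def li_threshold(image: np.ndarray, tol: float = 1e-8, max_iter: int = 500) -> float:
    """Li & Tam's iterative minimum cross-entropy threshold.

    Iterates t_{k+1} = (mu_bg - mu_fg) / (ln(mu_bg) - ln(mu_fg)), where
    mu_bg/mu_fg are the means of pixels below/above t_k, until the update is
    below ``tol``. The image is shifted so its minimum is zero (the returned
    threshold is shifted back), which makes the log-means well defined.
    """
    image = np.asarray(image, dtype=float)
    lo = float(image.min())
    hi = float(image.max())
    if hi == lo:
        raise DegenerateInputError("cannot threshold a constant image")
    offset = lo
    img = image - offset
    # tiny positive floor keeps ln(mean) finite when the background is all zeros
    eps = max(img.max() * 1e-12, np.finfo(float).tiny)
    t = float(img.mean())
    for _ in range(max_iter):
        fg = img > t
        mean_fg = float(img[fg].mean()) if fg.any() else eps
        bg = ~fg
        mean_bg = float(img[bg].mean()) if bg.any() else eps
        mean_fg = max(mean_fg, eps)
        mean_bg = max(mean_bg, eps)
        if mean_fg == mean_bg:
            break
        t_next = (mean_bg - mean_fg) / (np.log(mean_bg) - np.log(mean_fg))
        if abs(t_next - t) < tol:
            t = t_next
            break
        t = t_next
    return float(t + offset)


def _log_response(blurred: np.ndarray, log_sigma: float) -> np.ndarray:
    """Negated scale-normalised Laplacian of Gaussian: bright blobs -> peaks."""
    return -(log_sigma**2) * ndi.gaussian_laplace(blurred, sigma=log_sigma)


def detect_seeds(
    blurred: np.ndarray, foreground: np.ndarray, config: SegmentationConfig
) -> np.ndarray:
    """Local maxima of the LoG response inside the foreground mask.

    Candidate maxima (3x3-neighbourhood plateaus included) are ranked by
    response value, ties broken by (row, column), then greedily accepted if at
    least ``min_seed_distance`` (Euclidean) from every accepted seed.
    Returns an (n, 2) integer array of (row, col) coordinates.
    """
    resp = _log_response(blurred, config.log_sigma)
    local_max = resp == ndi.maximum_filter(resp, size=3)
    candidates = np.argwhere(local_max & foreground)
    if candidates.size == 0:
        return np.empty((0, 2), dtype=int)
    values = resp[candidates[:, 0], candidates[:, 1]]
    order = np.lexsort((candidates[:, 1], candidates[:, 0], -values))
    candidates = candidates[order]

    accepted: list[np.ndarray] = []
    min_d2 = config.min_seed_distance**2
    for c in candidates:
        if all(((c - a) ** 2).sum() >= min_d2 for a in accepted):
            accepted.append(c)
    return np.array(accepted, dtype=int)


def _relabel_sequential(mask: np.ndarray) -> np.ndarray:
    """Relabel to contiguous 1..K preserving first-appearance (raster) order."""
    if not (mask > 0).any():
        return np.zeros_like(mask, dtype=np.int32)
    flat = mask.ravel()
    vals, first = np.unique(flat, return_index=True)
    keep = vals > 0
    vals, first = vals[keep], first[keep]
    order = np.argsort(first, kind="stable")
    lut = np.zeros(int(mask.max()) + 1, dtype=np.int32)
    lut[vals[order]] = np.arange(1, len(vals) + 1, dtype=np.int32)
    return lut[mask].astype(np.int32)


def segment_nuclei(image: np.ndarray, config: SegmentationConfig | None = None) -> np.ndarray:
    """Segment nuclei on a single-channel image; returns an int label mask."""
    if config is None:
        config = SegmentationConfig()
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise InputError(f"expected a 2-D image, got shape {image.shape}")

    blurred = ndi.gaussian_filter(image, sigma=config.blur_sigma)
    thr = li_threshold(blurred)
    foreground = blurred > thr
    if not foreground.any() or foreground.all():
        return np.zeros(image.shape, dtype=np.int32)
    separation = blurred[foreground].mean() - blurred[~foreground].mean()
    if separation < config.min_contrast_snr * blurred.std():
        return np.zeros(image.shape, dtype=np.int32)

    seeds = detect_seeds(blurred, foreground, config)
    if len(seeds) == 0:
        return np.zeros(image.shape, dtype=np.int32)
    markers = np.zeros(image.shape, dtype=np.int32)
    markers[seeds[:, 0], seeds[:, 1]] = np.arange(1, len(seeds) + 1)

    labels = watershed(-blurred, markers=markers, mask=foreground, connectivity=1)

    # area filter
    counts = np.bincount(labels.ravel())
    bad = np.flatnonzero(
        (counts < config.min_area) | (counts > config.max_area)
    )
    for b in bad:
        if b == 0:
            continue
        labels[labels == b] = 0

    if config.border_policy == "drop":
        border = np.concatenate(
            [labels[0, :], labels[-1, :], labels[:, 0], labels[:, -1]]
        )
        for b in np.unique(border[border > 0]):
            labels[labels == b] = 0

    return _relabel_sequential(labels)


def measure_rois(
    mask: np.ndarray,
    channels: Mapping[str, np.ndarray],
    metadata: Mapping[str, object] | None = None,
) -> pd.DataFrame:
    """One record per label: area, centroid and per-channel mean intensity.

    ``metadata`` values (e.g. fov_id, condition, well, timepoint_h) are
    broadcast to every record. Records are emitted in ascending label order.
    """
    mask = np.asarray(mask)
    for name, img in channels.items():
        if np.asarray(img).shape != mask.shape:
            raise InputError(
                f"channel {name!r} shape {np.asarray(img).shape} does not match "
                f"mask shape {mask.shape}"
            )
    n_labels = int(mask.max())
    labels = np.arange(1, n_labels + 1)
    if n_labels == 0:
        cols = ["cell_id", "area_px", "centroid_row", "centroid_col"] + list(channels)
        return pd.DataFrame(columns=cols)

    areas = np.bincount(mask.ravel(), minlength=n_labels + 1)[1:]
    centroids = ndi.center_of_mass(np.ones_like(mask), labels=mask, index=labels)
    centroids = np.asarray(centroids, dtype=float)

    rec: dict[str, object] = {
        "cell_id": labels,
        "area_px": areas.astype(int),
        "centroid_row": centroids[:, 0],
        "centroid_col": centroids[:, 1],
    }
    for name, img in channels.items():
        rec[name] = ndi.mean(np.asarray(img, dtype=float), labels=mask, index=labels)
    df = pd.DataFrame(rec)
    defaults = {"fov_id": "fov0", "condition": "na", "well": "na", "timepoint_h": 0.0}
    meta = {**defaults, **(dict(metadata) if metadata else {})}
    for key, value in meta.items():
        df[key] = value
    ordered = [
        "cell_id", "fov_id", "condition", "well", "timepoint_h",
        "area_px", "centroid_row", "centroid_col",
    ]
    extra = [c for c in df.columns if c not in ordered]
    return df[ordered + extra]


def segment_and_measure(
    image: np.ndarray,
    channel_map: Mapping[str, int],
    seg_channel: str = "lamin_a",
    config: SegmentationConfig | None = None,
    metadata: Mapping[str, object] | None = None,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Segment on ``seg_channel`` of a (C, H, W) stack and measure all channels."""
    image = np.asarray(image, dtype=float)
    if image.ndim == 2:
        image = image[None]
    if seg_channel not in channel_map:
        raise InputError(f"segmentation channel {seg_channel!r} not in channel map")
    mask = segment_nuclei(image[channel_map[seg_channel]], config)
    channels = {name: image[idx] for name, idx in channel_map.items()}
    return mask, measure_rois(mask, channels, metadata)
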