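"""Translocation readouts: ratio time series, TIRF normalization, response stats.

The central readout of a translocation experiment is the localization
ratio: mean background-subtracted sensor intensity inside the organelle
mask divided by the mean in a cytosolic (or whole-cell) region. The ratio
is ~1 for a purely cytosolic sensor and rises as the sensor binds the
membrane. For TIRF time-lapses the readout is instead F_t/F_pre, the
background-subtracted footprint intensity normalized to its
pre-stimulation mean.

Scalar response statistics per cell are the baseline-subtracted area under
the post-stimulation curve (AUC, in ratio*minutes) and the change in ratio
at a fixed time after stimulation. Inference operates on replicate means
(superplot convention): the grand mean is the unweighted mean of
per-replicate means, so replicates — not individual cells — are the units
of inference.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import threshold_otsu

from .masking import MaskProfile, Optics, OrganelleMask, make_organelle_mask
from .stack import ImageStack

__all__ = [
    "RoiSet",
    "RatioTimeSeries",
    "ResponseSummary",
    "background_level",
    "localization_ratio",
    "ratio_timeseries",
    "tirf_normalize",
    "footprint_from_min_projection",
    "response_auc",
    "change_in_ratio",
    "replicate_summary",
]

logger = logging.getLogger(__name__)


@dataclass
class RoiSet:
    """Regions of interest as boolean grids congruent with the frames.

    ``background`` must be disjoint from every cell region; each optional
    cytosol region must be contained in its cell region. ``footprint``
    holds TIRF cell-footprint regions.
    """

    background: np.ndarray
    cells: dict = field(default_factory=dict)
    cytosol: dict = field(default_factory=dict)
    footprint: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.background = np.asarray(self.background, dtype=bool)
        self.cells = {k: np.asarray(v, dtype=bool) for k, v in self.cells.items()}
        self.cytosol = {k: np.asarray(v, dtype=bool) for k, v in self.cytosol.items()}
        self.footprint = {k: np.asarray(v, dtype=bool) for k, v in self.footprint.items()}
        if not self.background.any():
            raise ValueError("background ROI is empty")
        for cid, cell in self.cells.items():
            if (self.background & cell).any():
                raise ValueError(f"background ROI overlaps cell {cid!r}")
        for cid, cyt in self.cytosol.items():
            if cid in self.cells and (cyt & ~self.cells[cid]).any():
                raise ValueError(f"cytosol ROI of cell {cid!r} leaves its cell region")

    def denominator_region(self, cell_id) -> np.ndarray:
        """Cytosol ROI when drawn, else the whole-cell ROI."""
        if cell_id in self.cytosol:
            return self.cytosol[cell_id]
        return self.cells[cell_id]

    @classmethod
    def from_label_images(cls, background, cell_labels, cytosol_labels=None) -> "RoiSet":
        """Build from label images (0 = outside, k = cell id k)."""
        cell_labels = np.asarray(cell_labels)
        cells = {int(k): cell_labels == k for k in np.unique(cell_labels) if k != 0}
        cytosol = {}
        if cytosol_labels is not None:
            cytosol_labels = np.asarray(cytosol_labels)
            cytosol = {int(k): cytosol_labels == k for k in np.unique(cytosol_labels) if k != 0}
        return cls(background=background, cells=cells, cytosol=cytosol)


@dataclass
class RatioTimeSeries:
    """Per-cell readout versus time.

    ``kind`` is one of ``pm_cyto_ratio``, ``organelle_ratio`` or
    ``tirf_norm``; ``stim_index`` is the first frame at/after the
    stimulation. Missing frames (dropped mask, low signal) are NaN.
    """

    cell_id: object
    times: np.ndarray
    values: np.ndarray
    stim_index: int
    kind: str = "pm_cyto_ratio"
    replicate_id: object = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=np.float64)
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.times.shape != self.values.shape or self.times.ndim != 1:
            raise ValueError("times and values must be congruent 1-D arrays")
        if self.times.size >= 2 and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if not (0 <= self.stim_index < self.times.size):
            raise ValueError("stim_index out of range")

    @property
    def missing_fraction(self) -> float:
        return float(np.isnan(self.values).mean())


@dataclass
class ResponseSummary:
    """Scalar response statistics for one cell."""

    cell_id: object
    replicate_id: object
    auc: float
    baseline: float
    delta_at: dict = field(default_factory=dict)


def background_level(frame: np.ndarray, roi: np.ndarray) -> float:
    """Mean intensity inside the background ROI of one frame."""
    frame = np.asarray(frame, dtype=np.float64)
    roi = np.asarray(roi, dtype=bool)
    if roi.shape != frame.shape:
        raise ValueError("background ROI shape does not match the frame")
    if not roi.any():
        raise ValueError("background ROI is empty")
    return float(frame[roi].mean())


def localization_ratio(
    frame: np.ndarray,
    mask,
    denom_region: np.ndarray,
    bg: float,
    cell_region: np.ndarray | None = None,
    exclude_mask_from_denominator: bool = True,
) -> float:
    """Background-subtracted mask mean over denominator-region mean.

    The numerator averages the frame inside ``mask`` (intersected with the
    cell region when given); the denominator averages inside
    ``denom_region``, by default with mask pixels removed so membrane
    signal cannot inflate a cytosolic denominator. Returns NaN (not an
    exception) when the numerator region is empty or the denominator does
    not exceed background — per-frame dropouts are data, not errors.
    """
    if bg < 0:
        raise ValueError("background must be non-negative")
    frame = np.asarray(frame, dtype=np.float64)
    grid = mask.grid if isinstance(mask, OrganelleMask) else np.asarray(mask, dtype=bool)
    if grid.shape != frame.shape or np.asarray(denom_region).shape != frame.shape:
        raise ValueError("mask/denominator shape does not match the frame")
    num_region = grid & cell_region if cell_region is not None else grid
    denom = np.asarray(denom_region, dtype=bool)
    if exclude_mask_from_denominator:
        denom = denom & ~grid
    if not num_region.any() or not denom.any():
        return float("nan")
    num = frame[num_region].mean() - bg
    den = frame[denom].mean() - bg
    if den <= 0:
        return float("nan")
    return float(num / den)


def ratio_timeseries(
    stack: ImageStack,
    marker_channel,
    sensor_channel,
    rois: RoiSet,
    profile: MaskProfile,
    stim_index: int | None = None,
    optics: Optics | None = None,
    kind: str = "pm_cyto_ratio",
    max_missing_fraction: float = 0.2,
    replicate_id=None,
) -> dict:
    """Localization-ratio trace per cell from a two-channel stack.

    Per frame: segment the marker channel (wavelet-product mask), estimate
    the background from the background ROI, and compute the localization
    ratio on the sensor channel for every cell. Cells whose fraction of
    missing frames exceeds ``max_missing_fraction`` are dropped with a
    logged reason (the automated analogue of excluding cells that moved
    too much).
    """
    optics = optics or stack.optics
    if stim_index is None:
        stim_index = stack.stim_frame
    if stim_index is None:
        raise ValueError("stim_index not given and the stack records no stim_frame")
    mi = stack.channel_index(marker_channel)
    si = stack.channel_index(sensor_channel)
    times = stack.times_s

    values = {cid: np.empty(stack.n_frames) for cid in rois.cells}
    for t in range(stack.n_frames):
        marker = stack.data[t, mi]
        sensor = stack.data[t, si]
        mask = make_organelle_mask(marker, optics, profile, frame_index=t)
        bg = background_level(sensor, rois.background)
        for cid in rois.cells:
            values[cid][t] = localization_ratio(
                sensor,
                mask,
                rois.denominator_region(cid),
                bg,
                cell_region=rois.cells[cid],
            )

    out = {}
    for cid, vals in values.items():
        missing = float(np.isnan(vals).mean())
        if missing > max_missing_fraction:
            logger.warning(
                "dropping cell %r: %.0f%% of frames missing (low signal or empty mask)",
                cid, 100 * missing,
            )
            continue
        out[cid] = RatioTimeSeries(
            cell_id=cid, times=times, values=vals, stim_index=stim_index,
            kind=kind, replicate_id=replicate_id,
        )
    return out


def footprint_from_min_projection(substack: np.ndarray):
    """Cell-footprint region from a minimum-intensity projection.

    The minimum projection over time keeps only pixels that stay bright in
    every frame, so a jittering cell contributes the intersection of its
    positions. An Otsu threshold plus largest-connected-component
    selection stands in for manual footprint drawing; the projection is
    returned alongside the region for manual override.
    """
    substack = np.asarray(substack, dtype=np.float64)
    if substack.ndim == 4:  # (T, 1, Y, X)
        substack = substack[:, 0]
    if substack.ndim != 3 or substack.shape[0] < 2:
        raise ValueError("need a (T, Y, X) sub-stack with at least 2 frames")
    proj = substack.min(axis=0)
    if np.ptp(proj) == 0:
        raise ValueError("degenerate (constant) minimum projection: no footprint found")
    thr = threshold_otsu(proj)
    fg = proj > thr
    labels, n = ndimage.label(fg)
    if n == 0:
        raise ValueError("no foreground after thresholding the minimum projection")
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    region = labels == (1 + int(np.argmax(sizes)))
    return region, proj


def tirf_normalize(
    trace,
    pre_frames: int,
    bg,
    times=None,
    stim_index: int | None = None,
    cell_id=None,
    replicate_id=None,
) -> RatioTimeSeries:
    """Normalize a footprint-mean trace to its pre-stimulation baseline.

    ``F_pre`` is the mean of the background-subtracted footprint means over
    the first ``pre_frames`` frames; each output value is
    ``(mean_t - bg_t) / F_pre``. ``bg`` may be scalar or per-frame.
    """
    trace = np.asarray(trace, dtype=np.float64)
    if pre_frames < 1:
        raise ValueError("pre_frames must be >= 1")
    if pre_frames > trace.size:
        raise ValueError("pre_frames exceeds the trace length")
    bg_arr = np.broadcast_to(np.asarray(bg, dtype=np.float64), trace.shape)
    corrected = trace - bg_arr
    f_pre = corrected[:pre_frames].mean()
    if f_pre <= 0:
        raise ValueError("F_pre <= 0: cell unusable for normalization")
    if times is None:
        times = np.arange(trace.size, dtype=np.float64)
    return RatioTimeSeries(
        cell_id=cell_id,
        times=times,
        values=corrected / f_pre,
        stim_index=pre_frames if stim_index is None else stim_index,
        kind="tirf_norm",
        replicate_id=replicate_id,
    )


def response_auc(series: RatioTimeSeries, delta_times=()) -> ResponseSummary:
    """Baseline-subtracted post-stimulation area under the curve.

    Baseline is the mean value before ``stim_index``; the AUC is the
    signed trapezoidal integral of (value - baseline) from the stimulation
    frame to the end, expressed in ratio*minutes. ``delta_times`` requests
    change-in-ratio values (seconds after stimulation) in the same pass.
    """
    if series.stim_index < 1:
        raise ValueError("no pre-stimulation frames: cannot form a baseline")
    if series.times.size - series.stim_index < 2:
        raise ValueError("need at least 2 post-stimulation frames")
    pre = series.values[: series.stim_index]
    if np.all(np.isnan(pre)):
        raise ValueError("all pre-stimulation frames missing")
    baseline = float(np.nanmean(pre))

    t_post = series.times[series.stim_index:]
    v_post = series.values[series.stim_index:]
    ok = ~np.isnan(v_post)
    if ok.sum() < 2:
        raise ValueError("fewer than 2 usable post-stimulation frames")
    auc = float(np.trapezoid(v_post[ok] - baseline, t_post[ok] / 60.0))

    deltas = {dt: change_in_ratio(series, dt, baseline=baseline) for dt in delta_times}
    return ResponseSummary(
        cell_id=series.cell_id,
        replicate_id=series.replicate_id,
        auc=auc,
        baseline=baseline,
        delta_at=deltas,
    )


def change_in_ratio(series: RatioTimeSeries, at_time: float, baseline: float | None = None) -> float:
    """Value at the frame nearest ``at_time`` seconds after stimulation,
    minus the pre-stimulation baseline mean."""
    if at_time < 0:
        raise ValueError("at_time must be at/after the stimulation")
    target = series.times[series.stim_index] + at_time
    if target > series.times[-1]:
        raise ValueError("at_time lies beyond the end of the series")
    if baseline is None:
        if series.stim_index < 1:
            raise ValueError("no pre-stimulation frames: cannot form a baseline")
        baseline = float(np.nanmean(series.values[: series.stim_index]))
    idx = int(np.argmin(np.abs(series.times - target)))
    return float(series.values[idx] - baseline)


def replicate_summary(summaries, value: str = "auc") -> dict:
    """Two-level (superplot) aggregation of per-cell statistics.

    ``summaries`` is a sequence of ResponseSummary (or a DataFrame with
    ``replicate_id`` and the value column). Returns the per-cell table,
    the per-replicate means, and the grand mean with its SEM computed
    **across replicate means** (SD of replicate means / sqrt(n_replicates))
    — cells do not vote individually. Replicates with zero cells are
    dropped with a warning; with a single replicate the SEM is reported as
    NaN.
    """
    if isinstance(summaries, pd.DataFrame):
        cells = summaries.copy()
    else:
        rows = []
        for s in summaries:
            row = {"cell_id": s.cell_id, "replicate_id": s.replicate_id,
                   "auc": s.auc, "baseline": s.baseline}
            for dt, dv in s.delta_at.items():
                row[f"delta_{dt:g}s"] = dv
            rows.append(row)
        cells = pd.DataFrame(rows)
    if "replicate_id" not in cells or cells["replicate_id"].isna().any():
        raise ValueError("every cell needs a replicate_id")
    if value not in cells:
        raise ValueError(f"no column {value!r} in the per-cell table")

    valid = cells.dropna(subset=[value])
    dropped = set(cells["replicate_id"]) - set(valid["replicate_id"])
    for rid in dropped:
        logger.warning("replicate %r has no usable cells; dropped", rid)

    rep_means = (
        valid.groupby("replicate_id", sort=True)[value].agg(["mean", "count"])
        .rename(columns={"mean": f"{value}_mean", "count": "n_cells"})
        .reset_index()
    )
    means = rep_means[f"{value}_mean"].to_numpy()
    n_rep = means.size
    grand = float(means.mean())
    sem = float(means.std(ddof=1) / math.sqrt(n_rep)) if n_rep > 1 else float("nan")
    return {
        "cell_table": cells,
        "replicate_table": rep_means,
        "grand_mean": grand,
        "sem": sem,
        "n_replicates": int(n_rep),
    }
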