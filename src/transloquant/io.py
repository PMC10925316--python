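"""Reading and writing stacks, ground truth, ROIs, configs and results.

Conventions: stacks are multi-page TIFF in (T, C, Y, X) order with a YAML
sidecar (same stem, ``.yaml``) carrying the acquisition metadata the TIFF
tags cannot (pixel size, emission wavelength, NA, frame interval,
stimulation frame). Masks and ROIs are label/binary TIFFs. Tables are CSV.
Pixel indices are 0-based, row-major (Y before X); time is in seconds from
the first frame; the stimulation is identified by frame index.
"""

from __future__ import annotations

from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .masking import DEFAULT_PROFILES, Optics, make_organelle_mask
from .quant import RoiSet, ratio_timeseries, replicate_summary, response_auc
from .stack import ImageStack
from .synthetic import SyntheticScene

__all__ = [
    "read_stack",
    "write_stack",
    "write_scene",
    "read_roi_set",
    "write_roi_set",
    "scene_roi_set",
    "run_pipeline",
]

_REQUIRED_META = ("pixel_size_nm", "wavelength_em_nm", "numerical_aperture", "frame_interval_s")


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".yaml")


def write_stack(stack: ImageStack, path) -> Path:
    """Write a stack as multi-page TIFF plus a YAML metadata sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, stack.data.astype(np.float32), metadata={"axes": "TCYX"})
    meta = {
        "dimension_order": "TCYX",
        "pixel_size_nm": stack.optics.pixel_size,
        "wavelength_em_nm": stack.optics.wavelength_em,
        "numerical_aperture": stack.optics.numerical_aperture,
        "frame_interval_s": stack.frame_interval_s,
        "stim_frame": stack.stim_frame,
        "channel_names": list(stack.channel_names),
    }
    with open(_sidecar_path(path), "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=True)
    return path


def read_stack(path, dimension_order: str | None = None) -> ImageStack:
    """Read a multi-page TIFF stack and its metadata sidecar.

    ``dimension_order`` overrides the sidecar's order hint (e.g. "CTYX"
    for stacks written channel-first); the returned stack is always
    logically (T, C, Y, X). Missing required metadata raises an error
    naming every absent field, because the masking stage cannot run
    without the optics.
    """
    path = Path(path)
    data = np.asarray(tifffile.imread(path), dtype=np.float64)
    sidecar = _sidecar_path(path)
    meta: dict = {}
    if sidecar.exists():
        with open(sidecar) as fh:
            meta = yaml.safe_load(fh) or {}
    missing = [k for k in _REQUIRED_META if meta.get(k) in (None, "")]
    if missing:
        raise ValueError(
            f"stack {path.name} is missing required metadata fields {missing}; "
            "provide them in the YAML sidecar"
        )
    order = (dimension_order or meta.get("dimension_order") or "TCYX").upper()
    if data.ndim == 3:  # single channel or single frame
        data = data[:, None] if order.startswith("T") else data[None]
    if data.ndim != 4:
        raise ValueError(f"cannot interpret TIFF with shape {data.shape} as a T,C,Y,X stack")
    if sorted(order) != sorted("TCYX"):
        raise ValueError(f"bad dimension order {order!r}")
    data = np.transpose(data, [order.index(ax) for ax in "TCYX"])
    return ImageStack(
        data=data,
        optics=Optics(
            wavelength_em=float(meta["wavelength_em_nm"]),
            numerical_aperture=float(meta["numerical_aperture"]),
            pixel_size=float(meta["pixel_size_nm"]),
        ),
        frame_interval_s=float(meta["frame_interval_s"]),
        stim_frame=meta.get("stim_frame"),
        channel_names=tuple(meta.get("channel_names") or ()),
    )


def write_scene(scene: SyntheticScene, directory) -> Path:
    """Write a synthetic scene: stack + sidecar, truth TIFFs, params YAML."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_stack(scene.stack, directory / "stack.tif")
    for name, grid in (
        ("truth_mask", scene.truth_mask),
        ("truth_structure", scene.truth_structure),
        ("truth_cytosol", scene.truth_cytosol),
        ("cell_region", scene.cell_region),
        ("background_region", scene.background_region),
    ):
        tifffile.imwrite(directory / f"{name}.tif", grid.astype(np.uint8))
    np.savetxt(directory / "truth_ratio.csv",
               np.column_stack([scene.stack.times_s, scene.truth_ratio,
                                scene.truth_bound_fraction]),
               delimiter=",", header="time_s,truth_ratio,bound_fraction", comments="")
    with open(directory / "scene.yaml", "w") as fh:
        yaml.safe_dump(
            {"params": asdict(scene.params), "kinetics": asdict(scene.kinetics)},
            fh, sort_keys=True,
        )
    return directory


def scene_roi_set(scene: SyntheticScene, cytosol_margin: int = 2) -> RoiSet:
    """ROIs a user would draw on a synthetic scene: background patch,
    whole-cell region, and a cytosol region eroded away from the membrane."""
    from scipy import ndimage as ndi

    cell = scene.cell_region
    cytosol = ndi.binary_erosion(scene.truth_cytosol, iterations=cytosol_margin)
    if not cytosol.any():
        cytosol = scene.truth_cytosol
    return RoiSet(
        background=scene.background_region,
        cells={1: cell},
        cytosol={1: cytosol & cell},
    )


def write_roi_set(rois: RoiSet, directory) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(directory / "background.tif", rois.background.astype(np.uint8))
    for name, regions in (("cells", rois.cells), ("cytosol", rois.cytosol),
                          ("footprint", rois.footprint)):
        if not regions:
            continue
        label = np.zeros(rois.background.shape, dtype=np.uint16)
        for cid, grid in regions.items():
            label[grid] = int(cid)
        tifffile.imwrite(directory / f"{name}.tif", label)
    return directory


def read_roi_set(directory) -> RoiSet:
    directory = Path(directory)
    background = tifffile.imread(directory / "background.tif").astype(bool)

    def load_labels(name):
        p = directory / f"{name}.tif"
        if not p.exists():
            return {}
        label = tifffile.imread(p)
        return {int(k): label == k for k in np.unique(label) if k != 0}

    return RoiSet(
        background=background,
        cells=load_labels("cells"),
        cytosol=load_labels("cytosol"),
        footprint=load_labels("footprint"),
    )


def run_pipeline(
    stack_path,
    roi_dir,
    out_dir,
    organelle: str = "plasma_membrane",
    marker_channel="marker",
    sensor_channel="sensor",
    stim_index: int | None = None,
    delta_times=(30.0,),
    profile_overrides: dict | None = None,
    replicate_id=1,
) -> dict:
    """Mask -> ratio -> summaries on one stack; writes CSVs + provenance.

    Outputs into ``out_dir``: ``timeseries.csv`` (long format: cell_id,
    replicate_id, time_s, value, kind), ``summary.csv`` (per-cell AUC,
    deltas, baseline), ``replicate_summary.csv``, per-frame masks as a
    multi-page TIFF, and ``provenance.yaml`` echoing every resolved
    parameter. Deterministic: fixed inputs give byte-identical CSVs.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stack = read_stack(stack_path)
    rois = read_roi_set(roi_dir)
    profile = DEFAULT_PROFILES[organelle]
    if profile_overrides:
        profile = profile.with_overrides(**profile_overrides)

    series = ratio_timeseries(
        stack, marker_channel, sensor_channel, rois, profile,
        stim_index=stim_index, replicate_id=replicate_id,
    )
    if not series:
        raise RuntimeError("pipeline stage 'ratio': no usable cells")

    masks = np.stack([
        make_organelle_mask(stack.data[t, stack.channel_index(marker_channel)],
                            stack.optics, profile, t).grid
        for t in range(stack.n_frames)
    ])
    tifffile.imwrite(out_dir / "masks.tif", masks.astype(np.uint8))

    long_rows = []
    summaries = []
    for cid, s in sorted(series.items(), key=lambda kv: str(kv[0])):
        for t, v in zip(s.times, s.values):
            long_rows.append({"cell_id": cid, "replicate_id": replicate_id,
                              "time_s": t, "value": v, "kind": s.kind})
        try:
            summaries.append(response_auc(s, delta_times=delta_times))
        except ValueError as exc:
            raise RuntimeError(f"pipeline stage 'summarize', cell {cid}: {exc}") from exc

    pd.DataFrame(long_rows).to_csv(out_dir / "timeseries.csv", index=False, float_format="%.9g")
    agg = replicate_summary(summaries)
    agg["cell_table"].to_csv(out_dir / "summary.csv", index=False, float_format="%.9g")
    agg["replicate_table"].assign(grand_mean=agg["grand_mean"], sem=agg["sem"]).to_csv(
        out_dir / "replicate_summary.csv", index=False, float_format="%.9g"
    )

    from . import __version__

    provenance = {
        "package_version": __version__,
        "stack": str(stack_path),
        "rois": str(roi_dir),
        "organelle": organelle,
        "marker_channel": marker_channel,
        "sensor_channel": sensor_channel,
        "stim_index": stim_index if stim_index is not None else stack.stim_frame,
        "delta_times_s": list(delta_times),
        "profile": asdict(profile),
        "optics": asdict(stack.optics),
        "n_cells_analyzed": len(series),
    }
    with open(out_dir / "provenance.yaml", "w") as fh:
        yaml.safe_dump(provenance, fh, sort_keys=True)
    return {"series": series, "summary": agg, "out_dir": out_dir}
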