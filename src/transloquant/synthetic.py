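"""Synthetic microscopy scenes and assay tables with known ground truth.

Every downstream stage of the pipeline (masking, ratio extraction, TIRF
normalization, binding fits) is benchmarked against scenes produced here,
because the imaging regimes being emulated — adherent cells expressing a
cytosolic lipid biosensor plus an organelle marker, imaged at
diffraction-limited resolution every few tens of seconds — leave no public
raw data to test against.

A scene is a two-channel time-lapse:

* channel 0 ("marker"): a fixed organelle structure (plasma-membrane ring,
  mitochondrial/Golgi blobs, ER mesh, or endosomal puncta) convolved with a
  Gaussian point-spread function.
* channel 1 ("sensor"): a biosensor whose total photon budget is split
  between a membrane-bound pool sitting on the organelle structure and a
  cytosolic pool filling the cell body (nucleus excluded by default), with
  the bound fraction f(t) following prescribed translocation kinetics.

Poisson shot noise and Gaussian read noise are applied per pixel per frame;
all ground truth (masks, cytosol region, true localization-ratio trace) is
recorded from the noiseless images.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .binding import BindingDataset, one_site_model
from .masking import ORGANELLES, Optics, airy_radius_px
from .stack import ImageStack

__all__ = [
    "SceneParams",
    "TranslocationKinetics",
    "SyntheticScene",
    "simulate_translocation",
    "simulate_cell_scene",
    "simulate_tirf_scene",
    "simulate_binding_assay",
]


@dataclass(frozen=True)
class SceneParams:
    """Geometry, optics, photon budget and acquisition settings of a scene.

    Defaults emulate a single adherent cell imaged with a high-NA oil
    objective at 100 nm pixels, a 30 s frame interval and a stimulation
    after 2 minutes of baseline — the acquisition regime typical of live
    biosensor translocation experiments.

    Notes
    -----
    ``marker_brightness`` is the peak photon rate of the organelle marker
    (photons/pixel on the structure before blurring); ``biosensor_total``
    is the total sensor photon budget per frame, partitioned between
    membrane and cytosol by the kinetics; ``background_level`` is a uniform
    photon floor; ``read_noise_sd`` is the camera's additive Gaussian noise.
    """

    image_size: int = 128
    pixel_size: float = 100.0  # nm/pixel
    wavelength_em: float = 610.0  # nm
    numerical_aperture: float = 1.45
    n_cells: int = 1
    cell_radius: float = 45.0  # pixels
    nucleus_radius: float = 18.0  # pixels
    pm_thickness: float = 3.0  # pixels, pre-blur ring width
    organelle_kind: str = "plasma_membrane"
    marker_brightness: float = 400.0
    biosensor_total: float = 1.0e6
    background_level: float = 20.0
    read_noise_sd: float = 2.0
    nuclear_fraction: float = 0.0
    frame_interval: float = 30.0  # s
    n_frames: int = 20
    stim_frame: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.organelle_kind not in ORGANELLES:
            raise ValueError(
                f"unknown organelle_kind {self.organelle_kind!r}; expected one of {ORGANELLES}"
            )
        for name in ("image_size", "cell_radius", "nucleus_radius", "pm_thickness",
                     "pixel_size", "wavelength_em", "numerical_aperture",
                     "frame_interval"):
            if getattr(self, name) <= 0:
                raise ValueError(f"SceneParams.{name} must be positive")
        if self.nucleus_radius >= self.cell_radius:
            raise ValueError("nucleus_radius must be smaller than cell_radius")
        if not (0 <= self.stim_frame < self.n_frames):
            raise ValueError("stim_frame must lie within [0, n_frames)")
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if not (0 <= self.nuclear_fraction < 1):
            raise ValueError("nuclear_fraction must lie in [0, 1)")

    @property
    def optics(self) -> Optics:
        return Optics(self.wavelength_em, self.numerical_aperture, self.pixel_size)

    @property
    def psf_sigma_px(self) -> float:
        """Gaussian PSF sigma: the Airy radius taken as the PSF FWHM."""
        return airy_radius_px(self.optics) / 2.355


@dataclass(frozen=True)
class TranslocationKinetics:
    """Membrane-bound fraction of the sensor as a function of time.

    Baseline ``f_pre`` until the stimulation, then a single-exponential
    rise with time constant ``tau_on`` toward the plateau ``f_max``. If an
    ``antagonist_frame`` is set, the bound fraction decays back toward
    ``f_pre`` with time constant ``tau_off`` from that frame onward
    (modelling e.g. receptor-antagonist reversal of the stimulus).

    The default constants are illustrative: published traces constrain the
    qualitative shape (rise over ~1-5 min, optional reversal) but no
    quantitative rate constants.
    """

    f_pre: float = 0.1
    f_max: float = 0.3
    tau_on: float = 60.0  # s
    tau_off: float | None = None  # s
    antagonist_frame: int | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.f_pre <= self.f_max <= 1):
            raise ValueError("need 0 <= f_pre <= f_max <= 1")
        if self.tau_on <= 0:
            raise ValueError("tau_on must be positive")
        if self.antagonist_frame is not None and (self.tau_off is None or self.tau_off <= 0):
            raise ValueError("antagonist reversal requires a positive tau_off")


@dataclass
class SyntheticScene:
    """A generated stack bundled with its ground truth.

    ``truth_mask`` is the observable organelle footprint: the noiseless
    PSF-convolved marker structure thresholded at a quarter of its
    maximum, the region holding ~90% of the blurred marker signal.
    ``truth_structure`` is the pre-blur geometric structure.
    ``truth_cytosol`` is the cytosolic region (cell minus nucleus minus
    organelle footprint), disjoint from ``truth_mask``. ``truth_ratio`` is
    the true localization ratio per frame, computed on the noiseless sensor
    channel with the truth regions and exact background.
    ``truth_bound_fraction`` is f(t) itself.
    """

    stack: ImageStack
    truth_mask: np.ndarray
    truth_structure: np.ndarray
    truth_cytosol: np.ndarray
    truth_ratio: np.ndarray
    truth_bound_fraction: np.ndarray
    params: SceneParams
    kinetics: TranslocationKinetics

    @property
    def cell_region(self) -> np.ndarray:
        """Whole-cell region: union of footprint, cytosol and nucleus."""
        return self._cell_region

    @property
    def background_region(self) -> np.ndarray:
        """Pixels well outside every cell, for background ROIs."""
        return self._background_region


def simulate_translocation(
    kinetics: TranslocationKinetics, times, stim_time: float
) -> np.ndarray:
    """Evaluate the bound-fraction trace f(t) at the given times.

    f(t) = f_pre before the stimulation; rises exponentially toward f_max
    with constant tau_on afterwards; if an antagonist time is set (via
    ``antagonist_frame`` resolved to a time by the caller or the kinetics
    carried by a scene), decays toward f_pre with tau_off thereafter.
    """
    times = np.asarray(times, dtype=np.float64)
    if times.ndim != 1 or times.size == 0:
        raise ValueError("times must be a non-empty 1-D sequence")
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")

    k = kinetics
    f = np.full(times.shape, k.f_pre)
    post = times >= stim_time
    f[post] = k.f_max - (k.f_max - k.f_pre) * np.exp(-(times[post] - stim_time) / k.tau_on)

    if k.antagonist_frame is not None:
        # the antagonist frame indexes the same clock as `times`
        t_ant = times[k.antagonist_frame] if k.antagonist_frame < times.size else times[-1]
        f_at_ant = k.f_max - (k.f_max - k.f_pre) * math.exp(-max(t_ant - stim_time, 0.0) / k.tau_on)
        rev = times >= t_ant
        f[rev] = k.f_pre + (f_at_ant - k.f_pre) * np.exp(-(times[rev] - t_ant) / k.tau_off)

    return np.clip(f, 0.0, 1.0)


def _disk(shape, center, radius) -> np.ndarray:
    yy, xx = np.ogrid[: shape[0], : shape[1]]
    return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius**2


def _cell_centers(params: SceneParams, rng: np.random.Generator) -> list[tuple[float, float]]:
    """Place n_cells non-overlapping cell centers; single cell sits centered."""
    n, size, r = params.n_cells, params.image_size, params.cell_radius
    if n == 1:
        return [(size / 2, size / 2)]
    centers: list[tuple[float, float]] = []
    for _ in range(10000):
        if len(centers) == n:
            break
        c = tuple(rng.uniform(r + 2, size - r - 2, size=2))
        if all((c[0] - o[0]) ** 2 + (c[1] - o[1]) ** 2 > (2 * r + 2) ** 2 for o in centers):
            centers.append(c)
    if len(centers) < n:
        raise ValueError("could not place n_cells non-overlapping cells; reduce n_cells or cell_radius")
    return centers


def _organelle_structure(
    params: SceneParams, center, cell: np.ndarray, nucleus: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Binary pre-blur structure for one cell, restricted to the cell body."""
    shape = cell.shape
    kind = params.organelle_kind
    yy, xx = np.ogrid[: shape[0], : shape[1]]
    r2 = (yy - center[0]) ** 2 + (xx - center[1]) ** 2
    interior = cell & ~nucleus

    if kind == "plasma_membrane":
        inner = params.cell_radius - params.pm_thickness
        return (r2 <= params.cell_radius**2) & (r2 > inner**2)

    if kind == "mitochondria":
        # curvilinear blobs: short random walks, dilated to ~2 px thickness
        struct = np.zeros(shape, dtype=bool)
        for _ in range(6):
            y, x = center[0] + rng.uniform(-0.6, 0.6) * params.cell_radius, center[1] + rng.uniform(-0.6, 0.6) * params.cell_radius
            ang = rng.uniform(0, 2 * np.pi)
            for _ in range(25):
                iy, ix = int(round(y)), int(round(x))
                if 0 <= iy < shape[0] and 0 <= ix < shape[1]:
                    struct[iy, ix] = True
                ang += rng.normal(0, 0.4)
                y += math.sin(ang)
                x += math.cos(ang)
        return ndimage.binary_dilation(struct, iterations=1) & interior

    if kind == "golgi":
        # a compact cluster of blobs hugging the nucleus
        struct = np.zeros(shape, dtype=bool)
        base_ang = rng.uniform(0, 2 * np.pi)
        for _ in range(5):
            ang = base_ang + rng.normal(0, 0.4)
            rad = params.nucleus_radius + 3 + rng.uniform(0, 3)
            cy = center[0] + rad * math.sin(ang)
            cx = center[1] + rad * math.cos(ang)
            struct |= _disk(shape, (cy, cx), rng.uniform(2, 4))
        return struct & interior

    if kind == "er":
        # reticular mesh: ridges of a band-passed random field
        field_ = rng.normal(size=shape)
        smooth = ndimage.gaussian_filter(field_, 2.0)
        mesh = np.abs(smooth) < 0.25 * smooth.std()
        # keep the mesh out of the outermost cell rim so it reads as internal
        inner_cell = r2 <= (params.cell_radius - 3) ** 2
        return mesh & inner_cell & ~nucleus

    if kind == "endosome":
        struct = np.zeros(shape, dtype=bool)
        n_pts = 30
        placed = 0
        for _ in range(10 * n_pts):
            if placed == n_pts:
                break
            ang = rng.uniform(0, 2 * np.pi)
            rad = rng.uniform(params.nucleus_radius + 2, params.cell_radius - 3)
            iy = int(round(center[0] + rad * math.sin(ang)))
            ix = int(round(center[1] + rad * math.cos(ang)))
            if 0 <= iy < shape[0] and 0 <= ix < shape[1] and not struct[iy, ix]:
                struct[iy, ix] = True
                placed += 1
        return ndimage.binary_dilation(struct, iterations=1) & interior

    raise ValueError(f"unknown organelle_kind {kind!r}")


def simulate_cell_scene(
    params: SceneParams,
    kinetics: TranslocationKinetics | None = None,
    noise: bool = True,
) -> SyntheticScene:
    """Generate a two-channel (marker, sensor) time-lapse with ground truth.

    The marker channel is static; the sensor channel redistributes its
    photon budget between the organelle structure and the cytosol following
    f(t). Identical ``params`` (including ``seed``) give bit-identical
    output. With ``noise=False`` the stack holds the noiseless expectation
    images (useful as an oracle).
    """
    if kinetics is None:
        kinetics = TranslocationKinetics()
    rng = np.random.default_rng(params.seed)
    size = params.image_size
    shape = (size, size)
    sigma = params.psf_sigma_px

    centers = _cell_centers(params, rng)
    cell = np.zeros(shape, dtype=bool)
    nucleus = np.zeros(shape, dtype=bool)
    structure = np.zeros(shape, dtype=bool)
    for c in centers:
        this_cell = _disk(shape, c, params.cell_radius)
        this_nuc = _disk(shape, c, params.nucleus_radius)
        cell |= this_cell
        nucleus |= this_nuc
        structure |= _organelle_structure(params, c, this_cell, this_nuc, rng)

    # the cytosolic pool fills the whole cell body (nucleus excluded by
    # default): in a confocal slice cytosol lies under/around the organelle,
    # so the membrane-bound pool adds on top of it rather than replacing it
    body = cell & ~nucleus
    cytosol_geom = body & ~structure
    if not structure.any() or not cytosol_geom.any():
        raise ValueError("degenerate geometry: empty organelle structure or cytosol")

    def blur(img):
        return ndimage.gaussian_filter(img, sigma, mode="reflect")

    # marker channel: static, blurred structure + background
    marker_clean = params.marker_brightness * blur(structure.astype(np.float64))
    marker_clean += params.background_level

    # observable footprint: pixels above a quarter of the blurred
    # structure's peak. For a Gaussian ridge this contains ~90% of the
    # signal mass (+-1.67 sigma), i.e. the whole visible organelle area
    # rather than just the half-max crest of a thin, diffraction-blurred
    # structure.
    psf_struct = blur(structure.astype(np.float64))
    truth_mask = psf_struct >= 0.25 * psf_struct.max()
    truth_cytosol = cytosol_geom & ~truth_mask

    times = np.arange(params.n_frames) * params.frame_interval
    stim_time = params.stim_frame * params.frame_interval
    f_trace = simulate_translocation(kinetics, times, stim_time)

    n_struct = int(structure.sum())
    n_body = int(body.sum())
    n_nuc = int(nucleus.sum())
    nuc_budget = params.nuclear_fraction * params.biosensor_total
    mobile = params.biosensor_total - nuc_budget

    data = np.empty((params.n_frames, 2, size, size), dtype=np.float64)
    truth_ratio = np.empty(params.n_frames)
    bg = params.background_level

    base_nuc = np.zeros(shape)
    if nuc_budget > 0:
        base_nuc[nucleus] = nuc_budget / n_nuc

    for t, f in enumerate(f_trace):
        sensor = np.zeros(shape)
        sensor[body] = (1.0 - f) * mobile / n_body
        sensor[structure] += f * mobile / n_struct
        sensor += base_nuc
        sensor_clean = blur(sensor) + bg

        # numerator cropped by the cell region, matching the measurement
        # convention (mask intersected with the whole-cell ROI)
        mem_mean = sensor_clean[truth_mask & cell].mean()
        cyt_mean = sensor_clean[truth_cytosol].mean()
        truth_ratio[t] = (mem_mean - bg) / (cyt_mean - bg)

        if noise:
            # shot noise on total photon count, then camera read noise
            marker_noisy = rng.poisson(marker_clean).astype(np.float64)
            sensor_noisy = rng.poisson(sensor_clean).astype(np.float64)
            marker_noisy += rng.normal(0.0, params.read_noise_sd, shape)
            sensor_noisy += rng.normal(0.0, params.read_noise_sd, shape)
            data[t, 0] = np.clip(marker_noisy, 0.0, None)
            data[t, 1] = np.clip(sensor_noisy, 0.0, None)
        else:
            data[t, 0] = marker_clean
            data[t, 1] = sensor_clean

    stack = ImageStack(
        data=data,
        optics=params.optics,
        frame_interval_s=params.frame_interval,
        stim_frame=params.stim_frame,
        channel_names=("marker", "sensor"),
    )
    scene = SyntheticScene(
        stack=stack,
        truth_mask=truth_mask,
        truth_structure=structure,
        truth_cytosol=truth_cytosol,
        truth_ratio=truth_ratio,
        truth_bound_fraction=f_trace,
        params=params,
        kinetics=kinetics,
    )
    scene._cell_region = cell
    scene._background_region = ~ndimage.binary_dilation(cell, iterations=5)
    return scene


def simulate_tirf_scene(
    params: SceneParams,
    kinetics: TranslocationKinetics | None = None,
    jitter_px: float = 0.0,
):
    """Single-channel TIRF footprint time-lapse plus ground truth.

    In TIRF only the basal membrane is excited, so the cell appears as a
    bright footprint whose mean intensity tracks the membrane-bound sensor
    fraction. Returns ``(stack, truth)`` where truth carries the footprint
    mask, f(t), and the true normalized trace F_t/F_pre.
    """
    if kinetics is None:
        kinetics = TranslocationKinetics()
    rng = np.random.default_rng(params.seed)
    size = params.image_size
    shape = (size, size)
    times = np.arange(params.n_frames) * params.frame_interval
    stim_time = params.stim_frame * params.frame_interval
    f_trace = simulate_translocation(kinetics, times, stim_time)

    center0 = (size / 2, size / 2)
    footprint0 = _disk(shape, center0, params.cell_radius)
    per_px = params.biosensor_total / footprint0.sum()
    bg = params.background_level

    data = np.empty((params.n_frames, 1, size, size))
    truth_trace = f_trace / np.mean(f_trace[: max(params.stim_frame, 1)])
    for t, f in enumerate(f_trace):
        if jitter_px > 0:
            c = (center0[0] + rng.uniform(-jitter_px, jitter_px),
                 center0[1] + rng.uniform(-jitter_px, jitter_px))
        else:
            c = center0
        fp = _disk(shape, c, params.cell_radius)
        clean = np.where(fp, f * per_px, 0.0)
        clean = ndimage.gaussian_filter(clean, params.psf_sigma_px, mode="reflect") + bg
        noisy = rng.poisson(clean).astype(np.float64)
        noisy += rng.normal(0.0, params.read_noise_sd, shape)
        data[t, 0] = np.clip(noisy, 0.0, None)

    stack = ImageStack(
        data=data,
        optics=params.optics,
        frame_interval_s=params.frame_interval,
        stim_frame=params.stim_frame,
        channel_names=("sensor",),
    )
    truth = {
        "footprint": footprint0,
        "bound_fraction": f_trace,
        "normalized_trace": truth_trace,
    }
    return stack, truth


def simulate_binding_assay(
    bg: float,
    bmax: float,
    kd: float,
    concentrations,
    cv: float = 0.0,
    seed: int = 0,
    n_replicates: int = 1,
) -> BindingDataset:
    """Draw percent-bound observations from the one-site model.

    Observations are ``model(X) * eps`` with ``eps`` lognormal with mean 1
    and coefficient of variation ``cv``, truncated to [0, 100]. ``cv=0``
    reproduces the model exactly. True parameters are recorded for
    closed-loop recovery tests.
    """
    if not (0 <= bg <= bmax <= 100):
        raise ValueError("need 0 <= bg <= bmax <= 100")
    if kd <= 0:
        raise ValueError("kd must be positive")
    x = np.asarray(concentrations, dtype=np.float64)
    if np.any(x < 0):
        raise ValueError("concentrations must be non-negative")
    if cv < 0:
        raise ValueError("cv must be non-negative")
    rng = np.random.default_rng(seed)
    xs, ys, reps = [], [], []
    mu = one_site_model(x, bg, bmax, kd)
    sigma = math.sqrt(math.log(1.0 + cv * cv)) if cv > 0 else 0.0
    for r in range(1, n_replicates + 1):
        if sigma > 0:
            eps = np.exp(rng.normal(-0.5 * sigma * sigma, sigma, x.shape))
        else:
            eps = np.ones_like(x)
        y = np.clip(mu * eps, 0.0, 100.0)
        xs.append(x)
        ys.append(y)
        reps.append(np.full(x.shape, r, dtype=int))
    return BindingDataset(
        concentration_uM=np.concatenate(xs),
        percent_bound=np.concatenate(ys),
        replicate=np.concatenate(reps),
        true_params={"bg": bg, "bmax": bmax, "kd": kd, "cv": cv, "seed": seed},
    )
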