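# Methods

## The measurement model

A translocating lipid biosensor distributes between a membrane-bound pool
and a cytosolic pool. In a confocal slice the observable is the sensor
intensity averaged over an organelle mask versus a cytosolic reference
region, both background-subtracted:

    R(t) = (⟨I⟩_mask∩cell − bg) / (⟨I⟩_cyto − bg)

R ≈ 1 for a purely cytosolic sensor and grows as the membrane-bound
fraction f(t) grows. In TIRF only the basal membrane is excited, so the
readout simplifies to F_t/F_pre, the footprint mean normalized to its
pre-stimulation average.

Both readouts are invariant to detector gain (numerator and denominator
scale together) and to a uniform offset (removed with the background);
the test suite asserts both invariances exactly.

## Organelle masking

The marker channel is segmented per frame by a multiscale wavelet
product:

1. Airy radius in pixels: r = 0.61 λ_em / (NA · pixel size).
2. Gaussian ladder at scales {m_i · r}. The per-organelle multiplier sets
   are (1,2,3,4) for plasma membrane, mitochondria and Golgi, (1,2) for
   the ER — short ladders suit fine reticular structure — and (1,2,3)
   for endosomes.
3. Band-pass planes w_i = G_{m_i} − G_{m_{i+1}} (negative values clamped
   to 0 so products of two negative bands cannot create mask pixels).
4. Pixel-wise product of all planes; threshold; 1–2 one-pixel dilation
   cycles (3×3 element) so the whole organelle area is covered.

Two conventions required a decision where common practice varies:

- **Width convention.** "Blur at N× the Airy disc size" is mapped to a
  Gaussian whose *FWHM* is N·r (σ = N·r/2.355). Using σ = N·r directly
  over-smooths thin structures — the smallest band is then already ~2.4×
  wider than the diffraction limit — and measurably destroys the ladder's
  scale selectivity (plasma-membrane mask IoU drops from ~0.84 to ~0.31
  on the synthetic benchmark). Both conventions are available via
  `MaskProfile.sigma_convention`.
- **Threshold base.** The product of n band-pass planes has units of
  intensity^n, so a fixed cut expressed in intensity units cannot be
  consistent across image gains or ladder lengths: on bright images it
  passes nearly everything, on dim ones nothing. The default therefore
  thresholds the product at mean + 0.5·SD *of the product image*, the
  usual choice for multiscale-product detectors; the absolute reading
  (0.5·SD of the original frame) is available via
  `MaskProfile.threshold_base` and its gain dependence is pinned by a
  regression test. With the product-statistic threshold the mask is
  exactly gain-invariant.

Masking is strictly per-frame and reflective padding is used at borders.
A literal, loop-based re-implementation of the whole pipeline (explicit
kernels, explicit products, explicit dilation) serves as an oracle; the
optimized path must match it bit-for-bit on the boolean mask.

## Ratio extraction conventions

- Background: mean of the background ROI, estimated per frame (tolerates
  slow illumination drift).
- Numerator: mask ∩ whole-cell ROI.
- Denominator: cytosol ROI when drawn, else the whole-cell ROI; mask
  pixels are excluded from the denominator by default so membrane signal
  cannot inflate it (configurable).
- Missing frames (empty mask or denominator at/below background) are NaN,
  not errors; cells with more than 20% missing frames are dropped with a
  logged reason — the automated analogue of excluding cells that moved
  too much during acquisition.

## Response statistics

- Baseline: mean of the pre-stimulation frames.
- AUC: signed trapezoidal integral of (R − baseline) from the stimulation
  frame to the end, in ratio·minutes. Baseline subtraction makes a
  non-responding cell score exactly 0; a 100×-refined Riemann oracle on
  smooth traces agrees within 1%.
- Δratio(t): value at the frame nearest (stimulation + t) minus baseline;
  nearest-frame lookup rather than interpolation, matching the ~30 s
  acquisition granularity.
- Aggregation: per-replicate means first, then the grand mean of replicate
  means with SEM across replicates — cells never vote individually, so
  unbalanced replicates are not over-weighted. Downstream hypothesis
  tests are expected to consume the replicate-means table.

## Synthetic scenes

The generator emulates a single adherent cell (configurable to several)
at 100 nm pixels with a high-NA objective: a circular cell body, nucleus,
and one organelle structure — plasma-membrane ring (3 px pre-blur),
curvilinear mitochondrial blobs, a perinuclear Golgi cluster, an ER mesh
(ridges of a band-passed random field), or endosomal puncta. The PSF is a
single isotropic Gaussian whose FWHM equals the Airy radius — the
standard desk-scale surrogate. Noise is Poisson shot noise followed by
additive Gaussian read noise (σ = 2), the usual sCMOS approximation.

The cytosolic pool fills the whole cell body (the cytosol underlies the
organelle in a slice); the membrane pool, fraction f(t) of the photon
budget, adds on top of the structure pixels. The noiseless sensor sum
therefore equals background + budget for every f — a conservation law the
tests check.

Ground truth recorded before noise:

- `truth_structure`: the pre-blur geometry;
- `truth_mask`: the observable footprint — blurred structure above ¼ of
  its peak, the region holding ≈90% of a Gaussian ridge's signal mass
  (half-max would keep only the crest of a thin, diffraction-blurred
  structure, not "the whole organelle area" the dilation step is meant to
  cover);
- `truth_ratio`: computed from the noiseless sensor frames with the truth
  footprint (∩ cell) and truth cytosol, using the exact background.

With f = 0 the true ratio is ≈0.87–0.90, not exactly 1: the
plasma-membrane footprint straddles the dark cell edge, so its blurred
mean is slightly below the interior cytosol level. This mirrors real
images and is asserted as such.

Translocation kinetics are a baseline f_pre, a single-exponential rise to
f_max after stimulation (τ_on), and an optional exponential reversal
(τ_off) after an antagonist frame. The defaults — f_pre = 0.1,
f_max = 0.3, τ_on = 60 s, 30 s frames, stimulation after 2 min — are
illustrative values chosen to give a basal ratio of ~1.3 and a peak of
~2.5–3, the magnitude typical of published biosensor traces; they are not
measured constants.

What the generator does *not* emulate: photobleaching, cell movement
(except TIRF jitter), 3-D effects, organelle dynamics, multi-cell
crowding. Passing closed-loop tests therefore shows estimator
correctness under the stated imaging model, not robustness to every
real-world artifact.

## Binding fits

The one-site model Y = BG + (Bmax − BG)·X/(Kd + X) is fitted by bounded
least squares (scipy trust-region reflective). Following the standard
constrained procedure, BG is fixed to min(Y) by default and Bmax bounded
above by 100%; initialization is Bmax₀ = max(Y), Kd₀ = median(X>0).

Residuals are weighted relatively, (model − y)/model — equivalent to 1/Y²
weighting — because densitometry error grows with band intensity; the
generator's noise model (lognormal, constant CV) has exactly this
structure, and under it relative weighting reduces the Monte-Carlo median
Kd error from ~16% to ~14% at CV = 10%. Unweighted fitting is available
(`weighting="none"`). R² is always reported on unweighted residuals.

Confidence intervals are asymptotic: covariance from the Jacobian at the
optimum scaled by the weighted residual variance, Student-t quantiles on
n − p degrees of freedom. A 200-run Monte-Carlo at CV = 10% calibrates
them: observed 95% CI coverage is ~91%.

The closed-loop recovery test uses five concentrations {0, 100, 250, 500,
1000} µM including a zero-ligand point, so that min(Y) equals the true
background and noiseless recovery is exact (df = 3 with BG fixed).
Degenerate data (flat response) is flagged `converged=False` rather than
returning a number.

Percent bound is P/(P+S)·100. When a protein-only control pellet is
supplied, both baseline-correction orders are reported (band subtraction
before the percentage, or percentage subtraction after), since "input
used as baseline" admits either. Flotation fractions multiply the middle
(soluble) band by its 1:6 loading dilution before normalizing; CD molar
ellipticity is m°·10⁶/(pathlength(mm)·concentration(µM)·n peptide bonds).

## Numerical and degenerate-input choices

- Constant frames produce empty masks (strict inequality at the
  threshold); all-zero gel lanes, empty ROIs, F_pre ≤ 0, non-increasing
  time vectors and out-of-range stimulation frames raise errors naming
  the problem.
- All randomness flows through `numpy.random.default_rng(seed)`; equal
  seeds give bit-identical scenes, tables and pipeline CSVs.
- Time is seconds from the first frame; stimulation is a frame index;
  pixel indices are 0-based row-major.

## Problem sizes

The shipped benchmarks use 128×128 px scenes with 20 frames (64×128 px, 12
frames for the end-to-end demo), 20 seeds for ratio recovery, and 200
Monte-Carlo runs for CI calibration — sizes at which every closed-loop
statistic is stable to well within its acceptance margin while the whole
suite runs in seconds.
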