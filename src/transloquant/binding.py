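"""In-vitro biochemistry: co-sedimentation, binding fits, flotation, CD.

Covers the quantitative arm of a liposome binding study:

* percent protein bound from supernatant/pellet gel band densitometry,
* the one-site specific binding model with background,
  ``Y = BG + (Bmax - BG) * X / (Kd + X)``, and its constrained
  least-squares fit,
* flotation-assay fraction accounting with the middle-fraction dilution
  correction,
* conversion of observed CD ellipticity (millidegrees) to molar
  ellipticity (deg cm^2 dmol^-1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "GelBands",
    "BindingDataset",
    "BindingFit",
    "percent_bound",
    "percent_bound_report",
    "one_site_model",
    "fit_binding",
    "flotation_fractions",
    "molar_ellipticity",
]


@dataclass(frozen=True)
class GelBands:
    """Supernatant (S) and pellet (P) band intensities for one condition.

    ``control_pellet`` is the pellet band of the protein-only control (no
    liposomes); when supplied, a baseline-corrected percent bound is
    reported alongside the raw value.
    """

    supernatant: float
    pellet: float
    condition: str = ""
    control_pellet: float | None = None

    def __post_init__(self) -> None:
        if self.supernatant < 0 or self.pellet < 0:
            raise ValueError("band intensities must be non-negative")
        if self.supernatant + self.pellet <= 0:
            raise ValueError("S + P must be positive")
        if self.control_pellet is not None and self.control_pellet < 0:
            raise ValueError("control_pellet must be non-negative")


@dataclass
class BindingDataset:
    """Concentration / percent-bound observations, optionally with truth.

    ``concentration_uM`` and ``percent_bound`` are parallel arrays;
    ``replicate`` labels rows by experimental replicate. When the dataset
    was simulated, ``true_params`` records the generating (BG, Bmax, Kd)
    for closed-loop recovery tests.
    """

    concentration_uM: np.ndarray
    percent_bound: np.ndarray
    replicate: np.ndarray | None = None
    true_params: dict | None = None

    def __post_init__(self) -> None:
        self.concentration_uM = np.asarray(self.concentration_uM, dtype=np.float64)
        self.percent_bound = np.asarray(self.percent_bound, dtype=np.float64)
        if self.concentration_uM.shape != self.percent_bound.shape:
            raise ValueError("concentration and percent_bound must be congruent")
        if np.any(self.concentration_uM < 0):
            raise ValueError("concentrations must be non-negative")
        if np.any((self.percent_bound < 0) | (self.percent_bound > 100)):
            raise ValueError("percent_bound must lie in [0, 100]")
        if self.replicate is None:
            self.replicate = np.ones(self.concentration_uM.shape, dtype=int)
        else:
            self.replicate = np.asarray(self.replicate)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "concentration_uM": self.concentration_uM,
                "percent_bound": self.percent_bound,
                "replicate": self.replicate,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "BindingDataset":
        rep = df["replicate"].to_numpy() if "replicate" in df else None
        return cls(
            concentration_uM=df["concentration_uM"].to_numpy(),
            percent_bound=df["percent_bound"].to_numpy(),
            replicate=rep,
        )


@dataclass
class BindingFit:
    """Result of the constrained one-site fit.

    ``bg`` is the background percent bound (fixed or free), ``bmax`` the
    plateau, ``kd`` the half-maximal ligand concentration in uM.
    ``ci95`` maps each free parameter name to its asymptotic 95% interval
    (Student-t on ``df`` degrees of freedom). ``converged`` is False when
    the optimizer failed or the parameters are unidentifiable (e.g. a flat
    response), in which case the point estimates are not meaningful.
    """

    bg: float
    bmax: float
    kd: float
    bg_fixed: bool
    stderr: dict
    ci95: dict
    r_squared: float
    df: int
    converged: bool
    message: str = ""

    def predict(self, x) -> np.ndarray:
        return one_site_model(x, self.bg, self.bmax, self.kd)

    def to_dict(self) -> dict:
        return {
            "bg": self.bg,
            "bmax": self.bmax,
            "kd": self.kd,
            "bg_fixed": self.bg_fixed,
            "stderr": self.stderr,
            "ci95": {k: list(v) for k, v in self.ci95.items()},
            "r_squared": self.r_squared,
            "df": self.df,
            "converged": self.converged,
            "message": self.message,
        }


def percent_bound(bands: GelBands) -> float:
    """Percent protein bound, ``100 * P / (P + S)``."""
    return 100.0 * bands.pellet / (bands.pellet + bands.supernatant)


def percent_bound_report(bands: GelBands) -> dict:
    """Raw and baseline-corrected percent bound for one condition.

    When a protein-only control pellet is available, two corrected values
    are reported, because "control pellet used as baseline" admits either
    arithmetic order: subtracting the control band intensity before forming
    the percentage, or subtracting the control condition's percent bound
    from the raw percentage (clipped at 0).
    """
    s, p = bands.supernatant, bands.pellet
    raw = percent_bound(bands)
    out = {"condition": bands.condition, "percent_bound": raw}
    if bands.control_pellet is not None:
        # subtract the control band before forming the percentage ...
        p_corr = max(p - bands.control_pellet, 0.0)
        out["percent_bound_band_corrected"] = (
            100.0 * p_corr / (p_corr + s) if (p_corr + s) > 0 else 0.0
        )
        # ... or subtract the control's percent bound afterwards
        ctrl_pct = 100.0 * bands.control_pellet / (bands.control_pellet + s)
        out["percent_bound_baseline_subtracted"] = max(raw - ctrl_pct, 0.0)
    return out


def one_site_model(x, bg: float, bmax: float, kd: float):
    """One-site specific binding with background.

    ``Y = BG + (Bmax - BG) * X / (Kd + X)``; Y(0) = BG, Y(Kd) is the
    midpoint (BG + Bmax)/2, Y(inf) = Bmax.
    """
    if kd <= 0:
        raise ValueError("Kd must be positive")
    x = np.asarray(x, dtype=np.float64)
    if np.any(x < 0):
        raise ValueError("concentrations must be non-negative")
    return bg + (bmax - bg) * x / (kd + x)


def fit_binding(
    data: BindingDataset,
    fix_bg_to_min: bool = True,
    bmax_upper: float = 100.0,
    bg: float | None = None,
    weighting: str = "relative",
) -> BindingFit:
    """Constrained least-squares fit of the one-site model.

    With ``fix_bg_to_min`` (the default) BG is fixed to ``min(Y)`` — the
    standard curve-fitting convention of constraining the background to the
    smallest observed value — leaving Kd and Bmax free (2 parameters).
    ``bg`` overrides the fixed value explicitly. Bmax is box-constrained to
    ``(BG, bmax_upper]`` and Kd to ``(0, 1e4 * max(X)]``.

    ``weighting="relative"`` (default) minimizes relative residuals
    ``(model - y)/model`` — the 1/Y^2 weighting appropriate when the
    measurement error is proportional to the signal, as it is for gel
    densitometry; ``"none"`` minimizes raw residuals. R^2 is always
    reported on the unweighted residuals for comparability.

    Reports asymptotic standard errors and Student-t 95% confidence
    intervals from the Jacobian at the optimum, R^2, and residual degrees
    of freedom. A flat response (all Y equal) or optimizer failure is
    flagged via ``converged=False`` rather than returning a silent answer.
    """
    if weighting not in ("relative", "none"):
        raise ValueError("weighting must be 'relative' or 'none'")
    x = data.concentration_uM
    y = data.percent_bound
    if fix_bg_to_min or bg is not None:
        bg_val = float(np.min(y)) if bg is None else float(bg)
        n_free = 2
    else:
        bg_val = None
        n_free = 3
    n = x.size
    if n < n_free + 1 or np.unique(x).size < n_free:
        raise ValueError(
            f"need more distinct concentrations than the {n_free} free parameters"
        )
    df = n - n_free

    flat = np.ptp(y) == 0

    def weight(res_raw, model):
        if weighting == "relative":
            return res_raw / np.maximum(np.abs(model), 1e-9)
        return res_raw

    kd0 = float(np.median(x[x > 0])) if np.any(x > 0) else 1.0
    if bg_val is not None:

        def resid(theta):
            bmax, kd = theta
            m = one_site_model(x, bg_val, bmax, kd)
            return weight(m - y, m)

        theta0 = np.array([max(np.max(y), bg_val + 1e-6), kd0])
        lower = np.array([bg_val, 1e-12])
        upper = np.array([bmax_upper, 1e4 * max(np.max(x), 1.0)])
        names = ["bmax", "kd"]
    else:

        def resid(theta):
            bg_f, bmax, kd = theta
            m = one_site_model(x, bg_f, bmax, kd)
            return weight(m - y, m)

        theta0 = np.array([np.min(y), max(np.max(y), np.min(y) + 1e-6), kd0])
        lower = np.array([0.0, 0.0, 1e-12])
        upper = np.array([100.0, bmax_upper, 1e4 * max(np.max(x), 1.0)])
        names = ["bg", "bmax", "kd"]

    theta0 = np.clip(theta0, lower + 1e-12, upper)
    sol = optimize.least_squares(resid, theta0, bounds=(lower, upper), method="trf")

    # weighted SS drives the covariance; R^2 is reported unweighted
    ss_w = float(sol.fun @ sol.fun)
    if bg_val is not None:
        yhat = one_site_model(x, bg_val, *sol.x)
    else:
        yhat = one_site_model(x, *sol.x)
    ss_res = float(np.sum((yhat - y) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan

    # asymptotic covariance from the Jacobian at the optimum
    stderr: dict = {}
    ci95: dict = {}
    identifiable = sol.success and not flat
    if identifiable and df >= 1:
        jtj = sol.jac.T @ sol.jac
        try:
            cov = np.linalg.inv(jtj) * (ss_w / df)
            se = np.sqrt(np.clip(np.diag(cov), 0, None))
            tcrit = stats.t.ppf(0.975, df)
            for nm, est, s_ in zip(names, sol.x, se):
                stderr[nm] = float(s_)
                ci95[nm] = (float(est - tcrit * s_), float(est + tcrit * s_))
        except np.linalg.LinAlgError:
            identifiable = False

    if bg_val is not None:
        bmax_hat, kd_hat = sol.x
        bg_hat = bg_val
    else:
        bg_hat, bmax_hat, kd_hat = sol.x

    msg = sol.message
    if flat:
        msg = "flat response: Kd unidentifiable"

    return BindingFit(
        bg=float(bg_hat),
        bmax=float(bmax_hat),
        kd=float(kd_hat),
        bg_fixed=bg_val is not None,
        stderr=stderr,
        ci95=ci95,
        r_squared=float(r2),
        df=int(df),
        converged=bool(identifiable),
        message=msg,
    )


def flotation_fractions(
    top: float, middle: float, pellet: float, middle_dilution: float = 6.0
) -> dict:
    """Flotation-assay fractions with the middle-fraction dilution correction.

    The soluble (middle) band is loaded at a 1:``middle_dilution`` dilution
    relative to the top and pellet samples, so its intensity is multiplied
    by that factor before normalization. Returns fractions summing to 1.
    """
    if top < 0 or middle < 0 or pellet < 0:
        raise ValueError("band intensities must be non-negative")
    mid_corr = middle * middle_dilution
    total = top + mid_corr + pellet
    if total <= 0:
        raise ValueError("all-zero band intensities")
    return {
        "liposome_bound": top / total,
        "soluble": mid_corr / total,
        "aggregated": pellet / total,
    }


@dataclass(frozen=True)
class CDMeasurement:
    """One CD observation: millidegrees plus the normalization quantities."""

    signal_mdeg: float
    pathlength_mm: float
    concentration_uM: float
    n_bonds: int

    def __post_init__(self) -> None:
        if self.pathlength_mm <= 0 or self.concentration_uM <= 0 or self.n_bonds <= 0:
            raise ValueError("pathlength, concentration and n_bonds must be positive")


def molar_ellipticity(meas: CDMeasurement) -> float:
    """Mean-residue molar ellipticity in deg cm^2 dmol^-1.

    ``mdeg * 1e6 / (pathlength_mm * concentration_uM * n_bonds)`` where n
    is the number of peptide bonds in the protein.
    """
    return meas.signal_mdeg * 1.0e6 / (
        meas.pathlength_mm * meas.concentration_uM * meas.n_bonds
    )
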