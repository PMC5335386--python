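"""Two-photon line-scan diffusion analysis.

A fluorophore puffed from a point source spreads through the tissue; a
line scan orthogonal to the pipette records a kymograph (position × time).
Each intensity profile, after subtraction of the averaged pre-puff
baseline, is Gaussian with width γ obeying γ² = 4·D·t for free diffusion,
so the diffusion coefficient is the slope of γ²/4 against time.  Comparing
the free-solution coefficient with the in-tissue apparent coefficient
gives the tortuosity λ = √(D_free/D*), and the Stokes–Einstein relation
converts a coefficient into a hydrodynamic diameter d_H = kT/(3πηD).

Positions in μm, times in ms (line rate in Hz), D in μm²/ms, d_H in nm.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import lmfit

__all__ = [
    "LineScanError",
    "Kymograph",
    "Profile",
    "ProfileFit",
    "DiffusionEstimate",
    "extract_profiles",
    "fit_gaussian_profile",
    "estimate_diffusion_coefficient",
    "tortuosity",
    "hydrodynamic_diameter",
    "LineScanDiffusionModel",
    "DiffusionResults",
    "BOLTZMANN",
    "DEFAULT_TEMPERATURE_K",
    "DEFAULT_VISCOSITY_PAS",
]

BOLTZMANN = 1.38e-23            # J/K
DEFAULT_TEMPERATURE_K = 295.0
DEFAULT_VISCOSITY_PAS = 9.68e-4  # water


class LineScanError(ValueError):
    pass


@dataclass
class Kymograph:
    """Line-scan intensity record: rows are positions, columns are lines."""

    intensity: np.ndarray
    pixel_um: float
    line_rate_hz: float = 625.0
    puff_index: int = 0

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.ndim != 2:
            raise LineScanError("intensity must be (position, time)")
        if self.line_rate_hz <= 0 or self.pixel_um <= 0:
            raise LineScanError("line rate and pixel size must be > 0")
        if not 0 <= self.puff_index < self.intensity.shape[1]:
            raise LineScanError("puff index outside the record")

    @property
    def n_pixels(self) -> int:
        return self.intensity.shape[0]

    @property
    def n_lines(self) -> int:
        return self.intensity.shape[1]

    @property
    def positions_um(self) -> np.ndarray:
        n = self.n_pixels
        return (np.arange(n) - (n - 1) / 2.0) * self.pixel_um

    @classmethod
    def from_csv(cls, path, pixel_um: float, line_rate_hz: float = 625.0,
                 puff_index: int = 0) -> "Kymograph":
        arr = pd.read_csv(path, header=None).to_numpy(dtype=float)
        return cls(arr, pixel_um, line_rate_hz, puff_index)

    def to_csv(self, path) -> None:
        pd.DataFrame(self.intensity).to_csv(path, index=False, header=False)


@dataclass
class Profile:
    """One baseline-subtracted intensity profile at a time after the puff."""

    time_ms: float
    positions_um: np.ndarray
    intensity: np.ndarray


@dataclass
class ProfileFit:
    """Gaussian fit A·exp(−(x−x₀)²/γ²) + c of one profile."""

    time_ms: float
    amplitude: float
    center_um: float
    gamma_um: float
    gamma_stderr_um: float
    offset: float
    rsquared: float
    success: bool


def extract_profiles(kymo: Kymograph, interval_ms: float = 150.0) -> list[Profile]:
    """Sample profiles at a fixed cadence after the puff.

    The average of all pre-puff lines is subtracted from every profile to
    remove residual fluorescence.  Raises when the puff is at line 0 (no
    baseline available).
    """
    if kymo.puff_index < 1:
        raise LineScanError("no pre-puff lines; cannot form a baseline")
    stride = max(1, int(round(interval_ms * kymo.line_rate_hz / 1000.0)))
    baseline = kymo.intensity[:, : kymo.puff_index].mean(axis=1)
    x = kymo.positions_um
    out = []
    j = kymo.puff_index + stride
    while j < kymo.n_lines:
        t_ms = (j - kymo.puff_index) / kymo.line_rate_hz * 1000.0
        out.append(Profile(t_ms, x, kymo.intensity[:, j] - baseline))
        j += stride
    return out


def _gauss(x, amp, x0, gamma, offset):
    return amp * np.exp(-((x - x0) ** 2) / gamma**2) + offset


def fit_gaussian_profile(profile: Profile) -> ProfileFit:
    """Levenberg–Marquardt Gaussian fit of one profile.

    γ is the width parameter in exp(−x²/γ²), so γ² = 4Dt for a diffusing
    point source.  A flat or non-converging profile is returned with
    ``success=False`` and excluded downstream.
    """
    x = profile.positions_um
    y = profile.intensity
    if len(x) < 10:
        raise LineScanError("profile needs at least 10 samples")
    fail = ProfileFit(profile.time_ms, 0.0, 0.0, np.nan, np.nan, 0.0, 0.0, False)
    span = x.max() - x.min()
    off0 = float(np.median(y))
    amp0 = float(y.max() - off0)
    if amp0 <= 0 or np.ptp(y) < 1e-12:
        return fail
    model = lmfit.Model(_gauss)
    params = model.make_params(
        amp=dict(value=amp0, min=0),
        x0=dict(value=float(x[np.argmax(y)]), min=x.min(), max=x.max()),
        gamma=dict(value=span / 4, min=1e-3, max=span * 10),
        offset=dict(value=off0),
    )
    try:
        res = model.fit(y, params, x=x)
    except Exception:
        return fail
    if not res.success:
        return fail
    ss_tot = float(((y - y.mean()) ** 2).sum())
    rsq = 1.0 - res.chisqr / ss_tot if ss_tot > 0 else 0.0
    gerr = res.params["gamma"].stderr
    return ProfileFit(
        time_ms=profile.time_ms,
        amplitude=float(res.best_values["amp"]),
        center_um=float(res.best_values["x0"]),
        gamma_um=float(res.best_values["gamma"]),
        gamma_stderr_um=float(gerr) if gerr is not None else np.nan,
        offset=float(res.best_values["offset"]),
        rsquared=rsq,
        success=True,
    )


@dataclass
class DiffusionEstimate:
    """D from the γ²/4-vs-time regression, with derived tissue quantities."""

    d_um2_ms: float
    rsquared: float
    intercept_um2: float
    n_profiles: int
    lambda_tortuosity: float | None = None
    d_h_nm: float | None = None
    temperature_k: float = DEFAULT_TEMPERATURE_K
    viscosity_pas: float = DEFAULT_VISCOSITY_PAS


def estimate_diffusion_coefficient(
    fits: list[ProfileFit], window_s: float = 2.0
) -> DiffusionEstimate:
    """Linear regression of γᵢ²/4 against time over the linearity window.

    Only successful fits within ``window_s`` after the puff enter the
    regression (at least 3 required); the slope is D in μm²/ms and the
    intercept absorbs the initial source width.  A negative slope is
    reported with a warning.
    """
    good = [f for f in fits if f.success and f.time_ms <= window_s * 1000.0]
    if len(good) < 3:
        raise LineScanError(
            f"need >= 3 usable profiles in the window, got {len(good)}"
        )
    t = np.array([f.time_ms for f in good])
    y = np.array([f.gamma_um**2 / 4.0 for f in good])
    A = np.column_stack([t, np.ones_like(t)])
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    slope, intercept = float(coef[0]), float(coef[1])
    pred = A @ coef
    ss_res = float(((y - pred) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    rsq = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    if slope < 0:
        warnings.warn("negative diffusion slope; check the linearity window")
    return DiffusionEstimate(d_um2_ms=slope, rsquared=rsq,
                             intercept_um2=intercept, n_profiles=len(good))


def tortuosity(d_free: float, d_star: float) -> float:
    """Hindrance to diffusion in tissue: λ = √(D_free / D*)."""
    if d_free <= 0 or d_star <= 0:
        raise LineScanError("both coefficients must be > 0")
    lam = math.sqrt(d_free / d_star)
    if lam < 1.0:
        warnings.warn(f"tortuosity {lam:.2f} < 1 (apparent D exceeds free D)")
    return lam


def hydrodynamic_diameter(d_um2_ms: float,
                          temperature_k: float = DEFAULT_TEMPERATURE_K,
                          viscosity_pas: float = DEFAULT_VISCOSITY_PAS) -> float:
    """Stokes–Einstein diameter d_H = kT/(3πηD), in nm."""
    if d_um2_ms <= 0:
        raise LineScanError("D must be > 0")
    d_si = d_um2_ms * 1e-9  # μm²/ms -> m²/s
    d_h_m = BOLTZMANN * temperature_k / (3.0 * math.pi * viscosity_pas * d_si)
    return d_h_m * 1e9


class LineScanDiffusionModel:
    """Kymograph → diffusion-coefficient pipeline as a fittable model."""

    def __init__(self, kymograph: Kymograph, interval_ms: float = 150.0,
                 window_s: float = 2.0):
        self.kymograph = kymograph
        self.interval_ms = interval_ms
        self.window_s = window_s

    def fit(self) -> "DiffusionResults":
        profiles = extract_profiles(self.kymograph, self.interval_ms)
        fits = [fit_gaussian_profile(p) for p in profiles]
        est = estimate_diffusion_coefficient(fits, self.window_s)
        return DiffusionResults(estimate=est, profile_fits=fits)


@dataclass
class DiffusionResults:
    """Fitted diffusion coefficient with per-profile Gaussian fits."""

    estimate: DiffusionEstimate
    profile_fits: list[ProfileFit] = field(default_factory=list)

    @property
    def d_um2_ms(self) -> float:
        return self.estimate.d_um2_ms

    def tortuosity_vs(self, d_free: float) -> float:
        return tortuosity(d_free, self.estimate.d_um2_ms)

    def hydrodynamic_diameter_nm(self) -> float:
        return hydrodynamic_diameter(self.estimate.d_um2_ms,
                                     self.estimate.temperature_k,
                                     self.estimate.viscosity_pas)

    def summary(self) -> pd.DataFrame:
        rows = {
            "D (um^2/ms)": self.estimate.d_um2_ms,
            "regression R^2": self.estimate.rsquared,
            "intercept (um^2)": self.estimate.intercept_um2,
            "profiles used": self.estimate.n_profiles,
            "d_H (nm)": (self.hydrodynamic_diameter_nm()
                         if self.estimate.d_um2_ms > 0 else np.nan),
        }
        return pd.DataFrame({"value": rows})

    def __repr__(self) -> str:
        return "DiffusionResults\n" + self.summary().to_string()
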