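"""Seeded synthetic-data generators for every input class of the pipeline.

Real recordings (astrocyte transporter currents, two-photon line scans,
tomography-derived geometry statistics) are emulated with the statistical
structure the analyses assume: fSTCs are a glutamate-clearance waveform
convolved with a distortion filter plus Gaussian noise and paired-pulse
facilitation; kymographs follow the analytic point-source diffusion
solution with Poisson photon noise; scene specifications are drawn from
truncated normals around the reconstruction statistics.  Every generator
is a pure function of its spec (bit-reproducible per seed) and returns
the ground truth alongside the data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.stats import truncnorm

from .geometry import SceneSpec
from .linescan import Kymograph
from .stc import CurrentTrace

__all__ = [
    "SynthSpec",
    "TABLE_STATS_CONTROL",
    "TABLE_STATS_TFLLR",
    "synth_fstc",
    "synth_kymograph",
    "synth_scene_specs",
]


@dataclass(frozen=True)
class SynthSpec:
    """Parameters of the synthetic recordings.

    Clearance is an instantaneously-rising biexponential (defaults chosen
    so the fitted fSTC decay lands near the control values τ_fast ≈ 5 ms,
    τ_slow ≈ 18 ms and the clearance centroid near 16.5 ms); the filter
    is a gamma kernel (shape 2) peaking ~2 ms after the stimulus.  The
    sub-saturating-TBOA condition scales the amplitude by
    ``tboa_amp_scale`` and the slow decay by ``tboa_tau_scale``.
    """

    seed: int = 0
    # currents
    rate_khz: float = 10.0
    duration_ms: float = 400.0
    stim_ms: float = 50.0
    ipi_ms: float = 100.0
    amplitude_pa: float = 27.7
    facilitation: float = 1.7
    noise_sd_pa: float = 0.3
    clearance_frac_fast: float = 0.3
    clearance_tau_fast_ms: float = 5.0
    clearance_tau_slow_ms: float = 18.0
    filter_shape: float = 2.0
    filter_scale_ms: float = 2.0
    tboa_amp_scale: float = 0.36
    tboa_tau_scale: float = 2.2
    # kymographs
    d_um2_ms: float = 0.5
    source_offset_um: float = 5.0
    line_rate_hz: float = 625.0
    # scan line long enough (384 μm) that even the widest profile in the
    # 2 s linearity window (γ ≈ 63 μm at D = 0.5 μm²/ms) leaves flat wings,
    # keeping the Gaussian width and offset jointly identifiable
    pixel_um: float = 1.0
    n_pixels: int = 384
    kymo_duration_s: float = 2.5
    puff_delay_s: float = 0.2
    peak_counts: float = 2000.0
    baseline_counts: float = 50.0
    poisson_noise: bool = True
    n_repeats: int = 10  # consecutive applications averaged per kymograph

    def validate(self) -> None:
        if self.facilitation < 1:
            raise ValueError("facilitation must be >= 1")
        if self.noise_sd_pa < 0:
            raise ValueError("noise SD must be >= 0")


def _clearance_waveform(t_ms: np.ndarray, frac_fast: float, tau_fast: float,
                        tau_slow: float) -> np.ndarray:
    out = np.zeros_like(t_ms)
    m = t_ms >= 0
    out[m] = (frac_fast * np.exp(-t_ms[m] / tau_fast)
              + (1 - frac_fast) * np.exp(-t_ms[m] / tau_slow))
    return out


def _gamma_filter(t_ms: np.ndarray, shape: float, scale_ms: float,
                  dt_ms: float) -> np.ndarray:
    h = np.where(t_ms >= 0,
                 np.power(np.maximum(t_ms, 0) / scale_ms, shape - 1)
                 * np.exp(-np.maximum(t_ms, 0) / scale_ms), 0.0)
    area = h.sum() * dt_ms
    return h / area


def synth_fstc(spec: SynthSpec | None = None, tboa: bool = False
               ) -> tuple[CurrentTrace, CurrentTrace, dict]:
    """Generate a (single, paired) transporter-current pair plus ground truth.

    The fSTC is clearance ⊗ filter, scaled to the target amplitude
    (inward-negative); the paired record carries the facilitated second
    response at the inter-pulse interval.  ``tboa`` switches to the
    sub-saturating-antagonist condition (smaller, slower response).
    The truth dict holds the clearance waveform, its windowed centroid,
    the unit-area filter and the facilitation factor.
    """
    spec = spec or SynthSpec()
    spec.validate()
    dt = 1.0 / spec.rate_khz
    n = int(round(spec.duration_ms * spec.rate_khz)) + 1
    rng = np.random.default_rng(spec.seed + (1_000_003 if tboa else 0))

    tau_fast = spec.clearance_tau_fast_ms
    tau_slow = spec.clearance_tau_slow_ms
    amp = spec.amplitude_pa
    if tboa:
        tau_slow = tau_slow * spec.tboa_tau_scale
        amp = amp * spec.tboa_amp_scale

    n_resp = n - int(round(spec.stim_ms * spec.rate_khz))
    t = np.arange(n_resp) * dt
    clearance = _clearance_waveform(t, spec.clearance_frac_fast,
                                    tau_fast, tau_slow)
    filt = _gamma_filter(t, spec.filter_shape, spec.filter_scale_ms, dt)
    resp = np.convolve(clearance, filt)[:n_resp] * dt
    resp = resp / resp.max() * amp

    i_stim = int(round(spec.stim_ms * spec.rate_khz))
    i_stim2 = int(round((spec.stim_ms + spec.ipi_ms) * spec.rate_khz))

    single = np.zeros(n)
    single[i_stim:] -= resp
    paired = np.zeros(n)
    paired[i_stim:] -= resp
    n2 = n - i_stim2
    paired[i_stim2:] -= spec.facilitation * resp[:n2]
    single += rng.normal(0.0, spec.noise_sd_pa, n)
    paired += rng.normal(0.0, spec.noise_sd_pa, n)

    win = min(100.0, spec.duration_ms - spec.stim_ms)
    iw = int(round(win * spec.rate_khz))
    cw = clearance[:iw]
    truth = {
        "clearance": clearance,
        "clearance_centroid_ms": float(np.dot(t[:iw], cw) / cw.sum()),
        "filter": filt,
        "facilitation": spec.facilitation,
        "amplitude_pa": amp,
        "tau_fast_ms": tau_fast,
        "tau_slow_ms": tau_slow,
    }
    return (
        CurrentTrace(single, spec.rate_khz, spec.stim_ms),
        CurrentTrace(paired, spec.rate_khz, spec.stim_ms),
        truth,
    )


def synth_kymograph(spec: SynthSpec | None = None,
                    d_um2_ms: float | None = None
                    ) -> tuple[Kymograph, dict]:
    """Kymograph of point-source diffusion observed along a scan line.

    The intensity follows the instantaneous-point-source solution of the
    diffusion equation sampled along a line offset ``source_offset_um``
    from the source, at the line rate, with optional Poisson photon noise
    and pre-puff baseline lines included.  Fitted profile widths obey
    γ²(t) = 4·D·t exactly in the noise-free case.
    """
    spec = spec or SynthSpec()
    d = d_um2_ms if d_um2_ms is not None else spec.d_um2_ms
    if d <= 0:
        raise ValueError("D must be > 0")
    rng = np.random.default_rng(spec.seed + 7_000_017)
    n_lines = int(round(spec.kymo_duration_s * spec.line_rate_hz))
    puff_index = int(round(spec.puff_delay_s * spec.line_rate_hz))
    x = (np.arange(spec.n_pixels) - (spec.n_pixels - 1) / 2.0) * spec.pixel_um
    line_times_ms = np.arange(n_lines) / spec.line_rate_hz * 1000.0
    tp = puff_index / spec.line_rate_hz * 1000.0

    img = np.full((spec.n_pixels, n_lines), spec.baseline_counts)
    rho2 = spec.source_offset_um**2
    t_ref = 150.0  # reference time for the peak-amplitude normalization, ms
    a_ref = (4 * math.pi * d * t_ref) ** -1.5 * math.exp(-rho2 / (4 * d * t_ref))
    for j in range(puff_index + 1, n_lines):
        td = line_times_ms[j] - tp
        amp = ((4 * math.pi * d * td) ** -1.5
               * math.exp(-rho2 / (4 * d * td)) / a_ref * spec.peak_counts)
        img[:, j] += amp * np.exp(-(x**2) / (4 * d * td))
    if spec.poisson_noise:
        # the recorded kymograph is the average of n_repeats applications
        img = rng.poisson(img * spec.n_repeats).astype(float) / spec.n_repeats

    kymo = Kymograph(img, spec.pixel_um, spec.line_rate_hz, puff_index)
    truth = {"d_um2_ms": d, "puff_time_ms": tp}
    return kymo, truth


# Reconstruction statistics (mean, SD) for the two conditions: PSD area and
# per-process astrocyte surface area in μm², volumes in μm³, distance in nm,
# process count dimensionless.
TABLE_STATS_CONTROL = {
    "psd_area": (0.10, 0.11),
    "pre_volume": (0.08, 0.08),
    "post_volume": (0.04, 0.04),
    "astro_area_per_process": (0.80, 0.45),
    "n_astro": (2.25, 1.54),
    "psd_astro_distance_nm": (116.5, 55.4),
}
TABLE_STATS_TFLLR = {
    "psd_area": (0.08, 0.05),
    "pre_volume": (0.06, 0.03),
    "post_volume": (0.03, 0.02),
    "astro_area_per_process": (0.57, 0.22),
    "n_astro": (4.23, 2.38),
    "psd_astro_distance_nm": (190.9, 74.6),
}

_FLOOR = {
    "psd_area": 0.005,
    "pre_volume": 0.005,
    "post_volume": 0.005,
    "astro_area_per_process": 0.05,
    "n_astro": 0.0,
    "psd_astro_distance_nm": 0.0,
}


def _truncated_draw(rng, mean, sd, lo, size):
    if sd == 0:
        return np.full(size, mean)
    a = (lo - mean) / sd
    return truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=size,
                         random_state=rng)


def synth_scene_specs(stats: dict[str, tuple[float, float]] | None = None,
                      n: int = 1, seed: int = 0) -> list[SceneSpec]:
    """Draw scene specifications from truncated normals around the
    reconstruction statistics (control set by default).

    Negative draws are truncated at physical floors (distance ≥ 0, small
    positive volumes/areas); process counts are rounded to integers ≥ 0.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    stats = stats or TABLE_STATS_CONTROL
    rng = np.random.default_rng(seed)
    draws = {}
    for key, (mean, sd) in stats.items():
        draws[key] = _truncated_draw(rng, mean, sd, _FLOOR[key], n)
    specs = []
    base = SceneSpec()
    for i in range(n):
        specs.append(
            replace(
                base,
                psd_area=float(draws["psd_area"][i]),
                pre_volume=float(draws["pre_volume"][i]),
                post_volume=float(draws["post_volume"][i]),
                astro_area_per_process=float(draws["astro_area_per_process"][i]),
                n_astro=int(round(draws["n_astro"][i])),
                psd_astro_distance_nm=float(draws["psd_astro_distance_nm"][i]),
            )
        )
    return specs
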