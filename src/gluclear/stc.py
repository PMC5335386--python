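"""Astrocyte transporter-current analysis.

The synaptically-activated transporter current (STC) is a temporally
distorted readout of glutamate clearance.  This module isolates the
facilitated STC (fSTC) from interleaved single/paired stimulation, fits
its kinetics (rise, fast/slow decay, centroid), derives the linear filter
from recordings in a sub-saturating transporter antagonist (TBOA, 10 μM) —
where the prolonged fSTC approximates an instantaneously-rising clearance
with the fSTC's own decay — and deconvolves that filter from the control
fSTC to recover the glutamate-clearance time course and its centroid ⟨t⟩.

Traces are sampled at a fixed rate (default 10 kHz), currents in pA,
times in ms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import lmfit

__all__ = [
    "TraceError",
    "FitError",
    "CurrentTrace",
    "ExpFitResult",
    "ClearanceEstimate",
    "isolate_fstc",
    "blank_artifact",
    "fit_multiexponential",
    "rise_20_80",
    "centroid",
    "wiener_deconvolve",
    "derive_filter",
    "estimate_clearance",
    "measure_sustained_current",
    "TransporterCurrentModel",
    "TransporterCurrentResults",
]


class TraceError(ValueError):
    pass


class FitError(RuntimeError):
    pass


@dataclass
class CurrentTrace:
    """A uniformly sampled membrane-current record.

    samples : pA (inward currents negative, as recorded)
    rate_khz : sampling rate (default 10 kHz)
    stim_ms : stimulus time within the record
    """

    samples: np.ndarray
    rate_khz: float = 10.0
    stim_ms: float = 50.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or len(self.samples) < 2:
            raise TraceError("samples must be a 1-D array")
        if self.rate_khz <= 0:
            raise TraceError("sampling rate must be > 0")
        if not 0 <= self.stim_ms <= self.duration_ms:
            raise TraceError("stimulus time outside the record")

    @property
    def dt_ms(self) -> float:
        return 1.0 / self.rate_khz

    @property
    def duration_ms(self) -> float:
        return (len(self.samples) - 1) / self.rate_khz

    @property
    def time_ms(self) -> np.ndarray:
        return np.arange(len(self.samples)) * self.dt_ms

    def index_of(self, t_ms: float) -> int:
        return int(round(t_ms * self.rate_khz))

    def baseline(self, window_ms: float = 50.0) -> float:
        i1 = self.index_of(self.stim_ms)
        i0 = max(0, i1 - self.index_of(window_ms) if window_ms else 0)
        i0 = max(0, i1 - int(round(window_ms * self.rate_khz)))
        if i1 <= i0:
            return 0.0
        return float(self.samples[i0:i1].mean())

    @classmethod
    def from_csv(cls, path, stim_ms: float = 50.0) -> "CurrentTrace":
        df = pd.read_csv(path)
        t = df.iloc[:, 0].to_numpy(dtype=float)
        i = df.iloc[:, 1].to_numpy(dtype=float)
        dts = np.diff(t)
        if len(dts) and (dts.max() - dts.min()) > 1e-6 * dts.mean():
            raise TraceError("non-uniform sampling in CSV")
        rate = 1.0 / dts.mean() if len(dts) else 10.0
        return cls(i, rate_khz=rate, stim_ms=stim_ms)

    def to_csv(self, path) -> None:
        pd.DataFrame({"time_ms": self.time_ms, "current_pa": self.samples}
                     ).to_csv(path, index=False)


@dataclass
class ExpFitResult:
    """Kinetic summary of a multi-exponential fSTC fit.

    The fitted form is A·(1−exp(−(t−t0)/τ_rise))·(f·exp(−(t−t0)/τ_fast)
    + (1−f)·exp(−(t−t0)/τ_slow)), with τ_fast ≤ τ_slow and f ∈ [0, 1].
    """

    amplitude_pa: float        # the equation's scale parameter A
    peak_pa: float             # peak of the fitted waveform (unsigned)
    t0_ms: float
    tau_rise_ms: float
    tau_fast_ms: float
    tau_slow_ms: float
    frac_fast: float
    rise_20_80_ms: float
    centroid_ms: float
    rsquared: float
    sign: int = -1

    def decay_waveform(self, t_ms: np.ndarray) -> np.ndarray:
        """Instantaneously-rising biexponential with the fitted decay."""
        t = np.asarray(t_ms, dtype=float)
        out = np.zeros_like(t)
        m = t >= 0
        out[m] = (self.frac_fast * np.exp(-t[m] / self.tau_fast_ms)
                  + (1 - self.frac_fast) * np.exp(-t[m] / self.tau_slow_ms))
        return out


@dataclass
class ClearanceEstimate:
    """Deconvolved glutamate-clearance waveform and its centroid."""

    time_ms: np.ndarray
    clearance: np.ndarray       # unit peak, non-negative
    centroid_ms: float
    filter_waveform: np.ndarray
    regularization: float
    reconstruction_rms: float   # relative RMS of conv(clearance, filter) vs input


def isolate_fstc(single: CurrentTrace, paired: CurrentTrace,
                 ipi_ms: float = 100.0) -> CurrentTrace:
    """Facilitated STC: paired-pulse response minus single-pulse response.

    The residual (the second-pulse response riding on facilitation) is
    time-shifted so it is referenced to its own stimulus, yielding a trace
    whose stimulus time matches the single-pulse record.
    """
    if ipi_ms <= 0:
        raise TraceError("inter-pulse interval must be > 0")
    if abs(single.rate_khz - paired.rate_khz) > 1e-9:
        raise TraceError("sampling-rate mismatch between single and paired")
    n = min(len(single.samples), len(paired.samples))
    diff = paired.samples[:n] - single.samples[:n]
    shift = int(round(ipi_ms * single.rate_khz))
    if shift >= n:
        raise TraceError("inter-pulse interval exceeds the record")
    out = diff[shift:]
    return CurrentTrace(out, rate_khz=single.rate_khz, stim_ms=single.stim_ms)


def blank_artifact(trace: CurrentTrace, half_width_ms: float = 0.5) -> CurrentTrace:
    """Blank ±half_width around the stimulus and bridge by linear interpolation."""
    i0 = max(0, trace.index_of(trace.stim_ms - half_width_ms))
    i1 = min(len(trace.samples) - 1, trace.index_of(trace.stim_ms + half_width_ms))
    s = trace.samples.copy()
    s[i0:i1 + 1] = np.interp(np.arange(i0, i1 + 1), [i0 - 1, i1 + 1],
                             [s[max(i0 - 1, 0)], s[min(i1 + 1, len(s) - 1)]])
    return CurrentTrace(s, trace.rate_khz, trace.stim_ms)


def _model_curve(t, amp, t0, tau_rise, tau_fast, tau_slow, frac_fast):
    out = np.zeros_like(t)
    m = t > t0
    tt = t[m] - t0
    out[m] = (amp * (1.0 - np.exp(-tt / tau_rise))
              * (frac_fast * np.exp(-tt / tau_fast)
                 + (1 - frac_fast) * np.exp(-tt / tau_slow)))
    return out


def fit_multiexponential(trace: CurrentTrace,
                         window_ms: tuple[float, float] | None = None,
                         n_starts: int = 4) -> ExpFitResult:
    """Least-squares fit of the rising × biexponential-decay product.

    Multi-start over decay initializations; polarity is detected from the
    peak and the fit runs on the rectified waveform.  Raises
    :class:`FitError` when no start converges.
    """
    if window_ms is None:
        window_ms = (trace.stim_ms, trace.duration_ms)
    i0 = trace.index_of(window_ms[0])
    i1 = trace.index_of(window_ms[1])
    t = trace.time_ms[i0:i1] - trace.stim_ms
    y = trace.samples[i0:i1] - trace.baseline()
    if np.allclose(y, 0):
        raise FitError("flat trace; nothing to fit")
    sign = -1 if abs(y.min()) > abs(y.max()) else 1
    y = sign * y
    peak = y.max()

    model = lmfit.Model(_model_curve)
    best = None
    span = max(t[-1], 1.0)
    # cap tau_rise well below the record: an unbounded rise constant is
    # degenerate with the amplitude (A·(1-exp(-t/tau)) -> ramp)
    t_peak = t[int(np.argmax(y))] - t[0]
    rise_cap = max(4.0 * max(t_peak, 0.5), 2.0)
    for tau_slow0 in np.geomspace(5.0, span / 2.0, n_starts):
        for tau_rise0 in (0.3, 1.0):
            params = model.make_params(
                amp=dict(value=peak * 1.5, min=0, max=peak * 20),
                t0=dict(value=0.2, min=-1.0, max=span / 2),
                tau_rise=dict(value=tau_rise0, min=1e-3, max=rise_cap),
                tau_fast=dict(value=tau_slow0 / 4, min=1e-3, max=span * 2),
                tau_slow=dict(value=tau_slow0, min=1e-3, max=span * 4),
                frac_fast=dict(value=0.6, min=0.0, max=1.0),
            )
            try:
                res = model.fit(y, params, t=t)
            except Exception:
                continue
            if best is None or res.chisqr < best.chisqr:
                best = res
    if best is None:
        raise FitError("multi-exponential fit failed for every start")

    p = {k: float(v) for k, v in best.best_values.items()}
    if p["tau_fast"] > p["tau_slow"]:
        p["tau_fast"], p["tau_slow"] = p["tau_slow"], p["tau_fast"]
        p["frac_fast"] = 1.0 - p["frac_fast"]
    ss_tot = float(((y - y.mean()) ** 2).sum())
    rsq = 1.0 - best.chisqr / ss_tot if ss_tot > 0 else 1.0

    fitted = CurrentTrace(sign * best.best_fit, trace.rate_khz, stim_ms=0.0)
    r2080 = rise_20_80(fitted)
    cen = centroid(fitted, window_ms=(0.0, min(100.0, fitted.duration_ms)))
    return ExpFitResult(
        amplitude_pa=p["amp"], peak_pa=float(np.abs(best.best_fit).max()),
        t0_ms=p["t0"], tau_rise_ms=p["tau_rise"],
        tau_fast_ms=p["tau_fast"], tau_slow_ms=p["tau_slow"],
        frac_fast=p["frac_fast"], rise_20_80_ms=r2080, centroid_ms=cen,
        rsquared=rsq, sign=sign,
    )


def rise_20_80(trace: CurrentTrace, baseline_ms: float = 50.0) -> float:
    """Time between the 20% and 80% crossings on the rising phase, ms.

    Crossings are linearly interpolated between samples; on a
    non-monotonic rise the first crossings are used (with a warning).
    """
    base = trace.baseline(baseline_ms)
    y = trace.samples - base
    i_stim = trace.index_of(trace.stim_ms)
    seg = y[i_stim:]
    if np.allclose(seg, 0):
        raise TraceError("flat trace; no peak")
    sign = -1 if abs(seg.min()) > abs(seg.max()) else 1
    seg = sign * seg
    i_peak = int(np.argmax(seg))
    peak = seg[i_peak]
    rising = seg[: i_peak + 1]
    times = {}
    for level in (0.2, 0.8):
        thr = level * peak
        above = np.nonzero(rising >= thr)[0]
        if len(above) == 0:
            raise TraceError("rise crossings not found")
        j = above[0]
        if j == 0:
            times[level] = 0.0
        else:
            frac = (thr - rising[j - 1]) / (rising[j] - rising[j - 1])
            times[level] = (j - 1 + frac) * trace.dt_ms
    if np.any(np.diff(rising) < 0):
        warnings.warn("non-monotonic rise; using first crossings")
    return times[0.8] - times[0.2]


def centroid(trace: CurrentTrace, window_ms: tuple[float, float] = (0.0, 100.0),
             baseline_ms: float = 50.0) -> float:
    """First temporal moment ⟨t⟩ = Σ t·|I(t)| / Σ |I(t)|, measured from
    the stimulus over the analysis window (default 0–100 ms post-stimulus)."""
    base = trace.baseline(baseline_ms)
    i0 = trace.index_of(trace.stim_ms + window_ms[0])
    i1 = min(len(trace.samples), trace.index_of(trace.stim_ms + window_ms[1]))
    y = np.abs(trace.samples[i0:i1] - base)
    denom = y.sum()
    if denom <= 0:
        raise TraceError("zero integral in centroid window")
    t = (np.arange(i0, i1) * trace.dt_ms) - trace.stim_ms - window_ms[0]
    return float(np.dot(t, y) / denom)


def wiener_deconvolve(x: np.ndarray, h: np.ndarray,
                      reg: float | None = None,
                      noise_sd: float | None = None) -> tuple[np.ndarray, float]:
    """Frequency-domain deconvolution: find e with x ≈ discrete conv(e, h).

    Callers encoding the continuous convolution x = ∫e(τ)·k(t−τ)dτ pass
    ``h = k·dt`` so the estimate comes back on the physical scale.
    Wiener-style regularization: Ĝ = H*/(|H|² + λ·max|H|²).  λ defaults to
    the measured noise-to-signal power ratio when ``noise_sd`` is given,
    else 1e-4.  Returns (estimate, λ).
    """
    x = np.asarray(x, dtype=float)
    h = np.asarray(h, dtype=float)
    if not np.any(h):
        raise TraceError("all-zero filter")
    n = len(x) + len(h)
    H = np.fft.rfft(h, n)
    X = np.fft.rfft(x, n)
    h2 = np.abs(H) ** 2
    if reg is None:
        if noise_sd is not None and noise_sd > 0:
            sig_power = float(np.mean(x ** 2))
            reg = max((noise_sd ** 2) / max(sig_power, 1e-30), 1e-8)
        else:
            reg = 1e-4
    G = np.conj(H) / (h2 + reg * h2.max())
    est = np.fft.irfft(X * G, n)[: len(x)]
    return est, reg


def _biexp_decay(t, amp, tau_fast, tau_slow, frac_fast):
    return amp * (frac_fast * np.exp(-t / tau_fast)
                  + (1 - frac_fast) * np.exp(-t / tau_slow))


def fit_biexponential_decay(trace: CurrentTrace,
                            window_ms: tuple[float, float] | None = None
                            ) -> tuple[float, float, float, int]:
    """Fit a biexponential to the decay phase (from the peak onward).

    Returns (tau_fast, tau_slow, frac_fast, sign).  Used where only the
    decay time course matters (filter derivation), avoiding the rise/decay
    trade-off of the full product model.
    """
    i0 = trace.index_of(trace.stim_ms)
    i1 = (trace.index_of(window_ms[1]) if window_ms
          else len(trace.samples))
    y = trace.samples[i0:i1] - trace.baseline()
    if np.allclose(y, 0):
        raise FitError("flat trace; nothing to fit")
    sign = -1 if abs(y.min()) > abs(y.max()) else 1
    y = sign * y
    ip = int(np.argmax(y))
    yd = y[ip:]
    t = np.arange(len(yd)) * trace.dt_ms
    span = max(t[-1], 1.0)
    model = lmfit.Model(_biexp_decay)
    best = None
    for tau_slow0 in np.geomspace(8.0, span / 2.0, 4):
        params = model.make_params(
            amp=dict(value=float(yd[0]), min=0),
            tau_fast=dict(value=tau_slow0 / 5, min=1e-3, max=span * 2),
            tau_slow=dict(value=tau_slow0, min=1e-3, max=span * 4),
            frac_fast=dict(value=0.5, min=0.0, max=1.0),
        )
        try:
            res = model.fit(yd, params, t=t)
        except Exception:
            continue
        if best is None or res.chisqr < best.chisqr:
            best = res
    if best is None:
        raise FitError("biexponential decay fit failed")
    p = best.best_values
    tf, ts, f = float(p["tau_fast"]), float(p["tau_slow"]), float(p["frac_fast"])
    if tf > ts:
        tf, ts, f = ts, tf, 1.0 - f
    return tf, ts, f, sign


def derive_filter(fstc_tboa: CurrentTrace,
                  analysis_ms: float = 200.0,
                  support_ms: float = 30.0,
                  reg: float | None = None) -> np.ndarray:
    """Derive the linear distortion filter from a sub-saturating-TBOA fSTC.

    With most transporters blocked, clearance is slow and the fSTC decay
    tracks it, so the TBOA clearance is approximated by an instantaneous
    rise followed by the fSTC's own fitted biexponential decay (fitted on
    the decay phase).  The filter is the deconvolution of the fSTC by that
    clearance, rectified, restricted to its physical support
    (``support_ms``: the distortion kernel is fast, and truncation removes
    the rectified noise tail that would otherwise bias the clearance
    estimate), and normalized to unit area (Σh·dt = 1).
    """
    tau_fast, tau_slow, frac_fast, sign = fit_biexponential_decay(fstc_tboa)
    i0 = fstc_tboa.index_of(fstc_tboa.stim_ms)
    i1 = min(len(fstc_tboa.samples),
             fstc_tboa.index_of(fstc_tboa.stim_ms + analysis_ms))
    y = sign * (fstc_tboa.samples[i0:i1] - fstc_tboa.baseline())
    dt = fstc_tboa.dt_ms
    t = np.arange(i1 - i0) * dt
    clearance = (frac_fast * np.exp(-t / tau_fast)
                 + (1 - frac_fast) * np.exp(-t / tau_slow))
    noise_sd = float(np.std(fstc_tboa.samples[:i0])) if i0 > 10 else None
    filt, _ = wiener_deconvolve(y, clearance * dt, reg=reg, noise_sd=noise_sd)
    filt = np.clip(filt, 0.0, None)
    if support_ms is not None:
        filt[int(round(support_ms / dt)):] = 0.0
    area = filt.sum() * dt
    if area <= 0:
        raise FitError("derived filter has zero area")
    return filt / area


def estimate_clearance(fstc_ctrl: CurrentTrace, filt: np.ndarray,
                       analysis_ms: float = 200.0,
                       centroid_window_ms: float = 100.0,
                       reg: float | None = None) -> ClearanceEstimate:
    """Deconvolve the filter from a control fSTC to get glutamate clearance.

    The filter must be area-normalized on the trace's sampling grid.  The
    returned waveform is rectified at zero and peak-normalized; the
    centroid is computed on the raw (unrectified) estimate over
    ``centroid_window_ms`` after the stimulus, so zero-mean deconvolution
    noise cancels instead of being rectified into spurious tail mass.
    Convolving the raw estimate back with the filter reproduces the input
    (relative RMS reported in the result).
    """
    dt = fstc_ctrl.dt_ms
    filt = np.asarray(filt, dtype=float)
    if not np.any(filt):
        raise TraceError("all-zero filter")
    i0 = fstc_ctrl.index_of(fstc_ctrl.stim_ms)
    i1 = min(len(fstc_ctrl.samples),
             fstc_ctrl.index_of(fstc_ctrl.stim_ms + analysis_ms))
    y = fstc_ctrl.samples[i0:i1] - fstc_ctrl.baseline()
    sign = -1 if abs(y.min()) > abs(y.max()) else 1
    y = sign * y
    noise_sd = float(np.std(fstc_ctrl.samples[:i0])) if i0 > 10 else None
    est, lam = wiener_deconvolve(y, filt * dt, reg=reg, noise_sd=noise_sd)

    recon = np.convolve(est, filt)[: len(y)] * dt
    denom = float(np.sqrt(np.mean(y ** 2)))
    rms = float(np.sqrt(np.mean((recon - y) ** 2)) / denom) if denom > 0 else np.inf

    t = np.arange(len(est)) * dt
    iw = min(len(est), int(round(centroid_window_ms / dt)))
    w = est[:iw]
    if w.sum() <= 0:
        raise FitError("clearance estimate vanished; centroid undefined")
    cen = float(np.dot(t[:iw], w) / w.sum())
    rectified = np.clip(est, 0.0, None)
    peak = rectified.max()
    if peak <= 0:
        raise FitError("clearance estimate vanished after rectification")
    return ClearanceEstimate(time_ms=t, clearance=rectified / peak,
                             centroid_ms=cen,
                             filter_waveform=filt, regularization=lam,
                             reconstruction_rms=rms)


def measure_sustained_current(trace: CurrentTrace,
                              offset_ms: float = 200.0,
                              width_ms: float = 50.0) -> float:
    """Mean baseline-subtracted current in [stim+offset, stim+offset+width].

    This is the sustained K⁺-current window (50 ms starting 200 ms after
    the stimulus).  Raises if the record is too short.
    """
    end = trace.stim_ms + offset_ms + width_ms
    if trace.duration_ms + 1e-9 < end:
        raise TraceError(
            f"record ends at {trace.duration_ms:.1f} ms; needs {end:.1f} ms"
        )
    i0 = trace.index_of(trace.stim_ms + offset_ms)
    i1 = trace.index_of(end)
    return float(trace.samples[i0:i1].mean() - trace.baseline())


# ---------------------------------------------------------------------------
# Model / Results front end
# ---------------------------------------------------------------------------


class TransporterCurrentModel:
    """fSTC analysis pipeline packaged as a fittable model.

    Built from the recorded traces (single, paired, and optionally the
    same pair in sub-saturating TBOA); :meth:`fit` isolates the fSTCs,
    fits their kinetics, derives the filter from the TBOA condition and
    deconvolves the control clearance.
    """

    def __init__(self, single: CurrentTrace, paired: CurrentTrace,
                 tboa_single: CurrentTrace | None = None,
                 tboa_paired: CurrentTrace | None = None,
                 ipi_ms: float = 100.0):
        self.single = single
        self.paired = paired
        self.tboa_single = tboa_single
        self.tboa_paired = tboa_paired
        self.ipi_ms = ipi_ms

    @classmethod
    def from_csv(cls, single_path, paired_path, tboa_single_path=None,
                 tboa_paired_path=None, stim_ms: float = 50.0,
                 ipi_ms: float = 100.0) -> "TransporterCurrentModel":
        load = lambda p: CurrentTrace.from_csv(p, stim_ms=stim_ms) if p else None
        return cls(load(single_path), load(paired_path),
                   load(tboa_single_path), load(tboa_paired_path), ipi_ms)

    def fit(self, reg: float | None = None) -> "TransporterCurrentResults":
        fstc = isolate_fstc(self.single, self.paired, self.ipi_ms)
        kin = fit_multiexponential(fstc)
        cen = centroid(fstc)
        clearance = None
        filt = None
        if self.tboa_single is not None and self.tboa_paired is not None:
            fstc_tboa = isolate_fstc(self.tboa_single, self.tboa_paired,
                                     self.ipi_ms)
            filt = derive_filter(fstc_tboa, reg=reg)
            clearance = estimate_clearance(fstc, filt, reg=reg)
        return TransporterCurrentResults(
            fstc=fstc, kinetics=kin, fstc_centroid_ms=cen,
            filter_waveform=filt, clearance=clearance,
        )


@dataclass
class TransporterCurrentResults:
    """Estimates from one cell's transporter-current recordings."""

    fstc: CurrentTrace
    kinetics: ExpFitResult
    fstc_centroid_ms: float
    filter_waveform: np.ndarray | None = None
    clearance: ClearanceEstimate | None = None

    def summary(self) -> pd.DataFrame:
        rows = {
            "fSTC peak (pA)": self.kinetics.peak_pa * self.kinetics.sign,
            "fSTC 20-80% rise (ms)": self.kinetics.rise_20_80_ms,
            "fSTC tau_fast (ms)": self.kinetics.tau_fast_ms,
            "fSTC tau_slow (ms)": self.kinetics.tau_slow_ms,
            "fSTC fast fraction": self.kinetics.frac_fast,
            "fSTC centroid <t> (ms)": self.fstc_centroid_ms,
            "fit R^2": self.kinetics.rsquared,
        }
        if self.clearance is not None:
            rows["clearance centroid <t> (ms)"] = self.clearance.centroid_ms
            rows["deconvolution reconstruction RMS"] = (
                self.clearance.reconstruction_rms)
        return pd.DataFrame({"value": rows})

    def __repr__(self) -> str:
        return "TransporterCurrentResults\n" + self.summary().to_string()
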