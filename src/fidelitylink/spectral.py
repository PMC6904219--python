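"""Time-frequency power and aperiodic/oscillatory spectral decomposition.

Morlet wavelet power (complex Gaussian-windowed sinusoid, sigma_t =
n_cycles / (2 pi f), unit-energy normalisation) with a z-score baseline
over time and trials; irregular-resampling auto-spectral analysis (IRASA)
splitting a power spectrum into a fractal 1/f component and an oscillatory
residual, with the aperiodic slope/intercept obtained by least squares on
the log-log fractal spectrum; and a Monte-Carlo study of how epoch length
governs the reliability of the slope estimate.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
import pandas as pd
from scipy import signal as sps

from ._utils import DomainError, check_seed

__all__ = [
    "TFRPower",
    "IRASAResult",
    "morlet_wavelet",
    "morlet_tfr",
    "baseline_ztransform",
    "band_window_average",
    "irasa_decompose",
    "epoch_length_reliability",
]

DEFAULT_H_SET = np.round(np.arange(1.1, 1.95, 0.05), 2)


@dataclass
class TFRPower:
    """Electrodes x frequencies x times x trials power.

    ``baseline_state`` is 'raw' (power >= 0) or 'ztransformed' (per
    electrode x frequency, mean 0 / SD 1 over times and trials jointly).
    ``valid`` flags, per frequency x time, samples whose wavelet support
    lies entirely inside the epoch.
    """

    power: np.ndarray
    freqs_hz: np.ndarray
    times_s: np.ndarray
    baseline_state: str = "raw"
    valid: np.ndarray | None = None


def morlet_wavelet(freq_hz: float, fs: float, n_cycles: float = 6.0) -> np.ndarray:
    """Complex Morlet wavelet sampled at ``fs``, normalised to unit energy.

    sigma_t = n_cycles / (2 pi f); support is +-5 sigma_t.
    """
    sigma = n_cycles / (2.0 * np.pi * freq_hz)
    half = int(np.ceil(5.0 * sigma * fs))
    t = np.arange(-half, half + 1) / fs
    w = np.exp(2j * np.pi * freq_hz * t) * np.exp(-(t**2) / (2 * sigma**2))
    return w / np.sqrt(np.sum(np.abs(w) ** 2))


def morlet_tfr(
    epochs: np.ndarray,
    fs: float,
    freqs_hz=None,
    n_cycles: float = 6.0,
    t0_s: float = -1.0,
    times_s=None,
) -> TFRPower:
    """Morlet wavelet power of epoched data.

    Parameters
    ----------
    epochs : (n_electrodes, n_samples, n_trials) array
        Epoched time-series; a 2-D (n_trials, n_samples) array is treated
        as a single electrode.
    freqs_hz : frequencies of interest; default 8-30 Hz in 0.5 Hz steps.
    t0_s : time of the first sample relative to stimulus onset.
    times_s : output time grid; default -1 to 3 s in 25 ms steps clipped to
        the epoch extent.

    Power is the squared magnitude of the complex convolution.  Samples for
    which the wavelet extends beyond the epoch are flagged in ``valid``.
    """
    x = np.asarray(epochs, dtype=float)
    if x.ndim == 2:
        x = x.T[None, :, :]  # (1, n_samples, n_trials)
    n_el, n_samp, n_tr = x.shape
    if freqs_hz is None:
        freqs_hz = np.arange(8.0, 30.0 + 1e-9, 0.5)
    freqs_hz = np.asarray(freqs_hz, dtype=float)
    if np.any(freqs_hz >= fs / 2):
        raise DomainError("frequency at or above Nyquist")
    if n_cycles < 1:
        raise DomainError("n_cycles must be >= 1")
    sample_times = t0_s + np.arange(n_samp) / fs
    if times_s is None:
        times_s = np.arange(-1.0, 3.0 + 1e-9, 0.025)
        times_s = times_s[(times_s >= sample_times[0]) & (times_s <= sample_times[-1])]
    times_s = np.asarray(times_s, dtype=float)
    idx = np.round((times_s - t0_s) * fs).astype(int)
    if idx.min() < 0 or idx.max() >= n_samp:
        raise DomainError("requested times outside the epoch")

    power = np.empty((n_el, len(freqs_hz), len(times_s), n_tr))
    valid = np.empty((len(freqs_hz), len(times_s)), dtype=bool)
    for fi, f in enumerate(freqs_hz):
        w = morlet_wavelet(f, fs, n_cycles)
        half = (len(w) - 1) // 2
        if len(w) > 2 * n_samp:
            raise DomainError(
                f"epoch too short for the {f} Hz wavelet ({len(w)} samples needed)"
            )
        conv = sps.fftconvolve(x, w[None, :, None].conj(), mode="same", axes=1)
        power[:, fi, :, :] = np.abs(conv[:, idx, :]) ** 2
        valid[fi] = (idx - half >= 0) & (idx + half < n_samp)
    return TFRPower(power=power, freqs_hz=freqs_hz, times_s=times_s, valid=valid)


def baseline_ztransform(tfr: TFRPower) -> TFRPower:
    """z-score power per electrode x frequency over all times and trials.

    Raises on already-transformed input and on any electrode/frequency with
    zero power variance (e.g. a constant signal).
    """
    if tfr.baseline_state != "raw":
        raise DomainError("TFR is already baseline-transformed")
    p = tfr.power
    if p.shape[2] * p.shape[3] < 2:
        raise DomainError("need >= 2 time x trial samples")
    mean = p.mean(axis=(2, 3), keepdims=True)
    sd = p.std(axis=(2, 3), keepdims=True)
    zero = np.squeeze(sd, axis=(2, 3)) == 0
    if np.any(zero):
        el, fr = np.argwhere(zero)[0]
        raise DomainError(
            f"zero power SD at electrode {el}, frequency {tfr.freqs_hz[fr]} Hz"
        )
    return TFRPower(
        power=(p - mean) / sd,
        freqs_hz=tfr.freqs_hz,
        times_s=tfr.times_s,
        baseline_state="ztransformed",
        valid=tfr.valid,
    )


def band_window_average(
    tfr: TFRPower,
    window_s: tuple,
    band_hz: tuple = (8.0, 30.0),
    electrodes=None,
) -> np.ndarray:
    """Mean power over electrodes x band x window, one value per trial.

    The canonical windows are 500-1500 ms post-stimulus and -1000 to
    -375 ms pre-stimulus, both over 8-30 Hz; theta (3-7 Hz) and gamma
    (40-50 Hz) variants are parameterisations of ``band_hz``.
    """
    fsel = (tfr.freqs_hz >= band_hz[0]) & (tfr.freqs_hz <= band_hz[1])
    tsel = (tfr.times_s >= window_s[0]) & (tfr.times_s <= window_s[1])
    if not fsel.any() or not tsel.any():
        raise DomainError("band or window outside the TFR grid")
    p = tfr.power
    if electrodes is not None:
        p = p[np.asarray(electrodes)]
        if p.shape[0] == 0:
            raise DomainError("empty electrode selection")
    return p[:, fsel][:, :, tsel].mean(axis=(0, 1, 2))


@dataclass
class IRASAResult:
    """Fractal/oscillatory split of a power spectrum.

    ``slope``/``intercept`` solve log10(fractal) = slope * log10(f) +
    intercept by least squares over ``fit_band_hz``; ``osc_band_power`` is
    the mean oscillatory power over ``osc_band_hz`` (8-25 Hz by default).
    """

    freqs_hz: np.ndarray
    psd: np.ndarray
    fractal_psd: np.ndarray
    oscillatory_psd: np.ndarray
    slope: float
    intercept: float
    osc_band_power: float
    h_set: np.ndarray


def _psd(x: np.ndarray, fs: float, nperseg: int):
    return sps.welch(x, fs=fs, nperseg=min(nperseg, x.shape[-1]), axis=-1)


def irasa_decompose(
    data: np.ndarray,
    fs: float,
    h_set=None,
    seg_s: float = 1.0,
    fit_band_hz: tuple = (1.0, 25.0),
    osc_band_hz: tuple = (8.0, 25.0),
) -> IRASAResult:
    """Irregular-resampling separation of fractal and oscillatory spectra.

    The signal is resampled by each factor h and its reciprocal 1/h; a
    power-law spectrum is invariant to the geometric mean of such a pair,
    while narrow-band oscillatory peaks are displaced and suppressed by the
    median across the factor set.  The fractal component is that median;
    the oscillatory component is the residual PSD; fractal + oscillatory
    equals the original PSD on the evaluated grid by construction.

    ``data`` may be a single time-series or (n_epochs, n_samples) epochs,
    whose periodograms are averaged before decomposition (the robust,
    trial-averaged estimate of the 1/f curve).

    The top of ``fit_band_hz`` must stay at or below fs / (2 * h_max), the
    highest frequency the resampling pair can represent (fs/4 for the
    default h_max close to 2).
    """
    x = np.atleast_2d(np.asarray(data, dtype=float))
    if h_set is None:
        h_set = DEFAULT_H_SET
    h_set = np.asarray(h_set, dtype=float)
    if np.any(h_set <= 1):
        raise DomainError("resampling factors must be > 1")
    h_max = h_set.max()
    if fit_band_hz[1] > fs / (2 * h_max) + 1e-9:
        raise DomainError(
            f"fit band top {fit_band_hz[1]} Hz exceeds fs/(2*h_max) = {fs / (2 * h_max):.3g} Hz"
        )
    # the slowest resampled copy (factor 1/h_max) must still hold one PSD
    # segment, so the segment length is capped accordingly; every PSD then
    # shares one frequency grid
    nperseg = min(int(round(seg_s * fs)), int(np.floor(x.shape[-1] / h_max)))
    if nperseg < 16:
        raise DomainError(
            f"epoch too short for PSD estimation: need >= {int(np.ceil(16 * h_max))} "
            f"samples ({16 * h_max / fs:.3g} s at {fs} Hz)"
        )
    freqs, psd = _psd(x, fs, nperseg)
    psd = psd.mean(axis=0)

    geo = np.empty((len(h_set), len(freqs)))
    for i, h in enumerate(h_set):
        frac = Fraction(h).limit_denominator(20)
        up, down = frac.numerator, frac.denominator
        x_up = sps.resample_poly(x, up, down, axis=-1)
        x_dn = sps.resample_poly(x, down, up, axis=-1)
        _, p_up = _psd(x_up, fs, nperseg)
        _, p_dn = _psd(x_dn, fs, nperseg)
        geo[i] = np.sqrt(p_up.mean(axis=0) * p_dn.mean(axis=0))
    fractal = np.median(geo, axis=0)
    oscillatory = psd - fractal

    fit = (freqs >= fit_band_hz[0]) & (freqs <= fit_band_hz[1]) & (fractal > 0)
    if fit.sum() < 2:
        raise DomainError("fewer than 2 frequencies in the fit band")
    slope, intercept = np.polyfit(np.log10(freqs[fit]), np.log10(fractal[fit]), 1)
    osc = (freqs >= osc_band_hz[0]) & (freqs <= osc_band_hz[1])
    return IRASAResult(
        freqs_hz=freqs,
        psd=psd,
        fractal_psd=fractal,
        oscillatory_psd=oscillatory,
        slope=float(slope),
        intercept=float(intercept),
        osc_band_power=float(oscillatory[osc].mean()) if osc.any() else np.nan,
        h_set=h_set,
    )


def epoch_length_reliability(
    slope: float,
    lengths_s,
    n_reps: int,
    fs: float = 200.0,
    seed=None,
    **irasa_kwargs,
) -> pd.DataFrame:
    """Reliability of the 1/f slope estimate as a function of epoch length.

    For each epoch length, ``n_reps`` independent pure-1/f epochs with
    exponent ``slope`` are simulated and decomposed; the table reports the
    mean and SD of the fitted slope per length.  Short epochs give
    unreliable (high-SD) estimates; the SD shrinks as epochs lengthen.
    """
    from .synthdata import colored_noise

    lengths_s = list(lengths_s)
    if sorted(lengths_s) != lengths_s:
        raise DomainError("lengths must be sorted ascending")
    if n_reps < 2:
        raise DomainError("need n_reps >= 2")
    rng = check_seed(seed)
    rows = []
    for L in lengths_s:
        n = int(round(L * fs))
        est = np.empty(n_reps)
        for r in range(n_reps):
            x = colored_noise(n, fs, slope, rng)
            seg = min(1.0, L)
            est[r] = irasa_decompose(x, fs, seg_s=seg, **irasa_kwargs).slope
        rows.append(dict(length_s=L, mean_slope=est.mean(), sd_slope=est.std(ddof=1)))
    return pd.DataFrame(rows)
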