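"""Synthetic study generator with known ground truth.

Emulates the statistical structure of a paired-associates EEG-fMRI study:
four repeated dynamic stimuli per modality presented 12 times in each of
four 48-trial blocks, a latent per-trial pattern fidelity bounded in [0, 1],
spatially correlated voxel noise, a negative fidelity -> alpha/beta power
coupling with confidence / BOLD-amplitude / pre-stimulus-power nuisances,
and epoched electrophysiology with controlled 1/f (aperiodic) and
oscillatory content.  Every downstream stage of the pipeline can therefore
be checked against the generating parameters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._utils import BalancedDesignError, DomainError, check_seed

__all__ = [
    "GroundTruth",
    "make_trial_table",
    "make_stimulus_prototypes",
    "make_ground_truth",
    "simulate_bold_session",
    "simulate_trial_power",
    "colored_noise",
    "cov_factor",
    "simulate_eeg_epochs",
]


@dataclass
class GroundTruth:
    """Parameters of the synthetic world the pipeline must recover.

    Attributes
    ----------
    prototypes : (n_stimuli, n_voxels) array
        Noise-free stimulus pattern templates (mu_s).
    fidelity : (n_trials,) array in [0, 1]
        Latent per-trial pattern fidelity f_t.
    coupling : float
        Slope beta of the negative fidelity -> post-stimulus power coupling.
    noise_cov : (n_voxels, n_voxels) array
        Symmetric positive-definite spatial covariance of the voxel noise.
    aperiodic_slope : float
        True 1/f exponent chi of the electrophysiological background.
    osc_amplitude : float
        Amplitude of the injected oscillation.
    """

    prototypes: np.ndarray
    fidelity: np.ndarray
    coupling: float
    noise_cov: np.ndarray
    aperiodic_slope: float = 1.0
    osc_amplitude: float = 1.0

    def __post_init__(self):
        cov = np.asarray(self.noise_cov, dtype=float)
        if not np.allclose(cov, cov.T):
            raise DomainError("noise_cov must be symmetric")
        if np.linalg.eigvalsh(cov).min() < -1e-10:
            raise DomainError("noise_cov must be positive-semidefinite")
        f = np.asarray(self.fidelity, dtype=float)
        if f.min() < 0 or f.max() > 1:
            raise DomainError("fidelity must lie in [0, 1]")


def cov_factor(cov: np.ndarray) -> np.ndarray:
    """Matrix square root L with L @ L.T = cov, valid for semidefinite cov."""
    vals, vecs = np.linalg.eigh(np.asarray(cov, dtype=float))
    return vecs * np.sqrt(np.clip(vals, 0.0, None))


def make_trial_table(
    n_blocks: int = 4,
    trials_per_block: int = 48,
    n_stimuli: int = 4,
    memory_rate: float = 0.634,
    seed=None,
    iti_s: float = 8.0,
    duration_s: float = 3.0,
) -> pd.DataFrame:
    """Generate a balanced trial table for an associative-memory paradigm.

    Each block contains ``trials_per_block`` encoding trials with every
    stimulus presented exactly ``trials_per_block / n_stimuli`` times,
    followed by the matching retrieval trials in shuffled order.  A pair is
    "remembered" when the cued stimulus was later selected correctly AND the
    confidence rating exceeded 1 (i.e. the decision was not a guess); the
    ``remembered`` column always equals ``correct & (confidence > 1)``.

    Blocks alternate between visual and auditory modality.

    Returns a DataFrame with columns trial_id, stimulus (1..n_stimuli),
    phase ('encoding'/'retrieval'), block, modality, confidence (1..4),
    correct, remembered, onset_s, duration_s.
    """
    if not 0.0 <= memory_rate <= 1.0:
        raise DomainError("memory_rate must be in [0, 1]")
    if trials_per_block % n_stimuli:
        raise BalancedDesignError(
            f"trials_per_block={trials_per_block} not divisible by n_stimuli={n_stimuli}"
        )
    rng = check_seed(seed)
    reps = trials_per_block // n_stimuli
    rows = []
    trial_id = 0
    for block in range(1, n_blocks + 1):
        modality = "visual" if block % 2 == 1 else "auditory"
        enc_stims = rng.permutation(np.repeat(np.arange(1, n_stimuli + 1), reps))
        remembered = rng.random(trials_per_block) < memory_rate
        confidence = np.empty(trials_per_block, dtype=int)
        correct = np.empty(trials_per_block, dtype=bool)
        for i, rem in enumerate(remembered):
            if rem:
                correct[i] = True
                confidence[i] = rng.integers(2, 5)
            elif rng.random() < 0.25:
                # a confident-guess style miss: correct choice rated as a guess
                correct[i] = True
                confidence[i] = 1
            else:
                correct[i] = False
                confidence[i] = rng.integers(1, 5)
        for phase in ("encoding", "retrieval"):
            order = np.arange(trials_per_block) if phase == "encoding" else rng.permutation(trials_per_block)
            for pos, idx in enumerate(order):
                rows.append(
                    dict(
                        trial_id=trial_id,
                        stimulus=int(enc_stims[idx]),
                        phase=phase,
                        block=block,
                        modality=modality,
                        confidence=int(confidence[idx]),
                        correct=bool(correct[idx]),
                        remembered=bool(remembered[idx]),
                        onset_s=pos * iti_s,
                        duration_s=duration_s,
                    )
                )
                trial_id += 1
    return pd.DataFrame(rows)


def make_stimulus_prototypes(
    n_voxels: int, n_stimuli: int, separation: float, seed=None
) -> np.ndarray:
    """Equal-norm stimulus prototypes with all pairwise distances equal.

    Built from a random orthonormal frame scaled so that every pair of
    prototypes is exactly ``separation`` apart in Euclidean distance.
    """
    if separation < 0:
        raise DomainError("separation must be >= 0")
    if n_voxels < n_stimuli:
        raise DomainError("need n_voxels >= n_stimuli")
    rng = check_seed(seed)
    basis, _ = np.linalg.qr(rng.standard_normal((n_voxels, n_stimuli)))
    # orthonormal e_i are sqrt(2) apart; rescale to the requested separation
    return (separation / np.sqrt(2.0)) * basis.T


def _beta_params(mean: float, sd: float) -> tuple[float, float]:
    var = sd**2
    if var >= mean * (1 - mean):
        raise DomainError("fidelity sd too large for a Beta distribution with this mean")
    k = mean * (1 - mean) / var - 1.0
    return mean * k, (1 - mean) * k


def make_ground_truth(
    n_trials: int,
    n_voxels: int = 40,
    n_stimuli: int = 4,
    separation: float = 2.0,
    fidelity_mean: float = 0.5,
    fidelity_sd: float = 0.2,
    coupling: float = 1.0,
    noise_scale: float = 1.0,
    spatial_corr: float = 0.3,
    aperiodic_slope: float = 1.0,
    osc_amplitude: float = 1.0,
    seed=None,
) -> GroundTruth:
    """Assemble a :class:`GroundTruth` with Beta-distributed fidelity.

    ``fidelity_sd = 0`` gives constant fidelity equal to ``fidelity_mean``
    (the restricted-variance regime).  Voxel noise covariance has unit-lag
    correlation ``spatial_corr`` decaying geometrically with voxel index,
    a simple positive-definite stand-in for smooth spatial noise.
    """
    rng = check_seed(seed)
    protos = make_stimulus_prototypes(n_voxels, n_stimuli, separation, rng)
    if fidelity_sd == 0:
        fid = np.full(n_trials, float(fidelity_mean))
    else:
        a, b = _beta_params(fidelity_mean, fidelity_sd)
        fid = rng.beta(a, b, size=n_trials)
    idx = np.arange(n_voxels)
    cov = noise_scale**2 * spatial_corr ** np.abs(idx[:, None] - idx[None, :])
    return GroundTruth(
        prototypes=protos,
        fidelity=fid,
        coupling=coupling,
        noise_cov=cov,
        aperiodic_slope=aperiodic_slope,
        osc_amplitude=osc_amplitude,
    )


def simulate_bold_session(
    table: pd.DataFrame,
    truth: GroundTruth,
    tr_s: float = 2.0,
    n_volumes: int | None = None,
    hrf_params: dict | None = None,
    seed=None,
) -> tuple[np.ndarray, np.ndarray]:
    """Forward-model a voxel time-series for one run.

    Each trial contributes its noise-free pattern ``f_t * mu_{s(t)}``
    through a boxcar of the trial duration convolved with the canonical
    double-gamma haemodynamic response, plus temporally white, spatially
    correlated Gaussian noise drawn from ``truth.noise_cov``.

    Returns ``(timeseries, true_patterns)`` where ``timeseries`` is
    (n_volumes, n_voxels) and ``true_patterns`` is the (n_trials, n_voxels)
    noiseless pattern of every trial, in table row order.
    """
    from .glm import build_design_matrix  # local import: glm does not import synthdata

    rng = check_seed(seed)
    onsets = table["onset_s"].to_numpy(float)
    if len(np.unique(onsets)) < len(onsets):
        warnings.warn("overlapping identical onsets: per-trial design will be collinear")
    if n_volumes is None:
        n_volumes = int(np.ceil((onsets.max() + table["duration_s"].max() + 24.0) / tr_s))
    design = build_design_matrix(
        table, n_volumes=n_volumes, tr_s=tr_s, mode="per_trial",
        hrf=hrf_params, add_intercept=False,
    )
    fid = np.asarray(truth.fidelity, dtype=float)
    if fid.shape[0] != len(table):
        raise DomainError("truth.fidelity length must match the trial table")
    stim = table["stimulus"].to_numpy(int) - 1
    true_patterns = fid[:, None] * truth.prototypes[stim]
    signal = design.matrix @ true_patterns
    n_vox = truth.prototypes.shape[1]
    if np.any(truth.noise_cov):
        L = cov_factor(truth.noise_cov)
        noise = rng.standard_normal((n_volumes, n_vox)) @ L.T
    else:
        noise = np.zeros((n_volumes, n_vox))
    return signal + noise, true_patterns


def simulate_trial_power(
    fidelity: np.ndarray,
    coupling: float,
    noise_sd: float = 0.3,
    confidence_coef: float = 0.0,
    bold_coef: float = 0.0,
    baseline: float = 0.0,
    confidence_fidelity_corr: float = 0.3,
    seed=None,
) -> tuple[pd.DataFrame, dict]:
    """Per-trial post-stimulus power coupled negatively to fidelity.

    post_power_t = baseline - coupling * f_t + confidence_coef * conf_t
                   + bold_coef * bold_t + eps_t,     eps ~ N(0, noise_sd^2)

    Pre-stimulus power is independent noise by construction; BOLD amplitude
    is an independent standard normal; confidence is an ordinal 1-4 rating
    obtained by quartile-thresholding a latent Gaussian correlated with
    fidelity at ``confidence_fidelity_corr`` (so the confidence-nuisance
    pathway is exercised).

    Returns ``(frame, coefficients)`` with the generating coefficients.
    """
    if not np.isfinite(coupling):
        raise DomainError("coupling must be finite")
    if noise_sd < 0:
        raise DomainError("noise_sd must be >= 0")
    rng = check_seed(seed)
    fid = np.asarray(fidelity, dtype=float)
    n = fid.shape[0]
    sd = fid.std()
    fz = (fid - fid.mean()) / sd if sd > 0 else np.zeros(n)
    r = confidence_fidelity_corr
    latent = r * fz + np.sqrt(max(0.0, 1 - r**2)) * rng.standard_normal(n)
    confidence = 1 + np.searchsorted(
        [-0.6744897501960817, 0.0, 0.6744897501960817], latent, side="left"
    ).clip(0, 3) if n else np.empty(0, int)
    confidence = np.asarray(confidence, dtype=int)
    bold = rng.standard_normal(n)
    eps = noise_sd * rng.standard_normal(n) if noise_sd > 0 else np.zeros(n)
    post = baseline - coupling * fid + confidence_coef * confidence + bold_coef * bold + eps
    pre = baseline + (noise_sd if noise_sd > 0 else 1.0) * rng.standard_normal(n)
    frame = pd.DataFrame(
        dict(post_power=post, pre_power=pre, bold_amplitude=bold, confidence=confidence)
    )
    coeffs = dict(
        baseline=baseline, coupling=coupling, confidence_coef=confidence_coef,
        bold_coef=bold_coef, noise_sd=noise_sd,
    )
    return frame, coeffs


def colored_noise(
    n_samples: int, fs: float, exponent: float, rng, size: int | tuple = (),
) -> np.ndarray:
    """Gaussian noise with power spectral density proportional to f^(-exponent).

    Synthesised by scaling the FFT of white noise by f^(-exponent/2); the DC
    bin is set to zero, so every epoch is exactly mean-free in expectation of
    its spectral content.
    """
    if isinstance(size, int):
        size = (size,)
    shape = tuple(size) + (n_samples,)
    white = rng.standard_normal(shape)
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    scale = np.zeros_like(freqs)
    scale[1:] = freqs[1:] ** (-exponent / 2.0)
    out = np.fft.irfft(spec * scale, n=n_samples, axis=-1)
    return out


def simulate_eeg_epochs(
    n_trials: int,
    fs: float,
    duration_s: float,
    slope: float = 1.0,
    intercept: float = 1.0,
    osc_freq: float = 10.0,
    osc_amp: float = 1.0,
    seed=None,
) -> np.ndarray:
    """Epochs of 1/f background plus a random-phase sinusoid.

    Each epoch is coloured noise with PSD proportional to
    ``intercept * f^(-slope)`` plus ``osc_amp * sin(2 pi osc_freq t + phi)``
    with phi drawn uniformly per trial.  Returns (n_trials, n_samples).
    """
    if duration_s <= 0:
        raise DomainError("duration_s must be > 0")
    if osc_amp != 0 and not 0 < osc_freq < fs / 2:
        raise DomainError("osc_freq must lie strictly below the Nyquist frequency")
    rng = check_seed(seed)
    n_samples = int(round(duration_s * fs))
    epochs = np.sqrt(intercept) * colored_noise(n_samples, fs, slope, rng, size=n_trials)
    if osc_amp != 0:
        t = np.arange(n_samples) / fs
        phases = rng.uniform(0, 2 * np.pi, size=n_trials)
        epochs = epochs + osc_amp * np.sin(2 * np.pi * osc_freq * t + phases[:, None])
    return epochs
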