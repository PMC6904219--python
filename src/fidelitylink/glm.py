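"""Condition- and trial-level pattern estimation by HRF-convolved regression.

Events are modelled as boxcars spanning the stimulus duration, convolved
with the canonical double-gamma haemodynamic response on a fine temporal
grid and downsampled to the scan repetition time.  Ordinary least squares
then yields one activity pattern per condition (or per trial) together with
the residual time-series used downstream for noise-covariance estimation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special

from ._utils import CollinearityError, DomainError

__all__ = ["DesignMatrix", "canonical_hrf", "build_design_matrix", "estimate_betas"]

#: canonical double-gamma parameters: response peak 6 s, undershoot peak 16 s,
#: response/undershoot amplitude ratio 6 (the de-facto standard)
DEFAULT_HRF = dict(peak_s=6.0, undershoot_s=16.0, ratio=6.0)


@dataclass
class DesignMatrix:
    """A time x regressors design with labels and sampling interval."""

    matrix: np.ndarray
    labels: list
    dt_s: float

    def __post_init__(self):
        if np.any(np.all(self.matrix == 0, axis=0)):
            raise DomainError("design contains an all-zero column")


def canonical_hrf(t: np.ndarray, peak_s: float = 6.0, undershoot_s: float = 16.0,
                  ratio: float = 6.0) -> np.ndarray:
    """Double-gamma haemodynamic response sampled at times ``t`` (seconds).

    Gamma densities with unit scale: shape ``peak_s`` for the response and
    ``undershoot_s`` for the undershoot, the latter divided by ``ratio``.
    Normalised to unit peak.
    """
    t = np.asarray(t, dtype=float)
    h = np.zeros_like(t)
    pos = t > 0
    tp = t[pos]

    def gpdf(x, shape):
        return x ** (shape - 1) * np.exp(-x) / special.gamma(shape)

    h[pos] = gpdf(tp, peak_s) - gpdf(tp, undershoot_s) / ratio
    return h / h.max()


def build_design_matrix(
    table: pd.DataFrame,
    n_volumes: int,
    tr_s: float,
    mode: str = "per_condition",
    hrf: dict | None = None,
    oversample: int = 16,
    add_intercept: bool = True,
) -> DesignMatrix:
    """Boxcar-convolved design matrix from a trial table.

    Parameters
    ----------
    mode : {'per_condition', 'per_trial'}
        One column per stimulus, or one column per trial (least-squares-all
        single-trial estimation).
    oversample : int
        Convolution is carried out at dt = tr_s / oversample before
        downsampling to the volume grid.
    """
    if mode not in ("per_condition", "per_trial"):
        raise DomainError(f"unknown mode {mode!r}")
    hrf_params = dict(DEFAULT_HRF)
    if hrf:
        hrf_params.update(hrf)
    onsets = table["onset_s"].to_numpy(float)
    durations = table["duration_s"].to_numpy(float)
    scan_len = n_volumes * tr_s
    if np.any(onsets < 0) or np.any(onsets + durations > scan_len):
        raise DomainError("event onset/duration outside the scan")

    dt = tr_s / oversample
    n_fine = n_volumes * oversample
    hrf_t = np.arange(0, 32.0, dt)
    hrf_kernel = canonical_hrf(hrf_t, **hrf_params)

    if mode == "per_condition":
        labels = sorted(table["stimulus"].unique())
        groups = [np.flatnonzero(table["stimulus"].to_numpy() == lab) for lab in labels]
    else:
        labels = table["trial_id"].tolist()
        groups = [[i] for i in range(len(table))]

    cols = np.zeros((n_fine, len(groups)))
    for j, idx in enumerate(groups):
        stick = np.zeros(n_fine)
        for i in idx:
            a = int(round(onsets[i] / dt))
            b = min(n_fine, a + max(1, int(round(durations[i] / dt))))
            stick[a:b] = 1.0
        cols[:, j] = np.convolve(stick, hrf_kernel)[:n_fine]
    sampled = cols[::oversample, :]

    if add_intercept:
        sampled = np.column_stack([sampled, np.ones(n_volumes)])
        labels = list(labels) + ["intercept"]
    return DesignMatrix(matrix=sampled, labels=list(labels), dt_s=tr_s)


def estimate_betas(
    timeseries: np.ndarray, design: DesignMatrix
) -> tuple[np.ndarray, np.ndarray]:
    """Per-voxel ordinary least squares against the design.

    Returns ``(betas, residuals)``: betas is (n_regressors, n_voxels) in
    design column order (including the intercept if present), residuals is
    the (n_volumes, n_voxels) time-series left over after the fit, suitable
    for noise-covariance estimation.

    Raises
    ------
    CollinearityError
        If the design is rank deficient; the message names the columns that
        can be expressed through earlier ones.
    """
    X = design.matrix
    Y = np.asarray(timeseries, dtype=float)
    if Y.shape[0] != X.shape[0]:
        raise DomainError("timeseries and design row counts differ")
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        _, R = np.linalg.qr(X)
        diag = np.abs(np.diag(R))
        bad = [design.labels[i] for i in np.flatnonzero(diag < 1e-10 * diag.max())]
        raise CollinearityError(f"design is rank deficient; offending columns: {bad}")
    betas, *_ = np.linalg.lstsq(X, Y, rcond=None)
    residuals = Y - X @ betas
    return betas, residuals
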