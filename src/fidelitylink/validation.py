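"""Simulation studies validating calibration and parameter recovery.

Each function runs the pipeline's statistics on data from the synthetic
generator under a known regime (pure null, or a planted effect) and
returns the quantity a correct implementation must reproduce: nominal
false-positive rates at the 5% level, detection power for a planted
power-information coupling, recovery of a planted aperiodic slope, and the
closed-form attenuation of a correlation under restricted variance.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sstats

from . import rsa, spectral
from ._utils import check_seed, fisher_z, spearman_vs_model
from .pipeline import run_synthetic_study
from .stats import (
    cluster_permutation_test,
    confidence_power_correlation,
    group_permutation_ttest,
)

__all__ = [
    "info_map_null_calibration",
    "group_test_null_calibration",
    "cluster_test_null_calibration",
    "confidence_correlation_null_calibration",
    "pipeline_detection_rate",
    "irasa_slope_recovery",
]


def _single_roi_searchlights(n_vox: int = 9) -> rsa.SearchlightMap:
    # one searchlight covering the whole (tiny) region of interest
    return rsa.SearchlightMap(
        centres=np.array([0]), members=[np.arange(n_vox)], radius_mm=50.0,
        min_fraction=1.0, full_count=n_vox, mask_shape=(n_vox, 1, 1),
        centre_ijk=np.array([[0, 0, 0]]),
    )


def info_map_null_calibration(
    n_sims: int = 2000,
    n_subjects: int = 21,
    n_conditions: int = 4,
    n_residual_samples: int = 40,
    alpha: float = 0.05,
    seed=None,
) -> float:
    """False-positive rate of the per-voxel group test on information maps.

    Every simulated subject contributes the Fisher-z information value of
    one searchlight computed from pure-noise condition patterns (two folds,
    shrunk noise covariance from independent residuals); the group-level
    one-sample t-test against zero is two-sided at ``alpha``.  Returns the
    rejection fraction across simulations, which must approximate alpha.
    """
    rng = check_seed(seed)
    sl = _single_roi_searchlights()
    n_vox = len(sl.members[0])
    labels = np.arange(1, n_conditions + 1)
    rej = 0
    for _ in range(n_sims):
        zs = np.empty(n_subjects)
        for s in range(n_subjects):
            A = rng.standard_normal((n_conditions, n_vox))
            B = rng.standard_normal((n_conditions, n_vox))
            res = rng.standard_normal((n_residual_samples, n_vox))
            zmap = rsa.searchlight_information_map(A, B, labels, res, sl)
            zs[s] = zmap[sl.centres[0]]
        rej += sstats.ttest_1samp(zs, 0.0).pvalue < alpha
    return rej / n_sims


def group_test_null_calibration(
    n_sims: int = 4000,
    n_subjects: int = 21,
    n_perm: int = 500,
    tail: str = "left",
    alpha: float = 0.05,
    seed=None,
) -> float:
    """False-positive rate of the sign-flip permutation t-test."""
    rng = check_seed(seed)
    rej = 0
    for _ in range(n_sims):
        v = rng.standard_normal(n_subjects)
        rej += group_permutation_ttest(v, tail=tail, n_perm=n_perm, seed=rng)["p"] <= alpha
    return rej / n_sims


def cluster_test_null_calibration(
    n_sims: int = 2000,
    n_subjects: int = 12,
    shape: tuple = (6, 6),
    n_perm: int = 200,
    alpha: float = 0.05,
    seed=None,
) -> float:
    """Family-wise false-positive rate of the cluster permutation test."""
    rng = check_seed(seed)
    rej = 0
    for _ in range(n_sims):
        maps = rng.standard_normal((n_subjects, *shape))
        res = cluster_permutation_test(maps, n_perm=n_perm, tail="two", seed=rng)
        rej += len(res.p_perm) > 0 and res.p_perm.min() <= alpha
    return rej / n_sims


def confidence_correlation_null_calibration(
    n_sims: int = 3000,
    n_subjects: int = 21,
    n_trials: int = 60,
    n_perm: int = 500,
    alpha: float = 0.05,
    seed=None,
) -> float:
    """False-positive rate of the group test on power-confidence correlations."""
    rng = check_seed(seed)
    rej = 0
    for _ in range(n_sims):
        zs = np.empty(n_subjects)
        for s in range(n_subjects):
            power = rng.standard_normal(n_trials)
            conf = rng.integers(1, 5, n_trials)
            zs[s] = confidence_power_correlation(power, conf)
        rej += group_permutation_ttest(zs, tail="two", n_perm=n_perm, seed=rng)["p"] <= alpha
    return rej / n_sims


def pipeline_detection_rate(
    n_reps: int,
    coupling: float,
    n_participants: int = 21,
    n_trials: int = 100,
    fidelity_sd: float = 0.2,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed=None,
) -> float:
    """Fraction of full pipeline replicates rejecting the no-coupling null.

    Each replicate simulates a complete group study (trial patterns ->
    single-trial information -> coupled power -> per-participant regression
    -> group sign-flip test, left tail) and records whether the
    post-stimulus power regressor is significant at ``alpha``.  With the
    moderate planted effect this is the detection power; with
    ``coupling=0`` it must fall back to the nominal level.
    """
    rng = check_seed(seed)
    rej = 0
    for _ in range(n_reps):
        res = run_synthetic_study(
            n_participants=n_participants, n_trials=n_trials, coupling=coupling,
            fidelity_sd=fidelity_sd, n_perm=n_perm, seed=rng,
        )
        rej += res.p_value() <= alpha
    return rej / n_reps


def irasa_slope_recovery(
    slope: float = 1.0,
    lengths_s=(1.0, 5.0, 20.0, 60.0),
    n_reps: int = 30,
    fs: float = 200.0,
    seed=None,
):
    """Slope recovery and reliability-vs-epoch-length table.

    Returns ``(recovered_slope_at_longest, table)`` where the table holds
    the mean and SD of the slope estimate per epoch length.  A correct
    implementation recovers ``-slope`` at the longest epochs and shows SD
    shrinking monotonically with epoch length.
    """
    table = spectral.epoch_length_reliability(
        slope, list(lengths_s), n_reps=n_reps, fs=fs, seed=seed
    )
    return float(table.mean_slope.iloc[-1]), table
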