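"""End-to-end synthetic study: patterns -> trial information -> power -> link.

Convenience drivers that wire the generator through the full analysis
chain, used by the worked examples, the command-line interface and the
recovery/calibration studies.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import synthdata, trialinfo
from ._utils import check_seed
from .rsa import shrink_covariance
from .stats import PowerInformationLink, PowerInformationLinkResults

__all__ = ["simulate_participant", "run_synthetic_study"]


def simulate_participant(
    n_trials: int = 100,
    n_voxels: int = 30,
    n_stimuli: int = 4,
    separation: float = 3.0,
    fidelity_mean: float = 0.5,
    fidelity_sd: float = 0.2,
    coupling: float = 1.0,
    power_noise_sd: float = 0.3,
    noise_scale: float = 1.0,
    n_residual_samples: int = 80,
    seed=None,
    participant: object = 0,
) -> pd.DataFrame:
    """One participant's per-trial information and power table.

    Trials are split into two folds; each trial's ROI pattern is
    ``f_t * mu_s`` plus spatially correlated Gaussian noise.  The noise
    covariance is estimated (with diagonal shrinkage) from an independent
    residual sample with the same spatial structure, as it would be from
    GLM residuals.  Trial information comes from the cross-validated
    distance machinery; post-stimulus power is coupled negatively to the
    same latent fidelity.
    """
    rng = check_seed(seed)
    truth = synthdata.make_ground_truth(
        n_trials=n_trials,
        n_voxels=n_voxels,
        n_stimuli=n_stimuli,
        separation=separation,
        fidelity_mean=fidelity_mean,
        fidelity_sd=fidelity_sd,
        coupling=coupling,
        noise_scale=noise_scale,
        seed=rng,
    )
    # stimulus sequence balanced within each fold, as in the blocked paradigm
    half = n_trials // 2
    base = np.tile(np.arange(1, n_stimuli + 1), int(np.ceil(half / n_stimuli)))[:half]
    stim = np.concatenate(
        [rng.permutation(base), rng.permutation(np.resize(base, n_trials - half))]
    )
    chol = synthdata.cov_factor(truth.noise_cov)
    patterns = truth.fidelity[:, None] * truth.prototypes[stim - 1] + (
        rng.standard_normal((n_trials, n_voxels)) @ chol.T
    )
    residuals = rng.standard_normal((n_residual_samples, n_voxels)) @ chol.T
    cov = shrink_covariance(residuals)

    half = n_trials // 2
    info = trialinfo.perception_trial_information(
        patterns[:half], patterns[half:], stim[:half], stim[half:], cov,
        trial_ids_a=np.arange(half), trial_ids_b=np.arange(half, n_trials),
    ).sort_values("trial_id")

    power, _ = synthdata.simulate_trial_power(
        truth.fidelity, coupling=coupling, noise_sd=power_noise_sd, seed=rng
    )
    table = pd.DataFrame(
        dict(
            participant=participant,
            trial_id=np.arange(n_trials),
            fidelity=truth.fidelity,
            z_info=info.set_index("trial_id")["z_info"].reindex(np.arange(n_trials)).to_numpy(),
        )
    )
    return pd.concat([table.reset_index(drop=True), power.reset_index(drop=True)], axis=1)


def run_synthetic_study(
    n_participants: int = 21,
    n_trials: int = 100,
    coupling: float = 1.0,
    fidelity_sd: float = 0.2,
    n_perm: int = 2000,
    tail: str = "left",
    seed=None,
    **participant_kwargs,
) -> PowerInformationLinkResults:
    """Simulate a full group study and fit the power-information link.

    Returns the fitted :class:`PowerInformationLinkResults`; the underlying
    per-trial data are reachable through ``results.model.data``.
    """
    rng = check_seed(seed)
    tables = [
        simulate_participant(
            n_trials=n_trials, coupling=coupling, fidelity_sd=fidelity_sd,
            seed=rng, participant=pid, **participant_kwargs,
        )
        for pid in range(n_participants)
    ]
    model = PowerInformationLink(pd.concat(tables, ignore_index=True))
    return model.fit(tail=tail, n_perm=n_perm, seed=rng)
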