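"""Shared numerical helpers and package-wide exceptions."""

from __future__ import annotations

import numpy as np
from scipy import stats

#: correlations are clipped to this magnitude before atanh so Fisher z stays finite
RHO_CLIP = 1.0 - 1e-10


class FidelityLinkError(Exception):
    """Base class for all package errors."""


class BalancedDesignError(FidelityLinkError):
    """Trial counts cannot be balanced across stimuli."""


class CollinearityError(FidelityLinkError):
    """A design or regressor matrix is rank deficient."""


class DomainError(FidelityLinkError):
    """A parameter is outside its valid domain."""


class DegenerateModelError(FidelityLinkError):
    """A model RDM or statistic is undefined for the given labels."""


class SingularityError(FidelityLinkError):
    """A covariance estimate is singular (e.g. a zero-variance voxel)."""


def fisher_z(rho: np.ndarray | float) -> np.ndarray | float:
    """atanh of a correlation, with |rho| clipped just below 1.

    The clip bounds |z| at atanh(1 - 1e-10) so downstream group statistics
    remain finite even for tie-limited perfect orderings.
    """
    return np.arctanh(np.clip(rho, -RHO_CLIP, RHO_CLIP))


def spearman_vs_model(values: np.ndarray, model: np.ndarray) -> np.ndarray:
    """Spearman correlation of each row of ``values`` against a fixed model vector.

    Vectorised over rows (average ranks for ties, Pearson on the ranks), which
    matters in the trial-level loops where scipy's per-call overhead dominates.
    Rows with zero rank variance return NaN.

    Parameters
    ----------
    values : (n_rows, n) or (n,) array
    model : (n,) array, typically binary 0/1 dissimilarity values
    """
    values = np.atleast_2d(np.asarray(values, dtype=float))
    model = np.asarray(model, dtype=float)
    if values.shape[1] != model.shape[0]:
        raise ValueError("values and model length mismatch")
    rv = stats.rankdata(values, axis=1)
    rm = stats.rankdata(model)
    rv_c = rv - rv.mean(axis=1, keepdims=True)
    rm_c = rm - rm.mean()
    denom = np.sqrt((rv_c**2).sum(axis=1) * (rm_c**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = (rv_c @ rm_c) / denom
    rho[denom == 0] = np.nan
    return rho if rho.size > 1 else rho


def spearman_rows_binary(values: np.ndarray, diff_mask: np.ndarray) -> np.ndarray:
    """Row-wise Spearman correlation against per-row binary 0/1 models.

    ``diff_mask[t, u]`` is True where the model value is 1 (different
    stimuli).  Exploits the closed form for the rank correlation against a
    binary vector (average ranks for ties): with n0 zeros and n1 ones,
    rho = (n/2) * sum_{m=1} rank_c / sqrt(sum rank_c^2 * n0*n1*n/4).
    Rows with a constant value vector or a one-sided model return NaN.
    """
    V = np.atleast_2d(np.asarray(values, dtype=float))
    M = np.atleast_2d(np.asarray(diff_mask, dtype=bool))
    n = V.shape[1]
    rv = stats.rankdata(V, axis=1)
    rv_c = rv - rv.mean(axis=1, keepdims=True)
    s1 = (rv_c * M).sum(axis=1)
    n1 = M.sum(axis=1)
    n0 = n - n1
    ss_v = (rv_c**2).sum(axis=1)
    ss_m = n0 * n1 * n / 4.0
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = (s1 * n / 2.0) / np.sqrt(ss_v * ss_m)
    rho[(ss_v == 0) | (n0 == 0) | (n1 == 0)] = np.nan
    return rho


def check_seed(seed) -> np.random.Generator:
    """Return a Generator from a seed, Generator or SeedSequence."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)
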