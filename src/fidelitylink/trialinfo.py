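"""Single-trial stimulus-specific information inside a region of interest.

For every trial, cross-validated Mahalanobis distances are computed between
that trial's pattern and a set of independent comparison patterns, and
Spearman-correlated with the trial's own binary model (distance 0 to
patterns of the matching stimulus, 1 to patterns of differing stimuli).
The Fisher z of that correlation is the trial's information value: positive
when matching patterns are closest.

Cross-validation scheme (the discriminant weight is always independent of
the patterns it is projected onto):

* perception - trial t is compared with every trial u of the *other* fold;
  the weight for the pair is Sigma^-1 applied to the difference of u's-fold
  condition means with u left out of its own mean.  Same-stimulus pairs
  then have an identically zero weight (there is nothing to discriminate),
  which keeps the trial statistic exactly centred under the null.
* retrieval - remembered trial t is compared with every perception trial u;
  the weight is Sigma^-1 (stimulus-average of retrieval trials  -
  perception condition mean from the partition NOT containing u).  The only
  term that reuses trial t is constant across comparisons and therefore
  invisible to the rank correlation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ._utils import (
    DomainError,
    FidelityLinkError,
    fisher_z,
    spearman_rows_binary,
)
from .rsa import ShrunkCovariance

__all__ = [
    "ParticipantFlaggedError",
    "perception_trial_information",
    "retrieval_trial_information",
]


class ParticipantFlaggedError(FidelityLinkError):
    """A participant cannot contribute (e.g. a stimulus has no usable trial)."""


def _precision(cov) -> np.ndarray:
    sigma = cov.sigma if isinstance(cov, ShrunkCovariance) else np.asarray(cov, float)
    return np.linalg.inv(sigma)


def _condition_means(patterns, labels, conditions):
    means, counts = [], []
    for c in conditions:
        idx = np.flatnonzero(labels == c)
        counts.append(len(idx))
        means.append(patterns[idx].mean(axis=0) if len(idx) else np.full(patterns.shape[1], np.nan))
    return np.array(means), np.array(counts)


def _one_direction(P_test, lab_test, ids_test, P_train, lab_train, M, conditions):
    """Distances from every test-fold trial to every train-fold trial."""
    mean_tr, n_tr = _condition_means(P_train, lab_train, conditions)
    cond_pos = {c: i for i, c in enumerate(conditions)}
    s_test = np.array([cond_pos[c] for c in lab_test])
    s_train = np.array([cond_pos[c] for c in lab_train])
    if np.any(n_tr[np.unique(s_test)] < 1):
        raise ParticipantFlaggedError("a stimulus has no comparison pattern in the training fold")
    # leave-one-out condition mean for every training trial
    loo = (mean_tr[s_train] * n_tr[s_train, None] - P_train) / np.maximum(
        n_tr[s_train, None] - 1, 1
    )
    single = n_tr[s_train] == 1          # no other trial of this stimulus: pair dropped
    MPt = M @ P_test.T                   # v x nT
    MPu = M @ P_train.T                  # v x nU
    t1 = np.einsum("tv,vt->t", mean_tr[s_test], MPt)       # const per test trial
    t2 = mean_tr @ MPu                                     # n_cond x nU
    t3 = P_test @ (M @ loo.T)                              # nT x nU
    t4 = np.einsum("uv,vu->u", loo, MPu)
    d = t1[:, None] - t2[s_test] - t3 + t4[None, :]
    same = s_test[:, None] == s_train[None, :]
    d[same] = 0.0                        # zero discriminant for same-stimulus pairs
    valid = ~(single[None, :] & same)    # LOO undefined for singleton same-stim pairs
    return d, same, valid


def perception_trial_information(
    patterns_a: np.ndarray,
    patterns_b: np.ndarray,
    labels_a,
    labels_b,
    cov,
    trial_ids_a=None,
    trial_ids_b=None,
) -> pd.DataFrame:
    """Per-trial information for perception trials across two folds.

    Every trial is compared with all trials of the other fold; distances
    are Spearman-correlated with the trial's 0/1 model and Fisher
    z-transformed.  Returns a DataFrame with columns trial_id, fold,
    z_info, n_comparison_patterns, phase; trials whose correlation is
    undefined carry NaN.
    """
    A, B = np.asarray(patterns_a, float), np.asarray(patterns_b, float)
    la, lb = np.asarray(labels_a), np.asarray(labels_b)
    conditions = np.unique(np.concatenate([la, lb]))
    if len(conditions) < 2:
        raise DomainError("need >= 2 distinct stimuli")
    if A.shape[1] != B.shape[1] or A.shape[1] == 0:
        raise DomainError("folds must share a non-empty voxel set")
    M = _precision(cov)
    ids_a = np.arange(len(la)) if trial_ids_a is None else np.asarray(trial_ids_a)
    ids_b = len(la) + np.arange(len(lb)) if trial_ids_b is None else np.asarray(trial_ids_b)
    rows = []
    for (P_t, l_t, ids, P_u, l_u, fold) in [
        (A, la, ids_a, B, lb, 0),
        (B, lb, ids_b, A, la, 1),
    ]:
        d, same, valid = _one_direction(P_t, l_t, ids, P_u, l_u, M, conditions)
        diff_mask = ~same & valid
        n_comp = valid.sum(axis=1)
        if valid.all():
            # common balanced case: one vectorised rank correlation
            z = fisher_z(spearman_rows_binary(d, diff_mask))
        else:
            z = np.full(len(l_t), np.nan)
            for t in range(len(l_t)):
                v = valid[t]
                if v.sum() < 3 or diff_mask[t].sum() == 0 or (v & same[t]).sum() == 0:
                    continue
                rho = spearman_rows_binary(d[t, v][None, :], diff_mask[t, v][None, :])[0]
                z[t] = fisher_z(rho) if np.isfinite(rho) else np.nan
        for t in range(len(l_t)):
            rows.append(
                dict(trial_id=ids[t], fold=fold, z_info=z[t],
                     n_comparison_patterns=int(n_comp[t]), phase="perception")
            )
    return pd.DataFrame(rows)


def retrieval_trial_information(
    retrieval_patterns: np.ndarray,
    retrieval_labels,
    perception_patterns: np.ndarray,
    perception_labels,
    perception_folds,
    cov,
    remembered=None,
    trial_ids=None,
) -> pd.DataFrame:
    """Per-trial reinstatement information for remembered retrieval trials.

    Each remembered retrieval trial is compared with every perception trial
    (both partitions); the weight pairs the stimulus-averaged retrieval
    pattern with the perception condition mean of the *other* partition.
    Distances are correlated with the match-0 / differ-1 model and Fisher
    z-transformed.

    Raises :class:`ParticipantFlaggedError` when a required stimulus
    average is missing, and :class:`DomainError` when unremembered trials
    are passed without a ``remembered`` mask to exclude them.
    """
    R = np.asarray(retrieval_patterns, float)
    lr = np.asarray(retrieval_labels)
    P = np.asarray(perception_patterns, float)
    lp = np.asarray(perception_labels)
    folds = np.asarray(perception_folds)
    ids = np.arange(len(lr)) if trial_ids is None else np.asarray(trial_ids)
    if remembered is not None:
        remembered = np.asarray(remembered, dtype=bool)
        if not remembered.all():
            R, lr, ids = R[remembered], lr[remembered], ids[remembered]
    if len(lr) == 0:
        raise DomainError("no remembered retrieval trials")
    conditions = np.unique(lp)
    cond_pos = {c: i for i, c in enumerate(conditions)}
    M = _precision(cov)

    rbar, n_r = _condition_means(R, lr, conditions)
    used = np.unique([cond_pos[c] for c in lr])
    if np.any(n_r[used] < 1) or np.any(np.isnan(rbar[used])):
        raise ParticipantFlaggedError("missing stimulus average at retrieval")
    fold_ids = np.unique(folds)
    if len(fold_ids) != 2:
        raise DomainError("perception trials must come from two partitions")
    pbar = {}
    for f in fold_ids:
        m, n = _condition_means(P[folds == f], lp[folds == f], conditions)
        if np.any(n < 1):
            raise ParticipantFlaggedError(f"missing perception condition mean in partition {f}")
        pbar[f] = m
    other = {fold_ids[0]: fold_ids[1], fold_ids[1]: fold_ids[0]}
    W = np.array([pbar[other[f]][cond_pos[c]] for f, c in zip(folds, lp)])

    s_r = np.array([cond_pos[c] for c in lr])
    s_p = np.array([cond_pos[c] for c in lp])
    MPr = M @ R.T
    MPp = M @ P.T
    t1 = np.einsum("tv,vt->t", rbar[s_r], MPr)
    t2 = rbar @ MPp                                    # n_cond x nP
    t3 = R @ (M @ W.T)                                 # nR x nP
    t4 = np.einsum("uv,vu->u", W, MPp)
    d = t1[:, None] - t2[s_r] - t3 + t4[None, :]
    diff_mask = s_r[:, None] != s_p[None, :]
    z = fisher_z(spearman_rows_binary(d, diff_mask))
    return pd.DataFrame(
        dict(
            trial_id=ids,
            z_info=z,
            n_comparison_patterns=d.shape[1],
            phase="retrieval",
        )
    )
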