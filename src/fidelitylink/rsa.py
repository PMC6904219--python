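"""Representational similarity machinery.

Cross-validated Mahalanobis (crossnobis) distances between activity
patterns estimated on independent data folds, noise-covariance shrinkage
toward the diagonal, volumetric searchlight construction with the
membership-fraction rule, binary model dissimilarity structures for
perception and memory reinstatement, information maps, ROI dilation and a
feature-space similarity contrast for electrophysiological patterns.

Sign convention used throughout: distances are correlated (Spearman)
against a 0/1 model in which 0 marks same-stimulus pairs and 1 marks
different-stimulus pairs.  Informative patterns put matching pairs closest,
so the correlation is *positive* when stimulus-specific structure is
present, and "information" is the Fisher z of that correlation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from ._utils import (
    DegenerateModelError,
    DomainError,
    SingularityError,
    fisher_z,
    spearman_vs_model,
)

__all__ = [
    "ShrunkCovariance",
    "SearchlightMap",
    "ModelRDM",
    "shrink_covariance",
    "crossnobis_distance",
    "build_searchlights",
    "model_rdm",
    "searchlight_information_map",
    "dilate_roi",
    "eeg_feature_rsa",
]


@dataclass
class ShrunkCovariance:
    """Noise covariance shrunk toward its diagonal.

    sigma = (1 - lam) * S + lam * diag(S), with lam the optimal
    shrinkage intensity clipped to [0, 1].
    """

    sigma: np.ndarray
    lam: float
    source_df: int

    def solve(self, b: np.ndarray) -> np.ndarray:
        """sigma^-1 @ b via Cholesky."""
        from scipy.linalg import cho_factor, cho_solve

        return cho_solve(cho_factor(self.sigma), b)


def shrink_covariance(residuals: np.ndarray) -> ShrunkCovariance:
    """Optimal shrinkage of the sample covariance toward its diagonal.

    Uses the analytic optimal intensity for the diagonal target
    (ratio of the summed sampling variances of the off-diagonal entries to
    their summed squares), clipped to [0, 1].  The result is positive
    definite whenever every voxel has non-zero variance, even with fewer
    samples than voxels.

    Parameters
    ----------
    residuals : (n_samples, n_voxels) array
        Mean-free noise samples, e.g. GLM residuals.
    """
    X = np.asarray(residuals, dtype=float)
    n, p = X.shape
    if n < 2 or p < 1:
        raise DomainError("need >= 2 samples and >= 1 voxel")
    Xc = X - X.mean(axis=0)
    S = Xc.T @ Xc / (n - 1)
    var = np.diag(S)
    if np.any(var <= 0):
        bad = int(np.flatnonzero(var <= 0)[0])
        raise SingularityError(f"voxel {bad} has zero variance")
    if p == 1:
        return ShrunkCovariance(sigma=S.copy(), lam=0.0, source_df=n - 1)
    # sampling variance of each off-diagonal covariance entry
    W = Xc[:, :, None] * Xc[:, None, :]          # n x p x p products
    var_s = n / (n - 1) ** 3 * ((W - W.mean(axis=0)) ** 2).sum(axis=0)
    off = ~np.eye(p, dtype=bool)
    denom = (S[off] ** 2).sum()
    lam = 1.0 if denom == 0 else float(np.clip(var_s[off].sum() / denom, 0.0, 1.0))
    sigma = (1 - lam) * S + lam * np.diag(var)
    return ShrunkCovariance(sigma=sigma, lam=lam, source_df=n - 1)


def crossnobis_distance(
    patterns_a: np.ndarray,
    patterns_b: np.ndarray,
    cov: ShrunkCovariance | np.ndarray,
    labels_a=None,
    labels_b=None,
) -> np.ndarray:
    """Cross-validated Mahalanobis distances between condition patterns.

    d(j, k) = (u_j^A - u_k^A)^T Sigma^-1 (u_j^B - u_k^B)

    Because Sigma^-1 is symmetric this single bilinear form already equals
    the average over the two fold assignments.  The expectation under pure
    noise is zero, so individual distances may be negative; the diagonal
    d(j, j) is identically zero by construction.

    Parameters
    ----------
    patterns_a, patterns_b : (n_conditions, n_voxels) arrays
        Condition patterns from two independent folds, same condition order.
    cov : ShrunkCovariance or matrix
    labels_a, labels_b : optional condition labels; must match if given.
    """
    A = np.asarray(patterns_a, dtype=float)
    B = np.asarray(patterns_b, dtype=float)
    if A.shape != B.shape:
        raise DomainError("fold pattern shapes differ")
    if labels_a is not None or labels_b is not None:
        if list(labels_a) != list(labels_b):
            raise DomainError("condition labels differ across folds")
    sigma = cov.sigma if isinstance(cov, ShrunkCovariance) else np.asarray(cov, float)
    if sigma.shape[0] != A.shape[1]:
        raise DomainError("covariance dimension does not match voxel count")
    G = A @ np.linalg.solve(sigma, B.T)          # G[j, k] = u_j^A Sigma^-1 u_k^B
    return np.diag(G)[:, None] - G - G.T + np.diag(G)[None, :]


@dataclass
class SearchlightMap:
    """Spherical searchlight membership over a voxel mask.

    ``centres`` and the entries of ``members`` index the flattened in-mask
    voxel array (C order over the mask grid), the same ordering as pattern
    matrix columns.  ``full_count`` is the analytic voxel count of a
    complete sphere of the given radius on this grid spacing.
    """

    centres: np.ndarray
    members: list
    radius_mm: float
    min_fraction: float
    full_count: int
    grid_spacing_mm: tuple = (3.0, 3.0, 4.0)
    mask_shape: tuple | None = None
    centre_ijk: np.ndarray | None = None

    @property
    def n_centres(self) -> int:
        return len(self.centres)


def _sphere_offsets(spacing_mm, radius_mm) -> np.ndarray:
    sx, sy, sz = spacing_mm
    nx = int(np.floor(radius_mm / sx))
    ny = int(np.floor(radius_mm / sy))
    nz = int(np.floor(radius_mm / sz))
    ii, jj, kk = np.mgrid[-nx : nx + 1, -ny : ny + 1, -nz : nz + 1]
    keep = (ii * sx) ** 2 + (jj * sy) ** 2 + (kk * sz) ** 2 <= radius_mm**2 + 1e-9
    return np.column_stack([ii[keep], jj[keep], kk[keep]])


def build_searchlights(
    mask: np.ndarray,
    spacing_mm: tuple = (3.0, 3.0, 4.0),
    radius_mm: float = 10.0,
    min_fraction: float = 0.6,
) -> SearchlightMap:
    """Spherical searchlights on a regular voxel grid.

    Membership is by inclusive centre-to-centre Euclidean distance
    <= ``radius_mm``; on the default 3 x 3 x 4 mm grid a 10 mm sphere holds
    121 voxels.  Centres whose in-mask member count falls below
    ``min_fraction`` of the full-sphere count (the 60% rule by default,
    e.g. at the edge of the brain) are discarded.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim != 3:
        raise DomainError("mask must be a 3-D boolean grid")
    if not mask.any():
        raise DomainError("mask is empty")
    if radius_mm <= 0 or not 0 < min_fraction <= 1:
        raise DomainError("invalid radius or min_fraction")
    offsets = _sphere_offsets(spacing_mm, radius_mm)
    full = len(offsets)
    index_vol = -np.ones(mask.shape, dtype=int)
    coords = np.column_stack(np.nonzero(mask))
    index_vol[mask] = np.arange(len(coords))
    centres, members, centre_ijk = [], [], []
    shape = np.array(mask.shape)
    for vox_idx, ijk in enumerate(coords):
        pts = ijk + offsets
        ok = np.all((pts >= 0) & (pts < shape), axis=1)
        pts = pts[ok]
        mem = index_vol[pts[:, 0], pts[:, 1], pts[:, 2]]
        mem = mem[mem >= 0]
        if len(mem) / full >= min_fraction:
            centres.append(vox_idx)
            members.append(np.sort(mem))
            centre_ijk.append(ijk)
    return SearchlightMap(
        centres=np.array(centres, dtype=int),
        members=members,
        radius_mm=radius_mm,
        min_fraction=min_fraction,
        full_count=full,
        grid_spacing_mm=tuple(spacing_mm),
        mask_shape=mask.shape,
        centre_ijk=np.array(centre_ijk, dtype=int),
    )


@dataclass
class ModelRDM:
    """Binary model dissimilarities: 0 same stimulus, 1 different stimulus.

    ``values[j, k]`` compares row condition j with column condition k.  For
    the retrieval-reinstatement model the rows are retrieval conditions and
    the columns perception conditions, so within-phase pairs are excluded
    structurally.
    """

    values: np.ndarray
    phase: str
    row_labels: np.ndarray = field(default=None)
    col_labels: np.ndarray = field(default=None)


def model_rdm(labels_row, labels_col=None, phase: str = "perception") -> ModelRDM:
    """Binary dissimilarity model from stimulus labels.

    ``phase='perception'`` compares one set of labels across two folds
    (columns default to the rows); ``phase='reinstatement'`` expects
    retrieval labels as rows and perception labels as columns, which
    excludes any perception-perception or retrieval-retrieval pair.
    """
    if phase not in ("perception", "reinstatement"):
        raise DomainError(f"unknown phase {phase!r}")
    row = np.asarray(labels_row)
    col = row if labels_col is None else np.asarray(labels_col)
    if len(np.unique(np.concatenate([row, col]))) < 2:
        raise DegenerateModelError("all stimulus labels identical: model is degenerate")
    values = (row[:, None] != col[None, :]).astype(float)
    return ModelRDM(values=values, phase=phase, row_labels=row, col_labels=col)


def searchlight_information_map(
    patterns_a: np.ndarray,
    patterns_b: np.ndarray,
    labels,
    residuals: np.ndarray,
    searchlights: SearchlightMap,
) -> np.ndarray:
    """Fisher-z information value at every valid searchlight centre.

    Per centre: crossnobis distances between the condition patterns of the
    two folds restricted to member voxels (noise covariance shrunk from the
    residual columns of the same members), Spearman-correlated with the
    binary perception model over all cross-fold pairs (same-stimulus pairs
    included), Fisher z-transformed, and written at the centre voxel.

    Returns a 1-D array over all in-mask voxels, NaN everywhere except at
    valid centres; centres whose distance vector is constant are flagged
    NaN as well.
    """
    A = np.asarray(patterns_a, float)
    B = np.asarray(patterns_b, float)
    labels = np.asarray(labels)
    model = model_rdm(labels, phase="perception").values.ravel()
    n_voxels = A.shape[1]
    out = np.full(n_voxels, np.nan)
    for centre, mem in zip(searchlights.centres, searchlights.members):
        if len(model) < 3:
            continue
        cov = shrink_covariance(residuals[:, mem])
        d = crossnobis_distance(A[:, mem], B[:, mem], cov).ravel()
        if np.ptp(d) == 0:
            continue
        rho = spearman_vs_model(d, model)[0]
        if np.isnan(rho):
            continue
        out[centre] = fisher_z(rho)
    return out


def dilate_roi(cluster_voxels, searchlights: SearchlightMap) -> np.ndarray:
    """Union of the members of every searchlight centred in the cluster.

    Extends a cluster of centre voxels with every neighbouring voxel that
    contributed to those searchlights; always a superset of the input.
    """
    cluster = np.atleast_1d(np.asarray(cluster_voxels, dtype=int))
    if cluster.size == 0:
        warnings.warn("empty cluster: ROI is empty")
        return np.array([], dtype=int)
    sets = [cluster]
    centre_pos = {c: i for i, c in enumerate(searchlights.centres)}
    for v in cluster:
        if v in centre_pos:
            sets.append(searchlights.members[centre_pos[v]])
    return np.unique(np.concatenate(sets))


def eeg_feature_rsa(features: np.ndarray, labels) -> float:
    """Stimulus-information contrast in a spatiotemporal feature space.

    Pairwise trial similarity is the Spearman correlation over the
    flattened (electrode x frequency x time) feature vector, Fisher
    z-transformed; the returned scalar is mean same-stimulus similarity
    minus mean different-stimulus similarity across all trial pairs.
    Trials with a constant feature vector are flagged missing and their
    pairs excluded.
    """
    from scipy.stats import rankdata

    F = np.asarray(features, dtype=float)
    if F.ndim > 2:
        F = F.reshape(F.shape[0], -1)
    labels = np.asarray(labels)
    n = F.shape[0]
    if n < 2 or len(np.unique(labels)) < 2:
        raise DegenerateModelError("need >= 2 trials and >= 2 distinct labels")
    valid = F.std(axis=1) > 0
    ranks = rankdata(F, axis=1).astype(float)
    with np.errstate(invalid="ignore"):
        rho = np.corrcoef(ranks)
    z = fisher_z(np.clip(rho, -1.0, 1.0))
    iu, ju = np.triu_indices(n, k=1)
    ok = valid[iu] & valid[ju]
    same = labels[iu] == labels[ju]
    same_ok, diff_ok = same & ok, ~same & ok
    if not same_ok.any() or not diff_ok.any():
        raise DegenerateModelError("no valid same- or different-stimulus pair")
    return float(z[iu, ju][same_ok].mean() - z[iu, ju][diff_ok].mean())
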