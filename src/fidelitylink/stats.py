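"""Linking power to information: regression, permutation and Bayesian inference.

The central object is :class:`PowerInformationLink`, a statsmodels-style
model built from per-trial tables (one row per trial with the Fisher-z
information value, post- and pre-stimulus alpha/beta power, BOLD amplitude
and confidence rating, keyed by participant).  ``fit()`` runs an ordinary
least-squares multiple regression per participant (information as outcome,
z-scored predictors), converts each coefficient to a t-value, and carries
the per-participant t-values to a group-level sign-flip permutation t-test.
The returned :class:`PowerInformationLinkResults` holds the estimates,
their group p-values, Cohen's d_z, JZS Bayes factors on demand, a
``summary()`` table and a strip plot.

Also here: the generic one-sample sign-flip permutation test (exhaustive
for small samples), cluster-based permutation inference over feature maps,
the JZS default-prior Bayes factor, the power-confidence correlation, and
the correlation-attenuation simulation for restricted fidelity variance.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import integrate, ndimage
from scipy import stats as sstats
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from ._utils import CollinearityError, DomainError, FidelityLinkError, check_seed, fisher_z
from .trialinfo import ParticipantFlaggedError

logger = logging.getLogger("fidelitylink")

__all__ = [
    "LinkRegressionResult",
    "ClusterResult",
    "PowerInformationLink",
    "PowerInformationLinkResults",
    "fit_link_regression",
    "group_permutation_ttest",
    "cluster_permutation_test",
    "jzs_bayes_factor",
    "bayes_factor_label",
    "confidence_power_correlation",
    "attenuation_simulation",
    "apply_participant_exclusion",
]

REGRESSORS = ("post_power", "pre_power", "bold_amplitude", "confidence")


@dataclass
class LinkRegressionResult:
    """Per-participant t-values of the information ~ power regression."""

    t_values: dict
    n_trials: int
    participant_id: object = None


def fit_link_regression(
    info,
    post_power,
    pre_power,
    bold_amplitude,
    confidence,
    mode: str = "continuous",
    participant_id=None,
) -> LinkRegressionResult:
    """OLS of per-trial information on power and nuisance regressors.

    Outcome: Fisher-z information per trial.  Predictors (z-scored, plus an
    intercept): post-stimulus power, pre-stimulus power, BOLD amplitude,
    confidence rating.  ``mode='median_split'`` replaces the continuous
    post-stimulus power by a 0/1 indicator of above-median power.  Rows
    with any missing value are dropped (complete cases, logged).

    Returns t = beta / SE(beta) for every regressor.
    """
    if mode not in ("continuous", "median_split"):
        raise DomainError(f"unknown mode {mode!r}")
    cols = dict(
        info=np.asarray(info, float),
        post_power=np.asarray(post_power, float),
        pre_power=np.asarray(pre_power, float),
        bold_amplitude=np.asarray(bold_amplitude, float),
        confidence=np.asarray(confidence, float),
    )
    df = pd.DataFrame(cols)
    n0 = len(df)
    df = df.dropna()
    if len(df) < n0:
        logger.info("participant %s: dropped %d incomplete trials", participant_id, n0 - len(df))
    n = len(df)
    n_regressors = len(REGRESSORS)
    if n < n_regressors + 2:
        raise ParticipantFlaggedError(
            f"participant {participant_id}: only {n} complete trials"
        )
    if mode == "median_split":
        df["post_power"] = (df["post_power"] > df["post_power"].median()).astype(float)

    X = np.empty((n, n_regressors + 1))
    X[:, 0] = 1.0
    for j, name in enumerate(REGRESSORS, start=1):
        x = df[name].to_numpy()
        sd = x.std()
        if sd == 0:
            raise CollinearityError(f"regressor {name} is constant")
        X[:, j] = (x - x.mean()) / sd
    if np.linalg.cond(X) > 1e8:
        raise CollinearityError("regressors are collinear (condition number > 1e8)")

    import statsmodels.api as sm

    fit = sm.OLS(df["info"].to_numpy(), X).fit()
    t = {name: float(fit.tvalues[j]) for j, name in enumerate(REGRESSORS, start=1)}
    return LinkRegressionResult(t_values=t, n_trials=n, participant_id=participant_id)


def _t_stat(values: np.ndarray) -> float:
    n = len(values)
    sd = values.std(ddof=1)
    if sd == 0:
        return 0.0 if values.mean() == 0 else np.inf * np.sign(values.mean())
    return float(values.mean() / (sd / np.sqrt(n)))


def group_permutation_ttest(
    values, tail: str = "two", n_perm: int = 2000, seed=None
) -> dict:
    """One-sample sign-flip permutation test of mean zero.

    The observed one-sample t is compared with its distribution under
    random sign flips of the participant values.  With n <= 12 the full
    2^n flip set is enumerated (exact p); otherwise ``n_perm`` random
    flips are drawn and p = (#{as or more extreme} + 1) / (n_perm + 1).

    tail: 'left' (negative means expected), 'right', or 'two'.
    """
    if tail not in ("left", "right", "two"):
        raise DomainError(f"unknown tail {tail!r}")
    v = np.asarray(values, dtype=float)
    n = len(v)
    if n < 2:
        raise DomainError("need >= 2 participants")
    if n_perm < 1:
        raise DomainError("need n_perm >= 1")
    if np.all(v == 0):
        warnings.warn("all values are zero; p = 1")
        return dict(p=1.0, t=0.0, mean=0.0, n=n, exhaustive=True, n_perm=0)
    t_obs = _t_stat(v)
    exhaustive = n <= 12
    if exhaustive:
        bits = np.arange(2**n)[:, None] >> np.arange(n)[None, :] & 1
        signs = np.where(bits, 1.0, -1.0)
    else:
        rng = check_seed(seed)
        signs = rng.choice([-1.0, 1.0], size=(n_perm, n))
    flipped = signs * v
    means = flipped.mean(axis=1)
    sds = flipped.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_perm = means / (sds / np.sqrt(n))
    t_perm = np.nan_to_num(t_perm, nan=0.0, posinf=np.inf, neginf=-np.inf)
    eps = 1e-12
    if tail == "left":
        extreme = t_perm <= t_obs + eps
    elif tail == "right":
        extreme = t_perm >= t_obs - eps
    else:
        extreme = np.abs(t_perm) >= abs(t_obs) - eps
    if exhaustive:
        p = extreme.mean()
    else:
        p = (extreme.sum() + 1) / (n_perm + 1)
    return dict(
        p=float(p), t=t_obs, mean=float(v.mean()), n=n,
        exhaustive=exhaustive, n_perm=int(len(signs)),
    )


@dataclass
class ClusterResult:
    """Clusters of supra-threshold features with permutation p-values."""

    clusters: list
    cluster_stats: np.ndarray
    p_perm: np.ndarray
    n_perm: int
    t_map: np.ndarray = None
    threshold: float = None


def _grid_adjacency(shape) -> csr_matrix:
    n = int(np.prod(shape))
    idx = np.arange(n).reshape(shape)
    rows, cols = [], []
    for axis in range(len(shape)):
        a = np.moveaxis(idx, axis, 0)
        rows.append(a[:-1].ravel())
        cols.append(a[1:].ravel())
    r = np.concatenate(rows)
    c = np.concatenate(cols)
    data = np.ones(len(r), dtype=bool)
    adj = csr_matrix((data, (r, c)), shape=(n, n))
    return adj + adj.T


def _components(adj: csr_matrix, supra: np.ndarray) -> list:
    nodes = np.flatnonzero(supra)
    if len(nodes) == 0:
        return []
    sub = adj[nodes][:, nodes]
    n_comp, lab = connected_components(sub, directed=False)
    return [nodes[lab == i] for i in range(n_comp)]


def cluster_permutation_test(
    data: np.ndarray,
    adjacency=None,
    cluster_alpha: float = 0.05,
    n_perm: int = 2000,
    tail: str = "right",
    seed=None,
) -> ClusterResult:
    """Cluster-based sign-flip permutation test over feature maps.

    ``data`` is (n_participants, *feature_shape); per feature a one-sample
    t is computed, thresholded at the ``cluster_alpha`` quantile of the
    Student t distribution (tail-appropriate), and contiguous
    supra-threshold features are grouped under ``adjacency`` (a sparse
    boolean matrix over flattened features; ``None`` uses lattice adjacency
    of the feature grid).  The cluster statistic is the summed t
    ("maxsum"); its null comes from the maximal cluster mass under random
    participant sign flips.  Features with no neighbours form singleton
    clusters.
    """
    X = np.asarray(data, dtype=float)
    n_sub = X.shape[0]
    shape = X.shape[1:]
    Xf = X.reshape(n_sub, -1)
    n_feat = Xf.shape[1]
    grid = adjacency is None and len(shape) >= 1
    adj = None
    if not grid:
        adj = csr_matrix(adjacency)
        if adj.shape != (n_feat, n_feat):
            raise DomainError("adjacency must be n_features x n_features")
    df = n_sub - 1
    if tail == "two":
        t_crit = sstats.t.ppf(1 - cluster_alpha / 2, df)
    else:
        t_crit = sstats.t.ppf(1 - cluster_alpha, df)

    def _supra_sets(tm):
        if tail == "right":
            yield tm > t_crit
        elif tail == "left":
            yield tm < -t_crit
        else:
            yield tm > t_crit
            yield tm < -t_crit

    def _clusters_of(tm, supra):
        if grid:
            lab, n_lab = ndimage.label(supra.reshape(shape))
            lab = lab.ravel()
            return [np.flatnonzero(lab == i) for i in range(1, n_lab + 1)]
        return _components(adj, supra)

    def max_mass(tm):
        mass = 0.0
        for supra in _supra_sets(tm):
            for comp in _clusters_of(tm, supra):
                mass = max(mass, abs(tm[comp].sum()))
        return mass

    def _t_rows(signs):
        # sign flips leave per-feature sums of squares unchanged, so only
        # the flipped means need recomputing
        m = signs @ Xf / n_sub
        ssq = (Xf**2).sum(axis=0)
        var = (ssq - n_sub * m**2) / (n_sub - 1)
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.nan_to_num(m * np.sqrt(n_sub) / np.sqrt(var))

    t_obs = _t_rows(np.ones((1, n_sub)))[0]
    clusters, stats_ = [], []
    for supra in _supra_sets(t_obs):
        for comp in _clusters_of(t_obs, supra):
            clusters.append(comp)
            stats_.append(t_obs[comp].sum())
    stats_ = np.asarray(stats_)

    rng = check_seed(seed)
    signs = rng.choice([-1.0, 1.0], size=(n_perm, n_sub))
    t_perm = _t_rows(signs)
    null = np.fromiter((max_mass(t_perm[i]) for i in range(n_perm)),
                       dtype=float, count=n_perm)
    p = np.array([
        (np.sum(null >= abs(s) - 1e-12) + 1) / (n_perm + 1) for s in stats_
    ])
    return ClusterResult(
        clusters=clusters, cluster_stats=stats_, p_perm=p, n_perm=n_perm,
        t_map=t_obs.reshape(shape), threshold=t_crit,
    )


def jzs_bayes_factor(values=None, t=None, n=None, prior_scale: float = 0.707) -> float:
    """JZS default-prior Bayes factor for a one-sample t-test (BF10).

    Cauchy prior with scale ``prior_scale`` on the standardised effect
    size, i.e. a scaled inverse-gamma(1/2) mixture over the variance ratio
    g, integrated by adaptive quadrature:

        BF10 = [ int_0^inf (1+Ng)^(-1/2) (1 + t^2 / ((1+Ng) nu))^(-(nu+1)/2)
                 p(g) dg ] / (1 + t^2/nu)^(-(nu+1)/2)

    with p(g) = r (2 pi)^(-1/2) g^(-3/2) exp(-r^2 / (2g)) and nu = n - 1.
    BF10 < 1 favours the null.  Depends on the data only through |t| (the
    two-sided formulation), so it is invariant to sign flips of the values.
    """
    if prior_scale <= 0:
        raise DomainError("prior_scale must be > 0")
    if values is not None:
        v = np.asarray(values, dtype=float)
        n = len(v)
        if n < 2:
            raise DomainError("need >= 2 values")
        t = _t_stat(v)
    elif t is None or n is None:
        raise DomainError("provide either values or (t, n)")
    if n < 2:
        raise DomainError("need n >= 2")
    nu = n - 1
    r = prior_scale
    t2 = float(t) ** 2

    def integrand(g):
        return (
            (1 + n * g) ** -0.5
            * (1 + t2 / ((1 + n * g) * nu)) ** (-(nu + 1) / 2)
            * r / np.sqrt(2 * np.pi) * g ** -1.5 * np.exp(-(r**2) / (2 * g))
        )

    num, err = integrate.quad(integrand, 0, np.inf, limit=200,
                              epsabs=1e-13, epsrel=1e-10)
    if not np.isfinite(num) or num <= 0 or err > 1e-6 * num:
        raise FidelityLinkError(
            f"Bayes-factor integration did not converge (value={num}, abserr={err})"
        )
    den = (1 + t2 / nu) ** (-(nu + 1) / 2)
    return float(num / den)


def bayes_factor_label(bf10: float) -> str:
    """Evidence category for a Bayes factor, following the usual rule of thumb."""
    bands = [
        (100, "extreme evidence for H1"), (30, "very strong evidence for H1"),
        (10, "strong evidence for H1"), (3, "moderate evidence for H1"),
        (1, "anecdotal evidence for H1"),
    ]
    if bf10 >= 1:
        for cut, lab in bands:
            if bf10 >= cut:
                return lab
    inv = 1.0 / bf10
    for cut, lab in bands:
        if inv >= cut:
            return lab.replace("H1", "H0")
    return "anecdotal evidence for H0"


def confidence_power_correlation(power, confidence) -> float:
    """Fisher z of the rank correlation between power and confidence.

    Spearman is used for the ordinal 1-4 ratings.  Participants with fewer
    than 3 complete trials or a constant confidence vector are flagged.
    """
    p = np.asarray(power, dtype=float)
    c = np.asarray(confidence, dtype=float)
    ok = np.isfinite(p) & np.isfinite(c)
    p, c = p[ok], c[ok]
    if len(p) < 3:
        raise ParticipantFlaggedError("fewer than 3 complete trials")
    if np.ptp(c) == 0:
        raise ParticipantFlaggedError("constant confidence rating")
    rho = sstats.spearmanr(p, c).statistic
    return float(fisher_z(rho))


def attenuation_simulation(
    fidelity_sd,
    coupling: float = 1.0,
    noise_sd: float = 0.3,
    n_trials: int = 200,
    n_reps: int = 200,
    seed=None,
) -> pd.DataFrame:
    """Observed power-fidelity correlation under restricted fidelity variance.

    For each fidelity SD, ``n_reps`` replicates draw Gaussian fidelity and
    power = -coupling * fidelity + noise; the per-replicate Pearson r is
    recorded.  The expected value is the closed-form attenuated correlation

        rho = -coupling * sd / sqrt(coupling^2 sd^2 + noise_sd^2),

    so the observed correlation shrinks toward zero as the across-trial
    variation of fidelity shrinks, whatever the true coupling.  At sd = 0
    the correlation is undefined and reported as 0.
    """
    rng = check_seed(seed)
    rows = []
    for sd in fidelity_sd:
        if sd < 0:
            raise DomainError("fidelity_sd must be >= 0")
        rs = np.empty(n_reps)
        for i in range(n_reps):
            f = sd * rng.standard_normal(n_trials)
            power = -coupling * f + noise_sd * rng.standard_normal(n_trials)
            rs[i] = 0.0 if sd == 0 else sstats.pearsonr(power, f).statistic
        denom = np.sqrt(coupling**2 * sd**2 + noise_sd**2)
        expected = 0.0 if denom == 0 else -coupling * sd / denom
        rows.append(
            dict(
                fidelity_sd=sd,
                mean_r=rs.mean(),
                mean_abs_r=np.abs(rs).mean(),
                se_r=rs.std(ddof=1) / np.sqrt(n_reps),
                expected_r=expected,
            )
        )
    return pd.DataFrame(rows)


def apply_participant_exclusion(
    trial_table: pd.DataFrame,
    min_remembered: int = 10,
    min_forgotten: int = 10,
    participant_col: str = "participant",
) -> list:
    """Participants retained under the minimum-trial-count rule.

    Participants with fewer than ``min_remembered`` remembered or
    ``min_forgotten`` forgotten trials are dropped before group inference;
    each exclusion is logged with its reason.
    """
    keep = []
    for pid, grp in trial_table.groupby(participant_col):
        n_rem = int(grp["remembered"].sum())
        n_for = int((~grp["remembered"].astype(bool)).sum())
        if n_rem < min_remembered:
            logger.info("participant %s excluded: %d remembered trials", pid, n_rem)
        elif n_for < min_forgotten:
            logger.info("participant %s excluded: %d forgotten trials", pid, n_for)
        else:
            keep.append(pid)
    return keep


class PowerInformationLink:
    """Trial-level link between spectral power and pattern information.

    Parameters
    ----------
    data : DataFrame
        One row per trial with columns ``participant``, ``z_info``,
        ``post_power``, ``pre_power``, ``bold_amplitude``, ``confidence``.

    The model regresses, within each participant, the Fisher-z information
    value on z-scored post-stimulus power plus the three nuisance
    regressors (pre-stimulus power, BOLD amplitude, confidence), and tests
    the per-participant t-values against zero with a sign-flip permutation
    t-test at the group level.  The hypothesised direction is negative
    (power decreases accompany higher-fidelity information), hence the
    default left tail for the power regressor.
    """

    REQUIRED = ("participant", "z_info") + REGRESSORS

    def __init__(self, data: pd.DataFrame):
        missing = [c for c in self.REQUIRED if c not in data.columns]
        if missing:
            raise DomainError(f"missing columns: {missing}")
        self.data = data.copy()

    @classmethod
    def from_tables(cls, info: pd.DataFrame, power: pd.DataFrame,
                    on=("participant", "trial_id")) -> "PowerInformationLink":
        """Merge a per-trial information table with a per-trial power table."""
        merged = info.merge(power, on=list(on), how="inner")
        return cls(merged)

    def fit(self, mode: str = "continuous", tail: str = "left",
            n_perm: int = 2000, seed=None) -> "PowerInformationLinkResults":
        rows, excluded = [], []
        for pid, grp in self.data.groupby("participant"):
            try:
                res = fit_link_regression(
                    grp["z_info"], grp["post_power"], grp["pre_power"],
                    grp["bold_amplitude"], grp["confidence"],
                    mode=mode, participant_id=pid,
                )
            except ParticipantFlaggedError as exc:
                logger.info("excluding participant %s: %s", pid, exc)
                excluded.append(pid)
                continue
            rows.append(dict(participant=pid, n_trials=res.n_trials, **res.t_values))
        if len(rows) < 2:
            raise DomainError("fewer than 2 participants with a valid regression")
        tvals = pd.DataFrame(rows).set_index("participant")
        rng = check_seed(seed)
        group = {}
        for name in REGRESSORS:
            reg_tail = tail if name == "post_power" else "two"
            group[name] = group_permutation_ttest(
                tvals[name].to_numpy(), tail=reg_tail, n_perm=n_perm, seed=rng
            )
        return PowerInformationLinkResults(
            model=self, participant_t=tvals, group=group, mode=mode,
            tail=tail, excluded=excluded,
        )


@dataclass
class PowerInformationLinkResults:
    """Fitted power-information link with group-level inference."""

    model: PowerInformationLink
    participant_t: pd.DataFrame
    group: dict
    mode: str
    tail: str
    excluded: list = field(default_factory=list)

    @property
    def n_participants(self) -> int:
        return len(self.participant_t)

    def cohens_dz(self, regressor: str = "post_power") -> float:
        """Standardised group effect size mean(t) / sd(t)."""
        t = self.participant_t[regressor].to_numpy()
        return float(t.mean() / t.std(ddof=1))

    def p_value(self, regressor: str = "post_power") -> float:
        return self.group[regressor]["p"]

    def bayes_factor(self, regressor: str = "post_power",
                     prior_scale: float = 0.707) -> float:
        """JZS BF10 on the participant t-values of one regressor."""
        return jzs_bayes_factor(self.participant_t[regressor].to_numpy(),
                                prior_scale=prior_scale)

    def summary(self) -> pd.DataFrame:
        """Group-level table: mean t, d_z, permutation p and tail per regressor."""
        rows = []
        for name in REGRESSORS:
            g = self.group[name]
            rows.append(
                dict(
                    regressor=name,
                    mean_t=g["mean"],
                    cohens_dz=self.cohens_dz(name),
                    p_perm=g["p"],
                    tail=self.tail if name == "post_power" else "two",
                    n_participants=g["n"],
                )
            )
        return pd.DataFrame(rows).set_index("regressor")

    def plot(self, ax=None):
        """Strip plot of per-participant t-values per regressor."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 4))
        for i, name in enumerate(REGRESSORS):
            y = self.participant_t[name].to_numpy()
            x = np.full_like(y, i, dtype=float) + np.linspace(-0.12, 0.12, len(y))
            ax.plot(x, y, "o", alpha=0.6, ms=4)
            ax.hlines(y.mean(), i - 0.25, i + 0.25, color="k")
        ax.axhline(0, color="grey", lw=0.8, ls="--")
        ax.set_xticks(range(len(REGRESSORS)), REGRESSORS, rotation=20)
        ax.set_ylabel("participant t-value")
        return ax

    def __repr__(self):
        g = self.group["post_power"]
        return (
            f"<PowerInformationLinkResults n={self.n_participants} mode={self.mode} "
            f"post_power: mean t={g['mean']:.3f}, p={g['p']:.4g} ({self.tail}-tailed)>"
        )
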