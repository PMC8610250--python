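"""Group-level statistics: cluster permutation tests, nuisance
regression, component comparison z-scores, and the distance mixed model.

The cluster-based permutation test controls the family-wise error over
frequencies (and optionally over components) nonparametrically: paired
one-tailed t statistics of subject MI spectra against their surrogate
95th-percentile reference are thresholded, adjacent suprathreshold
frequencies form clusters whose summed t is compared against the
permutation distribution of maximum cluster statistics obtained by
randomly interchanging each subject's observed and reference spectra.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "Cluster",
    "ClusterTestResult",
    "NuisanceDesign",
    "LMEMFit",
    "cluster_permutation_test",
    "multi_component_correction",
    "build_nuisance_design",
    "regress_nuisance",
    "component_z_scores",
    "fit_distance_lmem",
    "head_centre_distance",
    "Z_CRIT_ONE_TAILED_P01",
]

# one-tailed p = 0.01 critical value used for component comparisons
Z_CRIT_ONE_TAILED_P01 = 2.33


@dataclass(frozen=True)
class Cluster:
    """Maximal run of adjacent suprathreshold frequencies."""

    freq_lo_idx: int
    freq_hi_idx: int  # inclusive
    sum_t: float
    p_value: float

    @property
    def significant_at(self) -> float:
        return self.p_value


@dataclass
class ClusterTestResult:
    clusters: list[Cluster]
    t_values: np.ndarray
    threshold_p: float = 0.05
    n_permutations: int = 5000
    alpha: float = 0.05
    excluded_freqs: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    @property
    def significant(self) -> list[Cluster]:
        return [c for c in self.clusters if c.p_value < self.alpha]


@dataclass
class NuisanceDesign:
    """Head-movement nuisance regressors: 6 raw position/rotation
    signals plus their first differences, each raised to powers 1-3
    (36 columns), drift-removed by a third-order polynomial fit."""

    regressors: np.ndarray
    rank_deficient: bool = False


@dataclass
class LMEMFit:
    beta0: float
    beta1: float
    beta1_se: float
    t_value: float
    dof: int
    p_value: float
    random_slope_var: float
    converged: bool


def _paired_t(diffs: np.ndarray) -> np.ndarray:
    """One-sample t over axis 0; zero-variance columns with nonzero mean
    get +/-inf (sign of the mean), all-zero columns get NaN."""
    n = diffs.shape[0]
    mean = diffs.mean(axis=0)
    sd = diffs.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    zero_sd = sd == 0
    t[zero_sd & (mean > 0)] = np.inf
    t[zero_sd & (mean < 0)] = -np.inf
    t[zero_sd & (mean == 0)] = np.nan
    return t


def _clusters_from_t(t: np.ndarray, t_crit: float) -> list[tuple[int, int, float]]:
    """(lo, hi inclusive, sum t) for maximal runs of t >= t_crit."""
    supra = t >= t_crit
    out = []
    i = 0
    n = t.size
    while i < n:
        if supra[i]:
            j = i
            while j + 1 < n and supra[j + 1]:
                j += 1
            out.append((i, j, float(t[i : j + 1].sum())))
            i = j + 1
        else:
            i += 1
    return out


def _max_cluster_stats(t2d: np.ndarray, t_crit: float) -> np.ndarray:
    """Maximum cluster-sum per row of a (permutations x freqs) t matrix,
    vectorised over rows. Rows containing +inf report inf."""
    supra = t2d >= t_crit
    vals = np.where(supra, t2d, 0.0)
    n_rows = t2d.shape[0]
    cs = np.concatenate([np.zeros((n_rows, 1)), np.cumsum(vals, axis=1)], axis=1)
    pad = np.zeros((n_rows, 1), dtype=bool)
    edges = np.diff(
        np.concatenate([pad, supra, pad], axis=1).astype(np.int8), axis=1
    )
    rows_s, starts = np.nonzero(edges == 1)
    rows_e, ends = np.nonzero(edges == -1)
    sums = cs[rows_e, ends] - cs[rows_s, starts]
    out = np.zeros(n_rows)
    np.maximum.at(out, rows_s, sums)
    # inf - inf in the cumsum yields NaN for clusters after an inf one;
    # any row holding an inf cluster maxes out regardless
    out[np.isposinf(vals).any(axis=1)] = np.inf
    return out


def _perm_t_matrix(diffs: np.ndarray, signs: np.ndarray) -> np.ndarray:
    """t statistics for many sign-flip permutations at once.

    ``diffs`` is subjects x freqs, ``signs`` is perms x subjects with
    entries +/-1. Per-subject sign flips leave sum(d^2) invariant, so
    the permuted SD follows from the permuted mean alone.
    """
    n = diffs.shape[0]
    mean = signs @ diffs / n  # perms x freqs
    msq = np.mean(diffs**2, axis=0)  # freqs
    var = (msq[None, :] - mean**2) * n / (n - 1)
    var = np.maximum(var, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / np.sqrt(var / n)
    zero = var == 0
    t[zero & (mean > 0)] = np.inf
    t[zero & (mean < 0)] = -np.inf
    t[zero & (mean == 0)] = np.nan
    return t


def cluster_permutation_test(
    subject_spectra: np.ndarray,
    subject_null95_spectra: np.ndarray,
    n_perm: int = 5000,
    thresh_p: float = 0.05,
    alpha: float = 0.05,
    seed: int | np.random.Generator = 0,
) -> ClusterTestResult:
    """Cluster-based permutation test of MI spectra against a reference.

    Per frequency, a paired one-tailed t test (observed > reference) is
    thresholded at ``thresh_p``; adjacent suprathreshold frequencies
    form clusters scored by their summed t. The null interchanges each
    subject's observed and reference spectra with probability 1/2
    (equivalently flips the sign of the paired difference), recomputes
    the max cluster statistic, and each observed cluster's Monte-Carlo
    p is (1 + #{null max >= observed}) / (n_perm + 1).

    Frequencies where every subject's difference is exactly zero are
    excluded (reported in ``excluded_freqs``); zero-variance frequencies
    with a nonzero mean difference count as infinitely suprathreshold.
    """
    obs = np.atleast_2d(np.asarray(subject_spectra, dtype=float))
    ref = np.atleast_2d(np.asarray(subject_null95_spectra, dtype=float))
    if obs.shape != ref.shape:
        raise ValueError("spectra and reference spectra must share shape")
    n_subj, n_freq = obs.shape
    if n_subj < 2:
        raise ValueError("need >= 2 subjects")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    diffs = obs - ref
    t_obs = _paired_t(diffs)
    excluded = np.flatnonzero(np.isnan(t_obs))
    if excluded.size:
        warnings.warn(
            f"{excluded.size} frequencies with all-zero differences excluded",
            stacklevel=2,
        )
        t_obs = t_obs.copy()
        t_obs[excluded] = -np.inf  # never suprathreshold
    t_crit = stats.t.ppf(1.0 - thresh_p, df=n_subj - 1)
    obs_clusters = _clusters_from_t(t_obs, t_crit)
    signs = rng.choice([-1.0, 1.0], size=(n_perm, n_subj))
    t_perm = _perm_t_matrix(diffs, signs)
    t_perm = np.nan_to_num(t_perm, nan=-np.inf)
    null_max = _max_cluster_stats(t_perm, t_crit)
    clusters = [
        Cluster(lo, hi, s, float((1 + np.sum(null_max >= s)) / (n_perm + 1)))
        for lo, hi, s in obs_clusters
    ]
    return ClusterTestResult(
        clusters=clusters, t_values=t_obs, threshold_p=thresh_p,
        n_permutations=n_perm, alpha=alpha, excluded_freqs=excluded,
    )


def multi_component_correction(
    component_spectra: list[np.ndarray],
    component_null95: list[np.ndarray],
    n_perm: int = 5000,
    thresh_p: float = 0.05,
    alpha: float = 0.05,
    seed: int | np.random.Generator = 0,
) -> list[ClusterTestResult]:
    """Cluster permutation corrected jointly across components.

    Identical to :func:`cluster_permutation_test` except the permutation
    null pools the maximum cluster statistic across ALL components for
    each permutation draw (one sign flip per subject per draw, applied
    to every component, respecting within-subject dependence), so the
    family-wise error is controlled over frequencies x components
    jointly rather than per component.
    """
    if len(component_spectra) < 1:
        raise ValueError("need >= 1 component")
    if len(component_spectra) != len(component_null95):
        raise ValueError("spectra/reference component counts differ")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    diffs_list, t_obs_list, excl_list = [], [], []
    n_subj = None
    for obs, ref in zip(component_spectra, component_null95):
        obs = np.atleast_2d(np.asarray(obs, dtype=float))
        ref = np.atleast_2d(np.asarray(ref, dtype=float))
        if obs.shape != ref.shape:
            raise ValueError("spectra and reference spectra must share shape")
        if n_subj is None:
            n_subj = obs.shape[0]
        elif obs.shape[0] != n_subj:
            raise ValueError("all components must share the subject axis")
        d = obs - ref
        t = _paired_t(d)
        excl = np.flatnonzero(np.isnan(t))
        t = t.copy()
        t[excl] = -np.inf
        diffs_list.append(d)
        t_obs_list.append(t)
        excl_list.append(excl)
    if n_subj < 2:
        raise ValueError("need >= 2 subjects")
    t_crit = stats.t.ppf(1.0 - thresh_p, df=n_subj - 1)
    signs = rng.choice([-1.0, 1.0], size=(n_perm, n_subj))
    null_max = np.zeros(n_perm)
    for d in diffs_list:
        t_perm = np.nan_to_num(_perm_t_matrix(d, signs), nan=-np.inf)
        null_max = np.maximum(null_max, _max_cluster_stats(t_perm, t_crit))
    results = []
    for t_obs, excl in zip(t_obs_list, excl_list):
        obs_clusters = _clusters_from_t(t_obs, t_crit)
        clusters = [
            Cluster(lo, hi, s, float((1 + np.sum(null_max >= s)) / (n_perm + 1)))
            for lo, hi, s in obs_clusters
        ]
        results.append(
            ClusterTestResult(
                clusters=clusters, t_values=t_obs, threshold_p=thresh_p,
                n_permutations=n_perm, alpha=alpha, excluded_freqs=excl,
            )
        )
    return results


def _remove_poly_drift(col: np.ndarray, order: int = 3) -> np.ndarray:
    t = np.linspace(-1.0, 1.0, col.size)
    design = np.polynomial.polynomial.polyvander(t, order)
    coef, *_ = np.linalg.lstsq(design, col, rcond=None)
    return col - design @ coef


def build_nuisance_design(head_signals: np.ndarray) -> NuisanceDesign:
    """36-column head-movement nuisance design.

    From 6 continuous head-position signals (x, y, z translation and
    three rotation angles) their first differences are added (12
    signals), each raised to powers 1, 2 and 3 (36 columns); every
    column is drift-removed by subtracting its least-squares third-order
    polynomial fit. Constant inputs leave derivative columns at zero,
    which is flagged as a rank-deficient design.
    """
    h = np.asarray(head_signals, dtype=float)
    if h.ndim != 2 or h.shape[1] != 6:
        raise ValueError("head_signals must be time x 6")
    deriv = np.diff(h, axis=0, prepend=h[:1])
    base = np.concatenate([h, deriv], axis=1)  # time x 12
    cols = [base**p for p in (1, 2, 3)]
    design = np.concatenate(cols, axis=1)  # time x 36
    design = np.apply_along_axis(_remove_poly_drift, 0, design)
    rank = np.linalg.matrix_rank(design)
    return NuisanceDesign(regressors=design, rank_deficient=rank < design.shape[1])


def regress_nuisance(series: np.ndarray, design: NuisanceDesign) -> np.ndarray:
    """Residual of a time series after projecting out the nuisance
    design (least squares; minimum-norm solution when rank-deficient).
    The operation is a projection: applying it twice equals once."""
    y = np.asarray(series, dtype=float)
    d = design.regressors
    if y.shape[0] != d.shape[0]:
        raise ValueError("series and design lengths differ")
    coef, *_ = np.linalg.lstsq(d, y, rcond=None)
    return y - d @ coef


def component_z_scores(mi: np.ndarray) -> np.ndarray:
    """Leave-one-out z-scores of component MI spectra.

    For component j at frequency i, z = (MI_ij - mean of the other
    components at i) / SD of the other components at i (sample SD).
    |z| >= 2.33 marks a one-tailed p = 0.01 deviation from the grand
    average of the remaining components. Entries whose leave-one-out
    SD is zero are NaN.
    """
    m = np.asarray(mi, dtype=float)
    if m.ndim != 2 or m.shape[0] < 3:
        raise ValueError("need a components x frequencies matrix with >= 3 components")
    n = m.shape[0]
    z = np.empty_like(m)
    for j in range(n):
        others = np.delete(m, j, axis=0)
        mu = others.mean(axis=0)
        sd = others.std(axis=0, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            z[j] = (m[j] - mu) / sd
        z[j, sd == 0] = np.nan
    return z


def head_centre_distance(coords_mm: np.ndarray) -> np.ndarray:
    """Euclidean distance of component coordinates (n x 3, mm) to the
    head centre: r = sqrt(x^2 + y^2 + z^2)."""
    c = np.atleast_2d(np.asarray(coords_mm, dtype=float))
    if c.shape[1] != 3:
        raise ValueError("coordinates must be n x 3")
    return np.linalg.norm(c, axis=1)


def fit_distance_lmem(
    mi_band: np.ndarray,
    r: np.ndarray,
    subject_ids: np.ndarray,
    random_intercept: bool = False,
) -> LMEMFit:
    """Mixed model of band MI against component distance to head centre.

    MI_j = beta0 + (beta1 + S_1j) * r + e_j: fixed intercept, fixed
    slope on r, and a subject-specific random slope (no random
    intercept unless requested). Fitted by maximum likelihood
    (statsmodels MixedLM); the slope test reports t = beta1 / se with
    residual degrees of freedom n_obs - 2.

    Parameters
    ----------
    mi_band : MI values, one per (subject, component) observation.
    r : head-centre distance per observation (same length).
    subject_ids : grouping labels per observation.
    """
    import statsmodels.api as sm

    y = np.asarray(mi_band, dtype=float).ravel()
    rr = np.asarray(r, dtype=float).ravel()
    groups = np.asarray(subject_ids).ravel()
    if not (y.size == rr.size == groups.size):
        raise ValueError("mi_band, r and subject_ids must have equal length")
    if np.unique(groups).size < 2:
        raise ValueError("need >= 2 subjects")
    exog = np.column_stack([np.ones_like(rr), rr])
    if random_intercept:
        exog_re = np.column_stack([np.ones_like(rr), rr])
    else:
        exog_re = rr[:, None]
    model = sm.MixedLM(y, exog, groups=groups, exog_re=exog_re)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = model.fit(reml=False, method="bfgs")
            converged = bool(fit.converged)
        except Exception:
            fit = None
            converged = False
    if fit is None or not np.all(np.isfinite(fit.params[:2])):
        return LMEMFit(
            beta0=np.nan, beta1=np.nan, beta1_se=np.nan, t_value=np.nan,
            dof=y.size - 2, p_value=np.nan, random_slope_var=np.nan,
            converged=False,
        )
    beta0, beta1 = float(fit.params[0]), float(fit.params[1])
    se = float(fit.bse[1])
    dof = y.size - 2
    t_val = beta1 / se if se > 0 else np.nan
    p = float(2.0 * stats.t.sf(abs(t_val), df=dof)) if np.isfinite(t_val) else np.nan
    slope_var = float(np.asarray(fit.cov_re)[-1, -1])
    return LMEMFit(
        beta0=beta0, beta1=beta1, beta1_se=se, t_value=float(t_val),
        dof=dof, p_value=p, random_slope_var=slope_var, converged=converged,
    )
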