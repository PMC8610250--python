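"""Sparse NMF network decomposition and component characterisation.

The group modulation-index matrix X (frequencies stacked by subject x
voxels) is factorised as X ~ A Y with nonnegative A (participant-
specific spectral profiles) and Y (spatial component maps), minimising

    ||X - A Y||_F^2 + eta ||A||_F^2 + lambda * sum_j ||y_j||_1^2

by alternating nonnegativity-constrained least squares; the squared-L1
column penalty drives spatially sparse maps. Rank is chosen by the
fraction of the singular-value mass (90% rule), the best of many
random restarts is kept by residual, maps are thresholded at a
percentile, and component spectrotemporal profiles (frequency bands x
respiration-phase bins) are clustered hierarchically with a
silhouette-guided cut.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.linalg import svdvals
from scipy.optimize import nnls

__all__ = [
    "NMFDecomposition",
    "ComponentProfile",
    "ClusteringResult",
    "normalize_subject_mi",
    "build_group_matrix",
    "split_group_matrix",
    "select_rank",
    "select_rank_subjects",
    "sparse_nmf",
    "threshold_map",
    "component_profiles",
    "cluster_components",
]


@dataclass
class NMFDecomposition:
    basis: np.ndarray  # (frequencies*subjects) x k, nonneg
    coefficients: np.ndarray  # k x n_voxels, nonneg
    residual: float
    eta: float
    lam: float
    n_restarts: int
    best_seed: int
    objective_trace: np.ndarray = field(default_factory=lambda: np.array([]))
    converged: bool = True


@dataclass
class ComponentProfile:
    """z-scored band x phase-bin modulation profile of one component."""

    values: np.ndarray  # bands x bins
    component_id: int
    peak_voxel_coords_mm: np.ndarray | None = None


@dataclass
class ClusteringResult:
    labels: np.ndarray
    n_clusters: int
    silhouette_curve: dict[int, float]
    linkage_matrix: np.ndarray


def normalize_subject_mi(mi_run1: np.ndarray, mi_run2: np.ndarray) -> np.ndarray:
    """Balance baseline differences: each run is divided by its own
    global standard deviation, then the two runs are averaged."""
    a = np.asarray(mi_run1, dtype=float)
    b = np.asarray(mi_run2, dtype=float)
    if a.shape != b.shape:
        raise ValueError("runs must share shape")
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        raise ValueError("zero standard deviation in a run")
    return 0.5 * (a / sa + b / sb)


def build_group_matrix(subject_matrices: list[np.ndarray]) -> np.ndarray:
    """Stack per-subject frequencies x voxels matrices into the group
    NMF input: (n_freq * n_subjects) rows x n_voxels columns, subject
    blocks in order."""
    mats = [np.asarray(m, dtype=float) for m in subject_matrices]
    shape = mats[0].shape
    if any(m.shape != shape for m in mats):
        raise ValueError("subject matrices must share shape")
    return np.concatenate(mats, axis=0)


def split_group_matrix(x: np.ndarray, n_subjects: int) -> list[np.ndarray]:
    """Inverse of :func:`build_group_matrix`."""
    if x.shape[0] % n_subjects:
        raise ValueError("row count is not a multiple of n_subjects")
    return list(np.split(np.asarray(x), n_subjects, axis=0))


def select_rank(matrix: np.ndarray, fraction: float = 0.9) -> int:
    """Smallest k whose leading singular values account for ``fraction``
    of the total singular-value mass (values below numerical tolerance
    are treated as zero)."""
    m = np.asarray(matrix, dtype=float)
    sv = svdvals(m)
    tol = max(m.shape) * np.finfo(float).eps * (sv[0] if sv.size else 0.0)
    sv = sv[sv > tol]
    if sv.size == 0:
        raise ValueError("all-zero matrix has no rank")
    cum = np.cumsum(sv) / sv.sum()
    return int(np.searchsorted(cum, fraction) + 1)


def select_rank_subjects(
    subject_matrices: list[np.ndarray], fraction: float = 0.9
) -> tuple[int, np.ndarray]:
    """Rank selection applied to each subject's normalised MI matrix,
    aggregated by the median (rounded to the nearest integer). Returns
    (aggregate rank, per-subject ranks)."""
    ks = np.array([select_rank(m, fraction) for m in subject_matrices])
    return int(round(float(np.median(ks)))), ks


def _nnls_columns(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Column-wise nonnegative least squares: argmin_{x>=0} ||a x - b||."""
    out = np.empty((a.shape[1], b.shape[1]))
    for j in range(b.shape[1]):
        out[:, j], _ = nnls(a, b[:, j])
    return out


def _objective(x, a, y, eta, lam):
    resid = x - a @ y
    return (
        np.sum(resid**2)
        + eta * np.sum(a**2)
        + lam * np.sum(y.sum(axis=0) ** 2)
    )


def sparse_nmf(
    x: np.ndarray,
    k: int,
    eta: float | None = None,
    lam: float = 0.01,
    n_restarts: int = 100,
    max_iter: int = 200,
    tol: float = 1e-6,
    seed: int = 0,
) -> NMFDecomposition:
    """Sparse NMF by alternating nonnegativity-constrained least squares.

    Both penalties fold into augmented least-squares problems solved
    exactly per column (active-set NNLS), so the objective is
    non-increasing at every half-step. Restarts use distinct seeded
    nonnegative random initialisations; the restart with the smallest
    data residual ||X - A Y||_F wins.

    Parameters
    ----------
    eta : Frobenius penalty on the basis A; default (max X)^2.
    lam : squared-L1 penalty on each coefficient column of Y (drives
        spatial sparsity); default 0.01.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("input matrix must be nonnegative")
    if k < 1:
        raise ValueError("k must be >= 1")
    if not np.any(x):
        zero_a = np.zeros((x.shape[0], k))
        zero_y = np.zeros((k, x.shape[1]))
        return NMFDecomposition(zero_a, zero_y, 0.0, eta or 0.0, lam, n_restarts, seed)
    if eta is None:
        eta = float(x.max()) ** 2
    m, n = x.shape
    sqrt_eta = np.sqrt(eta)
    sqrt_lam = np.sqrt(lam)
    best = None
    for restart in range(n_restarts):
        rng = np.random.default_rng([seed, restart])
        a = rng.random((m, k)) * np.sqrt(x.mean() / k)
        trace = []
        prev = np.inf
        converged = False
        for _ in range(max_iter):
            # Y-step: rows [A; sqrt(lam) * 1_k'] since ||y_j||_1^2 = (1'y_j)^2
            a_aug = np.vstack([a, sqrt_lam * np.ones((1, k))])
            x_aug = np.vstack([x, np.zeros((1, n))])
            y = _nnls_columns(a_aug, x_aug)
            # A-step: columns [Y, sqrt(eta) I_k] acting on A'
            y_aug = np.hstack([y, sqrt_eta * np.eye(k)])
            x_aug2 = np.hstack([x, np.zeros((m, k))])
            a = _nnls_columns(y_aug.T, x_aug2.T).T
            obj = _objective(x, a, y, eta, lam)
            trace.append(obj)
            if np.isfinite(prev) and prev - obj <= tol * max(abs(obj), 1.0):
                converged = True
                break
            prev = obj
        residual = float(np.linalg.norm(x - a @ y))
        if best is None or residual < best[0]:
            best = (residual, a, y, restart, np.array(trace), converged)
    residual, a, y, best_seed, trace, converged = best
    return NMFDecomposition(
        basis=a, coefficients=y, residual=residual, eta=eta, lam=lam,
        n_restarts=n_restarts, best_seed=best_seed, objective_trace=trace,
        converged=converged,
    )


def threshold_map(weights: np.ndarray, percentile: float = 99.0) -> np.ndarray:
    """Voxel ids surviving a percentile threshold of a component map.

    Retains the top ceil((1 - percentile/100) * n) voxels by weight
    (ties broken by ascending voxel id), e.g. 202 of 20,173 voxels at
    the 99th percentile. Returned ids are sorted ascending.
    """
    w = np.asarray(weights, dtype=float).ravel()
    n = w.size
    # (100 - p) * n / 100 keeps exact-integer cases exact in floats
    m = int(np.ceil((100.0 - percentile) * n / 100.0 - 1e-9))
    m = max(m, 0)
    order = np.lexsort((np.arange(n), -w))  # weight desc, id asc on ties
    return np.sort(order[:m])


def component_profiles(
    group_mi: np.ndarray,
    voxel_sets: list[np.ndarray],
    coords_mm: np.ndarray | None = None,
) -> list[ComponentProfile]:
    """Component spectrotemporal profiles.

    ``group_mi`` is voxels x bands x phase-bins (group-average MI
    resolved over the respiratory cycle). Each component's profile is
    the mean over its thresholded voxel set, z-scored over the whole
    band x bin matrix. ``coords_mm`` (voxels x 3) attaches the peak
    voxel's coordinates when given.
    """
    g = np.asarray(group_mi, dtype=float)
    if g.ndim != 3:
        raise ValueError("group_mi must be voxels x bands x bins")
    profiles = []
    for cid, vox in enumerate(voxel_sets):
        vox = np.asarray(vox, dtype=np.intp)
        if vox.size == 0:
            raise ValueError(f"component {cid} has an empty voxel set")
        prof = g[vox].mean(axis=0)
        sd = prof.std()
        if sd == 0:
            raise ValueError(f"component {cid} profile is constant")
        prof = (prof - prof.mean()) / sd
        peak = None
        if coords_mm is not None:
            strength = g[vox].mean(axis=(1, 2))
            peak = np.asarray(coords_mm)[vox[np.argmax(strength)]]
        profiles.append(ComponentProfile(values=prof, component_id=cid,
                                         peak_voxel_coords_mm=peak))
    return profiles


def cluster_components(
    profiles: list[ComponentProfile],
    candidate_counts: range | list[int] | None = None,
    method: str = "average",
    metric: str = "euclidean",
) -> ClusteringResult:
    """Hierarchical clustering of component profiles with a
    silhouette-guided cut.

    Profiles are flattened and clustered agglomeratively (Euclidean
    distance, average linkage by default). The mean silhouette is
    evaluated at each candidate cluster count and the FIRST local
    maximum of the silhouette curve picks the count (falling back to
    the global maximum when the curve is monotone).
    """
    from sklearn.metrics import silhouette_score

    if len(profiles) < 3:
        raise ValueError("need >= 3 profiles")
    flat = np.stack([np.asarray(p.values).ravel() for p in profiles])
    if np.allclose(flat, flat[0]):
        raise ValueError("all profiles identical: silhouette undefined")
    if candidate_counts is None:
        candidate_counts = range(2, len(profiles))
    counts = [int(c) for c in candidate_counts]
    if any(c < 2 or c > len(profiles) for c in counts):
        raise ValueError("candidate counts must lie in [2, n_profiles]")
    lk = linkage(flat, method=method, metric=metric)
    curve: dict[int, float] = {}
    labels_by_count = {}
    for c in counts:
        labels = fcluster(lk, t=c, criterion="maxclust")
        labels_by_count[c] = labels
        if np.unique(labels).size < 2:
            curve[c] = -1.0
        else:
            curve[c] = float(silhouette_score(flat, labels, metric=metric))
    vals = [curve[c] for c in counts]
    chosen = None
    for i, v in enumerate(vals):
        left = vals[i - 1] if i > 0 else -np.inf
        right = vals[i + 1] if i + 1 < len(vals) else -np.inf
        if v > left and v >= right:
            chosen = counts[i]
            break
    if chosen is None:
        chosen = counts[int(np.argmax(vals))]
    return ClusteringResult(
        labels=labels_by_count[chosen], n_clusters=chosen,
        silhouette_curve=curve, linkage_matrix=lk,
    )
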