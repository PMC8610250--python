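"""Minimal LCMV beamforming: unit-gain spatial filters for extracting
per-voxel time series from a sensor-level mixture.

The linearly constrained minimum variance (LCMV) filter for a voxel
with leadfield l is w = C^-1 l (l' C^-1 l)^-1: it passes the voxel's
source with unit gain while minimising output variance, i.e.
suppressing contributions from elsewhere. Regularisation defaults to
lambda = 0 with a pseudo-inverse fallback for rank-deficient
covariances. Three-column leadfields are reduced to the orientation of
maximum output power (smallest generalized eigenvalue of l' C^-1 l).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import eigh, pinvh

__all__ = ["SpatialFilter", "lcmv_filter", "apply_filter"]


@dataclass
class SpatialFilter:
    weights: np.ndarray  # one weight per sensor
    orientation: np.ndarray | None = None  # unit 3-vector for 3-col leadfields
    regularization: float = 0.0


def lcmv_filter(
    covariance: np.ndarray, leadfield: np.ndarray, lam: float = 0.0
) -> SpatialFilter:
    """LCMV spatial filter for one voxel.

    Parameters
    ----------
    covariance : sensors x sensors symmetric sensor covariance.
    leadfield : sensors x 1 (fixed orientation) or sensors x 3 (free
        orientation; the direction yielding maximum output power is
        selected before solving).
    lam : Tikhonov regularisation added as lam * I (default 0; a
        pseudo-inverse handles singular covariances).
    """
    c = np.asarray(covariance, dtype=float)
    if c.ndim != 2 or c.shape[0] != c.shape[1]:
        raise ValueError("covariance must be square")
    if not np.allclose(c, c.T, atol=1e-10 * max(1.0, np.abs(c).max())):
        raise ValueError("covariance must be symmetric")
    l = np.asarray(leadfield, dtype=float)
    if l.ndim == 1:
        l = l[:, None]
    if l.shape[0] != c.shape[0] or l.shape[1] not in (1, 3):
        raise ValueError("leadfield must be sensors x 1 or sensors x 3")
    if lam < 0:
        raise ValueError("lam must be >= 0")
    c_reg = c + lam * np.eye(c.shape[0]) if lam > 0 else c
    c_inv = pinvh(c_reg)
    orientation = None
    if l.shape[1] == 3:
        # output power 1/(u' l'C^-1 l u) is maximal along the eigenvector
        # of l'C^-1 l with the smallest eigenvalue
        gram = l.T @ c_inv @ l
        w_eig, v = eigh(gram)
        orientation = v[:, 0] / np.linalg.norm(v[:, 0])
        l = l @ orientation[:, None]
    gram = l.T @ c_inv @ l
    w = (c_inv @ l) @ pinvh(gram)
    return SpatialFilter(weights=w[:, 0], orientation=orientation, regularization=lam)


def apply_filter(filt: SpatialFilter, sensor_series: np.ndarray) -> np.ndarray:
    """Project sensor data (sensors x time) to the voxel time series as
    a weighted sum per sample."""
    x = np.asarray(sensor_series, dtype=float)
    if x.ndim == 1:
        x = x[None, :]
    if x.shape[0] != filt.weights.size:
        raise ValueError("sensor count does not match filter weights")
    return filt.weights @ x
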