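"""Time-lagged canonical correlation analysis and kinetic-variance scoring.

tCCA relates a feature time series X_t to its lagged copy Y_t = X_{t+lag}
through the SVD of the whitened cross-correlation matrix

    C_X^{-1/2} C_XY C_Y^{-1/2} = U Σ V^T,

where C_X, C_Y, C_XY are mean-subtracted sample covariances.  The singular
values are the autocorrelations of the extracted collective coordinates;
the sum of their squares (the squared Frobenius norm of the whitened
correlation matrix) is the *kinetic variance*, identical to the VAMP-2
score used to rank feature sets for Markov state modelling.

tICA is the reversible variant: the symmetrized time-lagged covariance is
diagonalized against the full-data covariance as a generalized eigenvalue
problem; for data obeying detailed balance its eigenvalues coincide with
the tCCA singular values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .chain import ParameterError
from .features import FeatureMatrix

_RANK_TOL = 1e-8  # relative spectral cutoff for whiteners


def _as_arrays(trajectories) -> list[np.ndarray]:
    out = []
    for t in trajectories if isinstance(trajectories, (list, tuple)) else [trajectories]:
        out.append(t.values if isinstance(t, FeatureMatrix) else np.asarray(t, float))
    return out


def _lagged_pairs(arrays: list[np.ndarray], lag: int):
    """Pool (x_t, x_{t+lag}) pairs within each trajectory only."""
    xs, ys = [], []
    for a in arrays:
        if lag >= len(a):
            raise ParameterError(
                f"lag {lag} >= trajectory length {len(a)}"
            )
        if lag == 0:
            xs.append(a)
            ys.append(a)
        else:
            xs.append(a[:-lag])
            ys.append(a[lag:])
    return np.vstack(xs), np.vstack(ys)


def _inv_sqrt(c: np.ndarray, epsilon: float) -> tuple[np.ndarray, int]:
    """Symmetric inverse square root with diagonal shrinkage + rank cutoff."""
    d = c.shape[0]
    ridge = epsilon * np.trace(c) / max(d, 1)
    vals, vecs = scipy.linalg.eigh(c + ridge * np.eye(d))
    cutoff = _RANK_TOL * vals.max()
    keep = vals > cutoff
    rank = int(keep.sum())
    inv = np.zeros_like(vals)
    inv[keep] = 1.0 / np.sqrt(vals[keep])
    return (vecs * inv) @ vecs.T, rank


@dataclass
class TCCAModel:
    """Fitted tCCA decomposition.

    ``U``/``V`` are the left/right singular functions expressed in the
    original (unwhitened) feature basis: projecting is
    ``(x - mean_x) @ U``.  Singular values are sorted descending and, for
    full-rank unregularized data, lie in [0, 1] up to numerical slack.
    """

    lag: int
    mean_x: np.ndarray
    mean_y: np.ndarray
    cov_x: np.ndarray
    cov_y: np.ndarray
    cov_xy: np.ndarray
    U: np.ndarray
    V: np.ndarray
    singular_values: np.ndarray
    regularization: float
    labels: list[str] | None = None

    def project(self, fm, n_components: int | None = None) -> np.ndarray:
        """Map features onto the dominant left singular functions."""
        if isinstance(fm, FeatureMatrix):
            if self.labels is not None and fm.labels != self.labels:
                raise ParameterError("feature labels do not match the model's")
            x = fm.values
        else:
            x = np.atleast_2d(np.asarray(fm, dtype=np.float64))
        k = n_components or self.U.shape[1]
        return (x - self.mean_x) @ self.U[:, :k]

    def kinetic_variance(self, k: int | None = None) -> float:
        """Sum of the k largest squared singular values (VAMP-2 score)."""
        sigma = self.singular_values
        if k is None:
            k = len(sigma)
        if k > len(sigma):
            raise ParameterError(f"k={k} exceeds rank {len(sigma)}")
        return float(np.sum(sigma[:k] ** 2))

    def save_h5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as h5:
            g = h5.create_group("tcca")
            g.create_dataset("U", data=self.U)
            g.create_dataset("V", data=self.V)
            g.create_dataset("sigma", data=self.singular_values)
            g.create_dataset("mean_x", data=self.mean_x)
            g.create_dataset("mean_y", data=self.mean_y)
            g.attrs["lag"] = self.lag
            g.attrs["epsilon"] = self.regularization


def estimate_tcca(
    trajectories,
    lag: int,
    dim: int | None = None,
    regularization: float = 1e-10,
) -> TCCAModel:
    """Fit tCCA at the given lag (frames).

    Instantaneous/lagged pairs are confined within each trajectory; the
    covariances use separate X and Y means.  Whitening adds a relative
    diagonal shrinkage ``regularization * trace/d`` and truncates the
    retained spectrum at 1e-8 of the largest eigenvalue.  Zero-variance
    features are removed with a warning.
    """
    arrays = _as_arrays(trajectories)
    labels = None
    first = trajectories[0] if isinstance(trajectories, (list, tuple)) else trajectories
    if isinstance(first, FeatureMatrix):
        labels = first.labels
    x, y = _lagged_pairs(arrays, lag)
    n, d = x.shape

    var = x.var(axis=0)
    keep = var > 1e-300
    if not np.all(keep):
        warnings.warn(f"removed {int((~keep).sum())} zero-variance feature(s)")
        x, y = x[:, keep], y[:, keep]
        d = x.shape[1]
    mean_x = x.mean(axis=0)
    mean_y = y.mean(axis=0)
    xc = x - mean_x
    yc = y - mean_y
    cov_x = xc.T @ xc / n
    cov_y = yc.T @ yc / n
    cov_xy = xc.T @ yc / n

    wx, rank_x = _inv_sqrt(cov_x, regularization)
    wy, rank_y = _inv_sqrt(cov_y, regularization)
    kmat = wx @ cov_xy @ wy
    u, s, vt = np.linalg.svd(kmat)
    rank = min(rank_x, rank_y)
    if dim is not None:
        rank = min(rank, dim)
    u, s, vt = u[:, :rank], s[:rank], vt[:rank]

    # re-embed removed features as zero rows so labels stay aligned
    U = wx @ u
    V = wy @ vt.T
    if not np.all(keep):
        U_full = np.zeros((len(keep), rank))
        V_full = np.zeros((len(keep), rank))
        U_full[keep] = U
        V_full[keep] = V
        mx = np.zeros(len(keep))
        my = np.zeros(len(keep))
        mx[keep], my[keep] = mean_x, mean_y
        U, V, mean_x, mean_y = U_full, V_full, mx, my
        full = np.zeros((len(keep), len(keep)))
        cov_x_f = full.copy(); cov_x_f[np.ix_(keep, keep)] = cov_x
        cov_y_f = full.copy(); cov_y_f[np.ix_(keep, keep)] = cov_y
        cov_xy_f = full.copy(); cov_xy_f[np.ix_(keep, keep)] = cov_xy
        cov_x, cov_y, cov_xy = cov_x_f, cov_y_f, cov_xy_f

    return TCCAModel(
        lag=lag,
        mean_x=mean_x,
        mean_y=mean_y,
        cov_x=cov_x,
        cov_y=cov_y,
        cov_xy=cov_xy,
        U=U,
        V=V,
        singular_values=s,
        regularization=regularization,
        labels=labels,
    )


def project(model: TCCAModel, fm, n_components: int | None = None) -> np.ndarray:
    """Functional alias of :meth:`TCCAModel.project`."""
    return model.project(fm, n_components)


def kinetic_variance(model: TCCAModel, k: int | None = None) -> float:
    """Functional alias of :meth:`TCCAModel.kinetic_variance`."""
    return model.kinetic_variance(k)


def estimate_tica(
    trajectories, lag: int, dim: int | None = None, regularization: float = 1e-10
):
    """Reversible tICA: solve ½(C_XY + C_YX) V = C V Λ.

    ``C`` is the covariance of the pooled full data set.  Eigenvalues are
    real (the symmetrization enforces reversibility) and sorted descending.

    Returns
    -------
    eigenvalues : (k,) ndarray
    eigenvectors : (d, k) ndarray, columns C-orthonormal
    """
    arrays = _as_arrays(trajectories)
    x, y = _lagged_pairs(arrays, lag)
    full = np.vstack(arrays)
    mean = full.mean(axis=0)
    n = len(x)
    xc, yc = x - mean, y - mean
    cov_xy = xc.T @ yc / n
    sym = 0.5 * (cov_xy + cov_xy.T)
    fc = full - mean
    cov = fc.T @ fc / len(full)
    d = cov.shape[0]
    ridge = regularization * np.trace(cov) / max(d, 1)
    vals, vecs = scipy.linalg.eigh(sym, cov + ridge * np.eye(d))
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    if dim is not None:
        vals, vecs = vals[:dim], vecs[:, :dim]
    return vals, vecs
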