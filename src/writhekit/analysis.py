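"""Ensemble diagnostics: writhe-sign asymmetry and distribution distances.

The central diagnostic for chirality is the per-frame pair of sums of
negative and of positive pairwise writhe values at segment length 1: an
ensemble and its mirror image have the two distributions exactly swapped,
so any asymmetry between them is a parity-odd fingerprint of the ensemble
that distance-based observables cannot see.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.linalg
from scipy import stats

from .chain import ChainCoordinates, ParameterError
from .writhe import writhe_matrix


@dataclass
class SignAsymmetry:
    """Per-frame negative/positive writhe sums and summary statistics."""

    negative_sums: np.ndarray  # per frame, <= 0
    positive_sums: np.ndarray  # per frame, >= 0
    asymmetry: float  # mean(positive) - mean(|negative|)
    kde_negative: object
    kde_positive: object


def writhe_sign_asymmetry(ensemble: ChainCoordinates, l: int = 1) -> SignAsymmetry:
    """Separate sums of negative and positive pairwise writhe per frame.

    Uses the non-excluded upper triangle of the segment-length-``l`` writhe
    matrix.  Kernel densities use Gaussian kernels with Scott's bandwidth
    rule.  The asymmetry statistic is the difference between the means of
    the positive-sum distribution and the mirrored (absolute) negative-sum
    distribution; it vanishes for any parity-symmetric ensemble.
    """
    if ensemble.n_atoms < 5:
        raise ParameterError("need >= 5 atoms for a meaningful writhe profile")
    wm = writhe_matrix(ensemble, l)
    vals, _ = wm.upper_triangle()
    neg = np.where(vals < 0.0, vals, 0.0).sum(axis=1)
    pos = np.where(vals > 0.0, vals, 0.0).sum(axis=1)

    def kde(x):
        if np.std(x) < 1e-12:
            return None
        return stats.gaussian_kde(x)  # Scott's rule

    return SignAsymmetry(
        negative_sums=neg,
        positive_sums=pos,
        asymmetry=float(pos.mean() - np.abs(neg).mean()),
        kde_negative=kde(neg),
        kde_positive=kde(pos),
    )


def swapped_tail_ks(a: SignAsymmetry, b: SignAsymmetry) -> dict:
    """Two-sample KS tests comparing sign-asymmetry tails of two ensembles.

    Compares b's positive sums against a's positive sums and likewise for
    the negative tails; additionally tests b's positive tail against the
    mirror of its own negative tail (symmetric ensembles pass the latter).
    """
    pos = stats.ks_2samp(a.positive_sums, b.positive_sums)
    neg = stats.ks_2samp(a.negative_sums, b.negative_sums)
    self_sym = stats.ks_2samp(b.positive_sums, -b.negative_sums)
    return {
        "positive": {"statistic": pos.statistic, "pvalue": pos.pvalue},
        "negative": {"statistic": neg.statistic, "pvalue": neg.pvalue},
        "self_symmetry": {
            "statistic": self_sym.statistic,
            "pvalue": self_sym.pvalue,
        },
    }


def frechet_distance(features_a: np.ndarray, features_b: np.ndarray) -> float:
    """Fréchet distance between Gaussian fits of two feature samples.

    ``‖μ_A − μ_B‖² + tr(Σ_A + Σ_B − 2 (Σ_A Σ_B)^{1/2})``; symmetric,
    nonnegative, zero iff the fitted Gaussians coincide.  Near-singular
    covariances get a small diagonal jitter with a warning.
    """
    a = np.atleast_2d(np.asarray(features_a, dtype=np.float64))
    b = np.atleast_2d(np.asarray(features_b, dtype=np.float64))
    d = a.shape[1]
    if a.shape[0] <= d or b.shape[0] <= d:
        raise ParameterError("need more samples than feature dimensions")
    mu_a, mu_b = a.mean(axis=0), b.mean(axis=0)
    ca = np.cov(a, rowvar=False).reshape(d, d)
    cb = np.cov(b, rowvar=False).reshape(d, d)
    prod = ca @ cb
    sq, _ = scipy.linalg.sqrtm(prod, disp=False)
    if not np.all(np.isfinite(sq)):
        warnings.warn("singular covariances: adding diagonal jitter")
        jitter = 1e-9 * np.eye(d)
        sq, _ = scipy.linalg.sqrtm((ca + jitter) @ (cb + jitter), disp=False)
    sq = np.real(sq)
    val = float(np.sum((mu_a - mu_b) ** 2) + np.trace(ca + cb - 2.0 * sq))
    return max(val, 0.0)


def radius_of_gyration(ensemble: ChainCoordinates) -> np.ndarray:
    """Per-frame radius of gyration of the bead trace (parity-even)."""
    pos = ensemble.positions
    centered = pos - pos.mean(axis=1, keepdims=True)
    return np.sqrt((centered**2).sum(axis=-1).mean(axis=1))


def bend_angle(ensemble: ChainCoordinates, i: int = 0, j: int | None = None,
               k: int | None = None) -> np.ndarray:
    """Per-frame bend angle (rad) at bead j formed with beads i and k.

    Defaults to first–middle–last; parity-even, so mirror-image ensembles
    have identical distributions.
    """
    n = ensemble.n_atoms
    j = n // 2 if j is None else j
    k = n - 1 if k is None else k
    pos = ensemble.positions
    u = pos[:, i] - pos[:, j]
    v = pos[:, k] - pos[:, j]
    cosang = np.einsum("fi,fi->f", u, v) / (
        np.linalg.norm(u, axis=1) * np.linalg.norm(v, axis=1)
    )
    return np.arccos(np.clip(cosang, -1.0, 1.0))
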