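"""Markov state models: discretization, estimation, validation, and
transition-path observables.

The workflow mirrors standard practice for conformational kinetics:
K-means discretization of low-dimensional tCCA projections, sliding-window
transition counts at a lag time, reversible maximum-likelihood estimation
of the transition matrix on the largest connected set, and validation via
implied timescales (lag-invariance), the Chapman-Kolmogorov test, and
cross-validated VAMP-2 scores.  Metastable coarse-graining uses a
PCCA-style spectral simplex transformation of the leading eigenvectors;
mean first passage times and reactive fluxes come from transition path
theory; uncertainty from trajectory/block bootstrap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.linalg
from scipy.sparse.csgraph import connected_components
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .chain import ParameterError


# ---------------------------------------------------------------------------
# discretization
# ---------------------------------------------------------------------------

@dataclass
class Discretization:
    centers: np.ndarray  # (k, n_components)
    assignments: list[np.ndarray]  # per trajectory
    seed: int

    @property
    def n_states(self) -> int:
        return self.centers.shape[0]


def _as_traj_list(projections) -> list[np.ndarray]:
    if isinstance(projections, (list, tuple)):
        arrs = [np.asarray(p, dtype=np.float64) for p in projections]
    else:
        arrs = [np.asarray(projections, dtype=np.float64)]
    return [a[:, None] if a.ndim == 1 else a for a in arrs]


def discretize(projections, k: int, seed: int = 0, n_init: int = 10) -> Discretization:
    """K-means (k-means++ seeding, fixed seed) on pooled projections."""
    trajs = _as_traj_list(projections)
    pooled = np.vstack(trajs)
    if k >= len(pooled):
        raise ParameterError(f"k={k} must be < total frames {len(pooled)}")
    km = KMeans(n_clusters=k, init="k-means++", n_init=n_init, random_state=seed)
    km.fit(pooled)
    if len(np.unique(km.labels_)) < k:
        km = KMeans(n_clusters=k, init="k-means++", n_init=n_init,
                    random_state=seed + 1)
        km.fit(pooled)
        if len(np.unique(km.labels_)) < k:
            raise ParameterError("empty cluster after re-seeding")
    assignments, start = [], 0
    for t in trajs:
        assignments.append(km.labels_[start: start + len(t)].copy())
        start += len(t)
    return Discretization(centers=km.cluster_centers_, assignments=assignments,
                          seed=seed)


def silhouette_scan(
    projection, k_values, seed: int = 0, subsample: int = 10000
) -> dict[int, float]:
    """Mean silhouette score of K-means clusterings for each k.

    Frames are capped at ``subsample`` (seeded) to bound the O(n^2)
    silhouette cost.
    """
    trajs = _as_traj_list(projection)
    pooled = np.vstack(trajs)
    if np.allclose(pooled, pooled[0]):
        raise ParameterError("all points identical: silhouette undefined")
    rng = np.random.default_rng(seed)
    if len(pooled) > subsample:
        idx = rng.choice(len(pooled), size=subsample, replace=False)
        pooled = pooled[idx]
    scores = {}
    for k in k_values:
        if not (2 <= k < len(pooled)):
            raise ParameterError(f"k={k} outside [2, n_frames)")
        km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(pooled)
        scores[k] = float(silhouette_score(pooled, km.labels_))
    return scores


# ---------------------------------------------------------------------------
# MSM estimation
# ---------------------------------------------------------------------------

@dataclass
class MarkovModel:
    """Reversible (by default) maximum-likelihood Markov state model."""

    lag: int
    counts: np.ndarray  # full k x k count matrix
    transition_matrix: np.ndarray  # on the active set
    stationary_distribution: np.ndarray
    active_set: np.ndarray  # original state indices
    reversible: bool
    lag_unit_ns: float = 1.0

    @property
    def n_states(self) -> int:
        return self.transition_matrix.shape[0]

    def eigenvalues(self, k: int | None = None) -> np.ndarray:
        """Transition-matrix eigenvalues sorted by decreasing magnitude.

        For reversible models these are real; computed in the
        π-symmetrized basis for numerical symmetry.
        """
        T = self.transition_matrix
        if self.reversible:
            pi = self.stationary_distribution
            sqrt_pi = np.sqrt(pi)
            sym = (sqrt_pi[:, None] * T) / sqrt_pi[None, :]
            vals = scipy.linalg.eigvalsh(0.5 * (sym + sym.T))
            vals = vals[np.argsort(-vals)]
        else:
            vals = np.linalg.eigvals(T)
            vals = vals[np.argsort(-np.abs(vals))]
        return vals[:k] if k is not None else vals

    def map_assignments(self, assignments: np.ndarray) -> np.ndarray:
        """Map original state labels to active-set indices (-1 outside)."""
        lookup = -np.ones(self.counts.shape[0], dtype=np.int64)
        lookup[self.active_set] = np.arange(len(self.active_set))
        return lookup[assignments]


def count_matrix(assignments, n_states: int, lag: int) -> np.ndarray:
    """Sliding-window transition counts pooled over trajectories."""
    c = np.zeros((n_states, n_states))
    for a in assignments if isinstance(assignments, (list, tuple)) else [assignments]:
        a = np.asarray(a)
        if lag >= len(a):
            raise ParameterError(f"lag {lag} >= trajectory length {len(a)}")
        np.add.at(c, (a[:-lag], a[lag:]), 1.0)
    return c


def _largest_connected(counts: np.ndarray) -> np.ndarray:
    """States in the largest strongly connected component of the count graph."""
    adj = (counts > 0).astype(np.int8)
    n_comp, labels = connected_components(adj, directed=True, connection="strong")
    # weight components by total counts, not state number
    best, best_w = 0, -1.0
    for c in range(n_comp):
        idx = np.where(labels == c)[0]
        w = counts[np.ix_(idx, idx)].sum()
        if w > best_w:
            best, best_w = c, w
    return np.where(labels == best)[0]


def _reversible_mle(counts: np.ndarray, tol: float = 1e-10,
                    max_iter: int = 10000) -> tuple[np.ndarray, np.ndarray]:
    """Self-consistent iteration for the reversible ML transition matrix.

    Fixed-point update on the symmetric edge weights
    ``x_ij <- (c_ij + c_ji) / (c_i / x_i + c_j / x_j)``; the stationary
    distribution is the normalized row sum of x.
    """
    c = counts
    c_sym = c + c.T
    row = c.sum(axis=1)
    x = c_sym / c_sym.sum()
    for _ in range(max_iter):
        xi = x.sum(axis=1)
        q = row / xi
        x_new = c_sym / (q[:, None] + q[None, :])
        x_new /= x_new.sum()
        delta = np.abs(x_new - x).max()
        x = x_new
        if delta < tol:
            break
    pi = x.sum(axis=1)
    T = x / pi[:, None]
    return T, pi


def estimate_msm(
    assignments,
    lag: int,
    n_states: int | None = None,
    reversible: bool = True,
    lag_unit_ns: float = 1.0,
) -> MarkovModel:
    """Maximum-likelihood MSM at the given lag.

    Counts are restricted to the largest strongly connected set (logged via
    warning if states are dropped).  The reversible estimator iterates the
    self-consistent fixed point to 1e-10; the non-reversible estimator is
    the row-normalized count matrix.
    """
    traj_list = assignments if isinstance(assignments, (list, tuple)) else [assignments]
    if n_states is None:
        n_states = int(max(np.max(a) for a in traj_list)) + 1
    c = count_matrix(traj_list, n_states, lag)
    active = _largest_connected(c)
    if len(active) == 0:
        raise ParameterError("empty active set")
    if len(active) < n_states:
        warnings.warn(
            f"restricting to largest connected set: {len(active)}/{n_states} states"
        )
    ca = c[np.ix_(active, active)]
    if reversible:
        T, pi = _reversible_mle(ca)
    else:
        T = ca / ca.sum(axis=1, keepdims=True)
        vals, vecs = np.linalg.eig(T.T)
        i = np.argmin(np.abs(vals - 1.0))
        pi = np.real(vecs[:, i])
        pi = pi / pi.sum()
    return MarkovModel(
        lag=lag,
        counts=c,
        transition_matrix=T,
        stationary_distribution=pi,
        active_set=active,
        reversible=reversible,
        lag_unit_ns=lag_unit_ns,
    )


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

def implied_timescales(
    models: list[MarkovModel],
    n_timescales: int = 5,
    convergence_threshold: float = 0.10,
    cap: float = 1e12,
) -> dict:
    """Implied timescales t_i(τ) = −τ / ln λ_i across a series of lags.

    Timescales are in frames (multiply by the frame spacing for physical
    time).  Non-positive or >= 1 eigenvalues yield NaN / a capped value with
    a warning.  A timescale index is flagged converged when its relative
    change over the last three successive lags stays below the threshold.
    """
    lags = np.array([m.lag for m in models])
    its = np.full((len(models), n_timescales), np.nan)
    for r, m in enumerate(models):
        vals = m.eigenvalues(n_timescales + 1)[1:]  # skip stationary λ=1
        for i, lam in enumerate(vals[:n_timescales]):
            lam = float(np.real(lam))
            if lam <= 0.0:
                continue
            if lam >= 1.0:
                warnings.warn("eigenvalue >= 1: timescale capped")
                its[r, i] = cap
            else:
                its[r, i] = -m.lag / np.log(lam)
    converged = np.zeros(n_timescales, dtype=bool)
    if len(models) >= 3:
        tail = its[-3:]
        with np.errstate(invalid="ignore", divide="ignore"):
            rel = np.abs(np.diff(tail, axis=0)) / np.abs(tail[1:])
        converged = np.all(np.nan_to_num(rel, nan=np.inf) < convergence_threshold,
                           axis=0)
    return {"lags": lags, "timescales": its, "converged": converged}


def ck_test(
    model: MarkovModel,
    assignments,
    multiples=(2, 3, 4),
    memberships: np.ndarray | None = None,
) -> dict:
    """Chapman-Kolmogorov test: T(τ)^k vs T estimated at kτ.

    Transition probabilities are aggregated over metastable sets (crisp
    memberships; identity if none given) with stationary weighting.
    Returns the per-multiple predicted/estimated set-to-set probability
    matrices and the maximum absolute deviation.
    """
    traj_list = assignments if isinstance(assignments, (list, tuple)) else [assignments]
    n_full = model.counts.shape[0]
    if memberships is None:
        memberships = np.eye(model.n_states)
    chi = memberships
    pi = model.stationary_distribution
    # stationary-weighted aggregation operators
    w = chi * pi[:, None]
    w = w / w.sum(axis=0, keepdims=True)

    def coarse(T):
        return w.T @ T @ chi

    shortest = min(len(a) for a in traj_list)
    predicted, estimated, used = [coarse(np.eye(model.n_states))], [
        coarse(np.eye(model.n_states))
    ], [1]
    max_dev = 0.0
    for k in multiples:
        if k * model.lag >= shortest:
            warnings.warn(f"multiple {k}: kτ exceeds trajectory length; skipped")
            continue
        pred = coarse(np.linalg.matrix_power(model.transition_matrix, k))
        m_k = estimate_msm(traj_list, lag=k * model.lag, n_states=n_full,
                           reversible=model.reversible)
        # align state spaces: both restricted to the original active set
        lookup = -np.ones(n_full, dtype=int)
        lookup[m_k.active_set] = np.arange(len(m_k.active_set))
        common = lookup[model.active_set]
        if np.any(common < 0):
            warnings.warn(f"multiple {k}: active sets differ; skipped")
            continue
        est = coarse(m_k.transition_matrix[np.ix_(common, common)])
        predicted.append(pred)
        estimated.append(est)
        used.append(k)
        max_dev = max(max_dev, float(np.abs(pred - est).max()))
    return {
        "multiples": used,
        "predicted": predicted,
        "estimated": estimated,
        "max_deviation": max_dev,
    }


def _vamp2_score_on(test_assign, lag: int, n_states: int,
                    epsilon: float = 1e-12) -> float:
    """VAMP-2 of a trained state space evaluated on held-out pairs.

    The trained discretization's state indicator functions span the
    approximation space; the score is
    ‖(U^T C00 U)^{-1/2} U^T C0t V (V^T Ctt V)^{-1/2}‖_F² evaluated with
    test covariances, which for indicator features reduces to whitened
    count statistics on the test set.
    """
    c_test = count_matrix(test_assign, n_states, lag)
    n = c_test.sum()
    if n == 0:
        raise ParameterError("no held-out transition pairs")
    c00 = np.diag(c_test.sum(axis=1) / n)
    ctt = np.diag(c_test.sum(axis=0) / n)
    c0t = c_test / n
    d = n_states
    ridge = epsilon * np.eye(d)

    def inv_sqrt(c):
        vals, vecs = scipy.linalg.eigh(c + ridge)
        good = vals > 1e-12 * vals.max()
        inv = np.zeros_like(vals)
        inv[good] = 1.0 / np.sqrt(vals[good])
        return (vecs * inv) @ vecs.T

    k = inv_sqrt(c00) @ c0t @ inv_sqrt(ctt)
    s = np.linalg.svd(k, compute_uv=False)
    return float(np.sum(s**2))


def cv_vamp2(
    projections,
    k: int,
    lag: int,
    folds: int = 5,
    seed: int = 0,
    n_singular: int | None = None,
) -> dict:
    """5-fold cross-validated VAMP-2 score of a k-state MSM discretization.

    Trajectories (or contiguous blocks of a single trajectory — never
    frame-shuffled, to respect autocorrelation) are split into folds; the
    discretization is fit on training folds and the VAMP-2 score of the
    resulting state space is evaluated on held-out lagged pairs.
    """
    trajs = _as_traj_list(projections)
    if len(trajs) < folds:
        # split the (single or few) trajectories into contiguous blocks
        blocks = []
        for t in trajs:
            n_blk = int(np.ceil(folds / len(trajs)))
            edges = np.linspace(0, len(t), n_blk + 1).astype(int)
            blocks.extend(t[a:b] for a, b in zip(edges[:-1], edges[1:]) if b - a > lag)
        trajs = blocks
    if len(trajs) < folds:
        raise ParameterError("too few contiguous blocks for the requested folds")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(trajs))
    fold_of = np.empty(len(trajs), dtype=int)
    for rank, idx in enumerate(order):
        fold_of[idx] = rank % folds
    scores = []
    for f in range(folds):
        train = [t for t, ff in zip(trajs, fold_of) if ff != f]
        test = [t for t, ff in zip(trajs, fold_of) if ff == f]
        disc = discretize(train, k=k, seed=seed)
        km_centers = disc.centers
        test_assign = [
            np.argmin(
                ((t[:, None, :] - km_centers[None]) ** 2).sum(-1), axis=1
            )
            for t in test
        ]
        scores.append(_vamp2_score_on(test_assign, lag, k))
    scores = np.asarray(scores)
    return {"mean": float(scores.mean()), "sd": float(scores.std(ddof=1)),
            "scores": scores, "fold_of": fold_of}


# ---------------------------------------------------------------------------
# coarse-graining (PCCA-style)
# ---------------------------------------------------------------------------

def coarse_grain(model: MarkovModel, m: int) -> dict:
    """Fuzzy metastable memberships from the leading m eigenvectors.

    A PCCA-style inner-simplex construction: the leading right eigenvectors
    (in the π-weighted geometry) embed microstates near an (m-1)-simplex;
    vertices are located by successive farthest-point selection and
    memberships follow from the affine transformation onto barycentric
    coordinates, clipped to be nonnegative and renormalized.
    """
    if not (1 <= m <= model.n_states):
        raise ParameterError("m must satisfy 1 <= m <= n_states")
    if m == 1:
        chi = np.ones((model.n_states, 1))
        return {"memberships": chi, "assignments": np.zeros(model.n_states, int)}
    if m == model.n_states:
        chi = np.eye(m)
        return {"memberships": chi, "assignments": np.arange(m)}
    pi = model.stationary_distribution
    sqrt_pi = np.sqrt(pi)
    T = model.transition_matrix
    sym = (sqrt_pi[:, None] * T) / sqrt_pi[None, :]
    vals, vecs = scipy.linalg.eigh(0.5 * (sym + sym.T))
    order = np.argsort(-vals)
    vals = vals[order]
    if vals[m - 1] - vals[m] < 1e-12:
        raise ParameterError(
            f"degenerate eigenvalues at the m={m} cut; choose a different m"
        )
    # right eigenvectors of T
    psi = vecs[:, order[:m]] / sqrt_pi[:, None]
    psi /= np.sign(psi[0, 0]) if psi[0, 0] != 0 else 1.0
    # inner simplex: farthest-point vertex search
    verts = [int(np.argmax(np.linalg.norm(psi - psi.mean(0), axis=1)))]
    for _ in range(1, m):
        d = np.min(
            [np.linalg.norm(psi - psi[v], axis=1) for v in verts], axis=0
        )
        verts.append(int(np.argmax(d)))
    # the constant eigenvector is in the span, so the affine barycentric
    # map is linear in the eigenvector coordinates
    chi = psi @ np.linalg.inv(psi[verts])
    chi = np.clip(chi, 0.0, None)
    chi /= chi.sum(axis=1, keepdims=True)
    return {"memberships": chi, "assignments": np.argmax(chi, axis=1)}


# ---------------------------------------------------------------------------
# transition path theory
# ---------------------------------------------------------------------------

def tpt_observables(model: MarkovModel, source, sink) -> dict:
    """Committors, net reactive flux, and MFPT between state sets.

    ``source`` (A) and ``sink`` (B) are disjoint, nonempty index sets on
    the active state space.  The forward committor solves the standard
    linear system; net flux is ``max(0, f_ij - f_ji)`` with
    ``f_ij = π_i q⁻_i T_ij q⁺_j``; the MFPT solves the first-step system
    and is reported both in lag units and physical time, π-weighted over A.
    """
    A = np.unique(np.asarray(source, dtype=int))
    B = np.unique(np.asarray(sink, dtype=int))
    n = model.n_states
    if len(A) == 0 or len(B) == 0:
        raise ParameterError("source and sink must be nonempty")
    if np.intersect1d(A, B).size:
        raise ParameterError("source and sink must be disjoint")
    if len(A) + len(B) >= n:
        warnings.warn("A ∪ B covers all states: committor is trivial")
    T = model.transition_matrix
    pi = model.stationary_distribution

    # forward committor: q=0 on A, q=1 on B, (T - I) q = 0 elsewhere
    q_plus = np.zeros(n)
    q_plus[B] = 1.0
    inter = np.setdiff1d(np.arange(n), np.concatenate([A, B]))
    if len(inter):
        M = np.eye(len(inter)) - T[np.ix_(inter, inter)]
        rhs = T[np.ix_(inter, B)].sum(axis=1)
        q_plus[inter] = np.linalg.solve(M, rhs)

    # backward committor via the time-reversed chain
    T_rev = (pi[None, :] * T.T) / pi[:, None]
    q_minus = np.zeros(n)
    q_minus[A] = 1.0
    if len(inter):
        M = np.eye(len(inter)) - T_rev[np.ix_(inter, inter)]
        rhs = T_rev[np.ix_(inter, A)].sum(axis=1)
        q_minus[inter] = np.linalg.solve(M, rhs)

    flux = pi[:, None] * q_minus[:, None] * T * q_plus[None, :]
    np.fill_diagonal(flux, 0.0)
    net_flux = np.clip(flux - flux.T, 0.0, None)

    # MFPT to B by first-step analysis, in lag units
    m = np.zeros(n)
    notB = np.setdiff1d(np.arange(n), B)
    M = np.eye(len(notB)) - T[np.ix_(notB, notB)]
    m[notB] = np.linalg.solve(M, np.ones(len(notB)))
    mfpt_lag = float(np.sum(pi[A] * m[A]) / np.sum(pi[A]))
    return {
        "committor_forward": q_plus,
        "committor_backward": q_minus,
        "net_flux": net_flux,
        "total_flux": float(flux[A].sum() - flux[:, A].sum()),
        "mfpt_lag_units": mfpt_lag,
        "mfpt_frames": mfpt_lag * model.lag,
        "mfpt_ns": mfpt_lag * model.lag * model.lag_unit_ns,
    }


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------

def bootstrap_ci(
    trajectories,
    estimator,
    n_boot: int = 1000,
    seed: int = 0,
    confidence: float = 0.95,
    n_blocks: int = 10,
) -> dict:
    """Percentile bootstrap CI by resampling trajectories (or blocks).

    A single trajectory is cut into ``n_blocks`` contiguous blocks first.
    ``estimator`` maps a list of trajectories to a scalar or array;
    replicates where it raises are dropped (count reported).
    """
    trajs = trajectories if isinstance(trajectories, (list, tuple)) else [trajectories]
    trajs = [np.asarray(t) for t in trajs]
    if len(trajs) < 2:
        t = trajs[0]
        edges = np.linspace(0, len(t), n_blocks + 1).astype(int)
        trajs = [t[a:b] for a, b in zip(edges[:-1], edges[1:]) if b > a]
    rng = np.random.default_rng(seed)
    reps, failed = [], 0
    for _ in range(n_boot):
        pick = rng.integers(0, len(trajs), size=len(trajs))
        sample = [trajs[i] for i in pick]
        try:
            reps.append(np.asarray(estimator(sample), dtype=np.float64))
        except Exception:
            failed += 1
    if not reps:
        raise ParameterError("estimator failed on every bootstrap replicate")
    reps = np.stack(reps)
    alpha = (1.0 - confidence) / 2.0
    lo = np.quantile(reps, alpha, axis=0)
    hi = np.quantile(reps, 1.0 - alpha, axis=0)
    return {
        "lower": lo,
        "upper": hi,
        "replicates": reps,
        "n_failed": failed,
        "point": np.median(reps, axis=0),
    }


# ---------------------------------------------------------------------------
# hyperparameter grid scan
# ---------------------------------------------------------------------------

def grid_scan(
    tcca_projections_by_dim: dict[int, list[np.ndarray]],
    cluster_counts=(10, 20, 40, 60, 80, 100),
    lags=(1, 2, 5, 10),
    seed: int = 0,
    cv_folds: int = 5,
    its_index: int = 0,
) -> list[dict]:
    """Sweep tCCA dimension x cluster count x lag, as used for model selection.

    For each (dim, k) cell an MSM series over ``lags`` is estimated; the
    report carries the largest implied timescale per lag, its convergence
    flag, and the cross-validated VAMP-2 score at the shortest lag.
    """
    report = []
    for dim, projections in sorted(tcca_projections_by_dim.items()):
        for k in cluster_counts:
            disc = discretize(projections, k=k, seed=seed)
            models = [estimate_msm(disc.assignments, lag=lag) for lag in lags]
            its = implied_timescales(models, n_timescales=1)
            try:
                cv = cv_vamp2(projections, k=k, lag=lags[0], folds=cv_folds,
                              seed=seed)
                cv_mean, cv_sd = cv["mean"], cv["sd"]
            except ParameterError:
                cv_mean, cv_sd = np.nan, np.nan
            report.append(
                {
                    "dim": dim,
                    "k": k,
                    "lags": list(lags),
                    "largest_its": its["timescales"][:, its_index].tolist(),
                    "converged": bool(its["converged"][its_index]),
                    "cv_vamp2_mean": cv_mean,
                    "cv_vamp2_sd": cv_sd,
                }
            )
    return report
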