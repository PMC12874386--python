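"""Synthetic chain ensembles with known topology and kinetics.

Everything downstream — writhe oracles, tCCA/MSM recovery, and generative
model training — is exercised on the fixtures generated here:

* canonical parametric curves (helices, circles, a Hopf link, a planar
  zig-zag) whose writhe or linking number is known exactly;
* chiral helical-fragment ensembles with a controlled handedness bias,
  emulating an ensemble with asymmetric populations of positive- and
  negative-writhe chain crossings;
* a two-state switching polymer whose hidden states are mirror images of
  each other: identical in every Euclidean distance, opposite in writhe,
  with analytic relaxation time ``-1 / ln(1 - k12 - k21)`` frames.

All generators are seeded and deterministic; geometric defaults (3.8 Å
virtual bonds, 0.3 Å jitter) match a Cα-trace polymer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .chain import ChainCoordinates, ParameterError

BOND_LENGTH = 3.8  # Å, Cα-Cα virtual bond


@dataclass
class FixtureSpec:
    """Parameters of a synthetic ensemble."""

    n_atoms: int = 10
    n_frames: int = 1000
    seed: int = 0
    bond_length: float = BOND_LENGTH
    jitter: float = 0.3  # Å, within-state Gaussian noise
    handedness_bias: float = 0.8  # P(negative-writhe state)
    k12: float = 0.01  # per-frame switching rates (two-state fixture)
    k21: float = 0.01


# ---------------------------------------------------------------------------
# canonical curves
# ---------------------------------------------------------------------------

def _helix_points(resolution: int, turns: float, radius: float, pitch: float,
                  right_handed: bool = True) -> np.ndarray:
    t = np.linspace(0.0, 2.0 * np.pi * turns, resolution)
    z = pitch * t
    if not right_handed:
        z = -z
    return np.stack([radius * np.cos(t), radius * np.sin(t), z], axis=1)


def canonical_curves(name: str, resolution: int = 64, **kwargs):
    """Deterministic parametric point sets with known writhe properties.

    Parameters
    ----------
    name : {"helix", "circle", "hopf_link", "planar_zigzag"}
    resolution : number of sample points (per circle for the Hopf link)

    Returns
    -------
    ndarray (n, 3), or a tuple of two such arrays for ``hopf_link`` (two
    interlocked unit circles in orthogonal planes, centers 1 apart).
    """
    if resolution < 8:
        raise ParameterError("resolution must be >= 8")
    if name == "helix":
        return _helix_points(
            resolution,
            turns=kwargs.get("turns", 2.0),
            radius=kwargs.get("radius", 1.0),
            pitch=kwargs.get("pitch", 0.1),
            right_handed=kwargs.get("right_handed", True),
        )
    if name == "circle":
        t = np.linspace(0.0, 2.0 * np.pi, resolution, endpoint=False)
        return np.stack([np.cos(t), np.sin(t), np.zeros_like(t)], axis=1)
    if name == "hopf_link":
        t = np.linspace(0.0, 2.0 * np.pi, resolution, endpoint=False)
        a = np.stack([np.cos(t), np.sin(t), np.zeros_like(t)], axis=1)
        b = np.stack([1.0 + np.cos(t), np.zeros_like(t), np.sin(t)], axis=1)
        return a, b
    if name == "planar_zigzag":
        x = BOND_LENGTH * 0.9 * np.arange(resolution)
        y = BOND_LENGTH * 0.44 * (np.arange(resolution) % 2)
        return np.stack([x, y, np.zeros_like(x)], axis=1)
    raise ParameterError(f"unknown canonical curve {name!r}")


# ---------------------------------------------------------------------------
# chiral helical-fragment templates
# ---------------------------------------------------------------------------

def helical_fragment(n_atoms: int, bond_length: float = BOND_LENGTH,
                     turn_deg: float = 100.0, rise: float = 1.5,
                     negative_writhe: bool = True) -> np.ndarray:
    """Cα-trace helical fragment with exact virtual-bond length.

    ``turn_deg`` and ``rise`` follow α-helix-like geometry (~3.6 residues
    per turn, 1.5 Å rise); the radius is solved so consecutive beads are
    exactly ``bond_length`` apart.  ``negative_writhe=True`` yields the
    handedness whose total writhe (l=1) is negative under this package's
    sign convention; the other handedness is its exact mirror image.
    """
    theta = np.deg2rad(turn_deg)
    chord_sq = bond_length**2 - rise**2
    if chord_sq <= 0:
        raise ParameterError("rise must be smaller than bond length")
    radius = np.sqrt(chord_sq) / (2.0 * np.sin(theta / 2.0))
    k = np.arange(n_atoms)
    pts = np.stack(
        [radius * np.cos(k * theta), radius * np.sin(k * theta), rise * k],
        axis=1,
    )
    pts -= pts.mean(axis=0)
    # the right-handed template has negative total writhe under this
    # package's sign convention; mirror for the positive form
    if not negative_writhe:
        pts = pts * np.array([1.0, 1.0, -1.0])
    return pts


def hairpin_template(n_atoms: int, bond_length: float = BOND_LENGTH,
                     negative_writhe: bool = True) -> np.ndarray:
    """Open loop whose termini pass over each other: one clear crossing.

    A 1.25-turn low-pitch helix — a curved hairpin whose single crossing has
    a definite sign; the mirror image has the opposite crossing.
    """
    turns = 1.25
    theta = 2.0 * np.pi * turns / (n_atoms - 1)
    rise = 0.35 * bond_length
    chord_sq = bond_length**2 - rise**2
    radius = np.sqrt(chord_sq) / (2.0 * np.sin(theta / 2.0))
    k = np.arange(n_atoms)
    pts = np.stack(
        [radius * np.cos(k * theta), radius * np.sin(k * theta), rise * k],
        axis=1,
    )
    pts -= pts.mean(axis=0)
    if not negative_writhe:
        pts = pts * np.array([1.0, 1.0, -1.0])
    return pts


# ---------------------------------------------------------------------------
# ensembles
# ---------------------------------------------------------------------------

def _random_rotations(rng: np.random.Generator, n: int) -> np.ndarray:
    """Uniform random proper rotation matrices (QR with sign fix)."""
    mats = rng.normal(size=(n, 3, 3))
    out = np.empty_like(mats)
    for i, m in enumerate(mats):
        q, r = np.linalg.qr(m)
        q *= np.sign(np.diag(r))
        if np.linalg.det(q) < 0:
            q[:, 0] *= -1
        out[i] = q
    return out


def chiral_chain_ensemble(spec: FixtureSpec, rotate: bool = True):
    """Noisy helical fragments with biased handedness.

    Each frame is the helical-fragment template in one of its two mirror
    forms — the negative-writhe form drawn with probability
    ``spec.handedness_bias`` — plus isotropic Gaussian jitter and (by
    default) a random global rotation.

    Returns
    -------
    coords : ChainCoordinates
    meta : dict with ``is_negative`` per-frame bools and the two templates.
    """
    p = spec.handedness_bias
    if not (0.0 <= p <= 1.0):
        raise ParameterError("handedness bias must lie in [0, 1]")
    if spec.n_atoms < 6:
        raise ParameterError("need >= 6 atoms for a resolvable crossing")
    rng = np.random.default_rng(spec.seed)
    neg = helical_fragment(spec.n_atoms, spec.bond_length, negative_writhe=True)
    pos = neg * np.array([1.0, 1.0, -1.0])
    is_negative = rng.random(spec.n_frames) < p
    frames = np.where(is_negative[:, None, None], neg[None], pos[None])
    frames = frames + rng.normal(scale=spec.jitter, size=frames.shape)
    if rotate:
        rots = _random_rotations(rng, spec.n_frames)
        frames = np.einsum("fij,faj->fai", rots, frames)
    meta = {
        "is_negative": is_negative,
        "template_negative": neg,
        "template_positive": pos,
        "handedness_bias": p,
        "seed": spec.seed,
    }
    return ChainCoordinates(frames), meta


def two_state_polymer(spec: FixtureSpec, rotate: bool = False):
    """Hidden two-state switching polymer with mirror-image states.

    State 0 is a hairpin with a negative-writhe crossing; state 1 is its
    exact mirror image.  The hidden state follows a two-state Markov chain
    with per-frame switching probabilities ``k12`` (0→1) and ``k21`` (1→0),
    so the slow relaxation time is ``-1 / ln(1 - k12 - k21)`` frames.
    Because the states are mirror images, every Euclidean distance has
    identical statistics in both states — only parity-odd features (writhe)
    can resolve the transition.

    Returns
    -------
    coords : ChainCoordinates
    labels : ndarray of hidden states (0/1) per frame
    meta : dict with templates, rates, and the analytic relaxation time.
    """
    k12, k21 = spec.k12, spec.k21
    if k12 <= 0 or k21 <= 0:
        raise ParameterError("switching rates must be positive")
    if k12 + k21 >= 1.0:
        raise ParameterError("k12 + k21 must be < 1")
    rng = np.random.default_rng(spec.seed)
    t0 = hairpin_template(spec.n_atoms, spec.bond_length, negative_writhe=True)
    t1 = t0 * np.array([1.0, 1.0, -1.0])
    labels = np.empty(spec.n_frames, dtype=np.int64)
    # start from the stationary distribution
    labels[0] = int(rng.random() < k12 / (k12 + k21))
    u = rng.random(spec.n_frames)
    for t in range(1, spec.n_frames):
        prev = labels[t - 1]
        flip = u[t] < (k12 if prev == 0 else k21)
        labels[t] = 1 - prev if flip else prev
    frames = np.where(labels[:, None, None] == 0, t0[None], t1[None])
    frames = frames + rng.normal(scale=spec.jitter, size=frames.shape)
    if rotate:
        rots = _random_rotations(rng, spec.n_frames)
        frames = np.einsum("fij,faj->fai", rots, frames)
    meta = {
        "template_state0": t0,
        "template_state1": t1,
        "k12": k12,
        "k21": k21,
        "relaxation_time_frames": -1.0 / np.log(1.0 - k12 - k21),
        "seed": spec.seed,
    }
    return ChainCoordinates(frames), labels, meta
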