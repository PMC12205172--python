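"""Simulated two-modality benchmarks with planted manifold ambiguity.

Four synthetic designs mimic single-cell differentiation geometries:

* ``t_branch`` — three unit segments in a T; the two collinear arms are
  exact mirror images (one congruent pair -> two substitutable regions).
* ``y_branch`` — three arms at 120 degrees, all congruent by rotation.
* ``x_branch`` — four arms at 90 degrees, all congruent by rotation.
* ``decay_path`` — a single hook-shaped arc with exponentially decaying
  sampling density and no congruent disjoint segments: the negative
  control, uniquely alignable.

Each dataset carries two modalities observing the same cells: the shared
2-D latent coordinates are lifted to ``px``- and ``py``-dimensional feature
spaces by independent random linear maps with orthonormalized columns
(scaled by sqrt(p) so individual features have unit-order magnitude), then
i.i.d. Gaussian noise with standard deviation ``noise_sd`` is added to the
features.  Identity cell-cell correspondence and branch labels are
returned as ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .manifold import ModalityData

__all__ = [
    "SimulatedPair",
    "simulate_branch_dataset",
    "simulate_decay_path",
    "simulate",
    "BRANCH_SHAPES",
]

BRANCH_SHAPES = ("t_branch", "y_branch", "x_branch")


@dataclass
class SimulatedPair:
    """Two modalities over the same cells with ground truth."""

    modality_x: ModalityData
    modality_y: ModalityData
    manifold_coords_x: np.ndarray
    manifold_coords_y: np.ndarray
    correspondence: np.ndarray  # identity pairing: cell i <-> cell i
    branch_labels: np.ndarray
    shape: str
    seed: int

    @property
    def n_cells(self) -> int:
        return self.modality_x.n_cells


def _lift(latent: np.ndarray, p_dim: int, noise_sd: float, rng: np.random.Generator) -> np.ndarray:
    """Isometric (up to scale) random lift of 2-D latent coords to p_dim."""
    G = rng.standard_normal((p_dim, latent.shape[1]))
    Q, _ = np.linalg.qr(G)  # orthonormal columns: distances preserved
    feats = latent @ (np.sqrt(p_dim) * Q).T
    return feats + noise_sd * rng.standard_normal(feats.shape)


def _branch_arms(shape: str) -> list[tuple[np.ndarray, float]]:
    """(unit direction, length) per arm, all arms rooted at the origin.

    Geodesic distances on a star graph are blind to the angles between
    arms, so equal-length arms would all be mutually congruent in the
    geodesic metric regardless of geometry.  The T therefore gets a
    longer stem: only its two collinear arms are congruent, as intended.
    """
    if shape == "t_branch":
        # two collinear, mirror-congruent arms plus a longer stem
        return [
            (np.array([-1.0, 0.0]), 1.0),
            (np.array([1.0, 0.0]), 1.0),
            (np.array([0.0, -1.0]), 1.5),
        ]
    if shape == "y_branch":
        angles = np.deg2rad([90.0, 210.0, 330.0])
        return [(np.array([np.cos(a), np.sin(a)]), 1.0) for a in angles]
    if shape == "x_branch":
        angles = np.deg2rad([0.0, 90.0, 180.0, 270.0])
        return [(np.array([np.cos(a), np.sin(a)]), 1.0) for a in angles]
    raise ValueError(f"unknown branch shape {shape!r}; expected one of {BRANCH_SHAPES}")


def simulate_branch_dataset(
    shape: str,
    n: int = 300,
    px: int = 1000,
    py: int = 2000,
    noise_sd: float = 0.1,
    seed: int = 0,
) -> SimulatedPair:
    """Branching dataset with exactly congruent (hence ambiguous) arms.

    The congruent arms reuse a single draw of arc-length parameters, so
    their latent point sets are identical up to the generating rotation or
    reflection (exact to machine precision); the whole point set therefore
    admits the arm-exchanging isometry that creates the planted ambiguity.
    For ``t_branch`` the perpendicular stem draws its own parameters and
    takes no part in any congruence.
    """
    arms = _branch_arms(shape)
    n_branches = len(arms)
    if n % n_branches != 0:
        raise ValueError(f"n={n} must be divisible by the branch count {n_branches}")
    per = n // n_branches
    rng = np.random.default_rng(seed)

    t_shared = rng.uniform(0.02, 1.0, size=per)  # offset keeps arms disjoint
    latent_parts = []
    labels = []
    for b, (direction, length) in enumerate(arms):
        if shape == "t_branch" and b == 2:
            t = rng.uniform(0.02, 1.0, size=per)  # stem: independent draw
        else:
            t = t_shared
        latent_parts.append(np.outer(length * t, direction))
        labels.extend([f"branch{b}"] * per)
    latent = np.vstack(latent_parts)
    labels = np.asarray(labels)

    X = _lift(latent, px, noise_sd, rng)
    Y = _lift(latent, py, noise_sd, rng)
    return SimulatedPair(
        modality_x=ModalityData(X, labels=labels),
        modality_y=ModalityData(Y, labels=labels),
        manifold_coords_x=latent.copy(),
        manifold_coords_y=latent.copy(),
        correspondence=np.arange(n),
        branch_labels=labels,
        shape=shape,
        seed=seed,
    )


# decay profile: rate such that first-to-last arc-length-quartile cell
# count ratio is ~4 (solves (1-exp(-l/4)) / (exp(-3l/4)-exp(-l)) = 4)
_DECAY_LAMBDA = 1.85


def _hook_curve(s: np.ndarray) -> np.ndarray:
    """Arc-length parametrization of a J-shaped hook.

    Straight segment of length 2 from (0, 2) down to (0, 0), then a
    semicircular hook of radius 0.5 around (0.5, 0).  Total length
    2 + pi/2; the straight and curved parts are incongruent, so no two
    disjoint segments of the curve match geometrically.
    """
    s = np.asarray(s, dtype=float)
    pts = np.empty((s.size, 2))
    straight = s <= 2.0
    pts[straight, 0] = 0.0
    pts[straight, 1] = 2.0 - s[straight]
    arc = ~straight
    theta = (s[arc] - 2.0) / 0.5  # 0 .. pi
    pts[arc, 0] = 0.5 - 0.5 * np.cos(theta)
    pts[arc, 1] = -0.5 * np.sin(theta)
    return pts


def simulate_decay_path(
    n: int = 300,
    px: int = 1000,
    py: int = 2000,
    noise_sd: float = 0.1,
    seed: int = 0,
) -> SimulatedPair:
    """Hook-shaped path with decaying density: the unambiguous control.

    Cells are placed along the hook by inverse-CDF sampling of a truncated
    exponential over arc length, so density decays monotonically from the
    straight end into the hook; labels record the arc-length quartile.
    """
    rng = np.random.default_rng(seed)
    L = 2.0 + np.pi / 2.0
    u = rng.uniform(size=n)
    # truncated exponential on [0, L], rate lambda/L
    s = -(L / _DECAY_LAMBDA) * np.log1p(-u * (1.0 - np.exp(-_DECAY_LAMBDA)))
    latent = _hook_curve(s)
    quartile = np.minimum((s / (L / 4)).astype(int), 3)
    labels = np.asarray([f"q{qi}" for qi in quartile])

    X = _lift(latent, px, noise_sd, rng)
    Y = _lift(latent, py, noise_sd, rng)
    return SimulatedPair(
        modality_x=ModalityData(X, labels=labels),
        modality_y=ModalityData(Y, labels=labels),
        manifold_coords_x=latent.copy(),
        manifold_coords_y=latent.copy(),
        correspondence=np.arange(n),
        branch_labels=labels,
        shape="decay_path",
        seed=seed,
    )


def simulate(
    shape: str,
    n: int = 300,
    px: int = 1000,
    py: int = 2000,
    noise_sd: float = 0.1,
    seed: int = 0,
) -> SimulatedPair:
    """Dispatch on shape name (``t_branch``/``y_branch``/``x_branch``/``decay_path``)."""
    if shape == "decay_path":
        return simulate_decay_path(n=n, px=px, py=py, noise_sd=noise_sd, seed=seed)
    return simulate_branch_dataset(shape, n=n, px=px, py=py, noise_sd=noise_sd, seed=seed)
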