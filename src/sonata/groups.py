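"""Aggregation of ambiguous cell pairs into substitutable cell groups.

Significant ambiguous pairs become cannot-link constraints: two cells the
manifold confuses must sit in *different* groups, because the groups are
the units that substitute for one another during integration.  Cells
participating in at least one constraint are clustered COP-k-means-style
(greedy constraint-respecting nearest-centroid with restarts) in a 2-D
classical-MDS embedding of their geodesic submatrix; the group count is
picked where the violated-constraint curve plateaus (elbow).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.cluster import kmeans_plusplus

from .ambiguity import AmbiguityResult
from .manifold import GeodesicMatrix

__all__ = [
    "ConstraintSet",
    "ElbowCurve",
    "AmbiguousGroupSet",
    "classical_mds",
    "cluster_with_constraints",
    "select_n_groups",
    "find_ambiguous_groups",
]


@dataclass
class ConstraintSet:
    """Cannot-link constraints: unordered pairs of cell indices."""

    cannot_link: set[tuple[int, int]]

    def __post_init__(self) -> None:
        norm = set()
        for i, j in self.cannot_link:
            if i == j:
                raise ValueError(f"self-pair ({i},{i}) is not a valid constraint")
            norm.add((min(i, j), max(i, j)))
        self.cannot_link = norm

    @property
    def cells(self) -> np.ndarray:
        """Sorted unique cell indices appearing in any constraint."""
        if not self.cannot_link:
            return np.array([], dtype=int)
        return np.unique([c for pair in self.cannot_link for c in pair])

    def __len__(self) -> int:
        return len(self.cannot_link)


@dataclass
class ElbowCurve:
    n_groups_tried: list[int]
    violations: list[int]


@dataclass
class AmbiguousGroupSet:
    """Disjoint substitutable cell groups; -1 marks unambiguous cells."""

    assignment: np.ndarray  # length n_cells; group id or -1
    chosen_n_groups: int
    elbow: ElbowCurve | None = None

    @property
    def groups(self) -> dict[int, np.ndarray]:
        out = {}
        for gid in np.unique(self.assignment):
            if gid >= 0:
                out[int(gid)] = np.where(self.assignment == gid)[0]
        return out

    @property
    def is_empty(self) -> bool:
        return self.chosen_n_groups == 0

    def __len__(self) -> int:
        return len(self.groups)


def classical_mds(dist: np.ndarray, n_components: int = 2) -> np.ndarray:
    """Classical (Torgerson) MDS of a distance matrix.

    Deterministic eigendecomposition of the double-centered squared
    distances; negative eigenvalues (non-Euclidean distances) are dropped.
    """
    D2 = np.asarray(dist, dtype=float) ** 2
    n = D2.shape[0]
    J = np.eye(n) - np.full((n, n), 1.0 / n)
    B = -0.5 * J @ D2 @ J
    w, V = np.linalg.eigh(B)
    order = np.argsort(w)[::-1][:n_components]
    w_top = np.maximum(w[order], 0.0)
    coords = V[:, order] * np.sqrt(w_top)
    # sign convention for determinism: largest-magnitude coordinate positive
    for c in range(coords.shape[1]):
        k = np.argmax(np.abs(coords[:, c]))
        if coords[k, c] < 0:
            coords[:, c] = -coords[:, c]
    return coords


def _count_violations(labels: np.ndarray, pairs: np.ndarray) -> int:
    if pairs.size == 0:
        return 0
    return int((labels[pairs[:, 0]] == labels[pairs[:, 1]]).sum())


def cluster_with_constraints(
    embedding: np.ndarray,
    constraints: ConstraintSet | set | list,
    n_groups: int,
    seed: int = 0,
    n_restarts: int = 10,
    max_iter: int = 50,
) -> tuple[np.ndarray, int]:
    """COP-k-means: nearest-centroid assignment honoring cannot-links.

    ``embedding`` has one row per constrained cell; constraint pairs index
    into those rows.  Points are processed greedily: each goes to the
    nearest centroid among those not violating a cannot-link against
    already-assigned points this sweep, falling back to the overall
    nearest when every group violates (the violation is counted, not
    fatal).  Best of ``n_restarts`` by (violations, then inertia).
    """
    X = np.asarray(embedding, dtype=float)
    m = X.shape[0]
    if not isinstance(constraints, ConstraintSet):
        constraints = ConstraintSet(set(map(tuple, constraints)))
    if n_groups < 1:
        raise ValueError("n_groups must be >= 1")
    if n_groups > m:
        raise ValueError(f"n_groups={n_groups} exceeds number of cells {m}")
    pairs = (
        np.asarray(sorted(constraints.cannot_link), dtype=int)
        if len(constraints)
        else np.empty((0, 2), dtype=int)
    )
    # adjacency lists for the greedy feasibility check
    adj: list[list[int]] = [[] for _ in range(m)]
    for i, j in pairs:
        adj[i].append(j)
        adj[j].append(i)

    rng = np.random.default_rng(seed)
    best: tuple[int, float, np.ndarray] | None = None
    for restart in range(n_restarts):
        if n_groups == 1:
            centroids = X.mean(axis=0, keepdims=True)
        else:
            centroids, _ = kmeans_plusplus(
                X, n_clusters=n_groups, random_state=int(rng.integers(2**31))
            )
        labels = np.full(m, -1)
        order = rng.permutation(m)
        for _ in range(max_iter):
            new_labels = np.full(m, -1)
            d2 = ((X[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
            for idx in order:
                ranked = np.argsort(d2[idx], kind="stable")
                chosen = ranked[0]
                for c in ranked:
                    if all(new_labels[nb] != c for nb in adj[idx]):
                        chosen = c
                        break
                new_labels[idx] = chosen
            if (new_labels == labels).all():
                labels = new_labels
                break
            labels = new_labels
            for c in range(n_groups):
                mask = labels == c
                if mask.any():
                    centroids[c] = X[mask].mean(axis=0)
        viol = _count_violations(labels, pairs)
        inertia = float(((X - centroids[labels]) ** 2).sum())
        if best is None or (viol, inertia) < best[:2]:
            best = (viol, inertia, labels.copy())
    assert best is not None
    return best[2], best[0]


def select_n_groups(curve: ElbowCurve, resolved_frac: float = 0.05) -> int:
    """Elbow of the violations-vs-group-count curve.

    Primary rule: the smallest group count resolving at least
    ``1 - resolved_frac`` of the baseline (k=1) violations — the point
    where the curve has, for practical purposes, reached its plateau.
    When no count achieves that, falls back to the point of maximal
    vertical distance below the chord joining the curve's endpoints.
    Flat curve -> 1; fewer than 3 points -> argmin of violations;
    ties -> smaller count.
    """
    ks = np.asarray(curve.n_groups_tried)
    vs = np.asarray(curve.violations, dtype=float)
    if ks.size != vs.size:
        raise ValueError("curve arrays must have equal length")
    if ks.size < 3:
        return int(ks[np.argmin(vs)])
    if np.allclose(vs, vs[0]):
        return 1
    resolved = np.where(vs <= resolved_frac * vs[0])[0]
    if resolved.size:
        return int(ks[resolved[0]])
    # vertical distance below the chord from first to last point
    chord = vs[0] + (vs[-1] - vs[0]) * (ks - ks[0]) / (ks[-1] - ks[0])
    gap = chord - vs
    if gap.max() <= 0:
        return int(ks[np.argmin(vs)])
    return int(ks[np.argmax(gap)])  # argmax takes the first (smallest k) tie


def find_ambiguous_groups(
    result: AmbiguityResult,
    embedding: np.ndarray | GeodesicMatrix,
    Kmax: int = 8,
    seed: int = 0,
    strength_frac: float = 0.1,
) -> AmbiguousGroupSet:
    """Cluster constrained cells for k = 1..Kmax and pick the elbow.

    ``embedding`` may be per-cell coordinates (full modality) or a
    :class:`GeodesicMatrix`, in which case the constrained cells'
    submatrix is embedded by 2-D classical MDS.  Cells in no significant
    pair are labeled -1 (unambiguous).  Returns an empty group set when
    there are no significant pairs.

    Groups are built from the pairs that carry the ambiguity signal:
    significant pairs whose fold change is below ``strength_frac`` times
    the 90th-percentile fold of all significant pairs are left out of the
    constraint set.  Such pairs — orders of magnitude weaker than the
    headline signal — reflect partial local congruences (any two equal
    arc-length segments look alike) rather than substitutable regions;
    the relative cut is inert when all significant folds are comparable.
    """
    sig_mask = result.significant.copy()
    if sig_mask.any() and result.fold_change is not None and strength_frac > 0:
        fold = result.fold_change
        cut = strength_frac * np.quantile(fold[sig_mask], 0.9)
        sig_mask &= fold >= cut
    pairs = np.column_stack([result.cell_i[sig_mask], result.cell_j[sig_mask]])
    n_cells = int(max(result.cell_j.max(), result.cell_i.max())) + 1 if result.n_pairs else 0
    if pairs.shape[0] == 0:
        return AmbiguousGroupSet(
            assignment=np.full(n_cells, -1), chosen_n_groups=0, elbow=None
        )
    constraints = ConstraintSet(set(map(tuple, pairs.tolist())))
    cells = constraints.cells
    pos = {c: t for t, c in enumerate(cells)}
    local_pairs = {(pos[i], pos[j]) for i, j in constraints.cannot_link}

    if isinstance(embedding, GeodesicMatrix):
        coords = classical_mds(embedding.dist[np.ix_(cells, cells)])
    else:
        coords = np.asarray(embedding, dtype=float)[cells]

    rng = np.random.default_rng(seed)
    ks, viols, labelings = [], [], []
    kmax_eff = min(Kmax, cells.size)
    for k in range(1, kmax_eff + 1):
        labels, v = cluster_with_constraints(
            coords, local_pairs, k, seed=int(rng.integers(2**31))
        )
        ks.append(k)
        viols.append(v)
        labelings.append(labels)
    curve = ElbowCurve(n_groups_tried=ks, violations=viols)
    k_star = select_n_groups(curve)
    labels = labelings[ks.index(k_star)]

    assignment = np.full(n_cells, -1)
    assignment[cells] = labels
    return AmbiguousGroupSet(assignment=assignment, chosen_n_groups=k_star, elbow=curve)
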