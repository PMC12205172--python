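"""Alternative integration solutions from ambiguous group swaps.

Two substitutable cell groups Gs, Gt define a soft permutation P of the
source modality's cells: rows in Gs redistribute their mass onto Gt
according to the self-alignment coupling (and vice versa) while all other
cells stay put.  Applying P to an existing cross-modality coupling
``gamma_xy`` produces the alternative solution ``P @ gamma_xy`` — the
integration the original method would have reported had it resolved the
ambiguity the other way.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .ambiguity import NullSpline
from .groups import AmbiguousGroupSet
from .manifold import GeodesicMatrix
from .selfalign import Coupling

__all__ = ["SoftPermutation", "AlternativeSolution", "build_soft_permutation", "generate_alternatives"]


@dataclass
class SoftPermutation:
    """Row-stochastic group-swap matrix; identity off the swapped groups."""

    P: np.ndarray
    source_group: np.ndarray
    target_group: np.ndarray

    def __post_init__(self) -> None:
        P = np.asarray(self.P, dtype=float)
        if P.ndim != 2 or P.shape[0] != P.shape[1]:
            raise ValueError("P must be square")
        if (P < 0).any():
            raise ValueError("P must be nonnegative")
        if not np.allclose(P.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("P rows must sum to 1")
        self.P = P

    @property
    def n(self) -> int:
        return self.P.shape[0]


@dataclass
class AlternativeSolution:
    """A candidate cross-modality coupling with its provenance."""

    gamma_alt: np.ndarray
    name: str
    swapped_groups: tuple[int, int] | None = None
    scores: dict | None = None


def build_soft_permutation(
    Gs: np.ndarray,
    Gt: np.ndarray,
    self_coupling: np.ndarray,
    n_cells: int,
) -> SoftPermutation:
    """Assemble the group-swap matrix from the self-alignment coupling.

    Rows indexed by Gs carry the (renormalized) coupling mass toward Gt
    and vice versa; all other rows are identity.  The raw coupling rows
    generally do not sum to one, so each swapped row is rescaled — the
    result stays a transport-like (row-stochastic) operator.  A cell with
    no cross-group mass is mapped to the cell of the other group holding
    the most total cross-group mass (with a warning).
    """
    Gs = np.asarray(Gs, dtype=int)
    Gt = np.asarray(Gt, dtype=int)
    if Gs.size == 0 or Gt.size == 0:
        raise ValueError("groups must be nonempty")
    if np.intersect1d(Gs, Gt).size:
        raise ValueError("groups must be disjoint")
    C = np.asarray(self_coupling, dtype=float)
    if C.shape != (n_cells, n_cells):
        raise ValueError("self_coupling must be n_cells x n_cells")

    P = np.eye(n_cells)
    block = C[np.ix_(Gs, Gt)]
    # the argmax-mass fallback target for zero rows, per direction
    fallback_t = Gt[np.argmax(block.sum(axis=0))]
    fallback_s = Gs[np.argmax(block.sum(axis=1))]
    n_zero = 0
    for idx, others, fallback in ((Gs, Gt, fallback_t), (Gt, Gs, fallback_s)):
        for i in idx:
            row = C[i, others]
            tot = row.sum()
            P[i, :] = 0.0
            if tot <= 0:
                n_zero += 1
                P[i, fallback] = 1.0
            else:
                P[i, others] = row / tot
    if n_zero:
        warnings.warn(
            f"{n_zero} cells had no cross-group mass; mapped to the "
            "highest-mass cell of the opposite group",
            stacklevel=2,
        )
    return SoftPermutation(P=P, source_group=Gs, target_group=Gt)


def generate_alternatives(
    groups: AmbiguousGroupSet,
    self_coupling: np.ndarray,
    gamma_xy: Coupling | np.ndarray,
    null_spline: NullSpline | None = None,
    geodesic: GeodesicMatrix | np.ndarray | None = None,
) -> list[AlternativeSolution]:
    """One candidate per ambiguous group pair, plus the original.

    The original coupling is always first in the returned list (named
    ``"original"``) so users can compare candidates.  When ``null_spline``
    and ``geodesic`` are provided, a group pair yields a candidate only if
    its mean inter-group self-coupling mass exceeds the null expectation
    at the corresponding distances — group pairs the self-alignment never
    actually confused produce no alternative.  Candidates are emitted
    unranked: geometry cannot decide which solution is biologically true.
    """
    gamma = gamma_xy.gamma if isinstance(gamma_xy, Coupling) else np.asarray(gamma_xy)
    C = np.asarray(self_coupling, dtype=float)
    n = C.shape[0]
    if gamma.shape[0] != n:
        raise ValueError("gamma_xy rows must match the diagnosed modality")

    out = [AlternativeSolution(gamma_alt=gamma.copy(), name="original")]
    if groups.is_empty:
        return out

    Kd = None
    if geodesic is not None:
        Kd = np.asarray(
            geodesic.dist if isinstance(geodesic, GeodesicMatrix) else geodesic
        )
    gdict = groups.groups
    for s, t in combinations(sorted(gdict), 2):
        Gs, Gt = gdict[s], gdict[t]
        if null_spline is not None and Kd is not None:
            inter = C[np.ix_(Gs, Gt)]
            expected = np.asarray(null_spline(Kd[np.ix_(Gs, Gt)]))
            if inter.mean() <= expected.mean():
                continue  # groups never actually confused with each other
        P = build_soft_permutation(Gs, Gt, C, n)
        out.append(
            AlternativeSolution(
                gamma_alt=P.P @ gamma,
                name=f"swap_{s}_{t}",
                swapped_groups=(s, t),
            )
        )
    return out
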