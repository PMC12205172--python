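"""Gromov-Wasserstein self-alignment and baseline cross-modality alignment.

The Gromov-Wasserstein (GW) problem matches two metric spaces pair-to-pair:
given intra-space distance matrices ``K_src`` (n x n) and ``K_dst`` (m x m)
and marginals ``p``, ``q``, it seeks a coupling ``G`` in the transportation
polytope minimizing

    sum_{i,j,k,l} L(K_src[i,k], K_dst[j,l]) G[i,j] G[k,l]

For the quadratic loss ``L(a,b) = (a-b)^2 / 2`` the fourth-order tensor is
never materialized: the decomposition L(a,b) = a^2/2 + b^2/2 - a*b reduces
the inner product to two matrix products (Peyre-Cuturi-Solomon
factorization).  The solver is entropically regularized: each outer
iteration linearizes the objective at the current coupling and re-projects
with a log-stabilized Sinkhorn loop, warm-starting the dual potentials.

Self-alignment runs GW between a modality and noise-perturbed variational
copies of itself; where distant regions of the manifold are congruent, the
transported mass spreads over both the identity and the region-swapping
isometries, which is precisely the ambiguity signal diagnosed downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Callable

import numpy as np

from .manifold import (
    GeodesicMatrix,
    ModalityData,
    geodesics_from_points,
    make_variational,
)

__all__ = [
    "Coupling",
    "CostSpec",
    "QUADRATIC",
    "SelfAlignmentEnsemble",
    "gw_coupling",
    "self_align",
    "cross_modality_align",
    "default_k",
    "default_k_schedule",
]

MARGINAL_TOL = 1e-6


@dataclass
class CostSpec:
    """Pairwise ground loss with its low-rank tensor factorization.

    ``loss(a, b) = f1(a) + f2(b) - h1(a) * h2(b)`` must hold elementwise;
    the default is the quadratic loss ``(a - b)^2 / 2``.
    """

    name: str
    loss: Callable[[np.ndarray, np.ndarray], np.ndarray]
    f1: Callable[[np.ndarray], np.ndarray]
    f2: Callable[[np.ndarray], np.ndarray]
    h1: Callable[[np.ndarray], np.ndarray]
    h2: Callable[[np.ndarray], np.ndarray]


QUADRATIC = CostSpec(
    name="quadratic",
    loss=lambda a, b: 0.5 * (a - b) ** 2,
    f1=lambda a: 0.5 * a**2,
    f2=lambda b: 0.5 * b**2,
    h1=lambda a: a,
    h2=lambda b: b,
)


@dataclass
class Coupling:
    """Nonnegative matrix with prescribed row/column marginals.

    ``gamma[i, j]`` is the correspondence probability between cell ``i`` of
    the source space and cell ``j`` of the destination space.
    """

    gamma: np.ndarray
    row_marginal: np.ndarray
    col_marginal: np.ndarray
    objective: float = np.nan
    converged: bool = True
    objective_history: list[float] = field(default_factory=list)
    epsilon: float = np.nan

    def __post_init__(self) -> None:
        g = np.asarray(self.gamma, dtype=float)
        p = np.asarray(self.row_marginal, dtype=float)
        q = np.asarray(self.col_marginal, dtype=float)
        if g.shape != (p.size, q.size):
            raise ValueError("gamma shape must match marginal lengths")
        if (g < -1e-12).any():
            raise ValueError("coupling entries must be nonnegative")
        if not (
            np.allclose(g.sum(axis=1), p, atol=MARGINAL_TOL)
            and np.allclose(g.sum(axis=0), q, atol=MARGINAL_TOL)
        ):
            raise ValueError(f"marginal constraints violated beyond {MARGINAL_TOL}")
        self.gamma, self.row_marginal, self.col_marginal = g, p, q

    @property
    def shape(self) -> tuple[int, int]:
        return self.gamma.shape

    def hardened(self) -> np.ndarray:
        """Row-argmax assignment (source index -> destination index)."""
        return self.gamma.argmax(axis=1)


@dataclass
class SelfAlignmentEnsemble:
    """Couplings from aligning a modality to its variational replicates."""

    couplings: list[Coupling]
    consensus: np.ndarray
    replicate_meta: list[dict]
    source_geodesic: GeodesicMatrix
    k_source: int


def _uniform(n: int) -> np.ndarray:
    return np.full(n, 1.0 / n)


def _sinkhorn_stabilized(
    M: np.ndarray,
    p: np.ndarray,
    q: np.ndarray,
    eps: float,
    alpha: np.ndarray,
    beta: np.ndarray,
    max_iter: int = 2000,
    tol: float = 1e-9,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, bool]:
    """Entropic OT projection with log-stabilization.

    Scaling vectors are absorbed into the dual potentials ``alpha, beta``
    whenever they threaten to overflow, so arbitrarily small ``eps`` is
    safe.  Potentials are passed in/out for warm starts across outer GW
    iterations.  Returns ``(coupling, alpha, beta, converged)``.
    """
    n, m = M.shape
    u = np.ones(n)
    v = np.ones(m)

    def kernel(a: np.ndarray, b: np.ndarray) -> np.ndarray:
        return np.exp((a[:, None] + b[None, :] - M) / eps)

    K = kernel(alpha, beta)
    converged = False
    for it in range(max_iter):
        Kv = K @ v
        Kv[Kv == 0] = np.finfo(float).tiny
        u = p / Kv
        Ktu = K.T @ u
        Ktu[Ktu == 0] = np.finfo(float).tiny
        v = q / Ktu
        if max(np.abs(np.log(u)).max(), np.abs(np.log(v)).max()) > 40.0:
            alpha = alpha + eps * np.log(u)
            beta = beta + eps * np.log(v)
            u = np.ones(n)
            v = np.ones(m)
            K = kernel(alpha, beta)
            continue
        if it % 10 == 0 or it == max_iter - 1:
            T = u[:, None] * K * v[None, :]
            err = np.abs(T.sum(axis=1) - p).max() + np.abs(T.sum(axis=0) - q).max()
            if err < tol:
                converged = True
                break
    alpha = alpha + eps * np.log(np.maximum(u, np.finfo(float).tiny))
    beta = beta + eps * np.log(np.maximum(v, np.finfo(float).tiny))
    T = kernel(alpha, beta)
    return T, alpha, beta, converged


def _gw_objective(
    constC: np.ndarray, hC1: np.ndarray, hC2: np.ndarray, T: np.ndarray
) -> float:
    return float(((constC - hC1 @ T @ hC2.T) * T).sum())


def gw_coupling(
    K_src: GeodesicMatrix | np.ndarray,
    K_dst: GeodesicMatrix | np.ndarray,
    p: np.ndarray | None = None,
    q: np.ndarray | None = None,
    cost: CostSpec = QUADRATIC,
    epsilon: float = 5e-3,
    max_iter: int = 200,
    tol: float = 1e-8,
    seed: int = 0,
    normalize: bool = True,
    n_restarts: int | None = None,
) -> Coupling:
    """Solve the entropically regularized Gromov-Wasserstein problem.

    Distance matrices are max-normalized before solving (so ``epsilon``
    transfers across datasets); a seeded, vanishingly small multiplicative
    jitter on the product-measure initialization breaks the symmetric fixed
    point that exists whenever the two spaces share an isometry.  The
    alternating scheme is only locally convergent, so the solve is restarted
    from ``n_restarts`` jittered initializations (default: 5 when
    ``n * m <= 10_000``, where restarts are cheap and local optima most
    visible, else 1) and the lowest-objective solution is kept.

    Returns a feasible :class:`Coupling` carrying the (unregularized) GW
    objective of the best iterate and a convergence flag.
    """
    C1 = np.asarray(K_src.dist if isinstance(K_src, GeodesicMatrix) else K_src, dtype=float)
    C2 = np.asarray(K_dst.dist if isinstance(K_dst, GeodesicMatrix) else K_dst, dtype=float)
    if C1.ndim != 2 or C1.shape[0] != C1.shape[1]:
        raise ValueError("K_src must be a square distance matrix")
    if C2.ndim != 2 or C2.shape[0] != C2.shape[1]:
        raise ValueError("K_dst must be a square distance matrix")
    n, m = C1.shape[0], C2.shape[0]
    p = _uniform(n) if p is None else np.asarray(p, dtype=float)
    q = _uniform(m) if q is None else np.asarray(q, dtype=float)
    if p.size != n or q.size != m:
        raise ValueError("marginal lengths must match distance matrices")
    if (p <= 0).any() or (q <= 0).any():
        raise ValueError("marginals must be strictly positive")
    if not (np.isclose(p.sum(), 1.0) and np.isclose(q.sum(), 1.0)):
        raise ValueError("marginals must sum to 1")

    if normalize:
        if C1.max() > 0:
            C1 = C1 / C1.max()
        if C2.max() > 0:
            C2 = C2 / C2.max()

    constC = np.add.outer(cost.f1(C1) @ p, cost.f2(C2) @ q)
    hC1 = cost.h1(C1)
    hC2 = cost.h2(C2)

    if n_restarts is None:
        n_restarts = 10 if n * m <= 10_000 else 1
    rng = np.random.default_rng(seed)

    # epsilon annealing: start coarse, tighten geometrically to the target
    # over the first iterations; coarse smoothing flattens spurious basins
    eps_start = max(epsilon, 0.05)
    n_anneal = 10

    def rounded_objective(T: np.ndarray) -> float:
        # score of the hardened (row-argmax) assignment carrying the row
        # marginals; entropic blur can invert the ranking of basins, the
        # rounded score cannot
        R = np.zeros_like(T)
        R[np.arange(n), T.argmax(axis=1)] = p
        return _gw_objective(constC, hC1, hC2, R)

    best: dict | None = None
    all_runs: list[np.ndarray] = []
    for restart in range(n_restarts):
        if restart == 0:
            T = np.outer(p, q) * (1.0 + 1e-4 * rng.standard_normal((n, m)))
        else:  # spiky random couplings explore distinct basins
            T = rng.gamma(0.5, size=(n, m)) + 1e-12
        np.clip(T, 1e-300, None, out=T)
        T /= T.sum()
        alpha = np.zeros(n)
        beta = np.zeros(m)
        run_converged = False
        run_history: list[float] = []
        run_T, run_obj = None, np.inf
        for it in range(max_iter):
            if it < n_anneal:
                eps_it = eps_start * (epsilon / eps_start) ** ((it + 1) / n_anneal)
            else:
                eps_it = epsilon
            tens = constC - hC1 @ T @ hC2.T
            T_new, alpha, beta, _ = _sinkhorn_stabilized(
                tens, p, q, eps_it, alpha, beta, tol=min(tol, 1e-9)
            )
            delta = np.abs(T_new - T).sum()
            obj = _gw_objective(constC, hC1, hC2, T_new)
            # only near-feasible iterates may be kept as candidates
            feas = max(
                np.abs(T_new.sum(axis=1) - p).max(),
                np.abs(T_new.sum(axis=0) - q).max(),
            )
            if feas < MARGINAL_TOL / 10 and obj <= run_obj:
                run_obj, run_T = obj, T_new
            if np.isfinite(run_obj):
                run_history.append(run_obj)
            T = T_new
            if it >= n_anneal and delta < tol:
                run_converged = True
                break
        if run_T is None:  # no inner loop converged: force a tight projection
            tens = constC - hC1 @ T @ hC2.T
            run_T, alpha, beta, _ = _sinkhorn_stabilized(
                tens, p, q, epsilon, alpha, beta, max_iter=20_000, tol=1e-10
            )
            run_obj = _gw_objective(constC, hC1, hC2, run_T)
            run_history.append(run_obj)
        all_runs.append(run_T)
        score = (rounded_objective(run_T), run_obj)
        if best is None or score < best["score"]:
            best = {
                "T": run_T,
                "obj": run_obj,
                "score": score,
                "history": run_history,
                "converged": run_converged,
            }
        if not run_converged:
            warnings.warn(
                f"GW solver did not converge in {max_iter} outer iterations "
                f"(last coupling change {delta:.2e}); returning best iterate",
                stacklevel=2,
            )
    assert best is not None
    best_T, best_obj, history = best["T"], best["obj"], best["history"]

    uniform_square = (
        n == m
        and np.allclose(p, 1.0 / n)
        and np.allclose(q, 1.0 / n)
    )
    if uniform_square and n <= 12:
        # entropic blur can park the iterate between vertices of nearly tied
        # basins; refine on the discrete assignment polytope instead.
        # Hungarian-round every restart, hill-climb with pairwise swaps on
        # the exact vertex objective, and return a feasible coupling
        # concentrated on the winning vertex.
        from scipy.optimize import linear_sum_assignment

        def vertex_obj(perm: np.ndarray) -> float:
            P = np.zeros((n, n))
            P[np.arange(n), perm] = 1.0 / n
            return _gw_objective(constC, hC1, hC2, P)

        cand: set[tuple[int, ...]] = set()
        for T_r in all_runs:
            _, cols = linear_sum_assignment(-T_r)
            cand.add(tuple(int(c) for c in cols))
        for _ in range(10 * n):  # multistart: random vertices are cheap here
            cand.add(tuple(int(c) for c in rng.permutation(n)))
        best_perm, best_vobj = None, np.inf
        for start in cand:
            perm = np.array(start)
            vobj = vertex_obj(perm)
            improved = True
            while improved:
                improved = False
                for i in range(n - 1):
                    for j in range(i + 1, n):
                        perm[i], perm[j] = perm[j], perm[i]
                        v = vertex_obj(perm)
                        if v < vobj - 1e-15:
                            vobj = v
                            improved = True
                        else:
                            perm[i], perm[j] = perm[j], perm[i]
                if improved:
                    continue
                # escape 2-swap local minima with 3-cycle rotations
                for i, j, k in combinations(range(n), 3):
                    for a, b, c in ((j, k, i), (k, i, j)):
                        old = (perm[i], perm[j], perm[k])
                        perm[i], perm[j], perm[k] = perm[a], perm[b], perm[c]
                        v = vertex_obj(perm)
                        if v < vobj - 1e-15:
                            vobj = v
                            improved = True
                        else:
                            perm[i], perm[j], perm[k] = old
            if vobj < best_vobj:
                best_vobj, best_perm = vobj, perm.copy()
        P = np.zeros((n, n))
        P[np.arange(n), best_perm] = 1.0 / n
        T0 = 0.75 * P + 0.25 * np.outer(p, q)  # feasible, argmax on the vertex
        T = T0
        alpha = np.zeros(n)
        beta = np.zeros(n)
        for _ in range(30):
            tens = constC - hC1 @ T @ hC2.T
            T_new, alpha, beta, _ = _sinkhorn_stabilized(
                tens, p, q, epsilon, alpha, beta, tol=1e-10
            )
            if np.abs(T_new - T).sum() < tol:
                T = T_new
                break
            T = T_new
        feas = max(np.abs(T.sum(axis=1) - p).max(), np.abs(T.sum(axis=0) - q).max())
        if feas < MARGINAL_TOL / 10 and (T.argmax(axis=1) == best_perm).all():
            best_T = T
        else:  # iteration left the basin: keep the explicit sharp coupling
            best_T = T0
        best_obj = _gw_objective(constC, hC1, hC2, best_T)
        return Coupling(
            gamma=best_T,
            row_marginal=p,
            col_marginal=q,
            objective=best_obj,
            converged=best["converged"],
            objective_history=history,
            epsilon=epsilon,
        )

    # final polish: re-project the incumbent so marginals hold tightly even
    # when an inner loop stopped at its iteration cap
    tens = constC - hC1 @ best_T @ hC2.T
    T_fin, _, _, _ = _sinkhorn_stabilized(
        tens, p, q, epsilon, np.zeros(n), np.zeros(m), max_iter=20_000, tol=1e-10
    )
    obj_fin = _gw_objective(constC, hC1, hC2, T_fin)
    fin_feasible = (
        max(np.abs(T_fin.sum(axis=1) - p).max(), np.abs(T_fin.sum(axis=0) - q).max())
        < MARGINAL_TOL / 10
    )
    if fin_feasible and obj_fin <= best_obj:
        best_T, best_obj = T_fin, obj_fin
        history.append(obj_fin)
    return Coupling(
        gamma=best_T,
        row_marginal=p,
        col_marginal=q,
        objective=best_obj,
        converged=best["converged"],
        objective_history=history,
        epsilon=epsilon,
    )


def default_k(n: int) -> int:
    """Default neighbor count: 10% of cells, at least 2."""
    return max(2, int(0.1 * n))


def default_k_schedule(n: int) -> list[int]:
    """Neighbor-count ladder for variational replicates: 5/10/20% of n."""
    return [max(2, int(0.05 * n)), max(2, int(0.1 * n)), max(2, int(0.2 * n))]


def self_align(
    data: ModalityData,
    n_replicates: int = 20,
    noise_sd: float = 0.1,
    k_schedule: list[int] | None = None,
    epsilon: float = 5e-3,
    seed: int = 0,
    source_k: int | None = None,
    max_iter: int = 200,
    tol: float = 1e-8,
) -> SelfAlignmentEnsemble:
    """Align a modality against variational copies of itself.

    For each replicate a perturbed copy is built (Gaussian feature noise,
    neighbor count cycled through ``k_schedule``) and the GW coupling
    between the source geodesics and the replicate geodesics is solved with
    uniform marginals.  The consensus is the elementwise mean of the
    replicate couplings, symmetrized as ``(G + G.T) / 2`` since cell-cell
    ambiguity is a symmetric relation.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    n = data.n_cells
    if k_schedule is None:
        k_schedule = default_k_schedule(n)
    if source_k is None:
        source_k = default_k(n)
    K_src, _ = geodesics_from_points(data, source_k)

    rng = np.random.default_rng(seed)
    couplings: list[Coupling] = []
    meta: list[dict] = []
    failures = 0
    for r in range(n_replicates):
        rep_seed = int(rng.integers(2**31))
        k_r = k_schedule[r % len(k_schedule)]
        rep = make_variational(data, noise_sd=noise_sd, k=k_r, seed=rep_seed)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cpl = gw_coupling(
                    K_src,
                    rep.geodesic,
                    epsilon=epsilon,
                    max_iter=max_iter,
                    tol=tol,
                    seed=rep_seed,
                )
        except Exception as exc:  # pragma: no cover - defensive
            warnings.warn(f"replicate {r} failed: {exc}", stacklevel=2)
            failures += 1
            continue
        couplings.append(cpl)
        meta.append(
            {"replicate": r, "seed": rep_seed, "noise_sd": noise_sd, "k": k_r,
             "k_used": rep.k_used, "objective": cpl.objective,
             "converged": cpl.converged}
        )
    if not couplings:
        raise RuntimeError("all self-alignment replicates failed")
    consensus = np.mean([c.gamma for c in couplings], axis=0)
    consensus = 0.5 * (consensus + consensus.T)
    return SelfAlignmentEnsemble(
        couplings=couplings,
        consensus=consensus,
        replicate_meta=meta,
        source_geodesic=K_src,
        k_source=source_k,
    )


def cross_modality_align(
    data_x: ModalityData,
    data_y: ModalityData,
    k: int | None = None,
    epsilon: float = 5e-3,
    seed: int = 0,
    max_iter: int = 200,
    tol: float = 1e-8,
) -> Coupling:
    """Baseline diagonal integration: GW between two modality geodesics.

    No shared features are assumed; each modality is reduced to its
    geodesic distance matrix and the GW coupling with uniform marginals is
    the integration solution (the object the diagnosis then examines).
    """
    kx = default_k(data_x.n_cells) if k is None else k
    ky = default_k(data_y.n_cells) if k is None else k
    Kx, _ = geodesics_from_points(data_x, kx)
    Ky, _ = geodesics_from_points(data_y, ky)
    return gw_coupling(Kx, Ky, epsilon=epsilon, max_iter=max_iter, tol=tol, seed=seed)
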