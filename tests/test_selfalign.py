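"""Gromov-Wasserstein solver, self-alignment ensemble, baseline aligner."""

import itertools
import warnings

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from sonata.manifold import ModalityData
from sonata.selfalign import (
    QUADRATIC,
    Coupling,
    cross_modality_align,
    gw_coupling,
    self_align,
)

MARG_TOL = 1e-6


def exhaustive_gw_permutation(C1, C2):
    """Oracle: minimize the quadratic GW objective over all permutations."""
    n = C1.shape[0]
    c1, c2 = C1 / C1.max(), C2 / C2.max()
    best, best_perm = np.inf, None
    for perm in itertools.permutations(range(n)):
        pm = np.array(perm)
        cost = (0.5 * (c1 - c2[np.ix_(pm, pm)]) ** 2).sum() / n**2
        if cost < best:
            best, best_perm = cost, pm
    return best, best_perm


def feasible(cpl: Coupling) -> bool:
    return np.allclose(cpl.gamma.sum(axis=1), cpl.row_marginal, atol=MARG_TOL) and np.allclose(
        cpl.gamma.sum(axis=0), cpl.col_marginal, atol=MARG_TOL
    )


class TestQuadraticCost:
    def test_values(self):
        assert QUADRATIC.loss(3.0, 1.0) == pytest.approx(2.0)
        assert QUADRATIC.loss(2.0, 2.0) == 0.0

    def test_factorization_identity(self, rng):
        a, b = rng.normal(size=10), rng.normal(size=10)
        np.testing.assert_allclose(
            QUADRATIC.loss(a, b),
            QUADRATIC.f1(a) + QUADRATIC.f2(b) - QUADRATIC.h1(a) * QUADRATIC.h2(b),
        )


class TestGwCoupling:
    def test_two_point_spaces_marginals(self):
        C = np.array([[0.0, 1.0], [1.0, 0.0]])
        cpl = gw_coupling(C, C, seed=0)
        np.testing.assert_allclose(cpl.gamma.sum(axis=1), [0.5, 0.5], atol=MARG_TOL)
        np.testing.assert_allclose(cpl.gamma.sum(axis=0), [0.5, 0.5], atol=MARG_TOL)
        # identical spaces: the optimum attains (near-)zero objective
        assert cpl.objective < 1e-6

    def test_identical_space_recovers_identity(self, rng):
        X = rng.normal(size=(5, 3))
        C = cdist(X, X)
        _, oracle_perm = exhaustive_gw_permutation(C, C)
        np.testing.assert_array_equal(oracle_perm, np.arange(5))
        cpl = gw_coupling(C, C, seed=1)
        np.testing.assert_array_equal(cpl.hardened(), np.arange(5))

    @pytest.mark.parametrize("trial", range(6))
    def test_matches_exhaustive_permutation_oracle(self, trial):
        rng = np.random.default_rng(100 + trial)
        n = int(rng.integers(3, 7))
        X, Y = rng.normal(size=(n, 2)), rng.normal(size=(n, 2))
        C1, C2 = cdist(X, X), cdist(Y, Y)
        _, oracle_perm = exhaustive_gw_permutation(C1, C2)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cpl = gw_coupling(C1, C2, seed=trial, n_restarts=4, max_iter=40)
        np.testing.assert_array_equal(cpl.hardened(), oracle_perm)

    def test_feasibility_nonsquare_shapes(self, rng):
        A, B = rng.normal(size=(7, 2)), rng.normal(size=(11, 3))
        C1, C2 = cdist(A, A), cdist(B, B)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cpl = gw_coupling(C1, C2, seed=0, max_iter=60)
        assert cpl.shape == (7, 11)
        assert feasible(cpl)

    def test_objective_history_non_increasing(self, rng):
        A, B = rng.normal(size=(15, 2)), rng.normal(size=(15, 2))
        C1, C2 = cdist(A, A), cdist(B, B)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cpl = gw_coupling(C1, C2, seed=0, max_iter=60)
        h = np.asarray(cpl.objective_history)
        assert h.size >= 1
        assert (np.diff(h) <= 1e-12).all()

    def test_scale_awareness(self, rng):
        """Scaling both metrics by c (and eps by c^2) leaves the argmax
        pattern unchanged and scales the quadratic objective by c^2."""
        n, c = 5, 3.0
        A, B = rng.normal(size=(n, 2)), rng.normal(size=(n, 2))
        C1, C2 = cdist(A, A), cdist(B, B)
        kw = dict(seed=0, normalize=False, max_iter=60, n_restarts=4)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            base = gw_coupling(C1, C2, epsilon=5e-3, **kw)
            scaled = gw_coupling(c * C1, c * C2, epsilon=5e-3 * c**2, **kw)
        np.testing.assert_array_equal(base.hardened(), scaled.hardened())
        assert scaled.objective == pytest.approx(c**2 * base.objective, rel=1e-3)

    def test_dimension_errors(self):
        with pytest.raises(ValueError):
            gw_coupling(np.ones((3, 4)), np.eye(3))
        with pytest.raises(ValueError):
            gw_coupling(np.zeros((3, 3)), np.zeros((3, 3)), p=np.array([0.5, 0.5, 0.0]))

    def test_convergence_warning_on_tiny_budget(self, rng):
        A, B = rng.normal(size=(20, 2)), rng.normal(size=(20, 2))
        C1, C2 = cdist(A, A), cdist(B, B)
        with pytest.warns(UserWarning, match="did not converge"):
            cpl = gw_coupling(C1, C2, seed=0, max_iter=2, n_restarts=1)
        assert not cpl.converged
        assert feasible(cpl)


class TestSelfAlign:
    def test_single_noiseless_replicate_concentrates_on_diagonal(self, rng):
        data = ModalityData(np.sort(rng.normal(size=(30, 1)), axis=0))
        ens = self_align(data, n_replicates=1, noise_sd=0.0, seed=0)
        n = 30
        diag_mass = np.trace(ens.consensus)
        assert diag_mass > 2.0 / n  # far above the uniform 1/n
        near = np.abs(np.subtract.outer(np.arange(n), np.arange(n))) <= 3
        band_fraction = near.mean()  # a uniform coupling would put this here
        assert ens.consensus[near].sum() > 2 * band_fraction

    def test_consensus_symmetric_nonnegative_unit_mass(self, random_modality):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ens = self_align(random_modality, n_replicates=3, seed=0)
        C = ens.consensus
        np.testing.assert_allclose(C, C.T, atol=1e-12)
        assert (C >= 0).all()
        assert C.sum() == pytest.approx(1.0, abs=1e-8)
        assert len(ens.replicate_meta) == 3

    def test_mirrored_branches_attract_consensus_mass(self, small_t_pair, small_t_report):
        """Mass concentrates between the congruent (mirrored) arms."""
        lab = small_t_pair.branch_labels
        C = small_t_report.ensemble.consensus
        b0, b1, b2 = (lab == f"branch{i}" for i in range(3))
        mirrored = C[np.ix_(b0, b1)].mean()
        unrelated = (C[np.ix_(b0, b2)].mean() + C[np.ix_(b1, b2)].mean()) / 2
        assert mirrored > 2 * unrelated

    def test_replicate_count_validation(self, random_modality):
        with pytest.raises(ValueError):
            self_align(random_modality, n_replicates=0)


class TestCrossModalityAlign:
    def test_exact_copy_recovers_identity(self, rng):
        X = rng.normal(size=(30, 5))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cpl = cross_modality_align(ModalityData(X), ModalityData(X.copy()), seed=0)
        np.testing.assert_array_equal(cpl.hardened(), np.arange(30))

    def test_output_is_valid_coupling(self, small_t_pair):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cpl = cross_modality_align(
                small_t_pair.modality_x, small_t_pair.modality_y, seed=0
            )
        assert feasible(cpl)
        assert cpl.shape == (150, 150)
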