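"""SparCC estimator: variation matrix, basis system, pipeline, p-values."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from occnet.abundance import AbundanceTable
from occnet.sparcc import (
    SparccConfig,
    basis_correlations,
    pvalues,
    run_sparcc,
    variation_matrix,
)
from occnet.synthetic import CommunitySpec, generate_community


def closed_form_d3(t: np.ndarray) -> np.ndarray:
    """Independent oracle: exact 3-taxon solution of the basis system.

    omega_i = (t_ij + t_ik - t_jk) / 2, rho from the definitional identity.
    """
    om = np.array(
        [
            (t[0, 1] + t[0, 2] - t[1, 2]) / 2,
            (t[0, 1] + t[1, 2] - t[0, 2]) / 2,
            (t[0, 2] + t[1, 2] - t[0, 1]) / 2,
        ]
    )
    rho = np.eye(3)
    for i in range(3):
        for j in range(i + 1, 3):
            rho[i, j] = rho[j, i] = (om[i] + om[j] - t[i, j]) / (
                2 * np.sqrt(om[i] * om[j])
            )
    return np.clip(rho, -1, 1)


class TestVariationMatrix:
    def test_proportional_taxa_have_zero_logratio_variance(self):
        base = np.array([[1.0, 2.0, 5.0], [2.0, 1.0, 3.0]]).T  # samples x taxa
        frac = np.column_stack([base[:, 0], 3.0 * base[:, 0], base[:, 1]])
        t = variation_matrix(frac)
        assert t[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_variance_of_log_ratios(self):
        # 2 taxa, 3 samples with log-ratios {0, 1, 2}: var (n-1) = 1
        x1 = np.array([1.0, np.e, np.e**2])
        frac = np.column_stack([x1, np.ones(3), np.full(3, 5.0)])
        frac = frac / frac.sum(axis=1, keepdims=True)
        t = variation_matrix(frac)
        assert t[0, 1] == pytest.approx(1.0, rel=1e-10)

    def test_symmetric_with_zero_diagonal(self):
        rng = np.random.default_rng(0)
        frac = rng.dirichlet(np.ones(6), size=20)
        t = variation_matrix(frac)
        np.testing.assert_allclose(t, t.T, atol=1e-14)
        np.testing.assert_array_equal(np.diag(t), 0.0)
        assert np.all(t >= 0)

    def test_nonpositive_fractions_rejected(self):
        with pytest.raises(ValueError, match="resample"):
            variation_matrix(np.array([[0.5, 0.5, 0.0], [0.2, 0.4, 0.4]]))


class TestBasisCorrelations:
    def test_symmetric_equidistant_triple_gives_unit_variances(self):
        t = np.array([[0, 2, 2], [2, 0, 2], [2, 2, 0]], float)
        omega, rho, degenerate = basis_correlations(t)
        np.testing.assert_allclose(omega, 1.0)
        assert rho[0, 1] == pytest.approx(0.0)
        assert not degenerate.any()

    def test_agreement_with_closed_form_oracle_on_random_input(self):
        rng = np.random.default_rng(5)
        frac = rng.dirichlet(np.ones(3) * 5, size=50)
        t = variation_matrix(frac)
        _, rho, _ = basis_correlations(t)
        np.testing.assert_allclose(rho, closed_form_d3(t), atol=1e-10)

    def test_infeasible_variance_flags_degenerate_taxon(self):
        # closed form gives omega_0 = (0.5 + 0.5 - 2)/2 = -0.5
        t = np.array([[0, 0.5, 0.5], [0.5, 0, 2], [0.5, 2, 0]], float)
        omega, rho, degenerate = basis_correlations(t)
        assert omega[0] == pytest.approx(-0.5)
        assert degenerate.tolist() == [True, False, False]
        assert rho[0, 1] == 0.0 and rho[0, 2] == 0.0
        assert rho[0, 0] == 1.0

    def test_output_clamped_to_correlation_range(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            frac = rng.dirichlet(np.ones(5), size=8)  # few samples: noisy t
            _, rho, _ = basis_correlations(variation_matrix(frac))
            assert np.all(rho <= 1.0) and np.all(rho >= -1.0)
            np.testing.assert_array_equal(np.diag(rho), 1.0)

    def test_excluded_pair_changes_system_but_still_reported(self):
        rng = np.random.default_rng(3)
        frac = rng.dirichlet(np.ones(6), size=40)
        t = variation_matrix(frac)
        _, rho_all, _ = basis_correlations(t)
        _, rho_ex, _ = basis_correlations(t, {(0, 1)})
        assert rho_ex.shape == (6, 6)
        assert np.isfinite(rho_ex[0, 1])  # excluded pair still gets a value
        assert not np.allclose(rho_all, rho_ex)

    def test_too_few_taxa_rejected(self):
        with pytest.raises(ValueError, match="3 taxa"):
            basis_correlations(np.zeros((2, 2)))


class TestRunSparcc:
    def test_default_configuration_values(self):
        cfg = SparccConfig()
        assert (
            cfg.n_iterations,
            cfg.exclusion_threshold,
            cfg.exclusion_max,
            cfg.n_permutations,
        ) == (50, 0.10, 10, 100)
        assert cfg.one_sided
        assert SparccConfig.quick().n_permutations == 50

    def test_null_community_estimates_are_small(self):
        spec = CommunitySpec(n_taxa=50, n_samples=200, depth=10_000, seed=1)
        table, _ = generate_community(spec)
        result = run_sparcc(table, SparccConfig(n_iterations=10, seed=1))
        off = np.abs(result.correlations[np.triu_indices(50, k=1)])
        assert np.median(off) < 0.1

    def test_planted_pair_is_the_largest_entry(self):
        basis = np.eye(15)
        basis[3, 9] = basis[9, 3] = 0.8
        spec = CommunitySpec(
            n_taxa=15, n_samples=200, depth=10_000, basis_correlation=basis, seed=2
        )
        table, _ = generate_community(spec)
        result = run_sparcc(table, SparccConfig(n_iterations=10, seed=2))
        corr = np.abs(np.triu(result.correlations, k=1))
        assert np.unravel_index(corr.argmax(), corr.shape) == (3, 9)

    def test_symmetry_unit_diagonal_and_determinism(self):
        spec = CommunitySpec(n_taxa=8, n_samples=40, depth=2000, seed=4)
        table, _ = generate_community(spec)
        cfg = SparccConfig(n_iterations=5, seed=9)
        r1 = run_sparcc(table, cfg)
        r2 = run_sparcc(table, cfg)
        np.testing.assert_array_equal(r1.correlations, r2.correlations)
        np.testing.assert_allclose(r1.correlations, r1.correlations.T, atol=1e-15)
        np.testing.assert_array_equal(np.diag(r1.correlations), 1.0)

    def test_scratch_file_layout_and_equivalence(self, tmp_path):
        spec = CommunitySpec(n_taxa=6, n_samples=30, depth=1000, seed=5)
        table, _ = generate_community(spec)
        scratch = tmp_path / "run.h5"
        cfg_disk = SparccConfig(n_iterations=4, seed=3, scratch_path=scratch)
        cfg_mem = SparccConfig(n_iterations=4, seed=3)
        r_disk = run_sparcc(table, cfg_disk)
        r_mem = run_sparcc(table, cfg_mem)
        np.testing.assert_array_equal(r_disk.correlations, r_mem.correlations)
        import h5py

        with h5py.File(scratch) as fh:
            assert sorted(fh.keys()) == [f"iter_{k:04d}" for k in range(4)]
            assert fh["iter_0000/rho"].shape == (6, 6)

    def test_too_few_taxa_rejected(self):
        table = AbundanceTable(
            ["a", "b"], ["s1", "s2", "s3", "s4"], np.ones((2, 4))
        )
        with pytest.raises(ValueError, match="3 taxa"):
            run_sparcc(table)


@pytest.fixture(scope="module")
def planted():
    basis = np.eye(8)
    basis[1, 5] = basis[5, 1] = 0.8
    spec = CommunitySpec(
        n_taxa=8, n_samples=100, depth=5000, basis_correlation=basis, seed=6
    )
    table, _ = generate_community(spec)
    cfg = SparccConfig(
        n_iterations=5, n_permutations=50, seed=6, permutation_iterations=2
    )
    observed = run_sparcc(table, cfg)
    return table, observed, cfg


class TestPvalues:

    def test_all_pvalues_within_add_one_bounds(self, planted):
        table, observed, cfg = planted
        p = pvalues(table, observed, cfg)
        off = p[np.triu_indices(8, k=1)]
        assert np.all(off >= 1 / 51) and np.all(off <= 1.0)
        np.testing.assert_array_equal(np.diag(p), 0.0)

    def test_strong_planted_pair_attains_minimum_pvalue(self, planted):
        table, observed, cfg = planted
        p = pvalues(table, observed, cfg)
        assert p[1, 5] == pytest.approx(1 / 51)

    def test_two_sided_pvalues_are_sign_symmetric(self, planted):
        table, observed, cfg = planted
        from dataclasses import replace

        from occnet.sparcc import CorrelationResult

        cfg2 = replace(cfg, one_sided=False, n_permutations=20)
        p_pos = pvalues(table, observed, cfg2)
        flipped = CorrelationResult(
            taxon_ids=observed.taxon_ids,
            correlations=-observed.correlations
            + 2 * np.eye(8),  # keep unit diagonal
            config=observed.config,
        )
        p_neg = pvalues(table, flipped, cfg2)
        np.testing.assert_allclose(p_pos, p_neg)


@given(st.integers(0, 2**31 - 1))
def test_estimates_always_valid_correlation_matrices(seed):
    rng = np.random.default_rng(seed)
    counts = rng.integers(0, 50, size=(5, 12)).astype(float)
    counts[0, :] += 1  # avoid an all-zero table
    table = AbundanceTable(
        [f"t{i}" for i in range(5)], [f"s{j}" for j in range(12)], counts
    )
    result = run_sparcc(table, SparccConfig(n_iterations=2, seed=seed % 1000))
    c = result.correlations
    np.testing.assert_allclose(c, c.T, atol=1e-14)
    np.testing.assert_array_equal(np.diag(c), 1.0)
    assert np.all(c >= -1.0) and np.all(c <= 1.0)
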