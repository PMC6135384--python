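import numpy as np
import pandas as pd
import pytest

import foramstats as fs
from foramstats.io import ValidationError, island_of


def community(rng, n=8, m=5):
    return pd.DataFrame(
        rng.integers(1, 20, size=(n, m)).astype(float),
        index=[f"s{i}" for i in range(n)], columns=[f"t{j}" for j in range(m)])


def brute_force_constrained_eigs(Y, X):
    """Independent oracle: dense eigendecomposition of the projected
    cross-product matrix."""
    Y = np.asarray(Y, float)
    X = np.asarray(X, float)
    total = Y.sum()
    P = Y / total
    r, c = P.sum(axis=1), P.sum(axis=0)
    Q = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    Xc = X - r @ X
    Xs = Xc / np.sqrt(r @ (Xc ** 2))
    B = np.sqrt(r)[:, None] * Xs
    H = B @ np.linalg.pinv(B.T @ B) @ B.T
    M = (H @ Q) @ (H @ Q).T
    eig = np.linalg.eigvalsh(M)[::-1]
    return eig[eig > 1e-12]


class TestCCACore:
    def test_toy_eigenvalues_match_dense_oracle(self, rng):
        for _ in range(10):
            Y = rng.integers(1, 15, size=(3, 3)).astype(float)
            X = rng.normal(size=(3, 1))
            res = fs.cca(pd.DataFrame(Y), X)
            oracle = brute_force_constrained_eigs(Y, X)
            mine = res.eigenvalues[: res.n_constrained]
            assert np.allclose(np.sort(mine), np.sort(oracle), atol=1e-8)

    def test_five_by_five_eigenvalues_match_oracle(self, rng):
        Y = rng.integers(1, 30, size=(5, 5)).astype(float)
        X = rng.normal(size=(5, 2))
        res = fs.cca(pd.DataFrame(Y), X)
        oracle = brute_force_constrained_eigs(Y, X)
        assert np.allclose(
            np.sort(res.eigenvalues[: res.n_constrained]), np.sort(oracle),
            atol=1e-8)

    def test_matches_scikit_bio(self, rng):
        skbio_ord = pytest.importorskip("skbio.stats.ordination")
        Y = community(rng)
        X = pd.DataFrame(rng.normal(size=(8, 2)), index=Y.index, columns=["a", "b"])
        res = fs.cca(Y, X)
        ref = skbio_ord.cca(Y, X)
        k = res.n_constrained
        assert np.allclose(res.eigenvalues[:k], np.asarray(ref.eigvals)[:k], atol=1e-10)

    def test_total_inertia_is_chi_square_statistic(self, rng):
        Y = community(rng).to_numpy()
        res = fs.cca(pd.DataFrame(Y), None)
        total = Y.sum()
        expected = Y.sum(axis=1)[:, None] * Y.sum(axis=0)[None, :] / total
        chi2 = ((Y - expected) ** 2 / expected).sum() / total
        assert res.total_inertia == pytest.approx(chi2, abs=1e-10)

    def test_eigenvalues_sum_to_total_inertia(self, rng):
        Y = community(rng)
        X = pd.DataFrame(rng.normal(size=(8, 2)), index=Y.index, columns=["a", "b"])
        res = fs.cca(Y, X)
        assert res.eigenvalues.sum() == pytest.approx(res.total_inertia, abs=1e-10)
        assert res.constrained_inertia <= res.total_inertia + 1e-10

    def test_species_scores_are_weighted_averages_of_lc_sites(self, rng):
        Y = community(rng, n=10, m=6)
        X = pd.DataFrame(rng.normal(size=(10, 3)), index=Y.index,
                         columns=list("abc"))
        res = fs.cca(Y, X)
        arr = Y.to_numpy()
        P = arr / arr.sum()
        c = P.sum(axis=0)
        k = res.n_constrained
        wavg = (P.T @ res.site_scores_lc.to_numpy()[:, :k]) / c[:, None]
        assert np.allclose(wavg, res.species_scores.to_numpy()[:, :k], atol=1e-8)

    def test_env_built_from_ca_axis_recovers_ca_eigenvalue(self, rng):
        Y = community(rng, n=9, m=6)
        ca = fs.correspondence_analysis(Y)
        env = ca.site_scores_lc["CA1"].to_frame("v")
        res = fs.cca(Y, 2.0 * env + 5.0)  # affine function of CA1 site scores
        assert res.eigenvalues[0] == pytest.approx(ca.eigenvalues[0], abs=1e-10)

    def test_orthogonal_constraint_explains_nothing(self, rng):
        Y = community(rng, n=8, m=3)
        arr = Y.to_numpy()
        P = arr / arr.sum()
        r = P.sum(axis=1)
        ca = fs.correspondence_analysis(Y)
        # build env r-orthogonal to the span of {1, all CA site axes}
        basis = np.hstack([np.ones((8, 1)), ca.site_scores_lc.to_numpy()])
        W = r[:, None] * basis
        v = rng.normal(size=8)
        v = v - basis @ np.linalg.lstsq(W.T @ basis, W.T @ v, rcond=None)[0]
        res = fs.cca(Y, v[:, None])
        assert res.constrained_inertia == pytest.approx(0.0, abs=1e-10)

    def test_axis_count_bound(self, rng):
        Y = community(rng, n=8, m=6)
        X = pd.DataFrame(rng.normal(size=(8, 3)), index=Y.index, columns=list("abc"))
        res = fs.cca(Y, X)
        assert res.n_constrained <= min(3, 5, 7)


class TestCCAValidation:
    def test_rank_deficient_error_lists_columns(self, rng):
        Y = community(rng)
        X = pd.DataFrame({"a": rng.normal(size=8)}, index=Y.index)
        X["b"] = 2.0 * X["a"] + 1.0
        with pytest.raises(ValidationError, match="b"):
            fs.cca(Y, X)

    def test_drop_collinear_aliases_with_warning(self, rng):
        Y = community(rng)
        X = pd.DataFrame({"a": rng.normal(size=8)}, index=Y.index)
        X["b"] = 2.0 * X["a"] + 1.0
        with pytest.warns(UserWarning, match="aliased"):
            res = fs.cca(Y, X, drop_collinear=True)
        assert res.n_constrained == 1
        assert list(res.biplot_scores.index) == ["a", "b"]

    def test_constant_environment_error(self, rng):
        Y = community(rng)
        with pytest.raises(ValidationError, match="no variance"):
            fs.cca(Y, np.ones((8, 1)))

    def test_zero_row_error(self, rng):
        Y = community(rng)
        Y.iloc[2] = 0.0
        with pytest.raises(ValidationError, match="s2"):
            fs.cca(Y, np.arange(8.0)[:, None])


class TestPermutationTest:
    def test_strong_gradient_is_significant(self):
        sim = fs.simulate_community(fs.SimulationDesign(rng_seed=11))
        g = np.array(sim.truth["gradients"])[:, 0:1]
        F, p = fs.permutation_test(sim.assemblage, g, n_permutations=999, rng_seed=5)
        assert p <= 0.01
        assert F > 1.0

    def test_p_value_form(self, rng):
        Y = community(rng)
        X = rng.normal(size=(8, 1))
        F, p = fs.permutation_test(Y, X, n_permutations=99, rng_seed=0)
        assert 1 / 100 <= p <= 1.0

    def test_seed_reproducibility(self, rng):
        Y = community(rng)
        X = rng.normal(size=(8, 1))
        out1 = fs.permutation_test(Y, X, n_permutations=99, rng_seed=7)
        out2 = fs.permutation_test(Y, X, n_permutations=99, rng_seed=7)
        assert out1 == out2


class TestGalapagosOrdination:
    @pytest.fixture()
    def fixture_cca(self, galapagos, galapagos_env_frame):
        a, _, _ = galapagos
        with pytest.warns(UserWarning, match="aliased"):
            return fs.cca(a, galapagos_env_frame, drop_collinear=True)

    def test_cca1_sign_separates_groups(self, fixture_cca):
        """CCA1 puts San Cristobal + Floreana opposite Darwin + Baltra,
        matching the left/right triplot groups up to a global sign."""
        for scores in (fixture_cca.site_scores_wa, fixture_cca.site_scores_lc):
            cca1 = scores["CCA1"]
            scfl = [cca1[s] for s in cca1.index if island_of(s) in ("SC", "FL")]
            darbal = [cca1[s] for s in cca1.index if island_of(s) in ("DAR", "BAL")]
            assert len(set(np.sign(scfl))) == 1
            assert len(set(np.sign(darbal))) == 1
            assert np.sign(scfl[0]) == -np.sign(darbal[0])

    def test_triplot_tables(self, fixture_cca):
        tri = fs.triplot_coordinates(fixture_cca, (1, 2))
        assert tri["sites"].shape == (19, 2)
        assert tri["species"].shape == (28, 2)
        assert tri["arrows"].shape == (8, 2)

    def test_triplot_same_axis_error(self, fixture_cca):
        with pytest.raises(ValidationError):
            fs.triplot_coordinates(fixture_cca, (1, 1))
        with pytest.raises(ValidationError):
            fs.triplot_coordinates(fixture_cca, (1, 99))

    def test_biplot_invariant_to_affine_env_rescaling(
            self, galapagos, galapagos_env_frame):
        a, _, _ = galapagos
        scaled = galapagos_env_frame.copy()
        scaled["mean_chl"] = scaled["mean_chl"] * 40.0 - 3.0
        with pytest.warns(UserWarning, match="aliased"):
            r1 = fs.cca(a, galapagos_env_frame, drop_collinear=True)
        with pytest.warns(UserWarning, match="aliased"):
            r2 = fs.cca(a, scaled, drop_collinear=True)
        assert np.allclose(r1.biplot_scores.to_numpy(),
                           r2.biplot_scores.to_numpy(), atol=1e-8)
        assert np.allclose(r1.eigenvalues, r2.eigenvalues, atol=1e-10)
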