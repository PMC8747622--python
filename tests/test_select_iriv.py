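"""IRIV: inclusion designs, DMEAN/Mann-Whitney classification, elimination."""

import numpy as np
import pytest
from sklearn.cross_decomposition import PLSRegression

from spadspec import IrivConfig, SimConfig, generate_dataset, run_iriv
from spadspec._pls import kfold_indices
from spadspec.select_iriv import (backward_eliminate, build_inclusion_matrix,
                                  classify, iriv_round)


class TestInclusionMatrix:
    def test_column_means_concentrate(self):
        cfg = IrivConfig(n_rows=500, inclusion_prob=0.5, seed=0)
        A = build_inclusion_matrix(50, cfg)
        tol = 3 * np.sqrt(0.25 / 500)
        assert np.all(np.abs(A.mean(axis=0) - 0.5) <= tol)

    def test_every_row_has_at_least_two_ones(self):
        cfg = IrivConfig(n_rows=200, inclusion_prob=0.15, seed=1)
        A = build_inclusion_matrix(5, cfg)
        assert A.sum(axis=1).min() >= 2

    def test_same_seed_identical(self):
        cfg = IrivConfig(n_rows=50, seed=3)
        np.testing.assert_array_equal(build_inclusion_matrix(20, cfg),
                                      build_inclusion_matrix(20, cfg))

    def test_rejects_single_variable(self):
        with pytest.raises(ValueError):
            build_inclusion_matrix(1, IrivConfig())


class TestClassification:
    @pytest.mark.parametrize("dmean,p,expected", [
        (-0.1, 0.01, "strong"),
        (-0.1, 0.50, "weak"),
        (0.1, 0.50, "uninformative"),
        (0.1, 0.01, "interfering"),
    ])
    def test_rule_table(self, dmean, p, expected):
        assert classify(dmean, p) == expected

    def test_boundaries_go_to_weaker_class(self):
        assert classify(-0.1, 0.05) == "weak"
        assert classify(0.1, 0.05) == "uninformative"
        assert classify(0.0, 0.01) == "uninformative"

    def test_partition_is_exhaustive_and_exclusive(self, rng):
        """Every (DMEAN, p) pair off the boundary maps to exactly one class."""
        for dmean in rng.uniform(-1, 1, 50):
            for p in rng.uniform(0, 1, 10):
                if dmean == 0 or p == 0.05:
                    continue
                assert classify(dmean, p) in ("strong", "weak",
                                              "uninformative", "interfering")


class TestIrivRound:
    def _system(self, rng, n=80):
        X = rng.normal(size=(n, 4)) * 0.1
        y = 3 * X[:, 0] + 2 * X[:, 1] - X[:, 2] + rng.normal(0, 0.02, n)
        return X, y

    def test_informative_variable_has_negative_dmean(self, rng):
        """Sign convention pin: removing a variable that carries unique
        signal inflates RMSECV, so its DMEAN must come out negative."""
        X, y = self._system(rng)
        rnd = iriv_round(X, y, np.arange(4), IrivConfig(n_rows=100, seed=0))
        assert rnd.dmean[0] < 0
        assert rnd.category[0] == "strong"

    def test_pure_noise_variable_flagged_for_elimination(self):
        """A noise variable appended to a linear system is classified
        uninformative or interfering in >= 9/10 seeded replicates."""
        good = 0
        for seed in range(10):
            r = np.random.default_rng(seed)
            X, y = self._system(r, n=200)
            X = np.column_stack([X[:, :3], r.normal(0, 0.1, X.shape[0])])
            rnd = iriv_round(X, y, np.arange(4),
                             IrivConfig(n_rows=300, seed=seed))
            if rnd.category[3] in ("uninformative", "interfering"):
                good += 1
        assert good >= 9

    def test_round_requires_two_variables(self, rng):
        X, y = self._system(rng)
        with pytest.raises(ValueError):
            iriv_round(X, y, np.array([0]), IrivConfig(n_rows=50))


class TestBackwardElimination:
    def test_single_variable_returned_unchanged(self, rng):
        X = rng.normal(size=(30, 5))
        y = rng.normal(size=30)
        out = backward_eliminate(X, y, np.array([2]), IrivConfig(seed=0))
        np.testing.assert_array_equal(out, [2])

    def test_duplicated_variable_one_copy_eliminated(self, rng):
        X = rng.normal(size=(60, 4)) * 0.1
        X[:, 3] = X[:, 0]  # exact duplicate
        y = 5 * X[:, 0] + rng.normal(0, 0.01, 60)
        out = backward_eliminate(X, y, np.arange(4), IrivConfig(seed=1))
        assert not {0, 3} <= set(out)
        assert len(set(out) & {0, 3}) >= 1

    def test_greedy_path_matches_brute_force_oracle(self, rng):
        """p=6 toy problem: every theta value along the greedy path equals an
        independent scikit-learn CV recomputation over explicit subsets."""
        n, p = 40, 6
        X = rng.normal(size=(n, p)) * 0.1
        y = 2 * X[:, 1] - 3 * X[:, 4] + rng.normal(0, 0.05, n)
        cfg = IrivConfig(seed=0, cv_folds=5, max_pls_components=5)
        folds = kfold_indices(n, 5, np.random.default_rng(99))

        def oracle_rmsecv(subset, n_comp):
            sse = 0.0
            for tr, te in folds:
                m = PLSRegression(n_components=n_comp, scale=False)
                m.fit(X[np.ix_(tr, subset)], y[tr])
                r = y[te] - m.predict(X[np.ix_(te, subset)]).ravel()
                sse += r @ r
            return np.sqrt(sse / n)

        trace = []
        backward_eliminate(X, y, np.arange(p), cfg, trace=trace, folds=folds)
        assert trace, "trace must record at least one step"
        for variables, theta_t, theta_minus in trace:
            if variables.size == 1:
                continue
            t = variables.size
            n_comp = max(1, min(cfg.max_pls_components, t - 1, n - 2))
            assert theta_t == pytest.approx(
                oracle_rmsecv(variables.tolist(), n_comp), abs=1e-8)
            for i in range(t):
                subset = np.delete(variables, i).tolist()
                assert theta_minus[i] == pytest.approx(
                    oracle_rmsecv(subset, n_comp), abs=1e-8)


class TestRunIriv:
    def test_retained_counts_non_increasing_and_terminates(self):
        cfg = SimConfig(n_samples=80, n_bands=30, seed=8,
                        informative_bands=(5, 20), effect_sizes=(-0.01, 0.01),
                        noise_sd=0.003, spectral_corr_length=0.0)
        ds = generate_dataset(cfg)
        sel, res = run_iriv(ds, IrivConfig(n_rows=100, seed=8))
        counts = res.retained_after_rounds
        assert all(b <= a for a, b in zip(counts, counts[1:]))
        assert len(res.rounds) <= IrivConfig().max_rounds
        assert set(sel.indices) <= set(range(30))

    def test_null_response_still_terminates(self):
        """y pure noise: the algorithm must terminate, selection stays small."""
        r = np.random.default_rng(0)
        from spadspec import SpectralDataset
        ds = SpectralDataset(X=r.normal(size=(60, 25)) * 0.1,
                             y=r.normal(50, 5, 60),
                             wavelengths=np.linspace(400, 1000, 25))
        sel, res = run_iriv(ds, IrivConfig(n_rows=80, seed=0, max_rounds=20))
        assert len(res.rounds) <= 20
        assert sel.n_selected < 25

    def test_planted_recovery_small_scale(self):
        cfg = SimConfig(n_samples=100, n_bands=40, seed=13,
                        informative_bands=(3, 12, 22, 33),
                        effect_sizes=(-0.01, -0.01, 0.01, 0.01),
                        noise_sd=0.003, spectral_corr_length=0.0)
        ds = generate_dataset(cfg)
        sel, _ = run_iriv(ds, IrivConfig(n_rows=120, seed=13))
        assert len(set(cfg.informative_bands) & set(sel.indices)) >= 3

    def test_history_frame_schema(self):
        cfg = SimConfig(n_samples=60, n_bands=12, seed=2,
                        informative_bands=(4,), effect_sizes=(0.01,),
                        noise_sd=0.004, spectral_corr_length=0.0)
        ds = generate_dataset(cfg)
        _, res = run_iriv(ds, IrivConfig(n_rows=60, seed=2))
        df = res.history_frame(ds.wavelengths)
        assert list(df.columns) == ["round", "variable", "wavelength_nm",
                                    "dmean", "pvalue", "category"]
        assert df["category"].isin(("strong", "weak", "uninformative",
                                    "interfering")).all()
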