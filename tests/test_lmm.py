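"""Crossed random-effects REML: oracle equivalence, invariances, inference."""

import numpy as np
import pytest

import iscmix as im
from iscmix.lmm import CrossedLMMSpec, CrossedREMLSolver, fit_crossed_lmm
from _oracles import dense_reml_oracle


def within_pairs(n):
    return [(i, j) for i in range(n) for j in range(i + 1, n)]


def incidence(pairs, n):
    Z = np.zeros((len(pairs), n))
    for k, (i, j) in enumerate(pairs):
        Z[k, i] = Z[k, j] = 1.0
    return Z


def simulate_pair_z(rng, pairs, beta0, tau, sigma, n_sub):
    a = rng.normal(0, tau, n_sub)
    return beta0 + np.array([a[i] + a[j] for i, j in pairs]) + rng.normal(
        0, sigma, len(pairs)
    )


class TestFitCrossedLMM:
    def test_constant_response_returns_exact_intercept(self):
        pairs = within_pairs(4)
        spec = CrossedLMMSpec(
            y=np.full(len(pairs), 0.2),
            X=np.ones((len(pairs), 1)),
            names=["intercept"],
            members=[np.array(pairs)],
        )
        fit = fit_crossed_lmm(spec)
        assert fit.beta[0] == pytest.approx(0.2, abs=1e-14)

    def test_no_subject_effect_collapses_to_ols(self, rng):
        pairs = within_pairs(8)
        y = 0.3 + rng.normal(0, 0.2, len(pairs))  # independent pairs
        spec = CrossedLMMSpec(
            y=y, X=np.ones((len(pairs), 1)), names=["intercept"],
            members=[np.array(pairs)],
        )
        fit = fit_crossed_lmm(spec)
        assert fit.beta[0] == pytest.approx(y.mean(), abs=1e-6)

    def test_monte_carlo_recovery_of_intercept(self):
        # known beta0 = 0.3, tau2 = 0.02, sigma2 = 0.05, 6 subjects
        pairs = within_pairs(6)
        rng = np.random.default_rng(42)
        est = []
        for _ in range(200):
            y = simulate_pair_z(rng, pairs, 0.3, np.sqrt(0.02), np.sqrt(0.05), 6)
            spec = CrossedLMMSpec(
                y=y, X=np.ones((len(pairs), 1)), names=["intercept"],
                members=[np.array(pairs)],
            )
            est.append(fit_crossed_lmm(spec).beta[0])
        est = np.asarray(est)
        se = est.std(ddof=1) / np.sqrt(len(est))
        assert abs(est.mean() - 0.3) < 3 * se

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_dense_covariance_oracle_single_factor(self, seed):
        rng = np.random.default_rng(seed)
        n_sub = 6
        pairs = within_pairs(n_sub)
        y = simulate_pair_z(rng, pairs, 0.3, 0.15, 0.2, n_sub)
        X = np.ones((len(pairs), 1))
        fit = CrossedREMLSolver(X, [np.array(pairs)]).fit(y, ["intercept"])
        beta_o, ll_o, _, _ = dense_reml_oracle(y, X, [incidence(pairs, n_sub)])
        assert np.abs(fit.beta - beta_o).max() < 1e-6
        assert abs(fit.loglik - ll_o) < 1e-6

    @pytest.mark.parametrize("seed", [3, 4])
    def test_matches_dense_covariance_oracle_crossed_factors(self, seed):
        rng = np.random.default_rng(seed)
        C, A = 5, 4
        rows = [(c, a) for c in range(C) for a in range(A)]
        n = len(rows)
        ac, aa = rng.normal(0, 0.1, C), rng.normal(0, 0.12, A)
        age = rng.uniform(-15, 15, C)
        X = np.column_stack([np.ones(n), [age[c] for c, _ in rows]])
        y = (0.2 + 0.003 * X[:, 1]
             + np.array([ac[c] + aa[a] for c, a in rows])
             + rng.normal(0, 0.15, n))
        members = [np.array([[c] for c, _ in rows]), np.array([[a] for _, a in rows])]
        fit = CrossedREMLSolver(X, members).fit(y, ["intercept", "age"])
        Zc = np.zeros((n, C)); Za = np.zeros((n, A))
        for k, (c, a) in enumerate(rows):
            Zc[k, c] = Za[k, a] = 1.0
        beta_o, ll_o, _, _ = dense_reml_oracle(y, X, [Zc, Za])
        assert np.abs(fit.beta - beta_o).max() < 1e-6
        assert abs(fit.loglik - ll_o) < 1e-6

    def test_doubled_triangle_equals_single_triangle(self, rng):
        n_sub = 7
        pairs = within_pairs(n_sub)
        y1 = simulate_pair_z(rng, pairs, 0.25, 0.12, 0.18, n_sub)
        i1 = np.array([i for i, _ in pairs]); j1 = np.array([j for _, j in pairs])
        single = CrossedLMMSpec(
            y=y1, X=np.ones((len(pairs), 1)), names=["intercept"],
            members=[np.column_stack([i1, j1])], pair_i=i1, pair_j=j1,
        )
        y2 = np.r_[y1, y1]
        i2, j2 = np.r_[i1, j1], np.r_[j1, i1]
        doubled = CrossedLMMSpec(
            y=y2, X=np.ones((2 * len(pairs), 1)), names=["intercept"],
            members=[np.column_stack([i2, j2])], pair_i=i2, pair_j=j2,
            doubling=True,
        )
        f1, f2 = fit_crossed_lmm(single), fit_crossed_lmm(doubled)
        assert np.allclose(f1.beta, f2.beta, atol=1e-12)
        assert np.allclose(f1.se, f2.se, atol=1e-12)
        assert np.allclose(f1.df, f2.df, atol=1e-9)

    def test_subject_label_permutation_invariance(self, rng):
        n_sub = 6
        pairs = within_pairs(n_sub)
        y = simulate_pair_z(rng, pairs, 0.3, 0.1, 0.2, n_sub)
        perm = rng.permutation(n_sub)
        members_p = [np.array([[perm[i], perm[j]] for i, j in pairs])]
        f1 = CrossedREMLSolver(
            np.ones((len(pairs), 1)), [np.array(pairs)]
        ).fit(y, ["intercept"])
        f2 = CrossedREMLSolver(np.ones((len(pairs), 1)), members_p).fit(
            y, ["intercept"]
        )
        assert np.allclose(f1.beta, f2.beta, atol=1e-10)
        assert np.allclose(f1.se, f2.se, atol=1e-10)

    def test_too_few_subjects_rejected(self):
        pairs = within_pairs(3)
        spec = CrossedLMMSpec(
            y=np.zeros(len(pairs)), X=np.ones((len(pairs), 1)),
            names=["intercept"], members=[np.array(pairs)],
        )
        with pytest.raises(ValueError, match="4 subjects"):
            fit_crossed_lmm(spec)


class TestSatterthwaite:
    def test_df_bracketed_for_balanced_intercept_model(self, rng):
        n_sub = 21
        pairs = within_pairs(n_sub)
        y = simulate_pair_z(rng, pairs, 0.3, 0.15, 0.2, n_sub)
        fit = CrossedREMLSolver(
            np.ones((len(pairs), 1)), [np.array(pairs)]
        ).fit(y, ["intercept"])
        # the intercept df tracks the between-subject df (n_sub - 1) but the
        # exact Satterthwaite value (verified against a dense-information
        # computation) can dip a few percent below it depending on the
        # realized tau^2/sigma^2; it never approaches the pair count
        assert 0.85 * (n_sub - 1) <= fit.df[0] <= len(pairs) - 1
        assert fit.df[0] < len(pairs) / 2

    def test_df_deterministic(self, rng):
        n_sub = 8
        pairs = within_pairs(n_sub)
        y = simulate_pair_z(rng, pairs, 0.3, 0.15, 0.2, n_sub)
        fit = CrossedREMLSolver(
            np.ones((len(pairs), 1)), [np.array(pairs)]
        ).fit(y, ["intercept"])
        d1 = im.satterthwaite_df(fit, np.array([1.0]))
        d2 = im.satterthwaite_df(fit, np.array([1.0]))
        assert d1 == d2 == fit.df[0]

    def test_boundary_variance_falls_back_conservatively(self, rng):
        n_sub = 8
        pairs = within_pairs(n_sub)
        y = 0.3 + rng.normal(0, 0.2, len(pairs))  # no subject effect
        fit = CrossedREMLSolver(
            np.ones((len(pairs), 1)), [np.array(pairs)]
        ).fit(y, ["intercept"])
        if fit.boundary:
            assert fit.df[0] == n_sub - 1


class TestModelBuilders:
    def test_within_group_intercept_recovers_expected_isc(
        self, small_cohort, small_isc
    ):
        eff = small_cohort.truth.effect_nodes
        fits = im.within_group_model(small_isc, "adult", nodes=list(eff))
        adults = small_isc.group_indices("adult")
        for f in fits:
            expected = np.mean(
                [
                    im.expected_isc(small_cohort.truth, int(i), int(j), f.node)
                    for i in adults for j in adults if i < j
                ]
            )
            # 176 volumes: sampling SE of r ~ 0.07; intercept averages 15 pairs
            assert f.beta_r[0] == pytest.approx(expected, abs=0.1)
            assert f.converged

    def test_contrast_centered_at_zero_for_random_partition(self, rng):
        # one homogeneous group split in two: affiliation effect ~ 0
        cfg = im.SyntheticCohortConfig(
            n_per_group={"child4": 6, "child6": 6},
            mesh_spec=(2, 2, 3.0),
            coupling={"child4": 0.4, "child6": 0.4},
            age_slope=0.0,
            seed=77,
        )
        coh = im.simulate_cohort(cfg)
        m = im.pairwise_isc(coh.subjects)
        fits = im.group_contrast_model(m, "child4", "child6", nodes=[0])
        f = fits[0]
        assert abs(f.beta[1]) < 3 * f.se[1]

    def test_age_model_constant_age_raises(self, rng):
        subs = []
        for k in range(5):
            subs.append(
                im.SubjectTimeSeries(
                    data=rng.normal(size=(1, 120)), subject_id=f"c{k}",
                    group="child4", age_months=60.0,
                )
            )
        for k in range(5):
            subs.append(
                im.SubjectTimeSeries(
                    data=rng.normal(size=(1, 120)), subject_id=f"a{k}",
                    group="adult", age_months=250.0,
                )
            )
        m = im.pairwise_isc(subs)
        with pytest.raises(ValueError, match="constant"):
            im.child_to_adult_age_model(m, "child4", "adult")

    def test_fits_to_frame_reports_r_scale(self, small_isc):
        fits = im.within_group_model(small_isc, "adult", nodes=[0])
        df = im.fits_to_frame(fits)
        row = df.iloc[0]
        assert row["beta_r"] == pytest.approx(np.tanh(row["beta_z"]))
        assert {"node", "effect", "se", "t", "df", "p"} <= set(df.columns)
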