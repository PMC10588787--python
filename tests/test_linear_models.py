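"""Moderated contrasts, BH adjustment, Welch t-tests and sample PCA."""

import subprocess

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from triomics import (
    ContrastSpec,
    ModerationPrior,
    SimulationConfig,
    TriomicsError,
    adjust_bh,
    fit_moderated_contrasts,
    generate_study,
    pca_samples,
    two_sided_ttests,
)
from triomics.linear_models import estimate_prior, trigamma_inverse

from conftest import make_matrix, make_meta


def bh_by_definition(p):
    """Brute-force step-up: independent oracle for adjust_bh."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj


class TestAdjustBH:
    def test_textbook_example(self):
        np.testing.assert_allclose(
            adjust_bh([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_and_degenerate(self):
        assert adjust_bh([0.3])[0] == pytest.approx(0.3)
        np.testing.assert_allclose(adjust_bh([1.0, 1.0, 1.0]), 1.0)

    def test_matches_step_up_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            p = rng.random(rng.integers(1, 50))
            np.testing.assert_allclose(adjust_bh(p), bh_by_definition(p), atol=1e-12)

    def test_nan_rejected(self):
        with pytest.raises(TriomicsError):
            adjust_bh([0.1, np.nan])

    @settings(deadline=None, max_examples=50)
    @given(
        st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=30),
        st.randoms(use_true_random=False),
    )
    def test_permutation_equivariance(self, p, rnd):
        perm = list(range(len(p)))
        rnd.shuffle(perm)
        direct = adjust_bh(np.array(p)[perm])
        permuted = adjust_bh(p)[perm]
        np.testing.assert_allclose(direct, permuted, atol=1e-12)


def null_matrix_and_meta(n_analytes=200, n_per_group=8, seed=0):
    meta = make_meta(n_per_group=n_per_group, seed=seed)
    rng = np.random.default_rng(seed + 1)
    m = make_matrix(rng.normal(0, 1, (3 * n_per_group, n_analytes)))
    return m, meta


class TestModeratedContrasts:
    def test_zero_prior_df_gives_ordinary_t(self):
        m, meta = null_matrix_and_meta()
        plain = fit_moderated_contrasts(
            m, meta, prior=ModerationPrior(d0=0.0, s0_sq=1.0)
        )
        # ordinary contrast t computed independently per analyte via OLS
        import statsmodels.api as sm

        g = meta.group
        X = pd.get_dummies(g)[["healthy", "remission", "active"]].astype(float)
        X["age"] = meta.age - meta.age.mean()
        X["sex"] = meta.sex
        sub = plain.for_contrast("healthy_vs_active")
        for analyte in list(m.analyte_ids[:10]):
            fit = sm.OLS(m.values[analyte].to_numpy(), X.to_numpy()).fit()
            t_oracle = fit.t_test(np.array([-1.0, 0, 1.0, 0, 0]))
            assert sub.loc[analyte, "t"] == pytest.approx(
                float(np.squeeze(t_oracle.tvalue)), abs=1e-10
            )
            assert sub.loc[analyte, "p"] == pytest.approx(
                float(np.squeeze(t_oracle.pvalue)), abs=1e-10
            )

    def test_infinite_prior_df_shrinks_fully(self):
        m, meta = null_matrix_and_meta()
        res = fit_moderated_contrasts(
            m, meta, prior=ModerationPrior(d0=np.inf, s0_sq=2.5)
        )
        spec = ContrastSpec.from_name("healthy_vs_active")
        sub = res.for_contrast("healthy_vs_active")
        # with s2 fully shrunk, t is the estimate over sqrt(s0^2 * v): all
        # analytes share the same estimate-to-t ratio
        ratio = sub["estimate"] / sub["t"]
        assert float(ratio.std()) < 1e-10

    def test_null_type_one_error(self):
        """Uniform p-values under the global null (2000 analytes)."""
        m, meta = null_matrix_and_meta(n_analytes=2000, n_per_group=12, seed=3)
        res = fit_moderated_contrasts(m, meta)
        p = res.for_contrast("remission_vs_active")["p"].to_numpy()
        assert 0.04 <= (p < 0.05).mean() <= 0.06

    def test_fold_change_recovery(self):
        """Planted log2 shift of 2 is estimated within 0.1 on average."""
        cfg = SimulationConfig(
            n_per_group=12,
            block_sizes={"metabolite": 300},
            effects=[("metabolite", tuple(range(50)), "healthy_vs_active", 2.0)],
            seed=17,
        )
        study = generate_study(cfg)
        res = fit_moderated_contrasts(study.blocks["metabolite"], study.meta)
        sub = res.for_contrast("healthy_vs_active")
        planted = [a for _, a in study.truth.true_effect_sets["healthy_vs_active"]]
        assert float(sub.loc[planted, "estimate"].mean()) == pytest.approx(2.0, abs=0.1)

    def test_shrinkage_pulls_between_sample_and_prior(self):
        """Posterior variance lies strictly between s^2 and s0^2."""
        m, meta = null_matrix_and_meta(seed=9)
        res = fit_moderated_contrasts(m, meta)
        prior = res.prior
        assert np.isfinite(prior.d0) and prior.d0 > 0
        # sample residual variances recomputed independently with lstsq
        g = meta.group.to_numpy()
        X = np.column_stack(
            [
                (g == "healthy").astype(float),
                (g == "remission").astype(float),
                (g == "active").astype(float),
                meta.age.to_numpy() - meta.age.to_numpy().mean(),
                meta.sex.to_numpy(),
            ]
        )
        Y = m.values.to_numpy()
        beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
        resid = Y - X @ beta
        d = X.shape[0] - X.shape[1]
        s2 = (resid**2).sum(axis=0) / d
        # implied posterior variance from the moderated and the plain t
        sub = res.for_contrast("healthy_vs_active")
        plain = fit_moderated_contrasts(
            m, meta, prior=ModerationPrior(d0=0.0, s0_sq=1.0)
        ).for_contrast("healthy_vs_active")
        s2_post = s2 * (plain["t"].to_numpy() / sub["t"].to_numpy()) ** 2
        lo = np.minimum(s2, prior.s0_sq)
        hi = np.maximum(s2, prior.s0_sq)
        inside = (s2_post > lo - 1e-12) & (s2_post < hi + 1e-12)
        assert inside.all()

    def test_rank_deficient_design_named(self):
        meta = make_meta(n_per_group=4)
        meta.table["age"] = 30.0  # constant age (centred -> zero column)
        m = make_matrix(np.random.default_rng(0).normal(size=(12, 5)))
        with pytest.raises(TriomicsError, match="age"):
            fit_moderated_contrasts(m, meta)

    def test_pairwise_subset_mode_runs(self):
        m, meta = null_matrix_and_meta(n_analytes=50)
        res = fit_moderated_contrasts(m, meta, groups_subset=True)
        assert set(res.table["contrast"]) == {
            "healthy_vs_active", "healthy_vs_remission", "remission_vs_active",
        }

    def test_flags_match_adjusted_p(self):
        m, meta = null_matrix_and_meta(n_analytes=100, seed=5)
        res = fit_moderated_contrasts(m, meta, q=0.5)
        t = res.table
        assert (t["significant"] == (t["p_adj"] <= 0.5)).all()
        assert (t["p_adj"] >= t["p"] - 1e-15).all()


class TestPriorEstimation:
    def test_recovers_known_prior(self):
        """Sampling s2 ~ s0^2 * F(d, d0) recovers (d0, s0^2) by moments."""
        rng = np.random.default_rng(12)
        d, d0, s0_sq = 10, 8.0, 4.0
        chi_num = rng.chisquare(d, 20_000) / d
        chi_den = rng.chisquare(d0, 20_000) / d0
        s2 = s0_sq * chi_num / chi_den
        prior = estimate_prior(s2, d)
        assert prior.d0 == pytest.approx(d0, rel=0.1)
        assert prior.s0_sq == pytest.approx(s0_sq, rel=0.05)

    def test_trigamma_inverse_roundtrip(self):
        from scipy.special import polygamma

        for y in (0.1, 0.5, 1.0, 5.0, 50.0):
            x = float(polygamma(1, y))
            assert trigamma_inverse(x) == pytest.approx(y, rel=1e-6)

    def test_matches_limma_squeezevar(self, tmp_path):
        """Independent oracle: Bioconductor limma::squeezeVar on the same s2."""
        rng = np.random.default_rng(4)
        s2 = rng.chisquare(10, 150) / 10 * 2.0
        d = 10
        s2_file = tmp_path / "s2.txt"
        np.savetxt(s2_file, s2)
        script = tmp_path / "squeeze.R"
        script.write_text(
            f"""suppressMessages(library(limma))
s2 <- scan("{s2_file}")
fit <- squeezeVar(s2, df={d})
cat(fit$df.prior, fit$var.prior, sep="\\n")
"""
        )
        proc = subprocess.run(
            ["Rscript", "--vanilla", str(script)],
            capture_output=True, text=True, timeout=120,
        )
        if proc.returncode != 0:
            pytest.skip(f"Rscript unavailable: {proc.stderr[:200]}")
        d0_r, s0_r = (float(x) for x in proc.stdout.split())
        prior = estimate_prior(s2, d)
        assert prior.d0 == pytest.approx(d0_r, rel=1e-4)
        assert prior.s0_sq == pytest.approx(s0_r, rel=1e-4)


class TestWelchTTests:
    def test_identical_groups_null(self):
        vals = np.tile(np.array([[1.0], [2.0], [3.0], [4.0]]), (3, 1))
        m = make_matrix(vals)
        meta = make_meta(n_per_group=4)
        res = two_sided_ttests(m, meta, "healthy", "active")
        row = res.table.iloc[0]
        assert row["t"] == pytest.approx(0.0)
        assert row["p"] == pytest.approx(1.0)

    def test_hand_computed_welch(self):
        from triomics import SampleMeta

        vals = np.array([[1.0], [2.0], [3.0], [4.0], [5.0], [6.0], [0.0], [0.0]])
        ids = [f"S{i}" for i in range(8)]
        m = make_matrix(vals, sample_ids=ids)
        meta = SampleMeta(
            pd.DataFrame(
                {
                    "group": ["healthy"] * 3 + ["active"] * 3 + ["remission"] * 2,
                    "age": np.arange(30.0, 38.0),
                    "sex": [0, 1] * 4,
                },
                index=ids,
            )
        )
        res = two_sided_ttests(m, meta, "healthy", "active")
        row = res.table.iloc[0]
        assert abs(row["t"]) == pytest.approx(3.674, abs=1e-3)
        assert row["p"] == pytest.approx(0.0214, abs=1e-3)
        assert row["estimate"] == pytest.approx(3.0)

    def test_swapping_groups_negates_t(self):
        m, meta = null_matrix_and_meta(n_analytes=20)
        ab = two_sided_ttests(m, meta, "healthy", "active").table
        ba = two_sided_ttests(m, meta, "active", "healthy").table
        np.testing.assert_allclose(ab["t"], -ba["t"], atol=1e-12)
        np.testing.assert_allclose(ab["p"], ba["p"], atol=1e-12)

    def test_tiny_group_rejected(self):
        m = make_matrix(np.ones((4, 2)))
        meta = make_meta(n_per_group=1, sample_ids=["S0", "S1", "S2"])
        with pytest.raises(Exception):
            two_sided_ttests(m, meta, "healthy", "active")


class TestPCA:
    def test_rank_one_data(self):
        u = np.arange(1.0, 11.0)[:, None]
        v = np.array([[1.0, 2.0, 3.0]])
        m = make_matrix(u @ v)
        scores, loadings, frac = pca_samples(m, 2, scale=False)
        assert frac[0] == pytest.approx(1.0)

    def test_reconstruction_identity(self):
        rng = np.random.default_rng(6)
        m = make_matrix(rng.normal(size=(10, 8)))
        scores, loadings, _ = pca_samples(m, 8, scale=False)
        X = m.values.to_numpy()
        Xc = X - X.mean(axis=0)
        np.testing.assert_allclose(
            scores.to_numpy() @ loadings.to_numpy().T, Xc, atol=1e-10
        )

    def test_agreement_with_sklearn_oracle(self):
        from sklearn.decomposition import PCA

        rng = np.random.default_rng(7)
        m = make_matrix(rng.normal(size=(10, 8)))
        scores, loadings, frac = pca_samples(m, 3, scale=False)
        oracle = PCA(n_components=3).fit(m.values.to_numpy())
        np.testing.assert_allclose(frac, oracle.explained_variance_ratio_, atol=1e-8)
        for i in range(3):
            a = loadings.to_numpy()[:, i]
            b = oracle.components_[i]
            assert min(np.abs(a - b).max(), np.abs(a + b).max()) < 1e-8

    def test_orthonormal_loadings_and_sign_convention(self):
        rng = np.random.default_rng(8)
        m = make_matrix(rng.normal(size=(12, 6)))
        _, loadings, frac = pca_samples(m, 4)
        L = loadings.to_numpy()
        np.testing.assert_allclose(L.T @ L, np.eye(4), atol=1e-10)
        for i in range(4):
            j = np.argmax(np.abs(L[:, i]))
            assert L[j, i] > 0
        assert frac.sum() <= 1.0 + 1e-12

    def test_too_many_components_rejected(self):
        m = make_matrix(np.ones((4, 3)) + np.eye(4, 3))
        with pytest.raises(TriomicsError):
            pca_samples(m, 5)
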