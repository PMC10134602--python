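"""Design building, GLS fitting, moderation, weights and contrast tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import reboundomics as rb
from reboundomics import differential as diff
from reboundomics.containers import ValidationError


def _sample_table(n_donors=8, groups=("MS", "HC"), times=("T1", "T2", "T3", "PP"), seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for g in groups:
        for i in range(n_donors):
            donor = f"{g}{i:02d}"
            age = rng.normal(30, 3)
            for t in times:
                rows.append(
                    {"sample": f"{donor}_{t}", "donor": donor, "group": g,
                     "timepoint": t, "age": age,
                     "memory_fraction": rng.uniform(0.3, 0.6),
                     "viability": rng.uniform(0.8, 0.99)}
                )
    return rb.SampleTable(pd.DataFrame(rows).set_index("sample"))


class TestBuildDesign:
    def test_column_count_two_groups_four_times(self):
        samples = _sample_table()
        design = rb.build_design(samples, ["age", "memory_fraction", "viability"], "T1")
        # intercept + 2 groups x 3 non-reference times + 3 covariates
        assert design.n_coef == 1 + 6 + 3

    def test_single_group_single_time(self):
        samples = _sample_table(groups=("MS",), times=("T1",))
        design = rb.build_design(samples, ["age"], "T1")
        assert design.column_names == ["intercept", "age"]

    def test_group_missing_timepoint_drops_column(self):
        samples = _sample_table(times=("BP", "T1", "T3"))
        data = samples.data[~((samples.data["group"] == "HC") &
                              (samples.data["timepoint"] == "BP"))]
        design = rb.build_design(rb.SampleTable(data), [], "T1")
        assert "MS:BP" in design.column_names
        assert "HC:BP" not in design.column_names

    def test_rank_deficiency_reported(self):
        samples = _sample_table()
        samples.data["age2"] = samples.data["age"]
        with pytest.raises(ValidationError, match="collinear"):
            rb.build_design(samples, ["age", "age2"], "T1")

    def test_unknown_covariate_errors(self):
        with pytest.raises(ValidationError, match="bmi"):
            rb.build_design(_sample_table(), ["bmi"], "T1")

    def test_contrast_vector_within_group(self):
        design = rb.build_design(_sample_table(), [], "T1")
        c = design.contrast("MS", "T3", "T1")
        nonzero = {design.column_names[i]: v for i, v in enumerate(c) if v}
        assert nonzero == {"MS:T3": 1.0}
        c2 = design.contrast("MS", "PP", "T3")
        nonzero2 = {design.column_names[i]: v for i, v in enumerate(c2) if v}
        assert nonzero2 == {"MS:PP": 1.0, "MS:T3": -1.0}


class TestFitFeatureModels:
    def test_gls_reduces_to_ols_at_rho_zero(self, null_fits):
        data, design = null_fits
        fits = rb.fit_feature_models(data, design, rho=0.0)
        x = design.matrix.to_numpy()
        ref, *_ = np.linalg.lstsq(x, data.to_numpy().T, rcond=None)
        assert np.allclose(fits.coef, ref.T, atol=1e-10)

    def test_exact_fit_recovers_coefficients(self):
        rng = np.random.default_rng(5)
        x = np.column_stack([np.ones(12), rng.normal(size=(12, 2))])
        design = rb.DesignMatrix(
            pd.DataFrame(x, columns=["intercept", "a", "b"],
                         index=[f"s{i}" for i in range(12)]),
            pd.Series([f"d{i // 2}" for i in range(12)],
                      index=[f"s{i}" for i in range(12)]),
            reference_time="T1",
        )
        b_true = np.array([1.0, 2.0, 3.0])
        y = (x @ b_true)[None, :]
        data = rb.OmicsMatrix(
            pd.DataFrame(y, index=["f0"], columns=design.matrix.index), "m"
        )
        fits = rb.fit_feature_models(data, design, rho=0.4)
        assert fits.coef[0] == pytest.approx(b_true, abs=1e-10)
        assert fits.sigma2[0] == pytest.approx(0.0, abs=1e-16)

    @pytest.mark.parametrize("use_weights", [False, True])
    def test_matches_direct_gls_solve(self, use_weights):
        """Oracle: explicit normal equations with the full covariance."""
        rng = np.random.default_rng(6)
        n, p, g = 20, 4, 5
        x = np.column_stack([np.ones(n), rng.normal(size=(n, p - 1))])
        donors = pd.Series([f"d{i // 4}" for i in range(n)],
                           index=[f"s{i}" for i in range(n)])
        design = rb.DesignMatrix(
            pd.DataFrame(x, columns=[f"c{j}" for j in range(p)], index=donors.index),
            donors, reference_time="T1",
        )
        y = rng.normal(size=(g, n))
        data = rb.OmicsMatrix(
            pd.DataFrame(y, index=[f"f{i}" for i in range(g)], columns=donors.index), "m"
        )
        rho = 0.5
        weights = rng.uniform(0.5, 2.0, size=(g, n)) if use_weights else None
        fits = rb.fit_feature_models(data, design, rho=rho, weights=weights)

        d = donors.to_numpy()
        block = (d[:, None] == d[None, :]).astype(float)
        corr = (1 - rho) * np.eye(n) + rho * block
        for i in range(g):
            w = weights[i] if use_weights else np.ones(n)
            dw = np.diag(1.0 / np.sqrt(w))
            v = dw @ corr @ dw
            vinv = np.linalg.inv(v)
            ref = np.linalg.solve(x.T @ vinv @ x, x.T @ vinv @ y[i])
            assert fits.coef[i] == pytest.approx(ref, abs=1e-8)
            r = y[i] - x @ ref
            s2 = (r @ vinv @ r) / (n - p)
            assert fits.sigma2[i] == pytest.approx(s2, rel=1e-8)

    def test_rho_too_negative_for_block_size_errors(self):
        # blocks of 4: equicorrelation needs rho > -1/3
        rng = np.random.default_rng(8)
        n = 12
        x = np.column_stack([np.ones(n), rng.normal(size=n)])
        idx = [f"s{i}" for i in range(n)]
        design = rb.DesignMatrix(
            pd.DataFrame(x, columns=["intercept", "c"], index=idx),
            pd.Series([f"d{i // 4}" for i in range(n)], index=idx),
            reference_time="T1",
        )
        data = rb.OmicsMatrix(
            pd.DataFrame(rng.normal(size=(3, n)), index=["f0", "f1", "f2"],
                         columns=idx), "m",
        )
        with pytest.raises(ValidationError, match="positive definite"):
            rb.fit_feature_models(data, design, rho=-0.5)


class TestBlockCorrelation:
    def test_all_singleton_blocks_returns_zero(self):
        rng = np.random.default_rng(7)
        n = 10
        x = np.column_stack([np.ones(n), rng.normal(size=n)])
        design = rb.DesignMatrix(
            pd.DataFrame(x, columns=["intercept", "c"], index=[f"s{i}" for i in range(n)]),
            pd.Series([f"d{i}" for i in range(n)], index=[f"s{i}" for i in range(n)]),
            reference_time="T1",
        )
        data = rb.OmicsMatrix(
            pd.DataFrame(rng.normal(size=(20, n)), index=[f"f{i}" for i in range(20)],
                         columns=design.matrix.index), "m",
        )
        with pytest.warns(UserWarning, match="no donor"):
            assert rb.estimate_block_correlation(data, design) == 0.0

    @pytest.mark.parametrize("rho", [0.0, 0.5])
    def test_parameter_recovery(self, rho):
        cfg = rb.CohortConfig(
            n_donors_per_group={"MS": 8, "HC": 8}, timepoints=("T1", "T2", "T3", "PP"),
            n_cpgs=2000, n_genes=10, frac_rebound=0.0, rho_donor=rho, seed=21,
        )
        beta, _, samples, _, _ = rb.generate_cohort(cfg)
        m = rb.beta_m_transform(beta, "m")
        design = rb.build_design(samples, ["age", "memory_fraction", "viability"], "T1")
        est = rb.estimate_block_correlation(m, design)
        assert est == pytest.approx(rho, abs=0.05 if rho == 0 else 0.1)


class TestEbayesModerate:
    def test_prior_df_zero_gives_ordinary_t(self, null_fits):
        data, design = null_fits
        fits = rb.fit_feature_models(data, design, rho=0.0)
        mod = rb.ebayes_moderate(fits, prior_df=0.0, prior_var=1.0)
        c = np.array([0.0, 1.0, 0.0, 0.0])
        res = rb.test_contrast(fits, c, moderation=mod)
        # independent textbook OLS t-test per feature
        x = design.matrix.to_numpy()
        xtx_inv = np.linalg.inv(x.T @ x)
        n, p = x.shape
        for i in range(0, 50):
            y = data.to_numpy()[i]
            b = xtx_inv @ x.T @ y
            s2 = ((y - x @ b) ** 2).sum() / (n - p)
            t_ref = b[1] / np.sqrt(s2 * xtx_inv[1, 1])
            p_ref = 2 * stats.t.sf(abs(t_ref), n - p)
            assert res.table["t"].iloc[i] == pytest.approx(t_ref, abs=1e-8)
            assert res.table["p"].iloc[i] == pytest.approx(p_ref, abs=1e-8)

    def test_infinite_prior_df_gives_z_statistic(self, null_fits):
        data, design = null_fits
        fits = rb.fit_feature_models(data, design, rho=0.0)
        mod = rb.ebayes_moderate(fits, prior_df=np.inf, prior_var=2.0)
        assert np.all(mod.s2_post == 2.0)
        c = np.array([0.0, 1.0, 0.0, 0.0])
        res = rb.test_contrast(fits, c, moderation=mod)
        xtx_inv = np.linalg.inv(design.matrix.to_numpy().T @ design.matrix.to_numpy())
        se = np.sqrt(2.0 * xtx_inv[1, 1])
        assert np.allclose(res.table["t"], fits.coef[:, 1] / se, atol=1e-10)

    def test_hyperparameter_recovery(self):
        rng = np.random.default_rng(30)
        dg, s02_true = 30.0, 4.0
        s2 = s02_true * rng.chisquare(dg, 10000) / dg
        d0, s02 = diff.fit_scaled_f(s2, dg)
        assert s02 == pytest.approx(s02_true, rel=0.1)
        assert d0 > 50 or np.isinf(d0)  # near-infinite prior df

    def test_identical_variances_handled(self, null_fits):
        data, design = null_fits
        fits = rb.fit_feature_models(data, design, rho=0.0)
        fits.sigma2 = np.full_like(fits.sigma2, 3.0)
        mod = rb.ebayes_moderate(fits)
        assert np.isinf(mod.df_prior)
        assert np.all(np.isfinite(mod.s2_post))

    def test_posterior_between_prior_and_sample(self, null_fits):
        data, design = null_fits
        fits = rb.fit_feature_models(data, design, rho=0.0)
        mod = rb.ebayes_moderate(fits)
        lo = np.minimum(fits.sigma2, mod.s2_prior)
        hi = np.maximum(fits.sigma2, mod.s2_prior)
        assert np.all(mod.s2_post >= lo - 1e-12)
        assert np.all(mod.s2_post <= hi + 1e-12)


class TestVoomWeights:
    def _design(self, samples):
        return rb.build_design(samples, [], "T1")

    def test_constant_variance_gives_flat_weights(self):
        # counts engineered so log-CPM noise is homoscedastic across abundance
        rng = np.random.default_rng(31)
        samples = _sample_table(n_donors=4)
        n = len(samples.data)
        mu = rng.uniform(6, 12, 2000)
        y = mu[:, None] + rng.normal(0, 0.4, (2000, n))
        counts = np.round(2.0**y).astype(int)
        mat = rb.OmicsMatrix(
            pd.DataFrame(counts, index=[f"g{i}" for i in range(2000)],
                         columns=samples.data.index), "count",
        )
        design = self._design(samples)
        w = rb.voom_weights(mat, design, rb.tmm_factors(mat))
        assert w.max() / w.min() < 1.6

    def test_poisson_counts_weights_increase_with_abundance(self):
        rng = np.random.default_rng(32)
        samples = _sample_table(n_donors=4)
        n = len(samples.data)
        mu = np.geomspace(5, 5000, 1500)
        counts = rng.poisson(mu[:, None], (1500, n))
        mat = rb.OmicsMatrix(
            pd.DataFrame(counts, index=[f"g{i}" for i in range(1500)],
                         columns=samples.data.index), "count",
        )
        design = self._design(samples)
        w = rb.voom_weights(mat, design, rb.tmm_factors(mat))
        mean_w = w.mean(axis=1)
        assert mean_w[mu > 1000].mean() > mean_w[mu < 50].mean()

    def test_no_residual_df_errors(self):
        samples = _sample_table(n_donors=1, groups=("MS",), times=("T1", "T2"))
        mat = rb.OmicsMatrix(
            pd.DataFrame([[5, 6]], index=["g0"], columns=samples.data.index), "count"
        )
        design = rb.build_design(samples, [], "T1")
        with pytest.raises(ValidationError, match="degrees of freedom"):
            rb.voom_weights(mat, design, rb.tmm_factors(mat))

    def test_few_genes_warns_uniform(self):
        samples = _sample_table(n_donors=4, groups=("MS",), times=("T1", "T2"))
        rng = np.random.default_rng(33)
        mat = rb.OmicsMatrix(
            pd.DataFrame(rng.poisson(100, (10, len(samples.data))),
                         index=[f"g{i}" for i in range(10)],
                         columns=samples.data.index), "count",
        )
        design = rb.build_design(samples, [], "T1")
        with pytest.warns(UserWarning, match="too few genes"):
            w = rb.voom_weights(mat, design, rb.tmm_factors(mat))
        assert np.all(w == 1.0)


class TestContrasts:
    def test_zero_contrast_gives_p_one(self, null_fits):
        data, design = null_fits
        fits = rb.fit_feature_models(data, design, rho=0.0)
        rb.ebayes_moderate(fits)
        res = rb.test_contrast(fits, np.zeros(4))
        assert np.all(res.table["estimate"] == 0.0)
        assert np.all(res.table["p"] == 1.0)

    def test_wrong_length_contrast_errors(self, null_fits):
        data, design = null_fits
        fits = rb.fit_feature_models(data, design, rho=0.0)
        with pytest.raises(ValidationError, match="length"):
            rb.test_contrast(fits, np.zeros(7))

    def test_deterministic(self, null_fits):
        data, design = null_fits
        fits = rb.fit_feature_models(data, design, rho=0.0)
        rb.ebayes_moderate(fits)
        c = np.array([0.0, 1.0, -1.0, 0.0])
        r1 = rb.test_contrast(fits, c)
        r2 = rb.test_contrast(fits, c)
        pd.testing.assert_frame_equal(r1.table, r2.table)

    def test_planted_effect_recovered(self, cohort, balanced_config):
        beta, _, samples, _, truth = cohort
        m = rb.beta_m_transform(beta, "m")
        design = rb.build_design(samples, ["age", "memory_fraction", "viability"], "T1")
        rho = rb.estimate_block_correlation(m, design)
        fits = rb.fit_feature_models(m, design, rho=rho)
        rb.ebayes_moderate(fits)
        res = rb.test_contrast(fits, design.contrast("MS", "T3", "T1"))
        cpgs = sorted(truth.rebound_cpgs)
        signs = np.sign([truth.cpg_effects[c] for c in cpgs])
        est = res.table.loc[cpgs, "estimate"].to_numpy() * signs
        assert est.mean() == pytest.approx(balanced_config.effect_m, abs=0.2)


class TestMeanBetaDifference:
    def test_arithmetic_and_antisymmetry(self):
        samples = _sample_table(n_donors=3, groups=("MS",), times=("T1", "T3"))
        df = samples.data
        vals = np.where(df["timepoint"] == "T1", 0.40, 0.47)[None, :]
        beta = rb.OmicsMatrix(
            pd.DataFrame(vals, index=["cg0"], columns=df.index), "beta"
        )
        d = rb.mean_beta_difference(beta, samples, "MS", "T1", "T3")
        assert d.iloc[0] == pytest.approx(0.07)
        d_rev = rb.mean_beta_difference(beta, samples, "MS", "T3", "T1")
        assert d_rev.iloc[0] == pytest.approx(-0.07)

    def test_identical_timepoints_give_zero(self):
        samples = _sample_table(n_donors=3, groups=("MS",), times=("T1", "T3"))
        beta = rb.OmicsMatrix(
            pd.DataFrame(np.full((2, len(samples.data)), 0.3),
                         index=["cg0", "cg1"], columns=samples.data.index), "beta",
        )
        d = rb.mean_beta_difference(beta, samples, "MS", "T1", "T3")
        assert np.allclose(d, 0.0)

    def test_missing_cell_errors(self):
        samples = _sample_table(n_donors=3, groups=("MS",), times=("T1", "T3"))
        beta = rb.OmicsMatrix(
            pd.DataFrame(np.full((1, len(samples.data)), 0.3),
                         index=["cg0"], columns=samples.data.index), "beta",
        )
        with pytest.raises(ValidationError, match="PP"):
            rb.mean_beta_difference(beta, samples, "MS", "T1", "PP")


class TestActivationContrast:
    def _activation_cohort(self, n_donors=20, n_genes=500, n_affected=100, lfc=2.0, seed=40):
        rng = np.random.default_rng(seed)
        rows = []
        for i in range(n_donors):
            donor = f"d{i:02d}"
            for state in ("resting", "activated"):
                level = rng.uniform(0.0, 0.05) if state == "resting" else rng.uniform(0.4, 0.9)
                rows.append({"sample": f"{donor}_{state}", "donor": donor, "group": "MS",
                             "timepoint": "T1", "state": state, "activation_level": level})
        samples = rb.SampleTable(pd.DataFrame(rows).set_index("sample"))
        df = samples.data
        activated = (df["state"] == "activated").to_numpy(float)
        base = rng.uniform(5, 10, n_genes)
        eta = base[:, None] + rng.normal(0, 0.3, (n_genes, len(df)))
        eta[:n_affected] += lfc * activated[None, :]
        counts = rng.poisson(2.0**eta)
        mat = rb.OmicsMatrix(
            pd.DataFrame(counts, index=[f"g{i}" for i in range(n_genes)],
                         columns=df.index), "count",
        )
        return mat, samples

    def test_planted_activation_effect_detected(self):
        counts, samples = self._activation_cohort()
        res = rb.activation_contrast(counts, samples)
        flagged = res.table.index[res.table["significant"]]
        affected = {f"g{i}" for i in range(100)}
        assert len(affected & set(flagged)) >= 90

    def test_null_has_few_flags(self):
        counts, samples = self._activation_cohort(n_affected=0, seed=41)
        res = rb.activation_contrast(counts, samples)
        assert res.table["significant"].mean() <= 0.05

    def test_single_state_errors(self):
        counts, samples = self._activation_cohort(n_donors=4)
        resting = samples.data[samples.data["state"] == "resting"]
        with pytest.raises(ValidationError, match="resting"):
            rb.activation_contrast(
                counts.subset_samples(resting.index), rb.SampleTable(resting)
            )


class TestBHAdjust:
    def test_single_p_unchanged(self):
        assert rb.bh_adjust(np.array([0.03]))[0] == pytest.approx(0.03)

    def test_all_equal_unchanged(self):
        out = rb.bh_adjust(np.full(5, 0.2))
        assert np.allclose(out, 0.2)

    def test_step_up_by_hand(self):
        out = rb.bh_adjust(np.array([0.01, 0.02, 0.03, 0.04]))
        assert np.allclose(out, 0.04)

    def test_matches_brute_force_step_up(self):
        rng = np.random.default_rng(50)
        for _ in range(20):
            p = rng.uniform(size=rng.integers(1, 200))
            ours = rb.bh_adjust(p)
            # brute force: adj_i = min over j with p_j >= p_i of p_j * n / rank_j
            n = len(p)
            order = np.argsort(p)
            ref = np.empty(n)
            running = 1.0
            for rank in range(n, 0, -1):
                idx = order[rank - 1]
                running = min(running, p[idx] * n / rank)
                ref[idx] = running
            assert np.allclose(ours, ref, atol=1e-12)

    def test_invalid_p_errors(self):
        with pytest.raises(ValidationError):
            rb.bh_adjust(np.array([0.5, 1.5]))
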