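import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from imprintscreen import DataError, EBayesParams
from imprintscreen import diffmeth as dm

from conftest import make_dataset


def two_group_dataset(rng, n_probes, n_case=5, n_ctrl=7, sd=0.05, base=0.5):
    beta = np.clip(base + rng.normal(0, sd, size=(n_probes, n_case + n_ctrl)), 0, 1)
    return make_dataset(beta, groups=["NLRP7_RHM"] * n_case
                        + ["PLACENTA_FIRST"] * 3 + ["PLACENTA_TERM"] * (n_ctrl - 3))


class TestGroupDifference:
    def test_matches_textbook_formula(self):
        """Seeded draws, n = 4 + 7: delta and pooled variance equal a direct
        per-probe computation with scipy off the raw arrays."""
        rng = np.random.default_rng(42)
        beta = rng.uniform(0.2, 0.8, size=(30, 11))
        ds = make_dataset(beta, groups=["NLRP7_RHM"] * 4 + ["PLACENTA_FIRST"] * 3
                          + ["PLACENTA_TERM"] * 4)
        out = dm.group_difference(ds, "NLRP7_RHM",
                                  ["PLACENTA_FIRST", "PLACENTA_TERM"])
        for i in range(30):
            case, ctrl = beta[i, :4], beta[i, 4:]
            delta = case.mean() - ctrl.mean()
            s2 = ((case.var(ddof=1) * 3 + ctrl.var(ddof=1) * 6) / 9)
            assert out["delta_beta"].iloc[i] == pytest.approx(delta, abs=1e-12)
            assert out["s_sq"].iloc[i] == pytest.approx(s2, rel=1e-10)
            assert out["df_residual"].iloc[i] == 9
            # and the ordinary t matches scipy's pooled two-sample t
            t_sp, _ = sps.ttest_ind(case, ctrl)
            t_ours = delta / np.sqrt(s2 * (1 / 4 + 1 / 7))
            assert t_ours == pytest.approx(t_sp, rel=1e-10)

    def test_zero_variance_groups(self):
        ds = make_dataset([[0.1, 0.1, 0.5, 0.5]],
                          groups=["NLRP7_RHM"] * 2 + ["PLACENTA_TERM"] * 2)
        out = dm.group_difference(ds, "NLRP7_RHM", ["PLACENTA_TERM"])
        assert out["delta_beta"].iloc[0] == pytest.approx(-0.4)
        assert out["s_sq"].iloc[0] == 0.0

    def test_identical_groups_zero_delta(self):
        ds = make_dataset([[0.3, 0.4, 0.3, 0.4]],
                          groups=["NLRP7_RHM"] * 2 + ["PLACENTA_TERM"] * 2)
        out = dm.group_difference(ds, "NLRP7_RHM", ["PLACENTA_TERM"])
        assert out["delta_beta"].iloc[0] == pytest.approx(0.0)

    def test_group_with_one_sample_fatal(self):
        ds = make_dataset([[0.1, 0.5, 0.5]],
                          groups=["NLRP7_RHM", "PLACENTA_TERM", "PLACENTA_TERM"])
        with pytest.raises(DataError, match="case=1"):
            dm.group_difference(ds, "NLRP7_RHM", ["PLACENTA_TERM"])


class TestEBayes:
    def test_equal_variances_are_fixed_point(self):
        """When every probe has the same s2, moderation leaves it unchanged
        for any finite prior weight."""
        gd = pd.DataFrame({
            "delta_beta": np.linspace(-0.3, 0.3, 60),
            "s_sq": np.full(60, 0.01),
            "df_residual": 10, "n_case": 5, "n_control": 7,
        })
        for d0 in (1.0, 4.0, 100.0):
            prior = EBayesParams(d0=d0, s0_sq=0.01)
            _, out = dm.ebayes_moderate(gd, prior=prior)
            np.testing.assert_allclose(out["s_sq_post"], 0.01, rtol=1e-12)

    def test_tiny_prior_df_approaches_ordinary_t(self):
        rng = np.random.default_rng(1)
        gd = pd.DataFrame({
            "delta_beta": rng.normal(0, 0.1, 100),
            "s_sq": rng.uniform(0.001, 0.02, 100),
            "df_residual": 10, "n_case": 5, "n_control": 7,
        })
        prior = EBayesParams(d0=1e-9, s0_sq=0.01)
        _, out = dm.ebayes_moderate(gd, prior=prior)
        ordinary = dm.ordinary_t(gd)
        np.testing.assert_allclose(out["t_mod"], ordinary["t_ordinary"], rtol=1e-4)

    def test_moderation_shrinks_toward_prior(self):
        """Probes quieter than the prior get larger variance (smaller |t|);
        noisier probes get shrunk variance (larger |t|)."""
        rng = np.random.default_rng(2)
        ds = two_group_dataset(rng, 2000)
        gd = dm.group_difference(ds, "NLRP7_RHM",
                                 ["PLACENTA_FIRST", "PLACENTA_TERM"])
        prior, out = dm.ebayes_moderate(gd)
        ordinary = dm.ordinary_t(gd)
        below = gd["s_sq"] < prior.s0_sq
        nz = ordinary["t_ordinary"].abs() > 0
        assert (out.loc[below & nz, "t_mod"].abs()
                <= ordinary.loc[below & nz, "t_ordinary"].abs() + 1e-12).all()
        above = gd["s_sq"] > prior.s0_sq
        assert (out.loc[above & nz, "t_mod"].abs()
                >= ordinary.loc[above & nz, "t_ordinary"].abs() - 1e-12).all()

    def test_sign_consistency_and_monotonicity(self):
        gd = pd.DataFrame({
            "delta_beta": np.linspace(-0.5, 0.5, 101),
            "s_sq": np.full(101, 0.01),
            "df_residual": 10, "n_case": 5, "n_control": 7,
        })
        _, out = dm.ebayes_moderate(gd, prior=EBayesParams(4.0, 0.01))
        nz = out["delta_beta"] != 0
        assert (np.sign(out.loc[nz, "t_mod"])
                == np.sign(out.loc[nz, "delta_beta"])).all()
        assert (np.diff(out["t_mod"]) > 0).all()

    def test_identical_variances_give_infinite_prior_df(self):
        gd = pd.DataFrame({
            "delta_beta": np.zeros(80),
            "s_sq": np.full(80, 0.004),
            "df_residual": 10, "n_case": 5, "n_control": 7,
        })
        prior, out = dm.ebayes_moderate(gd)
        assert np.isinf(prior.d0)
        # log-scale moment correction: s0^2 = s2 * (df/2) / exp(digamma(df/2))
        from scipy.special import digamma
        expected = 0.004 * 5 / np.exp(digamma(5.0))
        assert prior.s0_sq == pytest.approx(expected, rel=1e-9)
        np.testing.assert_allclose(out["s_sq_post"], prior.s0_sq)
        assert (out["p_value"] == 1.0).all()

    def test_parameter_recovery_from_simulated_variances(self):
        """10,000 probes with s2 ~ s0^2 * (chi2_d0 / d0)^-1 * chi2_df / df:
        the moment estimator recovers d0 within 25% and s0^2 within 10%."""
        rng = np.random.default_rng(123)
        n, d0, s0_sq, df = 10_000, 4.0, 0.01, 10
        true_var = s0_sq * d0 / rng.chisquare(d0, size=n)
        s_sq = true_var * rng.chisquare(df, size=n) / df
        prior = dm.fit_variance_prior(s_sq, df)
        assert prior.d0 == pytest.approx(d0, rel=0.25)
        assert prior.s0_sq == pytest.approx(s0_sq, rel=0.10)

    def test_trigamma_inverse_round_trip(self):
        from scipy.special import polygamma
        for y in (0.01, 0.5, 1.0, 5.0, 40.0):
            x = float(polygamma(1, y))
            assert dm.trigamma_inverse(x) == pytest.approx(y, rel=1e-6)

    def test_too_few_probes_fatal(self):
        gd = pd.DataFrame({"delta_beta": [0.1] * 10, "s_sq": [0.01] * 10,
                           "df_residual": 10, "n_case": 5, "n_control": 7})
        with pytest.raises(DataError, match="50 probes"):
            dm.ebayes_moderate(gd)


class TestNullCalibration:
    def test_moderated_p_uniform_under_global_null(self):
        """Global null, 20,000 probes, 5 vs 7: P(p < 0.01) = 0.01 within
        3 binomial SE."""
        rng = np.random.default_rng(20260927)
        ds = two_group_dataset(rng, 20_000)
        _, table = dm.run_diffmeth(ds)
        rate = float((table["p_value"] < 0.01).mean())
        se = np.sqrt(0.01 * 0.99 / 20_000)
        assert abs(rate - 0.01) < 3 * se


class TestAgainstLimma:
    def test_moderated_t_matches_limma(self, tmp_path):
        """Independent oracle: Bioconductor limma's lmFit/eBayes on the same
        matrix reproduces our prior (d0, s0^2), moderated t and p-values."""
        rng = np.random.default_rng(77)
        n, n_case, n_ctrl = 400, 5, 7
        true_var = 0.01 * 4 / rng.chisquare(4, size=n)
        beta = 0.5 + rng.normal(size=(n, n_case + n_ctrl)) * np.sqrt(true_var)[:, None]
        beta = np.clip(beta, 0, 1)
        ds = make_dataset(beta, groups=["NLRP7_RHM"] * n_case
                          + ["PLACENTA_TERM"] * n_ctrl)
        gd = dm.group_difference(ds, "NLRP7_RHM", ["PLACENTA_TERM"])
        prior, ours = dm.ebayes_moderate(gd)

        mat = tmp_path / "beta.csv"
        pd.DataFrame(beta).to_csv(mat, index=False)
        rscript = tmp_path / "oracle.R"
        rscript.write_text(f"""
suppressMessages(library(limma))
x <- as.matrix(read.csv("{mat.as_posix()}"))
grp <- factor(c(rep("case", {n_case}), rep("ctrl", {n_ctrl})), levels=c("ctrl","case"))
fit <- lmFit(x, model.matrix(~ grp))
fit <- eBayes(fit)
out <- data.frame(t=fit$t[,2], p=fit$p.value[,2], coef=fit$coefficients[,2])
write.csv(out, "{(tmp_path / 'limma.csv').as_posix()}", row.names=FALSE)
cat(fit$df.prior[1], fit$s2.prior[1], sep="\\n")
""")
        res = subprocess.run(["Rscript", rscript.as_posix()],
                             capture_output=True, text=True, check=True)
        d0_l, s0_l = [float(v) for v in res.stdout.strip().split()[-2:]]
        limma = pd.read_csv(tmp_path / "limma.csv")

        assert prior.d0 == pytest.approx(d0_l, rel=1e-4)
        assert prior.s0_sq == pytest.approx(s0_l, rel=1e-4)
        np.testing.assert_allclose(ours["delta_beta"], limma["coef"], rtol=1e-8)
        np.testing.assert_allclose(ours["t_mod"], limma["t"], rtol=1e-5)
        np.testing.assert_allclose(ours["p_value"], limma["p"], rtol=1e-5)
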