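"""Trial-design REML, de-regression and entry-mean heritability."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

from cbsdgs import stage1
from cbsdgs.stage1 import MixedModelSpec, Stage1Fit


def _balanced_oneway(n_clones, reps, sigma_c, sigma_e, seed):
    rng = np.random.default_rng(seed)
    c = rng.normal(0, sigma_c, n_clones)
    y = np.repeat(c, reps) + rng.normal(0, sigma_e, n_clones * reps)
    return pd.DataFrame({
        "clone": np.repeat([f"c{i:03d}" for i in range(n_clones)], reps),
        "y": y})


class TestREML:
    def test_balanced_design_matches_anova_closed_form(self):
        """REML equals the ANOVA estimator (MS_clone - MS_error)/r when the
        layout is balanced and the estimate is interior."""
        df = _balanced_oneway(120, 2, 1.0, 1.0, seed=9)
        fit = stage1.reml_fit(MixedModelSpec(
            response="y", data=df, fixed=[], random=["clone"]))
        means = df.groupby("clone")["y"].mean()
        ms_c = 2 * means.var(ddof=1)
        ms_e = df.groupby("clone")["y"].var(ddof=1).mean()
        assert fit.varcomps["clone"] == pytest.approx((ms_c - ms_e) / 2,
                                                      abs=1e-6)
        assert fit.varcomps["residual"] == pytest.approx(ms_e, abs=1e-6)

    def test_constant_response_gives_zero_components(self):
        df = _balanced_oneway(30, 2, 1, 1, seed=0)
        df["y"] = 3.0
        fit = stage1.reml_fit(MixedModelSpec(
            response="y", data=df, fixed=[], random=["clone"]))
        assert all(v == 0.0 for v in fit.varcomps.values())
        assert (fit.blups == 0).all()

    def test_constant_covariate_leaves_fit_unchanged(self):
        df = _balanced_oneway(60, 2, 1.0, 1.0, seed=3)
        df["cmds"] = 2.5
        base = stage1.reml_fit(MixedModelSpec(
            response="y", data=df, fixed=[], random=["clone"]))
        with_cov = stage1.reml_fit(MixedModelSpec(
            response="y", data=df, fixed=["cmds"], random=["clone"]))
        assert with_cov.varcomps["clone"] == pytest.approx(
            base.varcomps["clone"], rel=1e-6)
        pd.testing.assert_series_equal(base.blups, with_cov.blups,
                                       rtol=1e-6, atol=1e-9)

    def test_loglik_history_is_bounded_by_optimum(self):
        """Every likelihood evaluated during optimisation is <= the optimum."""
        from cbsdgs._reml import reml_independent
        df = _balanced_oneway(50, 2, 1.0, 1.0, seed=4)
        Z = pd.get_dummies(df["clone"]).to_numpy(float)
        fit = reml_independent(df["y"].to_numpy(), np.ones((len(df), 1)), [Z],
                               ["clone"])
        assert max(fit.history) <= fit.loglik + 1e-6

    def test_lme4_oracle_agreement(self, tmp_path):
        """Variance components and BLUPs match lme4's REML on the same data."""
        df = _balanced_oneway(60, 2, 1.2, 0.8, seed=11)
        rng = np.random.default_rng(1)
        df["block"] = rng.integers(0, 12, len(df)).astype(str)
        blk = pd.Series(rng.normal(0, 0.5, 12), index=[str(i) for i in range(12)])
        df["y"] = df["y"] + blk.loc[df["block"]].to_numpy()
        csv = tmp_path / "d.csv"
        df.to_csv(csv, index=False)
        rscript = tmp_path / "fit.R"
        rscript.write_text(textwrap.dedent(f"""
            suppressMessages(library(lme4))
            d <- read.csv("{csv}")
            m <- lmer(y ~ (1|clone) + (1|block), data=d, REML=TRUE)
            vc <- as.data.frame(VarCorr(m))
            write.csv(vc[, c("grp", "vcov")], "{tmp_path}/vc.csv",
                      row.names=FALSE)
            b <- ranef(m)$clone
            write.csv(data.frame(clone=rownames(b), blup=b[,1]),
                      "{tmp_path}/blup.csv", row.names=FALSE)
        """))
        subprocess.run(["Rscript", str(rscript)], check=True,
                       capture_output=True)
        vc = pd.read_csv(tmp_path / "vc.csv").set_index("grp")["vcov"]
        fit = stage1.reml_fit(MixedModelSpec(
            response="y", data=df, fixed=[], random=["clone", "block"]))
        assert fit.varcomps["clone"] == pytest.approx(vc["clone"], rel=1e-3)
        assert fit.varcomps["block"] == pytest.approx(vc["block"], rel=1e-2)
        assert fit.varcomps["residual"] == pytest.approx(vc["Residual"],
                                                         rel=1e-3)
        blup_r = pd.read_csv(tmp_path / "blup.csv").set_index("clone")["blup"]
        merged = pd.concat([fit.blups, blup_r], axis=1).dropna()
        assert np.corrcoef(merged.iloc[:, 0], merged.iloc[:, 1])[0, 1] > 0.9999


class TestDeregression:
    @pytest.mark.parametrize("blup,pev,sigma_c2,expected", [
        (1.0, 0.0, 1.0, 1.0),     # full reliability: identity
        (0.5, 0.5, 1.0, 1.0),
        (0.3, 0.9, 1.0, 3.0),
    ])
    def test_formula(self, blup, pev, sigma_c2, expected):
        fit = Stage1Fit(varcomps={"clone": sigma_c2, "residual": 1.0},
                        blups=pd.Series({"a": blup}),
                        pevs=pd.Series({"a": pev}), H2=0.5, loglik=0.0,
                        n_plots_per_clone=pd.Series({"a": 2}),
                        beta=pd.Series(dtype=float))
        out = stage1.deregress(fit)
        assert out.loc["a", "dereg"] == pytest.approx(expected, abs=1e-12)

    def test_low_reliability_flagged_not_returned(self):
        fit = Stage1Fit(varcomps={"clone": 1.0, "residual": 1.0},
                        blups=pd.Series({"a": 0.3, "b": 0.2}),
                        pevs=pd.Series({"a": 0.99, "b": 0.2}), H2=0.5,
                        loglik=0.0,
                        n_plots_per_clone=pd.Series({"a": 2, "b": 2}),
                        beta=pd.Series(dtype=float))
        out = stage1.deregress(fit)
        assert out.loc["a", "excluded"] and np.isnan(out.loc["a", "dereg"])
        assert not out.loc["b", "excluded"]

    def test_variance_inflates_relative_to_blups(self, small_cfg, small_pheno):
        fit = stage1.fit_panel(small_pheno,
                               response=f"{small_cfg.trait}_latent",
                               design="alpha")
        d = stage1.deregress(fit)
        kept = d[~d["excluded"]]
        assert kept["dereg"].var() >= fit.blups.loc[kept.index].var()

    def test_zero_clone_variance_raises(self):
        fit = Stage1Fit(varcomps={"clone": 0.0, "residual": 1.0},
                        blups=pd.Series({"a": 0.0}),
                        pevs=pd.Series({"a": 0.0}), H2=0.0, loglik=0.0,
                        n_plots_per_clone=pd.Series({"a": 1}),
                        beta=pd.Series(dtype=float))
        with pytest.raises(ValueError):
            stage1.deregress(fit)


class TestHeritability:
    @pytest.mark.parametrize("vc,expected", [
        ({"clone": 1.0, "residual": 1.0}, 1.0 / 1.5),
        ({"clone": 0.0, "residual": 1.0}, 0.0),
        ({"clone": 1.0, "residual": 0.0}, 1.0),
    ])
    def test_entry_mean_formula(self, vc, expected):
        n_plots = pd.Series({"a": 2, "b": 2, "c": 2})
        h2 = stage1.broad_sense_h2_from_components(vc, n_plots)
        assert h2 == pytest.approx(expected, abs=1e-12)

    def test_harmonic_mean_for_unbalanced_counts(self):
        vc = {"clone": 1.0, "residual": 1.0}
        n_plots = pd.Series({"a": 1, "b": 4})  # harmonic mean = 1.6
        assert stage1.broad_sense_h2_from_components(vc, n_plots) == \
            pytest.approx(1.0 / (1.0 + 1.0 / 1.6))

    def test_zero_plot_clones_excluded(self):
        vc = {"clone": 1.0, "residual": 1.0}
        n_plots = pd.Series({"a": 2, "b": 0})
        assert stage1.broad_sense_h2_from_components(vc, n_plots) == \
            pytest.approx(2.0 / 3.0)


class TestCorrelations:
    def test_self_and_sign_flip(self, rng):
        x = pd.Series(rng.normal(0, 1, 50),
                      index=[f"c{i}" for i in range(50)])
        tab = stage1.correlate_traits({"x": x, "neg": -x})
        by = tab.set_index(["set_a", "set_b"])["r"]
        assert by[("x", "x")] == pytest.approx(1.0)
        assert by[("x", "neg")] == pytest.approx(-1.0)

    def test_no_overlap_is_missing_not_zero(self):
        a = pd.Series([1.0, 2.0], index=["a", "b"])
        b = pd.Series([1.0, 2.0], index=["c", "d"])
        tab = stage1.correlate_traits({"a": a, "b": b})
        row = tab.set_index(["set_a", "set_b"]).loc[("a", "b")]
        assert np.isnan(row["r"]) and row["n"] == 0

    def test_attenuation_below_generating_genetic_correlation(self):
        """Observed de-regressed-BLUP correlation between two locations sits
        below the generating genetic correlation but above zero."""
        from cbsdgs import simdata
        rs = []
        for seed in range(5):
            cfg = simdata.SimConfig(
                n_clones_panel1=150, n_clones_panel2=0, markers_per_chrom=150,
                ai_fraction=0.8, genetic_corr=0.6, seed=seed,
                h2_per_location={"A": 0.5, "B": 0.5}, background_n=40)
            geno, truth = simdata.simulate_genotypes(cfg)
            ph = simdata.simulate_phenotypes(geno, truth, cfg)
            sets = {}
            for loc in ("A", "B"):
                fit = stage1.fit_panel(ph[ph["location"] == loc],
                                       response=f"{cfg.trait}_latent",
                                       design="alpha")
                sets[loc] = stage1.deregress(fit)["dereg"]
            rs.append(stage1.correlate_traits(sets)
                      .set_index(["set_a", "set_b"])["r"][("A", "B")])
        mean_r = float(np.mean(rs))
        assert 0.0 < mean_r < 0.6
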