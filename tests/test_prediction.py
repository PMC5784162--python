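"""Kernels, GBLUP variants, Bayesian regressions, RF, CV harness."""

import numpy as np
import pandas as pd
import pytest

from cbsdgs import genomics, prediction, simdata
from cbsdgs.genomics import GRM
from cbsdgs.prediction import KernelSet


@pytest.fixture(scope="module")
def sim():
    cfg = simdata.SimConfig(
        n_clones_panel1=120, n_clones_panel2=120, markers_per_chrom=200,
        background_n=60, ai_fraction=0.5, seed=5)
    geno, truth = simdata.simulate_genotypes(cfg)
    y = simdata.simulate_clone_values(truth, 0.5, seed=50)
    return geno, truth, y


class TestGBLUP:
    def test_identity_grm_predicts_the_mean(self, sim):
        geno, _, y = sim
        n = geno.n_clones
        G = GRM(np.eye(n), geno.clones)
        train = y.iloc[:200]
        res = prediction.gblup(train, G, y.index[200:])
        assert np.allclose(res.predictions, res.intercept, atol=1e-8)

    def test_duplicate_clone_recovers_training_effect(self, sim):
        geno, _, y = sim
        # make the "test" clone an exact genotype copy of a training clone
        dup = geno.take_clones(list(geno.clones))
        dup.dosages[-1] = dup.dosages[0]
        G = genomics.grm_vanraden(dup)
        train = y.iloc[:-1]
        res = prediction.gblup(train, G, [y.index[-1]])
        # its GEBV equals the training clone's fitted genetic effect
        res_train = prediction.gblup(train, G, [y.index[0]],
                                     allow_overlap=True)
        assert res.predictions.iloc[0] == pytest.approx(
            res_train.predictions.iloc[0], abs=1e-8)

    def test_overlap_rejected_unless_allowed(self, sim):
        geno, _, y = sim
        G = genomics.grm_vanraden(geno)
        with pytest.raises(ValueError, match="overlap"):
            prediction.gblup(y, G, y.index[:5])

    def test_affine_invariance_of_accuracy(self, sim):
        geno, truth, y = sim
        G = genomics.grm_vanraden(geno)
        train, test = y.iloc[:200], y.index[200:]
        a1 = prediction.gblup(train, G, test).predictions
        a2 = prediction.gblup(3.0 * train + 7.0, G, test).predictions
        r = np.corrcoef(a1, a2)[0, 1]
        assert r > 1 - 1e-9


class TestMultiKernel:
    def test_zero_kernel_collapses_to_single(self, sim):
        geno, _, y = sim
        G = genomics.grm_vanraden(geno)
        ks = KernelSet({"g": G.matrix, "null": np.zeros_like(G.matrix)},
                       geno.clones)
        train, test = y.iloc[:200], y.index[200:]
        multi = prediction.multikernel_gblup(train, ks, test)
        single = prediction.gblup(train, G, test)
        np.testing.assert_allclose(multi.predictions, single.predictions,
                                   atol=1e-6)

    def test_components_sum_to_total(self, sim):
        geno, _, y = sim
        ks = prediction.build_chromosome_kernels(geno, [4, 5])
        train, test = y.iloc[:200], y.index[200:]
        res = prediction.multikernel_gblup(train, ks, test)
        total = res.intercept + res.components.sum(axis=1)
        np.testing.assert_allclose(res.predictions, total, atol=1e-8)

    def test_requires_two_kernels(self, sim):
        geno, _, y = sim
        G = genomics.grm_vanraden(geno)
        with pytest.raises(ValueError):
            prediction.multikernel_gblup(y.iloc[:50],
                                         KernelSet({"g": G.matrix},
                                                   geno.clones),
                                         y.index[50:60])


class TestChromosomeKernels:
    def test_empty_focal_equals_whole_genome_grm(self, sim):
        geno, _, _ = sim
        ks = prediction.build_chromosome_kernels(geno, [])
        G = genomics.grm_vanraden(geno)
        assert list(ks.kernels) == ["whole"]
        np.testing.assert_allclose(ks.kernels["whole"], G.matrix, atol=1e-10)

    def test_marker_counts_conserved(self, sim):
        geno, _, _ = sim
        ks = prediction.build_chromosome_kernels(geno, [4, 5])
        assert set(ks.kernels) == {"chr4", "chr5", "rest"}
        poly = int(np.sum((geno.maf() > 0)))
        total = sum(m["n_markers"] for m in ks.meta.values())
        assert total == poly

    def test_weighted_sum_reconstructs_whole_genome_grm(self, sim):
        geno, _, _ = sim
        ks = prediction.build_chromosome_kernels(geno, [4, 5])
        denoms = {k: ks.meta[k]["denominator"] for k in ks.kernels}
        total_denom = sum(denoms.values())
        recon = sum(ks.kernels[k] * (denoms[k] / total_denom)
                    for k in ks.kernels)
        G = genomics.grm_vanraden(geno)
        np.testing.assert_allclose(recon, G.matrix, atol=1e-10)

    def test_missing_focal_chromosome_raises(self, sim):
        geno, _, _ = sim
        with pytest.raises(ValueError, match="focal"):
            prediction.build_chromosome_kernels(geno, [99])


class TestRKHS:
    def test_identical_clones_have_unit_kernel(self, sim):
        geno, _, _ = sim
        dup = geno.take_clones(list(geno.clones[:20]))
        dup.dosages[1] = dup.dosages[0]
        ks = prediction.rkhs_kernels(dup)
        for K in ks.kernels.values():
            assert K[0, 1] == pytest.approx(1.0, abs=1e-12)
            assert np.allclose(np.diag(K), 1.0)

    def test_flat_limit_for_tiny_bandwidth(self, sim):
        geno, _, _ = sim
        ks = prediction.rkhs_kernels(geno.take_clones(geno.clones[:30]),
                                     thetas=[1e-12])
        K = next(iter(ks.kernels.values()))
        assert K.min() > 1 - 1e-6

    def test_hand_value_one_marker_difference(self):
        d = np.array([[0.0, 1.0], [2.0, 1.0]])
        markers = pd.DataFrame({"chrom": [1, 1], "pos": [100, 200],
                                "ref": "A", "alt": "T"})
        g = genomics.GenotypeMatrix(d, markers, ["a", "b"])
        ks = prediction.rkhs_kernels(g, thetas=[0.05])
        # d^2 = 4, K = exp(-4 * 0.05) = 0.8187
        assert ks.kernels["theta=0.05"][0, 1] == pytest.approx(
            np.exp(-0.2), abs=1e-10)
        assert ks.kernels["theta=0.05"][0, 1] == pytest.approx(0.8187,
                                                               abs=5e-5)

    def test_all_kernels_psd(self, sim):
        geno, _, _ = sim
        ks = prediction.rkhs_kernels(geno.take_clones(geno.clones[:60]))
        for K in ks.kernels.values():
            ev = np.linalg.eigvalsh(K)
            assert ev.min() >= -1e-8 * np.trace(K) / K.shape[0]


class TestBayes:
    def test_seed_determinism(self, sim):
        geno, _, y = sim
        gt = geno.take_clones(geno.clones[:80]).take_markers(np.arange(150))
        e1, _ = prediction.bayes_regression(gt, y.iloc[:80], "BayesCpi",
                                            iters=400, burnin=100, seed=9)
        e2, _ = prediction.bayes_regression(gt, y.iloc[:80], "BayesCpi",
                                            iters=400, burnin=100, seed=9)
        pd.testing.assert_series_equal(e1, e2)
        e3, _ = prediction.bayes_regression(gt, y.iloc[:80], "BayesCpi",
                                            iters=400, burnin=100, seed=10)
        assert not np.allclose(e1, e3)

    def test_null_effects_shrink_with_sample_size(self):
        """With the likelihood dominating the slab prior, posterior-mean
        effects under a pure-noise phenotype shrink as n grows."""
        cfg = simdata.SimConfig(
            n_clones_panel1=300, n_clones_panel2=300, markers_per_chrom=200,
            background_n=60, ai_fraction=0.5, seed=5)
        geno, _ = simdata.simulate_genotypes(cfg)
        poly = np.flatnonzero(geno.maf() > 0.1)[:20]
        rng = np.random.default_rng(0)
        mags = []
        for n in (50, 500):
            gt = geno.take_clones(geno.clones[:n]).take_markers(poly)
            vals = []
            for s in range(5):
                ynull = pd.Series(rng.normal(0, 1, n), index=gt.clones)
                eff, _ = prediction.bayes_regression(
                    gt, ynull, "BayesA", iters=600, burnin=150, seed=s)
                vals.append(np.abs(eff).mean())
            mags.append(np.mean(vals))
        assert mags[1] < mags[0]

    def test_sparse_recovery_bayesb(self, sim):
        geno, _, _ = sim
        rng = np.random.default_rng(8)
        gt = geno.take_clones(geno.clones[:200]).take_markers(np.arange(300))
        maf = gt.maf()
        j = int(np.flatnonzero(maf > 0.35)[3])
        w = gt.dosages[:, j]
        beta = np.sqrt(0.15 / (2 * 0.45 * 0.55 * 0.85))
        y = pd.Series(beta * (w - w.mean()) + rng.normal(0, 1, 200),
                      index=gt.clones)
        eff, _ = prediction.bayes_regression(gt, y, "BayesB", iters=1200,
                                             burnin=300, seed=1)
        # top posterior-mean marker is the causal one or a close LD partner
        top = int(np.abs(eff).idxmax())
        r = np.corrcoef(gt.dosages[:, top], w)[0, 1]
        assert abs(r) > 0.5

    def test_invalid_model_and_iters(self, sim):
        geno, _, y = sim
        gt = geno.take_clones(geno.clones[:50])
        with pytest.raises(ValueError):
            prediction.bayes_regression(gt, y.iloc[:50], "BayesZ")
        with pytest.raises(ValueError):
            prediction.bayes_regression(gt, y.iloc[:50], "BayesA", iters=100,
                                        burnin=100)


class TestRandomForest:
    def test_constant_response_gives_constant_predictions(self, sim):
        geno, _, _ = sim
        gt = geno.take_clones(geno.clones[:60])
        gp = geno.take_clones(geno.clones[60:90])
        y = pd.Series(2.5, index=gt.clones)
        res = prediction.random_forest(gt, y, gp, ntree=50, seed=0)
        assert np.allclose(res.predictions, 2.5)

    def test_seed_reproducibility_and_mtry_clip(self, sim, caplog):
        import logging
        geno, _, y = sim
        gt = geno.take_clones(geno.clones[:80]).take_markers(np.arange(100))
        gp = geno.take_clones(geno.clones[80:110]).take_markers(np.arange(100))
        with caplog.at_level(logging.WARNING):
            r1 = prediction.random_forest(gt, y.iloc[:80], gp, ntree=100,
                                          mtry=300, seed=4)
        assert "clipping" in caplog.text
        r2 = prediction.random_forest(gt, y.iloc[:80], gp, ntree=100,
                                      mtry=300, seed=4)
        pd.testing.assert_series_equal(r1.predictions, r2.predictions)


class TestCrossValidation:
    def test_oracle_model_has_accuracy_one(self, sim):
        geno, _, y = sim

        def oracle(_geno, _train, test_ids, _seed):
            return y.loc[test_ids]

        acc = prediction.cross_validate([oracle], geno, y, k=5, reps=1,
                                        seed=0)
        assert np.allclose(acc["accuracy"], 1.0)

    def test_small_fold_rejected(self, sim):
        geno, _, y = sim
        with pytest.raises(ValueError, match="fold"):
            prediction.cross_validate(["gblup"], geno, y.iloc[:30], k=5,
                                      reps=1, seed=0)

    def test_kfold_gblup_runs_and_reports(self, sim):
        geno, _, y = sim
        acc = prediction.cross_validate(["gblup"], geno, y, k=4, reps=1,
                                        seed=1)
        assert len(acc) == 4
        assert acc["accuracy"].between(-1, 1).all()

    def test_cross_panel_scheme(self, sim):
        geno, _, y = sim
        acc = prediction.cross_validate(["gblup"], geno, y,
                                        scheme="cross_panel", seed=1)
        assert len(acc) == 1
        assert acc["n_test"].iloc[0] == int((geno.panel == 2).sum())
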