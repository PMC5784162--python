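"""Genomic prediction: GBLUP, multi-kernel GBLUP, RKHS, Bayesian marker
regressions, Random Forest, and a cross-validation harness.

Single- and multi-kernel GBLUP fit mixed models by REML on the training
clones and propagate genetic effects to untrained clones through the genomic
relationships (``g_test = sum_k sigma_k^2 K_k[test, train] V^-1 (y - mu)``),
so a model's prediction decomposes exactly into per-kernel components.  The
GWAS-guided variant partitions the genome into per-chromosome kernels
(e.g. the chromosome carrying the introgression segment, the QTL-cluster
chromosome, and the rest of the genome).  RKHS uses Gaussian kernels
``K_ij = exp(-d_ij * theta)`` over a ladder of bandwidths fitted jointly
with REML weights, capturing non-additive signal; Random Forest is delegated
to scikit-learn with the conventional ntree/mtry settings.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genomics import GRM, GenotypeMatrix, grm_vanraden
from ._reml import reml_kernel, reml_multikernel

logger = logging.getLogger(__name__)

RKHS_THETAS = (0.0000005, 0.00005, 0.0005, 0.005, 0.01, 0.05)


@dataclass
class KernelSet:
    """Named clone x clone covariance kernels sharing one clone index."""

    kernels: dict[str, np.ndarray]
    clones: pd.Index
    meta: dict = field(default_factory=dict)
    varcomps: dict[str, float] | None = None

    def __post_init__(self):
        n = len(self.clones)
        for name, K in self.kernels.items():
            if K.shape != (n, n):
                raise ValueError(f"kernel {name!r} shape mismatch")

    def align(self, clone_ids) -> "KernelSet":
        pos = self.clones.get_indexer(pd.Index(clone_ids))
        if (pos < 0).any():
            raise KeyError("clones missing from kernel set")
        ix = np.ix_(pos, pos)
        return KernelSet({k: K[ix] for k, K in self.kernels.items()},
                         pd.Index(clone_ids), meta=self.meta)


@dataclass
class PredictionResult:
    """Predicted genetic values with optional per-kernel decomposition."""

    predictions: pd.Series
    model: str
    components: pd.DataFrame | None = None   # per-kernel contributions
    varcomps: dict[str, float] | None = None
    intercept: float = 0.0
    marker_effects: pd.Series | None = None


def _check_split(train_ids, predict_for, allow_overlap):
    overlap = pd.Index(train_ids).intersection(pd.Index(predict_for))
    if len(overlap) and not allow_overlap:
        raise ValueError(f"train/test overlap: {list(overlap[:5])} "
                         "(pass allow_overlap=True to permit)")


def gblup(train: pd.Series, G: GRM, predict_for,
          allow_overlap: bool = False) -> PredictionResult:
    """Single-kernel GBLUP: REML on the training clones, GEBVs through G."""
    train = pd.Series(train).dropna()
    predict_for = pd.Index(predict_for)
    for ids in (train.index, predict_for):
        if (G.clones.get_indexer(ids) < 0).any():
            raise KeyError("clones missing from the GRM")
    _check_split(train.index, predict_for, allow_overlap)
    y = train.to_numpy(float)
    Ktt = G.align(train.index)
    fit = reml_kernel(y, np.ones((len(y), 1)), Ktt)
    mu = float(fit.beta[0])
    # V^-1 (y - mu) via the spectral decomposition of K_tt
    d = fit.sigma_g2 * fit.eigvals + fit.sigma_e2
    d = np.maximum(d, 1e-12)
    alpha = fit.eigvecs @ ((fit.eigvecs.T @ (y - mu)) / d)
    pos_t = G.clones.get_indexer(train.index)
    pos_p = G.clones.get_indexer(predict_for)
    Kpt = G.matrix[np.ix_(pos_p, pos_t)]
    gebv = fit.sigma_g2 * (Kpt @ alpha)
    preds = pd.Series(mu + gebv, index=predict_for, name="gebv")
    return PredictionResult(predictions=preds, model="gblup",
                            varcomps={"sigma_g2": fit.sigma_g2,
                                      "sigma_e2": fit.sigma_e2},
                            intercept=mu)


def multikernel_gblup(train: pd.Series, kernels: KernelSet, predict_for,
                      allow_overlap: bool = False) -> PredictionResult:
    """Multi-kernel GBLUP: one REML variance per kernel, additive components.

    The prediction for each clone is the intercept plus the sum of per-kernel
    components, returned in ``components`` so kernel contributions to
    accuracy can be assessed separately.
    """
    if len(kernels.kernels) < 2:
        raise ValueError("need at least 2 kernels")
    train = pd.Series(train).dropna()
    predict_for = pd.Index(predict_for)
    _check_split(train.index, predict_for, allow_overlap)
    for ids in (train.index, predict_for):
        if (kernels.clones.get_indexer(ids) < 0).any():
            raise ValueError("kernel clone set does not cover train/predict clones")
    sub = kernels.align(train.index)
    y = train.to_numpy(float)
    fit = reml_multikernel(y, np.ones((len(y), 1)), sub.kernels)
    mu = float(fit.beta[0])
    pos_t = kernels.clones.get_indexer(train.index)
    pos_p = kernels.clones.get_indexer(predict_for)
    comp = {}
    for name, K in kernels.kernels.items():
        Kpt = K[np.ix_(pos_p, pos_t)]
        comp[name] = fit.sigma2[name] * (Kpt @ fit.Vinv_resid)
    components = pd.DataFrame(comp, index=predict_for)
    preds = mu + components.sum(axis=1)
    preds.name = "gebv"
    vc = dict(fit.sigma2)
    vc["sigma_e2"] = fit.sigma_e2
    return PredictionResult(predictions=preds, model="mk-gblup",
                            components=components, varcomps=vc, intercept=mu)


def build_chromosome_kernels(geno: GenotypeMatrix, focal_chroms=()
                             ) -> KernelSet:
    """One VanRaden GRM per focal chromosome plus one for the remainder.

    With no focal chromosomes this degenerates to the single whole-genome
    GRM.  The set records per-kernel marker counts and VanRaden normalisers,
    through which the weighted kernel sum reconstructs the whole-genome GRM.
    """
    chroms = geno.markers["chrom"].astype(str)
    kernels, meta = {}, {}
    used = np.zeros(geno.n_markers, bool)
    for c in focal_chroms:
        mask = (chroms == str(c)).to_numpy()
        if not mask.any():
            raise ValueError(f"focal chromosome {c} has no markers")
        g = grm_vanraden(geno, marker_mask=mask)
        kernels[f"chr{c}"] = g.matrix
        meta[f"chr{c}"] = {"n_markers": g.n_markers,
                           "denominator": g.denominator}
        used |= mask
    rest = ~used
    if rest.any():
        g = grm_vanraden(geno, marker_mask=rest)
        name = "rest" if focal_chroms else "whole"
        kernels[name] = g.matrix
        meta[name] = {"n_markers": g.n_markers, "denominator": g.denominator}
    return KernelSet(kernels=kernels, clones=geno.clones, meta=meta)


def rkhs_kernels(geno: GenotypeMatrix, thetas=RKHS_THETAS,
                 distance: str = "squared") -> KernelSet:
    """Gaussian kernels ``K_ij = exp(-d_ij * theta)`` over a bandwidth ladder.

    ``d_ij`` is the squared Euclidean distance between dosage rows by default
    (``distance="euclidean"`` uses the unsquared distance).  ``K_ii = 1`` for
    every bandwidth.
    """
    thetas = tuple(thetas)
    if any(t <= 0 for t in thetas):
        raise ValueError("thetas must be positive")
    D = geno.dosages
    D = np.where(np.isnan(D), np.nanmean(D, axis=0), D)
    sq = np.sum(D ** 2, axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * (D @ D.T)
    np.maximum(d2, 0.0, out=d2)
    d = d2 if distance == "squared" else np.sqrt(d2)
    kernels = {f"theta={t:g}": np.exp(-d * t) for t in thetas}
    return KernelSet(kernels=kernels, clones=geno.clones,
                     meta={"thetas": thetas, "distance": distance})


def rkhs(train: pd.Series, geno: GenotypeMatrix, predict_for,
         thetas=RKHS_THETAS, **kw) -> PredictionResult:
    """Multi-kernel RKHS: all bandwidth kernels fitted jointly by REML."""
    ks = rkhs_kernels(geno, thetas=thetas)
    res = multikernel_gblup(train, ks, predict_for, **kw)
    res.model = "rkhs"
    return res


# ------------------------------------------------------- Bayesian regressions

_MODEL_CODES = {"BayesA": 0, "BayesB": 1, "BayesCpi": 2, "BL": 3}


def bayes_regression(geno_train: GenotypeMatrix, y: pd.Series, model: str,
                     iters: int = 6000, burnin: int = 1000, seed: int = 0,
                     pi0: float = 0.95, geno_test: GenotypeMatrix | None = None,
                     r2: float = 0.5) -> tuple[pd.Series, PredictionResult]:
    """Gibbs-sampled whole-genome regression under the named prior.

    Returns (posterior-mean marker effects, predictions).  Dosages are
    centred internally; hyperpriors use degrees of freedom 5 (residual) and
    4.1 (slab) with scales matched so the prior expects a fraction ``r2`` of
    the phenotypic variance to be genetic.
    """
    from ._gibbs import gibbs_sampler

    if model not in _MODEL_CODES:
        raise ValueError(f"unknown model {model!r}")
    if iters <= burnin:
        raise ValueError("iters must exceed burnin")
    y = pd.Series(y).loc[geno_train.clones]
    yv = y.to_numpy(float)
    mu_w = np.nanmean(geno_train.dosages, axis=0)
    W = np.where(np.isnan(geno_train.dosages), 0.0,
                 geno_train.dosages - mu_w)
    n, m = W.shape
    vary = float(np.var(yv))
    msx = float(np.mean(np.var(W, axis=0))) or 1.0
    nu_a, nu_e = 4.1, 5.0
    frac_in = 1.0 if model in ("BayesA", "BL") else (1.0 - pi0)
    Sa = r2 * vary * (nu_a - 2.0) / (nu_a * m * msx * frac_in)
    Se = vary * (1.0 - r2) * (nu_e - 2.0) / nu_e
    eff, mu, pip, se2 = gibbs_sampler(
        np.ascontiguousarray(W), np.ascontiguousarray(yv),
        _MODEL_CODES[model], iters, burnin, int(seed) % (2 ** 31),
        pi0, nu_a, nu_e, Sa * nu_a, Se * nu_e)
    if not np.all(np.isfinite(eff)):
        raise RuntimeError("divergent chain: non-finite posterior mean")
    effects = pd.Series(eff, index=pd.RangeIndex(m), name="effect")

    if geno_test is not None:
        Wt = np.where(np.isnan(geno_test.dosages), 0.0,
                      geno_test.dosages - mu_w)
        preds = pd.Series(mu + Wt @ eff, index=geno_test.clones)
    else:
        preds = pd.Series(mu + W @ eff, index=geno_train.clones)
    res = PredictionResult(predictions=preds, model=model, intercept=float(mu),
                           marker_effects=effects,
                           varcomps={"sigma_e2": float(se2),
                                     "mean_pip": float(pip.mean())})
    return effects, res


def random_forest(geno_train: GenotypeMatrix, y: pd.Series,
                  geno_test: GenotypeMatrix, ntree: int = 500,
                  mtry: int = 300, seed: int = 0) -> PredictionResult:
    """Random Forest regression on dosage columns (delegated to scikit-learn).

    Captures non-additive (epistatic/dominance) signal, so its predictions
    are total genetic values rather than breeding values.  ``mtry`` is
    clipped to the marker count with a warning.
    """
    from sklearn.ensemble import RandomForestRegressor

    y = pd.Series(y).loc[geno_train.clones].to_numpy(float)
    if not np.all(np.isfinite(geno_train.dosages)) or \
       not np.all(np.isfinite(geno_test.dosages)):
        raise ValueError("non-numeric (missing) dosages; impute first")
    m = geno_train.n_markers
    if mtry > m:
        logger.warning("mtry %d > %d markers; clipping", mtry, m)
        mtry = m
    rf = RandomForestRegressor(n_estimators=ntree, max_features=mtry,
                               random_state=int(seed) % (2 ** 31), n_jobs=1)
    rf.fit(geno_train.dosages, y)
    preds = pd.Series(rf.predict(geno_test.dosages), index=geno_test.clones)
    return PredictionResult(predictions=preds, model="rf")


# ------------------------------------------------------------ cross-validation

MODEL_NAMES = ("gblup", "mk-gblup", "rkhs", "bayesA", "bayesB", "bayesCpi",
               "bl", "rf")


def _fit_predict(model: str, geno: GenotypeMatrix, train: pd.Series,
                 test_ids, seed: int, G: GRM | None = None,
                 focal_chroms=(), bayes_iters: int = 2500,
                 bayes_burnin: int = 500) -> pd.Series:
    if callable(model):
        # custom model: f(geno, train, test_ids, seed) -> Series
        return pd.Series(model(geno, train, test_ids, seed)).loc[test_ids]
    if model == "gblup":
        G = G or grm_vanraden(geno)
        return gblup(train, G, test_ids).predictions
    if model == "mk-gblup":
        ks = build_chromosome_kernels(geno, focal_chroms)
        return multikernel_gblup(train, ks, test_ids).predictions
    if model == "rkhs":
        return rkhs(train, geno, test_ids).predictions
    if model in ("bayesA", "bayesB", "bayesCpi", "bl"):
        name = {"bayesA": "BayesA", "bayesB": "BayesB",
                "bayesCpi": "BayesCpi", "bl": "BL"}[model]
        gt = geno.take_clones(train.index)
        gp = geno.take_clones(test_ids)
        _, res = bayes_regression(gt, train, name, iters=bayes_iters,
                                  burnin=bayes_burnin, seed=seed, geno_test=gp)
        return res.predictions
    if model == "rf":
        gt = geno.take_clones(train.index)
        gp = geno.take_clones(test_ids)
        return random_forest(gt, train, gp, seed=seed).predictions
    raise ValueError(f"unknown model {model!r}")


def cross_validate(models, geno: GenotypeMatrix, dereg: pd.Series,
                   scheme: str = "kfold", k: int = 5, reps: int = 10,
                   seed: int = 0, focal_chroms=(), min_test: int = 10,
                   **model_kw) -> pd.DataFrame:
    """Cross-validated predictive accuracy per model.

    Accuracy is the Pearson correlation between predictions and the
    de-regressed BLUPs of held-out clones.  ``scheme="kfold"`` runs
    ``reps`` repetitions of ``k``-fold CV on the clones shared between
    genotypes and phenotypes; ``scheme="cross_panel"`` trains on panel 1 and
    predicts panel 2 (requires panel labels).
    """
    dereg = pd.Series(dereg).dropna()
    shared = geno.clones.intersection(dereg.index)
    g = geno.take_clones(shared)
    y = dereg.loc[shared]
    rng = np.random.default_rng(seed)
    G = grm_vanraden(g)
    rows = []
    if scheme == "kfold":
        for rep in range(reps):
            perm = rng.permutation(len(shared))
            folds = np.array_split(perm, k)
            for fold_i, test_pos in enumerate(folds):
                if len(test_pos) < min_test:
                    raise ValueError(f"fold with {len(test_pos)} test clones "
                                     f"(min {min_test})")
                test_ids = shared[test_pos]
                train = y.drop(index=test_ids)
                fold_seed = int(rng.integers(2 ** 31))
                for model in models:
                    preds = _fit_predict(model, g, train, test_ids, fold_seed,
                                         G=G, focal_chroms=focal_chroms,
                                         **model_kw)
                    acc = float(np.corrcoef(preds.loc[test_ids],
                                            y.loc[test_ids])[0, 1])
                    label = model if isinstance(model, str) else \
                        getattr(model, "__name__", "custom")
                    rows.append({"model": label, "rep": rep, "fold": fold_i,
                                 "accuracy": acc, "n_test": len(test_ids)})
    elif scheme == "cross_panel":
        if g.panel is None:
            raise ValueError("cross_panel requires panel labels")
        train_ids = g.clones[g.panel == 1]
        test_ids = g.clones[g.panel == 2]
        if len(test_ids) < min_test:
            raise ValueError("too few test clones")
        train = y.loc[train_ids]
        for model in models:
            preds = _fit_predict(model, g, train, test_ids,
                                 int(rng.integers(2 ** 31)), G=G,
                                 focal_chroms=focal_chroms, **model_kw)
            acc = float(np.corrcoef(preds.loc[test_ids],
                                    y.loc[test_ids])[0, 1])
            rows.append({"model": model, "rep": 0, "fold": 0,
                         "accuracy": acc, "n_test": len(test_ids)})
    else:
        raise ValueError("scheme must be 'kfold' or 'cross_panel'")
    return pd.DataFrame(rows)
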