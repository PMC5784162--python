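"""Mixed-linear-model association (MLMA) with leave-one-chromosome-out kinship.

For each chromosome the polygenic variance components are re-estimated with a
genomic relationship matrix built from all *other* chromosomes (LOCO), which
removes proximal contamination: the candidate marker never contributes to the
kinship that absorbs it.  Each marker is then tested by generalized least
squares under that fit.  After rotating by the inverse square root of the
fitted covariance the test reduces to per-marker least squares with an
estimated residual scale, so the reported p-value is a t-test with n - 2
degrees of freedom; with an identity kinship it coincides exactly with
ordinary least squares.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .genomics import GRM, GenotypeMatrix, grm_vanraden
from ._reml import reml_kernel

logger = logging.getLogger(__name__)


def bonferroni_threshold(n_markers: int, alpha: float = 0.05) -> float:
    """Genome-wide significance threshold on the -log10 scale.

    ``-log10(alpha / n_markers)``; with the 41,530-marker MAF>0.01 panel and
    alpha 0.05 this is 5.92 (commonly printed as 5.9).
    """
    if n_markers < 1:
        raise ValueError("n_markers must be >= 1")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    return float(-np.log10(alpha / n_markers))


def pve(effect: float, freq: float, pheno_var: float) -> float:
    """Phenotypic variance explained by a marker: ``2 p (1-p) beta^2 / Var(y)``.

    Clipped to [0, 1].
    """
    if not 0.0 < freq < 1.0:
        raise ValueError("freq must be in (0, 1)")
    if pheno_var <= 0:
        raise ValueError("pheno_var must be positive")
    return float(np.clip(2.0 * freq * (1.0 - freq) * effect ** 2 / pheno_var,
                         0.0, 1.0))


def _gls_scan(y: np.ndarray, W: np.ndarray, Vhalf_inv: np.ndarray | None
              ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-marker GLS of y on [1, w] after rotating by V^{-1/2}.

    Returns (effects, standard errors, p-values).  The residual scale is
    estimated per marker, giving a t(n-2) test that matches OLS exactly when
    the rotation is the identity.
    """
    n = y.size
    if Vhalf_inv is None:
        a = np.ones(n)
        ys = y
        Ws = W
    else:
        a = Vhalf_inv @ np.ones(n)
        ys = Vhalf_inv @ y
        Ws = Vhalf_inv @ W
    S11 = float(a @ a)
    S12 = a @ Ws                      # (m,)
    S22 = np.einsum("ij,ij->j", Ws, Ws)
    r1 = float(a @ ys)
    r2 = Ws.T @ ys
    det = S11 * S22 - S12 ** 2
    det = np.where(det <= 0, np.nan, det)
    beta0 = (S22 * r1 - S12 * r2) / det
    beta1 = (S11 * r2 - S12 * r1) / det
    yty = float(ys @ ys)
    rss = yty - beta0 * r1 - beta1 * r2
    dof = n - 2
    sigma2 = np.maximum(rss, 1e-300) / dof
    se = np.sqrt(sigma2 * S11 / det)
    with np.errstate(invalid="ignore", divide="ignore"):
        tstat = beta1 / se
    pvals = 2.0 * stats.t.sf(np.abs(tstat), dof)
    pvals = np.clip(pvals, np.finfo(float).tiny, 1.0)
    return beta1, se, pvals


def mlma_loco(geno: GenotypeMatrix, dereg: pd.Series, maf_min: float = 0.05,
              kinship: str = "loco", min_shared: int = 50) -> pd.DataFrame:
    """MLMA scan of all markers passing the MAF filter.

    Parameters
    ----------
    kinship
        ``"loco"`` (default) re-estimates variance components per left-out
        chromosome; ``"whole"`` uses a single whole-genome kinship;
        ``"identity"`` is the sigma_g^2 = 0 limit (plain regression), kept as
        a diagnostic oracle.

    Returns a GWAS table with chrom, pos, freq, effect, se, p and
    ``-log10(p)``; metadata (trait name, n, kinship mode, MAF filter) is
    attached in ``DataFrame.attrs``.
    """
    dereg = pd.Series(dereg).dropna()
    shared = geno.clones.intersection(dereg.index)
    if len(shared) < min_shared:
        raise ValueError(f"only {len(shared)} shared clones (need {min_shared})")
    g = geno.take_clones(shared)
    y = dereg.loc[shared].to_numpy(float)
    y = y - y.mean()

    maf = g.maf()
    keep = maf > maf_min
    chroms = g.markers["chrom"].astype(str).to_numpy()
    uniq = pd.unique(chroms)
    if kinship == "loco" and len(uniq) < 2:
        logger.warning("single chromosome: falling back to whole-genome kinship")
        kinship = "whole"

    D = g.dosages
    Dimp = np.where(np.isnan(D), np.nanmean(D, axis=0), D)

    results = []
    if kinship == "identity":
        idx = np.flatnonzero(keep)
        eff, se, p = _gls_scan(y, Dimp[:, idx], None)
        results.append((idx, eff, se, p))
    elif kinship == "whole":
        G = grm_vanraden(g)
        fit = reml_kernel(y, np.ones((len(shared), 1)), G.matrix)
        Vhi = _vhalf_inv(fit)
        idx = np.flatnonzero(keep)
        eff, se, p = _gls_scan(y, Dimp[:, idx], Vhi)
        results.append((idx, eff, se, p))
    else:
        for chrom in uniq:
            on = chroms == chrom
            idx = np.flatnonzero(keep & on)
            if idx.size == 0:
                continue
            G = grm_vanraden(g, marker_mask=~on)
            fit = reml_kernel(y, np.ones((len(shared), 1)), G.matrix)
            Vhi = _vhalf_inv(fit)
            eff, se, p = _gls_scan(y, Dimp[:, idx], Vhi)
            results.append((idx, eff, se, p))

    all_idx = np.concatenate([r[0] for r in results])
    order = np.argsort(all_idx)
    table = pd.DataFrame({
        "chrom": g.markers["chrom"].to_numpy()[all_idx][order],
        "pos": g.markers["pos"].to_numpy()[all_idx][order],
        "freq": g.allele_freq()[all_idx][order],
        "effect": np.concatenate([r[1] for r in results])[order],
        "se": np.concatenate([r[2] for r in results])[order],
        "p": np.concatenate([r[3] for r in results])[order],
    })
    table["neglog10p"] = -np.log10(table["p"])
    table.attrs.update({"trait": dereg.name or "trait", "n_clones": len(shared),
                        "kinship": kinship, "maf_min": maf_min})
    return table


def _vhalf_inv(fit) -> np.ndarray:
    """V^{-1/2} from a single-kernel REML fit's spectral decomposition."""
    d = fit.sigma_g2 * fit.eigvals + fit.sigma_e2
    d = np.maximum(d, 1e-12)
    return (fit.eigvecs / np.sqrt(d)) @ fit.eigvecs.T


def annotate_hits(table: pd.DataFrame, gff_path, threshold: float
                  ) -> pd.DataFrame:
    """Map significant SNPs (``-log10 p > threshold``) onto GFF3 gene models.

    Gene intervals are 1-based inclusive.  SNPs inside no gene are reported
    with ``gene = "intergenic"``.  Raises if the chromosome namespaces of the
    two files do not overlap.
    """
    import gffutils

    db = gffutils.create_db(str(gff_path), ":memory:", force=True,
                            keep_order=True, merge_strategy="create_unique")
    genes = [(f.seqid, f.start, f.end, f.id) for f in db.features_of_type("gene")]
    gff_chroms = {g[0] for g in genes}
    sig = table[table["neglog10p"] > threshold]
    snp_chroms = set(sig["chrom"].astype(str))
    if snp_chroms and not (snp_chroms & gff_chroms):
        raise ValueError(
            f"chromosome names do not match: GWAS {sorted(snp_chroms)} vs "
            f"GFF {sorted(gff_chroms)}")
    rows = []
    for _, snp in sig.iterrows():
        hits = [gid for (c, s, e, gid) in genes
                if c == str(snp["chrom"]) and s <= snp["pos"] <= e]
        for gid in (hits or ["intergenic"]):
            rows.append({"chrom": snp["chrom"], "pos": snp["pos"],
                         "p": snp["p"], "neglog10p": snp["neglog10p"],
                         "gene": gid})
    return pd.DataFrame(rows, columns=["chrom", "pos", "p", "neglog10p", "gene"])


def to_qqman(table: pd.DataFrame, path) -> None:
    """Write the scan as a qqman-style TSV (SNP, CHR, BP, P)."""
    out = pd.DataFrame({
        "SNP": [f"S{c}_{p}" for c, p in zip(table["chrom"], table["pos"])],
        "CHR": table["chrom"], "BP": table["pos"], "P": table["p"]})
    out.to_csv(path, sep="\t", index=False)
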