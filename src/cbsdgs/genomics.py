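"""Genotype container, marker QC cascade, genomic relationship matrix, PCA.

Dosages code the count of the ALT allele (0/1/2; fractional values in [0,2]
are accepted everywhere, as produced by imputation), with ``nan`` for missing
calls.  Allele frequencies are always the observed mean dosage / 2.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._reml import bend_psd, reml_kernel

logger = logging.getLogger(__name__)

MARKER_COLUMNS = ("chrom", "pos", "ref", "alt")


@dataclass
class GenotypeMatrix:
    """Clones x markers dosage matrix with a marker map and panel labels.

    Parameters
    ----------
    dosages
        ``(n_clones, n_markers)`` float array of ALT-allele dosages in
        ``[0, 2]``; ``nan`` marks missing calls.
    markers
        Marker map with columns ``chrom, pos, ref, alt`` (and optionally
        ``ar2``, the imputation allelic-r2 quality); positions strictly
        increasing within each chromosome.
    clones
        Clone identifiers, one per row.
    panel
        Optional panel label per clone (e.g. 1 / 2).
    """

    dosages: np.ndarray
    markers: pd.DataFrame
    clones: pd.Index
    panel: pd.Series | None = None

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages, float)
        self.clones = pd.Index(self.clones)
        self.markers = self.markers.reset_index(drop=True)
        n, m = self.dosages.shape
        if len(self.clones) != n:
            raise ValueError("clone ids do not match dosage rows")
        if len(self.markers) != m:
            raise ValueError("marker map length does not match dosage columns")
        for col in ("chrom", "pos"):
            if col not in self.markers.columns:
                raise ValueError(f"marker map missing column {col!r}")
        with np.errstate(invalid="ignore"):
            if np.nanmin(self.dosages, initial=0) < -1e-9 or \
               np.nanmax(self.dosages, initial=0) > 2 + 1e-9:
                raise ValueError("dosages must lie in [0, 2]")
        for chrom, grp in self.markers.groupby("chrom", sort=False):
            if not grp["pos"].is_monotonic_increasing:
                raise ValueError(f"positions not increasing on chrom {chrom}")
        if self.panel is not None:
            self.panel = pd.Series(np.asarray(self.panel), index=self.clones)

    # ------------------------------------------------------------------ basic
    @property
    def n_clones(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_markers(self) -> int:
        return self.dosages.shape[1]

    def allele_freq(self) -> np.ndarray:
        """Observed ALT allele frequency per marker (mean dosage / 2)."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosages, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        p = self.allele_freq()
        return np.minimum(p, 1.0 - p)

    def missing_rate(self) -> np.ndarray:
        return np.mean(np.isnan(self.dosages), axis=0)

    def take_markers(self, mask_or_idx) -> "GenotypeMatrix":
        idx = np.asarray(mask_or_idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return replace(self, dosages=self.dosages[:, idx],
                       markers=self.markers.iloc[idx],
                       clones=self.clones, panel=self.panel)

    def take_clones(self, clone_ids) -> "GenotypeMatrix":
        pos = self.clones.get_indexer(pd.Index(clone_ids))
        if (pos < 0).any():
            missing = list(pd.Index(clone_ids)[pos < 0])
            raise KeyError(f"unknown clones: {missing[:5]}")
        panel = self.panel.iloc[pos] if self.panel is not None else None
        return replace(self, dosages=self.dosages[pos],
                       markers=self.markers, clones=pd.Index(clone_ids),
                       panel=panel)

    def chrom_mask(self, chroms) -> np.ndarray:
        chroms = {str(c) for c in np.atleast_1d(chroms)}
        return self.markers["chrom"].astype(str).isin(chroms).to_numpy()

    # ------------------------------------------------------------------- I/O
    def to_dosage_csv(self, path) -> None:
        df = pd.DataFrame(self.dosages, index=self.clones,
                          columns=[f"{c}_{p}" for c, p in
                                   zip(self.markers["chrom"], self.markers["pos"])])
        df.to_csv(path, index_label="clone")

    def to_vcf(self, path) -> None:
        """Write a minimal plain-text VCF (GT from rounded dosage, DS exact)."""
        mk = self.markers
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write('##INFO=<ID=AR2,Number=1,Type=Float,'
                     'Description="Imputation allelic r-squared">\n')
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,'
                     'Description="ALT dosage">\n')
            for chrom in mk["chrom"].astype(str).unique():
                end = int(mk.loc[mk["chrom"].astype(str) == chrom, "pos"].max()) + 1
                fh.write(f"##contig=<ID={chrom},length={end}>\n")
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                     + "\t".join(map(str, self.clones)) + "\n")
            gt_codes = {0: "0/0", 1: "0/1", 2: "1/1"}
            has_ar2 = "ar2" in mk.columns
            for j in range(self.n_markers):
                row = mk.iloc[j]
                info = f"AR2={row['ar2']:.4f}" if has_ar2 else "."
                cells = []
                for d in self.dosages[:, j]:
                    if np.isnan(d):
                        cells.append("./.:.")
                    else:
                        cells.append(f"{gt_codes[int(round(d))]}:{d:g}")
                fh.write(f"{row['chrom']}\t{int(row['pos'])}\t"
                         f"S{row['chrom']}_{int(row['pos'])}\t"
                         f"{row.get('ref', 'A')}\t{row.get('alt', 'T')}\t.\t.\t"
                         f"{info}\tGT:DS\t" + "\t".join(cells) + "\n")

    @classmethod
    def from_vcf(cls, path, panel: pd.Series | None = None) -> "GenotypeMatrix":
        """Read bi-allelic SNPs from VCF (dosage from DS if present, else GT)."""
        from cyvcf2 import VCF

        vcf = VCF(str(path))
        clones = pd.Index(vcf.samples)
        rows, dos = [], []
        for var in vcf:
            if len(var.ALT) != 1:
                continue
            try:
                d = np.asarray(var.format("DS"), float).ravel()
            except (KeyError, TypeError):
                # cyvcf2 gt_types: 0 HOM_REF, 1 HET, 2 UNKNOWN, 3 HOM_ALT
                gt = np.asarray(var.gt_types)
                d = np.choose(gt, [0.0, 1.0, np.nan, 2.0])
            ar2 = var.INFO.get("AR2")
            rec = {"chrom": var.CHROM, "pos": var.POS,
                   "ref": var.REF, "alt": var.ALT[0]}
            if ar2 is not None:
                rec["ar2"] = float(ar2)
            rows.append(rec)
            dos.append(d)
        if not rows:
            raise ValueError(f"no bi-allelic SNPs found in {path}")
        return cls(dosages=np.array(dos).T, markers=pd.DataFrame(rows),
                   clones=clones, panel=panel)


# ---------------------------------------------------------------------- QC

def filter_markers(geno: GenotypeMatrix, max_missing: float = 0.6,
                   ar2_min: float = 0.3, maf_min: float = 0.01,
                   order: tuple[str, ...] = ("missing", "ar2", "maf"),
                   ) -> GenotypeMatrix:
    """Marker QC cascade: missingness, imputation quality (AR2), then MAF.

    Markers are removed when missingness exceeds ``max_missing``, when AR2 is
    not strictly greater than ``ar2_min``, or when MAF is not strictly greater
    than ``maf_min``.  Counts removed at each step are logged.  Markers with
    no AR2 field pass the AR2 step.
    """
    for name, t in (("max_missing", max_missing), ("ar2_min", ar2_min),
                    ("maf_min", maf_min)):
        if not 0.0 <= t <= 1.0:
            raise ValueError(f"{name} must be in [0, 1]")
    keep = np.ones(geno.n_markers, bool)
    for step in order:
        # thresholds at their no-op extreme (ar2/maf 0, missing 1) disable
        # the step; otherwise the comparison is strict ("higher than")
        if step == "missing":
            fail = geno.missing_rate() > max_missing
        elif step == "ar2":
            if ar2_min > 0 and "ar2" in geno.markers.columns:
                ar2 = geno.markers["ar2"].to_numpy(float)
                fail = ~(ar2 > ar2_min)
            else:
                fail = np.zeros(geno.n_markers, bool)
        elif step == "maf":
            fail = ~(geno.maf() > maf_min) if maf_min > 0 else \
                np.zeros(geno.n_markers, bool)
        else:
            raise ValueError(f"unknown filter step {step!r}")
        removed = int(np.sum(fail & keep))
        keep &= ~fail
        logger.info("filter %-7s removed %d markers (%d remain)",
                    step, removed, int(keep.sum()))
    if not keep.any():
        raise ValueError("all markers removed by the filter cascade")
    return geno.take_markers(keep)


# --------------------------------------------------------------------- GRM

@dataclass
class GRM:
    """Genomic relationship matrix with its clone index."""

    matrix: np.ndarray
    clones: pd.Index
    method: str = "vanraden"
    n_markers: int = 0
    denominator: float = field(default=0.0)   # 2 sum p(1-p), the VanRaden scale

    def align(self, clone_ids) -> np.ndarray:
        pos = self.clones.get_indexer(pd.Index(clone_ids))
        if (pos < 0).any():
            raise KeyError("clones missing from GRM")
        return self.matrix[np.ix_(pos, pos)]

    def to_csv(self, path) -> None:
        pd.DataFrame(self.matrix, index=self.clones,
                     columns=self.clones).to_csv(path, index_label="clone")


def grm_vanraden(geno: GenotypeMatrix, marker_mask=None) -> GRM:
    """VanRaden genomic relationship matrix.

    ``G = W W' / (2 sum_k p_k (1 - p_k))`` where ``W`` is the dosage matrix
    column-centred by ``2 p_k`` and ``p_k`` the observed allele frequency.
    Missing dosages are mean-imputed for the cross-product.
    """
    if geno.n_clones < 2:
        raise ValueError("need at least 2 clones")
    g = geno if marker_mask is None else geno.take_markers(marker_mask)
    p = g.allele_freq()
    poly = (p > 0) & (p < 1)
    if not poly.any():
        raise ValueError("no polymorphic markers for the GRM")
    D = g.dosages[:, poly]
    p = p[poly]
    W = np.where(np.isnan(D), 0.0, D - 2.0 * p)
    denom = 2.0 * float(np.sum(p * (1.0 - p)))
    G = (W @ W.T) / denom
    return GRM(matrix=G, clones=g.clones, method="vanraden",
               n_markers=int(poly.sum()), denominator=denom)


def snp_heritability(dereg: pd.Series, G: GRM,
                     min_shared: int = 30) -> tuple[float, dict[str, float]]:
    """SNP heritability from the one-step mixed model ``y = mu + g + e``.

    ``g ~ N(0, G sigma_g^2)``; returns ``h2 = sigma_g^2 / (sigma_g^2 +
    sigma_e^2)`` together with the variance components.  Non-PSD ``G`` is bent
    (negative eigenvalues clipped) with a warning.
    """
    dereg = pd.Series(dereg).dropna()
    shared = dereg.index.intersection(G.clones)
    if len(shared) < min_shared:
        raise ValueError(f"only {len(shared)} clones shared; need >= {min_shared}")
    y = dereg.loc[shared].to_numpy(float)
    K = bend_psd(G.align(shared))
    fit = reml_kernel(y, np.ones((len(shared), 1)), K)
    return fit.h2, {"sigma_g2": fit.sigma_g2, "sigma_e2": fit.sigma_e2,
                    "loglik": fit.loglik, "n": float(len(shared))}


# --------------------------------------------------------------------- PCA

def pca(geno: GenotypeMatrix, k: int = 10,
        standardize: bool = False) -> tuple[pd.DataFrame, np.ndarray]:
    """Principal components of the clone covariance of centred dosages.

    Returns (scores DataFrame with columns PC1..PCk, variance fractions).
    Dosages are centred per marker (mean imputation for missing calls);
    ``standardize`` additionally scales each marker to unit variance.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    k = min(k, geno.n_clones, geno.n_markers)
    D = geno.dosages
    mu = np.nanmean(D, axis=0)
    W = np.where(np.isnan(D), 0.0, D - mu)
    if standardize:
        sd = W.std(axis=0)
        sd[sd == 0] = 1.0
        W = W / sd
    U, svals, _ = np.linalg.svd(W, full_matrices=False)
    var = svals ** 2
    frac = var / var.sum()
    scores = pd.DataFrame(U[:, :k] * svals[:k], index=geno.clones,
                          columns=[f"PC{i+1}" for i in range(k)])
    return scores, frac[:k]
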