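"""Linkage-disequilibrium diagnostics: LD scores and local r2.

r2 is the squared Pearson correlation of dosage vectors (genotypic r2).  The
LD score of a marker is the sum of small-sample *adjusted* r2,

    r2_adj = r2 - (1 - r2) / (n - 2),

over all markers within a physical window (self-pair included, so the score
of an isolated marker is 1).  The adjustment makes the score unbiased at
zero true LD, which is what the null-mean diagnostics rely on.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .genomics import GenotypeMatrix

logger = logging.getLogger(__name__)


def adjusted_r2(r2, n: int):
    """Small-sample adjusted squared correlation (vectorised over ``r2``)."""
    if n <= 2:
        raise ValueError("n must exceed 2")
    r2 = np.asarray(r2, float)
    out = r2 - (1.0 - r2) / (n - 2)
    return float(out) if out.ndim == 0 else out


def _chrom_dosages(geno: GenotypeMatrix, chrom):
    mask = geno.chrom_mask(chrom)
    if mask.sum() < 2:
        raise ValueError(f"need >= 2 markers on chrom {chrom}")
    D = geno.dosages[:, mask]
    D = np.where(np.isnan(D), np.nanmean(D, axis=0), D)
    pos = geno.markers.loc[mask, "pos"].to_numpy()
    sd = D.std(axis=0)
    poly = sd > 0
    if (~poly).any():
        logger.info("excluding %d monomorphic markers on chrom %s",
                    int((~poly).sum()), chrom)
    return D[:, poly], pos[poly]


def ld_scores(geno: GenotypeMatrix, chrom, window_bp: int = 1_000_000
              ) -> pd.DataFrame:
    """Per-marker LD score: sum of adjusted r2 within +- ``window_bp``.

    Monomorphic markers (undefined correlations) are excluded with a log
    message.  Returns a table (chrom, pos, ld_score, n_in_window).
    """
    D, pos = _chrom_dosages(geno, chrom)
    n = D.shape[0]
    C = np.corrcoef(D.T)
    r2 = C ** 2
    r2a = adjusted_r2(r2, n)
    in_win = np.abs(pos[:, None] - pos[None, :]) <= window_bp
    scores = np.sum(np.where(in_win, r2a, 0.0), axis=1)
    return pd.DataFrame({"chrom": chrom, "pos": pos, "ld_score": scores,
                         "n_in_window": in_win.sum(axis=1)})


def local_r2(geno: GenotypeMatrix, index_chrom, index_pos: int,
             window_bp: int = 1_000_000) -> pd.DataFrame:
    """Pairwise r2 between an index SNP and every marker within +- ``window_bp``.

    Used for the local-LD view around a top GWAS hit (1 Mb upstream and 1 Mb
    downstream by default, a 2 Mb span).
    """
    D, pos = _chrom_dosages(geno, index_chrom)
    hits = np.flatnonzero(pos == index_pos)
    if hits.size == 0:
        mask = geno.chrom_mask(index_chrom)
        if index_pos in set(geno.markers.loc[mask, "pos"]):
            raise ValueError("index SNP is monomorphic")
        raise KeyError(f"index SNP {index_chrom}:{index_pos} not in the map")
    j = int(hits[0])
    sel = np.abs(pos - pos[j]) <= window_bp
    x = D[:, j]
    sub = D[:, sel]
    xc = x - x.mean()
    sc = sub - sub.mean(axis=0)
    num = xc @ sc
    den = np.sqrt((xc @ xc) * np.einsum("ij,ij->j", sc, sc))
    r2 = (num / den) ** 2
    return pd.DataFrame({"chrom": index_chrom, "pos": pos[sel], "r2": r2})
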