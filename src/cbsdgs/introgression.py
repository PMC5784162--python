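"""Introgression-segment detection from ancestry-informative (AI) SNPs.

AI SNPs are fixed for different alleles in pure *M. esculenta* (E) and pure
*M. glaziovii* (G).  Matched AI markers are oriented so dosage counts the G
allele, each chromosome is divided into non-overlapping windows of 20 AI
SNPs, and each window x clone is called G/G, G/E or E/E when the most common
genotype class reaches at least ``ratio`` (default 2) times the proportion of
the second most common class — otherwise "NoCall".  Contiguous runs of
identical non-EE calls are merged into reportable segments.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genomics import GenotypeMatrix

logger = logging.getLogger(__name__)

CLASSES = ("EE", "GE", "GG")   # index = G-allele dosage 0/1/2


def validate_catalog(catalog: pd.DataFrame) -> pd.DataFrame:
    """Check an AI catalog (chrom, pos, esculenta_allele, glaziovii_allele)."""
    need = {"chrom", "pos", "esculenta_allele", "glaziovii_allele"}
    if not need <= set(catalog.columns):
        raise ValueError(f"catalog must have columns {sorted(need)}")
    if (catalog["esculenta_allele"] == catalog["glaziovii_allele"]).any():
        raise ValueError("catalog rows with identical E and G alleles")
    if catalog.duplicated(["chrom", "pos"]).any():
        raise ValueError("duplicate positions in the AI catalog")
    return catalog


@dataclass
class MatchedAISnps:
    """AI SNPs matched to the marker map, oriented to count the G allele."""

    dosages: np.ndarray          # clones x matched AI SNPs (G-allele dosage)
    markers: pd.DataFrame        # chrom, pos of matched SNPs (sorted per chrom)
    clones: pd.Index
    flipped: np.ndarray          # which matched SNPs had ref/alt swapped


def match_ai_snps(geno: GenotypeMatrix, catalog: pd.DataFrame) -> MatchedAISnps:
    """Match catalog AI SNPs to the genotype map by (chrom, pos).

    Allele orientation is reconciled: when the VCF ALT allele is the G allele
    the dosage is used as is; when REF/ALT are swapped the dosage is flipped
    to ``2 - d``; records whose allele pair does not match the catalog are
    dropped with a log message.
    """
    catalog = validate_catalog(catalog)
    mk = geno.markers.assign(_col=np.arange(geno.n_markers))
    mk["chrom"] = mk["chrom"].astype(str)
    cat = catalog.copy()
    cat["chrom"] = cat["chrom"].astype(str)
    merged = mk.merge(cat, on=["chrom", "pos"], how="inner")
    if merged.empty:
        raise ValueError("no AI SNPs matched the marker map")
    direct = ((merged["ref"] == merged["esculenta_allele"])
              & (merged["alt"] == merged["glaziovii_allele"])).to_numpy()
    swapped = ((merged["ref"] == merged["glaziovii_allele"])
               & (merged["alt"] == merged["esculenta_allele"])).to_numpy()
    bad = ~(direct | swapped)
    if bad.any():
        logger.info("dropping %d AI SNPs with mismatching allele pairs",
                    int(bad.sum()))
    merged = merged[~bad]
    direct = direct[~bad]
    if merged.empty:
        raise ValueError("no AI SNPs with matching alleles")
    cols = merged["_col"].to_numpy()
    dos = geno.dosages[:, cols].copy()
    dos[:, ~direct] = 2.0 - dos[:, ~direct]
    order = np.lexsort((merged["pos"].to_numpy(),
                        merged["chrom"].to_numpy()))
    return MatchedAISnps(dosages=dos[:, order],
                         markers=merged.iloc[order][["chrom", "pos"]]
                         .reset_index(drop=True),
                         clones=geno.clones,
                         flipped=(~direct)[order])


def call_windows(matched: MatchedAISnps, window: int = 20, ratio: float = 2.0,
                 min_nonmissing: int = 10) -> pd.DataFrame:
    """Windowed majority ancestry calls.

    Per chromosome, AI SNPs (already position-sorted) are chunked into
    non-overlapping windows of ``window`` SNPs; trailing remainders are
    dropped.  Genotype classes are counted on the G-allele dosage (rounded:
    2 -> G/G, 1 -> G/E, 0 -> E/E; missing excluded).  The majority class is
    called iff its proportion is at least ``ratio`` times the second most
    common class's proportion; windows with fewer than ``min_nonmissing``
    informative SNPs are NoCall.

    Returns a long table: clone, window, chrom, start, end, call and the
    three class proportions.
    """
    rows = []
    wid = 0
    chroms = matched.markers["chrom"].to_numpy()
    pos = matched.markers["pos"].to_numpy()
    n_clones = len(matched.clones)
    for chrom in pd.unique(chroms):
        idx = np.flatnonzero(chroms == chrom)
        n_win, rem = divmod(idx.size, window)
        if rem:
            logger.info("chrom %s: dropping %d trailing AI SNPs (< window)",
                        chrom, rem)
        for w in range(n_win):
            members = idx[w * window:(w + 1) * window]
            D = matched.dosages[:, members]
            valid = ~np.isnan(D)
            Dr = np.where(valid, np.round(D), -1).astype(int)
            counts = np.stack([(Dr == k).sum(axis=1) for k in range(3)], axis=1)
            nonmiss = valid.sum(axis=1)
            with np.errstate(invalid="ignore", divide="ignore"):
                props = counts / np.maximum(nonmiss, 1)[:, None]
            order = np.argsort(counts, axis=1)
            top = order[:, 2]
            second = order[:, 1]
            top_p = props[np.arange(n_clones), top]
            second_p = props[np.arange(n_clones), second]
            callable_ = (nonmiss >= min_nonmissing) & (top_p > 0) \
                & (top_p >= ratio * second_p)
            call = np.where(callable_, np.array(CLASSES)[top], "NoCall")
            start = int(pos[members[0]])
            end = int(pos[members[-1]])
            for clone_i, c, pEE, pGE, pGG, nm in zip(
                    matched.clones, call, props[:, 0], props[:, 1],
                    props[:, 2], nonmiss):
                rows.append({"clone": clone_i, "window": wid, "chrom": chrom,
                             "start": start, "end": end, "call": c,
                             "p_EE": pEE, "p_GE": pGE, "p_GG": pGG,
                             "n_informative": int(nm)})
            wid += 1
    return pd.DataFrame(rows)


def segments_from_windows(calls: pd.DataFrame) -> pd.DataFrame:
    """Merge maximal runs of identical non-EE window calls into segments.

    NoCall (and EE) windows break a run.  Returns (clone, chrom, start, end,
    call, n_windows); all-EE input yields an empty table.
    """
    segs = []
    for clone, sub in calls.sort_values(["clone", "chrom", "window"]) \
                           .groupby("clone", sort=False):
        for chrom, cs in sub.groupby("chrom", sort=False):
            run_call, run_start, run_end, run_n = None, None, None, 0
            for _, row in cs.iterrows():
                c = row["call"]
                if c in ("GG", "GE") and c == run_call:
                    run_end = row["end"]
                    run_n += 1
                    continue
                if run_call is not None:
                    segs.append({"clone": clone, "chrom": chrom,
                                 "start": run_start, "end": run_end,
                                 "call": run_call, "n_windows": run_n})
                if c in ("GG", "GE"):
                    run_call, run_start, run_end, run_n = (
                        c, row["start"], row["end"], 1)
                else:
                    run_call = None
            if run_call is not None:
                segs.append({"clone": clone, "chrom": chrom,
                             "start": run_start, "end": run_end,
                             "call": run_call, "n_windows": run_n})
    return pd.DataFrame(segs, columns=["clone", "chrom", "start", "end",
                                       "call", "n_windows"])


def segments_to_bed(segments: pd.DataFrame, path) -> None:
    """Write segments as BED (0-based half-open; clone/call in the name)."""
    with open(path, "w") as fh:
        for _, s in segments.iterrows():
            fh.write(f"{s['chrom']}\t{int(s['start']) - 1}\t{int(s['end'])}\t"
                     f"{s['clone']}:{s['call']}\n")
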