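"""Synthetic two-panel cassava breeding data with a known genetic architecture.

The generator emulates the structure the downstream analyses assume: two
breeding panels scored for an ordinal 1-5 severity trait at several locations
(alpha-lattice and augmented-with-checks field designs), a dense bi-allelic
SNP panel with local LD from founder-haplotype block copying, a wild-donor
(*M. glaziovii*-style) introgression block on chromosome 4 carrying
diagnostic alleles, a QTL cluster plus a polygenic background, and
location-varying entry-mean heritability.  Every simulated quantity that a
downstream stage estimates (breeding values, total genetic values, window
ancestry, marker effects) is recorded in a :class:`TruthSet` so that
parameter-recovery tests have an oracle.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genomics import GenotypeMatrix

logger = logging.getLogger(__name__)

_BASES = np.array(list("ACGT"))


@dataclass
class AlphaLattice:
    """Replicated alpha-lattice layout: reps split into blocks grouped in ranges."""

    reps: int = 2
    block_size: int = 25
    blocks_per_range: int = 4


@dataclass
class Augmented:
    """Unreplicated augmented design: checks repeated in every incomplete block."""

    n_checks: int = 6
    block_size: int = 25


@dataclass
class QTL:
    chrom: int
    pos: int
    additive: float
    dominance: float = 0.0


@dataclass
class IntrogressionSpec:
    """A donor introgression segment and its effect on the latent trait."""

    chrom: int = 4
    start: int = 8_000_000
    end: int = 16_000_000
    carrier_freq: float = 0.25          # frequency of the donor haplotype
    effect: float = -0.5                # per donor-allele effect (resistance)


@dataclass
class SimConfig:
    """Study conditions for the synthetic breeding panels.

    Defaults are a desk-scale downscaling of the real panels: 5 chromosomes of
    1,000 markers each (30 Mb), 900 clones in two panels, three locations per
    panel with entry-mean heritabilities inside the range the field trials
    span, a resistance-conferring introgression block on chromosome 4 and a
    QTL cluster (standing in for the chromosome-11 cluster) on chromosome 5.
    """

    n_clones_panel1: int = 300
    n_clones_panel2: int = 600
    n_chrom: int = 5
    markers_per_chrom: int = 1000
    chrom_length_bp: int = 30_000_000
    qtl_spec: list[QTL] = field(default_factory=lambda: [
        QTL(chrom=5, pos=15_000_000, additive=0.5),
        QTL(chrom=5, pos=15_400_000, additive=0.4, dominance=0.2),
        QTL(chrom=5, pos=15_800_000, additive=0.3),
    ])
    introgression_spec: IntrogressionSpec = field(default_factory=IntrogressionSpec)
    h2_per_location: dict[str, float] = field(default_factory=lambda: {
        "Namulonge": 0.25, "Ngetta": 0.55, "Kasese": 0.4})
    locations: list[str] | None = None     # default: keys of h2_per_location
    design: AlphaLattice | Augmented = field(default_factory=AlphaLattice)
    score_thresholds: tuple[float, float, float, float] = (-1.8, -0.6, 0.6, 1.8)
    seed: int = 0
    # architecture / population parameters
    n_founders: int = 40
    ld_block_len: int = 25              # markers copied per founder block
    background_n: int = 200             # markers with polygenic effects
    background_var: float = 1.0         # additive variance of the background
    ai_fraction: float = 0.2            # fraction of markers that are AI SNPs
    error_rate: float = 0.01            # genotype-call error rate
    genetic_corr: float = 0.7           # genetic correlation across locations
    block_var: float = 0.1
    range_var: float = 0.1
    location_means: dict[str, float] | None = None
    trait: str = "cbsd6s"

    def __post_init__(self):
        cuts = np.asarray(self.score_thresholds, float)
        if len(cuts) != 4 or not np.all(np.diff(cuts) > 0):
            raise ValueError("score_thresholds must be 4 strictly increasing cutpoints")
        for loc, h2 in self.h2_per_location.items():
            if not 0.0 <= h2 <= 1.0:
                raise ValueError(f"h2 for {loc} must be in [0, 1]")
        for q in self.qtl_spec:
            if not 1 <= q.chrom <= self.n_chrom or not 0 < q.pos <= self.chrom_length_bp:
                raise ValueError(f"QTL at {q.chrom}:{q.pos} outside chromosome bounds")
        if self.locations is None:
            self.locations = list(self.h2_per_location)

    @property
    def n_clones(self) -> int:
        return self.n_clones_panel1 + self.n_clones_panel2


@dataclass
class TruthSet:
    """Generating truth for parameter-recovery tests."""

    true_breeding_values: pd.Series          # additive genetic value per clone
    true_total_genetic_values: pd.Series     # + dominance deviations
    true_ancestry: pd.DataFrame              # clone x AI window: GG/GE/EE
    qtl_effects: pd.Series                   # per-marker additive effect
    carrier_gametes: pd.DataFrame            # clone -> (gamete1, gamete2) bool
    ai_catalog: pd.DataFrame                 # chrom, pos, E allele, G allele
    windows: pd.DataFrame                    # window id, chrom, start, end


def simulate_genotypes(cfg: SimConfig) -> tuple[GenotypeMatrix, TruthSet]:
    """Simulate the two-panel genotype matrix and its generating truth.

    Allele frequencies are drawn from a U-shaped Beta(0.5, 0.5); local LD is
    induced by copying founder haplotypes in blocks of ``cfg.ld_block_len``
    markers; introgression carriers receive the donor-diagnostic haplotype
    across the configured interval, and window-level ancestry truth is
    recorded on the ancestry-informative (AI) SNPs in non-overlapping windows
    of 20.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_clones
    m_per = cfg.markers_per_chrom
    spacing = cfg.chrom_length_bp // m_per

    chroms = np.repeat(np.arange(1, cfg.n_chrom + 1), m_per)
    pos = np.tile(spacing * (np.arange(m_per) + 1), cfg.n_chrom)
    m = chroms.size

    # AI SNP designation (background fixed for the esculenta allele).
    ai_mask = rng.random(m) < cfg.ai_fraction
    intro = cfg.introgression_spec
    seg_mask = (chroms == intro.chrom) & (pos >= intro.start) & (pos <= intro.end)
    n_seg_ai = int(np.sum(ai_mask & seg_mask))
    if n_seg_ai < 20:
        raise ValueError(
            f"introgression interval contains {n_seg_ai} AI markers; "
            "at least 20 are required for window calling")

    p = rng.beta(0.5, 0.5, size=m).clip(0.01, 0.99)
    p[ai_mask] = 0.0    # esculenta background is fixed at the E (ref) allele

    # Founder haplotypes and block copying.
    H = (rng.random((2 * cfg.n_founders, m)) < p).astype(np.int8)
    n_blocks = int(np.ceil(m_per / cfg.ld_block_len))
    # per-chromosome block boundaries so blocks never span chromosomes
    block_id = np.concatenate([
        c * n_blocks + np.minimum(np.arange(m_per) // cfg.ld_block_len,
                                  n_blocks - 1)
        for c in range(cfg.n_chrom)])
    total_blocks = cfg.n_chrom * n_blocks

    # Donor haplotype: diagnostic (G) allele at every AI SNP in the segment,
    # plus a fixed random haplotype at the non-AI segment markers.
    donor = (rng.random(m) < np.where(p > 0, p, 0.5)).astype(np.int8)
    donor[ai_mask & seg_mask] = 1
    donor[~seg_mask] = 0

    gametes = np.empty((2, n, m), dtype=np.int8)
    carrier = rng.random((2, n)) < intro.carrier_freq
    for g in range(2):
        choice = rng.integers(0, 2 * cfg.n_founders, size=(n, total_blocks))
        gametes[g] = H[choice[:, block_id], np.arange(m)]
        for r in np.flatnonzero(carrier[g]):
            gametes[g, r, seg_mask] = donor[seg_mask]
    dos = (gametes[0] + gametes[1]).astype(float)

    # Genotyping / imputation error: re-draw a fraction of calls from HWE.
    if cfg.error_rate > 0:
        err = rng.random(dos.shape) < cfg.error_rate
        redraw = rng.binomial(2, np.broadcast_to(p, dos.shape)[err]).astype(float)
        dos[err] = redraw

    clones = pd.Index([f"UG{i:05d}" for i in range(n)], name="clone")
    panel = pd.Series(np.r_[np.ones(cfg.n_clones_panel1, int),
                            np.full(cfg.n_clones_panel2, 2)], index=clones)
    ref = _BASES[rng.integers(0, 4, m)]
    alt_shift = rng.integers(1, 4, m)
    alt = _BASES[(np.searchsorted(_BASES, ref) + alt_shift) % 4]
    markers = pd.DataFrame({"chrom": chroms, "pos": pos, "ref": ref, "alt": alt,
                            "ar2": rng.beta(8, 1.5, m).round(4)})
    geno = GenotypeMatrix(dosages=dos, markers=markers, clones=clones,
                          panel=panel)

    # --- marker effects: explicit QTL + polygenic background + introgression
    effects = np.zeros(m)
    for q in cfg.qtl_spec:
        j = int(np.argmin(np.abs(pos - q.pos) + 1e9 * (chroms != q.chrom)))
        effects[j] += q.additive
    bg_candidates = np.flatnonzero(~ai_mask & (p > 0.05) & (p < 0.95))
    bg = rng.choice(bg_candidates, size=min(cfg.background_n, bg_candidates.size),
                    replace=False)
    raw = rng.normal(0.0, 1.0, bg.size)
    bg_bv = (dos[:, bg] - dos[:, bg].mean(0)) @ raw
    sd = bg_bv.std()
    raw = raw * (np.sqrt(cfg.background_var) / sd if sd > 0 else 0.0)
    effects[bg] += raw
    # introgression effect acts through the donor-haplotype count
    donor_dose = carrier[0].astype(int) + carrier[1].astype(int)

    bv = (dos - dos.mean(0)) @ effects + intro.effect * (donor_dose - donor_dose.mean())
    dom = np.zeros(n)
    for q in cfg.qtl_spec:
        if q.dominance:
            j = int(np.argmin(np.abs(pos - q.pos) + 1e9 * (chroms != q.chrom)))
            het = (np.round(dos[:, j]) == 1).astype(float)
            dom += q.dominance * (het - het.mean())
    tbv = pd.Series(bv, index=clones)
    tgv = pd.Series(bv + dom, index=clones)

    # --- AI catalog and window-level ancestry truth
    ai_idx = np.flatnonzero(ai_mask)
    catalog = pd.DataFrame({
        "chrom": chroms[ai_idx], "pos": pos[ai_idx],
        "esculenta_allele": ref[ai_idx], "glaziovii_allele": alt[ai_idx]})
    windows, win_rows = [], []
    wid = 0
    for chrom in range(1, cfg.n_chrom + 1):
        on_chr = ai_idx[chroms[ai_idx] == chrom]
        n_win = on_chr.size // 20
        for w in range(n_win):
            members = on_chr[w * 20:(w + 1) * 20]
            in_seg = seg_mask[members].mean() > 0.5
            windows.append({"window": wid, "chrom": chrom,
                            "start": int(pos[members[0]]),
                            "end": int(pos[members[-1]]),
                            "in_segment": bool(in_seg)})
            if in_seg:
                cls = np.where(donor_dose == 2, "GG",
                               np.where(donor_dose == 1, "GE", "EE"))
            else:
                cls = np.full(n, "EE")
            win_rows.append(cls)
            wid += 1
    windows = pd.DataFrame(windows)
    true_anc = pd.DataFrame(np.array(win_rows).T, index=clones,
                            columns=windows["window"])

    truth = TruthSet(
        true_breeding_values=tbv, true_total_genetic_values=tgv,
        true_ancestry=true_anc,
        qtl_effects=pd.Series(effects, index=pd.RangeIndex(m)),
        carrier_gametes=pd.DataFrame(
            {"gamete1": carrier[0], "gamete2": carrier[1]}, index=clones),
        ai_catalog=catalog, windows=windows)
    return geno, truth


# ------------------------------------------------------------- phenotypes

def _layout_alpha_lattice(clones, locations, design, rng):
    rows = []
    for loc in locations:
        for rep in range(1, design.reps + 1):
            order = rng.permutation(len(clones))
            for i, ci in enumerate(order):
                blk = i // design.block_size
                rng_id = blk // design.blocks_per_range
                rows.append({"clone": clones[ci], "location": loc, "rep": rep,
                             "block": f"{loc}_r{rep}_b{blk}",
                             "range": f"{loc}_r{rep}_g{rng_id}",
                             "is_check": 0})
    return pd.DataFrame(rows)


def _layout_augmented(clones, locations, design, rng):
    checks = [f"CHECK{i+1}" for i in range(design.n_checks)]
    rows = []
    for loc in locations:
        order = rng.permutation(len(clones))
        n_blocks = int(np.ceil(len(clones) / design.block_size))
        for blk in range(n_blocks):
            members = order[blk * design.block_size:(blk + 1) * design.block_size]
            bid = f"{loc}_b{blk}"
            for ci in members:
                rows.append({"clone": clones[ci], "location": loc, "rep": 1,
                             "block": bid, "range": "none", "is_check": 0})
            for ch in checks:
                rows.append({"clone": ch, "location": loc, "rep": 1,
                             "block": bid, "range": "none", "is_check": 1})
    return pd.DataFrame(rows), checks


def simulate_phenotypes(geno: GenotypeMatrix, truth: TruthSet, cfg: SimConfig,
                        clones=None) -> pd.DataFrame:
    """Plot-level phenotypes under the configured field design.

    The latent value of a plot is location mean + location-specific genetic
    value + block/range effects + residual, with the residual variance chosen
    per location so the entry-mean heritability matches
    ``cfg.h2_per_location``.  The ordinal severity score is
    ``1 + #cutpoints below the latent value``; both surfaces are returned
    (columns ``<trait>`` and ``<trait>_latent``), along with a mildly
    heritable ``cmds`` covariate used by the fixed-covariate re-fit.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    if clones is None:
        clones = list(geno.clones)
    design = cfg.design
    checks: list[str] = []
    if isinstance(design, AlphaLattice):
        layout = _layout_alpha_lattice(clones, cfg.locations, design, rng)
        reps = design.reps
    else:
        layout, checks = _layout_augmented(clones, cfg.locations, design, rng)
        reps = 1

    all_ids = list(clones) + checks
    g = truth.true_total_genetic_values.reindex(all_ids)
    if checks:
        g.loc[checks] = rng.normal(0.0, g.loc[clones].std() or 1.0, len(checks))
    vg = float(g.loc[clones].var())

    loc_means = cfg.location_means or {}
    sb2, sr2 = cfg.block_var, cfg.range_var
    # location-specific genetic values with correlation cfg.genetic_corr
    rg = cfg.genetic_corr
    gloc = {}
    for loc in cfg.locations:
        dev = rng.normal(0.0, np.sqrt(vg) if vg > 0 else 0.0, len(all_ids))
        gloc[loc] = np.sqrt(rg) * g.to_numpy() + np.sqrt(1 - rg) * dev
    gloc = pd.DataFrame(gloc, index=all_ids)

    blk_eff = {b: rng.normal(0, np.sqrt(sb2)) for b in layout["block"].unique()}
    rng_eff = {r: (0.0 if r == "none" else rng.normal(0, np.sqrt(sr2)))
               for r in layout["range"].unique()}

    latent = np.empty(len(layout))
    for loc in cfg.locations:
        h2 = cfg.h2_per_location.get(loc, 0.5)
        extra = 0.0 if isinstance(design, Augmented) else sr2
        if h2 >= 1.0:
            if sb2 > 0 or extra > 0:
                raise ValueError(
                    f"h2 = 1 at {loc} is inconsistent with nonzero "
                    "block/range variance")
            se2 = 0.0
        elif h2 <= 0.0:
            se2 = max(vg, 1.0) * 100.0
        elif vg == 0.0:
            se2 = 1.0     # no genetic variance: any target h2 is vacuous
        else:
            se2 = reps * vg * (1.0 - h2) / h2 - sb2 - extra
            if se2 < 0:
                logger.warning("design variances exceed the residual budget at "
                               "%s; clipping", loc)
                se2 = 0.0
        sel = layout["location"] == loc
        idx = np.flatnonzero(sel.to_numpy())
        sub = layout.iloc[idx]
        latent[idx] = (loc_means.get(loc, 0.0)
                       + gloc.loc[sub["clone"], loc].to_numpy()
                       + np.array([blk_eff[b] for b in sub["block"]])
                       + np.array([rng_eff[r] for r in sub["range"]])
                       + rng.normal(0.0, np.sqrt(se2), idx.size))

    cuts = np.asarray(cfg.score_thresholds, float)
    score = 1 + np.searchsorted(cuts, latent, side="left")
    out = layout.copy()
    out[cfg.trait] = score.astype(int)
    out[f"{cfg.trait}_latent"] = latent
    # CMD severity covariate: independent mildly-heritable nuisance trait
    cmd_g = pd.Series(rng.normal(0, 0.5, len(all_ids)), index=all_ids)
    out["cmds"] = (3.0 + cmd_g.loc[out["clone"]].to_numpy()
                   + rng.normal(0, 0.7, len(out))).round(1)
    return out


def simulate_clone_values(truth: TruthSet, h2: float, seed: int = 0,
                          total: bool = False) -> pd.Series:
    """Clone-mean phenotype at narrow-sense heritability ``h2``.

    A stand-in for the de-regressed BLUPs that stage 1 would deliver:
    ``y = g + e`` with ``Var(e) = Var(g) (1 - h2) / h2``.  ``total=True``
    uses total genetic values (additive + dominance) as the signal.
    """
    if not 0 < h2 <= 1:
        raise ValueError("h2 must be in (0, 1]")
    rng = np.random.default_rng(seed)
    g = (truth.true_total_genetic_values if total
         else truth.true_breeding_values)
    vg = float(g.var())
    ve = vg * (1.0 - h2) / h2
    return g + rng.normal(0.0, np.sqrt(ve), g.size)


# ------------------------------------------------------------------ writers

def write_outputs(geno: GenotypeMatrix, truth: TruthSet, pheno: pd.DataFrame,
                  outdir) -> dict[str, str]:
    """Write genotypes (VCF + dosage CSV), phenotypes, truth and AI catalog."""
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": out / "genotypes.vcf",
        "dosages": out / "dosages.csv",
        "phenotypes": out / "phenotypes.csv",
        "truth": out / "truth.csv",
        "ai_catalog": out / "ai_catalog.csv",
    }
    geno.to_vcf(paths["vcf"])
    geno.to_dosage_csv(paths["dosages"])
    pheno.to_csv(paths["phenotypes"], index=False)
    pd.DataFrame({"tbv": truth.true_breeding_values,
                  "tgv": truth.true_total_genetic_values}).to_csv(
        paths["truth"], index_label="clone")
    truth.ai_catalog.to_csv(paths["ai_catalog"], index=False)
    return {k: str(v) for k, v in paths.items()}
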