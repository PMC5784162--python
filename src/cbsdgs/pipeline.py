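"""End-to-end orchestration of the two-stage analysis.

A single :class:`RunConfig` drives: synthetic-data generation (or ingestion
of VCF/CSV inputs) -> stage-1 trial mixed models and de-regressed BLUPs ->
marker QC, GRM, PCA and SNP heritability -> MLMA-LOCO GWAS -> genomic
prediction -> introgression calling -> LD diagnostics.  Each stage writes
plain-text outputs into the run directory and appends to a manifest
(parameters, derived per-stage seeds, row counts) so a run is reproducible
from its config + seed alone.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import genomics, gwas, introgression, ldscore, prediction, simdata, stage1

logger = logging.getLogger(__name__)

ALL_STAGES = ("simdata", "stage1", "genomics", "gwas", "prediction",
              "introgression", "ldscore")


@dataclass
class RunConfig:
    """Configuration of a pipeline run."""

    outdir: str = "run"
    seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES
    sim: simdata.SimConfig | None = None
    maf_min: float = 0.01
    ar2_min: float = 0.3
    max_missing: float = 0.6
    gwas_maf: float = 0.05
    alpha: float = 0.05
    models: tuple[str, ...] = ("gblup", "rkhs", "rf")
    cv_k: int = 5
    cv_reps: int = 2
    focal_chroms: tuple = (4, 5)
    ld_chrom: int | str = 4

    def __post_init__(self):
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        if not self.stages:
            raise ValueError("at least one stage must be enabled")


def _stage_seed(base: int, stage: str) -> int:
    """Derive a per-stage seed so stages can be re-run in isolation."""
    child = np.random.SeedSequence([base, ALL_STAGES.index(stage)])
    return int(child.generate_state(1)[0] % (2 ** 31))


def run(config: RunConfig) -> Path:
    """Execute the enabled stages, returning the run directory."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"version": __version__, "seed": config.seed,
                "stages": list(config.stages), "rows": {}, "params": {
                    "maf_min": config.maf_min, "ar2_min": config.ar2_min,
                    "gwas_maf": config.gwas_maf, "alpha": config.alpha,
                    "models": list(config.models)}}
    state: dict = {}

    for stage in [s for s in ALL_STAGES if s in config.stages]:
        seed = _stage_seed(config.seed, stage)
        logger.info("stage %s (seed %d)", stage, seed)
        try:
            rows = _STAGE_FUNCS[stage](config, state, out, seed)
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
        manifest["rows"][stage] = rows
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                 sort_keys=True))
    return out


def _run_simdata(config, state, out, seed):
    cfg = config.sim or simdata.SimConfig()
    cfg.seed = seed
    geno, truth = simdata.simulate_genotypes(cfg)
    pheno = simdata.simulate_phenotypes(geno, truth, cfg)
    simdata.write_outputs(geno, truth, pheno, out)
    state.update(geno=geno, truth=truth, pheno=pheno, simcfg=cfg)
    return {"clones": geno.n_clones, "markers": geno.n_markers,
            "plots": len(pheno)}


def _run_stage1(config, state, out, seed):
    cfg = state["simcfg"]
    design = "alpha" if isinstance(cfg.design, simdata.AlphaLattice) else "augmented"
    fit = stage1.fit_panel(state["pheno"], response=f"{cfg.trait}_latent",
                           design=design)
    dereg = stage1.deregress(fit)
    fit.summary().to_csv(out / "stage1_summary.csv", index=False)
    dereg.to_csv(out / "dereg_blups.csv", index_label="clone")
    state["fit"] = fit
    state["dereg"] = dereg["dereg"].dropna()
    return {"clones": len(dereg), "H2": round(fit.H2, 4)}


def _run_genomics(config, state, out, seed):
    geno_f = genomics.filter_markers(state["geno"], config.max_missing,
                                     config.ar2_min, config.maf_min)
    G = genomics.grm_vanraden(geno_f)
    G.to_csv(out / "grm.csv")
    scores, frac = genomics.pca(geno_f, k=10)
    scores.to_csv(out / "pca_scores.csv")
    h2, vc = genomics.snp_heritability(state["dereg"], G)
    pd.DataFrame([{"snp_h2": h2, **vc}]).to_csv(out / "snp_h2.csv", index=False)
    state.update(geno_f=geno_f, grm=G, pca_frac=frac, snp_h2=h2)
    return {"markers_post_qc": geno_f.n_markers, "snp_h2": round(h2, 4),
            "pc1_frac": round(float(frac[0]), 4)}


def _run_gwas(config, state, out, seed):
    table = gwas.mlma_loco(state["geno_f"], state["dereg"],
                           maf_min=config.gwas_maf)
    thresh = gwas.bonferroni_threshold(len(table), config.alpha)
    table.to_csv(out / "gwas.tsv", sep="\t", index=False)
    gwas.to_qqman(table, out / "gwas_qqman.tsv")
    top = table.loc[table["p"].idxmin()]
    state.update(gwas_table=table, bonferroni=thresh, top_snp=top)
    return {"markers_tested": len(table), "bonferroni": round(thresh, 3),
            "top_chrom": str(top["chrom"]), "top_pos": int(top["pos"]),
            "top_neglog10p": round(float(top["neglog10p"]), 3)}


def _run_prediction(config, state, out, seed):
    acc = prediction.cross_validate(
        config.models, state["geno_f"], state["dereg"], k=config.cv_k,
        reps=config.cv_reps, seed=seed, focal_chroms=config.focal_chroms)
    acc.to_csv(out / "cv_accuracy.csv", index=False)
    state["cv"] = acc
    summary = acc.groupby("model")["accuracy"].mean()
    return {"rows": len(acc),
            **{f"acc_{m}": round(float(v), 4) for m, v in summary.items()}}


def _run_introgression(config, state, out, seed):
    truth = state["truth"]
    matched = introgression.match_ai_snps(state["geno"], truth.ai_catalog)
    calls = introgression.call_windows(matched)
    segs = introgression.segments_from_windows(calls)
    calls.to_csv(out / "ancestry_calls.tsv", sep="\t", index=False)
    introgression.segments_to_bed(segs, out / "introgression_segments.bed")
    state.update(anc_calls=calls, segments=segs)
    return {"windows": int(calls["window"].nunique()), "segments": len(segs)}


def _run_ldscore(config, state, out, seed):
    scores = ldscore.ld_scores(state["geno_f"], config.ld_chrom)
    scores.to_csv(out / "ld_scores.tsv", sep="\t", index=False)
    state["ld"] = scores
    return {"markers": len(scores),
            "mean_ld_score": round(float(scores["ld_score"].mean()), 3)}


_STAGE_FUNCS = {
    "simdata": _run_simdata, "stage1": _run_stage1, "genomics": _run_genomics,
    "gwas": _run_gwas, "prediction": _run_prediction,
    "introgression": _run_introgression, "ldscore": _run_ldscore,
}
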