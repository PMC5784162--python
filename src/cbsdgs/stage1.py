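"""Stage 1 of the two-stage analysis: trial-design mixed models.

A plot-level linear mixed model accounts for the field design — fixed
population mean, location (and check effect or a disease-severity covariate
when requested), random clone, incomplete block and, for the replicated
alpha-lattice design, range nested in location-rep.  Clone BLUPs and their
prediction error variances (PEV) are extracted at the REML optimum and
de-regressed by the reliability,

    dereg BLUP = BLUP / (1 - PEV / sigma_c^2),

which removes shrinkage so the second stage (GWAS, genomic prediction) sees
approximately unregressed genetic values.  Broad-sense heritability is
computed on an entry-mean basis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._reml import reml_independent

logger = logging.getLogger(__name__)

DEFAULT_RELIABILITY_FLOOR = 0.05


@dataclass
class MixedModelSpec:
    """Specification of a stage-1 model.

    ``fixed`` lists column names treated as fixed effects (categorical unless
    the column is numeric, in which case it enters as a covariate — the CMD
    re-fit passes ``cmds`` here).  ``random`` lists grouping columns; clone
    must be among them.  An intercept (population mean) is always included.
    """

    response: str
    data: pd.DataFrame
    fixed: list[str] = field(default_factory=lambda: ["location"])
    random: list[str] = field(default_factory=lambda: ["clone", "block"])
    clone_col: str = "clone"

    def __post_init__(self):
        if self.clone_col not in self.random:
            raise ValueError("clone must be among the random terms")
        for col in [self.response, *self.fixed, *self.random]:
            if col not in self.data.columns:
                raise ValueError(f"column {col!r} not in the data")


@dataclass
class Stage1Fit:
    """REML variance components, clone BLUPs/PEVs and derived quantities."""

    varcomps: dict[str, float]
    blups: pd.Series
    pevs: pd.Series
    H2: float
    loglik: float
    n_plots_per_clone: pd.Series
    beta: pd.Series
    dereg_blups: pd.Series | None = None

    def summary(self) -> pd.DataFrame:
        rows = [{"component": k, "variance": v} for k, v in self.varcomps.items()]
        rows.append({"component": "H2_entry_mean", "variance": self.H2})
        return pd.DataFrame(rows)


def _design_matrix(col: pd.Series) -> tuple[np.ndarray, list]:
    levels = pd.Index(col.astype(str).unique())
    Z = (col.astype(str).to_numpy()[:, None] == levels.to_numpy()[None, :])
    return Z.astype(float), list(levels)


def reml_fit(spec: MixedModelSpec) -> Stage1Fit:
    """Fit the trial-design mixed model by REML.

    Aliased fixed-effect columns are dropped with a warning; random terms with
    fewer than two levels are rejected.
    """
    data = spec.data.dropna(subset=[spec.response]).reset_index(drop=True)
    y = data[spec.response].to_numpy(float)

    X_parts = [np.ones((len(data), 1))]
    names = ["(intercept)"]
    for term in spec.fixed:
        col = data[term]
        if pd.api.types.is_numeric_dtype(col) and col.nunique() > 8:
            X_parts.append(col.to_numpy(float)[:, None])
            names.append(term)
        else:
            Z, levels = _design_matrix(col)
            X_parts.append(Z[:, 1:])   # drop first level against the intercept
            names.extend(f"{term}[{l}]" for l in levels[1:])
    X = np.hstack(X_parts)

    Z_list, level_lists = [], []
    for term in spec.random:
        Z, levels = _design_matrix(data[term])
        if len(levels) < 2:
            raise ValueError(f"random term {term!r} has < 2 levels")
        Z_list.append(Z)
        level_lists.append(levels)

    fit = reml_independent(y, X, Z_list, term_names=list(spec.random))

    clone_levels = level_lists[spec.random.index(spec.clone_col)]
    blups = pd.Series(fit.blups[spec.clone_col], index=clone_levels, name="blup")
    pevs = pd.Series(fit.pevs[spec.clone_col], index=clone_levels, name="pev")
    n_plots = data.groupby(data[spec.clone_col].astype(str)).size().reindex(
        clone_levels).fillna(0).astype(int)

    sigma_c2 = fit.varcomps[spec.clone_col]
    h2 = broad_sense_h2_from_components(fit.varcomps, n_plots,
                                        clone_term=spec.clone_col)
    beta = (pd.Series(fit.beta, index=names) if len(fit.beta) == len(names)
            else pd.Series(fit.beta))   # aliased columns were dropped inside
    out = Stage1Fit(varcomps=fit.varcomps, blups=blups, pevs=pevs, H2=h2,
                    loglik=fit.loglik, n_plots_per_clone=n_plots, beta=beta)
    if sigma_c2 > 0:
        out.dereg_blups = deregress(out)["dereg"]
    return out


def deregress(fit: Stage1Fit,
              reliability_floor: float = DEFAULT_RELIABILITY_FLOOR
              ) -> pd.DataFrame:
    """De-regress clone BLUPs: ``dereg = BLUP / (1 - PEV / sigma_c^2)``.

    Returns a DataFrame with columns ``dereg``, ``reliability`` and
    ``excluded``; clones whose reliability is at or below the floor (the
    formula diverges as PEV approaches the clonal variance) are flagged and
    their de-regressed value set to ``NaN`` rather than returned.
    """
    sigma_c2 = fit.varcomps.get("clone", 0.0)
    if sigma_c2 <= 0:
        raise ValueError("clonal variance is zero; de-regression undefined")
    rel = 1.0 - fit.pevs / sigma_c2
    excluded = rel <= reliability_floor
    dereg = fit.blups / rel.where(~excluded)
    return pd.DataFrame({"dereg": dereg, "reliability": rel,
                         "excluded": excluded})


def broad_sense_h2_from_components(varcomps: dict[str, float],
                                   n_plots_per_clone: pd.Series,
                                   clone_term: str = "clone") -> float:
    """Entry-mean broad-sense heritability.

    ``H2 = sigma_c^2 / (sigma_c^2 + sigma_other^2 / r_bar)`` with ``r_bar``
    the harmonic mean number of plots per clone and ``sigma_other^2`` the sum
    of all non-clone variance components (block, range, residual), each of
    which contributes once per plot.  Clones with zero plots are excluded
    from the harmonic mean.
    """
    sigma_c2 = varcomps.get(clone_term, 0.0)
    other = sum(v for k, v in varcomps.items() if k != clone_term)
    counts = np.asarray(n_plots_per_clone, float)
    counts = counts[counts > 0]
    if counts.size == 0:
        raise ValueError("no clone has any plot")
    r_bar = counts.size / np.sum(1.0 / counts)
    if sigma_c2 <= 0:
        return 0.0
    if other <= 0:
        return 1.0
    return float(sigma_c2 / (sigma_c2 + other / r_bar))


def broad_sense_h2(fit: Stage1Fit) -> float:
    return broad_sense_h2_from_components(fit.varcomps, fit.n_plots_per_clone)


def correlate_traits(dereg_sets: dict[str, pd.Series],
                     min_shared: int = 3) -> pd.DataFrame:
    """Pairwise Pearson correlations of de-regressed BLUP sets.

    Each correlation uses the clone intersection of the pair; pairs with
    fewer than ``min_shared`` shared clones are reported as missing, not 0.
    Returns a long-format table (set_a, set_b, r, n).
    """
    names = list(dereg_sets)
    rows = []
    for i, a in enumerate(names):
        for b in names[i:]:
            sa = pd.Series(dereg_sets[a]).dropna()
            sb = pd.Series(dereg_sets[b]).dropna()
            shared = sa.index.intersection(sb.index)
            if len(shared) < min_shared:
                rows.append({"set_a": a, "set_b": b, "r": np.nan,
                             "n": len(shared)})
                continue
            r = float(np.corrcoef(sa.loc[shared], sb.loc[shared])[0, 1])
            rows.append({"set_a": a, "set_b": b, "r": r, "n": len(shared)})
    return pd.DataFrame(rows)


def fit_panel(pheno: pd.DataFrame, response: str, design: str = "alpha",
              covariate: str | None = None) -> Stage1Fit:
    """Convenience wrapper selecting the per-panel model by design flag.

    ``alpha`` fits clone + block + range(loc-rep) random terms; ``augmented``
    fits clone + block with a fixed check effect.  ``covariate`` adds a fixed
    numeric covariate (the CMD-severity re-fit).
    """
    if design == "alpha":
        fixed = ["location"]
        random = ["clone", "block", "range"]
    elif design == "augmented":
        fixed = ["location", "is_check"]
        random = ["clone", "block"]
    else:
        raise ValueError("design must be 'alpha' or 'augmented'")
    if covariate:
        fixed.append(covariate)
    if "location" in fixed and pheno["location"].nunique() < 2:
        fixed.remove("location")
    if design == "augmented" and pheno["is_check"].nunique() < 2:
        fixed.remove("is_check")
    spec = MixedModelSpec(response=response, data=pheno, fixed=fixed,
                          random=random)
    return reml_fit(spec)
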