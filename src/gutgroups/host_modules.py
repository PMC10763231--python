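"""Host co-expression modules and their association with the microbiota.

A deliberately minimal, reproducible variant of weighted co-expression
module detection: genes are standardized, dissimilarity is 1 - |Pearson r|,
average-linkage hierarchical clustering is cut at a fixed height, and
clusters below the minimum size fall into the unassigned "grey" module.
Each module is summarized by its eigengene (first principal component of the
module's standardized expression, unit variance, sign-oriented along the
module mean).  Eigengenes are then correlated with per-sample functional
group or phylum abundances, and the "consistently opposite" association
pattern of the two groups is quantified by a permutation test.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .datatypes import FunctionalGroupMap, GutgroupsError
from .stats import pearson, significance_tier

__all__ = [
    "detect_modules",
    "ModuleSet",
    "module_eigengenes",
    "associate",
    "AssociationTable",
    "opposite_pattern_test",
    "OppositePatternResult",
    "MODULE_COLORS",
]

logger = logging.getLogger(__name__)

#: Color-style module labels, assigned in decreasing module-size order.
MODULE_COLORS = (
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan", "midnightblue",
    "lightcyan", "grey60", "lightgreen", "lightyellow", "royalblue", "darkred",
    "darkgreen", "darkturquoise", "darkgrey", "orange", "darkorange", "white",
    "skyblue", "saddlebrown", "steelblue", "paleturquoise", "violet",
)

GREY = "grey"


def _standardize(X: np.ndarray) -> np.ndarray:
    """Column-wise z-score (population variance)."""
    return (X - X.mean(axis=0)) / X.std(axis=0)


@dataclasses.dataclass(frozen=True)
class ModuleSet:
    """Gene -> module assignment plus per-module eigengene summaries."""

    module_of_gene: pd.Series  # gene -> color label; "grey" = unassigned
    eigengenes: pd.DataFrame  # samples x modules, unit variance columns
    variance_explained: pd.Series  # per module, in (0, 1]

    def modules(self) -> list[str]:
        return [m for m in self.eigengenes.columns]


def detect_modules(
    expr: pd.DataFrame,
    min_size: int = 30,
    cut_height: float = 0.25,
) -> ModuleSet:
    """Cluster genes into co-expression modules.

    Parameters
    ----------
    expr : samples x genes expression matrix (>= 8 samples).
    min_size : clusters smaller than this merge into "grey".
    cut_height : flat-cut height on the 1 - |r| dissimilarity scale.
    """
    if expr.shape[0] < 8:
        raise GutgroupsError("module detection needs at least 8 samples")
    X = expr.to_numpy(dtype=float)
    variances = X.var(axis=0)
    constant = variances == 0
    if constant.all():
        raise GutgroupsError("all genes are constant; no modules to detect")
    if constant.any():
        dropped = list(expr.columns[constant])
        logger.info("dropping %d constant gene(s): %s...", len(dropped), dropped[:5])
        expr = expr.loc[:, ~constant]
        X = X[:, ~constant]
    genes = expr.columns
    Z = _standardize(X)
    corr = np.clip(np.corrcoef(Z, rowvar=False), -1.0, 1.0)
    dissim = 1.0 - np.abs(corr)
    np.fill_diagonal(dissim, 0.0)
    condensed = squareform((dissim + dissim.T) / 2.0, checks=False)
    link = hierarchy.linkage(condensed, method="average")
    flat = hierarchy.fcluster(link, t=cut_height, criterion="distance")

    labels = pd.Series(index=genes, dtype=object)
    sizes = pd.Series(flat).value_counts()
    kept = [c for c in sizes.index if sizes[c] >= min_size]
    kept.sort(key=lambda c: (-sizes[c], c))  # big modules get early colors
    color_of = {c: MODULE_COLORS[i % len(MODULE_COLORS)] for i, c in enumerate(kept)}
    for gene, c in zip(genes, flat):
        labels[gene] = color_of.get(c, GREY)
    if constant.any():
        for g in dropped:
            labels[g] = GREY
    eig, var_exp = module_eigengenes(expr, labels)
    return ModuleSet(module_of_gene=labels, eigengenes=eig, variance_explained=var_exp)


def module_eigengenes(
    expr: pd.DataFrame,
    module_of_gene: pd.Series,
) -> tuple[pd.DataFrame, pd.Series]:
    """First-PC eigengene and variance explained for every non-grey module.

    The eigengene is scaled to unit (population) variance and sign-oriented
    so it correlates positively with the module's mean standardized
    expression.  A one-gene module's eigengene is that standardized gene.
    """
    modules = [m for m in pd.unique(module_of_gene) if m != GREY]
    if not modules:
        raise GutgroupsError("no non-grey modules")
    eig = {}
    var_exp = {}
    for m in modules:
        members = module_of_gene.index[module_of_gene == m]
        members = [g for g in members if g in expr.columns]
        Z = _standardize(expr[members].to_numpy(dtype=float))
        if Z.shape[1] == 1:
            me = Z[:, 0]
            var_exp[m] = 1.0
        else:
            U, s, _ = np.linalg.svd(Z, full_matrices=False)
            me = U[:, 0]
            var_exp[m] = float(s[0] ** 2 / (s**2).sum())
        me = me / me.std()
        if np.corrcoef(me, Z.mean(axis=1))[0, 1] < 0:
            me = -me
        eig[m] = me
    frame = pd.DataFrame(eig, index=expr.index)
    return frame, pd.Series(var_exp, name="variance_explained")


@dataclasses.dataclass(frozen=True)
class AssociationTable:
    """Pearson r and p between module eigengenes (rows) and taxa/groups (cols)."""

    r: pd.DataFrame
    p: pd.DataFrame

    def tiers(self) -> pd.DataFrame:
        return self.p.map(significance_tier)


def associate(eigengenes: pd.DataFrame, group_abundance: pd.DataFrame) -> AssociationTable:
    """Correlate each module eigengene with each taxon/group abundance vector."""
    if not eigengenes.index.equals(group_abundance.index):
        common = eigengenes.index.intersection(group_abundance.index)
        if len(common) != len(eigengenes.index) or len(common) != len(group_abundance.index):
            raise GutgroupsError("eigengenes and abundances must cover the same samples")
        group_abundance = group_abundance.loc[eigengenes.index]
    n = eigengenes.shape[0]
    if n < 4:
        raise GutgroupsError("association needs at least 4 samples")
    r = pd.DataFrame(index=eigengenes.columns, columns=group_abundance.columns, dtype=float)
    p = r.copy()
    for m in eigengenes.columns:
        for g in group_abundance.columns:
            r.loc[m, g], p.loc[m, g] = pearson(eigengenes[m], group_abundance[g])
    return AssociationTable(r=r, p=p)


@dataclasses.dataclass(frozen=True)
class OppositePatternResult:
    statistic: float  # mean over FG2 phyla of corr(FG1 vector, FG2 vector)
    per_phylum: pd.Series  # the same correlation per FG2 phylum
    p_value: float  # permutation p for statistic < 0 (one-sided)
    n_permutations: int
    consistently_opposite: bool  # statistic < 0 and p < 0.05


def opposite_pattern_test(
    assoc: AssociationTable,
    fgmap: FunctionalGroupMap,
    permutations: int = 999,
    seed: int | None = 0,
) -> OppositePatternResult:
    """Quantify whether FG1 and FG2 associate oppositely with host modules.

    The FG1 module-correlation vector (mean over FG1 phyla columns of the
    association table) is correlated, across modules, with each FG2 phylum's
    vector.  A strongly negative average says: modules tracking
    Proteobacteria anti-track Fusobacteria/Firmicutes/Bacteroidetes.  The
    p-value permutes the module rows of the FG1 vector (one-sided, lower
    tail), with p = (b + 1) / (B + 1).
    """
    fg1 = list(fgmap.phyla("FG1"))
    fg2 = list(fgmap.phyla("FG2"))
    missing = [c for c in fg1 + fg2 if c not in assoc.r.columns]
    if missing:
        raise GutgroupsError(f"association table lacks phylum column(s): {missing}")
    if assoc.r.shape[0] < 5:
        raise GutgroupsError("opposite-pattern test needs at least 5 modules")
    v1 = assoc.r[fg1].mean(axis=1).to_numpy(dtype=float)
    V2 = assoc.r[fg2].to_numpy(dtype=float)

    def mean_corr(v: np.ndarray) -> tuple[float, np.ndarray]:
        vc = v - v.mean()
        denom_v = np.sqrt((vc**2).sum())
        W = V2 - V2.mean(axis=0)
        denom_w = np.sqrt((W**2).sum(axis=0))
        rs = (vc @ W) / (denom_v * denom_w)
        return float(rs.mean()), rs

    observed, per_phylum = mean_corr(v1)
    rng = np.random.default_rng(seed)
    b = 0
    for _ in range(permutations):
        stat, _ = mean_corr(rng.permutation(v1))
        if stat <= observed:
            b += 1
    p = (b + 1) / (permutations + 1)
    return OppositePatternResult(
        statistic=observed,
        per_phylum=pd.Series(per_phylum, index=fg2, name="corr_with_FG1_pattern"),
        p_value=float(p),
        n_permutations=permutations,
        consistently_opposite=bool(observed < 0 and p < 0.05),
    )
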