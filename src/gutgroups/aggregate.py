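"""Gene -> category aggregation, relative abundance and the FG2/FG1 ratio.

Category abundance is the plain sum of the abundances of the genes carrying a
given label; genes without a label at the requested level are excluded from
every category but their mass is tracked as ``unassigned``.  The FG2/FG1
ratio — summed relative abundance of Fusobacteria + Firmicutes +
Bacteroidetes over the relative abundance of Proteobacteria in the same
sample — is the biomarker the pipeline exists to compute; it is invariant to
any positive per-sample rescaling of the raw abundances.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datatypes import (
    LINEAGE_RANKS,
    FeatureProfile,
    FunctionalGroupMap,
    GeneAbundanceMatrix,
    GeneAnnotationTable,
    GutgroupsError,
    RatioTable,
)

__all__ = [
    "aggregate_by_category",
    "to_relative",
    "fg_ratio",
    "label_by_ratio",
    "normalize_per_group",
]


def aggregate_by_category(
    abund: GeneAbundanceMatrix,
    annot: GeneAnnotationTable,
    level: str,
) -> FeatureProfile:
    """Sum per-gene abundance into per-category abundance at *level*.

    For the multi-label CAZy level a gene contributes its full abundance once
    to each family it carries.  Genes lacking a label at *level* contribute
    to the per-sample ``unassigned`` mass instead of any category.
    """
    missing = abund.gene_ids.difference(annot.gene_ids)
    if len(missing):
        raise GutgroupsError(f"abundance matrix contains unannotated gene ids: {list(missing[:5])}")
    genes = abund.gene_ids
    values = abund.frame.to_numpy(dtype=float)

    if level == "CAZy":
        fam_cols: dict[str, np.ndarray] = {}
        cazy = annot.frame.loc[genes, "cazy"]
        labelled_mask = np.array([len(s) > 0 for s in cazy])
        for j, fams in enumerate(cazy):
            for fam in fams:
                fam_cols.setdefault(fam, np.zeros(values.shape[0]))
                fam_cols[fam] += values[:, j]
        if not fam_cols:
            raise GutgroupsError(f"no gene carries a label at level {level!r}")
        frame = pd.DataFrame(fam_cols, index=abund.sample_ids).sort_index(axis=1)
    else:
        labels = annot.labels_at(level).reindex(genes)
        labelled_mask = labels.notna().to_numpy()
        if not labelled_mask.any():
            raise GutgroupsError(f"no gene carries a label at level {level!r}")
        frame = (
            pd.DataFrame(values[:, labelled_mask],
                         index=abund.sample_ids,
                         columns=labels[labelled_mask].to_numpy())
            .T.groupby(level=0).sum().T
        )
    unassigned = pd.Series(
        values[:, ~labelled_mask].sum(axis=1), index=abund.sample_ids, name="unassigned"
    )
    return FeatureProfile(frame=frame, level=level, normalization="raw", unassigned=unassigned)


def to_relative(
    profile: FeatureProfile,
    denominator_mode: str = "classified_all",
    annot: GeneAnnotationTable | None = None,
) -> FeatureProfile:
    """Convert a raw profile to relative abundance (rows summing to 1).

    ``classified_all`` divides by the total classified mass at the profile's
    level (the row sum over categories).  ``bacteria_only`` restricts both
    the numerator features and the denominator to Bacteria, dropping
    non-bacterial columns; it requires *annot* and a taxonomic level.
    """
    if profile.normalization != "raw":
        raise GutgroupsError("to_relative expects a raw profile")
    frame = profile.frame
    if denominator_mode == "bacteria_only":
        if annot is None or profile.level not in LINEAGE_RANKS:
            raise GutgroupsError("bacteria_only requires an annotation table and a taxonomic level")
        bact = annot.frame.loc[annot.frame["superkingdom"] == "Bacteria", profile.level]
        keep = [c for c in frame.columns if c in set(bact)]
        frame = frame[keep]
    elif denominator_mode != "classified_all":
        raise GutgroupsError(f"unknown denominator_mode {denominator_mode!r}")
    sums = frame.to_numpy(dtype=float).sum(axis=1)
    if (sums <= 0).any():
        bad = frame.index[sums <= 0].tolist()
        raise GutgroupsError(f"zero classified abundance in sample(s): {bad}")
    rel = frame.div(sums, axis=0)
    return FeatureProfile(frame=rel, level=profile.level, normalization="relative")


def fg_ratio(
    phylum_profile: FeatureProfile,
    fgmap: FunctionalGroupMap,
    pseudocount: float = 0.0,
) -> RatioTable:
    """Per-sample FG2/FG1 ratio from a relative phylum-level profile.

    ratio = (sum of FG2 phylum relative abundances + pseudocount)
          / (sum of FG1 phylum relative abundances + pseudocount).

    With pseudocount 0, a sample with zero FG1 abundance is an error rather
    than an infinite ratio.
    """
    if phylum_profile.level != "phylum" or phylum_profile.normalization != "relative":
        raise GutgroupsError("fg_ratio expects a relative phylum-level profile")
    if pseudocount < 0:
        raise GutgroupsError("pseudocount must be >= 0")
    frame = phylum_profile.frame
    fg1 = [p for p in fgmap.phyla("FG1")]
    fg2 = [p for p in fgmap.phyla("FG2")]
    missing_fg1 = [p for p in fg1 if p not in frame.columns]
    if missing_fg1:
        raise GutgroupsError(f"FG1 phyla absent from profile columns: {missing_fg1}")
    num = frame[[p for p in fg2 if p in frame.columns]].sum(axis=1) + pseudocount
    den = frame[fg1].sum(axis=1) + pseudocount
    if (den == 0).any():
        bad = frame.index[den == 0].tolist()
        raise GutgroupsError(
            f"FG1 abundance is zero with pseudocount 0 in sample(s): {bad}; "
            "set a positive pseudocount to define a ratio"
        )
    ratio = (num / den).rename("ratio")
    return RatioTable(frame=ratio.to_frame())


def label_by_ratio(ratios: RatioTable, threshold: float = 1.0) -> RatioTable:
    """Mark each sample high_FG2 (ratio > threshold) or high_FG1 (ties included)."""
    if threshold <= 0:
        raise GutgroupsError("threshold must be > 0")
    frame = ratios.frame.copy()
    frame["label"] = np.where(frame["ratio"] > threshold, "high_FG2", "high_FG1")
    return RatioTable(frame=frame)


def normalize_per_group(
    category_counts: pd.DataFrame,
    group_totals: pd.Series,
    scale: float = 100_000.0,
) -> pd.DataFrame:
    """Normalize per-group category counts to counts per *scale* annotated genes.

    ``category_counts`` is groups x categories; ``group_totals`` gives each
    group's total number of annotated genes.  value = scale * count / total.
    """
    totals = group_totals.reindex(category_counts.index)
    if totals.isna().any() or (totals <= 0).any():
        bad = category_counts.index[totals.isna() | (totals <= 0)].tolist()
        raise GutgroupsError(f"missing/zero annotated-gene total for group(s): {bad}")
    counts = category_counts.to_numpy(dtype=float)
    if (counts > totals.to_numpy()[:, None]).any():
        raise GutgroupsError("category count exceeds the group total")
    return category_counts.div(totals, axis=0) * scale
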