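"""Functional profiles: CAZy substrates, SCFA key-enzyme genes, VF/ARG classes.

Carbohydrate-active enzyme (CAZy) families are grouped into substrate
classes (arabinoxylan, pectin, mucin, inulin, cellulose, starch); the lists
overlap deliberately — e.g. GH3 and GH5 act on several substrates — and a
multi-substrate gene contributes to every class it matches.  Virulence
factor (VF) and antibiotic resistance gene (ARG) classes are profiled per
functional group as gene counts per 100,000 annotated genes, with an
abundance-weighted variant behind a flag.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping

import numpy as np
import pandas as pd

from .aggregate import normalize_per_group
from .datatypes import (
    FeatureProfile,
    FunctionalGroupMap,
    GeneAbundanceMatrix,
    GeneAnnotationTable,
    GutgroupsError,
)
from .stats import mann_whitney

__all__ = [
    "SubstrateMap",
    "DEFAULT_SUBSTRATE_MAP",
    "ScfaEnzymeMap",
    "DEFAULT_SCFA_ENZYMES",
    "cazy_substrate_profile",
    "scfa_gene_profile",
    "class_count_profile",
    "filter_low_abundance",
    "compare_groups",
]

PER_100K = 100_000.0


@dataclasses.dataclass(frozen=True)
class SubstrateMap:
    """Substrate class -> set of CAZy family labels (families may repeat)."""

    mapping: Mapping[str, frozenset]

    def __post_init__(self) -> None:
        for sub, fams in self.mapping.items():
            if not fams:
                raise GutgroupsError(f"substrate {sub!r} has an empty family set")

    def substrates_of(self, families) -> tuple[str, ...]:
        fams = set(families)
        return tuple(s for s, f in self.mapping.items() if fams & f)


#: Substrate attribution of CAZy families for the six carbohydrate classes.
DEFAULT_SUBSTRATE_MAP = SubstrateMap(
    {
        "arabinoxylan": frozenset(
            "CE1 CE2 CE4 CE6 CE7 GH10 GH11 GH115 GH43 GH51 GH67 GH3 GH5".split()
        ),
        "pectin": frozenset("CE12 CE8 GH28 PL1 PL9".split()),
        "mucin": frozenset(
            "GH1 GH2 GH3 GH4 GH18 GH19 GH20 GH29 GH33 GH38 GH58 GH79 GH84 GH85 "
            "GH88 GH89 GH92 GH95 GH98 GH99 GH101 GH105 GH109 GH110 GH113 "
            "PL6 PL8 PL12 PL13 PL21".split()
        ),
        "inulin": frozenset("GH32 GH91".split()),
        "cellulose": frozenset("GH1 GH44 GH48 GH8 GH9 GH3 GH5".split()),
        "starch": frozenset("GH13 GH31 GH97".split()),
    }
)


@dataclasses.dataclass(frozen=True)
class ScfaEnzymeMap:
    """SCFA -> {enzyme symbol: KO identifier}.

    The enzyme symbols are fixed by the analysis (FTHFS for acetate, PcoAt
    for propionate, Buk/AtoA/AtoD for butyrate); the KO identifiers are
    configuration, editable per annotation release.
    """

    mapping: Mapping[str, Mapping[str, str]]

    def __post_init__(self) -> None:
        if not self.mapping:
            raise GutgroupsError("empty SCFA enzyme map")
        symbols = [sym for enz in self.mapping.values() for sym in enz]
        if len(symbols) != len(set(symbols)):
            raise GutgroupsError("enzyme symbols must be unique across SCFAs")

    def kos_of(self, scfa: str) -> tuple[str, ...]:
        return tuple(self.mapping[scfa].values())


#: Default KO assignments for the SCFA marker enzymes.
DEFAULT_SCFA_ENZYMES = ScfaEnzymeMap(
    {
        "acetate": {"FTHFS": "K01938"},
        "propionate": {"PcoAt": "K01026"},
        "butyrate": {"Buk": "K00929", "AtoA": "K01035", "AtoD": "K01034"},
    }
)


def _group_of_genes(annot: GeneAnnotationTable, fgmap: FunctionalGroupMap) -> pd.Series:
    return annot.frame["phylum"].map(lambda p: fgmap.group_of(p))


def cazy_substrate_profile(
    abund: GeneAbundanceMatrix,
    annot: GeneAnnotationTable,
    fgmap: FunctionalGroupMap,
    smap: SubstrateMap = DEFAULT_SUBSTRATE_MAP,
) -> pd.DataFrame:
    """Per-sample, per-group substrate abundances, scaled to 100,000.

    For each sample and functional group, a substrate's value is the summed
    abundance of the group's genes carrying at least one CAZy family in the
    substrate's set, divided by the group's total CAZy-gene abundance in
    that sample, times 100,000.  Genes matching several substrates count
    toward each.  Rows are indexed by (sample_id, group).
    """
    groups = _group_of_genes(annot, fgmap)
    genes = abund.gene_ids
    values = abund.frame.to_numpy(dtype=float)
    cazy = annot.frame.loc[genes, "cazy"]
    gene_groups = groups.reindex(genes)
    out_rows = {}
    for grp in ("FG1", "FG2"):
        in_grp = (gene_groups == grp).to_numpy()
        has_cazy = np.array([len(s) > 0 for s in cazy])
        denom = values[:, in_grp & has_cazy].sum(axis=1)
        if (denom <= 0).any():
            bad = abund.sample_ids[denom <= 0].tolist()
            raise GutgroupsError(f"group {grp} has zero CAZy abundance in sample(s): {bad}")
        sub_vals = {}
        for substrate, fams in smap.mapping.items():
            matches = np.array([bool(set(s) & fams) for s in cazy])
            sub_vals[substrate] = values[:, in_grp & matches].sum(axis=1) / denom * PER_100K
        for i, sid in enumerate(abund.sample_ids):
            out_rows[(sid, grp)] = {s: v[i] for s, v in sub_vals.items()}
    frame = pd.DataFrame.from_dict(out_rows, orient="index")
    frame.index = pd.MultiIndex.from_tuples(frame.index, names=["sample_id", "group"])
    return frame


def scfa_gene_profile(
    ko_profile: FeatureProfile,
    emap: ScfaEnzymeMap = DEFAULT_SCFA_ENZYMES,
) -> pd.DataFrame:
    """Per-sample summed abundance of each SCFA's key-enzyme KOs.

    KOs absent from the profile contribute zero.
    """
    if ko_profile.level != "KO":
        raise GutgroupsError("scfa_gene_profile expects a KO-level profile")
    frame = ko_profile.frame
    out = {}
    for scfa in emap.mapping:
        kos = [k for k in emap.kos_of(scfa) if k in frame.columns]
        out[scfa] = frame[kos].sum(axis=1) if kos else pd.Series(0.0, index=frame.index)
    return pd.DataFrame(out)


def class_count_profile(
    annot: GeneAnnotationTable,
    fgmap: FunctionalGroupMap,
    field: str,
    abund: GeneAbundanceMatrix | None = None,
    abundance_weighted: bool = False,
) -> pd.DataFrame:
    """VF-class or ARG-class profile per functional group, per 100,000 genes.

    Counts the genes of each class within each functional group and
    normalizes to the group's total number of annotated genes (scale
    100,000).  Genes whose phylum maps to neither group are excluded.  With
    ``abundance_weighted=True`` the counts and totals are weighted by each
    gene's total abundance across samples (requires *abund*).
    """
    if field not in ("vf_class", "arg_class"):
        raise GutgroupsError("field must be 'vf_class' or 'arg_class'")
    groups = _group_of_genes(annot, fgmap)
    labels = annot.frame[field]
    if abundance_weighted:
        if abund is None:
            raise GutgroupsError("abundance_weighted requires an abundance matrix")
        weights = abund.frame.sum(axis=0).reindex(annot.gene_ids).fillna(0.0)
    else:
        weights = pd.Series(1.0, index=annot.gene_ids)
    counts: dict[str, dict[str, float]] = {}
    totals: dict[str, float] = {}
    for grp in ("FG1", "FG2"):
        sel = groups == grp
        totals[grp] = float(weights[sel].sum())
        if totals[grp] <= 0:
            raise GutgroupsError(f"group {grp} has no annotated genes")
        labelled = sel & labels.notna()
        counts[grp] = weights[labelled].groupby(labels[labelled]).sum().to_dict()
    table = (
        pd.DataFrame.from_dict(counts, orient="index")
        .reindex(["FG1", "FG2"])
        .fillna(0.0)
        .sort_index(axis=1)
    )
    return normalize_per_group(table, pd.Series(totals), scale=PER_100K)


def filter_low_abundance(profile: pd.DataFrame, min_value: float = 1.0) -> pd.DataFrame:
    """Drop features below *min_value* (per 100,000) in every sample.

    A feature reaching the threshold in at least one sample is retained
    unchanged; the boundary value itself is retained.
    """
    vals = profile.to_numpy(dtype=float)
    keep = (vals >= min_value).any(axis=0)
    return profile.loc[:, keep]


def compare_groups(x, y, mode: str = "auto") -> tuple[float, float]:
    """Two-sided Mann-Whitney U comparison of a feature between two groups."""
    return mann_whitney(x, y, mode=mode)
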