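"""Core domain types for gut-metagenome functional-group analysis.

The central objects are thin, validated wrappers around :class:`pandas.DataFrame`:
a per-gene annotation table (taxonomy lineage plus functional labels), a
samples x genes abundance matrix, per-sample metadata for the feeding trial
design (diet x week x replicate), and level-tagged feature profiles produced by
aggregation.  Validation happens at construction so downstream operations can
assume clean inputs.
"""

from __future__ import annotations

import dataclasses
import io
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

#: Taxonomic ranks carried by every gene annotation, outermost first.
LINEAGE_RANKS = (
    "superkingdom",
    "phylum",
    "class",
    "order",
    "family",
    "genus",
    "species",
)

#: Sentinel used for unresolved taxonomy at any rank.
UNKNOWN = "unknown"

#: Diet arms of the feeding trial: carnivorous, omnivorous, herbivorous.
DIETS = ("CD", "OD", "HD")

#: Sampling time points (weeks after the start of the trial).
WEEKS = (1, 3)

#: Levels a FeatureProfile may be aggregated at.
PROFILE_LEVELS = (
    "superkingdom",
    "phylum",
    "class",
    "order",
    "family",
    "genus",
    "species",
    "KO",
    "CAZy",
    "VF-class",
    "ARG-class",
    "viral-family",
    "viral-genus",
)

#: Normalization states of a FeatureProfile.
NORMALIZATIONS = ("raw", "relative", "per_100k")


class GutgroupsError(ValueError):
    """Base error for invalid inputs to the analysis."""


# ---------------------------------------------------------------------------
# Gene annotations
# ---------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class GeneAnnotationTable:
    """Per-gene taxonomy and functional annotation.

    ``frame`` is indexed by ``gene_id`` and has columns ``length_bp``, the
    seven :data:`LINEAGE_RANKS`, ``ko`` (``None`` when unannotated), ``cazy``
    (a frozenset of CAZy family labels, possibly empty), ``vf_class`` and
    ``arg_class`` (``None`` when the gene carries no such label).  Missing
    functional annotation is represented as absence rather than an
    empty-string category so that category sums can never silently include
    unannotated genes.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.frame
        required = ["length_bp", *LINEAGE_RANKS, "ko", "cazy", "vf_class", "arg_class"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise GutgroupsError(f"annotation table missing columns: {missing}")
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise GutgroupsError(f"duplicate gene_id(s): {dups[:5]}")
        lengths = df["length_bp"].to_numpy()
        if not np.issubdtype(np.asarray(lengths).dtype, np.number) or (lengths <= 0).any():
            bad = df.index[np.asarray(lengths) <= 0].tolist()
            raise GutgroupsError(f"non-positive gene length for: {bad[:5]}")
        for rank in LINEAGE_RANKS:
            col = df[rank]
            if col.isna().any() or (col.astype(str).str.len() == 0).any():
                raise GutgroupsError(f"empty lineage label at rank {rank!r}; use {UNKNOWN!r}")

    @property
    def gene_ids(self) -> pd.Index:
        return self.frame.index

    def __len__(self) -> int:
        return len(self.frame)

    def lineage_of(self, gene_id: str) -> tuple[str, ...]:
        row = self.frame.loc[gene_id]
        return tuple(row[r] for r in LINEAGE_RANKS)

    def labels_at(self, level: str) -> pd.Series:
        """Category label per gene at *level*; ``None`` where unannotated.

        Taxonomic levels map the ``unknown`` sentinel to ``None``; functional
        levels (KO, VF-class, ARG-class) pass their optional label through.
        CAZy is multi-label and handled by the aggregation layer directly.
        """
        if level in LINEAGE_RANKS:
            col = self.frame[level]
            return col.where(col != UNKNOWN, other=None)
        if level == "KO":
            return self.frame["ko"]
        if level == "VF-class":
            return self.frame["vf_class"]
        if level == "ARG-class":
            return self.frame["arg_class"]
        raise GutgroupsError(f"no single-label column for level {level!r}")


def build_annotation_frame(records: Iterable[Mapping]) -> pd.DataFrame:
    """Assemble an annotation frame from record dicts (helper for IO/simulation)."""
    rows = []
    for rec in records:
        row = {
            "gene_id": rec["gene_id"],
            "length_bp": int(rec["length_bp"]),
            "ko": rec.get("ko") or None,
            "cazy": frozenset(rec.get("cazy") or ()),
            "vf_class": rec.get("vf_class") or None,
            "arg_class": rec.get("arg_class") or None,
        }
        lineage = list(rec.get("lineage") or ())
        lineage = [str(x) if str(x) else UNKNOWN for x in lineage]
        lineage = lineage[: len(LINEAGE_RANKS)]
        lineage += [UNKNOWN] * (len(LINEAGE_RANKS) - len(lineage))
        row.update(dict(zip(LINEAGE_RANKS, lineage)))
        rows.append(row)
    frame = pd.DataFrame(rows).set_index("gene_id")
    return frame


# ---------------------------------------------------------------------------
# Abundance matrices and profiles
# ---------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class GeneAbundanceMatrix:
    """Samples x genes abundance matrix (non-negative reals)."""

    frame: pd.DataFrame  # rows = samples, columns = genes

    def __post_init__(self) -> None:
        df = self.frame
        if df.shape[1] == 0:
            raise GutgroupsError("abundance matrix has no gene columns")
        if df.index.has_duplicates:
            raise GutgroupsError("duplicate sample ids in abundance matrix")
        if df.columns.has_duplicates:
            raise GutgroupsError("duplicate gene ids in abundance matrix")
        vals = df.to_numpy(dtype=float)
        if np.isnan(vals).any():
            raise GutgroupsError("NaN entries in abundance matrix")
        if (vals < 0).any():
            i, j = np.argwhere(vals < 0)[0]
            raise GutgroupsError(
                f"negative abundance at sample {df.index[i]!r}, gene {df.columns[j]!r}"
            )
        if (vals.sum(axis=1) <= 0).any():
            bad = df.index[vals.sum(axis=1) <= 0].tolist()
            raise GutgroupsError(f"sample(s) with no positive abundance: {bad}")

    @property
    def sample_ids(self) -> pd.Index:
        return self.frame.index

    @property
    def gene_ids(self) -> pd.Index:
        return self.frame.columns


@dataclasses.dataclass(frozen=True)
class FeatureProfile:
    """Samples x features abundance profile tagged with level and normalization.

    ``unassigned`` optionally carries the per-sample abundance mass of genes
    that lacked a label at this level (tracked, never folded into a category).
    """

    frame: pd.DataFrame
    level: str
    normalization: str = "raw"
    unassigned: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.level not in PROFILE_LEVELS:
            raise GutgroupsError(f"unknown profile level {self.level!r}")
        if self.normalization not in NORMALIZATIONS:
            raise GutgroupsError(f"unknown normalization {self.normalization!r}")
        vals = self.frame.to_numpy(dtype=float)
        if (vals < 0).any():
            raise GutgroupsError("negative values in feature profile")
        if self.normalization == "relative":
            sums = vals.sum(axis=1)
            if not np.allclose(sums, 1.0, atol=1e-9):
                bad = self.frame.index[~np.isclose(sums, 1.0, atol=1e-9)].tolist()
                raise GutgroupsError(f"relative profile rows do not sum to 1: {bad}")

    @property
    def sample_ids(self) -> pd.Index:
        return self.frame.index

    @property
    def feature_ids(self) -> pd.Index:
        return self.frame.columns


# ---------------------------------------------------------------------------
# Sample metadata
# ---------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class SampleMetadata:
    """Feeding-trial design: diet arm, sampling week and replicate per sample."""

    frame: pd.DataFrame  # indexed by sample_id; columns diet, week, replicate

    def __post_init__(self) -> None:
        df = self.frame
        for col in ("diet", "week", "replicate"):
            if col not in df.columns:
                raise GutgroupsError(f"metadata missing column {col!r}")
        if df.index.has_duplicates:
            raise GutgroupsError("duplicate sample ids in metadata")
        bad_diet = set(df["diet"]) - set(DIETS)
        if bad_diet:
            raise GutgroupsError(f"unknown diet value(s): {sorted(bad_diet)}")
        bad_week = set(int(w) for w in df["week"]) - set(WEEKS)
        if bad_week:
            raise GutgroupsError(f"unknown week value(s): {sorted(bad_week)}")

    @property
    def sample_ids(self) -> pd.Index:
        return self.frame.index

    def cells(self) -> pd.Series:
        """diet x week cell label per sample, e.g. ``'CD_w1'``."""
        return self.frame["diet"].astype(str) + "_w" + self.frame["week"].astype(int).astype(str)


# ---------------------------------------------------------------------------
# Functional groups and the FG2/FG1 ratio
# ---------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class FunctionalGroupMap:
    """Phylum -> functional-group assignment.

    FG1 is the Proteobacteria component of the community; FG2 the jointly
    co-occurring Fusobacteria + Firmicutes + Bacteroidetes component.  Phyla
    outside both groups map to ``"other"``.
    """

    mapping: Mapping[str, str]

    def __post_init__(self) -> None:
        groups = set(self.mapping.values())
        bad = groups - {"FG1", "FG2", "other"}
        if bad:
            raise GutgroupsError(f"functional groups must be FG1/FG2/other, got {sorted(bad)}")
        fg1, fg2 = self.phyla("FG1"), self.phyla("FG2")
        if not fg1 or not fg2:
            raise GutgroupsError("both FG1 and FG2 must be non-empty")
        if set(fg1) & set(fg2):
            raise GutgroupsError("FG1 and FG2 must be disjoint")

    def phyla(self, group: str) -> tuple[str, ...]:
        return tuple(p for p, g in self.mapping.items() if g == group)

    def group_of(self, phylum: str) -> str:
        return self.mapping.get(phylum, "other")


#: The partition found for the grass-carp gut community: Proteobacteria against
#: the co-occurring Fusobacteria/Firmicutes/Bacteroidetes block.
DEFAULT_FG_MAP = FunctionalGroupMap(
    {
        "Proteobacteria": "FG1",
        "Fusobacteria": "FG2",
        "Firmicutes": "FG2",
        "Bacteroidetes": "FG2",
    }
)


@dataclasses.dataclass(frozen=True)
class RatioTable:
    """Per-sample FG2/FG1 ratio, optionally with a high-FG2/high-FG1 label."""

    frame: pd.DataFrame  # indexed by sample_id; columns ratio [, label]

    def __post_init__(self) -> None:
        if "ratio" not in self.frame.columns:
            raise GutgroupsError("ratio table must have a 'ratio' column")
        if (self.frame["ratio"].to_numpy(dtype=float) <= 0).any():
            raise GutgroupsError("ratios must be positive")


# ---------------------------------------------------------------------------
# Pipeline configuration
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class PipelineConfig:
    """Tunable thresholds and modes for the full analysis pipeline.

    The co-occurrence edge rule defaults to |Spearman rho| > 0.5 with
    p < 0.05; the random-matrix-theory threshold scan is opt-in.
    """

    denominator_mode: str = "classified_all"  # or "bacteria_only"
    spearman_r_min: float = 0.5
    p_max: float = 0.05
    use_rmt_threshold: bool = False
    permutations: int = 999
    ratio_pseudocount: float = 0.0
    ratio_label_threshold: float = 1.0
    module_min_size: int = 30
    module_cut_height: float = 0.25
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.denominator_mode not in ("classified_all", "bacteria_only"):
            raise GutgroupsError(f"unknown denominator_mode {self.denominator_mode!r}")
        if not 0 < self.spearman_r_min < 1:
            raise GutgroupsError("spearman_r_min must be in (0, 1)")
        if not 0 < self.p_max < 1:
            raise GutgroupsError("p_max must be in (0, 1)")
        if self.permutations < 99:
            raise GutgroupsError("permutations must be >= 99")
        if self.ratio_pseudocount < 0:
            raise GutgroupsError("ratio_pseudocount must be >= 0")
        if self.ratio_label_threshold <= 0:
            raise GutgroupsError("ratio_label_threshold must be > 0")


# ---------------------------------------------------------------------------
# Diet formulation table (fixture-validation input)
# ---------------------------------------------------------------------------

_DIET_FORMULATION_TSV = """\
ingredient\tCD\tOD\tHD
Soybean protein concentrate\t0\t210.32\t420.64
Vital gluten\t0\t44\t88
Casein\t304\t152\t0
Gelatin\t76\t38\t0
Wheat gluten\t310\t265\t220
Soybean oil\t84.2\t82.7\t81.1
Lysine\t0\t3.69\t7.37
Methionine\t7.24\t9.245\t11.25
VC phosphate\t1\t1\t1
Vitamin premix\t2\t2\t2
Mineral premix\t2\t2\t2
Monocalcium phosphate\t20\t20\t20
Choline chloride\t2\t2\t2
Microcrystalline cellulose\t80\t80\t80
Zeolite powder\t111.56\t88.045\t64.64
"""


def diet_formulation_table() -> pd.DataFrame:
    """Ingredient masses (g/kg diet) of the three experimental formulations.

    Fifteen ingredients per diet; each column totals 1000 g/kg.  Used as a
    consistency fixture for the trial design, not as an analysis input.
    """
    return pd.read_csv(io.StringIO(_DIET_FORMULATION_TSV), sep="\t", index_col=0)
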