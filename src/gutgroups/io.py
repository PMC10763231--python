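"""Tab-separated readers and writers for the package's file dialect.

One unambiguous dialect throughout: UTF-8 TSV with a header row.  Lineage is
serialized as semicolon-joined ranks (missing trailing ranks fill with
``unknown``); a gene's CAZy family set is comma-joined; absent functional
labels are empty fields.  Numeric tables are written with shortest
round-trip float formatting, so write-then-read reproduces values exactly.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import yaml

from .datatypes import (
    LINEAGE_RANKS,
    UNKNOWN,
    FeatureProfile,
    GeneAbundanceMatrix,
    GeneAnnotationTable,
    GutgroupsError,
    PipelineConfig,
    SampleMetadata,
    build_annotation_frame,
)

__all__ = [
    "read_gene_annotations",
    "write_gene_annotations",
    "read_abundance_matrix",
    "write_abundance_matrix",
    "read_sample_metadata",
    "write_sample_metadata",
    "read_profile",
    "write_profile",
    "load_config",
]

_MANDATORY_ANNOT_COLUMNS = ("gene_id", "length", "lineage")


def read_gene_annotations(path) -> GeneAnnotationTable:
    """Read a per-gene annotation TSV.

    Mandatory columns: ``gene_id``, ``length``, ``lineage`` (semicolon-joined
    ranks, superkingdom first).  Optional: ``ko``, ``cazy`` (comma-joined
    family labels), ``vf_class``, ``arg_class``.  Empty functional fields
    become absent labels; a lineage shorter than seven ranks is padded with
    ``unknown``.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _MANDATORY_ANNOT_COLUMNS if c not in df.columns]
    if missing:
        raise GutgroupsError(f"annotation file {path} missing mandatory column(s): {missing}")
    dup = df["gene_id"][df["gene_id"].duplicated()]
    if len(dup):
        raise GutgroupsError(f"duplicate gene_id in {path}: {sorted(set(dup))[:5]}")
    records = []
    for row in df.itertuples(index=False):
        rec = row._asdict()
        try:
            length = int(float(rec["length"]))
        except ValueError as exc:
            raise GutgroupsError(f"non-numeric length for gene {rec['gene_id']!r}") from exc
        if length <= 0:
            raise GutgroupsError(f"non-positive length for gene {rec['gene_id']!r}")
        lineage = [part.strip() or UNKNOWN for part in rec["lineage"].split(";")]
        records.append(
            {
                "gene_id": rec["gene_id"],
                "length_bp": length,
                "lineage": lineage,
                "ko": rec.get("ko", "").strip() or None,
                "cazy": tuple(f for f in rec.get("cazy", "").split(",") if f.strip()),
                "vf_class": rec.get("vf_class", "").strip() or None,
                "arg_class": rec.get("arg_class", "").strip() or None,
            }
        )
    return GeneAnnotationTable(build_annotation_frame(records))


def write_gene_annotations(annot: GeneAnnotationTable, path) -> None:
    df = annot.frame
    out = pd.DataFrame(
        {
            "gene_id": df.index,
            "length": df["length_bp"].to_numpy(),
            "lineage": [";".join(df.loc[g, list(LINEAGE_RANKS)]) for g in df.index],
            "ko": [k or "" for k in df["ko"]],
            "cazy": [",".join(sorted(s)) for s in df["cazy"]],
            "vf_class": [v or "" for v in df["vf_class"]],
            "arg_class": [a or "" for a in df["arg_class"]],
        }
    )
    out.to_csv(path, sep="\t", index=False)


def read_abundance_matrix(path) -> GeneAbundanceMatrix:
    """Read a samples x genes abundance TSV (first column = sample id)."""
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    if df.shape[1] == 0:
        raise GutgroupsError(f"abundance file {path} has no gene columns")
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()].tolist()
            raise GutgroupsError(
                f"non-numeric abundance in column {col!r}, sample(s) {bad[:3]}"
            )
    neg = df.lt(0)
    if neg.any().any():
        col = neg.any()[neg.any()].index[0]
        row = df.index[neg[col]][0]
        raise GutgroupsError(f"negative abundance at sample {row!r}, gene {col!r}")
    return GeneAbundanceMatrix(df)


def write_abundance_matrix(abund: GeneAbundanceMatrix, path) -> None:
    abund.frame.rename_axis("sample_id").to_csv(path, sep="\t")


def read_sample_metadata(path) -> SampleMetadata:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return SampleMetadata(df)


def write_sample_metadata(meta: SampleMetadata, path) -> None:
    meta.frame.rename_axis("sample_id").to_csv(path, sep="\t")


def read_profile(path, level: str, normalization: str = "raw") -> FeatureProfile:
    frame = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    unassigned = None
    if "__unassigned__" in frame.columns:
        unassigned = frame.pop("__unassigned__")
    return FeatureProfile(
        frame=frame, level=level, normalization=normalization, unassigned=unassigned
    )


def write_profile(profile: FeatureProfile, path) -> None:
    out = profile.frame.copy()
    if profile.unassigned is not None:
        out["__unassigned__"] = profile.unassigned
    out.rename_axis("sample_id").to_csv(path, sep="\t")


def load_config(path) -> PipelineConfig:
    """Load a PipelineConfig from a YAML mapping (unknown keys are an error)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    valid = {f.name for f in PipelineConfig.__dataclass_fields__.values()}
    unknown = set(raw) - valid
    if unknown:
        raise GutgroupsError(f"unknown config key(s): {sorted(unknown)}")
    return PipelineConfig(**raw)
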