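"""End-to-end orchestration: from input tables to the full report bundle.

Runs, in order: taxonomic/functional aggregation, relative abundance, the
FG2/FG1 ratio with high-FG2/high-FG1 labels, alpha diversity, Bray-Curtis +
PCoA + PERMANOVA/ANOSIM by diet, core-taxon co-occurrence networks and the
two-group partition, host module detection and module-microbiota
association with the opposite-pattern test, CAZy substrate / SCFA / VF /
ARG profiles, and virome-bacteriome coupling.  Every randomized stage draws
its seed deterministically from the pipeline seed, so a fixed seed gives a
bit-reproducible bundle.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import aggregate as agg
from . import ecology, functions, host_modules, network, virome
from .datatypes import (
    DEFAULT_FG_MAP,
    FeatureProfile,
    GeneAbundanceMatrix,
    GeneAnnotationTable,
    GutgroupsError,
    PipelineConfig,
    SampleMetadata,
)
from .io import write_profile
from .simulate import SimulatedDataset
from .stats import spearman_matrix

__all__ = ["run_pipeline", "run_pipeline_on_dataset", "PipelineResult"]


_STAGES = ("permanova", "anosim", "partition", "opposite_gut", "opposite_liver", "mantel")


def _stage_seeds(root_seed: int) -> dict[str, int]:
    children = np.random.SeedSequence(root_seed).spawn(len(_STAGES))
    return {
        stage: int(child.generate_state(1, dtype=np.uint32)[0] % (2**31))
        for stage, child in zip(_STAGES, children)
    }


@dataclasses.dataclass
class PipelineResult:
    """In-memory bundle of every stage's output tables."""

    profiles: dict[str, FeatureProfile]
    ratios: pd.DataFrame
    alpha: pd.DataFrame
    pcoa_coords: pd.DataFrame
    tests: pd.DataFrame
    core: network.CoreTaxaResult
    genus_network: network.CooccurrenceNetwork
    phylum_network: network.CooccurrenceNetwork
    partition: network.PartitionResult
    modules_gut: host_modules.ModuleSet
    modules_liver: host_modules.ModuleSet
    association_gut: host_modules.AssociationTable
    association_liver: host_modules.AssociationTable
    opposite_gut: host_modules.OppositePatternResult
    opposite_liver: host_modules.OppositePatternResult
    cazy_substrates: pd.DataFrame
    scfa_genes: pd.DataFrame
    vf_classes: pd.DataFrame
    arg_classes: pd.DataFrame
    virome_alpha: pd.DataFrame | None
    virome_mantel: virome.MantelResult | None
    taxon_phage_rho: pd.DataFrame | None
    config: PipelineConfig


def _check_sample_ids(named: dict[str, pd.Index]) -> None:
    items = list(named.items())
    ref_name, ref = items[0]
    for name, ids in items[1:]:
        if set(ids) != set(ref):
            diff = sorted(set(ids) ^ set(ref))
            raise GutgroupsError(
                f"sample ids of {name} and {ref_name} differ; symmetric difference: {diff}"
            )


def run_pipeline(
    config: PipelineConfig,
    annotations: GeneAnnotationTable,
    abundance: GeneAbundanceMatrix,
    metadata: SampleMetadata,
    expression_gut: pd.DataFrame | None = None,
    expression_liver: pd.DataFrame | None = None,
    viral_profile: FeatureProfile | None = None,
    out_dir: str | Path | None = None,
) -> PipelineResult:
    """Run the full analysis; optionally write per-stage TSVs to *out_dir*."""
    named = {"abundance": abundance.sample_ids, "metadata": metadata.sample_ids}
    if expression_gut is not None:
        named["gut expression"] = expression_gut.index
    if expression_liver is not None:
        named["liver expression"] = expression_liver.index
    if viral_profile is not None:
        named["viral profile"] = viral_profile.sample_ids
    _check_sample_ids(named)
    order = abundance.sample_ids
    metadata = SampleMetadata(metadata.frame.loc[order])
    seeds = _stage_seeds(config.rng_seed)
    fgmap = DEFAULT_FG_MAP

    # --- aggregation and the ratio --------------------------------------
    profiles: dict[str, FeatureProfile] = {}
    for level in ("phylum", "genus", "KO", "CAZy"):
        raw = agg.aggregate_by_category(abundance, annotations, level)
        profiles[f"{level}_raw"] = raw
        rel = agg.to_relative(raw, "classified_all")
        profiles[f"{level}_relative"] = rel
    phylum_rel = profiles["phylum_relative"]
    genus_rel = profiles["genus_relative"]
    ratios = agg.label_by_ratio(
        agg.fg_ratio(phylum_rel, fgmap, config.ratio_pseudocount),
        config.ratio_label_threshold,
    ).frame

    # --- diversity and ordination ----------------------------------------
    alpha = ecology.alpha_diversity_table(profiles["genus_raw"])
    bc = ecology.bray_curtis(phylum_rel)
    coords = ecology.pcoa(bc).coordinates
    diet = metadata.frame["diet"].to_numpy()
    perm = ecology.permanova(bc, diet, config.permutations, seed=seeds["permanova"])
    ano = ecology.anosim(bc, diet, config.permutations, seed=seeds["anosim"])
    tests = pd.DataFrame(
        [dataclasses.asdict(perm), dataclasses.asdict(ano)],
    ).assign(grouping="diet")

    # --- co-occurrence networks and the partition ------------------------
    core = network.core_taxa(genus_rel, metadata)
    core_profile = FeatureProfile(
        genus_rel.frame[list(core.core)], level="genus", normalization="raw"
    )
    r_min = config.spearman_r_min
    if config.use_rmt_threshold:
        rho, _ = spearman_matrix(core_profile.frame.to_numpy())
        r_min = network.rmt_threshold(np.nan_to_num(rho), fallback=config.spearman_r_min)
    genus_net = network.correlation_network(core_profile, r_min, config.p_max)
    phylum_net = network.correlation_network(phylum_rel, r_min, config.p_max)
    partition = network.partition_functional_groups(phylum_net, seed=seeds["partition"])

    # --- host association -------------------------------------------------
    group_abund = phylum_rel.frame.copy()
    group_abund["FG1"] = phylum_rel.frame[list(fgmap.phyla("FG1"))].sum(axis=1)
    group_abund["FG2"] = phylum_rel.frame[
        [p for p in fgmap.phyla("FG2") if p in phylum_rel.frame.columns]
    ].sum(axis=1)
    modules_gut = modules_liver = None
    assoc_gut = assoc_liver = opp_gut = opp_liver = None
    if expression_gut is not None:
        modules_gut = host_modules.detect_modules(
            expression_gut, config.module_min_size, config.module_cut_height
        )
        assoc_gut = host_modules.associate(modules_gut.eigengenes, group_abund)
        opp_gut = host_modules.opposite_pattern_test(
            assoc_gut, fgmap, config.permutations, seed=seeds["opposite_gut"]
        )
    if expression_liver is not None:
        modules_liver = host_modules.detect_modules(
            expression_liver, config.module_min_size, config.module_cut_height
        )
        assoc_liver = host_modules.associate(modules_liver.eigengenes, group_abund)
        opp_liver = host_modules.opposite_pattern_test(
            assoc_liver, fgmap, config.permutations, seed=seeds["opposite_liver"]
        )

    # --- functional profiles ----------------------------------------------
    cazy_sub = functions.cazy_substrate_profile(abundance, annotations, fgmap)
    scfa = functions.scfa_gene_profile(profiles["KO_raw"])
    vf = functions.class_count_profile(annotations, fgmap, "vf_class")
    arg = functions.filter_low_abundance(
        functions.class_count_profile(annotations, fgmap, "arg_class"), min_value=1.0
    )

    # --- virome ------------------------------------------------------------
    virome_alpha = virome_mantel = phage_rho = None
    if viral_profile is not None:
        viral = FeatureProfile(
            viral_profile.frame.loc[order], viral_profile.level, viral_profile.normalization
        )
        alpha_v = ecology.alpha_diversity_table(viral)
        virome_alpha = virome.alpha_coupling(alpha_v, alpha)
        viral_rel = FeatureProfile(
            viral.frame.div(viral.frame.sum(axis=1), axis=0), viral.level, "relative"
        )
        virome_mantel = virome.mantel(
            ecology.bray_curtis(viral_rel),
            bc,
            permutations=config.permutations,
            seed=seeds["mantel"],
        )
        phage_rho, _ = virome.taxon_phage_correlations(genus_rel, viral_rel)

    result = PipelineResult(
        profiles=profiles,
        ratios=ratios,
        alpha=alpha,
        pcoa_coords=coords,
        tests=tests,
        core=core,
        genus_network=genus_net,
        phylum_network=phylum_net,
        partition=partition,
        modules_gut=modules_gut,
        modules_liver=modules_liver,
        association_gut=assoc_gut,
        association_liver=assoc_liver,
        opposite_gut=opp_gut,
        opposite_liver=opp_liver,
        cazy_substrates=cazy_sub,
        scfa_genes=scfa,
        vf_classes=vf,
        arg_classes=arg,
        virome_alpha=virome_alpha,
        virome_mantel=virome_mantel,
        taxon_phage_rho=phage_rho,
        config=config,
    )
    if out_dir is not None:
        _write_bundle(result, Path(out_dir))
    return result


def run_pipeline_on_dataset(
    config: PipelineConfig, dataset: SimulatedDataset, out_dir=None
) -> PipelineResult:
    """Convenience: run the pipeline on a simulated dataset bundle."""
    return run_pipeline(
        config,
        dataset.annotations,
        dataset.abundance,
        dataset.metadata,
        dataset.expression_gut,
        dataset.expression_liver,
        dataset.viral_profile,
        out_dir=out_dir,
    )


def _write_bundle(result: PipelineResult, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    for name, profile in result.profiles.items():
        write_profile(profile, out_dir / f"{name}.tsv")
    result.ratios.rename_axis("sample_id").to_csv(out_dir / "ratios.tsv", sep="\t")
    result.alpha.rename_axis("sample_id").to_csv(out_dir / "alpha.tsv", sep="\t")
    result.pcoa_coords.rename_axis("sample_id").to_csv(out_dir / "pcoa_coords.tsv", sep="\t")
    result.tests.to_csv(out_dir / "tests.tsv", sep="\t", index=False)
    for label, net in (("genus", result.genus_network), ("phylum", result.phylum_network)):
        net.edges.to_csv(out_dir / f"network_{label}_edges.tsv", sep="\t", index=False)
        net.write_graphml(out_dir / f"network_{label}.graphml")
    pd.Series(result.partition.group_of_node, name="group").rename_axis("node").to_csv(
        out_dir / "partition.tsv", sep="\t"
    )
    for tissue, mods, assoc in (
        ("gut", result.modules_gut, result.association_gut),
        ("liver", result.modules_liver, result.association_liver),
    ):
        if mods is None:
            continue
        mods.module_of_gene.rename("module").rename_axis("gene").to_csv(
            out_dir / f"modules_{tissue}.tsv", sep="\t"
        )
        mods.eigengenes.rename_axis("sample_id").to_csv(
            out_dir / f"eigengenes_{tissue}.tsv", sep="\t"
        )
        long = (
            assoc.r.rename_axis("module")
            .reset_index()
            .melt(id_vars="module", var_name="taxon", value_name="r")
            .merge(
                assoc.p.rename_axis("module")
                .reset_index()
                .melt(id_vars="module", var_name="taxon", value_name="p")
            )
        )
        long["tier"] = [assoc.tiers().loc[m, t] for m, t in zip(long["module"], long["taxon"])]
        long.to_csv(out_dir / f"association_{tissue}.tsv", sep="\t", index=False)
    result.cazy_substrates.to_csv(out_dir / "cazy_substrates.tsv", sep="\t")
    result.scfa_genes.rename_axis("sample_id").to_csv(out_dir / "scfa_genes.tsv", sep="\t")
    result.vf_classes.rename_axis("group").to_csv(out_dir / "vf_classes.tsv", sep="\t")
    result.arg_classes.rename_axis("group").to_csv(out_dir / "arg_classes.tsv", sep="\t")
    if result.virome_alpha is not None:
        result.virome_alpha.rename_axis("index").to_csv(
            out_dir / "virome_alpha_coupling.tsv", sep="\t"
        )
        pd.DataFrame([dataclasses.asdict(result.virome_mantel)]).to_csv(
            out_dir / "virome_mantel.tsv", sep="\t", index=False
        )
        result.taxon_phage_rho.rename_axis("taxon").to_csv(
            out_dir / "taxon_phage_corr.tsv", sep="\t"
        )
    log = {
        "config": dataclasses.asdict(result.config),
        "seed": result.config.rng_seed,
        "n_samples": int(len(result.ratios)),
    }
    (out_dir / "run_log.json").write_text(json.dumps(log, indent=2, sort_keys=True))
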