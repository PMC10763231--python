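"""Synthetic multi-omics datasets with planted functional-group structure.

The generator emulates the statistical features the analysis relies on,
with known ground truth:

* a logistic-normal bacterial community over ~4 dominant phyla, driven by
  two anti-correlated latent factors (FG1 = Proteobacteria,
  FG2 = Fusobacteria/Firmicutes/Bacteroidetes), so that the two groups
  co-exclude each other across samples;
* a diet effect that raises FG2 on the log scale in the omnivorous and
  herbivorous arms relative to the carnivorous arm, mirroring the observed
  abundance shifts;
* gene-level abundance obtained by splitting each taxon's abundance over
  its genes with fixed weights, and functional annotation biased so FG2
  taxa carry fiber-degrading CAZy families (arabinoxylan/pectin/cellulose)
  and SCFA key-enzyme KOs while FG1 taxa carry starch families and more
  VF/ARG labels;
* host gut and liver expression with planted co-expression modules coupled
  with opposite signs to the two group latents;
* a phage community whose taxa track assigned bacterial host taxa.

Everything is drawn from a single seeded generator: identical seeds give
identical outputs.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping

import numpy as np
import pandas as pd

from .datatypes import (
    DIETS,
    WEEKS,
    FeatureProfile,
    FunctionalGroupMap,
    GeneAbundanceMatrix,
    GeneAnnotationTable,
    GutgroupsError,
    SampleMetadata,
    build_annotation_frame,
)
from .functions import DEFAULT_SCFA_ENZYMES, DEFAULT_SUBSTRATE_MAP

__all__ = ["SimulationParams", "SyntheticTruth", "SimulatedDataset", "simulate_dataset"]


#: Mean phylum shares the community is centred on (dominant Proteobacteria,
#: then Bacteroidetes/Firmicutes/Fusobacteria, and a small unassigned tail).
_PHYLUM_SHARES = {
    "Proteobacteria": 0.54,
    "Bacteroidetes": 0.17,
    "Firmicutes": 0.14,
    "Fusobacteria": 0.07,
    "Actinobacteria": 0.02,
}

#: Log-scale loading of the group latent factor on each member taxon.
_GROUP_LOADING = 0.25

#: Share of a host module's latent that is the group latent (the remainder is
#: module-specific, so distinct modules of the same sign stay separable).
_MODULE_GROUP_SHARE = 0.80

_FIBER_FAMILIES = tuple(
    sorted(
        DEFAULT_SUBSTRATE_MAP.mapping["arabinoxylan"]
        | DEFAULT_SUBSTRATE_MAP.mapping["pectin"]
        | DEFAULT_SUBSTRATE_MAP.mapping["cellulose"]
    )
)
_STARCH_FAMILIES = tuple(sorted(DEFAULT_SUBSTRATE_MAP.mapping["starch"]))
_SCFA_KOS = tuple(ko for enz in DEFAULT_SCFA_ENZYMES.mapping.values() for ko in enz.values())

_VF_CLASSES = (
    "adherence",
    "antiphagocytosis",
    "endotoxin",
    "iron uptake",
    "manganese uptake",
    "secretion system",
)
_ARG_CLASSES = (
    "beta-lactam",
    "macrolide",
    "tetracycline",
    "aminoglycoside",
    "rifamycin",
    "oxazolidinone",
)


@dataclasses.dataclass
class SimulationParams:
    """Knobs of the synthetic study; defaults mirror the feeding-trial design
    (3 diets x 2 weeks x 6 replicates) and a clearly structured community."""

    n_samples_per_cell: int = 6
    n_taxa_per_phylum: Mapping[str, int] = dataclasses.field(
        default_factory=lambda: {
            "Proteobacteria": 8,
            "Bacteroidetes": 6,
            "Firmicutes": 6,
            "Fusobacteria": 4,
            "Actinobacteria": 2,
        }
    )
    genes_per_taxon: int = 20
    group_anticorr: float = 0.9
    diet_effect: float = 0.8
    n_host_genes: int = 240
    n_modules: int = 6
    module_coupling: float = 0.9
    n_viral_taxa: int = 10
    virome_coupling: float = 0.9
    noise_sd: float = 0.35
    seed: int = 0

    def __post_init__(self) -> None:
        counts = [
            self.n_samples_per_cell,
            self.genes_per_taxon,
            self.n_host_genes,
            self.n_modules,
            self.n_viral_taxa,
        ]
        if any(c <= 0 for c in counts) or any(v <= 0 for v in self.n_taxa_per_phylum.values()):
            raise GutgroupsError("all simulation counts must be positive")
        for name in ("group_anticorr", "module_coupling", "virome_coupling"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise GutgroupsError(f"{name} must lie in [0, 1]")
        if self.diet_effect < 0:
            raise GutgroupsError("diet_effect must be >= 0")
        if self.noise_sd <= 0:
            raise GutgroupsError("noise_sd must be > 0")


@dataclasses.dataclass(frozen=True)
class SyntheticTruth:
    """Planted structure: the recovery target for every downstream test."""

    phylum_of_taxon: pd.Series
    fg_of_phylum: FunctionalGroupMap
    latent_fg1: pd.Series  # per-sample latent driving Proteobacteria
    latent_fg2: pd.Series  # per-sample latent driving the FG2 block
    module_of_gene: pd.Series  # host gene -> planted module label (M1..Mk)
    module_sign: pd.Series  # module -> +1 (toward FG1) or -1 (toward FG2)
    module_latents: pd.DataFrame  # samples x modules: each module's latent factor
    phage_host: pd.Series  # viral taxon -> bacterial host taxon
    seed: int


@dataclasses.dataclass(frozen=True)
class SimulatedDataset:
    annotations: GeneAnnotationTable
    abundance: GeneAbundanceMatrix
    metadata: SampleMetadata
    expression_gut: pd.DataFrame
    expression_liver: pd.DataFrame
    viral_profile: FeatureProfile
    truth: SyntheticTruth


def simulate_dataset(params: SimulationParams | None = None) -> SimulatedDataset:
    """Draw one fully labelled synthetic dataset."""
    params = params or SimulationParams()
    rng = np.random.default_rng(params.seed)

    # ---- design ---------------------------------------------------------
    samples, diets, weeks, reps = [], [], [], []
    for week in WEEKS:
        for diet in DIETS:
            for rep in range(1, params.n_samples_per_cell + 1):
                samples.append(f"{diet}_w{week}_r{rep}")
                diets.append(diet)
                weeks.append(week)
                reps.append(rep)
    meta = SampleMetadata(
        pd.DataFrame(
            {"diet": diets, "week": weeks, "replicate": reps},
            index=pd.Index(samples, name="sample_id"),
        )
    )
    n = len(samples)
    plant_fed = np.isin(diets, ("OD", "HD"))

    # ---- latent community state ----------------------------------------
    a = params.group_anticorr
    cov = np.array([[1.0, -a], [-a, 1.0]])
    z = rng.multivariate_normal([0.0, 0.0], cov, size=n)
    z1, z2 = z[:, 0], z[:, 1]

    # ---- taxa -----------------------------------------------------------
    fgmap = FunctionalGroupMap(
        {
            "Proteobacteria": "FG1",
            "Fusobacteria": "FG2",
            "Firmicutes": "FG2",
            "Bacteroidetes": "FG2",
        }
    )
    taxa, phylum_of_taxon = [], {}
    for phylum, k in params.n_taxa_per_phylum.items():
        for i in range(1, k + 1):
            name = f"{phylum[:6]}_g{i}"
            taxa.append(name)
            phylum_of_taxon[name] = phylum
    phylum_of_taxon = pd.Series(phylum_of_taxon, name="phylum")

    log_abund = np.empty((n, len(taxa)))
    for j, taxon in enumerate(taxa):
        phylum = phylum_of_taxon[taxon]
        share = _PHYLUM_SHARES.get(phylum, 0.02)
        base = np.log(share / params.n_taxa_per_phylum[phylum]) + rng.uniform(-0.3, 0.3)
        group = fgmap.group_of(phylum)
        latent = z1 if group == "FG1" else z2 if group == "FG2" else 0.0
        shift = params.diet_effect * plant_fed if group == "FG2" else 0.0
        log_abund[:, j] = (
            base
            + _GROUP_LOADING * latent
            + shift
            + params.noise_sd * rng.standard_normal(n)
        )
    taxon_abund = np.exp(log_abund) * 1e4  # arbitrary sequencing-depth scale

    # ---- genes ----------------------------------------------------------
    records = []
    gene_cols = []
    for taxon in taxa:
        phylum = phylum_of_taxon[taxon]
        group = fgmap.group_of(phylum)
        weights = rng.uniform(0.5, 1.5, size=params.genes_per_taxon)
        weights /= weights.sum()
        for g in range(params.genes_per_taxon):
            gene_id = f"{taxon}_gene{g + 1:03d}"
            # KO: SCFA marker genes sit mostly in FG2 taxa
            ko = None
            u = rng.random()
            p_scfa = 0.05 if group == "FG2" else 0.01
            if u < p_scfa:
                ko = _SCFA_KOS[rng.integers(len(_SCFA_KOS))]
            elif u < 0.7:
                ko = f"K{rng.integers(2000, 2050):05d}"
            # CAZy: fiber degraders in FG2, starch utilisers in FG1
            cazy: tuple[str, ...] = ()
            if group == "FG2" and rng.random() < 0.30:
                k = 1 + int(rng.random() < 0.3)
                cazy = tuple(rng.choice(_FIBER_FAMILIES, size=k, replace=False))
            elif group == "FG1" and rng.random() < 0.30:
                cazy = (str(rng.choice(_STARCH_FAMILIES)),)
            elif group == "other" and rng.random() < 0.10:
                cazy = (str(rng.choice(_FIBER_FAMILIES + _STARCH_FAMILIES)),)
            # VF / ARG: FG1 carries roughly 3x the label probability of FG2
            vf = None
            if rng.random() < (0.15 if group == "FG1" else 0.05):
                vf = str(rng.choice(_VF_CLASSES))
            arg = None
            if rng.random() < (0.12 if group == "FG1" else 0.04):
                arg = str(rng.choice(_ARG_CLASSES))
            records.append(
                {
                    "gene_id": gene_id,
                    "length_bp": int(rng.integers(300, 3000)),
                    "lineage": (
                        "Bacteria",
                        phylum,
                        f"{phylum}_cls",
                        f"{phylum}_ord",
                        f"{taxon}_fam",
                        taxon,
                        f"{taxon}_sp",
                    ),
                    "ko": ko,
                    "cazy": cazy,
                    "vf_class": vf,
                    "arg_class": arg,
                    "_weight": weights[g],
                }
            )
            gene_cols.append(gene_id)
    weights_vec = np.array([r.pop("_weight") for r in records])
    taxon_idx = np.repeat(np.arange(len(taxa)), params.genes_per_taxon)
    gene_abund = taxon_abund[:, taxon_idx] * weights_vec[None, :]
    annotations = GeneAnnotationTable(build_annotation_frame(records))
    abundance = GeneAbundanceMatrix(
        pd.DataFrame(gene_abund, index=meta.sample_ids, columns=gene_cols)
    )

    # ---- host expression -------------------------------------------------
    module_labels = [f"M{i + 1}" for i in range(params.n_modules)]
    module_sign = pd.Series(
        {m: (1 if i % 2 == 0 else -1) for i, m in enumerate(module_labels)}, name="sign"
    )
    genes_per_module = np.full(params.n_modules, params.n_host_genes // params.n_modules)
    genes_per_module[: params.n_host_genes % params.n_modules] += 1
    host_genes, module_of_gene = [], {}
    for m, cnt in zip(module_labels, genes_per_module):
        for i in range(cnt):
            g = f"host_{m}_{i + 1:03d}"
            host_genes.append(g)
            module_of_gene[g] = m
    module_of_gene = pd.Series(module_of_gene, name="module")

    beta = _MODULE_GROUP_SHARE
    c = params.module_coupling

    # each module's latent: its group latent (z1 toward FG1, z2 toward FG2)
    # mixed with a module-specific component so same-sign modules separate
    module_latents = {}
    for m, sign in module_sign.items():
        latent = z1 if sign > 0 else z2
        u = beta * latent + np.sqrt(1.0 - beta**2) * rng.standard_normal(n)
        # unit sample variance so the planted gene-latent coupling is exact
        module_latents[m] = (u - u.mean()) / u.std()
    module_latents = pd.DataFrame(module_latents, index=meta.sample_ids)

    def expression_matrix() -> pd.DataFrame:
        cols = {}
        for m in module_sign.index:
            u_m = module_latents[m].to_numpy()
            members = module_of_gene.index[module_of_gene == m]
            noise = rng.standard_normal((n, len(members)))
            block = c * u_m[:, None] + np.sqrt(max(1.0 - c**2, 1e-12)) * noise
            for k, g in enumerate(members):
                cols[g] = block[:, k]
        return pd.DataFrame(cols, index=meta.sample_ids)[host_genes]

    expr_gut = expression_matrix()
    expr_liver = expression_matrix()

    # ---- virome ----------------------------------------------------------
    hosts = [taxa[i % len(taxa)] for i in range(params.n_viral_taxa)]
    vc = params.virome_coupling
    # phages track their host's share of the community (the scale on which
    # downstream correlations are computed), not its absolute abundance
    rel_taxa = taxon_abund / taxon_abund.sum(axis=1, keepdims=True)
    host_log = np.log(rel_taxa[:, [taxa.index(h) for h in hosts]])
    host_std = (host_log - host_log.mean(axis=0)) / host_log.std(axis=0)
    viral_names = [f"phage_{h}" for h in hosts]
    log_v = (
        rng.uniform(-1.0, 1.0, size=params.n_viral_taxa)[None, :]
        + vc * host_std
        + np.sqrt(max(1.0 - vc**2, 1e-12)) * rng.standard_normal((n, params.n_viral_taxa))
    )
    viral = np.exp(log_v) * 1e3
    viral_profile = FeatureProfile(
        frame=pd.DataFrame(viral, index=meta.sample_ids, columns=viral_names),
        level="viral-genus",
        normalization="raw",
    )

    truth = SyntheticTruth(
        phylum_of_taxon=phylum_of_taxon,
        fg_of_phylum=fgmap,
        latent_fg1=pd.Series(z1, index=meta.sample_ids, name="latent_fg1"),
        latent_fg2=pd.Series(z2, index=meta.sample_ids, name="latent_fg2"),
        module_of_gene=module_of_gene,
        module_sign=module_sign,
        module_latents=module_latents,
        phage_host=pd.Series(dict(zip(viral_names, hosts)), name="host_taxon"),
        seed=params.seed,
    )
    return SimulatedDataset(
        annotations=annotations,
        abundance=abundance,
        metadata=meta,
        expression_gut=expr_gut,
        expression_liver=expr_liver,
        viral_profile=viral_profile,
        truth=truth,
    )
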