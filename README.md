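# gutgroups

Functional-group analysis of fish gut metagenomes: from annotated
gene-abundance tables to co-occurrence networks, the **FG2/FG1 ratio**
biomarker, host module–microbiota association, CAZy/VF/ARG functional
profiles, and virome–bacteriome coupling.

## The problem

The gut microbiota of grass carp (and many other fish) is dominated by a
small number of phyla whose abundances move in opposite directions across
individuals and diets: *Proteobacteria* on one side, and a jointly
co-occurring *Fusobacteria* / *Firmicutes* / *Bacteroidetes* block on the
other. These two components — **Functional Group 1 (FG1)** and
**Functional Group 2 (FG2)** — differ in their genetic capacity for
carbohydrate degradation, short-chain fatty-acid production, virulence
factors and antibiotic resistance, and they associate with host gene
expression modules with consistently opposite signs. Their abundance ratio
is therefore a compact biomarker of community state:

```
ratio(s) = ( rel. abundance of Fusobacteria + Firmicutes + Bacteroidetes in sample s )
         / ( rel. abundance of Proteobacteria in sample s )
```

This package implements the full analysis chain around that statistic for
users of shotgun-metagenome gene catalogues — microbial ecologists and
aquaculture researchers who already have per-gene taxonomy (NCBI-nr style
lineages) and functional labels (KO, CAZy, VFDB class, CARD class) plus a
samples × genes abundance matrix.

Core machinery:

- **Aggregation** — gene → category abundance sums per level (phylum,
  genus, KO, CAZy, …), relative abundance, per-group per-100,000-gene
  normalization, the FG2/FG1 ratio and high-FG2/high-FG1 sample labels.
- **Ecology** — ACE/Chao1/Shannon/Simpson, analytic rarefaction,
  Bray–Curtis, PCoA, PERMANOVA and ANOSIM with permutation p-values on the
  (b+1)/(B+1) lattice.
- **Co-occurrence** — core-genus selection, signed Spearman networks
  (|rho| > 0.5, p < 0.05 by default; random-matrix-style threshold scan as
  an option), and a signed-agreement bipartition that splits taxa into the
  two mutually exclusive ecological groups.
- **Host association** — reproducible co-expression module detection
  (1 − |r| dissimilarity, average linkage, static cut), module eigengenes,
  Pearson module–taxon association, and a permutation test for the
  "consistently opposite" FG1-vs-FG2 association pattern.
- **Functional profiles** — CAZy substrate classes (arabinoxylan, pectin,
  mucin, inulin, cellulose, starch), SCFA key-enzyme genes (FTHFS, PcoAt,
  Buk/AtoA/AtoD), VF/ARG class counts per functional group, the
  1-per-100,000 low-abundance filter, Mann–Whitney group comparisons.
- **Virome** — Spearman coupling of alpha diversity, Mantel tests on
  Bray–Curtis matrices, and taxon × phage correlation tables.
- **Synthetic data** — a fully labelled logistic-normal community
  generator (anti-correlated group latents, diet effects, planted host
  modules, host-tracking phages) so the entire pipeline is testable
  without any sequencing data.

## Worked example

```python
import gutgroups as gg

ds = gg.simulate_dataset(gg.SimulationParams(seed=1))

phylum = gg.to_relative(gg.aggregate_by_category(ds.abundance, ds.annotations, "phylum"))
print((100 * phylum.frame.mean()).round(2).sort_values(ascending=False).to_string())

ratios = gg.label_by_ratio(gg.fg_ratio(phylum, gg.DEFAULT_FG_MAP))
print(ratios.frame.join(ds.metadata.frame).groupby("diet")["ratio"].median().round(3).to_string())

net = gg.correlation_network(phylum, r_min=0.5, p_max=0.05)
print(gg.partition_functional_groups(net).group_of_node)
```

prints

```
Proteobacteria    44.79
Bacteroidetes     24.89
Firmicutes        19.43
Fusobacteria       9.12
Actinobacteria     1.77
diet
CD    0.734
HD    1.555
OD    1.769
{'Actinobacteria': 'G_A', 'Bacteroidetes': 'G_B', 'Firmicutes': 'G_B',
 'Fusobacteria': 'G_B', 'Proteobacteria': 'G_A'}
```

Proteobacteria dominates the simulated community; the FG2/FG1 ratio is
roughly doubled under the plant-based diets (OD/HD) relative to the
carnivorous diet (CD); and the co-occurrence partition separates
Proteobacteria from the Fusobacteria/Firmicutes/Bacteroidetes block — the
planted two-group structure, recovered from abundance data alone.

The same analyses are available from the shell:

```bash
gutgroups simulate --seed 1 --out data/
gutgroups all --data data/ --seed 1 --out results/
```

which writes per-stage TSVs (`ratios.tsv`, `network_phylum_edges.tsv`,
`partition.tsv`, `association_gut.tsv`, `cazy_substrates.tsv`, …) plus a
`run_log.json` recording the configuration and seed. Identical seeds give
byte-identical outputs.

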