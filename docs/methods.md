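# Methods

This note documents the statistical procedures implemented in `gutgroups`,
the synthetic-data model used to validate them, and the numerical and
design choices that were genuinely open.

## The FG2/FG1 ratio

All category abundances are plain sums of per-gene abundance over the genes
carrying the category's label; genes without a label at the requested level
are excluded from every category but their mass is tracked separately as
`unassigned`, so that relative-abundance denominators contain only
classified mass. The FG2/FG1 ratio of a sample is

    ratio = (sum of relative abundances of Fusobacteria, Firmicutes, Bacteroidetes + c)
          / (relative abundance of Proteobacteria + c)

with pseudocount c = 0 by default. The ratio is invariant to any positive
rescaling of a sample's raw abundances and to the choice of
relative-abundance denominator (all-classified vs bacteria-only), because
both numerator and denominator scale identically. A sample with zero
Proteobacteria and c = 0 is an error rather than an infinite ratio; real
gut communities of this type always carry Proteobacteria, and an explicit
pseudocount is available for sparse simulated data. Samples are labelled
`high_FG2` when ratio > 1 (FG2 mass exceeds FG1 mass) and `high_FG1`
otherwise, ties to `high_FG1`; the threshold of 1 is a package convention —
it is the only scale-free choice, but it is a choice, and it is
configurable (`ratio_label_threshold`).

## Ecology

* **Shannon** uses the natural log; **Simpson** is reported as the
  Gini–Simpson index 1 − Σp². Neither variant is universal, so both are
  stated here explicitly.
* **Chao1** uses the bias-corrected form S_obs + F₁(F₁−1)/(2(F₂+1)), which
  stays defined at F₂ = 0 and equals S_obs when F₁ = 0.
* **ACE** uses the standard abundance-based coverage estimator with rare
  cutoff 10. When every rare species is a singleton the coverage estimate
  is zero and ACE is undefined; the implementation then falls back to the
  bias-corrected Chao1 value. ACE and Chao1 require integer counts;
  real-valued input is rounded with a warning.
* **Rarefaction** is the analytic hypergeometric expectation
  E[S(d)] = Σᵢ [1 − C(N−nᵢ, d)/C(N, d)], computed with log-gamma for
  stability — no resampling, hence no Monte-Carlo error.
* **PCoA** is Gower double-centering plus a symmetric eigendecomposition.
  Negative eigenvalues (expected for Bray–Curtis) are reported but excluded
  from the proportion-explained denominator, so the reported proportions
  describe the embeddable part of the variation.
* **PERMANOVA** uses the one-way pseudo-F computed from within-group
  pairwise squared distances; **ANOSIM** uses midranks on tied distances
  with R = (mean between − mean within rank)/(M/2). Both permute labels
  freely (no strata) and report p = (b+1)/(B+1), one-sided. Permutations
  are drawn from a caller-supplied seed; the pipeline derives per-stage
  seeds deterministically from its root seed via `numpy.random.SeedSequence`
  spawning, so a fixed seed reproduces every output byte-for-byte. These
  tests are implemented in-package rather than delegated so that the
  permutation stream is seedable; the test suite cross-checks the
  statistics against scikit-bio.
* A Tukey-HSD-over-ANOVA utility (`multi_group_comparison`) covers routine
  three-group comparisons of ratios and diversity indices; it is a thin
  wrapper over the standard procedures, not a contribution.

## Co-occurrence networks and the two-group partition

Edges are Spearman correlations with midranks; p-values use the
t-distribution approximation for n ≥ 10 samples and exact rank-permutation
enumeration below that (feasible for n ≤ 8; n = 9 uses the approximation).
The default edge rule keeps |rho| > 0.5 with p < 0.05, both strict. No
multiple-testing correction is applied on edge p-values by default;
Benjamini–Hochberg adjustment is available where pairwise tables are
produced. Taxa with zero variance cannot carry a rank correlation and are
excluded from edges with a warning.

An optional **random-matrix threshold scan** replaces the fixed 0.5: for
each candidate threshold t in 0.30…0.90 (step 0.01) the correlation matrix
is hard-thresholded, its eigenvalue spectrum unfolded with a smoothed
spline of the cumulative level count, and the nearest-neighbour spacing
distribution compared by chi-square (fixed bins of width 0.5) against the
Poisson form e^(−s) and the Wigner–Dyson form (π s/2)e^(−π s²/4). The
smallest t whose spacings fit Poisson better is returned — the point at
which the network decomposes into uncorrelated blocks. If no t qualifies
(e.g. a structureless matrix) the scan falls back to the fixed threshold
with a warning. The procedure needs ≥ 10 taxa to populate the spacing
histogram.

**Partition.** The two ecological groups are the bipartition maximizing the
signed agreement score Σ over edges of +|rho| when a positive edge lies
within a group or a negative edge crosses groups, and −|rho| otherwise.
Networks of ≤ 15 nodes are solved exactly by enumerating all 2^(k−1)
bipartitions; larger networks use greedy best-single-flip moves from 20
random restarts (seeded). The group containing the lexicographically first
node is always labelled G_A, which fixes the labelling deterministically;
equal-score partitions resolve to the first one found in enumeration
order. Nodes with no incident edges do not affect the score and land in
G_A.

## Host module association

Module detection is a deliberately minimal, reproducible variant of
weighted co-expression analysis: genes are standardized, dissimilarity is
1 − |Pearson r|, average-linkage hierarchical clustering is cut at a fixed
height (default 0.25), and clusters smaller than `module_min_size`
(default 30) fall into the unassigned "grey" module. Soft-threshold power
selection and topological-overlap transforms are intentionally omitted:
the static-cut variant is deterministic, has two interpretable parameters,
and is sufficient to reproduce the association logic downstream.

Each module's **eigengene** is the first principal component of the
module's standardized expression, scaled to unit (population) variance and
sign-oriented to correlate positively with the module's mean expression —
removing the PCA sign ambiguity. `variance_explained` is the leading
eigenvalue share of the module's correlation spectrum.

**Association** is the Pearson correlation of each eigengene with each
taxon or group abundance vector, with two-sided t-test p-values and the
conventional significance tiers ($ p<0.1, * p<0.05, ** p<0.01,
*** p<0.001). Both the per-phylum and the summed FG1/FG2 columns are
produced, since either convention is defensible.

The **opposite-pattern statistic** quantifies "FG1 and FG2 associate with
host modules in opposite directions": across modules, the FG1
module-correlation vector is correlated with each FG2 phylum's vector; the
statistic is the average over FG2 phyla. The p-value permutes the module
rows of the FG1 vector (one-sided, lower tail, p = (b+1)/(B+1));
"consistently opposite" is declared when the statistic is negative with
p < 0.05. At least 5 modules are required for the permutation distribution
to be non-trivial.

## Functional profiles

CAZy families map to six substrate classes (arabinoxylan, pectin, mucin,
inulin, cellulose, starch). The lists overlap by construction — GH1, GH3
and GH5 appear under several substrates — and a gene carrying families in
k substrate classes contributes its abundance to all k; no deduplication
is applied. Substrate values are normalized per sample and functional
group by the group's total CAZy-gene abundance and scaled to 100,000,
making them invariant to per-sample sequencing depth.

SCFA capacity is profiled through marker genes: FTHFS
(formate–tetrahydrofolate ligase, acetogenesis), PcoAt (propionate
CoA-transferase), and Buk/AtoA/AtoD (butyrate kinase and acetoacetate
CoA-transferase subunits). The enzyme symbols are fixed; their KO
identifiers ship as editable configuration (`ScfaEnzymeMap`), defaulting
to K01938, K01026, K00929, K01035, K01034, since KO assignments depend on
the annotation release.

VF and ARG class profiles count genes (not abundance) per class per
functional group, normalized to the group's total annotated genes per
100,000; an abundance-weighted variant is available behind a flag. ARG
classes below 1 per 100,000 in every sample are dropped by the
low-abundance filter (boundary value retained). Group comparisons use the
two-sided Mann–Whitney U test: exact enumeration when both n ≤ 8 with no
ties, otherwise the normal approximation with tie and continuity
corrections.

## Virome coupling

Alpha-diversity coupling is the Spearman correlation of matched viral and
bacterial index columns (shared Spearman routine, so tie handling matches
the network module). Beta-diversity coupling is a Mantel test on the two
Bray–Curtis matrices — Spearman on the n(n−1)/2 off-diagonal pairs by
default (invariant to monotone transforms of either matrix), Pearson
optionally — permuting one matrix's sample order, one-sided. The
taxon × phage table is all-pairs Spearman; constant features yield missing
entries rather than errors.

## The synthetic-data generator

The generator produces the statistical structure the analysis assumes,
with known ground truth, and defines the conditions under which the
package is validated.

**Community.** Two latent factors (z₁, z₂) per sample are bivariate normal
with correlation −`group_anticorr` (default 0.9). Each taxon's
log-abundance is a phylum baseline + 0.25·(its group's latent) +
`diet_effect`·1[FG2 taxon, OD/HD sample] + N(0, `noise_sd`²) with
noise_sd = 0.35; abundances are exponentiated and closed to relative form
downstream (logistic-normal). Phylum baselines centre the mean composition
on a Proteobacteria-dominated community (54/17/14/7% for the four dominant
phyla plus a small Actinobacteria tail), with 8/6/6/4/2 taxa per phylum and
20 genes per taxon whose fixed weights split the taxon's abundance. The
group loading of 0.25 and noise of 0.35 were fixed by a pre-build
simulation study so that (i) summed FG1 and FG2 relative abundances are
strongly anti-correlated (compositional closure contributes most of this),
(ii) the phylum co-occurrence network at the default edge rule yields the
planted bipartition, and (iii) a diet effect of 0.5–0.8 on the log scale
is detectable at n = 6 replicates per diet×week cell — the regime the
analysis is designed for, where diet shifts are large relative to
within-group spread. The default `diet_effect` of 0.8 reflects a clearly
significant diet response at this sample size.

**Annotation.** FG2 genes carry fiber-degrading CAZy families
(arabinoxylan/pectin/cellulose lists) with probability 0.3 (sometimes two
families, exercising multi-substrate attribution); FG1 genes carry starch
families with probability 0.3. SCFA marker KOs occur at 5% in FG2 taxa vs
1% in FG1. VF and ARG labels are per-gene Bernoulli with FG1 probabilities
3× FG2's (0.15 vs 0.05, and 0.12 vs 0.04), planting directionality without
asserting effect magnitudes.

**Host expression.** There are 6 planted modules of 40 genes (two tissues,
gut and liver, same module structure with independent noise). Modules
alternate sign: +1 modules couple toward the FG1 latent z₁, −1 modules
toward z₂. Each module has its own latent uₘ = 0.8·(group latent) +
0.6·(module-specific noise), standardized; member genes are
`module_coupling`·uₘ + √(1−coupling²)·noise. The module-specific component
is essential: if same-sign modules shared one latent exactly they would be
statistically indistinguishable and no clustering method could recover
them. The module's own latent uₘ (stored in `SyntheticTruth.module_latents`)
is the recovery target for eigengenes; its 0.8 group share keeps the
opposite-signed coupling to the community state.

**Virome.** Each of the 10 viral taxa is assigned a bacterial host taxon
(cycling through phyla) and tracks the standardized log *relative*
abundance of its host with weight `virome_coupling` (default 0.9) —
relative rather than absolute abundance, because phage and host are
measured in the same compositional sample and downstream correlations are
computed on relative profiles.

**What the generator does not emulate** — and hence what passing tests do
not establish about real data: sequencing noise and zero-inflation
(abundances are strictly positive), realistic taxon richness (26 genera vs
hundreds; in particular the "core genera" of a simulated study cover
essentially the whole community, so core-contribution fractions are near
100% rather than the 80–90% typical of real communities), within-phylum
correlation structure beyond a single shared latent, gene-length effects
on abundance estimation, and any upstream read-processing artefacts.

## Numerical conventions

* Standardization uses population variance throughout the module
  machinery; eigengines are unit-population-variance.
* Relative profiles must have rows summing to 1 within 1e-9; text
  round-trips use shortest-repr float formatting and round-trip parsing,
  so written tables reread exactly.
* Permutation p-values are never 0: p = (b+1)/(B+1).
* All randomized stages draw from seeds spawned deterministically from the
  pipeline's root seed; no stage touches global random state.

## Known limitations

* The partition's greedy path (for networks > 15 nodes) is a local search
  with restarts; it matches the exhaustive optimum on all tested networks
  but carries no optimality guarantee.
* The random-matrix threshold scan is one defensible operationalization of
  spectral thresholding; different unfolding or goodness-of-fit choices
  shift the returned threshold by a few grid steps. The fixed
  |rho| > 0.5 rule is the default path.
* Module detection deliberately omits soft-thresholding and topological
  overlap; on data where module boundaries are defined by network topology
  rather than raw correlation, results will differ from full WGCNA.
* ANOSIM/PERMANOVA assume exchangeable samples under the null; the design's
  week structure is ignored when permuting (no restricted permutations).
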