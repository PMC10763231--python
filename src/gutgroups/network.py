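"""Signed co-occurrence networks and the two-group partition.

Core taxa are the top-abundance genera detected in every diet x week cell.
Edges are Spearman correlations passing |rho| > r_min and p < p_max; a
negative edge is a co-exclusion.  The two "ecological groups" are found by
maximizing a signed agreement score: positive edges want their endpoints on
the same side, negative edges on opposite sides.  An optional random-matrix
style scan chooses the correlation threshold as the smallest value at which
the thresholded matrix's eigenvalue spacings look Poissonian (uncorrelated
blocks) rather than Wigner-Dyson (one strongly coupled system).
"""

from __future__ import annotations

import dataclasses
import itertools
import warnings

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.interpolate import UnivariateSpline

from .datatypes import FeatureProfile, GutgroupsError, SampleMetadata
from .stats import spearman, spearman_matrix

__all__ = [
    "core_taxa",
    "CoreTaxaResult",
    "correlation_network",
    "CooccurrenceNetwork",
    "rmt_threshold",
    "partition_functional_groups",
    "PartitionResult",
]


# ---------------------------------------------------------------------------
# Core taxa
# ---------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class CoreTaxaResult:
    core: tuple[str, ...]  # taxa in the core set
    candidates: tuple[str, ...]  # top_n taxa by overall mean abundance
    cell_contribution: pd.Series  # per diet x week cell: core share of total


def core_taxa(
    profile: FeatureProfile,
    meta: SampleMetadata,
    top_n: int = 30,
    presence_threshold: float = 0.0,
) -> CoreTaxaResult:
    """Top-abundance taxa shared by every diet x week cell.

    Candidates are the *top_n* taxa by overall mean relative abundance; the
    core keeps those whose mean abundance exceeds *presence_threshold* in
    every cell.  Also reports, per cell, the fraction of total abundance the
    core accounts for (the "shared genera contributed" fraction).
    """
    frame = profile.frame
    missing = frame.index.difference(meta.sample_ids)
    if len(missing):
        raise GutgroupsError(f"metadata missing sample(s): {list(missing[:5])}")
    cells = meta.cells().reindex(frame.index)
    counts = cells.value_counts()
    expected = {f"{d}_w{w}" for d in ("CD", "OD", "HD") for w in (1, 3)}
    empty = expected & (expected - set(counts.index))
    present_cells = sorted(set(cells))
    if len(present_cells) < 1 or counts.min() < 1:
        raise GutgroupsError("every diet x week cell needs at least one sample")
    if empty and set(meta.frame["diet"]) == {"CD", "OD", "HD"}:
        raise GutgroupsError(f"empty diet x week cell(s): {sorted(empty)}")

    overall_mean = frame.mean(axis=0)
    candidates = overall_mean.sort_values(ascending=False, kind="stable").index[:top_n]
    cell_means = frame.groupby(cells).mean()
    detected = (cell_means[candidates] > presence_threshold).all(axis=0)
    core = tuple(c for c in candidates if detected[c])
    contribution = frame[list(core)].groupby(cells).sum().sum(axis=1) / frame.groupby(
        cells
    ).sum().sum(axis=1)
    return CoreTaxaResult(
        core=core,
        candidates=tuple(candidates),
        cell_contribution=contribution.rename("core_contribution"),
    )


# ---------------------------------------------------------------------------
# Correlation network
# ---------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class CooccurrenceNetwork:
    """Taxa as nodes; significant signed Spearman correlations as edges."""

    nodes: pd.Series  # mean relative abundance per taxon
    edges: pd.DataFrame  # columns node_a, node_b, rho, p, sign
    threshold_used: float

    def __post_init__(self) -> None:
        if len(self.edges):
            if (self.edges["node_a"] == self.edges["node_b"]).any():
                raise GutgroupsError("self-edges are not allowed")
            if (self.edges["rho"].abs() < self.threshold_used).any():
                raise GutgroupsError("edge below the correlation threshold")

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for taxon, abund in self.nodes.items():
            g.add_node(taxon, mean_abundance=float(abund))
        for row in self.edges.itertuples(index=False):
            g.add_edge(row.node_a, row.node_b, rho=float(row.rho), p=float(row.p), sign=row.sign)
        return g

    def write_graphml(self, path) -> None:
        nx.write_graphml(self.to_networkx(), path)


def correlation_network(
    profile: FeatureProfile,
    r_min: float = 0.5,
    p_max: float = 0.05,
) -> CooccurrenceNetwork:
    """Build the signed Spearman co-occurrence network of a taxon profile.

    Keeps edges with |rho| > r_min and p < p_max (both strict).  Taxa with
    zero variance cannot carry a rank correlation; they stay in the node set
    but are excluded from edges with a warning.  For n < 10 samples the
    p-values come from exact rank-permutation enumeration, otherwise from
    the t approximation.
    """
    frame = profile.frame
    n, m = frame.shape
    if n < 5:
        raise GutgroupsError("correlation network needs at least 5 samples")
    if m < 2:
        raise GutgroupsError("correlation network needs at least 2 taxa")
    X = frame.to_numpy(dtype=float)
    const = np.ptp(X, axis=0) == 0
    if const.any():
        warnings.warn(
            f"constant taxa excluded from edges: {list(frame.columns[const])}", stacklevel=2
        )
    taxa = frame.columns
    if n < 10:
        rho = np.full((m, m), np.nan)
        p = np.full((m, m), np.nan)
        for i, j in itertools.combinations(range(m), 2):
            if const[i] or const[j]:
                continue
            rho[i, j], p[i, j] = spearman(X[:, i], X[:, j])
            rho[j, i], p[j, i] = rho[i, j], p[i, j]
    else:
        rho, p = spearman_matrix(X)
    rows = []
    for i, j in itertools.combinations(range(m), 2):
        if np.isnan(rho[i, j]):
            continue
        if abs(rho[i, j]) > r_min and p[i, j] < p_max:
            rows.append(
                {
                    "node_a": taxa[i],
                    "node_b": taxa[j],
                    "rho": float(rho[i, j]),
                    "p": float(p[i, j]),
                    "sign": "co-exclusion" if rho[i, j] < 0 else "co-occurrence",
                }
            )
    edges = pd.DataFrame(rows, columns=["node_a", "node_b", "rho", "p", "sign"])
    return CooccurrenceNetwork(nodes=frame.mean(axis=0), edges=edges, threshold_used=r_min)


# ---------------------------------------------------------------------------
# Random-matrix threshold scan
# ---------------------------------------------------------------------------

_SPACING_BINS = np.array([0.0, 0.5, 1.0, 1.5, 2.0, 2.5, 3.0, np.inf])


def _nn_spacings(evals: np.ndarray) -> np.ndarray | None:
    """Unfolded nearest-neighbour eigenvalue spacings (mean ~ 1)."""
    e = np.sort(evals)
    e = np.unique(np.round(e, 12))
    n = e.size
    if n < 8:
        return None
    # unfold by a smoothed empirical staircase: fit a cubic spline to the
    # cumulative level count and difference the smoothed positions
    try:
        spline = UnivariateSpline(e, np.arange(1, n + 1), k=3, s=np.sqrt(n))
        unfolded = spline(e)
    except Exception:
        return None
    s = np.diff(unfolded)
    s = s[s >= 0]
    if s.size < 6 or s.mean() <= 0:
        return None
    return s / s.mean()


def _chi2_gof(s: np.ndarray, cdf) -> float:
    """Chi-square statistic of spacings against a distribution on fixed bins."""
    obs, _ = np.histogram(s, bins=_SPACING_BINS)
    probs = np.diff([cdf(b) for b in _SPACING_BINS])
    exp = probs * s.size
    keep = exp > 1e-9
    return float(((obs[keep] - exp[keep]) ** 2 / exp[keep]).sum())


def _poisson_cdf(x: float) -> float:
    return 1.0 - np.exp(-x) if np.isfinite(x) else 1.0


def _wigner_cdf(x: float) -> float:
    return 1.0 - np.exp(-np.pi * x * x / 4.0) if np.isfinite(x) else 1.0


def rmt_threshold(
    corr: np.ndarray,
    grid: np.ndarray | None = None,
    fallback: float = 0.5,
) -> float:
    """Scan correlation thresholds for the Poisson/Wigner spacing transition.

    For each candidate threshold t the matrix is hard-thresholded
    (|rho| < t set to 0, unit diagonal kept), its eigenvalue spectrum
    unfolded, and the nearest-neighbour spacing distribution compared by
    chi-square against the Poisson (uncorrelated) and Wigner-Dyson
    (correlated) forms.  Returns the smallest t at which Poisson fits
    better; falls back to *fallback* with a warning when no t qualifies.
    """
    corr = np.asarray(corr, dtype=float)
    if corr.ndim != 2 or corr.shape[0] != corr.shape[1]:
        raise GutgroupsError("rmt_threshold expects a square correlation matrix")
    if corr.shape[0] < 10:
        raise GutgroupsError(
            "matrix too small for a spacing-distribution scan; use the fixed threshold"
        )
    if not np.allclose(corr, corr.T, atol=1e-8):
        raise GutgroupsError("correlation matrix must be symmetric")
    if grid is None:
        grid = np.arange(0.30, 0.901, 0.01)
    for t in grid:
        M = np.where(np.abs(corr) >= t, corr, 0.0)
        np.fill_diagonal(M, 1.0)
        evals = np.linalg.eigvalsh(M)
        s = _nn_spacings(evals)
        if s is None:
            continue
        if _chi2_gof(s, _poisson_cdf) < _chi2_gof(s, _wigner_cdf):
            return float(round(t, 10))
    warnings.warn("no threshold produced Poissonian spacings; falling back", stacklevel=2)
    return float(fallback)


# ---------------------------------------------------------------------------
# Two-group partition
# ---------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class PartitionResult:
    group_of_node: dict[str, str]  # node -> "G_A" / "G_B"
    score: float
    is_exhaustive: bool


def _partition_score(rho: np.ndarray, ia: np.ndarray, ib: np.ndarray, side: np.ndarray) -> float:
    same = side[ia] == side[ib]
    return float(np.sum(np.where(same, rho, -rho)))


def partition_functional_groups(
    net: CooccurrenceNetwork,
    seed: int | None = 0,
    exhaustive_limit: int = 15,
    restarts: int = 20,
) -> PartitionResult:
    """Split network nodes into two groups maximizing signed-edge agreement.

    score = sum over edges of +|rho| when a positive edge lies within a group
    or a negative edge crosses groups, else -|rho|.  Networks with at most
    *exhaustive_limit* nodes are solved by enumerating all bipartitions;
    larger networks use greedy single-node moves from *restarts* random
    starts.  The group containing the lexicographically first node is always
    labelled G_A.
    """
    if len(net.edges) == 0:
        raise GutgroupsError("cannot partition an edgeless network")
    nodes = sorted(net.nodes.index)
    idx = {v: i for i, v in enumerate(nodes)}
    k = len(nodes)
    ia = net.edges["node_a"].map(idx).to_numpy()
    ib = net.edges["node_b"].map(idx).to_numpy()
    rho = net.edges["rho"].to_numpy(dtype=float)

    if k <= exhaustive_limit:
        best_side, best_score = None, -np.inf
        for mask in range(2 ** (k - 1)):  # node 0 fixed on side 0
            side = np.array([0] + [(mask >> i) & 1 for i in range(k - 1)], dtype=np.int8)
            sc = _partition_score(rho, ia, ib, side)
            if sc > best_score + 1e-12:
                best_score, best_side = sc, side
        exhaustive = True
    else:
        rng = np.random.default_rng(seed)
        best_side, best_score = None, -np.inf
        for _ in range(restarts):
            side = rng.integers(0, 2, size=k).astype(np.int8)
            improved = True
            while improved:
                improved = False
                # greedy: flip the single best-improving node, if any
                base = _partition_score(rho, ia, ib, side)
                gains = np.empty(k)
                for v in range(k):
                    side[v] ^= 1
                    gains[v] = _partition_score(rho, ia, ib, side) - base
                    side[v] ^= 1
                v = int(np.argmax(gains))
                if gains[v] > 1e-12:
                    side[v] ^= 1
                    improved = True
            sc = _partition_score(rho, ia, ib, side)
            if sc > best_score + 1e-12:
                best_score, best_side = sc, side.copy()
        exhaustive = False

    if best_side[0] == 1:  # normalize: first node's group is G_A
        best_side = 1 - best_side
    group_of_node = {v: ("G_A" if best_side[i] == 0 else "G_B") for v, i in idx.items()}
    return PartitionResult(group_of_node=group_of_node, score=best_score, is_exhaustive=exhaustive)
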