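"""Core taxa, co-occurrence networks, RMT threshold scan and the partition."""

import itertools

import numpy as np
import pandas as pd
import pytest

import gutgroups as gg
from gutgroups.network import CooccurrenceNetwork, rmt_threshold
from gutgroups.stats import spearman


def _meta(n_per_cell=1):
    rows = []
    for week in (1, 3):
        for diet in ("CD", "OD", "HD"):
            for r in range(1, n_per_cell + 1):
                rows.append((f"{diet}_w{week}_r{r}", diet, week, r))
    frame = pd.DataFrame(
        rows, columns=["sample_id", "diet", "week", "replicate"]
    ).set_index("sample_id")
    return gg.SampleMetadata(frame)


def _profile(frame):
    return gg.FeatureProfile(frame, level="genus", normalization="raw")


class TestCoreTaxa:
    def test_presence_pattern_hand_enumeration(self):
        meta = _meta()
        samples = list(meta.sample_ids)
        frame = pd.DataFrame(
            {
                "everywhere": [5.0] * 6,
                "missing_one_cell": [3.0, 3.0, 3.0, 3.0, 3.0, 0.0],
                "rare_everywhere": [0.5] * 6,
                "tiny": [0.1] * 6,
                "absent": [0.0] * 6,
            },
            index=samples,
        )
        res = gg.core_taxa(_profile(frame), meta, top_n=4)
        assert set(res.core) == {"everywhere", "rare_everywhere", "tiny"}
        assert "missing_one_cell" not in res.core
        # contribution fractions match hand arithmetic per cell
        for sid in samples:
            cell = f"{meta.frame.loc[sid, 'diet']}_w{meta.frame.loc[sid, 'week']}"
            expected = frame.loc[sid, list(res.core)].sum() / frame.loc[sid].sum()
            assert res.cell_contribution[cell] == pytest.approx(expected)

    def test_missing_metadata_sample_is_an_error(self):
        meta = _meta()
        frame = pd.DataFrame({"t": np.ones(7)}, index=list(meta.sample_ids) + ["extra"])
        with pytest.raises(gg.GutgroupsError, match="extra"):
            gg.core_taxa(_profile(frame), meta)


class TestCorrelationNetwork:
    def test_monotone_pairs_give_signed_edges(self):
        x = np.arange(12, dtype=float)
        frame = pd.DataFrame({"up1": x, "up2": x**2 + 1, "down": -x + 20})
        net = gg.correlation_network(_profile(frame), r_min=0.5, p_max=0.05)
        edges = {(r.node_a, r.node_b): r.sign for r in net.edges.itertuples()}
        assert edges[("up1", "up2")] == "co-occurrence"
        assert edges[("up1", "down")] == "co-exclusion"
        rho = net.edges.set_index(["node_a", "node_b"])["rho"]
        assert rho[("up1", "up2")] == pytest.approx(1.0)
        assert rho[("up1", "down")] == pytest.approx(-1.0)

    def test_subthreshold_correlation_keeps_no_edge(self):
        # ranks permuted so the sample Spearman rho sits near 0.4, below 0.5
        # (rho = 0.4 exactly is unattainable at n = 10: it needs an odd
        # squared rank-difference sum)
        x = np.arange(1, 11, dtype=float)
        rng = np.random.default_rng(0)
        for _ in range(2000):
            y = rng.permutation(x)
            rho, _ = spearman(x, y, exact=False)
            if abs(rho - 0.4) < 0.02:
                break
        else:
            pytest.fail("no permutation with rho near 0.4 found")
        assert abs(rho) < 0.5
        frame = pd.DataFrame({"a": x, "b": y})
        net = gg.correlation_network(_profile(frame), r_min=0.5, p_max=0.05)
        assert len(net.edges) == 0

    def test_constant_taxon_warns_and_is_excluded_from_edges(self):
        x = np.arange(12, dtype=float)
        frame = pd.DataFrame({"a": x, "b": 2 * x, "const": np.ones(12)})
        with pytest.warns(UserWarning, match="const"):
            net = gg.correlation_network(_profile(frame), 0.5, 0.05)
        assert "const" not in set(net.edges["node_a"]) | set(net.edges["node_b"])
        assert "const" in net.nodes.index

    def test_edge_set_shrinks_as_threshold_grows(self, genus_relative):
        sizes = []
        for r_min in (0.3, 0.5, 0.7, 0.9):
            net = gg.correlation_network(genus_relative, r_min, 0.05)
            sizes.append(len(net.edges))
        assert sizes == sorted(sizes, reverse=True)


class TestRmtThreshold:
    def test_identity_matrix_falls_back(self):
        with pytest.warns(UserWarning, match="falling back"):
            t = rmt_threshold(np.eye(20), fallback=0.5)
        assert t == 0.5

    def test_planted_blocks_are_retained_at_returned_threshold(self):
        rng = np.random.default_rng(1)
        n, k = 60, 20
        u = rng.normal(size=n)
        v = rng.normal(size=n)
        X = np.empty((n, k))
        for j in range(k):
            latent = u if j < 10 else v
            X[:, j] = 3.0 * latent + rng.normal(size=n)
        corr = np.corrcoef(X, rowvar=False)
        t = rmt_threshold(corr)
        assert t < 0.9
        thresholded = np.abs(corr) >= t
        # both planted blocks survive the scan (most within-block edges kept),
        # while the weak background is almost entirely removed
        within1 = thresholded[:10, :10][np.triu_indices(10, 1)]
        within2 = thresholded[10:, 10:][np.triu_indices(10, 1)]
        background = thresholded[:10, 10:]
        assert within1.mean() > 0.7 and within2.mean() > 0.7
        assert background.mean() < 0.05

    def test_pure_noise_network_is_sparse_at_returned_threshold(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(50, 20))
        corr = np.corrcoef(X, rowvar=False)
        t = rmt_threshold(corr)
        off = np.abs(corr)[np.triu_indices(20, 1)]
        assert (off >= t).mean() < 0.05

    def test_small_matrix_rejected(self):
        with pytest.raises(gg.GutgroupsError, match="fixed threshold"):
            rmt_threshold(np.eye(5))


def _net(edges, nodes=None):
    frame = pd.DataFrame(edges, columns=["node_a", "node_b", "rho"])
    frame["p"] = 0.001
    frame["sign"] = np.where(frame["rho"] < 0, "co-exclusion", "co-occurrence")
    all_nodes = nodes or sorted(set(frame["node_a"]) | set(frame["node_b"]))
    return CooccurrenceNetwork(
        nodes=pd.Series(0.1, index=pd.Index(all_nodes)), edges=frame, threshold_used=0.0
    )


def _brute_force_best(net):
    nodes = sorted(net.nodes.index)
    best = -np.inf
    for bits in itertools.product([0, 1], repeat=len(nodes) - 1):
        side = dict(zip(nodes, (0,) + bits))
        score = 0.0
        for r in net.edges.itertuples():
            same = side[r.node_a] == side[r.node_b]
            score += r.rho if same else -r.rho
        best = max(best, score)
    return best


class TestPartition:
    def test_single_negative_edge_separates_nodes(self):
        res = gg.partition_functional_groups(_net([("a", "b", -0.8)]))
        assert res.group_of_node["a"] != res.group_of_node["b"]
        assert res.score == pytest.approx(0.8)
        assert res.is_exhaustive

    def test_six_node_toy_matches_brute_force_maximum(self):
        rng = np.random.default_rng(3)
        nodes = list("abcdef")
        edges = [
            (x, y, float(rng.uniform(-1, 1)))
            for x, y in itertools.combinations(nodes, 2)
            if rng.random() < 0.7
        ]
        net = _net(edges, nodes)
        res = gg.partition_functional_groups(net)
        assert res.score == pytest.approx(_brute_force_best(net), abs=1e-9)

    def test_greedy_path_matches_exhaustive_on_small_networks(self):
        rng = np.random.default_rng(4)
        for trial in range(10):
            nodes = [f"n{i}" for i in range(9)]
            edges = [
                (x, y, float(rng.uniform(-1, 1)))
                for x, y in itertools.combinations(nodes, 2)
                if rng.random() < 0.5
            ]
            if not edges:
                continue
            net = _net(edges, nodes)
            exh = gg.partition_functional_groups(net)
            greedy = gg.partition_functional_groups(net, exhaustive_limit=2, seed=trial)
            assert not greedy.is_exhaustive
            assert greedy.score == pytest.approx(exh.score, abs=1e-9)

    def test_score_invariant_under_group_label_swap(self):
        net = _net([("a", "b", -0.9), ("b", "c", 0.7), ("a", "c", -0.5)])
        res = gg.partition_functional_groups(net)
        swapped = {n: ("G_A" if g == "G_B" else "G_B") for n, g in res.group_of_node.items()}
        side = {n: 0 if g == "G_A" else 1 for n, g in swapped.items()}
        score = sum(
            r.rho if side[r.node_a] == side[r.node_b] else -r.rho
            for r in net.edges.itertuples()
        )
        assert score == pytest.approx(res.score)

    def test_edgeless_network_is_an_error(self):
        empty = CooccurrenceNetwork(
            nodes=pd.Series(0.1, index=pd.Index(["a", "b"])),
            edges=pd.DataFrame(columns=["node_a", "node_b", "rho", "p", "sign"]),
            threshold_used=0.5,
        )
        with pytest.raises(gg.GutgroupsError):
            gg.partition_functional_groups(empty)

    def test_recovers_planted_groups_on_synthetic_phyla(self, dataset, phylum_relative):
        net = gg.correlation_network(phylum_relative, 0.5, 0.05)
        res = gg.partition_functional_groups(net)
        fgmap = dataset.truth.fg_of_phylum
        sides = {
            g: {res.group_of_node[p] for p in fgmap.phyla(g) if p in res.group_of_node}
            for g in ("FG1", "FG2")
        }
        assert len(sides["FG1"]) == 1 and len(sides["FG2"]) == 1
        assert sides["FG1"] != sides["FG2"]
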