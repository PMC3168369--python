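import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from netprior.graph_io import GeneScoreTable
from netprior.network_builder import SubNetwork
from netprior.ranker import WeightVector
from netprior.scorer import (
    combine_liptak,
    correct_network_p,
    gene_network_percentile,
    gene_report,
    p_to_z,
    score_all_networks,
    snp_to_gene_p,
    z_to_p,
)


class TestPToZ:
    def test_mean_maps_to_zero(self):
        assert p_to_z(0.5, 0.5, 0.4) == pytest.approx(0.0)

    def test_three_point_dataset(self):
        # dataset {0.1, 0.5, 0.9}: mean 0.5, sample sd 0.4
        assert p_to_z(0.1, 0.5, 0.4) == pytest.approx(1.0)

    def test_antisymmetric_about_mean(self):
        for p in (0.01, 0.2, 0.77):
            assert p_to_z(p, 0.4, 0.3) + p_to_z(2 * 0.4 - p, 0.4, 0.3) == pytest.approx(0.0)

    def test_degenerate_sd_rejected(self):
        with pytest.raises(ValueError):
            p_to_z(0.5, 0.5, 0.0)


class TestCombineLiptak:
    def test_equal_weights_cancel(self):
        z = combine_liptak({"A": 0.3, "B": 0.3, "C": 0.3}, {"A": 1, "B": 1, "C": 1})
        assert z == pytest.approx(math.sqrt(3))

    def test_all_zero_z(self):
        assert combine_liptak({"A": 0.2, "B": 0.7}, {"A": 0, "B": 0}) == 0.0

    def test_hand_computed_two_gene(self):
        z = combine_liptak({"A": 0.5, "B": 0.5}, {"A": 1.2, "B": -0.4})
        assert z == pytest.approx(0.4 / math.sqrt(0.5))

    def test_scale_invariance(self):
        w = {"A": 0.11, "B": 0.42, "C": 0.05}
        z = {"A": 1.4, "B": -0.3, "C": 2.2}
        base = combine_liptak(w, z)
        scaled = combine_liptak({g: 7.3 * v for g, v in w.items()}, z)
        assert scaled == pytest.approx(base, abs=1e-12)

    def test_equal_weights_reduce_to_stouffer(self):
        rng = np.random.default_rng(2)
        z = {f"G{i}": float(v) for i, v in enumerate(rng.normal(size=10))}
        w = {g: 0.037 for g in z}
        stouffer = sum(z.values()) / math.sqrt(len(z))
        assert combine_liptak(w, z) == pytest.approx(stouffer, abs=1e-12)

    def test_empty_intersection_raises(self):
        with pytest.raises(ValueError, match="shared"):
            combine_liptak({"A": 1.0}, {"B": 0.5})


class TestZToP:
    def test_zero_is_half(self):
        assert z_to_p(0.0) == pytest.approx(0.5)

    def test_five_percent_quantile(self):
        assert z_to_p(1.6449) == pytest.approx(0.05, abs=1e-4)

    def test_symmetry(self):
        for z in (-2.3, -0.1, 0.7, 3.1):
            assert z_to_p(z) + z_to_p(-z) == pytest.approx(1.0)


class TestCorrectNetworkP:
    def test_examples(self):
        assert correct_network_p(1e-6, 50, 100) == pytest.approx(5e-3)
        assert correct_network_p(0.01, 50, 2849) == 1.0
        assert correct_network_p(0.0, 7, 13) == 0.0

    def test_invalid_counts(self):
        with pytest.raises(ValueError):
            correct_network_p(0.1, 0, 5)


def _net(seed, members, edges=()):
    g = nx.Graph()
    g.add_nodes_from(members)
    g.add_edges_from(edges)
    return SubNetwork(seed=seed, graph=g)


def _wv(net, weights):
    return WeightVector(net.network_id, weights, {g: 0.5 for g in weights}, 1, True)


class TestScoreAllNetworks:
    def test_single_network_all_null(self):
        # three genes at the dataset mean give z=0 everywhere -> p_network 0.5
        table = GeneScoreTable.from_pairs(
            [("A", 0.5), ("B", 0.5), ("C", 0.5), ("D", 0.1), ("E", 0.9)]
        )
        net = _net("A", ["A", "B", "C"])
        scores = score_all_networks([net], [_wv(net, {"A": 0.1, "B": 0.1, "C": 0.1})], table)
        row = scores.iloc[0]
        assert row["p_network"] == pytest.approx(0.5)
        assert row["rank"] == 1 and row["percentile"] == pytest.approx(100.0)

    def test_hub_signal_ranks_first(self):
        # identical membership; network X puts the large z on its heavy gene
        table = GeneScoreTable.from_pairs(
            [("H", 0.001), ("A", 0.5), ("B", 0.6), ("C", 0.4), ("D", 0.3)]
        )
        n1 = _net("H", ["H", "A", "B"])
        n2 = _net("A", ["H", "A", "B"])
        w1 = _wv(n1, {"H": 0.6, "A": 0.1, "B": 0.1})  # hub-weighted on the signal gene
        w2 = _wv(n2, {"H": 0.1, "A": 0.6, "B": 0.1})
        scores = score_all_networks([n1, n2], [w1, w2], table)
        assert scores.iloc[0]["network_id"] == "net:H"
        # cross-check by direct weighted-combination arithmetic
        zmap = {
            g: (table.mean_p - p) / table.sd_p for g, p in table.pvalues().items()
        }
        z1 = combine_liptak(w1.weights, zmap)
        z2 = combine_liptak(w2.weights, zmap)
        assert z1 > z2
        assert scores.set_index("network_id").at["net:H", "z_comb"] == pytest.approx(z1)

    def test_missing_genes_dropped(self):
        table = GeneScoreTable.from_pairs([("A", 0.2), ("B", 0.8), ("C", 0.5)])
        net = _net("A", ["A", "B", "GHOST"])
        scores = score_all_networks([net], [_wv(net, {"A": 0.2, "B": 0.2, "GHOST": 0.2})], table)
        assert scores.iloc[0]["n_genes"] == 2

    def test_ranks_are_total_order(self):
        rng = np.random.default_rng(4)
        table = GeneScoreTable.from_pairs(
            [(f"G{i}", float(p)) for i, p in enumerate(rng.uniform(size=40).clip(1e-9, 1))]
        )
        nets, wvs = [], []
        for k in range(12):
            members = [f"G{i}" for i in rng.choice(40, size=6, replace=False)]
            net = _net(members[0], members)
            nets.append(net)
            wvs.append(_wv(net, {g: float(w) for g, w in zip(members, rng.uniform(0.01, 0.3, 6))}))
        # seeds may repeat -> keep unique ids only
        seen, uniq_nets, uniq_wvs = set(), [], []
        for net, wv in zip(nets, wvs):
            if net.network_id not in seen:
                seen.add(net.network_id)
                uniq_nets.append(net)
                uniq_wvs.append(wv)
        scores = score_all_networks(uniq_nets, uniq_wvs, table)
        assert sorted(scores["rank"]) == list(range(1, len(scores) + 1))
        assert (scores.sort_values("rank")["percentile"].diff().dropna() > 0).all()

    def test_gene_partition_by_alpha(self):
        table = GeneScoreTable.from_pairs([("A", 0.01), ("B", 0.5), ("C", 0.04)])
        net = _net("A", ["A", "B", "C"])
        scores = score_all_networks([net], [_wv(net, {"A": 0.1, "B": 0.1, "C": 0.1})], table)
        assert scores.iloc[0]["significant_genes"] == ["A", "C"]
        assert scores.iloc[0]["nonsignificant_genes"] == ["B"]


class TestGeneNetworkPercentile:
    def _table(self, rows):
        return pd.DataFrame(rows)

    def test_best_network_rule(self):
        table = self._table(
            [
                {"network_id": "net:A", "rank": 5, "percentile": 5.0,
                 "significant_genes": ["X"], "nonsignificant_genes": []},
                {"network_id": "net:B", "rank": 90, "percentile": 90.0,
                 "significant_genes": [], "nonsignificant_genes": ["X"]},
            ]
        )
        assert gene_network_percentile("X", table) == 5.0
        assert gene_network_percentile("ABSENT", table) is None

    def test_random_assignment_matches_min_scan_oracle(self):
        rng = np.random.default_rng(9)
        genes = [f"G{i}" for i in range(50)]
        rows = []
        for k in range(10):
            members = list(rng.choice(genes, size=12, replace=False))
            rows.append(
                {"network_id": f"net:N{k}", "rank": k + 1, "percentile": 10.0 * (k + 1),
                 "significant_genes": members[:4], "nonsignificant_genes": members[4:]}
            )
        table = self._table(rows)
        for gene in genes:
            expected = min(
                (r["percentile"] for r in rows
                 if gene in r["significant_genes"] or gene in r["nonsignificant_genes"]),
                default=None,
            )
            assert gene_network_percentile(gene, table) == expected


class TestSnpToGene:
    GENES = pd.DataFrame(
        [{"gene": "GA", "chrom": "1", "start": 100000, "end": 110000}]
    )

    def _snps(self, rows):
        return pd.DataFrame(rows, columns=["snp", "chrom", "pos", "p"])

    def test_flank_boundary_inclusive(self):
        snps = self._snps([("rs1", "1", 50000, 0.01)])  # exactly start - 50 kb
        t = snp_to_gene_p(snps, self.GENES)
        assert t.pvalues() == {"GA": pytest.approx(0.01)}

    def test_sidak_over_multiple_snps(self):
        snps = self._snps(
            [("rs1", "1", 100500, 0.01), ("rs2", "1", 101000, 0.5), ("rs3", "1", 102000, 0.9)]
        )
        t = snp_to_gene_p(snps, self.GENES)
        assert t.pvalues()["GA"] == pytest.approx(1 - 0.99**3)

    def test_snp_feeds_multiple_overlapping_genes(self):
        genes = pd.DataFrame(
            [
                {"gene": "GA", "chrom": "1", "start": 100000, "end": 110000},
                {"gene": "GB", "chrom": "1", "start": 105000, "end": 115000},
            ]
        )
        snps = self._snps([("rs1", "1", 106000, 0.02)])
        t = snp_to_gene_p(snps, genes)
        assert set(t.genes) == {"GA", "GB"}

    def test_gene_without_snps_omitted(self):
        genes = pd.DataFrame(
            [
                {"gene": "GA", "chrom": "1", "start": 100000, "end": 110000},
                {"gene": "GB", "chrom": "2", "start": 100000, "end": 110000},
            ]
        )
        snps = self._snps([("rs1", "1", 105000, 0.2)])
        t = snp_to_gene_p(snps, genes)
        assert t.genes == ["GA"]


def test_gene_report_structure():
    table = GeneScoreTable.from_pairs([("A", 0.01), ("B", 0.5), ("C", 0.9)])
    net = _net("A", ["A", "B"])
    scores = score_all_networks([net], [_wv(net, {"A": 0.3, "B": 0.3})], table)
    report = gene_report(scores, table).set_index("gene")
    assert report.at["A", "gene_rank"] == 1
    assert report.at["A", "best_network_id"] == "net:A"
    assert math.isnan(report.at["C", "network_percentile"])  # C is in no network
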