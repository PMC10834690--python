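"""TO-GCN construction: correlations, seed, leveling, attachment, diagnostic."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from togcn.data import ExpressionMatrix, PipelineConfig
from togcn.network import (
    assign_levels,
    attach_structural_genes,
    build_togcn,
    correlation_edges,
    determine_cutoffs,
    level_diagnostic,
    pairwise_pearson,
    select_seed_tf,
)


def _sm(rows: dict) -> ExpressionMatrix:
    return ExpressionMatrix(pd.DataFrame(rows, dtype=float).T)


class TestPairwisePearson:
    def test_perfect_linear(self):
        sm = _sm({"x": [1, 2, 3, 4, 5], "y": [2, 4, 6, 8, 10]})
        r = pairwise_pearson(sm, ["x"], ["y"])["r"].iloc[0]
        assert r == pytest.approx(1.0, abs=1e-12)

    def test_perfect_antilinear(self):
        sm = _sm({"x": [1, 2, 3, 4, 5], "y": [5, 4, 3, 2, 1]})
        r = pairwise_pearson(sm, ["x"], ["y"])["r"].iloc[0]
        assert r == pytest.approx(-1.0, abs=1e-12)

    def test_hand_computed_value(self):
        sm = _sm({"x": [1, 2, 3, 4, 5], "y": [2, 4, 5, 4, 5]})
        r = pairwise_pearson(sm, ["x"], ["y"])["r"].iloc[0]
        assert r == pytest.approx(6 / np.sqrt(60), abs=1e-12)

    def test_matches_two_pass_brute_force(self):
        rng = np.random.default_rng(42)
        x = rng.normal(10, 3, size=(30, 6))
        genes = [f"g{i}" for i in range(30)]
        sm = ExpressionMatrix(pd.DataFrame(np.abs(x), index=genes))
        out = pairwise_pearson(sm, genes, genes)
        vals = sm.values.to_numpy()
        lookup = {g: i for i, g in enumerate(genes)}

        def brute(a, b):
            xa, xb = vals[lookup[a]], vals[lookup[b]]
            ma, mb = xa.mean(), xb.mean()
            num = ((xa - ma) * (xb - mb)).sum()
            den = np.sqrt(((xa - ma) ** 2).sum() * ((xb - mb) ** 2).sum())
            return num / den

        for _, row in out.sample(200, random_state=0).iterrows():
            assert row["r"] == pytest.approx(brute(row["gene_a"], row["gene_b"]), abs=1e-12)

    def test_too_few_stages_rejected(self):
        sm = _sm({"x": [1, 2], "y": [2, 1]})
        with pytest.raises(ValueError, match="3 stages"):
            pairwise_pearson(sm, ["x"], ["y"])

    def test_constant_gene_excluded_with_warning(self):
        sm = _sm({"flat": [3, 3, 3, 3], "x": [1, 2, 3, 4]})
        with pytest.warns(UserWarning, match="constant"):
            out = pairwise_pearson(sm, ["flat", "x"], ["x"])
        assert set(out["gene_a"]) == {"x"}

    def test_sign_classification(self):
        sm = _sm({"x": [1, 2, 3, 4, 5], "y": [2, 4, 6, 8, 10], "z": [5, 4, 3, 2, 1]})
        corr = pairwise_pearson(sm, ["x"], ["y", "z"])
        cfg = PipelineConfig(pos_r_cutoff=0.8, neg_r_cutoff=-0.53)
        lab = correlation_edges(corr, cfg).set_index("gene_b")["sign_class"]
        assert lab["y"] == "positive" and lab["z"] == "negative"


class TestCutoffs:
    def test_fixed_cutoffs_returned_verbatim(self):
        sm = _sm({"a": [1, 2, 3, 4, 5], "b": [2, 1, 4, 3, 5]})
        cfg = PipelineConfig(pos_r_cutoff=0.8, neg_r_cutoff=-0.53)
        assert determine_cutoffs(sm, None, cfg) == (0.8, -0.53)
        cfg2 = PipelineConfig(pos_r_cutoff=0.85, neg_r_cutoff=-0.63)
        assert determine_cutoffs(sm, None, cfg2) == (0.85, -0.63)

    def test_permutation_calibration_controls_null_tail(self):
        rng = np.random.default_rng(0)
        genes = [f"g{i}" for i in range(60)]
        sm = ExpressionMatrix(
            pd.DataFrame(rng.gamma(3, 10, size=(60, 6)), index=genes)
        )
        cfg = PipelineConfig(rng_seed=1)
        pos, neg = determine_cutoffs(sm, target_null_tail=0.01, config=cfg,
                                     n_null_pairs=4000)
        assert 0 < pos <= 1 and -1 <= neg < 0
        # realized exceedance of the calibrated cutoff on fresh shuffles
        x = sm.values.to_numpy()
        r2 = np.random.default_rng(7)
        exceed = 0
        trials = 3000
        for _ in range(trials):
            i, j = r2.integers(60), r2.integers(60)
            a = x[i, r2.permutation(6)]
            b = x[j, r2.permutation(6)]
            exceed += np.corrcoef(a, b)[0, 1] >= pos
        assert exceed / trials <= 0.02


class TestSeedSelection:
    def test_single_decreasing_tf(self):
        sm = _sm({"t1": [10, 8, 6, 4, 2]})
        assert select_seed_tf(sm, ["t1"]) == "t1"

    def test_non_monotone_competitor_rejected(self):
        sm = _sm({"t1": [10, 8, 6, 4, 2], "t2": [3, 2, 9, 1, 1]})
        assert select_seed_tf(sm, ["t1", "t2"]) == "t1"

    def test_largest_first_stage_z_wins(self):
        sm = _sm({"t1": [10, 8, 6, 4, 2], "t2": [100, 10, 5, 2, 1]})
        # z1: 1.414 vs 1.99 (population sd over the TF's own profile)
        assert select_seed_tf(sm, ["t1", "t2"]) == "t2"

    def test_no_monotone_tf_errors_with_candidates(self):
        sm = _sm({"t1": [1, 5, 1, 5, 1], "t2": [2, 9, 2, 9, 2]})
        with pytest.raises(ValueError, match="nearest candidates"):
            select_seed_tf(sm, ["t1", "t2"], step_tolerance=0.0)

    def test_empty_tf_list_rejected(self, toy_expr):
        with pytest.raises(ValueError):
            select_seed_tf(toy_expr, [])


class TestAssignLevels:
    def test_seed_only(self):
        g = nx.Graph()
        g.add_node("S")
        levels, un = assign_levels(g, "S")
        assert levels == {"S": 1} and un == []

    def test_path_levels(self):
        g = nx.Graph([("S", "A"), ("A", "B")])
        levels, _ = assign_levels(g, "S")
        assert levels == {"S": 1, "A": 2, "B": 3}

    def test_triangle_shortest_path_wins(self):
        g = nx.Graph([("S", "A"), ("S", "B"), ("A", "B")])
        levels, _ = assign_levels(g, "S")
        assert levels == {"S": 1, "A": 2, "B": 2}

    def test_unreachable_reported(self):
        g = nx.Graph([("S", "A")])
        g.add_node("lonely")
        levels, un = assign_levels(g, "S")
        assert "lonely" not in levels and un == ["lonely"]

    def test_invariant_to_insertion_order(self):
        edges = [("S", "A"), ("A", "B"), ("S", "C"), ("C", "B"), ("B", "D")]
        g1 = nx.Graph(edges)
        g2 = nx.Graph(list(reversed(edges)))
        assert assign_levels(g1, "S")[0] == assign_levels(g2, "S")[0]

    def test_missing_seed_errors(self):
        with pytest.raises(KeyError):
            assign_levels(nx.Graph([("A", "B")]), "S")


class TestAttachment:
    def _corr(self, rows):
        return pd.DataFrame(rows, columns=["gene_a", "gene_b", "r"])

    def test_single_supporter(self):
        levels = {"tf3": 3}
        att, sup, un = attach_structural_genes(
            levels, self._corr([("tf3", "enz", 0.9)]), PipelineConfig()
        )
        assert att["enz"] == (3, "tf3", 0.9) and un == []

    def test_max_r_rule(self):
        levels = {"tf2": 2, "tf4": 4}
        att, *_ = attach_structural_genes(
            levels,
            self._corr([("tf2", "enz", 0.85), ("tf4", "enz", 0.95)]),
            PipelineConfig(),
        )
        assert att["enz"] == (4, "tf4", 0.95)

    def test_below_cutoff_unattached(self):
        levels = {"tf2": 2}
        att, sup, un = attach_structural_genes(
            levels, self._corr([("tf2", "enz", 0.5)]), PipelineConfig()
        )
        assert att == {} and un == ["enz"]


class TestDiagnosticAndBuild:
    def test_recovers_planted_levels(self, small_cascade, small_stage_means, small_params):
        counts, design, catalog, sites, truth = small_cascade
        cfg = small_params.analysis_config()
        net = build_togcn(small_stage_means, catalog.tf_ids, catalog.structural_ids, cfg)
        assert net.seed_tf == truth.seed_tf
        reach = [g for g in truth.tf_levels if g in net.levels]
        correct = sum(net.levels[g] == truth.tf_levels[g] for g in reach)
        assert correct / len(reach) >= 0.9

    def test_diagnostic_diagonal(self, small_cascade, small_stage_means, small_params):
        counts, design, catalog, sites, truth = small_cascade
        cfg = small_params.analysis_config()
        net = build_togcn(small_stage_means, catalog.tf_ids, catalog.structural_ids, cfg)
        diag, peaks = level_diagnostic(net, small_stage_means)
        assert list(diag.index) == list(range(1, net.n_levels + 1))
        seq = [peaks[l] for l in sorted(peaks)]
        assert seq == sorted(seq)

    def test_single_level_network(self):
        sm = _sm({"t1": [10, 8, 6, 4, 2], "e": [9, 7, 5, 3, 1]})
        from togcn.network import TOGCN

        net = TOGCN(
            seed_tf="t1", levels={"t1": 1},
            tf_edges=pd.DataFrame(columns=["gene_a", "gene_b", "r"]),
            neg_tf_edges=pd.DataFrame(columns=["gene_a", "gene_b", "r"]),
            attachments={}, support_edges=pd.DataFrame(columns=["tf", "structural", "r"]),
        )
        diag, peaks = level_diagnostic(net, sm)
        assert diag.shape == (1, 5) and peaks == {1: 1}

    def test_raising_cutoff_never_adds_edges(self, small_cascade, small_stage_means, small_params):
        counts, design, catalog, sites, truth = small_cascade
        lo = build_togcn(small_stage_means, catalog.tf_ids, catalog.structural_ids,
                         small_params.analysis_config())
        hi = build_togcn(small_stage_means, catalog.tf_ids, catalog.structural_ids,
                         small_params.analysis_config(pos_r_cutoff=0.6))
        assert len(hi.tf_edges) <= len(lo.tf_edges)
        assert len(hi.levels) <= len(lo.levels)

    def test_graph_export_has_all_members(self, small_cascade, small_stage_means, small_params):
        counts, design, catalog, sites, truth = small_cascade
        net = build_togcn(small_stage_means, catalog.tf_ids, catalog.structural_ids,
                          small_params.analysis_config())
        g = net.to_graph()
        for tf in net.levels:
            assert g.nodes[tf]["level"] == net.levels[tf]
        for enz, (lvl, best, r) in net.attachments.items():
            assert g.nodes[enz]["kind"] == "structural"
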