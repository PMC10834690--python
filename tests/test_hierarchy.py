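"""Phase subnetworks, regulator chains, binding-site validation, ranking."""

import itertools

import numpy as np
import pandas as pd
import pytest

from togcn.data import BindingSiteTable, GeneCatalog, PipelineConfig
from togcn.hierarchy import (
    chains_to_frame,
    extract_phase_subnetwork,
    filter_chains_by_binding_sites,
    infer_upstream_chains,
    rank_top_regulators,
    tf_family_census,
)
from togcn.network import TOGCN


def _toy_togcn(levels, tf_edges, support, attachments):
    return TOGCN(
        seed_tf=min(levels, key=levels.get),
        levels=levels,
        tf_edges=pd.DataFrame(tf_edges, columns=["gene_a", "gene_b", "r"]),
        neg_tf_edges=pd.DataFrame(columns=["gene_a", "gene_b", "r"]),
        attachments=attachments,
        support_edges=pd.DataFrame(support, columns=["tf", "structural", "r"]),
    )


def _catalog(rows):
    return GeneCatalog(pd.DataFrame(rows))


@pytest.fixture()
def toy_net():
    # S(1) - A(2) - B(3) - C(4); enzyme E attached at 4, supported by B and C
    levels = {"S": 1, "A": 2, "B": 3, "C": 4}
    tf_edges = [("S", "A", 0.9), ("A", "B", 0.85), ("B", "C", 0.83), ("S", "B", 0.81)]
    support = [("C", "E", 0.95), ("B", "E", 0.82)]
    return _toy_togcn(levels, tf_edges, support, {"E": (4, "C", 0.95)})


class TestPhaseSubnetwork:
    def _cat(self):
        return _catalog(
            {
                "gene_id": ["S", "A", "B", "C", "E", "F"],
                "is_tf": [True, True, True, True, False, False],
                "tf_family": ["MYB_related", "GRAS", "GRAS", "B3", "", ""],
                "enzyme_role": ["", "", "", "", "KCR", "ACCase"],
                "phase": ["", "", "", "", "elongation", "de_novo"],
            }
        )

    def test_induced_subnetwork(self, toy_net):
        sub = extract_phase_subnetwork(toy_net, self._cat(), "elongation")
        assert sub.structural_genes == ["E"]
        assert set(sub.tf_ids) == {"B", "C"}
        assert len(sub.tf_edges) == 1  # only B-C among member TFs

    def test_phase_without_attached_genes_is_empty(self, toy_net):
        sub = extract_phase_subnetwork(toy_net, self._cat(), "de_novo")
        assert sub.structural_genes == [] and sub.tf_ids == []

    def test_unknown_phase_rejected(self, toy_net):
        with pytest.raises(KeyError):
            extract_phase_subnetwork(toy_net, self._cat(), "mystery")

    def test_family_census_conserves_counts(self, toy_net):
        sub = extract_phase_subnetwork(toy_net, self._cat(), "elongation")
        census = tf_family_census(sub, self._cat())
        assert census["count"].sum() == len(sub.tf_ids)
        row = census.set_index("tf_family")
        assert row.loc["GRAS", "count"].sum() == 1
        assert row.loc["B3", "count"].sum() == 1

    def test_census_empty_subnetwork(self, toy_net):
        sub = extract_phase_subnetwork(toy_net, self._cat(), "de_novo")
        assert tf_family_census(sub, self._cat()).empty


class TestChainEnumeration:
    def test_direct_regulator_single_chain(self):
        net = _toy_togcn(
            {"A": 2, "T": 3},
            [("A", "T", 0.9)],
            [],
            {},
        )
        chains = infer_upstream_chains(net, "T", PipelineConfig(max_chain_order=1))
        assert len(chains) == 1
        assert chains[0].tfs == ("A",) and chains[0].order == 1

    def test_order3_chain_enumerated(self, toy_net):
        chains = infer_upstream_chains(toy_net, "E", PipelineConfig())
        paths = {c.path for c in chains}
        assert ("S", "A", "B", "E") in paths  # order 3 through the cascade
        assert ("S", "B", "C", "E") in paths
        for c in chains:
            assert list(c.levels) == sorted(set(c.levels)), "levels strictly increase"

    def test_truncation_at_order1(self, toy_net):
        chains = infer_upstream_chains(toy_net, "E", PipelineConfig(max_chain_order=1))
        assert {c.path for c in chains} == {("B", "E"), ("C", "E")}

    def test_adjacent_only_switch(self, toy_net):
        # S(1)-B(3) edge skips level 2; adjacent_only must exclude paths using it
        all_chains = infer_upstream_chains(toy_net, "E", PipelineConfig())
        adj_chains = infer_upstream_chains(
            toy_net, "E", PipelineConfig(), adjacent_only=True
        )
        assert ("S", "B", "E") in {c.path for c in all_chains}
        assert ("S", "B", "E") not in {c.path for c in adj_chains}

    def test_unattached_target_rejected(self, toy_net):
        with pytest.raises(KeyError):
            infer_upstream_chains(toy_net, "nope", PipelineConfig())

    def test_matches_brute_force_on_random_leveled_graphs(self):
        rng = np.random.default_rng(0)
        cfg = PipelineConfig(max_chain_order=3)
        for trial in range(25):
            n = int(rng.integers(5, 12))
            tfs = [f"t{i}" for i in range(n)]
            levels = {t: int(rng.integers(1, 6)) for t in tfs}
            edges = []
            for a, b in itertools.combinations(tfs, 2):
                if levels[a] != levels[b] and rng.random() < 0.45:
                    edges.append((a, b, float(rng.uniform(0.8, 1.0))))
            target = "enz"
            supporters = [t for t in tfs if rng.random() < 0.4] or [tfs[0]]
            support = [(t, target, float(rng.uniform(0.8, 1.0))) for t in supporters]
            net = _toy_togcn(levels, edges, support,
                             {target: (max(levels.values()), supporters[0], 0.9)})
            got = {c.path for c in infer_upstream_chains(net, target, cfg)}

            # brute force: depth-limited simple paths with strictly
            # increasing levels, enumerated over all TF orderings
            adj = {t: set() for t in tfs}
            for a, b, _ in edges:
                adj[a].add(b)
                adj[b].add(a)
            expect = set()
            for s in supporters:
                stack = [(s,)]
                while stack:
                    path = stack.pop()
                    expect.add(tuple(reversed(path)) + (target,))
                    if len(path) < cfg.max_chain_order:
                        for nxt in adj[path[-1]]:
                            if nxt not in path and levels[nxt] < levels[path[-1]]:
                                stack.append(path + (nxt,))
            assert got == expect, f"trial {trial} mismatch"


class TestValidationAndRanking:
    def _chains(self, toy_net):
        return infer_upstream_chains(toy_net, "E", PipelineConfig())

    def test_fully_supported_chain_validated(self, toy_net):
        sites = BindingSiteTable(
            pd.DataFrame(
                {"tf_gene_id": ["S", "A", "B"], "target_gene_id": ["A", "B", "E"]}
            )
        )
        chains = filter_chains_by_binding_sites(self._chains(toy_net), sites)
        by_path = {c.path: c for c in chains}
        assert by_path[("S", "A", "B", "E")].validated

    def test_missing_last_site_flags(self, toy_net):
        sites = BindingSiteTable(
            pd.DataFrame({"tf_gene_id": ["S", "A"], "target_gene_id": ["A", "B"]})
        )
        chains = filter_chains_by_binding_sites(self._chains(toy_net), sites)
        c = {c.path: c for c in chains}[("S", "A", "B", "E")]
        assert c.site_flags == (True, True, False) and not c.validated

    def test_adding_decoys_never_unvalidates(self, toy_net):
        base = BindingSiteTable(
            pd.DataFrame({"tf_gene_id": ["S", "A", "B"], "target_gene_id": ["A", "B", "E"]})
        )
        more = BindingSiteTable(
            pd.concat(
                [base.table,
                 pd.DataFrame({"tf_gene_id": ["C", "B"], "target_gene_id": ["E", "C"]})],
                ignore_index=True,
            )
        )
        v1 = {c.path for c in filter_chains_by_binding_sites(self._chains(toy_net), base) if c.validated}
        v2 = {c.path for c in filter_chains_by_binding_sites(self._chains(toy_net), more) if c.validated}
        assert v1 <= v2

    def test_ranking_by_validated_count(self, toy_net):
        sites = BindingSiteTable(
            pd.DataFrame(
                {
                    "tf_gene_id": ["S", "A", "B", "S", "B", "C"],
                    "target_gene_id": ["A", "B", "E", "B", "C", "E"],
                }
            )
        )
        chains = filter_chains_by_binding_sites(self._chains(toy_net), sites)
        rank = rank_top_regulators(chains)
        assert rank["tf"].iloc[0] == "S"  # roots the most validated chains
        assert rank["n_validated_chains"].iloc[0] >= rank["n_validated_chains"].iloc[-1]

    def test_empty_input_empty_ranking(self):
        assert rank_top_regulators([]).empty

    def test_validated_chain_edges_subset_of_positive_edges(
        self, small_cascade, small_stage_means, small_params
    ):
        from togcn.network import build_togcn

        counts, design, catalog, sites, truth = small_cascade
        cfg = small_params.analysis_config()
        net = build_togcn(small_stage_means, catalog.tf_ids, catalog.structural_ids, cfg)
        pos_pairs = set()
        for a, b in zip(net.tf_edges["gene_a"], net.tf_edges["gene_b"]):
            pos_pairs |= {(a, b), (b, a)}
        targets = sorted(net.attachments)[:5]
        chains = []
        for t in targets:
            chains.extend(infer_upstream_chains(net, t, cfg))
        chains = filter_chains_by_binding_sites(chains, sites)
        for c in chains:
            if c.validated:
                for i in range(len(c.tfs) - 1):
                    assert (c.tfs[i], c.tfs[i + 1]) in pos_pairs

    def test_chain_frame_round_trip_fields(self, toy_net):
        chains = filter_chains_by_binding_sites(
            self._chains(toy_net),
            BindingSiteTable(pd.DataFrame({"tf_gene_id": ["B"], "target_gene_id": ["E"]})),
        )
        frame = chains_to_frame(chains)
        assert len(frame) == len(chains)
        assert (frame["order"] == [c.order for c in chains]).all()
        assert all(p.count(";") == c.order for p, c in zip(frame["path"], chains))
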