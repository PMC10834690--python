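"""Hierarchical regulator chains and phase-specific subnetworks.

A regulatory chain of order k is a path of k TFs with strictly
increasing network levels (earlier-peaking regulators upstream),
connected by positive co-expression edges, ending at a target gene
through a positive supporting edge. A chain is *validated* when every
regulator -> immediate-downstream pair carries a predicted binding site
in the downstream gene's promoter. Top-tier regulators are ranked by
how many validated chains they root.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field, replace

import networkx as nx
import pandas as pd

from .data import BindingSiteTable, GeneCatalog, PipelineConfig
from .network import TOGCN

__all__ = [
    "RegulatoryChain",
    "SubnetworkSummary",
    "extract_phase_subnetwork",
    "tf_family_census",
    "infer_upstream_chains",
    "filter_chains_by_binding_sites",
    "rank_top_regulators",
    "chains_to_frame",
]


@dataclass(frozen=True)
class RegulatoryChain:
    """An ordered root -> ... -> direct regulator -> target path."""

    tfs: tuple[str, ...]
    target: str
    levels: tuple[int, ...]  # levels of the TFs
    edge_r: tuple[float, ...]  # per hop, including TF -> target
    site_flags: tuple[bool, ...] = ()
    validated: bool = False

    @property
    def order(self) -> int:
        return len(self.tfs)

    @property
    def root(self) -> str:
        return self.tfs[0]

    @property
    def path(self) -> tuple[str, ...]:
        return self.tfs + (self.target,)


@dataclass
class SubnetworkSummary:
    """Induced phase subnetwork: enzymes of one biosynthesis phase, the
    TFs supporting them, and TF-TF edges among those TFs."""

    phase: str
    structural_genes: list[str]
    tfs: pd.DataFrame  # gene_id, level, tf_family
    tf_edges: pd.DataFrame
    support_edges: pd.DataFrame

    @property
    def tf_ids(self) -> list[str]:
        return list(self.tfs["gene_id"])


def extract_phase_subnetwork(
    togcn: TOGCN, catalog: GeneCatalog, phase: str
) -> SubnetworkSummary:
    """Induced subnetwork on the attached structural genes of one phase."""
    phase_genes = set(catalog.genes_in_phase(phase))  # raises on unknown phase
    members = sorted(g for g in togcn.attachments if g in phase_genes)
    sup = togcn.support_edges[togcn.support_edges["structural"].isin(members)]
    tfs = sorted(set(sup["tf"]))
    tf_table = pd.DataFrame(
        {
            "gene_id": tfs,
            "level": [togcn.levels.get(t) for t in tfs],
            "tf_family": [catalog.tf_family(t) for t in tfs],
        }
    )
    tf_set = set(tfs)
    edges = togcn.tf_edges[
        togcn.tf_edges["gene_a"].isin(tf_set) & togcn.tf_edges["gene_b"].isin(tf_set)
    ]
    return SubnetworkSummary(
        phase=phase,
        structural_genes=members,
        tfs=tf_table,
        tf_edges=edges.reset_index(drop=True),
        support_edges=sup.reset_index(drop=True),
    )


def tf_family_census(
    subnetwork: SubnetworkSummary, catalog: GeneCatalog
) -> pd.DataFrame:
    """Counts of member TFs per (family, level); empty family -> 'unassigned'."""
    if subnetwork.tfs.empty:
        return pd.DataFrame(columns=["tf_family", "level", "count"])
    t = subnetwork.tfs.copy()
    t["tf_family"] = t["tf_family"].replace("", "unassigned")
    out = (
        t.groupby(["tf_family", "level"], dropna=False)
        .size()
        .reset_index(name="count")
        .sort_values(["tf_family", "level"])
        .reset_index(drop=True)
    )
    return out


# ---------------------------------------------------------------------------
# chains
# ---------------------------------------------------------------------------


def _chain_index(togcn: TOGCN) -> tuple[dict, dict, dict]:
    """(positive TF adjacency, edge-r lookup, supporters per structural
    gene), computed once per network and cached on the object."""
    cached = getattr(togcn, "_chain_index_cache", None)
    if cached is not None:
        return cached
    adj: dict[str, set[str]] = defaultdict(set)
    rlook: dict[tuple[str, str], float] = {}
    for a, b, r in zip(togcn.tf_edges["gene_a"], togcn.tf_edges["gene_b"],
                       togcn.tf_edges["r"]):
        adj[a].add(b)
        adj[b].add(a)
        rlook[(a, b)] = rlook[(b, a)] = float(r)
    supporters: dict[str, list[str]] = defaultdict(list)
    for tf, st, r in zip(togcn.support_edges["tf"], togcn.support_edges["structural"],
                         togcn.support_edges["r"]):
        rlook[(tf, st)] = float(r)
        supporters[st].append(tf)
    for st in supporters:
        supporters[st].sort()
    # sorted neighbour lists give deterministic enumeration order
    adj_sorted = {k: sorted(v) for k, v in adj.items()}
    togcn._chain_index_cache = (adj_sorted, rlook, dict(supporters))
    return togcn._chain_index_cache


def infer_upstream_chains(
    togcn: TOGCN,
    target_gene: str,
    config: PipelineConfig | None = None,
    adjacent_only: bool = False,
) -> list[RegulatoryChain]:
    """Enumerate all simple upstream chains of order 1..max_chain_order.

    The target must be an attached structural gene (its supporters are
    the TFs with a positive supporting edge) or a leveled TF (its
    supporters are its positive neighbours of strictly lower level).
    Consecutive chain TFs must share a positive edge and strictly
    increase in level (exactly +1 with ``adjacent_only``). Chains are
    returned in deterministic order (root id, then path).
    """
    config = config or PipelineConfig()
    adj, rlook, supp = _chain_index(togcn)
    levels = togcn.levels

    if target_gene in togcn.attachments:
        supporters = supp.get(target_gene, [])
    elif target_gene in levels:
        target_level = levels[target_gene]
        supporters = [
            t for t in adj.get(target_gene, [])
            if levels.get(t, 10**9) < target_level
        ]
    else:
        raise KeyError(
            f"target {target_gene!r} is neither an attached structural gene nor a leveled TF"
        )

    chains: list[RegulatoryChain] = []
    max_order = config.max_chain_order

    def extend(path: list[str]) -> None:
        """path is ordered downstream -> upstream; path[0] supports the target."""
        chains.append(_finalize(path))
        if len(path) >= max_order:
            return
        head = path[-1]
        head_level = levels[head]
        for nxt in adj.get(head, ()):
            lvl = levels.get(nxt)
            if lvl is None or lvl >= head_level:
                continue
            if adjacent_only and head_level - lvl != 1:
                continue
            if nxt in path:
                continue
            extend(path + [nxt])

    def _finalize(path: list[str]) -> RegulatoryChain:
        ordered = tuple(reversed(path))  # root first
        edge_r = tuple(
            rlook[(ordered[i], ordered[i + 1])] for i in range(len(ordered) - 1)
        ) + (rlook[(ordered[-1], target_gene)],)
        return RegulatoryChain(
            tfs=ordered,
            target=target_gene,
            levels=tuple(levels[t] for t in ordered),
            edge_r=edge_r,
        )

    for s in supporters:
        if s in levels:
            extend([s])
    chains.sort(key=lambda c: (c.root, c.path))
    return chains


def filter_chains_by_binding_sites(
    chains: list[RegulatoryChain], sites: BindingSiteTable
) -> list[RegulatoryChain]:
    """Flag each hop by binding-site presence; validated = all hops flagged."""
    out = []
    for c in chains:
        nodes = c.path
        flags = tuple((nodes[i], nodes[i + 1]) in sites for i in range(len(nodes) - 1))
        out.append(replace(c, site_flags=flags, validated=all(flags)))
    return out


def rank_top_regulators(chains: list[RegulatoryChain]) -> pd.DataFrame:
    """Rank root TFs by number of validated chains they root.

    Ties break on summed edge r (descending), then gene id. Returns a
    DataFrame (tf, n_validated_chains, sum_r) in rank order.
    """
    score: dict[str, int] = defaultdict(int)
    sum_r: dict[str, float] = defaultdict(float)
    for c in chains:
        if c.validated:
            score[c.root] += 1
            sum_r[c.root] += float(sum(c.edge_r))
    rows = sorted(score, key=lambda t: (-score[t], -sum_r[t], t))
    return pd.DataFrame(
        {
            "tf": rows,
            "n_validated_chains": [score[t] for t in rows],
            "sum_r": [sum_r[t] for t in rows],
        }
    )


def chains_to_frame(chains: list[RegulatoryChain]) -> pd.DataFrame:
    """One row per chain, semicolon-joined path, for TSV export."""
    return pd.DataFrame(
        {
            "root": [c.root for c in chains],
            "target": [c.target for c in chains],
            "order": [c.order for c in chains],
            "path": [";".join(c.path) for c in chains],
            "levels": [";".join(map(str, c.levels)) for c in chains],
            "edge_r": [";".join(f"{r:.4f}" for r in c.edge_r) for c in chains],
            "site_flags": [
                ";".join("1" if f else "0" for f in c.site_flags) for c in chains
            ],
            "validated": [c.validated for c in chains],
        }
    )
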