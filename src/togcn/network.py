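"""Time-ordered gene co-expression network construction.

Pipeline: Pearson correlation of stage-mean profiles -> signed edge
classification at per-tissue cutoffs -> seed TF selection (highest and
monotonically declining first-stage expression) -> breadth-first level
assignment in the positive TF-TF graph -> attachment of enzyme
("structural") genes at the level of their best-correlated TF -> a
level x stage z-score diagnostic whose peak stages should tile the
diagonal when the network is genuinely time-ordered.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .data import ExpressionMatrix, PipelineConfig

__all__ = [
    "TOGCN",
    "pairwise_pearson",
    "correlation_edges",
    "determine_cutoffs",
    "select_seed_tf",
    "assign_levels",
    "attach_structural_genes",
    "level_diagnostic",
    "build_togcn",
]


@dataclass
class TOGCN:
    """A leveled co-expression network.

    ``levels`` maps each reachable TF to its level (seed at 1);
    ``tf_edges`` holds positive-class TF-TF edges; ``neg_tf_edges``
    records negative-class TF-TF pairs (exported, not used for
    leveling); ``attachments`` maps each attached structural gene to
    (level, best supporting TF, r); ``support_edges`` keeps every
    positive TF-structural edge.
    """

    seed_tf: str
    levels: dict[str, int]
    tf_edges: pd.DataFrame  # gene_a, gene_b, r
    neg_tf_edges: pd.DataFrame
    attachments: dict[str, tuple[int, str, float]]
    support_edges: pd.DataFrame  # tf, structural, r
    unleveled_tfs: list[str] = field(default_factory=list)
    unattached_structural: list[str] = field(default_factory=list)
    pos_cutoff: float = 0.8
    neg_cutoff: float = -0.53

    @property
    def n_levels(self) -> int:
        return max(self.levels.values()) if self.levels else 0

    def members_at_level(self, level: int) -> list[str]:
        tfs = sorted(g for g, l in self.levels.items() if l == level)
        struct = sorted(g for g, (l, _, _) in self.attachments.items() if l == level)
        return tfs + struct

    def to_graph(self) -> nx.Graph:
        """Full network as an undirected graph with node/edge attributes."""
        g = nx.Graph()
        for tf, lvl in self.levels.items():
            g.add_node(tf, kind="tf", level=lvl)
        for gene, (lvl, best, r) in self.attachments.items():
            g.add_node(gene, kind="structural", level=lvl, best_tf=best, best_r=float(r))
        for _, row in self.tf_edges.iterrows():
            g.add_edge(row["gene_a"], row["gene_b"], r=float(row["r"]), sign_class="positive")
        for _, row in self.neg_tf_edges.iterrows():
            g.add_edge(row["gene_a"], row["gene_b"], r=float(row["r"]), sign_class="negative")
        for _, row in self.support_edges.iterrows():
            g.add_edge(row["tf"], row["structural"], r=float(row["r"]), sign_class="positive")
        return g


# ---------------------------------------------------------------------------
# correlations
# ---------------------------------------------------------------------------


def _stage_profiles(stage_means: ExpressionMatrix, genes: list[str]) -> np.ndarray:
    missing = [g for g in genes if g not in stage_means.values.index]
    if missing:
        raise KeyError(f"genes missing from stage means: {missing[:5]}")
    return stage_means.values.loc[genes].to_numpy(dtype=float)


def pairwise_pearson(
    stage_means: ExpressionMatrix,
    genes_a: list[str],
    genes_b: list[str],
) -> pd.DataFrame:
    """Pearson correlation between every (a, b) gene pair over stages.

    Requires >= 3 stages. Genes with a constant stage profile have no
    defined correlation; their pairs are dropped with a warning.
    Returns a long DataFrame (gene_a, gene_b, r).
    """
    if stage_means.shape[1] < 3:
        raise ValueError("pairwise_pearson needs at least 3 stages")
    xa = _stage_profiles(stage_means, genes_a)
    xb = _stage_profiles(stage_means, genes_b)
    sd_a = xa.std(axis=1)
    sd_b = xb.std(axis=1)
    const_a = [g for g, s in zip(genes_a, sd_a) if s == 0]
    const_b = [g for g, s in zip(genes_b, sd_b) if s == 0]
    if const_a or const_b:
        warnings.warn(
            f"excluding constant-profile genes from correlation: "
            f"{(const_a + const_b)[:5]}",
            stacklevel=2,
        )
    keep_a = [i for i, s in enumerate(sd_a) if s > 0]
    keep_b = [i for i, s in enumerate(sd_b) if s > 0]
    if not keep_a or not keep_b:
        return pd.DataFrame(columns=["gene_a", "gene_b", "r"])
    za = xa[keep_a] - xa[keep_a].mean(axis=1, keepdims=True)
    zb = xb[keep_b] - xb[keep_b].mean(axis=1, keepdims=True)
    za /= np.linalg.norm(za, axis=1, keepdims=True)
    zb /= np.linalg.norm(zb, axis=1, keepdims=True)
    r = np.clip(za @ zb.T, -1.0, 1.0)
    ia, ib = np.meshgrid(keep_a, keep_b, indexing="ij")
    return pd.DataFrame(
        {
            "gene_a": [genes_a[i] for i in ia.ravel()],
            "gene_b": [genes_b[i] for i in ib.ravel()],
            "r": r.ravel(),
        }
    )


def correlation_edges(corr: pd.DataFrame, config: PipelineConfig) -> pd.DataFrame:
    """Classify correlations as positive / negative / none at the cutoffs."""
    out = corr.copy()
    out["sign_class"] = np.where(
        out["r"] >= config.pos_r_cutoff,
        "positive",
        np.where(out["r"] <= config.neg_r_cutoff, "negative", "none"),
    )
    return out


def determine_cutoffs(
    stage_means: ExpressionMatrix,
    target_null_tail: float | None = None,
    config: PipelineConfig | None = None,
    n_null_pairs: int = 20_000,
    rng_seed: int | None = None,
) -> tuple[float, float]:
    """Correlation cutoffs: fixed configuration values, or an opt-in
    permutation calibration.

    When ``target_null_tail`` is None the configured (published) cutoffs
    are returned verbatim. Otherwise each gene's stage order is shuffled
    independently and the cutoffs are set at the null tail quantiles.
    With very few stages the permutation null is coarse; if it is
    degenerate (all |r| = 1) the fixed cutoffs are returned with a
    warning.
    """
    config = config or PipelineConfig()
    if stage_means.shape[1] < 3:
        raise ValueError("determine_cutoffs needs at least 3 stages")
    if target_null_tail is None:
        return config.pos_r_cutoff, config.neg_r_cutoff
    rng = np.random.default_rng(config.rng_seed if rng_seed is None else rng_seed)
    x = stage_means.values.to_numpy(dtype=float)
    x = x[x.std(axis=1) > 0]
    if len(x) < 2:
        warnings.warn("too few variable genes for calibration; using fixed cutoffs",
                      stacklevel=2)
        return config.pos_r_cutoff, config.neg_r_cutoff
    n_genes, t = x.shape
    rs = np.empty(n_null_pairs)
    for k in range(n_null_pairs):
        i, j = rng.integers(n_genes), rng.integers(n_genes)
        a = x[i, rng.permutation(t)]
        b = x[j, rng.permutation(t)]
        denom = a.std() * b.std()
        rs[k] = 0.0 if denom == 0 else np.corrcoef(a, b)[0, 1]
    if np.all(np.abs(rs) > 0.999):
        warnings.warn("degenerate permutation null; using fixed cutoffs", stacklevel=2)
        return config.pos_r_cutoff, config.neg_r_cutoff
    pos = float(np.quantile(rs, 1.0 - target_null_tail))
    neg = float(np.quantile(rs, target_null_tail))
    return pos, min(neg, -1e-9)


# ---------------------------------------------------------------------------
# seed, levels, attachments
# ---------------------------------------------------------------------------


def select_seed_tf(
    stage_means: ExpressionMatrix,
    tf_ids: list[str],
    step_tolerance: float = 0.3,
) -> str:
    """Pick the level-1 anchor TF.

    Among TFs whose stage-mean profile never increases between
    consecutive stages by more than ``step_tolerance`` times the
    profile's dynamic range (a relative tolerance that absorbs
    replicate noise), return the one with the largest first-stage
    z-score (z over the TF's own profile, population sd); ties break on
    gene id.
    """
    if not tf_ids:
        raise ValueError("no TFs supplied")
    x = _stage_profiles(stage_means, list(tf_ids))
    sd = x.std(axis=1)
    steps = np.diff(x, axis=1)
    span = x.max(axis=1) - x.min(axis=1)
    monotone = np.all(steps <= step_tolerance * span[:, None], axis=1) & (sd > 0)
    if not monotone.any():
        # report nearest candidates by worst violating step
        worst = steps.max(axis=1)
        order = np.argsort(worst)
        near = [tf_ids[i] for i in order[:5]]
        raise ValueError(
            f"no TF with a monotonically decreasing profile; nearest candidates: {near}"
        )
    z1 = (x[:, 0] - x.mean(axis=1)) / np.where(sd > 0, sd, np.inf)
    candidates = sorted(
        ((-z1[i], tf_ids[i]) for i in range(len(tf_ids)) if monotone[i])
    )
    return candidates[0][1]


def assign_levels(tf_positive_graph: nx.Graph, seed_tf: str) -> tuple[dict[str, int], list[str]]:
    """Breadth-first layering: level = 1 + shortest-path distance from seed.

    Returns (levels, unreachable TFs). Deterministic: depends only on
    the graph's edge set, not on node insertion order.
    """
    if seed_tf not in tf_positive_graph:
        raise KeyError(f"seed TF {seed_tf!r} absent from graph")
    dist = nx.single_source_shortest_path_length(tf_positive_graph, seed_tf)
    levels = {g: d + 1 for g, d in dist.items()}
    unreachable = sorted(set(tf_positive_graph.nodes) - set(levels))
    return levels, unreachable


def attach_structural_genes(
    levels: dict[str, int],
    tf_structural_corr: pd.DataFrame,
    config: PipelineConfig,
) -> tuple[dict[str, tuple[int, str, float]], pd.DataFrame, list[str]]:
    """Attach each structural gene at the level of its best-correlated TF.

    ``tf_structural_corr`` is long form (gene_a=TF, gene_b=structural, r).
    Only positive-class correlations (r >= pos cutoff) to leveled TFs
    count as support. Returns (attachments, support edge table,
    unattached genes).
    """
    sup = tf_structural_corr[
        (tf_structural_corr["r"] >= config.pos_r_cutoff)
        & tf_structural_corr["gene_a"].isin(levels)
    ].copy()
    sup = sup.rename(columns={"gene_a": "tf", "gene_b": "structural"})
    attachments: dict[str, tuple[int, str, float]] = {}
    for gene, rows in sup.groupby("structural"):
        # max r; deterministic tie-break on TF id
        best = rows.sort_values(["r", "tf"], ascending=[False, True]).iloc[0]
        attachments[str(gene)] = (levels[best["tf"]], str(best["tf"]), float(best["r"]))
    all_struct = sorted(tf_structural_corr["gene_b"].unique())
    unattached = [g for g in all_struct if g not in attachments]
    return attachments, sup.reset_index(drop=True), unattached


def level_diagnostic(
    togcn: TOGCN, stage_means: ExpressionMatrix
) -> tuple[pd.DataFrame, dict[int, int]]:
    """Average z-scored stage profile per level, plus each level's peak stage.

    Each member gene's profile (leveled TFs and attached structural
    genes) is z-scored over stages (population sd); constant profiles
    are excluded. Empty levels yield NaN rows.
    """
    n_stages = togcn_stage_count = stage_means.shape[1]
    rows = {}
    peaks: dict[int, int] = {}
    for lvl in range(1, togcn.n_levels + 1):
        members = [g for g in togcn.members_at_level(lvl) if g in stage_means.values.index]
        profiles = []
        for g in members:
            x = stage_means.values.loc[g].to_numpy(dtype=float)
            sd = x.std()
            if sd > 0:
                profiles.append((x - x.mean()) / sd)
        if profiles:
            mean_z = np.mean(profiles, axis=0)
            peaks[lvl] = int(np.argmax(mean_z)) + 1
        else:
            mean_z = np.full(n_stages, np.nan)
        rows[lvl] = mean_z
    mat = pd.DataFrame.from_dict(rows, orient="index", columns=stage_means.sample_ids)
    mat.index.name = "level"
    return mat, peaks


# ---------------------------------------------------------------------------
# end-to-end construction
# ---------------------------------------------------------------------------


def build_togcn(
    stage_means: ExpressionMatrix,
    tf_ids: list[str],
    structural_ids: list[str],
    config: PipelineConfig,
    seed_tf: str | None = None,
) -> TOGCN:
    """Construct the full leveled network from stage-mean expression."""
    tf_ids = [g for g in tf_ids if g in stage_means.values.index]
    structural_ids = [g for g in structural_ids if g in stage_means.values.index]
    tt = pairwise_pearson(stage_means, tf_ids, tf_ids)
    tt = tt[tt["gene_a"] < tt["gene_b"]]  # unordered pairs once
    pos = tt[tt["r"] >= config.pos_r_cutoff].reset_index(drop=True)
    neg = tt[tt["r"] <= config.neg_r_cutoff].reset_index(drop=True)
    graph = nx.Graph()
    graph.add_nodes_from(tf_ids)
    graph.add_edges_from(zip(pos["gene_a"], pos["gene_b"]))
    if seed_tf is None:
        # escalate the monotonicity tolerance if replicate noise leaves no
        # strictly qualifying candidate
        for tol in (0.3, 0.6):
            try:
                seed_tf = select_seed_tf(stage_means, tf_ids, step_tolerance=tol)
                break
            except ValueError:
                continue
        if seed_tf is None:
            seed_tf = select_seed_tf(stage_means, tf_ids, step_tolerance=np.inf)
    levels, unreachable = assign_levels(graph, seed_tf)
    # drop edges not among leveled TFs? keep all positive edges; levels cover reachable set
    if structural_ids:
        ts = pairwise_pearson(stage_means, tf_ids, structural_ids)
        attachments, support, unattached = attach_structural_genes(levels, ts, config)
    else:
        attachments, support, unattached = {}, pd.DataFrame(columns=["tf", "structural", "r"]), []
    return TOGCN(
        seed_tf=seed_tf,
        levels=levels,
        tf_edges=pos.rename(columns=str),
        neg_tf_edges=neg,
        attachments=attachments,
        support_edges=support,
        unleveled_tfs=unreachable,
        unattached_structural=unattached,
        pos_cutoff=config.pos_r_cutoff,
        neg_cutoff=config.neg_r_cutoff,
    )
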