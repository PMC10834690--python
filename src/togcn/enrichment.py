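"""Hypergeometric term enrichment and genomic cluster detection.

Enrichment: one-sided upper-tail hypergeometric test per term against a
user-supplied universe, BH-corrected. Clustering: single-linkage along
each chromosome with a base-pair gap threshold between successive gene
starts; descriptive (no significance test is attached to clusters).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .data import GeneCatalog, PipelineConfig
from .diffexpr import benjamini_hochberg

__all__ = ["hypergeometric_enrichment", "detect_genomic_clusters"]


def hypergeometric_enrichment(
    study_genes,
    term_to_genes: dict,
    universe,
    config: PipelineConfig | None = None,
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of each term in the study set.

    p = P(X >= k) with X ~ Hypergeom(N=|universe|, K=|term|, n=|study|),
    terms intersected with the universe first. Returns one row per term
    (term, k, K, n, N, p_value, adj_p, significant), sorted by p.
    """
    config = config or PipelineConfig()
    universe = set(universe)
    study = set(study_genes)
    outside = sorted(study - universe)
    if outside:
        raise ValueError(f"study genes outside the universe: {outside[:5]}")
    N, n = len(universe), len(study)
    rows = []
    for term in sorted(term_to_genes):
        members = set(term_to_genes[term]) & universe
        K = len(members)
        if K == 0:
            continue
        k = len(members & study)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append({"term": term, "k": k, "K": K, "n": n, "N": N,
                     "p_value": min(p, 1.0)})
    if not rows:
        return pd.DataFrame(
            columns=["term", "k", "K", "n", "N", "p_value", "adj_p", "significant"]
        )
    out = pd.DataFrame(rows)
    out["adj_p"] = benjamini_hochberg(out["p_value"].to_numpy())
    out["significant"] = out["adj_p"] < config.fdr_cutoff
    return out.sort_values(["p_value", "term"]).reset_index(drop=True)


def detect_genomic_clusters(
    catalog: GeneCatalog,
    pathway_genes,
    config: PipelineConfig | None = None,
) -> pd.DataFrame:
    """Single-linkage positional clusters of pathway genes.

    Per chromosome, genes are sorted by start; successive genes whose
    start-to-start gap is at most ``cluster_max_gap_bp`` join one
    cluster; clusters with at least ``cluster_min_genes`` members are
    reported. Genes without coordinates are skipped with a warning.
    Returns (chrom, start, end, n_genes, members) with 1-based
    inclusive coordinates and semicolon-joined member ids.
    """
    import warnings

    config = config or PipelineConfig()
    t = catalog.table
    rows = []
    skipped = []
    for g in pathway_genes:
        if g not in t.index or int(t.at[g, "start0"]) < 0 or str(t.at[g, "chrom"]) == "":
            skipped.append(g)
            continue
        rows.append((str(t.at[g, "chrom"]), int(t.at[g, "start0"]), int(t.at[g, "end0"]), g))
    if skipped:
        warnings.warn(
            f"{len(skipped)} pathway genes lack coordinates and were skipped "
            f"(e.g. {skipped[:3]})",
            stacklevel=2,
        )
    clusters = []
    df = pd.DataFrame(rows, columns=["chrom", "start0", "end0", "gene_id"])
    for chrom, sub in df.groupby("chrom"):
        sub = sub.sort_values(["start0", "gene_id"])
        current: list[tuple[int, int, str]] = []
        prev_start = None
        for _, row in sub.iterrows():
            if prev_start is not None and row["start0"] - prev_start > config.cluster_max_gap_bp:
                clusters.append((chrom, current))
                current = []
            current.append((row["start0"], row["end0"], row["gene_id"]))
            prev_start = row["start0"]
        if current:
            clusters.append((chrom, current))
    out = []
    for chrom, members in clusters:
        if len(members) < config.cluster_min_genes:
            continue
        out.append(
            {
                "chrom": chrom,
                "start": members[0][0] + 1,  # back to 1-based inclusive
                "end": max(e for _, e, _ in members),
                "n_genes": len(members),
                "members": ";".join(g for _, _, g in members),
            }
        )
    return (
        pd.DataFrame(out, columns=["chrom", "start", "end", "n_genes", "members"])
        .sort_values(["chrom", "start"])
        .reset_index(drop=True)
    )
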