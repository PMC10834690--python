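"""Negative-binomial differential expression over time points and tissues.

A deliberately transparent NB Wald test: median-of-ratios size factors;
per-gene method-of-moments dispersion moderated by the pooled
(matrix-wide) dispersion — each gene uses the larger of its own and the
pooled estimate, which protects against the severe variance
underestimation that 2-3 replicates produce; log2 fold change of
normalized group means with a 0.5 pseudocount; and a Wald statistic
referred to a t distribution whose degrees of freedom are the residual
df plus a moderation credit for the pooled prior. This is not a DESeq2
re-implementation (no trended shrinkage, no outlier filtering);
downstream network construction only needs a DEG set with honest
FDR / fold-change semantics.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .data import ExpressionMatrix, PipelineConfig, SampleDesign, stage_mean_matrix

__all__ = [
    "benjamini_hochberg",
    "nb_differential_expression",
    "pairwise_timepoint_degs",
    "low_expression_filter",
    "tissue_specific_sets",
]

_DISPERSION_FLOOR = 1e-8
_MODERATION_PRIOR_DF = 4  # information credited to the pooled dispersion prior


def benjamini_hochberg(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def median_of_ratios_size_factors(counts: pd.DataFrame) -> pd.Series:
    """DESeq-style size factors: median across genes of each sample's
    ratio to the per-gene geometric mean (genes with any zero excluded)."""
    logc = np.log(counts.where(counts > 0))
    log_geomean = logc.mean(axis=1)
    usable = log_geomean.notna() & np.isfinite(log_geomean)
    if not usable.any():
        # degenerate matrix: fall back to library-size normalization
        tot = counts.sum(axis=0).astype(float)
        return tot / np.exp(np.log(tot.replace(0, np.nan)).mean())
    ratios = logc.loc[usable].sub(log_geomean[usable], axis=0)
    sf = np.exp(ratios.median(axis=0))
    return sf.fillna(1.0)


def nb_differential_expression(
    counts: ExpressionMatrix,
    design: SampleDesign,
    group_a: list[str],
    group_b: list[str],
    config: PipelineConfig | None = None,
    contrast: str = "A-B",
) -> pd.DataFrame:
    """NB Wald test of group B versus group A (log2FC = B over A).

    Returns a DEGTable DataFrame with columns gene_id, contrast,
    log2_fc, p_value, adj_p, passes; ``passes`` is
    ``adj_p < fdr_cutoff and |log2_fc| >= lfc_cutoff``.
    """
    config = config or PipelineConfig()
    if counts.unit != "count":
        raise ValueError("nb_differential_expression requires raw counts")
    if not group_a or not group_b:
        raise ValueError("both groups need at least one sample")
    missing = [s for s in group_a + group_b if s not in counts.values.columns]
    if missing:
        raise KeyError(f"samples not in matrix: {missing[:5]}")

    sub = counts.values[group_a + group_b].astype(float)
    sf = median_of_ratios_size_factors(sub)
    norm = sub.div(sf, axis=1)
    na, nb = len(group_a), len(group_b)
    a = norm[group_a].to_numpy()
    b = norm[group_b].to_numpy()
    mu_a = a.mean(axis=1)
    mu_b = b.mean(axis=1)

    # pooled method-of-moments NB dispersion on normalized counts:
    # Var(K) ~ mu + alpha mu^2 within each group
    def _group_alpha(x: np.ndarray, mu: np.ndarray, n: int) -> np.ndarray:
        if n < 2:
            return np.zeros_like(mu)
        var = x.var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            alpha = (var - mu) / np.square(mu)
        return np.where(np.isfinite(alpha), alpha, 0.0)

    w_a = max(na - 1, 0)
    w_b = max(nb - 1, 0)
    denom = max(w_a + w_b, 1)
    alpha = (w_a * _group_alpha(a, mu_a, na) + w_b * _group_alpha(b, mu_b, nb)) / denom
    # moderate: no gene may claim less dispersion than the matrix-wide
    # pooled estimate (few-replicate MoM severely underestimates otherwise)
    pooled = float(np.mean(np.clip(alpha, 0.0, None)))
    alpha = np.maximum.reduce([alpha, np.full_like(alpha, pooled),
                               np.full_like(alpha, _DISPERSION_FLOOR)])

    pseudo = 0.5
    log2_fc = np.log2(mu_b + pseudo) - np.log2(mu_a + pseudo)

    # delta-method variance of log2(mean + pseudo) under the NB model
    def _var_log2_mean(mu: np.ndarray, n: int) -> np.ndarray:
        var_mean = (mu + alpha * np.square(mu)) / n
        return var_mean / np.square((mu + pseudo) * np.log(2.0))

    se = np.sqrt(_var_log2_mean(mu_a, na) + _var_log2_mean(mu_b, nb))
    both_zero = (mu_a == 0) & (mu_b == 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        wald = np.where(se > 0, log2_fc / se, 0.0)
    # residual df plus a moderation credit for the pooled dispersion prior
    df_total = max(na + nb - 2, 1) + _MODERATION_PRIOR_DF
    p = 2.0 * stats.t.sf(np.abs(wald), df=df_total)
    p = np.where(both_zero, 1.0, np.clip(p, 0.0, 1.0))
    adj = benjamini_hochberg(p)
    passes = (adj < config.fdr_cutoff) & (np.abs(log2_fc) >= config.lfc_cutoff)
    return pd.DataFrame(
        {
            "gene_id": counts.gene_ids,
            "contrast": contrast,
            "log2_fc": log2_fc,
            "p_value": p,
            "adj_p": adj,
            "passes": passes,
        }
    )


def pairwise_timepoint_degs(
    counts: ExpressionMatrix,
    design: SampleDesign,
    tissue: str,
    config: PipelineConfig | None = None,
    catalog=None,
    stages: list[int] | None = None,
) -> dict:
    """Differential expression between every unordered stage pair.

    Returns ``{"table": all records, "union": passing gene set,
    "tf": TF subset, "non_tf": the rest, "n_contrasts": int}``; the
    TF split requires a catalog (absent one, all genes are non-TF).
    """
    config = config or PipelineConfig()
    use_stages = stages if stages is not None else design.stages(tissue)
    if len(use_stages) < 2:
        raise ValueError("need at least 2 stages for pairwise contrasts")
    frames = []
    for s1, s2 in itertools.combinations(sorted(use_stages), 2):
        ga = design.samples_for(tissue, s1)
        gb = design.samples_for(tissue, s2)
        frames.append(
            nb_differential_expression(
                counts, design, ga, gb, config, contrast=f"{tissue}:{s1}-{s2}"
            )
        )
    table = pd.concat(frames, ignore_index=True)
    union = set(table.loc[table["passes"], "gene_id"])
    if catalog is not None:
        tf = {g for g in union if catalog.is_tf(g)}
    else:
        tf = set()
    return {
        "table": table,
        "union": union,
        "tf": tf,
        "non_tf": union - tf,
        "n_contrasts": len(frames),
    }


def low_expression_filter(
    deg_union: set,
    tpm: ExpressionMatrix,
    design: SampleDesign,
    tissue: str,
    config: PipelineConfig | None = None,
) -> set:
    """Drop genes whose per-stage mean TPM is below the floor at every stage.

    A gene survives if any stage mean reaches ``min_mean_tpm``.
    """
    config = config or PipelineConfig()
    if config.min_mean_tpm == 0:
        return set(deg_union)
    stage_means = stage_mean_matrix(tpm, design, tissue).values
    missing = [g for g in deg_union if g not in stage_means.index]
    if missing:
        raise KeyError(f"TPM matrix does not cover DEGs: {missing[:5]}")
    keep = stage_means.loc[sorted(deg_union)].max(axis=1) >= config.min_mean_tpm
    return set(keep.index[keep])


def tissue_specific_sets(deg_a: set, deg_b: set) -> tuple[set, set, set]:
    """(a_only, b_only, shared) partition of two DEG sets."""
    deg_a, deg_b = set(deg_a), set(deg_b)
    return deg_a - deg_b, deg_b - deg_a, deg_a & deg_b
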