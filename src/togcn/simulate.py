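"""Synthetic time-course count data with a planted regulatory cascade.

The generator emulates the structure a time-ordered co-expression
analysis exploits in real developmental RNA-seq:

* a seed TF whose expression is highest at the first stage and declines
  monotonically;
* TF strata ("levels") whose mean profiles peak progressively later, so
  that the level x stage heat-map shows a diagonal;
* adjacent-level profiles strongly positively correlated (a target gene
  tracks its regulator with a one-stage lag) while profiles two or more
  levels apart correlate weakly — this is what makes breadth-first level
  assignment at a high Pearson cutoff recover the planted cascade;
* enzyme ("structural") genes driven by same-level TFs;
* negative-binomial count noise with per-sample library-size factors;
* a binding-site table containing every planted regulator->target pair
  plus uniform decoy pairs that never coincide with planted ones.

Level mean profiles are designed numerically: profiles are initialised
on the geodesic through expression-profile space whose angular step
gives the requested adjacent-level correlation, then refined by a
penalised quasi-Newton fit so that every profile peaks at its own stage
center, the level-1 profile is strictly decreasing, adjacent-level
correlations sit at ``adjacent_r`` and correlations across a gap of two
or more levels stay below ``skip_r_max``. (Simple shifted unimodal
bumps cannot do this: over a handful of mean-centered stages their
adjacent-shift Pearson correlation is bounded far below the cutoffs
used for network construction.)
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from functools import lru_cache
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .data import (
    ROLE_PHASE,
    BindingSiteTable,
    ExpressionMatrix,
    GeneCatalog,
    SampleDesign,
)

__all__ = ["CascadeParams", "SyntheticTruth", "simulate_cascade", "simulate_null",
           "design_level_profiles"]

_TF_FAMILIES = [
    "bZIP", "B3", "MYB_related", "GRAS", "Dof", "LEC1", "WRI",
    "NAC", "ERF", "WRKY", "bHLH", "C2H2", "HD-ZIP", "Trihelix",
]
_DE_NOVO_ROLES = ["ACCase", "MCAT", "KAS", "KAR", "ENR", "SAD", "Fat"]
_ELONGATION_ROLES = ["LACS", "KCS", "KCR", "HCD", "ECR", "GPAT", "LPAAT", "PAP", "DGAT", "PDAT"]


@dataclass
class CascadeParams:
    """Study-design parameters of the planted cascade.

    Defaults mirror a five-stage fruit development course with three
    replicates, five TF levels (a single seed at level 1), ten TFs and
    forty enzyme genes per downstream level, NB dispersion 0.1
    (variance = mu + 0.1 mu^2), and a 10% decoy binding-site rate.
    """

    n_stages: int = 5
    n_replicates: int = 3
    n_levels: int = 5
    tfs_per_level: int = 10
    structural_per_level: int = 40
    seed_tf_count: int = 1
    baseline_mean: float = 50.0
    peak_fold: float = 8.0
    nb_dispersion: float = 0.1
    decoy_site_rate: float = 0.1
    n_noise_genes: int = 2500
    noise_magnitude_sigma: float = 1.0  # heavier-tailed background expression
    library_size_cv: float = 0.1
    tissue: str = "fruit"
    adjacent_r: float = 0.55
    skip_r_max: float = -0.40
    profile_jitter: float = 0.04  # radians of random rotation per gene
    magnitude_sigma: float = 0.3  # log-normal per-gene expression scale
    hub_fraction: float = 0.7  # share of level-3 TFs parented by the hub
    hub_enzyme_bias: float = 0.3  # share of level-2 enzymes driven by the hub
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_levels > self.n_stages + 1:
            raise ValueError("n_levels must be <= n_stages + 1")
        if self.n_levels < 2 or self.n_stages < 3:
            raise ValueError("need at least 2 levels and 3 stages")
        for name in ("baseline_mean", "peak_fold", "tfs_per_level"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")
        if not 0 <= self.decoy_site_rate <= 1:
            raise ValueError("decoy_site_rate must be in [0,1]")

    def analysis_config(self, **overrides) -> "PipelineConfig":
        """Correlation cutoffs matched to this generator's geometry.

        The published per-tissue cutoffs belong to the real datasets they
        were calibrated on. For a simulated cascade the discriminative
        cutoff sits between the designed adjacent-level correlation
        (``adjacent_r``, the planted regulator-target coupling) and the
        designed ceiling for non-adjacent pairs (``skip_r_max``). It is
        placed at 0.4x the adjacent correlation — below the midpoint —
        because measured correlations attenuate under count noise and a
        missed planted edge (which strands or shifts whole downstream
        strata in the breadth-first leveling) costs more than a spurious
        one.
        """
        from .data import PipelineConfig

        pos = round(0.4 * self.adjacent_r, 3)
        kw = {"pos_r_cutoff": max(pos, 0.05), "neg_r_cutoff": -0.55,
              "rng_seed": self.rng_seed}
        kw.update(overrides)
        return PipelineConfig(**kw)


@dataclass
class SyntheticTruth:
    """Ground truth emitted alongside a simulated dataset."""

    seed_tf: str
    hub_tf: str
    tf_levels: dict[str, int]
    structural_levels: dict[str, int]
    edges: list[tuple[str, str]]  # planted regulator -> target pairs
    binding_sites: set[tuple[str, str]]  # = planted edge pairs
    decoy_sites: set[tuple[str, str]]
    focal_chain: list[str]  # hub, TF, TF, enzyme
    de_genes: dict[str, list[str]]  # "s-t" stage pair -> planted DE genes
    planted_clusters: list[dict]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "seed_tf": self.seed_tf,
            "hub_tf": self.hub_tf,
            "tf_levels": self.tf_levels,
            "structural_levels": self.structural_levels,
            "edges": sorted(map(list, self.edges)),
            "binding_sites": sorted(map(list, self.binding_sites)),
            "decoy_sites": sorted(map(list, self.decoy_sites)),
            "focal_chain": self.focal_chain,
            "de_genes": {k: sorted(v) for k, v in self.de_genes.items()},
            "planted_clusters": self.planted_clusters,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        d = json.loads(Path(path).read_text())
        return cls(
            seed_tf=d["seed_tf"],
            hub_tf=d["hub_tf"],
            tf_levels={k: int(v) for k, v in d["tf_levels"].items()},
            structural_levels={k: int(v) for k, v in d["structural_levels"].items()},
            edges=[tuple(e) for e in d["edges"]],
            binding_sites={tuple(e) for e in d["binding_sites"]},
            decoy_sites={tuple(e) for e in d["decoy_sites"]},
            focal_chain=list(d["focal_chain"]),
            de_genes={k: list(v) for k, v in d["de_genes"].items()},
            planted_clusters=d["planted_clusters"],
        )


# ---------------------------------------------------------------------------
# level profile design
# ---------------------------------------------------------------------------


@lru_cache(maxsize=32)
def design_level_profiles(
    n_stages: int,
    n_levels: int,
    adjacent_r: float = 0.55,
    skip_r_max: float = -0.40,
) -> np.ndarray:
    """Design ``n_levels`` mean-profile shapes over ``n_stages`` stages.

    Returns an (L, T) array of centered unit-norm rows. Row ``l`` peaks
    at stage center ``1 + l*(T-1)/(L-1)`` (rounded to the grid), row 0
    is strictly decreasing, Pearson correlation between adjacent rows is
    close to ``adjacent_r`` and correlation between rows two or more
    levels apart does not exceed ``skip_r_max`` by construction.
    Deterministic (no randomness involved).
    """
    T, L = n_stages, n_levels
    s = np.arange(T, dtype=float)
    centers = np.round(np.linspace(0, T - 1, L)).astype(int)
    phi = np.arccos(adjacent_r + 0.02)  # slight overshoot; penalty relaxes it
    a = np.cos(phi * s)
    b = np.sin(phi * s)
    a -= a.mean()
    a /= np.linalg.norm(a)
    b -= b.mean()
    b -= (b @ a) * a
    b /= np.linalg.norm(b)
    x0 = np.array([np.cos(phi * l) * a + np.sin(phi * l) * b for l in range(L)])

    def normalized(x: np.ndarray) -> np.ndarray:
        xc = x - x.mean(axis=1, keepdims=True)
        return xc / np.maximum(np.linalg.norm(xc, axis=1, keepdims=True), 1e-12)

    def penalty(flat: np.ndarray) -> float:
        x = flat.reshape(L, T)
        xn = normalized(x)
        r = xn @ xn.T
        # span-normalized view: y in [0,1] per profile, which is the scale
        # the expression means live on after affine mapping
        lo = x.min(axis=1, keepdims=True)
        span = np.maximum(x.max(axis=1, keepdims=True) - lo, 1e-9)
        y = (x - lo) / span
        p = 0.0
        for l in range(L):
            for m in range(l + 1, L):
                if m - l == 1:
                    # the seed couples extra tightly to level 2 so the
                    # first BFS hop survives the seed's own count noise
                    target = max(adjacent_r, 0.75) if l == 0 else adjacent_r
                    p += 400.0 * (target - r[l, m]) ** 2
                else:
                    p += 200.0 * max(0.0, r[l, m] - skip_r_max) ** 2
        for l in range(L):
            c = centers[l]
            others = np.delete(np.arange(T), c)
            # genuine bumps: the peak stage clearly dominates every other,
            # on the min-max scale the count means will live on
            p += 100.0 * np.sum(np.maximum(0.0, y[l, others] - y[l, c] + 0.30) ** 2)
            if c > 0:  # steep rising edge: clearly off the stage before the peak
                # extra steep into stage 1 so no downstream TF mimics the
                # seed's first-stage-anchored decline under count noise
                ceil = 0.35 if c == 1 else 0.50
                p += 200.0 * max(0.0, y[l, c - 1] - ceil) ** 2
        p += 300.0 * np.sum(np.maximum(0.0, np.diff(y[0]) + 0.02) ** 2)
        # seed prominence: the level-1 profile is a first-stage spike with
        # a steep initial drop, the signature of a first-stage anchor TF
        p += 400.0 * max(0.0, 0.85 - xn[0, 0]) ** 2
        p += 200.0 * max(0.0, y[0, 1] - 0.45) ** 2
        p += 0.01 * np.sum(np.diff(xn, 2, axis=1) ** 2)
        nrm = np.linalg.norm(x - x.mean(axis=1, keepdims=True), axis=1)
        p += np.sum((nrm - 1.0) ** 2)
        return p

    res = minimize(penalty, x0.ravel(), method="L-BFGS-B", options={"maxiter": 3000})
    xn = normalized(res.x.reshape(L, T))
    peaks = xn.argmax(axis=1)
    if np.any(np.diff(peaks) < 0):
        raise RuntimeError(
            f"profile design failed: peak stages {peaks + 1} not non-decreasing "
            f"for T={T}, L={L}"
        )
    if np.any(np.diff(xn[0]) >= 0):
        raise RuntimeError("profile design failed: level-1 profile not strictly decreasing")
    xn.setflags(write=False)
    return xn


def _rotate_within_sphere(v: np.ndarray, angle: float, rng: np.random.Generator) -> np.ndarray:
    """Rotate a centered unit vector by ``angle`` toward a random centered
    direction orthogonal to it; correlation with the original is cos(angle)."""
    u = rng.standard_normal(v.size)
    u -= u.mean()
    u -= (u @ v) * v
    n = np.linalg.norm(u)
    if n < 1e-12:
        return v
    u /= n
    return np.cos(angle) * v + np.sin(angle) * u


def _profile_to_mean(shape: np.ndarray, baseline: float, fold: float, scale: float) -> np.ndarray:
    """Affine-map a centered shape to a nonnegative mean profile in
    [baseline, baseline*fold] times a per-gene magnitude factor."""
    lo, hi = shape.min(), shape.max()
    x = (shape - lo) / (hi - lo) if hi > lo else np.full_like(shape, 0.5)
    return scale * baseline * (1.0 + (fold - 1.0) * x)


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, alpha: float) -> np.ndarray:
    """NB counts with variance mu + alpha*mu^2 (Poisson when alpha == 0)."""
    mean = np.asarray(mean, dtype=float)
    if alpha == 0:
        return rng.poisson(mean)
    n = 1.0 / alpha
    p = n / (n + mean)
    return rng.negative_binomial(n, p)


# ---------------------------------------------------------------------------
# catalogs and coordinates
# ---------------------------------------------------------------------------


def _place_coordinates(
    gene_ids: list[str],
    structural_ids: list[str],
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, list[dict]]:
    """Assign chromosomes/coordinates. Three dense enzyme clusters are
    planted (mirroring multi-megabase biosynthetic gene clusters); all
    other genes are spaced 6 Mb apart so no spurious cluster can form
    under a 2 Mb single-linkage gap."""
    cluster_specs = [
        ("Chr01", 31_000_000, 5),
        ("Chr07", 500_000, 5),
        ("Chr12", 1_000_000, 5),
    ]
    coords: dict[str, tuple[str, int, int]] = {}
    planted_clusters = []
    struct_iter = iter(structural_ids)
    for chrom, start, k in cluster_specs:
        members = []
        pos = start
        for _ in range(k):
            g = next(struct_iter, None)
            if g is None:
                break
            length = int(rng.integers(1000, 4001))
            coords[g] = (chrom, pos, pos + length)
            members.append(g)
            pos += length + int(rng.integers(200_000, 1_500_001))
        if members:
            planted_clusters.append(
                {"chrom": chrom, "members": members,
                 "start": coords[members[0]][1], "end": coords[members[-1]][2]}
            )
    chroms = [f"Chr{i:02d}" for i in range(1, 13)]
    offsets = {c: 50_000_000 for c in chroms}  # far from planted clusters
    i = 0
    for g in gene_ids:
        if g in coords:
            continue
        chrom = chroms[i % len(chroms)]
        i += 1
        length = int(rng.integers(1000, 4001))
        coords[g] = (chrom, offsets[chrom], offsets[chrom] + length)
        offsets[chrom] += 6_000_000  # > cluster gap, never merges
    df = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "chrom": [coords[g][0] for g in gene_ids],
            "start0": [coords[g][1] for g in gene_ids],
            "end0": [coords[g][2] for g in gene_ids],
            "strand": ["+" if rng.random() < 0.5 else "-" for _ in gene_ids],
        }
    )
    return df, planted_clusters


# ---------------------------------------------------------------------------
# main simulators
# ---------------------------------------------------------------------------


def _make_design(params: CascadeParams) -> SampleDesign:
    rows = []
    for st in range(1, params.n_stages + 1):
        for rep in range(1, params.n_replicates + 1):
            rows.append(
                {
                    "sample_id": f"{params.tissue}{st}_r{rep}",
                    "tissue": params.tissue,
                    "stage_index": st,
                    "replicate": rep,
                }
            )
    return SampleDesign(pd.DataFrame(rows))


def simulate_cascade(
    params: CascadeParams,
) -> tuple[ExpressionMatrix, SampleDesign, GeneCatalog, BindingSiteTable, SyntheticTruth]:
    """Simulate a staged count matrix with a planted TF cascade.

    Returns (counts, design, catalog, binding sites, truth). Fully
    reproducible from ``params.rng_seed``.
    """
    rng = np.random.default_rng(params.rng_seed)
    T, L = params.n_stages, params.n_levels
    shapes = design_level_profiles(T, L, params.adjacent_r, params.skip_r_max)

    # --- gene roster -------------------------------------------------------
    seeds = [f"TF_L1_{i + 1:02d}" for i in range(params.seed_tf_count)]
    tf_ids: dict[int, list[str]] = {1: seeds}
    for l in range(2, L + 1):
        tf_ids[l] = [f"TF_L{l}_{i + 1:02d}" for i in range(params.tfs_per_level)]
    struct_ids: dict[int, list[str]] = {
        l: [f"ENZ_L{l}_{i + 1:02d}" for i in range(params.structural_per_level)]
        for l in range(2, L + 1)
    }
    noise_ids = [f"NOISE_{i + 1:04d}" for i in range(params.n_noise_genes)]
    all_tfs = [g for l in sorted(tf_ids) for g in tf_ids[l]]
    all_struct = [g for l in sorted(struct_ids) for g in struct_ids[l]]
    gene_ids = all_tfs + all_struct + noise_ids

    # --- mean profiles -----------------------------------------------------
    mean_profiles: dict[str, np.ndarray] = {}
    for l in sorted(tf_ids):
        for g in tf_ids[l]:
            shape = shapes[l - 1]
            if l > 1:  # the seed keeps its exact strictly-decreasing shape
                angle = abs(rng.normal(0.0, params.profile_jitter))
                shape = _rotate_within_sphere(shape, angle, rng)
            scale = float(np.exp(rng.normal(0.0, params.magnitude_sigma)))
            mean_profiles[g] = _profile_to_mean(shape, params.baseline_mean, params.peak_fold, scale)
    for l in sorted(struct_ids):
        for g in struct_ids[l]:
            angle = abs(rng.normal(0.0, params.profile_jitter))
            shape = _rotate_within_sphere(shapes[l - 1], angle, rng)
            scale = float(np.exp(rng.normal(0.0, params.magnitude_sigma)))
            mean_profiles[g] = _profile_to_mean(shape, params.baseline_mean, params.peak_fold, scale)
    # stage-flat background; numerous enough that per-sample totals stay
    # stable and TPM normalization does not couple the cascade genes
    for g in noise_ids:
        scale = float(np.exp(rng.normal(0.0, params.noise_magnitude_sigma)))
        mean_profiles[g] = np.full(T, params.baseline_mean * scale)

    # --- planted regulatory edges -----------------------------------------
    seed_tf = seeds[0]
    hub_tf = tf_ids[2][0]
    parent: dict[str, str] = {}
    for g in tf_ids[2]:
        parent[g] = seed_tf
    if L >= 3:
        n_hub = int(round(params.hub_fraction * len(tf_ids[3])))
        for i, g in enumerate(tf_ids[3]):
            if i < n_hub:
                parent[g] = hub_tf
            else:
                others = [t for t in tf_ids[2] if t != hub_tf] or tf_ids[2]
                parent[g] = others[int(rng.integers(len(others)))]
        for l in range(4, L + 1):
            for g in tf_ids[l]:
                parent[g] = tf_ids[l - 1][int(rng.integers(len(tf_ids[l - 1])))]
    driver: dict[str, str] = {}
    for l in sorted(struct_ids):
        n_hub_enz = int(round(params.hub_enzyme_bias * len(struct_ids[l]))) if l == 2 else 0
        for i, g in enumerate(struct_ids[l]):
            if i < n_hub_enz:  # the hub directly drives a battery of enzymes
                driver[g] = hub_tf
            else:
                driver[g] = tf_ids[l][int(rng.integers(len(tf_ids[l])))]

    # guarantee one fully planted order-3 chain: the seed regulates the
    # hub, the hub one of its level-3 children, which drives an enzyme —
    # the chain's root is the top-tier (seed) regulator
    focal_chain: list[str] = []
    if L >= 3:
        b = next(g for g in tf_ids[3] if parent[g] == hub_tf)
        e = struct_ids[3][0]
        driver[e] = b
        focal_chain = [seed_tf, hub_tf, b, e]

    edges = [(parent[g], g) for g in parent] + [(driver[g], g) for g in driver]
    planted_pairs = set(edges)

    # --- binding sites: planted pairs plus uniform decoys ------------------
    # decoy_site_rate is the contamination fraction of the final table
    # (promoter-scan false positives): decoys/(planted+decoys) = rate
    network_genes = all_tfs + all_struct
    decoys: set[tuple[str, str]] = set()
    if params.decoy_site_rate > 0:
        n_decoys = int(round(
            params.decoy_site_rate / (1.0 - params.decoy_site_rate) * len(planted_pairs)
        ))
        candidates = [
            (tf, g)
            for tf in all_tfs
            for g in network_genes
            if g != tf and (tf, g) not in planted_pairs
        ]
        pick = rng.choice(len(candidates), size=min(n_decoys, len(candidates)),
                          replace=False)
        decoys = {candidates[i] for i in pick}
    site_rows = sorted(planted_pairs | decoys)
    sites = BindingSiteTable(
        pd.DataFrame(site_rows, columns=["tf_gene_id", "target_gene_id"])
    )

    # --- catalog -----------------------------------------------------------
    coord_df, planted_clusters = _place_coordinates(gene_ids, all_struct, rng)
    families = {g: _TF_FAMILIES[i % len(_TF_FAMILIES)] for i, g in enumerate(all_tfs)}
    roles = {}
    for l in sorted(struct_ids):
        pool = _DE_NOVO_ROLES if l <= (L + 1) // 2 else _ELONGATION_ROLES
        for i, g in enumerate(struct_ids[l]):
            roles[g] = pool[i % len(pool)]
    cat = coord_df.copy()
    cat["is_tf"] = cat["gene_id"].isin(all_tfs)
    cat["tf_family"] = cat["gene_id"].map(families).fillna("")
    cat["enzyme_role"] = cat["gene_id"].map(roles).fillna("")
    cat["phase"] = cat["enzyme_role"].map(lambda r: ROLE_PHASE.get(r, "")).fillna("")
    catalog = GeneCatalog(cat)

    # --- counts ------------------------------------------------------------
    design = _make_design(params)
    lib = np.exp(rng.normal(0.0, params.library_size_cv, size=T * params.n_replicates))
    counts = np.zeros((len(gene_ids), T * params.n_replicates), dtype=np.int64)
    sample_ids = []
    j = 0
    for st in range(T):
        for rep in range(params.n_replicates):
            sample_ids.append(f"{params.tissue}{st + 1}_r{rep + 1}")
            mu = np.array([mean_profiles[g][st] for g in gene_ids]) * lib[j]
            counts[:, j] = _nb_draw(rng, mu, params.nb_dispersion)
            j += 1
    expr = ExpressionMatrix(
        pd.DataFrame(counts, index=gene_ids, columns=sample_ids), unit="count"
    )

    # --- planted DE sets ---------------------------------------------------
    de_genes: dict[str, list[str]] = {}
    for a in range(1, T + 1):
        for b in range(a + 1, T + 1):
            hits = [
                g
                for g in gene_ids
                if abs(np.log2(mean_profiles[g][a - 1] / mean_profiles[g][b - 1])) >= 1.0
            ]
            de_genes[f"{a}-{b}"] = hits

    truth = SyntheticTruth(
        seed_tf=seed_tf,
        hub_tf=hub_tf,
        tf_levels={g: l for l in tf_ids for g in tf_ids[l]},
        structural_levels={g: l for l in struct_ids for g in struct_ids[l]},
        edges=edges,
        binding_sites=planted_pairs,
        decoy_sites=decoys,
        focal_chain=focal_chain,
        de_genes=de_genes,
        planted_clusters=planted_clusters,
    )
    return expr, design, catalog, sites, truth


def simulate_null(
    params: CascadeParams,
) -> tuple[ExpressionMatrix, SampleDesign, GeneCatalog, BindingSiteTable, SyntheticTruth]:
    """Simulate stage-flat NB counts with no planted structure.

    The gene roster matches :func:`simulate_cascade` in size and TF
    labelling so the downstream pipeline runs unchanged; the truth
    object carries empty edge, site and DE sets.
    """
    rng = np.random.default_rng(params.rng_seed)
    T = params.n_stages
    n_tf = params.seed_tf_count + (params.n_levels - 1) * params.tfs_per_level
    n_struct = (params.n_levels - 1) * params.structural_per_level
    tf_ids = [f"TF_{i + 1:04d}" for i in range(n_tf)]
    struct_ids = [f"ENZ_{i + 1:04d}" for i in range(n_struct)]
    noise_ids = [f"NOISE_{i + 1:04d}" for i in range(params.n_noise_genes)]
    gene_ids = tf_ids + struct_ids + noise_ids

    scales = np.exp(rng.normal(0.0, params.magnitude_sigma, size=len(gene_ids)))
    base = params.baseline_mean * scales
    design = _make_design(params)
    lib = np.exp(rng.normal(0.0, params.library_size_cv, size=T * params.n_replicates))
    counts = np.zeros((len(gene_ids), T * params.n_replicates), dtype=np.int64)
    sample_ids = []
    j = 0
    for st in range(T):
        for rep in range(params.n_replicates):
            sample_ids.append(f"{params.tissue}{st + 1}_r{rep + 1}")
            counts[:, j] = _nb_draw(rng, base * lib[j], params.nb_dispersion)
            j += 1
    expr = ExpressionMatrix(
        pd.DataFrame(counts, index=gene_ids, columns=sample_ids), unit="count"
    )

    coord_df, _ = _place_coordinates(gene_ids, [], rng)
    cat = coord_df.copy()
    cat["is_tf"] = cat["gene_id"].isin(tf_ids)
    cat["tf_family"] = ""
    cat["enzyme_role"] = ""
    cat["phase"] = ""
    catalog = GeneCatalog(cat)
    sites = BindingSiteTable(pd.DataFrame(columns=["tf_gene_id", "target_gene_id"]))
    truth = SyntheticTruth(
        seed_tf="",
        hub_tf="",
        tf_levels={},
        structural_levels={},
        edges=[],
        binding_sites=set(),
        decoy_sites=set(),
        focal_chain=[],
        de_genes={},
        planted_clusters=[],
    )
    return expr, design, catalog, sites, truth
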