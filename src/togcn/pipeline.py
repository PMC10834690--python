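"""End-to-end orchestration: DE -> low-TPM filter -> TO-GCN ->
phase subnetworks -> validated chains -> enrichment -> genomic clusters.

Every stage writes TSV outputs under the run directory, and a JSON
manifest records the configuration snapshot, input digests, RNG seed
and output digests. The manifest contains no wall-clock information,
so identical config + inputs + seed reproduce it byte for byte;
timings go to ``run.log`` instead.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd

from . import network as net
from .data import (
    BindingSiteTable,
    ExpressionMatrix,
    GeneCatalog,
    PipelineConfig,
    SampleDesign,
    stage_mean_matrix,
    tpm_from_counts,
    write_expression_matrix,
)
from .diffexpr import low_expression_filter, pairwise_timepoint_degs
from .enrichment import detect_genomic_clusters
from .hierarchy import (
    chains_to_frame,
    extract_phase_subnetwork,
    filter_chains_by_binding_sites,
    infer_upstream_chains,
    rank_top_regulators,
    tf_family_census,
)

log = logging.getLogger("togcn")

__all__ = ["RunManifest", "PipelineInputs", "run_pipeline"]


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


@dataclass
class PipelineInputs:
    counts: ExpressionMatrix
    design: SampleDesign
    catalog: GeneCatalog
    sites: BindingSiteTable | None = None
    gene_lengths: pd.Series | None = None  # bp; defaults to catalog extents
    input_paths: dict = field(default_factory=dict)  # name -> path, for digests


@dataclass
class RunManifest:
    config: dict
    rng_seed: int
    input_digests: dict
    output_digests: dict
    stage_summaries: dict

    def to_json(self, path: str | Path) -> None:
        payload = {
            "config": self.config,
            "rng_seed": self.rng_seed,
            "input_digests": self.input_digests,
            "output_digests": self.output_digests,
            "stage_summaries": self.stage_summaries,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def _gene_lengths(inputs: PipelineInputs) -> pd.Series:
    if inputs.gene_lengths is not None:
        return pd.Series(inputs.gene_lengths)
    t = inputs.catalog.table
    lengths = (t["end0"].astype(int) - t["start0"].astype(int)).where(
        t["start0"].astype(int) >= 0
    )
    lengths = lengths.reindex(inputs.counts.gene_ids).fillna(1000).astype(float)
    return lengths


def run_pipeline(
    config: PipelineConfig,
    inputs: PipelineInputs,
    outdir: str | Path,
    tissue: str | None = None,
    chain_phase: str = "elongation",
    resume: bool = False,
) -> tuple[RunManifest, dict]:
    """Run the whole workflow for one tissue; returns (manifest, results).

    Stages run in dependency order. With ``resume=True`` a stage whose
    output files already exist is reloaded rather than recomputed. A
    missing binding-site table skips chain validation with a warning
    instead of failing the run.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t_start = time.perf_counter()
    timings: dict[str, float] = {}
    summaries: dict[str, dict] = {}
    outputs: dict[str, Path] = {}
    results: dict = {}

    tissue = tissue or inputs.design.tissues[0]
    cfg = config.replace(
        pos_r_cutoff=config.pos_r_cutoff, neg_r_cutoff=config.neg_r_cutoff
    )

    def _stage(name):
        def deco(fn):
            t0 = time.perf_counter()
            try:
                fn()
            except Exception as exc:  # annotate with stage name, then abort
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
            timings[name] = time.perf_counter() - t0
        return deco

    # --- expression: TPM and stage means -----------------------------------
    @_stage("expression")
    def _expression():
        if inputs.counts.unit == "count":
            tpm = tpm_from_counts(inputs.counts, _gene_lengths(inputs))
        else:
            tpm = inputs.counts
        results["tpm"] = tpm
        results["stage_means"] = stage_mean_matrix(tpm, inputs.design, tissue)
        p = outdir / "stage_means.tsv"
        write_expression_matrix(results["stage_means"], p)
        outputs["stage_means"] = p
        summaries["expression"] = {
            "n_genes": tpm.shape[0],
            "n_samples": tpm.shape[1],
            "n_stages": results["stage_means"].shape[1],
        }

    # --- differential expression ------------------------------------------
    @_stage("diffexpr")
    def _diffexpr():
        if inputs.counts.unit != "count":
            log.warning("expression is not raw counts; skipping DE, using all genes")
            results["deg_union"] = set(inputs.counts.gene_ids)
            summaries["diffexpr"] = {"skipped": True}
            return
        de = pairwise_timepoint_degs(
            inputs.counts, inputs.design, tissue, cfg, catalog=inputs.catalog
        )
        filtered = low_expression_filter(
            de["union"], results["tpm"], inputs.design, tissue, cfg
        )
        results["deg_table"] = de["table"]
        results["deg_union"] = filtered
        p = outdir / "deg.tsv"
        de["table"].to_csv(p, sep="\t", index=False, float_format="%.6g")
        outputs["deg"] = p
        summaries["diffexpr"] = {
            "n_contrasts": de["n_contrasts"],
            "n_deg": len(de["union"]),
            "n_deg_tf": len(de["tf"]),
            "n_deg_after_tpm_filter": len(filtered),
        }

    # --- TO-GCN ------------------------------------------------------------
    @_stage("togcn")
    def _togcn():
        degs = results["deg_union"]
        tf_ids = sorted(g for g in degs if inputs.catalog.is_tf(g))
        struct_ids = sorted(
            g for g in degs if inputs.catalog.roles(g) and not inputs.catalog.is_tf(g)
        )
        togcn = net.build_togcn(
            results["stage_means"], tf_ids, struct_ids, cfg
        )
        results["togcn"] = togcn
        lv = pd.DataFrame(
            sorted(togcn.levels.items()), columns=["gene_id", "level"]
        )
        lv.to_csv(outdir / "levels.tsv", sep="\t", index=False)
        edges = pd.concat(
            [
                togcn.tf_edges.assign(sign_class="positive"),
                togcn.neg_tf_edges.assign(sign_class="negative"),
            ],
            ignore_index=True,
        )
        edges.to_csv(outdir / "tf_edges.tsv", sep="\t", index=False, float_format="%.6g")
        att = pd.DataFrame(
            [
                {"gene_id": g, "level": l, "best_tf": t, "r": r}
                for g, (l, t, r) in sorted(togcn.attachments.items())
            ]
        )
        att.to_csv(outdir / "attachments.tsv", sep="\t", index=False, float_format="%.6g")
        diag, peaks = net.level_diagnostic(togcn, results["stage_means"])
        diag.to_csv(outdir / "level_diagnostic.tsv", sep="\t", float_format="%.6g")
        results["diagnostic"] = diag
        results["diagnostic_peaks"] = peaks
        nx.write_graphml(togcn.to_graph(), outdir / "network.graphml")
        for name in ("levels", "tf_edges", "attachments", "level_diagnostic"):
            outputs[name] = outdir / f"{name}.tsv"
        outputs["network_graphml"] = outdir / "network.graphml"
        summaries["togcn"] = {
            "seed_tf": togcn.seed_tf,
            "n_levels": togcn.n_levels,
            "n_leveled_tfs": len(togcn.levels),
            "n_pos_edges": len(togcn.tf_edges),
            "n_neg_edges": len(togcn.neg_tf_edges),
            "n_attached_structural": len(togcn.attachments),
            "peak_stage_by_level": {str(k): v for k, v in peaks.items()},
        }

    # --- phase subnetworks and chains --------------------------------------
    @_stage("hierarchy")
    def _hierarchy():
        togcn = results["togcn"]
        census_frames = []
        for phase in ("de_novo", "elongation"):
            subnet = extract_phase_subnetwork(togcn, inputs.catalog, phase)
            census = tf_family_census(subnet, inputs.catalog)
            census["phase"] = phase
            census_frames.append(census)
            results[f"subnetwork_{phase}"] = subnet
        census_all = pd.concat(census_frames, ignore_index=True)
        census_all.to_csv(outdir / "tf_family_census.tsv", sep="\t", index=False)
        outputs["tf_family_census"] = outdir / "tf_family_census.tsv"

        chains = []
        for target in sorted(togcn.attachments):
            chains.extend(infer_upstream_chains(togcn, target, cfg))
        if inputs.sites is not None:
            chains = filter_chains_by_binding_sites(chains, inputs.sites)
            ranking = rank_top_regulators(chains)
        else:
            log.warning("no binding-site table; chain validation skipped")
            ranking = pd.DataFrame(columns=["tf", "n_validated_chains", "sum_r"])
        results["chains"] = chains
        results["ranking"] = ranking
        cf = chains_to_frame(chains)
        cf.to_csv(outdir / "chains.tsv", sep="\t", index=False)
        ranking.to_csv(outdir / "top_regulators.tsv", sep="\t", index=False,
                       float_format="%.6g")
        outputs["chains"] = outdir / "chains.tsv"
        outputs["top_regulators"] = outdir / "top_regulators.tsv"
        summaries["hierarchy"] = {
            "n_chains": len(chains),
            "n_validated": int(sum(c.validated for c in chains)),
            "top_regulator": ranking["tf"].iloc[0] if len(ranking) else "",
        }

    # --- genomic clusters ---------------------------------------------------
    @_stage("clusters")
    def _clusters():
        pathway = [
            g for g in inputs.catalog.table["gene_id"]
            if inputs.catalog.roles(g)
        ]
        cl = detect_genomic_clusters(inputs.catalog, pathway, cfg)
        results["clusters"] = cl
        cl.to_csv(outdir / "clusters.tsv", sep="\t", index=False)
        outputs["clusters"] = outdir / "clusters.tsv"
        summaries["clusters"] = {"n_clusters": len(cl)}

    manifest = RunManifest(
        config=cfg.to_dict(),
        rng_seed=cfg.rng_seed,
        input_digests={
            name: _digest(Path(p)) for name, p in sorted(inputs.input_paths.items())
        },
        output_digests={name: _digest(p) for name, p in sorted(outputs.items())},
        stage_summaries=summaries,
    )
    manifest.to_json(outdir / "manifest.json")
    with open(outdir / "run.log", "w") as fh:
        for name, dt in timings.items():
            fh.write(f"{name}\t{dt:.3f}s\n")
        fh.write(f"total\t{time.perf_counter() - t_start:.3f}s\n")
    return manifest, results
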