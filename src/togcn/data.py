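"""Domain types and file I/O for time-course expression analysis.

All tabular interchange is TSV. Expression matrices are genes x samples
with the first column holding gene identifiers. Genomic coordinates are
1-based inclusive on input (GFF convention) and converted to 0-based
half-open internally for arithmetic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "SampleDesign",
    "GeneCatalog",
    "BindingSiteTable",
    "PipelineConfig",
    "FormatError",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_sample_design",
    "write_sample_design",
    "read_gene_catalog",
    "write_gene_catalog",
    "read_binding_sites",
    "write_binding_sites",
    "tpm_from_counts",
    "stage_mean_matrix",
]

#: enzyme role -> biosynthesis phase. De novo C16-C18 synthesis is
#: plastidial; elongation (>C18) and TAG assembly happen at the ER.
ROLE_PHASE = {
    "ACCase": "de_novo",
    "MCAT": "de_novo",
    "KAS": "de_novo",
    "KAR": "de_novo",
    "ENR": "de_novo",
    "HAD": "de_novo",
    "SAD": "de_novo",
    "Fat": "de_novo",
    "LACS": "elongation",
    "KCS": "elongation",
    "KCR": "elongation",
    "HCD": "elongation",
    "ECR": "elongation",
    "GPAT": "elongation",
    "LPAAT": "elongation",
    "PAP": "elongation",
    "DGAT": "elongation",
    "PDAT": "elongation",
}


class FormatError(ValueError):
    """Raised when an input file violates the documented format."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """Genes x samples nonnegative expression values.

    ``unit`` is ``"TPM"`` or ``"count"``. ``values`` is a DataFrame whose
    index are unique gene ids and whose columns are unique sample ids.
    """

    values: pd.DataFrame
    unit: str = "TPM"

    def __post_init__(self) -> None:
        if self.unit not in ("TPM", "count"):
            raise ValueError(f"unknown expression unit {self.unit!r}")
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].tolist()
            raise FormatError(f"duplicate gene ids: {dups[:5]}")
        if self.values.columns.duplicated().any():
            raise FormatError("duplicate sample ids")
        arr = self.values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise FormatError("non-numeric expression values")
        if np.isnan(arr).any():
            raise FormatError("missing values in expression matrix")
        if (arr < 0).any():
            raise FormatError("negative expression values")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        missing = [g for g in genes if g not in self.values.index]
        if missing:
            raise KeyError(f"genes not in matrix: {missing[:5]}")
        return ExpressionMatrix(self.values.loc[list(genes)], unit=self.unit)


@dataclass
class SampleDesign:
    """Maps each sample to (tissue, stage_index, replicate).

    Within a tissue, stage indices must form a contiguous 1..T range.
    """

    table: pd.DataFrame  # columns: sample_id, tissue, stage_index, replicate

    REQUIRED = ("sample_id", "tissue", "stage_index", "replicate")

    def __post_init__(self) -> None:
        for col in self.REQUIRED:
            if col not in self.table.columns:
                raise FormatError(f"sample design missing column {col!r}")
        if self.table["sample_id"].duplicated().any():
            raise FormatError("duplicate sample ids in design")
        self.table = self.table.copy()
        self.table["stage_index"] = self.table["stage_index"].astype(int)
        self.table["replicate"] = self.table["replicate"].astype(int)
        if (self.table["stage_index"] < 1).any() or (self.table["replicate"] < 1).any():
            raise FormatError("stage_index and replicate must be >= 1")
        for tissue, sub in self.table.groupby("tissue"):
            stages = sorted(sub["stage_index"].unique())
            if stages != list(range(1, len(stages) + 1)):
                raise FormatError(
                    f"stage indices for tissue {tissue!r} are not contiguous 1..T: {stages}"
                )

    @property
    def tissues(self) -> list[str]:
        return sorted(self.table["tissue"].unique())

    def stages(self, tissue: str) -> list[int]:
        sub = self.table[self.table["tissue"] == tissue]
        if sub.empty:
            raise KeyError(f"tissue {tissue!r} absent from design")
        return sorted(sub["stage_index"].unique())

    def samples_for(self, tissue: str, stage: int | None = None) -> list[str]:
        sub = self.table[self.table["tissue"] == tissue]
        if sub.empty:
            raise KeyError(f"tissue {tissue!r} absent from design")
        if stage is not None:
            sub = sub[sub["stage_index"] == stage]
        return list(sub["sample_id"])


@dataclass
class GeneCatalog:
    """Per-gene annotation: TF flag/family, enzyme role(s), phase, coordinates.

    A gene may carry several enzyme roles (``enzyme_role`` is a
    comma-joined label list); a gene that is both a TF and an enzyme must
    be explicitly marked ``dual_annotation``. Coordinates are stored
    0-based half-open (``start0``, ``end0``); TSV input is 1-based
    inclusive, BED input 0-based half-open.
    """

    table: pd.DataFrame

    REQUIRED = ("gene_id", "is_tf")

    def __post_init__(self) -> None:
        t = self.table.copy()
        for col in self.REQUIRED:
            if col not in t.columns:
                raise FormatError(f"gene catalog missing column {col!r}")
        if t["gene_id"].duplicated().any():
            raise FormatError("duplicate gene ids in catalog")
        defaults = {
            "tf_family": "",
            "enzyme_role": "",
            "phase": "",
            "chrom": "",
            "start0": -1,
            "end0": -1,
            "strand": "",
            "dual_annotation": False,
        }
        for col, dv in defaults.items():
            if col not in t.columns:
                t[col] = dv
        t["is_tf"] = t["is_tf"].astype(bool)
        t["dual_annotation"] = t["dual_annotation"].astype(bool)
        t = t.fillna({"tf_family": "", "enzyme_role": "", "phase": "", "chrom": "", "strand": ""})
        bad = t["is_tf"] & (t["enzyme_role"].astype(str) != "") & ~t["dual_annotation"]
        if bad.any():
            genes = t.loc[bad, "gene_id"].tolist()
            raise FormatError(
                f"TF genes with enzyme roles must be flagged dual_annotation: {genes[:5]}"
            )
        has_coords = (t["start0"].astype(int) >= 0) & (t["end0"].astype(int) >= 0)
        if (t.loc[has_coords, "start0"].astype(int) >= t.loc[has_coords, "end0"].astype(int)).any():
            raise FormatError("catalog coordinates must satisfy start <= end")
        self.table = t.set_index("gene_id", drop=False)

    def is_tf(self, gene: str) -> bool:
        if gene not in self.table.index:
            return False  # uncataloged genes are treated as non-TF
        return bool(self.table.at[gene, "is_tf"])

    def tf_family(self, gene: str) -> str:
        if gene not in self.table.index:
            return ""
        return str(self.table.at[gene, "tf_family"])

    def roles(self, gene: str) -> list[str]:
        if gene not in self.table.index:
            return []
        raw = str(self.table.at[gene, "enzyme_role"])
        return [r for r in raw.split(",") if r]

    def phase(self, gene: str) -> str:
        if gene not in self.table.index:
            return ""
        return str(self.table.at[gene, "phase"])

    @property
    def tf_ids(self) -> list[str]:
        return list(self.table.loc[self.table["is_tf"], "gene_id"])

    @property
    def structural_ids(self) -> list[str]:
        mask = (self.table["enzyme_role"].astype(str) != "") & ~self.table["is_tf"]
        return list(self.table.loc[mask, "gene_id"])

    def genes_in_phase(self, phase: str) -> list[str]:
        if phase not in ("de_novo", "elongation"):
            raise KeyError(f"unknown biosynthesis phase {phase!r}")
        return list(self.table.loc[self.table["phase"] == phase, "gene_id"])


@dataclass
class BindingSiteTable:
    """Predicted TF -> target binding sites in target promoters.

    Pairs are deduplicated on construction; optional motif/score columns
    are carried through. Lookup is by the unordered-unique set of
    (tf_gene_id, target_gene_id) ordered pairs.
    """

    table: pd.DataFrame  # columns: tf_gene_id, target_gene_id[, motif, score]

    def __post_init__(self) -> None:
        t = self.table.copy()
        for col in ("tf_gene_id", "target_gene_id"):
            if col not in t.columns:
                raise FormatError(f"binding-site table missing column {col!r}")
        t = t.drop_duplicates(subset=["tf_gene_id", "target_gene_id"], keep="first")
        self.table = t.reset_index(drop=True)
        self._pairs = set(zip(self.table["tf_gene_id"], self.table["target_gene_id"]))

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return tuple(pair) in self._pairs

    def __len__(self) -> int:
        return len(self._pairs)

    @property
    def pairs(self) -> set[tuple[str, str]]:
        return set(self._pairs)

    def validate_against(self, catalog: GeneCatalog) -> None:
        """Warn on TF ids not flagged is_tf in the catalog."""
        bad = [tf for tf in self.table["tf_gene_id"].unique() if not catalog.is_tf(tf)]
        if bad:
            warnings.warn(
                f"{len(bad)} binding-site regulators are not TFs in the catalog "
                f"(e.g. {bad[:3]})",
                stacklevel=2,
            )


@dataclass
class PipelineConfig:
    """Tunable thresholds of the whole workflow.

    Defaults follow the published analysis: FDR 0.05 with |log2FC| >= 1
    for differential expression, mean-TPM 0.5 floor, Pearson cutoffs
    0.8/-0.53 (fruit) and 0.85/-0.63 (leaf), chains up to third order,
    2 kb promoters, and 2 Mb / 3-gene genomic clustering.
    """

    fdr_cutoff: float = 0.05
    lfc_cutoff: float = 1.0
    min_mean_tpm: float = 0.5
    pos_r_cutoff: float = 0.8
    neg_r_cutoff: float = -0.53
    max_chain_order: int = 3
    promoter_bp: int = 2000
    cluster_max_gap_bp: int = 2_000_000
    cluster_min_genes: int = 3
    rng_seed: int = 0

    #: published per-tissue correlation cutoffs
    TISSUE_CUTOFFS = {"fruit": (0.8, -0.53), "leaf": (0.85, -0.63)}

    def __post_init__(self) -> None:
        if not 0 < self.fdr_cutoff < 1:
            raise ValueError("fdr_cutoff must be in (0,1)")
        if self.lfc_cutoff < 0:
            raise ValueError("lfc_cutoff must be >= 0")
        if self.min_mean_tpm < 0:
            raise ValueError("min_mean_tpm must be >= 0")
        if not (self.pos_r_cutoff > 0 > self.neg_r_cutoff):
            raise ValueError("need pos_r_cutoff > 0 > neg_r_cutoff")
        if self.pos_r_cutoff > 1 or self.neg_r_cutoff < -1:
            raise ValueError("correlation cutoffs must lie in [-1,1]")
        if self.max_chain_order < 1:
            raise ValueError("max_chain_order must be >= 1")

    @classmethod
    def for_tissue(cls, tissue: str, **overrides) -> "PipelineConfig":
        pos, neg = cls.TISSUE_CUTOFFS.get(tissue, (0.8, -0.53))
        kw = {"pos_r_cutoff": pos, "neg_r_cutoff": neg}
        kw.update(overrides)
        return cls(**kw)

    def replace(self, **kw) -> "PipelineConfig":
        return replace(self, **kw)

    def to_dict(self) -> dict:
        return {
            k: getattr(self, k)
            for k in (
                "fdr_cutoff lfc_cutoff min_mean_tpm pos_r_cutoff neg_r_cutoff "
                "max_chain_order promoter_bp cluster_max_gap_bp cluster_min_genes rng_seed"
            ).split()
        }


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def _read_tsv(path: str | Path, **kw) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"file not found: {path}")
    if path.stat().st_size == 0:
        raise FormatError(f"empty file: {path}")
    try:
        return pd.read_csv(path, sep="\t", **kw)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"empty file: {path}") from exc


def read_expression_matrix(path: str | Path, unit: str = "TPM") -> ExpressionMatrix:
    """Read a genes x samples TSV (first column gene ids, header present)."""
    df = _read_tsv(path, index_col=0)
    df.index = df.index.astype(str)
    df.index.name = "gene_id"
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise FormatError(f"non-numeric values in {path}: {exc}") from exc
    if unit == "count":
        arr = df.to_numpy()
        if not np.allclose(arr, np.round(arr)):
            raise FormatError(f"non-integer counts in {path}")
        df = df.round().astype(int)
    return ExpressionMatrix(df, unit=unit)


def write_expression_matrix(expr: ExpressionMatrix, path: str | Path) -> None:
    df = expr.values.copy()
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t", float_format="%.6g")


def read_sample_design(path: str | Path) -> SampleDesign:
    return SampleDesign(_read_tsv(path, dtype={"sample_id": str, "tissue": str}))


def write_sample_design(design: SampleDesign, path: str | Path) -> None:
    design.table.to_csv(path, sep="\t", index=False)


def read_gene_catalog(path: str | Path) -> GeneCatalog:
    """Read a catalog TSV; 1-based inclusive ``start``/``end`` accepted."""
    df = _read_tsv(path, dtype={"gene_id": str})
    if "start" in df.columns and "start0" not in df.columns:
        start = pd.to_numeric(df["start"], errors="coerce").fillna(0).astype(int)
        end = pd.to_numeric(df["end"], errors="coerce").fillna(0).astype(int)
        present = (start > 0) & (end > 0)
        df["start0"] = np.where(present, start - 1, -1)
        df["end0"] = np.where(present, end, -1)
        df = df.drop(columns=["start", "end"])
    return GeneCatalog(df)


def write_gene_catalog(catalog: GeneCatalog, path: str | Path) -> None:
    df = catalog.table.reset_index(drop=True).copy()
    has = df["start0"].astype(int) >= 0
    df["start"] = np.where(has, df["start0"].astype(int) + 1, "")
    df["end"] = np.where(has, df["end0"].astype(int), "")
    df = df.drop(columns=["start0", "end0"])
    df.to_csv(path, sep="\t", index=False)


def read_catalog_coordinates_bed(catalog: GeneCatalog, bed_path: str | Path) -> GeneCatalog:
    """Overlay 0-based half-open BED coordinates onto an existing catalog."""
    bed = pd.read_csv(
        bed_path, sep="\t", header=None, comment="#",
        names=["chrom", "start0", "end0", "gene_id", "score", "strand"],
        usecols=range(6),
    )
    t = catalog.table.reset_index(drop=True).copy()
    bed = bed.set_index("gene_id")
    known = t["gene_id"].isin(bed.index)
    unknown = bed.index.difference(t["gene_id"])
    if len(unknown):
        warnings.warn(f"{len(unknown)} BED genes absent from catalog", stacklevel=2)
    for col in ("chrom", "start0", "end0", "strand"):
        t.loc[known, col] = bed.loc[t.loc[known, "gene_id"], col].to_numpy()
    return GeneCatalog(t)


def read_catalog_coordinates_gff(catalog: GeneCatalog, gff_path: str | Path) -> GeneCatalog:
    """Overlay gene coordinates from a GFF3 file (1-based inclusive).

    Only ``gene`` features are used; the gene id is taken from the
    ``ID=`` attribute (stripping any ``gene:`` prefix).
    """
    rows = {}
    for line in Path(gff_path).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 9 or parts[2] != "gene":
            continue
        attrs = dict(
            kv.split("=", 1) for kv in parts[8].split(";") if "=" in kv
        )
        gid = attrs.get("ID", "").removeprefix("gene:")
        if gid:
            rows[gid] = (parts[0], int(parts[3]) - 1, int(parts[4]), parts[6])
    t = catalog.table.reset_index(drop=True).copy()
    known = t["gene_id"].isin(rows)
    unknown = set(rows) - set(t["gene_id"])
    if unknown:
        warnings.warn(f"{len(unknown)} GFF genes absent from catalog", stacklevel=2)
    for col, idx in (("chrom", 0), ("start0", 1), ("end0", 2), ("strand", 3)):
        t.loc[known, col] = [rows[g][idx] for g in t.loc[known, "gene_id"]]
    return GeneCatalog(t)


def read_binding_sites(path: str | Path, catalog: GeneCatalog | None = None) -> BindingSiteTable:
    df = _read_tsv(path, dtype={"tf_gene_id": str, "target_gene_id": str})
    sites = BindingSiteTable(df)
    if catalog is not None:
        sites.validate_against(catalog)
    return sites


def write_binding_sites(sites: BindingSiteTable, path: str | Path) -> None:
    sites.table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# expression utilities
# ---------------------------------------------------------------------------


def tpm_from_counts(counts: ExpressionMatrix, lengths: pd.Series | dict) -> ExpressionMatrix:
    """Convert raw counts to TPM given per-gene lengths in bp.

    Per sample: rate_g = count_g / length_kb_g, TPM_g = rate_g / sum(rates) * 1e6,
    so every sample column sums to 1e6 unless it is all zero.
    """
    if counts.unit != "count":
        raise ValueError("tpm_from_counts expects a count matrix")
    lengths = pd.Series(lengths)
    missing = [g for g in counts.gene_ids if g not in lengths.index]
    if missing:
        raise ValueError(f"missing gene lengths: {missing[:5]}")
    lengths = lengths.loc[counts.gene_ids].astype(float)
    if (lengths <= 0).any():
        bad = list(lengths.index[lengths <= 0])
        raise ValueError(f"non-positive gene lengths: {bad[:5]}")
    rate = counts.values.div(lengths / 1000.0, axis=0)
    colsum = rate.sum(axis=0)
    zero_cols = colsum == 0
    if zero_cols.any():
        warnings.warn(
            f"all-zero sample columns left as zero TPM: {list(colsum.index[zero_cols])}",
            stacklevel=2,
        )
    colsum = colsum.replace(0, np.nan)
    tpm = rate.div(colsum, axis=1).fillna(0.0) * 1e6
    return ExpressionMatrix(tpm, unit="TPM")


def stage_mean_matrix(
    expr: ExpressionMatrix, design: SampleDesign, tissue: str
) -> ExpressionMatrix:
    """Collapse replicates to arithmetic per-stage means for one tissue.

    Returns one column per stage, named ``"<tissue><stage>"``, in stage order.
    """
    stages = design.stages(tissue)
    cols = {}
    for st in stages:
        samples = design.samples_for(tissue, st)
        samples = [s for s in samples if s in expr.values.columns]
        if not samples:
            raise ValueError(f"no samples in matrix for tissue {tissue!r} stage {st}")
        cols[f"{tissue}{st}"] = expr.values[samples].mean(axis=1)
    return ExpressionMatrix(pd.DataFrame(cols), unit=expr.unit)
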