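"""Static figures and summary tables for a finished run."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

__all__ = ["render_reports"]


def render_reports(results: dict, outdir: str | Path) -> list[Path]:
    """Render the level/stage heat-map, TF-family bars and chain table.

    Returns the list of files written. With an empty network a text
    note is written instead of an empty image.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    diag: pd.DataFrame | None = results.get("diagnostic")
    if diag is None or diag.empty or diag.isna().all(axis=None):
        p = outdir / "report.txt"
        p.write_text("no leveled TFs: the network is empty\n")
        return [p]

    # diagonal heat-map: levels x stages, symmetric blue-red scale
    fig, ax = plt.subplots(figsize=(1.2 + 0.6 * diag.shape[1], 1.0 + 0.45 * diag.shape[0]))
    vmax = float(np.nanmax(np.abs(diag.to_numpy())))
    im = ax.imshow(diag.to_numpy(), cmap="RdBu_r", vmin=-vmax, vmax=vmax, aspect="auto")
    ax.set_xticks(range(diag.shape[1]), diag.columns, rotation=45, ha="right")
    ax.set_yticks(range(diag.shape[0]), [f"Level {i}" for i in diag.index])
    ax.set_xlabel("stage")
    fig.colorbar(im, ax=ax, label="mean z-score")
    fig.tight_layout()
    p = outdir / "level_heatmap.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    written.append(p)

    ranking: pd.DataFrame | None = results.get("ranking")
    if ranking is not None and len(ranking):
        top = ranking.head(15)
        fig, ax = plt.subplots(figsize=(6, 0.5 + 0.3 * len(top)))
        ax.barh(top["tf"][::-1], top["n_validated_chains"][::-1], color="#2c7fb8")
        ax.set_xlabel("validated chains rooted")
        fig.tight_layout()
        p = outdir / "top_regulators.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        written.append(p)

    for phase in ("de_novo", "elongation"):
        subnet = results.get(f"subnetwork_{phase}")
        if subnet is None or subnet.tfs.empty:
            continue
        counts = subnet.tfs["tf_family"].replace("", "unassigned").value_counts()
        fig, ax = plt.subplots(figsize=(6, 0.5 + 0.3 * len(counts)))
        ax.barh(counts.index[::-1], counts.values[::-1], color="#41ab5d")
        ax.set_xlabel(f"TFs in {phase} subnetwork")
        fig.tight_layout()
        p = outdir / f"family_{phase}.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        written.append(p)
    return written
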