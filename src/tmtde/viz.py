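"""Figures: clustered DE heatmaps, pathway heatmaps, DE count bar plots.

Every figure writes a TSV sidecar next to the image containing exactly the
numbers plotted (in plotted order), so rendered content is machine-checkable
without parsing pixels.  Row ordering in heatmaps is the leaf order of
average-linkage hierarchical clustering on Euclidean distances of
(optionally row-scaled) values, which is deterministic for fixed input.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .de_analysis import DEResultSet, STATUS_DOWN, STATUS_UP
from .enrichment import EnrichmentRecord
from .quant_io import QuantTable

logger = logging.getLogger(__name__)


@dataclass
class HeatmapSpec:
    linkage: str = "average"
    metric: str = "euclidean"
    row_scale: bool = True
    vmin: float | None = None
    vmax: float | None = None
    cmap: str = "RdBu_r"


def _row_scaled(mat: pd.DataFrame) -> pd.DataFrame:
    mu = mat.mean(axis=1)
    sd = mat.std(axis=1, ddof=0).replace(0, 1.0)
    return mat.sub(mu, axis=0).div(sd, axis=0)


def cluster_row_order(mat: pd.DataFrame, spec: HeatmapSpec) -> list[str]:
    """Leaf order of hierarchical clustering of the heatmap rows."""
    if len(mat) < 2:
        return list(mat.index)
    data = _row_scaled(mat) if spec.row_scale else mat
    link = hierarchy.linkage(pdist(data.to_numpy(), metric=spec.metric),
                             method=spec.linkage)
    leaves = hierarchy.leaves_list(link)
    return [mat.index[i] for i in leaves]


def _sidecar_path(out_path) -> Path:
    p = Path(out_path)
    return p.with_suffix(p.suffix + ".tsv") if p.suffix != ".tsv" else p


def de_heatmap(
    results: DEResultSet,
    q: QuantTable,
    spec: HeatmapSpec | None = None,
    out_path="de_heatmap.png",
) -> Path:
    """Heatmap of per-sample values for the differentially abundant proteins.

    Rows are the up/down-called proteins of ``results`` (clustered), columns
    the samples of ``q``.  Values are plotted on the log2 scale (taken from
    ``q`` directly when it is log2, else log2 of its linear values).
    """
    spec = spec or HeatmapSpec()
    de_ids = sorted(results.up_ids | results.down_ids)
    if not de_ids:
        raise ValueError("no differentially abundant proteins: nothing to plot")
    missing = [p for p in de_ids if p not in q.values.index]
    if missing:
        raise ValueError(f"DE proteins absent from quant table: {missing[:5]}")

    mat = q.values.loc[de_ids]
    if q.scale == "linear":
        with np.errstate(divide="ignore"):
            mat = np.log2(mat.where(mat > 0))
    mat = mat.dropna(how="all")
    order = cluster_row_order(mat.fillna(mat.mean(axis=None)), spec)
    mat = mat.loc[order]
    shown = _row_scaled(mat) if spec.row_scale else mat

    fig_h = max(2.0, 0.22 * len(mat) + 1.5)
    fig, ax = plt.subplots(figsize=(max(4.0, 0.5 * mat.shape[1] + 2), fig_h))
    im = ax.pcolormesh(shown.to_numpy(), cmap=spec.cmap,
                       vmin=spec.vmin, vmax=spec.vmax)
    ax.set_xticks(np.arange(mat.shape[1]) + 0.5, mat.columns,
                  rotation=90, fontsize=7)
    ax.set_yticks(np.arange(len(mat)) + 0.5, mat.index, fontsize=6)
    ax.invert_yaxis()
    ax.set_title(f"Differentially abundant proteins: {results.contrast.name}")
    fig.colorbar(im, ax=ax, label="row-scaled log2" if spec.row_scale else "log2")
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)

    shown.to_csv(_sidecar_path(out_path), sep="\t")
    logger.info("wrote %s (%d proteins)", out_path, len(mat))
    return Path(out_path)


def pathway_heatmap(
    records: list[EnrichmentRecord],
    ratios: pd.Series,
    out_path="pathway_heatmap.png",
) -> Path:
    """One panel per enriched gene set: member proteins vs their log2 ratios,
    annotated with the set's BH q-value.  Records with an empty overlap are
    skipped with a warning."""
    if not records:
        raise ValueError("no enrichment records: nothing to plot")
    panels = []
    for rec in records:
        ids = sorted(i for i in rec.overlap_ids if i in ratios.index)
        if not ids:
            logger.warning("set %r has no overlapping proteins with ratios; skipped",
                           rec.set_name)
            continue
        panels.append((rec, ids))
    if not panels:
        raise ValueError("every enrichment record had an empty overlap")

    lim = float(np.nanmax(np.abs(ratios.to_numpy()))) or 1.0
    fig, axes = plt.subplots(
        1, len(panels),
        figsize=(2.2 * len(panels) + 1.5, max(2.0, 0.3 * max(len(i) for _, i in panels) + 1.5)),
        squeeze=False,
    )
    sidecar_rows = []
    for ax, (rec, ids) in zip(axes[0], panels):
        vals = ratios.loc[ids].to_numpy()[:, None]
        im = ax.pcolormesh(vals, cmap="RdBu_r", vmin=-lim, vmax=lim)
        ax.set_yticks(np.arange(len(ids)) + 0.5, ids, fontsize=6)
        ax.set_xticks([])
        ax.invert_yaxis()
        ax.set_title(f"{rec.set_name}\nq={rec.q_value:.2e}", fontsize=7)
        sidecar_rows += [
            {"set_name": rec.set_name, "protein_id": pid,
             "log2_ratio": float(ratios[pid]), "q_value": rec.q_value}
            for pid in ids
        ]
    fig.colorbar(im, ax=axes[0][-1], label="log2 ratio")
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)

    pd.DataFrame(sidecar_rows).to_csv(_sidecar_path(out_path), sep="\t", index=False)
    return Path(out_path)


def counts_barplot(results: list[DEResultSet], out_path="de_counts.png") -> Path:
    """Bar plot of up/down DE counts per contrast."""
    if not results:
        raise ValueError("no result sets")
    rows = [
        {"contrast": r.contrast.name,
         "n_up": r.counts[STATUS_UP],
         "n_down": r.counts[STATUS_DOWN]}
        for r in results
    ]
    df = pd.DataFrame(rows)
    x = np.arange(len(df))
    fig, ax = plt.subplots(figsize=(1.6 * len(df) + 2, 3.5))
    ax.bar(x - 0.2, df["n_up"], width=0.4, color="#c0392b", label="up")
    ax.bar(x + 0.2, df["n_down"], width=0.4, color="#2980b9", label="down")
    ax.set_xticks(x, df["contrast"], rotation=30, ha="right")
    ax.set_ylabel("proteins")
    ax.legend()
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
    df.to_csv(_sidecar_path(out_path), sep="\t", index=False)
    return Path(out_path)
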