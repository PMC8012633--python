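"""End-to-end pipeline orchestration.

Stage order is fixed: filter -> log2 -> cyclic LOESS -> back to linear ->
group means -> contrast ratios -> log2 -> Tukey fences -> calls, followed
by cross-contrast comparison, optional enrichment and figures.  Every run
writes a machine-readable manifest (parameters, versions, per-stage counts)
and is bit-reproducible for a fixed config and seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .contrast_compare import (common_sets, de_membership_sets,
                               shared_universe, venn_partition)
from .de_analysis import (DEResultSet, STATUS_DOWN, STATUS_UP,
                          differential_abundance)
from .enrichment import enrich
from .preprocess import (back_to_linear, cyclic_loess_normalize,
                         filter_low_observation, to_log2)
from .quant_io import (Contrast, QuantTable, StudyDesign, read_design,
                       read_gmt, read_quant_table, write_quant_table,
                       write_results)
from .synthetic_data import SimConfig, simulate_dataset
from .viz import counts_barplot, de_heatmap

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """An error in a named pipeline stage."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Everything one run needs; exactly one of ``inputs`` / ``simulate``."""

    outdir: str = "tmtde_out"
    seed: int = 0
    inputs: dict | None = None          # quant, design, id_column, intensity_prefix
    simulate: dict | None = None        # SimConfig fields
    contrasts: list[dict] = field(default_factory=list)
    filter: dict = field(default_factory=dict)      # min_zeros_per_group, min_groups
    normalize: dict = field(default_factory=dict)   # span, iterations
    de: dict = field(default_factory=dict)          # k, quantile_method, mean_scale
    enrichment: dict = field(default_factory=dict)  # gmt, alpha, direction
    figures: bool = True
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if (self.inputs is None) == (self.simulate is None):
            raise ValueError("config needs exactly one of 'inputs' or 'simulate'")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        stray = set(raw) - known
        if stray:
            raise ValueError(f"unknown config keys: {sorted(stray)}")
        return cls(**raw)

    def contrast_objects(self, design: StudyDesign) -> list[Contrast]:
        if self.contrasts:
            out = [Contrast(c["numerator"], c["denominator"], c.get("name", ""))
                   for c in self.contrasts]
        elif self.simulate is not None:
            out = SimConfig(**{**self.simulate, "seed": self.seed}).contrast_objects()
        else:
            raise ValueError("no contrasts configured")
        for c in out:
            c.validate_against(design)
        return out


def _stage(name: str):
    def deco(fn):
        def wrapped(*a, **kw):
            try:
                return fn(*a, **kw)
            except StageError:
                raise
            except Exception as e:  # noqa: BLE001 - re-raise with stage name
                raise StageError(name, e) from e
        return wrapped
    return deco


def _df_hash(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every stage and write tables, figures and a run manifest.

    Returns the manifest dict.  Any stage failure raises :class:`StageError`
    naming the stage.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "tmtde_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "seed": cfg.seed,
        "config": {
            k: v for k, v in dataclasses.asdict(cfg).items() if k != "outdir"
        },
        "stages": {},
        "outputs": {},
    }

    # -- load or simulate --------------------------------------------------
    @_stage("input")
    def load():
        if cfg.simulate is not None:
            sim_cfg = SimConfig(**{**cfg.simulate, "seed": cfg.seed})
            table, design, truth = simulate_dataset(sim_cfg)
            truth.effects.to_csv(outdir / "sim_truth.tsv", sep="\t")
            write_quant_table(table, outdir / "sim_quant.tsv", zeros_for_missing=True)
            pd.Series(design.sample_to_group).to_csv(
                outdir / "sim_design.tsv", sep="\t", header=False)
            return table, design
        table, report = read_quant_table(
            cfg.inputs["quant"],
            id_column=cfg.inputs.get("id_column", "Protein IDs"),
            intensity_prefix=cfg.inputs.get("intensity_prefix",
                                            "Reporter intensity corrected"),
        )
        manifest["stages"]["ingest"] = {
            "n_rows_read": report.n_rows_read,
            "n_flagged_dropped": report.n_flagged_dropped,
        }
        return table, read_design(cfg.inputs["design"])

    table, design = load()
    manifest["stages"]["input"] = {
        "n_proteins": table.n_proteins,
        "n_samples": table.n_samples,
        "groups": design.group_sizes(),
    }

    # -- filter ------------------------------------------------------------
    @_stage("filter")
    def do_filter():
        return filter_low_observation(
            table, design,
            min_zeros_per_group=cfg.filter.get("min_zeros_per_group", 3),
            min_groups=cfg.filter.get("min_groups", 2),
        )

    filtered, freport = do_filter()
    manifest["stages"]["filter"] = {
        "n_input": freport.n_input,
        "n_removed": freport.n_removed,
        "n_kept": freport.n_kept,
        "min_zeros_per_group": freport.min_zeros_per_group,
        "min_groups": freport.min_groups,
        "warnings": freport.warnings,
    }
    (outdir / "filter_report.json").write_text(
        json.dumps(manifest["stages"]["filter"] | {"removed_ids": freport.removed_ids},
                   indent=2))

    # -- normalize ---------------------------------------------------------
    @_stage("normalize")
    def do_normalize():
        logt = to_log2(filtered)
        normed, nreport = cyclic_loess_normalize(
            logt,
            span=cfg.normalize.get("span", 0.7),
            iterations=cfg.normalize.get("iterations", 3),
        )
        return back_to_linear(normed), nreport

    normalized, nreport = do_normalize()
    manifest["stages"]["normalize"] = {
        "span": nreport.span,
        "iterations": nreport.iterations,
        "max_trend_pre": nreport.max_trend_pre,
        "max_trend_post": nreport.max_trend_post,
        "skipped_pairs": [list(p) for p in nreport.skipped_pairs],
    }
    (outdir / "normalization_report.json").write_text(json.dumps(
        manifest["stages"]["normalize"]
        | {"pre_medians": nreport.pre_medians, "post_medians": nreport.post_medians},
        indent=2))

    # -- differential abundance, both quantile conventions -----------------
    contrasts = cfg.contrast_objects(design)
    primary_method = cfg.de.get("quantile_method", "linear")
    alt_method = "hinges" if primary_method == "linear" else "linear"

    @_stage("de")
    def do_de() -> list[DEResultSet]:
        out = []
        for c in contrasts:
            res = differential_abundance(
                normalized, design, c,
                k=cfg.de.get("k", 1.5),
                quantile_method=primary_method,
                mean_scale=cfg.de.get("mean_scale", "linear"),
            )
            path = outdir / f"de_{c.name}.tsv"
            write_results(res, path)
            manifest["outputs"][f"de_{c.name}"] = _df_hash(path)
            alt = differential_abundance(
                normalized, design, c,
                k=cfg.de.get("k", 1.5),
                quantile_method=alt_method,
                mean_scale=cfg.de.get("mean_scale", "linear"),
            )
            manifest["stages"].setdefault("de", {})[c.name] = {
                "n_up": res.counts[STATUS_UP],
                "n_down": res.counts[STATUS_DOWN],
                "fences": [res.fences.lower, res.fences.upper],
                "quantile_method": primary_method,
                f"n_up_{alt_method}": alt.counts[STATUS_UP],
                f"n_down_{alt_method}": alt.counts[STATUS_DOWN],
            }
            out.append(res)
        return out

    results = do_de()

    # -- cross-contrast comparison ----------------------------------------
    if len(results) >= 2:
        @_stage("compare")
        def do_compare():
            universe = shared_universe(results)
            part = venn_partition(
                {k: v & universe for k, v in de_membership_sets(results).items()},
                universe,
            )
            part.to_frame().to_csv(outdir / "venn_regions.tsv", sep="\t", index=False)
            up, down = common_sets(results[0], results[1])
            pd.DataFrame({
                "direction": ["up"] * len(up) + ["down"] * len(down),
                "protein_id": sorted(up) + sorted(down),
            }).to_csv(outdir / "common_proteins.tsv", sep="\t", index=False)
            manifest["stages"]["compare"] = {
                "universe_size": part.universe_size,
                "not_enriched": len(part.not_enriched),
                "n_common_up": len(up),
                "n_common_down": len(down),
            }

        do_compare()

    # -- enrichment --------------------------------------------------------
    gmt_path = cfg.enrichment.get("gmt")
    if gmt_path:
        @_stage("enrichment")
        def do_enrich():
            sets = read_gmt(gmt_path)
            alpha = cfg.enrichment.get("alpha", 0.05)
            universe = [
                table.gene_symbols.get(p) or p for p in results[0].protein_ids
            ]
            for res in results:
                for direction, ids in (("up", res.up_ids), ("down", res.down_ids)):
                    if cfg.enrichment.get("direction", "both") not in ("both", direction):
                        continue
                    if not ids:
                        continue
                    query = [table.gene_symbols.get(p) or p for p in ids]
                    recs = enrich(query, sets, universe, alpha=alpha)
                    write_results(
                        recs, outdir / f"enrichment_{res.contrast.name}_{direction}.tsv")
                    manifest["stages"].setdefault("enrichment", {})[
                        f"{res.contrast.name}_{direction}"
                    ] = {"n_sets_tested": len(recs),
                         "n_significant": sum(r.q_value <= alpha for r in recs)}

        do_enrich()

    # -- figures -----------------------------------------------------------
    if cfg.figures:
        @_stage("figures")
        def do_figures():
            logt = to_log2(normalized)
            for res in results:
                if res.up_ids | res.down_ids:
                    de_heatmap(res, logt,
                               out_path=outdir / f"heatmap_{res.contrast.name}.png")
            counts_barplot(results, out_path=outdir / "de_counts.png")

        do_figures()

    manifest_json = json.dumps(manifest, indent=2, sort_keys=True)
    (outdir / "manifest.json").write_text(manifest_json)
    manifest["manifest_sha256"] = hashlib.sha256(manifest_json.encode()).hexdigest()
    logger.info("pipeline complete: %s", outdir)
    return manifest
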