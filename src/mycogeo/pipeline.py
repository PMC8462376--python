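"""End-to-end orchestration: ingest/simulate through maps and OA curves.

Each stage is a pure function of (inputs, config); the run manifest
records the config snapshot, per-stage timings, and output inventory so
a run can be reproduced byte-for-byte from its manifest.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import classify as cls
from . import kriging, paired, variogram
from .config import PipelineConfig, stage_seed
from .simulate import simulate_study
from .table import (
    SpatialOtuTable,
    read_spatial_otu_table,
    remove_singletons,
    write_spatial_otu_table,
)

logger = logging.getLogger(__name__)

__all__ = ["RunManifest", "run_pipeline"]


@dataclass
class RunManifest:
    config: dict
    seed: int
    stage_timings: dict[str, float] = field(default_factory=dict)
    outputs: list[str] = field(default_factory=list)
    audit: dict = field(default_factory=dict)

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, default=str))


def _load_or_simulate(cfg: PipelineConfig, out: Path, manifest: RunManifest) -> SpatialOtuTable:
    if cfg.abundance_path is not None:
        return read_spatial_otu_table(
            cfg.abundance_path, cfg.metadata_path, normalized=cfg.abundance_normalized
        )
    table, truth = simulate_study(cfg.synthetic)
    write_spatial_otu_table(table, out / "abundance.tsv", out / "metadata.tsv")
    truth.to_csv(out / "ground_truth.tsv", sep="\t", index=False)
    manifest.outputs += ["abundance.tsv", "metadata.tsv", "ground_truth.tsv"]
    return table


def run_pipeline(cfg: PipelineConfig) -> RunManifest:
    """Run every stage, write TSV outputs under ``cfg.output_dir``.

    Stages: ingest/simulate -> paired-habitat test -> singleton removal
    -> classification -> occupancy comparison -> Mantel screen -> range
    estimation -> culling -> range comparison -> paired kriged maps ->
    occupancy-abundance points and loess curves -> manifest.
    """
    cfg.validate()
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=cfg.to_dict(), seed=cfg.seed)

    def timed(stage, fn):
        t0 = time.perf_counter()
        result = fn()
        manifest.stage_timings[stage] = round(time.perf_counter() - t0, 4)
        logger.info("stage %-10s %.2fs", stage, manifest.stage_timings[stage])
        return result

    table = timed("ingest", lambda: _load_or_simulate(cfg, out, manifest))

    # paired-habitat test runs on the unfiltered table (dissimilarity keeps singletons)
    results = timed(
        "paired",
        lambda: paired.inter_habitat_test(
            table,
            scale=cfg.paired_scale,
            n_randomizations=cfg.n_randomizations,
            seed=stage_seed(cfg.seed, "paired"),
        ),
    )
    paired.results_to_frame(results).to_csv(out / "paired_habitat.tsv", sep="\t", index=False)
    manifest.outputs.append("paired_habitat.tsv")

    filtered = remove_singletons(table)
    classifications = timed(
        "classify", lambda: cls.classify_otus(filtered, scope=cfg.classification_scope)
    )
    cls.classifications_to_frame(classifications).to_csv(
        out / "classifications.tsv", sep="\t", index=False
    )
    occ_cmp = cls.compare_occupancy(classifications)
    occ_cmp.to_csv(out / "occupancy_comparison.tsv", sep="\t", index=False)
    manifest.outputs += ["classifications.tsv", "occupancy_comparison.tsv"]

    screen = timed(
        "screen",
        lambda: variogram.mantel_screen(
            filtered,
            alpha=cfg.alpha,
            n_permutations=cfg.n_permutations,
            seed=stage_seed(cfg.seed, "screen"),
        ),
    )
    screen.to_csv(out / "mantel_screen.tsv", sep="\t", index=False)
    manifest.outputs.append("mantel_screen.tsv")

    normalized = filtered if filtered.normalized else filtered.log1p_normalized()
    estimates = timed(
        "ranges",
        lambda: variogram.estimate_ranges(
            normalized,
            classifications,
            screen,
            n_bins=cfg.variogram_bins,
            min_pairs=cfg.variogram_min_pairs,
            report=cfg.range_report,
        ),
    )
    diag = _transect_diagonal(table)
    estimates, audit = variogram.cull_and_flag(
        estimates, min_range_m=cfg.min_range_m, max_range_m=diag, tukey_fence=cfg.tukey_fence
    )
    variogram.estimates_to_frame(estimates).to_csv(out / "range_estimates.tsv", sep="\t", index=False)
    manifest.audit = asdict(audit) | {"n_remaining": audit.n_remaining}
    (out / "culling_audit.json").write_text(json.dumps(manifest.audit, indent=2))
    range_cmp = variogram.compare_ranges(estimates)
    range_cmp.to_csv(out / "range_comparison.tsv", sep="\t", index=False)
    manifest.outputs += ["range_estimates.tsv", "culling_audit.json", "range_comparison.tsv"]

    maps = timed(
        "maps",
        lambda: kriging.paired_surface_maps(
            normalized, classifications, estimates, grid_resolution=cfg.grid_resolution
        ),
    )
    if len(maps):
        maps[["otu_id", "transect", "raster_correlation"]].to_csv(
            out / "map_synchrony.tsv", sep="\t", index=False
        )
        manifest.outputs.append("map_synchrony.tsv")
        for _, row in maps.iterrows():
            for hab_col in ("soil_surface", "phylloplane_surface"):
                surf = row[hab_col]
                name = f"surface_{surf.otu_id}_{surf.transect_id}_{surf.habitat}.tsv"
                surf.to_frame().to_csv(out / name, sep="\t", index=False)
                manifest.outputs.append(name)
            if cfg.render_maps:
                png = f"maps_{row['otu_id']}_{row['transect']}.png"
                kriging.render_surface_pair(
                    row["soil_surface"], row["phylloplane_surface"], out / png
                )
                manifest.outputs.append(png)

    oa = timed(
        "oa", lambda: cls.occupancy_abundance_points(normalized, classifications)
    )
    oa.to_csv(out / "oa_points.tsv", sep="\t", index=False)
    manifest.outputs.append("oa_points.tsv")
    curves = []
    for (habitat, label), grp in oa.groupby(["habitat", "label"], sort=False):
        if len(grp) < max(5, cfg.loess_degree + 2):
            continue
        curve = cls.loess_curve(
            grp["occupancy"].to_numpy(float),
            grp["local_abundance"].to_numpy(float),
            span=cfg.loess_span,
            degree=cfg.loess_degree,
        )
        curve.insert(0, "habitat", habitat)
        curve.insert(1, "label", label)
        curves.append(curve)
    if curves:
        pd.concat(curves).to_csv(out / "oa_curves.tsv", sep="\t", index=False)
        manifest.outputs.append("oa_curves.tsv")

    manifest.write(out / "manifest.json")
    return manifest


def _transect_diagonal(table: SpatialOtuTable) -> float:
    """Largest within-transect extent: the outlier fence for range sizes."""
    diag = 0.0
    for _, grp in table.metadata.groupby("transect", sort=False):
        dx = grp["x"].max() - grp["x"].min()
        dy = grp["y"].max() - grp["y"].min()
        diag = max(diag, float((dx**2 + dy**2) ** 0.5))
    return diag if diag > 0 else float("inf")
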