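"""Pipeline configuration: every tunable in one place, YAML round-trip.

A single master seed deterministically spawns per-stage seeds so each
stage is reproducible in isolation while the full run stays collision
free.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import yaml

from .design import StudyDesign
from .simulate import SyntheticParams

__all__ = ["PipelineConfig", "stage_seed"]


@dataclass
class PipelineConfig:
    """All tunables of the end-to-end run with the study's defaults."""

    seed: int = 0
    # inputs: either a TSV pair...
    abundance_path: str | None = None
    metadata_path: str | None = None
    abundance_normalized: bool = False
    # ...or synthetic parameters
    synthetic: SyntheticParams | None = None
    # paired-habitat test
    n_randomizations: int = 99
    paired_scale: str = "both"
    # statistics
    n_permutations: int = 999
    alpha: float = 0.05
    # classification
    classification_scope: str = "per_transect"
    # loess
    loess_span: float = 0.75
    loess_degree: int = 2
    # variography
    variogram_bins: int = 12
    variogram_min_pairs: int = 10
    min_range_m: float = 1.0
    range_report: str = "effective"
    tukey_fence: bool = False
    # kriging
    grid_resolution: float = 0.5
    render_maps: bool = False
    # output
    output_dir: str = "mycogeo_out"

    def validate(self) -> None:
        has_files = self.abundance_path is not None and self.metadata_path is not None
        if not has_files and self.synthetic is None:
            raise ValueError("config must name either input TSVs or synthetic parameters")

    # -- YAML round trip -------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        if self.synthetic is not None:
            d["synthetic"]["design"] = asdict(self.synthetic.design)
            d["synthetic"]["design"]["habitats"] = list(self.synthetic.design.habitats)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        syn = d.pop("synthetic", None)
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**d)
        if syn is not None:
            syn = dict(syn)
            des = syn.pop("design", None)
            design = StudyDesign(**{**des, "habitats": tuple(des["habitats"])}) if des else StudyDesign()
            cfg.synthetic = SyntheticParams(design=design, **syn)
        return cfg

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


_STAGES = (
    "simulate",
    "paired",
    "classify",
    "screen",
    "ranges",
    "maps",
    "oa",
)


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed spawned from the master seed (< 2^31)."""
    if stage not in _STAGES:
        raise ValueError(f"unknown stage {stage!r}; expected one of {_STAGES}")
    ss = np.random.SeedSequence([int(master_seed), _STAGES.index(stage)])
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31 - 1))
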