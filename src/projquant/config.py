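"""Pipeline configuration: one file, every stage parameter, strict parsing.

Defaults are the canonical analysis parameters (eight binarization
thresholds 0.2–0.9, 10,000-voxel component cutoff, 80% injection-site
rule, σ = 4 filters, 75/95% contour levels, 225 µm peak ROI, top-75
ranking, 300 ms ΔF/F baseline, 10–260 ms evoked window, 40 × 25 pixel
frontal mask at 80% of max).  Unknown keys are rejected so a typo cannot
silently fall back to a default.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .skeleton import DEFAULT_THRESHOLDS

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    seed: int = 0
    input_dir: str | None = None
    output_dir: str | None = None

    # skeletonization
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS
    min_component_size: int = 10_000
    connectivity: int = 26

    # mapping / QC
    atlas_voxel_size_um: float = 25.0
    qc_targets: tuple[str, ...] = ("SSp-bfd", "SSs")
    qc_min_fraction: float = 0.8

    # region quantification
    rollup_levels: int = 1
    top_n: int = 75

    # similarity
    sigma_spatial: float = 4.0
    line_order: tuple[str, ...] = ("SynthCre",)

    # hotspot topography
    mo_regions: tuple[str, ...] = ("MOp", "MOs")
    mo_layers: tuple[str, ...] = ("2/3", "5")
    sigma_hotspot_px: float = 4.0
    contour_levels: tuple[float, float] = (0.75, 0.95)
    roi_um: float = 225.0
    sigma_striatum: float = 4.0

    # wide-field
    baseline_ms: float = 300.0
    window_ms: tuple[float, float] = (10.0, 260.0)
    com_mask_shape: tuple[int, int] = (25, 40)
    com_frac: float = 0.8

    def __post_init__(self) -> None:
        if self.qc_min_fraction < 0 or self.qc_min_fraction > 1:
            raise ValueError("qc_min_fraction must lie in [0, 1]")
        if self.min_component_size < 0:
            raise ValueError("min_component_size must be >= 0")
        lo, hi = self.contour_levels
        if not 0 < lo < hi <= 1:
            raise ValueError(f"contour_levels must satisfy 0 < lo < hi <= 1, got {self.contour_levels}")

    # ------------------------------------------------------------------ #
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        names = {f.name for f in dataclasses.fields(cls)}
        unknown = sorted(set(d) - names)
        if unknown:
            raise ValueError(f"unknown configuration key(s): {unknown}")
        kwargs = {}
        for f in dataclasses.fields(cls):
            if f.name not in d:
                continue
            v = d[f.name]
            if isinstance(v, list):
                v = tuple(v)
            kwargs[f.name] = v
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(data, dict):
            raise ValueError("configuration file must hold a mapping")
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
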