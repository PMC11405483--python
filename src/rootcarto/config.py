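"""Run configuration shared by the CLI and the pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

#: default outer radii (µm) of the concentric tissue layers, innermost first.
#: Desk-scale geometry matching the synthetic generator's defaults.
DEFAULT_LAYER_RADII: dict[str, float] = {
    "vascular": 7.0,
    "pericycle": 11.0,
    "endodermis": 15.0,
    "cortex": 20.0,
    "epidermis": 25.5,
}


@dataclass
class RunConfig:
    """All tunable knobs of the analysis pipeline.

    Thresholds follow the package's documented defaults; every value can be
    overridden from YAML (see :meth:`from_yaml`).
    """

    # io
    channel_map: dict[str, int | str] | None = None
    voxel_size: tuple[float, float, float] | None = None

    # segmentation
    threshold_method: str = "triangle"      # or "otsu" / "fixed"
    fixed_threshold: float | None = None
    min_object_voxels: int = 8
    split_touching: bool = False
    min_seed_sep_um: float = 3.0
    vmin_um3: float = 5.0                   # curation volume window
    vmax_um3: float = 500.0

    # root frame / annotation
    layer_radii: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_LAYER_RADII))
    lrc_extent_um: float = 35.0             # max z of the lateral root cap
    columella_radius_um: float = 6.0
    zone_k: float = 1.5                     # PD/TD spacing-increase factor
    zone_k2: float = 3.0                    # TD/EZ spacing-increase factor
    calibration_window_um: float = 15.0     # |z| window for the 2C reference

    # chromatin
    enrichment_threshold: float = 0.55
    hue_ranges: tuple[tuple[int, int], ...] = ((0, 15), (16, 58), (59, 255))

    # replication
    noise_k: float = 3.0                    # background mean + k*SD noise floor
    coverage_threshold: float = 0.6
    min_spots: int = 3
    min_spot_voxels: int = 2

    seed: int = 0

    def __post_init__(self) -> None:
        radii = list(self.layer_radii.values())
        if any(b <= a for a, b in zip(radii, radii[1:])):
            raise ValueError("layer radii must be strictly increasing outward")
        if not 0.5 < self.enrichment_threshold <= 1.0:
            raise ValueError("enrichment threshold must be in (0.5, 1]")
        if not 0.0 < self.coverage_threshold <= 1.0:
            raise ValueError("coverage threshold must be in (0, 1]")
        if self.zone_k <= 1.0 or self.zone_k2 <= 1.0:
            raise ValueError("zone spacing factors must exceed 1")
        if self.noise_k < 0:
            raise ValueError("noise_k must be non-negative")

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(asdict(self), sort_keys=False))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if "voxel_size" in data and data["voxel_size"] is not None:
            data["voxel_size"] = tuple(data["voxel_size"])
        if "hue_ranges" in data:
            data["hue_ranges"] = tuple(tuple(r) for r in data["hue_ranges"])
        return cls(**data)
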