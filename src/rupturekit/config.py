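"""TOML run configuration binding all pipeline stages together.

A config file has optional sections; absent sections fall back to the
documented defaults of each stage::

    [paths]
    output_dir = "out"
    plate_map = "plate_map.csv"     # optional
    image_root = "images"           # optional

    [run]
    seed = 1

    [segmentation]                  # SegmentationParams fields
    erosion_radius = 3

    [filters]                       # FilterConfig fields (global scalars)
    rfp_expression_min = 40.0

    [calling]
    k = 1.0
    min_rfp_events = 175
    control_condition = "CTRL"

    [stats]
    alpha = 0.05
    lfc_cut = 0.3

    [lamina]                        # GapParams fields
    merge_cut_um3 = 5.0
    voxel_spacing = [0.2, 0.1, 0.1]
"""

from __future__ import annotations

import dataclasses
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

from .calling import DEFAULT_MIN_RFP_EVENTS, FilterConfig
from .lamina import GapParams
from .segmentation import SegmentationParams

__all__ = ["RunConfig", "load_config", "ConfigError"]


class ConfigError(ValueError):
    """Invalid or inconsistent run configuration."""


@dataclass
class RunConfig:
    output_dir: Path = Path("out")
    plate_map: Path | None = None
    image_root: Path | None = None
    seed: int = 0
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    filters: FilterConfig = field(default_factory=FilterConfig)
    k: float = 1.0
    min_rfp_events: int = DEFAULT_MIN_RFP_EVENTS
    control_condition: str = "CTRL"
    alpha: float = 0.05
    lfc_cut: float = 0.3
    lamina: GapParams = field(default_factory=GapParams)
    voxel_spacing: tuple[float, float, float] = (0.2, 0.1, 0.1)

    def validate(self, require_inputs: bool = False) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ConfigError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.lfc_cut < 0:
            raise ConfigError("lfc_cut must be >= 0")
        if self.min_rfp_events < 0:
            raise ConfigError("min_rfp_events must be >= 0")
        if any(s <= 0 for s in self.voxel_spacing):
            raise ConfigError("voxel_spacing entries must be positive")
        if require_inputs:
            for name in ("plate_map", "image_root"):
                p = getattr(self, name)
                if p is not None and not Path(p).exists():
                    raise ConfigError(f"{name} does not exist: {p}")

    def as_dict(self) -> dict:
        """Flat JSON-serializable view, used for the manifest config hash."""
        d = {
            "output_dir": str(self.output_dir),
            "plate_map": str(self.plate_map) if self.plate_map else None,
            "image_root": str(self.image_root) if self.image_root else None,
            "seed": self.seed,
            "k": self.k,
            "min_rfp_events": self.min_rfp_events,
            "control_condition": self.control_condition,
            "alpha": self.alpha,
            "lfc_cut": self.lfc_cut,
            "voxel_spacing": list(self.voxel_spacing),
            "segmentation": dataclasses.asdict(self.segmentation),
            "filters": dataclasses.asdict(self.filters),
            "lamina": dataclasses.asdict(self.lamina),
        }
        return d


def _build(cls, section: dict, where: str):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(section) - known
    if unknown:
        raise ConfigError(f"[{where}]: unknown keys {sorted(unknown)}")
    try:
        return cls(**section)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"[{where}]: {exc}") from exc


def load_config(path=None, overrides: dict | None = None) -> RunConfig:
    """Load a TOML config file (or defaults when ``path`` is None)."""
    raw: dict = {}
    if path is not None:
        p = Path(path)
        if not p.exists():
            raise ConfigError(f"config file not found: {p}")
        with open(p, "rb") as fh:
            try:
                raw = tomllib.load(fh)
            except tomllib.TOMLDecodeError as exc:
                raise ConfigError(f"{p}: {exc}") from exc

    known_sections = {"paths", "run", "segmentation", "filters", "calling",
                      "stats", "lamina"}
    unknown = set(raw) - known_sections
    if unknown:
        raise ConfigError(f"unknown config sections {sorted(unknown)}")

    cfg = RunConfig()
    paths = raw.get("paths", {})
    if "output_dir" in paths:
        cfg.output_dir = Path(paths["output_dir"])
    if "plate_map" in paths:
        cfg.plate_map = Path(paths["plate_map"])
    if "image_root" in paths:
        cfg.image_root = Path(paths["image_root"])
    cfg.seed = int(raw.get("run", {}).get("seed", cfg.seed))
    if "segmentation" in raw:
        cfg.segmentation = _build(SegmentationParams, raw["segmentation"],
                                  "segmentation")
    if "filters" in raw:
        fsec = dict(raw["filters"])
        if "solidity_quantiles" in fsec:
            fsec["solidity_quantiles"] = tuple(fsec["solidity_quantiles"])
        cfg.filters = _build(FilterConfig, fsec, "filters")
    calling = raw.get("calling", {})
    cfg.k = float(calling.get("k", cfg.k))
    cfg.min_rfp_events = int(calling.get("min_rfp_events", cfg.min_rfp_events))
    cfg.control_condition = calling.get("control_condition",
                                        cfg.control_condition)
    stats = raw.get("stats", {})
    cfg.alpha = float(stats.get("alpha", cfg.alpha))
    cfg.lfc_cut = float(stats.get("lfc_cut", cfg.lfc_cut))
    if "lamina" in raw:
        lsec = dict(raw["lamina"])
        cfg.voxel_spacing = tuple(lsec.pop("voxel_spacing", cfg.voxel_spacing))
        if "volume_bounds_um3" in lsec and lsec["volume_bounds_um3"] is not None:
            lsec["volume_bounds_um3"] = tuple(lsec["volume_bounds_um3"])
        cfg.lamina = _build(GapParams, lsec, "lamina")
    for key, val in (overrides or {}).items():
        setattr(cfg, key, val)
    cfg.validate()
    return cfg
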