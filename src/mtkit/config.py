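"""Pipeline configuration: one human-readable YAML file governs every
threshold; unknown keys are rejected so typos cannot silently fall back to
defaults."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigurationError
from .imaging import OocyteGeometry  # noqa: F401  (re-export convenience)
from .streaming import ClassifierParams, FlowParams
from .transport import SegmentationParams

__all__ = ["PtmParams", "ImagingParams", "PipelineConfig", "load_config"]


@dataclass(frozen=True)
class PtmParams:
    tolerance_da: float = 0.01

    def __post_init__(self) -> None:
        if self.tolerance_da <= 0:
            raise ConfigurationError(f"tolerance_da must be > 0, got {self.tolerance_da}")


@dataclass(frozen=True)
class ImagingParams:
    crescent_threshold_frac: float = 0.5
    enrichment_band_frac: float = 0.15
    enrichment_ratio_min: float = 1.3
    peak_margin_frac: float = 0.1
    peak_prominence_frac: float = 0.2

    def __post_init__(self) -> None:
        if not (0 < self.crescent_threshold_frac < 1):
            raise ConfigurationError(
                f"crescent_threshold_frac must be in (0, 1), got {self.crescent_threshold_frac}"
            )
        if not (0 < self.enrichment_band_frac < 1):
            raise ConfigurationError(
                f"enrichment_band_frac must be in (0, 1), got {self.enrichment_band_frac}"
            )
        if self.enrichment_ratio_min <= 0:
            raise ConfigurationError("enrichment_ratio_min must be > 0")


@dataclass(frozen=True)
class PipelineConfig:
    """All analysis parameters plus the run seed and output directory."""

    seed: int = 0
    out_dir: str = "mtk-report"
    transport: SegmentationParams = field(default_factory=SegmentationParams)
    flow: FlowParams = field(default_factory=FlowParams)
    classifier: ClassifierParams = field(default_factory=ClassifierParams)
    ptm: PtmParams = field(default_factory=PtmParams)
    imaging: ImagingParams = field(default_factory=ImagingParams)


_BLOCKS = {
    "transport": SegmentationParams,
    "flow": FlowParams,
    "classifier": ClassifierParams,
    "ptm": PtmParams,
    "imaging": ImagingParams,
}


def _build(cls, data: dict, context: str):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ConfigurationError(f"unknown key(s) in {context}: {sorted(unknown)}")
    try:
        return cls(**data)
    except TypeError as e:
        raise ConfigurationError(f"invalid {context}: {e}") from e


def load_config(source: str | Path | dict | None = None) -> PipelineConfig:
    """Build a PipelineConfig from a YAML file or a nested dict.

    Missing blocks/keys take their documented defaults; unknown keys raise
    a ConfigurationError naming the offending key.
    """
    if source is None:
        return PipelineConfig()
    if isinstance(source, (str, Path)):
        data = yaml.safe_load(Path(source).read_text()) or {}
    else:
        data = dict(source)
    if not isinstance(data, dict):
        raise ConfigurationError("config root must be a mapping")
    top_known = {"seed", "out_dir", *_BLOCKS}
    unknown = set(data) - top_known
    if unknown:
        raise ConfigurationError(f"unknown top-level key(s): {sorted(unknown)}")
    kwargs: dict = {}
    if "seed" in data:
        kwargs["seed"] = int(data["seed"])
    if "out_dir" in data:
        kwargs["out_dir"] = str(data["out_dir"])
    for name, cls in _BLOCKS.items():
        if name in data:
            block = data[name] or {}
            if not isinstance(block, dict):
                raise ConfigurationError(f"config block {name!r} must be a mapping")
            kwargs[name] = _build(cls, block, f"config block {name!r}")
    return PipelineConfig(**kwargs)
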