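"""Pipeline configuration with the analysis constants as defaults."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    """All tunable thresholds and shuffle sizes of the analysis pipeline.

    Defaults are the values used throughout the analysis: HD cells need an
    HD score > 0.4 with a tuning-curve peak > 5 Hz and a distributive
    ratio > 0.2; score significance uses 100 positional shuffles and
    visually driven changes 500 trial-label shuffles, both at the 99th
    percentile; the theta-index class boundary defaults to the mixture fit
    (override with ``theta_index_threshold``); cycle skipping uses 0.1,
    bidirectionality 0.2 and theta synchrony 0.2.
    """

    hd_score_threshold: float = 0.4
    hd_peak_threshold_hz: float = 5.0
    distributive_ratio_threshold: float = 0.2
    bd_threshold: float = 0.2
    skipping_threshold: float = 0.1
    synchrony_threshold: float = 0.2
    theta_index_threshold: float | None = None   # None = fit the mixture
    n_positional_shuffles: int = 100
    n_label_shuffles: int = 500
    shuffle_percentile: float = 99.0
    min_shift_s: float = 20.0
    speed_min_cms: float = 3.0
    seed: int = 0

    def to_yaml(self, path: str | Path):
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        valid = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - valid
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)
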