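"""Pipeline configuration.

Every threshold used by the preprocessing and feature-extraction stages is a
wall-clock or physical-unit rule (hours, mg, degrees Celsius), collected here
with its default so that a study can override any of them from a YAML file.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml


@dataclass
class ApEnParams:
    """Approximate-entropy parameterization.

    m is the embedding (template) length; the tolerance r is either an
    absolute value or ``r_coeff * sd(x)`` when ``r_mode == "relative_sd"``.
    """

    m: int = 2
    r_mode: str = "relative_sd"  # "relative_sd" | "absolute"
    r_coeff: float = 0.2
    r_absolute: float = 0.0

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError(f"m must be >= 1, got {self.m}")
        if self.r_mode not in ("relative_sd", "absolute"):
            raise ValueError(f"unknown r_mode {self.r_mode!r}")
        if self.r_mode == "relative_sd" and self.r_coeff < 0:
            raise ValueError("r_coeff must be non-negative")
        if self.r_mode == "absolute" and self.r_absolute < 0:
            raise ValueError("r_absolute must be non-negative")

    def tolerance(self, sd: float) -> float:
        return self.r_coeff * sd if self.r_mode == "relative_sd" else self.r_absolute


@dataclass
class PipelineConfig:
    """Signal-conditioning and feature-extraction thresholds.

    Defaults implement the published processing rules for wrist-worn
    GENEActiv-style recordings: non-wear stillness thresholds of 13 mg
    (standard deviation) or 50 mg (range) on at least two of three axes over a
    60-min window centred on each 15-min block; valid days require >= 16 h of
    wear and usable wear periods >= 7 valid days; nights (noon-to-noon) with
    more than 10% non-wear are dropped; wrist temperatures below 24 degC are
    linearly interpolated; temperature is averaged into 15-min bins and
    smoothed with a 7-point (q=3) moving average; the sleep night window is
    19:00-14:00 (>= 61 of 77 quarter-hour points required) and the day window
    08:00-08:00 (>= 77 of 97 points); a night additionally needs >= 15
    in-sleep temperature points.
    """

    # non-wear detection
    nonwear_sd_mg: float = 13.0
    nonwear_range_mg: float = 50.0
    nonwear_min_axes: int = 2
    nonwear_block_min: int = 15
    nonwear_window_min: int = 60

    # valid-day / valid-night filters
    valid_day_hours: float = 16.0
    valid_day_inclusive: bool = True
    min_valid_days: int = 7
    night_nonwear_max_frac: float = 0.10
    night_def_start_hour: int = 12  # nights are noon-to-noon 24-h windows

    # temperature conditioning
    low_temp_c: float = 24.0
    temp_bin_min: int = 15
    smooth_q: int = 3

    # sleep-night / day windows for temperature features
    night_window_start_hour: int = 19   # 19:00 ...
    night_window_end_hour: int = 14     # ... to 14:00 next day
    day_window_start_hour: int = 8      # 08:00 to 08:00 next day
    min_night_coverage: int = 61        # of the 77 quarter-hour night points
    min_day_coverage: int = 77          # of the 97 quarter-hour day points
    min_sleep_points: int = 15

    # entropy
    apen: ApEnParams = field(default_factory=ApEnParams)

    # modelling
    m_sel: int = 10
    logreg_c: float = 1.0

    # exploratory screen
    spearman_strong: float = 0.3
    spearman_alpha: float = 0.05

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        apen = ApEnParams(**raw.pop("apen", {}))
        return cls(apen=apen, **raw)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))


DEFAULT_CONFIG = PipelineConfig()
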