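"""Run configuration.

Every analysis constant lives here rather than being hard-coded: sampling
rates, preprocessing thresholds, tessellation geometry, kernel parameters,
the train fraction and the saliency threshold.  Configurations round-trip
through flat YAML files and carry a content hash that output files embed
for provenance.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field, fields, replace
from pathlib import Path

import yaml

from .kernels import ResponseKernel, make_kernel
from .regions import DEFAULT_OUTER_ECC, RegionMap, build_region_map

__all__ = ["RunConfig", "load_config", "save_config"]


@dataclass(frozen=True)
class RunConfig:
    """All tunable constants of the pipeline with their standard defaults."""

    # sampling
    tracker_rate: float = 500.0       # Hz, eye-tracker input
    movie_rate: float = 25.0          # Hz, movie/model rate
    # preprocessing
    blink_velocity_sd: float = 3.0    # blink threshold, SD of change velocity
    gaze_radius: float = 2.5          # deg, fixation window
    gaze_purge_after: float = 2.0     # s purged after a deviation
    max_missing_postblink: float = 0.30
    max_missing_postgaze: float = 0.50
    min_trials_per_condition: int = 2
    # tessellation
    n_sectors: int = 8
    inner_ecc: float = 1.5            # deg, central-disc radius
    outer_ecc: float = DEFAULT_OUTER_ECC
    pixels_per_degree: float = 19.1
    # response kernels
    kernel_n: float = 10.1
    kernel_t_max: float = 0.93        # s
    kernel_duration: float = 4.0      # s
    light_gain: float = 1.0
    dark_gain: float = 0.5
    # fitting and analysis
    train_frac: float = 0.7
    saliency_threshold: float = 5.0   # cd/m^2
    response_window: float = 1.5      # s
    epoch_length: float = 3.0         # s
    epoch_baseline: float = 0.25      # s
    # frame decoding
    max_luminance: float = 100.0      # cd/m^2 at code value 255
    gamma: float = 2.2
    # randomness
    seed: int = 0

    def region_map(self) -> RegionMap:
        return build_region_map(n_sectors=self.n_sectors,
                                inner_ecc=self.inner_ecc,
                                outer_ecc=self.outer_ecc)

    def kernels(self) -> tuple[ResponseKernel, ResponseKernel]:
        common = dict(n=self.kernel_n, t_max=self.kernel_t_max,
                      duration=self.kernel_duration, rate=self.movie_rate)
        return (make_kernel(gain=self.light_gain, polarity="light", **common),
                make_kernel(gain=self.dark_gain, polarity="dark", **common))

    def hash(self) -> str:
        payload = yaml.safe_dump(asdict(self), sort_keys=True)
        return hashlib.sha1(payload.encode()).hexdigest()[:12]

    def with_overrides(self, **kw) -> "RunConfig":
        return replace(self, **kw)


def load_config(path: str | Path | None = None, **overrides) -> RunConfig:
    """Load a flat YAML mapping into a RunConfig; unknown keys are rejected."""
    cfg = RunConfig()
    if path is not None:
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(RunConfig)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = replace(cfg, **data)
    if overrides:
        cfg = replace(cfg, **overrides)
    return cfg


def save_config(cfg: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(asdict(cfg), sort_keys=True))
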