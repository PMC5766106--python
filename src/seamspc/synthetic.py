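"""Seeded generator of multi-sensor ocean-observatory scenarios.

Emulates the statistical structure a seabed lander produces, at the level the
monitoring statistics care about (latent factors, loadings, noise, sampling
rates) rather than ocean physics:

* a slow seasonal latent trend driving three offset-but-correlated
  temperature sensors, with conductivity and salinity tied to temperature;
* two latent current-forcing factors (east and north) expressed through two
  profiler blocks with depth-attenuation gradients and overlapping depths,
  the eastern direction more pronounced;
* a biomass factor behind three echo-sounder depth bands and chlorophyll;
* a weakly structured turbidity variable;
* heterogeneous sampling intervals (5 min, 10 min, 1 h) and sporadic
  missing values.

Anomalies (mean shift, drift, saturation/flat-line, decorrelation of a
redundant sensor, dropout) can be injected from a chosen onset with ground
truth labels, for power and coverage studies.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .alignment import SensorStream
from .diagnostics import RedundancyGroup
from .multiblock import BlockSpec

__all__ = [
    "ScenarioConfig",
    "ScenarioTruth",
    "AnomalySpec",
    "generate_scenario",
    "inject_anomaly",
    "default_blocks",
    "default_redundancy_groups",
]

AQUA_DEPTHS = tuple(3.0 + 2.5 * k for k in range(9))       # 3 .. 23 m
CONTI_DEPTHS = tuple(8.0 + 5.0 * k for k in range(30))     # 8 .. 153 m
OVERLAP_DEPTHS = (8.0, 13.0, 18.0, 23.0)

FACTORS = ("season", "east", "north", "biomass")


@dataclass
class ScenarioConfig:
    """Knobs of the default deployment scenario.

    The defaults mirror a summer deployment: a 3.5-month record, 10
    individual sensor variables plus 18 + 60 current-speed variables, the
    native sampling intervals of the instruments, a seasonal temperature
    rise of ~1.5 units over the record and weak sporadic missingness.
    """

    start: str = "2015-05-16"
    end: str = "2015-08-31 23:59"
    seed: int = 0
    # latent structure
    trend_amplitude: float = 1.5          # seasonal rise over the record, temp units
    current_smoothing_hours: float = 6.0  # correlation time of current factors
    biomass_smoothing_hours: float = 12.0
    current_amp_east: float = 1.0         # east more pronounced than north
    current_amp_north: float = 0.6
    # noise levels (native units; temperatures ~0.05 => redundancy r ~ 0.99)
    temp_noise_sd: float = 0.05
    current_noise_sd: float = 0.08        # per-depth-bin measurement noise
    current_common_noise_sd: float = 0.10  # shared within one profiler+direction
    biomass_noise_sd: float = 1.0
    turbidity_noise_sd: float = 0.2
    # sampling
    fast_interval: str = "5min"           # conductivity / temperature / turbidity
    current_interval: str = "10min"       # both profilers
    slow_interval: str = "1h"             # chlorophyll, biomass
    missing_rate: float = 0.001
    # rare per-sensor outages (expected count per stream over the record)
    outage_rate: float = 0.3
    outage_hours: tuple[float, float] = (7.0, 24.0)

    def validate(self) -> None:
        if not 0 <= self.missing_rate <= 1:
            raise ValueError("missing_rate must be in [0, 1]")
        for name in ("temp_noise_sd", "current_noise_sd", "biomass_noise_sd",
                     "turbidity_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if pd.Timestamp(self.end) <= pd.Timestamp(self.start):
            raise ValueError("scenario end must follow start")


@dataclass
class ScenarioTruth:
    """Ground truth behind a generated scenario, for recovery tests."""

    latents: pd.DataFrame            # master grid x FACTORS, unit-variance factors
    loadings: pd.DataFrame           # variable x FACTORS, native units
    offsets: pd.Series
    noise_sd: pd.Series
    intervals: pd.Series             # per-variable sampling interval


@dataclass
class AnomalySpec:
    """One injected sensor fault.

    ``magnitude`` is in units of the target's pre-onset standard deviation;
    ``ceiling_quantile`` applies to saturation (the clip level as a quantile
    of pre-onset values).
    """

    kind: str
    targets: Sequence[str]
    onset: str | pd.Timestamp
    magnitude: float = 4.0
    ceiling_quantile: float = 0.5

    KINDS = ("mean_shift", "drift", "saturation", "decorrelation", "dropout")

    def __post_init__(self) -> None:
        if self.kind not in self.KINDS:
            raise ValueError(f"unknown anomaly kind {self.kind!r}; one of {self.KINDS}")
        if self.magnitude < 0:
            raise ValueError("magnitude must be >= 0")
        self.targets = list(self.targets)
        self.onset = pd.Timestamp(self.onset)


def _smooth_factor(rng: np.random.Generator, n: int, width: int) -> np.ndarray:
    """Unit-variance stationary factor: Gaussian-smoothed white noise."""
    x = rng.standard_normal(n + 6 * width)
    k = np.exp(-0.5 * (np.arange(-3 * width, 3 * width + 1) / max(width, 1)) ** 2)
    k /= k.sum()
    y = np.convolve(x, k, mode="same")[3 * width: 3 * width + n]
    sd = y.std()
    return y / sd if sd > 0 else y


def _build_variable_plan(config: ScenarioConfig):
    """Per variable: (name, interval, offset, loadings-on-FACTORS, noise sd,
    common-noise group or None)."""
    c = config
    plan: list[tuple[str, str, float, dict, float, str | None]] = []
    # three redundant thermometers: same trend, different mounting offsets
    for name, offset in (("temp_cond", 7.0), ("temp_aqua", 7.3), ("temp_conti", 7.6)):
        interval = c.fast_interval if name == "temp_cond" else c.current_interval
        plan.append((name, interval, offset,
                     {"season": c.trend_amplitude}, c.temp_noise_sd, None))
    plan.append(("conductivity", c.fast_interval, 35.0,
                 {"season": 0.6 * c.trend_amplitude}, 0.03, None))
    plan.append(("salinity", c.fast_interval, 34.8,
                 {"season": 0.25 * c.trend_amplitude}, 0.02, None))
    plan.append(("chlorophyll", c.slow_interval, 1.5,
                 {"biomass": 0.6, "season": 0.2}, 0.3, None))
    plan.append(("turbidity", c.fast_interval, 0.6,
                 {"season": 0.03}, c.turbidity_noise_sd, None))
    for name, load, offset in (("biomass_5m", 3.0, -62.0),
                               ("biomass_50m", 2.4, -66.0),
                               ("biomass_120m", 1.8, -71.0)):
        plan.append((name, c.slow_interval, offset,
                     {"biomass": load}, c.biomass_noise_sd, None))
    # shared current field, attenuated towards the seabed; the two profilers
    # observe the same factors at their own depth bins, each with some
    # instrument-common noise (so within-profiler redundancy beats
    # cross-profiler redundancy, as for real ADCPs)
    def gradient(depth: float) -> float:
        return 0.35 + 0.65 * depth / max(CONTI_DEPTHS)

    for sensor, depths in (("aqua", AQUA_DEPTHS), ("conti", CONTI_DEPTHS)):
        for direction, amp in (("E", c.current_amp_east), ("N", c.current_amp_north)):
            factor = "east" if direction == "E" else "north"
            for d in depths:
                plan.append((f"{sensor}_{direction}_{d:g}m", c.current_interval,
                             8.0, {factor: amp * gradient(d)},
                             c.current_noise_sd, f"{sensor}_{direction}"))
    return plan


def generate_scenario(config: ScenarioConfig | None = None,
                      ) -> tuple[list[SensorStream], ScenarioTruth]:
    """Generate the sensor streams of one scenario plus its ground truth.

    Fully deterministic for a fixed config (including ``seed``): the same
    config yields byte-identical streams.
    """
    config = config or ScenarioConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    master_step = pd.Timedelta(config.fast_interval)
    master = pd.date_range(config.start, config.end, freq=master_step)
    n = len(master)
    per_hour = pd.Timedelta("1h") / master_step

    # latent trajectories on the master grid, unit variance each
    ramp = np.linspace(-1.0, 1.0, n)
    wiggle = _smooth_factor(rng, n, int(48 * per_hour))
    season = ramp + 0.3 * wiggle
    season /= season.std()
    east = _smooth_factor(rng, n, int(config.current_smoothing_hours * per_hour))
    north = _smooth_factor(rng, n, int(config.current_smoothing_hours * per_hour))
    biomass = _smooth_factor(rng, n, int(config.biomass_smoothing_hours * per_hour))
    latents = pd.DataFrame(
        {"season": season, "east": east, "north": north, "biomass": biomass},
        index=master)

    plan = _build_variable_plan(config)
    loadings = pd.DataFrame(0.0, index=[p[0] for p in plan], columns=list(FACTORS))
    offsets = pd.Series({p[0]: p[2] for p in plan})
    noise_sd = pd.Series({p[0]: p[4] for p in plan})
    intervals = pd.Series({p[0]: p[1] for p in plan})

    # instrument-common noise, one smooth trajectory per profiler+direction
    common_groups = sorted({p[5] for p in plan if p[5] is not None})
    width = int(config.current_smoothing_hours * per_hour)
    common = {g: config.current_common_noise_sd * _smooth_factor(rng, n, width)
              for g in common_groups}

    streams: list[SensorStream] = []
    L = latents.to_numpy()
    for name, interval, offset, loads, sd, group in plan:
        step = pd.Timedelta(interval)
        stride = int(step / master_step)
        idx = np.arange(0, n, stride)
        w = np.zeros(len(FACTORS))
        for f, v in loads.items():
            w[FACTORS.index(f)] = v
            loadings.loc[name, f] = v
        signal = offset + L[idx] @ w + sd * rng.standard_normal(len(idx))
        if group is not None:
            signal += common[group][idx]
        if config.missing_rate > 0:
            drop = rng.random(len(idx)) < config.missing_rate
            signal[drop] = np.nan
        if config.outage_rate > 0:
            for _ in range(rng.poisson(config.outage_rate)):
                lo_h, hi_h = config.outage_hours
                dur = pd.Timedelta(hours=float(rng.uniform(lo_h, hi_h)))
                t0 = master[int(rng.integers(0, n))]
                gap = (master[idx] >= t0) & (master[idx] < t0 + dur)
                signal[gap] = np.nan
        streams.append(SensorStream(name, master[idx], signal, step))

    truth = ScenarioTruth(latents=latents, loadings=loadings, offsets=offsets,
                          noise_sd=noise_sd, intervals=intervals)
    return streams, truth


def inject_anomaly(streams: Sequence[SensorStream], spec: AnomalySpec,
                   seed: int | None = None,
                   ) -> tuple[list[SensorStream], dict[str, np.ndarray]]:
    """Apply one anomaly from its onset onward; return streams + truth labels.

    ``labels[name]`` is a boolean mask over that stream's samples marking the
    affected cells.  Streams not targeted are returned unchanged.
    Decorrelation draws replacement noise from ``default_rng(seed)``.
    """
    by_name = {s.name: s for s in streams}
    unknown = [t for t in spec.targets if t not in by_name]
    if unknown:
        raise ValueError(f"anomaly targets not present: {unknown}")
    t_min = min(s.timestamps[0] for s in streams)
    t_max = max(s.timestamps[-1] for s in streams)
    if not t_min <= spec.onset <= t_max:
        raise ValueError(f"onset {spec.onset} outside scenario span [{t_min}, {t_max}]")
    rng = np.random.default_rng(seed)

    out: list[SensorStream] = []
    labels: dict[str, np.ndarray] = {}
    for s in streams:
        if s.name not in spec.targets:
            out.append(s)
            continue
        values = s.values.copy()
        after = s.timestamps >= spec.onset
        pre = values[~after]
        pre = pre[np.isfinite(pre)]
        if pre.size < 2:
            raise ValueError(f"{s.name}: no pre-onset data to calibrate the anomaly")
        sd = float(pre.std(ddof=1))
        idx = np.flatnonzero(after)
        if spec.kind == "mean_shift":
            values[idx] += spec.magnitude * sd
        elif spec.kind == "drift":
            ramp = np.linspace(0.0, 1.0, len(idx)) if len(idx) > 1 else np.ones(len(idx))
            values[idx] += spec.magnitude * sd * ramp
        elif spec.kind == "saturation":
            ceiling = float(np.quantile(pre, spec.ceiling_quantile))
            values[idx] = np.minimum(values[idx], ceiling)
        elif spec.kind == "decorrelation":
            values[idx] = float(pre.mean()) + sd * rng.standard_normal(len(idx))
        elif spec.kind == "dropout":
            values[idx] = np.nan
        mask = np.zeros(len(values), dtype=bool)
        mask[idx] = True
        labels[s.name] = mask
        out.append(SensorStream(s.name, s.timestamps, values, s.nominal_interval))
    return out, labels


def default_blocks(block_components: int = 3) -> BlockSpec:
    """The deployment's block structure: two profiler blocks, rest individual."""
    aqua = [f"aqua_{d}_{x:g}m" for d in ("E", "N") for x in AQUA_DEPTHS]
    conti = [f"conti_{d}_{x:g}m" for d in ("E", "N") for x in CONTI_DEPTHS]
    return BlockSpec(blocks={"aqua": aqua, "conti": conti},
                     block_components=block_components)


def default_redundancy_groups() -> list[RedundancyGroup]:
    """Temperature trio plus the profilers' overlapping depth bins."""
    groups = [RedundancyGroup("temperature",
                              ["temp_cond", "temp_aqua", "temp_conti"])]
    for direction in ("E", "N"):
        for d in OVERLAP_DEPTHS:
            groups.append(RedundancyGroup(
                f"current_{direction}_{d:g}m",
                [f"aqua_{direction}_{d:g}m", f"conti_{direction}_{d:g}m"]))
    return groups
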