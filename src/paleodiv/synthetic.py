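"""Seeded synthetic sediment records for testing and calibration.

Two regimes mirror the statistical character of real subalpine-lake
records:

``macro`` (plant macroremains)
    84 samples by default, 24-351 yr/sample temporal resolution, ~10 cm^3
    sample volumes and a deposition intensity low enough that many samples
    contain no remains at all and influx sums sit well below one particle
    cm^-2 yr^-1 — the regime that makes plain rarefaction impossible.
``pollen``
    62 samples, 50-379 yr/sample, 1 cm^3 volumes and count sums of
    hundreds of grains per sample; no empty samples.

Counts follow a Poisson-multinomial scheme: the total number of particles
in a sample is Poisson with mean intensity x volume x duration (intensity
in particles cm^-3 yr^-1), allocated to taxa by the relative-abundance
weights in force at the sample's midpoint age. A step change in the number
of available taxa (``gen_richness_step``) produces records with a known
richness trajectory for parameter-recovery checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
import json

import numpy as np
import pandas as pd

from .record_io import AgeDepthModel, SampleSeries

# default taxon pool: geometric rank-abundance, mixed functional groups
_POOL = [
    ("Larix", "tree"), ("Pinus_cembra", "tree"), ("Picea", "tree"),
    ("Betula", "tree"), ("Abies", "tree"), ("Pinus_sylvestris", "tree"),
    ("Juniperus", "shrub"), ("Alnus_viridis", "shrub"), ("Salix", "shrub"),
    ("Rhododendron", "shrub"), ("Vaccinium", "shrub"),
    ("Poaceae", "herb"), ("Cyperaceae", "herb"), ("Artemisia", "herb"),
    ("Ranunculaceae", "herb"), ("Asteraceae", "herb"), ("Apiaceae", "herb"),
    ("Rumex", "herb"), ("Potentilla", "herb"), ("Bryales", "other"),
]


def _geometric_weights(k: int, ratio: float = 0.75) -> np.ndarray:
    w = ratio ** np.arange(k)
    return w / w.sum()


@dataclass
class ScenarioConfig:
    """Parameters of one synthetic-record scenario.

    ``intensity`` is the expected particle deposition in particles cm^-3
    yr^-1; the expected count of a sample is intensity x volume x duration.
    """

    regime: str = "macro"
    n_samples: int = 84
    resolution_range: tuple = (24.0, 351.0)   # yr per sample
    volume_range: tuple = (8.0, 12.0)         # cm^3
    intensity: float = 8e-4                   # particles cm^-3 yr^-1
    taxa: tuple = tuple(name for name, _ in _POOL)
    groups: tuple = tuple(group for _, group in _POOL)
    weights: tuple = tuple(_geometric_weights(len(_POOL)))
    age_start: float = 0.0                    # cal BP of the record top
    total_depth: float = 500.0                # cm of sediment
    n_control_points: int = 12
    agedepth_jitter: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        for name, rng in (("resolution_range", self.resolution_range),
                          ("volume_range", self.volume_range)):
            lo, hi = rng
            if lo <= 0 or hi < lo:
                raise ValueError(f"{name} must be positive and ordered")
        if self.intensity < 0:
            raise ValueError("intensity must be >= 0")
        if not (len(self.taxa) == len(self.groups) == len(self.weights)):
            raise ValueError("taxa, groups and weights must have equal length")
        w = np.asarray(self.weights, dtype=float)
        if abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("taxon weights must sum to 1")

    @classmethod
    def macro_like(cls, seed: int = 0, **overrides) -> "ScenarioConfig":
        return cls(regime="macro", seed=seed, **overrides)

    @classmethod
    def pollen_like(cls, seed: int = 0, **overrides) -> "ScenarioConfig":
        defaults = dict(
            regime="pollen",
            n_samples=62,
            resolution_range=(50.0, 379.0),
            volume_range=(1.0, 1.0),
            intensity=3.0,
        )
        defaults.update(overrides)
        return cls(seed=seed, **defaults)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, default=list)

    @classmethod
    def from_json(cls, path) -> "ScenarioConfig":
        with open(path) as fh:
            raw = json.load(fh)
        for key in ("resolution_range", "volume_range", "taxa", "groups", "weights"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def gen_age_depth(seed, total_depth, total_age, n_points=12, jitter=0.3,
                  age_start=0.0) -> AgeDepthModel:
    """Monotone piecewise-linear age-depth model with jittered segment rates.

    Depth control points are equally spaced over [0, total_depth]; segment
    age increments are perturbed multiplicatively by up to ``jitter`` and
    renormalized so the ends are exact. ``jitter`` = 0 gives an exactly
    linear model. Monotone by construction for any jitter < 1.
    """
    if total_depth <= 0 or total_age <= 0:
        raise ValueError("total_depth and total_age must be > 0")
    if n_points < 2:
        raise ValueError("need at least 2 control points")
    rng = np.random.default_rng(seed)
    jitter = min(float(jitter), 0.95)
    depths = np.linspace(0.0, total_depth, n_points)
    incr = 1.0 + jitter * rng.uniform(-1.0, 1.0, n_points - 1)
    incr = incr / incr.sum() * total_age
    ages = age_start + np.concatenate([[0.0], np.cumsum(incr)])
    return AgeDepthModel(depths=depths, ages=ages)


def gen_record(config: ScenarioConfig, weights_fn=None):
    """Generate (SampleSeries, AgeDepthModel) for a scenario.

    ``weights_fn(mid_age) -> weight vector`` overrides the static taxon
    weights per sample (used for records with a known richness
    trajectory). Reproducible: the same config yields the same record.
    In the pollen regime, sample totals below 100 grains are redrawn so the
    record keeps the no-sparse-samples character of real pollen data.
    """
    ss = np.random.SeedSequence(config.seed)
    seed_model, seed_counts = ss.spawn(2)
    rng = np.random.default_rng(seed_counts)

    lo, hi = config.resolution_range
    durations = rng.uniform(lo, hi, config.n_samples)
    total_age = float(durations.sum())
    model = gen_age_depth(
        seed_model, config.total_depth, total_age,
        n_points=config.n_control_points, jitter=config.agedepth_jitter,
        age_start=config.age_start,
    )
    age_bounds = config.age_start + np.concatenate([[0.0], np.cumsum(durations)])
    depth_bounds = model.depth_at(age_bounds)
    mid_ages = 0.5 * (age_bounds[:-1] + age_bounds[1:])

    vlo, vhi = config.volume_range
    volumes = rng.uniform(vlo, vhi, config.n_samples)

    base_w = np.asarray(config.weights, dtype=float)
    counts = np.zeros((config.n_samples, len(config.taxa)))
    for s in range(config.n_samples):
        w = base_w if weights_fn is None else np.asarray(weights_fn(mid_ages[s]), dtype=float)
        mean = config.intensity * volumes[s] * durations[s]
        total = int(rng.poisson(mean))
        if config.regime == "pollen":
            while total < 100:
                total = int(rng.poisson(mean))
        if total > 0:
            counts[s] = rng.multinomial(total, w / w.sum())

    samples = SampleSeries(
        counts=pd.DataFrame(
            counts,
            index=pd.Index([f"s{i + 1:03d}" for i in range(config.n_samples)],
                           name="sample_id"),
            columns=list(config.taxa),
        ),
        depth_top=depth_bounds[:-1],
        depth_bottom=depth_bounds[1:],
        volume=volumes,
        groups=pd.Series(list(config.groups), index=list(config.taxa), name="group"),
    )
    return samples, model


def gen_richness_step(config: ScenarioConfig, S_early: int, S_late: int,
                      change_age=None):
    """Record whose available taxon pool steps from S_early to S_late taxa.

    Ages run into the past, so the *early* epoch is the older (larger cal
    BP) part of the record, beyond ``change_age`` (default: the record's
    midpoint age). Weights are equal within the truncated pool of each
    epoch. Returns (samples, model, change_age).
    """
    pool = len(config.taxa)
    if not (1 <= S_early <= pool and 1 <= S_late <= pool):
        raise ValueError(f"epoch richness must be within the taxon pool (1..{pool})")

    lo, hi = config.resolution_range
    expected_span = config.n_samples * 0.5 * (lo + hi)
    if change_age is None:
        change_age = config.age_start + 0.5 * expected_span

    def weights_fn(mid_age):
        S = S_early if mid_age >= change_age else S_late
        w = np.zeros(pool)
        w[:S] = 1.0 / S
        return w

    samples, model = gen_record(config, weights_fn=weights_fn)
    return samples, model, float(change_age)
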