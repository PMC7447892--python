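"""Condition-level population statistics of precipitate particles.

Per-particle metrics are aggregated into per-condition summaries: mean ± SD
of fractal dimension, density and surface-to-volume ratio over the biggest
particles (strictly more than 5000 voxels by default, to minimise the
resolution bias quantified by the sphere calibration), fractal-dimension
histograms, and a descriptive ranking of conditions along a user-given
expected-shear order. The SD here is the particle-to-particle spread of the
population — a property of the sample, not a measurement error — so it is
deliberately large compared to SDs of ensemble-averaging methods such as
laser diffraction, and no standard errors or hypothesis tests are reported.

The :func:`camp_number` utility computes the shear/aging parameter
γ = sqrt(P / (V ρ ν)) from power input, reactor volume, suspension density
and kinematic viscosity, relating precipitation conditions to the velocity
gradient their flocs experienced.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .morphometry import ParticleMetrics

#: Population size cut (voxels, strict >) used for condition summaries.
DEFAULT_POPULATION_MIN_VOXELS = 5000


@dataclass
class GroupSummary:
    """Mean ± SD of the key metrics for one condition's large particles."""

    condition: str
    n_particles: int
    mean_D: float
    sd_D: float | None
    mean_density: float
    sd_density: float | None
    mean_surface_to_volume: float
    sd_surface_to_volume: float | None
    threshold_voxels: int


@dataclass
class DimensionHistogram:
    """Fixed-width histogram of fractal dimensions for one condition."""

    bin_edges: np.ndarray
    counts: np.ndarray
    condition: str

    @property
    def n(self) -> int:
        return int(self.counts.sum())


def filter_population(metrics: Sequence[ParticleMetrics],
                      min_voxels: int = DEFAULT_POPULATION_MIN_VOXELS
                      ) -> list[ParticleMetrics]:
    """Keep particles strictly larger than ``min_voxels`` voxels.

    Voxel counts refer to the original acquisition grid (before any isotropic
    resampling). Idempotent.
    """
    return [m for m in metrics if m.voxel_count > min_voxels]


def _mean_sd(values: np.ndarray) -> tuple[float, float | None]:
    mean = float(np.mean(values))
    sd = float(np.std(values, ddof=1)) if len(values) >= 2 else None
    return mean, sd


def summarize_group(metrics: Sequence[ParticleMetrics], condition: str,
                    threshold_voxels: int = DEFAULT_POPULATION_MIN_VOXELS
                    ) -> GroupSummary:
    """Arithmetic mean and sample SD (n−1) of D, density and surface/volume."""
    if len(metrics) == 0:
        raise ValueError(f"no particles to summarize for condition {condition!r}")
    d = np.array([m.fractal_dimension for m in metrics], dtype=float)
    rho = np.array([m.density for m in metrics], dtype=float)
    sv = np.array([m.surface_to_volume_per_um for m in metrics], dtype=float)
    mean_d, sd_d = _mean_sd(d)
    mean_rho, sd_rho = _mean_sd(rho)
    mean_sv, sd_sv = _mean_sd(sv)
    return GroupSummary(
        condition=condition, n_particles=len(metrics),
        mean_D=mean_d, sd_D=sd_d,
        mean_density=mean_rho, sd_density=sd_rho,
        mean_surface_to_volume=mean_sv, sd_surface_to_volume=sd_sv,
        threshold_voxels=threshold_voxels)


def dimension_histogram(metrics: Sequence[ParticleMetrics], condition: str = "",
                        bin_width: float = 0.1) -> DimensionHistogram:
    """Histogram of D with fixed-width bins spanning [floor(min), ceil(max)]."""
    if len(metrics) == 0:
        raise ValueError("no particles to histogram")
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    d = np.array([m.fractal_dimension for m in metrics], dtype=float)
    lo = math.floor(d.min())
    hi = math.ceil(d.max())
    if hi == lo:
        hi = lo + 1
    n_bins = int(round((hi - lo) / bin_width))
    edges = lo + bin_width * np.arange(n_bins + 1)
    counts, _ = np.histogram(d, bins=edges)
    return DimensionHistogram(bin_edges=edges, counts=counts, condition=condition)


def rank_conditions(summaries: Sequence[GroupSummary],
                    order: Sequence[str]) -> tuple[pd.DataFrame, bool]:
    """Arrange condition summaries along a given (expected-shear) order.

    Returns the ordered table and a descriptive flag: is the mean fractal
    dimension non-decreasing along the order? (Denser, less fractal-looking
    flocs are expected after stronger shear as loose branches shear off and
    reorganize.)
    """
    by_name = {s.condition: s for s in summaries}
    unknown = [c for c in order if c not in by_name]
    if unknown:
        raise ValueError(f"unknown condition(s) in order: {unknown}")
    rows = []
    for c in order:
        s = by_name[c]
        rows.append({
            "condition": s.condition, "n_particles": s.n_particles,
            "mean_D": s.mean_D, "sd_D": s.sd_D,
            "mean_density": s.mean_density, "sd_density": s.sd_density,
            "mean_surface_to_volume": s.mean_surface_to_volume,
            "sd_surface_to_volume": s.sd_surface_to_volume,
        })
    table = pd.DataFrame(rows)
    means = table["mean_D"].to_numpy()
    trend = bool(np.all(np.diff(means) >= 0))
    table.attrs["mean_D_nondecreasing"] = trend
    return table, trend


def camp_number(P: float, V: float, rho: float, nu: float) -> float:
    """Shear/aging parameter γ = sqrt(P / (V ρ ν)), in s⁻¹.

    Parameters
    ----------
    P : power input, W
    V : reactor volume, m³
    rho : suspension density, kg/m³
    nu : kinematic viscosity, m²/s
    """
    for name, v in [("P", P), ("V", V), ("rho", rho), ("nu", nu)]:
        if v <= 0:
            raise ValueError(f"{name} must be > 0, got {v}")
    return math.sqrt(P / (V * rho * nu))
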