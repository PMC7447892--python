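"""Per-particle morphometrics: volume, enclosing sphere, density, surface.

All quantities are physical (µm-scaled through the particle's geometry):

* volume — voxel count times the volume of one voxel;
* diameter — the smallest sphere enclosing all voxel centres (exact minimal
  sphere via Welzl's move-to-front algorithm over convex-hull candidates, not
  an approximation);
* density — filled volume over the volume of the encompassing sphere, the
  image-analysis proxy for packing density (actual mass density is not
  recoverable from image analysis);
* surface area — exposed voxel faces weighted by their physical face areas
  (a Manhattan surface: exact and oracle-testable, with a consistent bias
  across particles, rather than a meshed estimate).

The enclosing sphere covers voxel *centres*, not voxel cubes; padding the
diameter by one pixel diagonal (dx·√2) approximates the cube-enclosing sphere
if needed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial import ConvexHull, QhullError

from .reconstruction import Particle


@dataclass
class ParticleMetrics:
    """Flat record of every per-particle quantity the pipeline reports."""

    label: int
    voxel_count: int
    volume_um3: float
    diameter_um: float
    density: float
    surface_area_um2: float
    surface_to_volume_per_um: float
    fractal_dimension: float = float("nan")
    fit_r2: float = float("nan")
    monofractal_flag: bool = False
    condition: str = ""


def particle_volume(p: Particle) -> tuple[int, float]:
    """Voxel count and physical volume (count × dx·dy·dz) of a particle."""
    n = p.voxel_count
    if n == 0:
        raise ValueError("empty particle")
    return n, n * p.geometry.voxel_volume


# ---------------------------------------------------------------------------
# exact minimal enclosing sphere (Welzl, move-to-front)

def _circumsphere(support: list[np.ndarray]) -> tuple[np.ndarray, float] | None:
    """Unique sphere with all support points (≤ 4) on its surface, minimal
    among such spheres; None for degenerate (collinear/coplanar) sets."""
    k = len(support)
    if k == 0:
        return np.zeros(3), -1.0
    a = support[0]
    if k == 1:
        return a.copy(), 0.0
    rows = np.array([q - a for q in support[1:]])          # (k-1, 3)
    rhs = 0.5 * np.einsum("ij,ij->i", rows, rows)
    gram = rows @ rows.T
    try:
        sol = np.linalg.solve(gram, rhs)
    except np.linalg.LinAlgError:
        # near-degenerate support (collinear/coplanar within epsilon):
        # minimal-norm solution keeps the recursion well-defined
        sol = np.linalg.lstsq(gram, rhs, rcond=None)[0]
    if not np.all(np.isfinite(sol)):
        return None
    center = a + sol @ rows
    return center, float(np.linalg.norm(center - a))


def _welzl(points: np.ndarray, rng: np.random.Generator) -> tuple[np.ndarray, float]:
    """Expected-linear-time minimal enclosing ball with move-to-front."""
    pts = [points[i] for i in rng.permutation(len(points))]

    def mtf_ball(end: int, support: list[np.ndarray]) -> tuple[np.ndarray, float]:
        ball = _circumsphere(support)
        center, r = ball if ball is not None else (np.zeros(3), -1.0)
        if len(support) == 4:
            return center, r
        i = 0
        while i < end:
            p = pts[i]
            if np.linalg.norm(p - center) > r * (1 + 1e-12) + 1e-14:
                center, r = mtf_ball(i, support + [p])
                pts.insert(0, pts.pop(i))  # move-to-front
            i += 1
        return center, r

    return mtf_ball(len(pts), [])


def minimal_enclosing_sphere_points(points: np.ndarray,
                                    seed: int = 0) -> tuple[np.ndarray, float]:
    """Exact smallest sphere enclosing a point set; returns (center, radius).

    Candidate points are first reduced to the convex hull vertices (the
    minimal ball is determined by hull vertices only); degenerate hulls fall
    back to the full set.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[1] != 3:
        raise ValueError("expected an (n, 3) point array")
    if len(points) == 0:
        raise ValueError("empty point set")
    points = np.unique(points, axis=0)
    if len(points) == 1:
        return points[0].copy(), 0.0
    if len(points) > 16:
        try:
            points = points[ConvexHull(points).vertices]
        except QhullError:
            pass  # flat/collinear particle: Welzl on all points
    import sys
    limit = sys.getrecursionlimit()
    if limit < len(points) * 4 + 1000:
        sys.setrecursionlimit(len(points) * 4 + 1000)
    rng = np.random.default_rng(seed)
    center, r = _welzl(points, rng)
    # one exact tightening pass: radius must reach the farthest point
    r = float(np.max(np.linalg.norm(points - center, axis=1)))
    return center, r


def min_enclosing_sphere(p: Particle) -> tuple[np.ndarray, float]:
    """Smallest sphere enclosing all voxel centres of a particle.

    Returns (center, diameter), both in µm, center in (z, y, x) order.
    """
    center, radius = minimal_enclosing_sphere_points(p.centers_um())
    return center, 2.0 * radius


def particle_density(p: Particle, diameter_um: float | None = None,
                     volume_um3: float | None = None) -> float:
    """Filled-volume fraction of the minimal enclosing sphere, in (0, 1].

    A single voxel (diameter 0) has density 1 by convention; the value is
    clipped at 1 (voxelization can overfill the analytic sphere slightly).
    """
    if volume_um3 is None:
        _, volume_um3 = particle_volume(p)
    if diameter_um is None:
        _, diameter_um = min_enclosing_sphere(p)
    if diameter_um <= 0:
        return 1.0
    sphere = math.pi / 6.0 * diameter_um ** 3
    return min(1.0, volume_um3 / sphere)


def surface_area(p: Particle) -> float:
    """Physical area (µm²) of all exposed voxel faces.

    A face between a foreground voxel and background (or the volume edge)
    contributes its face area: dy·dz for x-normal, dx·dz for y-normal,
    dx·dy for z-normal faces.
    """
    mask = p.mask()
    g = p.geometry
    face_areas = (g.dx * g.dy, g.dx * g.dz, g.dy * g.dz)  # z-, y-, x-normal
    total = 0.0
    for axis, area in enumerate(face_areas):
        padded = np.pad(mask, [(1, 1) if ax == axis else (0, 0)
                               for ax in range(3)])
        exposed = np.diff(padded.astype(np.int8), axis=axis) != 0
        total += area * int(exposed.sum())
    return total


def surface_to_volume(p: Particle) -> float:
    """Surface area per filled volume, µm⁻¹ (proxy for surface/mass)."""
    _, vol = particle_volume(p)
    return surface_area(p) / vol


def basic_metrics(p: Particle) -> ParticleMetrics:
    """All morphometric quantities of one particle (fractal fields unset)."""
    n, vol = particle_volume(p)
    _, diameter = min_enclosing_sphere(p)
    area = surface_area(p)
    return ParticleMetrics(
        label=p.label,
        voxel_count=n,
        volume_um3=vol,
        diameter_um=diameter,
        density=particle_density(p, diameter_um=diameter, volume_um3=vol),
        surface_area_um2=area,
        surface_to_volume_per_um=area / vol,
        condition=p.condition,
    )
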