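"""End-to-end plumbing: stack → masks → particles → metrics.

Chains the segmentation, reconstruction, morphometry and fractal modules
with the fixed filter order (label → small-object cut → border cut → pillar
cut). Box counting runs on each particle's isotropically resampled mask
(cubic cells); morphometrics use the original anisotropic geometry.
"""

from __future__ import annotations

import logging
from typing import Sequence

from . import fractal, morphometry, reconstruction, segmentation
from .morphometry import ParticleMetrics
from .reconstruction import BinaryVolume, LabeledVolume, Particle
from .stack_io import ImageStack, RunConfig

logger = logging.getLogger(__name__)


def reconstruct_stack(stack: ImageStack, config: RunConfig | None = None
                      ) -> LabeledVolume:
    """Binarize every slice, stack to 3D and label + filter particles."""
    config = config or RunConfig()
    masks = segmentation.binarize_stack(stack, config)
    volume = reconstruction.stack_masks(masks, geometry=stack.geometry)
    labeled = reconstruction.label_components(volume, config.connectivity)
    return reconstruction.apply_filters(
        labeled, min_voxels=config.min_voxels,
        pillar_min_z_span=config.pillar_min_z_span,
        pillar_max_footprint_dev=config.pillar_max_footprint_dev)


def particle_fractal_fit(particle: Particle,
                         config: RunConfig | None = None) -> fractal.FractalFit:
    """Box-count fit on the particle's isotropically resampled mask."""
    config = config or RunConfig()
    vol = BinaryVolume(particle.mask(), particle.geometry)
    iso = reconstruction.resample_isotropic(vol)
    sizes = fractal.default_ladder(iso.voxels.shape)
    fit_range = None
    if config.fit_min_eps is not None or config.fit_max_eps is not None:
        fit_range = (config.fit_min_eps or 1, config.fit_max_eps or int(sizes[-1]))
    curve = fractal.box_count(iso.voxels, sizes=sizes,
                              pitch_um=iso.geometry.dx)
    return fractal.fit_fractal_dimension(
        curve, fit_range=fit_range, r2_min=config.r2_min,
        max_local_dev=config.max_local_slope_dev)


def analyze_particles(particles: Sequence[Particle],
                      config: RunConfig | None = None) -> list[ParticleMetrics]:
    """Morphometrics plus fractal dimension for each particle."""
    config = config or RunConfig()
    out = []
    for p in particles:
        m = morphometry.basic_metrics(p)
        try:
            fit = particle_fractal_fit(p, config)
            m.fractal_dimension = fit.dimension
            m.fit_r2 = fit.r2
            m.monofractal_flag = fit.monofractal_flag
        except ValueError as exc:  # e.g. too few ladder points for a sliver
            logger.warning("no fractal fit for particle %d: %s", p.label, exc)
        out.append(m)
    return out


def run_stack(stack: ImageStack, config: RunConfig | None = None,
              condition: str = "") -> list[ParticleMetrics]:
    """Full pipeline on one acquisition: reconstruct, extract, analyze."""
    config = config or RunConfig()
    labeled = reconstruct_stack(stack, config)
    particles = reconstruction.extract_particles(labeled, condition=condition)
    return analyze_particles(particles, config)
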