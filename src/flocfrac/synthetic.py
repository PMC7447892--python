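"""Ground-truth aggregates and a virtual wide-field microscope.

No real precipitate stacks ship with the package; everything downstream of
acquisition is exercised against synthetic data with known ground truth:

* deterministic solids (spheres, cubes, rods, Menger sponges) with closed-form
  voxel counts and known fractal dimensions;
* an off-lattice particle-cluster diffusion-limited aggregation (DLA)
  simulator — the classical growth model whose mass-radius dimension of
  roughly 2.5 brackets the diffusion-limited regime that slowly-diffusing
  macromolecules such as antibodies are expected to follow (in contrast to a
  reaction-limited regime near 1.7, reachable here by lowering the sticking
  probability);
* a z-stack renderer that emulates what a wide-field microscope records of a
  3D object: a sharp silhouette near each focal plane, progressively blurred
  out-of-focus content, background, shot-like noise, and optional
  interference spots that repeat identically in every slice (the "pillar"
  artifact of the 3D reconstruction).

All generators are bit-reproducible given their parameters and seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from scipy.spatial import cKDTree

from .reconstruction import BinaryVolume
from .stack_io import ImageStack, VoxelGeometry

logger = logging.getLogger(__name__)


@dataclass
class AggregateSpec:
    """What to generate: a deterministic solid or a seeded DLA cluster."""

    kind: str                       # sphere | cube | rod | menger | dla
    size: float                     # radius / side / length / level / n_monomers
    monomer_radius: float = 1.0     # dla only, voxels
    seed: int = 0
    label: str = ""


def solid_sphere(radius: float) -> np.ndarray:
    """Pixelated perfect sphere: voxel centres inside the analytic radius.

    Grid side 2·ceil(r)+1, centre voxel at the sphere centre.
    """
    if radius < 1:
        raise ValueError("radius must be >= 1")
    n = int(np.ceil(radius))
    ax = np.arange(-n, n + 1)
    z, y, x = np.meshgrid(ax, ax, ax, indexing="ij")
    return (z * z + y * y + x * x) <= radius * radius


def solid_cube(side: int) -> np.ndarray:
    if side < 1:
        raise ValueError("side must be >= 1")
    return np.ones((side, side, side), dtype=bool)


def solid_rod(length: int) -> np.ndarray:
    """Straight 1-voxel-wide rod of ``length`` voxels along x."""
    if length < 1:
        raise ValueError("length must be >= 1")
    return np.ones((1, 1, length), dtype=bool)


def menger_sponge(level: int) -> np.ndarray:
    """Level-k Menger sponge: side 3^k, exactly 20^k foreground voxels,
    box-count dimension log 20 / log 3 ≈ 2.7268."""
    if not 0 <= level <= 4:
        raise ValueError("menger level must be in [0, 4]")
    cell = np.ones((3, 3, 3), dtype=bool)
    cell[1, 1, :] = cell[1, :, 1] = cell[:, 1, 1] = False
    sponge = np.ones((1, 1, 1), dtype=bool)
    for _ in range(level):
        sponge = np.kron(sponge, cell)
    return sponge


def generate_solid(spec: AggregateSpec,
                   geometry: VoxelGeometry | None = None) -> BinaryVolume:
    """Rasterize a deterministic solid into a :class:`BinaryVolume`."""
    builders = {
        "sphere": lambda: solid_sphere(spec.size),
        "cube": lambda: solid_cube(int(spec.size)),
        "rod": lambda: solid_rod(int(spec.size)),
        "menger": lambda: menger_sponge(int(spec.size)),
    }
    if spec.kind not in builders:
        raise ValueError(f"unknown solid kind {spec.kind!r}")
    return BinaryVolume(builders[spec.kind](), geometry or VoxelGeometry(1, 1, 1))


# ---------------------------------------------------------------------------
# diffusion-limited aggregation

def generate_dla(n_monomers: int, monomer_radius: float = 1.0, seed: int = 0,
                 stick_probability: float = 1.0) -> np.ndarray:
    """Off-lattice particle-cluster DLA; returns (n, 3) monomer centres.

    A seed monomer sits at the origin. Each subsequent monomer is released
    from a random point on a launch sphere just outside the cluster and
    random-walks with step length equal to the monomer radius until it
    contacts a cluster monomer (centre distance ≤ 2r), where it sticks with
    ``stick_probability`` (1 = diffusion-limited; values ≪ 1 emulate
    reaction-limited growth). The contact point is resolved exactly: each
    step segment is intersected analytically with the contact spheres of
    nearby monomers and the walker is deposited at the first crossing
    (avoiding the deposition bias of letting walkers overshoot into the
    cluster). Walkers escaping a kill radius (10× the launch radius) are
    relaunched uniformly on the launch sphere, the harmonic measure of
    returns from far away. Far from the cluster the walk is accelerated by
    jumping the distance to the nearest cluster monomer minus the contact
    distance — an exact shortcut for isotropic Brownian motion.

    Fully deterministic given (n_monomers, monomer_radius, seed).
    """
    if n_monomers < 1:
        raise ValueError("n_monomers must be >= 1")
    if monomer_radius <= 0:
        raise ValueError("monomer_radius must be > 0")
    if not 0 < stick_probability <= 1:
        raise ValueError("stick_probability must be in (0, 1]")
    r = float(monomer_radius)
    contact = 2.0 * r
    contact2 = contact * contact
    rng = np.random.default_rng(seed)
    pts = np.zeros((n_monomers, 3))
    count = 1
    cluster_radius = 0.0
    tree = cKDTree(pts[:1])
    tree_n = 1          # points indexed by the tree; newer ones checked directly
    rebuild_every = 64

    def random_dir() -> np.ndarray:
        v = rng.normal(size=3)
        return v / np.linalg.norm(v)

    def nearest_distance(pos: np.ndarray) -> float:
        dist, _ = tree.query(pos)
        if tree_n < count:
            dist = min(dist, float(np.min(
                np.linalg.norm(pts[tree_n:count] - pos, axis=1))))
        return float(dist)

    def contact_candidates(pos: np.ndarray, reach: float) -> list[np.ndarray]:
        cand = [pts[j] for j in tree.query_ball_point(pos, reach)]
        if tree_n < count:
            recent = pts[tree_n:count]
            dd = np.linalg.norm(recent - pos, axis=1)
            cand.extend(p for p, d0 in zip(recent, dd) if d0 <= reach)
        return cand

    while count < n_monomers:
        launch = cluster_radius + 5.0 * r
        kill = 10.0 * launch
        pos = launch * random_dir()
        while True:
            gap = nearest_distance(pos) - contact
            if gap > r:
                pos = pos + gap * random_dir()  # walk-on-spheres jump
                if np.linalg.norm(pos) > kill:
                    pos = launch * random_dir()
                continue
            # near the cluster: r-step with exact first-crossing detection
            u = random_dir()
            t_hit, anchor = None, None
            for cpt in contact_candidates(pos, r + contact):
                w = pos - cpt
                b = float(np.dot(w, u))
                c0 = float(np.dot(w, w)) - contact2
                disc = b * b - c0
                if disc < 0:
                    continue
                t = -b - np.sqrt(disc)
                if -1e-9 <= t <= r and (t_hit is None or t < t_hit):
                    t_hit, anchor = max(t, 0.0), cpt
            if t_hit is not None:
                if stick_probability >= 1.0 or rng.random() < stick_probability:
                    hit = pos + t_hit * u
                    d = hit - anchor
                    norm = np.linalg.norm(d)
                    d = d / norm if norm > 0 else random_dir()
                    pts[count] = anchor + contact * d
                    cluster_radius = max(cluster_radius,
                                         float(np.linalg.norm(pts[count])))
                    count += 1
                    if count - tree_n >= rebuild_every or count == n_monomers:
                        tree = cKDTree(pts[:count])
                        tree_n = count
                    break
                pos = pos + r * random_dir()  # rejected contact: keep walking
                continue
            pos = pos + r * u
            if np.linalg.norm(pos) > kill:
                pos = launch * random_dir()
    return pts


def radius_of_gyration(points: np.ndarray) -> float:
    c = points.mean(axis=0)
    return float(np.sqrt(np.mean(np.sum((points - c) ** 2, axis=1))))


def mass_radius_dimension(points: np.ndarray, n_min: int = 50) -> float:
    """Mass-radius scaling exponent D from log Rg(n) vs log n over the
    cluster's growth history (monomers are stored in sticking order)."""
    n = len(points)
    if n <= n_min:
        raise ValueError("cluster too small for mass-radius regression")
    ns = np.unique(np.geomspace(n_min, n, 30).astype(int))
    rgs = np.array([radius_of_gyration(points[:k]) for k in ns])
    slope = np.polyfit(np.log(ns), np.log(rgs), 1)[0]
    return 1.0 / slope


def voxelize(points: np.ndarray, monomer_radius: float, pitch: float = 1.0,
             pad: int = 2) -> BinaryVolume:
    """Rasterize monomer spheres onto a cubic grid of the given pitch.

    A voxel is foreground iff its centre lies within ``monomer_radius`` of
    any monomer centre; the bounding box is padded by ``pad`` voxels.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[1] != 3 or len(points) == 0:
        raise ValueError("expected a non-empty (n, 3) point cloud")
    r = float(monomer_radius)
    origin = points.min(axis=0) - (pad + 0.5) * pitch
    extent = points.max(axis=0) - origin + (pad + 0.5) * pitch + r
    shape = np.ceil(extent / pitch).astype(int) + 1
    vol = np.zeros(shape, dtype=bool)
    reach = int(np.ceil(r / pitch))
    off = np.arange(-reach, reach + 1)
    oz, oy, ox = np.meshgrid(off, off, off, indexing="ij")
    offsets = np.stack([oz, oy, ox], axis=-1).reshape(-1, 3)
    base = np.rint((points - origin) / pitch).astype(int)      # (n, 3)
    cand = base[:, None, :] + offsets[None, :, :]              # (n, m, 3)
    centers = cand * pitch + origin
    ok = np.linalg.norm(centers - points[:, None, :], axis=2) <= r
    cand = cand[ok]
    vol[cand[:, 0], cand[:, 1], cand[:, 2]] = True
    return BinaryVolume(vol, VoxelGeometry(pitch, pitch, pitch))


# ---------------------------------------------------------------------------
# virtual wide-field microscope

@dataclass
class MicroscopeModel:
    """Defocus-blur imaging model of a high-NA wide-field objective.

    Defaults correspond to a 100×/1.40 NA oil objective sampled at
    0.092 µm/px: geometric defocus blur for that aperture grows by roughly
    the defocus distance itself (≈ 2.4 µm blur radius per µm of defocus,
    ≈ 26 px/µm), so a Gaussian sigma growth of 8 px per µm of defocus is a
    conservative stand-in; the depth of field λn/NA² is ≈ 0.3 µm.
    """

    in_focus_sigma: float = 0.6          # px, residual blur at best focus
    defocus_sigma_per_um: float = 8.0    # px of extra sigma per µm of defocus
    depth_of_field: float = 0.3          # µm, zone treated as in focus
    noise_sd: float = 0.02               # additive Gaussian, intensity fraction
    background_level: float = 0.1        # intensity fraction
    interference_spots: int = 0          # z-spanning artifact discs
    spot_amplitude: float = 0.8
    spot_radius_px: float = 3.0
    spot_positions: tuple | None = None  # explicit (y, x) centres; None = random
    object_intensity: float = 0.8

    def __post_init__(self) -> None:
        for name in ("in_focus_sigma", "defocus_sigma_per_um", "depth_of_field",
                     "noise_sd", "background_level", "spot_amplitude",
                     "spot_radius_px", "object_intensity"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.interference_spots < 0:
            raise ValueError("interference_spots must be non-negative")


def render_stack(truth: BinaryVolume, model: MicroscopeModel | None = None,
                 seed: int = 0, name: str = "synthetic") -> ImageStack:
    """Render a ground-truth volume into a wide-field z-stack.

    Output slice k is the maximum projection of every truth slice m blurred
    with sigma = sqrt(s0² + (c · max(0, |z_k − z_m| − DOF/2))²), where s0 is
    the in-focus blur, c the defocus blur growth and DOF the depth of field —
    the in-focus optical section stays sharp while planes further away
    contribute only smeared-out intensity. Background level, additive
    Gaussian noise and any interference-spot discs (identical in every slice)
    are added on top; intensities are clipped to [0, 1].
    """
    model = model or MicroscopeModel()
    rng = np.random.default_rng(seed)
    vox = truth.voxels
    nz, ny, nx = vox.shape
    dz = truth.geometry.dz
    # distinct |k - m| values share one blurred copy of each truth slice
    silhouettes = vox.astype(float) * model.object_intensity
    out = np.zeros((nz, ny, nx))
    blurred_cache: dict[tuple[int, int], np.ndarray] = {}
    occupied = [m for m in range(nz) if vox[m].any()]
    for k in range(nz):
        acc = out[k]
        for m in occupied:
            defocus = max(0.0, abs(k - m) * dz - model.depth_of_field / 2.0)
            if model.defocus_sigma_per_um == 0 and defocus > 0:
                # ideal-sectioning limit: zero blur growth means out-of-focus
                # planes are rejected entirely rather than shown sharp
                continue
            sigma = float(np.hypot(model.in_focus_sigma,
                                   model.defocus_sigma_per_um * defocus))
            key = (m, round(sigma * 100))
            img = blurred_cache.get(key)
            if img is None:
                img = ndi.gaussian_filter(silhouettes[m], sigma) if sigma > 0 \
                    else silhouettes[m]
                blurred_cache[key] = img
            np.maximum(acc, img, out=acc)
    out += model.background_level
    if model.interference_spots:
        spot = _spot_image((ny, nx), model, rng)
        out += spot[None, :, :]
    if model.noise_sd > 0:
        out += rng.normal(0.0, model.noise_sd, size=out.shape)
    np.clip(out, 0.0, 1.0, out=out)
    return ImageStack(out, truth.geometry, name=name)


def _spot_image(shape: tuple[int, int], model: MicroscopeModel,
                rng: np.random.Generator) -> np.ndarray:
    """Bright discs at random positions, to be repeated in every slice."""
    ny, nx = shape
    img = np.zeros(shape)
    ry = np.arange(ny)[:, None]
    rx = np.arange(nx)[None, :]
    margin = int(model.spot_radius_px) + 3
    if model.spot_positions is not None:
        centres = list(model.spot_positions)[:model.interference_spots]
    else:
        centres = [(rng.integers(margin, max(margin + 1, ny - margin)),
                    rng.integers(margin, max(margin + 1, nx - margin)))
                   for _ in range(model.interference_spots)]
    for cy, cx in centres:
        disc = (ry - cy) ** 2 + (rx - cx) ** 2 <= model.spot_radius_px ** 2
        img[disc] = model.spot_amplitude
    return img


def place_solids(shape: tuple[int, int, int], solids: list[tuple[np.ndarray, tuple[int, int, int]]],
                 geometry: VoxelGeometry | None = None) -> BinaryVolume:
    """Compose a scene: paste solid masks at (z, y, x) corner offsets."""
    scene = np.zeros(shape, dtype=bool)
    for mask, (z0, y0, x0) in solids:
        sz, sy, sx = mask.shape
        if z0 < 0 or y0 < 0 or x0 < 0 or z0 + sz > shape[0] \
                or y0 + sy > shape[1] or x0 + sx > shape[2]:
            raise ValueError("solid does not fit in the scene at that offset")
        scene[z0:z0 + sz, y0:y0 + sy, x0:x0 + sx] |= mask
    return BinaryVolume(scene, geometry or VoxelGeometry())
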