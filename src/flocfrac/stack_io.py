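"""Reading/writing image stacks, metrics tables and run configuration.

The physical anchor of every micrometre-scale quantity in the package is a
:class:`VoxelGeometry` — the x/y pixel pitch and the z step of the acquisition.
Axis order throughout the package is ``(z, y, x)`` with 0-based indices; the
physical coordinate of the centre of voxel ``(k, j, i)`` is
``(k*dz, j*dy, i*dx)`` in µm.

Geometry is always supplied by the user (config or CLI flags), never parsed
from TIFF metadata: resolution-tag dialects are unreliable across writers. If
a multi-page TIFF carries resolution tags that disagree with the supplied
geometry, a warning is logged and the supplied geometry wins.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

logger = logging.getLogger(__name__)

#: Default acquisition pitch (µm): wide-field 100x oil stack, 0.092 µm/px in
#: x/y and a 0.198 µm focus step between slices.
DEFAULT_DX = 0.092
DEFAULT_DY = 0.092
DEFAULT_DZ = 0.198


@dataclass(frozen=True)
class VoxelGeometry:
    """Physical pitch of a stack: µm per pixel in x, y and per z step."""

    dx: float = DEFAULT_DX
    dy: float = DEFAULT_DY
    dz: float = DEFAULT_DZ

    def __post_init__(self) -> None:
        for name in ("dx", "dy", "dz"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be a positive finite number, got {v!r}")

    @property
    def anisotropy(self) -> float:
        """Ratio dz/dx — how much coarser the z sampling is than x/y."""
        return self.dz / self.dx

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in µm³."""
        return self.dx * self.dy * self.dz

    @property
    def is_isotropic(self) -> bool:
        return np.isclose(self.dx, self.dy) and np.isclose(self.dx, self.dz)


@dataclass
class ImageStack:
    """Ordered grayscale slices of one field, z increasing with slice index."""

    slices: np.ndarray  # (z, y, x), integer or unit-interval float intensities
    geometry: VoxelGeometry = field(default_factory=VoxelGeometry)
    name: str = ""

    def __post_init__(self) -> None:
        arr = np.asarray(self.slices)
        if arr.ndim == 2:
            arr = arr[None]
        if arr.ndim != 3:
            raise ValueError(f"stack must be (z, y, x), got shape {arr.shape}")
        self.slices = arr

    def __len__(self) -> int:
        return self.slices.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.slices.shape


@dataclass
class RunConfig:
    """Every tunable parameter of the pipeline, serialisable for provenance.

    All fields have working defaults; CLI flags override config-file values
    which override these defaults.
    """

    # geometry (µm)
    dx: float = DEFAULT_DX
    dy: float = DEFAULT_DY
    dz: float = DEFAULT_DZ
    # segmentation
    edge_threshold: float = 1.0     # multiplier on the automatic (Otsu) gradient level
    close_radius: int = 2           # px, disk closing of the edge map
    fill_holes: bool = True
    clear_border_2d: bool = True
    # reconstruction filters
    connectivity: int = 26          # 6 | 18 | 26
    min_voxels: int = 50            # artifact cut ("very small" objects)
    pillar_min_z_span: float = 0.95
    pillar_max_footprint_dev: float = 0.1
    # box counting / fit
    eps_ladder: str = "pow2"
    fit_min_eps: int | None = None
    fit_max_eps: int | None = None
    r2_min: float = 0.98
    max_local_slope_dev: float = 0.15
    # population
    population_min_voxels: int = 5000

    @property
    def geometry(self) -> VoxelGeometry:
        return VoxelGeometry(self.dx, self.dy, self.dz)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
        return path


def _sorted_tiff_files(directory: Path) -> list[Path]:
    files = sorted(
        p for p in directory.iterdir()
        if p.suffix.lower() in {".tif", ".tiff"} and p.is_file()
    )
    if not files:
        raise ValueError(f"no TIFF files found in {directory}")
    return files


def read_stack(path: str | Path, geometry: VoxelGeometry | None = None,
               name: str | None = None) -> ImageStack:
    """Read a multi-page TIFF or a directory of numbered single-page TIFFs.

    Slices are ordered by page index (multi-page) or lexicographic filename
    (directory); intensities are preserved bit-exact. All slices must share
    one height × width.
    """
    path = Path(path)
    geometry = geometry or VoxelGeometry()
    if path.is_dir():
        files = _sorted_tiff_files(path)
        pages = [tifffile.imread(f) for f in files]
        shapes = {p.shape for p in pages}
        if len(shapes) > 1:
            raise ValueError(f"mixed slice dimensions in {path}: {sorted(shapes)}")
        if any(p.ndim != 2 for p in pages):
            raise ValueError("directory mode expects single-page 2D TIFFs")
        arr = np.stack(pages)
    else:
        arr = tifffile.imread(path)
        if arr.ndim == 2:
            arr = arr[None]
        if arr.ndim != 3:
            raise ValueError(f"expected grayscale pages, got shape {arr.shape}")
        _warn_on_conflicting_tags(path, geometry)
    return ImageStack(arr, geometry, name=name or path.stem)


def _warn_on_conflicting_tags(path: Path, geometry: VoxelGeometry) -> None:
    try:
        with tifffile.TiffFile(path) as tf:
            page = tf.pages[0]
            xres = page.tags.get("XResolution")
            if xres is None:
                return
            num, den = xres.value
            if num == 0 or den == 0:
                return
            tag_dx = den / num  # pitch in the tag's unit
            if not np.isclose(tag_dx, geometry.dx, rtol=0.05):
                logger.warning(
                    "TIFF resolution tag of %s (%.4g) conflicts with configured "
                    "dx=%.4g; using configured geometry", path, tag_dx, geometry.dx)
    except Exception:  # malformed tags never block reading
        pass


def write_stack(stack_or_volume, path: str | Path) -> Path:
    """Write a stack or binary volume as a multi-page TIFF.

    Boolean data is written as 8-bit 0/255 pages; other dtypes pass through.
    """
    path = Path(path)
    arr = getattr(stack_or_volume, "slices", None)
    if arr is None:
        arr = getattr(stack_or_volume, "voxels", stack_or_volume)
    arr = np.asarray(arr)
    if arr.ndim == 2:
        arr = arr[None]
    if arr.dtype == bool:
        arr = arr.astype(np.uint8) * 255
    tifffile.imwrite(path, arr)
    return path


#: Fixed output schema of the per-particle metrics table.
METRICS_COLUMNS = [
    "label", "voxel_count", "volume_um3", "diameter_um", "density",
    "surface_area_um2", "surface_to_volume_per_um", "fractal_dimension",
    "fit_r2", "monofractal_flag", "condition",
]


def metrics_frame(particles: Sequence) -> pd.DataFrame:
    """Per-particle metrics as a schema-stable DataFrame (fixed column order)."""
    rows = []
    for m in particles:
        d = dataclasses.asdict(m) if dataclasses.is_dataclass(m) else dict(m)
        rows.append({c: d.get(c) for c in METRICS_COLUMNS})
    return pd.DataFrame(rows, columns=METRICS_COLUMNS)


def write_metrics(particles: Sequence, path: str | Path) -> Path:
    """Write one CSV row per particle; an empty list yields a header-only file."""
    path = Path(path)
    metrics_frame(particles).to_csv(path, index=False)
    return path


def read_metrics(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_provenance(config: RunConfig, path: str | Path, seed: int | None = None,
                     extra: dict | None = None) -> Path:
    """Record the full run configuration (and seed) as JSON."""
    import flocfrac

    payload = {
        "flocfrac_version": flocfrac.__version__,
        "numpy_version": np.__version__,
        "seed": seed,
        "config": config.to_dict(),
    }
    if extra:
        payload.update(extra)
    path = Path(path)
    path.write_text(json.dumps(payload, indent=2))
    return path
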