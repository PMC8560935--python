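"""Binary/continuous vegetation rasters with real-world cell sizes.

A :class:`Landscape` is the shared substrate for recolonization
simulation and patch metrics: a 2-D array of vegetation cover in
[0, 1], a ground-sample distance (meters per cell edge), and an
optional mask of non-marsh cells excluded from cover accounting.

Rasters round-trip to single-band float TIFF or 8-bit PNG, with cell
size carried in a small JSON sidecar (``<raster>.json``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["Landscape", "seed_random_patches", "read_landscape", "write_landscape"]


@dataclass
class Landscape:
    grid: np.ndarray
    cell_size: float = 1.0
    mask: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        if self.grid.ndim != 2:
            raise ValueError("landscape grid must be 2-D")
        if not self.cell_size > 0:
            raise ValueError(f"cell_size must be > 0, got {self.cell_size}")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.grid.shape:
                raise ValueError("mask shape must match grid shape")
        unmasked = self.grid[self.unmasked]
        if unmasked.size and (
            not np.all(np.isfinite(unmasked))
            or unmasked.min() < 0.0
            or unmasked.max() > 1.0
        ):
            raise ValueError("unmasked cover values must be finite and in [0, 1]")

    @property
    def extent(self) -> tuple[int, int]:
        return self.grid.shape

    @property
    def unmasked(self) -> np.ndarray:
        """Boolean array of cells that count as marsh."""
        if self.mask is None:
            return np.ones(self.grid.shape, dtype=bool)
        return ~self.mask

    @property
    def n_unmasked(self) -> int:
        return int(self.unmasked.sum())

    @property
    def cell_area(self) -> float:
        return self.cell_size**2

    def cover_fraction(self, threshold: float | None = None) -> float:
        """Mean cover over unmasked cells; with ``threshold``, the
        fraction of unmasked cells at or above it."""
        vals = self.grid[self.unmasked]
        if vals.size == 0:
            return 0.0
        if threshold is None:
            return float(vals.mean())
        return float((vals >= threshold).mean())

    def copy(self) -> "Landscape":
        return Landscape(
            self.grid.copy(),
            self.cell_size,
            None if self.mask is None else self.mask.copy(),
        )


def seed_random_patches(
    extent: tuple[int, int],
    cell_size: float,
    remnant_cover: float,
    patch_radius: float,
    rng_seed: int,
) -> Landscape:
    """Seed disc-shaped remnant patches uniformly at random.

    Emulates a disturbance that clears all vegetation outside randomly
    distributed mussel mounds: discs of value 1 and radius
    ``patch_radius`` (meters) are dropped with overlap allowed until
    the realized cover fraction is within one patch-area of
    ``remnant_cover``. Reproducible under ``rng_seed``.
    """
    if not 0.0 <= remnant_cover <= 1.0:
        raise ValueError(f"remnant_cover must lie in [0, 1], got {remnant_cover}")
    if patch_radius < cell_size:
        raise ValueError("patch_radius must be at least one cell")
    rows, cols = extent
    grid = np.zeros((rows, cols), dtype=float)
    if remnant_cover == 0.0:
        return Landscape(grid, cell_size)
    if remnant_cover == 1.0:
        return Landscape(np.ones_like(grid), cell_size)

    rng = np.random.default_rng(rng_seed)
    n_cells = rows * cols
    r_cells = patch_radius / cell_size
    yy, xx = np.mgrid[0:rows, 0:cols]
    disc_cells = np.count_nonzero(
        (yy - rows // 2) ** 2 + (xx - cols // 2) ** 2 <= r_cells**2
    )
    patch_frac = disc_cells / n_cells
    # One disc must be resolvable against the target
    max_attempts = int(10 * np.ceil(remnant_cover / max(patch_frac, 1e-12))) + 100

    import warnings

    target_cells = remnant_cover * n_cells
    for _ in range(max_attempts):
        if grid.sum() + 0.5 * disc_cells >= target_cells:
            break
        cy = rng.uniform(0, rows)
        cx = rng.uniform(0, cols)
        sel = (yy - cy) ** 2 + (xx - cx) ** 2 <= r_cells**2
        grid[sel] = 1.0
    else:
        warnings.warn(
            "patch placement did not reach the requested cover; realized "
            f"cover = {grid.mean():.4f} (requested {remnant_cover:.4f})",
            stacklevel=2,
        )
    return Landscape(grid, cell_size)


def write_landscape(landscape: Landscape, path: str | Path) -> None:
    """Write a raster as float TIFF (``.tif``) or 8-bit PNG (``.png``)
    plus a JSON sidecar carrying ``cell_size``."""
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        import tifffile

        tifffile.imwrite(path, landscape.grid.astype(np.float32))
    elif path.suffix.lower() == ".png":
        from PIL import Image

        arr = (np.clip(landscape.grid, 0, 1) >= 0.5).astype(np.uint8) * 255
        Image.fromarray(arr, mode="L").save(path)
    else:
        raise ValueError(f"unsupported raster format: {path.suffix}")
    sidecar = {"cell_size": landscape.cell_size}
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar))


def read_landscape(path: str | Path, cell_size: float | None = None) -> Landscape:
    """Read a raster written by :func:`write_landscape` (or any
    single-band TIFF/PNG); ``cell_size`` overrides the sidecar."""
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        import tifffile

        grid = np.asarray(tifffile.imread(path), dtype=float)
    elif path.suffix.lower() == ".png":
        from PIL import Image

        grid = np.asarray(Image.open(path).convert("L"), dtype=float) / 255.0
    else:
        raise ValueError(f"unsupported raster format: {path.suffix}")
    if cell_size is None:
        sidecar = path.with_suffix(path.suffix + ".json")
        if sidecar.exists():
            cell_size = float(json.loads(sidecar.read_text())["cell_size"])
        else:
            cell_size = 1.0
    return Landscape(np.clip(grid, 0.0, 1.0), cell_size)
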