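"""Gridded height fields of the running track and their roughness statistics.

The track surface is represented as a node-registered rectangular grid of
heights. Coordinates follow the convention used throughout the package:
``x`` lateral (across the track), ``y`` longitudinal (along the track),
``z`` up, all in metres. Row ``iy`` of the height matrix is a lateral line
at constant ``y``; column ``ix`` is a longitudinal transect at constant
``x``.

Three families of statistics are computed here:

* **patch statistics** — the median and interquartile range (IQR) of the
  heights inside a rear-foot sized, axis-aligned patch. The patch IQR is
  the per-landing unevenness measure used by the foot-placement models.
* **amplitude / wavelength** — consecutive peak-to-valley height
  differences and peak-to-peak separations of local extrema along
  longitudinal transects, the track-level roughness description.
* **cell grids** — a tiling of the track into half-foot by one-foot cells
  used to count footsteps and compute the foot-placement index.

Quantiles are computed everywhere with the linearly interpolated
order-statistic rule (``numpy.percentile`` default).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import uniform_filter1d

from .errors import (
    ConfigurationError,
    DomainError,
    TerrainParseError,
    ValidationError,
)

#: Foot length of the mean subject (m); rear-foot patches are half this.
DEFAULT_FOOT_LENGTH = 0.19

#: Rear-foot sized sampling patch (width across track, length along it), m.
DEFAULT_PATCH_SIZE = (0.095, 0.095)

#: Moving-average window applied before local-extremum detection (m).
DEFAULT_SMOOTH_WINDOW = 0.020


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class TerrainField:
    """A gridded sagittal/lateral height map of the track surface.

    Parameters
    ----------
    heights : ndarray, shape (ny, nx)
        Surface heights in metres. Must be finite.
    resolution : float or (float, float)
        Grid spacing ``(dx, dy)`` in metres; a scalar means square cells.
    origin : (float, float)
        World coordinates ``(x0, y0)`` of node ``[0, 0]``.
    """

    heights: np.ndarray
    resolution: tuple
    origin: tuple = (0.0, 0.0)
    units: str = "m"

    def __post_init__(self):
        self.heights = np.asarray(self.heights, dtype=float)
        if self.heights.ndim != 2:
            raise ValidationError("heights must be a 2D array")
        if not np.all(np.isfinite(self.heights)):
            raise ValidationError("heights must be finite (no NaN/inf)")
        if np.isscalar(self.resolution):
            self.resolution = (float(self.resolution), float(self.resolution))
        else:
            self.resolution = (float(self.resolution[0]), float(self.resolution[1]))
        if min(self.resolution) <= 0:
            raise ValidationError("grid resolution must be > 0")
        self.origin = (float(self.origin[0]), float(self.origin[1]))

    # -- geometry ----------------------------------------------------------
    @property
    def ny(self) -> int:
        return self.heights.shape[0]

    @property
    def nx(self) -> int:
        return self.heights.shape[1]

    @property
    def dx(self) -> float:
        return self.resolution[0]

    @property
    def dy(self) -> float:
        return self.resolution[1]

    @property
    def x(self) -> np.ndarray:
        """Lateral node coordinates (m)."""
        return self.origin[0] + self.dx * np.arange(self.nx)

    @property
    def y(self) -> np.ndarray:
        """Longitudinal node coordinates (m)."""
        return self.origin[1] + self.dy * np.arange(self.ny)

    @property
    def track_width(self) -> float:
        return self.dx * (self.nx - 1)

    @property
    def track_length(self) -> float:
        return self.dy * (self.ny - 1)

    @property
    def bounds(self) -> tuple:
        """``(xmin, ymin, xmax, ymax)`` of the gridded region."""
        x0, y0 = self.origin
        return (x0, y0, x0 + self.track_width, y0 + self.track_length)

    # -- operations --------------------------------------------------------
    def mean_subtracted(self) -> "TerrainField":
        """Return a copy with the grand mean height removed."""
        return TerrainField(
            self.heights - self.heights.mean(),
            self.resolution,
            self.origin,
            self.units,
        )

    def interpolate(self, x, y):
        """Bilinear height interpolation at world coordinates (vectorised)."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        fx = np.clip((x - self.origin[0]) / self.dx, 0, self.nx - 1)
        fy = np.clip((y - self.origin[1]) / self.dy, 0, self.ny - 1)
        ix = np.clip(fx.astype(int), 0, self.nx - 2)
        iy = np.clip(fy.astype(int), 0, self.ny - 2)
        tx, ty = fx - ix, fy - iy
        h = self.heights
        return (
            h[iy, ix] * (1 - tx) * (1 - ty)
            + h[iy, ix + 1] * tx * (1 - ty)
            + h[iy + 1, ix] * (1 - tx) * ty
            + h[iy + 1, ix + 1] * tx * ty
        )


@dataclass
class PatchStats:
    """Height statistics of one axis-aligned terrain patch."""

    center: tuple
    h_iqr: float
    h_median: float
    patch_size: tuple
    clipped: bool = False
    n_nodes: int = 0

    def __post_init__(self):
        if self.h_iqr < 0:
            raise ValidationError("h_iqr must be >= 0")
        if min(self.patch_size) <= 0:
            raise ValidationError("patch_size must be > 0")


@dataclass
class TerrainStats:
    """Pooled amplitude / wavelength statistics of a field.

    ``amplitude`` is the absolute height difference between consecutive
    alternating extrema (peak-to-valley), ``wavelength`` the longitudinal
    separation of consecutive peaks. ``wavelengths_empty`` flags fields
    (e.g. flat ground) on which no peak pair was found.
    """

    amplitude_mean: float
    amplitude_sd: float
    wavelength_mean: float
    wavelength_sd: float
    n_amplitudes: int = 0
    n_wavelengths: int = 0
    wavelengths_empty: bool = False


@dataclass
class CellGrid:
    """Tiling of the analysed track region into footstep-counting cells.

    Cells are half-open ``[start, end)`` along both axes. Index ``i`` runs
    along the track (rows, cell side = 1.0 foot length) and ``j`` across it
    (columns, cell side = 0.5 foot length).
    """

    origin: tuple            # (x0, y0) of cell (0, 0)
    cell_length: float       # along-track side (m)
    cell_width: float        # across-track side (m)
    n_rows: int
    n_cols: int
    foot_length: float
    medians: np.ndarray = None    # (n_rows, n_cols) terrain medians
    iqrs: np.ndarray = None       # (n_rows, n_cols) terrain IQRs
    counts: np.ndarray = field(default=None)  # int footstep counts

    def __post_init__(self):
        if self.counts is None:
            self.counts = np.zeros((self.n_rows, self.n_cols), dtype=int)
        self.counts = np.asarray(self.counts)
        if np.any(self.counts < 0):
            raise ValidationError("cell counts must be non-negative")

    def cell_index(self, x, y):
        """Map world coordinates to ``(i, j)``; -1 marks out-of-region."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        j = np.floor((x - self.origin[0]) / self.cell_width).astype(int)
        i = np.floor((y - self.origin[1]) / self.cell_length).astype(int)
        ok = (i >= 0) & (i < self.n_rows) & (j >= 0) & (j < self.n_cols)
        i = np.where(ok, i, -1)
        j = np.where(ok, j, -1)
        return i, j

    def count_footsteps(self, xy) -> int:
        """Accumulate heel landings into ``counts``; returns #inside."""
        xy = np.atleast_2d(np.asarray(xy, dtype=float))
        i, j = self.cell_index(xy[:, 0], xy[:, 1])
        ok = i >= 0
        np.add.at(self.counts, (i[ok], j[ok]), 1)
        return int(ok.sum())


# ---------------------------------------------------------------------------
# I/O: delimited grid + JSON sidecar, bit-exact round trip
# ---------------------------------------------------------------------------

def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def save_terrain(terrain_field: TerrainField, path) -> Path:
    """Write a field as a whitespace-delimited matrix plus JSON metadata.

    Heights are written with 17 significant digits so that
    ``load_terrain(save_terrain(f))`` reproduces them bit-exactly.
    """
    path = Path(path)
    np.savetxt(path, terrain_field.heights, fmt="%.17g")
    meta = {
        "resolution": list(terrain_field.resolution),
        "origin": list(terrain_field.origin),
        "units": terrain_field.units,
        "shape": list(terrain_field.heights.shape),
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))
    return path


def load_terrain(path, mean_subtract: bool = False) -> TerrainField:
    """Read a delimited grid + JSON sidecar written by :func:`save_terrain`.

    Raises
    ------
    TerrainParseError
        If a row is malformed (message names the 1-based row).
    ValidationError
        If the metadata is inconsistent with the grid.
    """
    path = Path(path)
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip().replace(",", " ")
            if not line:
                continue
            try:
                row = [float(tok) for tok in line.split()]
            except ValueError as exc:
                raise TerrainParseError(
                    f"malformed terrain grid row {lineno} in {path}: {exc}"
                ) from None
            if rows and len(row) != len(rows[0]):
                raise TerrainParseError(
                    f"terrain grid row {lineno} has {len(row)} columns, "
                    f"expected {len(rows[0])}"
                )
            rows.append(row)
    if not rows:
        raise TerrainParseError(f"terrain grid {path} is empty")
    heights = np.array(rows, dtype=float)

    meta_path = _sidecar_path(path)
    if not meta_path.exists():
        raise ValidationError(f"missing terrain metadata sidecar {meta_path}")
    meta = json.loads(meta_path.read_text())
    if "shape" in meta and tuple(meta["shape"]) != heights.shape:
        raise ValidationError(
            f"metadata shape {meta['shape']} does not match grid "
            f"shape {list(heights.shape)}"
        )
    terrain = TerrainField(
        heights,
        tuple(meta["resolution"]),
        tuple(meta.get("origin", (0.0, 0.0))),
        meta.get("units", "m"),
    )
    return terrain.mean_subtracted() if mean_subtract else terrain


# ---------------------------------------------------------------------------
# Patch statistics
# ---------------------------------------------------------------------------

def patch_stats(
    terrain_field: TerrainField,
    center,
    patch_size=DEFAULT_PATCH_SIZE,
) -> PatchStats:
    """Median and IQR of heights inside an axis-aligned patch.

    The patch defaults to the rear-foot size (95 mm x 95 mm, half a foot
    length per side). All grid nodes whose coordinates fall inside the
    patch (inclusive of its boundary) contribute. Patches overhanging the
    track edge are clipped to the gridded region and flagged.
    """
    if np.isscalar(patch_size):
        patch_size = (float(patch_size), float(patch_size))
    cx, cy = float(center[0]), float(center[1])
    wx, wy = patch_size[0] / 2.0, patch_size[1] / 2.0
    xmin, ymin, xmax, ymax = terrain_field.bounds
    eps = 1e-12
    if cx + wx < xmin - eps or cx - wx > xmax + eps \
            or cy + wy < ymin - eps or cy - wy > ymax + eps:
        raise DomainError(
            f"patch centered at ({cx:.3f}, {cy:.3f}) lies fully outside the field"
        )
    clipped = (cx - wx < xmin - eps or cx + wx > xmax + eps
               or cy - wy < ymin - eps or cy + wy > ymax + eps)
    x = terrain_field.x
    y = terrain_field.y
    mx = (x >= cx - wx - eps) & (x <= cx + wx + eps)
    my = (y >= cy - wy - eps) & (y <= cy + wy + eps)
    vals = terrain_field.heights[np.ix_(my, mx)]
    if vals.size == 0:
        raise DomainError("patch contains no grid nodes")
    q25, q50, q75 = np.percentile(vals, [25, 50, 75])
    return PatchStats(
        center=(cx, cy),
        h_iqr=float(q75 - q25),
        h_median=float(q50),
        patch_size=tuple(patch_size),
        clipped=bool(clipped),
        n_nodes=int(vals.size),
    )


# ---------------------------------------------------------------------------
# Amplitude / wavelength along longitudinal transects
# ---------------------------------------------------------------------------

def _alternating_extrema(h_smooth: np.ndarray):
    """Indices and types (+1 peak / -1 valley) of alternating extrema."""
    interior = h_smooth[1:-1]
    is_max = (interior > h_smooth[:-2]) & (interior >= h_smooth[2:])
    is_min = (interior < h_smooth[:-2]) & (interior <= h_smooth[2:])
    idx = np.nonzero(is_max | is_min)[0] + 1
    if idx.size == 0:
        return idx, np.array([], dtype=int)
    types = np.where(is_max[idx - 1], 1, -1)
    # enforce alternation: among consecutive same-type extrema keep the
    # more extreme one
    keep_idx = [idx[0]]
    keep_typ = [types[0]]
    for k in range(1, idx.size):
        if types[k] == keep_typ[-1]:
            better = (
                h_smooth[idx[k]] > h_smooth[keep_idx[-1]]
                if types[k] == 1
                else h_smooth[idx[k]] < h_smooth[keep_idx[-1]]
            )
            if better:
                keep_idx[-1] = idx[k]
        else:
            keep_idx.append(idx[k])
            keep_typ.append(types[k])
    return np.array(keep_idx), np.array(keep_typ)


def measure_amplitude_wavelength(
    terrain_field: TerrainField,
    smooth_window: float = DEFAULT_SMOOTH_WINDOW,
) -> TerrainStats:
    """Peak-to-valley amplitudes and peak-to-peak wavelengths of a field.

    Along every longitudinal transect (grid column) the heights are first
    smoothed with a moving average of width ``smooth_window`` and
    alternating local maxima/minima are located. Each extremum is then
    refined to the raw-height extremum within half a smoothing window, so
    amplitudes are not attenuated by the smoothing. Amplitudes are the
    absolute height differences between consecutive alternating extrema;
    wavelengths are the separations of consecutive peaks. Statistics are
    pooled over all transects.
    """
    dy = terrain_field.dy
    w = max(1, int(round(smooth_window / dy)))
    half = max(1, w // 2)
    amplitudes = []
    wavelengths = []
    n = terrain_field.ny
    for ix in range(terrain_field.nx):
        h = terrain_field.heights[:, ix]
        hs = uniform_filter1d(h, size=w, mode="nearest")
        idx, typ = _alternating_extrema(hs)
        if idx.size < 2:
            continue
        # refine each extremum on the raw transect
        refined_pos = np.empty(idx.size, dtype=int)
        refined_val = np.empty(idx.size)
        for k, (i0, t0) in enumerate(zip(idx, typ)):
            lo, hi = max(0, i0 - half), min(n, i0 + half + 1)
            seg = h[lo:hi]
            off = np.argmax(seg) if t0 == 1 else np.argmin(seg)
            refined_pos[k] = lo + off
            refined_val[k] = seg[off]
        amplitudes.append(np.abs(np.diff(refined_val)))
        peaks = refined_pos[typ == 1]
        if peaks.size >= 2:
            wavelengths.append(np.diff(peaks) * dy)
    amplitudes = np.concatenate(amplitudes) if amplitudes else np.array([])
    wavelengths = np.concatenate(wavelengths) if wavelengths else np.array([])
    return TerrainStats(
        amplitude_mean=float(amplitudes.mean()) if amplitudes.size else 0.0,
        amplitude_sd=float(amplitudes.std()) if amplitudes.size else 0.0,
        wavelength_mean=float(wavelengths.mean()) if wavelengths.size else 0.0,
        wavelength_sd=float(wavelengths.std()) if wavelengths.size else 0.0,
        n_amplitudes=int(amplitudes.size),
        n_wavelengths=int(wavelengths.size),
        wavelengths_empty=wavelengths.size == 0,
    )


# ---------------------------------------------------------------------------
# Cell grid
# ---------------------------------------------------------------------------

def build_cell_grid(
    terrain_field: TerrainField,
    foot_length: float = DEFAULT_FOOT_LENGTH,
    region=None,
) -> CellGrid:
    """Tile the analysed region into 0.5 x 1.0 foot-length cells.

    ``region`` is ``(x0, y0, x1, y1)`` and defaults to the whole field.
    The longer cell side (one foot length) runs along the track. Cells
    tile the region from its lower corner; a trailing sliver narrower than
    a cell is not tiled. Per-cell terrain medians and IQRs are computed
    over the grid nodes inside each (half-open) cell.
    """
    if foot_length <= 0:
        raise ConfigurationError("foot_length must be > 0")
    if foot_length > terrain_field.track_width:
        raise ConfigurationError(
            f"foot_length {foot_length} m exceeds track width "
            f"{terrain_field.track_width} m"
        )
    if region is None:
        region = terrain_field.bounds
    x0, y0, x1, y1 = map(float, region)
    cell_length = 1.0 * foot_length
    cell_width = 0.5 * foot_length
    eps = 1e-9
    n_rows = int(np.floor((y1 - y0) / cell_length + eps))
    n_cols = int(np.floor((x1 - x0) / cell_width + eps))
    if n_rows < 1 or n_cols < 1:
        raise ConfigurationError("analysed region smaller than one cell")

    medians = np.full((n_rows, n_cols), np.nan)
    iqrs = np.full((n_rows, n_cols), np.nan)
    gx = terrain_field.x
    gy = terrain_field.y
    jx = np.floor((gx - x0) / cell_width + eps).astype(int)
    iy = np.floor((gy - y0) / cell_length + eps).astype(int)
    for i in range(n_rows):
        my = iy == i
        if not my.any():
            continue
        for j in range(n_cols):
            mx = jx == j
            if not mx.any():
                continue
            vals = terrain_field.heights[np.ix_(my, mx)]
            q25, q50, q75 = np.percentile(vals, [25, 50, 75])
            medians[i, j] = q50
            iqrs[i, j] = q75 - q25
    return CellGrid(
        origin=(x0, y0),
        cell_length=cell_length,
        cell_width=cell_width,
        n_rows=n_rows,
        n_cols=n_cols,
        foot_length=foot_length,
        medians=medians,
        iqrs=iqrs,
    )
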