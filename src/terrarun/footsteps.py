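"""Blind and directed foot-placement schemes and the foot-placement index.

Two extreme stepping hypotheses are simulated on a terrain field and
compared with observed footsteps:

* the **blind** scheme samples rear-foot sized landing patches uniformly
  at random over the analysed region — the null model of a runner who
  ignores the terrain;
* the **directed** scheme is a Markov-chain walk that, at every step,
  takes an open-loop stride dictated by the measured mean step length
  and width, searches the surrounding region (bounded by the measured
  step variability) for the patch with the lowest height interquartile
  range, and perturbs the chosen location with bounded von Mises noise —
  a runner who aims each footstep at the most level reachable ground.

The **foot-placement index** p_ij of a grid cell is its heel-landing
count divided by the mean total count of the step-length-sized
neighbourhoods (full track width, one step length long) that contain the
cell — an estimate of the landing probability relative to reachable
cells: 1 on the stepped cells of a perfectly periodic pattern, and the
reciprocal of the number of cells per step-length box for uniformly
random stepping.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DomainError, ValidationError
from .terrain import CellGrid, TerrainField, patch_stats

# ---------------------------------------------------------------------------
# Precomputed patch-IQR lookup
# ---------------------------------------------------------------------------

class PatchStatTable:
    """Exact patch median/IQR at every node-centred patch position.

    Patches are ``patch_size`` squares; the table covers all centres for
    which the patch lies fully inside the field. Percentiles use the
    same linearly interpolated order-statistic rule as
    :func:`terrarun.terrain.patch_stats`, so a table lookup at a
    node-centred position reproduces ``patch_stats`` exactly. Continuous
    query positions snap to the nearest node centre (the grid resolution
    is far below any terrain feature).
    """

    def __init__(self, terrain_field: TerrainField, patch_size: float = 0.095,
                 chunk_rows: int = 256):
        self.field = terrain_field
        self.patch_size = float(patch_size)
        dx, dy = terrain_field.resolution
        # nodes within +-patch/2 of a node-centred patch (inclusive), as
        # in terrain.patch_stats
        hx = int(np.floor(self.patch_size / 2.0 / dx + 1e-9))
        hy = int(np.floor(self.patch_size / 2.0 / dy + 1e-9))
        h = terrain_field.heights
        ny, nx = h.shape
        wy, wx = 2 * hy + 1, 2 * hx + 1
        if ny < wy or nx < wx:
            raise DomainError("field smaller than one patch")
        self.iy0, self.ix0 = hy, hx
        out_ny, out_nx = ny - wy + 1, nx - wx + 1
        iqr = np.empty((out_ny, out_nx))
        med = np.empty((out_ny, out_nx))
        win = np.lib.stride_tricks.sliding_window_view(h, (wy, wx))
        m = wy * wx
        # order-statistic ranks of the linearly interpolated quartiles
        ranks = [(m - 1) * q / 4.0 for q in (1, 2, 3)]
        exact = all(float(r).is_integer() for r in ranks)
        for r0 in range(0, out_ny, chunk_rows):
            r1 = min(r0 + chunk_rows, out_ny)
            block = win[r0:r1].reshape(r1 - r0, out_nx, m)
            if exact:
                kth = [int(r) for r in ranks]
                part = np.partition(block, kth, axis=2)
                q25 = part[:, :, kth[0]]
                q50 = part[:, :, kth[1]]
                q75 = part[:, :, kth[2]]
            else:
                q25, q50, q75 = np.percentile(block, [25, 50, 75], axis=2)
            iqr[r0:r1] = q75 - q25
            med[r0:r1] = q50
        self.iqr = iqr
        self.median = med

    def indices(self, x, y):
        """Snap world coordinates to valid patch-centre indices."""
        f = self.field
        ix = np.rint((np.asarray(x) - f.origin[0]) / f.dx).astype(int) - self.ix0
        iy = np.rint((np.asarray(y) - f.origin[1]) / f.dy).astype(int) - self.iy0
        ix = np.clip(ix, 0, self.iqr.shape[1] - 1)
        iy = np.clip(iy, 0, self.iqr.shape[0] - 1)
        return iy, ix

    def centers(self, iy, ix):
        """World coordinates of patch-centre indices."""
        f = self.field
        return (f.origin[0] + (np.asarray(ix) + self.ix0) * f.dx,
                f.origin[1] + (np.asarray(iy) + self.iy0) * f.dy)

    def iqr_at(self, x, y):
        iy, ix = self.indices(x, y)
        return self.iqr[iy, ix]

    def median_at(self, x, y):
        iy, ix = self.indices(x, y)
        return self.median[iy, ix]

    @property
    def valid_bounds(self):
        """(xmin, ymin, xmax, ymax) of fully interior patch centres."""
        f = self.field
        return (f.origin[0] + self.ix0 * f.dx,
                f.origin[1] + self.iy0 * f.dy,
                f.origin[0] + (self.ix0 + self.iqr.shape[1] - 1) * f.dx,
                f.origin[1] + (self.iy0 + self.iqr.shape[0] - 1) * f.dy)


# ---------------------------------------------------------------------------
# Blind scheme
# ---------------------------------------------------------------------------

def blind_sample(
    terrain_field: TerrainField,
    n: int,
    patch_size: float = 0.095,
    seed: int = 0,
    region=None,
    table: PatchStatTable = None,
) -> pd.DataFrame:
    """Uniform random sample of rear-foot sized landing patches.

    Returns a DataFrame with one row per sample (``x``, ``y``,
    ``h_iqr``, ``h_median``). Deterministic given ``seed``.
    """
    if n < 1:
        raise ValidationError("n must be >= 1")
    table = table or PatchStatTable(terrain_field, patch_size)
    xmin, ymin, xmax, ymax = region or table.valid_bounds
    if xmax <= xmin or ymax <= ymin:
        raise DomainError("sampling region smaller than one patch")
    rng = np.random.default_rng(seed)
    x = rng.uniform(xmin, xmax, n)
    y = rng.uniform(ymin, ymax, n)
    return pd.DataFrame({
        "x": x, "y": y,
        "h_iqr": table.iqr_at(x, y),
        "h_median": table.median_at(x, y),
    })


# ---------------------------------------------------------------------------
# Directed scheme (Markov-chain walk)
# ---------------------------------------------------------------------------

@dataclass
class DirectedWalkConfig:
    """Parameters of the directed foot-placement walk.

    Step statistics default to the mean subject on uneven ground
    (step length 126 %LL of a 0.89 m leg, width 4.7 %LL, variabilities
    6 %LL and 3.4 %LL). ``kappa`` is the von Mises concentration of the
    sensorimotor noise; the noise support (base) widths equal the step
    width and length standard deviations.
    """

    step_length: float = 1.12        # s_l, m
    step_length_sd: float = 0.053    # sigma_sl, m
    step_width: float = 0.042        # s_w, m
    step_width_sd: float = 0.030     # sigma_sw, m
    kappa: float = 1.0
    n_substeps: int = 10             # search grid half-resolution: sigma/10
    patch_size: float = 0.095
    n_steps: int = 100_000
    noise: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.step_length_sd <= 0 or self.step_width_sd <= 0:
            raise ValidationError("step variabilities must be positive")
        if self.kappa <= 0:
            raise ValidationError("kappa must be positive")
        if self.n_steps < 1:
            raise ValidationError("n_steps must be >= 1")


@dataclass
class StepSequence:
    """Footsteps of one simulated (or observed) stepping sequence."""

    positions: np.ndarray            # (n, 2) x, y
    directions: np.ndarray           # (n,) ±1 along the track
    h_iqr: np.ndarray                # patch IQR at each landing
    h_median: np.ndarray
    target_iqr: np.ndarray = None    # patch IQR at the open-loop target
    chosen_iqr: np.ndarray = None    # patch IQR of the minimisation pick
    clamped: np.ndarray = None       # search region clipped to track

    def realized_steps(self):
        """Per-step |dy| (length) and |dx| (width), same-direction pairs."""
        same = self.directions[1:] == self.directions[:-1]
        d = np.diff(self.positions, axis=0)
        return np.abs(d[same, 1]), np.abs(d[same, 0])

    def summary(self) -> dict:
        lengths, widths = self.realized_steps()
        return {
            "n_steps": int(self.positions.shape[0]),
            "mean_step_length": float(lengths.mean()) if lengths.size else np.nan,
            "sd_step_length": float(lengths.std()) if lengths.size else np.nan,
            "mean_step_width": float(widths.mean()) if widths.size else np.nan,
            "sd_step_width": float(widths.std()) if widths.size else np.nan,
            "mean_h_iqr": float(self.h_iqr.mean()),
            "median_h_iqr": float(np.median(self.h_iqr)),
        }


def directed_walk(
    terrain_field: TerrainField,
    cfg: DirectedWalkConfig,
    table: PatchStatTable = None,
) -> StepSequence:
    """Markov-chain walk that aims each step at the most level patch.

    Per step: (1) *open loop* — the target is one mean step length ahead
    in the current direction of travel and one mean step width to the
    alternating side; (2) *minimisation* — the patch height-IQR is
    evaluated on a (2n+1) x (2n+1) candidate grid spanning ±sigma about
    the target with sub-steps sigma/n (n = 10), and the lowest-IQR
    candidate wins; ties are broken by distance to the open-loop target
    (a uniformly level search region leaves the stride untouched), then
    lexicographically by (y, x); (3) *noise*
    — von Mises angles (kappa = 1, mean 0) are mapped linearly onto
    supports of width sigma_sw and sigma_sl and added. When the open-
    loop target leaves the straight section, the runner is reset to the
    track centre line and the direction of travel toggles before the
    minimisation stage.

    Candidate evaluation snaps to the node-centred patch table, which
    reproduces :func:`terrarun.terrain.patch_stats` exactly at those
    positions.
    """
    table = table or PatchStatTable(terrain_field, cfg.patch_size)
    xmin, ymin, xmax, ymax = table.valid_bounds
    x_center = 0.5 * (xmin + xmax)
    rng = np.random.default_rng(cfg.seed)

    n = cfg.n_substeps
    off_x = np.linspace(-cfg.step_width_sd, cfg.step_width_sd, 2 * n + 1)
    off_y = np.linspace(-cfg.step_length_sd, cfg.step_length_sd, 2 * n + 1)

    if cfg.noise:
        # angles on (-pi, pi] mapped so the support width equals sigma
        eta_x = rng.vonmises(0.0, cfg.kappa, cfg.n_steps) \
            * cfg.step_width_sd / (2 * np.pi)
        eta_y = rng.vonmises(0.0, cfg.kappa, cfg.n_steps) \
            * cfg.step_length_sd / (2 * np.pi)
    else:
        eta_x = np.zeros(cfg.n_steps)
        eta_y = np.zeros(cfg.n_steps)

    pos = np.empty((cfg.n_steps, 2))
    dirs = np.empty(cfg.n_steps, dtype=int)
    iqr_land = np.empty(cfg.n_steps)
    med_land = np.empty(cfg.n_steps)
    iqr_target = np.empty(cfg.n_steps)
    iqr_chosen = np.empty(cfg.n_steps)
    clamped = np.zeros(cfg.n_steps, dtype=bool)

    x, y = x_center, ymin + 0.05 * (ymax - ymin)
    j = 0            # direction exponent: travel sign = (-1)^j
    for i in range(cfg.n_steps):
        sgn_w = 1.0 if i % 2 == 0 else -1.0
        travel = 1.0 if j % 2 == 0 else -1.0
        xt = x + sgn_w * cfg.step_width
        yt = y + travel * cfg.step_length
        if yt > ymax or yt < ymin:
            # reset to the track centre and reverse direction of travel
            j ^= 1
            travel = -travel
            x = x_center
            xt = x + sgn_w * cfg.step_width
            yt = y + travel * cfg.step_length
        cand_x = xt + off_x
        cand_y = yt + off_y
        if (cand_x[0] < xmin or cand_x[-1] > xmax
                or cand_y[0] < ymin or cand_y[-1] > ymax):
            clamped[i] = True
            cand_x = np.clip(cand_x, xmin, xmax)
            cand_y = np.clip(cand_y, ymin, ymax)
        iy, _ = table.indices(np.full_like(cand_y, x_center), cand_y)
        _, ix = table.indices(cand_x, np.full_like(cand_x, y))
        vals = table.iqr[np.ix_(iy, ix)]
        ties = np.argwhere(vals == vals.min())
        if ties.shape[0] == 1:
            ky, kx = ties[0]
        else:
            # tie-break: nearest to the open-loop target, then by (y, x)
            cxs, cys = table.centers(iy[ties[:, 0]], ix[ties[:, 1]])
            d2 = (cxs - xt) ** 2 + (cys - yt) ** 2
            ky, kx = ties[np.lexsort((cxs, cys, d2))[0]]
        bx, by = table.centers(iy[ky], ix[kx])
        iqr_chosen[i] = vals[ky, kx]
        iqr_target[i] = table.iqr_at(xt, yt)

        x = float(np.clip(bx + eta_x[i], xmin, xmax))
        y = float(np.clip(by + eta_y[i], ymin, ymax))
        pos[i] = (x, y)
        dirs[i] = int(travel)
        iqr_land[i] = table.iqr_at(x, y)
        med_land[i] = table.median_at(x, y)

    return StepSequence(pos, dirs, iqr_land, med_land, iqr_target,
                        iqr_chosen, clamped)


# ---------------------------------------------------------------------------
# Foot-placement index
# ---------------------------------------------------------------------------

@dataclass
class PlacementIndexMap:
    """Cellwise foot-placement index and its ingredients."""

    index: np.ndarray        # p_ij; NaN where undefined
    counts: np.ndarray       # f_ij
    normalizer: np.ndarray   # S per row
    defined: np.ndarray      # bool mask
    step_length: float
    window_rows: int

    def to_frame(self, grid: CellGrid = None) -> pd.DataFrame:
        rows = []
        ni, nj = self.index.shape
        for i in range(ni):
            for j in range(nj):
                row = {
                    "i": i, "j": j,
                    "count": int(self.counts[i, j]),
                    "p": self.index[i, j],
                    "defined": bool(self.defined[i, j]),
                }
                if grid is not None and grid.medians is not None:
                    row["cell_median"] = grid.medians[i, j]
                    row["cell_iqr"] = grid.iqrs[i, j]
                rows.append(row)
        return pd.DataFrame(rows)


def foot_placement_index(
    grid: CellGrid,
    footsteps,
    step_length: float,
) -> PlacementIndexMap:
    """Foot-placement index p_ij = f_ij / S on a cell grid.

    ``f_ij`` counts heel landings per cell. For every window of
    consecutive rows spanning one step length (and the full track
    width), ``S_i`` is its total count; the normaliser S of a cell is
    the mean ``S_i`` over all fully contained windows covering its row.
    Rows with no containing window, or with S = 0, are undefined and
    flagged.
    """
    if step_length < grid.cell_length:
        raise ConfigurationError(
            "step length smaller than one cell; index undefined"
        )
    counts = np.zeros((grid.n_rows, grid.n_cols), dtype=int)
    xy = np.atleast_2d(np.asarray(footsteps, dtype=float))
    i, j = grid.cell_index(xy[:, 0], xy[:, 1])
    inside = i >= 0
    np.add.at(counts, (i[inside], j[inside]), 1)

    w = max(1, int(round(step_length / grid.cell_length)))
    n_rows = grid.n_rows
    row_tot = counts.sum(axis=1)
    normal = np.full(n_rows, np.nan)
    if n_rows >= w:
        csum = np.concatenate([[0], np.cumsum(row_tot)])
        win_tot = csum[w:] - csum[:-w]          # S_i per window start
        for r in range(n_rows):
            a = max(0, r - w + 1)
            b = min(r, n_rows - w)
            if b >= a:
                normal[r] = win_tot[a:b + 1].mean()
    defined_rows = np.isfinite(normal) & (normal > 0)
    index = np.full(counts.shape, np.nan)
    index[defined_rows] = counts[defined_rows] / normal[defined_rows, None]
    return PlacementIndexMap(
        index=index,
        counts=counts,
        normalizer=normal,
        defined=np.broadcast_to(defined_rows[:, None], counts.shape).copy(),
        step_length=float(step_length),
        window_rows=w,
    )


# ---------------------------------------------------------------------------
# Scheme comparison
# ---------------------------------------------------------------------------

def compare_schemes(
    terrain_field: TerrainField,
    observed: StepSequence,
    cfg: DirectedWalkConfig,
    n_blind: int = None,
    seed: int = 0,
    n_bins: int = 30,
    table: PatchStatTable = None,
):
    """Blind vs directed vs observed landing-unevenness comparison.

    Runs the blind sampler and the directed walk on ``terrain_field``
    and aligns their landing-patch h_IQR histograms and summary
    statistics with those of the observed step sequence. Returns
    ``(summary_frame, histogram_frame)``.
    """
    table = table or PatchStatTable(terrain_field, cfg.patch_size)
    n_blind = n_blind or cfg.n_steps
    blind = blind_sample(terrain_field, n_blind, cfg.patch_size,
                         seed=seed, table=table)
    directed = directed_walk(terrain_field, cfg, table=table)

    datasets = {
        "blind": blind["h_iqr"].to_numpy(),
        "directed": directed.h_iqr,
        "observed": np.asarray(observed.h_iqr, dtype=float),
    }
    all_vals = np.concatenate(list(datasets.values()))
    hi = all_vals.max() if all_vals.size else 1.0
    edges = np.linspace(0.0, max(hi, 1e-9), n_bins + 1)
    hist_rows = {}
    summary_rows = []
    for name, vals in datasets.items():
        dens, _ = np.histogram(vals, bins=edges, density=vals.size > 0)
        hist_rows[name] = dens
        row = {"scheme": name, "n": vals.size,
               "mean_h_iqr": float(vals.mean()) if vals.size else np.nan,
               "median_h_iqr": float(np.median(vals)) if vals.size else np.nan}
        if name == "directed":
            row.update({f"{k}": v for k, v in directed.summary().items()
                        if "step" in k})
        if name == "observed":
            lengths, widths = observed.realized_steps()
            if lengths.size:
                row.update(mean_step_length=float(lengths.mean()),
                           sd_step_length=float(lengths.std()),
                           mean_step_width=float(widths.mean()),
                           sd_step_width=float(widths.std()))
        summary_rows.append(row)
    hist = pd.DataFrame(hist_rows)
    hist.insert(0, "bin_left", edges[:-1])
    hist.insert(1, "bin_right", edges[1:])
    return pd.DataFrame(summary_rows).set_index("scheme"), hist
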