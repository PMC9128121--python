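"""Gridded environmental covariates and their extraction at point locations.

The covariate world is a planar, projected grid (meters): a static ocean-depth
layer, a static land mask, and daily sea-ice concentration layers (percent,
0-100).  Eight covariates are extracted for the step-selection analysis, in a
fixed column order:

    0 Depth      bilinear ocean depth (m, <= 0 over ocean)
    1 Conc       sea-ice concentration that day (%)
    2 Conc2      Conc squared
    3 SDConc     SD of concentration in cells whose centres lie within 100 km
    4 D2Land     distance to the nearest land cell (m)
    5 D2Land2    D2Land squared
    6 D2Ice      unsigned distance to the 10% concentration contour (m)
    7 D2Ice2     D2Ice squared

Distance layers use the Euclidean distance transform on cell centres; the
contour distance is the distance to the boundary between the below-10% and
above-10% regions (distance to the nearest opposite-region cell centre minus
half a cell, floored at zero).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

COVARIATE_NAMES = [
    "depth",
    "conc",
    "conc2",
    "sdconc",
    "d2land",
    "d2land2",
    "d2ice",
    "d2ice2",
]

N_COVARIATES = len(COVARIATE_NAMES)

SDCONC_RADIUS_M = 100_000.0
ICE_EDGE_THRESHOLD = 10.0


@dataclass(frozen=True)
class GridSpec:
    """Planar raster grid: origin at the lower-left corner, square cells."""

    x0: float
    y0: float
    cell_size: float
    nrows: int
    ncols: int

    def __post_init__(self):
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if self.nrows < 1 or self.ncols < 1:
            raise ValueError("grid must have at least one cell")

    @property
    def width(self) -> float:
        return self.ncols * self.cell_size

    @property
    def height(self) -> float:
        return self.nrows * self.cell_size

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        xs = self.x0 + (np.arange(self.ncols) + 0.5) * self.cell_size
        ys = self.y0 + (np.arange(self.nrows) + 0.5) * self.cell_size
        return xs, ys

    def in_bounds(self, points: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(np.asarray(points, dtype=float))
        return (
            (p[:, 0] >= self.x0)
            & (p[:, 0] <= self.x0 + self.width)
            & (p[:, 1] >= self.y0)
            & (p[:, 1] <= self.y0 + self.height)
        )

    def point_to_rc(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Nearest-cell (row, col) indices, clipped to the grid."""
        p = np.atleast_2d(np.asarray(points, dtype=float))
        col = np.clip(
            np.floor((p[:, 0] - self.x0) / self.cell_size).astype(int), 0, self.ncols - 1
        )
        row = np.clip(
            np.floor((p[:, 1] - self.y0) / self.cell_size).astype(int), 0, self.nrows - 1
        )
        return row, col

    def fractional_rc(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Continuous (row, col) coordinates in cell-centre index space."""
        p = np.atleast_2d(np.asarray(points, dtype=float))
        fc = (p[:, 0] - self.x0) / self.cell_size - 0.5
        fr = (p[:, 1] - self.y0) / self.cell_size - 0.5
        return fr, fc


def bilinear(field: np.ndarray, grid: GridSpec, points: np.ndarray) -> np.ndarray:
    """Bilinear interpolation of a (nrows, ncols) field at projected points."""
    fr, fc = grid.fractional_rc(points)
    fr = np.clip(fr, 0.0, grid.nrows - 1.0)
    fc = np.clip(fc, 0.0, grid.ncols - 1.0)
    r0 = np.clip(np.floor(fr).astype(int), 0, grid.nrows - 2) if grid.nrows > 1 else np.zeros_like(fr, int)
    c0 = np.clip(np.floor(fc).astype(int), 0, grid.ncols - 2) if grid.ncols > 1 else np.zeros_like(fc, int)
    r1 = np.minimum(r0 + 1, grid.nrows - 1)
    c1 = np.minimum(c0 + 1, grid.ncols - 1)
    wr = fr - r0
    wc = fc - c0
    return (
        field[r0, c0] * (1 - wr) * (1 - wc)
        + field[r1, c0] * wr * (1 - wc)
        + field[r0, c1] * (1 - wr) * wc
        + field[r1, c1] * wr * wc
    )


@dataclass
class CovariateStack:
    """Static depth/land layers plus daily sea-ice concentration layers."""

    grid: GridSpec
    depth: np.ndarray  # (nrows, ncols), meters, <= 0 over ocean
    ice_conc: np.ndarray  # (n_days, nrows, ncols), percent in [0, 100]
    land_mask: np.ndarray  # (nrows, ncols) bool
    dates: np.ndarray  # (n_days,) datetime64[D]
    _cache: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        self.depth = np.asarray(self.depth, dtype=float)
        self.ice_conc = np.asarray(self.ice_conc, dtype=float)
        self.land_mask = np.asarray(self.land_mask, dtype=bool)
        self.dates = np.asarray(self.dates, dtype="datetime64[D]")
        shape = (self.grid.nrows, self.grid.ncols)
        if self.depth.shape != shape or self.land_mask.shape != shape:
            raise ValueError("layer shapes do not match the grid")
        if self.ice_conc.ndim != 3 or self.ice_conc.shape[1:] != shape:
            raise ValueError("ice_conc must be (n_days, nrows, ncols)")
        if self.ice_conc.shape[0] != self.dates.shape[0]:
            raise ValueError("one date per ice layer required")
        if self.ice_conc.min() < 0 or self.ice_conc.max() > 100:
            raise ValueError("ice concentration must lie in [0, 100]")
        if self.land_mask.all() or not self.land_mask.any():
            raise ValueError("grid needs at least one ocean cell and one land cell")

    @property
    def n_days(self) -> int:
        return int(self.ice_conc.shape[0])

    def day_index(self, date) -> int:
        d = np.datetime64(date, "D")
        idx = int((d - self.dates[0]) / np.timedelta64(1, "D"))
        if idx < 0 or idx >= self.n_days:
            raise ValueError(f"date {d} outside the stack's range "
                             f"[{self.dates[0]}, {self.dates[-1]}]")
        return idx

    # ---- derived, cached layers -------------------------------------------

    def d2land_field(self) -> np.ndarray:
        """Distance (m) from each cell centre to the nearest land cell centre."""
        key = "d2land"
        if key not in self._cache:
            self._cache[key] = (
                ndimage.distance_transform_edt(~self.land_mask) * self.grid.cell_size
            )
        return self._cache[key]

    def d2ice_field(self, day: int) -> np.ndarray:
        """Unsigned distance (m) to the 10% concentration contour on a day."""
        key = ("d2ice", day)
        if key not in self._cache:
            below = self.ice_conc[day] < ICE_EDGE_THRESHOLD
            if below.all() or not below.any():
                raise ValueError(f"no {ICE_EDGE_THRESHOLD}% contour on day {day}")
            cs = self.grid.cell_size
            d_to_below = ndimage.distance_transform_edt(~below) * cs
            d_to_above = ndimage.distance_transform_edt(below) * cs
            d = np.where(below, d_to_above, d_to_below) - 0.5 * cs
            self._cache[key] = np.maximum(d, 0.0)
        return self._cache[key]

    def sdconc_field(self, day: int) -> np.ndarray:
        """Local SD of concentration over cells within 100 km of each centre."""
        key = ("sdconc", day)
        if key not in self._cache:
            mask = self._disc_mask()
            # centre on the global mean first: the local variance is
            # unchanged but the raw-moment cancellation is well conditioned
            conc = self.ice_conc[day] - self.ice_conc[day].mean()
            cnt = ndimage.convolve(
                np.ones_like(conc), mask, mode="constant", cval=0.0
            )
            s = ndimage.convolve(conc, mask, mode="constant", cval=0.0)
            s2 = ndimage.convolve(conc * conc, mask, mode="constant", cval=0.0)
            m = s / cnt
            var = np.maximum(s2 / cnt - m * m, 0.0)
            self._cache[key] = np.sqrt(var)
        return self._cache[key]

    def _disc_mask(self) -> np.ndarray:
        key = "disc"
        if key not in self._cache:
            rad = SDCONC_RADIUS_M / self.grid.cell_size
            n = int(np.floor(rad))
            dy, dx = np.mgrid[-n : n + 1, -n : n + 1]
            self._cache[key] = (dx * dx + dy * dy <= rad * rad).astype(float)
        return self._cache[key]

    def _ocean_centers(self) -> np.ndarray:
        key = "ocean_xy"
        if key not in self._cache:
            xs, ys = self.grid.cell_centers()
            rows, cols = np.where(~self.land_mask)
            self._cache[key] = np.column_stack([xs[cols], ys[rows]])
        return self._cache[key]

    # ---- point queries -----------------------------------------------------

    def is_land(self, points: np.ndarray) -> np.ndarray:
        row, col = self.grid.point_to_rc(points)
        return self.land_mask[row, col]

    def nearest_ocean(self, points: np.ndarray) -> np.ndarray:
        """Snap each point to the nearest ocean cell centre."""
        p = np.atleast_2d(np.asarray(points, dtype=float))
        oc = self._ocean_centers()
        d2 = ((p[:, None, :] - oc[None, :, :]) ** 2).sum(axis=2)
        return oc[np.argmin(d2, axis=1)]


def extract_covariates_batch(points, date, stack: CovariateStack) -> np.ndarray:
    """Raw 8-column covariate matrix for projected points on a given date.

    Raises ``ValueError`` naming the first off-grid point.
    """
    p = np.atleast_2d(np.asarray(points, dtype=float))
    inb = stack.grid.in_bounds(p)
    if not inb.all():
        bad = p[~inb][0]
        raise ValueError(f"point ({bad[0]:.1f}, {bad[1]:.1f}) lies off the grid")
    day = stack.day_index(date)
    row, col = stack.grid.point_to_rc(p)

    depth = bilinear(stack.depth, stack.grid, p)
    conc = stack.ice_conc[day][row, col]
    sdconc = stack.sdconc_field(day)[row, col]
    d2land = bilinear(stack.d2land_field(), stack.grid, p)
    d2ice = stack.d2ice_field(day)[row, col]

    return np.column_stack(
        [depth, conc, conc**2, sdconc, d2land, d2land**2, d2ice, d2ice**2]
    )


def extract_covariates(point, date, stack: CovariateStack) -> np.ndarray:
    """Raw 8-vector of covariates at one projected point on a given date."""
    return extract_covariates_batch(np.asarray(point, float)[None, :], date, stack)[0]


@dataclass(frozen=True)
class DesignInfo:
    """Per-covariate means and SDs used to centre and scale a design matrix."""

    means: np.ndarray
    sds: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "means", np.asarray(self.means, dtype=float))
        object.__setattr__(self, "sds", np.asarray(self.sds, dtype=float))
        if np.any(self.sds <= 0):
            raise ValueError("all scaling SDs must be positive")

    def apply(self, raw: np.ndarray) -> np.ndarray:
        return (np.asarray(raw, dtype=float) - self.means) / self.sds


def stack_normalizer(
    stack: CovariateStack, rng: np.random.Generator, n_sample: int = 2000
) -> DesignInfo:
    """Covariate means/SDs from a random sample of ocean points and days.

    Used by the synthetic track generator so selection coefficients act on
    approximately unit-scale covariates.
    """
    oc = stack._ocean_centers()
    idx = rng.integers(0, oc.shape[0], size=n_sample)
    jitter = rng.uniform(-0.5, 0.5, size=(n_sample, 2)) * stack.grid.cell_size
    pts = oc[idx] + jitter
    pts = np.clip(
        pts,
        [stack.grid.x0, stack.grid.y0],
        [stack.grid.x0 + stack.grid.width, stack.grid.y0 + stack.grid.height],
    )
    days = rng.integers(0, stack.n_days, size=n_sample)
    rows = []
    for d in np.unique(days):
        rows.append(extract_covariates_batch(pts[days == d], stack.dates[d], stack))
    raw = np.vstack(rows)
    sds = raw.std(axis=0)
    if np.any(sds <= 0):
        sds = np.where(sds <= 0, 1.0, sds)
    return DesignInfo(means=raw.mean(axis=0), sds=sds)
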