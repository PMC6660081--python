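"""Edge-effect detection and trimming.

Two strategies run per meridian on the levelled, apex-relative surface:

1. a moving median (default; windowed mean optional) of the absolute
   radial slope — where it exceeds three times its own meridian mean the
   first cutting edge fires;
2. a search for a local minimum of elevation radially inside the first
   edge (tear pooling produces a dip before the lift-off).

The ultimate cutting edge is whichever candidate is closest to the apex,
and everything at or beyond it is invalidated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .errors import ConfigurationError, QualityError
from .surface_io import MeridianProfile, PolarSurface

logger = logging.getLogger(__name__)


@dataclass
class MovingWindowConfig:
    """Sliding-window parameters for the slope screen.

    The window is capped both by radial distance (``halfwidth`` on each
    side) and by element count (``max_elements`` in total); at the ends
    of a meridian the backward/forward parts shrink to what is
    available.
    """

    halfwidth: float = 0.1          # mm, each side
    max_elements: int = 11          # total, odd
    statistic: str = "median"       # "median" or "mean"
    threshold_factor: float = 3.0

    def __post_init__(self) -> None:
        if self.halfwidth <= 0:
            raise ConfigurationError("window halfwidth must be > 0")
        if self.max_elements < 3 or self.max_elements % 2 == 0:
            raise ConfigurationError("max_elements must be odd and >= 3")
        if self.statistic not in ("median", "mean"):
            raise ConfigurationError(f"unknown statistic {self.statistic!r}")
        if self.threshold_factor <= 1:
            raise ConfigurationError("threshold_factor must be > 1")


@dataclass
class EdgeProfile:
    """Per-meridian cutting radii and which strategy fired."""

    angles: np.ndarray
    r_edge1: np.ndarray     # nan = none
    r_edge2: np.ndarray     # nan = none
    r_ultimate: np.ndarray  # nan = none
    strategy: np.ndarray    # "1", "2", "both", "none"
    limbus_radius: np.ndarray

    def __post_init__(self) -> None:
        n = self.angles.size
        for name in ("r_edge1", "r_edge2", "r_ultimate", "strategy", "limbus_radius"):
            if getattr(self, name).shape != (n,):
                raise ConfigurationError(f"{name} must have one entry per meridian")


def meridian_slope(profile: MeridianProfile) -> np.ndarray | None:
    """First radial derivative dz/dr over the valid nodes.

    Central differences at interior nodes, one-sided at the ends; returns
    an array aligned with the valid nodes, or None when fewer than three
    nodes are valid.
    """
    r = profile.r[profile.valid]
    z = profile.z[profile.valid]
    if r.size < 3:
        return None
    return np.gradient(z, r)


def moving_statistic(
    values: np.ndarray, grid: np.ndarray, config: MovingWindowConfig
) -> np.ndarray:
    """Sliding-window median (or mean) with distance and count caps.

    Element i aggregates the values at indices j with
    ``|grid[j] - grid[i]| <= halfwidth`` and ``|j - i| <= (max_elements-1)/2``;
    both caps apply simultaneously, and the backward/forward half-windows
    shrink naturally at the array boundaries.
    """
    values = np.asarray(values, dtype=float)
    grid = np.asarray(grid, dtype=float)
    if values.shape != grid.shape:
        raise ConfigurationError("values and grid must be aligned")
    n = values.size
    if n == 0:
        return values.copy()
    if n > 1 and np.any(np.diff(grid) <= 0):
        raise ConfigurationError("grid must be strictly increasing")
    half_count = (config.max_elements - 1) // 2
    agg = np.median if config.statistic == "median" else np.mean

    steps = np.diff(grid)
    uniform = n > 2 and np.allclose(steps, steps[0], rtol=1e-9, atol=1e-12)
    if uniform:
        half = min(half_count, int(np.floor(config.halfwidth / steps[0] + 1e-9)))
        out = np.empty(n)
        w = 2 * half + 1
        if n >= w and half > 0:
            from numpy.lib.stride_tricks import sliding_window_view

            windows = sliding_window_view(values, w)
            out[half:n - half] = agg(windows, axis=1)
        for i in range(min(half, n)):
            out[i] = agg(values[max(0, i - half):i + half + 1])
        for i in range(max(0, n - half), n):
            out[i] = agg(values[max(0, i - half):i + half + 1])
        if half == 0:
            out[:] = values
        return out

    lo_d = np.searchsorted(grid, grid - config.halfwidth - 1e-12, side="left")
    hi_d = np.searchsorted(grid, grid + config.halfwidth + 1e-12, side="right")
    out = np.empty(n)
    for i in range(n):
        lo = max(lo_d[i], i - half_count)
        hi = min(hi_d[i], i + half_count + 1)
        out[i] = agg(values[lo:hi])
    return out


def first_cutting_edge(
    m: np.ndarray,
    grid: np.ndarray,
    config: MovingWindowConfig,
    search_start: float = 0.0,
    baseline: str = "post_limbus",
) -> float | None:
    """Smallest radius where the slope screen exceeds its threshold.

    ``m`` is the moving statistic of the absolute slope on ``grid``.
    The threshold is ``threshold_factor`` times the mean of ``m`` over
    the search domain (``baseline="post_limbus"``) or over the whole
    meridian (``baseline="full"``).
    """
    m = np.asarray(m, dtype=float)
    grid = np.asarray(grid, dtype=float)
    if baseline not in ("post_limbus", "full"):
        raise ConfigurationError(f"unknown baseline {baseline!r}")
    domain = grid >= search_start
    if not domain.any():
        return None
    base = np.abs(m[domain]).mean() if baseline == "post_limbus" else np.abs(m).mean()
    if not np.isfinite(base) or base == 0:
        return None
    threshold = config.threshold_factor * base
    if not np.isfinite(threshold):  # threshold_factor -> inf
        return None
    exceed = domain & (np.abs(m) > threshold)
    if not exceed.any():
        return None
    return float(grid[np.argmax(exceed)])


def second_cutting_edge(
    profile: MeridianProfile,
    r_edge1: float | None,
    search_start: float = 0.0,
    min_prominence: float = 0.02,  # mm; default 20 um
    ordering: str = "radius",
) -> float | None:
    """Radius of a pre-edge elevation minimum (tear-pool dip), or None.

    Looks for strict local minima of z(r) with at least
    ``min_prominence`` prominence, at radii in (search_start, r_edge1)
    (the whole valid meridian when ``r_edge1`` is None).  With
    ``ordering="radius"`` the innermost minimum wins (most conservative
    cut); ``ordering="value"`` picks the lowest-elevation minimum.
    """
    if ordering not in ("radius", "value"):
        raise ConfigurationError(f"unknown ordering {ordering!r}")
    r = profile.r[profile.valid]
    z = profile.z[profile.valid]
    if r.size < 3:
        return None
    upper = np.inf if r_edge1 is None else r_edge1
    peaks, _ = find_peaks(-z, prominence=min_prominence)
    if peaks.size == 0:
        return None
    cand = peaks[(r[peaks] > search_start) & (r[peaks] < upper)]
    if cand.size == 0:
        return None
    if ordering == "radius":
        pick = cand[0]
    else:
        pick = cand[int(np.argmin(z[cand]))]
    return float(r[pick])


def ultimate_edge(r_edge1: float | None, r_edge2: float | None) -> float | None:
    """The cutting edge closest to the apex among the defined candidates."""
    candidates = [r for r in (r_edge1, r_edge2) if r is not None and np.isfinite(r)]
    if not candidates:
        return None
    return float(min(candidates))


def detect_edges(
    surface: PolarSurface,
    limbus_radius: np.ndarray | float,
    config: MovingWindowConfig | None = None,
    search_offset: float = 0.25,
    baseline: str = "post_limbus",
    min_prominence_mm: float = 0.02,
    ordering: str = "radius",
) -> EdgeProfile:
    """Run both strategies on every meridian of a levelled surface.

    ``limbus_radius`` is a scalar or one value per meridian; the search
    domain starts ``search_offset`` beyond it so the limbal transition
    itself is never classified as an artefact.
    """
    if config is None:
        config = MovingWindowConfig()
    n = surface.n_meridians
    limbus = np.broadcast_to(np.asarray(limbus_radius, dtype=float), (n,)).copy()
    fallback = np.nanmedian(limbus) if np.isfinite(limbus).any() else 6.0
    limbus[~np.isfinite(limbus)] = fallback

    e1 = np.full(n, np.nan)
    e2 = np.full(n, np.nan)
    ult = np.full(n, np.nan)
    strategy = np.full(n, "none", dtype=object)
    for i in range(n):
        prof = MeridianProfile(
            angle=float(surface.angles[i]),
            r=surface.r,
            z=surface.z[i],
            valid=surface.valid[i],
        )
        slope = meridian_slope(prof)
        if slope is None:
            continue
        r_valid = surface.r[prof.valid]
        start = limbus[i] + search_offset
        m = moving_statistic(np.abs(slope), r_valid, config)
        r1 = first_cutting_edge(m, r_valid, config, search_start=start, baseline=baseline)
        r2 = second_cutting_edge(
            prof, r1, search_start=start, min_prominence=min_prominence_mm,
            ordering=ordering,
        )
        ru = ultimate_edge(r1, r2)
        e1[i] = np.nan if r1 is None else r1
        e2[i] = np.nan if r2 is None else r2
        ult[i] = np.nan if ru is None else ru
        if r1 is not None and r2 is not None:
            strategy[i] = "both"
        elif r1 is not None:
            strategy[i] = "1"
        elif r2 is not None:
            strategy[i] = "2"
        if ru is not None and ru < limbus[i]:
            logger.warning(
                "meridian %.0f deg: cut at %.2f mm is inside the limbus (%.2f mm)",
                surface.angles[i], ru, limbus[i],
            )
    return EdgeProfile(
        angles=surface.angles.copy(),
        r_edge1=e1,
        r_edge2=e2,
        r_ultimate=ult,
        strategy=np.asarray(strategy, dtype=object),
        limbus_radius=limbus,
    )


def trim_surface(
    surface: PolarSurface, edges: EdgeProfile, max_cut_fraction: float = 0.5
) -> PolarSurface:
    """Invalidate every node at or beyond the ultimate cutting edge.

    Nothing is interpolated over the cut.  If more than
    ``max_cut_fraction`` of the meridians are cut at or inside their
    limbus (the whole sclera amputated), the measurement is unusable and
    a QualityError is raised.
    """
    if edges.angles.size != surface.n_meridians:
        raise ConfigurationError("edge profile does not match the surface")
    out = surface.copy()
    fully_cut = 0
    for i in range(surface.n_meridians):
        ru = edges.r_ultimate[i]
        if np.isfinite(ru):
            out.valid[i, surface.r >= ru] = False
            if ru <= edges.limbus_radius[i]:
                fully_cut += 1
    out.z[~out.valid] = np.nan
    if fully_cut > max_cut_fraction * surface.n_meridians:
        raise QualityError(
            f"{fully_cut}/{surface.n_meridians} meridians cut at or inside the "
            "limbus; measurement unusable"
        )
    return out
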