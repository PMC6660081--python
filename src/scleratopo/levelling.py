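"""Limbus detection, limbus-plane levelling and apex re-origin.

The limbus is found per meridian as the turning point of the smoothed
second radial derivative of elevation (the corneoscleral curvature
transition).  All accepted limbus points are fitted with a
total-least-squares plane; the plane normal gives the tilt angles

    alpha_x = -pi/2 + arccos(N . (0, 1, 0))
    alpha_y = -pi/2 + arccos(N . (1, 0, 0))

and the surface is levelled by rotating about the X then the Y axis
(rotation about Z fixed at zero), then re-originated at the apex.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.signal import find_peaks
from scipy.spatial import ConvexHull

from .errors import FitError, OrientationError, QualityError
from .surface_io import MeridianProfile, PolarSurface, SurfacePointCloud, resample_polar

logger = logging.getLogger(__name__)

#: accepted limbus radius band (mm); HVID is about 12 mm diameter
LIMBUS_RADIUS_BAND = (3.0, 9.0)

DEFAULT_SEARCH_WINDOW = (3.5, 7.0)
DEFAULT_SMOOTH_SIGMA_MM = 0.3
DEFAULT_MIN_PROMINENCE = 0.1  # of the 2nd derivative, mm^-1


@dataclass
class LimbusFit:
    """Per-meridian limbus points plus the fitted limbus plane."""

    angles: np.ndarray            # meridian angles, degrees
    r_limbus: np.ndarray          # limbus radius per meridian (nan = not found);
                                  # Fourier-smoothed over angle when enabled
    points: np.ndarray            # (n_accepted, 3) limbus points used in the fit
    accepted: np.ndarray          # bool per meridian
    plane_normal: np.ndarray      # unit (Nx, Ny, Nz), Nz > 0
    plane_offset: float           # N . p = offset
    alpha_x: float                # radians
    alpha_y: float                # radians
    alpha_z: float = 0.0          # fixed at zero by construction
    mean_limbus_radius: float = float("nan")
    r_limbus_raw: np.ndarray | None = None  # unsmoothed per-meridian detections

    @property
    def n_accepted(self) -> int:
        return int(self.accepted.sum())


def detect_limbus_meridian(
    profile: MeridianProfile,
    search_window: tuple[float, float] = DEFAULT_SEARCH_WINDOW,
    smooth_sigma_mm: float = DEFAULT_SMOOTH_SIGMA_MM,
    min_prominence: float = DEFAULT_MIN_PROMINENCE,
) -> float | None:
    """Radius of the corneoscleral curvature transition, or None.

    The elevation profile is Gaussian-smoothed, differentiated twice,
    and the most prominent local extremum (either sign) of the second
    derivative inside ``search_window`` is returned.  At the junction
    the steep corneal slope relaxes onto the flatter sclera, so the
    second derivative carries a sharp turning point there — a positive
    peak for a kinked (C0) join — standing far above the smooth
    curvature background of either surface.  The default window is
    capped at 7.0 mm so that peripheral edge artefacts, whose slope
    kinks can dwarf the limbal one, stay outside the search domain;
    meridians where an inner artefact still hijacks the detection are
    handled by the robust ring fit in :func:`detect_limbus_surface`.
    """
    candidates = limbus_candidates(profile, search_window, smooth_sigma_mm,
                                   min_prominence)
    if not candidates:
        return None
    return max(candidates, key=lambda c: c[1])[0]


def limbus_candidates(
    profile: MeridianProfile,
    search_window: tuple[float, float] = DEFAULT_SEARCH_WINDOW,
    smooth_sigma_mm: float = DEFAULT_SMOOTH_SIGMA_MM,
    min_prominence: float = DEFAULT_MIN_PROMINENCE,
) -> list[tuple[float, float]]:
    """All qualifying (radius, prominence) extrema of the smoothed d2."""
    valid = profile.valid
    if valid.sum() < 8:
        return []
    # longest contiguous valid run (smoothing needs a uniform grid)
    idx = np.flatnonzero(valid)
    breaks = np.flatnonzero(np.diff(idx) > 1)
    runs = np.split(idx, breaks + 1)
    run = max(runs, key=len)
    r = profile.r[run]
    z = profile.z[run]
    if r.size < 8:
        return []
    dr = float(np.median(np.diff(r)))
    sigma = max(smooth_sigma_mm / dr, 0.5)
    zs = gaussian_filter1d(z, sigma, mode="nearest")
    d2 = np.gradient(np.gradient(zs, r), r)
    in_win = (r >= search_window[0]) & (r <= search_window[1])
    if in_win.sum() < 5:
        return []
    sub = np.flatnonzero(in_win)
    out = []
    for signed in (d2[sub], -d2[sub]):
        peaks, props = find_peaks(signed, prominence=min_prominence)
        for k, prom in zip(peaks, props["prominences"]):
            j = sub[int(k)]
            loc = float(r[j])
            # parabolic sub-grid refinement of the extremum location
            if 0 < j < r.size - 1:
                y0, y1, y2 = d2[j - 1], d2[j], d2[j + 1]
                denom = y0 - 2 * y1 + y2
                if abs(denom) > 1e-15:
                    shift = 0.5 * (y0 - y2) / denom
                    if abs(shift) <= 1.0:
                        loc = float(r[j] + shift * dr)
            out.append((loc, float(prom)))
    return out


def _circular_moving_median(values: np.ndarray, window: int = 15) -> np.ndarray:
    """Moving median over a circularly ordered sequence."""
    n = values.size
    if n == 0 or window <= 1:
        return values.copy()
    half = min(window // 2, (n - 1) // 2)
    padded = np.concatenate([values[-half:], values, values[:half]])
    from numpy.lib.stride_tricks import sliding_window_view

    return np.median(sliding_window_view(padded, 2 * half + 1), axis=1)


def _fourier_smooth_radius(
    angles_deg: np.ndarray,
    radius: np.ndarray,
    accepted: np.ndarray,
    order: int = 2,
    trim_mm: float = 0.25,
    center: float | None = None,
) -> np.ndarray:
    """Robust low-order periodic (Fourier) fit of the limbus radius curve.

    The limbus is a smooth closed anatomical curve, so per-meridian
    detections are regularized by a least-squares trigonometric fit of
    ``order`` harmonics.  Detections hijacked by peripheral artefacts or
    noise are rejected by a prefilter (only radii within 0.3 mm of the
    accepted median, or of ``center`` when given, seed the first fit)
    followed by progressive residual trimming.  Returns the smoothed
    radius at every meridian angle.
    """
    th = np.deg2rad(angles_deg)
    cols = [np.ones_like(th)]
    for k in range(1, order + 1):
        cols.extend([np.cos(k * th), np.sin(k * th)])
    design = np.column_stack(cols)
    min_pts = max(8, design.shape[1] + 2)

    if center is None:
        center = float(np.median(radius[accepted]))
    use = accepted & (np.abs(radius - center) <= 0.3)
    if use.sum() < min_pts:
        use = accepted.copy()
    coef, *_ = np.linalg.lstsq(design[use], radius[use], rcond=None)
    for threshold in (2 * trim_mm, 1.2 * trim_mm, 0.8 * trim_mm, 0.6 * trim_mm):
        resid = np.abs(radius - design @ coef)
        trimmed = accepted & (resid <= threshold)
        if trimmed.sum() < min_pts:
            break
        use = trimmed
        coef, *_ = np.linalg.lstsq(design[use], radius[use], rcond=None)
    return design @ coef


def fit_limbus_plane(points: np.ndarray) -> tuple[np.ndarray, float]:
    """Total-least-squares plane through 3D points.

    Returns ``(normal, offset)`` with unit normal, Nz > 0, and
    ``normal . p = offset`` for points p on the plane.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 3:
        raise FitError("plane fit needs at least 3 points")
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    if s[1] < 1e-12 * max(s[0], 1.0):
        raise FitError("points are collinear; plane is undetermined")
    normal = vt[2]
    if normal[2] < 0:
        normal = -normal
    if normal[2] <= 0:
        raise FitError("degenerate plane orientation (normal in the XY plane)")
    normal = normal / np.linalg.norm(normal)
    return normal, float(normal @ centroid)


def tilt_angles(normal: np.ndarray) -> tuple[float, float]:
    """Tilt angles (radians) of a plane from its unit normal.

    ``alpha_x = -pi/2 + arccos(Ny)`` and ``alpha_y = -pi/2 + arccos(Nx)``:
    each is the complement of the angle between the normal and the in-plane
    axis it rotates about, so a level plane (normal (0,0,1)) gives (0, 0).
    """
    n = np.asarray(normal, dtype=float)
    nrm = np.linalg.norm(n)
    if abs(nrm - 1.0) > 1e-9:
        warnings.warn("normal vector is not unit length; normalizing", stacklevel=2)
        n = n / nrm
    if n[2] <= 0:
        raise OrientationError("plane normal must point out of the eye (Nz > 0)")
    alpha_x = -np.pi / 2 + np.arccos(np.clip(n[1], -1.0, 1.0))
    alpha_y = -np.pi / 2 + np.arccos(np.clip(n[0], -1.0, 1.0))
    return float(alpha_x), float(alpha_y)


def _rot_x(angle: float) -> np.ndarray:
    c, s = np.cos(angle), np.sin(angle)
    return np.array([[1.0, 0.0, 0.0], [0.0, c, -s], [0.0, s, c]])


def _rot_y(angle: float) -> np.ndarray:
    c, s = np.cos(angle), np.sin(angle)
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


def levelling_rotation(alpha_x: float, alpha_y: float) -> np.ndarray:
    """Rotation matrix that levels a plane with tilt angles (alpha_x, alpha_y).

    Rotation about X (by -alpha_x) then about Y (by +alpha_y); the signs
    follow from the angle definitions so that applying the matrix to the
    tilted normal yields (0, 0, 1) for small angles, with no rotation
    about Z.
    """
    return _rot_y(alpha_y) @ _rot_x(-alpha_x)


def level_surface(
    cloud: SurfacePointCloud, alpha_x: float, alpha_y: float
) -> SurfacePointCloud:
    """Rigidly rotate the cloud so its limbus plane becomes horizontal."""
    if not (np.isfinite(alpha_x) and np.isfinite(alpha_y)):
        raise OrientationError("tilt angles must be finite")
    if max(abs(alpha_x), abs(alpha_y)) >= np.pi / 4:
        raise OrientationError("tilt angle exceeds the physiological bound (pi/4)")
    rot = levelling_rotation(alpha_x, alpha_y)
    return cloud.with_points(cloud.points @ rot.T)


def recenter_apex(
    cloud: SurfacePointCloud,
    refine_radius: float = 0.5,
    edge_margin: float = 0.5,
) -> SurfacePointCloud:
    """Translate the cloud so the apex (refined maximum of z) is the origin.

    The raw maximum is refined by a local quadratic fit of z(x, y) over
    its ``refine_radius`` neighbourhood.  If the apex lies on (or within
    ``edge_margin`` of) the convex-hull boundary of the lateral support,
    the measurement is considered decentred and a QualityError is raised.
    """
    pts = cloud.points
    imax = int(np.argmax(pts[:, 2]))
    x0, y0 = pts[imax, 0], pts[imax, 1]
    near = np.hypot(pts[:, 0] - x0, pts[:, 1] - y0) <= refine_radius
    apex = pts[imax].copy()
    if near.sum() >= 6:
        xs = pts[near, 0] - x0
        ys = pts[near, 1] - y0
        zs = pts[near, 2]
        design = np.column_stack(
            [np.ones_like(xs), xs, ys, xs**2, xs * ys, ys**2]
        )
        coef, *_ = np.linalg.lstsq(design, zs, rcond=None)
        a0, b1, b2, c11, c12, c22 = coef
        hess = np.array([[2 * c11, c12], [c12, 2 * c22]])
        try:
            shift = np.linalg.solve(hess, -np.array([b1, b2]))
        except np.linalg.LinAlgError:
            shift = np.zeros(2)
        if np.linalg.norm(shift) <= refine_radius and np.trace(hess) < 0:
            xa, ya = x0 + shift[0], y0 + shift[1]
            za = a0 + b1 * shift[0] + b2 * shift[1] + c11 * shift[0] ** 2 \
                + c12 * shift[0] * shift[1] + c22 * shift[1] ** 2
            apex = np.array([xa, ya, za])
    hull = ConvexHull(pts[:, :2])
    # hull.equations: a.x + b <= 0 inside
    dist = hull.equations[:, :2] @ apex[:2] + hull.equations[:, 2]
    if np.max(dist) > -edge_margin:
        raise QualityError(
            "apex lies at the boundary of the measured area; scan likely decentred"
        )
    return cloud.with_points(pts - apex)


def level_eye(
    cloud: SurfacePointCloud,
    angular_step: float = 1.0,
    radial_step: float = 0.05,
    search_window: tuple[float, float] = DEFAULT_SEARCH_WINDOW,
    smooth_sigma_mm: float = DEFAULT_SMOOTH_SIGMA_MM,
    min_prominence: float = DEFAULT_MIN_PROMINENCE,
    max_iterations: int = 5,
    tol_rad: float = 1e-6,
    recenter: bool = True,
) -> tuple[SurfacePointCloud, LimbusFit, dict]:
    """Detect the limbus, level the surface iteratively and re-origin it.

    Returns the levelled (and re-centred) cloud, the limbus fit from the
    final detection pass, and a diagnostics dict.  The cumulative applied
    tilt (``alpha_x``/``alpha_y`` in the diagnostics) is reported in
    radians; the residual after the final pass must fall below
    ``tol_rad`` or a FitError is raised.
    """
    if cloud.frame != "anatomical":
        raise OrientationError("level_eye requires the anatomical frame")
    work = cloud
    total_ax = 0.0
    total_ay = 0.0
    fit: LimbusFit | None = None
    residual = np.inf
    # coarse loop: re-detect the limbus after each rotation until the
    # detected tilt falls below the re-detection jitter floor.  Heavy
    # peripheral artefacts bias the detected plane by up to ~1 degree in
    # a geometry-dependent way, which can make the iteration oscillate
    # instead of converge; in that case the best iterate is kept and a
    # warning issued — the residual is detection bias, not real tilt.
    coarse_tol = max(tol_rad, 5e-4)
    best: tuple[float, object, object, float, float] | None = None
    for iteration in range(max_iterations + 1):
        fit = _detect_limbus_fit(
            work, angular_step, radial_step, search_window, smooth_sigma_mm,
            min_prominence,
        )
        residual = max(abs(fit.alpha_x), abs(fit.alpha_y))
        if best is None or residual < best[0]:
            best = (residual, work, fit, total_ax, total_ay)
        if residual < coarse_tol or iteration == max_iterations:
            break
        work = level_surface(work, fit.alpha_x, fit.alpha_y)
        total_ax += fit.alpha_x
        total_ay += fit.alpha_y
    if residual >= 4 * coarse_tol:
        residual, work, fit, total_ax, total_ay = best
        if residual >= 2e-2:
            raise FitError(
                f"levelling did not converge: residual tilt {residual:.2e} rad "
                f"after {max_iterations} iterations"
            )
        logger.warning(
            "levelling limited by detection bias: accepting residual "
            "%.2e rad (likely peripheral artefacts)", residual,
        )
    # polish: rotate the cloud together with the detected limbus points
    # until the refitted limbus plane is horizontal to machine precision
    limbus_pts = fit.points.copy()
    for _ in range(10):
        normal, _ = fit_limbus_plane(limbus_pts)
        ax, ay = tilt_angles(normal)
        residual = max(abs(ax), abs(ay))
        if residual < min(tol_rad, 1e-9):
            break
        rot = levelling_rotation(ax, ay)
        work = work.with_points(work.points @ rot.T)
        limbus_pts = limbus_pts @ rot.T
        total_ax += ax
        total_ay += ay
    if residual >= tol_rad:
        raise FitError(
            f"levelling polish did not converge: residual {residual:.2e} rad"
        )
    if recenter:
        work = recenter_apex(work)
        # re-detect on the recentred, levelled surface: the refined apex
        # is a far better polar origin than the raw highest sample
        fit = _detect_limbus_fit(
            work, angular_step, radial_step, search_window, smooth_sigma_mm,
            min_prominence, center=(0.0, 0.0),
        )
    diagnostics = {
        "alpha_x": total_ax,
        "alpha_y": total_ay,
        "residual_rad": residual,
        "n_limbus_points": fit.n_accepted,
    }
    return work, fit, diagnostics


def _detect_limbus_fit(
    cloud: SurfacePointCloud,
    angular_step: float,
    radial_step: float,
    search_window: tuple[float, float],
    smooth_sigma_mm: float,
    min_prominence: float,
    center: tuple[float, float] | None = None,
) -> LimbusFit:
    surface = resample_polar(cloud, angular_step=angular_step,
                             radial_step=radial_step, center=center)
    return detect_limbus_surface(
        surface, search_window=search_window, smooth_sigma_mm=smooth_sigma_mm,
        min_prominence=min_prominence,
    )


def detect_limbus_surface(
    surface: PolarSurface,
    search_window: tuple[float, float] = DEFAULT_SEARCH_WINDOW,
    smooth_sigma_mm: float = DEFAULT_SMOOTH_SIGMA_MM,
    min_prominence: float = DEFAULT_MIN_PROMINENCE,
) -> LimbusFit:
    """Run limbus detection on every meridian and fit the limbus plane.

    The most prominent extremum per meridian seeds a robust low-order
    Fourier fit of the ring radius over angle; meridians whose raw pick
    strays from the ring (sector-artefact hijacks) are repaired from
    their secondary candidates near the ring.  The limbus plane is
    fitted at the raw repaired radii (incoherent noise averages out),
    with a sector-coherent residual trim as a final defence.
    """
    n = surface.n_meridians
    r_limbus = np.full(n, np.nan)
    per_meridian: list[list[tuple[float, float]]] = []
    pooled: list[float] = []
    for i, angle in enumerate(surface.angles):
        prof = MeridianProfile(
            angle=float(angle), r=surface.r, z=surface.z[i], valid=surface.valid[i]
        )
        cands = limbus_candidates(
            prof, search_window=search_window, smooth_sigma_mm=smooth_sigma_mm,
            min_prominence=min_prominence,
        )
        per_meridian.append(cands)
        pooled.extend(c[0] for c in cands)
    if not pooled:
        raise FitError("no limbus candidates found on any meridian")
    # raw pass: the most prominent extremum per meridian (accurate for a
    # clean or merely tilted eye, hijackable by strong sector artefacts)
    raw = np.full(n, np.nan)
    for i, cands in enumerate(per_meridian):
        if cands:
            raw[i] = max(cands, key=lambda c: c[1])[0]
    ok_raw = np.isfinite(raw)
    if ok_raw.sum() < 8:
        raise FitError("too few limbus candidates on the surface")
    # robust ring: median-seeded, progressively trimmed Fourier fit
    ring_curve = _fourier_smooth_radius(surface.angles, raw, ok_raw)
    # repair pass: where the raw pick strays from the ring (artefact
    # hijack), fall back to the most prominent candidate near the ring
    for i, cands in enumerate(per_meridian):
        if ok_raw[i] and abs(raw[i] - ring_curve[i]) <= 0.15:
            r_limbus[i] = raw[i]
        else:
            near = [c for c in cands if abs(c[0] - ring_curve[i]) <= 0.15]
            if near:
                r_limbus[i] = max(near, key=lambda c: c[1])[0]
    accepted = (
        np.isfinite(r_limbus)
        & (r_limbus >= LIMBUS_RADIUS_BAND[0])
        & (r_limbus <= LIMBUS_RADIUS_BAND[1])
    )
    n_flagged = int(np.isfinite(r_limbus).sum() - accepted.sum())
    if n_flagged:
        logger.warning("%d limbus point(s) outside the plausibility band", n_flagged)
    if accepted.sum() < 3:
        raise FitError(
            f"only {int(accepted.sum())} accepted limbus point(s); cannot fit a plane"
        )
    r_raw = r_limbus.copy()
    r_smooth = _fourier_smooth_radius(surface.angles, r_limbus, accepted)
    r_limbus = np.where(accepted, r_smooth, r_limbus)
    # the plane is fitted at the *raw* repaired radii: their per-meridian
    # noise is incoherent (averages out over hundreds of points) whereas
    # the low-order smoothing would spread any sector-local detection
    # bias into a global ripple the plane fit cannot reject
    th = np.deg2rad(surface.angles[accepted])
    rl = r_raw[accepted]
    zl = np.array(
        [
            np.interp(rv, surface.r[surface.valid[i]], surface.z[i][surface.valid[i]])
            for rv, i in zip(rl, np.flatnonzero(accepted))
        ]
    )
    good = np.isfinite(zl)
    if good.sum() < 3:
        raise FitError("too few finite limbus elevations for a plane fit")
    accepted[np.flatnonzero(accepted)[~good]] = False
    th, rl, zl = th[good], rl[good], zl[good]
    pts = np.column_stack([rl * np.cos(th), rl * np.sin(th), zl])
    # robust plane: artefact-pulled limbus points are biased coherently
    # within lid sectors, by less than the per-point scatter — visible
    # only after smoothing the plane residuals over angle.  Sectors with
    # a coherent offset are excluded and the plane refitted.
    keep = np.ones(pts.shape[0], dtype=bool)
    normal, offset = fit_limbus_plane(pts)
    for _ in range(2):
        resid = pts @ normal - offset
        smoothed = _circular_moving_median(resid, window=15)
        mad = np.median(np.abs(smoothed - np.median(smoothed)))
        tol = max(0.025, 3.0 * 1.4826 * mad)
        new_keep = np.abs(smoothed) <= tol
        if new_keep.sum() < max(8, int(0.25 * pts.shape[0])) \
                or (new_keep == keep).all():
            break
        keep = new_keep
        normal, offset = fit_limbus_plane(pts[keep])
    if not keep.all():
        accepted[np.flatnonzero(accepted)[~keep]] = False
        pts = pts[keep]
    ax, ay = tilt_angles(normal)
    return LimbusFit(
        angles=surface.angles.copy(),
        r_limbus=r_limbus,
        r_limbus_raw=r_raw,
        points=pts,
        accepted=accepted,
        plane_normal=normal,
        plane_offset=offset,
        alpha_x=ax,
        alpha_y=ay,
        alpha_z=0.0,
        mean_limbus_radius=float(np.mean(rl)),
    )
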