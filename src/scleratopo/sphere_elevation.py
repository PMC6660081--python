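"""Best-fit sphere, relative elevation and reference-pattern correlation.

The fitted objective is the algebraic one,

    sum_i ((Xi - Xc)^2 + (Yi - Yc)^2 + (Zi - Zc)^2 - Rs^2)^2,

initialized from the linear Kasa solution and refined by nonlinear least
squares.  A geometric-distance objective is available as an option.
Sphere height is the upper sheet

    Zs = Zc + sqrt(Rs^2 - (X - Xc)^2 - (Y - Yc)^2)

and relative elevation is Zi - Zsi per node.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import pearsonr

from .errors import ConfigurationError, DataError, FitError
from .surface_io import PolarSurface, wrap_angle

#: quadrant labels -> central angle (degrees, anatomical convention)
QUADRANT_CENTERS = {"nasal": 0.0, "superior": 90.0, "temporal": 180.0, "inferior": -90.0}


@dataclass
class SphereFit:
    """Best-fit sphere parameters (mm) and fit diagnostics."""

    Xc: float
    Yc: float
    Zc: float
    Rs: float
    rms_residual: float  # rms geometric (radial) residual, mm
    n_points: int
    objective: str = "algebraic"

    @property
    def center(self) -> np.ndarray:
        return np.array([self.Xc, self.Yc, self.Zc])

    def to_dict(self) -> dict:
        return {
            "Xc_mm": self.Xc,
            "Yc_mm": self.Yc,
            "Zc_mm": self.Zc,
            "Rs_mm": self.Rs,
            "rms_residual_mm": self.rms_residual,
            "n_points": self.n_points,
            "objective": self.objective,
        }


@dataclass
class ElevationMap:
    """Relative elevation (Zi - Zsi) per polar node, plus its reference."""

    angles: np.ndarray
    r: np.ndarray
    relative: np.ndarray      # (n_angles, n_r), nan where undefined
    defined: np.ndarray       # bool mask
    reference: SphereFit


def kasa_sphere(points: np.ndarray) -> np.ndarray:
    """Linear (algebraic) sphere estimate: returns (Xc, Yc, Zc, Rs)."""
    pts = np.asarray(points, dtype=float)
    design = np.column_stack([2 * pts, np.ones(len(pts))])
    rhs = (pts**2).sum(axis=1)
    sol, *_ = np.linalg.lstsq(design, rhs, rcond=None)
    center = sol[:3]
    r2 = sol[3] + center @ center
    if r2 <= 0:
        raise FitError("Kasa initialization produced a non-positive radius")
    return np.append(center, np.sqrt(r2))


def sphere_objective(params: np.ndarray, points: np.ndarray) -> float:
    """Value of the algebraic sum-of-squared-errors objective."""
    c, rs = params[:3], params[3]
    res = ((points - c) ** 2).sum(axis=1) - rs**2
    return float((res**2).sum())


def fit_sphere(
    points: np.ndarray,
    objective: str = "algebraic",
    max_iterations: int = 200,
) -> SphereFit:
    """Least-squares sphere through 3D points.

    ``objective="algebraic"`` minimizes the squared-radius residuals
    (the default); ``objective="geometric"`` minimizes orthogonal
    distances.  The fit is deterministic for a fixed point set.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise DataError("points must be an (n, 3) array")
    if pts.shape[0] < 10:
        raise FitError("sphere fit needs at least 10 points")
    if objective not in ("algebraic", "geometric"):
        raise ConfigurationError(f"unknown objective {objective!r}")
    centered = pts - pts.mean(axis=0)
    sv = np.linalg.svd(centered, compute_uv=False)
    if sv[2] / np.sqrt(pts.shape[0]) < 1e-3:  # rms planarity within ~1 um
        raise FitError("points are (near-)coplanar; sphere is undetermined")

    x0 = kasa_sphere(pts)

    if objective == "algebraic":
        def residuals(p):
            return ((pts - p[:3]) ** 2).sum(axis=1) - p[3] ** 2
    else:
        def residuals(p):
            return np.linalg.norm(pts - p[:3], axis=1) - p[3]

    result = least_squares(
        residuals,
        x0,
        method="lm",
        xtol=1e-12,
        ftol=1e-14,
        gtol=1e-14,
        max_nfev=max_iterations * 5,
    )
    if not result.success:
        raise FitError(f"sphere fit did not converge: {result.message}")
    xc, yc, zc, rs = result.x
    rs = abs(float(rs))
    dist = np.linalg.norm(pts - result.x[:3], axis=1)
    rms = float(np.sqrt(np.mean((dist - rs) ** 2)))
    return SphereFit(
        Xc=float(xc), Yc=float(yc), Zc=float(zc), Rs=rs,
        rms_residual=rms, n_points=pts.shape[0], objective=objective,
    )


def sphere_height(
    fit: SphereFit, x: np.ndarray | float, y: np.ndarray | float
) -> np.ndarray | float:
    """Upper-sheet sphere height Zs at lateral position(s) (x, y).

    Raises DataError when every requested point lies outside the
    sphere's lateral footprint; out-of-footprint entries of an array
    query are returned as nan.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    arg = fit.Rs**2 - (x - fit.Xc) ** 2 - (y - fit.Yc) ** 2
    scalar = arg.ndim == 0
    arg = np.atleast_1d(arg)
    inside = arg >= -1e-12
    if not inside.any():
        raise DataError("point(s) outside the best-fit sphere's lateral footprint")
    zs = np.full(arg.shape, np.nan)
    zs[inside] = fit.Zc + np.sqrt(np.clip(arg[inside], 0.0, None))
    return float(zs[0]) if scalar else zs


def scleral_annulus_mask(
    surface: PolarSurface,
    limbus_radius: np.ndarray | float,
    offset: float = 0.25,
    outer_radius: np.ndarray | float | None = None,
) -> np.ndarray:
    """Valid nodes between (limbus + offset) and the per-meridian cut."""
    n = surface.n_meridians
    inner = np.broadcast_to(np.asarray(limbus_radius, dtype=float), (n,)).copy()
    fill = np.nanmedian(inner) if np.isfinite(inner).any() else 6.0
    inner[~np.isfinite(inner)] = fill
    mask = surface.valid & (surface.r[None, :] >= inner[:, None] + offset)
    if outer_radius is not None:
        outer = np.broadcast_to(np.asarray(outer_radius, dtype=float), (n,)).copy()
        outer[~np.isfinite(outer)] = np.inf
        mask &= surface.r[None, :] < outer[:, None]
    return mask


def relative_elevation(
    surface: PolarSurface, region: np.ndarray, fit: SphereFit
) -> ElevationMap:
    """Relative-elevation map z - Zs over the region's valid nodes."""
    if region.shape != surface.z.shape:
        raise ConfigurationError("region mask must match the surface")
    region = region & surface.valid
    th = np.deg2rad(surface.angles)[:, None]
    x = surface.r[None, :] * np.cos(th)
    y = surface.r[None, :] * np.sin(th)
    arg = fit.Rs**2 - (x - fit.Xc) ** 2 - (y - fit.Yc) ** 2
    footprint = arg >= -1e-12
    defined = region & footprint
    rel = np.full(surface.z.shape, np.nan)
    zs = fit.Zc + np.sqrt(np.clip(arg, 0.0, None))
    rel[defined] = surface.z[defined] - zs[defined]
    n_outside = int((region & ~footprint).sum())
    if n_outside:
        import logging

        logging.getLogger(__name__).warning(
            "%d region node(s) outside the sphere footprint", n_outside
        )
    return ElevationMap(
        angles=surface.angles.copy(), r=surface.r.copy(), relative=rel,
        defined=defined, reference=fit,
    )


def quadrant_masks(surface: PolarSurface, width: float = 90.0) -> dict[str, np.ndarray]:
    """Boolean node masks for the four 90-degree anatomical quadrants."""
    masks = {}
    for name, center in QUADRANT_CENTERS.items():
        delta = np.abs(wrap_angle(surface.angles - center))
        masks[name] = (delta < width / 2)[:, None] & np.ones(
            (1, surface.r.size), dtype=bool
        )
    return masks


def correlate_with_reference(
    surface: PolarSurface,
    region: np.ndarray,
    reference_radius: float = 11.5,
    min_nodes: int = 10,
) -> dict[str, float]:
    """Pearson correlation against an apex-aligned reference sphere.

    The reference is a sphere of ``reference_radius`` centred at
    (0, 0, -reference_radius) (apex at the origin); the correlation is
    computed per anatomical quadrant over matched nodes, nan when a
    quadrant has fewer than ``min_nodes`` usable nodes.
    """
    region = region & surface.valid
    ref_fit = SphereFit(
        Xc=0.0, Yc=0.0, Zc=-reference_radius, Rs=reference_radius,
        rms_residual=0.0, n_points=0,
    )
    arg = reference_radius**2 - surface.r**2
    footprint = (arg >= 0)[None, :] & np.ones((surface.n_meridians, 1), dtype=bool)
    ref_z = np.full(surface.z.shape, np.nan)
    ref_z[footprint] = (
        -reference_radius
        + np.sqrt(np.broadcast_to(np.clip(arg, 0, None)[None, :], surface.z.shape))[
            footprint
        ]
    )
    out = {}
    for name, qmask in quadrant_masks(surface).items():
        mask = region & qmask & footprint
        if mask.sum() < min_nodes:
            out[name] = float("nan")
            continue
        obs = surface.z[mask]
        ref = ref_z[mask]
        if np.ptp(obs) == 0 or np.ptp(ref) == 0:
            out[name] = float("nan")
            continue
        out[name] = float(pearsonr(obs, ref).statistic)
    return out
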