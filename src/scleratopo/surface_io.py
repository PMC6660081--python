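"""Domain types and I/O for anterior-eye elevation point clouds.

Coordinates are millimetres throughout.  Two reference frames are used:

``instrument``
    The frame in which the profilometer exports data: +x points to the
    patient's left as seen by the instrument (temporal for the left eye,
    nasal for the right eye), +y superior, +z toward the instrument.

``anatomical``
    +x nasal, +y superior, +z out of the eye — for *both* eyes, so that
    the 0-degree meridian is nasal regardless of laterality.

Angles are stored in degrees in [-180, 180): 0 nasal, +90 superior,
-90 inferior, +/-180 temporal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
import scipy.io
from scipy.interpolate import PchipInterpolator

from .errors import ConfigurationError, DataError, FormatError

logger = logging.getLogger(__name__)

LATERALITIES = ("OD", "OS")

#: default variable names expected inside a MAT-container export
DEFAULT_MAT_VARIABLES = {"x": "x", "y": "y", "z": "z"}

#: column names of the neutral CSV dialect
XYZ_CSV_COLUMNS = ("x_mm", "y_mm", "z_mm")

#: maximum lateral extent accepted without a warning (instrument covers a
#: 20 mm diameter; leave margin)
MAX_LATERAL_EXTENT_MM = 25.0


@dataclass
class SurfacePointCloud:
    """Raw (x, y, z) elevation samples of one eye.

    Parameters
    ----------
    points
        ``(n, 3)`` float array of coordinates in mm.
    laterality
        ``"OD"`` (right eye) or ``"OS"`` (left eye).
    source_id
        Opaque provenance string (file stem, synthetic recipe id, ...).
    frame
        ``"instrument"`` or ``"anatomical"``.
    """

    points: np.ndarray
    laterality: str
    source_id: str = ""
    frame: str = "instrument"

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3:
            raise DataError(f"points must be (n, 3); got shape {pts.shape}")
        if pts.shape[0] == 0:
            raise DataError("point cloud is empty")
        if not np.isfinite(pts).all():
            raise DataError("point cloud contains non-finite coordinates")
        if self.laterality not in LATERALITIES:
            raise ConfigurationError(
                f"unknown laterality {self.laterality!r}; expected one of {LATERALITIES}"
            )
        if self.frame not in ("instrument", "anatomical"):
            raise ConfigurationError(f"unknown frame {self.frame!r}")
        self.points = pts
        if pts.shape[0] < 100:
            logger.warning(
                "point cloud %s has only %d points (< 100)", self.source_id, pts.shape[0]
            )
        extent = float(
            max(np.ptp(pts[:, 0]), np.ptp(pts[:, 1])) if pts.shape[0] > 1 else 0.0
        )
        if extent > MAX_LATERAL_EXTENT_MM:
            logger.warning(
                "point cloud %s lateral extent %.1f mm exceeds %.0f mm",
                self.source_id,
                extent,
                MAX_LATERAL_EXTENT_MM,
            )

    @property
    def n_points(self) -> int:
        return int(self.points.shape[0])

    def with_points(self, points: np.ndarray) -> "SurfacePointCloud":
        return replace(self, points=np.asarray(points, dtype=float))


@dataclass
class MeridianProfile:
    """Elevation along one meridian on a fixed radial grid."""

    angle: float
    r: np.ndarray
    z: np.ndarray
    valid: np.ndarray

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        self.z = np.asarray(self.z, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if not (self.r.shape == self.z.shape == self.valid.shape):
            raise DataError("r, z and valid must have identical shapes")

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())


@dataclass
class PolarSurface:
    """Surface resampled onto meridians at fixed polar steps.

    ``z[i, j]`` is the elevation of meridian ``angles[i]`` at radius
    ``r[j]``; ``valid`` masks nodes with interpolation support.
    """

    angles: np.ndarray
    r: np.ndarray
    z: np.ndarray
    valid: np.ndarray
    angular_step: float = 1.0
    radial_step: float = 0.05

    def __post_init__(self) -> None:
        self.angles = np.asarray(self.angles, dtype=float)
        self.r = np.asarray(self.r, dtype=float)
        self.z = np.asarray(self.z, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.z.shape != (self.angles.size, self.r.size):
            raise DataError("z shape does not match (angles, r)")
        if self.valid.shape != self.z.shape:
            raise DataError("valid shape does not match z")
        if self.r.size >= 2 and not np.all(np.diff(self.r) > 0):
            raise DataError("radial grid must be strictly increasing")

    @property
    def n_meridians(self) -> int:
        return int(self.angles.size)

    def angle_index(self, angle: float) -> int:
        """Index of the meridian whose angle equals ``angle`` (wrapped)."""
        wrapped = wrap_angle(angle)
        idx = int(np.argmin(np.abs(self.angles - wrapped)))
        if abs(self.angles[idx] - wrapped) > self.angular_step / 2 + 1e-9:
            raise KeyError(f"no meridian at angle {angle}")
        return idx

    def meridian(self, angle: float) -> MeridianProfile:
        i = self.angle_index(angle)
        return MeridianProfile(
            angle=float(self.angles[i]), r=self.r, z=self.z[i], valid=self.valid[i]
        )

    def copy(self) -> "PolarSurface":
        return PolarSurface(
            angles=self.angles.copy(),
            r=self.r.copy(),
            z=self.z.copy(),
            valid=self.valid.copy(),
            angular_step=self.angular_step,
            radial_step=self.radial_step,
        )

    def to_dataframe(self) -> pd.DataFrame:
        """Long-format view: angle_deg, r_mm, z_mm, valid."""
        n_a, n_r = self.z.shape
        return pd.DataFrame(
            {
                "angle_deg": np.repeat(self.angles, n_r),
                "r_mm": np.tile(self.r, n_a),
                "z_mm": self.z.ravel(),
                "valid": self.valid.ravel(),
            }
        )

    def nodes_xyz(self, mask: np.ndarray | None = None) -> np.ndarray:
        """Cartesian coordinates of (valid) nodes as an (n, 3) array."""
        if mask is None:
            mask = self.valid
        th = np.deg2rad(self.angles)[:, None] * np.ones_like(self.r)[None, :]
        rr = np.ones_like(self.angles)[:, None] * self.r[None, :]
        x = rr * np.cos(th)
        y = rr * np.sin(th)
        return np.column_stack([x[mask], y[mask], self.z[mask]])


def wrap_angle(angle: float | np.ndarray) -> float | np.ndarray:
    """Wrap degrees into [-180, 180)."""
    wrapped = np.mod(np.asarray(angle, dtype=float) + 180.0, 360.0) - 180.0
    if np.isscalar(angle) or np.ndim(angle) == 0:
        return float(wrapped)
    return wrapped


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def load_point_cloud(
    path,
    dialect: str,
    laterality: str,
    mat_variables: dict | None = None,
    source_id: str | None = None,
) -> SurfacePointCloud:
    """Read a point cloud in the instrument frame.

    ``dialect`` is ``"xyz-csv"`` (header ``x_mm,y_mm,z_mm``) or
    ``"mat-container"`` (three equal-length double arrays whose variable
    names default to ``x``/``y``/``z`` and can be remapped through
    ``mat_variables``).  Rows with non-finite coordinates are dropped and
    the drop count logged.
    """
    if dialect == "xyz-csv":
        df = pd.read_csv(path, comment="#")
        missing = [c for c in XYZ_CSV_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"{path}: missing column(s) {', '.join(missing)}")
        pts = df.loc[:, list(XYZ_CSV_COLUMNS)].to_numpy(dtype=float)
    elif dialect == "mat-container":
        varmap = dict(DEFAULT_MAT_VARIABLES)
        if mat_variables:
            varmap.update(mat_variables)
        try:
            mat = scipy.io.loadmat(path)
        except (ValueError, OSError) as exc:
            raise FormatError(f"{path}: not a readable MAT container ({exc})") from exc
        cols = []
        for axis in ("x", "y", "z"):
            name = varmap[axis]
            if name not in mat:
                raise FormatError(f"{path}: missing MAT variable {name!r} (axis {axis})")
            cols.append(np.asarray(mat[name], dtype=float).ravel())
        if len({c.size for c in cols}) != 1:
            raise FormatError(f"{path}: x/y/z arrays have unequal lengths")
        pts = np.column_stack(cols)
    else:
        raise ConfigurationError(f"unknown dialect {dialect!r}")

    finite = np.isfinite(pts).all(axis=1)
    n_dropped = int((~finite).sum())
    if n_dropped:
        logger.info("%s: dropped %d non-finite row(s)", path, n_dropped)
    pts = pts[finite]
    if pts.shape[0] == 0:
        raise DataError(f"{path}: no finite points after filtering")
    return SurfacePointCloud(
        points=pts,
        laterality=laterality,
        source_id=source_id if source_id is not None else str(path),
        frame="instrument",
    )


def write_point_cloud(cloud: SurfacePointCloud, path, dialect: str = "xyz-csv",
                      mat_variables: dict | None = None, header_comment: str | None = None) -> None:
    """Write a point cloud in the given dialect (inverse of the reader)."""
    if dialect == "xyz-csv":
        df = pd.DataFrame(cloud.points, columns=list(XYZ_CSV_COLUMNS))
        with open(path, "w", encoding="utf-8", newline="") as fh:
            if header_comment:
                fh.write(f"# {header_comment}\n")
            df.to_csv(fh, index=False, float_format="%.9f")
    elif dialect == "mat-container":
        varmap = dict(DEFAULT_MAT_VARIABLES)
        if mat_variables:
            varmap.update(mat_variables)
        scipy.io.savemat(
            path,
            {
                varmap["x"]: cloud.points[:, 0],
                varmap["y"]: cloud.points[:, 1],
                varmap["z"]: cloud.points[:, 2],
            },
        )
    else:
        raise ConfigurationError(f"unknown dialect {dialect!r}")


def write_polar_csv(surface: PolarSurface, path, header_comment: str | None = None) -> None:
    df = surface.to_dataframe()
    with open(path, "w", encoding="utf-8", newline="") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, index=False, float_format="%.9f")


def read_polar_csv(path) -> PolarSurface:
    df = pd.read_csv(path, comment="#")
    angles = np.unique(df["angle_deg"].to_numpy())
    r = np.unique(df["r_mm"].to_numpy())
    n_a, n_r = angles.size, r.size
    if len(df) != n_a * n_r:
        raise FormatError(f"{path}: not a dense angle x radius table")
    df = df.sort_values(["angle_deg", "r_mm"], kind="mergesort")
    z = df["z_mm"].to_numpy().reshape(n_a, n_r)
    valid = df["valid"].to_numpy(dtype=bool).reshape(n_a, n_r)
    astep = float(np.median(np.diff(angles))) if n_a > 1 else 1.0
    rstep = float(np.median(np.diff(r))) if n_r > 1 else 0.05
    return PolarSurface(angles=angles, r=r, z=z, valid=valid,
                        angular_step=astep, radial_step=rstep)


# ---------------------------------------------------------------------------
# frame conversion
# ---------------------------------------------------------------------------

def to_anatomical_frame(cloud: SurfacePointCloud) -> SurfacePointCloud:
    """Re-sign the x axis by laterality so +x is nasal for both eyes.

    For OD the instrument frame already has +x nasal (identity); for OS
    the x coordinate is negated.  Applying the conversion twice restores
    the original cloud (the transformation is an involution that toggles
    the frame tag).
    """
    if cloud.laterality not in LATERALITIES:
        raise ConfigurationError(f"unknown laterality {cloud.laterality!r}")
    target = "anatomical" if cloud.frame == "instrument" else "instrument"
    pts = cloud.points.copy()
    if cloud.laterality == "OS":
        pts[:, 0] = -pts[:, 0]
    return replace(cloud, points=pts, frame=target)


def to_instrument_frame(cloud: SurfacePointCloud) -> SurfacePointCloud:
    """Inverse of :func:`to_anatomical_frame`."""
    if cloud.frame != "anatomical":
        raise ConfigurationError("cloud is not in the anatomical frame")
    return to_anatomical_frame(cloud)


# ---------------------------------------------------------------------------
# polar resampling
# ---------------------------------------------------------------------------

def resample_polar(
    cloud: SurfacePointCloud,
    angular_step: float = 1.0,
    radial_step: float = 0.05,
    center: tuple[float, float] | None = None,
    max_radius: float | None = None,
    min_sector_points: int = 4,
    max_gap_mm: float = 1.5,
) -> PolarSurface:
    """Resample scattered points onto meridians at fixed polar steps.

    Each meridian at angle theta is built from the points falling in the
    angular sector theta +/- angular_step/2 around ``center`` (default:
    the (x, y) of the highest point).  Within a sector, (r, z) pairs are
    sorted by radius and interpolated with a monotone piecewise-cubic
    scheme onto the radial grid.  Nodes outside the sector's radial span
    are never extrapolated, and nodes falling inside a radial data gap
    wider than ``max_gap_mm`` (genuinely missing coverage, e.g. lid
    occlusion) are marked invalid.  Sectors with fewer than
    ``min_sector_points`` points yield an entirely invalid meridian.
    """
    if cloud.frame != "anatomical":
        raise ConfigurationError("resample_polar requires the anatomical frame")
    pts = cloud.points
    if center is None:
        imax = int(np.argmax(pts[:, 2]))
        center = (float(pts[imax, 0]), float(pts[imax, 1]))
    dx = pts[:, 0] - center[0]
    dy = pts[:, 1] - center[1]
    rad = np.hypot(dx, dy)
    theta = np.degrees(np.arctan2(dy, dx))

    n_theta = int(round(360.0 / angular_step))
    if abs(n_theta * angular_step - 360.0) > 1e-9:
        raise ConfigurationError("angular_step must divide 360")
    angles = -180.0 + angular_step * np.arange(n_theta)

    # nearest sector index, with wrap-around
    sector = np.mod(np.round(theta / angular_step).astype(int) + n_theta // 2, n_theta)

    # near the apex all sectors converge: points laterally closer to a
    # meridian ray than half a radial step support that meridian too
    lat_tol = radial_step / 2
    r_cut = lat_tol / np.sin(np.deg2rad(angular_step) / 2)
    near_apex = np.flatnonzero(rad < r_cut)

    if max_radius is None:
        max_radius = float(rad.max())
    n_r = int(np.floor(max_radius / radial_step + 1e-9)) + 1
    grid = radial_step * np.arange(n_r)

    z = np.full((n_theta, n_r), np.nan)
    valid = np.zeros((n_theta, n_r), dtype=bool)

    order = np.argsort(sector, kind="stable")
    bounds = np.searchsorted(sector[order], np.arange(n_theta + 1))
    for i in range(n_theta):
        sel = order[bounds[i]:bounds[i + 1]]
        if near_apex.size:
            ang = angles[i]
            dth = np.deg2rad(np.abs(wrap_angle(theta[near_apex] - ang)))
            extra = near_apex[
                (dth < np.pi / 2) & (rad[near_apex] * np.sin(dth) <= lat_tol)
            ]
            if extra.size:
                sel = np.unique(np.concatenate([sel, extra]))
        if sel.size < min_sector_points:
            continue
        rs = rad[sel]
        zs = pts[sel, 2]
        srt = np.argsort(rs)
        rs, zs = rs[srt], zs[srt]
        # bin-average radii closer than half a grid step: near-duplicate
        # abscissae from different sector angles otherwise feed the
        # monotone-cubic interpolant wild local slopes
        rq = np.round(rs / (radial_step / 2)).astype(np.int64)
        uniq, inv = np.unique(rq, return_inverse=True)
        if uniq.size < rs.size:
            counts = np.bincount(inv)
            rs = np.bincount(inv, weights=rs) / counts
            zs = np.bincount(inv, weights=zs) / counts
        if rs.size < min_sector_points:
            continue
        interp = PchipInterpolator(rs, zs, extrapolate=False)
        lo, hi = rs[0], rs[-1]
        in_span = (grid >= lo - 1e-12) & (grid <= hi + 1e-12)
        if not in_span.any():
            continue
        zi = interp(grid[in_span])
        gsub = grid[in_span]
        ok = np.ones(gsub.size, dtype=bool)
        for b in np.flatnonzero(np.diff(rs) > max_gap_mm):
            ok &= ~((gsub > rs[b]) & (gsub < rs[b + 1]))
        cols = np.flatnonzero(in_span)[ok]
        z[i, cols] = zi[ok]
        valid[i, cols] = np.isfinite(z[i, cols])
    z[~valid] = np.nan
    return PolarSurface(
        angles=angles,
        r=grid,
        z=z,
        valid=valid,
        angular_step=angular_step,
        radial_step=radial_step,
    )
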