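"""Synthetic corneoscleral surfaces with planted ground truth.

An eye is a conicoid cornea joined (C0 by default) to a near-spherical
sclera at the limbus, optionally modulated by angular asymmetry
harmonics, decorated with peripheral artefacts (lid lift-off, tear
pooling, lash spikes), rigidly tilted, and sampled with Gaussian height
noise.  Everything planted is recorded in a GroundTruth object so every
pipeline stage can be tested against known answers.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from . import levelling
from .errors import ConfigurationError, DataError
from .surface_io import SurfacePointCloud


@dataclass
class ArtefactSpec:
    """One planted peripheral artefact.

    ``kind`` is ``liftoff`` (monotone ramp up beyond the onset, then a
    plateau), ``tearpool`` (a localized Gaussian dip centred at the
    onset) or ``lash_spike`` (a narrow high bump).  ``angular_extent``
    is a (lo, hi) degree interval, wrap-around allowed.
    """

    kind: str
    onset_radius: float
    amplitude: float
    angular_extent: tuple[float, float] = (-180.0, 180.0)
    ramp_width: float = 0.05

    def __post_init__(self) -> None:
        if self.kind not in ("liftoff", "tearpool", "lash_spike"):
            raise ConfigurationError(f"unknown artefact kind {self.kind!r}")
        if self.amplitude == 0:
            raise ConfigurationError("artefact amplitude must be nonzero")
        if self.ramp_width <= 0:
            raise ConfigurationError("artefact ramp_width must be > 0")

    def covers(self, theta_deg: np.ndarray) -> np.ndarray:
        lo, hi = self.angular_extent
        span = hi - lo
        if span >= 360.0:
            return np.ones(np.shape(theta_deg), dtype=bool)
        rel = np.mod(np.asarray(theta_deg, dtype=float) - lo, 360.0)
        return rel <= span + 1e-9


@dataclass
class EyeRecipe:
    """Full parameterization of one synthetic eye."""

    corneal_radius: float = 7.8
    corneal_asphericity: float = -0.25
    limbus_radius: float = 5.95          # HVID ~ 11.9 mm
    scleral_radius: float = 11.5
    scleral_centre_offset: tuple[float, float] = (0.0, 0.0)
    #: list of (order, amplitude mm, phase deg): amp * cos(order*(theta-phase))
    asymmetry_harmonics: list[tuple[int, float, float]] = field(default_factory=list)
    harmonic_ramp_mm: float = 1.0        # harmonic ramp width beyond its onset
    tilt: tuple[float, float] = (0.0, 0.0)  # (alpha_x, alpha_y), degrees
    noise_sd: float = 0.005              # mm along z
    artefacts: list[ArtefactSpec] = field(default_factory=list)
    point_count: int = 40000
    max_radius: float = 10.0
    blend_width: float = 0.0             # C1 blend zone at the limbus, mm
    sampling: str = "random"             # "random" or "polar_grid"
    laterality: str = "OD"
    seed: int | None = None

    def __post_init__(self) -> None:
        if min(self.corneal_radius, self.limbus_radius, self.scleral_radius) <= 0:
            raise ConfigurationError("all radii must be positive")
        if self.limbus_radius >= self.scleral_radius:
            raise ConfigurationError("limbus_radius must be < scleral_radius")
        if self.point_count < 1000:
            raise ConfigurationError("point_count must be >= 1000")
        if self.seed is None:
            raise ConfigurationError("seed is mandatory (reproducibility)")
        if self.sampling not in ("random", "polar_grid"):
            raise ConfigurationError(f"unknown sampling {self.sampling!r}")
        for art in self.artefacts:
            if art.onset_radius <= self.limbus_radius:
                raise ConfigurationError(
                    "artefact onset_radius must lie beyond the limbus"
                )


@dataclass
class GroundTruth:
    """Planted parameters, queryable per meridian."""

    recipe: EyeRecipe
    limbus_radius: float
    tilt_deg: tuple[float, float]
    scleral_radius: float
    scleral_center: np.ndarray  # pre-tilt centre of the scleral sphere

    def artefact_onset(self, theta_deg: np.ndarray | float) -> np.ndarray:
        """Innermost artefact onset radius per meridian angle (nan if none)."""
        th = np.atleast_1d(np.asarray(theta_deg, dtype=float))
        onset = np.full(th.shape, np.inf)
        for art in self.recipe.artefacts:
            hit = art.covers(th)
            onset[hit] = np.minimum(onset[hit], art.onset_radius)
        onset[~np.isfinite(onset)] = np.nan
        return onset

    def asymmetry_diff(self, theta_deg: np.ndarray, r: float) -> np.ndarray:
        """Planted raw-elevation asymmetry diff(theta) = z(theta) - z(theta-180)."""
        th = np.asarray(theta_deg, dtype=float)
        ramp = _harmonic_ramp(
            np.full(th.shape, float(r)), self.recipe.limbus_radius,
            self.recipe.harmonic_ramp_mm,
        )
        total = np.zeros(th.shape)
        for order, amp, phase in self.recipe.asymmetry_harmonics:
            total += amp * ramp * (
                np.cos(np.deg2rad(order * (th - phase)))
                - np.cos(np.deg2rad(order * (th - 180.0 - phase)))
            )
        dx, dy = self.recipe.scleral_centre_offset
        if dx or dy:
            thr = np.deg2rad(th)
            zc = self.scleral_center[2]
            rs = self.recipe.scleral_radius

            def sphere_z(tt):
                x = r * np.cos(tt) - dx
                y = r * np.sin(tt) - dy
                return zc + np.sqrt(np.clip(rs**2 - x**2 - y**2, 0, None))

            total += sphere_z(thr) - sphere_z(thr - np.pi)
        return total


def _smoothstep(u: np.ndarray) -> np.ndarray:
    u = np.clip(u, 0.0, 1.0)
    return u * u * (3.0 - 2.0 * u)


def _smootherstep(u: np.ndarray) -> np.ndarray:
    """Quintic step with zero 1st and 2nd derivatives at both ends."""
    u = np.clip(u, 0.0, 1.0)
    return u**3 * (u * (6.0 * u - 15.0) + 10.0)


HARMONIC_RAMP_START_MM = 1.0  # ramp onset beyond the limbus


def _harmonic_ramp(r: np.ndarray, limbus_radius: float, width: float) -> np.ndarray:
    # the ramp starts beyond the limbus and uses smootherstep so the
    # planted asymmetry cannot perturb the junction curvature signature
    # the limbus detector relies on
    start = limbus_radius + HARMONIC_RAMP_START_MM
    if width <= 0:
        return (r > start).astype(float)
    return _smootherstep((r - start) / width)


def _conicoid_sag(r: np.ndarray, radius: float, q: float) -> np.ndarray:
    """Sag of a conicoid with apical radius ``radius`` and asphericity Q."""
    arg = 1.0 - (1.0 + q) * r**2 / radius**2
    if np.any(arg < 0):
        raise DataError("conicoid undefined at the requested radius")
    return r**2 / (radius * (1.0 + np.sqrt(arg)))


def surface_height(recipe: EyeRecipe, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Noise-free pre-tilt elevation z(x, y) of the recipe's surface."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    r = np.hypot(x, y)
    theta = np.degrees(np.arctan2(y, x))
    rl = recipe.limbus_radius
    rc, q, rs = recipe.corneal_radius, recipe.corneal_asphericity, recipe.scleral_radius

    if rs <= rl:
        raise DataError("no C0 junction possible: scleral radius <= limbus radius")
    z_limbus = -_conicoid_sag(np.asarray(rl), rc, q)
    zc = float(z_limbus) - np.sqrt(rs**2 - rl**2)  # scleral centre height (C0)

    z = np.empty_like(r)
    corneal = r <= rl
    z[corneal] = -_conicoid_sag(r[corneal], rc, q)

    dx, dy = recipe.scleral_centre_offset
    arg = rs**2 - (x - dx) ** 2 - (y - dy) ** 2
    if np.any(arg[~corneal] <= 0):
        raise DataError("scleral sphere does not cover the requested extent")
    z_scl = zc + np.sqrt(np.clip(arg, 0.0, None))
    z[~corneal] = z_scl[~corneal]

    if recipe.blend_width > 0:
        bw = recipe.blend_width
        zone = (~corneal) & (r <= rl + bw)
        if np.any(zone):
            # blend a corneal tangent extension into the sclera for C1-ish joins
            sag_l = _conicoid_sag(np.asarray(rl), rc, q)
            darg = 1.0 - (1.0 + q) * rl**2 / rc**2
            slope_l = -rl / (rc * np.sqrt(darg))
            ext = float(-sag_l) + slope_l * (r[zone] - rl)
            w = _smoothstep((r[zone] - rl) / bw)
            z[zone] = (1 - w) * ext + w * z_scl[zone]

    ramp = _harmonic_ramp(r, rl, recipe.harmonic_ramp_mm)
    for order, amp, phase in recipe.asymmetry_harmonics:
        z = z + amp * ramp * np.cos(np.deg2rad(order * (theta - phase)))

    for art in recipe.artefacts:
        hit = art.covers(theta)
        if not np.any(hit):
            continue
        rr = r[hit]
        if art.kind == "liftoff":
            delta = art.amplitude * np.clip((rr - art.onset_radius) / art.ramp_width, 0.0, 1.0)
        elif art.kind == "tearpool":
            delta = -abs(art.amplitude) * np.exp(-((rr - art.onset_radius) / art.ramp_width) ** 2)
        else:  # lash_spike
            delta = art.amplitude * np.exp(-((rr - art.onset_radius) / art.ramp_width) ** 2)
        z[hit] = z[hit] + delta
    return z


def _sample_xy(recipe: EyeRecipe, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    if recipe.sampling == "random":
        r = recipe.max_radius * np.sqrt(rng.uniform(0.0, 1.0, recipe.point_count))
        th = rng.uniform(-np.pi, np.pi, recipe.point_count)
        return r * np.cos(th), r * np.sin(th)
    # deterministic polar grid, rotationally symmetric under 180 degrees
    n_ang = 720
    n_rings = max(recipe.point_count // n_ang, 4)
    radii = np.linspace(0.0, recipe.max_radius, n_rings + 1)[1:]
    ang = np.deg2rad(np.arange(n_ang) * (360.0 / n_ang)) - np.pi
    rr, aa = np.meshgrid(radii, ang)
    x = np.concatenate([[0.0], (rr * np.cos(aa)).ravel()])
    y = np.concatenate([[0.0], (rr * np.sin(aa)).ravel()])
    return x, y


def generate_eye(recipe: EyeRecipe) -> tuple[SurfacePointCloud, GroundTruth]:
    """Sample one synthetic eye in the anatomical frame.

    Returns the point cloud (tilted, noisy) and the planted ground
    truth.  Identical recipes (same seed) produce identical clouds.
    """
    rng = np.random.default_rng(recipe.seed)
    x, y = _sample_xy(recipe, rng)
    z = surface_height(recipe, x, y)
    if recipe.noise_sd > 0:
        z = z + rng.normal(0.0, recipe.noise_sd, z.shape)
    pts = np.column_stack([x, y, z])

    ax, ay = np.deg2rad(recipe.tilt[0]), np.deg2rad(recipe.tilt[1])
    if ax or ay:
        rot = levelling.levelling_rotation(ax, ay)
        pts = pts @ rot  # rot.T.T == rot; applies the inverse of the level rotation

    rl = recipe.limbus_radius
    z_limbus = -_conicoid_sag(np.asarray(rl), recipe.corneal_radius,
                              recipe.corneal_asphericity)
    center = np.array([recipe.scleral_centre_offset[0],
                       recipe.scleral_centre_offset[1],
                       float(z_limbus) - np.sqrt(recipe.scleral_radius**2 - rl**2)])
    cloud = SurfacePointCloud(
        points=pts,
        laterality=recipe.laterality,
        source_id=f"synthetic-seed{recipe.seed}",
        frame="anatomical",
    )
    truth = GroundTruth(
        recipe=copy.deepcopy(recipe),
        limbus_radius=rl,
        tilt_deg=(recipe.tilt[0], recipe.tilt[1]),
        scleral_radius=recipe.scleral_radius,
        scleral_center=center,
    )
    return cloud, truth


def generate_cohort(
    n_eyes: int,
    base_recipe: EyeRecipe,
    jitter: dict[str, float] | None = None,
    seed: int | None = None,
) -> list[tuple[SurfacePointCloud, GroundTruth]]:
    """Draw a reproducible cohort of eyes around a base recipe.

    ``jitter`` maps recipe aspects to normal standard deviations:
    scalar fields (``corneal_radius``, ``limbus_radius``,
    ``scleral_radius``, ``noise_sd`` is never jittered), plus the
    specials ``tilt_deg`` (both tilt angles), ``harmonic_amplitude`` and
    ``harmonic_phase_deg`` (applied to every harmonic).  A zero/empty
    jitter yields n identical eyes up to their noise seeds — pass
    ``noise_sd=0`` in the base recipe for exactly identical eyes.
    """
    if n_eyes < 2:
        raise ConfigurationError("a cohort needs at least 2 eyes")
    jitter = dict(jitter or {})
    master_seed = base_recipe.seed if seed is None else seed
    rng = np.random.default_rng(master_seed)
    eye_seeds = rng.integers(0, 2**31 - 1, size=n_eyes)

    allowed_scalar = {"corneal_radius", "corneal_asphericity", "limbus_radius",
                      "scleral_radius"}
    special = {"tilt_deg", "harmonic_amplitude", "harmonic_phase_deg"}
    unknown = set(jitter) - allowed_scalar - special
    if unknown:
        raise ConfigurationError(f"unknown jitter key(s): {sorted(unknown)}")

    out = []
    for i in range(n_eyes):
        rec = copy.deepcopy(base_recipe)
        rec.seed = int(eye_seeds[i])
        for name in allowed_scalar & set(jitter):
            setattr(rec, name, float(getattr(rec, name) + rng.normal(0, jitter[name])))
        if "tilt_deg" in jitter:
            sd = jitter["tilt_deg"]
            rec.tilt = (rec.tilt[0] + float(rng.normal(0, sd)),
                        rec.tilt[1] + float(rng.normal(0, sd)))
        if rec.asymmetry_harmonics and ("harmonic_amplitude" in jitter
                                        or "harmonic_phase_deg" in jitter):
            new_h = []
            for order, amp, phase in rec.asymmetry_harmonics:
                if "harmonic_amplitude" in jitter:
                    amp = float(amp + rng.normal(0, jitter["harmonic_amplitude"]))
                if "harmonic_phase_deg" in jitter:
                    phase = float(phase + rng.normal(0, jitter["harmonic_phase_deg"]))
                new_h.append((order, amp, phase))
            rec.asymmetry_harmonics = new_h
        out.append(generate_eye(rec))
    return out
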