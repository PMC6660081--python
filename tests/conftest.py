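"""Shared fixtures: analytic surfaces and cached processed eyes."""

from __future__ import annotations

import numpy as np
import pytest

from scleratopo import synthetic_eye as syn
from scleratopo.surface_io import MeridianProfile, PolarSurface, SurfacePointCloud

HEMISPHERE_R = 11.5


def hemisphere_cloud(
    radius: float = HEMISPHERE_R,
    center: tuple[float, float, float] = (0.0, 0.0, -HEMISPHERE_R),
    n_points: int = 60000,
    max_r: float = 10.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    laterality: str = "OD",
    frame: str = "anatomical",
) -> SurfacePointCloud:
    """Points on the upper sheet of a sphere, uniform over the disk."""
    rng = np.random.default_rng(seed)
    r = max_r * np.sqrt(rng.uniform(0, 1, n_points))
    th = rng.uniform(-np.pi, np.pi, n_points)
    x = center[0] + r * np.cos(th)
    y = center[1] + r * np.sin(th)
    z = center[2] + np.sqrt(radius**2 - r**2)
    if noise_sd > 0:
        z = z + rng.normal(0, noise_sd, z.shape)
    return SurfacePointCloud(
        points=np.column_stack([x, y, z]),
        laterality=laterality,
        source_id="hemisphere",
        frame=frame,
    )


def hemisphere_polar(
    radius: float = HEMISPHERE_R,
    max_r: float = 10.0,
    radial_step: float = 0.05,
    angular_step: float = 1.0,
    apex_relative: bool = True,
) -> PolarSurface:
    """Exact polar-grid hemisphere surface (no sampling error)."""
    n_theta = int(round(360 / angular_step))
    angles = -180.0 + angular_step * np.arange(n_theta)
    r = radial_step * np.arange(int(np.floor(max_r / radial_step)) + 1)
    z_line = np.sqrt(radius**2 - r**2) - (radius if apex_relative else 0.0)
    z = np.tile(z_line, (n_theta, 1))
    valid = np.ones_like(z, dtype=bool)
    return PolarSurface(angles=angles, r=r, z=z, valid=valid,
                        angular_step=angular_step, radial_step=radial_step)


def two_arc_meridian(
    junction: float = 5.9,
    corneal_radius: float = 7.8,
    scleral_radius: float = 11.5,
    max_r: float = 10.0,
    step: float = 0.05,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
) -> MeridianProfile:
    """C0 join of two circular arcs with a curvature step at ``junction``."""
    r = step * np.arange(int(np.floor(max_r / step)) + 1)
    z_c = np.sqrt(corneal_radius**2 - np.minimum(r, corneal_radius - 1e-9) ** 2) \
        - corneal_radius
    z_j = np.sqrt(corneal_radius**2 - junction**2) - corneal_radius
    c_s = z_j - np.sqrt(scleral_radius**2 - junction**2)
    z_s = c_s + np.sqrt(scleral_radius**2 - r**2)
    z = np.where(r <= junction, z_c, z_s)
    if noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng(0)
        z = z + rng.normal(0, noise_sd, z.shape)
    return MeridianProfile(angle=0.0, r=r, z=z, valid=np.ones_like(r, dtype=bool))


@pytest.fixture(scope="session")
def default_eye():
    """One default synthetic eye (tilted, noisy) with its ground truth."""
    recipe = syn.EyeRecipe(seed=42, noise_sd=0.005, tilt=(3.0, -2.0))
    return syn.generate_eye(recipe)


@pytest.fixture(scope="session")
def processed_default_eye(default_eye):
    from scleratopo.pipeline import process_eye

    cloud, truth = default_eye
    return process_eye(cloud), truth


@pytest.fixture(scope="session")
def artefact_eye():
    """Synthetic eye with lid-like sector artefacts and its truth."""
    recipe = syn.EyeRecipe(
        seed=7,
        noise_sd=0.005,
        artefacts=[
            syn.ArtefactSpec(kind="tearpool", onset_radius=6.9, amplitude=0.35,
                             ramp_width=0.2, angular_extent=(-130.0, -50.0)),
            syn.ArtefactSpec(kind="liftoff", onset_radius=7.4, amplitude=1.0,
                             ramp_width=0.25, angular_extent=(50.0, 130.0)),
            syn.ArtefactSpec(kind="liftoff", onset_radius=8.0, amplitude=1.5,
                             ramp_width=0.25, angular_extent=(150.0, 210.0)),
        ],
    )
    return syn.generate_eye(recipe)
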