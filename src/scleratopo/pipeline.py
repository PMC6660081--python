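"""End-to-end per-eye processing used by the CLI and the test-bench.

Order follows the method: anatomical frame -> limbus detection and
levelling -> apex re-origin -> polar resampling -> edge-effect
elimination -> scleral sphere fit and relative elevation -> per-meridian
sampling for the asymmetry stage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import asymmetry as asym
from . import edge_elimination as edge
from . import levelling
from . import sphere_elevation as sphere
from . import surface_io as sio
from .config import PipelineConfig
from .errors import FitError


@dataclass
class EyeResult:
    """Everything the per-eye stage produces."""

    cloud: sio.SurfacePointCloud          # levelled, apex at origin, anatomical
    surface: sio.PolarSurface             # resampled, untrimmed
    trimmed: sio.PolarSurface
    limbus: levelling.LimbusFit
    edges: edge.EdgeProfile
    sphere_fit: sphere.SphereFit
    elevation: sphere.ElevationMap
    correlations: dict[str, float]
    raw_at_radius: np.ndarray             # per meridian, at config sampling radius
    relative_at_radius: np.ndarray
    diagnostics: dict


def process_eye(cloud: sio.SurfacePointCloud, config: PipelineConfig | None = None) -> EyeResult:
    """Run the full artefact-elimination pipeline on one eye."""
    if config is None:
        config = PipelineConfig()
    if cloud.frame == "instrument":
        cloud = sio.to_anatomical_frame(cloud)

    levelled, limbus_fit, diag = levelling.level_eye(
        cloud,
        angular_step=config.angular_step_deg,
        radial_step=config.radial_step_mm,
        search_window=tuple(config.limbus.search_window_mm),
        smooth_sigma_mm=config.limbus.smooth_sigma_mm,
        min_prominence=config.limbus.min_prominence,
    )

    surface = sio.resample_polar(
        levelled,
        angular_step=config.angular_step_deg,
        radial_step=config.radial_step_mm,
        center=(0.0, 0.0),
    )
    limbus = levelling.detect_limbus_surface(
        surface,
        search_window=tuple(config.limbus.search_window_mm),
        smooth_sigma_mm=config.limbus.smooth_sigma_mm,
        min_prominence=config.limbus.min_prominence,
    )

    window_cfg = edge.MovingWindowConfig(
        halfwidth=config.window.halfwidth_mm,
        max_elements=config.window.max_elements,
        statistic=config.window.statistic,
        threshold_factor=config.threshold.factor,
    )
    edges = edge.detect_edges(
        surface,
        limbus.r_limbus,
        config=window_cfg,
        search_offset=config.edge.search_offset_mm,
        baseline=config.threshold.baseline,
        min_prominence_mm=config.edge.min_prominence_um / 1000.0,
        ordering=config.edge.second_edge_ordering,
    )
    trimmed = edge.trim_surface(surface, edges)

    annulus = sphere.scleral_annulus_mask(
        trimmed, limbus.r_limbus, offset=config.sphere.annulus_offset_mm
    )
    pts = trimmed.nodes_xyz(annulus)
    if pts.shape[0] < 10:
        raise FitError("too few scleral nodes remain after trimming")
    fit = sphere.fit_sphere(pts, objective=config.sphere.objective)
    elevation = sphere.relative_elevation(trimmed, annulus, fit)
    correlations = sphere.correlate_with_reference(
        trimmed, annulus, reference_radius=config.reference_radius_mm
    )

    raw_at = asym.sample_at_radius(trimmed, config.sampling_radius_mm)
    rel_surface = sio.PolarSurface(
        angles=trimmed.angles,
        r=trimmed.r,
        z=np.where(elevation.defined, elevation.relative, np.nan),
        valid=elevation.defined,
        angular_step=trimmed.angular_step,
        radial_step=trimmed.radial_step,
    )
    rel_at = asym.sample_at_radius(rel_surface, config.sampling_radius_mm)

    return EyeResult(
        cloud=levelled,
        surface=surface,
        trimmed=trimmed,
        limbus=limbus,
        edges=edges,
        sphere_fit=fit,
        elevation=elevation,
        correlations=correlations,
        raw_at_radius=raw_at,
        relative_at_radius=rel_at,
        diagnostics=diag,
    )


def group_asymmetry(
    values_matrix: np.ndarray,
    meridian_angles: np.ndarray,
    basis: str = "raw",
    sampling_radius: float = 8.0,
    variant: str = "welch",
) -> asym.GroupAsymmetry:
    """Asymmetry profiles + group statistics from per-eye meridian values."""
    vm = np.asarray(values_matrix, dtype=float)
    profiles = [
        asym.asymmetry_profile(
            vm[i], meridian_angles, basis=basis, sampling="fixed_radius",
            sampling_radius=sampling_radius,
        )
        for i in range(vm.shape[0])
    ]
    return asym.aggregate_group(
        profiles, values_matrix=vm, meridian_angles=meridian_angles, variant=variant
    )
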