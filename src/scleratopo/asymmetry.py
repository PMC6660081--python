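"""Per-meridian scleral asymmetry profiles and group statistics.

The asymmetry at angle theta in [0, 180) is the value at meridian theta
minus the value at the opposite meridian theta - 180; group aggregation
is missing-aware and per-angle significance uses a two-sample t-test
(Welch by default) with the binary decision 1 iff p < 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import ConfigurationError, DataError
from .surface_io import PolarSurface

HALF_TURN = 180


@dataclass
class AsymmetryProfile:
    """Opposite-meridian differences for one eye."""

    angles: np.ndarray        # 0..179 degrees
    diff: np.ndarray          # mm; nan where either meridian is missing
    basis: str = "raw"        # "raw" or "relative"
    sampling: str = "fixed_radius"
    sampling_radius: float = float("nan")

    def __post_init__(self) -> None:
        if self.angles.size != HALF_TURN or self.diff.size != HALF_TURN:
            raise DataError("asymmetry profile must cover 180 one-degree angles")


@dataclass
class GroupAsymmetry:
    """Per-angle group statistics over eyes."""

    angles: np.ndarray
    mean_diff: np.ndarray
    sd_diff: np.ndarray
    n_eyes: np.ndarray
    t_statistic: np.ndarray
    p_value: np.ndarray
    decision: np.ndarray      # 1 iff p < 0.05
    p_bh: np.ndarray          # Benjamini-Hochberg adjusted (informational)
    argmax_angle: float       # signed label, nasal-referenced
    argmax_axis_angle: float  # canonical label in [0, 180)
    max_mean_diff: float      # |mean| at the argmax, mm
    sd_at_max: float
    basis: str = "raw"


def sample_at_radius(surface: PolarSurface, r: float) -> np.ndarray:
    """Per-meridian elevation at radius ``r`` by linear interpolation.

    Only the two bracketing valid radial nodes are used; a meridian
    whose valid (trimmed) range does not bracket ``r`` yields nan —
    values are never extrapolated beyond the cut.
    """
    out = np.full(surface.n_meridians, np.nan)
    for i in range(surface.n_meridians):
        valid = surface.valid[i]
        if valid.sum() < 2:
            continue
        rv = surface.r[valid]
        zv = surface.z[i, valid]
        j = np.searchsorted(rv, r)
        if j == 0:
            if np.isclose(rv[0], r):
                out[i] = zv[0]
            continue
        if j == rv.size:
            if np.isclose(rv[-1], r):
                out[i] = zv[-1]
            continue
        lo, hi = rv[j - 1], rv[j]
        if hi - lo > 10 * surface.radial_step:
            continue  # r falls inside an invalidated gap
        w = 0.0 if hi == lo else (r - lo) / (hi - lo)
        out[i] = (1 - w) * zv[j - 1] + w * zv[j]
    return out


def sample_annulus_mean(surface: PolarSurface, region: np.ndarray) -> np.ndarray:
    """Per-meridian mean elevation over a region mask (missing-aware)."""
    mask = region & surface.valid
    out = np.full(surface.n_meridians, np.nan)
    counts = mask.sum(axis=1)
    has = counts > 0
    sums = np.where(mask, surface.z, 0.0).sum(axis=1)
    out[has] = sums[has] / counts[has]
    return out


def asymmetry_profile(
    values: np.ndarray,
    angles: np.ndarray,
    basis: str = "raw",
    sampling: str = "fixed_radius",
    sampling_radius: float = float("nan"),
) -> AsymmetryProfile:
    """diff(theta) = v(theta) - v(theta - 180) for theta in 0..179.

    ``values`` holds one scalar per meridian, indexed by ``angles``
    (degrees in [-180, 180), one-degree steps); missing values (nan)
    propagate into the profile.
    """
    values = np.asarray(values, dtype=float)
    angles = np.asarray(angles, dtype=float)
    if values.shape != angles.shape or values.size != 2 * HALF_TURN:
        raise DataError("values must be indexed by all 360 one-degree meridians")
    lookup = {int(round(a)): v for a, v in zip(angles, values)}
    out_angles = np.arange(HALF_TURN, dtype=float)
    diff = np.full(HALF_TURN, np.nan)
    for theta in range(HALF_TURN):
        v_pos = lookup.get(theta, np.nan)
        v_neg = lookup.get(theta - HALF_TURN, np.nan)
        diff[theta] = v_pos - v_neg
    return AsymmetryProfile(
        angles=out_angles, diff=diff, basis=basis, sampling=sampling,
        sampling_radius=sampling_radius,
    )


def per_meridian_ttest(
    values_a: np.ndarray,
    values_b: np.ndarray,
    variant: str = "welch",
) -> tuple[float, float, int]:
    """Two-sample t-test between group values at opposite meridians.

    Returns ``(t, p, decision)`` with a two-sided p and decision = 1 iff
    p < 0.05.  Degenerate inputs (both groups constant and equal) give
    p = 1, decision 0; groups with fewer than two finite values raise.
    """
    if variant not in ("welch", "pooled"):
        raise ConfigurationError(f"unknown t-test variant {variant!r}")
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    if a.size < 2 or b.size < 2:
        raise DataError("t-test needs at least two finite values per group")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        if a[0] == b[0]:
            return 0.0, 1.0, 0
        return float("inf") * np.sign(a[0] - b[0]), 0.0, 1
    res = stats.ttest_ind(a, b, equal_var=(variant == "pooled"))
    t = float(res.statistic)
    p = float(res.pvalue)
    return t, p, int(p < 0.05)


def benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    """BH-adjusted p-values (nan-aware)."""
    p = np.asarray(p, dtype=float)
    adj = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    ps = p[ok]
    m = ps.size
    if m == 0:
        return adj
    order = np.argsort(ps, kind="mergesort")
    ranked = ps[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    vals = np.empty(m)
    vals[order] = np.clip(ranked, 0.0, 1.0)
    adj[ok] = vals
    return adj


def aggregate_group(
    profiles: list[AsymmetryProfile],
    values_matrix: np.ndarray | None = None,
    meridian_angles: np.ndarray | None = None,
    variant: str = "welch",
) -> GroupAsymmetry:
    """Aggregate per-eye asymmetry profiles into group statistics.

    ``values_matrix`` (n_eyes x 360, aligned with ``meridian_angles``)
    supplies the per-eye raw values at each meridian for the per-angle
    two-sample t-tests; without it the t columns are nan.  The reported
    ``argmax_angle`` follows the signed nasal-referenced convention: the
    axis label is placed on the side where the group mean is positive
    (e.g. an axis of 142 degrees with a negative mean is labelled -38).
    """
    if len(profiles) < 2:
        raise DataError("group aggregation needs at least 2 profiles")
    basis = profiles[0].basis
    sampling = profiles[0].sampling
    for pr in profiles[1:]:
        if pr.basis != basis or pr.sampling != sampling:
            raise ConfigurationError("profiles mix bases or sampling modes")
    diffs = np.vstack([pr.diff for pr in profiles])
    n_eyes = np.isfinite(diffs).sum(axis=0)
    import warnings as _warnings

    with np.errstate(invalid="ignore"), _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.where(n_eyes > 0, np.nanmean(diffs, axis=0), np.nan)
        sd = np.where(n_eyes > 1, np.nanstd(diffs, axis=0, ddof=1), np.nan)

    t_stat = np.full(HALF_TURN, np.nan)
    p_val = np.full(HALF_TURN, np.nan)
    decision = np.zeros(HALF_TURN, dtype=int)
    if values_matrix is not None:
        if meridian_angles is None:
            raise ConfigurationError("values_matrix requires meridian_angles")
        vm = np.asarray(values_matrix, dtype=float)
        col = {int(round(a)): j for j, a in enumerate(meridian_angles)}
        for theta in range(HALF_TURN):
            ja = col.get(theta)
            jb = col.get(theta - HALF_TURN)
            if ja is None or jb is None:
                continue
            a = vm[:, ja]
            b = vm[:, jb]
            if np.isfinite(a).sum() < 2 or np.isfinite(b).sum() < 2:
                continue
            t_stat[theta], p_val[theta], decision[theta] = per_meridian_ttest(
                a, b, variant=variant
            )
    p_bh = benjamini_hochberg(p_val)

    searchable = (n_eyes >= 2) & np.isfinite(mean)
    if not searchable.any():
        raise DataError("no angle has two or more contributing eyes")
    masked = np.where(searchable, np.abs(mean), -np.inf)
    imax = int(np.argmax(masked))
    axis_angle = float(imax)
    signed = axis_angle if mean[imax] > 0 else axis_angle - HALF_TURN
    return GroupAsymmetry(
        angles=np.arange(HALF_TURN, dtype=float),
        mean_diff=mean,
        sd_diff=sd,
        n_eyes=n_eyes,
        t_statistic=t_stat,
        p_value=p_val,
        decision=decision,
        p_bh=p_bh,
        argmax_angle=float(signed),
        argmax_axis_angle=axis_angle,
        max_mean_diff=float(abs(mean[imax])),
        sd_at_max=float(sd[imax]),
        basis=basis,
    )


def directional_summary(group: GroupAsymmetry) -> list[dict]:
    """Contiguous angle ranges sharing a t-test decision (convenience)."""
    runs = []
    current = None
    for theta in range(HALF_TURN):
        d = int(group.decision[theta])
        if current is None or d != current["decision"]:
            if current is not None:
                runs.append(current)
            current = {
                "start_deg": float(theta),
                "end_deg": float(theta),
                "decision": d,
                "p_max": float(group.p_value[theta])
                if np.isfinite(group.p_value[theta]) else float("nan"),
            }
        else:
            current["end_deg"] = float(theta)
            p = group.p_value[theta]
            if np.isfinite(p):
                pm = current["p_max"]
                current["p_max"] = p if not np.isfinite(pm) else max(pm, p)
    if current is not None:
        runs.append(current)
    return runs
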