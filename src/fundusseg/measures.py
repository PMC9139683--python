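"""Glaucoma-screening key measures from disc/cup mask pairs.

The scalar measures are the cup-to-disc ratio (CDR — ratio of vertical
diameters), the cup-to-disc area ratio (CDAR — ratio of pixel counts) and
the rim-to-disc area ratio (RDAR — rim pixels over disc pixels, with
rim = disc minus cup); their errors are absolute GT-vs-estimate
differences. Boundary accuracy is evaluated on 360-degree radius profiles:
for every integer degree the distance from the disc centroid to the
structure's boundary, with per-angle relative (ratio) errors normalised by
the ground-truth radius and their average over the full circle.

Angle convention: 0 degrees points horizontally right and angles increase
counter-clockwise when the image is viewed normally (row axis pointing
down); x = column, y = row.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "RadiusProfile", "KeyMeasures", "MeasureErrors",
    "centroid", "vertical_diameter", "radius_profile", "rim_profile",
    "key_measures", "measure_errors", "radius_ratio_errors",
    "average_radius_ratio_errors",
]


def _check_mask(mask: np.ndarray) -> np.ndarray:
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise ValueError("mask must be 2-D")
    mask = mask > 0
    if not mask.any():
        raise ValueError("empty mask")
    return mask


def centroid(mask: np.ndarray) -> tuple[float, float]:
    """Centroid (x_c, y_c) = mean foreground (column, row) coordinates."""
    mask = _check_mask(mask)
    rows, cols = np.nonzero(mask)
    return (float(cols.mean()), float(rows.mean()))


def vertical_diameter(mask: np.ndarray) -> int:
    """Vertical extent in pixels: (max foreground row - min foreground row) + 1."""
    mask = _check_mask(mask)
    rows = np.nonzero(mask.any(axis=1))[0]
    return int(rows[-1] - rows[0] + 1)


def boundary_pixels(mask: np.ndarray) -> np.ndarray:
    """Foreground pixels with at least one background 4-neighbour (or on the edge)."""
    mask = _check_mask(mask)
    eroded = ndimage.binary_erosion(mask, structure=np.array(
        [[0, 1, 0], [1, 1, 1], [0, 1, 0]], bool), border_value=0)
    return mask & ~eroded


@dataclass
class RadiusProfile:
    """Per-degree boundary radii measured from a fixed centre."""

    center: tuple[float, float]          # (x_c, y_c)
    angles: np.ndarray                   # integer degrees, 0..n-1
    radii: np.ndarray                    # pixels, one per degree
    boundary_points: np.ndarray          # (n, 2) of (x, y); interpolated where needed
    interpolated: np.ndarray = field(default=None)  # bool per angle
    clamped: np.ndarray = field(default=None)       # set by rim_profile

    def __post_init__(self):
        if self.interpolated is None:
            self.interpolated = np.zeros(len(self.angles), bool)
        if self.clamped is None:
            self.clamped = np.zeros(len(self.angles), bool)

    def __len__(self) -> int:
        return len(self.angles)


def radius_profile(mask: np.ndarray, center: tuple[float, float] | None = None,
                   n_angles: int = 360) -> RadiusProfile:
    """Radius of a mask's boundary at every degree around ``center``.

    For each angle bin [m - 0.5, m + 0.5) degrees the radius is the distance
    to the *farthest* boundary pixel in the bin; bins containing no boundary
    pixel are filled by circular linear interpolation over angle.
    """
    mask = _check_mask(mask)
    if center is None:
        center = centroid(mask)
    xc, yc = center
    rows, cols = np.nonzero(boundary_pixels(mask))
    dx = cols - xc
    dy = yc - rows  # y grows downward; flip so angles run counter-clockwise
    ang = np.degrees(np.arctan2(dy, dx)) % 360.0
    dist = np.hypot(dx, dy)
    step = 360.0 / n_angles
    bins = np.floor(ang / step + 0.5).astype(int) % n_angles

    radii = np.full(n_angles, -1.0)
    bx = np.zeros(n_angles)
    by = np.zeros(n_angles)
    order = np.argsort(dist)  # ascending, so the farthest per bin wins
    radii[bins[order]] = dist[order]
    bx[bins[order]] = cols[order]
    by[bins[order]] = rows[order]

    missing = radii < 0
    if missing.all():
        raise ValueError("no boundary pixels found in any angular bin")
    if missing.any():
        # circular linear interpolation on the angle grid
        good = np.nonzero(~missing)[0]
        grid = np.arange(n_angles)
        radii[missing] = np.interp(grid[missing], good, radii[good],
                                   period=n_angles)
        theta = np.radians(grid[missing] * step)
        bx[missing] = xc + radii[missing] * np.cos(theta)
        by[missing] = yc - radii[missing] * np.sin(theta)

    return RadiusProfile(
        center=(float(xc), float(yc)),
        angles=np.arange(n_angles),
        radii=radii,
        boundary_points=np.stack([bx, by], axis=1),
        interpolated=missing,
    )


def rim_profile(disc: RadiusProfile, cup: RadiusProfile) -> RadiusProfile:
    """Neuroretinal rim thickness per degree: disc radius minus cup radius.

    Both profiles must share the disc centroid and angle grid. Angles where
    the cup radius exceeds the disc radius yield 0 with the ``clamped``
    flag set (rather than a negative thickness).
    """
    if len(disc) != len(cup) or not np.array_equal(disc.angles, cup.angles):
        raise ValueError("profiles are on different angle grids")
    if not np.allclose(disc.center, cup.center, atol=1e-6):
        raise ValueError("profiles must share the same centre (the disc centroid)")
    diff = disc.radii - cup.radii
    clamped = diff < 0
    return RadiusProfile(
        center=disc.center,
        angles=disc.angles.copy(),
        radii=np.where(clamped, 0.0, diff),
        boundary_points=disc.boundary_points.copy(),
        interpolated=disc.interpolated | cup.interpolated,
        clamped=clamped,
    )


@dataclass
class KeyMeasures:
    """Scalar screening measures for one disc/cup mask pair."""

    cdr: float
    cdar: float
    rdar: float
    vertical_disc_diameter: int
    vertical_cup_diameter: int
    disc_area: int
    cup_area: int
    rim_area: int


def key_measures(disc_mask: np.ndarray, cup_mask: np.ndarray | None) -> KeyMeasures:
    """CDR, CDAR and RDAR from a disc mask and a (possibly empty) cup mask.

    An empty cup is a valid degenerate case: CDR = CDAR = 0 and RDAR = 1.
    """
    disc = _check_mask(disc_mask)
    disc_area = int(disc.sum())
    vdd = vertical_diameter(disc)
    cup = None if cup_mask is None else np.asarray(cup_mask) > 0
    if cup is None or not cup.any():
        return KeyMeasures(cdr=0.0, cdar=0.0, rdar=1.0,
                           vertical_disc_diameter=vdd, vertical_cup_diameter=0,
                           disc_area=disc_area, cup_area=0, rim_area=disc_area)
    vdc = vertical_diameter(cup)
    cup_area = int(cup.sum())
    rim_area = int((disc & ~cup).sum())
    return KeyMeasures(
        cdr=vdc / vdd,
        cdar=cup_area / disc_area,
        rdar=rim_area / disc_area,
        vertical_disc_diameter=vdd,
        vertical_cup_diameter=vdc,
        disc_area=disc_area,
        cup_area=cup_area,
        rim_area=rim_area,
    )


@dataclass
class MeasureErrors:
    """Absolute errors of the scalar measures for one image."""

    cdre: float
    cdare: float
    rdare: float
    index: int = 0


def measure_errors(gt: KeyMeasures, est: KeyMeasures, index: int = 0) -> MeasureErrors:
    """|GT - estimate| for CDR, CDAR and RDAR."""
    return MeasureErrors(
        cdre=abs(gt.cdr - est.cdr),
        cdare=abs(gt.cdar - est.cdar),
        rdare=abs(gt.rdar - est.rdar),
        index=index,
    )


def radius_ratio_errors(gt: RadiusProfile, est: RadiusProfile):
    """Per-angle relative radius error |GT - est| / GT.

    Angles where the GT radius is 0 cannot be normalised; they are excluded
    (masked out) and their count is returned alongside the series.

    Returns
    -------
    errors : np.ndarray
        Per-angle series with NaN at excluded angles.
    n_excluded : int
    """
    if len(gt) != len(est) or not np.array_equal(gt.angles, est.angles):
        raise ValueError("profiles are on different angle grids")
    gt_r = gt.radii
    if np.all(gt_r == 0):
        raise ValueError("all ground-truth radii are zero")
    errors = np.full(len(gt), np.nan)
    valid = gt_r > 0
    errors[valid] = np.abs(gt_r[valid] - est.radii[valid]) / gt_r[valid]
    return errors, int((~valid).sum())


def average_radius_ratio_errors(series: np.ndarray) -> float:
    """Mean of a per-angle ratio-error series, ignoring excluded (NaN) angles."""
    series = np.asarray(series, dtype=float)
    if series.size == 0:
        raise ValueError("empty error series")
    valid = ~np.isnan(series)
    if not valid.any():
        raise ValueError("no valid angles in error series")
    return float(series[valid].mean())
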