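"""Per-image morphometrics.

Given a closed boundary polygon, computes the focal-plane area S, actual
perimeter P_o, equivalent perimeter P_e = 2*sqrt(pi*S) (the perimeter of
the circle with the same area), the excess perimeter index
EPI = (P_o - P_e)/P_e, the equivalent-circle diameter d = 2*sqrt(S/pi),
the boundary roughness (coefficient of variation of centroid-to-vertex
radii), and the spherical volume V = (4/3)*pi*(d/2)^3.

EPI is 0 for a circle and grows with boundary complexity; by the
isoperimetric inequality it is >= 0 for any exact simple polygon, with a
small negative tolerance (about -0.02) allowed for raster-derived
contours whose smoothing slightly shortens the perimeter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np

from .boundary import (
    Contour,
    SegmentationSettings,
    SpheroidImage,
    extract_contour,
    segment_spheroid,
)
from .errors import InvalidArgumentError

__all__ = [
    "MorphometricRecord",
    "polygon_area",
    "polygon_perimeter",
    "equivalent_perimeter",
    "excess_perimeter_index",
    "equivalent_diameter",
    "roughness",
    "spheroid_volume",
    "contour_metrics",
    "measure_image",
]


@dataclass(frozen=True)
class MorphometricRecord:
    """All shape measurements for one (well, day) image."""

    well_id: str
    day: int
    S: float          # area at focal plane, um^2
    P_o: float        # actual perimeter, um
    P_e: float        # equivalent perimeter, um
    EPI: float
    roughness: float
    d: float          # equivalent diameter, um
    V: float          # spherical volume, um^3

    def to_dict(self) -> dict:
        return asdict(self)


def _vertices(contour: Contour | np.ndarray, min_vertices: int = 3) -> np.ndarray:
    if isinstance(contour, Contour):
        v = contour.vertices
    else:
        v = np.asarray(contour, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2:
            raise InvalidArgumentError("contour must be an (N, 2) array")
        if v.shape[0] > 1 and np.allclose(v[0], v[-1]):
            v = v[:-1]
    if v.shape[0] < min_vertices:
        raise InvalidArgumentError(
            f"degenerate contour: {v.shape[0]} < {min_vertices} vertices")
    return v


def polygon_area(contour: Contour | np.ndarray,
                 pixel_size_um: float = 1.0) -> float:
    """Shoelace area of the closed polygon, in um^2.

    Clockwise input is equivalent to counter-clockwise: the absolute
    value is returned.
    """
    v = _vertices(contour)
    x, y = v[:, 0], v[:, 1]
    area_px = 0.5 * abs(float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)))
    if area_px == 0.0:
        raise InvalidArgumentError("contour encloses zero area")
    return area_px * pixel_size_um ** 2


def polygon_perimeter(contour: Contour | np.ndarray,
                      pixel_size_um: float = 1.0) -> float:
    """Perimeter P_o: sum of edge lengths including the closure edge, um."""
    v = _vertices(contour)
    d = np.diff(np.vstack([v, v[:1]]), axis=0)
    return float(np.hypot(d[:, 0], d[:, 1]).sum()) * pixel_size_um


def equivalent_perimeter(S: float) -> float:
    """P_e = 2*sqrt(pi*S), the perimeter of the equal-area circle."""
    if not math.isfinite(S) or S <= 0:
        raise InvalidArgumentError(f"area must be > 0, got {S}")
    return 2.0 * math.sqrt(math.pi * S)


def excess_perimeter_index(P_o: float, P_e: float) -> float:
    """EPI = (P_o - P_e) / P_e. Dimensionless and scale-invariant."""
    if not math.isfinite(P_o) or P_o <= 0:
        raise InvalidArgumentError(f"P_o must be > 0, got {P_o}")
    if not math.isfinite(P_e) or P_e <= 0:
        raise InvalidArgumentError(f"P_e must be > 0, got {P_e}")
    return (P_o - P_e) / P_e


def equivalent_diameter(S: float) -> float:
    """d = 2*sqrt(S/pi), diameter of the equal-area circle, um."""
    if not math.isfinite(S) or S <= 0:
        raise InvalidArgumentError(f"area must be > 0, got {S}")
    return 2.0 * math.sqrt(S / math.pi)


def roughness(contour: Contour | np.ndarray) -> float:
    """Coefficient of variation of centroid-to-vertex radii.

    Scale-invariant, zero for a perfect circle, increasing with radial
    protrusions. The centroid is the polygon (area) centroid, not the
    vertex mean, so dense vertex runs do not bias it.
    """
    v = _vertices(contour, min_vertices=16)
    x, y = v[:, 0], v[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    cross = x * yn - xn * y
    a = 0.5 * float(cross.sum())
    if a == 0.0:
        raise InvalidArgumentError("contour encloses zero area")
    cx = float(((x + xn) * cross).sum()) / (6.0 * a)
    cy = float(((y + yn) * cross).sum()) / (6.0 * a)
    r = np.hypot(x - cx, y - cy)
    mu = float(r.mean())
    if mu == 0.0:
        raise InvalidArgumentError("degenerate contour: zero mean radius")
    return float(r.std()) / mu


def spheroid_volume(d: float) -> float:
    """V = (4/3)*pi*(d/2)^3, the equal-diameter sphere volume, um^3."""
    if not math.isfinite(d) or d <= 0:
        raise InvalidArgumentError(f"diameter must be > 0, got {d}")
    return (4.0 / 3.0) * math.pi * (d / 2.0) ** 3


def contour_metrics(contour: Contour | np.ndarray, pixel_size_um: float,
                    well_id: str = "", day: int = 0) -> MorphometricRecord:
    """All morphometrics of one boundary polygon."""
    S = polygon_area(contour, pixel_size_um)
    P_o = polygon_perimeter(contour, pixel_size_um)
    P_e = equivalent_perimeter(S)
    d = equivalent_diameter(S)
    return MorphometricRecord(
        well_id=well_id,
        day=day,
        S=S,
        P_o=P_o,
        P_e=P_e,
        EPI=excess_perimeter_index(P_o, P_e),
        roughness=roughness(contour),
        d=d,
        V=spheroid_volume(d),
    )


def measure_image(image: SpheroidImage,
                  settings: SegmentationSettings = SegmentationSettings(),
                  area_mode: str = "contour") -> MorphometricRecord:
    """Segment, contour, and measure one image.

    ``area_mode`` selects the area estimator: ``"contour"`` (shoelace
    integral of the sub-pixel boundary, default) or ``"pixel_count"``
    (mask pixels times pixel area). Segmentation and contour failures
    propagate as package exceptions carrying well/day context.
    """
    if area_mode not in ("contour", "pixel_count"):
        raise InvalidArgumentError(f"unknown area_mode {area_mode!r}")
    mask = segment_spheroid(image, settings)
    contour = extract_contour(mask, image, smooth_px=settings.mask_smooth_px)
    rec = contour_metrics(contour, image.pixel_size_um,
                          well_id=image.well_id, day=image.day)
    if area_mode == "pixel_count":
        S = mask.area_px * image.pixel_size_um ** 2
        d = equivalent_diameter(S)
        rec = MorphometricRecord(
            well_id=rec.well_id, day=rec.day, S=S, P_o=rec.P_o,
            P_e=equivalent_perimeter(S),
            EPI=excess_perimeter_index(rec.P_o, equivalent_perimeter(S)),
            roughness=rec.roughness, d=d, V=spheroid_volume(d))
    return rec
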