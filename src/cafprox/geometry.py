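"""Tumor–bone interface geometry.

The invasive front is modelled as three stacked compartments in image
coordinates (origin top-left, y downward, units μm):

* a tumor zone at the top containing one or more tumor-nest polygons,
* a laminar stromal band of prescribed mean thickness,
* the bone region below the interface polyline.

The interface polyline is the shared boundary between the stromal band and
the bone region; osteoclasts sit on it and surface ROIs are anchored to it.
Waviness is a mean-zero sum of sinusoids, so the band area stays
``frame_width × band_thickness`` up to discretization.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import cached_property

import numpy as np
import shapely
from shapely.geometry import LineString, Point, Polygon, box

from .errors import ConfigError, GeometryError

__all__ = ["TissueGeometry", "make_interface", "make_flat_geometry"]


@dataclass
class TissueGeometry:
    """Region geometry of one invasive-front field, all lengths in μm."""

    interface: LineString
    stromal_band: Polygon
    tumor_nests: list[Polygon]
    bone_region: Polygon
    frame_width: float
    frame_height: float

    @cached_property
    def tissue_region(self):
        """Stromal band ∪ tumor nests — where stromal cells may live."""
        return shapely.union_all([self.stromal_band, *self.tumor_nests])

    @cached_property
    def band_thickness_mean(self) -> float:
        return self.stromal_band.area / self.frame_width

    def validate(self, tol: float = 1e-6) -> None:
        """Check the structural invariants; raise GeometryError on failure."""
        frame = box(-tol, -tol, self.frame_width + tol, self.frame_height + tol)
        for name, poly in [
            ("stromal_band", self.stromal_band),
            ("bone_region", self.bone_region),
            *[(f"tumor_nest[{i}]", p) for i, p in enumerate(self.tumor_nests)],
        ]:
            if not poly.is_valid:
                raise GeometryError(f"{name} polygon is invalid (self-intersecting?)")
            if not frame.contains(poly):
                raise GeometryError(f"{name} extends outside the frame")
        if self.stromal_band.intersection(self.bone_region).area > tol:
            raise GeometryError("stromal band overlaps bone region interior")
        for i, nest in enumerate(self.tumor_nests):
            if nest.intersection(self.bone_region).area > tol:
                raise GeometryError(f"tumor_nest[{i}] overlaps bone region")
        # interface must lie on the band/bone shared boundary
        band_b = self.stromal_band.boundary
        bone_b = self.bone_region.boundary
        for x, y in self.interface.coords:
            p = Point(x, y)
            if p.distance(band_b) > 1e-6 or p.distance(bone_b) > 1e-6:
                raise GeometryError(
                    "interface polyline does not lie on the band/bone boundary"
                )


def _interface_profile(
    x: np.ndarray,
    y0: float,
    frame_width: float,
    waviness_amplitude: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Mean-zero wavy interface depth profile with peak ≤ amplitude."""
    if waviness_amplitude == 0:
        return np.full_like(x, y0)
    ph1, ph2 = rng.uniform(0, 2 * np.pi, size=2)
    w = 2 * np.pi / frame_width
    wav = 0.6 * np.sin(2 * w * x + ph1) + 0.4 * np.sin(5 * w * x + ph2)
    return y0 + waviness_amplitude * wav


def make_interface(
    frame_width: float,
    band_thickness: float,
    waviness_amplitude: float,
    seed: int,
    *,
    tumor_zone_height: float = 300.0,
    bone_depth: float = 150.0,
    n_nests: int | None = None,
    nest_radius: float | None = None,
    dx: float = 10.0,
) -> TissueGeometry:
    """Construct a laminar tumor/stroma/bone geometry.

    The stromal band runs from ``y = tumor_zone_height`` down to the
    (possibly wavy) interface at mean depth ``tumor_zone_height +
    band_thickness``; the bone region fills the rest of the frame. Tumor
    nests are disc polygons placed just above the band, jittered by seed.
    """
    if frame_width <= 0 or band_thickness <= 0:
        raise ConfigError("frame_width and band_thickness must be positive")
    if waviness_amplitude < 0:
        raise ConfigError("waviness_amplitude must be >= 0")
    if tumor_zone_height <= 0 or bone_depth <= 0:
        raise ConfigError("tumor_zone_height and bone_depth must be positive")
    if waviness_amplitude >= min(band_thickness, bone_depth):
        raise ConfigError(
            "waviness_amplitude must be smaller than band_thickness and bone_depth"
        )
    rng = np.random.default_rng(seed)
    frame_height = tumor_zone_height + band_thickness + bone_depth
    y_top = tumor_zone_height
    y0 = tumor_zone_height + band_thickness

    n_pts = max(2, int(round(frame_width / dx)) + 1)
    xs = np.linspace(0.0, frame_width, n_pts)
    ys = _interface_profile(xs, y0, frame_width, waviness_amplitude, rng)
    iface_coords = list(zip(xs.tolist(), ys.tolist()))
    interface = LineString(iface_coords)

    band = Polygon(
        [(0.0, y_top), (frame_width, y_top)] + iface_coords[::-1]
    )
    bone = Polygon(
        iface_coords + [(frame_width, frame_height), (0.0, frame_height)]
    )

    if n_nests is None:
        n_nests = max(1, int(round(frame_width / 650.0)))
    if nest_radius is None:
        nest_radius = min(120.0, (tumor_zone_height - 10.0) / 2.0 - 1.0,
                          frame_width / (2.0 * n_nests) - 5.0)
    if nest_radius <= 0:
        raise ConfigError("frame too small for any tumor nest")
    nests = []
    pitch = frame_width / n_nests
    for i in range(n_nests):
        cx = (i + 0.5) * pitch + rng.uniform(-0.04, 0.04) * pitch
        cy = y_top - nest_radius - 10.0
        nests.append(Point(cx, cy).buffer(nest_radius, quad_segs=16))

    geom = TissueGeometry(
        interface=interface,
        stromal_band=band,
        tumor_nests=nests,
        bone_region=bone,
        frame_width=frame_width,
        frame_height=frame_height,
    )
    geom.validate()
    return geom


def make_flat_geometry(
    frame_width: float,
    band_thickness: float,
    *,
    tumor_zone_height: float = 300.0,
    bone_depth: float = 150.0,
    nest_inset: float = 50.0,
) -> TissueGeometry:
    """Flat-interface geometry with a single rectangular tumor nest.

    Useful for protocols that need a large, simple tumor compartment (e.g.
    sparse reference layouts) rather than the disc nests of
    :func:`make_interface`.
    """
    if frame_width <= 0 or band_thickness <= 0:
        raise ConfigError("frame_width and band_thickness must be positive")
    if tumor_zone_height <= 2 * nest_inset:
        raise ConfigError("tumor zone too small for the nest inset")
    frame_height = tumor_zone_height + band_thickness + bone_depth
    y_top = tumor_zone_height
    y0 = tumor_zone_height + band_thickness
    interface = LineString([(0.0, y0), (frame_width, y0)])
    band = box(0.0, y_top, frame_width, y0)
    bone = box(0.0, y0, frame_width, frame_height)
    nest = box(nest_inset, nest_inset, frame_width - nest_inset, y_top - 10.0)
    geom = TissueGeometry(
        interface=interface,
        stromal_band=band,
        tumor_nests=[nest],
        bone_region=bone,
        frame_width=frame_width,
        frame_height=frame_height,
    )
    geom.validate()
    return geom


def polygon_area_shoelace(coords) -> float:
    """Shoelace-formula polygon area; independent of shapely, for checks."""
    pts = np.asarray(coords, dtype=float)
    if np.allclose(pts[0], pts[-1]):
        pts = pts[:-1]
    x, y = pts[:, 0], pts[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))
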