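"""Nucleus geometry fitting and per-signal positional parameters.

The measurement convention follows the classic interphase-topology
analysis: a lymphocyte nucleus is modeled as a circle of equivalent-area
radius ``R = sqrt(Sn / pi)``; an adherent-cell (e.g. MSC) nucleus as the
moment-equivalent ellipse of its mask (semi-axes ``a >= b``, orientation
``theta``).  A signal's position is expressed as the normalized radius
vector

    circle :  r = |p - center| / R
    ellipse:  r = sqrt((x'/a)**2 + (y'/b)**2)

with ``(x', y')`` the signal coordinates after rotating by ``-theta``
about the nucleus center (the affine conversion that maps the ellipse to
the unit circle).  ``r`` runs from 0 at the nucleus center to 1 on the
boundary and is deliberately *not* clamped: on rasterized masks a signal
centroid can fall slightly outside the fitted boundary, and those values
are preserved and flagged.

Coordinates are image coordinates: x rightward, y downward, pixel
centers at integers.  Angles (``theta``, sector angles, the inter-signal
angle ``alpha``) are measured in this frame.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "NucleusGeometry",
    "SignalFeature",
    "NucleusRecord",
    "fit_geometry",
    "normalized_radius",
    "pair_metrics",
    "nucleolus_surface_distance",
    "sector_density",
    "build_record",
]


@dataclass(frozen=True)
class NucleusGeometry:
    """Fitted circle or ellipse model of one nucleus."""

    kind: str  # "circle" | "ellipse"
    center: tuple[float, float]  # (cx, cy) px
    R: float  # equivalent radius, px (circle; sqrt(a*b) for ellipse)
    a: float  # major semi-axis, px
    b: float  # minor semi-axis, px
    theta_deg: float  # major-axis orientation, [0, 180)
    Sn: float  # nucleus area, px

    def __post_init__(self) -> None:
        if self.kind not in ("circle", "ellipse"):
            raise ValueError(f"unknown geometry kind {self.kind!r}")
        if not (self.R > 0 and self.a > 0 and self.b > 0 and self.Sn > 0):
            raise ValueError("geometry radii and area must be positive")
        if self.a < self.b - 1e-9:
            raise ValueError("ellipse must satisfy a >= b")

    @property
    def axis_ratio(self) -> float:
        return self.a / self.b

    @property
    def norm_radius(self) -> float:
        """Length scale used to normalize distances: R for circles,
        geometric-mean radius sqrt(a*b) for ellipses."""
        return self.R if self.kind == "circle" else math.sqrt(self.a * self.b)

    @classmethod
    def circle(cls, center, R: float) -> "NucleusGeometry":
        return cls("circle", tuple(map(float, center)), float(R), float(R), float(R), 0.0,
                   math.pi * R * R)

    @classmethod
    def ellipse(cls, center, a: float, b: float, theta_deg: float) -> "NucleusGeometry":
        return cls("ellipse", tuple(map(float, center)), math.sqrt(a * b), float(a), float(b),
                   float(theta_deg) % 180.0, math.pi * a * b)


@dataclass
class SignalFeature:
    """One measured signal in one nucleus."""

    channel: str  # "fish" | "agnor"
    label: int
    centroid: tuple[float, float]
    area_px: float
    r: float
    S_norm: float
    outside_boundary: bool = False  # r > 1 on the fitted geometry


@dataclass
class NucleusRecord:
    """Per-nucleus aggregate of geometry and signal features."""

    nucleus_id: str
    geometry: NucleusGeometry
    fish: list[SignalFeature] = field(default_factory=list)
    agnor: list[SignalFeature] = field(default_factory=list)
    d_norm: float | None = None
    alpha_deg: float | None = None
    alpha_undefined: bool = False
    n_fish_flag: bool = False  # != 2 FISH blobs survived filtering
    border_flag: bool = False  # nucleus mask touches the image border
    nucleolus_dist_px: list[float] = field(default_factory=list)
    nucleolus_dist_norm: list[float] = field(default_factory=list)

    @property
    def axis_ratio(self) -> float:
        return self.geometry.axis_ratio

    @property
    def agnor_count(self) -> int:
        return len(self.agnor)

    @property
    def S_agnor_total(self) -> float:
        return float(sum(s.S_norm for s in self.agnor))


def fit_geometry(mask: np.ndarray, kind: str = "circle") -> NucleusGeometry:
    """Fit a circle or moment-equivalent ellipse to a binary mask.

    Circle: center = mask centroid, R = sqrt(area / pi).  Ellipse:
    semi-axes and orientation from the second central moments of the
    mask pixels (a filled ellipse has variance a**2/4 along its major
    axis), with a >= b enforced.
    """
    mask = np.asarray(mask, dtype=bool)
    ys, xs = np.nonzero(mask)
    if xs.size == 0:
        raise ValueError("empty mask")
    sn = float(xs.size)
    cx, cy = float(xs.mean()), float(ys.mean())
    if kind == "circle":
        return NucleusGeometry.circle((cx, cy), math.sqrt(sn / math.pi))
    if kind != "ellipse":
        raise ValueError(f"unknown geometry kind {kind!r}")
    dx = xs - cx
    dy = ys - cy
    raw20 = float(np.mean(dx * dx))
    raw02 = float(np.mean(dy * dy))
    mu11 = float(np.mean(dx * dy))
    raw_det = raw20 * raw02 - mu11 * mu11
    if raw_det <= 1e-9:
        raise ValueError("degenerate mask: collinear pixels")
    # + 1/12: variance of the uniform unit-pixel footprint, so rasterized
    # axes are unbiased.
    mu20 = raw20 + 1.0 / 12.0
    mu02 = raw02 + 1.0 / 12.0
    tr, det = mu20 + mu02, mu20 * mu02 - mu11 * mu11
    disc = max(tr * tr / 4.0 - det, 0.0)
    l1 = tr / 2.0 + math.sqrt(disc)
    l2 = tr / 2.0 - math.sqrt(disc)
    a, b = 2.0 * math.sqrt(l1), 2.0 * math.sqrt(l2)
    theta = 0.5 * math.degrees(math.atan2(2.0 * mu11, mu20 - mu02)) % 180.0
    # Sn is the measured pixel area, not pi*a*b of the moment ellipse.
    return NucleusGeometry("ellipse", (cx, cy), math.sqrt(a * b), a, b, theta, sn)


def normalized_radius(geom: NucleusGeometry, point) -> float:
    """Normalized radius vector of ``point`` (0 center, 1 boundary).

    Not clamped: values slightly above 1 are returned as-is.
    """
    px, py = float(point[0]), float(point[1])
    dx, dy = px - geom.center[0], py - geom.center[1]
    if geom.kind == "circle":
        return math.hypot(dx, dy) / geom.R
    t = math.radians(geom.theta_deg)
    xr = dx * math.cos(t) + dy * math.sin(t)
    yr = -dx * math.sin(t) + dy * math.cos(t)
    return math.hypot(xr / geom.a, yr / geom.b)


def pair_metrics(geom: NucleusGeometry, c1, c2) -> tuple[float, float | None]:
    """Normalized inter-signal distance and central angle for the two
    homolog signals.

    d_norm = |c1 - c2| / R (circle) or / sqrt(a*b) (ellipse).
    alpha_deg = angle at the nucleus center between the two centroid
    radius vectors, degrees in [0, 180]; None (undefined) if either
    centroid coincides with the center.
    """
    c1 = np.asarray(c1, dtype=float)
    c2 = np.asarray(c2, dtype=float)
    center = np.asarray(geom.center)
    d_norm = float(np.linalg.norm(c1 - c2)) / geom.norm_radius
    v1, v2 = c1 - center, c2 - center
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 == 0 or n2 == 0:
        return d_norm, None
    cosang = float(np.dot(v1, v2) / (n1 * n2))
    return d_norm, math.degrees(math.acos(max(-1.0, min(1.0, cosang))))


def nucleolus_surface_distance(
    point,
    nucleolus_boundaries: list[np.ndarray],
    nucleolus_pixel_sets: list[set[tuple[int, int]]] | None = None,
    norm_radius: float | None = None,
) -> tuple[float, float | None]:
    """Minimum distance from a signal centroid to the nearest nucleolus
    boundary pixel; 0 if the centroid lies inside a nucleolus.

    ``nucleolus_boundaries`` is a list of (k, 2) arrays of (x, y)
    boundary pixel coordinates, one per nucleolus.  Returns (distance_px,
    distance_norm); the normalized value is None when ``norm_radius`` is
    not given.  Raises if no nucleolus is supplied.
    """
    if not nucleolus_boundaries:
        raise ValueError("no nucleolus blobs supplied")
    px, py = float(point[0]), float(point[1])
    if nucleolus_pixel_sets is not None:
        key = (int(round(px)), int(round(py)))
        if any(key in s for s in nucleolus_pixel_sets):
            return 0.0, 0.0 if norm_radius else None
    else:
        # Only boundary pixels available (file-based contract): treat the
        # centroid as inside if it falls within the boundary's convex
        # hull (nucleolar blobs are convex to pixel accuracy).
        from scipy.spatial import Delaunay, QhullError

        for bnd in nucleolus_boundaries:
            pts = np.asarray(bnd, dtype=float)
            if len(pts) < 3:
                continue
            try:
                if Delaunay(pts).find_simplex([px, py]) >= 0:
                    return 0.0, 0.0 if norm_radius else None
            except QhullError:
                continue
    best = math.inf
    for bnd in nucleolus_boundaries:
        bnd = np.asarray(bnd, dtype=float)
        d = float(np.min(np.hypot(bnd[:, 0] - px, bnd[:, 1] - py)))
        best = min(best, d)
    return best, (best / norm_radius if norm_radius else None)


def sector_density(records, n_sectors: int, channel: str = "fish") -> np.ndarray:
    """Counts of signal centroids per equal angular sector about each
    nucleus center, pooled over ``records``.

    Sector 0 starts at the positive x-axis; sectors advance
    counterclockwise in image coordinates.  Signals exactly at a nucleus
    center are skipped (angle undefined).
    """
    if n_sectors < 2:
        raise ValueError("n_sectors must be >= 2")
    counts = np.zeros(n_sectors, dtype=int)
    width = 2.0 * math.pi / n_sectors
    for rec in records:
        cx, cy = rec.geometry.center
        for sig in getattr(rec, channel):
            dx, dy = sig.centroid[0] - cx, sig.centroid[1] - cy
            if dx == 0 and dy == 0:
                continue
            ang = math.atan2(-dy, dx) % (2.0 * math.pi)
            counts[min(int(ang / width), n_sectors - 1)] += 1
    return counts


def build_record(
    nucleus_id: str,
    geom: NucleusGeometry,
    fish_blobs=(),
    agnor_blobs=(),
    border_flag: bool = False,
) -> NucleusRecord:
    """Assemble a NucleusRecord from segmentation blobs.

    Pair metrics (d, alpha) are computed only when exactly two FISH
    blobs survived filtering; otherwise the record is flagged and kept.
    Signal-to-nucleolus surface distances are filled per FISH signal
    when at least one AgNOR/nucleolus blob is present.
    """
    rec = NucleusRecord(nucleus_id=nucleus_id, geometry=geom, border_flag=border_flag)
    for blob in fish_blobs:
        r = normalized_radius(geom, blob.centroid)
        rec.fish.append(
            SignalFeature("fish", blob.label, tuple(blob.centroid), blob.area_px, r,
                          blob.area_px / geom.Sn, outside_boundary=r > 1.0)
        )
    for blob in agnor_blobs:
        r = normalized_radius(geom, blob.centroid)
        rec.agnor.append(
            SignalFeature("agnor", blob.label, tuple(blob.centroid), blob.area_px, r,
                          blob.area_px / geom.Sn, outside_boundary=r > 1.0)
        )
    if len(rec.fish) == 2:
        d_norm, alpha = pair_metrics(geom, rec.fish[0].centroid, rec.fish[1].centroid)
        rec.d_norm = d_norm
        rec.alpha_deg = alpha
        rec.alpha_undefined = alpha is None
    else:
        rec.n_fish_flag = True
    if agnor_blobs:
        boundaries = [np.asarray(b.boundary, dtype=float) for b in agnor_blobs]
        pixel_sets = [b.pixel_set() for b in agnor_blobs]
        for sig in rec.fish:
            d_px, d_n = nucleolus_surface_distance(
                sig.centroid, boundaries, pixel_sets, norm_radius=geom.norm_radius
            )
            rec.nucleolus_dist_px.append(d_px)
            rec.nucleolus_dist_norm.append(d_n)
    return rec
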