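"""Synthetic nucleus-image populations with exact ground truth.

Generates the kind of single-cell crops the measurement pipeline is
built for: round lymphocyte-like nuclei or elliptical adherent-cell
(MSC-like) nuclei, each carrying two FISH homolog signals and one or
more nucleolar bodies, rendered as 8-bit RGB rasters plus a ground-truth
table of every object's true centroid, pixel area, 3D placement radius
and normalized planar radius.

Signals are placed by the 3D-to-2D projection model (`nullmodel`): a
3D position is drawn from a placement law (surface of the nucleus for
resting cells, an interior shell for activated ones), the nucleus is
randomly oriented and flattened, and the position is orthogonally
projected into the plane and mapped into the rendered nucleus.  With
size-dependent movement enabled, signals whose area fraction lies above
a quantile of the area law keep the peripheral (surface) placement
regardless of condition — the generator's analogue of large
heterochromatin domains that fail to relocate under stress.

Study-condition presets (see ``condition_spec``):

* ``control``            — both homologs on the nuclear surface; nucleoli
                           central (ball of normalized radius 0.5).
* ``activated``          — movable (small) signals in the shell
                           [0.40, 0.70]; large signals stay peripheral;
                           nucleoli moved to the shell [0.5, 0.6] and
                           enlarged by 50%.

Signal area fractions span 2-8% of the nucleus area by default.  Blobs
are rendered as filled ellipses of random eccentricity <= 1.5 with an
*exact* pixel count equal to the requested area, then clipped to the
nucleus mask, so the rendered truth is never off by rasterization.  The
true centroid recorded in the ground truth is the projected placement
position (pre-clip), which keeps the population's true-r distribution
exactly on the placement law's closed-form CDF.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .geometry import NucleusGeometry
from .nullmodel import PlacementModel, project, random_rotations, sample_placement

__all__ = [
    "NucleolusSpec",
    "PopulationSpec",
    "PlacementError",
    "condition_spec",
    "sample_geometry",
    "sample_signals",
    "sample_population_truth",
    "generate_population",
    "ground_truth_frame",
    "write_population",
    "GROUND_TRUTH_COLUMNS",
]

GROUND_TRUTH_COLUMNS = [
    "nucleus_id", "shape", "cx", "cy", "R_or_a", "b", "theta_deg",
    "object_type", "signal_id", "sx", "sy", "area_px", "true_r", "placement_rho",
]

_MARGIN_PX = 5


class PlacementError(RuntimeError):
    """Raised when a signal cannot be placed/rendered inside the nucleus."""


@dataclass(frozen=True)
class NucleolusSpec:
    """Nucleolar bodies per nucleus: count law, radial placement, size.

    ``area_fraction_range`` is the *total* nucleolar area per nucleus as
    a fraction of nucleus area; it is split across the bodies (with a
    +-20% per-body jitter), mirroring how total AgNOR area rather than
    per-body area is the conserved population quantity.  Counts above
    ``count_max`` are clipped so the bodies can stay disjoint.
    """

    count_law: str = "poisson1"  # "fixed" | "poisson1" (= 1 + Poisson(mean - 1))
    count_mean: float = 2.0
    count_max: int = 5
    placement: PlacementModel = field(default_factory=lambda: PlacementModel.ball(0.5))
    area_fraction_range: tuple[float, float] = (0.04, 0.08)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["placement"] = self.placement.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "NucleolusSpec":
        d = dict(d)
        d["placement"] = PlacementModel.from_dict(d["placement"])
        d["area_fraction_range"] = tuple(d["area_fraction_range"])
        return cls(**d)


@dataclass(frozen=True)
class PopulationSpec:
    """Full description of one synthetic population; with the seed it
    determines every generated byte."""

    n_nuclei: int = 100
    nucleus_shape: str = "circle"  # "circle" | "ellipse"
    radius_px_mean: float = 60.0
    radius_px_sd: float = 5.0
    axis_ratio_range: tuple[float, float] = (1.2, 1.6)
    n_fish_signals: int = 2
    placement: PlacementModel = field(default_factory=PlacementModel.surface)
    placement_immobile: PlacementModel = field(default_factory=PlacementModel.surface)
    area_fraction_range: tuple[float, float] = (0.02, 0.08)
    size_dependent_movement: bool = False
    movement_quantile: float = 0.75
    nucleolus: NucleolusSpec | None = field(default_factory=NucleolusSpec)
    noise_sigma: float = 0.0
    flatten_range: tuple[float, float] = (0.3, 1.0)
    canvas_px: int | None = None
    image_style: str = "fish"  # "fish" | "agnor"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_nuclei < 1:
            raise ValueError("n_nuclei must be >= 1")
        if self.nucleus_shape not in ("circle", "ellipse"):
            raise ValueError(f"unknown nucleus_shape {self.nucleus_shape!r}")
        lo, hi = self.axis_ratio_range
        if not (1.0 <= lo <= hi):
            raise ValueError("axis_ratio_range must satisfy 1 <= lo <= hi")
        lo, hi = self.area_fraction_range
        if not (0.0 < lo <= hi < 1.0):
            raise ValueError("area fractions must lie in (0, 1)")
        if self.image_style not in ("fish", "agnor"):
            raise ValueError(f"unknown image_style {self.image_style!r}")

    # -- canvas ----------------------------------------------------------
    @property
    def canvas(self) -> int:
        if self.canvas_px is not None:
            return int(self.canvas_px)
        extent = self.radius_px_mean + 4.0 * self.radius_px_sd
        if self.nucleus_shape == "ellipse":
            extent *= math.sqrt(self.axis_ratio_range[1])
        return int(2 * math.ceil(extent) + 2 * _MARGIN_PX)

    # -- JSON round trip -------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["placement"] = self.placement.to_dict()
        d["placement_immobile"] = self.placement_immobile.to_dict()
        d["nucleolus"] = self.nucleolus.to_dict() if self.nucleolus else None
        return d

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))

    @classmethod
    def from_dict(cls, d: dict) -> "PopulationSpec":
        d = dict(d)
        d["placement"] = PlacementModel.from_dict(d["placement"])
        d["placement_immobile"] = PlacementModel.from_dict(d["placement_immobile"])
        if d.get("nucleolus"):
            d["nucleolus"] = NucleolusSpec.from_dict(d["nucleolus"])
        for key in ("axis_ratio_range", "area_fraction_range", "flatten_range"):
            d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_json(cls, path) -> "PopulationSpec":
        return cls.from_dict(json.loads(Path(path).read_text()))


def condition_spec(condition: str, **overrides) -> PopulationSpec:
    """Preset PopulationSpec for a named study condition.

    ``control``: surface placement for all signals, central nucleoli.
    ``activated``: small signals relocated into the shell [0.40, 0.70],
    signals above the 0.75 area quantile stay on the surface; nucleoli
    moved to the shell [0.5, 0.6] and enlarged by 50%.
    """
    presets: dict[str, dict] = {
        "control": dict(
            placement=PlacementModel.surface(),
            placement_immobile=PlacementModel.surface(),
            size_dependent_movement=False,
            nucleolus=NucleolusSpec(placement=PlacementModel.ball(0.5),
                                    area_fraction_range=(0.04, 0.08)),
        ),
        "activated": dict(
            placement=PlacementModel.shell(0.40, 0.70),
            placement_immobile=PlacementModel.surface(),
            size_dependent_movement=True,
            movement_quantile=0.75,
            nucleolus=NucleolusSpec(placement=PlacementModel.shell(0.5, 0.6),
                                    area_fraction_range=(0.06, 0.12)),
        ),
    }
    if condition not in presets:
        raise ValueError(f"unknown condition {condition!r}; choose from {sorted(presets)}")
    kwargs = presets[condition]
    kwargs.update(overrides)
    return PopulationSpec(**kwargs)


# ---------------------------------------------------------------------------
# truth sampling


@dataclass
class TrueObject:
    """Analytic truth for one rendered object (FISH signal or nucleolus).

    ``centroid``/``true_r`` describe the sampled placement (exactly on
    the placement law); ``render_centroid``/``area_px`` describe the
    rasterized blob after clipping to the nucleus and are filled in at
    render time.  For blobs that straddle the fitted boundary the two
    centroids differ slightly (the clipped mass sits further inside).
    """

    object_type: str  # "fish" | "agnor"
    signal_id: int
    centroid: tuple[float, float]  # (sx, sy) px, pre-clip placement position
    area_fraction: float
    target_px: int  # requested pixel area before clipping
    rho: float  # 3D placement radius
    true_r: float  # normalized planar radius of the placement centroid
    ecc: float  # blob axis ratio (<= 1.5)
    phi_deg: float  # blob orientation
    movable: bool = True
    area_px: int = -1  # rendered (post-clip) pixel count; filled at render
    render_centroid: tuple[float, float] | None = None  # post-clip pixel centroid


@dataclass
class SyntheticNucleus:
    nucleus_id: str
    geometry: NucleusGeometry
    signals: list[TrueObject]
    nucleoli: list[TrueObject]
    image: np.ndarray | None = None

    @property
    def objects(self) -> list[TrueObject]:
        return self.signals + self.nucleoli


def sample_geometry(spec: PopulationSpec, rng: np.random.Generator) -> NucleusGeometry:
    """Draw one nucleus geometry that fits the canvas with >= 5 px margin."""
    canvas = spec.canvas
    half = canvas / 2.0
    for _ in range(1000):
        radius = spec.radius_px_mean + spec.radius_px_sd * rng.standard_normal()
        if radius < 8.0:
            continue
        if spec.nucleus_shape == "circle":
            extent = radius
        else:
            q = rng.uniform(*spec.axis_ratio_range)
            theta = rng.uniform(0.0, 180.0)
            extent = radius * math.sqrt(q)
        if extent + _MARGIN_PX > half:
            if spec.radius_px_sd == 0:
                raise ValueError(
                    f"canvas {canvas} px too small for nucleus extent {extent:.1f} px"
                )
            continue
        jitter = min(2.0, half - extent - _MARGIN_PX)
        cx = half + rng.uniform(-jitter, jitter)
        cy = half + rng.uniform(-jitter, jitter)
        if spec.nucleus_shape == "circle":
            return NucleusGeometry.circle((cx, cy), radius)
        a, b = radius * math.sqrt(q), radius / math.sqrt(q)
        return NucleusGeometry.ellipse((cx, cy), a, b, theta)
    raise ValueError(f"canvas {canvas} px too small for requested nucleus radii")


def _unit_to_image(geom: NucleusGeometry, xy: np.ndarray) -> tuple[float, float]:
    """Map unit-disk coordinates to image coordinates inside the nucleus."""
    x, y = float(xy[0]), float(xy[1])
    if geom.kind == "circle":
        return geom.center[0] + geom.R * x, geom.center[1] + geom.R * y
    t = math.radians(geom.theta_deg)
    ax, by = geom.a * x, geom.b * y
    return (
        geom.center[0] + ax * math.cos(t) - by * math.sin(t),
        geom.center[1] + ax * math.sin(t) + by * math.cos(t),
    )


def _place_objects(
    geom: NucleusGeometry,
    model_for_index,
    area_fractions: np.ndarray,
    object_type: str,
    spec: PopulationSpec,
    rng: np.random.Generator,
    movable_flags=None,
) -> list[TrueObject]:
    """Place one channel's objects with their blobs kept disjoint.

    If a later object cannot clear an earlier one at any angle (e.g.
    the first of two large signals projected near the center), the whole
    set is re-placed from scratch — a joint feasibility thinning whose
    restart probability is small enough to leave the radial law intact
    at test tolerances.
    """
    for _restart in range(20):
        out = _try_place_objects(geom, model_for_index, area_fractions,
                                 object_type, spec, rng, movable_flags)
        if out is not None:
            return out
    # give up on disjointness: place once more and accept overlaps
    return _try_place_objects(geom, model_for_index, area_fractions,
                              object_type, spec, rng, movable_flags,
                              require_clear=False)


def _try_place_objects(
    geom: NucleusGeometry,
    model_for_index,
    area_fractions: np.ndarray,
    object_type: str,
    spec: PopulationSpec,
    rng: np.random.Generator,
    movable_flags=None,
    require_clear: bool = True,
) -> list[TrueObject] | None:
    n = len(area_fractions)
    out: list[TrueObject] = []
    # (sx, sy, blob radius px) of same-channel objects already placed;
    # used to keep rendered blobs disjoint so a segmenter can resolve
    # them individually.
    occupied: list[tuple[float, float, float]] = []
    for i in range(n):
        model = model_for_index(i)
        ecc = rng.uniform(1.0, 1.5)
        phi = rng.uniform(0.0, 180.0)
        target = max(1, int(round(area_fractions[i] * geom.Sn)))
        # effective footprint radius: boundary-hugging crescents spread
        # tangentially up to ~sqrt(2) beyond the nominal semi-major axis
        radius_px = math.sqrt(target / math.pi) * math.sqrt(ecc) * 1.45

        def _clear(sx: float, sy: float) -> bool:
            return all(
                math.hypot(sx - ox, sy - oy) >= radius_px + orad + 4.0
                for ox, oy, orad in occupied
            )

        # Separation strategy: first angle-only nudges (rotating the
        # planar position about the nucleus center preserves its
        # normalized radius exactly, leaving the radial law untouched);
        # if the blobs are concentric and rotation cannot help, resample
        # the placement afresh (a hard-core thinning of the law).
        pts = rot = c = planar = None
        placed = False
        for attempt in range(200):
            if attempt % 40 == 0:
                pts = sample_placement(model, 1, rng)
                rot = random_rotations(1, rng)
                c = rng.uniform(*spec.flatten_range)
                planar = project(pts, rot, c)[0].copy()
            else:
                ang = rng.uniform(0.0, 2.0 * math.pi)
                ca, sa = math.cos(ang), math.sin(ang)
                planar = np.array([planar[0] * ca - planar[1] * sa,
                                   planar[0] * sa + planar[1] * ca])
            sx, sy = _unit_to_image(geom, planar)
            if _clear(sx, sy):
                placed = True
                break
        if require_clear and not placed:
            return None
        r_true = float(np.hypot(planar[0], planar[1]))
        occupied.append((sx, sy, radius_px))
        out.append(
            TrueObject(
                object_type=object_type,
                signal_id=i,
                centroid=(sx, sy),
                area_fraction=float(area_fractions[i]),
                target_px=target,
                rho=float(np.linalg.norm(pts[0])),
                true_r=r_true,
                ecc=ecc,
                phi_deg=phi,
                movable=bool(movable_flags[i]) if movable_flags is not None else True,
            )
        )
    return out


def sample_signals(
    geom: NucleusGeometry, spec: PopulationSpec, rng: np.random.Generator
) -> list[TrueObject]:
    """Draw the FISH signals of one nucleus: area fraction, size class,
    3D placement, projection, and mapping into the nucleus."""
    lo, hi = spec.area_fraction_range
    fracs = rng.uniform(lo, hi, size=spec.n_fish_signals)
    # Quantile threshold of the (uniform) area law above which signals
    # are pinned to the peripheral placement.
    thresh = lo + spec.movement_quantile * (hi - lo)
    movable = ~(spec.size_dependent_movement & (fracs > thresh))

    def model_for(i: int) -> PlacementModel:
        return spec.placement if movable[i] else spec.placement_immobile

    return _place_objects(geom, model_for, fracs, "fish", spec, rng, movable_flags=movable)


def _sample_nucleoli(
    geom: NucleusGeometry, spec: PopulationSpec, rng: np.random.Generator
) -> list[TrueObject]:
    ns = spec.nucleolus
    if ns is None:
        return []
    if ns.count_law == "fixed":
        count = int(round(ns.count_mean))
    elif ns.count_law == "poisson1":
        count = 1 + int(rng.poisson(max(ns.count_mean - 1.0, 0.0)))
    else:
        raise ValueError(f"unknown nucleolus count law {ns.count_law!r}")
    count = max(1, min(count, ns.count_max))
    total = rng.uniform(*ns.area_fraction_range)
    fracs = (total / count) * rng.uniform(0.8, 1.2, size=count)
    return _place_objects(geom, lambda i: ns.placement, fracs, "agnor", spec, rng)


def sample_population_truth(spec: PopulationSpec) -> list[SyntheticNucleus]:
    """Analytic truth for a whole population, without rasterization.

    Deterministic given the spec's seed, and consumes exactly the same
    random draws as ``generate_population``, so the analytic truth of a
    rendered population is identical to this fast path.
    """
    rng = np.random.default_rng([int(spec.seed) % (2**31), 0])
    out = []
    for i in range(spec.n_nuclei):
        geom = sample_geometry(spec, rng)
        signals = sample_signals(geom, spec, rng)
        nucleoli = _sample_nucleoli(geom, spec, rng)
        out.append(SyntheticNucleus(f"n{i:05d}", geom, signals, nucleoli))
    return out


# ---------------------------------------------------------------------------
# rendering

_FISH_STYLE = dict(background=(0, 0, 0), nucleus=(180, 0, 0),
                   nucleolus=(255, 0, 0), signal_green=255)
_AGNOR_STYLE = dict(background=(235, 235, 235), nucleus=(190, 190, 190),
                    nucleolus=(60, 45, 35))


def _nucleus_mask(geom: NucleusGeometry, canvas: int) -> np.ndarray:
    yy, xx = np.mgrid[0:canvas, 0:canvas]
    dx = xx - geom.center[0]
    dy = yy - geom.center[1]
    if geom.kind == "circle":
        return dx * dx + dy * dy <= geom.R * geom.R
    t = math.radians(geom.theta_deg)
    xr = dx * math.cos(t) + dy * math.sin(t)
    yr = -dx * math.sin(t) + dy * math.cos(t)
    return (xr / geom.a) ** 2 + (yr / geom.b) ** 2 <= 1.0


def _blob_pixels(obj: TrueObject, canvas: int, clip_mask: np.ndarray) -> np.ndarray:
    """Pixels of a rendered blob: the ``target_px`` in-nucleus pixels
    closest to the blob center in its elliptical metric.

    Returns an (m, 2) int array of (y, x).  Restricting the selection to
    ``clip_mask`` *before* taking the closest pixels conserves the blob
    area: a blob whose placement centroid sits at the nucleus boundary
    is rendered as a crescent hugging the envelope from inside (the
    shape peripheral chromatin domains actually take), rather than
    being cut in half.  The count equals ``target_px`` exactly unless
    the whole nucleus is smaller than the blob.
    """
    sx, sy = obj.centroid
    # semi-axes of an ellipse with area target_px and axis ratio ecc
    s = math.sqrt(obj.target_px / math.pi)
    aa, bb = s * math.sqrt(obj.ecc), s / math.sqrt(obj.ecc)
    t = math.radians(obj.phi_deg)
    for factor in (2.5, 5.0, 12.0):
        half = int(math.ceil(aa * factor)) + 2
        x0, x1 = int(math.floor(sx)) - half, int(math.floor(sx)) + half + 1
        y0, y1 = int(math.floor(sy)) - half, int(math.floor(sy)) + half + 1
        x0, y0 = max(x0, 0), max(y0, 0)
        x1, y1 = min(x1, canvas), min(y1, canvas)
        yy, xx = np.mgrid[y0:y1, x0:x1]
        inside = clip_mask[yy, xx].ravel()
        if inside.sum() >= obj.target_px or (x0 == 0 and y0 == 0
                                             and x1 == canvas and y1 == canvas):
            break
    dx = xx.ravel() - sx
    dy = yy.ravel() - sy
    xr = dx * math.cos(t) + dy * math.sin(t)
    yr = -dx * math.sin(t) + dy * math.cos(t)
    dist = (xr / aa) ** 2 + (yr / bb) ** 2
    dist[~inside] = np.inf
    order = np.lexsort((xx.ravel(), yy.ravel(), dist))
    take = order[: min(obj.target_px, int(inside.sum()))]
    return np.stack([yy.ravel()[take], xx.ravel()[take]], axis=1)


def render_nucleus(
    nuc: SyntheticNucleus, spec: PopulationSpec, rng: np.random.Generator
) -> np.ndarray:
    """Rasterize one nucleus; fills each object's post-clip area_px."""
    canvas = spec.canvas
    mask = _nucleus_mask(nuc.geometry, canvas)
    img = np.zeros((canvas, canvas, 3), dtype=float)
    style = _FISH_STYLE if spec.image_style == "fish" else _AGNOR_STYLE
    img[:] = style["background"]
    img[mask] = style["nucleus"]
    for obj in nuc.nucleoli:
        px = _render_object(obj, canvas, mask)
        img[px[:, 0], px[:, 1]] = style["nucleolus"]
    if spec.image_style == "fish":
        for obj in nuc.signals:
            px = _render_object(obj, canvas, mask)
            img[px[:, 0], px[:, 1], 1] = _FISH_STYLE["signal_green"]
    else:
        for obj in nuc.signals:
            obj.area_px = 0  # FISH channel absent in Ag-stained images
    if spec.noise_sigma > 0:
        img = img + rng.normal(0.0, spec.noise_sigma, size=img.shape)
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


def _render_object(obj: TrueObject, canvas: int, mask: np.ndarray) -> np.ndarray:
    px = _blob_pixels(obj, canvas, mask)
    if len(px) == 0:
        raise PlacementError(
            f"{obj.object_type} signal {obj.signal_id} could not be rendered inside the nucleus"
        )
    obj.area_px = int(len(px))
    obj.render_centroid = (float(px[:, 1].mean()), float(px[:, 0].mean()))
    return px


def generate_population(spec: PopulationSpec) -> list[SyntheticNucleus]:
    """Sample and rasterize a full population (images + truth)."""
    nuclei = sample_population_truth(spec)
    rng_noise = np.random.default_rng([int(spec.seed) % (2**31), 1])
    for nuc in nuclei:
        nuc.image = render_nucleus(nuc, spec, rng_noise)
    return nuclei


def ground_truth_frame(nuclei: list[SyntheticNucleus]) -> pd.DataFrame:
    """One ground-truth row per generated object.

    For rendered populations the recorded centroid (and hence true_r)
    is that of the rasterized, nucleus-clipped blob — the measurable
    truth; un-rendered objects keep the analytic placement centroid.
    ``placement_rho`` always records the 3D placement radius.
    """
    from .geometry import normalized_radius

    rows = []
    for nuc in nuclei:
        g = nuc.geometry
        for obj in nuc.objects:
            if obj.render_centroid is not None:
                sx, sy = obj.render_centroid
                true_r = normalized_radius(g, (sx, sy))
            else:
                (sx, sy), true_r = obj.centroid, obj.true_r
            rows.append(
                dict(
                    nucleus_id=nuc.nucleus_id,
                    shape=g.kind,
                    cx=g.center[0],
                    cy=g.center[1],
                    R_or_a=g.R if g.kind == "circle" else g.a,
                    b=g.b,
                    theta_deg=g.theta_deg,
                    object_type=obj.object_type,
                    signal_id=obj.signal_id,
                    sx=sx,
                    sy=sy,
                    area_px=obj.area_px,
                    true_r=true_r,
                    placement_rho=obj.rho,
                )
            )
    return pd.DataFrame(rows, columns=GROUND_TRUTH_COLUMNS)


def write_population(spec: PopulationSpec, outdir) -> pd.DataFrame:
    """Render a population to ``outdir``: one PNG per nucleus,
    ``ground_truth.csv`` and ``spec.json``.  Returns the truth table."""
    outdir = Path(outdir)
    imgdir = outdir / "images"
    imgdir.mkdir(parents=True, exist_ok=True)
    nuclei = generate_population(spec)
    for nuc in nuclei:
        path = imgdir / f"{nuc.nucleus_id}.png"
        try:
            iio.imwrite(path, nuc.image)
        except OSError as exc:  # pragma: no cover - I/O context
            raise OSError(f"failed writing {path}: {exc}") from exc
    truth = ground_truth_frame(nuclei)
    truth.to_csv(outdir / "ground_truth.csv", index=False, float_format="%.9g")
    spec.to_json(outdir / "spec.json")
    return truth
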