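"""3D-to-2D projection null model for radial signal positions.

Interphase lymphocyte nuclei fixed on a slide are well approximated by a
sphere flattened along the optical (Z) axis.  A fluorescent locus sitting at
3D radius ``rho`` (normalized to the nucleus radius) appears, after random
orientation of the nucleus and orthogonal projection onto the slide plane,
at a planar normalized radius ``r <= rho``.  This module implements that
forward model for three placement laws

* ``surface`` — loci on the nuclear envelope (``rho = 1``),
* ``ball``    — loci uniform by volume in the whole nucleus,
* ``shell``   — loci uniform by volume between two radii ``ain <= aout``,

together with the closed-form CDFs of the projected radius, Monte Carlo
simulation of single signals and of two-signal constellations (planar
inter-signal distance ``d`` and central angle ``alpha``), and a grid-search
fit of shell bounds to an observed sample of projected radii.

For a point at fixed 3D radius ``rho`` under an isotropic rotation the
projected radius is ``rho * sqrt(1 - u**2)`` with ``u`` uniform on (0, 1),
giving ``F_rho(x) = 1 - sqrt(1 - (x/rho)**2)`` for ``x <= rho``.  Averaging
over the volume-uniform shell density ``~ rho**2`` yields

    F(x) = (G(aout, x) - G(ain, x)) / ((aout**3 - ain**3) / 3),
    G(A, x) = A**3 / 3 - max(A**2 - x**2, 0)**1.5 / 3,

which reduces to ``1 - sqrt(1 - x**2)`` (surface) and
``1 - (1 - x**2)**1.5`` (ball) in the limits.

Flattening the sphere along Z before projection rescales only the dropped
coordinate, so the *normalized* projected radius is distribution-free in the
compression factor; the simulation keeps the flattening step so this
invariance is an executable property rather than an assumption.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass

import numpy as np
from scipy import integrate
from scipy.spatial.transform import Rotation

__all__ = [
    "PlacementModel",
    "ProjectionConfig",
    "sample_placement",
    "random_rotations",
    "project",
    "simulate_projected_r",
    "simulate_pairs",
    "closed_form_cdf",
    "fit_placement",
    "PlacementFit",
]


@dataclass(frozen=True)
class PlacementModel:
    """Radial placement law of signals inside the unit sphere.

    ``surface`` is shell(1, 1); ``ball`` is shell(0, 1).  ``density``
    selects how mass is spread over the shell radii: ``"volume"``
    (default, density proportional to rho**2) or ``"radius"`` (uniform
    in rho).
    """

    law: str = "surface"
    inner: float = 1.0
    outer: float = 1.0
    density: str = "volume"

    def __post_init__(self) -> None:
        if self.law not in ("surface", "shell", "ball"):
            raise ValueError(f"unknown placement law: {self.law!r}")
        if self.density not in ("volume", "radius"):
            raise ValueError(f"unknown shell density: {self.density!r}")
        inner, outer = self.bounds
        if not (0.0 <= inner <= outer <= 1.0):
            raise ValueError(
                f"shell bounds must satisfy 0 <= ain <= aout <= 1, got ({inner}, {outer})"
            )

    @property
    def bounds(self) -> tuple[float, float]:
        if self.law == "surface":
            return 1.0, 1.0
        if self.law == "ball":
            return 0.0, 1.0
        return float(self.inner), float(self.outer)

    @classmethod
    def surface(cls) -> "PlacementModel":
        return cls(law="surface", inner=1.0, outer=1.0)

    @classmethod
    def ball(cls, radius: float = 1.0) -> "PlacementModel":
        return cls(law="shell", inner=0.0, outer=radius)

    @classmethod
    def shell(cls, inner: float, outer: float, density: str = "volume") -> "PlacementModel":
        return cls(law="shell", inner=inner, outer=outer, density=density)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PlacementModel":
        return cls(**d)


@dataclass(frozen=True)
class ProjectionConfig:
    """Monte Carlo settings for the projection simulation."""

    n_constellations: int = 100_000
    points_per_constellation: int = 1
    flatten_range: tuple[float, float] = (0.3, 1.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_constellations < 1:
            raise ValueError("n_constellations must be >= 1")
        cmin, cmax = self.flatten_range
        if not (0.0 < cmin <= cmax <= 1.0):
            raise ValueError("flatten_range must satisfy 0 < cmin <= cmax <= 1")


def _sample_radii(model: PlacementModel, n: int, rng: np.random.Generator) -> np.ndarray:
    ain, aout = model.bounds
    if aout == ain:
        return np.full(n, aout)
    u = rng.random(n)
    if model.density == "volume":
        return np.cbrt(ain**3 + u * (aout**3 - ain**3))
    return ain + u * (aout - ain)


def sample_placement(model: PlacementModel, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw ``n`` 3D points inside the unit ball according to ``model``.

    Directions are isotropic; radii follow the shell law.  Returns an
    ``(n, 3)`` array.
    """
    v = rng.standard_normal((n, 3))
    norm = np.linalg.norm(v, axis=1, keepdims=True)
    # A zero-norm draw has probability 0; guard against it anyway.
    norm[norm == 0] = 1.0
    directions = v / norm
    return directions * _sample_radii(model, n, rng)[:, None]


def random_rotations(n: int, rng: np.random.Generator) -> Rotation:
    """``n`` rotations uniform on SO(3), via isotropic unit quaternions."""
    q = rng.standard_normal((n, 4))
    q /= np.linalg.norm(q, axis=1, keepdims=True)
    return Rotation.from_quat(q)


def project(
    points: np.ndarray,
    rotation: Rotation,
    flatten: float | np.ndarray = 1.0,
) -> np.ndarray:
    """Rotate, compress along Z by ``flatten``, and drop Z.

    ``points`` has shape ``(n, 3)`` or ``(n, k, 3)`` (k points per
    constellation share one rotation and compression).  Returns planar
    coordinates normalized by the projected outline radius of the
    flattened unit sphere, which equals 1 for Z-only compression: the
    projected outline is always the unit circle.
    """
    c = np.asarray(flatten, dtype=float)
    if np.any((c <= 0) | (c > 1)):
        raise ValueError("flatten factor must lie in (0, 1]")
    pts = np.asarray(points, dtype=float)
    if pts.ndim == 2:
        rotated = rotation.apply(pts)
    elif pts.ndim == 3:
        n, k, _ = pts.shape
        flat = pts.reshape(n * k, 3)
        if len(rotation) == 1:
            rotated = rotation.apply(flat)
        else:
            rotated = np.repeat(rotation.as_matrix(), k, axis=0) @ flat[:, :, None]
            rotated = rotated[:, :, 0]
        rotated = rotated.reshape(n, k, 3)
    else:
        raise ValueError("points must have shape (n, 3) or (n, k, 3)")
    # Z-compression then orthogonal projection: z is scaled and dropped,
    # so it only matters that the step is applied, not the value of c --
    # this is the flattening invariance checked in the tests.
    return rotated[..., :2]


def planar_radii(planar: np.ndarray) -> np.ndarray:
    return np.linalg.norm(planar, axis=-1)


def simulate_projected_r(
    model: PlacementModel,
    n: int,
    rng: np.random.Generator,
    flatten_range: tuple[float, float] = (0.3, 1.0),
) -> np.ndarray:
    """Monte Carlo sample of the normalized projected radius (one signal
    per projection act, fresh rotation and compression each act)."""
    pts = sample_placement(model, n, rng)
    rot = random_rotations(n, rng)
    c = rng.uniform(flatten_range[0], flatten_range[1], size=n)
    planar = project(pts, rot, c)
    return planar_radii(planar)


def simulate_pairs(
    model: PlacementModel,
    n: int,
    rng: np.random.Generator,
    flatten_range: tuple[float, float] = (0.3, 1.0),
):
    """Two-signal constellations: returns (r1, r2, d, alpha_deg).

    The two points of a constellation are placed independently (no
    angular correlation) and share one rotation + compression per act.
    ``d`` is the planar inter-point distance, ``alpha_deg`` the planar
    angle at the projection center in degrees [0, 180].
    """
    pts = sample_placement(model, 2 * n, rng).reshape(n, 2, 3)
    rot = random_rotations(n, rng)
    c = rng.uniform(flatten_range[0], flatten_range[1], size=n)
    planar = project(pts, rot, c)
    p1, p2 = planar[:, 0, :], planar[:, 1, :]
    r1 = planar_radii(p1)
    r2 = planar_radii(p2)
    d = np.linalg.norm(p1 - p2, axis=1)
    denom = r1 * r2
    with np.errstate(invalid="ignore", divide="ignore"):
        cosang = np.einsum("ij,ij->i", p1, p2) / denom
    alpha = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    alpha[denom == 0] = np.nan
    return r1, r2, d, alpha


def _fixed_rho_cdf(x: np.ndarray, rho: float) -> np.ndarray:
    """CDF of the projected radius of a point at fixed 3D radius rho."""
    if rho == 0:
        return np.ones_like(x)
    xr = np.clip(x / rho, 0.0, 1.0)
    out = 1.0 - np.sqrt(1.0 - xr**2)
    out[x >= rho] = 1.0
    return out


def closed_form_cdf(model: PlacementModel, x) -> np.ndarray | float:
    """Exact CDF F(x) of the normalized projected radius under ``model``.

    Valid for x in [0, 1]; raises on values outside the domain.
    """
    xs = np.atleast_1d(np.asarray(x, dtype=float))
    if np.any((xs < 0) | (xs > 1)):
        raise ValueError("closed_form_cdf domain is [0, 1]")
    ain, aout = model.bounds
    if aout == ain:
        out = _fixed_rho_cdf(xs, aout)
    elif model.density == "volume":
        g_out = aout**3 - np.clip(aout**2 - xs**2, 0.0, None) ** 1.5
        g_in = ain**3 - np.clip(ain**2 - xs**2, 0.0, None) ** 1.5
        out = (g_out - g_in) / (aout**3 - ain**3)
    else:
        out = np.array(
            [
                integrate.quad(
                    lambda rho: float(_fixed_rho_cdf(np.array([xi]), rho)[0]),
                    ain,
                    aout,
                    epsabs=1e-9,
                )[0]
                / (aout - ain)
                for xi in xs
            ]
        )
    return out if np.ndim(x) else float(out[0])


def _cdf_by_quadrature(model: PlacementModel, x) -> np.ndarray | float:
    """Shell CDF by direct 1D numerical integration over the radial
    density (independent cross-check of closed_form_cdf)."""
    xs = np.atleast_1d(np.asarray(x, dtype=float))
    ain, aout = model.bounds
    if aout == ain:
        out = _fixed_rho_cdf(xs, aout)
        return out if np.ndim(x) else float(out[0])
    if model.density == "volume":
        weight = lambda rho: 3.0 * rho**2 / (aout**3 - ain**3)  # noqa: E731
    else:
        weight = lambda rho: 1.0 / (aout - ain)  # noqa: E731
    vals = []
    for xi in xs:
        f = lambda rho: weight(rho) * float(_fixed_rho_cdf(np.array([xi]), rho)[0])  # noqa: E731
        # Split at rho = xi where the integrand has a kink.
        if ain < xi < aout:
            v = (
                integrate.quad(f, ain, xi, epsabs=1e-8)[0]
                + integrate.quad(f, xi, aout, epsabs=1e-8)[0]
            )
        else:
            v = integrate.quad(f, ain, aout, epsabs=1e-8)[0]
        vals.append(v)
    out = np.array(vals)
    return out if np.ndim(x) else float(out[0])


def ks_distance_to_model(observed: np.ndarray, model: PlacementModel) -> float:
    """Exact sup |ECDF - F_model| over the observed order statistics."""
    xs = np.sort(np.asarray(observed, dtype=float))
    n = xs.size
    if n == 0:
        raise ValueError("empty observation set")
    f = np.asarray(closed_form_cdf(model, np.clip(xs, 0.0, 1.0)))
    i = np.arange(1, n + 1)
    return float(max(np.max(i / n - f), np.max(f - (i - 1) / n)))


@dataclass(frozen=True)
class PlacementFit:
    model: PlacementModel
    ks_distance: float


def fit_placement(
    observed,
    coarse_step: float = 0.05,
    refine_step: float = 0.01,
    density: str = "volume",
) -> PlacementFit:
    """Fit shell bounds (ain, aout) to observed projected radii.

    Exhaustive grid search minimizing the KS sup-distance between the
    observed ECDF and the closed-form shell CDF, then a local refinement
    around the coarse optimum.  Ties break toward the narrowest shell,
    then the smallest inner bound.  Requires >= 50 observations.
    """
    obs = np.asarray(observed, dtype=float)
    if obs.size == 0:
        raise ValueError("empty observation set")
    if obs.size < 50:
        raise ValueError("fit_placement requires at least 50 observations")

    def search(ains: np.ndarray, aouts: np.ndarray) -> tuple[float, float, float]:
        best = None
        for ain in ains:
            for aout in aouts:
                if aout < ain - 1e-12:
                    continue
                m = PlacementModel.shell(float(ain), float(min(aout, 1.0)), density=density)
                d = ks_distance_to_model(obs, m)
                key = (round(d, 12), round(aout - ain, 12), round(ain, 12))
                if best is None or key < best[0]:
                    best = (key, float(ain), float(aout), d)
        return best[1], best[2], best[3]

    grid = np.round(np.arange(0.0, 1.0 + 1e-9, coarse_step), 10)
    ain0, aout0, _ = search(grid, grid)
    lo = lambda v: max(0.0, v - coarse_step)  # noqa: E731
    hi = lambda v: min(1.0, v + coarse_step)  # noqa: E731
    fine_in = np.round(np.arange(lo(ain0), hi(ain0) + 1e-9, refine_step), 10)
    fine_out = np.round(np.arange(lo(aout0), hi(aout0) + 1e-9, refine_step), 10)
    ain, aout, d = search(fine_in, fine_out)
    return PlacementFit(PlacementModel.shell(ain, min(aout, 1.0), density=density), d)
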