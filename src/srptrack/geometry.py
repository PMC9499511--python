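"""Spherocylinder cell geometry, compartments, and radial projection profiles.

The model cell is a spherocylinder: a cylinder of radius ``cylinder_radius``
and length ``cylinder_length`` capped by two hemispheres of the same radius,
surrounded by a membrane shell of thickness ``membrane_thickness``.  The long
axis is x, the optical axis is z, and the origin sits at the cell center.
All lengths are in micrometres.

Radial (short-axis) profiles are histograms of the signed in-plane offset
from the long axis, normalized by the local cytosol half-width, so the inner
membrane edge maps to r = +/-1.  Membrane-shell molecules therefore reach
|r| slightly above 1; profiles record the fraction of positions retained in
[-1, 1] so downstream decompositions can correct for the clipped tail.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

CYTOSOL = "cytosol"
MEMBRANE = "membrane"
OUTSIDE = "outside"

#: default number of radial histogram bins
N_BINS_DEFAULT = 18


@dataclass(frozen=True)
class CellGeometry:
    """Spherocylindrical cell with an optional membrane shell.

    Parameters
    ----------
    cylinder_radius : float
        Radius of the cytosol cylinder and of the hemispherical caps (µm).
    cylinder_length : float
        Length of the cylindrical part only (µm); the total tip-to-tip
        length is ``cylinder_length + 2 * cylinder_radius``.
    membrane_thickness : float
        Thickness of the membrane shell wrapped around the cytosol (µm).
    """

    cylinder_radius: float = 0.42
    cylinder_length: float = 3.0
    membrane_thickness: float = 0.05

    def __post_init__(self) -> None:
        if self.cylinder_radius <= 0:
            raise ValueError("cylinder_radius must be positive")
        if self.cylinder_length < 0:
            raise ValueError("cylinder_length must be non-negative")
        if self.membrane_thickness < 0:
            raise ValueError("membrane_thickness must be non-negative")
        if self.membrane_thickness >= self.cylinder_radius:
            raise ValueError("membrane_thickness must be < cylinder_radius")

    @property
    def cap_radius(self) -> float:
        return self.cylinder_radius

    @property
    def outer_radius(self) -> float:
        """Radius of the outer envelope (cytosol + membrane shell)."""
        return self.cylinder_radius + self.membrane_thickness

    @property
    def total_length(self) -> float:
        """Tip-to-tip length of the cytosol compartment."""
        return self.cylinder_length + 2.0 * self.cap_radius

    @property
    def outer_total_length(self) -> float:
        return self.cylinder_length + 2.0 * self.outer_radius

    @classmethod
    def single_compartment(cls) -> "CellGeometry":
        """The one-compartment variant: radius 0.47 µm, no shell."""
        return cls(cylinder_radius=0.47, cylinder_length=3.0, membrane_thickness=0.0)

    def cytosol_volume(self) -> float:
        return spherocylinder_volume(self.cylinder_radius, self.cylinder_length)

    def membrane_volume(self) -> float:
        outer = spherocylinder_volume(self.outer_radius, self.cylinder_length)
        return outer - self.cytosol_volume()


def spherocylinder_volume(radius: float, cylinder_length: float) -> float:
    """Closed-form volume of a cylinder with hemispherical caps."""
    return np.pi * radius**2 * cylinder_length + 4.0 / 3.0 * np.pi * radius**3


def axial_distance(points: np.ndarray, geom: CellGeometry) -> np.ndarray:
    """Distance of 3D points from the spherocylinder axis segment.

    The axis segment runs along x from -L/2 to +L/2 (L = cylinder_length),
    so the distance is radial in the cylindrical part and spherical about
    the cap centers in the pole regions.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    half = geom.cylinder_length / 2.0
    ax = np.clip(points[:, 0], -half, half)
    return np.sqrt((points[:, 0] - ax) ** 2 + points[:, 1] ** 2 + points[:, 2] ** 2)


def compartment_of(point: np.ndarray, geom: CellGeometry) -> str | np.ndarray:
    """Classify 3D point(s) as cytosol, membrane, or outside.

    The membrane is the closed shell ``cylinder_radius <= d <= outer_radius``
    where d is the distance from the axis segment; strictly inside is
    cytosol, beyond the outer envelope is outside.
    """
    pts = np.asarray(point, dtype=float)
    scalar = pts.ndim == 1
    d = axial_distance(pts, geom)
    out = np.where(
        d < geom.cylinder_radius,
        CYTOSOL,
        np.where(d <= geom.outer_radius, MEMBRANE, OUTSIDE),
    )
    return out[0] if scalar else out


@dataclass
class NormalizedPosition:
    """Positions in normalized cell coordinates.

    x_long runs from 0 at one pole tip to 1 at the other; r_short is the
    signed in-plane short-axis offset divided by the local cytosol
    half-width (inner membrane edge at +/-1).  z (µm) is carried through
    when known and None for observed 2D data.
    """

    x_long: np.ndarray
    r_short: np.ndarray
    z: Optional[np.ndarray] = None
    #: |r_short| beyond this is flagged as outside the cell envelope
    tolerance: float = field(default=0.35, repr=False)

    def __len__(self) -> int:
        return len(self.x_long)

    @property
    def outside_flag(self) -> np.ndarray:
        return np.abs(self.r_short) > 1.0 + self.tolerance


@dataclass(frozen=True)
class CellPose:
    """Placement of a cell in the image plane: center and long-axis angle."""

    center: tuple[float, float] = (0.0, 0.0)
    angle: float = 0.0

    @property
    def axis(self) -> np.ndarray:
        return np.array([np.cos(self.angle), np.sin(self.angle)])

    @property
    def normal(self) -> np.ndarray:
        return np.array([-np.sin(self.angle), np.cos(self.angle)])


def local_half_width(x_axis: np.ndarray, geom: CellGeometry) -> np.ndarray:
    """Cytosol half-width at axial coordinate x (µm from cell center).

    Equal to cylinder_radius in the cylindrical part; in the pole regions it
    is the half-width of the cap circle at that axial position.
    """
    x_axis = np.asarray(x_axis, dtype=float)
    half = geom.cylinder_length / 2.0
    excess = np.maximum(np.abs(x_axis) - half, 0.0)
    excess = np.minimum(excess, geom.cap_radius)
    return np.sqrt(np.maximum(geom.cap_radius**2 - excess**2, 1e-12))


def normalize_position(
    points: np.ndarray,
    pose: CellPose = CellPose(),
    geom: CellGeometry = CellGeometry(),
) -> NormalizedPosition:
    """Map 2D or 3D lab-frame positions into normalized cell coordinates."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if not np.isfinite(pose.angle) or pts.shape[1] not in (2, 3):
        raise ValueError("points must be (n,2) or (n,3)")
    rel = pts[:, :2] - np.asarray(pose.center)
    x_ax = rel @ pose.axis
    y_perp = rel @ pose.normal
    z = pts[:, 2].copy() if pts.shape[1] == 3 else None
    half_len = geom.total_length / 2.0
    x_long = (x_ax + half_len) / geom.total_length
    width = local_half_width(x_ax, geom)
    r_short = y_perp / width
    return NormalizedPosition(x_long=x_long, r_short=r_short, z=z)


def denormalize_position(
    norm: NormalizedPosition,
    pose: CellPose = CellPose(),
    geom: CellGeometry = CellGeometry(),
) -> np.ndarray:
    """Inverse of :func:`normalize_position` (2D part; z appended if known)."""
    x_ax = norm.x_long * geom.total_length - geom.total_length / 2.0
    y_perp = norm.r_short * local_half_width(x_ax, geom)
    xy = (
        np.asarray(pose.center)
        + x_ax[:, None] * pose.axis[None, :]
        + y_perp[:, None] * pose.normal[None, :]
    )
    if norm.z is not None:
        return np.column_stack([xy, norm.z])
    return xy


@dataclass
class RadialProfile:
    """Unit-normalized short-axis density histogram.

    ``sum(density * bin_width) == 1``; ``n_total`` counts the positions that
    contributed, and ``retention`` is the fraction of margin-surviving
    positions that fell inside the histogram range (used to undo range
    clipping when converting fitted profile weights back into molecule
    fractions).
    """

    bin_edges: np.ndarray
    density: np.ndarray
    n_total: int
    retention: float = 1.0
    n_excluded_margin: int = 0

    @property
    def bin_width(self) -> np.ndarray:
        return np.diff(self.bin_edges)

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def is_empty(self) -> bool:
        return self.n_total == 0

    def check_normalized(self, atol: float = 1e-9) -> bool:
        return bool(abs(float(np.sum(self.density * self.bin_width)) - 1.0) < atol)


def theoretical_cytosol_profile(
    geom: CellGeometry = CellGeometry(), n_b: int = N_BINS_DEFAULT
) -> RadialProfile:
    """Short-axis profile of a uniform cytosol distribution (cylindrical part).

    Projecting a uniform disc of unit radius onto one axis gives density
    proportional to the chord length sqrt(1 - u^2); bins integrate this
    exactly and the result is unit-normalized.
    """
    if n_b < 2:
        raise ValueError("n_b must be >= 2")
    edges = np.linspace(-1.0, 1.0, n_b + 1)

    def antider(u: np.ndarray) -> np.ndarray:
        # integral of sqrt(1-u^2)
        return 0.5 * (u * np.sqrt(np.maximum(1 - u**2, 0.0)) + np.arcsin(np.clip(u, -1, 1)))

    mass = antider(edges[1:]) - antider(edges[:-1])
    density = mass / mass.sum() / np.diff(edges)
    return RadialProfile(bin_edges=edges, density=density, n_total=0, retention=1.0)


def sample_cytosol_uniform(
    n: int, geom: CellGeometry = CellGeometry(), rng: np.random.Generator | None = None,
    cylindrical_only: bool = False,
) -> np.ndarray:
    """Uniform random 3D points in the cytosol (rejection from bounding box)."""
    rng = np.random.default_rng(rng)
    R, L = geom.cylinder_radius, geom.cylinder_length
    half_len = L / 2.0 if cylindrical_only else geom.total_length / 2.0
    out = np.empty((0, 3))
    while len(out) < n:
        m = max(2 * (n - len(out)), 1000)
        cand = rng.uniform(
            low=[-half_len, -R, -R], high=[half_len, R, R], size=(m, 3)
        )
        d = axial_distance(cand, geom)
        keep = d < R
        if cylindrical_only:
            keep &= np.abs(cand[:, 0]) <= L / 2.0
        out = np.vstack([out, cand[keep]])
    return out[:n]


def sample_membrane_shell(
    n: int, geom: CellGeometry = CellGeometry(), rng: np.random.Generator | None = None,
    cylindrical_only: bool = True,
) -> np.ndarray:
    """Uniform random 3D points in the membrane shell volume.

    By default restricted to the cylindrical part (radial profiles exclude
    the poles anyway); radius^2 is uniform between the inner and outer
    boundaries so the shell volume is sampled uniformly.
    """
    rng = np.random.default_rng(rng)
    r_in, r_out = geom.cylinder_radius, geom.outer_radius
    if cylindrical_only:
        x = rng.uniform(-geom.cylinder_length / 2.0, geom.cylinder_length / 2.0, n)
        rho = np.sqrt(rng.uniform(r_in**2, r_out**2, n))
        phi = rng.uniform(0.0, 2.0 * np.pi, n)
        return np.column_stack([x, rho * np.sin(phi), rho * np.cos(phi)])
    out = np.empty((0, 3))
    half_len = geom.outer_total_length / 2.0
    while len(out) < n:
        m = max(2 * (n - len(out)), 1000)
        cand = rng.uniform(
            low=[-half_len, -r_out, -r_out], high=[half_len, r_out, r_out], size=(m, 3)
        )
        d = axial_distance(cand, geom)
        out = np.vstack([out, cand[(d >= r_in) & (d <= r_out)]])
    return out[:n]
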