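"""Stroboscopic widefield movie rendering from ground-truth trajectories.

Emitters are rendered as 2D Gaussians whose width grows with defocus,
sigma(z) = sigma0 * sqrt(1 + (z/z_R)^2); the 1.5 ms laser pulse inside each
20 ms camera frame is short enough that motion blur is negligible and each
exposure is represented by a single position sample.  The camera model is
Poisson photon statistics times gain plus Gaussian read noise.  Emitters
photobleach irreversibly with geometric lifetimes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .geometry import CellGeometry, CellPose
from .tracks import Track


@dataclass(frozen=True)
class OpticsModel:
    psf_sigma0: float = 0.11  # in-focus Gaussian PSF std, µm
    z_depth: float = 0.40  # defocus depth scale z_R, µm
    pixel_size: float = 0.08  # µm/px (16 µm EMCCD px / 100x / 2.0x adapter)
    photons_per_exposure: float = 200.0
    background: float = 10.0  # photons per pixel per frame
    camera_gain: float = 1.0
    read_noise: float = 1.0  # photons rms

    def __post_init__(self) -> None:
        for name in ("psf_sigma0", "z_depth", "pixel_size", "photons_per_exposure",
                     "camera_gain"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.background < 0 or self.read_noise < 0:
            raise ValueError("background and read_noise must be >= 0")

    def sigma_at(self, z: float | np.ndarray) -> float | np.ndarray:
        return self.psf_sigma0 * np.sqrt(1.0 + (np.asarray(z) / self.z_depth) ** 2)


@dataclass(frozen=True)
class IlluminationModel:
    exposure: float = 0.0015  # laser pulse, s
    frame_interval: float = 0.020  # camera frame, s
    bleach_mean_frames: float = 40.0

    def __post_init__(self) -> None:
        if self.exposure > self.frame_interval:
            raise ValueError("exposure must not exceed the frame interval")


@dataclass
class FrameStack:
    frames: np.ndarray  # (T, H, W) photon counts (after gain)
    frame_interval: float
    pixel_size: float
    origin: tuple[float, float]  # µm position of pixel (0, 0) center (x, y)
    mask: np.ndarray | None = None  # per-cell label image

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def to_pixels(self, xy_um: np.ndarray) -> np.ndarray:
        """Lab µm -> fractional pixel coordinates (col, row)."""
        xy = np.atleast_2d(xy_um)
        return (xy - np.asarray(self.origin)) / self.pixel_size


def default_fov(
    geom: CellGeometry = CellGeometry(), optics: OpticsModel = OpticsModel(),
    pad_um: float = 0.8,
) -> tuple[tuple[int, int], tuple[float, float]]:
    """Image shape (H, W) and origin for a single cell centered in the FOV."""
    w_um = geom.outer_total_length + 2 * pad_um
    h_um = 2 * geom.outer_radius + 2 * pad_um
    W = int(np.ceil(w_um / optics.pixel_size))
    H = int(np.ceil(h_um / optics.pixel_size))
    origin = (-W / 2.0 * optics.pixel_size, -H / 2.0 * optics.pixel_size)
    return (H, W), origin


def _add_gaussian(img: np.ndarray, col: float, row: float, sigma_px: float,
                  amplitude: float) -> None:
    """Accumulate an integrated 2D Gaussian of total ``amplitude`` photons."""
    H, W = img.shape
    half = max(int(np.ceil(6 * sigma_px)), 3)
    c0, c1 = int(np.floor(col)) - half, int(np.floor(col)) + half + 1
    r0, r1 = int(np.floor(row)) - half, int(np.floor(row)) + half + 1
    c0c, c1c = max(c0, 0), min(c1, W)
    r0c, r1c = max(r0, 0), min(r1, H)
    if c0c >= c1c or r0c >= r1c:
        return  # outside the field of view: contributes nothing
    cols = np.arange(c0c, c1c)
    rows = np.arange(r0c, r1c)
    gx = np.exp(-0.5 * ((cols - col) / sigma_px) ** 2)
    gy = np.exp(-0.5 * ((rows - row) / sigma_px) ** 2)
    norm = amplitude / (2 * np.pi * sigma_px**2)
    img[r0c:r1c, c0c:c1c] += norm * gy[:, None] * gx[None, :]


def render_movie(
    tracks: Sequence[Track],
    optics: OpticsModel = OpticsModel(),
    illum: IlluminationModel = IlluminationModel(),
    seed: int | np.random.Generator = 0,
    shape: tuple[int, int] | None = None,
    origin: tuple[float, float] | None = None,
    n_frames: int | None = None,
    geom: CellGeometry = CellGeometry(),
    apply_bleaching: bool = True,
    noise: bool = True,
) -> FrameStack:
    """Render tracks (with true z when available) into a photon-count stack.

    Each track's emitter is active from its first frame until it bleaches
    (geometric lifetime) or the track ends; each active frame adds an
    expected-photon Gaussian; pixel values are Poisson draws of the expected
    image times gain plus read noise.
    """
    rng = np.random.default_rng(seed)
    if shape is None or origin is None:
        shape, origin = default_fov(geom, optics)
    if n_frames is None:
        n_frames = int(max(t.frames.max() for t in tracks)) + 1 if tracks else 1
    H, W = shape
    expected = np.full((n_frames, H, W), float(optics.background))
    for t in tracks:
        if apply_bleaching:
            lifetime = int(rng.geometric(1.0 / illum.bleach_mean_frames))
        else:
            lifetime = len(t)
        z = t.true_z if t.true_z is not None else np.zeros(len(t))
        for i in range(min(lifetime, len(t))):
            fr = int(t.frames[i])
            if fr >= n_frames:
                break
            col, row = (
                (t.positions[i, 0] - origin[0]) / optics.pixel_size,
                (t.positions[i, 1] - origin[1]) / optics.pixel_size,
            )
            sigma_px = float(optics.sigma_at(z[i])) / optics.pixel_size
            _add_gaussian(expected[fr], col, row, sigma_px, optics.photons_per_exposure)
    if noise:
        frames = rng.poisson(expected).astype(float) * optics.camera_gain
        if optics.read_noise > 0:
            frames += rng.normal(0.0, optics.read_noise * optics.camera_gain,
                                 frames.shape)
    else:
        frames = expected * optics.camera_gain  # expected image, no camera noise
    return FrameStack(
        frames=frames, frame_interval=illum.frame_interval,
        pixel_size=optics.pixel_size, origin=origin,
    )


def make_masks(
    geom: CellGeometry = CellGeometry(),
    cell_poses: Sequence[CellPose] = (CellPose(),),
    optics: OpticsModel = OpticsModel(),
    shape: tuple[int, int] | None = None,
    origin: tuple[float, float] | None = None,
    erosion_um: float = 0.24,
) -> np.ndarray:
    """Rasterized per-cell label masks: outer envelope projections,
    hole-filled, then eroded by ``erosion_um`` (240 nm default, 3 px at the
    default pixel size)."""
    from scipy.ndimage import binary_erosion, binary_fill_holes

    if shape is None or origin is None:
        shape, origin = default_fov(geom, optics)
    H, W = shape
    yy, xx = np.meshgrid(
        origin[1] + (np.arange(H) + 0.0) * optics.pixel_size,
        origin[0] + (np.arange(W) + 0.0) * optics.pixel_size,
        indexing="ij",
    )
    labels = np.zeros(shape, dtype=int)
    n_err = int(round(erosion_um / optics.pixel_size))
    selem = None
    if n_err > 0:
        r = n_err
        dy, dx = np.meshgrid(np.arange(-r, r + 1), np.arange(-r, r + 1), indexing="ij")
        selem = (dx**2 + dy**2) <= r**2
    for i, pose in enumerate(cell_poses, start=1):
        rel_x = (xx - pose.center[0]) * np.cos(pose.angle) + (yy - pose.center[1]) * np.sin(pose.angle)
        rel_y = -(xx - pose.center[0]) * np.sin(pose.angle) + (yy - pose.center[1]) * np.cos(pose.angle)
        half = geom.cylinder_length / 2.0
        ax = np.clip(rel_x, -half, half)
        d2d = np.sqrt((rel_x - ax) ** 2 + rel_y**2)
        cell = d2d <= geom.outer_radius
        cell = binary_fill_holes(cell)
        if selem is not None:
            cell = binary_erosion(cell, structure=selem)
        labels[cell] = i
    return labels
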