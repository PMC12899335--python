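"""Pinhole camera and procedural sky for image-plane trajectory encoding.

A fixed, upward-looking ideal pinhole camera (no distortion, no rolling
shutter) projects world points through the calibration matrix
``K = [[f_x, s, c_x], [0, f_y, c_y], [0, 0, 1]]``.  The focal length in
pixels follows from the field of view as ``f = (N_px/2) / tan(FOV/2)``,
and an object of physical size ``L`` at depth ``Z`` spans about
``f * L / Z`` pixels -- the few-pixel regime that motivates
trajectory-based classification in the first place.

The procedural background is a vertical sky gradient (zenith colour at
row 0, horizon colour at the bottom row) overlaid with semi-transparent
clouds: a sum of Gaussian blobs whose centres drift sinusoidally in
time, normalised to [0, 1], attenuated linearly toward the horizon row
and alpha-blended with a constant cloud colour.

Image convention: y = 0 at the top, pixel centres at integer
coordinates, colours float in [0, 255] quantised on write.  The
classifier consumes 3-D world tracks by default; the image-plane
encoding produced here is an alternative input channel.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CameraModel",
    "CloudBlob",
    "SkyConfig",
    "focal_from_fov",
    "project",
    "apparent_size",
    "render_frame",
    "encode_image_plane_track",
    "random_sky",
    "write_png",
]


def focal_from_fov(fov: float, n_px: int) -> float:
    """Focal length in pixels from a field of view (rad) and sensor size."""
    if not (0.0 < fov < math.pi):
        raise ValueError("FOV must lie in (0, pi)")
    return (n_px / 2.0) / math.tan(fov / 2.0)


@dataclass
class CameraModel:
    """Intrinsics of the fixed, upward-looking pinhole camera."""

    fx: float
    fy: float
    cx: float
    cy: float
    width: int
    height: int
    skew: float = 0.0

    def __post_init__(self) -> None:
        if self.fx <= 0 or self.fy <= 0:
            raise ValueError("focal lengths must be positive")
        if not (0 <= self.cx < self.width and 0 <= self.cy < self.height):
            raise ValueError("principal point must lie inside the image")

    @classmethod
    def from_fov(cls, fov: float, width: int, height: int) -> "CameraModel":
        """Square-pixel camera with the focal length set from the
        horizontal field of view and the principal point centred."""
        f = focal_from_fov(fov, width)
        return cls(fx=f, fy=f, cx=width / 2.0, cy=height / 2.0,
                   width=width, height=height)


def project(cam: CameraModel, x_world: np.ndarray) -> tuple[float, float, float] | None:
    """Project a world point; returns ``(u, v, depth)`` or ``None``.

    The optical axis is world +z (camera looking straight up), so the
    depth is the point's altitude; points at or below the camera plane
    (depth <= 0) are behind the camera and yield ``None``.
    """
    x, y, z = (float(c) for c in np.asarray(x_world, dtype=float))
    if z <= 0:
        return None
    u = cam.fx * x / z + cam.skew * y / z + cam.cx
    v = cam.fy * y / z + cam.cy
    return u, v, z


def apparent_size(cam: CameraModel, l_phys: float, depth: float) -> float:
    """On-sensor extent in pixels of an object of size ``l_phys`` at ``depth``."""
    if depth <= 0:
        raise ValueError("depth must be positive")
    return cam.fx * l_phys / depth


# ---------------------------------------------------------------------------
# sky background
# ---------------------------------------------------------------------------


@dataclass
class CloudBlob:
    """One Gaussian cloud blob with sinusoidal centre drift."""

    center: tuple[float, float]          # (x, y) pixels at t = 0
    radius: float                        # Gaussian sigma, pixels
    drift_amp: tuple[float, float] = (0.0, 0.0)   # pixels
    drift_freq: tuple[float, float] = (0.0, 0.0)  # rad/s
    phase: tuple[float, float] = (0.0, 0.0)


@dataclass
class SkyConfig:
    """Colours and cloud field of the procedural sky."""

    c_top: tuple[float, float, float] = (25.0, 60.0, 160.0)
    c_bottom: tuple[float, float, float] = (195.0, 215.0, 240.0)
    c_cloud: tuple[float, float, float] = (245.0, 245.0, 245.0)
    alpha_cloud: float = 0.55
    blobs: list[CloudBlob] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (0.0 <= self.alpha_cloud <= 1.0):
            raise ValueError("alpha_cloud must lie in [0, 1]")
        for c in (self.c_top, self.c_bottom, self.c_cloud):
            if any(not (0.0 <= v <= 255.0) for v in c):
                raise ValueError("colours must lie in [0, 255]")


def random_sky(rng: np.random.Generator, width: int, height: int,
               n_blobs: int = 6) -> SkyConfig:
    """A SkyConfig with randomly placed, slowly drifting cloud blobs."""
    blobs = [
        CloudBlob(
            center=(rng.uniform(0, width), rng.uniform(0, 0.7 * height)),
            radius=rng.uniform(0.05, 0.2) * width,
            drift_amp=(rng.uniform(5, 25), rng.uniform(2, 8)),
            drift_freq=(rng.uniform(0.02, 0.1), rng.uniform(0.02, 0.1)),
            phase=(rng.uniform(0, 2 * math.pi), rng.uniform(0, 2 * math.pi)),
        )
        for _ in range(n_blobs)
    ]
    return SkyConfig(blobs=blobs)


def _cloud_mask(sky: SkyConfig, t: float, width: int, height: int) -> np.ndarray:
    """Normalised, horizon-attenuated cloud opacity mask in [0, 1]."""
    if not sky.blobs:
        return np.zeros((height, width))
    yy, xx = np.mgrid[0:height, 0:width]
    m = np.zeros((height, width))
    for b in sky.blobs:
        cx = b.center[0] + b.drift_amp[0] * math.sin(b.drift_freq[0] * t + b.phase[0])
        cy = b.center[1] + b.drift_amp[1] * math.sin(b.drift_freq[1] * t + b.phase[1])
        m += np.exp(-((xx - cx) ** 2 + (yy - cy) ** 2) / (2.0 * b.radius**2))
    peak = m.max()
    if peak > 0:
        m /= peak
    # thinner clouds toward the horizon (bottom row)
    if height > 1:
        m *= (1.0 - yy / (height - 1))
    return np.clip(m, 0.0, 1.0)


def render_frame(
    cam: CameraModel,
    sky: SkyConfig,
    t: float,
    targets: list[tuple[np.ndarray, float]] | None = None,
    target_color: tuple[float, float, float] = (30.0, 30.0, 30.0),
) -> np.ndarray:
    """Render one frame as an (H, W, 3) float array in [0, 255].

    The sky gradient interpolates the zenith colour at row 0 to the
    horizon colour at the bottom row; clouds are alpha-blended with the
    opacity mask; each target ``(world position, physical size)`` is
    drawn as a filled disc at its projected position with its apparent
    size (minimum one pixel).  Deterministic given (config, t).
    """
    H, W = cam.height, cam.width
    alpha = (np.arange(H) / (H - 1))[:, None] if H > 1 else np.zeros((1, 1))
    c_top = np.asarray(sky.c_top)
    c_bottom = np.asarray(sky.c_bottom)
    img = (1.0 - alpha)[..., None] * c_top + alpha[..., None] * c_bottom
    img = np.broadcast_to(img, (H, W, 3)).copy()

    m = sky.alpha_cloud * _cloud_mask(sky, t, W, H)
    img = (1.0 - m)[..., None] * img + m[..., None] * np.asarray(sky.c_cloud)

    if targets:
        yy, xx = np.mgrid[0:H, 0:W]
        for pos, size in targets:
            pr = project(cam, pos)
            if pr is None:
                continue
            u, v, depth = pr
            r = max(apparent_size(cam, size, depth) / 2.0, 0.5)
            disc = (xx - u) ** 2 + (yy - v) ** 2 <= r * r
            img[disc] = target_color
    return np.clip(img, 0.0, 255.0)


def encode_image_plane_track(cam: CameraModel, record, l_phys: float) -> np.ndarray:
    """Encode a trajectory as per-frame ``(u, v, apparent size)``.

    Returns an (N, 3) array; frames whose position is behind the camera
    are marked with NaN in all three channels.
    """
    out = np.full((len(record.positions), 3), np.nan)
    for i, pos in enumerate(record.positions):
        pr = project(cam, pos)
        if pr is None:
            continue
        u, v, depth = pr
        out[i] = (u, v, apparent_size(cam, l_phys, depth))
    return out


def write_png(img: np.ndarray, path) -> None:
    """Quantise a float [0, 255] image to 8 bit and write a PNG."""
    from PIL import Image

    arr = np.clip(np.asarray(img), 0.0, 255.0).astype(np.uint8)
    Image.fromarray(arr).save(path)
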