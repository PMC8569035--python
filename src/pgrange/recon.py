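"""List-mode simple back-projection of Compton cones onto the image plane.

Each selected event defines a cone: apex at the Si scatter position,
axis pointing from the CdTe absorber hit through the apex toward the
source side, half-angle from the measured energy pair.  The image is
the accumulation of every event's cone intersected with the z = 0 plane
that contains the beam axis (2-D reconstruction, matching the planar
beam-trail images this method is used for).  No iterative deconvolution
is applied.
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass

import numpy as np

from .events import ComptonEvent
from .kinematics import (
    EnergyPair,
    FWHM_TO_SIGMA,
    compute_cos_theta,
    is_kinematically_valid,
)

log = logging.getLogger(__name__)


class Kernel(enum.Enum):
    """Cone-shell weighting used when a cone is painted onto the plane."""

    GAUSSIAN_ARM = "GAUSSIAN_ARM"   # Gaussian in angular residual, ARM-width
    HARD_SHELL = "HARD_SHELL"       # unweighted shell of fixed angular width


@dataclass(frozen=True)
class ImageGrid:
    """Pixel raster on the z = 0 image plane (mm; extents are pixel multiples)."""

    x_min: float
    x_max: float
    y_min: float
    y_max: float
    pixel: float = 1.0

    def __post_init__(self) -> None:
        if self.pixel <= 0:
            raise ValueError("pixel size must be positive")
        for lo, hi in ((self.x_min, self.x_max), (self.y_min, self.y_max)):
            n = (hi - lo) / self.pixel
            if hi <= lo or abs(n - round(n)) > 1e-9:
                raise ValueError("grid extents must be positive multiples of pixel")

    @classmethod
    def centered(cls, cx: float, cy: float = 0.0, side: float = 200.0,
                 pixel: float = 1.0) -> "ImageGrid":
        """Square field of view of ``side`` mm centred at (cx, cy)."""
        h = side / 2.0
        return cls(cx - h, cx + h, cy - h, cy + h, pixel)

    @property
    def nx(self) -> int:
        return round((self.x_max - self.x_min) / self.pixel)

    @property
    def ny(self) -> int:
        return round((self.y_max - self.y_min) / self.pixel)

    @property
    def x_centers(self) -> np.ndarray:
        return self.x_min + self.pixel * (np.arange(self.nx) + 0.5)

    @property
    def y_centers(self) -> np.ndarray:
        return self.y_min + self.pixel * (np.arange(self.ny) + 0.5)


@dataclass
class BackprojectionParams:
    """Kernel choice and widths for cone painting."""

    kernel: Kernel = Kernel.GAUSSIAN_ARM
    arm_fwhm: float = 5.4            # degrees FWHM, instrument angular resolution
    shell_halfwidth: float = 2.7     # degrees, HARD_SHELL half-width
    per_event_normalization: bool = True

    def __post_init__(self) -> None:
        if self.arm_fwhm <= 0 or self.shell_halfwidth <= 0:
            raise ValueError("kernel widths must be positive")


@dataclass
class ComptonImage:
    """Accumulated back-projection intensity in one energy window."""

    grid: ImageGrid
    values: np.ndarray               # shape (ny, nx), finite, >= 0
    window_label: str = ""
    n_events: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.grid.ny, self.grid.nx):
            raise ValueError("image shape does not match grid")
        if not np.all(np.isfinite(self.values)) or np.any(self.values < 0):
            raise ValueError("image values must be finite and non-negative")


def cone_from_event(ev: ComptonEvent):
    """Compton cone (apex mm, unit axis, half-angle radians) of one event.

    The axis points from the absorber hit toward the scatter hit and
    onward to the source side; the half-angle comes from the measured
    energy pair.
    """
    pair = EnergyPair(ev.scatter_hit.energy, ev.absorb_hit.energy)
    if not is_kinematically_valid(pair):
        raise ValueError(f"event {ev.event_id}: energies are kinematically invalid")
    apex = np.asarray(ev.scatter_hit.position, dtype=float)
    axis = apex - np.asarray(ev.absorb_hit.position, dtype=float)
    norm = np.linalg.norm(axis)
    if norm == 0:
        raise ValueError(f"event {ev.event_id}: coincident hit positions")
    axis /= norm
    half_angle = math.acos(min(1.0, max(-1.0, compute_cos_theta(pair))))
    return apex, axis, half_angle


def backproject(events, grid: ImageGrid, params: BackprojectionParams | None = None,
                window_label: str = "") -> ComptonImage:
    """Accumulate every event's cone onto the image grid.

    For each pixel centre p the angular residual alpha(p) - theta between
    the apex-to-pixel direction and the cone axis is weighted by the
    kernel (Gaussian of ARM width, or a hard shell); with per-event
    normalization each cone deposits unit total mass.  Kinematically
    invalid events are skipped with a logged count.
    """
    params = params or BackprojectionParams()
    xs, ys = np.meshgrid(grid.x_centers, grid.y_centers)
    px = np.column_stack([xs.ravel(), ys.ravel(), np.zeros(xs.size)])
    values = np.zeros(xs.size)
    sigma = math.radians(params.arm_fwhm) * FWHM_TO_SIGMA
    halfwidth = math.radians(params.shell_halfwidth)

    n_used = 0
    n_skipped = 0
    for ev in events:
        try:
            apex, axis, theta = cone_from_event(ev)
        except ValueError:
            n_skipped += 1
            continue
        v = px - apex
        vn = np.linalg.norm(v, axis=1)
        cos_a = np.clip(v @ axis / np.where(vn == 0, np.inf, vn), -1.0, 1.0)
        resid = np.arccos(cos_a) - theta
        if params.kernel is Kernel.GAUSSIAN_ARM:
            w = np.exp(-0.5 * (resid / sigma) ** 2)
        else:
            w = (np.abs(resid) <= halfwidth).astype(float)
        if params.per_event_normalization:
            total = w.sum()
            if total > 0:
                w = w / total
        values += w
        n_used += 1
    if n_skipped:
        log.warning("skipped %d kinematically invalid events", n_skipped)
    return ComptonImage(grid=grid, values=values.reshape(grid.ny, grid.nx),
                        window_label=window_label, n_events=n_used)
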