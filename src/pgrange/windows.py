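"""Dual- and triple-energy-window scatter correction of Compton images.

High-energy secondaries that scatter in both detector stacks leak into
the photopeak window and paint artifacts over the image.  As in SPECT
practice, the contamination under the photopeak is estimated from
back-projection images of adjacent energy windows and subtracted pixel
by pixel: DEW subtracts a width-scaled upper-side window image, TEW the
average of lower- and upper-side images.  Negative pixels are clipped
to zero -- negative intensity has no meaning downstream, and corrected
surroundings are expected to sit near zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .events import EnergyWindow
from .recon import ComptonImage


def _default_lower() -> EnergyWindow:
    return EnergyWindow("680", 670.0, 690.0)


def _default_main() -> EnergyWindow:
    return EnergyWindow("718", 708.0, 728.0)


def _default_upper() -> EnergyWindow:
    return EnergyWindow("760", 750.0, 770.0)


@dataclass(frozen=True)
class WindowTriplet:
    """Lower / main / upper photopeak-adjacent windows (keV)."""

    lower: EnergyWindow = field(default_factory=_default_lower)
    main: EnergyWindow = field(default_factory=_default_main)
    upper: EnergyWindow = field(default_factory=_default_upper)

    def __post_init__(self) -> None:
        if not (self.lower.hi < self.main.lo and self.main.hi < self.upper.lo):
            raise ValueError("windows must be disjoint and ordered lower < main < upper")


def _check_grids(*images: ComptonImage) -> None:
    grids = {im.grid for im in images}
    if len(grids) > 1:
        raise ValueError("scatter correction requires identical image grids")


def dew_image(main_img: ComptonImage, upper_img: ComptonImage,
              k: float | None = None, windows: WindowTriplet | None = None) -> ComptonImage:
    """Dual-energy-window corrected image: clip(main - k * upper, 0).

    ``k`` defaults to the main/upper window-width ratio (1 for the
    standard 20 keV windows); pass ``windows`` to derive it, or ``k``
    directly.
    """
    _check_grids(main_img, upper_img)
    if k is None:
        w = windows or WindowTriplet()
        k = w.main.width / w.upper.width
    values = np.clip(main_img.values - k * upper_img.values, 0.0, None)
    return ComptonImage(grid=main_img.grid, values=values, window_label="DEW",
                        n_events=main_img.n_events)


def tew_image(main_img: ComptonImage, lower_img: ComptonImage,
              upper_img: ComptonImage, windows: WindowTriplet | None = None) -> ComptonImage:
    """Triple-energy-window corrected image.

    Per pixel: clip(main - (lower * w_m/(2 w_l) + upper * w_m/(2 w_u)), 0);
    with equal window widths this is main - (lower + upper)/2.
    """
    _check_grids(main_img, lower_img, upper_img)
    w = windows or WindowTriplet()
    est = (lower_img.values * w.main.width / (2.0 * w.lower.width)
           + upper_img.values * w.main.width / (2.0 * w.upper.width))
    values = np.clip(main_img.values - est, 0.0, None)
    return ComptonImage(grid=main_img.grid, values=values, window_label="TEW",
                        n_events=main_img.n_events)
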