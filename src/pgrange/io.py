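"""Image and metadata output: float TIFF, plain-text matrix, YAML sidecar."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import tifffile
import yaml

from .recon import ComptonImage, ImageGrid


def save_image(img: ComptonImage, basepath, text: bool = True) -> list[Path]:
    """Write ``<base>.tif`` (32-bit float), optional ``<base>.txt`` matrix,
    and a ``<base>.meta.yaml`` sidecar; returns the written paths."""
    base = Path(basepath)
    base.parent.mkdir(parents=True, exist_ok=True)
    written = []
    tif = base.with_suffix(".tif")
    tifffile.imwrite(tif, img.values.astype(np.float32))
    written.append(tif)
    if text:
        txt = base.with_suffix(".txt")
        np.savetxt(txt, img.values, fmt="%.8g")
        written.append(txt)
    meta = base.with_suffix(".meta.yaml")
    with open(meta, "w") as fh:
        yaml.safe_dump(
            {
                "window_label": img.window_label,
                "n_events": int(img.n_events),
                "grid": {
                    "x_min": img.grid.x_min, "x_max": img.grid.x_max,
                    "y_min": img.grid.y_min, "y_max": img.grid.y_max,
                    "pixel": img.grid.pixel,
                },
            },
            fh, sort_keys=False,
        )
    written.append(meta)
    return written


def load_image(basepath) -> ComptonImage:
    """Read an image written by :func:`save_image` (TIFF + sidecar)."""
    base = Path(basepath)
    with open(base.with_suffix(".meta.yaml")) as fh:
        meta = yaml.safe_load(fh)
    grid = ImageGrid(**meta["grid"])
    values = tifffile.imread(base.with_suffix(".tif")).astype(float)
    return ComptonImage(grid=grid, values=values,
                        window_label=meta["window_label"],
                        n_events=meta["n_events"])
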