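"""Pseudo-color rendering of lifetime maps and phasor-density plots.

Mean lifetimes are mapped onto a piecewise-linear blue -> green -> red ramp
over a display range of 500-3500 ps by default (blue at the short end, red at
the long end), clamped at the edges; masked pixels render black.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
from PIL import Image

from .exceptions import ConfigurationError
from .fitting import LifetimeImage
from .phasor import PhasorMap, single_exp_phasor

__all__ = ["render_lifetime_image", "save_rgb", "phasor_density_plot"]

DEFAULT_RANGE_PS = (500.0, 3500.0)


def _bgr_ramp(frac: np.ndarray) -> np.ndarray:
    """Piecewise-linear blue->green->red lookup; frac in [0, 1] -> RGB floats."""
    frac = np.clip(frac, 0.0, 1.0)
    r = np.clip(2.0 * frac - 1.0, 0.0, 1.0)
    b = np.clip(1.0 - 2.0 * frac, 0.0, 1.0)
    g = 1.0 - r - b
    return np.stack([r, g, b], axis=-1)


def render_lifetime_image(
    image: LifetimeImage,
    range_ps: tuple[float, float] = DEFAULT_RANGE_PS,
    intensity_weighted: bool = False,
) -> np.ndarray:
    """Render a tau_m map as an RGB uint8 image.

    tau_m values are mapped linearly from blue (range low) through green
    (midpoint) to red (range high), clamped at the edges; masked-out pixels
    are black.  With ``intensity_weighted`` the brightness of each pixel is
    scaled by its photon count relative to the image maximum.
    """
    lo, hi = range_ps
    if not lo < hi:
        raise ConfigurationError("display range low must be < high")
    frac = (image.tau_m_map - lo) / (hi - lo)
    rgb = _bgr_ramp(np.nan_to_num(frac, nan=0.0))
    if intensity_weighted:
        imax = image.intensity_map.max()
        if imax > 0:
            rgb = rgb * (image.intensity_map / imax)[..., None]
    rgb[~image.mask] = 0.0
    return (rgb * 255.0 + 0.5).astype(np.uint8)


def save_rgb(rgb: np.ndarray, path: str | Path) -> Path:
    """Save an RGB uint8 array as PNG."""
    path = Path(path)
    Image.fromarray(rgb, mode="RGB").save(path)
    return path


def phasor_density_plot(
    pmap: PhasorMap, path: str | Path, bins: int = 200
) -> Path:
    """2-D phasor-density histogram with the universal semicircle overlaid."""
    pts = pmap.masked_points()
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.hist2d(
        pts[:, 0], pts[:, 1], bins=bins, range=[[0, 1], [0, 0.7]], cmap="inferno",
        cmin=1,
    )
    taus = np.logspace(1, 5, 400)  # ps
    circle = np.array(
        [single_exp_phasor(t, pmap.harmonic, pmap.angular_frequency) for t in taus]
    )
    ax.plot(circle[:, 0], circle[:, 1], "w--", lw=0.8)
    ax.set_xlabel("G")
    ax.set_ylabel("S")
    ax.set_xlim(0, 1)
    ax.set_ylim(0, 0.7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)
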