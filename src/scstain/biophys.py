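"""Optical density and intensity normalization.

The optical density of a transmitted-light stain image,

    OD(Y) = -(1/3) * sum_{c in R,G,B} log10(Y_c),

is a grayscale proxy for stain density: myelin-dense (dark) tissue has
high OD, exactly as it has a high scattering coefficient.  That shared
contrast is what makes OD-stain pairs usable as pixel-aligned pseudo
supervision for the SC-to-stain translator.  Both OD maps and SC maps
are histogram-equalized over their foreground before entering the
network so their intensity distributions line up.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import exposure

#: clamp for zero pixels; OD is undefined at exact zero transmittance
DEFAULT_EPSILON = 1.0 / 65535.0


@dataclass
class OpticalDensityMap:
    od: np.ndarray
    source: str = ""


def optical_density(y, epsilon=DEFAULT_EPSILON) -> OpticalDensityMap:
    """Per-pixel optical density of an RGB stain image with values in [0, 1]."""
    y = np.asarray(y, dtype=np.float64)
    if y.ndim != 3 or y.shape[-1] < 3:
        raise ValueError("optical_density expects an (H, W, >=3) RGB image")
    clamped = np.maximum(y[..., :3], epsilon)
    od = -np.log10(clamped).sum(axis=-1) / 3.0
    return OpticalDensityMap(od=od, source="rgb")


def hist_equalize(img, mask=None, nbins=256):
    """Histogram-equalize a single-channel image to [0, 1].

    The CDF is computed over ``mask`` only (default: the nonzero
    foreground, since background in both SC and OD maps is exactly
    zero), but the monotone mapping is applied to every pixel, so rank
    order is preserved.  Background pixels are returned as 0.  A
    constant image maps to the all-0.5 convention.
    """
    img = np.asarray(img, dtype=np.float64)
    if not np.all(np.isfinite(img)):
        raise ValueError("image must be finite")
    if img.max() == img.min():
        return np.full_like(img, 0.5)
    if mask is None:
        mask = img > 0
        if not mask.any() or img[mask].max() == img[mask].min():
            mask = np.ones_like(img, dtype=bool)
    out = exposure.equalize_hist(img, nbins=nbins, mask=mask)
    out = np.clip(out, 0.0, 1.0)
    out[~mask] = 0.0
    return out
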