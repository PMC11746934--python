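"""Slice-wise digital-staining inference and volume assembly.

A trained translator stains each scattering-coefficient slice
independently; slices are then stacked directly along z (no inter-slice
registration).  For 3-D visualization the white background is blackened
via a triangle threshold on grayscale, white matter is segmented with
the classical minimum-method histogram threshold, and per-axis
maximum-intensity projections expose continuous vessel structures.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import filters, morphology

from .biophys import hist_equalize
from .preprocess import ForegroundMask, _remove_small, foreground_from_triangle
from .tiling import split, stitch

#: standard luminance weights for grayscale conversion
LUMINANCE = np.array([0.2126, 0.7152, 0.0722])


@dataclass
class StainVolume:
    slices: list                      # z-ordered list of (H, W, 3) arrays
    spacing_um: float = 150.0
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.slices:
            raise ValueError("empty volume")
        if self.spacing_um <= 0:
            raise ValueError("slice spacing must be positive")
        shapes = {s.shape for s in self.slices}
        if len(shapes) != 1:
            raise ValueError("all slices must share one shape")

    def as_array(self):
        return np.stack(self.slices)


def gray(ds):
    return np.asarray(ds, dtype=np.float64) @ LUMINANCE


def stain_slice(G, x, mode="wsi", patch=256, overlap=True):
    """Digitally stain one SC map (cleaned beforehand; equalized here).

    mode "wsi" runs the fully-convolutional translator on the whole
    slide; mode "patches" splits/stitches (with half-patch overlap
    averaging by default, which suppresses seams).
    """
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 2:
        raise ValueError("stain_slice expects a single-channel SC map")
    xq = hist_equalize(x)
    if mode == "wsi":
        return np.clip(G.stain(xq), 0.0, 1.0)
    if mode != "patches":
        raise ValueError(f"unknown mode {mode!r}")
    stride = patch // 2 if overlap else patch
    patches, grid = split(xq, patch=patch, stride=stride, pad_value=0.0)
    stained = np.stack([G.stain(p) for p in patches])
    return np.clip(stitch(stained, grid), 0.0, 1.0)


def stain_volume(G, sc_slices, mode="wsi", spacing_um=150.0, provenance=None):
    """Stain a z-stack slice by slice and stack directly along z."""
    slices = [stain_slice(G, s, mode=mode) for s in sc_slices]
    prov = dict(provenance or {})
    prov.setdefault("inter_slice_registration", "none")
    return StainVolume(slices=slices, spacing_um=spacing_um, provenance=prov)


def blacken_background(ds, bright_floor=0.85):
    """Set non-tissue pixels of a stained image to black, tissue untouched.

    Background on a stained slide is the white glass, so only pixels
    that are both above the triangle threshold and brighter than
    ``bright_floor`` count as background; an all-tissue image passes
    through unchanged.
    """
    ds = np.asarray(ds, dtype=np.float64)
    g = gray(ds)
    fg = foreground_from_triangle(g, dark_foreground=True).mask
    fg |= g <= bright_floor
    fg = ndimage.binary_closing(fg, structure=morphology.disk(2).astype(bool),
                                border_value=1)
    fg = _remove_small(fg, 64)
    fg = ~_remove_small(~fg, 64)          # fill small holes
    if not fg.any():
        raise ValueError("empty foreground")
    out = ds.copy()
    out[~fg] = 0.0
    return out


def white_matter_mask(ds, foreground=None, smooth_radius=2) -> ForegroundMask:
    """Segment white matter (the darkest stain mode) on a stained image.

    Uses the minimum-method histogram threshold: the grayscale histogram
    is repeatedly smoothed until exactly two maxima remain and the
    threshold is the valley between them.  The mask is morphologically
    smoothed afterwards.
    """
    ds = np.asarray(ds, dtype=np.float64)
    g = gray(ds)
    if foreground is None:
        foreground = foreground_from_triangle(g, dark_foreground=True).mask
    vals = g[foreground]
    try:
        thr = filters.threshold_minimum(vals)
    except RuntimeError as exc:
        raise ValueError(
            "grayscale histogram stayed unimodal; cannot separate white "
            f"matter ({exc})") from exc
    mask = (g < thr) & foreground
    disk = morphology.disk(smooth_radius).astype(bool)
    mask = ndimage.binary_opening(mask, structure=disk)
    mask = ndimage.binary_closing(mask, structure=disk)
    return ForegroundMask(mask=mask, method="minimum")


def mip(vol: StainVolume, axis="z"):
    """Per-channel maximum-intensity projection along a named axis."""
    arr = vol.as_array()                       # (Z, H, W, 3)
    axes = {"z": 0, "y": 1, "x": 2, 0: 0, 1: 1, 2: 2}
    if axis not in axes:
        raise ValueError(f"invalid axis {axis!r}")
    return arr.max(axis=axes[axis])
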