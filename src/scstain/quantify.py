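"""Cortical-layer profile, contrast and thickness quantification.

Operates on any stained WSI plus layer-label masks (the phantom
provides labels natively; for real data they come from annotation
files).  Local thickness uses the classical inscribed-disc definition:
the thickness at a foreground pixel is the diameter of the largest disc
fully inside the mask that contains the pixel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage


@dataclass
class ThicknessStats:
    #: long-format samples: columns layer, roi, thickness_um
    samples: pd.DataFrame
    #: (layer, roi) -> dict(median, q1, q3, n)
    summaries: dict
    pitch_um: float


def line_profile(img, rect, axis="vertical"):
    """Mean-intensity profile across a rectangular ROI, min-max normalized.

    rect: (row0, row1, col0, col1).  axis "vertical" aggregates along
    the horizontal direction giving one value per row (the cortical
    depth profile); "horizontal" is the transpose.  Color channels are
    averaged.  A constant profile returns all zeros (documented
    convention for zero range).
    """
    img = np.asarray(img, dtype=np.float64)
    r0, r1, c0, c1 = rect
    if r1 <= r0 or c1 <= c0:
        raise ValueError("zero-area rect")
    if r0 < 0 or c0 < 0 or r1 > img.shape[0] or c1 > img.shape[1]:
        raise ValueError("rect outside image")
    roi = img[r0:r1, c0:c1]
    if roi.ndim == 3:
        roi = roi.mean(axis=-1)
    prof = roi.mean(axis=1) if axis == "vertical" else roi.mean(axis=0)
    lo, hi = prof.min(), prof.max()
    if hi == lo:
        return np.zeros_like(prof)
    return (prof - lo) / (hi - lo)


def layer_contrast(profile, band):
    """Contrast of a profile over a band: max - min inside the band."""
    profile = np.asarray(profile, dtype=np.float64)
    band = np.arange(*band) if isinstance(band, tuple) else np.asarray(band)
    if band.size == 0:
        raise ValueError("empty band")
    seg = profile[band]
    return float(seg.max() - seg.min())


def local_thickness(mask, pitch_um=1.0):
    """Inscribed-disc local thickness map of a binary mask, in microns.

    For each foreground pixel center c the distance transform gives the
    radius rho(c) = dt(c) - 1/2 of the largest disc centered there; the
    thickness at p is the largest diameter 2*rho(c) over all discs
    containing p.  Implemented by painting discs in order of decreasing
    radius (first write wins).  Zero outside the mask.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    dt = ndimage.distance_transform_edt(mask)
    thick = np.zeros(mask.shape)
    order = np.argsort(dt, axis=None)[::-1]
    h, w = mask.shape
    rows, cols = np.unravel_index(order, mask.shape)
    for r, c in zip(rows, cols):
        d = dt[r, c]
        if d <= 0:
            break
        rho = d - 0.5
        diam = 2.0 * rho
        ir = int(np.floor(rho))
        r0, r1 = max(r - ir, 0), min(r + ir + 1, h)
        c0, c1 = max(c - ir, 0), min(c + ir + 1, w)
        yy, xx = np.ogrid[r0 - r:r1 - r, c0 - c:c1 - c]
        disc = yy * yy + xx * xx <= rho * rho
        sub = thick[r0:r1, c0:c1]
        sub[disc & (sub == 0)] = diam
    thick[~mask] = 0.0
    return thick * pitch_um


def thickness_stats(thickness_um, layer_labels, roi_masks=None,
                    layers=(2, 3, 4), layer_names=None,
                    interior_only=True) -> ThicknessStats:
    """Per-layer, per-ROI thickness samples with median/quartile summaries.

    thickness_um: local-thickness map (already in microns);
    layer_labels: integer label map; roi_masks: dict name -> boolean
    mask (an "all" group over the full image is always included).
    Layers absent from an ROI yield an empty, flagged group rather than
    an error.  By default only interior pixels (one erosion) of each
    layer are sampled, so boundary discretization does not bias the
    quartiles.
    """
    thickness_um = np.asarray(thickness_um, dtype=np.float64)
    layer_labels = np.asarray(layer_labels)
    names = layer_names or {2: "IV", 3: "V", 4: "VI"}
    rois = {"all": np.ones(layer_labels.shape, dtype=bool)}
    rois.update(roi_masks or {})

    rows = []
    summaries = {}
    for lab in layers:
        layer_mask = layer_labels == lab
        if interior_only and layer_mask.any():
            layer_mask = ndimage.binary_erosion(layer_mask)
        for roi_name, roi in rois.items():
            sel = layer_mask & roi & (thickness_um > 0)
            vals = thickness_um[sel]
            key = (names.get(lab, str(lab)), roi_name)
            if vals.size == 0:
                summaries[key] = {"median": np.nan, "q1": np.nan,
                                  "q3": np.nan, "n": 0, "empty": True}
                continue
            summaries[key] = {
                "median": float(np.median(vals)),
                "q1": float(np.percentile(vals, 25)),
                "q3": float(np.percentile(vals, 75)),
                "n": int(vals.size), "empty": False,
            }
            rows.append(pd.DataFrame({
                "layer": names.get(lab, str(lab)),
                "roi": roi_name,
                "thickness_um": vals,
            }))
    samples = (pd.concat(rows, ignore_index=True) if rows
               else pd.DataFrame(columns=["layer", "roi", "thickness_um"]))
    return ThicknessStats(samples=samples, summaries=summaries, pitch_um=1.0)
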