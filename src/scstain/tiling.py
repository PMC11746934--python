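"""Deterministic WSI <-> patch conversion with exact round-trip.

Whole-slide images are padded (bottom/right) so the sliding window
covers them exactly, then cut row-major into a patch stack.  With
stride == patch the operation is invertible bit-for-bit; overlapping
strides stitch back by uniform averaging, which suppresses seam
artifacts at inference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class PatchGrid:
    wsi_shape: tuple          # original (rows, cols)
    patch: int
    stride: int
    pad: tuple                # (top, bottom, left, right)
    origins: list             # row-major window top-left coords in padded frame

    @property
    def padded_shape(self):
        return (self.wsi_shape[0] + self.pad[0] + self.pad[1],
                self.wsi_shape[1] + self.pad[2] + self.pad[3])

    def to_dict(self):
        return {"wsi_shape": list(self.wsi_shape), "patch": self.patch,
                "stride": self.stride, "pad": list(self.pad),
                "origins": [list(o) for o in self.origins]}

    @classmethod
    def from_dict(cls, d):
        return cls(wsi_shape=tuple(d["wsi_shape"]), patch=d["patch"],
                   stride=d["stride"], pad=tuple(d["pad"]),
                   origins=[tuple(o) for o in d["origins"]])


def _axis_pad(n, patch, stride):
    """Padded length so windows of ``patch`` at ``stride`` tile exactly."""
    if n <= patch:
        return patch
    n_win = int(np.ceil((n - patch) / stride)) + 1
    return (n_win - 1) * stride + patch


def split(img, patch=512, stride=None, pad_value=None):
    """Cut a WSI into a row-major patch stack; returns (patches, grid).

    ``pad_value`` defaults to the modality background: 0 for
    single-channel (SC/OD) input, 1.0 (white) for RGB input.
    """
    img = np.asarray(img)
    if patch < 32:
        raise ValueError("patch must be >= 32")
    stride = stride or patch
    if stride < 1:
        raise ValueError("stride must be >= 1")
    if pad_value is None:
        pad_value = 1.0 if img.ndim == 3 else 0.0
    h, w = img.shape[:2]
    hp = _axis_pad(h, patch, stride)
    wp = _axis_pad(w, patch, stride)
    pad = (0, hp - h, 0, wp - w)
    width = [(pad[0], pad[1]), (pad[2], pad[3])] + [(0, 0)] * (img.ndim - 2)
    padded = np.pad(img, width, mode="constant", constant_values=pad_value)
    origins = [(r, c)
               for r in range(0, hp - patch + 1, stride)
               for c in range(0, wp - patch + 1, stride)]
    patches = np.stack([padded[r:r + patch, c:c + patch] for r, c in origins])
    grid = PatchGrid(wsi_shape=(h, w), patch=patch, stride=stride,
                     pad=pad, origins=origins)
    return patches, grid


def stitch(patches, grid: PatchGrid):
    """Reassemble a patch stack; exact inverse of split when stride == patch."""
    patches = np.asarray(patches)
    if len(patches) != len(grid.origins):
        raise ValueError("patch count does not match grid")
    if patches.shape[1] != grid.patch or patches.shape[2] != grid.patch:
        raise ValueError("patch shape does not match grid")
    hp, wp = grid.padded_shape
    extra = patches.shape[3:]
    if grid.stride == grid.patch:
        out = np.zeros((hp, wp) + extra, dtype=patches.dtype)
        for (r, c), p in zip(grid.origins, patches):
            out[r:r + grid.patch, c:c + grid.patch] = p
    else:
        acc = np.zeros((hp, wp) + extra, dtype=np.float64)
        cnt = np.zeros((hp, wp) + (1,) * len(extra))
        for (r, c), p in zip(grid.origins, patches):
            acc[r:r + grid.patch, c:c + grid.patch] += p
            cnt[r:r + grid.patch, c:c + grid.patch] += 1.0
        out = (acc / np.maximum(cnt, 1.0)).astype(patches.dtype)
    h, w = grid.wsi_shape
    return out[:h, :w]
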