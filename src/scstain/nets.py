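"""Network contracts: translator G, discriminator D, projection head f,
registration network R, and the differentiable warping operator.

Profiles: "tiny" keeps the four networks under ~100k parameters total so
the full training protocol runs on one CPU in minutes; "full" is a
conventional full-size layout (6 residual blocks, 70x70-receptive-field
patch discriminator).  Displacement fields use the backward-warping
convention: the output samples the moving image at p + phi(p), so
phi registers the moving image onto the fixed one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import map_coordinates

from . import autodiff as ad
from . import nn
from .autodiff import Tensor


# ---------------------------------------------------------------------------
# warping
# ---------------------------------------------------------------------------

def warp_image(img, phi, mode="border"):
    """Backward-warp a numpy image: out(p) = img(p + phi(p)), bilinear.

    img: (H, W) or (H, W, C); phi: (2, H, W) giving (d_row, d_col) in
    pixels.  Out-of-bounds samples take the border value.
    """
    img = np.asarray(img, dtype=np.float64)
    phi = np.asarray(phi, dtype=np.float64)
    h, w = img.shape[:2]
    if phi.shape != (2, h, w):
        raise ValueError("phi must have shape (2, H, W) matching img")
    gr, gc = np.meshgrid(np.arange(h, dtype=np.float64),
                         np.arange(w, dtype=np.float64), indexing="ij")
    coords = np.stack([gr + phi[0], gc + phi[1]])
    if img.ndim == 2:
        return map_coordinates(img, coords, order=1, mode="nearest")
    return np.stack([map_coordinates(img[..., c], coords, order=1, mode="nearest")
                     for c in range(img.shape[-1])], axis=-1)


def warp(img, phi):
    """Graph-tracked warp (see :func:`scstain.autodiff.warp`).

    Accepts numpy arrays or Tensors shaped (N,C,H,W) / (N,2,H,W).
    """
    return ad.warp(ad.as_tensor(img), ad.as_tensor(phi))


def field_to_rgb(phi):
    """Visualization contract: red = vertical, green = horizontal offset."""
    phi = np.asarray(phi)
    peak = max(np.abs(phi).max(), 1e-9)
    rgb = np.zeros(phi.shape[1:] + (3,))
    rgb[..., 0] = 0.5 + 0.5 * phi[0] / peak
    rgb[..., 1] = 0.5 + 0.5 * phi[1] / peak
    return rgb


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _to_nchw(img, channels):
    """Coerce (H,W), (H,W,C), (C,H,W) or (N,C,H,W) to (N,C,H,W) float."""
    a = np.asarray(img, dtype=np.float64)
    if a.ndim == 2:
        a = a[None, None]
    elif a.ndim == 3:
        if a.shape[-1] == channels:
            a = a.transpose(2, 0, 1)[None]
        elif a.shape[0] == channels:
            a = a[None]
        else:
            raise ValueError(f"cannot interpret shape {a.shape} as {channels}-channel")
    elif a.ndim != 4:
        raise ValueError("expected a 2-D, 3-D or 4-D image array")
    if a.shape[1] != channels:
        raise ValueError(f"expected {channels} channel(s), got {a.shape[1]}")
    return a


def _pad_to_multiple(a, m, mode="reflect"):
    """numpy-level bottom/right pad of an NCHW array to a size multiple."""
    h, w = a.shape[2], a.shape[3]
    ph = (-h) % m
    pw = (-w) % m
    if ph or pw:
        a = np.pad(a, ((0, 0), (0, 0), (0, ph), (0, pw)), mode=mode)
    return a, (h, w)


@dataclass
class FeatureStack:
    """Unit-norm projected encoder features at sampled spatial sites."""

    embeddings: list      # per selected layer: Tensor (S_l, dim)
    indices: list         # per selected layer: flat spatial indices used
    layers: list          # encoder tap ids


# ---------------------------------------------------------------------------
# translator G
# ---------------------------------------------------------------------------

PROFILES = {
    "tiny": {"gc": (8, 16), "n_res": 2, "dc": (8, 16), "rc": (16, 32, 32),
             "nce_layers": (0, 1, 2), "mlp": 32, "emb": 32, "d_pool": 1,
             "reg_scale": 4},
    "full": {"gc": (32, 64), "n_res": 6, "dc": (64, 128, 256),
              "rc": (16, 32, 64), "nce_layers": (0, 1, 2, 3), "mlp": 256,
              "emb": 256, "d_pool": 2, "reg_scale": 4},
}


class Generator(nn.Module):
    """Residual encoder-decoder translator: SC-like grayscale -> stain RGB.

    The first half of the residual stack is the encoder whose feature
    maps feed the contrastive loss; the output is sigmoid-bounded to
    [0, 1].  Fully convolutional: any input size works.
    """

    def __init__(self, profile="tiny", seed=0):
        cfg = PROFILES[profile]
        self.profile = profile
        rng = np.random.default_rng(seed)
        c1, c2 = cfg["gc"]
        self.conv_in = nn.Conv2d(rng, 1, c1)
        self.norm_in = nn.InstanceNorm2d(c1)
        self.conv_down = nn.Conv2d(rng, c1, c2)
        self.norm_down = nn.InstanceNorm2d(c2)
        n_res = cfg["n_res"]
        self.res_enc = [nn.ResBlock(rng, c2) for _ in range(n_res // 2)]
        self.res_dec = [nn.ResBlock(rng, c2) for _ in range(n_res - n_res // 2)]
        self.conv_up = nn.Conv2d(rng, c2, c1)
        self.norm_up = nn.InstanceNorm2d(c1)
        self.conv_out = nn.Conv2d(rng, c1, 3)
        self.nce_layers = cfg["nce_layers"]
        self._tap_channels = [c1, c2] + [c2] * len(self.res_enc)

    # -- encoder -------------------------------------------------------
    def encode(self, x):
        """Run the encoder half; returns (latent, [tap feature maps])."""
        taps = []
        h = ad.relu(self.norm_in(self.conv_in(x)))
        taps.append(h)
        h = ad.relu(self.norm_down(self.conv_down(h)))
        taps.append(h)
        for blk in self.res_enc:
            h = blk(h)
            taps.append(h)
        return h, taps

    def decode(self, h):
        for blk in self.res_dec:
            h = blk(h)
        h = ad.relu(self.norm_up(self.conv_up(h)))
        return ad.sigmoid(self.conv_out(h))

    def forward(self, x):
        """x: numpy/Tensor image -> Tensor (N, 3, H, W) in [0, 1]."""
        if not isinstance(x, Tensor):
            x = Tensor(_to_nchw(x, 1))
        elif x.ndim != 4:
            raise ValueError("Tensor input must be NCHW")
        h, _ = self.encode(x)
        return self.decode(h)

    def __call__(self, x):
        return self.forward(x)

    def stain(self, x):
        """Inference convenience: (H, W) array -> (H, W, 3) numpy RGB."""
        with ad.no_grad():
            out = self.forward(np.asarray(x, dtype=np.float64))
        return out.data[0].transpose(1, 2, 0)


class ProjectionHead(nn.Module):
    """Per-layer two-layer MLPs projecting encoder features to unit-norm
    embeddings for the patch-wise contrastive loss."""

    def __init__(self, tap_channels, hidden=32, dim=32, seed=0):
        rng = np.random.default_rng(seed + 7)
        self.mlps = [(nn.Linear(rng, c, hidden), nn.Linear(rng, hidden, dim))
                     for c in tap_channels]

    def parameters(self):
        params = []
        for l1, l2 in self.mlps:
            params.extend(l1.parameters())
            params.extend(l2.parameters())
        return params

    def project(self, layer_idx, feats):
        l1, l2 = self.mlps[layer_idx]
        z = l2(ad.relu(l1(feats)))
        return nn.l2_normalize(z, axis=-1)


def make_projection_head(G: Generator, seed=0):
    cfg = PROFILES[G.profile]
    taps = [G._tap_channels[i] for i in G.nce_layers]
    return ProjectionHead(taps, hidden=cfg["mlp"], dim=cfg["emb"], seed=seed)


def encoder_features(G: Generator, img, f: ProjectionHead = None,
                     layers=None, n_samples=256, seed=0) -> FeatureStack:
    """Sample projected encoder features at random spatial sites.

    The same seed yields identical sites, so calling this on x and on
    G(x) produces aligned positive pairs.  If ``f`` is None, raw
    (unit-normalized) features are returned.
    """
    if not isinstance(img, Tensor):
        img = Tensor(_to_nchw(img, 1))
    layers = list(layers) if layers is not None else list(G.nce_layers)
    _, taps = G.encode(img)
    rng = np.random.default_rng(seed)
    embeddings, indices = [], []
    for k, li in enumerate(layers):
        feat = taps[li]
        n, c, h, w = feat.shape
        if n != 1:
            raise ValueError("contrastive sampling expects batch size 1")
        area = h * w
        s = min(n_samples, area)
        idx = np.sort(rng.choice(area, size=s, replace=False))
        picked = ad.gather_spatial(feat, idx)          # (1, S, C)
        picked = ad.reshape(picked, (s, c))
        if f is not None:
            z = f.project(k, picked)
        else:
            z = nn.l2_normalize(picked, axis=-1)
        embeddings.append(z)
        indices.append(idx)
    return FeatureStack(embeddings=embeddings, indices=indices, layers=layers)


# ---------------------------------------------------------------------------
# discriminator D
# ---------------------------------------------------------------------------

class Discriminator(nn.Module):
    """Patch discriminator producing a score map (LSGAN, no sigmoid)."""

    def __init__(self, profile="tiny", seed=0):
        cfg = PROFILES[profile]
        rng = np.random.default_rng(seed + 13)
        chans = cfg["dc"]
        self.convs = []
        self.norms = []
        c_prev = 3
        for i, c in enumerate(chans):
            self.convs.append(nn.Conv2d(rng, c_prev, c, pad_mode="zero"))
            self.norms.append(nn.InstanceNorm2d(c) if i > 0 else None)
            c_prev = c
        self.conv_out = nn.Conv2d(rng, c_prev, 1, pad_mode="zero")
        self.n_pool = len(chans)

    def __call__(self, y):
        if not isinstance(y, Tensor):
            y = Tensor(_to_nchw(y, 3))
        if y.shape[2] % self.size_multiple or y.shape[3] % self.size_multiple:
            raise ValueError(
                f"discriminator input sides must be multiples of {self.size_multiple}")
        h = y
        for conv, norm in zip(self.convs, self.norms):
            h = conv(h)
            if norm is not None:
                h = norm(h)
            h = ad.leaky_relu(h, 0.2)
            h = ad.avg_pool2d(h)
        return self.conv_out(h)

    @property
    def size_multiple(self):
        return 2 ** self.n_pool


# ---------------------------------------------------------------------------
# registration network R
# ---------------------------------------------------------------------------

def _bilinear_up_kernel(c, s):
    """Depthwise triangular kernel turning a zero-stuffed grid into an
    aligned bilinear x``s`` upsample (kernel length 2s-1)."""
    k1 = 1.0 - np.abs(np.arange(-(s - 1), s)) / s
    k2 = np.outer(k1, k1)
    w = np.zeros((c, c, 2 * s - 1, 2 * s - 1))
    for i in range(c):
        w[i, i] = k2
    return w


class RegNet(nn.Module):
    """Encoder-decoder predicting a dense displacement field from a
    (fixed, moving) image pair stacked as 2 channels.

    The field is predicted at 1/4 resolution (smooth deformations are
    low-frequency) and upsampled in-graph; the final conv is
    zero-initialized so training starts at the identity transform, and
    its output is scaled by a fixed flow gain so multi-pixel
    displacements are reachable without large weights.  Leaky
    activations keep the flow head trainable (plain ReLUs here are
    prone to dying under adversarially large early steps).
    """

    #: fixed multiplier on the predicted displacement (pixels per unit output)
    flow_gain = 8.0
    #: hard bound (px) on per-axis displacement via tanh saturation.
    #: Adjacent-section deformations are physically bounded; without this
    #: a constant large field (which costs zero total variation) lets the
    #: stage-II loss collapse by sampling the image border background.
    max_disp = 16.0

    #: Gaussian scale (px) of the auxiliary coarse input channels
    coarse_sigma = 4.0

    def __init__(self, profile="tiny", seed=0):
        cfg = PROFILES[profile]
        rng = np.random.default_rng(seed + 29)
        c1, c2, c3 = cfg["rc"]
        self.scale = cfg["reg_scale"]
        self.c1 = nn.Conv2d(rng, 4, c1)
        self.c2 = nn.Conv2d(rng, c1, c2)
        self.c3 = nn.Conv2d(rng, c2, c3)
        self.c4 = nn.Conv2d(rng, c3, c3)
        self.out = nn.Conv2d(rng, c3, 2, zero_init=True)
        self.upkernel = Tensor(_bilinear_up_kernel(2, self.scale))
        self.pretrained = False

    def __call__(self, fixed, moving):
        """fixed, moving: (H, W) numpy arrays -> Tensor field (1, 2, H, W)."""
        fixed = np.asarray(fixed, dtype=np.float64)
        moving = np.asarray(moving, dtype=np.float64)
        if fixed.shape != moving.shape or fixed.ndim != 2:
            raise ValueError("fixed and moving must be equal-shape 2-D arrays")
        from scipy.ndimage import gaussian_filter
        a = np.stack([fixed, moving,
                      gaussian_filter(fixed, self.coarse_sigma),
                      gaussian_filter(moving, self.coarse_sigma)])[None]
        a, (h, w) = _pad_to_multiple(a, self.scale)
        x = Tensor(a)
        hdd = ad.avg_pool2d(ad.leaky_relu(self.c1(x), 0.2))
        hdd = ad.avg_pool2d(ad.leaky_relu(self.c2(hdd), 0.2))
        hdd = ad.leaky_relu(self.c3(hdd), 0.2)
        hdd = ad.leaky_relu(self.c4(hdd), 0.2)
        phi = self.out(hdd) * self.flow_gain                  # (1,2,h/4,w/4)
        phi = ad.tanh(phi * (1.0 / self.max_disp)) * self.max_disp
        phi = ad.upsample_zero(phi, self.scale)
        phi = ad.conv2d(ad.pad2d(phi, self.scale - 1, mode="zero"), self.upkernel)
        if (h, w) != phi.shape[2:]:
            phi = ad.crop2d(phi, h, w)   # remove the internal padding
        return phi


def compose_fields(phi1, phi2):
    """Field of the composition warp(warp(y, phi1), phi2) (backward maps)."""
    return phi2 + np.stack([warp_image(phi1[c], phi2) for c in range(2)])


def register(R: RegNet, x, y_or_od, max_side=512, steps=3):
    """Predict the field registering ``y_or_od`` onto ``x`` (inference).

    The network is applied ``steps`` times with intermediate warping and
    the increments composed — iterative refinement sharpens the field
    well below the single-pass accuracy.  Inputs larger than
    ``max_side`` on the long side are downscaled for the network; the
    field is bilinearly upsampled back to the moving image's resolution
    with its values rescaled to full-resolution pixels.  Returns a
    (2, H, W) numpy array.
    """
    from skimage.transform import resize

    x = np.asarray(x, dtype=np.float64)
    mov = np.asarray(y_or_od, dtype=np.float64)
    if x.ndim != 2 or mov.ndim != 2:
        raise ValueError("register expects single-channel images")
    if x.shape != mov.shape:
        raise ValueError("fixed/moving shape mismatch")
    h, w = x.shape
    long_side = max(h, w)
    if long_side > max_side:
        zoom = max_side / long_side
        hs, ws = int(round(h * zoom)), int(round(w * zoom))
        xs = resize(x, (hs, ws), order=1, anti_aliasing=True)
        ms = resize(mov, (hs, ws), order=1, anti_aliasing=True)
    else:
        zoom = 1.0
        xs, ms = x, mov
    phi = None
    current = ms
    with ad.no_grad():
        for _ in range(max(steps, 1)):
            inc = R(xs, current).data[0]
            phi = inc if phi is None else compose_fields(phi, inc)
            current = warp_image(ms, phi)
    if zoom != 1.0:
        phi = np.stack([resize(phi[i], (h, w), order=1) for i in range(2)])
        phi /= zoom
    return phi
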