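"""Training objectives as pure, individually testable functions.

All losses accept numpy arrays or autodiff Tensors and return a Tensor
(call ``.item()`` for the scalar).  Conventions:

* Least-squares adversarial losses: real label 1, fake label 0, mean
  squared deviation of the discriminator score map.
* Patch-wise contrastive loss: minimized negative-log softmax over
  within-image negatives at temperature tau (default 0.07), averaged
  over sampled sites and layers.
* Registration losses: L1 data term plus a total-variation penalty on
  the displacement field, the vector forward differences of both
  displacement channels combined under one square root.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor, as_tensor


@dataclass
class LossWeights:
    w_gan: float = 1.0
    w_nce: float = 1.0
    w_pseudo: float = 10.0
    w_reg: float = 10.0

    def validate(self):
        vals = (self.w_gan, self.w_nce, self.w_pseudo, self.w_reg)
        if any(v < 0 for v in vals):
            raise ValueError("loss weights must be nonnegative")
        if all(v == 0 for v in vals):
            raise ValueError("at least one loss weight must be positive")


# ---------------------------------------------------------------------------
# adversarial
# ---------------------------------------------------------------------------

def lsgan_d(d_real, d_fake) -> Tensor:
    """Discriminator loss: mean (D(y)-1)^2 + mean D(G(x))^2."""
    d_real, d_fake = as_tensor(d_real), as_tensor(d_fake)
    return ad.tmean((d_real - 1.0) ** 2) + ad.tmean(d_fake ** 2)


def lsgan_g(d_fake) -> Tensor:
    """Generator adversarial loss: mean (D(G(x))-1)^2."""
    return ad.tmean((as_tensor(d_fake) - 1.0) ** 2)


# ---------------------------------------------------------------------------
# contrastive
# ---------------------------------------------------------------------------

def patch_nce(z, z_hat, tau=0.07) -> Tensor:
    """Multi-layer patch-wise contrastive loss.

    ``z`` and ``z_hat`` are FeatureStacks (or plain lists of (S, d)
    unit-norm embedding Tensors) sampled at identical sites from the
    input and the translated image.  Per site s:
    -log( exp(z_s . zhat_s / tau) / sum_t exp(z_s . zhat_t / tau) ),
    averaged over sites and layers.
    """
    z_list = getattr(z, "embeddings", z)
    zh_list = getattr(z_hat, "embeddings", z_hat)
    if len(z_list) != len(zh_list) or len(z_list) == 0:
        raise ValueError("feature stacks must be nonempty and aligned")
    total = None
    for zl, zhl in zip(z_list, zh_list):
        zl, zhl = as_tensor(zl), as_tensor(zhl)
        s = zl.shape[0]
        if s == 0:
            raise ValueError("no sampled sites")
        logits = ad.matmul(zl, ad.transpose(zhl, (1, 0))) * (1.0 / tau)
        shift = logits.data.max(axis=1, keepdims=True)       # detached
        lse = ad.tlog(ad.tsum(ad.texp(logits - shift), axis=1, keepdims=True)) + shift
        eye = np.eye(s)
        pos = ad.tsum(logits * eye, axis=1, keepdims=True)
        layer_loss = ad.tmean(lse - pos)
        total = layer_loss if total is None else total + layer_loss
    return total * (1.0 / len(z_list))


# ---------------------------------------------------------------------------
# pseudo-supervision
# ---------------------------------------------------------------------------

def l1(a, b) -> Tensor:
    return ad.tmean(ad.tabs(as_tensor(a) - as_tensor(b)))


def pseudo_loss(G, y, epsilon=None) -> Tensor:
    """Mean absolute error between G(equalized OD(y)) and y.

    ``y`` is an (H, W, 3) stain patch in [0, 1]; the optical density is
    computed, foreground-equalized and translated by G.
    """
    from .biophys import DEFAULT_EPSILON, hist_equalize, optical_density

    y = np.asarray(y, dtype=np.float64)
    od = optical_density(y, epsilon or DEFAULT_EPSILON).od
    odq = hist_equalize(od)
    out = G(odq)                                     # (1, 3, H, W)
    target = y.transpose(2, 0, 1)[None]
    return l1(out, target)


# ---------------------------------------------------------------------------
# registration
# ---------------------------------------------------------------------------

def _forward_diff(a4, axis):
    """Forward difference of (1,2,H,W) along a spatial axis, zero-padded
    back to full shape so out-of-range differences contribute nothing."""
    two = a4.shape[1]
    h, w = a4.shape[2], a4.shape[3]
    kshape = (two, two, 2, 1) if axis == 2 else (two, two, 1, 2)
    k = np.zeros(kshape)
    for c in range(two):
        k[c, c].flat[0] = -1.0
        k[c, c].flat[1] = 1.0
    d = ad.conv2d(a4, Tensor(k))
    pad_shape = (1, two, 1, w) if axis == 2 else (1, two, h, 1)
    return ad.concat([d, Tensor(np.zeros(pad_shape))], axis=axis)


def tv_norm(phi) -> Tensor:
    """Isotropic total variation of a displacement field (2, H, W).

    sum_{i,j} sqrt(|phi_{i+1,j}-phi_{i,j}|^2 + |phi_{i,j+1}-phi_{i,j}|^2)
    with the 2-vector differences of both displacement channels combined
    under one square root; forward differences off the last row/column
    are excluded (contribute zero).
    """
    phi = as_tensor(phi)
    if phi.ndim == 3:
        phi = ad.reshape(phi, (1,) + phi.shape)
    if phi.ndim != 4 or phi.shape[0] != 1:
        raise ValueError("tv_norm expects a (2, H, W) field")
    h, w = phi.shape[2], phi.shape[3]
    dr = (_forward_diff(phi, axis=2) if h > 1
          else Tensor(np.zeros(phi.shape)))
    dc = (_forward_diff(phi, axis=3) if w > 1
          else Tensor(np.zeros(phi.shape)))
    sq = ad.tsum(dr * dr, axis=1) + ad.tsum(dc * dc, axis=1)
    return ad.tsum(ad.sqrt0(sq))


def _tv_mean(phi) -> Tensor:
    """TV norm normalized per pixel, so its scale matches a mean L1 data
    term regardless of image size."""
    phi = as_tensor(phi)
    npx = phi.data.shape[-1] * phi.data.shape[-2]
    return tv_norm(phi) * (1.0 / npx)


def reg_stage1(x, od_y, phi, lambda_tv=0.1) -> Tensor:
    """Stage-I registration loss: ||X - phi o OD(Y)||_1 + lambda ||phi||_TV.

    Both terms are averaged per pixel so the TV weight is size-free.
    """
    x = as_tensor(x)
    od_y = as_tensor(od_y)
    phi = as_tensor(phi)
    if x.data.shape[-2:] != od_y.data.shape[-2:]:
        raise ValueError("shape mismatch between fixed and moving images")
    x4 = _as_n1hw(x)
    m4 = _as_n1hw(od_y)
    phi4 = phi if phi.ndim == 4 else ad.reshape(phi, (1,) + phi.shape)
    warped = ad.warp(m4, phi4)
    return l1(x4, warped) + _tv_mean(phi) * lambda_tv


def reg_stage2_R(ds, y, phi, lambda_tv=0.1) -> Tensor:
    """Stage-II R loss: ||G(X) - phi o Y||_1 + lambda ||phi||_TV (G frozen)."""
    ds = as_tensor(_rgb_nchw(ds))
    y4 = as_tensor(_rgb_nchw(y))
    phi = as_tensor(phi)
    if ds.data.shape != y4.data.shape:
        raise ValueError("shape mismatch between DS and PS images")
    phi4 = phi if phi.ndim == 4 else ad.reshape(phi, (1,) + phi.shape)
    warped = ad.warp(y4, phi4)
    return l1(ds, warped) + _tv_mean(phi) * lambda_tv


def reg_stage2_G(ds_patch, y_warped_patch) -> Tensor:
    """Stage-II G loss: mean L1 between G(x) and the registered PS patch."""
    a = as_tensor(_rgb_nchw(ds_patch))
    b = as_tensor(_rgb_nchw(y_warped_patch))
    if a.data.shape != b.data.shape:
        raise ValueError("patch grid mismatch")
    return l1(a, b)


def total_loss(components, weights: LossWeights) -> Tensor:
    """Weighted sum of the four translator objectives.

    ``components`` maps {"gan_g", "nce", "pseudo", "reg"} to losses.
    """
    weights.validate()
    pairs = (("gan_g", weights.w_gan), ("nce", weights.w_nce),
             ("pseudo", weights.w_pseudo), ("reg", weights.w_reg))
    total = None
    for key, wgt in pairs:
        if key not in components:
            continue
        term = as_tensor(components[key]) * wgt
        total = term if total is None else total + term
    if total is None:
        raise ValueError("no loss components given")
    return total


# ---------------------------------------------------------------------------
# shape helpers
# ---------------------------------------------------------------------------

def _as_n1hw(t: Tensor) -> Tensor:
    if t.ndim == 2:
        return ad.reshape(t, (1, 1) + t.shape)
    if t.ndim == 4:
        return t
    raise ValueError("expected a 2-D image or NCHW tensor")


def _rgb_nchw(a):
    if isinstance(a, Tensor):
        if a.ndim == 4:
            return a
        if a.ndim == 3 and a.shape[0] == 3:
            return ad.reshape(a, (1,) + a.shape)
        raise ValueError("expected RGB tensor")
    arr = np.asarray(a, dtype=np.float64)
    if arr.ndim == 3 and arr.shape[-1] == 3:
        return arr.transpose(2, 0, 1)[None]
    if arr.ndim == 3 and arr.shape[0] == 3:
        return arr[None]
    if arr.ndim == 4:
        return arr
    raise ValueError("expected an RGB image")
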