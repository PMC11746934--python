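"""Synthetic cortex phantoms with known ground truth.

A phantom slice mimics the two modalities of the digital-staining
problem: a scattering-coefficient (SC) map, bright in myelin-rich white
matter, and a silver-stain-like RGB image, dark in the same regions.
Both derive from a single latent myelin-density field over a layered
cortical geometry (supragranular layers, the darker IV/V/VI bands,
white matter) with gyral/sulcal boundary curvature, tubular vessel
voids, multiplicative speckle on SC and a per-slice nonlinear tone
curve on the stain.  Weak pairs add a known smooth deformation and
controlled content mismatch between "adjacent sections", so every
downstream stage can be scored against ground truth.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import yaml
from scipy.ndimage import gaussian_filter

# label legend
BACKGROUND, SUPRA, LAYER4, LAYER5, LAYER6, WM, VESSEL = range(7)

#: latent myelin density assigned to each label (vessel lumens are voids)
MYELIN_LEVELS = {
    BACKGROUND: 0.0,
    SUPRA: 0.15,
    LAYER4: 0.45,
    LAYER5: 0.62,
    LAYER6: 0.55,
    WM: 0.95,
    VESSEL: 0.02,
}


@dataclass
class PhantomParams:
    """Generator knobs; defaults give a plausible 12 um/px cortex slab."""

    #: fractions of image height: empty space above the pial surface,
    #: then layers I-III, IV, V, VI (white matter fills the remainder)
    surface_fraction: float = 0.10
    layer_fractions: tuple = (0.24, 0.10, 0.17, 0.15)
    #: boundary curvature amplitude as a fraction of height
    boundary_amplitude: float = 0.05
    n_vessels: int = 6
    vessel_radius: tuple = (2, 4)
    #: variance of the unit-mean multiplicative gamma speckle on SC
    speckle_var: float = 0.15
    #: SC model sc = sc_floor + sc_gain * myelin (mm^-1 at 1310 nm)
    sc_floor: float = 3.0
    sc_gain: float = 10.0
    #: per-channel stain absorption (dark brown: blue absorbed most)
    stain_vector: tuple = (0.70, 0.82, 0.96)
    #: per-slice tone nonlinearity applied to myelin before staining
    ps_gamma: float = 1.0
    #: illuminant tint multiplied into the rendered stain image
    illuminant: tuple = (1.0, 1.0, 1.0)
    pitch_um: float = 12.0

    def validate(self):
        if self.surface_fraction < 0 or any(f <= 0 for f in self.layer_fractions):
            raise ValueError("layer fractions must be positive")
        if self.surface_fraction + sum(self.layer_fractions) > 1.0:
            raise ValueError("layer fractions must sum to <= 1")
        if self.n_vessels < 0:
            raise ValueError("n_vessels must be >= 0")


@dataclass
class PhantomSlice:
    sc: np.ndarray          # (H, W) float, >= 0
    ps: np.ndarray          # (H, W, 3) float in [0, 1]
    labels: np.ndarray      # (H, W) uint8, legend above
    myelin: np.ndarray      # (H, W) float in [0, 1]
    pitch_um: float
    params: PhantomParams = None
    seed: int = None
    _recipe: dict = field(default=None, repr=False)


@dataclass
class WeakPair:
    x: np.ndarray           # SC map (H, W)
    y: np.ndarray           # stain image (H, W, 3), warped + perturbed
    phi_true: np.ndarray    # (2, H, W): field registering y back onto x
    seed: int
    x_slice: PhantomSlice = None
    y_slice: PhantomSlice = None


# ---------------------------------------------------------------------------
# tone map and its inverse (the oracle for digital-staining evaluation)
# ---------------------------------------------------------------------------

def ps_colormap(myelin, gamma=1.0, stain_vector=(0.70, 0.82, 0.96),
                illuminant=(1.0, 1.0, 1.0)):
    """Map latent myelin density to stain RGB: y_c = (1 - m**gamma * s_c) * i_c."""
    m = np.clip(np.asarray(myelin, dtype=np.float64), 0.0, 1.0) ** gamma
    s = np.asarray(stain_vector)
    i = np.asarray(illuminant)
    return np.clip((1.0 - m[..., None] * s[None, :]) * i[None, :], 0.0, 1.0)


def invert_ps_colormap(ps, gamma=1.0, stain_vector=(0.70, 0.82, 0.96)):
    """Recover myelin from an untinted rendered stain image."""
    s = np.asarray(stain_vector)
    m_g = ((1.0 - np.asarray(ps)) / s[None, None, :]).mean(axis=-1)
    return np.clip(m_g, 0.0, 1.0) ** (1.0 / gamma)


# ---------------------------------------------------------------------------
# internal renderer driven by an explicit, serializable recipe
# ---------------------------------------------------------------------------

def _boundary_curve(width, amplitude, harmonics):
    x = np.arange(width, dtype=np.float64) / max(width - 1, 1)
    curve = np.zeros(width)
    for (freq, phase, weight) in harmonics:
        curve += weight * np.sin(2 * np.pi * freq * x + phase)
    peak = np.abs(curve).max()
    if peak > 0:
        curve *= amplitude / peak
    return curve


def _draw_tube(labels, myelin, p0, p1, radius, n_wiggle=0.0):
    """Stamp a straight tubular void of the given radius onto the maps."""
    h, w = labels.shape
    length = int(np.hypot(p1[0] - p0[0], p1[1] - p0[1])) + 1
    t = np.linspace(0.0, 1.0, max(2 * length, 2))
    rr = p0[0] + (p1[0] - p0[0]) * t
    cc = p0[1] + (p1[1] - p0[1]) * t
    if n_wiggle:
        rr = rr + n_wiggle * np.sin(4 * np.pi * t)
    rr = np.clip(np.round(rr).astype(int), 0, h - 1)
    cc = np.clip(np.round(cc).astype(int), 0, w - 1)
    mask = np.zeros((h, w), dtype=bool)
    mask[rr, cc] = True
    if radius > 0:
        from scipy.ndimage import binary_dilation
        yy, xx = np.ogrid[-radius:radius + 1, -radius:radius + 1]
        mask = binary_dilation(mask, structure=yy * yy + xx * xx <= radius * radius)
    inside = mask & (labels != BACKGROUND)
    labels[inside] = VESSEL
    myelin[inside] = MYELIN_LEVELS[VESSEL]
    return inside


def _draw_disc(labels, myelin, center, radius):
    h, w = labels.shape
    rr, cc = np.ogrid[:h, :w]
    mask = (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius * radius
    inside = mask & (labels != BACKGROUND)
    labels[inside] = VESSEL
    myelin[inside] = MYELIN_LEVELS[VESSEL]
    return inside


def _render(height, width, recipe, params: PhantomParams, seed):
    """Render a PhantomSlice from an explicit recipe dict.

    recipe keys: harmonics (boundary curve spec), vessels (list of specs),
    ps_gamma, speckle_seed, texture_seed.
    """
    amp = params.boundary_amplitude * height
    curve = _boundary_curve(width, amp, recipe["harmonics"])
    surface = params.surface_fraction * height + curve

    bounds = [surface]
    for frac in params.layer_fractions:
        bounds.append(bounds[-1] + frac * height)

    rows = np.arange(height, dtype=np.float64)[:, None]
    labels = np.full((height, width), WM, dtype=np.uint8)
    labels[rows < bounds[4]] = LAYER6
    labels[rows < bounds[3]] = LAYER5
    labels[rows < bounds[2]] = LAYER4
    labels[rows < bounds[1]] = SUPRA
    labels[rows < bounds[0]] = BACKGROUND

    myelin = np.zeros((height, width))
    for lab, level in MYELIN_LEVELS.items():
        myelin[labels == lab] = level

    # gentle within-tissue texture so layers are not perfectly flat
    trng = np.random.default_rng(recipe["texture_seed"])
    texture = gaussian_filter(trng.standard_normal((height, width)), sigma=6)
    texture /= max(np.abs(texture).max(), 1e-9)
    tissue = labels != BACKGROUND
    myelin[tissue] = np.clip(myelin[tissue] * (1.0 + 0.08 * texture[tissue]), 0.0, 1.0)

    for spec in recipe["vessels"]:
        if spec["kind"] == "tube":
            _draw_tube(labels, myelin, spec["p0"], spec["p1"], spec["radius"],
                       spec.get("wiggle", 0.0))
        else:
            _draw_disc(labels, myelin, spec["center"], spec["radius"])

    sc = (params.sc_floor + params.sc_gain * myelin) * (labels != BACKGROUND)
    if params.speckle_var > 0:
        srng = np.random.default_rng(recipe["speckle_seed"])
        shape = 1.0 / params.speckle_var
        speckle = srng.gamma(shape, scale=1.0 / shape, size=sc.shape)
        sc = sc * speckle

    ps = ps_colormap(myelin, recipe["ps_gamma"], params.stain_vector,
                     params.illuminant)
    ps[labels == BACKGROUND] = np.asarray(params.illuminant)

    return PhantomSlice(sc=sc, ps=ps, labels=labels, myelin=myelin,
                        pitch_um=params.pitch_um, params=params, seed=seed,
                        _recipe=dict(recipe, height=height, width=width))


def _sample_vessels(rng, height, width, params: PhantomParams):
    """In-plane tubular voids placed in the deeper bands / white matter."""
    vessels = []
    depth_lo = (params.surface_fraction + params.layer_fractions[0]) * height
    for _ in range(params.n_vessels):
        r0 = rng.uniform(depth_lo, height - 4)
        c0 = rng.uniform(4, width - 4)
        angle = rng.uniform(0, np.pi)
        length = rng.uniform(0.1, 0.3) * min(height, width)
        r1 = np.clip(r0 + length * np.sin(angle), depth_lo, height - 1)
        c1 = np.clip(c0 + length * np.cos(angle), 0, width - 1)
        radius = int(rng.integers(params.vessel_radius[0], params.vessel_radius[1] + 1))
        vessels.append({"kind": "tube", "p0": (float(r0), float(c0)),
                        "p1": (float(r1), float(c1)), "radius": radius,
                        "wiggle": float(rng.uniform(0, 1.5))})
    return vessels


def _sample_recipe(rng, height, width, params: PhantomParams):
    harmonics = [
        (float(rng.uniform(0.8, 1.6)), float(rng.uniform(0, 2 * np.pi)), 1.0),
        (float(rng.uniform(2.0, 3.2)), float(rng.uniform(0, 2 * np.pi)), 0.4),
    ]
    return {
        "harmonics": harmonics,
        "vessels": _sample_vessels(rng, height, width, params),
        "ps_gamma": params.ps_gamma,
        "speckle_seed": int(rng.integers(2 ** 31)),
        "texture_seed": int(rng.integers(2 ** 31)),
    }


# ---------------------------------------------------------------------------
# public generators
# ---------------------------------------------------------------------------

def make_cortex_phantom(height, width, seed=0, params: PhantomParams = None):
    """Generate one synthetic cortex slice; pure function of (seed, params)."""
    if height < 64 or width < 64:
        raise ValueError("phantom dimensions must be >= 64")
    params = params or PhantomParams()
    params.validate()
    rng = np.random.default_rng(seed)
    recipe = _sample_recipe(rng, height, width, params)
    return _render(height, width, recipe, params, seed)


def random_smooth_field(shape, amplitude, seed, sigma=None):
    """Smooth random displacement field (2, H, W) with max norm == amplitude."""
    h, w = shape
    rng = np.random.default_rng(seed)
    sigma = sigma if sigma is not None else max(min(h, w) / 8.0, 4.0)
    phi = np.stack([gaussian_filter(rng.standard_normal((h, w)), sigma)
                    for _ in range(2)])
    mags = np.sqrt((phi ** 2).sum(axis=0))
    peak = mags.max()
    if peak > 0 and amplitude > 0:
        phi *= amplitude / peak
    else:
        phi[:] = 0.0
    return phi


def invert_field(phi, n_iter=10):
    """Fixed-point inverse of a (small, smooth) backward-warp field."""
    from .nets import warp_image
    inv = -phi.copy()
    for _ in range(n_iter):
        inv = -np.stack([warp_image(phi[0], inv), warp_image(phi[1], inv)])
    return inv


def make_weak_pair(slc: PhantomSlice, amplitude=8.0, content_jitter=0.0,
                   seed=0) -> WeakPair:
    """Derive a weakly-paired (x, y) from one phantom geometry.

    ``y`` is the stain render of the same geometry warped by the inverse
    of a random smooth field (so ``phi_true`` registers y back onto x),
    with a fraction ``content_jitter`` of the vessels independently
    re-placed, emulating genuine content mismatch between adjacent
    sections.
    """
    if amplitude < 0:
        raise ValueError("amplitude must be >= 0")
    if not (0 <= content_jitter < 1):
        raise ValueError("content_jitter must be in [0, 1)")
    h, w = slc.labels.shape
    if amplitude > min(h, w) / 4:
        raise ValueError("amplitude exceeds image size / 4")
    rng = np.random.default_rng(seed)

    recipe = dict(slc._recipe)
    params = slc.params
    if content_jitter > 0:
        vessels = list(recipe["vessels"])
        n_redo = int(np.ceil(content_jitter * len(vessels)))
        redo_idx = rng.choice(len(vessels), size=n_redo, replace=False)
        fresh = _sample_vessels(rng, h, w, params)
        for k, idx in enumerate(sorted(redo_idx)):
            vessels[idx] = fresh[k % len(fresh)]
        recipe["vessels"] = vessels
    # adjacent-section staining variability: new tone curve and speckle
    recipe["ps_gamma"] = float(params.ps_gamma * rng.uniform(0.8, 1.25))
    recipe["speckle_seed"] = int(rng.integers(2 ** 31))
    y_slice = _render(h, w, recipe, params, seed)

    if amplitude == 0:
        phi_true = np.zeros((2, h, w))
        y = y_slice.ps.copy()
    else:
        phi_true = random_smooth_field((h, w), amplitude, int(rng.integers(2 ** 31)))
        phi_inv = invert_field(phi_true)
        from .nets import warp_image
        y = warp_image(y_slice.ps, phi_inv)
    return WeakPair(x=slc.sc.copy(), y=np.clip(y, 0.0, 1.0),
                    phi_true=phi_true, seed=seed,
                    x_slice=slc, y_slice=y_slice)


def make_volume(n_slices, height, width, seed=0, params: PhantomParams = None,
                max_boundary_shift=2.0):
    """A z-stack of phantoms with smoothly drifting geometry.

    Layer-boundary phase and amplitude drift slowly across z (per-slice
    boundary displacement bounded by ``max_boundary_shift`` pixels) and a
    subset of vessels follow continuous 3-D paths, so they stay connected
    across >= 3 consecutive slices.
    """
    if n_slices < 2:
        raise ValueError("a volume needs n_slices >= 2")
    if height < 64 or width < 64:
        raise ValueError("phantom dimensions must be >= 64")
    params = params or PhantomParams()
    params.validate()
    rng = np.random.default_rng(seed)

    base = _sample_recipe(rng, height, width, params)
    # z-continuous vessels: smooth 3-D center paths crossing every slice
    n_z = max(1, params.n_vessels // 2)
    z_paths = []
    for _ in range(n_z):
        r = rng.uniform(0.75 * height, height - 8)
        c = rng.uniform(8, width - 8)
        dr = rng.uniform(-1.5, 1.5)
        dc = rng.uniform(-1.5, 1.5)
        radius = int(rng.integers(max(params.vessel_radius[0], 3),
                                  params.vessel_radius[1] + 2))
        z_paths.append({"r": r, "c": c, "dr": dr, "dc": dc, "radius": radius})

    amp = params.boundary_amplitude * height
    slices = []
    phase_shift = 0.0
    for z in range(n_slices):
        recipe = dict(base)
        freq0 = base["harmonics"][0][0]
        # bounded per-slice phase drift: displacement <= max_boundary_shift px
        max_dphase = max_boundary_shift / max(amp, 1e-9)
        phase_shift += float(rng.uniform(-max_dphase, max_dphase))
        recipe["harmonics"] = [(f, p + phase_shift * (i == 0), wgt)
                               for i, (f, p, wgt) in enumerate(base["harmonics"])]
        del freq0
        vessels = []
        for path in z_paths:
            center = (path["r"] + path["dr"] * z, path["c"] + path["dc"] * z)
            if 0 <= center[0] < height and 0 <= center[1] < width:
                vessels.append({"kind": "disc", "center": center,
                                "radius": path["radius"]})
        # plus a couple of per-slice in-plane tubes for realism
        vessels.extend(_sample_vessels(rng, height, width,
                                       dataclasses.replace(params, n_vessels=2)))
        recipe["vessels"] = vessels
        recipe["ps_gamma"] = float(params.ps_gamma * rng.uniform(0.85, 1.2))
        recipe["speckle_seed"] = int(rng.integers(2 ** 31))
        recipe["texture_seed"] = base["texture_seed"]
        slices.append(_render(height, width, recipe, params,
                              seed=int(rng.integers(2 ** 31))))
    return slices


# ---------------------------------------------------------------------------
# disk I/O
# ---------------------------------------------------------------------------

def save_phantom_set(out_dir, slices, params: PhantomParams, seed):
    """Write SC (float32 TIFF), PS (8-bit RGB TIFF), labels and a YAML sidecar."""
    import tifffile
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for i, slc in enumerate(slices):
        tifffile.imwrite(out / f"sc_{i:03d}.tiff", slc.sc.astype(np.float32))
        tifffile.imwrite(out / f"ps_{i:03d}.tiff",
                         (np.clip(slc.ps, 0, 1) * 255).round().astype(np.uint8))
        tifffile.imwrite(out / f"labels_{i:03d}.tiff", slc.labels)
    meta = {"seed": int(seed), "n_slices": len(slices),
            "pitch_um": float(params.pitch_um),
            "params": {k: (list(v) if isinstance(v, tuple) else v)
                       for k, v in dataclasses.asdict(params).items()}}
    with open(out / "phantom.yaml", "w") as fh:
        yaml.safe_dump(meta, fh)
    return out
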