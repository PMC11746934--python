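"""Training protocol: contrastive-unpaired backbone steps, optical-density
pseudo-supervised steps, stage-I registration pre-training, and stage-II
alternating fine-tuning across image scales.

Phases (in order):

1. ``pretrain_registration`` — R learns to map (X, OD(Y)) whole-slide
   pairs to a smooth displacement field by minimizing the stage-I
   cross-modal L1 + TV loss.
2. ``train_step_cut`` / ``train_step_pseudo`` — the translator G, the
   discriminator D and the projection head f are trained on patches:
   least-squares adversarial + patch-wise contrastive on the SC domain,
   plus L1 pseudo-supervision on pixel-aligned OD(Y)/Y pairs (with OD
   translations optionally fed to D, closing the domain gap).
3. ``finetune_alternating`` — with a coarsely trained G, R and G take
   turns: R refines the field at WSI scale against G(X); G refines
   against registered stain patches cropped on a shared grid.

Everything is deterministic under a fixed seed on a single device.
"""

from __future__ import annotations

import csv
import dataclasses
import hashlib
import warnings
from dataclasses import dataclass, field

import numpy as np
import yaml

from . import losses as L
from . import nn
from .autodiff import Tensor
from . import autodiff as ad
from .biophys import hist_equalize, optical_density
from .losses import LossWeights
from .nets import (Discriminator, Generator, ProjectionHead, RegNet,
                   encoder_features, make_projection_head, warp_image)
from .tiling import split

_LUM = np.array([0.2126, 0.7152, 0.0722])


@dataclass
class TrainConfig:
    profile: str = "tiny"
    patch: int = 64                      # full-size profile uses 512
    iters_pretrain_reg: int = 1600
    iters_cut: int = 1200
    iters_alt: int = 250
    lr: float = 1e-3
    lr_reg: float = 1e-3
    betas: tuple = (0.5, 0.999)
    seed: int = 0
    weights: LossWeights = field(default_factory=LossWeights)
    adversarial_on_od: bool = True
    lambda_tv: float = 0.1
    tau: float = 0.07
    n_nce: int = 64
    alt_ratio: int = 1                   # R steps per G step per WSI

    def to_dict(self):
        d = dataclasses.asdict(self)
        d["betas"] = list(self.betas)
        return d

    def config_hash(self):
        return hashlib.sha256(
            yaml.safe_dump(self.to_dict(), sort_keys=True).encode()).hexdigest()[:16]


def _opt(net, cfg: TrainConfig, lr=None):
    """Lazily attach a persistent Adam optimizer to a network."""
    if getattr(net, "_opt", None) is None:
        net._opt = nn.Adam(net.parameters(), lr=lr or cfg.lr, betas=cfg.betas)
    return net._opt


def _append_log(log_path, row):
    if log_path is None:
        return
    import os
    write_header = not os.path.exists(log_path)
    with open(log_path, "a", newline="") as fh:
        wr = csv.DictWriter(fh, fieldnames=list(row))
        if write_header:
            wr.writeheader()
        wr.writerow(row)


def _check_finite(value, what):
    if not np.isfinite(value):
        raise RuntimeError(f"{what} diverged (non-finite loss {value}); "
                           "lower the learning rate or TV weight")


def _luminance_t(rgb_tensor):
    """Graph-tracked luminance of an (N,3,H,W) tensor -> (N,1,H,W)."""
    w = Tensor(_LUM.reshape(1, 3, 1, 1))
    return ad.tsum(rgb_tensor * w, axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# stage I: registration pre-training
# ---------------------------------------------------------------------------

def pretrain_registration(R: RegNet, dataset, cfg: TrainConfig, log_path=None):
    """Pre-train R on (X, OD(Y)) whole-slide pairs (both equalized).

    dataset: list of (x_eq, od_eq) single-channel arrays.  The training
    objective is the stage-I L1 + TV loss evaluated as a two-scale
    pyramid (a Gaussian-smoothed copy of both images widens the capture
    range early; its weight drops once coarse alignment is found) with a
    step-down of the learning rate for fine convergence — a standard
    coarse-to-fine schedule for deformable registration.  Returns the
    per-iteration loss history; R is updated in place and flagged
    pretrained.
    """
    from scipy.ndimage import gaussian_filter

    if not dataset:
        raise ValueError("empty dataset")
    opt = _opt(R, cfg, lr=cfg.lr_reg)
    pyramids = [(x, od, gaussian_filter(x, R.coarse_sigma),
                 gaussian_filter(od, R.coarse_sigma)) for x, od in dataset]
    history = []
    n_iters = cfg.iters_pretrain_reg
    for it in range(n_iters):
        frac = it / max(n_iters, 1)
        w_coarse = 1.0 if frac < 0.5 else 0.2
        opt.lr = cfg.lr_reg if frac < 0.75 else 0.3 * cfg.lr_reg
        x, od, xs, ods = pyramids[it % len(pyramids)]
        phi = R(x, od)
        fine = L.reg_stage1(x, od, phi, 0.0)
        coarse = L.reg_stage1(xs, ods, phi, 0.0)
        loss = ((fine + coarse * w_coarse) * (1.0 / (1.0 + w_coarse))
                + L._tv_mean(phi) * cfg.lambda_tv)
        val = loss.item()
        _check_finite(val, "registration pre-training")
        opt.zero_grad()
        loss.backward()
        opt.step()
        history.append(val)
        _append_log(log_path, {"iter": it, "phase": "pretrain_reg", "loss": val})
    R.pretrained = True
    return history


# ---------------------------------------------------------------------------
# patch-scale steps
# ---------------------------------------------------------------------------

def train_step_cut(G: Generator, D: Discriminator, f: ProjectionHead,
                   batch, cfg: TrainConfig, nce_seed=0):
    """One discriminator update then one generator/head update.

    batch: list of (x, y) patch pairs — x single-channel equalized SC,
    y RGB stain.  Returns the loss record {gan_d, gan_g, nce}.
    """
    if not batch:
        raise ValueError("empty batch")
    d_opt = _opt(D, cfg)
    g_opt = _opt(G, cfg)
    f_opt = _opt(f, cfg)

    # --- D step (G fixed) ---
    d_loss = None
    for x, y in batch:
        with ad.no_grad():
            fake = G(x)
        term = L.lsgan_d(D(np.asarray(y)), D(Tensor(fake.data)))
        d_loss = term if d_loss is None else d_loss + term
    d_loss = d_loss * (1.0 / len(batch))
    d_opt.zero_grad()
    d_loss.backward()
    d_opt.step()

    # --- G (+f) step (D fixed) ---
    g_total = None
    gan_g_val = nce_val = 0.0
    use_nce = cfg.weights.w_nce > 0
    for k, (x, y) in enumerate(batch):
        fake_t = G(x)
        gan_g = L.lsgan_g(D(fake_t))
        gan_g_val += gan_g.item()
        term = gan_g * cfg.weights.w_gan
        if use_nce:
            seed = nce_seed * 1000003 + k
            z = encoder_features(G, np.asarray(x, dtype=np.float64), f,
                                 n_samples=cfg.n_nce, seed=seed)
            z = _detach_stack(z)
            zh = encoder_features(G, _luminance_t(fake_t), f,
                                  n_samples=cfg.n_nce, seed=seed)
            nce = L.patch_nce(z, zh, cfg.tau)
            nce_val += nce.item()
            term = term + nce * cfg.weights.w_nce
        g_total = term if g_total is None else g_total + term
    g_total = g_total * (1.0 / len(batch))
    _check_finite(g_total.item(), "generator training")
    g_opt.zero_grad()
    f_opt.zero_grad()
    g_total.backward()
    g_opt.step()
    if use_nce:
        f_opt.step()
    n = len(batch)
    return {"gan_d": d_loss.item(), "gan_g": gan_g_val / n, "nce": nce_val / n}


def _detach_stack(stack):
    """Stop gradients through the x-side embeddings (standard practice:
    only the translated side pushes the encoder via the NCE loss)."""
    from .nets import FeatureStack
    return FeatureStack(
        embeddings=[Tensor(e.data) for e in stack.embeddings],
        indices=stack.indices, layers=stack.layers)


def train_step_pseudo(G: Generator, D: Discriminator, batch_y,
                      cfg: TrainConfig):
    """One pseudo-supervised G update on OD(y)/y pairs.

    With ``adversarial_on_od`` the OD translations also pass through D
    as fakes (domain adaptation); otherwise D is untouched.
    """
    if not batch_y:
        raise ValueError("empty batch")
    g_opt = _opt(G, cfg)
    record = {"pseudo": 0.0, "gan_d": 0.0, "gan_g": 0.0}
    n = len(batch_y)

    prepared = []
    for y in batch_y:
        y = np.asarray(y, dtype=np.float64)
        odq = hist_equalize(optical_density(y).od)
        prepared.append((odq, y))

    if cfg.adversarial_on_od:
        d_opt = _opt(D, cfg)
        d_loss = None
        for odq, y in prepared:
            with ad.no_grad():
                fake = G(odq)
            term = L.lsgan_d(D(y), D(Tensor(fake.data)))
            d_loss = term if d_loss is None else d_loss + term
        d_loss = d_loss * (1.0 / n)
        d_opt.zero_grad()
        d_loss.backward()
        d_opt.step()
        record["gan_d"] = d_loss.item()

    g_total = None
    for odq, y in prepared:
        fake = G(odq)
        pseudo = L.l1(fake, y.transpose(2, 0, 1)[None])
        record["pseudo"] += pseudo.item() / n
        term = pseudo * cfg.weights.w_pseudo
        if cfg.adversarial_on_od:
            gan_g = L.lsgan_g(D(fake))
            record["gan_g"] += gan_g.item() / n
            term = term + gan_g * cfg.weights.w_gan
        g_total = term if g_total is None else g_total + term
    g_total = g_total * (1.0 / n)
    _check_finite(g_total.item(), "pseudo-supervised training")
    g_opt.zero_grad()
    g_total.backward()
    g_opt.step()
    return record


# ---------------------------------------------------------------------------
# stage II: alternating fine-tuning
# ---------------------------------------------------------------------------

def finetune_alternating(G: Generator, D: Discriminator, f: ProjectionHead,
                         R: RegNet, pairs, cfg: TrainConfig, log_path=None):
    """Alternate R updates (WSI scale) and G updates (patch scale).

    The R step minimizes the stage-II WSI loss against the frozen
    translator's output.  The G step optimizes the full weighted sum of
    the four objectives — adversarial, contrastive, pseudo-supervised
    and the registration-based patch term — so the misaligned L1
    supervision refines rather than overwrites the learned tone mapping.
    Patch crops of the registered stain and of X share grid coordinates
    exactly.  Returns the loss history.
    """
    from .nets import encoder_features, register

    if not getattr(R, "pretrained", False):
        warnings.warn("registration network was not pre-trained; "
                      "alternating fine-tuning may start far from identity")
    rng = np.random.default_rng(cfg.seed + 11)
    g_opt = _opt(G, cfg)
    f_opt = _opt(f, cfg)
    d_opt = _opt(D, cfg)
    r_opt = _opt(R, cfg, lr=cfg.lr_reg)
    w = cfg.weights

    prepped = []
    for p in pairs:
        x_eq = hist_equalize(np.asarray(p.x, dtype=np.float64))
        od_eq = hist_equalize(optical_density(np.asarray(p.y)).od)
        prepped.append((x_eq, od_eq, np.asarray(p.y, dtype=np.float64)))

    history = []
    for it in range(cfg.iters_alt):
        x_eq, od_eq, y = prepped[it % len(prepped)]

        # --- R step(s), G fixed ---
        reg_r_val = np.nan
        for _ in range(cfg.alt_ratio):
            ds = G.stain(x_eq)
            phi_t = R(x_eq, od_eq)
            loss_r = L.reg_stage2_R(ds, y, phi_t, cfg.lambda_tv)
            reg_r_val = loss_r.item()
            _check_finite(reg_r_val, "alternating R training")
            r_opt.zero_grad()
            loss_r.backward()
            r_opt.step()

        # --- G step, R fixed: weighted sum of all four objectives ---
        phi = register(R, x_eq, od_eq)
        y_reg = warp_image(y, phi)
        xp, grid = split(x_eq, patch=cfg.patch, pad_value=0.0)
        yp, grid_y = split(y_reg, patch=cfg.patch, pad_value=1.0)
        assert grid.origins == grid_y.origins
        k = int(rng.integers(len(grid.origins)))

        # discriminator keeps pace with the evolving translator
        with ad.no_grad():
            fake_np = G(xp[k]).data
        d_loss = L.lsgan_d(D(yp[k]), D(Tensor(fake_np)))
        d_opt.zero_grad()
        d_loss.backward()
        d_opt.step()

        fake_t = G(xp[k])
        reg_term = L.reg_stage2_G(fake_t, yp[k])
        gan_term = L.lsgan_g(D(fake_t))
        odq = hist_equalize(optical_density(yp[k]).od)
        pseudo_term = L.l1(G(odq), yp[k].transpose(2, 0, 1)[None])
        seed = cfg.seed * 977 + it
        z = _detach_stack(encoder_features(G, xp[k], f, n_samples=cfg.n_nce,
                                           seed=seed))
        zh = encoder_features(G, _luminance_t(fake_t), f,
                              n_samples=cfg.n_nce, seed=seed)
        nce_term = L.patch_nce(z, zh, cfg.tau)
        total = L.total_loss({"gan_g": gan_term, "nce": nce_term,
                              "pseudo": pseudo_term, "reg": reg_term}, w)
        reg_g_val = reg_term.item()
        _check_finite(total.item(), "alternating G training")
        g_opt.zero_grad()
        f_opt.zero_grad()
        total.backward()
        g_opt.step()
        f_opt.step()

        history.append({"iter": it, "reg_R": reg_r_val, "reg_G": reg_g_val})
        _append_log(log_path, {"iter": it, "phase": "alternate",
                               "reg_R": reg_r_val, "reg_G": reg_g_val})
    return history


# ---------------------------------------------------------------------------
# full protocol + checkpointing
# ---------------------------------------------------------------------------

def build_networks(cfg: TrainConfig):
    G = Generator(cfg.profile, seed=cfg.seed)
    D = Discriminator(cfg.profile, seed=cfg.seed)
    f = make_projection_head(G, seed=cfg.seed)
    R = RegNet(cfg.profile, seed=cfg.seed)
    return G, D, f, R


def train_pipeline(pairs, cfg: TrainConfig, log_path=None, nets=None):
    """Run the full three-phase protocol on weakly-paired WSIs.

    pairs: list of WeakPair.  Returns (G, D, f, R, logs).
    """
    G, D, f, R = nets if nets is not None else build_networks(cfg)
    rng = np.random.default_rng(cfg.seed + 5)

    reg_data = []
    for p in pairs:
        x_eq = hist_equalize(np.asarray(p.x, dtype=np.float64))
        od_eq = hist_equalize(optical_density(np.asarray(p.y)).od)
        reg_data.append((x_eq, od_eq))
    logs = {"pretrain_reg": pretrain_registration(R, reg_data, cfg, log_path)}

    # patch pools for the coarse phase, cut on the deterministic grid
    x_pool, y_pool = [], []
    for (x_eq, _), p in zip(reg_data, pairs):
        xp, _ = split(x_eq, patch=cfg.patch, pad_value=0.0)
        yp, _ = split(np.asarray(p.y, dtype=np.float64), patch=cfg.patch,
                      pad_value=1.0)
        x_pool.extend(list(xp))
        y_pool.extend(list(yp))

    cut_log = []
    for it in range(cfg.iters_cut):
        xi = int(rng.integers(len(x_pool)))
        yi = int(rng.integers(len(y_pool)))
        rec = train_step_cut(G, D, f, [(x_pool[xi], y_pool[yi])], cfg,
                             nce_seed=cfg.seed * 131 + it)
        rec_p = train_step_pseudo(G, D, [y_pool[yi]], cfg)
        rec.update({"pseudo": rec_p["pseudo"]})
        cut_log.append(rec)
        _append_log(log_path, {"iter": it, "phase": "cut", **rec})
    logs["cut"] = cut_log

    logs["alternate"] = finetune_alternating(G, D, f, R, pairs, cfg, log_path)
    return G, D, f, R, logs


def save_checkpoint(path, G, D, f, R, cfg: TrainConfig):
    arrays = {}
    for name, net in (("G", G), ("D", D), ("f", f), ("R", R)):
        for i, p in enumerate(net.state_dict()):
            arrays[f"{name}_{i}"] = p
    arrays["_config"] = np.frombuffer(
        yaml.safe_dump(cfg.to_dict()).encode(), dtype=np.uint8)
    arrays["_hash"] = np.frombuffer(cfg.config_hash().encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_checkpoint(path):
    data = np.load(path)
    cfg_dict = yaml.safe_load(bytes(data["_config"]).decode())
    cfg_dict["weights"] = LossWeights(**cfg_dict["weights"])
    cfg_dict["betas"] = tuple(cfg_dict["betas"])
    cfg = TrainConfig(**cfg_dict)
    G, D, f, R = build_networks(cfg)
    for name, net in (("G", G), ("D", D), ("f", f), ("R", R)):
        state = [data[f"{name}_{i}"] for i in range(len(net.state_dict()))]
        net.load_state_dict(state)
    R.pretrained = True
    return G, D, f, R, cfg
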