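"""Joint Deep Classification + Segmentation (DCS) model.

A five-scale encoder/decoder segmentation network in the UNet3+ style:
full-scale skip connections (every decoder stage aggregates features from all
encoder and decoder scales), deep supervision (an auxiliary softmax head at
the bottleneck and at every decoder stage), space-time 3D convolutions with
spatial-only pooling (the time axis is never compressed), a classification-
guided module (CGM) branching from the bottleneck, and a tunable side input
that injects the one-hot-encoded DICOM series description at the bottleneck:
the 6-vector passes through an MLP producing one bottleneck-plane of values
(64 elements for the default 128-input geometry, reshaped 8x8 and tiled over
all frames) which is concatenated to the bottleneck features, bringing the
default bottleneck to 255 + 1 = 256 channels.

Training minimizes, at every deep-supervision head, a weighted combination of
focal Tversky loss (segmentation) and categorical cross-entropy on the CGM
output (classification), with head weights (0.25, 0.25, 0.25, 0.25, 1.00)
and term weights (1.00, 0.25).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import affine_transform

from . import nn
from .nn import Tensor, functional as F
from .prep import CLASSES, PreparedSample, preprocess

N_CLASSES = len(CLASSES)


@dataclass
class DCSConfig:
    filters: tuple = (16, 32, 64, 128, 255)
    tunable_filters: int = 1
    n_classes: int = N_CLASSES
    input_size: int = 128
    input_frames: int = 32
    source_channels: int | None = None   # per-source channels in decoder fusion
    decoder_channels: int | None = None  # fused decoder channels
    mlp_hidden: int = 32
    ds_weights: tuple = (0.25, 0.25, 0.25, 0.25, 1.00)
    seg_weight: float = 1.00
    cgm_weight: float = 0.25
    tversky_alpha: float = 0.7
    tversky_beta: float = 0.3
    tversky_gamma: float = 4.0 / 3.0
    dropout: float = 0.3
    epochs: int = 400
    batch_size: int = 8
    lr: float = 1e-3
    augment_geometric: bool = True
    augment_intensity: bool = True
    scramble_prob: float = 0.05
    sign_flip: bool = True
    seed: int = 0

    def __post_init__(self):
        self.filters = tuple(self.filters)
        self.ds_weights = tuple(self.ds_weights)
        if self.input_size % 16:
            raise ValueError("input size must be divisible by 2^4")
        if self.source_channels is None:
            self.source_channels = self.filters[0]
        if self.decoder_channels is None:
            self.decoder_channels = 5 * self.source_channels

    @property
    def bottleneck_size(self) -> int:
        return self.input_size // 16

    @property
    def bottleneck_channels(self) -> int:
        return self.filters[-1] + self.tunable_filters

    @classmethod
    def test_profile(cls, **kw) -> "DCSConfig":
        """Reduced configuration sized for CPU training in a test run."""
        defaults = dict(filters=(4, 8, 16, 32, 63), input_size=32, input_frames=8,
                        source_channels=4, decoder_channels=8, mlp_hidden=16,
                        epochs=60, batch_size=8, augment_geometric=False)
        defaults.update(kw)
        return cls(**defaults)


class _ConvBlock(nn.Module):
    """Conv3d -> instance norm -> ReLU, repeated."""

    def __init__(self, c_in, c_out, rng, n_convs=2):
        self.convs = [nn.Conv3d(c_in if i == 0 else c_out, c_out, 3, rng)
                      for i in range(n_convs)]

    def __call__(self, x):
        for c in self.convs:
            x = F.instance_norm(c(x)).relu()
        return x


class DCSNetwork(nn.Module):
    """The network itself; see module docstring for the architecture."""

    def __init__(self, config: DCSConfig, rng: np.random.Generator):
        cfg = self.config = config
        f = cfg.filters
        self.enc = []
        c_in = 2
        for s in range(5):
            self.enc.append(_ConvBlock(c_in, f[s], rng, n_convs=2 if s < 4 else 1))
            c_in = f[s]
        bs = cfg.bottleneck_size
        self.mlp1 = nn.Dense(cfg.n_classes, cfg.mlp_hidden, rng)
        self.mlp2 = nn.Dense(cfg.mlp_hidden, cfg.tunable_filters * bs * bs, rng)
        cb = cfg.bottleneck_channels
        self.cgm = nn.Dense(cb, cfg.n_classes, rng)

        sc, dc = cfg.source_channels, cfg.decoder_channels
        # decoder stages for scales 3,2,1,0; stage at scale s fuses 5 sources
        self.src_convs = []   # [stage][source] projection convs
        self.fuse_convs = []
        for s in (3, 2, 1, 0):
            convs = []
            for s_src in range(5):
                if s_src <= s:
                    convs.append(nn.Conv3d(f[s_src], sc, 3, rng))
                else:
                    convs.append(nn.Conv3d(cb if s_src == 4 else dc, sc, 3, rng))
            self.src_convs.append(convs)
            self.fuse_convs.append(nn.Conv3d(5 * sc, dc, 3, rng))
        self.heads = [nn.Conv3d(c, cfg.n_classes, 1, rng)
                      for c in [cb, dc, dc, dc, dc]]

    # -- forward -----------------------------------------------------------
    def __call__(self, x: Tensor, tunable: Tensor, rng=None, training=False,
                 encoder_only=False):
        cfg = self.config
        feats = []
        h = x
        for s in range(5):
            h = self.enc[s](h)
            feats.append(h)
            if s < 4:
                h = F.maxpool3d_spatial(h, 2)

        # tunable injection at the bottleneck
        n, _, t = x.shape[0], x.shape[1], x.shape[2]
        bs = cfg.bottleneck_size
        emb = self.mlp2(self.mlp1(tunable).relu())  # (N, tf*bs*bs)
        plane = emb.reshape(n, cfg.tunable_filters, 1, bs, bs)
        tile = np.ones((1, 1, t, 1, 1), dtype=np.float32)
        plane = plane * Tensor(tile)  # broadcast across frames
        bottleneck = nn.concat([feats[4], plane], axis=1)

        pooled = F.global_maxpool(bottleneck)
        if training and rng is not None:
            pooled = pooled.dropout(cfg.dropout, rng, training=True)
        cgm_probs = self.cgm(pooled).softmax(axis=1)

        if encoder_only:
            return bottleneck, cgm_probs

        # full-scale skip decoder
        decs = {4: bottleneck}
        for i, s in enumerate((3, 2, 1, 0)):
            srcs = []
            for s_src in range(5):
                conv = self.src_convs[i][s_src]
                if s_src <= s:
                    src = feats[s_src]
                    for _ in range(s - s_src):
                        src = F.maxpool3d_spatial(src, 2)
                    src = F.instance_norm(conv(src)).relu()
                else:
                    src = F.instance_norm(conv(decs[s_src])).relu()
                    for _ in range(s_src - s):
                        src = F.upsample3d_spatial(src, 2)
                srcs.append(src)
            decs[s] = F.instance_norm(
                self.fuse_convs[i](nn.concat(srcs, axis=1))).relu()

        seg_probs = []
        for head, scale_key in zip(self.heads, (4, 3, 2, 1, 0)):
            logits = head(decs[scale_key])
            for _ in range(scale_key):
                logits = F.upsample3d_spatial(logits, 2)
            seg_probs.append(logits.softmax(axis=1))
        return seg_probs, cgm_probs


# --------------------------------------------------------------------------
# losses
# --------------------------------------------------------------------------

def focal_tversky_loss(pred_probs: Tensor, truth_onehot: np.ndarray,
                       alpha: float = 0.7, beta: float = 0.3,
                       gamma: float = 4.0 / 3.0, eps: float = 1e-6) -> Tensor:
    """Sum over classes of (1 - Tversky index)^gamma.

    The Tversky index TI = TP / (TP + alpha*FN + beta*FP) is computed per
    class over all voxels of the batch.  alpha > beta penalizes false
    negatives more, countering the extreme foreground/background imbalance of
    small vessels.
    """
    if pred_probs.size == 0:
        raise ValueError("empty prediction tensor")
    g = Tensor(truth_onehot.astype(pred_probs.data.dtype))
    axes = (0, 2, 3, 4) if pred_probs.ndim == 5 else tuple(
        i for i in range(pred_probs.ndim) if i != 1)
    tp = (pred_probs * g).sum(axis=axes)
    fn = g.sum(axis=axes) - tp
    fp = pred_probs.sum(axis=axes) - tp
    ti = (tp + eps) / (tp + alpha * fn + beta * fp + eps)
    return ((1.0 - ti).clip_min(0.0) ** gamma).sum()


def categorical_cross_entropy(pred_probs: Tensor, truth_onehot: np.ndarray) -> Tensor:
    """Mean over the batch of -sum_c g_c log q_c."""
    g = Tensor(truth_onehot.astype(pred_probs.data.dtype))
    return -(g * pred_probs.clip_min(1e-9).log()).sum() * (1.0 / pred_probs.shape[0])


def combined_loss(seg_probs: list, cgm_probs: Tensor, truth_onehot: np.ndarray,
                  truth_class_onehot: np.ndarray, config: DCSConfig):
    """Deep-supervised weighted sum of segmentation and classification terms."""
    if len(seg_probs) != len(config.ds_weights):
        raise ValueError("one prediction per deep-supervision head required")
    ce = categorical_cross_entropy(cgm_probs, truth_class_onehot)
    total = None
    ft_final = None
    for w, probs in zip(config.ds_weights, seg_probs):
        ft = focal_tversky_loss(probs, truth_onehot, config.tversky_alpha,
                                config.tversky_beta, config.tversky_gamma)
        term = w * (config.seg_weight * ft + config.cgm_weight * ce)
        total = term if total is None else total + term
        ft_final = ft
    return total, ft_final, ce


# --------------------------------------------------------------------------
# augmentation
# --------------------------------------------------------------------------

def augment(sample: PreparedSample, rng: np.random.Generator,
            config: DCSConfig, flip_sign: bool = False) -> PreparedSample:
    """On-the-fly augmentation applied identically to both channels and mask.

    Geometric: rotation, translation and isotropic rescale (one affine per
    sample, shared across frames).  Intensity: brightness/contrast jitter on
    the magnitude channel.  The encoded description is replaced by a random
    one-hot with probability ``scramble_prob`` and the imaginary channel sign
    is inverted when ``flip_sign`` (alternated by the caller across samples).
    """
    ch = sample.channels.copy()
    mask = None if sample.truth_mask is None else sample.truth_mask.copy()
    s = ch.shape[-1]

    if config.augment_geometric:
        ang = np.deg2rad(rng.uniform(-10, 10))
        scale = rng.uniform(0.9, 1.1)
        shift = rng.uniform(-0.05, 0.05, size=2) * s
        c, si = np.cos(ang), np.sin(ang)
        mat = np.array([[c, -si], [si, c]]) / scale
        center = (s - 1) / 2.0
        off = center - mat @ (center + shift)
        for ci in range(2):
            for t in range(ch.shape[1]):
                ch[ci, t] = affine_transform(ch[ci, t], mat, offset=off, order=1,
                                             mode="constant", cval=0.0)
        if mask is not None:
            new_mask = np.empty_like(mask)
            for t in range(mask.shape[0]):
                new_mask[t] = affine_transform(mask[t].astype(float), mat,
                                               offset=off, order=0) > 0.5
            mask = new_mask

    if config.augment_intensity:
        ch[0] = np.clip(ch[0] * (1.0 + rng.uniform(-0.1, 0.1))
                        + rng.uniform(-0.1, 0.1), 0, None)

    if flip_sign:
        ch[1] = -ch[1]

    enc = sample.encoded
    if rng.random() < config.scramble_prob:
        onehot = np.zeros(config.n_classes, dtype=np.float32)
        onehot[rng.integers(config.n_classes)] = 1.0
        enc = type(enc)(onehot)

    return PreparedSample(channels=ch, encoded=enc, geometry=sample.geometry,
                          series=sample.series, truth_mask=mask,
                          truth_class=sample.truth_class)


# --------------------------------------------------------------------------
# model / results objects
# --------------------------------------------------------------------------

def _truth_tensors(batch, cfg: DCSConfig):
    n = len(batch)
    fshape = (n, cfg.n_classes, cfg.input_frames, cfg.input_size, cfg.input_size)
    seg = np.zeros(fshape, dtype=np.float32)
    cls = np.zeros((n, cfg.n_classes), dtype=np.float32)
    for i, s in enumerate(batch):
        m = s.truth_mask.astype(bool)
        seg[i, s.truth_class] = m
        seg[i, N_CLASSES - 1] = ~m
        cls[i, s.truth_class] = 1.0
    return seg, cls


def _input_tensors(batch):
    x = np.stack([s.channels for s in batch]).astype(np.float32)
    tun = np.stack([s.encoded.onehot for s in batch]).astype(np.float32)
    return Tensor(x), Tensor(tun)


class DeepClassSeg:
    """Joint classification+segmentation model (fit/predict interface)."""

    def __init__(self, config: DCSConfig | None = None):
        self.config = config or DCSConfig()
        self.rng = np.random.default_rng(self.config.seed)
        self.network = DCSNetwork(self.config, self.rng)

    # -- training ----------------------------------------------------------
    def fit(self, samples: list, epochs: int | None = None,
            verbose: bool = False) -> "DCSFitResults":
        cfg = self.config
        epochs = cfg.epochs if epochs is None else epochs
        opt = nn.Adam(self.network.parameters(), lr=cfg.lr)
        hist = []
        order = np.arange(len(samples))
        for epoch in range(epochs):
            self.rng.shuffle(order)
            ft_sum = ce_sum = 0.0
            nb = 0
            for start in range(0, len(order), cfg.batch_size):
                idx = order[start:start + cfg.batch_size]
                batch = [augment(samples[i], self.rng, cfg,
                                 flip_sign=cfg.sign_flip and bool(j % 2))
                         for j, i in enumerate(idx)]
                x, tun = _input_tensors(batch)
                seg_t, cls_t = _truth_tensors(batch, cfg)
                seg_probs, cgm = self.network(x, tun, rng=self.rng, training=True)
                loss, ft, ce = combined_loss(seg_probs, cgm, seg_t, cls_t, cfg)
                if not np.isfinite(loss.item()):
                    raise FloatingPointError(f"loss diverged at epoch {epoch}")
                opt.zero_grad()
                loss.backward()
                opt.step()
                ft_sum += ft.item()
                ce_sum += ce.item()
                nb += 1
            hist.append({"epoch": epoch, "focal_tversky": ft_sum / max(nb, 1),
                         "cgm_ce": ce_sum / max(nb, 1)})
            if verbose:
                print(f"epoch {epoch}: ft={hist[-1]['focal_tversky']:.4f} "
                      f"ce={hist[-1]['cgm_ce']:.4f}", flush=True)
        return DCSFitResults(self, pd.DataFrame(hist))

    # -- inference -----------------------------------------------------------
    def predict(self, sample: PreparedSample):
        """Classify and segment one prepared series.

        Returns ``(vessel_class, mask, confidence)``: the argmax CGM class
        (possibly "background"), the per-voxel argmax mask of the final head
        gated by the CGM probabilities and restricted to the predicted class,
        and the CGM confidence.
        """
        x, tun = _input_tensors([sample])
        seg_probs, cgm = self.network(x, tun, training=False)
        cgm_p = cgm.data[0]
        pred_class = int(np.argmax(cgm_p))
        probs = seg_probs[-1].data[0].copy()  # (6, F, S, S)
        # CGM gating: scale each vessel channel by its class probability
        probs[:N_CLASSES - 1] *= cgm_p[:N_CLASSES - 1, None, None, None]
        vox = np.argmax(probs, axis=0)
        if pred_class == N_CLASSES - 1:
            mask = np.zeros(vox.shape, dtype=bool)
        else:
            mask = vox == pred_class
        return CLASSES[pred_class], mask, float(cgm_p[pred_class])


    # -- persistence -------------------------------------------------------
    def save(self, path):
        import dataclasses
        import json
        cfg = dataclasses.asdict(self.config)
        np.savez_compressed(path, __config__=np.asarray(json.dumps(cfg)),
                            **self.network.state_dict())

    @classmethod
    def load(cls, path) -> "DeepClassSeg":
        import json
        data = np.load(path)
        cfg = DCSConfig(**json.loads(str(data["__config__"])))
        model = cls(cfg)
        model.network.load_state_dict(data)
        return model


@dataclass
class DCSFitResults:
    model: DeepClassSeg
    history: pd.DataFrame

    def summary(self) -> str:
        h = self.history
        cfg = self.model.config
        lines = [
            "Deep Classification + Segmentation fit",
            f"  filters {cfg.filters} + {cfg.tunable_filters} tunable "
            f"(bottleneck {cfg.bottleneck_channels})",
            f"  input {cfg.input_size}x{cfg.input_size}x{cfg.input_frames}, "
            f"parameters {self.model.network.n_parameters():,}",
            f"  epochs {len(h)}, batch {cfg.batch_size}, Adam lr {cfg.lr}",
        ]
        if len(h):
            lines.append(f"  focal Tversky {h['focal_tversky'].iloc[0]:.4f} -> "
                         f"{h['focal_tversky'].iloc[-1]:.4f}")
            lines.append(f"  CGM cross-entropy {h['cgm_ce'].iloc[0]:.4f} -> "
                         f"{h['cgm_ce'].iloc[-1]:.4f}")
        return "\n".join(lines)


# --------------------------------------------------------------------------
# spec-level convenience functions
# --------------------------------------------------------------------------

def build_model(config: DCSConfig | None = None) -> DeepClassSeg:
    return DeepClassSeg(config)


def prepare_training_samples(exams, config: DCSConfig,
                             dictionary: dict | None = None) -> list:
    """Preprocess every series of every phantom exam into training samples."""
    samples = []
    for ex in exams:
        for vessel, series in ex.series.items():
            ps = preprocess(series, dictionary=dictionary,
                            target_size=config.input_size,
                            target_frames=config.input_frames,
                            truth_mask=ex.truth_masks[vessel])
            ps.truth_class = CLASSES.index(vessel)
            samples.append(ps)
    return samples


def train_dcs(exams, config: DCSConfig | None = None, epochs=None,
              verbose=False):
    """Train on a set of synthetic exams; returns (model, history)."""
    config = config or DCSConfig()
    model = DeepClassSeg(config)
    samples = prepare_training_samples(exams, config)
    if not samples:
        raise ValueError("no training samples")
    results = model.fit(samples, epochs=epochs, verbose=verbose)
    return model, results.history


def infer(model: DeepClassSeg, sample: PreparedSample):
    return model.predict(sample)
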