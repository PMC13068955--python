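"""Deep temporal clustering (DTC) of two-channel flow curves.

A temporal autoencoder (1D conv -> max-pool -> two bidirectional LSTMs)
compresses each BSA-indexed, 30-frame, z-scored two-channel flow curve into a
short latent sequence z_i.  A clustering layer holds k centroids mu_j in that
latent space and assigns soft memberships with a Student's-t kernel
(one degree of freedom):

    q_ij = (1 + ||z_i - mu_j||^2)^-1 / sum_j' (1 + ||z_i - mu_j'||^2)^-1

Self-training sharpens the assignments towards the target distribution

    p_ij = (q_ij^2 / sum_i q_ij) / sum_j' (q_ij'^2 / sum_i q_ij')

by minimizing reconstruction MSE + KL(P || Q) jointly over autoencoder
weights and centroids (equal weights, Adam).  P is recomputed at fixed
assignment-update intervals; training stops when fewer than 0.1% of samples
change hard assignment between consecutive updates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from . import nn
from .nn import Tensor, functional as F
from .flowquant import FlowCurve

N_FRAMES = 30


# --------------------------------------------------------------------------
# preprocessing and exclusion rules
# --------------------------------------------------------------------------

@dataclass
class DTCInput:
    curves: np.ndarray          # (n, 30, 2), BSA-indexed and z-scored
    channel_labels: tuple = ("LPA", "RPA")
    sample_ids: list = None
    norm_mean: float = 0.0      # dataset-wide statistics used for z-scoring
    norm_sd: float = 1.0

    def __post_init__(self):
        self.curves = np.asarray(self.curves, dtype=np.float64)
        if self.curves.ndim != 3 or self.curves.shape[1] != N_FRAMES:
            raise ValueError(f"expected (n, {N_FRAMES}, channels) curves")
        if self.sample_ids is None:
            self.sample_ids = [f"s{i}" for i in range(len(self.curves))]

    @property
    def n(self):
        return len(self.curves)


def prep_curves(raw_curves, bsa, channel_labels=("LPA", "RPA"),
                sample_ids=None) -> DTCInput:
    """BSA-index, cubic-spline-resample to 30 frames and globally z-score.

    ``raw_curves`` is a sequence of (T_i, 2) arrays (mL/s; T_i may vary,
    >= 4 frames); ``bsa`` the per-sample body surface area (m^2).  One mean
    and SD computed over the whole dataset (all samples, frames and channels)
    are used for z-scoring, so between-sample amplitude differences survive
    normalization.
    """
    bsa = np.asarray(bsa, dtype=float)
    if np.any(bsa <= 0):
        raise ValueError("BSA must be positive")
    resampled = []
    for i, c in enumerate(raw_curves):
        c = np.asarray(c, dtype=float)
        if c.ndim != 2 or c.shape[0] < 4:
            raise ValueError("each curve needs >= 4 frames and 2 channels")
        indexed = c / bsa[i]
        if c.shape[0] == N_FRAMES:
            resampled.append(indexed.copy())
        else:
            x_old = np.linspace(0.0, 1.0, c.shape[0])
            x_new = np.linspace(0.0, 1.0, N_FRAMES)
            resampled.append(CubicSpline(x_old, indexed, axis=0)(x_new))
    arr = np.asarray(resampled)
    mean, sd = float(arr.mean()), float(arr.std())
    if sd == 0:
        raise ValueError("zero variance dataset: z-score undefined")
    return DTCInput(curves=(arr - mean) / sd, channel_labels=tuple(channel_labels),
                    sample_ids=sample_ids, norm_mean=mean, norm_sd=sd)


MIN_AORTIC_VOLUME_ML = 10.0


def exclusion_filter(aortic: FlowCurve | None, bsa, rr) -> tuple:
    """Exam-level exclusion rules applied before clustering.

    Returns ``(keep, reason)``.  Drops: aortic flow peaking in the second
    half of the cycle (pulse-gated acquisition, cannot be aligned with
    ECG-gated data); aortic net forward volume below 10 mL (non-
    physiological); missing RR interval or BSA.
    """
    if aortic is None:
        return False, "missing aortic curve"
    peak_frame = int(np.argmax(aortic.flow))
    if peak_frame >= aortic.n_frames / 2.0:
        return False, "pulse-gated"
    if aortic.net_forward_volume < MIN_AORTIC_VOLUME_ML:
        return False, "non-physiological"
    if rr is None or (isinstance(rr, float) and not np.isfinite(rr)):
        return False, "missing RR"
    if bsa is None or (isinstance(bsa, float) and not np.isfinite(bsa)):
        return False, "missing BSA"
    return True, None


# --------------------------------------------------------------------------
# soft assignment and target distribution
# --------------------------------------------------------------------------

def soft_assign(z: np.ndarray, centroids: np.ndarray) -> np.ndarray:
    """Student's-t (df=1) soft assignments Q (rows sum to 1)."""
    z = np.asarray(z, float)
    mu = np.asarray(centroids, float)
    if len(mu) < 2:
        raise ValueError("need k >= 2 centroids")
    d2 = ((z[:, None, :] - mu[None]) ** 2).sum(axis=2)
    kernel = 1.0 / (1.0 + d2)
    return kernel / kernel.sum(axis=1, keepdims=True)


def target_distribution(q: np.ndarray) -> np.ndarray:
    """Sharpened self-training target P from soft assignments Q."""
    q = np.asarray(q, float)
    weight = q ** 2 / q.sum(axis=0)
    return weight / weight.sum(axis=1, keepdims=True)


def _soft_assign_t(z: Tensor, centroids: Tensor) -> Tensor:
    """Autograd version of :func:`soft_assign` used inside training."""
    n, d = z.shape
    k = centroids.shape[0]
    diff = z.reshape(n, 1, d) - centroids.reshape(1, k, d)
    d2 = (diff * diff).sum(axis=2)
    kernel = (1.0 + d2) ** -1.0
    return kernel / kernel.sum(axis=1, keepdims=True)


# --------------------------------------------------------------------------
# temporal autoencoder
# --------------------------------------------------------------------------

@dataclass
class TAEConfig:
    conv_filters: int = 50
    conv_kernel: int = 10
    pool: int = 3
    lstm_units: tuple = (50, 1)
    decoder_dense: int = 50
    deconv_kernel: int = 10
    pretrain_epochs: int = 100
    lr: float = 1e-3
    mse_weight: float = 1.0
    kl_weight: float = 1.0
    update_interval: int = 100      # epochs between assignment updates
    convergence_frac: float = 1e-3  # < 0.1% of samples changing assignment
    max_epochs: int = 3000
    batch_size: int = 64
    kmeans_restarts: int = 10
    seed: int = 0

    def latent_length(self, n_frames: int = N_FRAMES) -> int:
        if n_frames % self.pool:
            raise ValueError("pool size must divide the frame count")
        return n_frames // self.pool

    def latent_dim(self, n_frames: int = N_FRAMES) -> int:
        return self.latent_length(n_frames) * 2 * self.lstm_units[-1]


class TemporalAutoencoder(nn.Module):
    """Conv -> pool -> BiLSTM x2 encoder; dense -> upsample -> deconv decoder."""

    def __init__(self, config: TAEConfig, n_channels: int = 2,
                 rng: np.random.Generator | None = None):
        cfg = self.config = config
        rng = rng if rng is not None else np.random.default_rng(cfg.seed)
        self.conv = nn.Conv1d(n_channels, cfg.conv_filters, cfg.conv_kernel, rng)
        self.lstm1 = nn.BiLSTM(cfg.conv_filters, cfg.lstm_units[0], rng)
        self.lstm2 = nn.BiLSTM(2 * cfg.lstm_units[0], cfg.lstm_units[1], rng)
        self.dec_dense = nn.Dense(2 * cfg.lstm_units[1], cfg.decoder_dense, rng)
        self.deconv = nn.Conv1d(cfg.decoder_dense, n_channels,
                                cfg.deconv_kernel, rng)

    def encode(self, x: Tensor) -> Tensor:
        """(N, T, C) -> latent sequence (N, T/pool, 2*units_last)."""
        h = self.conv(x.transpose(0, 2, 1)).relu()   # (N, F, T)
        h = F.maxpool1d(h, self.config.pool)
        h = h.transpose(0, 2, 1)                     # (N, T/pool, F)
        h = self.lstm1(h).tanh()
        return self.lstm2(h).tanh()

    def decode(self, latent: Tensor) -> Tensor:
        h = self.dec_dense(latent).relu()            # (N, L, dense)
        h = F.upsample1d(h.transpose(0, 2, 1), self.config.pool)
        return self.deconv(h).transpose(0, 2, 1)     # (N, T, C)

    def __call__(self, x: Tensor):
        latent = self.encode(x)
        recon = self.decode(latent)
        n = x.shape[0]
        z = latent.reshape(n, -1)
        return recon, z

    def latent(self, curves: np.ndarray) -> np.ndarray:
        """Latent vectors for an (n, T, C) array, without gradients."""
        lat = self.encode(Tensor(curves.astype(np.float32)))
        return lat.data.reshape(len(curves), -1).astype(np.float64)


def pretrain_autoencoder(data: DTCInput, config: TAEConfig | None = None,
                         model: TemporalAutoencoder | None = None,
                         epochs: int | None = None):
    """Minimize reconstruction MSE for ``pretrain_epochs``; returns (model, z, history)."""
    config = config or TAEConfig()
    rng = np.random.default_rng(config.seed)
    if model is None:
        model = TemporalAutoencoder(config, data.curves.shape[2], rng)
    epochs = config.pretrain_epochs if epochs is None else epochs
    x_all = data.curves.astype(np.float32)
    opt = nn.Adam(model.parameters(), lr=config.lr)
    history = []
    order = np.arange(data.n)
    for epoch in range(epochs):
        rng.shuffle(order)
        tot, nb = 0.0, 0
        for s in range(0, data.n, config.batch_size):
            xb = Tensor(x_all[order[s:s + config.batch_size]])
            recon, _ = model(xb)
            loss = ((recon - xb) ** 2).mean()
            if not np.isfinite(loss.item()):
                raise FloatingPointError(f"NaN loss at pretrain epoch {epoch}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            tot += loss.item()
            nb += 1
        history.append(tot / nb)
    return model, model.latent(data.curves), history


# --------------------------------------------------------------------------
# joint training
# --------------------------------------------------------------------------

@dataclass
class ClusterState:
    z: np.ndarray            # (n, d) latent vectors
    centroids: np.ndarray    # (k, d)
    q: np.ndarray            # (n, k) soft assignments
    p: np.ndarray            # (n, k) target distribution
    labels: np.ndarray       # (n,) hard assignments (argmax, ties -> lowest j)
    converged: bool
    fraction_changed: list   # per assignment-update step
    epochs_run: int

    @property
    def k(self):
        return self.centroids.shape[0]


class DeepTemporalClustering:
    """DTC model: fit() pretrains, initializes centroids by k-means and
    self-trains; returns a :class:`DTCResults`."""

    def __init__(self, data: DTCInput, k: int, config: TAEConfig | None = None):
        if k < 2:
            raise ValueError("k must be >= 2")
        self.data = data
        self.k = k
        self.config = config or TAEConfig()
        self.autoencoder: TemporalAutoencoder | None = None

    def fit(self, pretrained: TemporalAutoencoder | None = None,
            verbose: bool = False) -> "DTCResults":
        cfg = self.config
        data = self.data
        if data.n < 10 * self.k:
            raise ValueError("need at least 10*k samples")
        rng = np.random.default_rng(cfg.seed + 1)

        if pretrained is None:
            self.autoencoder, z, pre_hist = pretrain_autoencoder(data, cfg)
        else:
            self.autoencoder = pretrained
            z = pretrained.latent(data.curves)
            pre_hist = []

        km = KMeans(n_clusters=self.k, n_init=cfg.kmeans_restarts,
                    random_state=cfg.seed).fit(z)
        centroids = Tensor(km.cluster_centers_.astype(np.float32),
                           requires_grad=True)
        self.initial_labels = km.labels_.copy()

        opt = nn.Adam(self.autoencoder.parameters() + [centroids], lr=cfg.lr)
        x_all = data.curves.astype(np.float32)
        order = np.arange(data.n)
        prev_labels = None
        frac_hist = []
        converged = False
        p_full = None
        epoch = 0
        while epoch < cfg.max_epochs:
            if epoch % cfg.update_interval == 0:
                z = self.autoencoder.latent(data.curves)
                q_full = soft_assign(z, centroids.data.astype(np.float64))
                p_full = target_distribution(q_full)
                labels = q_full.argmax(axis=1)
                # fraction changed is bookkept between consecutive
                # assignment-update steps of the self-training phase; the
                # k-means initialization at epoch 0 is not an update step
                if epoch > 0:
                    if prev_labels is not None:
                        frac = float((labels != prev_labels).mean())
                        frac_hist.append(frac)
                        if verbose:
                            print(f"epoch {epoch}: fraction changed {frac:.4f}")
                        if frac < cfg.convergence_frac:
                            converged = True
                            break
                    prev_labels = labels
            rng.shuffle(order)
            for s in range(0, data.n, cfg.batch_size):
                idx = order[s:s + cfg.batch_size]
                xb = Tensor(x_all[idx])
                recon, zb = self.autoencoder(xb)
                mse = ((recon - xb) ** 2).mean()
                qb = _soft_assign_t(zb, centroids)
                pb = p_full[idx]
                kl = (Tensor(pb.astype(np.float32)) *
                      (Tensor(np.log(pb + 1e-12).astype(np.float32))
                       - qb.clip_min(1e-12).log())).sum() * (1.0 / len(idx))
                loss = cfg.mse_weight * mse + cfg.kl_weight * kl
                if not np.isfinite(loss.item()):
                    raise FloatingPointError(f"NaN loss at epoch {epoch}")
                opt.zero_grad()
                loss.backward()
                opt.step()
            epoch += 1

        z = self.autoencoder.latent(data.curves)
        q_full = soft_assign(z, centroids.data.astype(np.float64))
        state = ClusterState(
            z=z, centroids=centroids.data.astype(np.float64), q=q_full,
            p=target_distribution(q_full), labels=q_full.argmax(axis=1),
            converged=converged, fraction_changed=frac_hist, epochs_run=epoch)
        return DTCResults(model=self, state=state, pretrain_history=pre_hist)


@dataclass
class DTCResults:
    model: DeepTemporalClustering
    state: ClusterState
    pretrain_history: list = field(default_factory=list)

    @property
    def labels_(self):
        return self.state.labels

    def silhouette(self, space: str = "latent") -> float:
        data = self.state.z if space == "latent" else \
            self.model.data.curves.reshape(self.model.data.n, -1)
        return silhouette(self.state.labels, data)

    def centroid_curves(self) -> np.ndarray:
        """Per-cluster mean flow curves in the (z-scored) input space."""
        curves = self.model.data.curves
        return np.stack([curves[self.state.labels == j].mean(axis=0)
                         for j in range(self.state.k)])

    def summary(self) -> str:
        s = self.state
        n_per = np.bincount(s.labels, minlength=s.k)
        lines = [
            f"Deep temporal clustering (k={s.k}, n={len(s.labels)})",
            f"  converged: {s.converged} after {s.epochs_run} epochs",
            f"  final fraction changed: "
            f"{s.fraction_changed[-1]:.4%}" if s.fraction_changed else
            "  final fraction changed: n/a",
            f"  cluster sizes: {n_per.tolist()}",
            f"  silhouette (latent space): {self.silhouette():.3f}",
        ]
        return "\n".join(lines)


# --------------------------------------------------------------------------
# silhouette and k-sensitivity
# --------------------------------------------------------------------------

def silhouette(labels, data) -> float:
    """Mean silhouette score with Euclidean distance in the given space."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("silhouette requires >= 2 clusters")
    return float(silhouette_score(np.asarray(data), labels, metric="euclidean"))


def train_dtc(data: DTCInput, k: int, config: TAEConfig | None = None,
              pretrained: TemporalAutoencoder | None = None,
              verbose: bool = False) -> DTCResults:
    return DeepTemporalClustering(data, k, config).fit(pretrained, verbose=verbose)


def k_sensitivity(data: DTCInput, k_range=range(3, 9),
                  config: TAEConfig | None = None,
                  outcome_test=None, alpha: float = 0.05) -> pd.DataFrame:
    """Train at each k and tabulate convergence, silhouette and (optionally)
    outcome association.

    ``outcome_test``, if given, maps hard labels to a p-value (e.g. a
    time-varying Cox likelihood-ratio test against the null).  The selected k
    (attribute ``selected_k`` on the returned frame; None if no k converges)
    maximizes silhouette among converged runs, restricted to those with
    p < alpha when an outcome test is supplied and any k reaches it.
    """
    rows = []
    for k in k_range:
        try:
            res = train_dtc(data, k, config)
        except (FloatingPointError, ValueError) as exc:
            rows.append({"k": k, "converged": False, "silhouette": np.nan,
                         "outcome_p": np.nan, "note": str(exc)})
            continue
        sil = res.silhouette() if len(np.unique(res.labels_)) > 1 else np.nan
        pval = np.nan
        if outcome_test is not None:
            pval = float(outcome_test(res.labels_))
        rows.append({"k": k, "converged": res.state.converged,
                     "silhouette": sil, "outcome_p": pval, "note": ""})
    table = pd.DataFrame(rows)
    ok = table[table.converged & table.silhouette.notna()]
    if outcome_test is not None and (ok.outcome_p < alpha).any():
        ok = ok[ok.outcome_p < alpha]
    selected = int(ok.loc[ok.silhouette.idxmax(), "k"]) if len(ok) else None
    table.attrs["selected_k"] = selected
    return table
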