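"""Raw PCMR series -> model-ready tensors.

A phase-contrast series is a paired magnitude/phase cine.  The model input is
a 2 x F x S x S tensor: a contrast-equalized magnitude channel and the
"imaginary" channel M*sin(phi) of the complex signal M*exp(i*phi), in which
flowing blood carries high signal while static tissue and air are near zero.
The DICOM series description is separately encoded as a six-element one-hot
vector (five vessels + other/empty) via an editable token dictionary.

The stored-phase convention is declared here: phase is in radians on
(-pi, pi], and velocity is v = VENC * phi / pi (cm/s).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.ndimage import zoom as nd_zoom
from skimage.exposure import equalize_adapthist

#: class order used across the package; index 5 is background / other.
CLASSES = ("LPA", "RPA", "SVC", "IVC", "Ao", "background")
VESSEL_SLOTS = CLASSES[:5]

TARGET_SPACING = 2.0   # mm
TARGET_SIZE = 128      # pixels
TARGET_FRAMES = 32
CLAHE_CLIP = 0.02
CLAHE_TILES = 8


@dataclass
class PCMRSeries:
    """Paired magnitude/phase cine with acquisition metadata."""
    magnitude: np.ndarray  # (T,H,W), arbitrary units, >= 0
    phase: np.ndarray      # (T,H,W), radians in (-pi, pi]
    pixel_spacing: float   # mm (isotropic in-plane)
    rr_interval: float     # ms
    venc: float            # cm/s
    description: str = ""
    acquisition_time: float = 0.0  # seconds, used only for tie-breaking

    def __post_init__(self):
        self.magnitude = np.asarray(self.magnitude)
        self.phase = np.asarray(self.phase)
        if self.magnitude.shape != self.phase.shape:
            raise ValueError("magnitude and phase shapes differ")
        if self.magnitude.ndim != 3 or self.magnitude.shape[0] < 2:
            raise ValueError("expected a (T,H,W) cine with T >= 2")

    @property
    def n_frames(self):
        return self.magnitude.shape[0]

    def velocity(self) -> np.ndarray:
        """Velocity cine in cm/s under the declared phase convention."""
        return self.venc * self.phase / np.pi


def to_imaginary(series: PCMRSeries) -> np.ndarray:
    """Imaginary component M*sin(phi) of the complex PCMR signal."""
    return series.magnitude * np.sin(series.phase)


# --------------------------------------------------------------------------
# series-description encoding
# --------------------------------------------------------------------------

def _normalize(text: str) -> str:
    return " ".join(re.split(r"[^a-z0-9]+", text.lower())).strip()


def load_dictionary(path=None) -> dict:
    """Load the vessel-token dictionary (``VESSEL: tok, tok, ...`` lines)."""
    if path is None:
        src = resources.files("fontanflow").joinpath("data/vessel_tokens.txt")
        text = src.read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    out = {}
    for line in text.splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        vessel, toks = line.split(":", 1)
        vessel = vessel.strip()
        if vessel not in VESSEL_SLOTS:
            raise ValueError(f"unknown vessel in dictionary: {vessel}")
        out.setdefault(vessel, set()).update(
            _normalize(t) for t in toks.split(",") if _normalize(t))
    return out


@dataclass
class EncodedDescription:
    onehot: np.ndarray  # (6,) float, exactly one element 1

    @property
    def slot(self) -> str:
        return CLASSES[int(np.argmax(self.onehot))] \
            if self.onehot[:5].any() else "other"


def encode_description(text: str, dictionary: dict | None = None) -> EncodedDescription:
    """Map a series description to its one-hot slot.

    Matching is case-insensitive on whole-token boundaries.  Empty text,
    unmatched text, or text matching tokens of more than one vessel all map
    to the other/empty slot.
    """
    if dictionary is None:
        dictionary = load_dictionary()
    norm = f" {_normalize(text or '')} "
    hits = [v for v, toks in dictionary.items()
            if any(f" {t} " in norm for t in toks)]
    onehot = np.zeros(len(CLASSES), dtype=np.float32)
    if len(hits) == 1:
        onehot[VESSEL_SLOTS.index(hits[0])] = 1.0
    else:
        onehot[-1] = 1.0  # other / empty / ambiguous
    return EncodedDescription(onehot)


# --------------------------------------------------------------------------
# geometric preprocessing
# --------------------------------------------------------------------------

@dataclass
class GeometryRecord:
    """Everything needed to map a model-grid mask back onto the source grid."""
    orig_shape: tuple        # (T,H,W)
    orig_spacing: float
    zoom: tuple              # spatial zoom factors applied (fy, fx)
    resampled_shape: tuple   # (H',W') after resampling
    offset: tuple            # (oy, ox): source-resampled origin in the crop frame
    target_size: int
    target_frames: int
    imag_scale: float = 1.0  # imaginary channel was divided by this


def _crop_pad(frame_stack: np.ndarray, size: int):
    """Center crop/pad (T,H,W) -> (T,size,size); returns offsets (oy,ox) such
    that output[:, y, x] = input[:, y - oy, x - ox] where defined."""
    t, h, w = frame_stack.shape
    out = np.zeros((t, size, size), dtype=frame_stack.dtype)
    oy = (size - h) // 2
    ox = (size - w) // 2
    ys, yd = max(0, -oy), max(0, oy)
    xs, xd = max(0, -ox), max(0, ox)
    hh = min(h - ys, size - yd)
    ww = min(w - xs, size - xd)
    out[:, yd:yd + hh, xd:xd + ww] = frame_stack[:, ys:ys + hh, xs:xs + ww]
    return out, (oy, ox)


def _time_resample(stack: np.ndarray, n_out: int) -> np.ndarray:
    """Cubic-spline resampling along the frame axis, endpoints preserved."""
    t = stack.shape[0]
    if t == n_out:
        return stack.copy()
    x_old = np.linspace(0.0, 1.0, t)
    x_new = np.linspace(0.0, 1.0, n_out)
    return CubicSpline(x_old, stack, axis=0)(x_new)


@dataclass
class PreparedSample:
    channels: np.ndarray  # (2, F, S, S): CLAHE magnitude, normalized imaginary
    encoded: EncodedDescription
    geometry: GeometryRecord
    series: PCMRSeries = None  # back-reference for flow computation
    truth_mask: np.ndarray = None  # optional (F,S,S) mask on the model grid
    truth_class: int | None = None


def preprocess(series: PCMRSeries, dictionary: dict | None = None,
               target_size: int = TARGET_SIZE, target_frames: int = TARGET_FRAMES,
               target_spacing: float = TARGET_SPACING,
               truth_mask: np.ndarray | None = None) -> PreparedSample:
    """Resample to the model grid and build the two-channel input tensor.

    Steps: spline resampling to ``target_spacing``; center crop/pad to
    ``target_size``; spline interpolation to ``target_frames`` frames; CLAHE
    on the magnitude channel only; the imaginary channel follows the same
    geometry and is normalized by the 99th-percentile magnitude.
    """
    if series.pixel_spacing <= 0:
        raise ValueError("pixel spacing must be positive")
    mag = np.asarray(series.magnitude, dtype=np.float64)
    imag = to_imaginary(series).astype(np.float64)

    f = series.pixel_spacing / target_spacing
    if abs(f - 1.0) > 1e-9:
        mag = nd_zoom(mag, (1.0, f, f), order=3, grid_mode=True, mode='grid-constant')
        imag = nd_zoom(imag, (1.0, f, f), order=3, grid_mode=True, mode='grid-constant')
    resampled_shape = mag.shape[1:]

    mag, offset = _crop_pad(mag, target_size)
    imag, _ = _crop_pad(imag, target_size)

    mag = _time_resample(mag, target_frames)
    imag = _time_resample(imag, target_frames)

    scale = float(np.percentile(np.abs(mag), 99))
    scale = scale if scale > 0 else 1.0
    imag = imag / scale

    mag_max = mag.max()
    eq = np.empty_like(mag)
    for i in range(mag.shape[0]):
        frame = np.clip(mag[i] / mag_max, 0, 1) if mag_max > 0 else mag[i]
        eq[i] = equalize_adapthist(frame, kernel_size=target_size // CLAHE_TILES,
                                   clip_limit=CLAHE_CLIP)

    geom = GeometryRecord(orig_shape=series.magnitude.shape,
                          orig_spacing=series.pixel_spacing,
                          zoom=(f, f), resampled_shape=resampled_shape,
                          offset=offset, target_size=target_size,
                          target_frames=target_frames, imag_scale=scale)
    out_mask, truth_class = None, None
    if truth_mask is not None:
        out_mask = project_mask(np.asarray(truth_mask, dtype=float), geom)
    return PreparedSample(
        channels=np.stack([eq, imag]).astype(np.float32),
        encoded=encode_description(series.description, dictionary),
        geometry=geom, series=series, truth_mask=out_mask,
        truth_class=truth_class)


def project_mask(mask: np.ndarray, geom: GeometryRecord) -> np.ndarray:
    """Map a source-grid (T,H,W) mask onto the model grid (F,S,S), nearest."""
    m = mask.astype(np.float64)
    f = geom.zoom[0]
    if abs(f - 1.0) > 1e-9:
        m = nd_zoom(m, (1.0, f, f), order=0, grid_mode=True, mode='grid-constant')
    m, _ = _crop_pad(m, geom.target_size)
    t = m.shape[0]
    if t != geom.target_frames:
        idx = np.rint(np.linspace(0, t - 1, geom.target_frames)).astype(int)
        m = m[idx]
    return m > 0.5


def back_project(mask: np.ndarray, geom: GeometryRecord) -> np.ndarray:
    """Map a model-grid (F,S,S) mask back onto the source grid (T,H,W)."""
    m = np.asarray(mask, dtype=np.float64)
    # undo time interpolation (nearest frame)
    t = geom.orig_shape[0]
    if m.shape[0] != t:
        idx = np.rint(np.linspace(0, m.shape[0] - 1, t)).astype(int)
        m = m[idx]
    # undo crop/pad
    oy, ox = geom.offset
    hr, wr = geom.resampled_shape
    full = np.zeros((t, hr, wr))
    ys, yd = max(0, -oy), max(0, oy)
    xs, xd = max(0, -ox), max(0, ox)
    hh = min(hr - ys, geom.target_size - yd)
    ww = min(wr - xs, geom.target_size - xd)
    full[:, ys:ys + hh, xs:xs + ww] = m[:, yd:yd + hh, xd:xd + ww]
    # undo spatial zoom
    h, w = geom.orig_shape[1:]
    if full.shape[1:] != (h, w):
        full = nd_zoom(full, (1.0, h / full.shape[1], w / full.shape[2]), order=0, grid_mode=True, mode='grid-constant')
        full = full[:, :h, :w]
        if full.shape[1] < h or full.shape[2] < w:
            pad = ((0, 0), (0, h - full.shape[1]), (0, w - full.shape[2]))
            full = np.pad(full, pad)
    return full > 0.5
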