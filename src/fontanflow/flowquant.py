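"""Mask post-processing, flow quantification and agreement metrics.

Flow is computed from the phase cine under the package's phase convention
(v = VENC * phi / pi): the per-frame volumetric flow rate is the sum of
velocity over mask pixels times pixel area, and the net forward volume is the
time integral of that curve over one cardiac cycle.  Post-processing retains
the largest space-time connected component for the LPA, RPA and IVC and the
two largest for the aorta and SVC (neo/native aortas, bilateral SVCs).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.measure import label as cc_label

from .prep import PCMRSeries

#: vessels whose masks keep a single connected component
_SINGLE_COMPONENT = {"LPA", "RPA", "IVC"}
#: vessels whose masks keep the two largest components
_DOUBLE_COMPONENT = {"Ao", "SVC"}


@dataclass
class VesselMaskCine:
    mask: np.ndarray  # (T,H,W) bool
    vessel: str
    geometry: object = None

    def __post_init__(self):
        self.mask = np.asarray(self.mask).astype(bool)


@dataclass
class FlowCurve:
    flow: np.ndarray        # (T,) mL/s
    times: np.ndarray       # (T,) ms from cycle start
    rr_interval: float      # ms
    vessel: str = ""
    net_forward_volume: float = 0.0   # mL
    indexed_flow_rate: float | None = None  # L/min/m^2

    @property
    def n_frames(self):
        return len(self.flow)


def postprocess_mask(mask: VesselMaskCine) -> VesselMaskCine:
    """Connected-component retention rule.

    Components are labelled in 2D+time (26-connectivity) so a vessel is one
    object across frames.  LPA/RPA/IVC keep the single largest component;
    Ao/SVC keep the two largest; an empty mask stays empty.
    """
    if mask.vessel in _SINGLE_COMPONENT:
        keep = 1
    elif mask.vessel in _DOUBLE_COMPONENT:
        keep = 2
    else:
        raise ValueError(f"unknown vessel label: {mask.vessel!r}")
    m = mask.mask
    if not m.any():
        return mask
    labels = cc_label(m, connectivity=3)
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0
    order = np.argsort(sizes)[::-1][:keep]
    kept = np.isin(labels, order[sizes[order] > 0])
    return VesselMaskCine(kept, mask.vessel, mask.geometry)


def compute_flow_curve(mask: VesselMaskCine | np.ndarray, series: PCMRSeries,
                       bsa: float | None = None) -> FlowCurve:
    """Flow curve, net forward volume and (with BSA) indexed flow rate.

    flow(t) = sum over mask pixels of VENC*phi/pi * pixel_area (mL/s);
    the net forward volume integrates the periodic curve over one RR
    (trapezoidal with wrap-around, equal to the frame mean times RR);
    indexed rate = net volume * HR / BSA in L/min/m^2.
    """
    m = mask.mask if isinstance(mask, VesselMaskCine) else np.asarray(mask, bool)
    if m.shape != series.phase.shape:
        raise ValueError("mask not aligned to series")
    if not series.venc or not series.rr_interval:
        raise ValueError("series missing VENC or RR interval")
    vel = series.velocity()  # cm/s
    area_cm2 = (series.pixel_spacing / 10.0) ** 2
    flow = (vel * m).sum(axis=(1, 2)) * area_cm2  # mL/s
    t = len(flow)
    times = np.arange(t) * series.rr_interval / t
    # periodic trapezoid over one RR == mean * RR
    net = float(flow.mean() * series.rr_interval / 1000.0)  # mL
    indexed = None
    if bsa is not None:
        if bsa <= 0:
            raise ValueError("BSA must be positive")
        hr = 60000.0 / series.rr_interval  # beats/min
        indexed = net * hr / bsa / 1000.0  # L/min/m^2
    vessel = mask.vessel if isinstance(mask, VesselMaskCine) else ""
    return FlowCurve(flow=flow, times=times, rr_interval=series.rr_interval,
                     vessel=vessel, net_forward_volume=net,
                     indexed_flow_rate=indexed)


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap 2|A∩B|/(|A|+|B|); two empty masks agree perfectly (1)."""
    a = np.asarray(a, bool)
    b = np.asarray(b, bool)
    if a.shape != b.shape:
        raise ValueError("shape mismatch")
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * np.logical_and(a, b).sum() / denom)


def derived_indices(indexed_rates: dict) -> dict:
    """Hemodynamic indices from per-vessel indexed flow rates (L/min/m^2).

    Returns whichever of total PA flow, LPA/total-PA ratio, total VC flow,
    SVC/total-VC ratio and collateral fraction the available vessels permit;
    missing vessels simply omit the dependent indices.  Collateral flow is
    taken as the aortic minus caval fraction of aortic flow,
    100*(Ao - (SVC+IVC))/Ao — the aortopulmonary collateral estimate under
    conservation of flow in the Fontan circuit.
    """
    out = {}
    r = indexed_rates
    if "LPA" in r and "RPA" in r:
        total_pa = r["LPA"] + r["RPA"]
        out["total_pa_flow"] = total_pa
        if total_pa > 0:
            out["lpa_fraction"] = r["LPA"] / total_pa
    if "SVC" in r and "IVC" in r:
        total_vc = r["SVC"] + r["IVC"]
        out["total_vc_flow"] = total_vc
        if total_vc > 0:
            out["svc_fraction"] = r["SVC"] / total_vc
    if "Ao" in r and "SVC" in r and "IVC" in r and r["Ao"] > 0:
        out["collateral_pct"] = 100.0 * (r["Ao"] - (r["SVC"] + r["IVC"])) / r["Ao"]
    return out
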