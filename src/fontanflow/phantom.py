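"""Synthetic phase-contrast MR phantoms, flow-curve cohorts and outcomes.

Everything downstream of raw registry data is exercised on synthetic inputs
with known ground truth:

* :func:`generate_phantom_exam` builds a five-vessel PCMR exam — paired
  magnitude/phase cines of pulsatile lumen disks with a parabolic (Poiseuille)
  or plug through-plane velocity profile, exact ground-truth masks, and
  analytic ground-truth flow curves.
* :func:`generate_flow_cohort` draws cluster-structured two-channel flow-curve
  cohorts from waveform archetypes that mirror the hemodynamic phenotypes seen
  in Fontan patients (e.g. "diastolic-dominant, normal flow").
* :func:`generate_outcomes` simulates cluster-dependent event times with a
  piecewise-exponential hazard, independent exponential censoring and
  administrative censoring.

Phase convention: stored phase is in radians with phi = pi * v / VENC, i.e.
(-pi, pi] maps linearly onto (-VENC, +VENC] cm/s.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .prep import PCMRSeries

VESSELS = ("LPA", "RPA", "SVC", "IVC", "Ao")

#: magnitude of static tissue relative to lumen blood (arbitrary units)
TISSUE_SIGNAL = 0.4
LUMEN_SIGNAL = 1.0

# class-typical geometry defaults: center (fraction of grid), radius (mm),
# waveform kind and peak velocity (cm/s).  Venous vessels are larger and
# slower; the aorta is fast and systolic.
_VESSEL_DEFAULTS = {
    "LPA": ((0.30, 0.30), 7.0, "arterial", 60.0),
    "RPA": ((0.30, 0.70), 7.5, "arterial", 55.0),
    "SVC": ((0.65, 0.30), 8.0, "venous", 20.0),
    "IVC": ((0.72, 0.55), 9.5, "venous", 20.0),
    "Ao": ((0.50, 0.50), 11.0, "aortic", 90.0),
}

_DESCRIPTION_TEMPLATES = {
    "LPA": ("LPA flow", "lpa", "QF LPA", "left pulmonary artery"),
    "RPA": ("RPA flow", "rpa", "QF RPA", "right pulmonary artery"),
    "SVC": ("SVC flow", "svc", "QF SVC", "superior vena cava"),
    "IVC": ("IVC flow", "ivc", "QF IVC", "inferior vena cava"),
    "Ao": ("AO flow", "aao", "QF AAO", "ascending aorta"),
}


# --------------------------------------------------------------------------
# waveforms
# --------------------------------------------------------------------------

def _bump(tf: np.ndarray, center: float, width: float) -> np.ndarray:
    """Periodic Gaussian bump on the unit cycle."""
    d = np.minimum(np.abs(tf - center), 1.0 - np.abs(tf - center))
    return np.exp(-0.5 * (d / width) ** 2)


def waveform(kind: str, n_frames: int) -> np.ndarray:
    """Normalized (peak 1) centerline-velocity waveform over one cycle.

    ``aortic``/``arterial`` peak early in systole; ``venous`` is biphasic with
    low pulsatility; ``diastolic-dominant`` peaks in the second half of the
    cycle; ``constant`` is a plug test signal.
    """
    tf = np.arange(n_frames) / n_frames
    if kind in ("arterial", "aortic"):
        w = _bump(tf, 0.15, 0.07) + 0.15 * _bump(tf, 0.60, 0.15) + 0.05
    elif kind == "venous":
        w = 0.55 + 0.30 * _bump(tf, 0.20, 0.12) + 0.20 * _bump(tf, 0.70, 0.15)
    elif kind == "diastolic-dominant":
        w = 0.25 * _bump(tf, 0.15, 0.07) + _bump(tf, 0.65, 0.13) + 0.10
    elif kind == "constant":
        w = np.ones(n_frames)
    else:
        raise ValueError(f"unknown waveform kind: {kind!r}")
    return w / w.max()


# --------------------------------------------------------------------------
# phantom exams
# --------------------------------------------------------------------------

@dataclass
class VesselSpec:
    label: str
    center: tuple  # (row, col) in pixels
    radius_mm: float
    waveform: str = "arterial"
    peak_velocity: float = 60.0  # cm/s


@dataclass
class PhantomSpec:
    grid_size: tuple = (128, 128)
    pixel_spacing: float = 2.0  # mm
    n_frames: int = 32
    rr_interval: float = 900.0  # ms
    venc: float = 150.0  # cm/s
    vessels: list = field(default_factory=list)
    noise_sd_magnitude: float = 0.03  # fraction of lumen signal
    noise_sd_phase: float = 0.02  # radians
    profile: str = "parabolic"  # or "plug"
    seed: int = 0

    def validate(self):
        if self.n_frames < 8:
            raise ValueError("n_frames must be >= 8")
        if self.profile not in ("parabolic", "plug"):
            raise ValueError("profile must be 'parabolic' or 'plug'")
        for v in self.vessels:
            if v.radius_mm <= 2 * self.pixel_spacing:
                raise ValueError(f"{v.label}: radius must exceed 2x pixel spacing")
            if abs(v.peak_velocity) >= self.venc:
                raise ValueError(f"{v.label}: peak velocity {v.peak_velocity} cm/s "
                                 f"would alias at VENC {self.venc} cm/s")


def default_phantom_spec(grid_size=(128, 128), pixel_spacing=2.0, n_frames=32,
                         seed=0, jitter=0.0, rng=None, **kw) -> PhantomSpec:
    """A five-vessel spec with class-typical geometry and waveforms.

    ``jitter`` randomly perturbs vessel centers (fraction of grid), radii and
    peak velocities so that generated exams differ between patients.
    """
    rng = rng if rng is not None else np.random.default_rng(seed)
    h, w = grid_size
    vessels = []
    for label, ((fy, fx), r_mm, kind, vpk) in _VESSEL_DEFAULTS.items():
        cy, cx = fy * h, fx * w
        if jitter > 0:
            cy += rng.normal(0, jitter * h)
            cx += rng.normal(0, jitter * w)
            r_mm *= rng.uniform(0.85, 1.15)
            vpk *= rng.uniform(0.8, 1.2)
        vessels.append(VesselSpec(label, (cy, cx), r_mm, kind, vpk))
    return PhantomSpec(grid_size=grid_size, pixel_spacing=pixel_spacing,
                       n_frames=n_frames, vessels=vessels, seed=seed, **kw)


@dataclass
class SyntheticExam:
    exam_id: str
    patient_id: str
    series: dict  # vessel -> PCMRSeries
    truth_masks: dict  # vessel -> (T,H,W) bool
    truth_flow: dict  # vessel -> (T,) mL/s ground-truth flow curve
    descriptions: dict  # vessel -> str
    demographics: dict  # BSA (m^2), age (yr), sex
    spec: PhantomSpec = None


_SUPERSAMPLE = 4


def _vessel_velocity(spec: PhantomSpec, v: VesselSpec):
    """Per-frame velocity field (T,H,W) in cm/s, plus the lumen mask.

    The spatial profile is evaluated on a 4x supersampled grid and averaged
    back, so edge pixels carry partial-volume velocities (as in real PCMR)
    and the discrete flow integral matches the analytic one closely.  The
    binary truth mask is the set of pixels with >= 50% lumen coverage.
    """
    h, w = spec.grid_size
    ss = _SUPERSAMPLE
    step = 1.0 / ss
    coords = (np.arange(h * ss) + 0.5) * step - 0.5
    yy = coords[:, None]
    xx = coords[None, :w * ss]
    r_px = v.radius_mm / spec.pixel_spacing
    rr = np.sqrt((yy - v.center[0]) ** 2 + (xx - v.center[1]) ** 2)
    if spec.profile == "parabolic":
        fine = np.clip(1.0 - (rr / r_px) ** 2, 0.0, None)
    else:
        fine = (rr <= r_px).astype(float)
    profile = fine.reshape(h, ss, w, ss).mean(axis=(1, 3))
    coverage = (rr <= r_px).reshape(h, ss, w, ss).mean(axis=(1, 3))
    mask = coverage >= 0.5
    wave = waveform(v.waveform, spec.n_frames) * v.peak_velocity
    return wave[:, None, None] * profile[None], mask


def generate_phantom_exam(spec: PhantomSpec, exam_id: str = "exam0",
                          patient_id: str | None = None,
                          rng: np.random.Generator | None = None) -> SyntheticExam:
    """Generate one synthetic PCMR exam (one series per vessel in the spec)."""
    spec.validate()
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    series, masks, flows, descs = {}, {}, {}, {}
    pixel_area_cm2 = (spec.pixel_spacing / 10.0) ** 2
    for v in spec.vessels:
        vel, mask = _vessel_velocity(spec, v)
        # ground-truth flow from the exact velocity field (cm/s * cm^2 = mL/s)
        flow = vel.sum(axis=(1, 2)) * pixel_area_cm2
        mag = TISSUE_SIGNAL + (LUMEN_SIGNAL - TISSUE_SIGNAL) * mask
        mag = mag[None] + rng.normal(0, spec.noise_sd_magnitude * LUMEN_SIGNAL,
                                     size=vel.shape)
        mag = np.clip(mag, 0, None)
        phase = np.pi * vel / spec.venc
        phase = phase + rng.normal(0, spec.noise_sd_phase, size=vel.shape)
        phase = np.clip(phase, -np.pi + 1e-9, np.pi)
        desc = str(rng.choice(_DESCRIPTION_TEMPLATES[v.label]))
        series[v.label] = PCMRSeries(
            magnitude=mag.astype(np.float32), phase=phase.astype(np.float32),
            pixel_spacing=spec.pixel_spacing, rr_interval=spec.rr_interval,
            venc=spec.venc, description=desc,
            acquisition_time=float(rng.uniform(0, 3600)))
        masks[v.label] = np.broadcast_to(mask, vel.shape).copy()
        flows[v.label] = flow
        descs[v.label] = desc
    bsa = float(np.exp(rng.normal(np.log(1.5), 0.18)))
    demo = {"BSA": bsa, "age": float(rng.uniform(8, 30)),
            "sex": str(rng.choice(["M", "F"]))}
    return SyntheticExam(exam_id=exam_id,
                         patient_id=patient_id or f"pt_{exam_id}",
                         series=series, truth_masks=masks, truth_flow=flows,
                         descriptions=descs, demographics=demo, spec=spec)


def analytic_net_volume(spec: PhantomSpec, v: VesselSpec) -> float:
    """Closed-form net forward volume (mL) of one vessel over one cycle.

    For a parabolic profile the lumen-integrated flow is v_c(t) * pi R^2 / 2;
    for plug flow it is v_c(t) * pi R^2.  The cycle integral uses the mean of
    the (periodic) waveform times the RR interval.
    """
    wave = waveform(v.waveform, spec.n_frames) * v.peak_velocity  # cm/s
    area_cm2 = np.pi * (v.radius_mm / 10.0) ** 2
    factor = 0.5 if spec.profile == "parabolic" else 1.0
    mean_flow = wave.mean() * area_cm2 * factor  # mL/s
    return mean_flow * spec.rr_interval / 1000.0


# --------------------------------------------------------------------------
# flow-curve cohorts
# --------------------------------------------------------------------------

@dataclass
class FlowArchetype:
    """A cluster's two-channel waveform template.

    ``total`` is the indexed total flow (L/min/m^2), ``split`` the fraction of
    total flow in channel 0, and ``dia_frac`` the diastolic phase dominance
    (0 = purely systolic pulse, 1 = purely diastolic).
    """
    name: str
    total: float  # L/min/m^2
    split: float  # channel-0 fraction of total, in (0,1)
    dia_frac: float = 0.25
    pulsatility: float = 0.8

    def curves(self, n_frames: int = 30) -> np.ndarray:
        """(n_frames, 2) indexed flow (L/min/m^2), mean over cycle = total."""
        tf = np.arange(n_frames) / n_frames
        pulse = ((1.0 - self.dia_frac) * _bump(tf, 0.17, 0.08)
                 + self.dia_frac * _bump(tf, 0.62, 0.13))
        shape = 1.0 + self.pulsatility * (pulse - pulse.mean()) / (pulse.std() + 1e-12)
        shape = np.clip(shape, 0.05, None)
        shape = shape / shape.mean()
        tot = self.total * shape
        return np.stack([tot * self.split, tot * (1.0 - self.split)], axis=1)


#: archetype defaults mirroring the five pulmonary-artery phenotypes
PA_ARCHETYPES = [
    FlowArchetype("Norm-High", 2.91, 0.42, 0.20),
    FlowArchetype("Norm-Low", 1.42, 0.45, 0.35, pulsatility=0.5),
    FlowArchetype("Dia-Norm", 1.96, 0.38, 0.70),
    FlowArchetype("RPA-Norm", 2.34, 0.30, 0.25),
    FlowArchetype("Bal-Norm", 2.18, 0.52, 0.25),
]

#: archetype defaults mirroring the four vena-caval phenotypes (channel 0 = SVC)
VC_ARCHETYPES = [
    FlowArchetype("IVC-Norm", 2.32, 0.28, 0.45, pulsatility=0.45),
    FlowArchetype("SVC-High", 2.83, 0.56, 0.40, pulsatility=0.45),
    FlowArchetype("Norm-High", 2.86, 0.37, 0.30, pulsatility=0.55),
    FlowArchetype("Norm-Norm", 2.15, 0.37, 0.55, pulsatility=0.45),
]


@dataclass
class CohortSpec:
    archetypes: list = field(default_factory=lambda: list(PA_ARCHETYPES))
    n_per_cluster: int | list = 150
    n_frames: int = 30
    noise_sd: float = 0.15  # L/min/m^2, smooth waveform noise
    bsa_log_median: float = 1.5  # m^2 (lognormal median)
    bsa_log_sd: float = 0.18
    scan_probs: tuple = (0.7, 0.2, 0.1)  # P(1, 2, 3 scans per patient)
    stay_prob: float = 0.5  # P(consecutive scans keep the cluster)
    seed: int = 0

    @property
    def k_true(self):
        return len(self.archetypes)

    def validate(self):
        if self.k_true < 2:
            raise ValueError("need at least 2 archetypes")
        for a in self.archetypes:
            if not 0.0 < a.split < 1.0:
                raise ValueError(f"{a.name}: split fraction must be in (0,1)")


def archetype_separation(spec: CohortSpec) -> float:
    """Minimum pairwise Euclidean distance between archetype curve templates."""
    mats = [a.curves(spec.n_frames).ravel() for a in spec.archetypes]
    dists = [np.linalg.norm(mats[i] - mats[j])
             for i in range(len(mats)) for j in range(i + 1, len(mats))]
    return float(min(dists))


def _smooth_noise(rng, shape, sd):
    """Temporally smooth Gaussian noise with marginal SD ``sd`` (periodic)."""
    white = rng.normal(size=shape)
    sm = gaussian_filter1d(white, sigma=1.5, axis=0, mode="wrap")
    sm /= sm.std() + 1e-12
    return sm * sd


def generate_flow_cohort(spec: CohortSpec):
    """Draw a cluster-structured cohort of two-channel flow curves.

    Returns ``(curves, labels, demographics)`` where ``curves`` is
    (n_scans, n_frames, 2) in raw mL/s, ``labels`` the true cluster of each
    scan, and ``demographics`` a DataFrame with one row per scan
    (patient_id, scan_id, scan_time_yr, BSA, age, sex, label).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n_per = spec.n_per_cluster
    if np.isscalar(n_per):
        n_per = [int(n_per)] * spec.k_true
    templates = [a.curves(spec.n_frames) for a in spec.archetypes]

    curves, labels, rows = [], [], []
    scan_counts = np.arange(1, len(spec.scan_probs) + 1)
    pid = 0
    for j, n_j in enumerate(n_per):
        remaining = n_j
        while remaining > 0:
            n_scans = int(rng.choice(scan_counts, p=spec.scan_probs))
            n_scans = min(n_scans, remaining)
            bsa = float(np.exp(rng.normal(np.log(spec.bsa_log_median), spec.bsa_log_sd)))
            age = float(rng.uniform(6, 35))
            sex = str(rng.choice(["M", "F"]))
            lab = j
            t_scan = 0.0
            for s in range(n_scans):
                if s > 0:
                    t_scan += float(rng.uniform(0.5, 3.0))
                    if rng.random() > spec.stay_prob:
                        lab = int(rng.choice([x for x in range(spec.k_true) if x != lab]))
                indexed = templates[lab] + _smooth_noise(
                    rng, (spec.n_frames, 2), spec.noise_sd)
                raw = indexed * bsa * 1000.0 / 60.0  # L/min/m^2 -> mL/s
                curves.append(raw)
                labels.append(lab)
                rows.append({"patient_id": f"p{pid:05d}", "scan_id": f"p{pid:05d}_s{s}",
                             "scan_time_yr": t_scan, "BSA": bsa,
                             "age": age + t_scan, "sex": sex, "label": lab})
            remaining -= n_scans
            pid += 1
    demo = pd.DataFrame(rows)
    return np.asarray(curves), np.asarray(labels), demo


# --------------------------------------------------------------------------
# outcomes
# --------------------------------------------------------------------------

def generate_outcomes(labels, hazards, censor_rate: float = 0.03,
                      follow_up: float = 10.0, seed: int = 0,
                      patient_ids=None, scan_times=None) -> pd.DataFrame:
    """Simulate event times with cluster-specific exponential hazards.

    ``labels`` is per-subject (1-D) or, with ``scan_times``, per-scan so that
    the hazard follows the cluster of the most recent scan (piecewise
    exponential).  Censoring is independent exponential at ``censor_rate``
    plus administrative censoring at ``follow_up`` years.

    Returns a DataFrame (patient_id, time, event).
    """
    rng = np.random.default_rng(seed)
    labels = np.asarray(labels)
    hazards = np.asarray(hazards, dtype=float)
    if np.any(hazards <= 0):
        raise ValueError("hazards must be positive")

    if scan_times is None:
        n = len(labels)
        u = rng.exponential(1.0, size=n)
        t_event = u / hazards[labels]
    else:
        # piecewise-exponential: hazard switches at each scan time
        n = len(scan_times)
        t_event = np.empty(n)
        for i, (labs, times) in enumerate(zip(labels, scan_times)):
            labs, times = np.asarray(labs), np.asarray(times)
            target = rng.exponential(1.0)
            bounds = np.append(times, np.inf)
            cum, t = 0.0, np.inf
            for j in range(len(labs)):
                seg = bounds[j + 1] - bounds[j]
                h = hazards[labs[j]]
                if cum + h * seg >= target:
                    t = bounds[j] + (target - cum) / h
                    break
                cum += h * seg
            t_event[i] = t
    if censor_rate > 0:
        t_cens = rng.exponential(1.0 / censor_rate, size=n)
    else:
        t_cens = np.full(n, np.inf)
    t_cens = np.minimum(t_cens, follow_up)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    if patient_ids is None:
        patient_ids = [f"p{i:05d}" for i in range(n)]
    return pd.DataFrame({"patient_id": patient_ids, "time": time, "event": event})
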