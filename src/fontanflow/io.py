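"""Reading and writing exams: NPZ bundles and DICOM series.

Synthetic exams are stored either as a compact NPZ bundle (one ``.npz`` plus
a JSON manifest per exam — the primary format for tests and pipelines) or as
DICOM files via pydicom (one file per frame, paired magnitude/phase series
marked in ImageType, phase stored as rescaled integers).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pydicom
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid

from .prep import PCMRSeries

MANIFEST = "manifest.json"


# --------------------------------------------------------------------------
# NPZ bundle
# --------------------------------------------------------------------------

def write_exam_bundle(exam, directory) -> Path:
    """Write a SyntheticExam as <dir>/<exam_id>/{manifest.json, data.npz}."""
    root = Path(directory) / exam.exam_id
    root.mkdir(parents=True, exist_ok=True)
    arrays, meta = {}, {"exam_id": exam.exam_id, "patient_id": exam.patient_id,
                        "demographics": exam.demographics, "series": {}}
    for vessel, s in exam.series.items():
        arrays[f"{vessel}_magnitude"] = s.magnitude
        arrays[f"{vessel}_phase"] = s.phase
        if exam.truth_masks and vessel in exam.truth_masks:
            arrays[f"{vessel}_truth_mask"] = exam.truth_masks[vessel]
            arrays[f"{vessel}_truth_flow"] = exam.truth_flow[vessel]
        meta["series"][vessel] = {
            "pixel_spacing": s.pixel_spacing, "rr_interval": s.rr_interval,
            "venc": s.venc, "description": s.description,
            "acquisition_time": s.acquisition_time}
    np.savez_compressed(root / "data.npz", **arrays)
    (root / MANIFEST).write_text(json.dumps(meta, indent=1))
    return root


def read_exam_bundle(path):
    """Read a bundle directory back into a SyntheticExam."""
    from .phantom import SyntheticExam  # local import to avoid cycle

    root = Path(path)
    meta = json.loads((root / MANIFEST).read_text())
    data = np.load(root / "data.npz")
    series, masks, flows, descs = {}, {}, {}, {}
    for vessel, m in meta["series"].items():
        series[vessel] = PCMRSeries(
            magnitude=data[f"{vessel}_magnitude"],
            phase=data[f"{vessel}_phase"],
            pixel_spacing=m["pixel_spacing"], rr_interval=m["rr_interval"],
            venc=m["venc"], description=m["description"],
            acquisition_time=m.get("acquisition_time", 0.0))
        descs[vessel] = m["description"]
        if f"{vessel}_truth_mask" in data:
            masks[vessel] = data[f"{vessel}_truth_mask"].astype(bool)
            flows[vessel] = data[f"{vessel}_truth_flow"]
    return SyntheticExam(exam_id=meta["exam_id"], patient_id=meta["patient_id"],
                         series=series, truth_masks=masks, truth_flow=flows,
                         descriptions=descs, demographics=meta["demographics"])


def write_mask_nifti(mask: np.ndarray, path, pixel_spacing: float = 2.0):
    """Write a (T,H,W) binary mask as NIfTI (axes reordered to H,W,T)."""
    import nibabel as nib

    arr = np.asarray(mask, dtype=np.uint8).transpose(1, 2, 0)
    affine = np.diag([pixel_spacing, pixel_spacing, 1.0, 1.0])
    nib.save(nib.Nifti1Image(arr, affine), str(path))


def write_cohort_csv(curves: np.ndarray, demo, path) -> None:
    """Tidy cohort CSV (sample_id, channel, frame, flow_ml_s, BSA, label)."""
    import pandas as pd

    rows = []
    for i in range(len(curves)):
        sid = demo["scan_id"].iloc[i]
        for ch in range(curves.shape[2]):
            for fr in range(curves.shape[1]):
                rows.append({"sample_id": sid, "channel": ch, "frame": fr,
                             "flow_ml_s": curves[i, fr, ch],
                             "BSA": demo["BSA"].iloc[i],
                             "patient_id": demo["patient_id"].iloc[i],
                             "label": demo["label"].iloc[i]})
    pd.DataFrame(rows).to_csv(path, index=False)


# --------------------------------------------------------------------------
# DICOM
# --------------------------------------------------------------------------

_PHASE_SCALE = 4000.0 / np.pi  # radians -> stored int16


def _base_dataset(series: PCMRSeries, kind: str, frame: int, t_frames: int,
                  series_uid: str, study_uid: str, series_number: int) -> Dataset:
    ds = Dataset()
    ds.SOPClassUID = "1.2.840.10008.5.1.4.1.1.4"  # MR Image Storage
    ds.SOPInstanceUID = generate_uid()
    ds.StudyInstanceUID = study_uid
    ds.SeriesInstanceUID = series_uid
    ds.SeriesNumber = series_number
    ds.InstanceNumber = frame + 1
    ds.Modality = "MR"
    ds.SeriesDescription = series.description
    ds.ImageType = ["ORIGINAL", "PRIMARY", "M" if kind == "magnitude" else "P"]
    ds.PixelSpacing = [series.pixel_spacing, series.pixel_spacing]
    ds.NominalInterval = int(round(series.rr_interval))
    ds.CardiacNumberOfImages = t_frames
    ds.TriggerTime = frame * series.rr_interval / t_frames
    ds.SequenceName = f"fl_v{int(series.venc)}in"  # VENC convention
    ds.Rows, ds.Columns = series.magnitude.shape[1:]
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.BitsAllocated = 16
    ds.BitsStored = 16
    ds.HighBit = 15
    return ds


def write_exam_dicom(exam, directory) -> Path:
    """Write each vessel series as paired magnitude/phase DICOM files."""
    root = Path(directory) / exam.exam_id
    root.mkdir(parents=True, exist_ok=True)
    study_uid = generate_uid()
    num = 0
    for vessel, s in exam.series.items():
        t = s.n_frames
        for kind in ("magnitude", "phase"):
            num += 1
            series_uid = generate_uid()
            for frame in range(t):
                ds = _base_dataset(s, kind, frame, t, series_uid, study_uid, num)
                if kind == "magnitude":
                    arr = s.magnitude[frame]
                    scale = 4000.0 / max(float(arr.max()), 1e-9)
                    ds.PixelRepresentation = 0
                    ds.RescaleSlope = 1.0 / scale
                    ds.RescaleIntercept = 0.0
                    px = np.clip(arr * scale, 0, 65535).astype(np.uint16)
                else:
                    ds.PixelRepresentation = 1
                    ds.RescaleSlope = 1.0 / _PHASE_SCALE
                    ds.RescaleIntercept = 0.0
                    px = np.round(s.phase[frame] * _PHASE_SCALE).astype(np.int16)
                ds.PixelData = px.tobytes()
                meta = FileMetaDataset()
                meta.TransferSyntaxUID = ExplicitVRLittleEndian
                meta.MediaStorageSOPClassUID = ds.SOPClassUID
                meta.MediaStorageSOPInstanceUID = ds.SOPInstanceUID
                ds.file_meta = meta
                pydicom.dcmwrite(root / f"{vessel}_{kind[0]}_{frame:03d}.dcm",
                                 ds, enforce_file_format=True)
    return root


def _parse_venc(ds) -> float | None:
    name = getattr(ds, "SequenceName", "") or ""
    if "_v" in name:
        digits = "".join(ch for ch in name.split("_v", 1)[1] if ch.isdigit())
        if digits:
            return float(digits)
    return None


def read_dicom_series(path) -> list:
    """Discover paired magnitude/phase PCMR series under a DICOM tree.

    Returns ``(series_list, skipped)`` where ``skipped`` is a list of
    (identifier, reason) for unpaired or unreadable candidates.
    """
    groups: dict = {}
    skipped = []
    for f in sorted(Path(path).rglob("*.dcm")):
        try:
            ds = pydicom.dcmread(f)
        except Exception as exc:  # unreadable files are logged, not fatal
            skipped.append((str(f), f"unreadable: {exc}"))
            continue
        kind = "P" if "P" in list(getattr(ds, "ImageType", [])) else "M"
        desc = str(getattr(ds, "SeriesDescription", ""))
        key = (desc, str(getattr(ds, "StudyInstanceUID", "")))
        groups.setdefault(key, {"M": [], "P": []})[kind].append(ds)

    out = []
    for (desc, _), pair in groups.items():
        if not pair["M"] or not pair["P"]:
            skipped.append((desc, "missing magnitude or phase reconstruction"))
            continue
        mags = sorted(pair["M"], key=lambda d: int(d.InstanceNumber))
        phas = sorted(pair["P"], key=lambda d: int(d.InstanceNumber))
        if len(mags) != len(phas) or len(mags) < 2:
            skipped.append((desc, "cine too short or unpaired frames"))
            continue
        venc = _parse_venc(mags[0])
        if venc is None:
            skipped.append((desc, "no VENC in headers"))
            continue
        def stack(dsets):
            return np.stack([
                d.pixel_array.astype(np.float64) * float(getattr(d, "RescaleSlope", 1.0))
                + float(getattr(d, "RescaleIntercept", 0.0)) for d in dsets])
        out.append(PCMRSeries(
            magnitude=stack(mags), phase=stack(phas),
            pixel_spacing=float(mags[0].PixelSpacing[0]),
            rr_interval=float(mags[0].NominalInterval),
            venc=venc, description=desc))
    return out, skipped
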