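"""Tabular session I/O and the study manifest.

All time series travel as TSV: pupil (time_s, diameter, valid), physio
(time_s, pulse, resp), motion (6 columns × volumes), ROI BOLD (volume index
plus one column per ROI), ventricle (volume, value).  Ground truth and the
study manifest are JSON.  A NIfTI + mask extraction path exists for real
data but nothing in the pipeline requires images.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .nuisance import PhysioRecording
from .pupil import PupilTrace

MANIFEST_NAME = "manifest.json"
SESSION_FILES = ("pupil", "physio", "motion", "bold", "ventricle")


@dataclass
class SessionData:
    """One session's aligned inputs on the volume grid."""

    session_id: str
    pupil: PupilTrace
    physio: PhysioRecording
    motion: np.ndarray              # volumes x 6
    bold: np.ndarray                # volumes x n_rois
    roi_names: list[str]
    ventricle: np.ndarray           # volumes
    tr: float

    @property
    def n_volumes(self) -> int:
        return self.bold.shape[0]


def from_synthetic(session) -> SessionData:
    """Adapt a :class:`pupilbold.synth.SyntheticSession` to SessionData."""
    n_rois = session.bold.shape[1]
    return SessionData(
        session_id=session.session_id, pupil=session.pupil,
        physio=session.physio, motion=session.motion, bold=session.bold,
        roi_names=[f"roi_{i + 1}" for i in range(n_rois)],
        ventricle=session.ventricle, tr=session.config.tr)


def write_session(session, directory) -> dict[str, str]:
    """Write one session (synthetic or SessionData) as TSVs; returns paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    data = session if isinstance(session, SessionData) else \
        from_synthetic(session)
    paths = {}
    pupil = pd.DataFrame({"time_s": data.pupil.time,
                          "diameter": data.pupil.diameter,
                          "valid": data.pupil.valid.astype(int)})
    paths["pupil"] = directory / "pupil.tsv"
    pupil.to_csv(paths["pupil"], sep="\t", index=False, float_format="%.6f")
    t_phys = np.arange(data.physio.pulse.size) / data.physio.rate_pulse
    physio = pd.DataFrame({"time_s": t_phys, "pulse": data.physio.pulse,
                           "resp": data.physio.resp})
    paths["physio"] = directory / "physio.tsv"
    physio.to_csv(paths["physio"], sep="\t", index=False, float_format="%.6f")
    motion = pd.DataFrame(data.motion,
                          columns=[f"motion_{i + 1}" for i in range(6)])
    paths["motion"] = directory / "motion.tsv"
    motion.to_csv(paths["motion"], sep="\t", index=False)
    bold = pd.DataFrame(data.bold, columns=data.roi_names)
    bold.insert(0, "volume", np.arange(data.n_volumes))
    paths["bold"] = directory / "bold.tsv"
    bold.to_csv(paths["bold"], sep="\t", index=False)
    vent = pd.DataFrame({"volume": np.arange(data.n_volumes),
                         "value": data.ventricle})
    paths["ventricle"] = directory / "ventricle.tsv"
    vent.to_csv(paths["ventricle"], sep="\t", index=False)
    if hasattr(session, "truth"):
        truth = session.truth
        gt = {"coupling_mode": truth.coupling_mode,
              "true_lag": truth.true_lag, "true_ttp": truth.true_ttp,
              "true_ttp_peak": truth.true_ttp_peak,
              "event_onsets": list(map(float, truth.event_onsets)),
              "coupled_roi_ids": truth.coupled_roi_ids,
              "neural_signal": [float(v) for v in truth.neural_signal]}
        paths["ground_truth"] = directory / "ground_truth.json"
        paths["ground_truth"].write_text(json.dumps(gt))
    return {k: str(v) for k, v in paths.items()}


def read_session(paths: dict[str, str], tr: float = 2.0,
                 pupil_rate: float | None = None) -> SessionData:
    """Read a session bundle back, validating alignment.

    Errors name the offending file and quantity: missing columns, a pupil
    trace shorter than the volume grid, or BOLD/motion/ventricle length
    mismatches.
    """
    for key in SESSION_FILES:
        if key not in paths:
            raise ValueError(f"manifest entry missing the {key!r} file")
        if not Path(paths[key]).exists():
            raise FileNotFoundError(f"{key} file not found: {paths[key]}")
    pupil_df = pd.read_csv(paths["pupil"], sep="\t")
    for col in ("time_s", "diameter", "valid"):
        if col not in pupil_df:
            raise ValueError(f"{paths['pupil']}: missing column {col!r}")
    t = pupil_df["time_s"].to_numpy()
    rate = pupil_rate or 1.0 / np.median(np.diff(t))
    pupil = PupilTrace(diameter=pupil_df["diameter"].to_numpy(),
                       valid=pupil_df["valid"].to_numpy().astype(bool),
                       rate=float(round(rate, 6)))
    physio_df = pd.read_csv(paths["physio"], sep="\t")
    for col in ("time_s", "pulse", "resp"):
        if col not in physio_df:
            raise ValueError(f"{paths['physio']}: missing column {col!r}")
    phys_rate = 1.0 / np.median(np.diff(physio_df["time_s"].to_numpy()))
    physio = PhysioRecording(pulse=physio_df["pulse"].to_numpy(),
                             resp=physio_df["resp"].to_numpy(),
                             rate_pulse=phys_rate, rate_resp=phys_rate)
    motion = pd.read_csv(paths["motion"], sep="\t").to_numpy()
    bold_df = pd.read_csv(paths["bold"], sep="\t")
    if "volume" not in bold_df:
        raise ValueError(f"{paths['bold']}: missing column 'volume'")
    roi_names = [c for c in bold_df.columns if c != "volume"]
    bold = bold_df[roi_names].to_numpy()
    vent_df = pd.read_csv(paths["ventricle"], sep="\t")
    ventricle = vent_df["value"].to_numpy()
    n_vol = bold.shape[0]
    if motion.shape[0] != n_vol:
        raise ValueError(
            f"{paths['motion']}: {motion.shape[0]} rows but BOLD has "
            f"{n_vol} volumes")
    if ventricle.size != n_vol:
        raise ValueError(
            f"{paths['ventricle']}: {ventricle.size} rows but BOLD has "
            f"{n_vol} volumes")
    needed = int(round(n_vol * tr * pupil.rate))
    if pupil.n_samples < needed:
        raise ValueError(
            f"{paths['pupil']}: {pupil.n_samples} samples, "
            f"{needed - pupil.n_samples} short of the {needed} needed for "
            f"{n_vol} volumes at TR={tr}")
    session_id = Path(paths["bold"]).parent.name or "session"
    return SessionData(session_id=session_id, pupil=pupil, physio=physio,
                       motion=motion, bold=bold, roi_names=roi_names,
                       ventricle=ventricle, tr=tr)


def write_study(study, out_dir) -> Path:
    """Write a simulated study to ``out_dir`` with a JSON manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {"participants": []}
    for p_idx, sessions in enumerate(study):
        pid = f"sub-{p_idx + 1:02d}"
        entry = {"participant": pid, "include": True,
                 "exclusion_reason": None, "sessions": []}
        for s_idx, session in enumerate(sessions):
            sdir = out_dir / pid / f"ses-{s_idx + 1:02d}"
            paths = write_session(session, sdir)
            entry["sessions"].append(
                {"session_id": getattr(session, "session_id",
                                       f"{pid}_ses-{s_idx + 1:02d}"),
                 "paths": paths})
        manifest["participants"].append(entry)
    path = out_dir / MANIFEST_NAME
    path.write_text(json.dumps(manifest, indent=2))
    return path


def read_manifest(path) -> dict:
    manifest = json.loads(Path(path).read_text())
    if "participants" not in manifest:
        raise ValueError(f"{path}: not a study manifest")
    return manifest


def load_study(manifest_path, tr: float = 2.0) -> list[list[SessionData]]:
    """Read every included session listed in a manifest."""
    manifest = read_manifest(manifest_path)
    study = []
    for entry in manifest["participants"]:
        if not entry.get("include", True):
            continue
        study.append([read_session(s["paths"], tr=tr)
                      for s in entry["sessions"]])
    return study


def extract_roi_series(nifti_path, mask_path) -> np.ndarray:
    """Unweighted mean over mask voxels per volume from a 4D NIfTI."""
    import nibabel as nib
    img = nib.load(str(nifti_path))
    mask = nib.load(str(mask_path))
    data = np.asanyarray(img.dataobj)
    m = np.asanyarray(mask.dataobj).astype(bool)
    if data.shape[:3] != m.shape:
        raise ValueError(f"image grid {data.shape[:3]} does not match mask "
                         f"grid {m.shape}")
    if not m.any():
        raise ValueError("empty ROI mask")
    return data[m].mean(axis=0)
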