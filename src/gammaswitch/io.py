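"""Reading and writing of datasets: FIF signals, TSV tables, YAML config.

Layout (BIDS-iEEG-flavored, one directory per patient):

    <out>/config.yaml
    <out>/<pid>/<pid>_ieeg_raw.fif      continuous gameplay signal
    <out>/<pid>/<pid>_rest_raw.fif      non-gameplay rest signal
    <out>/<pid>/<pid>_events.tsv        one row per trial
    <out>/<pid>/<pid>_electrodes.tsv    montage
    <out>/<pid>/<pid>_sessions.json     session sample bounds

Continuous signals use MNE's native FIF format; events and electrodes
are plain tab-separated values.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import mne
import numpy as np
import pandas as pd
import yaml

from .datatypes import ElectrodeSite, Recording, TrialRecord, montage_to_frame
from .synth import (
    AccuracyModel,
    BurstSpec,
    GeneratorConfig,
    NoiseSpec,
    PatientData,
    RTModel,
)

EVENT_COLUMNS = [
    "onset_sample",
    "session",
    "trial_index",
    "rule",
    "is_switch",
    "is_incongruent",
    "prior_incorrect",
    "response_time_ms",
    "correct",
]


# ---------------------------------------------------------------------------
# Config round-trip
# ---------------------------------------------------------------------------

def config_to_dict(config: GeneratorConfig) -> dict:
    d = dataclasses.asdict(config)
    d["run_length_pmf"] = [float(x) for x in config.run_length_pmf]
    return d


def config_from_dict(d: dict) -> GeneratorConfig:
    d = dict(d)
    if "rt_model" in d and isinstance(d["rt_model"], dict):
        d["rt_model"] = RTModel(**d["rt_model"])
    if "accuracy_model" in d and isinstance(d["accuracy_model"], dict):
        d["accuracy_model"] = AccuracyModel(**d["accuracy_model"])
    if "noise" in d and isinstance(d["noise"], dict):
        d["noise"] = NoiseSpec(**d["noise"])
    d["burst_specs"] = [
        BurstSpec(**b) if isinstance(b, dict) else b for b in d.get("burst_specs", [])
    ]
    return GeneratorConfig(**d)


def save_config(config: GeneratorConfig, path: Path) -> None:
    Path(path).write_text(yaml.safe_dump(config_to_dict(config), sort_keys=False))


def load_config(path: Path) -> GeneratorConfig:
    return config_from_dict(yaml.safe_load(Path(path).read_text()))


# ---------------------------------------------------------------------------
# Recordings
# ---------------------------------------------------------------------------

def _to_raw(rec: Recording) -> mne.io.RawArray:
    info = mne.create_info(rec.ch_names, rec.sfreq, ch_types="ecog", verbose="error")
    return mne.io.RawArray(rec.data * 1e-6, info, verbose="error")  # uV -> V


def save_recording(rec: Recording, path: Path) -> None:
    _to_raw(rec).save(str(path), overwrite=True, verbose="error")


def load_recording(path: Path, sessions_json: Path | None = None, kind: str = "gameplay") -> Recording:
    raw = mne.io.read_raw_fif(str(path), preload=True, verbose="error")
    bounds: list[tuple[int, int]] = []
    events = np.empty(0, dtype=int)
    if sessions_json is not None and Path(sessions_json).exists():
        meta = json.loads(Path(sessions_json).read_text())
        bounds = [tuple(b) for b in meta.get(kind, [])]
    return Recording(
        data=raw.get_data() * 1e6,
        sfreq=float(raw.info["sfreq"]),
        ch_names=list(raw.ch_names),
        events=events,
        session_bounds=bounds,
        kind=kind,
    )


# ---------------------------------------------------------------------------
# Tables
# ---------------------------------------------------------------------------

def save_events(trials: Sequence[TrialRecord], path: Path) -> None:
    rows = []
    for t in trials:
        rows.append(
            {
                "onset_sample": t.cue_onset,
                "session": t.session,
                "trial_index": t.trial_index,
                "rule": t.rule,
                "is_switch": int(t.is_switch),
                "is_incongruent": "" if t.is_incongruent is None else int(t.is_incongruent),
                "prior_incorrect": int(t.prior_incorrect),
                "response_time_ms": t.response_time_ms,
                "correct": int(bool(t.correct)),
            }
        )
    pd.DataFrame(rows, columns=EVENT_COLUMNS).to_csv(path, sep="\t", index=False)


def load_events(path: Path, patient_id: str) -> list[TrialRecord]:
    df = pd.read_csv(path, sep="\t")
    trials = []
    for _, r in df.iterrows():
        incong = r["is_incongruent"]
        trials.append(
            TrialRecord(
                patient_id=patient_id,
                session=int(r["session"]),
                trial_index=int(r["trial_index"]),
                rule=str(r["rule"]),
                is_switch=bool(r["is_switch"]),
                is_incongruent=None if pd.isna(incong) else bool(int(incong)),
                prior_incorrect=bool(r["prior_incorrect"]),
                response_time_ms=float(r["response_time_ms"]),
                correct=bool(r["correct"]),
                cue_onset=int(r["onset_sample"]),
            )
        )
    return trials


def save_electrodes(montage: Sequence[ElectrodeSite], path: Path) -> None:
    montage_to_frame(montage).to_csv(path, sep="\t", index=False)


def load_electrodes(path: Path) -> list[ElectrodeSite]:
    df = pd.read_csv(path, sep="\t")
    return [
        ElectrodeSite(
            label=str(r["name"]),
            coordinates=(float(r["x"]), float(r["y"]), float(r["z"])),
            roi=str(r["roi"]),
            hemisphere=str(r["hemisphere"]),
            exclusion_reason=str(r["exclusion_reason"]),
        )
        for _, r in df.iterrows()
    ]


# ---------------------------------------------------------------------------
# Whole datasets
# ---------------------------------------------------------------------------

def save_patient(p: PatientData, out_dir: Path) -> Path:
    d = Path(out_dir) / p.patient_id
    d.mkdir(parents=True, exist_ok=True)
    save_recording(p.gameplay, d / f"{p.patient_id}_ieeg_raw.fif")
    save_recording(p.rest, d / f"{p.patient_id}_rest_raw.fif")
    save_events(p.trials, d / f"{p.patient_id}_events.tsv")
    save_electrodes(p.montage, d / f"{p.patient_id}_electrodes.tsv")
    (d / f"{p.patient_id}_sessions.json").write_text(
        json.dumps(
            {
                "gameplay": [list(b) for b in p.gameplay.session_bounds],
                "rest": [list(b) for b in p.rest.session_bounds],
            }
        )
    )
    return d


def load_patient(patient_dir: Path) -> PatientData:
    d = Path(patient_dir)
    pid = d.name
    sessions = d / f"{pid}_sessions.json"
    trials = load_events(d / f"{pid}_events.tsv", pid)
    gameplay = load_recording(d / f"{pid}_ieeg_raw.fif", sessions, "gameplay")
    gameplay.events = np.array([t.cue_onset for t in trials], dtype=int)
    rest = load_recording(d / f"{pid}_rest_raw.fif", sessions, "rest")
    montage = load_electrodes(d / f"{pid}_electrodes.tsv")
    return PatientData(pid, trials, montage, gameplay, rest)


def save_dataset(patients: Sequence[PatientData], config: GeneratorConfig, out_dir: Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    save_config(config, out / "config.yaml")
    for p in patients:
        save_patient(p, out)


def load_dataset(in_dir: Path) -> tuple[list[PatientData], GeneratorConfig]:
    root = Path(in_dir)
    config = load_config(root / "config.yaml")
    patients = [
        load_patient(d) for d in sorted(root.iterdir()) if d.is_dir()
    ]
    return patients, config
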