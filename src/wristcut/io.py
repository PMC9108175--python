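"""Plain-CSV dataset layout: writing and reading simulated or real studies.

Layout of a dataset directory::

    manifest.yaml                       seed, config, scheduled-trial count
    participants.csv                    id, age, sex, mass_kg, height_m, handedness
    trials.csv                          participant_id, activity_code, exclusion_flag
    raw_<id>_<activity>_<side>.csv      t_s, ax_g, ay_g, az_g        (30 Hz)
    counts_<id>_<activity>_<side>.csv   epoch_start_s, va, ml, ap    (5-s epochs)
    gas_<id>_<activity>.csv             t_s, vo2_ml_min, hr_bpm      (15-s grid)

Floats are written with fixed precision so that identical datasets are
byte-identical on disk.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .config import RunConfig
from .signal import FS_HZ
from .synth import ActivityProfile, Participant, StudyDataset, TrialRecording, builtin_activity_profiles

__all__ = ["write_dataset", "read_dataset", "dataset_hash"]

_CSV_KW = dict(index=False, lineterminator="\n")


def _trial_stub(t: TrialRecording) -> str:
    return f"{t.participant_id}_{t.activity_code}"


def write_dataset(ds: StudyDataset, path: str | Path) -> Path:
    """Write a study dataset to ``path`` in the plain-CSV layout."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)

    pd.DataFrame([
        {"id": p.id, "age": round(p.age, 3), "sex": p.sex,
         "mass_kg": round(p.mass, 3), "height_m": round(p.height, 4),
         "handedness": p.handedness}
        for p in ds.participants
    ]).to_csv(path / "participants.csv", **_CSV_KW)

    pd.DataFrame([
        {"participant_id": t.participant_id, "activity_code": t.activity_code,
         "exclusion_flag": t.exclusion_flag or ""}
        for t in ds.trials
    ]).to_csv(path / "trials.csv", **_CSV_KW)

    for t in ds.trials:
        stub = _trial_stub(t)
        for side in ("left", "right"):
            raw = t.raw(side)
            if raw is not None:
                n = raw.shape[0]
                df = pd.DataFrame({"t_s": np.arange(n) / FS_HZ,
                                   "ax_g": raw[:, 0], "ay_g": raw[:, 1],
                                   "az_g": raw[:, 2]})
                df.to_csv(path / f"raw_{stub}_{side}.csv", float_format="%.5f", **_CSV_KW)
            counts = t.counts(side)
            if counts is not None:
                df = pd.DataFrame({"epoch_start_s": counts[:, 0].astype(int),
                                   "va": counts[:, 1].astype(int),
                                   "ml": counts[:, 2].astype(int),
                                   "ap": counts[:, 3].astype(int)})
                df.to_csv(path / f"counts_{stub}_{side}.csv", **_CSV_KW)
        pd.DataFrame({"t_s": t.gas_t.astype(int), "vo2_ml_min": t.vo2,
                      "hr_bpm": t.hr}).to_csv(
            path / f"gas_{stub}.csv", float_format="%.4f", **_CSV_KW)

    manifest = {
        "seed": ds.seed,
        "n_scheduled": ds.n_scheduled,
        "n_excluded": ds.n_scheduled - len(ds.retained),
        "config": yaml.safe_load(ds.config.to_yaml()),
    }
    (path / "manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=False))
    return path


def _read_csv(path: Path) -> pd.DataFrame:
    try:
        return pd.read_csv(path)
    except Exception as exc:  # re-raise with the offending file named
        raise ValueError(f"malformed CSV {path}: {exc}") from exc


def read_dataset(path: str | Path) -> StudyDataset:
    """Read a dataset directory written by :func:`write_dataset`.

    Also accepts real data laid out in the same format; raw or counts
    files may be absent for a side, in which case cut-points needing
    that side cannot be evaluated.
    """
    path = Path(path)
    manifest = {}
    mpath = path / "manifest.yaml"
    if mpath.exists():
        manifest = yaml.safe_load(mpath.read_text()) or {}
    config = RunConfig(**manifest.get("config", {})) if manifest.get("config") else RunConfig()

    pdf = _read_csv(path / "participants.csv")
    participants = [
        Participant(id=str(r.id), age=float(r.age), sex=str(r.sex),
                    mass=float(r.mass_kg), height=float(r.height_m),
                    handedness=str(r.handedness))
        for r in pdf.itertuples()
    ]

    tdf = _read_csv(path / "trials.csv")
    trials: list[TrialRecording] = []
    for r in tdf.itertuples():
        stub = f"{r.participant_id}_{r.activity_code}"
        raw: dict[str, np.ndarray | None] = {}
        counts: dict[str, np.ndarray | None] = {}
        for side in ("left", "right"):
            rp = path / f"raw_{stub}_{side}.csv"
            raw[side] = _read_csv(rp)[["ax_g", "ay_g", "az_g"]].to_numpy() if rp.exists() else None
            cp = path / f"counts_{stub}_{side}.csv"
            counts[side] = _read_csv(cp).to_numpy(dtype=float) if cp.exists() else None
        gas = _read_csv(path / f"gas_{stub}.csv")
        flag = None if pd.isna(r.exclusion_flag) or r.exclusion_flag == "" else str(r.exclusion_flag)
        trials.append(TrialRecording(
            participant_id=str(r.participant_id), activity_code=str(r.activity_code),
            raw_left=raw["left"], raw_right=raw["right"],
            counts_left=counts["left"], counts_right=counts["right"],
            gas_t=gas["t_s"].to_numpy(dtype=float),
            vo2=gas["vo2_ml_min"].to_numpy(dtype=float),
            hr=gas["hr_bpm"].to_numpy(dtype=float),
            exclusion_flag=flag,
        ))
    return StudyDataset(participants=participants, profiles=builtin_activity_profiles(),
                        trials=trials, config=config, seed=manifest.get("seed"))


def dataset_hash(path: str | Path) -> str:
    """SHA-256 over all CSV/YAML files of a dataset directory (sorted)."""
    path = Path(path)
    h = hashlib.sha256()
    for f in sorted(path.glob("*")):
        if f.suffix in (".csv", ".yaml"):
            h.update(f.name.encode())
            h.update(f.read_bytes())
    return h.hexdigest()
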