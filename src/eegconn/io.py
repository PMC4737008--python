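"""Reading recordings from the fixture CSV+JSON format or EDF.

The fixture format is one CSV per recording (one column per channel, header
row = montage labels) with a JSON sidecar of the same stem holding
``{fs, subject_id, task_id, group}``. EDF files are read through ``mne`` when
it is installed, with group/subject/task taken from a sidecar JSON if present.
Channels are reordered to the canonical montage on read; unknown or missing
channel labels are an error.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import List, Sequence

import numpy as np
import pandas as pd

from .montage import MONTAGE_1020
from .simulate import Recording


def _reorder(data: np.ndarray, found: Sequence[str], montage: Sequence[str],
             source: str) -> np.ndarray:
    pos = {name: i for i, name in enumerate(found)}
    unknown = [n for n in found if n not in montage]
    if unknown:
        raise ValueError(f"{source}: unknown channel label(s) {unknown}")
    missing = [n for n in montage if n not in pos]
    if missing:
        raise ValueError(f"{source}: missing channel(s) {missing}")
    return data[[pos[n] for n in montage]]


def read_recording(csv_path: Path | str,
                   montage: Sequence[str] = MONTAGE_1020) -> Recording:
    """Read one fixture CSV+JSON pair; channels reordered to ``montage``."""
    csv_path = Path(csv_path)
    meta = json.loads(csv_path.with_suffix(".json").read_text())
    df = pd.read_csv(csv_path)
    data = _reorder(df.to_numpy().T, list(df.columns), montage, csv_path.name)
    return Recording(
        data=data,
        fs=float(meta["fs"]),
        montage=tuple(montage),
        subject_id=str(meta["subject_id"]),
        task_id=str(meta["task_id"]),
        group=int(meta["group"]),
    )


def read_edf(edf_path: Path | str,
             montage: Sequence[str] = MONTAGE_1020) -> Recording:
    """Read an EDF recording via mne (optional dependency); metadata from a
    sidecar JSON of the same stem when present."""
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - depends on extras
        raise ImportError("EDF input requires mne (pip install eegconn[edf])") from exc
    edf_path = Path(edf_path)
    raw = mne.io.read_raw_edf(edf_path, preload=True, verbose="error")
    sidecar = edf_path.with_suffix(".json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    data = _reorder(raw.get_data(), raw.ch_names, montage, edf_path.name)
    return Recording(
        data=data,
        fs=float(raw.info["sfreq"]),
        montage=tuple(montage),
        subject_id=str(meta.get("subject_id", edf_path.stem)),
        task_id=str(meta.get("task_id", "task1")),
        group=int(meta.get("group", 0)),
    )


def read_recordings(path: Path | str,
                    montage: Sequence[str] = MONTAGE_1020) -> List[Recording]:
    """Read every recording in a directory (fixture CSVs and/or EDFs).

    All recordings must share the sampling rate; output is sorted by
    (group, subject_id, task_id).
    """
    path = Path(path)
    recs: List[Recording] = []
    for p in sorted(path.glob("*.csv")):
        recs.append(read_recording(p, montage))
    for p in sorted(path.glob("*.edf")):
        recs.append(read_edf(p, montage))
    if not recs:
        raise FileNotFoundError(f"no recordings (*.csv or *.edf) in {path}")
    fs_set = {r.fs for r in recs}
    if len(fs_set) > 1:
        raise ValueError(f"sampling-rate mismatch across files: {sorted(fs_set)}")
    return sorted(recs, key=lambda r: (r.group, r.subject_id, r.task_id))
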