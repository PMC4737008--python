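"""Synthetic multichannel EEG with planted band-limited interregional correlations.

No public recordings exist for the motor-imagery training-vs-baseline study this
package re-implements, so experiments run on simulated data whose ground truth
is known. The generator plants a chosen Pearson correlation r between selected
channel pairs, restricted to a named frequency band, via source mixing::

    x = z,   y = r * z + sqrt(1 - r**2) * w

with z, w independent unit-variance noises band-limited to the band. Channels
not named in any coupling carry independent pink (1/f-like) background noise;
white sensor noise is added everywhere. Pearson correlation is scale-invariant,
so amplitudes are arbitrary units.

Group 1 is the trained group, group 0 the untrained baseline, matching the
label convention of the downstream classifier.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import signal as sp_signal

from .montage import MONTAGE_1020

#: Nominal analysis bands in Hz. "overall" is the full clinically filtered
#: signal; delta's lower edge is 0.5 Hz because a zero edge is not filterable
#: (and the preprocessing high-pass removes <0.5 Hz anyway).
BAND_HZ: Dict[str, Tuple[float, float]] = {
    "overall": (0.5, 40.0),
    "delta": (0.5, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 20.0),
}


@dataclasses.dataclass(frozen=True)
class CouplingSpec:
    """A planted correlation between one channel pair in one band.

    ``target_r_group0`` / ``target_r_group1`` are the population Pearson
    correlations realized for the baseline and trained group respectively.
    """

    channel_pair: Tuple[str, str]
    band: str = "overall"
    target_r_group0: float = 0.0
    target_r_group1: float = 0.0

    def __post_init__(self) -> None:
        a, b = self.channel_pair
        if a == b:
            raise ValueError(f"coupling pair must be two distinct channels, got {a!r}")
        if self.band not in BAND_HZ:
            raise ValueError(f"unknown band {self.band!r}; choose from {sorted(BAND_HZ)}")
        for r in (self.target_r_group0, self.target_r_group1):
            if not -1.0 <= r <= 1.0:
                raise ValueError(f"target correlation {r} outside [-1, 1]")

    def target_r(self, group: int) -> float:
        return self.target_r_group1 if group == 1 else self.target_r_group0


@dataclasses.dataclass
class SimulationConfig:
    """Full description of one simulated dataset; the seed fixes it bit-for-bit."""

    n_subjects_per_group: int = 4
    tasks_per_subject: int = 2
    duration_s: float = 60.0
    fs: float = 512.0
    montage: Tuple[str, ...] = MONTAGE_1020
    couplings: Tuple[CouplingSpec, ...] = ()
    noise_sd: float = 0.1
    pink_knee_hz: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        n = self.duration_s * self.fs
        if abs(n - round(n)) > 1e-9:
            raise ValueError("duration_s * fs must be an integer number of samples")
        if len(set(self.montage)) != len(self.montage):
            raise ValueError("montage labels must be unique")
        for c in self.couplings:
            for ch in c.channel_pair:
                if ch not in self.montage:
                    raise ValueError(f"coupling channel {ch!r} not in montage")
        keys = [(tuple(sorted(c.channel_pair)), c.band) for c in self.couplings]
        if len(set(keys)) != len(keys):
            raise ValueError("conflicting couplings: duplicate (pair, band)")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s * self.fs))


@dataclasses.dataclass
class Recording:
    """One subject x task multichannel series (channels x samples)."""

    data: np.ndarray
    fs: float
    montage: Tuple[str, ...]
    subject_id: str
    task_id: str
    group: int

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[0] != len(self.montage):
            raise ValueError(
                f"data must be (n_channels={len(self.montage)}, n_samples), "
                f"got {self.data.shape}"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("recording contains non-finite samples")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


def _band_sos(band: str, fs: float):
    low, high = BAND_HZ[band]
    return sp_signal.butter(4, (low, high), btype="bandpass", fs=fs, output="sos")


def bandlimited_noise(n: int, band: str, fs: float, rng: np.random.Generator) -> np.ndarray:
    """Zero-mean, unit-variance Gaussian noise band-limited to a named band."""
    x = rng.standard_normal(n)
    x = sp_signal.sosfiltfilt(_band_sos(band, fs), x)
    x -= x.mean()
    sd = x.std()
    return x / sd if sd > 0 else x


def pink_noise(
    n: int, fs: float, rng: np.random.Generator, knee_hz: float = 5.0
) -> np.ndarray:
    """Unit-variance background noise with a 1/(f + knee) power spectrum.

    The knee flattens the spectrum below ~``knee_hz``, matching the broadband
    shape of resting EEG and keeping the process short-memory enough that
    epoch-level sample correlations between independent channels concentrate
    near zero.
    """
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    amp = 1.0 / np.sqrt(f + knee_hz)
    amp[0] = 0.0  # no DC
    x = np.fft.irfft(spec * amp, n=n)
    x -= x.mean()
    return x / x.std()


def make_coupled_pair(
    n: int, r: float, band: str, fs: float, rng: np.random.Generator
) -> Tuple[np.ndarray, np.ndarray]:
    """Two band-limited series with population Pearson correlation ``r``.

    Returns zero-mean unit-variance x, y with x = z and
    y = r z + sqrt(1-r^2) w for independent band-limited z, w.
    """
    if not -1.0 <= r <= 1.0:
        raise ValueError(f"target correlation {r} outside [-1, 1]")
    if n < 2:
        raise ValueError("need at least 2 samples")
    z = bandlimited_noise(n, band, fs, rng)
    w = bandlimited_noise(n, band, fs, rng)
    y = r * z + np.sqrt(1.0 - r * r) * w
    return z, y


def _simulate_recording(
    cfg: SimulationConfig, group: int, rng: np.random.Generator
) -> np.ndarray:
    n = cfg.n_samples
    n_ch = len(cfg.montage)
    pos = {name: k for k, name in enumerate(cfg.montage)}
    data = np.zeros((n_ch, n))

    coupled = set()
    for c in cfg.couplings:
        x, y = make_coupled_pair(n, c.target_r(group), c.band, cfg.fs, rng)
        data[pos[c.channel_pair[0]]] += x
        data[pos[c.channel_pair[1]]] += y
        coupled.update(c.channel_pair)

    for name in cfg.montage:
        k = pos[name]
        if name not in coupled:
            # background brain activity on unmodelled channels
            data[k] += pink_noise(n, cfg.fs, rng, cfg.pink_knee_hz)
        else:
            # keep background at sensor-noise scale on coupled channels so the
            # planted correlation is realized without analytic compensation
            data[k] += cfg.noise_sd * pink_noise(n, cfg.fs, rng, cfg.pink_knee_hz)
        data[k] += cfg.noise_sd * rng.standard_normal(n)
    return data


def simulate_dataset(cfg: SimulationConfig) -> List[Recording]:
    """Simulate the full two-group study: one Recording per subject x task.

    Output order is (group, subject, task) lexicographic; identical config and
    seed reproduce the output bit-for-bit.
    """
    rng = np.random.default_rng(cfg.seed)
    recordings: List[Recording] = []
    for group in (0, 1):
        for s in range(cfg.n_subjects_per_group):
            for t in range(cfg.tasks_per_subject):
                data = _simulate_recording(cfg, group, rng)
                recordings.append(
                    Recording(
                        data=data,
                        fs=cfg.fs,
                        montage=tuple(cfg.montage),
                        subject_id=f"g{group}s{s + 1:02d}",
                        task_id=f"task{t + 1}",
                        group=group,
                    )
                )
    return recordings


def default_couplings(band: str = "overall") -> Tuple[CouplingSpec, ...]:
    """Three planted couplings on disjoint channel pairs.

    Contrast magnitudes follow the observed motor-imagery connectivity
    contrasts between trained and untrained groups (|r| in the 0.2-0.9 range,
    group differences of about 0.2): the frontotemporal F7-T3 edge weakens
    with training while the occipito-temporal O1-T6 edge strengthens. The
    third contrast is placed on the disjoint midline pair Cz-Fz so that no
    channel hosts two couplings (a shared channel would dilute both).
    """
    if band == "beta":
        values = [("O1", "T6", 0.35, 0.58), ("F7", "T3", 0.68, 0.50), ("Cz", "Fz", 0.57, 0.40)]
    else:
        values = [("F7", "T3", 0.67, 0.45), ("O1", "T6", 0.37, 0.54), ("Cz", "Fz", 0.53, 0.34)]
    return tuple(
        CouplingSpec(channel_pair=(a, b), band=band, target_r_group0=r0, target_r_group1=r1)
        for a, b, r0, r1 in values
    )


def study_config(
    seed: int = 0,
    band: str = "overall",
    couplings: Optional[Sequence[CouplingSpec]] = None,
) -> SimulationConfig:
    """Configuration matching the study geometry: 4 subjects/group x 2 tasks,
    60 s at 512 Hz, 19-channel 10-20 montage."""
    if couplings is None:
        couplings = default_couplings(band)
    return SimulationConfig(
        n_subjects_per_group=4,
        tasks_per_subject=2,
        duration_s=60.0,
        fs=512.0,
        couplings=tuple(couplings),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# fixture-format writer (CSV per recording + JSON sidecar)

def write_recording(rec: Recording, out_dir: Path | str) -> Path:
    """Write one recording as ``<stem>.csv`` (columns = channels, header =
    montage) plus ``<stem>.json`` metadata; returns the CSV path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stem = f"{rec.subject_id}_{rec.task_id}"
    csv_path = out_dir / f"{stem}.csv"
    np.savetxt(
        csv_path,
        rec.data.T,
        delimiter=",",
        header=",".join(rec.montage),
        comments="",
        fmt="%.10g",
    )
    meta = {
        "fs": rec.fs,
        "subject_id": rec.subject_id,
        "task_id": rec.task_id,
        "group": rec.group,
    }
    (out_dir / f"{stem}.json").write_text(json.dumps(meta, indent=2))
    return csv_path


def write_dataset(recordings: Sequence[Recording], out_dir: Path | str) -> List[Path]:
    return [write_recording(r, out_dir) for r in recordings]
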