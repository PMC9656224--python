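"""Domain model for multichannel physiological recordings.

A :class:`Recording` holds one subject's trials; each :class:`Trial` carries
an EEG matrix and a peripheral-channel matrix with named channels plus
continuous valence/arousal ratings on the 1-9 scale.  Windowing, channel
selection, label dichotomization and the native HDF5 layout live here.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import h5py
import numpy as np
import pandas as pd

__all__ = [
    "EMOTIV_14",
    "EEG_32",
    "PERIPHERAL_8",
    "LOW",
    "HIGH",
    "Trial",
    "Recording",
    "Window",
    "dichotomize",
    "slide_windows",
    "select_channels",
    "write_recording",
    "read_recording",
    "read_array_recording",
    "ratings_frame",
    "write_ratings_csv",
]

#: The 14-electrode consumer-headset subset (10-20 names).
EMOTIV_14 = (
    "AF3", "F7", "F3", "FC5", "T7", "P7", "O1",
    "O2", "P8", "T8", "FC6", "F4", "F8", "AF4",
)

#: 32-electrode cap layout (Geneva ordering) used by the array adapter.
EEG_32 = (
    "Fp1", "AF3", "F3", "F7", "FC5", "FC1", "C3", "T7",
    "CP5", "CP1", "P3", "P7", "PO3", "O1", "Oz", "Pz",
    "Fp2", "AF4", "Fz", "F4", "F8", "FC6", "FC2", "Cz",
    "C4", "T8", "CP6", "CP2", "P4", "P8", "PO4", "O2",
)

#: The 8 peripheral sensor channels in canonical order.
PERIPHERAL_8 = ("hEOG", "vEOG", "zEMG", "tEMG", "GSR", "Resp", "Plet", "Temp")

LOW = "low"
HIGH = "high"

#: Ratings at or below this value map to the low class.
RATING_SPLIT = 4.5


def _as_label_tuple(labels: Sequence[str]) -> tuple[str, ...]:
    out = tuple(str(c) for c in labels)
    if len(set(out)) != len(out):
        raise ValueError(f"duplicate channel labels: {sorted(out)}")
    return out


@dataclass
class Trial:
    """One stimulus presentation: EEG + peripheral signals and its ratings."""

    trial_id: str
    eeg: np.ndarray
    eeg_channels: tuple[str, ...]
    peripheral: np.ndarray
    peripheral_channels: tuple[str, ...]
    valence: float
    arousal: float

    def __post_init__(self) -> None:
        self.eeg = np.asarray(self.eeg, dtype=np.float64)
        self.peripheral = np.asarray(self.peripheral, dtype=np.float64)
        self.eeg_channels = _as_label_tuple(self.eeg_channels)
        self.peripheral_channels = _as_label_tuple(self.peripheral_channels)
        if self.eeg.ndim != 2 or self.peripheral.ndim != 2:
            raise ValueError("eeg and peripheral must be 2-D [channels x samples]")
        if self.eeg.shape[0] != len(self.eeg_channels):
            raise ValueError(
                f"trial {self.trial_id!r}: eeg has {self.eeg.shape[0]} rows "
                f"but {len(self.eeg_channels)} labels"
            )
        if self.peripheral.shape[0] != len(self.peripheral_channels):
            raise ValueError(
                f"trial {self.trial_id!r}: peripheral has {self.peripheral.shape[0]} "
                f"rows but {len(self.peripheral_channels)} labels"
            )
        if self.eeg.shape[0] < 2:
            raise ValueError(f"trial {self.trial_id!r}: need >= 2 EEG channels")
        if self.peripheral.size and self.eeg.shape[1] != self.peripheral.shape[1]:
            raise ValueError(
                f"trial {self.trial_id!r}: eeg has {self.eeg.shape[1]} samples, "
                f"peripheral has {self.peripheral.shape[1]}"
            )
        for name, value in (("valence", self.valence), ("arousal", self.arousal)):
            if not 1.0 <= float(value) <= 9.0:
                raise ValueError(
                    f"trial {self.trial_id!r}: {name}={value} outside [1, 9]"
                )

    @property
    def n_samples(self) -> int:
        return self.eeg.shape[1]


@dataclass
class Recording:
    """All trials of one subject, sharing a sampling rate and channel sets."""

    subject_id: str
    trials: list[Trial]
    rate_hz: float

    def __post_init__(self) -> None:
        if self.rate_hz <= 0:
            raise ValueError(f"rate_hz must be positive, got {self.rate_hz}")
        if not self.trials:
            raise ValueError(f"recording {self.subject_id!r} has no trials")
        first = self.trials[0]
        for t in self.trials[1:]:
            if t.eeg_channels != first.eeg_channels:
                raise ValueError(
                    f"recording {self.subject_id!r}: EEG channel sets differ "
                    f"between trials {first.trial_id!r} and {t.trial_id!r}"
                )
            if t.peripheral_channels != first.peripheral_channels:
                raise ValueError(
                    f"recording {self.subject_id!r}: peripheral channel sets "
                    f"differ between trials"
                )

    @property
    def eeg_channels(self) -> tuple[str, ...]:
        return self.trials[0].eeg_channels

    @property
    def peripheral_channels(self) -> tuple[str, ...]:
        return self.trials[0].peripheral_channels


@dataclass
class Window:
    """A fixed-duration multichannel segment inheriting its trial's ratings."""

    subject_id: str
    trial_id: str
    start_s: float
    length_s: float
    eeg: np.ndarray
    eeg_channels: tuple[str, ...]
    peripheral: np.ndarray
    peripheral_channels: tuple[str, ...]
    valence: float
    arousal: float

    @property
    def source(self) -> tuple[str, str]:
        return (self.subject_id, self.trial_id)


def dichotomize(rating: float) -> str:
    """Map a 1-9 rating to ``"low"`` (<= 4.5) or ``"high"`` (> 4.5)."""
    rating = float(rating)
    if not 1.0 <= rating <= 9.0:
        raise ValueError(f"rating {rating} outside [1, 9]")
    return LOW if rating <= RATING_SPLIT else HIGH


def _to_samples(seconds: float, rate_hz: float, what: str) -> int:
    n = seconds * rate_hz
    n_int = int(round(n))
    if n_int <= 0 or abs(n - n_int) > 1e-9:
        raise ValueError(
            f"{what} = {seconds}s at {rate_hz} Hz is not a positive integer "
            f"sample count"
        )
    return n_int


def slide_windows(
    trial: Trial,
    rate_hz: float,
    window_s: float = 4.0,
    step_s: float = 2.0,
    subject_id: str = "",
) -> list[Window]:
    """Cut a trial into left-aligned sliding windows.

    Returns ``floor((T - window_s)/step_s) + 1`` windows for a trial of
    duration ``T`` seconds; trailing samples shorter than a full window are
    discarded.  A trial shorter than one window is an error.
    """
    win = _to_samples(window_s, rate_hz, "window_s")
    step = _to_samples(step_s, rate_hz, "step_s")
    n = trial.n_samples
    if n < win:
        raise ValueError(
            f"trial {trial.trial_id!r} has {n} samples "
            f"(< one {win}-sample window)"
        )
    windows = []
    for start in range(0, n - win + 1, step):
        windows.append(
            Window(
                subject_id=subject_id,
                trial_id=trial.trial_id,
                start_s=start / rate_hz,
                length_s=window_s,
                eeg=trial.eeg[:, start : start + win],
                eeg_channels=trial.eeg_channels,
                peripheral=trial.peripheral[:, start : start + win],
                peripheral_channels=trial.peripheral_channels,
                valence=trial.valence,
                arousal=trial.arousal,
            )
        )
    return windows


def select_channels(trial: Trial, wanted: Sequence[str] = EMOTIV_14) -> Trial:
    """Restrict a trial's EEG matrix to ``wanted`` labels, in that order."""
    wanted = list(wanted)
    missing = [c for c in wanted if c not in trial.eeg_channels]
    if missing:
        raise KeyError(
            f"channels not present in trial {trial.trial_id!r}: {missing}"
        )
    idx = [trial.eeg_channels.index(c) for c in wanted]
    return replace(
        trial,
        eeg=trial.eeg[idx, :].copy(),
        eeg_channels=tuple(wanted),
    )


# ---------------------------------------------------------------------------
# Native HDF5 layout
# ---------------------------------------------------------------------------

def write_recording(recording: Recording, path: str | Path) -> None:
    """Serialize a recording to the native per-subject HDF5 layout."""
    with h5py.File(path, "w") as f:
        f.attrs["subject_id"] = recording.subject_id
        f.attrs["rate_hz"] = float(recording.rate_hz)
        f.attrs["trial_order"] = [t.trial_id for t in recording.trials]
        trials = f.create_group("trials")
        for t in recording.trials:
            g = trials.create_group(t.trial_id)
            g.create_dataset("eeg", data=t.eeg)
            g.create_dataset("peripheral", data=t.peripheral)
            g.attrs["eeg_channels"] = list(t.eeg_channels)
            g.attrs["peripheral_channels"] = list(t.peripheral_channels)
            g.attrs["valence"] = float(t.valence)
            g.attrs["arousal"] = float(t.arousal)


def _require_attr(obj, name: str, where: str):
    if name not in obj.attrs:
        raise ValueError(f"malformed recording file: missing attribute "
                         f"{name!r} on {where}")
    return obj.attrs[name]


def read_recording(path: str | Path) -> Recording:
    """Read a recording from the native HDF5 layout (round-trip identity)."""
    with h5py.File(path, "r") as f:
        subject_id = str(_require_attr(f, "subject_id", "/"))
        rate_hz = float(_require_attr(f, "rate_hz", "/"))
        if "trials" not in f:
            raise ValueError("malformed recording file: missing group 'trials'")
        order = [str(t) for t in _require_attr(f, "trial_order", "/")]
        trials = []
        for tid in order:
            if tid not in f["trials"]:
                raise ValueError(
                    f"malformed recording file: missing group 'trials/{tid}'"
                )
            g = f["trials"][tid]
            for ds in ("eeg", "peripheral"):
                if ds not in g:
                    raise ValueError(
                        f"malformed recording file: missing dataset "
                        f"'trials/{tid}/{ds}'"
                    )
            trials.append(
                Trial(
                    trial_id=tid,
                    eeg=g["eeg"][()],
                    eeg_channels=tuple(
                        str(c) for c in
                        _require_attr(g, "eeg_channels", f"trials/{tid}")
                    ),
                    peripheral=g["peripheral"][()],
                    peripheral_channels=tuple(
                        str(c) for c in
                        _require_attr(g, "peripheral_channels", f"trials/{tid}")
                    ),
                    valence=float(_require_attr(g, "valence", f"trials/{tid}")),
                    arousal=float(_require_attr(g, "arousal", f"trials/{tid}")),
                )
            )
    return Recording(subject_id=subject_id, trials=trials, rate_hz=rate_hz)


# ---------------------------------------------------------------------------
# Adapter for the published preprocessed per-subject array packaging
# ---------------------------------------------------------------------------

def read_array_recording(
    path: str | Path,
    subject_id: str | None = None,
    rate_hz: float = 128.0,
    n_eeg: int = 32,
) -> Recording:
    """Read a per-subject ``{data: trials x channels x samples, labels:
    trials x 4}`` archive (pickle ``.dat`` or ``.npz``) into a Recording.

    The first ``n_eeg`` channel rows are EEG (cap layout order), the rest
    peripheral; label columns 0 and 1 are the valence and arousal ratings.
    """
    path = Path(path)
    if path.suffix == ".npz":
        archive = np.load(path)
        payload = {"data": archive["data"], "labels": archive["labels"]}
    else:
        with open(path, "rb") as fh:
            payload = pickle.load(fh, encoding="latin1")
    for key in ("data", "labels"):
        if key not in payload:
            raise ValueError(f"malformed array recording: missing key {key!r}")
    data = np.asarray(payload["data"], dtype=np.float64)
    labels = np.asarray(payload["labels"], dtype=np.float64)
    if data.ndim != 3:
        raise ValueError(f"'data' must be 3-D, got shape {data.shape}")
    if labels.shape[0] != data.shape[0] or labels.shape[1] < 2:
        raise ValueError(
            f"'labels' shape {labels.shape} incompatible with "
            f"{data.shape[0]} trials"
        )
    n_channels = data.shape[1]
    if not 2 <= n_eeg < n_channels + 1:
        raise ValueError(f"n_eeg={n_eeg} invalid for {n_channels} channels")
    eeg_names = EEG_32 if n_eeg == 32 else tuple(f"EEG{i}" for i in range(n_eeg))
    n_per = n_channels - n_eeg
    per_names = PERIPHERAL_8 if n_per == 8 else tuple(
        f"PER{i}" for i in range(n_per)
    )
    if subject_id is None:
        subject_id = path.stem
    trials = [
        Trial(
            trial_id=f"trial{i:02d}",
            eeg=data[i, :n_eeg, :],
            eeg_channels=eeg_names,
            peripheral=data[i, n_eeg:, :],
            peripheral_channels=per_names,
            valence=float(labels[i, 0]),
            arousal=float(labels[i, 1]),
        )
        for i in range(data.shape[0])
    ]
    return Recording(subject_id=subject_id, trials=trials, rate_hz=rate_hz)


# ---------------------------------------------------------------------------
# Ratings export
# ---------------------------------------------------------------------------

def ratings_frame(recordings: Iterable[Recording]) -> pd.DataFrame:
    rows = [
        {
            "subject_id": rec.subject_id,
            "trial_id": t.trial_id,
            "valence": t.valence,
            "arousal": t.arousal,
        }
        for rec in recordings
        for t in rec.trials
    ]
    return pd.DataFrame(rows, columns=["subject_id", "trial_id", "valence", "arousal"])


def write_ratings_csv(recordings: Iterable[Recording], path: str | Path) -> None:
    ratings_frame(recordings).to_csv(path, index=False)
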