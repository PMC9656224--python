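"""Synthetic multichannel datasets with planted class-dependent structure.

EEG channels are mixtures of band-limited latent oscillations; a designated
channel subset shares one latent source with a mixing weight that depends
on the trial's class, so the MI graph differs between classes.  Peripheral
channels are noise processes whose mean shifts with class.  Everything is
driven by one seed, so datasets are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .core import EMOTIV_14, EEG_32, PERIPHERAL_8, Recording, Trial

__all__ = ["GeneratorSpec", "generate_dataset", "ground_truth"]


def _default_labels(n: int, pool: tuple[str, ...], prefix: str) -> tuple[str, ...]:
    if n <= len(pool):
        return pool[:n]
    return pool + tuple(f"{prefix}{i}" for i in range(n - len(pool)))


@dataclass
class GeneratorSpec:
    """Parameters of one synthetic dataset."""

    n_subjects: int = 4
    n_trials_per_subject: int = 16
    trial_length_s: float = 12.0
    rate_hz: float = 128.0
    n_eeg_channels: int = 14
    n_peripheral_channels: int = 8
    #: extra shared-source mixing weight for the high class on the coupled
    #: channels (low class keeps ``base_coupling``).
    coupling_effect: float = 0.7
    base_coupling: float = 0.1
    #: class-dependent mean shift (in noise-std units) on informative
    #: peripheral channels.
    peripheral_effect: float = 2.0
    mechanism_mode: str = "shared"  # or "idiosyncratic"
    #: rating ranges per class; low must stay <= 4.5, high > 4.5.
    label_rule: dict = field(
        default_factory=lambda: {"low": (1.0, 4.0), "high": (5.0, 9.0)}
    )
    #: None: min(4, channel count) of the respective modality.
    n_coupled_channels: int | None = None
    n_informative_peripheral: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_subjects", "n_trials_per_subject", "n_eeg_channels",
                     "n_peripheral_channels"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_eeg_channels < 2:
            raise ValueError("need >= 2 EEG channels")
        if self.coupling_effect < 0 or self.peripheral_effect < 0:
            raise ValueError("effect sizes must be >= 0")
        if self.base_coupling + self.coupling_effect > 1.0:
            raise ValueError("base_coupling + coupling_effect must be <= 1")
        if self.mechanism_mode not in ("shared", "idiosyncratic"):
            raise ValueError(f"unknown mechanism_mode {self.mechanism_mode!r}")
        n = self.trial_length_s * self.rate_hz
        if abs(n - round(n)) > 1e-9 or n <= 0:
            raise ValueError("trial_length_s x rate_hz must be a positive integer")
        if self.n_coupled_channels is None:
            self.n_coupled_channels = min(4, self.n_eeg_channels)
        if self.n_informative_peripheral is None:
            self.n_informative_peripheral = min(4, self.n_peripheral_channels)
        if not 2 <= self.n_coupled_channels <= self.n_eeg_channels:
            raise ValueError("n_coupled_channels out of range")
        if not 1 <= self.n_informative_peripheral <= self.n_peripheral_channels:
            raise ValueError("n_informative_peripheral out of range")
        for cls in ("low", "high"):
            if cls not in self.label_rule:
                raise ValueError(f"label_rule missing class {cls!r}")
            lo, hi = self.label_rule[cls]
            if not (1.0 <= lo <= hi <= 9.0):
                raise ValueError(f"label_rule[{cls!r}] outside [1, 9]")
        if self.label_rule["low"][1] > 4.5:
            raise ValueError("low-class ratings must stay <= 4.5")
        if self.label_rule["high"][0] <= 4.5:
            raise ValueError("high-class ratings must stay > 4.5")

    @property
    def eeg_labels(self) -> tuple[str, ...]:
        pool = EMOTIV_14 if self.n_eeg_channels <= 14 else EEG_32
        return _default_labels(self.n_eeg_channels, pool, "EEG")

    @property
    def peripheral_labels(self) -> tuple[str, ...]:
        return _default_labels(self.n_peripheral_channels, PERIPHERAL_8, "PER")

    @property
    def coupled_channels(self) -> tuple[str, ...]:
        return self.eeg_labels[: self.n_coupled_channels]

    @property
    def informative_peripheral(self) -> tuple[str, ...]:
        return self.peripheral_labels[: self.n_informative_peripheral]


def _oscillation(rng: np.random.Generator, t: np.ndarray,
                 n_components: int = 3) -> np.ndarray:
    """Unit-variance sum of random sinusoids (band-limited 4-30 Hz)."""
    freqs = rng.uniform(4.0, 30.0, size=n_components)
    phases = rng.uniform(0.0, 2 * np.pi, size=n_components)
    amps = rng.uniform(0.5, 1.0, size=n_components)
    sig = np.sum(
        amps[:, None] * np.sin(2 * np.pi * freqs[:, None] * t + phases[:, None]),
        axis=0,
    )
    return sig / sig.std()


def generate_dataset(spec: GeneratorSpec) -> list[Recording]:
    """Generate one recording per subject with balanced planted classes."""
    rng = np.random.default_rng(spec.seed)
    n_samples = int(round(spec.trial_length_s * spec.rate_hz))
    t = np.arange(n_samples) / spec.rate_hz
    coupled = set(spec.coupled_channels)
    informative = set(spec.informative_peripheral)

    recordings = []
    for s in range(spec.n_subjects):
        # per-subject effect directions
        if spec.mechanism_mode == "shared":
            coupling_sign = 1
            periph_sign = 1.0
        else:
            coupling_sign = 1 if rng.random() < 0.5 else -1
            periph_sign = 1.0 if rng.random() < 0.5 else -1.0
        n_trials = spec.n_trials_per_subject
        classes = np.array([0, 1] * ((n_trials + 1) // 2))[:n_trials]
        rng.shuffle(classes)
        trials = []
        for k in range(n_trials):
            is_high = bool(classes[k])
            shared_source = _oscillation(rng, t)
            if (is_high and coupling_sign > 0) or (not is_high and coupling_sign < 0):
                lam = spec.base_coupling + spec.coupling_effect
            else:
                lam = spec.base_coupling
            eeg = np.empty((spec.n_eeg_channels, n_samples))
            for i, ch in enumerate(spec.eeg_labels):
                background = (
                    _oscillation(rng, t)
                    + 0.3 * rng.standard_normal(n_samples)
                )
                background /= background.std()
                if ch in coupled:
                    eeg[i] = (
                        lam * shared_source
                        + np.sqrt(1.0 - lam**2) * background
                    )
                else:
                    eeg[i] = background
            peripheral = np.empty((spec.n_peripheral_channels, n_samples))
            for j, ch in enumerate(spec.peripheral_labels):
                noise = (
                    0.7 * rng.standard_normal(n_samples)
                    + 0.3 * _oscillation(rng, t, n_components=2)
                )
                shift = 0.0
                if ch in informative and is_high:
                    shift = periph_sign * spec.peripheral_effect
                elif ch in informative and not is_high:
                    shift = -periph_sign * spec.peripheral_effect
                peripheral[j] = shift + noise
            cls = "high" if is_high else "low"
            lo, hi = spec.label_rule[cls]
            trials.append(
                Trial(
                    trial_id=f"trial{k:02d}",
                    eeg=eeg,
                    eeg_channels=spec.eeg_labels,
                    peripheral=peripheral,
                    peripheral_channels=spec.peripheral_labels,
                    valence=float(rng.uniform(lo, hi)),
                    arousal=float(rng.uniform(lo, hi)),
                )
            )
        recordings.append(
            Recording(subject_id=f"s{s:02d}", trials=trials, rate_hz=spec.rate_hz)
        )
    return recordings


def ground_truth(spec: GeneratorSpec) -> dict:
    """Which channels/statistics carry the planted class signal."""
    return {
        "coupled_channels": list(spec.coupled_channels),
        "coupled_pairs": [
            list(p) for p in combinations(spec.coupled_channels, 2)
        ],
        "informative_peripheral_channels": list(spec.informative_peripheral),
        "planted_statistics": ["mean", "q25", "q50", "q75", "max", "min"],
        "mechanism_mode": spec.mechanism_mode,
    }
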