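"""Configuration and end-to-end feature extraction.

``extract_features`` turns recordings into the per-window feature table
consumed by the evaluation protocols: 12 statistics per peripheral channel
plus 5 global and 4-per-node graph measures of the MI connectivity graph.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .connectivity import DEFAULT_BINS, connectivity_matrix
from .core import EMOTIV_14, Recording, select_channels, slide_windows
from .evaluate import META_COLUMNS
from .fusion import GAConfig, concatenate
from .graphs import graph_feature_block
from .models import CNNArchitecture
from .peripheral import APEN_M, APEN_R_FACTOR, peripheral_feature_vector

__all__ = ["PipelineConfig", "extract_features", "adjacency_frame"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Pipeline defaults mirror the published settings: 4 s windows with a
    2 s step, the 14-electrode subset, and labels dichotomized at 4.5."""

    window_s: float = 4.0
    step_s: float = 2.0
    channels: tuple[str, ...] | None = EMOTIV_14
    mi_bins: int = DEFAULT_BINS
    apen_m: int = APEN_M
    apen_r_factor: float = APEN_R_FACTOR
    modularity_seed: int = 0
    classifier: str = "svm"
    protocol: str = "subject_dependent"
    dimension: str = "valence"
    use_ga: bool = False
    seed: int = 0
    ga: GAConfig = field(default_factory=GAConfig)
    cnn: CNNArchitecture = field(default_factory=CNNArchitecture)

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw)
        if "ga" in raw and isinstance(raw["ga"], dict):
            raw["ga"] = GAConfig(**raw["ga"])
        if "cnn" in raw and isinstance(raw["cnn"], dict):
            raw["cnn"] = CNNArchitecture(**raw["cnn"])
        if raw.get("channels") is not None:
            raw["channels"] = tuple(raw["channels"])
        unknown = set(raw) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def _maybe_select(recording: Recording, channels: Sequence[str] | None):
    """Apply the configured channel subset when it is available."""
    if channels is None:
        return recording.trials
    available = set(recording.eeg_channels)
    if set(channels) <= available:
        return [select_channels(t, channels) for t in recording.trials]
    if len(recording.eeg_channels) <= len(channels):
        # already a reduced montage (e.g. synthetic data) — keep as is
        return recording.trials
    missing = [c for c in channels if c not in available]
    raise KeyError(f"configured channels missing from recording "
                   f"{recording.subject_id!r}: {missing}")


def extract_features(
    recordings: Iterable[Recording],
    config: PipelineConfig | None = None,
) -> pd.DataFrame:
    """One row per window: meta columns, then fused named features."""
    config = config or PipelineConfig()
    rows: list[dict] = []
    t0 = time.monotonic()
    n_windows = 0
    for rec in recordings:
        for trial in _maybe_select(rec, config.channels):
            for window in slide_windows(
                trial, rec.rate_hz, config.window_s, config.step_s,
                subject_id=rec.subject_id,
            ):
                periph = peripheral_feature_vector(
                    window, m=config.apen_m, r_factor=config.apen_r_factor
                )
                adj = connectivity_matrix(window, bins=config.mi_bins)
                graph = graph_feature_block(adj, seed=config.modularity_seed)
                fused = concatenate(periph, graph, window.valence, window.arousal)
                row = {
                    "subject_id": window.subject_id,
                    "trial_id": window.trial_id,
                    "start_s": window.start_s,
                    "valence": window.valence,
                    "arousal": window.arousal,
                }
                row.update(zip(fused.names, fused.values))
                rows.append(row)
                n_windows += 1
    if not rows:
        raise ValueError("no windows extracted (empty input)")
    frame = pd.DataFrame(rows)
    logger.info(
        "extracted %d windows x %d features in %.1fs (config %s)",
        n_windows, frame.shape[1] - len(META_COLUMNS),
        time.monotonic() - t0, config.config_hash(),
    )
    return frame


def adjacency_frame(adj_weights: np.ndarray, labels: Sequence[str]) -> pd.DataFrame:
    """Square labelled connectivity matrix for diagnostic CSV export."""
    return pd.DataFrame(adj_weights, index=list(labels), columns=list(labels))
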