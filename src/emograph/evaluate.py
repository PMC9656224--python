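"""Training and evaluation protocols.

Both protocols consume a per-window feature table (meta columns
``subject_id, trial_id, start_s, valence, arousal`` followed by feature
columns) and produce an :class:`EvalReport` of per-subject accuracies.

* subject-dependent: per subject, stratified 85/15 window split, optional
  GA selection on the training side only;
* subject-independent (leave-one-subject-out): each subject in turn is the
  test set; GA selection and model fitting see only the pooled training
  subjects.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from sklearn.model_selection import GroupShuffleSplit, train_test_split

from .core import HIGH, dichotomize
from .fusion import GAConfig, SelectionResult, ga_select
from .models import make_classifier

__all__ = [
    "META_COLUMNS",
    "EvalReport",
    "accuracy",
    "feature_columns",
    "binary_labels",
    "subject_dependent_eval",
    "loocv_eval",
]

logger = logging.getLogger(__name__)

META_COLUMNS = ("subject_id", "trial_id", "start_s", "valence", "arousal")


def accuracy(pred: np.ndarray, truth: np.ndarray) -> float:
    """Fraction of agreeing entries."""
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape or pred.size == 0:
        raise ValueError("pred and truth must be equal-length non-empty arrays")
    return float(np.mean(pred == truth))


@dataclass
class EvalReport:
    """Per-subject accuracies with their mean and standard deviation."""

    protocol: str
    dimension: str
    learner: str
    use_ga: bool
    per_subject: dict[str, float]
    config: dict = field(default_factory=dict)

    @property
    def mean(self) -> float:
        return float(np.mean(list(self.per_subject.values())))

    @property
    def std(self) -> float:
        return float(np.std(list(self.per_subject.values())))

    def to_dict(self) -> dict:
        return {
            "protocol": self.protocol,
            "dimension": self.dimension,
            "learner": self.learner,
            "use_ga": self.use_ga,
            "per_subject": dict(self.per_subject),
            "mean": self.mean,
            "std": self.std,
            "config": dict(self.config),
        }


def feature_columns(features: pd.DataFrame) -> list[str]:
    missing = [c for c in META_COLUMNS if c not in features.columns]
    if missing:
        raise ValueError(f"feature table missing meta columns: {missing}")
    return [c for c in features.columns if c not in META_COLUMNS]


def binary_labels(features: pd.DataFrame, dimension: str) -> np.ndarray:
    """0/1 labels for one dimension (1 = high, rating > 4.5)."""
    if dimension not in ("valence", "arousal"):
        raise ValueError(f"dimension must be valence or arousal, got {dimension!r}")
    return np.array(
        [int(dichotomize(r) == HIGH) for r in features[dimension]], dtype=int
    )


LearnerFactory = Callable[[int], object]


def _resolve_learner(learner, seed: int, learner_params: dict | None):
    if callable(learner):
        return learner(seed)
    return make_classifier(learner, seed=seed, **(learner_params or {}))


def _fit_score(
    learner,
    seed: int,
    learner_params: dict | None,
    X_tr: np.ndarray,
    y_tr: np.ndarray,
    X_te: np.ndarray,
    y_te: np.ndarray,
    use_ga: bool,
    ga_config: GAConfig | None,
    ga_classifier_kind: str | None,
    names: list[str],
) -> tuple[float, SelectionResult | None]:
    selection = None
    if use_ga:
        kind = ga_classifier_kind or (learner if isinstance(learner, str) else "svm")
        selection = ga_select(
            X_tr, y_tr, classifier_kind=kind,
            cfg=ga_config or GAConfig(seed=seed), feature_names=names,
        )
        X_tr = X_tr[:, selection.mask]
        X_te = X_te[:, selection.mask]
    clf = _resolve_learner(learner, seed, learner_params)
    clf.fit(X_tr, y_tr)
    return accuracy(clf.predict(X_te), y_te), selection


def subject_dependent_eval(
    features: pd.DataFrame,
    dimension: str,
    learner="svm",
    use_ga: bool = False,
    ga_config: GAConfig | None = None,
    ga_classifier_kind: str | None = None,
    learner_params: dict | None = None,
    test_size: float = 0.15,
    group_by_trial: bool = False,
    seed: int = 0,
) -> EvalReport:
    """Per-subject 85/15 train/test evaluation.

    Windows of one trial may land on both sides of the split (the literal
    protocol); set ``group_by_trial`` to keep whole trials together and
    avoid the optimistic bias this induces.
    """
    cols = feature_columns(features)
    y_all = binary_labels(features, dimension)
    per_subject: dict[str, float] = {}
    for subject, idx in features.groupby("subject_id", sort=True).groups.items():
        sub = features.loc[idx]
        y = y_all[features.index.get_indexer(idx)]
        if np.unique(y).size < 2:
            msg = (f"subject {subject!r} has a single {dimension} class; "
                   f"excluded from the subject-dependent report")
            logger.warning(msg)
            warnings.warn(msg, stacklevel=2)
            continue
        X = sub[cols].to_numpy(dtype=np.float64)
        if group_by_trial:
            splitter = GroupShuffleSplit(
                n_splits=1, test_size=test_size, random_state=seed
            )
            tr, te = next(splitter.split(X, y, groups=sub["trial_id"]))
        else:
            tr, te = train_test_split(
                np.arange(len(y)), test_size=test_size, stratify=y,
                random_state=seed,
            )
        acc, _ = _fit_score(
            learner, seed, learner_params, X[tr], y[tr], X[te], y[te],
            use_ga, ga_config, ga_classifier_kind, cols,
        )
        per_subject[str(subject)] = acc
    return EvalReport(
        protocol="subject_dependent",
        dimension=dimension,
        learner=learner if isinstance(learner, str) else "custom",
        use_ga=use_ga,
        per_subject=per_subject,
        config={
            "test_size": test_size, "seed": seed,
            "group_by_trial": group_by_trial,
        },
    )


def loocv_eval(
    features: pd.DataFrame,
    dimension: str,
    learner="svm",
    use_ga: bool = False,
    ga_config: GAConfig | None = None,
    ga_classifier_kind: str | None = None,
    learner_params: dict | None = None,
    seed: int = 0,
) -> EvalReport:
    """Leave-one-subject-out evaluation (subject-independent protocol).

    GA selection, when enabled, runs only on the pooled training subjects
    with its own inner 85/15 split; the held-out subject's windows are
    scored once by the final model.
    """
    subjects = sorted(features["subject_id"].unique())
    if len(subjects) < 2:
        raise ValueError("leave-one-subject-out needs >= 2 subjects")
    cols = feature_columns(features)
    y_all = binary_labels(features, dimension)
    per_subject: dict[str, float] = {}
    for subject in subjects:
        test_mask = (features["subject_id"] == subject).to_numpy()
        y_tr, y_te = y_all[~test_mask], y_all[test_mask]
        if np.unique(y_tr).size < 2:
            raise ValueError(
                f"training pool for held-out subject {subject!r} has a "
                f"single {dimension} class"
            )
        X = features[cols].to_numpy(dtype=np.float64)
        acc, _ = _fit_score(
            learner, seed, learner_params, X[~test_mask], y_tr,
            X[test_mask], y_te, use_ga, ga_config, ga_classifier_kind, cols,
        )
        per_subject[str(subject)] = acc
    return EvalReport(
        protocol="subject_independent",
        dimension=dimension,
        learner=learner if isinstance(learner, str) else "custom",
        use_ga=use_ga,
        per_subject=per_subject,
        config={"seed": seed},
    )
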