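"""Two-level score-averaging SVM ensemble for virion-protein prediction.

Architecture (bottom up):

1. For one feature type, five RBF-kernel SVMs are trained, one per balanced
   undersampled subset.  Cost and gamma of each member are tuned by an
   exhaustive grid search over ``{2^e : e = -10..10}`` (441 pairs) using
   stratified internal cross-validation with mean accuracy as the objective.
   Member scores are posterior probabilities (sigmoid-calibrated decision
   values), so scores are comparable across members and feature spaces.
   Averaging the five member scores gives the per-feature *baseline* score.
2. The five baseline ensembles — one per evolutionary encoder (aac_pssm,
   pssm_composition, dpc_pssm, aadp_pssm, medp), all trained on the *same*
   five balanced subsets — are integrated by averaging their scores.  A
   protein is called a virion protein when the final score is >= the decision
   threshold (default 0.5; the boundary itself is called positive).

Both levels are exposed as sklearn-style classifiers whose ``X`` is a list of
``(ProteinRecord, PssmProfile)`` pairs (the field's analogue of a raw-text
corpus for a vectorising pipeline).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import joblib
import numpy as np
import sklearn
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.calibration import CalibratedClassifierCV
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .datasets import LabeledDataset, undersample_indices
from .encoders import EVOLUTIONARY_ENCODERS, ProteinFeatureEncoder
from .pssm import PssmProfile, ProteinRecord

#: Exponent range of the (C, gamma) search grid: 2^-10 .. 2^10, step 2^1.
DEFAULT_GRID = (-10, 10, 1)

DEFAULT_THRESHOLD = 0.5

MODEL_FORMAT_VERSION = 1


class ModelFormatError(RuntimeError):
    """Raised when a persisted model bundle has an incompatible format version."""


@dataclass
class SvmSpec:
    """One tuned RBF-SVM configuration."""

    C: float
    gamma: float
    cv_accuracy: float = float("nan")


@dataclass
class PredictionResult:
    """Per-protein prediction: baseline scores, final score, binary call."""

    protein_id: str
    baseline_scores: dict[str, float] = field(default_factory=dict)
    final_score: Optional[float] = None
    call: Optional[str] = None
    error: Optional[str] = None


def enumerate_grid(grid: tuple[int, int, int] = DEFAULT_GRID) -> list[tuple[float, float]]:
    """All (C, gamma) pairs of the exponent grid, in deterministic order."""
    lo, hi, step = grid
    exps = range(lo, hi + 1, step)
    return [(2.0**a, 2.0**b) for a in exps for b in exps]


def _resolve_grid(grid) -> list[tuple[float, float]]:
    if grid is None:
        grid = DEFAULT_GRID
    if isinstance(grid, tuple) and len(grid) == 3 and all(
        isinstance(v, int) for v in grid
    ):
        return enumerate_grid(grid)
    return [(float(c), float(g)) for c, g in grid]


def grid_search_svm(
    X: np.ndarray,
    y: np.ndarray,
    grid=DEFAULT_GRID,
    cv: int = 5,
    random_state: int = 0,
) -> SvmSpec:
    """Exhaustive (C, gamma) search maximising mean internal-CV accuracy.

    Ties are broken by enumeration order (smallest C, then smallest gamma),
    which makes the result deterministic for a fixed seed.  ``grid`` may be
    an ``(lo, hi, step)`` exponent triple or an explicit list of pairs.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("grid search needs at least two classes")
    if counts.min() < 2:
        raise ValueError("grid search needs >= 2 samples per class")
    n_splits = int(min(cv, counts.min()))
    pairs = _resolve_grid(grid)
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=random_state)
    splits = list(skf.split(X, y))
    best = None
    for C, gamma in pairs:
        correct = 0
        total = 0
        for tr, te in splits:
            clf = SVC(kernel="rbf", C=C, gamma=gamma)
            clf.fit(X[tr], y[tr])
            correct += int((clf.predict(X[te]) == y[te]).sum())
            total += len(te)
        acc = correct / total
        if best is None or acc > best.cv_accuracy:
            best = SvmSpec(C=C, gamma=gamma, cv_accuracy=acc)
    return best


def _calibrated_svm(spec: SvmSpec, y: np.ndarray, inner_cv: int) -> CalibratedClassifierCV:
    """A tuned RBF-SVM wrapped in sigmoid (Platt) calibration.

    Decision values are cross-fitted, one sigmoid is fitted on them, and the
    SVM is refitted on the whole subset (``ensemble=False``), so member
    scores are posterior probabilities in [0, 1].  Deterministic: the
    calibration splitter does not shuffle and the SVM solver is exact.
    """
    _, counts = np.unique(y, return_counts=True)
    cv = int(min(inner_cv, counts.min()))
    return CalibratedClassifierCV(
        SVC(kernel="rbf", C=spec.C, gamma=spec.gamma),
        method="sigmoid",
        cv=max(cv, 2),
        ensemble=False,
    )


class UndersampleSVMEnsemble(ClassifierMixin, BaseEstimator):
    """Per-feature ensemble: one calibrated RBF-SVM per balanced subset.

    Parameters
    ----------
    encoder : str
        Name of the feature encoder applied to each ``(record, profile)`` pair.
    n_subsets : int
        Number of balanced undersampled subsets (and therefore members).
    grid : tuple or list
        ``(lo, hi, step)`` exponent triple or explicit (C, gamma) pairs.
    inner_cv : int
        Folds of the internal grid-search cross-validation.
    threshold : float
        Score cutoff for the positive call (inclusive).
    random_state : int
        Master seed; subset ``i`` draws with seed ``random_state + i``.
    """

    def __init__(
        self,
        encoder: str = "aac_pssm",
        n_subsets: int = 5,
        grid=DEFAULT_GRID,
        inner_cv: int = 5,
        threshold: float = DEFAULT_THRESHOLD,
        random_state: int = 0,
    ):
        self.encoder = encoder
        self.n_subsets = n_subsets
        self.grid = grid
        self.inner_cv = inner_cv
        self.threshold = threshold
        self.random_state = random_state

    def _encode(self, X) -> np.ndarray:
        return ProteinFeatureEncoder(encoder=self.encoder).fit().transform(X)

    def fit(self, X, y):
        y = np.asarray(y, dtype=int)
        subsets = undersample_indices(
            y, n_subsets=self.n_subsets, seed=self.random_state
        )
        F = self._encode(X)
        self._fit_features(F, y, subsets)
        return self

    def _fit_features(self, F: np.ndarray, y: np.ndarray, subsets) -> None:
        """Train members on a precomputed feature matrix and given subsets."""
        self.classes_ = np.array([0, 1])
        self.members_ = []
        self.specs_ = []
        self.subset_indices_ = [np.asarray(s) for s in subsets]
        for i, idx in enumerate(self.subset_indices_):
            Xi, yi = F[idx], y[idx]
            spec = grid_search_svm(
                Xi,
                yi,
                grid=self.grid,
                cv=self.inner_cv,
                random_state=self.random_state + i,
            )
            member = _calibrated_svm(spec, yi, self.inner_cv)
            member.fit(Xi, yi)
            self.members_.append(member)
            self.specs_.append(spec)

    def _member_scores(self, F: np.ndarray) -> np.ndarray:
        """(n_members, n_samples) matrix of positive-class probabilities."""
        cols = []
        for member in self.members_:
            pos_col = int(np.flatnonzero(member.classes_ == 1)[0])
            cols.append(member.predict_proba(F)[:, pos_col])
        return np.vstack(cols)

    def decision_scores(self, X) -> np.ndarray:
        """Mean member score per protein, in [0, 1]."""
        F = self._encode(X)
        return self._member_scores(F).mean(axis=0)

    def predict_proba(self, X) -> np.ndarray:
        s = self.decision_scores(X)
        return np.column_stack([1.0 - s, s])

    def predict(self, X) -> np.ndarray:
        return (self.decision_scores(X) >= self.threshold).astype(int)


class Step3Classifier(ClassifierMixin, BaseEstimator):
    """Integrated virion-protein classifier over five evolutionary features.

    All per-feature baselines are trained on the *same* balanced subsets; the
    final score of a protein is the unweighted mean of the five baseline
    scores, and the positive ("virion") call fires at score >= ``threshold``.
    """

    def __init__(
        self,
        encoders: Sequence[str] = EVOLUTIONARY_ENCODERS,
        n_subsets: int = 5,
        grid=DEFAULT_GRID,
        inner_cv: int = 5,
        threshold: float = DEFAULT_THRESHOLD,
        random_state: int = 0,
    ):
        self.encoders = encoders
        self.n_subsets = n_subsets
        self.grid = grid
        self.inner_cv = inner_cv
        self.threshold = threshold
        self.random_state = random_state

    def fit(self, X, y):
        X = list(X)
        y = np.asarray(y, dtype=int)
        missing = [rec.id for rec, prof in X if prof is None]
        if missing:
            raise ValueError(
                f"profiles missing for: {', '.join(missing[:10])}"
                + (" ..." if len(missing) > 10 else "")
            )
        subsets = undersample_indices(
            y, n_subsets=self.n_subsets, seed=self.random_state
        )
        self.classes_ = np.array([0, 1])
        self.subset_indices_ = [np.asarray(s) for s in subsets]
        self.baselines_ = {}
        for enc in self.encoders:
            base = UndersampleSVMEnsemble(
                encoder=enc,
                n_subsets=self.n_subsets,
                grid=self.grid,
                inner_cv=self.inner_cv,
                threshold=self.threshold,
                random_state=self.random_state,
            )
            F = base._encode(X)
            base._fit_features(F, y, subsets)
            self.baselines_[enc] = base
        self.train_ids_ = [rec.id for rec, _ in X]
        return self

    def baseline_scores(self, X) -> dict[str, np.ndarray]:
        X = list(X)
        return {enc: base.decision_scores(X) for enc, base in self.baselines_.items()}

    def decision_scores(self, X) -> np.ndarray:
        scores = self.baseline_scores(X)
        return np.vstack(list(scores.values())).mean(axis=0)

    def predict_proba(self, X) -> np.ndarray:
        s = self.decision_scores(X)
        return np.column_stack([1.0 - s, s])

    def predict(self, X) -> np.ndarray:
        return (self.decision_scores(X) >= self.threshold).astype(int)

    def score_table(self, X) -> "pd.DataFrame":
        """Per-protein score table: id, per-baseline scores, final score, call."""
        import pandas as pd

        X = list(X)
        per = self.baseline_scores(X)
        final = np.vstack(list(per.values())).mean(axis=0)
        data = {"id": [rec.id for rec, _ in X]}
        for enc in self.encoders:
            data[f"score_{enc.upper()}"] = np.round(per[enc], 6)
        data["score_final"] = np.round(final, 6)
        data["call"] = [
            "virion" if s >= self.threshold else "nonvirion" for s in final
        ]
        return pd.DataFrame(data)


def train_step3(ds: LabeledDataset, seed: int = 0, **kwargs) -> Step3Classifier:
    """Train the integrated classifier on a labeled dataset with profiles."""
    clf = Step3Classifier(random_state=seed, **kwargs)
    return clf.fit(ds.pairs(), ds.labels())


def predict(
    model: Step3Classifier,
    pairs: Sequence[tuple[ProteinRecord, Optional[PssmProfile]]],
) -> list[PredictionResult]:
    """Predict per protein; a missing profile yields an error entry and the
    run continues."""
    results: list[PredictionResult] = []
    ok = [(rec, prof) for rec, prof in pairs if prof is not None]
    scored: dict[str, PredictionResult] = {}
    if ok:
        per = model.baseline_scores(ok)
        final = np.vstack(list(per.values())).mean(axis=0)
        for i, (rec, _) in enumerate(ok):
            scored[rec.id] = PredictionResult(
                protein_id=rec.id,
                baseline_scores={enc: float(per[enc][i]) for enc in model.encoders},
                final_score=float(final[i]),
                call="virion" if final[i] >= model.threshold else "nonvirion",
            )
    for rec, prof in pairs:
        if prof is None:
            results.append(
                PredictionResult(protein_id=rec.id, error="missing PSSM profile")
            )
        else:
            results.append(scored[rec.id])
    return results


def _params_hash(model: BaseEstimator) -> str:
    blob = json.dumps(model.get_params(), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def save_model(model: BaseEstimator, path: str | Path) -> Path:
    """Persist a trained classifier as a versioned joblib bundle."""
    path = Path(path)
    joblib.dump(
        {
            "format_version": MODEL_FORMAT_VERSION,
            "class": type(model).__name__,
            "sklearn_version": sklearn.__version__,
            "params_hash": _params_hash(model),
            "model": model,
        },
        path,
    )
    return path


def load_model(path: str | Path):
    """Load a persisted bundle, refusing on format-version mismatch."""
    bundle = joblib.load(path)
    if not isinstance(bundle, dict) or "format_version" not in bundle:
        raise ModelFormatError(f"{path}: not a recognised model bundle")
    if bundle["format_version"] != MODEL_FORMAT_VERSION:
        raise ModelFormatError(
            f"{path}: bundle format version {bundle['format_version']} != "
            f"supported version {MODEL_FORMAT_VERSION}"
        )
    return bundle["model"]
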