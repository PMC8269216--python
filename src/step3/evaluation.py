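"""Binary-classification metrics, cross-validation protocol, BLAST baseline.

Five metrics summarise a confusion table (TP, FP, TN, FN):

* sensitivity  SN  = TP / (TP + FN)
* specificity  SP  = TN / (TN + FP)
* accuracy     ACC = (TP + TN) / (TP + FP + TN + FN)
* F-value      F   = harmonic mean of precision TP / (TP + FP) and SN
* Matthews correlation coefficient
  MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))

plus the false-positive rate FPR = FP / (FP + TN) = 1 - SP.  Any metric with
a zero denominator is reported as 0 and flagged as degenerate.

The cross-validation protocol mirrors the ensemble training design: the
imbalanced training set is undersampled into five balanced subsets, each
subset is evaluated by stratified five-fold cross-validation of the full
multi-feature training + prediction path, and the per-subset metric reports
are averaged (means +/- standard deviations across the five subsets).

The sequence-similarity baseline calls a query a virion protein when it has
at least one BLAST hit against the positive training sequences at
E <= cutoff (default 0.01).  An external ``blastp`` backend is used when
available; the internal backend is a Smith-Waterman alignment whose score is
converted to an approximate E-value with gapped Karlin-Altschul statistics
(clearly a labelled approximation, not a BLAST reimplementation).
"""

from __future__ import annotations

import math
import shutil
import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices
from sklearn.model_selection import StratifiedKFold

from .datasets import LabeledDataset, undersample_indices
from .encoders import EVOLUTIONARY_ENCODERS, ProteinFeatureEncoder
from .ensemble import (
    DEFAULT_GRID,
    DEFAULT_THRESHOLD,
    Step3Classifier,
    _calibrated_svm,
    grid_search_svm,
)
from .pssm import ProteinRecord, write_fasta

DEFAULT_BLAST_EVALUE = 0.01

#: Gapped Karlin-Altschul parameters for BLOSUM62 with gap open 11 / extend 1.
_KA_LAMBDA = 0.267
_KA_K = 0.041


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "tn", "fn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class MetricsReport:
    sn: float
    sp: float
    acc: float
    f: float
    mcc: float
    fpr: float
    counts: ConfusionCounts
    degenerate: list[str] = field(default_factory=list)

    def as_dict(self) -> dict[str, float]:
        return {
            "SN": self.sn,
            "SP": self.sp,
            "ACC": self.acc,
            "F": self.f,
            "MCC": self.mcc,
            "FPR": self.fpr,
        }

    def __str__(self) -> str:  # 3-decimal display; full precision kept inside
        parts = [f"{k}={v:.3f}" for k, v in self.as_dict().items()]
        return " ".join(parts)


@dataclass
class CrossValidationResult:
    per_subset: list[MetricsReport]
    mean: dict[str, float]
    std: dict[str, float]

    def summary(self) -> str:
        return " ".join(
            f"{k}={self.mean[k]:.3f}±{self.std[k]:.3f}" for k in self.mean
        )


def compute_metrics(c: ConfusionCounts) -> MetricsReport:
    """All five metrics plus the false-positive rate from one confusion table.

    Zero-denominator terms are reported as 0 and listed in ``degenerate``.
    """
    if c.total == 0:
        raise ValueError("cannot compute metrics from an all-zero confusion table")
    degenerate = []

    def ratio(num: float, den: float, name: str) -> float:
        if den == 0:
            degenerate.append(name)
            return 0.0
        return num / den

    sn = ratio(c.tp, c.tp + c.fn, "SN")
    sp = ratio(c.tn, c.tn + c.fp, "SP")
    acc = (c.tp + c.tn) / c.total
    prec = ratio(c.tp, c.tp + c.fp, "precision")
    f = ratio(2.0 * prec * sn, prec + sn, "F")
    fpr = ratio(c.fp, c.fp + c.tn, "FPR")
    mcc_den = math.sqrt(
        float(c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
    )
    if mcc_den == 0:
        degenerate.append("MCC")
        mcc = 0.0
    else:
        mcc = (c.tp * c.tn - c.fp * c.fn) / mcc_den
    return MetricsReport(
        sn=sn, sp=sp, acc=acc, f=f, mcc=mcc, fpr=fpr, counts=c, degenerate=degenerate
    )


def confusion_from_labels(y_true, y_pred) -> ConfusionCounts:
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    return ConfusionCounts(
        tp=int(np.sum((y_true == 1) & (y_pred == 1))),
        fp=int(np.sum((y_true == 0) & (y_pred == 1))),
        tn=int(np.sum((y_true == 0) & (y_pred == 0))),
        fn=int(np.sum((y_true == 1) & (y_pred == 0))),
    )


def fivefold_cv(
    ds: LabeledDataset,
    seed: int = 0,
    encoders: Sequence[str] = EVOLUTIONARY_ENCODERS,
    n_subsets: int = 5,
    grid=DEFAULT_GRID,
    inner_cv: int = 5,
    threshold: float = DEFAULT_THRESHOLD,
) -> CrossValidationResult:
    """Stratified five-fold CV on each of the balanced subsets, averaged.

    Within each fold of each balanced subset, one tuned SVM per encoder is
    trained on the training split, the per-encoder probability scores on the
    held-out split are averaged, and calls at ``threshold`` accumulate into
    the subset's confusion table.  The final report is the mean (with
    standard deviation) of the per-subset metric reports.
    """
    X = ds.pairs()
    missing = [rec.id for rec, prof in X if prof is None]
    if missing:
        raise ValueError(f"profiles missing for: {', '.join(missing[:10])}")
    y = ds.labels()
    feature_mats = {
        enc: ProteinFeatureEncoder(encoder=enc).fit().transform(X) for enc in encoders
    }
    subsets = undersample_indices(y, n_subsets=n_subsets, seed=seed)
    reports = []
    for b, idx in enumerate(subsets):
        yb = y[idx]
        if np.unique(yb).size < 2:
            raise ValueError("stratification impossible: subset lost a class")
        skf = StratifiedKFold(n_splits=5, shuffle=True, random_state=seed + b)
        y_true_all: list[np.ndarray] = []
        y_pred_all: list[np.ndarray] = []
        for tr, te in skf.split(np.zeros(len(idx)), yb):
            fold_scores = np.zeros(len(te))
            for enc in encoders:
                F = feature_mats[enc][idx]
                spec = grid_search_svm(
                    F[tr], yb[tr], grid=grid, cv=inner_cv, random_state=seed + b
                )
                clf = _calibrated_svm(spec, yb[tr], inner_cv)
                clf.fit(F[tr], yb[tr])
                pos_col = int(np.flatnonzero(clf.classes_ == 1)[0])
                fold_scores += clf.predict_proba(F[te])[:, pos_col]
            fold_scores /= len(encoders)
            y_true_all.append(yb[te])
            y_pred_all.append((fold_scores >= threshold).astype(int))
        counts = confusion_from_labels(
            np.concatenate(y_true_all), np.concatenate(y_pred_all)
        )
        reports.append(compute_metrics(counts))
    keys = reports[0].as_dict().keys()
    vals = {k: np.array([r.as_dict()[k] for r in reports]) for k in keys}
    return CrossValidationResult(
        per_subset=reports,
        mean={k: float(v.mean()) for k, v in vals.items()},
        std={k: float(v.std(ddof=1)) if len(reports) > 1 else 0.0 for k, v in vals.items()},
    )


class LeakageError(ValueError):
    """Raised when a test set shares protein ids with the training set."""


def independent_test(
    model: Step3Classifier, test: LabeledDataset
) -> tuple[MetricsReport, pd.DataFrame]:
    """Single-pass evaluation of a trained model on a disjoint labeled set.

    Returns the metric report and the per-protein score table (the predict
    schema plus a ``label`` column).  Overlap with the training ids raises
    :class:`LeakageError`.
    """
    train_ids = set(getattr(model, "train_ids_", []))
    overlap = sorted(train_ids & set(test.ids))
    if overlap:
        raise LeakageError(
            f"test set shares ids with training set: {', '.join(overlap[:10])}"
        )
    pairs = test.pairs()
    missing = [rec.id for rec, prof in pairs if prof is None]
    if missing:
        raise ValueError(f"profiles missing for: {', '.join(missing[:10])}")
    table = model.score_table(pairs)
    table["label"] = test.labels()
    y_pred = (table["call"] == "virion").astype(int).to_numpy()
    report = compute_metrics(confusion_from_labels(test.labels(), y_pred))
    return report, table


@dataclass
class BaselineCall:
    protein_id: str
    call: str
    evalue: Optional[float]
    hit_id: Optional[str]


_local_aligner = None


def _get_local_aligner() -> Align.PairwiseAligner:
    global _local_aligner
    if _local_aligner is None:
        a = Align.PairwiseAligner()
        a.mode = "local"
        a.substitution_matrix = substitution_matrices.load("BLOSUM62")
        a.open_gap_score = -11.0
        a.extend_gap_score = -1.0
        _local_aligner = a
    return _local_aligner


def approximate_evalue(query: str, subject: str) -> float:
    """Approximate E-value of the best local alignment of two sequences.

    Smith-Waterman score under BLOSUM62 (gap open 11, extend 1) converted via
    gapped Karlin-Altschul statistics: bits = (lambda*S - ln K)/ln 2,
    E = m*n*2^(-bits).  Residues outside the matrix alphabet map to X.
    """
    alpha = set("ACDEFGHIKLMNPQRSTVWYBZX*")
    q = "".join(c if c in alpha else "X" for c in query)
    s = "".join(c if c in alpha else "X" for c in subject)
    score = _get_local_aligner().score(q, s)
    bits = (_KA_LAMBDA * score - math.log(_KA_K)) / math.log(2.0)
    return len(q) * len(s) * 2.0 ** (-bits)


def _blast_backend_available() -> bool:
    return shutil.which("blastp") is not None and shutil.which("makeblastdb") is not None


def blast_baseline_bulk(
    queries: Sequence[ProteinRecord],
    positives: Sequence[ProteinRecord],
    evalue_cutoff: float = DEFAULT_BLAST_EVALUE,
    backend: str = "auto",
) -> list[BaselineCall]:
    """Classify each query as virion iff it hits the positive set at E <= cutoff."""
    if not positives:
        import warnings

        warnings.warn("empty positive set: every query is called nonvirion")
        return [
            BaselineCall(q.id, "nonvirion", evalue=None, hit_id=None) for q in queries
        ]
    if backend == "auto":
        backend = "blast" if _blast_backend_available() else "internal"
    if backend == "blast":
        return _bulk_external(list(queries), list(positives), evalue_cutoff)
    if backend == "internal":
        return _bulk_internal(list(queries), list(positives), evalue_cutoff)
    raise ValueError(f"unknown backend {backend!r}; use 'auto', 'blast' or 'internal'")


def blast_baseline(
    query: ProteinRecord,
    positives: Sequence[ProteinRecord],
    evalue_cutoff: float = DEFAULT_BLAST_EVALUE,
    backend: str = "auto",
) -> BaselineCall:
    return blast_baseline_bulk([query], positives, evalue_cutoff, backend)[0]


def _bulk_internal(queries, positives, cutoff) -> list[BaselineCall]:
    out = []
    for q in queries:
        best_e, best_id = None, None
        for p in positives:
            e = approximate_evalue(q.sequence, p.sequence)
            if best_e is None or e < best_e:
                best_e, best_id = e, p.id
        call = "virion" if best_e is not None and best_e <= cutoff else "nonvirion"
        out.append(BaselineCall(q.id, call, evalue=best_e, hit_id=best_id))
    return out


def _bulk_external(queries, positives, cutoff) -> list[BaselineCall]:
    if not _blast_backend_available():
        raise RuntimeError(
            "backend='blast' requested but blastp/makeblastdb are not on PATH; "
            "use backend='internal'"
        )
    with tempfile.TemporaryDirectory() as tmp:
        tmp = Path(tmp)
        db_fasta = tmp / "positives.fasta"
        q_fasta = tmp / "queries.fasta"
        write_fasta(list(positives), db_fasta)
        write_fasta(list(queries), q_fasta)
        subprocess.run(
            ["makeblastdb", "-in", str(db_fasta), "-dbtype", "prot"],
            check=True,
            capture_output=True,
        )
        res = subprocess.run(
            [
                "blastp",
                "-query", str(q_fasta),
                "-db", str(db_fasta),
                "-outfmt", "6 qseqid sseqid evalue",
                "-evalue", str(max(cutoff, 10.0)),
            ],
            check=True,
            capture_output=True,
            text=True,
        )
    best: dict[str, tuple[float, str]] = {}
    for line in res.stdout.splitlines():
        qid, sid, ev = line.split("\t")
        ev = float(ev)
        if qid not in best or ev < best[qid][0]:
            best[qid] = (ev, sid)
    out = []
    for q in queries:
        if q.id in best and best[q.id][0] <= cutoff:
            out.append(BaselineCall(q.id, "virion", best[q.id][0], best[q.id][1]))
        else:
            hit = best.get(q.id)
            out.append(
                BaselineCall(
                    q.id, "nonvirion", hit[0] if hit else None, hit[1] if hit else None
                )
            )
    return out
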