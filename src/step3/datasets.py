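"""Labeled dataset assembly, undersampling into balanced subsets, redundancy reduction.

The training problem is imbalanced: phage genomes carry roughly 1.5-3 times
as many nonvirion as virion proteins, and training sets mirror that ratio.
Rather than training one model on imbalanced data, the majority (nonvirion)
class is undersampled: each balanced subset combines *all* positives with an
equal number of negatives drawn without replacement, and the draw is repeated
(five times by default) to produce the subsets that drive the ensemble.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
from Bio import Align

from .pssm import (
    PssmIntegrityError,
    PssmProfile,
    ProteinRecord,
    check_profile_against_record,
    normalize_pssm,
    parse_ascii_pssm,
    read_fasta,
)

#: Ratio band (negatives per positive) the source protocol calls typical.
TYPICAL_RATIO_RANGE = (1.5, 3.0)

DEFAULT_N_SUBSETS = 5
DEFAULT_REDUNDANCY_THRESHOLD = 0.4


class LabelConflictError(ValueError):
    """Raised when an id appears in both the positive and negative class."""


@dataclass
class LabeledDataset:
    """Protein records with binary labels plus their attached profiles."""

    records: list[ProteinRecord]
    profiles: dict[str, PssmProfile] = field(default_factory=dict)
    missing_profiles: list[str] = field(default_factory=list)

    @property
    def n_pos(self) -> int:
        return sum(1 for r in self.records if r.label == 1)

    @property
    def n_neg(self) -> int:
        return sum(1 for r in self.records if r.label == 0)

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def labels(self) -> np.ndarray:
        return np.array([r.label for r in self.records], dtype=int)

    def pairs(self) -> list[tuple[ProteinRecord, Optional[PssmProfile]]]:
        """(record, profile-or-None) pairs in record order — estimator input."""
        return [(r, self.profiles.get(r.id)) for r in self.records]

    def subset(self, ids: list[str]) -> "LabeledDataset":
        keep = set(ids)
        return LabeledDataset(
            records=[r for r in self.records if r.id in keep],
            profiles={k: v for k, v in self.profiles.items() if k in keep},
        )


@dataclass
class BalancedSubset:
    """All positive ids plus an equal number of sampled negative ids."""

    pos_ids: list[str]
    neg_ids: list[str]
    seed: int

    def __post_init__(self) -> None:
        if len(self.pos_ids) != len(self.neg_ids):
            raise ValueError(
                f"balanced subset must satisfy |pos| = |neg|; got "
                f"{len(self.pos_ids)} vs {len(self.neg_ids)}"
            )

    @property
    def ids(self) -> list[str]:
        return self.pos_ids + self.neg_ids


def build_dataset(
    pos_fasta: str | Path,
    neg_fasta: str | Path,
    pssm_dir: Optional[str | Path] = None,
    normalize: str = "sigmoid",
    check_sequences: bool = True,
) -> LabeledDataset:
    """Assemble a labeled dataset from positive/negative FASTA plus a PSSM dir.

    Profiles are matched by file stem (``<id>.pssm``) and normalised on load.
    Records without a profile are kept and listed in ``missing_profiles``.  An
    id present in both classes raises :class:`LabelConflictError`; a warning
    is emitted when the negative:positive ratio falls outside the typical
    1.5-3 band.
    """
    pos = read_fasta(pos_fasta)
    neg = read_fasta(neg_fasta)
    pos_ids = {r.id for r in pos}
    conflicts = sorted(pos_ids & {r.id for r in neg})
    if conflicts:
        raise LabelConflictError(
            f"ids present in both classes: {', '.join(conflicts)}"
        )
    records = []
    for r in pos:
        records.append(ProteinRecord(r.id, r.sequence, label=1))
    for r in neg:
        records.append(ProteinRecord(r.id, r.sequence, label=0))

    profiles: dict[str, PssmProfile] = {}
    missing: list[str] = []
    if pssm_dir is not None:
        pssm_dir = Path(pssm_dir)
        for rec in records:
            path = pssm_dir / f"{rec.id}.pssm"
            if not path.exists():
                missing.append(rec.id)
                continue
            prof = normalize_pssm(parse_ascii_pssm(path), method=normalize)
            if check_sequences:
                check_profile_against_record(rec, prof)
            elif prof.length != len(rec):
                raise PssmIntegrityError(
                    f"profile {rec.id!r}: length {prof.length} != sequence "
                    f"length {len(rec)}"
                )
            profiles[rec.id] = prof
    else:
        missing = [r.id for r in records]

    ds = LabeledDataset(records=records, profiles=profiles, missing_profiles=missing)
    if ds.n_pos > 0:
        ratio = ds.n_neg / ds.n_pos
        lo, hi = TYPICAL_RATIO_RANGE
        if not (lo <= ratio <= hi):
            warnings.warn(
                f"negative:positive ratio {ratio:.2f} falls outside the "
                f"typical {lo}-{hi} range for phage proteomes",
                stacklevel=2,
            )
    return ds


def undersample_indices(
    y: np.ndarray, n_subsets: int = DEFAULT_N_SUBSETS, seed: int = 0
) -> list[np.ndarray]:
    """Index-level undersampling: each subset keeps all positives and draws
    ``n_pos`` negatives without replacement.

    Draws are independent across subsets; subset ``i`` uses the derived seed
    ``seed + i`` so the whole run reproduces from one integer.
    """
    y = np.asarray(y, dtype=int)
    pos = np.flatnonzero(y == 1)
    neg = np.flatnonzero(y == 0)
    if len(pos) < 1:
        raise ValueError("undersampling needs at least one positive sample")
    if len(neg) < len(pos):
        raise ValueError(
            f"undersampling impossible: {len(neg)} negatives < {len(pos)} positives"
        )
    subsets = []
    for i in range(n_subsets):
        rng = np.random.default_rng(seed + i)
        drawn = rng.choice(neg, size=len(pos), replace=False)
        subsets.append(np.concatenate([pos, np.sort(drawn)]))
    return subsets


def undersample_subsets(
    ds: LabeledDataset, n_subsets: int = DEFAULT_N_SUBSETS, seed: int = 0
) -> list[BalancedSubset]:
    """Id-level view of :func:`undersample_indices` over a labeled dataset."""
    y = ds.labels()
    ids = np.array(ds.ids)
    out = []
    for i, idx in enumerate(undersample_indices(y, n_subsets=n_subsets, seed=seed)):
        sub_ids = ids[idx]
        sub_y = y[idx]
        out.append(
            BalancedSubset(
                pos_ids=list(sub_ids[sub_y == 1]),
                neg_ids=list(sub_ids[sub_y == 0]),
                seed=seed + i,
            )
        )
    return out


_identity_aligner = None


def _get_identity_aligner() -> Align.PairwiseAligner:
    global _identity_aligner
    if _identity_aligner is None:
        a = Align.PairwiseAligner()
        a.mode = "global"
        a.match_score = 1.0
        a.mismatch_score = 0.0
        a.open_gap_score = -1.0
        a.extend_gap_score = -0.5
        _identity_aligner = a
    return _identity_aligner


def sequence_identity(a: str, b: str) -> float:
    """Global-alignment identity: matched residues / length of the shorter
    sequence (the convention of greedy identity clustering tools)."""
    aln = _get_identity_aligner().align(a, b)[0]
    matches = 0
    for (a0, a1), (b0, b1) in zip(*aln.aligned):
        seg_a = a[a0:a1]
        seg_b = b[b0:b1]
        matches += sum(x == y for x, y in zip(seg_a, seg_b))
    return matches / min(len(a), len(b))


def redundancy_reduce(
    records: list[ProteinRecord],
    threshold: float = DEFAULT_REDUNDANCY_THRESHOLD,
    backend: str = "internal",
) -> list[ProteinRecord]:
    """Greedy incremental identity clustering; returns cluster representatives.

    Sequences are visited longest-first (ties broken by input order); a
    sequence joins the first representative it matches at >= ``threshold``
    identity, otherwise it founds a new cluster.  Deterministic for a fixed
    input.  ``backend='cdhit'`` delegates to an external ``cd-hit`` binary
    when present; the internal clustering is a documented stand-in whose
    cluster boundaries can differ from CD-HIT's word-filtered heuristic.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must lie in (0, 1]")
    if not records:
        return []
    if backend == "cdhit":
        return _redundancy_reduce_cdhit(records, threshold)
    if backend != "internal":
        raise ValueError(f"unknown backend {backend!r}; use 'internal' or 'cdhit'")
    order = sorted(range(len(records)), key=lambda i: (-len(records[i]), i))
    reps: list[ProteinRecord] = []
    for i in order:
        rec = records[i]
        if not any(sequence_identity(rec.sequence, rep.sequence) >= threshold
                   for rep in reps):
            reps.append(rec)
    return reps


def _redundancy_reduce_cdhit(
    records: list[ProteinRecord], threshold: float
) -> list[ProteinRecord]:
    import shutil
    import subprocess
    import tempfile

    from .pssm import write_fasta

    exe = shutil.which("cd-hit")
    if exe is None:
        raise RuntimeError(
            "backend='cdhit' requested but no 'cd-hit' executable is on PATH; "
            "install CD-HIT or use backend='internal'"
        )
    # word size must shrink with the identity threshold
    n = 2 if threshold < 0.5 else 3 if threshold < 0.6 else 4 if threshold < 0.7 else 5
    with tempfile.TemporaryDirectory() as tmp:
        inp = Path(tmp) / "in.fasta"
        out = Path(tmp) / "out.fasta"
        write_fasta(records, inp)
        subprocess.run(
            [exe, "-i", str(inp), "-o", str(out), "-c", str(threshold), "-n", str(n)],
            check=True,
            capture_output=True,
        )
        kept = {r.id for r in read_fasta(out)}
    return [r for r in records if r.id in kept]
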