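"""Synthetic sequences, profiles and labeled datasets with tunable class signal.

Real training data for virion-protein prediction comes from curated protein
databases plus iterative profile searches against a large reference database,
neither of which is practical to ship.  This module emulates the *shape* of
that data so every other component is exercisable end to end:

* sequences are i.i.d. uniform over the 20 canonical residues, with lengths
  uniform over a configurable range;
* raw profile scores are integer-rounded Gaussian noise (so fixtures look
  like genuine log-odds files);
* a class signal of size ``effect_size`` is added to a fixed set of profile
  columns in the positive class *before* rounding and normalisation.  The
  signal lives at the profile level because all five evolutionary encoders
  are profile-derived.

What this generator does *not* emulate: residue composition biases of real
proteins, homology structure between samples, or position-dependent profile
correlation.  Synthetic results therefore validate the machinery (encoders,
undersampling, tuning, integration, evaluation), not performance on real
phage proteomes.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np

from .datasets import LabeledDataset
from .pssm import (
    CANONICAL_AA,
    PssmProfile,
    ProteinRecord,
    normalize_pssm,
    write_ascii_pssm,
    write_fasta,
)

#: Columns (canonical residue indices) carrying the class signal by default.
DEFAULT_SIGNAL_COLUMNS = (0, 1, 2, 3, 4)


@dataclass
class SynthSpec:
    """Generator settings.

    Defaults reflect the package's reference study condition: 60 positives vs
    170 negatives (a ~1:2.8 imbalance, typical of phage proteomes), lengths
    50-150, unit-free integer log-odds noise with sd 2, and a strong class
    signal of +6 (three noise sds) on five profile columns.
    """

    n_pos: int = 60
    n_neg: int = 170
    length_range: tuple[int, int] = (50, 150)
    effect_size: float = 6.0
    noise_sd: float = 2.0
    signal_columns: tuple[int, ...] = DEFAULT_SIGNAL_COLUMNS
    seed: int = 0
    #: prepended to every record id, so independently drawn train/test sets
    #: can be kept id-disjoint
    id_prefix: str = ""

    def validate(self) -> None:
        if self.n_pos < 0 or self.n_neg < 0:
            raise ValueError("n_pos and n_neg must be nonnegative")
        lo, hi = self.length_range
        if lo < 3 or hi < lo:
            raise ValueError("length_range must satisfy 3 <= lo <= hi")
        if self.effect_size < 0:
            raise ValueError("effect_size must be nonnegative")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if any(not 0 <= c < 20 for c in self.signal_columns):
            raise ValueError("signal_columns must be residue indices in 0..19")


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(CANONICAL_AA), size=length))


def _random_profile(
    rng: np.random.Generator,
    protein_id: str,
    sequence: str,
    effect: float,
    noise_sd: float,
    signal_columns: tuple[int, ...],
) -> PssmProfile:
    L = len(sequence)
    raw = rng.normal(0.0, noise_sd, size=(L, 20))
    if effect:
        raw[:, list(signal_columns)] += effect
    raw = np.rint(raw).astype(int)
    pct = np.clip(np.rint(100.0 / (1.0 + np.exp(-raw / 2.0))), 0, 100).astype(int)
    return PssmProfile(protein_id=protein_id, raw=raw, sequence=sequence, percent=pct)


def generate_dataset(
    spec: SynthSpec,
    out_dir: Optional[str | Path] = None,
    normalize: str = "sigmoid",
) -> LabeledDataset:
    """Draw a labeled dataset from *spec*; optionally write it to disk.

    When ``out_dir`` is given, the on-disk layout exercises the whole I/O
    path: ``pos.fasta``, ``neg.fasta``, ``pssm/<id>.pssm`` and ``truth.tsv``.
    Fully deterministic from ``spec.seed``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.length_range
    records: list[ProteinRecord] = []
    profiles: dict[str, PssmProfile] = {}
    for label, n, prefix in ((1, spec.n_pos, "pos"), (0, spec.n_neg, "neg")):
        effect = spec.effect_size if label == 1 else 0.0
        for i in range(n):
            pid = f"{spec.id_prefix}{prefix}_{i + 1:04d}"
            seq = _random_sequence(rng, int(rng.integers(lo, hi + 1)))
            records.append(ProteinRecord(id=pid, sequence=seq, label=label))
            prof = _random_profile(
                rng, pid, seq, effect, spec.noise_sd, spec.signal_columns
            )
            profiles[pid] = normalize_pssm(prof, method=normalize)
    ds = LabeledDataset(records=records, profiles=profiles)
    if out_dir is not None:
        out_dir = Path(out_dir)
        (out_dir / "pssm").mkdir(parents=True, exist_ok=True)
        write_fasta([r for r in records if r.label == 1], out_dir / "pos.fasta")
        write_fasta([r for r in records if r.label == 0], out_dir / "neg.fasta")
        for pid, prof in profiles.items():
            write_ascii_pssm(prof, out_dir / "pssm" / f"{pid}.pssm")
        with open(out_dir / "truth.tsv", "w") as fh:
            fh.write("id\tlabel\n")
            for r in records:
                fh.write(f"{r.id}\t{r.label}\n")
    return ds


def generate_pssm_fixture(
    L: int,
    mode: str = "random",
    seed: int = 0,
    path: Optional[str | Path] = None,
    constant: int = 2,
    noise_sd: float = 2.0,
) -> PssmProfile:
    """Small structured profiles for targeted tests.

    Modes: ``zero`` (all scores 0, sigmoid-normalised entries all 0.5),
    ``constant`` (all scores equal to *constant*), ``onehot`` (row ``k`` has
    a +16 score at residue index ``k mod 20`` and -16 elsewhere, so the
    normalised row is a numerical one-hot), ``random`` (integer Gaussian
    scores).  When ``path`` is given the profile is also rendered as a valid
    ASCII file (byte-identical across runs for a fixed seed).
    """
    if L < 1:
        raise ValueError("L must be >= 1")
    rng = np.random.default_rng(seed)
    seq = _random_sequence(rng, L)
    if mode == "zero":
        raw = np.zeros((L, 20), dtype=int)
    elif mode == "constant":
        raw = np.full((L, 20), int(constant), dtype=int)
    elif mode == "onehot":
        raw = np.full((L, 20), -16, dtype=int)
        for k in range(L):
            raw[k, k % 20] = 16
    elif mode == "random":
        raw = np.rint(rng.normal(0.0, noise_sd, size=(L, 20))).astype(int)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    pct = np.clip(np.rint(100.0 / (1.0 + np.exp(-raw / 2.0))), 0, 100).astype(int)
    prof = PssmProfile(
        protein_id=f"fixture_{mode}_{L}", raw=raw, sequence=seq, percent=pct
    )
    prof = normalize_pssm(prof)
    if path is not None:
        write_ascii_pssm(prof, path)
    return prof
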