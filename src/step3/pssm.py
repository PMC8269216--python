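"""Reading, writing and normalising PSI-BLAST ASCII profiles and FASTA sequences.

A position-specific scoring matrix (PSSM) for a protein of length ``L`` is an
``L x 20`` matrix of integer log-odds scores produced by iterative profile
search (PSI-BLAST).  Row ``k`` describes the evolutionary preference of each of
the 20 canonical residues at sequence position ``k``.  Downstream feature
encoders consume a normalised version of the profile whose entries lie in
``[0, 1]`` and can be read as per-position residue propensities.

Two normalisations are supported:

``sigmoid``
    ``norm[i, j] = 1 / (1 + exp(-raw[i, j]))`` applied elementwise to the
    log-odds block.  This is the default: it preserves per-cell resolution and
    is the convention of the standard PSSM feature toolkits.
``percentage``
    The weighted-observed-percentage block of the ASCII file divided by 100.
    Only available when the source file carried that block.

Columns are re-mapped at parse time from the file's header order
(``A R N D C Q E G H I L K M F P S T W Y V``) to the fixed alphabetical order
``A C D E F G H I K L M N P Q R S T V W Y`` so that every encoder indexes
residues identically.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
from Bio import SeqIO

#: Canonical residue ordering used for every in-memory matrix and feature.
CANONICAL_AA = "ACDEFGHIKLMNPQRSTVWY"

#: Residue ordering of the PSI-BLAST ASCII header.
PSIBLAST_AA = "ARNDCQEGHILKMFPSTWYV"

AA_INDEX = {aa: i for i, aa in enumerate(CANONICAL_AA)}

_PSIBLAST_TO_CANONICAL = np.array([PSIBLAST_AA.index(aa) for aa in CANONICAL_AA])

_HEADER_LINE = (
    "Last position-specific scoring matrix computed, weighted observed "
    "percentages rounded down, information per position, and relative weight "
    "of gapless real matches to pseudocounts"
)


class PssmParseError(ValueError):
    """Raised when an ASCII PSSM file is malformed (names the offending line)."""


class PssmIntegrityError(ValueError):
    """Raised when a parsed profile is inconsistent with itself or its sequence."""


class FastaError(ValueError):
    """Raised for empty FASTA input or duplicate record identifiers."""


@dataclass
class ProteinRecord:
    """One protein sequence with an optional binary class label.

    label semantics: 1 = virion (structural) protein, 0 = nonvirion protein,
    None = unlabeled query.
    """

    id: str
    sequence: str
    label: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"record {self.id!r}: sequence must be non-empty")
        self.sequence = self.sequence.upper()
        if self.label is not None and self.label not in (0, 1):
            raise ValueError(f"record {self.id!r}: label must be 0, 1 or None")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class PssmProfile:
    """An ``L x 20`` evolutionary profile tied to one protein sequence.

    ``raw`` holds the integer log-odds block in canonical column order;
    ``percent`` the optional weighted-observed-percentage block; ``norm`` the
    normalised propensities in ``[0, 1]`` (``None`` until normalised).
    ``sequence`` is the residue string reconstructed from the row labels of the
    source file and is used for cross-checking against FASTA input.
    """

    protein_id: str
    raw: np.ndarray
    sequence: str
    percent: Optional[np.ndarray] = None
    norm: Optional[np.ndarray] = None
    column_order: str = CANONICAL_AA

    def __post_init__(self) -> None:
        self.raw = np.asarray(self.raw)
        if self.raw.ndim != 2 or self.raw.shape[1] != 20:
            raise PssmIntegrityError(
                f"profile {self.protein_id!r}: raw must be L x 20, "
                f"got shape {self.raw.shape}"
            )
        if self.raw.shape[0] < 1:
            raise PssmIntegrityError(f"profile {self.protein_id!r}: L must be >= 1")
        if len(self.sequence) != self.raw.shape[0]:
            raise PssmIntegrityError(
                f"profile {self.protein_id!r}: sequence length "
                f"{len(self.sequence)} != row count {self.raw.shape[0]}"
            )

    @property
    def length(self) -> int:
        return self.raw.shape[0]

    def validate(self) -> None:
        """Check all structural invariants, raising PssmIntegrityError on failure."""
        if self.norm is not None:
            if self.norm.shape != self.raw.shape:
                raise PssmIntegrityError(
                    f"profile {self.protein_id!r}: norm shape {self.norm.shape} "
                    f"!= raw shape {self.raw.shape}"
                )
            if np.any(self.norm < 0.0) or np.any(self.norm > 1.0):
                raise PssmIntegrityError(
                    f"profile {self.protein_id!r}: norm entries outside [0, 1]"
                )


def normalize_pssm(profile: PssmProfile, method: str = "sigmoid") -> PssmProfile:
    """Return a copy of *profile* with the ``norm`` matrix populated.

    ``sigmoid`` maps each log-odds score s to 1/(1+exp(-s)); scores of 0 map
    to 0.5 and the map is strictly monotone, so relative preferences within a
    column are preserved.  ``percentage`` divides the observed-percentage
    block by 100 and requires that block to be present.
    """
    if method == "sigmoid":
        with np.errstate(over="ignore"):
            norm = 1.0 / (1.0 + np.exp(-profile.raw.astype(float)))
    elif method == "percentage":
        if profile.percent is None:
            raise ValueError(
                f"profile {profile.protein_id!r} has no percentage block; "
                "use method='sigmoid' or re-parse a file that carries one"
            )
        norm = profile.percent.astype(float) / 100.0
    else:
        raise ValueError(f"unknown normalization method {method!r}")
    out = dataclasses.replace(profile, norm=norm)
    out.validate()
    return out


def parse_ascii_pssm(path: str | Path, protein_id: Optional[str] = None) -> PssmProfile:
    """Parse a PSI-BLAST ``-out_ascii_pssm`` file into a :class:`PssmProfile`.

    The first 20-column numeric block (log-odds) becomes ``raw``; the second
    block (weighted observed percentages), when present, is stored as
    ``percent``.  Columns are re-mapped to canonical alphabetical order.  The
    protein id defaults to the file stem.
    """
    path = Path(path)
    if protein_id is None:
        protein_id = path.stem
    lines = path.read_text().splitlines()

    header_idx = None
    file_order: list[str] = []
    for i, line in enumerate(lines):
        toks = line.split()
        if len(toks) in (20, 40) and all(len(t) == 1 and t.isalpha() for t in toks):
            header_idx = i
            file_order = toks[:20]
            break
    if header_idx is None:
        raise PssmParseError(f"{path}: no residue header line found")
    if sorted(file_order) != sorted(CANONICAL_AA):
        raise PssmParseError(
            f"{path}: line {header_idx + 1}: header is not a 20-residue alphabet"
        )

    raw_rows: list[list[int]] = []
    pct_rows: list[list[int]] = []
    residues: list[str] = []
    indices: list[int] = []
    has_percent = None
    for lineno in range(header_idx + 1, len(lines)):
        line = lines[lineno]
        toks = line.split()
        if not toks:
            break
        if not toks[0].lstrip("-").isdigit():
            break  # trailing statistics block
        if len(toks) < 2 or not (len(toks[1]) == 1 and toks[1].isalpha()):
            raise PssmParseError(
                f"{path}: line {lineno + 1}: expected '<pos> <residue> <scores>'"
            )
        n_numeric = len(toks) - 2
        # blast rows carry 20 scores, or 40 scores, or 40 scores plus two
        # information/weight columns (parsed and discarded).
        if n_numeric not in (20, 40, 42):
            raise PssmParseError(
                f"{path}: line {lineno + 1}: expected 20 or 40 score columns, "
                f"found {n_numeric}"
            )
        try:
            scores = [int(t) for t in toks[2 : 2 + min(n_numeric, 40)]]
        except ValueError as exc:
            raise PssmParseError(
                f"{path}: line {lineno + 1}: non-numeric score cell ({exc})"
            ) from None
        indices.append(int(toks[0]))
        residues.append(toks[1].upper())
        raw_rows.append(scores[:20])
        row_has_pct = n_numeric >= 40
        if has_percent is None:
            has_percent = row_has_pct
        elif has_percent != row_has_pct:
            raise PssmParseError(
                f"{path}: line {lineno + 1}: inconsistent column count across rows"
            )
        if row_has_pct:
            pct_rows.append(scores[20:40])

    if not raw_rows:
        raise PssmParseError(f"{path}: no data rows found after header")
    if indices != list(range(1, len(indices) + 1)):
        raise PssmIntegrityError(
            f"{path}: position indices are not contiguous 1..{len(indices)}"
        )

    perm = np.array([file_order.index(aa) for aa in CANONICAL_AA])
    raw = np.asarray(raw_rows, dtype=int)[:, perm]
    percent = np.asarray(pct_rows, dtype=int)[:, perm] if has_percent else None
    return PssmProfile(
        protein_id=protein_id,
        raw=raw,
        sequence="".join(residues),
        percent=percent,
    )


def write_ascii_pssm(profile: PssmProfile, path: str | Path) -> Path:
    """Render *profile* in the PSI-BLAST ASCII layout (round-trips exactly).

    Columns are written in the PSI-BLAST header order.  When the profile has
    no percentage block a zero block is emitted so the file keeps the full
    44-column row layout of the reference tool.
    """
    path = Path(path)
    inv = _PSIBLAST_TO_CANONICAL  # canonical index of each file column
    raw_file = profile.raw[:, [CANONICAL_AA.index(aa) for aa in PSIBLAST_AA]]
    if profile.percent is not None:
        pct_file = profile.percent[:, [CANONICAL_AA.index(aa) for aa in PSIBLAST_AA]]
    else:
        pct_file = np.zeros_like(raw_file)
    del inv

    lines = ["", _HEADER_LINE]
    head = "           " + "  ".join(PSIBLAST_AA) + "   " + "   ".join(PSIBLAST_AA)
    lines.append(head)
    for k in range(profile.length):
        cells = "".join(f"{v:4d}" for v in raw_file[k])
        pcts = "".join(f"{v:4d}" for v in pct_file[k])
        lines.append(f"{k + 1:5d} {profile.sequence[k]} {cells} {pcts}  0.00 0.00")
    lines += [
        "",
        "                      K         Lambda",
        "Standard Ungapped    0.1365     0.3179",
        "Standard Gapped      0.0410     0.2670",
        "PSI Ungapped         0.1365     0.3179",
        "PSI Gapped           0.0410     0.2670",
        "",
    ]
    path.write_text("\n".join(lines))
    return path


def read_fasta(path: str | Path, strict_alphabet: bool = False) -> list[ProteinRecord]:
    """Read a multi-record FASTA file into :class:`ProteinRecord` objects.

    Sequences are uppercased and input order is preserved.  Noncanonical
    residue letters (X, B, Z, U, ...) are retained by default — encoders give
    them zero contribution — unless ``strict_alphabet`` is set, in which case
    they are rejected.
    """
    path = Path(path)
    records = []
    seen: dict[str, int] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        seen[rec.id] = seen.get(rec.id, 0) + 1
        if strict_alphabet:
            bad = sorted({c for c in seq if c not in AA_INDEX})
            if bad:
                raise FastaError(
                    f"{path}: record {rec.id!r} contains noncanonical residues "
                    f"{''.join(bad)} (strict_alphabet=True)"
                )
        records.append(ProteinRecord(id=rec.id, sequence=seq))
    if not records:
        raise FastaError(f"{path}: no FASTA records found")
    dupes = sorted(k for k, v in seen.items() if v > 1)
    if dupes:
        raise FastaError(f"{path}: duplicate record ids: {', '.join(dupes)}")
    return records


def write_fasta(records: list[ProteinRecord], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), 70):
                fh.write(rec.sequence[i : i + 70] + "\n")
    return path


def check_profile_against_record(record: ProteinRecord, profile: PssmProfile) -> None:
    """Cross-check a profile against its FASTA record (length and residues)."""
    if profile.length != len(record):
        raise PssmIntegrityError(
            f"profile {profile.protein_id!r}: length {profile.length} != "
            f"sequence length {len(record)} of record {record.id!r}"
        )
    if profile.sequence != record.sequence:
        raise PssmIntegrityError(
            f"profile {profile.protein_id!r}: reconstructed sequence differs "
            f"from record {record.id!r}"
        )
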