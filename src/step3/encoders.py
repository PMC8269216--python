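"""Fixed-dimension feature encodings of one protein (sequence + profile).

Five evolutionary encoders operate on the normalised PSSM ``p`` (entries
``p[k, j]`` in ``[0, 1]``, ``k`` = position, ``j`` = residue index in
canonical order):

* ``aac_pssm`` (dim 20) — per-column mean of the profile,
  ``v[j] = (1/L) sum_k p[k, j]``.
* ``pssm_composition`` (dim 400) — profile rows grouped by the residue
  observed at that position; group sums divided by ``L`` and the resulting
  20 x 20 matrix flattened row-wise.  Residue groups absent from the sequence
  contribute exact zeros.
* ``dpc_pssm`` (dim 400) — dipeptide-style products capturing local order,
  ``y[i, j] = (1/(L-1)) sum_{k=1..L-1} p[k, i] * p[k+1, j]``.
* ``aadp_pssm`` (dim 420) — concatenation [aac_pssm || dpc_pssm].
* ``medp`` (dim 420) — concatenation [EEDP || EDP] where
  ``EEDP[i, j] = (1/(L-2)) sum_{k=2..L-1} ((p[k-1, i] - p[k+1, j]) / 2)^2``
  is a squared half-difference over a +/-1 window (the adopted reading of the
  evolutionary-difference transform; isolated in :func:`eedp_matrix` so an
  alternative can be swapped in) and ``EDP[j]`` is the mean over ``i`` of
  ``EEDP[i, j]``.

Four sequence-only encoders are provided for comparison: amino-acid
composition (``aac``), dipeptide composition (``dpc``), the quasi-sequence-
order descriptor (``qsorder``, computed once per distance matrix) and
pseudo-amino-acid composition (``paac``).

Noncanonical residues (X, B, Z, U, ...) contribute zero to composition counts
(denominators keep the full length) and are removed before the lag-based
qsorder/paac correlations.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from . import _scales
from .pssm import AA_INDEX, CANONICAL_AA, PssmProfile, ProteinRecord

EVOLUTIONARY_ENCODERS = (
    "aac_pssm",
    "pssm_composition",
    "dpc_pssm",
    "aadp_pssm",
    "medp",
)
COMPARISON_ENCODERS = ("aac", "dpc", "qsorder", "paac")
ALL_ENCODERS = EVOLUTIONARY_ENCODERS + COMPARISON_ENCODERS

DEFAULT_NLAG = 30
DEFAULT_QSO_WEIGHT = 0.1
DEFAULT_PAAC_LAMBDA = 30
DEFAULT_PAAC_WEIGHT = 0.05


def _norm(profile: PssmProfile) -> np.ndarray:
    if profile.norm is None:
        raise ValueError(
            f"profile {profile.protein_id!r} is not normalised; call "
            "normalize_pssm first"
        )
    return profile.norm


def encode_aac_pssm(profile: PssmProfile) -> np.ndarray:
    p = _norm(profile)
    return p.mean(axis=0)


def encode_pssm_composition(profile: PssmProfile, record: ProteinRecord) -> np.ndarray:
    p = _norm(profile)
    if len(record) != profile.length:
        raise ValueError(
            f"sequence length {len(record)} != profile length {profile.length} "
            f"for {record.id!r}"
        )
    L = profile.length
    M = np.zeros((20, 20))
    for k, aa in enumerate(record.sequence):
        g = AA_INDEX.get(aa)
        if g is not None:
            M[g] += p[k]
    return (M / L).ravel()


def encode_dpc_pssm(profile: PssmProfile) -> np.ndarray:
    p = _norm(profile)
    L = profile.length
    if L < 2:
        raise ValueError(
            f"profile {profile.protein_id!r}: dpc_pssm undefined for L < 2"
        )
    return (p[:-1].T @ p[1:]).ravel() / (L - 1)


def encode_aadp_pssm(profile: PssmProfile) -> np.ndarray:
    return np.concatenate([encode_aac_pssm(profile), encode_dpc_pssm(profile)])


def eedp_matrix(profile: PssmProfile) -> np.ndarray:
    """The 20 x 20 evolutionary-difference matrix behind the medp encoder."""
    p = _norm(profile)
    L = profile.length
    if L < 3:
        raise ValueError(
            f"profile {profile.protein_id!r}: medp window undefined for L < 3"
        )
    a = p[:-2]  # p[k-1, :] for interior positions k = 2..L-1
    b = p[2:]   # p[k+1, :]
    # sum_k ((a[k,i]-b[k,j])/2)^2 expanded to avoid an L x 20 x 20 temporary
    sa2 = (a * a).sum(axis=0)
    sb2 = (b * b).sum(axis=0)
    cross = a.T @ b
    return (sa2[:, None] + sb2[None, :] - 2.0 * cross) / (4.0 * (L - 2))


def encode_medp(profile: PssmProfile) -> np.ndarray:
    eedp = eedp_matrix(profile)
    edp = eedp.mean(axis=0)
    return np.concatenate([eedp.ravel(), edp])


def encode_aac(record: ProteinRecord) -> np.ndarray:
    v = np.zeros(20)
    for aa in record.sequence:
        g = AA_INDEX.get(aa)
        if g is not None:
            v[g] += 1.0
    return v / len(record)


def encode_dpc(record: ProteinRecord) -> np.ndarray:
    L = len(record)
    if L < 2:
        raise ValueError(f"record {record.id!r}: dpc undefined for L < 2")
    v = np.zeros((20, 20))
    seq = record.sequence
    for k in range(L - 1):
        i = AA_INDEX.get(seq[k])
        j = AA_INDEX.get(seq[k + 1])
        if i is not None and j is not None:
            v[i, j] += 1.0
    return v.ravel() / (L - 1)


def _canonical_indices(record: ProteinRecord) -> np.ndarray:
    return np.array(
        [AA_INDEX[aa] for aa in record.sequence if aa in AA_INDEX], dtype=int
    )


def encode_qsorder(
    record: ProteinRecord,
    nlag: int = DEFAULT_NLAG,
    weight: float = DEFAULT_QSO_WEIGHT,
) -> np.ndarray:
    """Quasi-sequence-order descriptor, once per distance matrix.

    For each distance matrix D the coupling terms are
    ``tau_d = sum_{k} D[s_k, s_{k+d}]^2`` for lags d = 1..nlag, and the
    feature block is ``[f_r / (1 + w T), w tau_d / (1 + w T)]`` with ``f`` the
    residue frequencies and ``T = sum_d tau_d``.  Blocks for the standardized
    physicochemical distance and the Grantham distance are concatenated,
    giving dimension 2 * (20 + nlag).
    """
    idx = _canonical_indices(record)
    L = len(idx)
    if L <= nlag:
        raise ValueError(
            f"record {record.id!r}: canonical length {L} must exceed nlag={nlag}; "
            "use a smaller nlag"
        )
    f = np.bincount(idx, minlength=20) / L
    blocks = []
    for D in (
        _scales.physicochemical_distance_matrix(),
        _scales.grantham_matrix(),
    ):
        tau = np.array(
            [np.sum(D[idx[:-d], idx[d:]] ** 2) for d in range(1, nlag + 1)]
        )
        denom = 1.0 + weight * tau.sum()
        blocks.append(np.concatenate([f / denom, weight * tau / denom]))
    return np.concatenate(blocks)


def encode_paac(
    record: ProteinRecord,
    lam: int = DEFAULT_PAAC_LAMBDA,
    weight: float = DEFAULT_PAAC_WEIGHT,
) -> np.ndarray:
    """Pseudo-amino-acid composition over three standardized property scales.

    The tier-d correlation is the mean over properties of squared differences,
    averaged along the chain:
    ``theta_d = (1/(L-d)) sum_k Theta(s_k, s_{k+d})``.  Features are
    ``[f_r / (1 + w T), w theta_d / (1 + w T)]`` with ``T = sum_d theta_d``,
    dimension 20 + lambda.  With w = 0 the first 20 entries reduce to the
    plain amino-acid composition of the canonical residues.
    """
    idx = _canonical_indices(record)
    L = len(idx)
    if L <= lam:
        raise ValueError(
            f"record {record.id!r}: canonical length {L} must exceed lambda={lam}"
        )
    props = _scales.standardized_paac_properties()  # 3 x 20
    f = np.bincount(idx, minlength=20) / L
    theta = np.empty(lam)
    for d in range(1, lam + 1):
        diffs = props[:, idx[:-d]] - props[:, idx[d:]]
        theta[d - 1] = np.mean((diffs**2).mean(axis=0))
    denom = 1.0 + weight * theta.sum()
    return np.concatenate([f / denom, weight * theta / denom])


def encoder_dim(
    encoder: str,
    nlag: int = DEFAULT_NLAG,
    lam: int = DEFAULT_PAAC_LAMBDA,
) -> int:
    dims = {
        "aac_pssm": 20,
        "pssm_composition": 400,
        "dpc_pssm": 400,
        "aadp_pssm": 420,
        "medp": 420,
        "aac": 20,
        "dpc": 400,
        "qsorder": 2 * (20 + nlag),
        "paac": 20 + lam,
    }
    if encoder not in dims:
        raise ValueError(f"unknown encoder {encoder!r}; choose from {ALL_ENCODERS}")
    return dims[encoder]


def encode(
    encoder: str,
    record: ProteinRecord | None,
    profile: PssmProfile | None,
    *,
    nlag: int = DEFAULT_NLAG,
    qso_weight: float = DEFAULT_QSO_WEIGHT,
    lam: int = DEFAULT_PAAC_LAMBDA,
    paac_weight: float = DEFAULT_PAAC_WEIGHT,
) -> np.ndarray:
    """Dispatch one protein through the named encoder."""
    if encoder in EVOLUTIONARY_ENCODERS and profile is None:
        rid = record.id if record is not None else "<unknown>"
        raise ValueError(f"encoder {encoder!r} needs a PSSM profile for {rid!r}")
    if encoder == "aac_pssm":
        return encode_aac_pssm(profile)
    if encoder == "pssm_composition":
        if record is None:
            raise ValueError("pssm_composition needs the protein sequence")
        return encode_pssm_composition(profile, record)
    if encoder == "dpc_pssm":
        return encode_dpc_pssm(profile)
    if encoder == "aadp_pssm":
        return encode_aadp_pssm(profile)
    if encoder == "medp":
        return encode_medp(profile)
    if record is None:
        raise ValueError(f"encoder {encoder!r} needs the protein sequence")
    if encoder == "aac":
        return encode_aac(record)
    if encoder == "dpc":
        return encode_dpc(record)
    if encoder == "qsorder":
        return encode_qsorder(record, nlag=nlag, weight=qso_weight)
    if encoder == "paac":
        return encode_paac(record, lam=lam, weight=paac_weight)
    raise ValueError(f"unknown encoder {encoder!r}; choose from {ALL_ENCODERS}")


class ProteinFeatureEncoder(TransformerMixin, BaseEstimator):
    """Stateless sklearn transformer wrapping one named encoder.

    ``X`` is an iterable of ``(ProteinRecord, PssmProfile | None)`` pairs; the
    output is an ``(n_samples, dim)`` float array.  Being stateless, ``fit``
    only validates the encoder name.
    """

    def __init__(
        self,
        encoder: str = "aac_pssm",
        nlag: int = DEFAULT_NLAG,
        qso_weight: float = DEFAULT_QSO_WEIGHT,
        lam: int = DEFAULT_PAAC_LAMBDA,
        paac_weight: float = DEFAULT_PAAC_WEIGHT,
    ):
        self.encoder = encoder
        self.nlag = nlag
        self.qso_weight = qso_weight
        self.lam = lam
        self.paac_weight = paac_weight

    def fit(self, X=None, y=None):
        self.dim_ = encoder_dim(self.encoder, nlag=self.nlag, lam=self.lam)
        return self

    def transform(self, X) -> np.ndarray:
        if not hasattr(self, "dim_"):
            self.fit()
        rows = [
            encode(
                self.encoder,
                record,
                profile,
                nlag=self.nlag,
                qso_weight=self.qso_weight,
                lam=self.lam,
                paac_weight=self.paac_weight,
            )
            for record, profile in X
        ]
        out = np.asarray(rows, dtype=float)
        if out.ndim != 2 or out.shape[1] != self.dim_:
            raise AssertionError(
                f"encoder {self.encoder!r} produced shape {out.shape}, "
                f"expected (*, {self.dim_})"
            )
        return out

    def feature_names(self) -> list[str]:
        """Column names for the batch feature table (fixed, documented order)."""
        enc = self.encoder
        aas = list(CANONICAL_AA)
        if enc in ("aac_pssm", "aac"):
            return [f"{enc}.{a}" for a in aas]
        if enc in ("pssm_composition", "dpc_pssm", "dpc"):
            return [f"{enc}.{a}{b}" for a in aas for b in aas]
        if enc == "aadp_pssm":
            return [f"{enc}.aac.{a}" for a in aas] + [
                f"{enc}.dpc.{a}{b}" for a in aas for b in aas
            ]
        if enc == "medp":
            return [f"{enc}.eedp.{a}{b}" for a in aas for b in aas] + [
                f"{enc}.edp.{a}" for a in aas
            ]
        if enc == "qsorder":
            names = []
            for mat in ("phys", "grantham"):
                names += [f"{enc}.{mat}.f.{a}" for a in aas]
                names += [f"{enc}.{mat}.tau{d}" for d in range(1, self.nlag + 1)]
            return names
        if enc == "paac":
            return [f"{enc}.f.{a}" for a in aas] + [
                f"{enc}.theta{d}" for d in range(1, self.lam + 1)
            ]
        raise ValueError(f"unknown encoder {enc!r}")
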