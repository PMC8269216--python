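"""Amino-acid property scales and pairwise distance matrices.

All tables are indexed in the canonical residue order ACDEFGHIKLMNPQRSTVWY.

Provenance:

* ``HYDROPHOBICITY`` — the normalised hydrophobicity scale used by the
  classic pseudo-amino-acid-composition descriptor (Tanford-derived values as
  tabulated on Chou's PAAC reference implementation).
* ``HYDROPHILICITY`` — Hopp & Woods hydrophilicity values.
* ``SIDE_CHAIN_MASS`` — side-chain masses in Daltons (glycine = 1).
* ``GRANTHAM_*`` — Grantham's composition (c), polarity (p) and molecular
  volume (v) properties; :func:`grantham_matrix` evaluates his distance
  D(i, j) = rho * sqrt(alpha*(c_i-c_j)^2 + beta*(p_i-p_j)^2 + gamma*(v_i-v_j)^2)
  with alpha=1.833, beta=0.1018, gamma=0.000399 and rho chosen so that the
  mean over the 190 unordered heterogeneous pairs is 100, reproducing the
  published table (e.g. Leu-Ile = 5, Cys-Trp = 215) to rounding.
* :func:`physicochemical_distance_matrix` — a standardized Euclidean distance
  over (hydrophobicity, hydrophilicity, side-chain mass), rescaled to a
  maximum of 1.  This fills the quasi-sequence-order descriptor's
  short-range-distance slot; it is a reconstruction built from the packaged
  scales, not a transcription of the Schneider-Wrede table.
"""

from __future__ import annotations

import numpy as np

from .pssm import CANONICAL_AA

# fmt: off
HYDROPHOBICITY = np.array([
    0.62,   # A
    0.29,   # C
    -0.90,  # D
    -0.74,  # E
    1.19,   # F
    0.48,   # G
    -0.40,  # H
    1.38,   # I
    -1.50,  # K
    1.06,   # L
    0.64,   # M
    -0.78,  # N
    0.12,   # P
    -0.85,  # Q
    -2.53,  # R
    -0.18,  # S
    -0.05,  # T
    1.08,   # V
    0.81,   # W
    0.26,   # Y
])

HYDROPHILICITY = np.array([
    -0.5,   # A
    -1.0,   # C
    3.0,    # D
    3.0,    # E
    -2.5,   # F
    0.0,    # G
    -0.5,   # H
    -1.8,   # I
    3.0,    # K
    -1.8,   # L
    -1.3,   # M
    0.2,    # N
    0.0,    # P
    0.2,    # Q
    3.0,    # R
    0.3,    # S
    -0.4,   # T
    -1.5,   # V
    -3.4,   # W
    -2.3,   # Y
])

SIDE_CHAIN_MASS = np.array([
    15.0,   # A
    47.0,   # C
    59.0,   # D
    73.0,   # E
    91.0,   # F
    1.0,    # G
    82.0,   # H
    57.0,   # I
    73.0,   # K
    57.0,   # L
    75.0,   # M
    58.0,   # N
    42.0,   # P
    72.0,   # Q
    101.0,  # R
    31.0,   # S
    45.0,   # T
    43.0,   # V
    130.0,  # W
    107.0,  # Y
])

GRANTHAM_COMPOSITION = np.array([
    0.0,    # A
    2.75,   # C
    1.38,   # D
    0.92,   # E
    0.0,    # F
    0.74,   # G
    0.58,   # H
    0.0,    # I
    0.33,   # K
    0.0,    # L
    0.0,    # M
    1.33,   # N
    0.39,   # P
    0.89,   # Q
    0.65,   # R
    1.42,   # S
    0.71,   # T
    0.0,    # V
    0.13,   # W
    0.20,   # Y
])

GRANTHAM_POLARITY = np.array([
    8.1,    # A
    5.5,    # C
    13.0,   # D
    12.3,   # E
    5.2,    # F
    9.0,    # G
    10.4,   # H
    5.2,    # I
    11.3,   # K
    4.9,    # L
    5.7,    # M
    11.6,   # N
    8.0,    # P
    10.5,   # Q
    10.5,   # R
    9.2,    # S
    8.6,    # T
    5.9,    # V
    5.4,    # W
    6.2,    # Y
])

GRANTHAM_VOLUME = np.array([
    31.0,   # A
    55.0,   # C
    54.0,   # D
    83.0,   # E
    132.0,  # F
    3.0,    # G
    96.0,   # H
    111.0,  # I
    119.0,  # K
    111.0,  # L
    105.0,  # M
    56.0,   # N
    32.5,   # P
    85.0,   # Q
    124.0,  # R
    32.0,   # S
    61.0,   # T
    84.0,   # V
    170.0,  # W
    136.0,  # Y
])
# fmt: on

_GRANTHAM_ALPHA = 1.833
_GRANTHAM_BETA = 0.1018
_GRANTHAM_GAMMA = 0.000399


def _pairwise_sq(v: np.ndarray) -> np.ndarray:
    d = v[:, None] - v[None, :]
    return d * d


def grantham_matrix() -> np.ndarray:
    """Grantham's chemical-distance matrix (20 x 20, canonical order)."""
    s = (
        _GRANTHAM_ALPHA * _pairwise_sq(GRANTHAM_COMPOSITION)
        + _GRANTHAM_BETA * _pairwise_sq(GRANTHAM_POLARITY)
        + _GRANTHAM_GAMMA * _pairwise_sq(GRANTHAM_VOLUME)
    )
    d = np.sqrt(s)
    off = d[np.triu_indices(20, k=1)]
    rho = 100.0 / off.mean()
    return rho * d


def _standardize(v: np.ndarray) -> np.ndarray:
    return (v - v.mean()) / v.std()


def physicochemical_distance_matrix() -> np.ndarray:
    """Standardized-property distance matrix in [0, 1] (20 x 20).

    Euclidean distance over the three standardized property scales
    (hydrophobicity, hydrophilicity, side-chain mass), divided by its maximum
    so the largest residue pair has distance 1.
    """
    s = (
        _pairwise_sq(_standardize(HYDROPHOBICITY))
        + _pairwise_sq(_standardize(HYDROPHILICITY))
        + _pairwise_sq(_standardize(SIDE_CHAIN_MASS))
    )
    d = np.sqrt(s)
    return d / d.max()


def standardized_paac_properties() -> np.ndarray:
    """The 3 x 20 standardized property table used by the PAAC correlation."""
    return np.vstack(
        [
            _standardize(HYDROPHOBICITY),
            _standardize(HYDROPHILICITY),
            _standardize(SIDE_CHAIN_MASS),
        ]
    )


def aa_order() -> str:
    return CANONICAL_AA
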