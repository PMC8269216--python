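# Methods

## Problem and model

Phage genomes are annotated poorly; the proteins that build the virion
(capsid, tail tube, baseplate, tail fibres) diverge so fast that pairwise
sequence search misses most of them. This package classifies a phage protein
as *virion* or *nonvirion* from its evolutionary profile — the L×20
position-specific scoring matrix (PSSM) produced by iterative profile search
— rather than from the raw sequence.

The classifier is a two-level score-averaging ensemble:

1. **Balanced subsets.** Training sets are imbalanced (typically 1.5–3
   nonvirion proteins per virion protein; the canonical training split is
   243 positives vs 694 negatives, a 1:2.86 ratio). Each balanced subset
   combines all positives with an equal number of negatives drawn without
   replacement; the draw is repeated five times.
2. **Per-feature baselines.** For each of five evolutionary encoders
   (AAC-PSSM, PSSM composition, DPC-PSSM, AADP-PSSM, MEDP; dimensions
   20/400/400/420/420), one RBF-kernel SVM is trained per subset — 25
   member SVMs in total, all sharing the same five subsets. Cost and gamma
   of every member are tuned by exhaustive grid search over
   {2^e : e = −10..10} (441 pairs) with stratified 5-fold internal CV and
   mean accuracy as the objective (ties broken deterministically by
   enumeration order). Member scores are Platt-calibrated posterior
   probabilities; the baseline score is their mean.
3. **Integration.** The final score is the unweighted mean of the five
   baseline scores; a protein is called virion when the score is ≥ 0.5
   (the boundary is inclusive).

Four sequence-only encoders (AAC, DPC, QSOrder, PAAC) are provided for
comparison, plus a sequence-similarity baseline that calls a query virion
iff it hits the positive training sequences at E ≤ 0.01.

## Profile normalisation

PSI-BLAST ASCII profiles carry an integer log-odds block and a
weighted-observed-percentage block. The default normalisation is the
elementwise logistic `1/(1+exp(−s))` of the log-odds block, which maps 0 to
0.5, is strictly monotone, and preserves per-cell resolution; dividing the
percentage block by 100 is available as an alternative
(`normalize_pssm(..., method="percentage")`). Columns are re-mapped at parse
time from the file header order (`ARNDCQEGHILKMFPSTWYV`) to the fixed
alphabetical order `ACDEFGHIKLMNPQRSTVWY`, so all encoders index residues
identically. Generating profiles (the external search: E = 0.001, 3
iterations, UniRef50) is out of scope; the package only consumes the ASCII
files.

## Encoder formulas and open choices

With `p[k, j]` the normalised profile:

- AAC-PSSM: column means, `v_j = (1/L) Σ_k p[k, j]`.
- PSSM composition: rows grouped by the residue observed at the position;
  group sums divided by **L** (not by group size), so residues absent from
  the sequence contribute exact zeros and the vector total is independent
  of composition.
- DPC-PSSM: `y_{i,j} = (1/(L−1)) Σ_{k≤L−1} p[k,i]·p[k+1,j]`, flattened
  row-wise. Requires L ≥ 2; length-1 inputs are rejected rather than
  zero-filled (silent zeros would poison training).
- AADP-PSSM: concatenation of the two above.
- MEDP = [EEDP ‖ EDP]: the EEDP transform is not pinned down by its original
  description; this package adopts
  `EEDP[i,j] = (1/(L−2)) Σ_{k=2..L−1} ((p[k−1,i] − p[k+1,j])/2)²`,
  a squared half-difference over a ±1 window, isolated in `eedp_matrix` so
  an alternative reading can be swapped in without touching callers.
  `EDP[j]` is the mean over `i` of `EEDP[i,j]`.

QSOrder uses two 20×20 residue-distance matrices. Grantham's chemical
distance is **computed** from his published formula and composition/
polarity/volume properties, with the scale factor fixed by the mean-distance
= 100 convention; the tests verify known entries (Leu-Ile = 5,
Cys-Trp = 215). The second matrix is a **reconstructed** standardized
physicochemical distance (Euclidean over standardized hydrophobicity,
hydrophilicity and side-chain mass, scaled to max 1) filling the
short-range-distance slot; it is not a transcription of the
Schneider–Wrede table, which is not available as a verifiable source here.
PAAC uses the classic three property scales (hydrophobicity, Hopp–Woods
hydrophilicity, side-chain mass), standardized over the 20 residues.
Defaults: QSOrder nlag = 30, weight = 0.1; PAAC λ = 30, w = 0.05 — the
descriptors' canonical defaults. Noncanonical residues (X, B, Z, U)
contribute zero to composition counts (denominators keep full length) and
are removed before the lag correlations.

## Score calibration

"Prediction score" is undefined for a margin classifier; averaging raw SVM
margins across heterogeneous feature spaces is scale-inconsistent. Members
are therefore wrapped in sigmoid (Platt) calibration
(`CalibratedClassifierCV(SVC, method="sigmoid", ensemble=False)`):
decision values are cross-fitted, one sigmoid is fitted, and the SVM is
refitted on the whole subset. Scores are posterior probabilities in [0, 1]
and directly comparable across members and features. Everything is
deterministic from one integer seed: subset *i* draws with seed
`seed + i`, grid-search fold shuffling uses the same derived seeds, and the
calibration splitter does not shuffle.

## Evaluation protocol

Metrics: SN, SP, ACC, F (harmonic mean of precision and SN), MCC, and the
false-positive rate FP/(FP+TN) = 1 − SP. Zero-denominator terms are
reported as 0 with an explicit degeneracy flag. Display rounds to 3
decimals; full precision is kept internally.

Cross-validation mirrors training: stratified 5-fold CV is run on each of
the five balanced subsets (per fold: one tuned, calibrated SVM per encoder;
scores averaged; calls at 0.5), and the per-subset reports are averaged with
standard deviations. Stratification guarantees both classes in every fold
on small fixtures. The independent test verifies id-disjointness from the
training set and fails loudly on overlap.

The similarity baseline prefers an external `blastp`; the internal fallback
scores a Smith–Waterman alignment (BLOSUM62, gap open 11 / extend 1) and
converts it to an E-value with gapped Karlin–Altschul constants
(λ = 0.267, K = 0.041). It is an approximation of BLAST statistics, adequate
for the clear-cut decisions the baseline makes, and is labelled as such.

## Synthetic data

The generator emulates the *shape* of profile-based training data:
uniform-random sequences (lengths 50–150 by default), integer-rounded
Gaussian log-odds noise (sd 2), and a class signal of +δ added to five fixed
profile columns of the positives before rounding. The signal lives at the
profile level because all five production encoders are profile-derived.
Defaults define the package's reference study condition: 60 positives vs
170 negatives (≈1:2.8, inside the typical band) with δ = 6 = 3 noise sds as
the separable regime. It deliberately does **not** model residue
composition bias, homology between samples, or positional correlation —
synthetic results validate the machinery, not real-proteome performance.
Generated ASCII files round-trip bit-exactly through the parser; the
percentage block of synthetic files is a plausible integer rendering
(rounded logistic), present so the two-block layout and the percentage
normalisation path are exercisable.

## Problem sizes and numerical choices

The acceptance script trains the full pipeline at the reference condition
with the complete 441-pair grid for the high-signal run; the 20-seed null
sweep and the CV summary use reduced exponent grids (step 2 over −2..2) —
a problem-size choice that leaves the protocol structure (5 subsets, 5
features, shared subsets, 0.5 cutoff) untouched and is asserted separately
(441 pairs enumerated, subset arithmetic at 243/694 → subsets of 486).
Grid-search ties break toward smaller C then smaller gamma. Model bundles
are versioned; loading refuses on a format-version mismatch rather than
risking silent cross-version drift.

## Known limitations

- The published benchmark figures for the original tool (independent-test
  SN 0.896, ACC 0.891, MCC 0.781) depend on its exact curated datasets and
  UniRef50-based profiles and are not reproducible from this repository;
  the package reproduces the method and its in-protocol arithmetic.
- The internal redundancy reducer is a greedy longest-first identity
  clustering, deterministic but not identical to CD-HIT's word-filtered
  heuristic; `backend="cdhit"` delegates when the binary exists.
- The internal E-value is approximate (no composition-based statistics, no
  edge-effect correction).
- EEDP follows the documented interpretation above; alternative readings of
  the original transform would change MEDP values (not its dimension).
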