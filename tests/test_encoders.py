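"""Feature encoders: dimensions, trivial identities, naive-loop oracle equivalence."""

import math

import numpy as np
import pytest

from step3._scales import (
    grantham_matrix,
    physicochemical_distance_matrix,
    standardized_paac_properties,
)
from step3.encoders import (
    ALL_ENCODERS,
    ProteinFeatureEncoder,
    encode,
    encode_aac,
    encode_aac_pssm,
    encode_aadp_pssm,
    encode_dpc,
    encode_dpc_pssm,
    encode_medp,
    encode_paac,
    encode_pssm_composition,
    encode_qsorder,
    encoder_dim,
    eedp_matrix,
)
from step3.pssm import AA_INDEX, CANONICAL_AA, PssmProfile, ProteinRecord
from step3.synthetic import generate_pssm_fixture

# ---------------------------------------------------------------------------
# independent naive-loop reference implementations (oracles)
# ---------------------------------------------------------------------------


def oracle_aac_pssm(p):
    L = p.shape[0]
    return np.array([sum(p[k, j] for k in range(L)) / L for j in range(20)])


def oracle_pssm_composition(p, seq):
    L = p.shape[0]
    M = [[0.0] * 20 for _ in range(20)]
    for k, aa in enumerate(seq):
        if aa in AA_INDEX:
            g = AA_INDEX[aa]
            for j in range(20):
                M[g][j] += p[k, j]
    return np.array([M[g][j] / L for g in range(20) for j in range(20)])


def oracle_dpc_pssm(p):
    L = p.shape[0]
    out = []
    for i in range(20):
        for j in range(20):
            out.append(sum(p[k, i] * p[k + 1, j] for k in range(L - 1)) / (L - 1))
    return np.array(out)


def oracle_eedp(p):
    L = p.shape[0]
    M = np.zeros((20, 20))
    for i in range(20):
        for j in range(20):
            s = 0.0
            for k in range(1, L - 1):  # interior positions (0-based)
                s += ((p[k - 1, i] - p[k + 1, j]) / 2.0) ** 2
            M[i, j] = s / (L - 2)
    return M


def oracle_aac(seq):
    return np.array(
        [sum(1 for c in seq if c == aa) for aa in CANONICAL_AA]
    ) / len(seq)


def oracle_dpc(seq):
    out = []
    for a in CANONICAL_AA:
        for b in CANONICAL_AA:
            out.append(
                sum(1 for k in range(len(seq) - 1) if seq[k] == a and seq[k + 1] == b)
            )
    return np.array(out, dtype=float) / (len(seq) - 1)


def oracle_qsorder(seq, nlag, w):
    idx = [AA_INDEX[c] for c in seq if c in AA_INDEX]
    L = len(idx)
    f = [sum(1 for i in idx if i == r) / L for r in range(20)]
    blocks = []
    for D in (physicochemical_distance_matrix(), grantham_matrix()):
        tau = []
        for d in range(1, nlag + 1):
            tau.append(sum(D[idx[k], idx[k + d]] ** 2 for k in range(L - d)))
        denom = 1.0 + w * sum(tau)
        blocks += [v / denom for v in f] + [w * t / denom for t in tau]
    return np.array(blocks)


def oracle_paac(seq, lam, w):
    idx = [AA_INDEX[c] for c in seq if c in AA_INDEX]
    L = len(idx)
    props = standardized_paac_properties()
    f = [sum(1 for i in idx if i == r) / L for r in range(20)]

    def theta_fn(a, b):
        return sum((props[t, a] - props[t, b]) ** 2 for t in range(3)) / 3.0

    theta = []
    for d in range(1, lam + 1):
        theta.append(
            sum(theta_fn(idx[k], idx[k + d]) for k in range(L - d)) / (L - d)
        )
    denom = 1.0 + w * sum(theta)
    return np.array([v / denom for v in f] + [w * t / denom for t in theta])


def _random_protein(rng, L):
    seq = "".join(rng.choice(list(CANONICAL_AA), size=L))
    raw = np.rint(rng.normal(0, 2, size=(L, 20))).astype(int)
    prof = PssmProfile(f"r{L}", raw, seq)
    prof.norm = 1.0 / (1.0 + np.exp(-raw.astype(float)))
    return ProteinRecord(f"r{L}", seq), prof


# ---------------------------------------------------------------------------


EXPECTED_DIMS = {
    "aac_pssm": 20,
    "pssm_composition": 400,
    "dpc_pssm": 400,
    "aadp_pssm": 420,
    "medp": 420,
    "aac": 20,
    "dpc": 400,
    "qsorder": 100,
    "paac": 50,
}


@pytest.mark.parametrize("name", ALL_ENCODERS)
def test_declared_dimension_on_valid_input(name, rng):
    rec, prof = _random_protein(rng, 40)
    v = encode(name, rec, prof)
    assert v.shape == (EXPECTED_DIMS[name],)
    assert encoder_dim(name) == EXPECTED_DIMS[name]
    assert np.all(np.isfinite(v))


@pytest.mark.parametrize("name", ALL_ENCODERS)
def test_oracle_equivalence_on_random_fixtures(name, rng):
    """Each encoder matches its naive multi-loop reference on 100 random
    proteins to 1e-12 relative tolerance."""
    oracles = {
        "aac_pssm": lambda r, p: oracle_aac_pssm(p.norm),
        "pssm_composition": lambda r, p: oracle_pssm_composition(p.norm, r.sequence),
        "dpc_pssm": lambda r, p: oracle_dpc_pssm(p.norm),
        "aadp_pssm": lambda r, p: np.concatenate(
            [oracle_aac_pssm(p.norm), oracle_dpc_pssm(p.norm)]
        ),
        "medp": lambda r, p: np.concatenate(
            [oracle_eedp(p.norm).ravel(), oracle_eedp(p.norm).mean(axis=0)]
        ),
        "aac": lambda r, p: oracle_aac(r.sequence),
        "dpc": lambda r, p: oracle_dpc(r.sequence),
        "qsorder": lambda r, p: oracle_qsorder(r.sequence, 30, 0.1),
        "paac": lambda r, p: oracle_paac(r.sequence, 30, 0.05),
    }
    min_len = 32  # > nlag / lambda
    for _ in range(100):
        L = int(rng.integers(min_len, 60))
        rec, prof = _random_protein(rng, L)
        got = encode(name, rec, prof)
        want = oracles[name](rec, prof)
        np.testing.assert_allclose(got, want, rtol=1e-12, atol=1e-15)


class TestAacPssm:
    def test_constant_half_profile(self):
        prof = generate_pssm_fixture(5, "zero")  # sigmoid(0) = 0.5 everywhere
        assert np.allclose(encode_aac_pssm(prof), 0.5)

    def test_row_permutation_invariance(self, rng):
        _, prof = _random_protein(rng, 15)
        perm = rng.permutation(15)
        shuffled = PssmProfile("s", prof.raw[perm], "".join(
            prof.sequence[i] for i in perm
        ))
        shuffled.norm = prof.norm[perm]
        np.testing.assert_allclose(
            encode_aac_pssm(prof), encode_aac_pssm(shuffled), rtol=1e-12
        )


class TestPssmComposition:
    def test_homopolymer_single_group(self, rng):
        seq = "AAAAA"
        raw = np.rint(rng.normal(0, 2, (5, 20))).astype(int)
        prof = PssmProfile("h", raw, seq)
        prof.norm = 1.0 / (1.0 + np.exp(-raw.astype(float)))
        v = encode_pssm_composition(prof, ProteinRecord("h", seq)).reshape(20, 20)
        np.testing.assert_allclose(v[0], prof.norm.sum(axis=0) / 5, rtol=1e-12)
        assert np.all(v[1:] == 0)

    def test_length_mismatch_is_error(self, rng):
        _, prof = _random_protein(rng, 6)
        with pytest.raises(ValueError, match="length"):
            encode_pssm_composition(prof, ProteinRecord("x", "ACD"))


class TestDpcPssm:
    def test_one_hot_product(self):
        # norm rows are exact one-hots at residues a=3, b=7
        prof = PssmProfile("oh", np.zeros((2, 20), dtype=int), "AC")
        norm = np.zeros((2, 20))
        norm[0, 3] = 1.0
        norm[1, 7] = 1.0
        prof.norm = norm
        v = encode_dpc_pssm(prof).reshape(20, 20)
        assert v[3, 7] == 1.0
        assert v.sum() == 1.0

    def test_constant_profile_gives_c_squared(self):
        prof = PssmProfile("c", np.zeros((4, 20), dtype=int), "ACDE")
        prof.norm = np.full((4, 20), 0.3)
        assert np.allclose(encode_dpc_pssm(prof), 0.09)

    def test_length_one_rejected(self):
        prof = PssmProfile("one", np.zeros((1, 20), dtype=int), "A")
        prof.norm = np.full((1, 20), 0.5)
        with pytest.raises(ValueError, match="L < 2"):
            encode_dpc_pssm(prof)

    def test_order_sensitivity(self, rng):
        """Unlike aac_pssm, dpc_pssm changes under row permutation."""
        _, prof = _random_protein(rng, 12)
        rev = PssmProfile("rev", prof.raw[::-1].copy(), prof.sequence[::-1])
        rev.norm = prof.norm[::-1].copy()
        assert not np.allclose(encode_dpc_pssm(prof), encode_dpc_pssm(rev))


class TestAadpAndMedp:
    def test_aadp_is_exact_concatenation(self, rng):
        _, prof = _random_protein(rng, 10)
        v = encode_aadp_pssm(prof)
        np.testing.assert_array_equal(v[:20], encode_aac_pssm(prof))
        np.testing.assert_array_equal(v[20:], encode_dpc_pssm(prof))

    def test_medp_edp_block_is_row_average_of_eedp(self, rng):
        _, prof = _random_protein(rng, 14)
        v = encode_medp(prof)
        eedp = v[:400].reshape(20, 20)
        np.testing.assert_allclose(v[400:], eedp.mean(axis=0), rtol=1e-12)

    def test_medp_constant_profile_matches_loop(self):
        c = 0.4
        prof = PssmProfile("c", np.zeros((6, 20), dtype=int), "ACDEFG")
        prof.norm = np.full((6, 20), c)
        v = encode_medp(prof)
        # constant profile: every half-difference is 0
        assert np.allclose(v, 0.0)
        np.testing.assert_allclose(
            eedp_matrix(prof), oracle_eedp(prof.norm), atol=1e-15
        )

    def test_medp_needs_length_three(self):
        prof = PssmProfile("s", np.zeros((2, 20), dtype=int), "AC")
        prof.norm = np.full((2, 20), 0.5)
        with pytest.raises(ValueError, match="L < 3"):
            encode_medp(prof)


class TestSequenceEncoders:
    def test_aac_homopolymer(self):
        v = encode_aac(ProteinRecord("p", "AAA"))
        assert v[0] == 1.0 and v[1:].sum() == 0.0

    def test_aac_direct_count(self):
        v = encode_aac(ProteinRecord("p", "ACDA"))
        assert v[AA_INDEX["A"]] == 0.5
        assert v[AA_INDEX["C"]] == 0.25
        assert v[AA_INDEX["D"]] == 0.25

    def test_aac_sums_to_one_for_canonical(self, rng):
        seq = "".join(rng.choice(list(CANONICAL_AA), size=30))
        assert encode_aac(ProteinRecord("p", seq)).sum() == pytest.approx(1.0)

    def test_aac_noncanonical_contributes_zero(self):
        v = encode_aac(ProteinRecord("p", "AXXA"))
        assert v[AA_INDEX["A"]] == 0.5
        assert v.sum() == pytest.approx(0.5)

    def test_dpc_single_dipeptide(self):
        v = encode_dpc(ProteinRecord("p", "AC")).reshape(20, 20)
        assert v[AA_INDEX["A"], AA_INDEX["C"]] == 1.0
        assert v.sum() == 1.0

    def test_dpc_homopolymer(self):
        v = encode_dpc(ProteinRecord("p", "AAAA")).reshape(20, 20)
        assert v[0, 0] == 1.0

    def test_qsorder_dimension_and_nlag_guard(self, rng):
        seq = "".join(rng.choice(list(CANONICAL_AA), size=40))
        assert encode_qsorder(ProteinRecord("p", seq), nlag=30).shape == (100,)
        with pytest.raises(ValueError, match="nlag"):
            encode_qsorder(ProteinRecord("p", seq), nlag=45)

    def test_qsorder_zero_weight_reduces_to_composition(self, rng):
        seq = "".join(rng.choice(list(CANONICAL_AA), size=40))
        rec = ProteinRecord("p", seq)
        v = encode_qsorder(rec, nlag=10, weight=0.0)
        np.testing.assert_allclose(v[:20], encode_aac(rec), rtol=1e-12)
        assert np.allclose(v[20:30], 0.0)

    def test_paac_zero_weight_reduces_to_composition(self, rng):
        seq = "".join(rng.choice(list(CANONICAL_AA), size=40))
        rec = ProteinRecord("p", seq)
        v = encode_paac(rec, lam=10, weight=0.0)
        np.testing.assert_allclose(v[:20], encode_aac(rec), rtol=1e-12)
        assert np.allclose(v[20:], 0.0)

    def test_paac_lambda_guard(self):
        with pytest.raises(ValueError, match="lambda"):
            encode_paac(ProteinRecord("p", "ACDEF"), lam=10)


class TestScales:
    def test_grantham_reproduces_published_values(self):
        """The computed chemical-distance matrix matches Grantham's table on
        well-known entries (mean over pairs is 100 by construction)."""
        G = grantham_matrix()
        ix = {a: i for i, a in enumerate(CANONICAL_AA)}
        known = {("L", "I"): 5, ("C", "W"): 215, ("G", "W"): 184, ("R", "L"): 102}
        for (a, b), want in known.items():
            assert G[ix[a], ix[b]] == pytest.approx(want, abs=0.6)
        assert np.allclose(G, G.T)
        assert np.allclose(np.diag(G), 0.0)

    def test_physicochemical_distance_matrix_properties(self):
        D = physicochemical_distance_matrix()
        assert D.shape == (20, 20)
        assert np.allclose(D, D.T)
        assert D.max() == pytest.approx(1.0)
        assert np.all(np.diag(D) == 0.0)


class TestBounds:
    @pytest.mark.parametrize("name", ["aac_pssm", "dpc_pssm", "pssm_composition"])
    def test_pssm_features_bounded_by_norm_bounds(self, name, rng):
        for _ in range(20):
            rec, prof = _random_protein(rng, int(rng.integers(5, 30)))
            v = encode(name, rec, prof)
            assert np.all(v >= 0.0) and np.all(v <= 1.0)


class TestTransformer:
    def test_transform_matrix_shape_and_names(self, rng):
        pairs = [_random_protein(rng, 35) for _ in range(4)]
        for name in ALL_ENCODERS:
            enc = ProteinFeatureEncoder(encoder=name).fit()
            F = enc.transform(pairs)
            assert F.shape == (4, EXPECTED_DIMS[name])
            assert len(enc.feature_names()) == EXPECTED_DIMS[name]

    def test_unknown_encoder_rejected(self):
        with pytest.raises(ValueError, match="unknown encoder"):
            ProteinFeatureEncoder(encoder="nope").fit()

    def test_sklearn_param_interface(self):
        enc = ProteinFeatureEncoder(encoder="paac", lam=5)
        assert enc.get_params()["lam"] == 5
        enc.set_params(lam=7)
        assert enc.fit().dim_ == 27
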