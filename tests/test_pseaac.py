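import numpy as np
import pytest

from oracles import pseaac_bruteforce

from aspasep import pseaac as ps
from aspasep.scales import (
    AMINO_ACIDS,
    CHOU_HYDROPHILICITY,
    CHOU_HYDROPHOBICITY,
    SIDE_CHAIN_MASS,
    PropertyScale,
)
from aspasep.seq_io import ProteinRecord, build_dataset
from conftest import random_sequence

RAW_SCALES = [CHOU_HYDROPHOBICITY.values, CHOU_HYDROPHILICITY.values, SIDE_CHAIN_MASS.values]


class TestNormalizeScale:
    def test_output_mean_zero_sd_one(self):
        for scale in (CHOU_HYDROPHOBICITY, CHOU_HYDROPHILICITY, SIDE_CHAIN_MASS):
            out = ps.normalize_scale(scale)
            vals = np.array(out.as_vector())
            assert abs(vals.mean()) < 1e-12
            assert abs(vals.std() - 1.0) < 1e-12

    def test_idempotent(self):
        once = ps.normalize_scale(CHOU_HYDROPHOBICITY)
        twice = ps.normalize_scale(once)
        assert np.allclose(once.as_vector(), twice.as_vector(), atol=1e-12)

    def test_constant_scale_rejected(self):
        flat = PropertyScale(name="flat", values={aa: 1.0 for aa in AMINO_ACIDS})
        with pytest.raises(ValueError):
            ps.normalize_scale(flat)


class TestCorrelationFactor:
    def test_homopolymer_is_zero(self):
        for k in (1, 2, 5):
            assert ps.correlation_factor("A" * 10, k) == 0.0

    def test_matches_explicit_double_loop(self):
        theta = ps.correlation_factor("ACDG", 1)
        oracle = pseaac_bruteforce("ACDG", 1, 1.0, RAW_SCALES)
        # reconstruct theta_1 from the oracle vector: x_21 = w*theta/(1+w*theta)
        x21 = oracle[20]
        assert theta == pytest.approx(x21 / (1 - x21), rel=1e-10)

    def test_invariant_under_reversal(self, rng):
        for _ in range(10):
            seq = random_sequence(rng, 30)
            for k in (1, 3):
                assert ps.correlation_factor(seq, k) == pytest.approx(
                    ps.correlation_factor(seq[::-1], k), rel=1e-12
                )

    def test_tier_beyond_length_rejected(self):
        with pytest.raises(ps.SequenceTooShortError):
            ps.correlation_factor("ACD", 3)


class TestPseaacVector:
    def test_lambda_zero_equals_composition(self, rng):
        seq = random_sequence(rng, 40)
        v = ps.pseaac_vector(seq, ps.PseAACConfig(lambda_=0, weight=0.05))
        freqs = np.array([seq.count(aa) / len(seq) for aa in AMINO_ACIDS])
        assert np.allclose(v, freqs, atol=1e-12)

    def test_weight_zero_limit_equals_composition(self, rng):
        seq = random_sequence(rng, 40)
        v = ps.pseaac_vector(seq, ps.PseAACConfig(lambda_=5, weight=0.0))
        freqs = np.array([seq.count(aa) / len(seq) for aa in AMINO_ACIDS])
        assert np.allclose(v[:20], freqs, atol=1e-12)
        assert np.allclose(v[20:], 0.0, atol=1e-12)

    def test_homopolymer_one_hot(self):
        v = ps.pseaac_vector("AAAAAA", ps.PseAACConfig(lambda_=2, weight=0.7))
        expected = np.zeros(22)
        expected[0] = 1.0
        assert np.allclose(v, expected, atol=1e-12)

    def test_matches_bruteforce_oracle(self):
        v = ps.pseaac_vector("ACDG", ps.PseAACConfig(lambda_=1, weight=0.05))
        oracle = pseaac_bruteforce("ACDG", 1, 0.05, RAW_SCALES)
        assert np.allclose(v, oracle, atol=1e-10)

    def test_sums_to_one_nonnegative(self, rng):
        for _ in range(20):
            seq = random_sequence(rng, int(rng.integers(10, 100)))
            v = ps.pseaac_vector(seq, ps.PseAACConfig(lambda_=5, weight=0.5))
            assert v.sum() == pytest.approx(1.0, abs=1e-9)
            assert (v >= 0).all()

    def test_permutation_changes_only_order_components(self, rng):
        seq = random_sequence(rng, 50)
        perm = "".join(rng.permutation(list(seq)))
        cfg = ps.PseAACConfig(lambda_=3, weight=0.2)
        v1, v2 = ps.pseaac_vector(seq, cfg), ps.pseaac_vector(perm, cfg)
        # composition parts stay proportional (equal f_u, different denominators)
        ratio = v1[:20][v1[:20] > 0] / v2[:20][v1[:20] > 0]
        assert np.allclose(ratio, ratio[0], rtol=1e-9)

    def test_increasing_weight_decreases_composition_components(self, rng):
        seq = random_sequence(rng, 40)
        lo = ps.pseaac_vector(seq, ps.PseAACConfig(lambda_=5, weight=0.05))
        hi = ps.pseaac_vector(seq, ps.PseAACConfig(lambda_=5, weight=0.5))
        mask = lo[:20] > 0
        assert (hi[:20][mask] < lo[:20][mask]).all()
        assert hi.sum() == pytest.approx(1.0, abs=1e-9)

    def test_too_short_rejected_with_id_in_dataset(self, rng):
        records = [
            ProteinRecord(id="ok", sequence=random_sequence(rng, 30), label="a"),
            ProteinRecord(id="tiny", sequence="ACDEF", label="a"),
        ]
        cfg = ps.PseAACConfig(lambda_=10)
        with pytest.raises(ps.SequenceTooShortError, match="tiny"):
            ps.featurize_dataset(records, cfg)


class TestFeaturizeDataset:
    def test_matrix_shape_and_row_sums(self, tiny_two_class):
        a, b = tiny_two_class
        ds = build_dataset(a, b)
        cfg = ps.PseAACConfig(lambda_=4, weight=0.1)
        m = ps.featurize_dataset(ds, cfg)
        assert m.shape == (6, 2 + 24)
        assert list(m.columns[:2]) == ["id", "label"]
        sums = m.iloc[:, 2:].sum(axis=1)
        assert np.allclose(sums, 1.0, atol=1e-9)

    def test_dropping_short_sequence_leaves_other_rows_unchanged(self, rng):
        recs = [
            ProteinRecord(id=f"r{i}", sequence=random_sequence(rng, 30), label="a")
            for i in range(3)
        ]
        short = ProteinRecord(id="short", sequence="ACD", label="a")
        cfg = ps.PseAACConfig(lambda_=5, on_short="drop")
        full = ps.featurize_dataset(recs, cfg)
        with_short = ps.featurize_dataset(recs + [short], cfg)
        assert list(with_short["id"]) == [r.id for r in recs]
        assert np.allclose(
            full.iloc[:, 2:].to_numpy(), with_short.iloc[:, 2:].to_numpy()
        )

    def test_all_too_short_rejected(self):
        recs = [ProteinRecord(id="a", sequence="ACD", label="x")]
        with pytest.raises(ps.SequenceTooShortError):
            ps.featurize_dataset(recs, ps.PseAACConfig(lambda_=5, on_short="drop"))


def test_oracle_equivalence_on_random_sequences(rng):
    """Vectors match the brute-force double-loop transcription to 1e-10."""
    for _ in range(15):
        L = int(rng.integers(20, 120))
        seq = random_sequence(rng, L)
        lam = int(rng.choice([1, 5, 10]))
        w = float(rng.choice([0.05, 0.5]))
        v = ps.pseaac_vector(seq, ps.PseAACConfig(lambda_=lam, weight=w))
        oracle = pseaac_bruteforce(seq, lam, w, RAW_SCALES)
        assert np.allclose(v, oracle, atol=1e-10)


def test_feature_matrix_sidecar(tmp_path, tiny_two_class):
    import json

    a, b = tiny_two_class
    cfg = ps.PseAACConfig(lambda_=2, weight=0.05)
    m = ps.featurize_dataset(build_dataset(a, b), cfg)
    out = tmp_path / "pseaac.tsv"
    ps.write_feature_matrix(m, out, cfg)
    meta = json.loads((tmp_path / "pseaac.tsv.meta.json").read_text())
    assert meta["lambda"] == 2 and meta["weight"] == 0.05
    assert meta["scales"] == [
        "chou_hydrophobicity", "chou_hydrophilicity", "side_chain_mass"
    ]
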