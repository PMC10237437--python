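import numpy as np
import pytest

import kleevec as kv
from kleevec.encoding import EncodedSet
from kleevec.exceptions import DegenerateContrastError, FormatError, InputError
from kleevec.indicator import leading_eigenpair
from kleevec.reference import set_gram

from test_reference import random_encoded_set


def random_symmetric(n, rng, shift=0.0):
    W = rng.standard_normal((n, n))
    return W + W.T + shift * np.eye(n)


class TestContrastMatrix:
    def test_two_set_identity(self, rng):
        # with N=2, M_a = 2*S_a/m_a - R = S_a/m_a - S_b/m_b
        a = random_encoded_set("a", 3, 4, rng)
        b = random_encoded_set("b", 2, 4, rng)
        ref = kv.compute_reference([a, b])
        Sa, ma = set_gram(a)
        Sb, mb = set_gram(b)
        M = kv.contrast_matrix(Sa, ma, ref, in_reference=True)
        np.testing.assert_allclose(M, Sa / ma - Sb / mb, atol=1e-12)

    def test_set_at_reference_mean_contrasts_to_zero(self, rng):
        sets = [random_encoded_set(f"s{i}", 2, 3, rng) for i in range(3)]
        ref = kv.compute_reference(sets)
        S_mean = ref.R / ref.N
        M = kv.contrast_matrix(S_mean, 1, ref, in_reference=True)
        np.testing.assert_allclose(M, 0.0, atol=1e-10)

    def test_in_reference_contrasts_sum_to_zero(self, rng):
        sets = [random_encoded_set(f"s{i}", int(rng.integers(1, 4)), 4, rng)
                for i in range(5)]
        ref = kv.compute_reference(sets)
        total = sum(
            kv.contrast_matrix(*set_gram(es), ref, in_reference=True) for es in sets
        )
        assert np.abs(total).max() <= 1e-9 * np.abs(ref.R).max()

    def test_single_set_reference_rejected(self, rng):
        es = random_encoded_set("a", 2, 3, rng)
        ref = kv.compute_reference([es])
        with pytest.raises(InputError, match="at least two sets"):
            kv.contrast_matrix(*set_gram(es), ref, in_reference=True)

    def test_extrapolation_formula(self, rng):
        sets = [random_encoded_set(f"s{i}", 2, 3, rng) for i in range(3)]
        ref = kv.compute_reference(sets)
        S, m = set_gram(random_encoded_set("new", 2, 3, rng))
        M = kv.contrast_matrix(S, m, ref, in_reference=False)
        np.testing.assert_allclose(M, S / m - ref.R / ref.N, atol=1e-12)


class TestLeadingEigenpair:
    def test_diagonal_matrix(self):
        lam, v = leading_eigenpair(np.diag([2.0, 1.0, 0.0, -1.0]))
        assert lam == pytest.approx(2.0)
        np.testing.assert_allclose(v, [1, 0, 0, 0], atol=1e-12)

    def test_rank_one(self, rng):
        u = rng.standard_normal(10)
        u /= np.linalg.norm(u)
        lam, v = leading_eigenpair(np.outer(u, u))
        assert lam == pytest.approx(1.0)
        # sign-normalised: compare up to the convention, not up to sign
        u_conv = -u if u[np.argmax(np.abs(u))] < 0 else u
        np.testing.assert_allclose(v, u_conv, atol=1e-8)

    @pytest.mark.parametrize("seed", range(5))
    def test_iterative_matches_dense_oracle(self, seed):
        rng = np.random.default_rng(seed)
        M = random_symmetric(12, rng, shift=8.0)
        lam_d, v_d = leading_eigenpair(M, method="dense")
        lam_i, v_i = leading_eigenpair(M, method="iterative")
        assert lam_i == pytest.approx(lam_d, rel=1e-8)
        assert min(np.abs(v_i - v_d).max(), np.abs(v_i + v_d).max()) < 1e-6

    def test_residual_bound(self, rng):
        M = random_symmetric(30, rng, shift=12.0)
        lam, v = leading_eigenpair(M, method="iterative")
        assert np.linalg.norm(M @ v - lam * v) <= 1e-8 * np.linalg.norm(M, 2)

    def test_sign_convention(self):
        lam, v = leading_eigenpair(np.diag([-3.0, 2.0, 1.0]))  # eigvec is +-e2
        assert lam == pytest.approx(2.0)
        assert v[1] > 0

    def test_no_positive_eigenvalue_reported(self):
        with pytest.raises(DegenerateContrastError, match="no positive eigenvalue"):
            leading_eigenpair(-np.eye(4))

    def test_asymmetric_matrix_rejected(self, rng):
        M = rng.standard_normal((5, 5))
        with pytest.raises(InputError, match="symmetric"):
            leading_eigenpair(M)

    def test_deterministic(self, rng):
        M = random_symmetric(40, rng, shift=15.0)
        r1 = leading_eigenpair(M, method="iterative")
        r2 = leading_eigenpair(M, method="iterative")
        assert r1[0] == r2[0]
        np.testing.assert_array_equal(r1[1], r2[1])


class TestComputeIndicators:
    def test_identical_sets_get_identical_vectors(self, rng):
        base = random_encoded_set("a", 3, 5, rng)
        twin = EncodedSet(set_name="b", matrix=base.matrix.copy())
        other = random_encoded_set("c", 2, 5, rng)
        ref = kv.compute_reference([base, twin, other])
        va, vb, _ = kv.compute_indicators([base, twin, other], ref)
        np.testing.assert_allclose(va.vector, vb.vector, atol=1e-9)
        assert va.eigenvalue == pytest.approx(vb.eigenvalue)

    def test_member_permutation_leaves_vector_unchanged(self, tiny_sets, tiny_ref, rng):
        es = tiny_sets[0]
        perm = EncodedSet(
            set_name=es.set_name, matrix=es.matrix[rng.permutation(es.m)]
        )
        [iv1] = kv.compute_indicators([es], tiny_ref)
        [iv2] = kv.compute_indicators([perm], tiny_ref)
        np.testing.assert_allclose(iv2.vector, iv1.vector, atol=1e-9)

    def test_vectors_are_unit_norm_with_positive_eigenvalue(self, tiny_vectors):
        for iv in tiny_vectors:
            assert np.linalg.norm(iv.vector) == pytest.approx(1.0, abs=1e-9)
            assert iv.eigenvalue > 0
            assert iv.in_reference

    def test_order_and_worker_partitioning(self, tiny_sets, tiny_ref):
        serial = kv.compute_indicators(tiny_sets, tiny_ref)
        parallel = kv.compute_indicators(tiny_sets, tiny_ref, workers=3)
        assert [iv.set_name for iv in serial] == [es.set_name for es in tiny_sets]
        for a, b in zip(serial, parallel):
            np.testing.assert_allclose(a.vector, b.vector, atol=1e-12)

    def test_extrapolated_vector_close_to_in_reference(self, tiny_sets):
        # low-divergence data: leaving one set out of the reference barely
        # moves its indicator vector
        target = tiny_sets[0]
        ref_without = kv.compute_reference(tiny_sets[1:])
        full_ref = kv.compute_reference(tiny_sets)
        [extrap] = kv.compute_indicators([target], ref_without)
        [full] = kv.compute_indicators([target], full_ref)
        assert not extrap.in_reference
        r = abs(kv.correlate(extrap.vector, full.vector))
        assert r > 0.95

    def test_extrapolation_can_be_disabled(self, tiny_sets):
        ref = kv.compute_reference(tiny_sets[1:])
        with pytest.raises(InputError, match="absent from the reference"):
            kv.compute_indicators([tiny_sets[0]], ref, allow_extrapolation=False)

    def test_errors_tagged_with_set_name(self, rng):
        es = random_encoded_set("culprit", 2, 3, rng)
        twin = EncodedSet(set_name="twin", matrix=es.matrix.copy())
        ref = kv.compute_reference([es, twin])
        # identical sets contrast to zero: no positive eigenvalue
        with pytest.raises(DegenerateContrastError, match="culprit"):
            kv.compute_indicators([es, twin], ref)


class TestIndicatorIO:
    def test_round_trip_preserves_float64(self, tmp_path, tiny_vectors):
        path = tmp_path / "ind.csv"
        kv.write_indicators(tiny_vectors, path)
        back = kv.read_indicators(path)
        assert [iv.set_name for iv in back] == [iv.set_name for iv in tiny_vectors]
        for a, b in zip(back, tiny_vectors):
            np.testing.assert_array_equal(a.vector, b.vector)
            assert a.eigenvalue == b.eigenvalue
            assert a.m == b.m

    def test_concatenated_files_read_as_union(self, tmp_path, tiny_vectors):
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        kv.write_indicators(tiny_vectors[:4], p1)
        kv.write_indicators(tiny_vectors[4:], p2)
        merged = tmp_path / "merged.csv"
        merged.write_bytes(p1.read_bytes() + p2.read_bytes())
        back = kv.read_indicators(merged)
        assert [iv.set_name for iv in back] == [iv.set_name for iv in tiny_vectors]

    def test_malformed_row_reports_line_number(self, tmp_path, tiny_vectors):
        path = tmp_path / "ind.csv"
        kv.write_indicators(tiny_vectors, path)
        lines = path.read_text().splitlines()
        lines[2] = "badset,notanint,1.0,0.5"
        path.write_text("\n".join(lines) + "\n")
        with pytest.raises(FormatError, match="line 3"):
            kv.read_indicators(path)

    def test_inconsistent_vector_length_rejected(self, tmp_path, tiny_vectors):
        path = tmp_path / "ind.csv"
        kv.write_indicators(tiny_vectors, path)
        with open(path, "a") as fh:
            fh.write("short,1,1.0,0.5,0.5\n")
        with pytest.raises(FormatError, match="inconsistent"):
            kv.read_indicators(path)
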