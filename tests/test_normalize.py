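import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chromo3d import apply_cutoff, contact_percentages, normalize_matrix
from chromo3d.io import ContactMatrix, GenomicRegion


def matrix(values, **kw):
    return ContactMatrix(values=np.asarray(values, dtype=float), **kw)


class TestNormalizeMatrix:
    def test_two_bin_worked_case(self):
        # C_01 = 2, zero diagonal: marginals 2 and 2, total 4, expected 1,
        # so the likelihood ratio is 2.0
        N = normalize_matrix(matrix([[0, 2], [2, 0]]))
        assert N.values[0, 1] == pytest.approx(2.0)
        assert N.normalized

    def test_uniform_matrix_gives_all_ones(self):
        N = normalize_matrix(matrix(np.ones((4, 4))))
        np.testing.assert_allclose(N.values, np.ones((4, 4)))

    def test_scale_invariance(self, rng):
        V = rng.integers(1, 30, (6, 6)).astype(float)
        V = V + V.T
        np.fill_diagonal(V, 0)
        N1 = normalize_matrix(matrix(V))
        N2 = normalize_matrix(matrix(7.3 * V))
        np.testing.assert_allclose(N1.values, N2.values, rtol=1e-12)

    def test_zero_marginal_bin_masked(self):
        V = np.array([[0, 2, 0], [2, 0, 0], [0, 0, 0]], dtype=float)
        N = normalize_matrix(matrix(V))
        assert np.all(N.values[2] == 0)
        assert np.all(N.values[:, 2] == 0)
        # remaining pair normalized over the live marginals only
        assert N.values[0, 1] == pytest.approx(2.0)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            normalize_matrix(matrix(np.zeros((3, 3))))

    def test_double_normalization_rejected(self):
        N = normalize_matrix(matrix(np.ones((4, 4))))
        with pytest.raises(ValueError, match="already normalized"):
            normalize_matrix(N)

    def test_expected_matrix_preserves_marginals(self, rng):
        V = rng.integers(1, 20, (5, 5)).astype(float)
        V = V + V.T
        m = V.sum(axis=1)
        expected = np.outer(m, m) / V.sum()
        np.testing.assert_allclose(expected.sum(axis=1), m)


class TestApplyCutoff:
    def build(self, vals):
        # 5-bin matrix; pair (0, 2), (0, 3), (0, 4) carry the given values
        V = np.zeros((5, 5))
        V[0, 2], V[0, 3], V[0, 4] = vals
        V = V + V.T
        return matrix(V, normalized=True)

    def test_strict_inequality_at_cutoff(self):
        CS = apply_cutoff(self.build([0.5, 0.66, 0.7]), cutoff=0.66)
        contacts = {tuple(p) for p in CS.contacts}
        assert (0, 4) in contacts           # 0.7  > 0.66
        assert (0, 3) not in contacts       # 0.66 is not > 0.66
        assert (0, 2) not in contacts       # 0.5

    def test_zero_cutoff_takes_every_positive_pair(self):
        CS = apply_cutoff(self.build([0.5, 0.66, 0.7]), cutoff=0.0)
        assert CS.n_contacts == 3

    def test_partition_covers_all_pairs(self, rng):
        n = 9
        V = rng.uniform(0, 2, (n, n))
        V = (V + V.T) / 2
        np.fill_diagonal(V, 0)
        CS = apply_cutoff(matrix(V, normalized=True), cutoff=0.8)
        assert CS.n_contacts + CS.n_noncontacts + len(CS.adjacent) == n * (n - 1) // 2

    def test_adjacent_pairs_kept_out_of_cutoff_classes(self):
        V = np.ones((4, 4)) * 5
        np.fill_diagonal(V, 0)
        CS = apply_cutoff(matrix(V, normalized=True), cutoff=0.1)
        adj = {tuple(p) for p in CS.adjacent}
        assert adj == {(0, 1), (1, 2), (2, 3)}
        assert all(j - i > 1 for i, j in CS.contacts)

    def test_monotone_in_cutoff(self, rng):
        n = 8
        V = rng.uniform(0, 3, (n, n))
        V = (V + V.T) / 2
        np.fill_diagonal(V, 0)
        M = matrix(V, normalized=True)
        lo = {tuple(p) for p in apply_cutoff(M, 0.5).contacts}
        hi = {tuple(p) for p in apply_cutoff(M, 1.5).contacts}
        assert hi <= lo

    def test_negative_cutoff_rejected(self):
        with pytest.raises(ValueError, match="nonnegative"):
            apply_cutoff(self.build([1, 1, 1]), cutoff=-0.1)

    def test_gap_flanking_bins_not_adjacent(self):
        # modeled bins 0,1,2 where bins 1 and 2 flank a centromere gap
        regions = [
            GenomicRegion("chr1", 0, 10, 0, True),
            GenomicRegion("chr1", 10, 20, 1, True),
            GenomicRegion("chr1", 40, 50, 2, True),
        ]
        V = np.ones((3, 3)) * 2
        np.fill_diagonal(V, 0)
        M = ContactMatrix(values=V, regions=regions, normalized=True)
        CS = apply_cutoff(M, cutoff=0.5)
        assert {tuple(p) for p in CS.adjacent} == {(0, 1)}
        # the gap pair (1, 2) is classified by the cutoff instead
        assert (1, 2) in {tuple(p) for p in CS.contacts}

    def test_contact_weights_exceed_cutoff(self, rng):
        V = rng.uniform(0, 3, (7, 7))
        V = (V + V.T) / 2
        np.fill_diagonal(V, 0)
        CS = apply_cutoff(matrix(V, normalized=True), cutoff=1.0)
        assert np.all(CS.contact_weights > 1.0)


class TestNormalizationProperties:
    @staticmethod
    def _random_matrix(seed, n):
        rng = np.random.default_rng(seed)
        V = rng.integers(1, 50, (n, n)).astype(float)
        V = V + V.T
        np.fill_diagonal(V, 0)
        return V

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), k=st.floats(0.01, 1000.0), n=st.integers(3, 12))
    def test_scale_invariance_holds_for_any_positive_factor(self, seed, k, n):
        V = self._random_matrix(seed, n)
        N1 = normalize_matrix(ContactMatrix(values=V))
        N2 = normalize_matrix(ContactMatrix(values=k * V))
        np.testing.assert_allclose(N1.values, N2.values, rtol=1e-9)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), lo=st.floats(0.0, 2.0), delta=st.floats(0.0, 3.0))
    def test_cutoff_monotonicity(self, seed, lo, delta):
        V = self._random_matrix(seed, 8)
        N = normalize_matrix(ContactMatrix(values=V))
        low = {tuple(p) for p in apply_cutoff(N, lo).contacts}
        high = {tuple(p) for p in apply_cutoff(N, lo + delta).contacts}
        assert high <= low


class TestContactPercentages:
    def test_half_of_pairs_in_contact(self):
        V = np.zeros((4, 4))
        V[0, 1] = V[0, 2] = V[0, 3] = 2.0
        V = V + V.T
        df = contact_percentages(matrix(V, normalized=True), cutoff=1.0)
        assert df.pct_in_contact.iloc[0] == pytest.approx(50.0)

    def test_cutoff_above_max_gives_zero(self):
        V = np.ones((4, 4))
        np.fill_diagonal(V, 0)
        df = contact_percentages(matrix(V, normalized=True), cutoff=10.0)
        assert df.pct_in_contact.iloc[0] == 0.0

    def test_zero_cutoff_on_positive_matrix_gives_hundred(self):
        V = np.ones((5, 5))
        np.fill_diagonal(V, 1.0)
        df = contact_percentages(matrix(V, normalized=True), cutoff=0.0)
        assert df.pct_in_contact.iloc[0] == 100.0

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="no matrices"):
            contact_percentages([], cutoff=0.5)
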