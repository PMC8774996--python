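import numpy as np
import pytest
from hypothesis import given, strategies as st

import covdet as cd
from covdet.exceptions import InvalidArgumentError
from covdet.features import _mode


def cofactor_det(A):
    """Independent determinant oracle: recursive cofactor expansion."""
    A = np.asarray(A, dtype=float)
    n = A.shape[0]
    if n == 1:
        return A[0, 0]
    total = 0.0
    for j in range(n):
        minor = np.delete(np.delete(A, 0, axis=0), j, axis=1)
        total += (-1) ** j * A[0, j] * cofactor_det(minor)
    return total


def random_psd(rng, n):
    B = rng.standard_normal((n, n))
    return B @ B.T / n


# ---------------------------------------------------------------------------
# covariance
# ---------------------------------------------------------------------------

def test_covariance_hand_example():
    M = cd.SegmentMatrix(np.array([[1.0, 2, 3], [2.0, 4, 6]]), m=2, k=3)
    C = cd.covariance_matrix(M)
    np.testing.assert_allclose(C.H, [[1, 2], [2, 4]])


def test_covariance_identical_rows_rank_one():
    M = cd.SegmentMatrix(np.array([[1.0, 5, 2], [1.0, 5, 2]]), m=2, k=3)
    H = cd.covariance_matrix(M).H
    assert H[0, 0] == H[0, 1] == H[1, 0] == H[1, 1]
    assert np.linalg.matrix_rank(H) <= 1


def test_covariance_constant_row_zero():
    M = cd.SegmentMatrix(np.array([[3.0, 3, 3], [1.0, 2, 4]]), m=2, k=3)
    H = cd.covariance_matrix(M).H
    np.testing.assert_allclose(H[0], 0.0)
    np.testing.assert_allclose(H[:, 0], 0.0)


def test_covariance_requires_two_observations():
    with pytest.raises(InvalidArgumentError):
        cd.covariance_matrix(cd.SegmentMatrix(np.ones((3, 1)), m=3, k=1))


# ---------------------------------------------------------------------------
# eigen determinant
# ---------------------------------------------------------------------------

def test_eigen_determinant_identity():
    C = cd.CovarianceMatrix(np.eye(3), np.zeros(3))
    eig, det = cd.eigen_determinant(C)
    np.testing.assert_allclose(eig.eigenvalues, 1.0)
    assert det == pytest.approx(1.0)


def test_eigen_determinant_rank_deficient():
    C = cd.CovarianceMatrix(np.array([[1.0, 2], [2.0, 4]]), np.zeros(2))
    eig, det = cd.eigen_determinant(C)
    np.testing.assert_allclose(sorted(eig.eigenvalues), [0.0, 5.0], atol=1e-12)
    assert det == pytest.approx(0.0, abs=1e-12)


def test_eigenvalue_product_matches_cofactor_oracle():
    rng = np.random.default_rng(3)
    for _ in range(25):
        n = rng.integers(2, 9)
        H = random_psd(rng, n)
        _, det = cd.eigen_determinant(cd.CovarianceMatrix(H, np.zeros(n)))
        expected = cofactor_det(H)
        assert det == pytest.approx(expected, rel=1e-8, abs=1e-12)


def test_eigendecomposition_reconstructs():
    rng = np.random.default_rng(4)
    H = random_psd(rng, 5)
    eig, _ = cd.eigen_determinant(cd.CovarianceMatrix(H, np.zeros(5)))
    V, lam = eig.eigenvectors, eig.eigenvalues
    assert np.all(np.diff(lam) <= 1e-12)  # descending
    np.testing.assert_allclose(V @ np.diag(lam) @ V.T, H, atol=1e-10)
    np.testing.assert_allclose(V.T @ V, np.eye(5), atol=1e-10)


# ---------------------------------------------------------------------------
# descriptors
# ---------------------------------------------------------------------------

def test_descriptors_symmetric_ramp():
    d = cd.stat_descriptors([1, 2, 3, 4, 5])
    assert (d.mean, d.median, d.minimum, d.maximum, d.range) == (3, 3, 1, 5, 4)
    assert d.variance == pytest.approx(2.5)
    assert d.standard_deviation == pytest.approx(1.5811, abs=1e-4)
    assert d.skewness == pytest.approx(0.0, abs=1e-12)


def test_descriptor_mode_majority_value():
    assert cd.stat_descriptors([2, 2, 3]).mode == 2


def test_descriptor_internal_identities():
    rng = np.random.default_rng(0)
    x = rng.standard_normal(64)
    d = cd.stat_descriptors(x)
    assert d.range == pytest.approx(d.maximum - d.minimum)
    assert d.standard_deviation == pytest.approx(np.sqrt(d.variance))
    assert d.minimum <= d.mode <= d.maximum
    assert d.minimum <= d.median <= d.maximum
    # Gaussian-like kurtosis is plain (not excess): near 3
    assert 2.0 < d.kurtosis < 4.5


def test_descriptors_constant_input():
    d = cd.stat_descriptors([7.0, 7.0, 7.0])
    assert (d.variance, d.skewness, d.kurtosis) == (0.0, 0.0, 0.0)
    assert d.mode == d.median == 7.0


def test_descriptors_errors():
    with pytest.raises(InvalidArgumentError):
        cd.stat_descriptors([1.0])
    with pytest.raises(InvalidArgumentError):
        cd.stat_descriptors([1.0, np.nan])


def test_mode_binning_variants():
    x = np.array([2.0, 2.0, 3.0])
    assert _mode(x, "exact") == 2.0
    assert _mode(x, "fd-value") == 2.0
    assert _mode(x, "fd-midpoint") == pytest.approx(2.25)


# ---------------------------------------------------------------------------
# feature records
# ---------------------------------------------------------------------------

def test_segment_feature_dimension():
    seg = cd.Segment(np.sin(np.linspace(0, 40, 1024)), index=0)
    rec = cd.segment_feature_record(seg, 32)
    assert rec.values.size == 320
    assert len(rec.names) == 320
    # descriptor-major flattening: first 32 names are the means
    assert all(n.startswith("mean_r") for n in rec.names[:32])


def test_channel_feature_dimension(ramp_channel):
    table = cd.extract_features([ramp_channel])
    cols = cd.descriptor_columns(table)
    assert len(cols) == 320
    assert len(table) == 4                       # 4 segments
    assert table[cols].size == 1280              # whole-channel dimension


def test_raw_rows_source_same_dimension():
    seg = cd.Segment(np.sin(np.linspace(0, 40, 1024)), index=0)
    rec = cd.segment_feature_record(seg, 32, feature_source="raw_rows")
    assert rec.values.size == 320


def test_constant_segment_all_zero_features():
    seg = cd.Segment(np.zeros(1024), index=0)
    rec = cd.segment_feature_record(seg, 32)
    assert rec.det == 0.0
    assert np.all(rec.values == 0.0)


@given(shift=st.floats(-50, 50), scale=st.floats(0.1, 10))
def test_shift_scale_equivariance(shift, scale):
    """Shifting a segment leaves H and det unchanged; scaling by c scales
    variance-like descriptors by c^2 and det by c^(2S)."""
    rng = np.random.default_rng(11)
    base = rng.standard_normal(64)
    seg = cd.Segment(base, 0)
    seg_shift = cd.Segment(base + shift, 0)
    seg_scale = cd.Segment(base * scale, 0)
    m = 4
    M0 = cd.to_subsegment_matrix(seg, m)
    H0 = cd.covariance_matrix(M0).H
    Hs = cd.covariance_matrix(cd.to_subsegment_matrix(seg_shift, m)).H
    Hc = cd.covariance_matrix(cd.to_subsegment_matrix(seg_scale, m)).H
    np.testing.assert_allclose(Hs, H0, atol=1e-8)
    np.testing.assert_allclose(Hc, H0 * scale ** 2, rtol=1e-9, atol=1e-12)
    _, d0 = cd.eigen_determinant(cd.CovarianceMatrix(H0, np.zeros(m)))
    _, dc = cd.eigen_determinant(cd.CovarianceMatrix(Hc, np.zeros(m)))
    assert dc == pytest.approx(d0 * scale ** (2 * m), rel=1e-6)
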