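import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from msntx import build_msn, regional_strength, threshold_msn, zscore_features
from msntx.msn import MSNMatrix, SubjectFeatures


def _subject(matrix, zscored=False):
    matrix = np.asarray(matrix, float)
    return SubjectFeatures(subject_id="s", region_ids=np.arange(1, matrix.shape[0] + 1),
                           matrix=matrix,
                           feature_names=tuple(f"f{i}" for i in range(matrix.shape[1])),
                           zscored=zscored)


# -- z-scoring ---------------------------------------------------------------

def test_zscore_three_point_column():
    sf = _subject(np.column_stack([[1.0, 2, 3], [5.0, 7, 9], [0.0, 1, -1]]))
    z = zscore_features(sf)
    assert np.allclose(z.matrix[:, 0], [-1, 0, 1])
    assert np.allclose(z.matrix[:, 1], [-1, 0, 1])


def test_zscore_idempotent():
    rng = np.random.default_rng(0)
    z1 = zscore_features(_subject(rng.normal(size=(10, 7))))
    z2 = zscore_features(z1)
    assert np.abs(z2.matrix - z1.matrix).max() < 1e-12


def test_zscore_matches_two_pass_oracle(rng):
    m = rng.normal(size=(10, 7)) * rng.uniform(0.1, 30, 7)
    z = zscore_features(_subject(m))
    for j in range(7):
        col = m[:, j]
        mean = sum(col) / len(col)                      # independent two-pass
        sd = (sum((x - mean) ** 2 for x in col) / (len(col) - 1)) ** 0.5
        assert np.allclose(z.matrix[:, j], (col - mean) / sd)
    assert np.abs(z.matrix.mean(axis=0)).max() < 1e-10
    assert np.abs(z.matrix.std(axis=0, ddof=1) - 1).max() < 1e-10


def test_zscore_constant_column_names_feature():
    m = np.random.default_rng(1).normal(size=(6, 3))
    m[:, 1] = 4.2
    with pytest.raises(ValueError, match="f1"):
        zscore_features(_subject(m))


# -- MSN construction --------------------------------------------------------

def test_identical_and_opposite_rows():
    v = np.array([1.0, -2.0, 3.0, 0.5])
    m = np.vstack([v, v, -v])
    msn = build_msn(_subject(m, zscored=True))
    assert msn.weights[0, 1] == pytest.approx(1.0)
    assert msn.weights[0, 2] == pytest.approx(-1.0)
    assert np.all(np.diag(msn.weights) == 0.0)


def test_matches_double_loop_pearson_oracle(rng):
    m = rng.normal(size=(6, 4))
    msn = build_msn(_subject(m, zscored=True))
    for i in range(6):
        for j in range(6):
            if i == j:
                continue
            a, b = m[i], m[j]
            r = (np.sum((a - a.mean()) * (b - b.mean()))
                 / np.sqrt(np.sum((a - a.mean()) ** 2) * np.sum((b - b.mean()) ** 2)))
            assert abs(msn.weights[i, j] - r) < 1e-12


def test_raw_input_refused_unless_flagged(rng):
    sf = _subject(rng.normal(size=(5, 4)))
    with pytest.raises(ValueError, match="z-scored"):
        build_msn(sf)
    build_msn(sf, allow_raw=True)


def test_constant_region_vector_degenerate():
    m = np.random.default_rng(2).normal(size=(5, 4))
    m[2] = 7.0
    with pytest.raises(ValueError, match="degenerate"):
        build_msn(_subject(m, zscored=True))


def test_affine_feature_rescaling_leaves_msn_invariant(rng):
    m = rng.normal(size=(12, 7))
    msn1 = build_msn(zscore_features(_subject(m)))
    m2 = m * rng.uniform(0.5, 50, 7) + rng.uniform(-10, 10, 7)
    msn2 = build_msn(zscore_features(_subject(m2)))
    assert np.abs(msn1.weights - msn2.weights).max() < 1e-9


def test_region_permutation_equivariance(rng):
    m = rng.normal(size=(9, 5))
    perm = rng.permutation(9)
    msn = build_msn(zscore_features(_subject(m)))
    msn_p = build_msn(zscore_features(_subject(m[perm])))
    assert np.allclose(msn_p.weights, msn.weights[np.ix_(perm, perm)])
    s = regional_strength(msn).to_numpy()
    s_p = regional_strength(msn_p).to_numpy()
    assert np.allclose(s_p, s[perm])


# -- thresholding ------------------------------------------------------------

def _toy_msn(weights):
    w = np.asarray(weights, float)
    w = np.triu(w, 1)
    return MSNMatrix(region_ids=np.arange(1, w.shape[0] + 1), weights=w + w.T)


def test_density_one_is_identity(rng):
    msn = build_msn(zscore_features(_subject(rng.normal(size=(6, 5)))))
    assert threshold_msn(msn, 1.0) is msn


def test_half_density_keeps_three_largest_pairs(rng):
    w = np.zeros((4, 4))
    vals = [0.9, 0.7, 0.5, 0.3, 0.1, -0.2]
    iu = np.triu_indices(4, 1)
    w[iu] = vals
    msn = _toy_msn(w)
    thr = threshold_msn(msn, 0.5)
    nz = thr.weights != 0
    assert nz.sum() == 6  # 6 of 12 off-diagonal cells
    kept = sorted(thr.weights[np.triu_indices(4, 1)][thr.weights[np.triu_indices(4, 1)] != 0])
    assert kept == [0.5, 0.7, 0.9]
    assert np.allclose(thr.weights, thr.weights.T)


def test_tie_break_is_lexicographic():
    w = np.full((4, 4), 0.4)
    msn = _toy_msn(w)
    thr = threshold_msn(msn, 0.5)
    iu, ju = np.triu_indices(4, 1)
    kept_pairs = [(i, j) for i, j in zip(iu, ju) if thr.weights[i, j] != 0]
    assert kept_pairs == [(0, 1), (0, 2), (0, 3)]  # first three in (row, col) order


@pytest.mark.parametrize("d1,d2", [(0.2, 0.5), (0.3, 0.9), (0.5, 1.0)])
def test_edge_sets_nested_across_densities(rng, d1, d2):
    msn = build_msn(zscore_features(_subject(rng.normal(size=(10, 7)))))
    e1 = threshold_msn(msn, d1).weights != 0
    e2 = threshold_msn(msn, d2).weights != 0
    assert not np.any(e1 & ~e2)


@pytest.mark.parametrize("density", [0.0, -0.1, 1.2])
def test_invalid_density_rejected(density, rng):
    msn = build_msn(zscore_features(_subject(rng.normal(size=(5, 4)))))
    with pytest.raises(ValueError):
        threshold_msn(msn, density)


# -- regional strength -------------------------------------------------------

def test_single_edge_and_zero_network():
    w = np.array([[0.0, 0.37], [0.37, 0.0]])
    s = regional_strength(MSNMatrix(region_ids=np.array([1, 2]), weights=w))
    assert np.allclose(s.to_numpy(), [0.37, 0.37])
    z = regional_strength(MSNMatrix(region_ids=np.array([1, 2]), weights=np.zeros((2, 2))))
    assert np.allclose(z.to_numpy(), 0.0)


def test_strength_equals_row_sum_oracle(rng):
    msn = build_msn(zscore_features(_subject(rng.normal(size=(8, 6)))))
    s = regional_strength(msn).to_numpy()
    oracle = [sum(msn.weights[i, j] for j in range(8)) for i in range(8)]
    assert np.abs(s - np.array(oracle)).max() < 1e-12


def test_all_ones_network_strength_is_n_minus_one():
    n = 7
    w = np.ones((n, n))
    np.fill_diagonal(w, 0.0)
    s = regional_strength(MSNMatrix(region_ids=np.arange(1, n + 1), weights=w))
    assert np.allclose(s.to_numpy(), n - 1)


@settings(max_examples=25, deadline=None)
@given(st.integers(min_value=0, max_value=2 ** 31 - 1))
def test_msn_symmetric_bounded_for_random_subjects(seed):
    m = np.random.default_rng(seed).normal(size=(7, 5))
    try:
        msn = build_msn(zscore_features(_subject(m)))
    except ValueError:
        return  # degenerate draws are allowed to be rejected
    assert np.allclose(msn.weights, msn.weights.T)
    assert msn.weights.min() >= -1.0 and msn.weights.max() <= 1.0
    assert np.all(np.diag(msn.weights) == 0.0)
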