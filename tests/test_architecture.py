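"""QTL assignment, effect sampling, masking, major designation and scaling."""

import numpy as np
import pytest
from scipy import stats

from breedsim import (
    EffectCovariance,
    LocusMap,
    OverlapScheme,
    Population,
    assign_qtl,
    build_architecture,
    designate_major,
    mask_effects,
    orient_favourable,
    sample_effects,
    scale_major,
)
from breedsim.architecture import genic_variance_fraction
from breedsim.phenotypes import breeding_values


@pytest.mark.parametrize(
    "scheme, expected_unique, expected_shared, expected_total",
    [
        (OverlapScheme(k_traits=2, w_envs=2, q=0.7, n_per_trait_env=1001), 177, 824, 2356),
        (OverlapScheme(k_traits=1, w_envs=2, q=0.0, n_per_trait_env=10), 10, 0, 20),
        (OverlapScheme(k_traits=2, w_envs=2, q=1.0, n_per_trait_env=10), 0, 10, 20),
    ],
)
def test_overlap_counting_rule(scheme, expected_unique, expected_shared, expected_total):
    """The environment-overlap split reproduces the reference QTL counts."""
    u, s = scheme.env_counts()
    assert (u, s) == (expected_unique, expected_shared)
    assert scheme.n_distinct == expected_total


def test_assign_qtl_design_matrix_structure(rng):
    scheme = OverlapScheme(n_per_trait_env=101)
    lm = LocusMap.regular(1000, 7, 1_000_000, rng)
    counts, loci, design, trait_of = assign_qtl(scheme, lm, rng)
    # per-environment column sums equal N for every trait-environment
    assert design.sum(axis=0).tolist() == [101, 101, 101, 101]
    assert len(np.unique(loci)) == counts["total"] == design.shape[0]
    # no pleiotropy: each QTL has a single trait's columns active
    for t in (0, 1):
        rows = trait_of == t
        other = design[rows][:, [2 - 2 * t, 3 - 2 * t]]
        assert not other.any()


def test_assign_qtl_rejects_small_panel(rng):
    lm = LocusMap.regular(100, 2, 1_000_000, rng)
    with pytest.raises(ValueError, match="cannot host"):
        assign_qtl(OverlapScheme(n_per_trait_env=101), lm, rng)


def test_effect_correlations_match_covariance(rng):
    """Cholesky construction reproduces the disease/yield G-by-E correlations."""
    cov = EffectCovariance()
    v = sample_effects(cov, 2356, rng)
    corr = np.corrcoef(v.T)
    assert corr[0, 1] == pytest.approx(0.8, abs=0.03)
    assert corr[2, 3] == pytest.approx(0.4, abs=0.04)
    assert abs(corr[0, 2]) < 0.06 and abs(corr[1, 3]) < 0.06
    # algebraic identity of the factorization
    L = cov.cholesky_upper()
    np.testing.assert_allclose(L.T @ L, cov.matrix, atol=1e-12)


def test_effect_columns_marginally_normal(rng):
    v = sample_effects(EffectCovariance(), 2356, rng)
    for j in range(4):
        assert stats.kstest(v[:, j], "norm").pvalue > 0.01


def test_identity_covariance_gives_uncorrelated_columns(rng):
    v = sample_effects(EffectCovariance(np.eye(4)), 2356, rng)
    corr = np.corrcoef(v.T) - np.eye(4)
    assert np.all(np.abs(corr) < 3 / np.sqrt(2356))


def test_non_psd_covariance_rejected():
    bad = np.eye(4)
    bad[0, 1] = bad[1, 0] = 1.5
    with pytest.raises(ValueError, match="positive semi-definite"):
        EffectCovariance(bad)


def test_mask_effects_matches_elementwise_loop(rng):
    v = rng.standard_normal((6, 4))
    design = (rng.random((6, 4)) < 0.5).astype(np.int8)
    a = mask_effects(v, design)
    for i in range(6):
        for j in range(4):
            assert a[i, j] == design[i, j] * v[i, j]
    np.testing.assert_array_equal(mask_effects(v, np.ones_like(design)), v)
    with pytest.raises(ValueError, match="shape"):
        mask_effects(v, design[:, :3])


def test_designate_major_ranking_and_ties():
    effects = np.zeros((6, 4))
    effects[:, 0] = [5, 4, 3, 2, 1, 0.5]
    design = np.zeros((6, 4), dtype=np.int8)
    design[:, 0] = 1
    trait_of = np.zeros(6, dtype=int)
    assert designate_major(effects, trait_of, n_major=2).tolist() == [0, 1]
    # all-equal effects: first rows by index win
    effects[:, 0] = 1.0
    assert designate_major(effects, trait_of, n_major=3).tolist() == [0, 1, 2]


def test_designate_major_matches_sort_oracle(rng):
    n = 40
    design = np.zeros((n, 4), dtype=np.int8)
    design[:, 0] = 1
    design[::2, 1] = 1
    v = rng.standard_normal((n, 4))
    effects = v * design
    trait_of = np.zeros(n, dtype=int)
    got = designate_major(effects, trait_of, n_major=7)
    score = np.abs(effects[:, :2]).sum(1) / np.maximum((np.abs(effects[:, :2]) > 0).sum(1), 1)
    oracle = np.sort(np.argsort(-score, kind="stable")[:7])
    np.testing.assert_array_equal(got, oracle)


def _reference_counts(arch, founders, n_parents=40, frac=0.2, seed=5):
    rng = np.random.default_rng(seed)
    n_ext = int(round(frac * n_parents))
    ec = founders.external.fav_counts(arch)[:, arch.major].sum(1)
    best = np.sort(np.argsort(-ec)[:n_ext])
    idx = rng.choice(founders.existing.n, n_parents - n_ext, replace=False)
    pool = Population.concatenate(
        [founders.existing.subset(np.sort(idx)), founders.external.subset(best)]
    )
    return pool.fav_counts(arch)


def test_scale_major_hits_target_fraction(small_arch, small_founders):
    counts = _reference_counts(small_arch, small_founders)
    scaled, c = scale_major(small_arch, counts, target_frac=0.10)
    assert genic_variance_fraction(scaled, counts) == pytest.approx(0.10, abs=1e-9)
    assert c > 0
    # the full disease-effect vector is standardised to unit SD
    d = scaled.effects[:, :2][scaled.design[:, :2] > 0]
    assert np.std(d) == pytest.approx(1.0, abs=1e-9)


def test_scale_major_agrees_with_bisection_oracle(small_arch, small_founders):
    """The closed-form constant matches a bisection on the fraction function."""
    counts = _reference_counts(small_arch, small_founders)
    _, c = scale_major(small_arch, counts, target_frac=0.10)

    def frac_of(cc):
        eff = small_arch.fav_effects[:, :2].mean(axis=1).copy()
        eff[small_arch.major] *= cc
        d_rows = small_arch.qtl_of_trait(0)
        dose_var = counts[:, d_rows].var(axis=0)
        contrib = dose_var * eff[d_rows] ** 2
        is_major = np.isin(d_rows, small_arch.major)
        return contrib[is_major].sum() / contrib.sum()

    lo, hi = 1e-9, 1e6
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if frac_of(mid) < 0.10:
            lo = mid
        else:
            hi = mid
    assert c == pytest.approx(0.5 * (lo + hi), abs=1e-6)


def test_scale_major_idempotent(small_arch, small_founders):
    counts = _reference_counts(small_arch, small_founders)
    once, _ = scale_major(small_arch, counts, target_frac=0.10)
    twice, c2 = scale_major(once, counts, target_frac=0.10)
    assert c2 == pytest.approx(1.0, abs=1e-9)
    np.testing.assert_allclose(twice.effects, once.effects, atol=1e-12)


def test_orientation_sign_symmetry():
    effects = np.array([[0.3, 0.1, 0, 0], [-0.3, -0.2, 0, 0]])
    design = np.array([[1, 1, 0, 0], [1, 1, 0, 0]], dtype=np.int8)
    trait_of = np.zeros(2, dtype=int)
    orient = orient_favourable(effects, design, trait_of)
    assert orient.tolist() == [1, -1]


def test_favourable_coding_shifts_tbv_by_constant(small_map, rng):
    """TBV in raw vs favourable coding differ by an additive constant only."""
    arch = build_architecture(OverlapScheme(n_per_trait_env=11), small_map, rng)
    hap = (rng.random((15, 2, small_map.n_loci)) < 0.5).astype(np.uint8)
    pop = Population(hap)
    g_fav = breeding_values(pop, arch)
    raw_counts = pop.allele_counts(arch.loci).astype(float)
    g_raw = raw_counts @ arch.effects
    diff = g_fav - g_raw
    np.testing.assert_allclose(diff - diff[0], 0.0, atol=1e-9)
    # rankings on any column are identical
    for j in range(4):
        np.testing.assert_array_equal(np.argsort(g_fav[:, j]), np.argsort(g_raw[:, j]))
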