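"""Programme orchestration: crossing plan, introgression, cycles, replicates."""

import numpy as np
import pandas as pd
import pytest

from breedsim import (
    FounderConfig,
    MeiosisParams,
    OverlapScheme,
    default_config,
    introgress_parents,
    make_crosses,
    plan_cohorts,
    run_programme,
    run_replicate,
    scaled_config,
)
from breedsim.phenotypes import trait_values
from breedsim.programme import ProgrammeConfig, replicate_seed, run_cycle, setup_replicate


@pytest.fixture(scope="module")
def tiny_config():
    """Scaled profile shrunk further for orchestration tests."""
    return scaled_config(
        n_loci=400,
        scheme=OverlapScheme(n_per_trait_env=41),
        founder=FounderConfig(n_existing=120, n_external=10),
        n_cycles=5,
        phenotypic_cycles=2,
        introgression_cycle=3,
    )


@pytest.fixture(scope="module")
def tiny_setup(tiny_config):
    rng = np.random.default_rng(replicate_seed(3, 0))
    return rng, setup_replicate(tiny_config, rng)


def test_full_scale_cohort_plan_matches_reference_structure():
    plan = plan_cohorts(default_config())
    assert plan["crosses"] == 350
    assert plan["f1"] == 3500
    assert plan["f2"] == 7000
    assert plan["f2_selected"] == 3500
    assert plan["f3"] == plan["f5"] == 35_000
    assert plan["stage1"] == 800
    assert plan["parents"] == 400


def test_scaled_profile_preserves_structural_ratios():
    full, scaled = plan_cohorts(default_config()), plan_cohorts(scaled_config())
    for key in full:
        assert full[key] / scaled[key] == 10


def test_config_consistency_validated():
    with pytest.raises(ValueError, match="pair all parents"):
        ProgrammeConfig(n_parents=400, n_primary=150)
    with pytest.raises(ValueError, match="best-primary"):
        ProgrammeConfig(n_backcross=70, n_topcross=90)


def test_make_crosses_uses_each_parent_once(tiny_config, tiny_setup):
    rng, (lm, arch, founders, state) = tiny_setup
    f1 = make_crosses(
        state.parents, state.parent_scores, arch, tiny_config, lm, np.random.default_rng(0)
    )
    plan = plan_cohorts(tiny_config)
    assert f1.n == plan["f1"]
    assert len(np.unique(f1.family)) == plan["crosses"]
    # primary-cross progeny (families 0..n_primary-1) use every parent once
    primary = f1.family < tiny_config.n_primary
    used = np.unique(f1.parents[primary])
    assert used.size == tiny_config.n_parents


def test_introgression_replaces_lowest_index_parents(tiny_setup):
    rng, (lm, arch, founders, state) = tiny_setup
    scores = np.arange(state.parents.n, dtype=float)
    pool, new_scores = introgress_parents(
        state.parents, scores, founders.external, 0.20, arch
    )
    n_replace = int(np.ceil(0.20 * state.parents.n))
    assert pool.n == state.parents.n
    # lowest-scoring parents are gone, everyone else retained
    surviving = set(pool.ids.tolist()) & set(state.parents.ids.tolist())
    assert surviving == set(state.parents.ids[n_replace:].tolist())
    # incoming lines are exactly existing external genotypes (no edits)
    ext_rows = [i for i, pid in enumerate(pool.ids) if pid in set(founders.external.ids.tolist())]
    assert len(ext_rows) == n_replace
    for i in ext_rows:
        src = np.flatnonzero(founders.external.ids == pool.ids[i])[0]
        np.testing.assert_array_equal(
            pool.haplotypes[i], founders.external.haplotypes[src]
        )


def test_introgression_zero_pct_is_identity(tiny_setup):
    rng, (lm, arch, founders, state) = tiny_setup
    pool, scores = introgress_parents(
        state.parents, state.parent_scores, founders.external, 0.0, arch
    )
    assert pool is state.parents


def test_introgression_line_counts():
    # ceil(pct * 400) external lines at full parent count
    assert int(np.ceil(0.01 * 400)) == 4
    assert int(np.ceil(0.20 * 400)) == 80


def test_cycle_produces_planned_cohorts_and_metrics(tiny_config, tiny_setup):
    rng, (lm, arch, founders, state) = tiny_setup
    state2, records = run_cycle(state, tiny_config, arch, lm, founders.external, rng)
    assert state2.cycle == 1
    assert state2.parents.n == tiny_config.n_parents
    metrics = {r["metric"] for r in records}
    assert {"genetic_gain", "freq_major", "freq_minor", "freq_yield"} <= metrics
    assert len(state2.training) == 1


def test_replicate_is_deterministic(tiny_config):
    a = run_replicate(tiny_config, replicate_seed(5, 0))
    b = run_replicate(tiny_config, replicate_seed(5, 0))
    pd.testing.assert_frame_equal(a, b)


def test_replicate_metrics_shape(tiny_config):
    tab = run_replicate(tiny_config, replicate_seed(6, 0))
    gains = tab[tab.metric == "genetic_gain"]
    assert set(gains.cycle) == set(range(1, tiny_config.n_cycles + 1))
    assert set(gains.trait) == {"disease", "yield"}
    acc = tab[tab.metric == "accuracy"]
    # lagged accuracy exists only in genomic-selection cycles
    assert set(acc.cycle) == set(
        range(tiny_config.phenotypic_cycles + 1, tiny_config.n_cycles + 1)
    )
    assert acc.value.between(-1, 1).all()
    freqs = tab[tab.metric.str.startswith("freq_")]
    assert freqs.value.between(0, 1).all()
    intr = tab[tab.metric == "freq_major_intr"]
    assert list(intr.cycle) == [tiny_config.introgression_cycle]


def test_f1_mean_tbv_matches_parent_mean(tiny_config, tiny_setup):
    """Without selection, crossing is Mendelian: progeny mean TBV equals the
    parental mean in expectation."""
    rng, (lm, arch, founders, state) = tiny_setup
    cfg = tiny_config
    f1 = make_crosses(
        state.parents, state.parent_scores, arch, cfg, lm, np.random.default_rng(2)
    )
    primary = f1.family < cfg.n_primary  # back/top crosses are selected, skip them
    tv_parents = trait_values(state.parents, arch).mean(axis=0)
    tv_f1 = trait_values(f1.subset(np.flatnonzero(primary)), arch).mean(axis=0)
    sd = trait_values(state.parents, arch).std(axis=0)
    assert np.all(np.abs(tv_f1 - tv_parents) < 0.25 * sd)


def test_run_programme_aggregates_replicates(tiny_config):
    raw, summary = run_programme(tiny_config, n_replicates=2, master_seed=9)
    assert set(raw.replicate) == {0, 1}
    row = summary[(summary.metric == "genetic_gain") & (summary.trait == "disease")]
    assert (row.n_replicates == 2).all()
    # SE equals SD/sqrt(n) recomputed from the raw table
    cell = raw[
        (raw.metric == "genetic_gain") & (raw.trait == "disease") & (raw.cycle == 2)
    ].value.to_numpy()
    expected_se = cell.std(ddof=1) / np.sqrt(2)
    got = summary[
        (summary.metric == "genetic_gain")
        & (summary.trait == "disease")
        & (summary.cycle == 2)
    ].se.iloc[0]
    assert got == pytest.approx(expected_se)
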