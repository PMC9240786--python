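"""The 8-cycle genomic-selection breeding programme.

Each cycle: 400 parents form 200 random bi-parental primary crosses (every
parent used once); the 150 crosses whose parents carry the most favourable
major-disease alleles spawn 90 top crosses and 60 backcrosses; every cross
yields 10 F1-type plants, each selfed to 2 F2 (7,000 F2); half the F2 are
selected (on GEBVs in genomic-selection cycles, at random in the phenotypic
cycles 1-3, where no genomic model exists yet); each selected F2 gives 10 F3
(35,000), advanced by single-seed descent to F5; 800 F5, equally represented
across the 350 families, enter Stage-1 trials phenotyped for both traits in
two environments; the top 400 on the selection index become the next cycle's
parents.  External lines are introgressed once, at the start of cycle 4, by
replacing the lowest-index parents with the external lines carrying the most
favourable major-disease alleles.

The marker-effect model is refreshed each cycle on a sliding window of the
last three cycles' 400 phenotyped parents; ranking the Stage-1 candidates
additionally uses their own phenotypes, while the reported prediction
accuracy follows the lagged protocol (effects estimated in the previous
cycle only).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace as dc_replace

import numpy as np
import pandas as pd
import yaml
from joblib import Parallel, delayed

from .architecture import (
    DISEASE,
    YIELD,
    TRAIT_NAMES,
    EffectCovariance,
    OverlapScheme,
    TraitArchitecture,
    build_architecture,
    scale_major,
    set_major_effect_size,
)
from .evaluation import genetic_gain, summarize_replicates, track_frequencies
from .founders import FounderConfig, FounderSet, generate_founders
from .genome import LocusMap
from .meiosis import MeiosisParams, cross, self_progeny, single_seed_descent
from .phenotypes import breeding_values, simulate_phenotypes, trait_values
from .population import Population
from .prediction import MarkerModel, fit_marker_effects, gebv, per_trait, prediction_accuracy
from .selection import IndexSpec, selection_index, truncation_select

__all__ = [
    "ProgrammeConfig",
    "default_config",
    "scaled_config",
    "trend_config",
    "plan_cohorts",
    "make_crosses",
    "introgress_parents",
    "run_cycle",
    "run_replicate",
    "run_programme",
    "config_from_yaml",
]


# ----------------------------------------------------------------------
@dataclass(frozen=True)
class ProgrammeConfig:
    """All knobs of one scenario run."""

    # genome / panel
    n_loci: int = 29_069
    n_chr: int = 7
    chrom_length: int = 655_000_000
    # cohort structure
    n_parents: int = 400
    n_primary: int = 200
    n_best_primary: int = 150
    n_backcross: int = 60
    n_topcross: int = 90
    n_progeny_per_cross: int = 10
    n_self_per_f1: int = 2
    n_f3_per_f2: int = 10
    n_ssd_generations: int = 2           # F3 -> F5
    n_stage1: int = 800
    # cycle plan
    n_cycles: int = 8
    phenotypic_cycles: int = 3
    introgression_cycle: int = 4
    introgression_pct: float = 0.20
    training_window: int = 3
    # scenario switches
    index: IndexSpec = field(default_factory=IndexSpec)
    major_effect_size: float | None = None
    topcross_ranks_first: bool = True    # best-ranked crosses feed the top crosses
    # components
    founder: FounderConfig = field(default_factory=FounderConfig)
    scheme: OverlapScheme = field(default_factory=OverlapScheme)
    meiosis: MeiosisParams = field(default_factory=lambda: MeiosisParams(mutation_rate=1e-5))
    h2: tuple[float, float] = (0.5, 0.25)
    n_major: int = 10
    major_target_frac: float = 0.10
    reference_external_frac: float = 0.20
    prediction_mode: str = "fast"

    def __post_init__(self) -> None:
        if 2 * self.n_primary != self.n_parents:
            raise ValueError("primary crosses must pair all parents exactly once")
        if self.n_backcross + self.n_topcross != self.n_best_primary:
            raise ValueError("backcrosses + top crosses must equal the best-primary count")
        if not 0.0 <= self.introgression_pct <= 1.0:
            raise ValueError("introgression percentage must lie in [0, 1]")
        if self.n_stage1 < self.n_parents:
            raise ValueError("Stage-1 cohort must be at least the parent count")


def default_config(**overrides) -> ProgrammeConfig:
    """The full-scale programme (400 parents, 29,069 loci)."""
    return ProgrammeConfig(**overrides)


def scaled_config(**overrides) -> ProgrammeConfig:
    """A structure-preserving desk-scale profile (1/10 cohort sizes).

    40 parents -> 20 primary + 6 back + 9 top crosses, 700 F2, 3,500 F3,
    80 Stage-1 lines, on a 1,500-locus panel with 501 QTL per trait per
    environment.  All selection fractions and per-plant multipliers match
    the full programme; the QTL count is kept at roughly half the full-scale
    architecture because the relative size of a major QTL against the
    polygenic background scales with the number of minor QTL, and shrinking
    it further would erase the majors' distinct character.
    """
    base = dict(
        n_loci=1500,
        n_parents=40,
        n_primary=20,
        n_best_primary=15,
        n_backcross=6,
        n_topcross=9,
        n_stage1=80,
        founder=FounderConfig(n_existing=185, n_external=10),
        scheme=OverlapScheme(n_per_trait_env=501),
    )
    base.update(overrides)
    return ProgrammeConfig(**base)


def trend_config(**overrides) -> ProgrammeConfig:
    """Desk-scale profile for introgression-percentage comparisons.

    Twice the :func:`scaled_config` cohort sizes (80 parents, 40 primary +
    12 back + 18 top crosses, 1,400 F2, 7,000 F3, 160 Stage-1) so that a 1%
    introgression still resolves to a single external line out of 80 parents
    rather than being rounded up to 2.5%.
    """
    base = dict(
        n_loci=1500,
        n_parents=80,
        n_primary=40,
        n_best_primary=30,
        n_backcross=12,
        n_topcross=18,
        n_stage1=160,
        founder=FounderConfig(n_existing=370, n_external=20),
        scheme=OverlapScheme(n_per_trait_env=501),
    )
    base.update(overrides)
    return ProgrammeConfig(**base)


def plan_cohorts(config: ProgrammeConfig) -> dict[str, int]:
    """Exact cohort sizes one cycle must produce (dry-run planner)."""
    crosses = config.n_primary + config.n_backcross + config.n_topcross
    f1 = crosses * config.n_progeny_per_cross
    f2 = f1 * config.n_self_per_f1
    f2_selected = f2 // 2
    f3 = f2_selected * config.n_f3_per_f2
    return {
        "crosses": crosses,
        "f1": f1,
        "f2": f2,
        "f2_selected": f2_selected,
        "f3": f3,
        "f5": f3,
        "stage1": config.n_stage1,
        "parents": config.n_parents,
    }


# ----------------------------------------------------------------------
def introgress_parents(
    parents: Population,
    parent_scores: np.ndarray,
    external: Population,
    pct: float,
    arch: TraitArchitecture,
) -> tuple[Population, np.ndarray]:
    """Replace the lowest-index parents with the best external lines.

    The ``ceil(pct * n_parents)`` external lines with the highest favourable
    major-disease allele counts displace the parents with the lowest
    selection-index scores.  Genotypes are untouched; only identities change.
    Returns the new pool and its score vector; the incoming external lines,
    having no performance records in the programme, enter below the retained
    parents (ordered among themselves by major allele count), so top crosses
    pair major-rich F1s with elite third parents rather than re-using the
    donors.
    """
    n_replace = math.ceil(pct * parents.n)
    if n_replace == 0:
        return parents, parent_scores
    if n_replace > external.n:
        raise ValueError(
            f"introgression needs {n_replace} external lines, only {external.n} available"
        )
    ext_counts = external.fav_counts(arch)[:, arch.major].sum(axis=1)
    best_ext = np.sort(np.lexsort((external.ids, -ext_counts))[:n_replace])
    keep = np.sort(np.argsort(parent_scores, kind="stable")[n_replace:])
    kept_scores = parent_scores[keep]
    base = float(kept_scores.min()) if kept_scores.size else 0.0
    ext_scores = base - 1e-3 * (1.0 + ext_counts[best_ext].max() - ext_counts[best_ext])
    pool = Population.concatenate(
        [parents.subset(keep), external.subset(best_ext)],
        generation=parents.generation,
    )
    return pool, np.concatenate([kept_scores, ext_scores])


# ----------------------------------------------------------------------
def make_crosses(
    parents: Population,
    parent_scores: np.ndarray,
    arch: TraitArchitecture,
    config: ProgrammeConfig,
    locus_map: LocusMap,
    rng: np.random.Generator,
) -> Population:
    """Primary, back and top crosses for one cycle -> all F1-type plants.

    Parents are paired at random into ``n_primary`` disjoint bi-parental
    crosses.  The ``n_best_primary`` crosses ranked by the parents' summed
    major favourable-allele counts spawn the top crosses (best ranks) and
    backcrosses (next ranks); the backcross recurrent parent is the cross
    parent with more major favourable alleles, the top-cross third parent is
    the highest-index parent outside the cross.  Family ids 0..n_crosses-1.
    """
    if parents.n != config.n_parents:
        raise ValueError(f"expected {config.n_parents} parents, got {parents.n}")
    perm = rng.permutation(parents.n)
    mothers, fathers = perm[::2], perm[1::2]
    n_prog = config.n_progeny_per_cross
    f1_primary = cross(
        parents, mothers, fathers, n_prog, locus_map, config.meiosis, rng,
        generation="F1", family=np.arange(config.n_primary), id_start=0,
    )
    major_counts = parents.fav_counts(arch)[:, arch.major].sum(axis=1)
    cross_score = major_counts[mothers] + major_counts[fathers]
    rank = np.lexsort((np.arange(config.n_primary), -cross_score))
    best = rank[: config.n_best_primary]
    if config.topcross_ranks_first:
        top_ids = best[: config.n_topcross]
        back_ids = best[config.n_topcross :]
    else:
        back_ids = best[: config.n_backcross]
        top_ids = best[config.n_backcross :]

    # one F1 per chosen cross acts as the BC/TC parent (its first progeny)
    f1_rep = {c: c * n_prog for c in range(config.n_primary)}
    combined = Population.concatenate([parents, _renumber(f1_primary, parents.ids.max() + 1)])
    n_par = parents.n

    # backcross: F1 x the cross parent with more major favourable alleles
    bc_mothers = np.array([n_par + f1_rep[c] for c in back_ids])
    bc_fathers = np.array(
        [
            mothers[c] if major_counts[mothers[c]] >= major_counts[fathers[c]] else fathers[c]
            for c in back_ids
        ]
    )
    # top cross: F1 x highest-index parent not in the cross
    score_order = np.argsort(-parent_scores, kind="stable")
    tc_mothers = np.array([n_par + f1_rep[c] for c in top_ids])
    tc_fathers = np.empty(len(top_ids), dtype=np.int64)
    for i, c in enumerate(top_ids):
        for cand in score_order:
            if cand != mothers[c] and cand != fathers[c]:
                tc_fathers[i] = cand
                break
    next_id = int(combined.ids.max()) + 1
    fam_bc = np.arange(config.n_primary, config.n_primary + config.n_backcross)
    fam_tc = np.arange(
        config.n_primary + config.n_backcross,
        config.n_primary + config.n_backcross + config.n_topcross,
    )
    bc = cross(
        combined, bc_mothers, bc_fathers, n_prog, locus_map, config.meiosis, rng,
        generation="BC1F1", family=fam_bc, id_start=next_id,
    )
    tc = cross(
        combined, tc_mothers, tc_fathers, n_prog, locus_map, config.meiosis, rng,
        generation="TC1F1", family=fam_tc, id_start=next_id + bc.n,
    )
    out = Population.concatenate([f1_primary, bc, tc], generation="F1")
    return out


def _renumber(pop: Population, start: int) -> Population:
    out = pop.subset(np.arange(pop.n))
    out.ids = np.arange(start, start + pop.n, dtype=np.int64)
    return out


# ----------------------------------------------------------------------
@dataclass
class ProgrammeState:
    """Mutable state carried between cycles of one replicate."""

    parents: Population
    parent_scores: np.ndarray
    base_mean: np.ndarray
    base_sd: np.ndarray
    training: list = field(default_factory=list)   # [(dosage, phenotypes, ids)]
    model: MarkerModel | None = None               # lagged model (previous cycles only)
    cycle: int = 0


def _index_scores(
    config: ProgrammeConfig,
    u_cols: np.ndarray,
    pop: Population,
    arch: TraitArchitecture,
) -> np.ndarray:
    """Selection index from trait-env score columns (GEBVs or phenotypes)."""
    u = per_trait(u_cols)
    counts = None
    if config.index.k > 0:
        counts = pop.fav_counts(arch)[:, arch.major].sum(axis=1)
    return selection_index(u[:, DISEASE], u[:, YIELD], config.index, counts)


def run_cycle(
    state: ProgrammeState,
    config: ProgrammeConfig,
    arch: TraitArchitecture,
    locus_map: LocusMap,
    external: Population,
    rng: np.random.Generator,
) -> tuple[ProgrammeState, list[dict]]:
    """Advance the programme one cycle; returns new state and metric rows."""
    cycle = state.cycle + 1
    plan = plan_cohorts(config)
    records: list[dict] = []
    is_gs = cycle > config.phenotypic_cycles

    parents, parent_scores = state.parents, state.parent_scores
    if cycle == config.introgression_cycle and config.introgression_pct > 0:
        parents, parent_scores = introgress_parents(
            parents, parent_scores, external, config.introgression_pct, arch
        )
        tv = trait_values(parents, arch)
        gains = genetic_gain(tv, state.base_mean, state.base_sd)
        for t, name in enumerate(TRAIT_NAMES):
            records.append(
                {"cycle": cycle, "metric": "genetic_gain_intr", "trait": name, "value": gains[t]}
            )
        for metric, value in track_frequencies(parents, arch).items():
            records.append({"cycle": cycle, "metric": metric + "_intr", "trait": "", "value": value})

    # crossing block -> F1-type plants -> F2
    f1 = make_crosses(parents, parent_scores, arch, config, locus_map, rng)
    if f1.n != plan["f1"]:
        raise RuntimeError(f"cohort mismatch: F1 {f1.n} != planned {plan['f1']}")
    f2 = self_progeny(
        f1, np.arange(f1.n), config.n_self_per_f1, locus_map, config.meiosis, rng,
        generation="F2",
    )
    if f2.n != plan["f2"]:
        raise RuntimeError(f"cohort mismatch: F2 {f2.n} != planned {plan['f2']}")

    # F2 selection: GEBVs in GS cycles, random in phenotypic cycles
    if is_gs and state.model is not None:
        u = gebv(f2.allele_counts(), state.model)
        scores = _index_scores(config, u, f2, arch)
    else:
        scores = rng.random(f2.n)
    keep = truncation_select(scores, plan["f2_selected"])
    f2_sel = f2.subset(keep)

    f3 = self_progeny(
        f2_sel, np.arange(f2_sel.n), config.n_f3_per_f2, locus_map, config.meiosis, rng,
        generation="F3",
    )
    if f3.n != plan["f3"]:
        raise RuntimeError(f"cohort mismatch: F3 {f3.n} != planned {plan['f3']}")
    f5 = single_seed_descent(
        f3, config.n_ssd_generations, locus_map, config.meiosis, rng, generation="F5"
    )

    # F5 -> Stage 1, equally represented across families
    if is_gs and state.model is not None:
        u = gebv(f5.allele_counts(), state.model)
        scores = _index_scores(config, u, f5, arch)
    else:
        scores = rng.random(f5.n)
    keep = truncation_select(scores, plan["stage1"], family_ids=f5.family, balance="equal")
    stage1 = f5.subset(keep, generation="Stage1")

    # Stage-1 trials: phenotype both traits in both environments
    g = breeding_values(stage1, arch)
    y = simulate_phenotypes(g, config.h2, rng)
    dosage = stage1.allele_counts()

    # lagged prediction accuracy on the Stage-1 candidates
    if is_gs and state.model is not None:
        u_lag = per_trait(gebv(dosage, state.model))
        g_trait = per_trait(g)
        for t, name in enumerate(TRAIT_NAMES):
            records.append(
                {
                    "cycle": cycle,
                    "metric": "accuracy",
                    "trait": name,
                    "value": prediction_accuracy(u_lag[:, t], g_trait[:, t]),
                }
            )

    # parent selection on the index; the ranking model includes own phenotypes
    if is_gs:
        window = state.training[-(config.training_window - 1):] if config.training_window > 1 else []
        geno_tr = np.concatenate([w[0] for w in window] + [dosage])
        phen_tr = np.concatenate([w[1] for w in window] + [y])
        h2_cols = np.repeat(config.h2, 2)
        ranking_model = fit_marker_effects(
            geno_tr, phen_tr, h2_cols, mode=config.prediction_mode, rng=rng, cycle=cycle
        )
        u_rank = gebv(dosage, ranking_model)
        scores = _index_scores(config, u_rank, stage1, arch)
    else:
        scores = _index_scores(config, y, stage1, arch)
    keep = truncation_select(scores, config.n_parents)
    new_parents = stage1.subset(keep, generation="parent")
    new_scores = scores[keep]

    # training window and lagged model for the next cycle
    training = state.training + [(dosage[keep], y[keep], stage1.ids[keep])]
    training = training[-config.training_window :]
    model = state.model
    if cycle + 1 > config.phenotypic_cycles:
        geno_tr = np.concatenate([w[0] for w in training])
        phen_tr = np.concatenate([w[1] for w in training])
        model = fit_marker_effects(
            geno_tr,
            phen_tr,
            np.repeat(config.h2, 2),
            mode=config.prediction_mode,
            rng=rng,
            cycle=cycle,
            training_ids=np.concatenate([w[2] for w in training]),
        )

    tv = trait_values(new_parents, arch)
    gains = genetic_gain(tv, state.base_mean, state.base_sd)
    for t, name in enumerate(TRAIT_NAMES):
        records.append(
            {"cycle": cycle, "metric": "genetic_gain", "trait": name, "value": gains[t]}
        )
    for metric, value in track_frequencies(new_parents, arch).items():
        records.append({"cycle": cycle, "metric": metric, "trait": "", "value": value})

    new_state = ProgrammeState(
        parents=new_parents,
        parent_scores=new_scores,
        base_mean=state.base_mean,
        base_sd=state.base_sd,
        training=training,
        model=model,
        cycle=cycle,
    )
    return new_state, records


# ----------------------------------------------------------------------
def setup_replicate(
    config: ProgrammeConfig, rng: np.random.Generator
) -> tuple[LocusMap, TraitArchitecture, FounderSet, ProgrammeState]:
    """Fresh genome, architecture, founders and initial parents."""
    locus_map = LocusMap.regular(config.n_loci, config.n_chr, config.chrom_length, rng)
    arch = build_architecture(config.scheme, locus_map, rng, n_major=config.n_major)
    founders = generate_founders(config.founder, locus_map, arch, rng)

    # reference pool for major-QTL scaling: parents with 20% external lines
    n_ext_ref = int(round(config.reference_external_frac * config.n_parents))
    ext_counts = founders.external.fav_counts(arch)[:, arch.major].sum(axis=1)
    best_ext = np.lexsort((founders.external.ids, -ext_counts))[:n_ext_ref]
    exist_idx = rng.choice(founders.existing.n, size=config.n_parents - n_ext_ref, replace=False)
    reference = Population.concatenate(
        [founders.existing.subset(np.sort(exist_idx)), founders.external.subset(np.sort(best_ext))]
    )
    arch, _ = scale_major(arch, reference.fav_counts(arch), config.major_target_frac)
    if config.major_effect_size is not None:
        arch = set_major_effect_size(arch, config.major_effect_size)

    par_idx = rng.choice(founders.existing.n, size=config.n_parents, replace=False)
    parents = founders.existing.subset(np.sort(par_idx), generation="parent")
    tv = trait_values(parents, arch)
    state = ProgrammeState(
        parents=parents,
        parent_scores=rng.random(parents.n),  # cycle-1 parents carry no records
        base_mean=tv.mean(axis=0),
        base_sd=tv.std(axis=0),
    )
    return locus_map, arch, founders, state


def run_replicate(config: ProgrammeConfig, seed) -> pd.DataFrame:
    """One replicate: fresh founders and architecture, all cycles."""
    rng = np.random.default_rng(seed)
    locus_map, arch, founders, state = setup_replicate(config, rng)
    rows: list[dict] = []
    for _ in range(config.n_cycles):
        state, records = run_cycle(state, config, arch, locus_map, founders.external, rng)
        rows.extend(records)
    return pd.DataFrame(rows)


def replicate_seed(master_seed: int, replicate: int) -> np.random.SeedSequence:
    """Replicate-specific seed, independent of the scenario being run.

    Keeping the seed a function of (master seed, replicate) only lets
    scenarios share common random numbers: within a replicate, founders,
    architecture and all meiosis draws coincide until the scenarios diverge.
    """
    return np.random.SeedSequence([int(master_seed), int(replicate)])


def run_programme(
    config: ProgrammeConfig,
    n_replicates: int = 50,
    master_seed: int = 0,
    n_jobs: int = 1,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run replicates and aggregate: returns (raw long table, summary)."""
    if n_replicates < 1:
        raise ValueError("need at least one replicate")
    tables = Parallel(n_jobs=n_jobs)(
        delayed(run_replicate)(config, replicate_seed(master_seed, r))
        for r in range(n_replicates)
    )
    frames = []
    for r, tab in enumerate(tables):
        tab = tab.copy()
        tab.insert(0, "replicate", r)
        frames.append(tab)
    raw = pd.concat(frames, ignore_index=True)
    return raw, summarize_replicates(raw)


# ----------------------------------------------------------------------
def config_from_yaml(path) -> ProgrammeConfig:
    """Build a ProgrammeConfig from a YAML scenario file.

    Top-level keys map to ProgrammeConfig fields; the nested blocks
    ``founder``, ``scheme``, ``index`` and ``meiosis`` map to their
    dataclasses.  A top-level ``scale: scaled`` selects the desk-scale
    profile as the base.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    base = scaled_config if raw.pop("scale", "full") == "scaled" else default_config
    nested = {
        "founder": FounderConfig,
        "scheme": OverlapScheme,
        "index": IndexSpec,
        "meiosis": MeiosisParams,
    }
    kwargs = {}
    for key, val in raw.items():
        if key in nested:
            if isinstance(val, dict):
                tup = {k: tuple(v) if isinstance(v, list) else v for k, v in val.items()}
                kwargs[key] = nested[key](**tup)
            else:
                raise ValueError(f"{key} block must be a mapping")
        elif key == "h2":
            kwargs[key] = tuple(val)
        else:
            kwargs[key] = val
    cfg = base()
    for key in kwargs:
        if not hasattr(cfg, key):
            raise ValueError(f"unknown configuration key {key!r}")
    return dc_replace(base(), **kwargs)
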