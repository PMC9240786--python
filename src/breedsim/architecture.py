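"""Multi-trait, multi-environment QTL architecture.

Two traits (disease resistance, grain yield) are each controlled by ~1,000
QTL per environment.  QTL may be shared between the two environments of a
trait (overlap rate ``q``) but, with trait-overlap ``p = 0``, never between
traits.  Effects for the four trait-environment combinations are drawn with
a target genetic correlation between environments (0.8 for disease, 0.4 for
yield) by multiplying an i.i.d. standard-normal matrix by the Cholesky
factor of the effect covariance, then masking with the 0/1 design matrix of
trait-environment memberships.  The ten largest disease QTL are designated
"major", rescaled so that they explain a target fraction (10%) of disease
genetic variance in a reference population containing 20% external lines,
and the whole disease-effect vector is standardised to unit SD.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np

from .genome import LocusMap

__all__ = [
    "OverlapScheme",
    "EffectCovariance",
    "TraitArchitecture",
    "assign_qtl",
    "sample_effects",
    "mask_effects",
    "designate_major",
    "scale_major",
    "orient_favourable",
]

DISEASE, YIELD = 0, 1
TRAIT_NAMES = ("disease", "yield")


# ----------------------------------------------------------------------
@dataclass(frozen=True)
class OverlapScheme:
    """QTL sharing pattern across traits and environments.

    ``n_per_trait_env`` QTL act on each trait in each environment; a QTL
    shared between both environments counts towards both.  ``q`` is the
    fraction of a trait's QTL (per environment) that are shared between the
    two environments; ``p`` is the analogous trait-overlap rate, zero here
    (no pleiotropy).
    """

    k_traits: int = 2
    w_envs: int = 2
    p: float = 0.0
    q: float = 0.7
    n_per_trait_env: int = 1001

    def __post_init__(self) -> None:
        if not (0.0 <= self.p <= 1.0 and 0.0 <= self.q <= 1.0):
            raise ValueError("overlap rates p, q must lie in [0, 1]")
        if self.n_per_trait_env < 1 or self.k_traits < 1 or self.w_envs < 1:
            raise ValueError("counts must be positive")
        if self.p != 0.0:
            raise NotImplementedError("pleiotropic architectures (p > 0) are not supported")
        if self.w_envs > 2:
            raise NotImplementedError("at most two environments are supported")

    def env_counts(self) -> tuple[int, int]:
        """(unique per environment, shared) QTL counts per trait.

        With ``s`` shared and ``u`` unique per environment, ``s + u`` equals
        the per-environment count ``N`` and the shared fraction of a trait's
        distinct QTL is ``s / (s + 2u) = q``; solving gives
        ``u = N (1 - q) / (1 + q)``, rounded to the nearest integer.
        For q = 0.7, N = 1,001 this yields u = 177, s = 824.
        """
        n = self.n_per_trait_env
        if self.w_envs == 1:
            return n, 0
        u = int(round(n * (1.0 - self.q) / (1.0 + self.q)))
        return u, n - u

    @property
    def n_distinct(self) -> int:
        """Total number of distinct QTL rows across all traits."""
        u, s = self.env_counts()
        per_trait = s + self.w_envs * u if self.w_envs == 2 else u
        return self.k_traits * per_trait


# ----------------------------------------------------------------------
@dataclass(frozen=True)
class EffectCovariance:
    """Covariance of QTL effects over the (trait, environment) columns.

    Column order is (disease-A, disease-B, yield-A, yield-B).  The default
    uses a between-environment genetic correlation of 0.8 for disease and
    0.4 for yield with zero cross-trait covariance.
    """

    matrix: np.ndarray = field(
        default_factory=lambda: np.array(
            [
                [1.0, 0.8, 0.0, 0.0],
                [0.8, 1.0, 0.0, 0.0],
                [0.0, 0.0, 1.0, 0.4],
                [0.0, 0.0, 0.4, 1.0],
            ]
        )
    )

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("covariance must be square")
        if not np.allclose(m, m.T):
            raise ValueError("covariance must be symmetric")
        eig = np.linalg.eigvalsh(m)
        if eig.min() < -1e-10:
            raise ValueError(
                f"covariance is not positive semi-definite (smallest eigenvalue {eig.min():.3g})"
            )
        object.__setattr__(self, "matrix", m)

    def cholesky_upper(self) -> np.ndarray:
        """Upper-triangular L with matrix = L'L (so v = u0 @ L)."""
        # Tiny jitter handles exactly-singular PSD inputs.
        m = self.matrix
        try:
            lower = np.linalg.cholesky(m)
        except np.linalg.LinAlgError:
            lower = np.linalg.cholesky(m + 1e-12 * np.eye(m.shape[0]))
        return lower.T


# ----------------------------------------------------------------------
@dataclass(frozen=True)
class TraitArchitecture:
    """QTL placement, effects, major set and favourable-allele orientation.

    ``effects`` are in raw allele-1 coding; ``orientation`` maps each QTL to
    its favourable allele (+1: allele 1, -1: allele 0).  ``fav_effects`` are
    the effects expressed on the favourable-allele count scale.
    """

    loci: np.ndarray                     # (n_qtl,) global locus indices
    design: np.ndarray                   # (n_qtl, 4) 0/1 design matrix X
    v: np.ndarray                        # (n_qtl, 4) correlated pre-mask effects
    effects: np.ndarray                  # (n_qtl, 4) a = X o v, raw coding
    trait_of: np.ndarray                 # (n_qtl,) trait index per QTL
    major: np.ndarray = field(default_factory=lambda: np.array([], dtype=np.int64))
    orientation: np.ndarray | None = None  # (n_qtl,) +1/-1
    scale_constant: float = 1.0

    @property
    def n_qtl(self) -> int:
        return int(self.loci.size)

    @property
    def fav_effects(self) -> np.ndarray:
        if self.orientation is None:
            raise ValueError("architecture has no favourable-allele orientation yet")
        return self.effects * self.orientation[:, None]

    def qtl_of_trait(self, trait: int) -> np.ndarray:
        """Row indices (into the QTL table) of the QTL acting on a trait."""
        return np.flatnonzero(self.trait_of == trait)

    @property
    def minor_disease(self) -> np.ndarray:
        """Disease QTL rows that are not in the major set."""
        d = self.qtl_of_trait(DISEASE)
        return np.setdiff1d(d, self.major)

    def trait_cols(self, trait: int) -> slice:
        return slice(2 * trait, 2 * trait + 2)

    # -- serialization --------------------------------------------------
    def to_json(self, path) -> None:
        payload = {
            "loci": self.loci.tolist(),
            "design": self.design.tolist(),
            "v": self.v.tolist(),
            "effects": self.effects.tolist(),
            "trait_of": self.trait_of.tolist(),
            "major": self.major.tolist(),
            "orientation": None if self.orientation is None else self.orientation.tolist(),
            "scale_constant": self.scale_constant,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "TraitArchitecture":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            loci=np.array(d["loci"], dtype=np.int64),
            design=np.array(d["design"], dtype=np.int8),
            v=np.array(d["v"], dtype=float),
            effects=np.array(d["effects"], dtype=float),
            trait_of=np.array(d["trait_of"], dtype=np.int64),
            major=np.array(d["major"], dtype=np.int64),
            orientation=None if d["orientation"] is None else np.array(d["orientation"], dtype=np.int64),
            scale_constant=float(d["scale_constant"]),
        )


# ----------------------------------------------------------------------
def assign_qtl(
    scheme: OverlapScheme,
    locus_map: LocusMap,
    rng: np.random.Generator,
) -> tuple[dict[str, int], np.ndarray, np.ndarray, np.ndarray]:
    """Place QTL on the panel and build the design matrix.

    Returns ``(counts, loci, X, trait_of)`` where ``counts`` records the
    per-trait unique/shared split, ``loci`` the sampled global locus
    indices (without replacement over the whole panel), ``X`` the 0/1
    design matrix over (trait, environment) columns and ``trait_of`` the
    trait index of each QTL row.
    """
    u, s = scheme.env_counts()
    per_trait = s + scheme.w_envs * u if scheme.w_envs == 2 else u
    total = scheme.k_traits * per_trait
    if total > locus_map.n_loci:
        raise ValueError(
            f"panel of {locus_map.n_loci} loci cannot host {total} distinct QTL"
        )
    loci = np.sort(rng.choice(locus_map.n_loci, size=total, replace=False))
    # randomise which sampled locus gets which role
    order = rng.permutation(total)
    n_cols = scheme.k_traits * scheme.w_envs
    design = np.zeros((total, n_cols), dtype=np.int8)
    trait_of = np.empty(total, dtype=np.int64)
    row = 0
    for t in range(scheme.k_traits):
        cols = [scheme.w_envs * t + e for e in range(scheme.w_envs)]
        if scheme.w_envs == 1:
            blocks = [(u, [cols[0]])]
        else:
            blocks = [(u, [cols[0]]), (u, [cols[1]]), (s, cols)]
        for count, active in blocks:
            design[np.ix_(order[row : row + count], active)] = 1
            trait_of[order[row : row + count]] = t
            row += count
    counts = {"unique_per_env": u, "shared": s, "per_trait": per_trait, "total": total}
    return counts, loci, design, trait_of


def sample_effects(
    cov: EffectCovariance, n_qtl: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw the correlated effect matrix v = u0 L with u0 ~ N(0, 1) i.i.d."""
    if n_qtl < 2:
        raise ValueError("need at least 2 QTL to sample effects")
    u0 = rng.standard_normal((n_qtl, cov.matrix.shape[0]))
    return u0 @ cov.cholesky_upper()


def mask_effects(v: np.ndarray, design: np.ndarray) -> np.ndarray:
    """Hadamard mask: a[i, j] = X[i, j] * v[i, j]."""
    v = np.asarray(v, dtype=float)
    if v.shape != design.shape:
        raise ValueError(f"shape mismatch: v {v.shape} vs design {design.shape}")
    return v * design


def orient_favourable(effects: np.ndarray, design: np.ndarray, trait_of: np.ndarray) -> np.ndarray:
    """Favourable allele per QTL: the allele raising its trait's merit.

    The orientation is the sign of the QTL's summed effect over its trait's
    environment columns (+1: allele 1 favourable, -1: allele 0).  Zero-effect
    loci default to allele 1.
    """
    n_envs = design.shape[1] // len(np.unique(trait_of)) if len(np.unique(trait_of)) else 2
    orient = np.ones(effects.shape[0], dtype=np.int64)
    for t in np.unique(trait_of):
        rows = trait_of == t
        cols = slice(2 * t, 2 * t + 2) if n_envs == 2 else slice(t, t + 1)
        total = effects[rows][:, cols].sum(axis=1)
        orient[rows] = np.where(total < 0, -1, 1)
    return orient


def designate_major(
    effects: np.ndarray, trait_of: np.ndarray, n_major: int = 10, trait: int = DISEASE
) -> np.ndarray:
    """Rows of the ``n_major`` disease QTL with the largest effects.

    Ranked by the mean absolute effect over the environments in which the
    QTL is active; ties broken by row (hence locus) order.
    """
    rows = np.flatnonzero(trait_of == trait)
    if rows.size < n_major:
        raise ValueError(f"only {rows.size} QTL for trait {trait}, need {n_major}")
    cols = slice(2 * trait, 2 * trait + 2)
    sub = np.abs(effects[rows][:, cols])
    active = sub > 0
    n_active = np.maximum(active.sum(axis=1), 1)
    score = sub.sum(axis=1) / n_active
    # stable sort on -score keeps row order among ties
    top = rows[np.argsort(-score, kind="stable")[:n_major]]
    return np.sort(top)


def _disease_components(
    arch: TraitArchitecture, fav_counts: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Environment-averaged disease TBV split into (major, minor) parts."""
    cols = arch.trait_cols(DISEASE)
    eff = arch.fav_effects[:, cols].mean(axis=1)
    d_rows = arch.qtl_of_trait(DISEASE)
    major = arch.major
    minor = np.setdiff1d(d_rows, major)
    g_major = fav_counts[:, major] @ eff[major]
    g_minor = fav_counts[:, minor] @ eff[minor]
    return g_major, g_minor


def genic_variance_fraction(arch: TraitArchitecture, fav_counts: np.ndarray) -> float:
    """Share of disease genic variance carried by the major QTL.

    Genic variance sums per-locus dosage variance times squared
    (environment-averaged) effect, the linkage-equilibrium variance
    decomposition; between-locus covariances (e.g. from population
    structure in a mixed pool) are deliberately excluded.
    """
    cols = arch.trait_cols(DISEASE)
    eff = arch.fav_effects[:, cols].mean(axis=1)
    d_rows = arch.qtl_of_trait(DISEASE)
    dose_var = fav_counts[:, d_rows].var(axis=0)
    contrib = dose_var * eff[d_rows] ** 2
    is_major = np.isin(d_rows, arch.major)
    total = float(contrib.sum())
    if total == 0:
        raise ValueError("no disease genic variance in the reference population")
    return float(contrib[is_major].sum() / total)


def scale_major(
    arch: TraitArchitecture,
    reference_fav_counts: np.ndarray,
    target_frac: float = 0.10,
) -> tuple[TraitArchitecture, float]:
    """Rescale the major disease QTL against a reference population.

    Finds the constant ``c`` such that, after multiplying the major-QTL
    disease effects by ``c``, the major loci carry ``target_frac`` of the
    disease genic variance (per-locus dosage variance times squared
    environment-averaged effect, summed over loci) in the reference
    population — the 400-line parent pool containing 20% external lines.
    The full disease-effect vector is then standardised so that its active
    (non-masked) entries have unit SD.

    Parameters
    ----------
    reference_fav_counts : (n_ref, n_qtl) array
        Favourable-allele counts (0/1/2) of the reference lines at the QTL.

    Returns
    -------
    (rescaled architecture, c)
    """
    if arch.orientation is None:
        raise ValueError("orient favourable alleles before scaling")
    cols = arch.trait_cols(DISEASE)
    eff = arch.fav_effects[:, cols].mean(axis=1)
    d_rows = arch.qtl_of_trait(DISEASE)
    dose_var = reference_fav_counts[:, d_rows].var(axis=0)
    contrib = dose_var * eff[d_rows] ** 2
    is_major = np.isin(d_rows, arch.major)
    var_major = float(contrib[is_major].sum())
    var_minor = float(contrib[~is_major].sum())
    if var_major <= 0:
        raise ValueError(
            "major QTL are monomorphic in the reference population; "
            "target variance fraction is unattainable"
        )
    t = target_frac
    # genic variance is additive over loci: c^2 A / (c^2 A + B) = t
    c = float(np.sqrt(t / (1.0 - t) * var_minor / var_major))
    effects = arch.effects.copy()
    d_cols = arch.trait_cols(DISEASE)
    effects[arch.major, d_cols] *= c
    # standardise all active disease effects to unit SD
    active = arch.design[:, d_cols] > 0
    sd = float(np.std(effects[:, d_cols][active]))
    effects[:, d_cols] /= sd
    return replace(arch, effects=effects, scale_constant=float(c)), float(c)


def set_major_effect_size(arch: TraitArchitecture, mean_size: float) -> TraitArchitecture:
    """Force the mean magnitude of active major disease effects to ``mean_size``.

    Used by the effect-size scenarios, where the mean major-QTL effect is a
    configured quantity (e.g. 3.21 vs 5.20) rather than an output of the
    variance-fraction scaling.
    """
    d_cols = arch.trait_cols(DISEASE)
    sub = arch.effects[arch.major, d_cols]
    active = arch.design[arch.major, d_cols] > 0
    cur = float(np.abs(sub[active]).mean())
    if cur == 0:
        raise ValueError("major effects are all zero")
    effects = arch.effects.copy()
    effects[arch.major, d_cols] *= mean_size / cur
    return replace(arch, effects=effects)


# ----------------------------------------------------------------------
def build_architecture(
    scheme: OverlapScheme,
    locus_map: LocusMap,
    rng: np.random.Generator,
    cov: EffectCovariance | None = None,
    n_major: int = 10,
) -> TraitArchitecture:
    """Assign QTL, sample and mask effects, orient and designate majors.

    Major-QTL rescaling is a separate step (:func:`scale_major`) because it
    needs a reference founder population.
    """
    cov = cov or EffectCovariance()
    _, loci, design, trait_of = assign_qtl(scheme, locus_map, rng)
    v = sample_effects(cov, loci.size, rng)
    effects = mask_effects(v, design)
    orientation = orient_favourable(effects, design, trait_of)
    major = designate_major(effects, trait_of, n_major=n_major)
    return TraitArchitecture(
        loci=loci,
        design=design,
        v=v,
        effects=effects,
        trait_of=trait_of,
        major=major,
        orientation=orientation,
    )
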