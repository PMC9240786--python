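"""True breeding values and simulated phenotypes.

TBV is purely additive: g = M a with M the favourable-allele dosage
(0/1/2) at the QTL and a the (rescaled) additive effects, one column per
trait-environment.  Phenotypes add an independent normal residual whose
variance is set from the trait's narrow-sense heritability,
Var(e) = (1 - h^2) / h^2 * sigma_a^2, so that the realized heritability on
the phenotyped cohort matches the target (disease 0.5, yield 0.25).
"""

from __future__ import annotations

import numpy as np

from .architecture import TraitArchitecture
from .population import Population

__all__ = ["breeding_values", "trait_values", "simulate_phenotypes", "DEFAULT_H2"]

#: narrow-sense heritability per trait (disease, yield)
DEFAULT_H2 = (0.5, 0.25)


def breeding_values(pop: Population, arch: TraitArchitecture) -> np.ndarray:
    """TBV matrix, one row per individual, one column per trait-environment."""
    m = pop.fav_counts(arch).astype(float)
    return m @ arch.fav_effects


def trait_values(pop: Population, arch: TraitArchitecture) -> np.ndarray:
    """Environment-averaged TBV per trait: (n, n_traits)."""
    g = breeding_values(pop, arch)
    n_traits = g.shape[1] // 2
    return g.reshape(g.shape[0], n_traits, 2).mean(axis=2)


def simulate_phenotypes(
    g: np.ndarray,
    h2: tuple[float, ...] = DEFAULT_H2,
    rng: np.random.Generator | None = None,
    sigma_a2: np.ndarray | None = None,
) -> np.ndarray:
    """Phenotypes y = g + e for each trait-environment column.

    ``h2`` gives one heritability per trait (each trait spans two adjacent
    columns of ``g``).  ``sigma_a2`` optionally fixes the additive variance
    per column; by default it is the realized TBV variance of this cohort,
    which keeps the realized heritability on target every cycle.
    """
    rng = np.random.default_rng(rng)
    g = np.asarray(g, dtype=float)
    n, n_cols = g.shape
    if n_cols != 2 * len(h2):
        raise ValueError(f"{n_cols} trait-env columns but {len(h2)} heritabilities")
    if any(not 0 < h <= 1 for h in h2):
        raise ValueError("heritabilities must lie in (0, 1]")
    if sigma_a2 is None:
        sigma_a2 = g.var(axis=0)
    sigma_a2 = np.asarray(sigma_a2, dtype=float)
    h2_cols = np.repeat(np.asarray(h2, dtype=float), 2)
    resid_sd = np.sqrt((1.0 - h2_cols) / h2_cols * sigma_a2)
    return g + rng.standard_normal(g.shape) * resid_sd[None, :]
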