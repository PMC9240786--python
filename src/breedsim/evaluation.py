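"""Programme evaluation metrics and replicate aggregation.

Genetic gain is the mean true breeding value of the lines selected as next-
cycle parents, centred on the starting population's mean and expressed in
units of the starting population's additive genetic SD (per trait, on the
environment-averaged TBV).  Allele-frequency trajectories are tracked as
the mean favourable-allele frequency of the three QTL groups (major
disease, minor disease, yield).  Replicate tables are long-format; the
summary reports mean and SE = SD / sqrt(n_replicates).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .architecture import DISEASE, YIELD, TRAIT_NAMES, TraitArchitecture
from .founders import realized_allele_freqs
from .phenotypes import trait_values
from .population import Population

__all__ = [
    "genetic_gain",
    "track_frequencies",
    "summarize_replicates",
]


def genetic_gain(
    selected_tbv: np.ndarray,
    base_mean: np.ndarray,
    base_sd: np.ndarray,
) -> np.ndarray:
    """Per-trait gain of a selected group, in base additive-SD units.

    ``selected_tbv`` is (n, n_traits) environment-averaged TBV;
    ``base_mean``/``base_sd`` are the starting population's per-trait TBV
    mean and SD, fixed at the beginning of cycle 1.
    """
    selected_tbv = np.atleast_2d(np.asarray(selected_tbv, dtype=float))
    if selected_tbv.shape[0] == 0:
        raise ValueError("empty selection")
    base_sd = np.asarray(base_sd, dtype=float)
    if np.any(base_sd <= 0):
        raise ValueError("base additive SD must be positive")
    return (selected_tbv.mean(axis=0) - np.asarray(base_mean, dtype=float)) / base_sd


def track_frequencies(pop: Population, arch: TraitArchitecture) -> dict[str, float]:
    """Mean favourable-allele frequency per QTL group in a cohort."""
    groups = {
        "freq_major": arch.major,
        "freq_minor": arch.minor_disease,
        "freq_yield": arch.qtl_of_trait(YIELD),
    }
    out = {}
    for name, rows in groups.items():
        _, mean = realized_allele_freqs(pop, arch.loci[rows], arch.orientation[rows])
        out[name] = mean
    return out


def summarize_replicates(results: pd.DataFrame) -> pd.DataFrame:
    """Mean and SE over replicates per (cycle, metric, trait) cell.

    SE is SD/sqrt(n); with a single replicate SE is reported as 0.
    """
    required = {"replicate", "cycle", "metric", "trait", "value"}
    missing = required - set(results.columns)
    if missing:
        raise ValueError(f"results table lacks columns: {sorted(missing)}")
    grouped = results.groupby(["cycle", "metric", "trait"], dropna=False)["value"]
    summary = grouped.agg(
        mean="mean",
        se=lambda v: 0.0 if len(v) < 2 else float(np.std(v, ddof=1) / np.sqrt(len(v))),
        n_replicates="size",
    ).reset_index()
    return summary
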