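"""Selection indices and truncation selection.

Candidates are ranked on a two-trait index
``I = wD uD / sd(uD) + wY uY / sd(uY) (+ k N)`` where u are GEBVs in
genomic-selection cycles or phenotypic values in phenotypic-selection
cycles, standardised by the candidate cohort's SDs, and N is optionally the
candidate's count of favourable alleles over the 10 major disease QTL
(marker-assisted term, k = 0.01 in the scenario that uses it).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["IndexSpec", "selection_index", "truncation_select"]


@dataclass(frozen=True)
class IndexSpec:
    """Index weights; ``k = 0`` disables the major-allele-count term."""

    w_disease: float = 0.5
    w_yield: float = 0.5
    k: float = 0.0

    def __post_init__(self) -> None:
        if self.w_disease < 0 or self.w_yield < 0:
            raise ValueError("index weights must be non-negative")
        if abs(self.w_disease + self.w_yield - 1.0) > 1e-9:
            raise ValueError("index weights must sum to 1")
        if self.k < 0:
            raise ValueError("k must be >= 0")


def selection_index(
    u_disease: np.ndarray,
    u_yield: np.ndarray,
    spec: IndexSpec,
    major_counts: np.ndarray | None = None,
) -> np.ndarray:
    """Per-candidate index, standardised by the cohort's own SDs."""
    ud = np.asarray(u_disease, dtype=float).ravel()
    uy = np.asarray(u_yield, dtype=float).ravel()
    if ud.size != uy.size:
        raise ValueError("trait score vectors differ in length")
    sd_d, sd_y = np.std(ud), np.std(uy)
    if (spec.w_disease > 0 and sd_d == 0) or (spec.w_yield > 0 and sd_y == 0):
        raise ValueError("zero SD in a weighted index component")
    index = np.zeros(ud.size)
    if spec.w_disease > 0:
        index += spec.w_disease * ud / sd_d
    if spec.w_yield > 0:
        index += spec.w_yield * uy / sd_y
    if spec.k > 0:
        if major_counts is None:
            raise ValueError("k > 0 requires major-QTL favourable-allele counts")
        index = index + spec.k * np.asarray(major_counts, dtype=float)
    return index


# ----------------------------------------------------------------------
def _ranked(scores: np.ndarray, ids: np.ndarray) -> np.ndarray:
    """Positions sorted by descending score, ties by ascending id."""
    return np.lexsort((ids, -scores))


def truncation_select(
    scores: np.ndarray,
    n_select: int,
    family_ids: np.ndarray | None = None,
    balance: str = "none",
    ids: np.ndarray | None = None,
) -> np.ndarray:
    """Select ``n_select`` candidates by score, optionally family-balanced.

    ``balance="none"`` takes the global top ``n_select`` (ties broken by
    id).  ``balance="equal"`` gives every family a base quota of
    ``n_select // n_families`` (filled by each family's best candidates) and
    awards the remaining slots one at a time to the family whose best
    unselected candidate scores highest; quotas a small family cannot fill
    are redistributed the same way.  Returns selected positions, sorted.
    """
    scores = np.asarray(scores, dtype=float).ravel()
    n = scores.size
    if not 0 <= n_select <= n:
        raise ValueError(f"cannot select {n_select} from {n} candidates")
    if ids is None:
        ids = np.arange(n)
    if balance == "none":
        return np.sort(_ranked(scores, ids)[:n_select])
    if balance != "equal":
        raise ValueError("balance must be 'none' or 'equal'")
    if family_ids is None:
        raise ValueError("family balancing needs family ids")
    family_ids = np.asarray(family_ids)
    families = np.unique(family_ids)
    base = n_select // families.size
    order = _ranked(scores, ids)
    by_family = {f: order[family_ids[order] == f] for f in families}
    taken = {f: min(base, by_family[f].size) for f in families}
    remaining = n_select - sum(taken.values())
    while remaining > 0:
        # one extra slot per family per round, to the families whose best
        # unselected candidate scores highest
        nexts = [
            (f, by_family[f][taken[f]])
            for f in families
            if taken[f] < by_family[f].size
        ]
        if not nexts:
            raise ValueError("not enough candidates to fill the selection")
        order_round = sorted(nexts, key=lambda fp: (-scores[fp[1]], ids[fp[1]]))
        for f, _ in order_round[: min(remaining, len(order_round))]:
            taken[f] += 1
        remaining -= min(remaining, len(order_round))
    selected = np.concatenate([by_family[f][: taken[f]] for f in families])
    return np.sort(selected)
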