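"""Meiosis, crossing, selfing and single-seed descent.

Gametes recombine with a Poisson(lambda) number of crossovers per
chromosome (default lambda = 1), placed uniformly on the physical (bp)
map with no interference, starting from a randomly chosen parental
haplotype per chromosome.  After recombination each locus mutates
(allele flip) independently with probability ``mutation_rate`` per
gamete (default 0.001).

All operations are vectorised over whole cohorts; the per-individual
wrappers exist for clarity and tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genome import LocusMap
from .population import Population

__all__ = [
    "MeiosisParams",
    "sample_gametes",
    "sample_gamete",
    "cross",
    "self_progeny",
    "single_seed_descent",
]


@dataclass(frozen=True)
class MeiosisParams:
    crossover_lambda: float = 1.0
    mutation_rate: float = 0.001

    def __post_init__(self) -> None:
        if self.crossover_lambda < 0:
            raise ValueError("crossover_lambda must be >= 0")
        if not 0.0 <= self.mutation_rate <= 1.0:
            raise ValueError("mutation_rate must lie in [0, 1]")


# ----------------------------------------------------------------------
def _recombine_chromosome(
    hap: np.ndarray,
    pos: np.ndarray,
    chrom_length: int,
    lam: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Recombined gametes for one chromosome; hap is (n, 2, Lc)."""
    n, _, n_loci = hap.shape
    start = rng.integers(0, 2, size=n, dtype=np.int8)
    counts = rng.poisson(lam, size=n)
    total = int(counts.sum())
    if total == 0 or n_loci == 0:
        source = np.broadcast_to(start[:, None], (n, n_loci))
    else:
        # crossover points, uniform on the physical map; a crossover before
        # locus j toggles the source haplotype of loci j..end
        xpos = rng.uniform(0.0, float(chrom_length), size=total)
        row = np.repeat(np.arange(n), counts)
        idx = np.searchsorted(pos, xpos)
        toggles = np.zeros((n, n_loci + 1), dtype=np.int8)
        np.add.at(toggles, (row, idx), 1)
        crossings = np.cumsum(toggles[:, :n_loci], axis=1, dtype=np.int8)
        source = (start[:, None] + crossings) & 1
    return np.where(source == 0, hap[:, 0, :], hap[:, 1, :])


def sample_gametes(
    haplotypes: np.ndarray,
    locus_map: LocusMap,
    params: MeiosisParams,
    rng: np.random.Generator,
    chunk_size: int = 8192,
) -> np.ndarray:
    """One gamete per input individual; returns (n, n_loci) alleles.

    Each row of ``haplotypes`` (shape (n, 2, n_loci)) is an independent
    meiosis.  To produce several gametes from one parent, repeat its row.
    Work is chunked to bound the crossover-counting workspace.
    """
    haplotypes = np.asarray(haplotypes, dtype=np.uint8)
    n, _, n_loci = haplotypes.shape
    if n_loci != locus_map.n_loci:
        raise ValueError("haplotype length does not match the locus map")
    out = np.empty((n, n_loci), dtype=np.uint8)
    for lo in range(0, n, chunk_size):
        hi = min(lo + chunk_size, n)
        for c in range(1, locus_map.n_chr + 1):
            sl = locus_map.chrom_slice(c)
            out[lo:hi, sl] = _recombine_chromosome(
                haplotypes[lo:hi, :, sl],
                locus_map.pos[sl].astype(float),
                int(locus_map.chrom_lengths[c - 1]),
                params.crossover_lambda,
                rng,
            )
        if params.mutation_rate > 0:
            out[lo:hi] ^= _mutation_flips(hi - lo, n_loci, params.mutation_rate, rng)
    return out


def _mutation_flips(n: int, n_loci: int, mu: float, rng: np.random.Generator) -> np.ndarray:
    """0/1 flip mask with per-cell probability ``mu``.

    For very low rates the mask is built sparsely from the binomial flip
    count (cell collisions are vanishingly rare and cancel by parity).
    """
    cells = n * n_loci
    if mu * cells > 1024 and mu > 1e-4:
        return (rng.random((n, n_loci)) < mu).astype(np.uint8)
    k = rng.binomial(cells, mu)
    mask = np.zeros(cells, dtype=np.uint8)
    if k:
        mask[rng.integers(0, cells, size=k)] ^= 1
    return mask.reshape(n, n_loci)


def sample_gamete(
    haplotypes: np.ndarray,
    locus_map: LocusMap,
    params: MeiosisParams,
    rng: np.random.Generator,
) -> np.ndarray:
    """Single gamete from one individual's (2, n_loci) haplotype pair."""
    return sample_gametes(haplotypes[None, ...], locus_map, params, rng)[0]


# ----------------------------------------------------------------------
def _progeny(
    pop: Population,
    mother_idx: np.ndarray,
    father_idx: np.ndarray,
    n_progeny: int,
    locus_map: LocusMap,
    params: MeiosisParams,
    rng: np.random.Generator,
    generation: str,
    family: np.ndarray | None,
    id_start: int,
) -> Population:
    mother_idx = np.atleast_1d(np.asarray(mother_idx, dtype=np.int64))
    father_idx = np.atleast_1d(np.asarray(father_idx, dtype=np.int64))
    if mother_idx.shape != father_idx.shape:
        raise ValueError("mother and father index vectors must match")
    if n_progeny < 1:
        raise ValueError("n_progeny must be >= 1")
    m_rep = np.repeat(mother_idx, n_progeny)
    f_rep = np.repeat(father_idx, n_progeny)
    maternal = sample_gametes(pop.haplotypes[m_rep], locus_map, params, rng)
    paternal = sample_gametes(pop.haplotypes[f_rep], locus_map, params, rng)
    hap = np.stack([maternal, paternal], axis=1)
    if family is None:
        fam = pop.family[m_rep]
    else:
        fam = np.repeat(np.asarray(family, dtype=np.int64), n_progeny)
    n_out = hap.shape[0]
    return Population(
        haplotypes=hap,
        ids=np.arange(id_start, id_start + n_out, dtype=np.int64),
        family=fam,
        generation=generation,
        parents=np.stack([pop.ids[m_rep], pop.ids[f_rep]], axis=1),
    )


def cross(
    pop: Population,
    mother_idx,
    father_idx,
    n_progeny: int,
    locus_map: LocusMap,
    params: MeiosisParams,
    rng: np.random.Generator,
    generation: str = "F1",
    family: np.ndarray | None = None,
    id_start: int = 0,
) -> Population:
    """Cross mother/father pairs, ``n_progeny`` offspring per pair.

    Index vectors select parents within ``pop``; progeny of pair ``i`` share
    a family id (``family[i]`` if given, else the mother's family).
    """
    return _progeny(
        pop, mother_idx, father_idx, n_progeny, locus_map, params, rng,
        generation, family, id_start,
    )


def self_progeny(
    pop: Population,
    idx,
    n_progeny: int,
    locus_map: LocusMap,
    params: MeiosisParams,
    rng: np.random.Generator,
    generation: str = "selfed",
    id_start: int = 0,
) -> Population:
    """Self each selected individual, ``n_progeny`` offspring each."""
    idx = np.atleast_1d(np.asarray(idx, dtype=np.int64))
    return _progeny(
        pop, idx, idx, n_progeny, locus_map, params, rng, generation, None, id_start
    )


def single_seed_descent(
    pop: Population,
    n_generations: int,
    locus_map: LocusMap,
    params: MeiosisParams,
    rng: np.random.Generator,
    generation: str | None = None,
) -> Population:
    """Advance every line by one selfed seed per generation.

    Population size and family labels are unchanged; heterozygosity halves
    per generation in expectation (mutation aside).
    """
    if n_generations < 0:
        raise ValueError("n_generations must be >= 0")
    out = pop
    for _ in range(n_generations):
        out = self_progeny(
            out, np.arange(out.n), 1, locus_map, params, rng,
            generation=generation or pop.generation,
        )
    if generation is not None:
        out.generation = generation
    return out
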