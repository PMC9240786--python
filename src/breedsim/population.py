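"""Cohorts of individuals carrying two haplotypes over the locus map."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .architecture import TraitArchitecture

__all__ = ["Population"]


@dataclass
class Population:
    """A cohort: ``haplotypes`` has shape (n, 2, n_loci) with alleles 0/1.

    ``family`` labels the original cross an individual descends from and is
    stable through selfing and single-seed descent; ``parents`` holds the
    two parent ids of each individual (-1 for founders).
    """

    haplotypes: np.ndarray
    ids: np.ndarray = None
    family: np.ndarray = None
    generation: str = "founder"
    parents: np.ndarray = None

    def __post_init__(self) -> None:
        self.haplotypes = np.ascontiguousarray(self.haplotypes, dtype=np.uint8)
        if self.haplotypes.ndim != 3 or self.haplotypes.shape[1] != 2:
            raise ValueError("haplotypes must have shape (n, 2, n_loci)")
        n = self.haplotypes.shape[0]
        if self.ids is None:
            self.ids = np.arange(n, dtype=np.int64)
        if self.family is None:
            self.family = np.arange(n, dtype=np.int64)
        if self.parents is None:
            self.parents = np.full((n, 2), -1, dtype=np.int64)
        self.ids = np.asarray(self.ids, dtype=np.int64)
        self.family = np.asarray(self.family, dtype=np.int64)
        self.parents = np.asarray(self.parents, dtype=np.int64)
        if not (self.ids.size == self.family.size == n == self.parents.shape[0]):
            raise ValueError("metadata length mismatch")

    # ------------------------------------------------------------------
    @property
    def n(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_loci(self) -> int:
        return self.haplotypes.shape[2]

    def allele_counts(self, loci: np.ndarray | slice = slice(None)) -> np.ndarray:
        """Allele-1 dosage (0/1/2) per individual at the requested loci."""
        return self.haplotypes[:, 0, loci].astype(np.int16) + self.haplotypes[:, 1, loci]

    def fav_counts(self, arch: TraitArchitecture) -> np.ndarray:
        """Favourable-allele dosage (0/1/2) at every QTL of the architecture."""
        if arch.orientation is None:
            raise ValueError("architecture has no favourable orientation")
        raw = self.allele_counts(arch.loci)
        return np.where(arch.orientation[None, :] == 1, raw, 2 - raw)

    def is_homozygous(self) -> np.ndarray:
        """Per-individual flag: both haplotypes identical at every locus."""
        return np.all(self.haplotypes[:, 0] == self.haplotypes[:, 1], axis=1)

    def heterozygosity(self) -> float:
        """Mean per-locus heterozygote fraction over the cohort."""
        return float(np.mean(self.haplotypes[:, 0] != self.haplotypes[:, 1]))

    def subset(self, idx: np.ndarray, generation: str | None = None) -> "Population":
        return Population(
            haplotypes=self.haplotypes[idx],
            ids=self.ids[idx],
            family=self.family[idx],
            generation=generation or self.generation,
            parents=self.parents[idx],
        )

    @staticmethod
    def concatenate(pops: list["Population"], generation: str | None = None) -> "Population":
        if not pops:
            raise ValueError("nothing to concatenate")
        return Population(
            haplotypes=np.concatenate([p.haplotypes for p in pops]),
            ids=np.concatenate([p.ids for p in pops]),
            family=np.concatenate([p.family for p in pops]),
            generation=generation or pops[0].generation,
            parents=np.concatenate([p.parents for p in pops]),
        )
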