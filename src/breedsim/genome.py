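"""Locus map: physical positions of the SNP panel on chromosomes.

The simulated genome mirrors a barley-like panel: a few (default 7)
chromosomes of roughly equal physical length carrying a dense set of
biallelic SNP loci.  All downstream machinery (meiosis, QTL placement,
VCF output) addresses loci through a single globally ordered index,
sorted by chromosome then position.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["LocusMap"]


@dataclass(frozen=True)
class LocusMap:
    """Positions of all loci, ordered by chromosome then bp position.

    Parameters
    ----------
    chrom : (n_loci,) int array
        Chromosome id of each locus, 1-based, non-decreasing.
    pos : (n_loci,) int array
        Physical position in bp, strictly increasing within a chromosome.
    chrom_lengths : (n_chr,) int array
        Physical length of each chromosome in bp.
    """

    chrom: np.ndarray
    pos: np.ndarray
    chrom_lengths: np.ndarray
    _offsets: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        chrom = np.asarray(self.chrom, dtype=np.int64)
        pos = np.asarray(self.pos, dtype=np.int64)
        lengths = np.asarray(self.chrom_lengths, dtype=np.int64)
        if chrom.shape != pos.shape or chrom.ndim != 1:
            raise ValueError("chrom and pos must be 1-D arrays of equal length")
        if lengths.ndim != 1 or lengths.size < 1:
            raise ValueError("need at least one chromosome")
        if np.any(np.diff(chrom) < 0):
            raise ValueError("loci must be sorted by chromosome")
        if chrom.size and (chrom.min() < 1 or chrom.max() > lengths.size):
            raise ValueError("chromosome ids must lie in 1..n_chr")
        for c in range(1, lengths.size + 1):
            p = pos[chrom == c]
            if p.size and np.any(np.diff(p) <= 0):
                raise ValueError(f"positions not strictly increasing on chromosome {c}")
            if p.size and (p.min() < 0 or p.max() > lengths[c - 1]):
                raise ValueError(f"position outside chromosome {c} length")
        object.__setattr__(self, "chrom", chrom)
        object.__setattr__(self, "pos", pos)
        object.__setattr__(self, "chrom_lengths", lengths)
        # start index of each chromosome's locus block, plus terminal sentinel
        counts = np.bincount(chrom, minlength=lengths.size + 1)[1:]
        object.__setattr__(self, "_offsets", np.concatenate([[0], np.cumsum(counts)]))

    # ------------------------------------------------------------------
    @property
    def n_loci(self) -> int:
        return int(self.chrom.size)

    @property
    def n_chr(self) -> int:
        return int(self.chrom_lengths.size)

    def chrom_slice(self, c: int) -> slice:
        """Global-index slice of the loci on chromosome ``c`` (1-based)."""
        if not 1 <= c <= self.n_chr:
            raise ValueError(f"no chromosome {c}")
        return slice(int(self._offsets[c - 1]), int(self._offsets[c]))

    # ------------------------------------------------------------------
    @classmethod
    def regular(
        cls,
        n_loci: int,
        n_chr: int = 7,
        chrom_lengths: np.ndarray | int | None = None,
        rng: np.random.Generator | None = None,
    ) -> "LocusMap":
        """Build a map with loci spread uniformly at random over chromosomes.

        Loci are split as evenly as possible across chromosomes (the
        remainder goes to the first chromosomes) and positions are drawn
        uniformly along each chromosome, then sorted and de-duplicated by
        nudging.  Default chromosome length is 655 Mb.
        """
        if n_chr < 1:
            raise ValueError("n_chr must be >= 1")
        if chrom_lengths is None:
            chrom_lengths = np.full(n_chr, 655_000_000, dtype=np.int64)
        elif np.isscalar(chrom_lengths):
            chrom_lengths = np.full(n_chr, int(chrom_lengths), dtype=np.int64)
        else:
            chrom_lengths = np.asarray(chrom_lengths, dtype=np.int64)
            if chrom_lengths.size != n_chr:
                raise ValueError("chrom_lengths size must equal n_chr")
        rng = np.random.default_rng(rng)
        base, extra = divmod(n_loci, n_chr)
        per_chr = [base + (1 if i < extra else 0) for i in range(n_chr)]
        if sum(per_chr) != n_loci:
            raise ValueError("per-chromosome locus counts do not sum to n_loci")
        chroms, positions = [], []
        for c, (k, L) in enumerate(zip(per_chr, chrom_lengths), start=1):
            p = np.sort(rng.choice(L, size=k, replace=False)) + 1 if k else np.array([], dtype=np.int64)
            chroms.append(np.full(k, c, dtype=np.int64))
            positions.append(p.astype(np.int64))
        return cls(np.concatenate(chroms), np.concatenate(positions), chrom_lengths)

    # ------------------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"chrom": self.chrom, "pos": self.pos, "locus_id": np.arange(self.n_loci)}
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, chrom_lengths: np.ndarray) -> "LocusMap":
        df = df.sort_values(["chrom", "pos"]).reset_index(drop=True)
        return cls(df["chrom"].to_numpy(), df["pos"].to_numpy(), chrom_lengths)
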