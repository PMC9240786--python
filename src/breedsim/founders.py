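"""Synthetic founder genotypes for the existing and external populations.

The study's founders are ~1,950 fully homozygous (inbred) barley lines
genotyped at 29,069 biallelic SNPs on 7 chromosomes, split into an
"existing" breeding population and a smaller "external" germplasm source
with strongly divergent allele frequencies at the disease QTL: the
favourable alleles of the 10 major disease QTL are absent from the existing
population but segregate at ~0.65 in the external one, while minor disease
QTL sit at a scenario-dependent mean frequency (0.85 / 0.52 / 0.27) in the
existing population.  This module generates such founders directly from
per-locus target frequencies; every line is drawn independently per locus
(linkage disequilibrium in the founders is not modelled — linkage builds up
through simulated meiosis).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .architecture import DISEASE, YIELD, TraitArchitecture
from .genome import LocusMap
from .population import Population

__all__ = [
    "FounderConfig",
    "FounderSet",
    "generate_founders",
    "realized_allele_freqs",
    "write_founders",
    "read_founders",
]


@dataclass(frozen=True)
class FounderConfig:
    """Target frequency structure of the two founder populations.

    Frequencies are of the *favourable* allele at QTL and of allele 1 at
    neutral markers.  ``minor_freq_mean`` selects the scenario level (high
    0.85, medium 0.52, low 0.27); the per-locus targets are spread uniformly
    within ``minor_halfwidth`` of the mean.  External minor-QTL frequencies
    sit below the existing ones by a per-locus offset drawn from
    ``minor_diff_range``.  ``yield_mode`` chooses between reading the yield
    band as per-population frequencies ("band") or as a between-population
    difference ("difference").
    """

    n_existing: int = 1850
    n_external: int = 100
    minor_freq_mean: float = 0.85
    minor_halfwidth: float = 0.10
    major_freq_existing: float = 0.0
    major_freq_external: float = 0.65
    minor_diff_range: tuple[float, float] = (0.03, 0.19)
    minor_lower_prob: float = 0.55
    yield_band: tuple[float, float] = (0.05, 0.13)
    yield_mode: str = "difference"
    yield_existing_range: tuple[float, float] = (0.2, 0.8)
    yield_lower_prob: float = 0.7
    neutral_range: tuple[float, float] = (0.05, 0.95)

    def __post_init__(self) -> None:
        for f in (self.minor_freq_mean, self.major_freq_existing, self.major_freq_external):
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"frequency target {f} outside [0, 1]")
        if self.n_existing < 2 or self.n_external < 2:
            raise ValueError("each founder population needs at least 2 lines")
        if self.yield_mode not in ("band", "difference"):
            raise ValueError("yield_mode must be 'band' or 'difference'")


@dataclass
class FounderSet:
    """Two homozygous founder populations over a shared locus map."""

    existing: Population
    external: Population
    locus_map: LocusMap
    targets: dict = field(default_factory=dict)  # per-population allele-1 targets

    def population(self, label: str) -> Population:
        if label == "existing":
            return self.existing
        if label == "external":
            return self.external
        raise KeyError(label)


# ----------------------------------------------------------------------
def _favourable_targets(
    cfg: FounderConfig, n_loci: int, arch: TraitArchitecture | None, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Per-locus allele-1 frequency targets for (existing, external)."""
    lo, hi = cfg.neutral_range
    f_exist = rng.uniform(lo, hi, size=n_loci)
    f_exter = rng.uniform(lo, hi, size=n_loci)
    if arch is None:
        return f_exist, f_exter

    fav_exist = np.full(arch.n_qtl, np.nan)
    fav_exter = np.full(arch.n_qtl, np.nan)

    d_rows = arch.qtl_of_trait(DISEASE)
    minor = np.setdiff1d(d_rows, arch.major)
    me = np.clip(
        rng.uniform(
            cfg.minor_freq_mean - cfg.minor_halfwidth,
            cfg.minor_freq_mean + cfg.minor_halfwidth,
            size=minor.size,
        ),
        0.02,
        0.98,
    )
    fav_exist[minor] = me
    # per-locus difference magnitude in the stated band; the external
    # population sits below the existing one at most loci, above at some
    delta = rng.uniform(*cfg.minor_diff_range, size=minor.size)
    sign = np.where(rng.random(minor.size) < cfg.minor_lower_prob, 1.0, -1.0)
    fav_exter[minor] = np.clip(me - sign * delta, 0.01, 0.98)

    fav_exist[arch.major] = cfg.major_freq_existing
    fav_exter[arch.major] = cfg.major_freq_external

    y_rows = arch.qtl_of_trait(YIELD)
    if cfg.yield_mode == "band":
        fav_exist[y_rows] = rng.uniform(*cfg.yield_band, size=y_rows.size)
        fav_exter[y_rows] = rng.uniform(*cfg.yield_band, size=y_rows.size)
    else:
        ye = rng.uniform(*cfg.yield_existing_range, size=y_rows.size)
        fav_exist[y_rows] = ye
        delta = rng.uniform(*cfg.yield_band, size=y_rows.size)
        sign = np.where(rng.random(y_rows.size) < cfg.yield_lower_prob, 1.0, -1.0)
        fav_exter[y_rows] = np.clip(ye - sign * delta, 0.01, 0.99)

    # favourable -> allele-1 frequency via orientation
    for fav, f1 in ((fav_exist, f_exist), (fav_exter, f_exter)):
        have = ~np.isnan(fav)
        rows = np.flatnonzero(have)
        loci = arch.loci[rows]
        orient = arch.orientation[rows]
        f1[loci] = np.where(orient == 1, fav[rows], 1.0 - fav[rows])
    return f_exist, f_exter


def _sample_inbred(n: int, freqs: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Homozygous lines: one allele draw per line per locus, doubled."""
    alleles = (rng.random((n, freqs.size)) < freqs[None, :]).astype(np.uint8)
    return np.repeat(alleles[:, None, :], 2, axis=1)


def generate_founders(
    cfg: FounderConfig,
    locus_map: LocusMap,
    arch: TraitArchitecture | None = None,
    rng: np.random.Generator | int | None = None,
) -> FounderSet:
    """Draw both founder populations from their target frequency profiles.

    QTL loci take class-specific favourable-allele targets from the
    architecture (major / minor disease, yield); all other loci are neutral
    markers with independent Uniform targets per population.  Every line is
    fully homozygous.
    """
    rng = np.random.default_rng(rng)
    f_exist, f_exter = _favourable_targets(cfg, locus_map.n_loci, arch, rng)
    existing = Population(
        _sample_inbred(cfg.n_existing, f_exist, rng), generation="founder_existing"
    )
    external = Population(
        _sample_inbred(cfg.n_external, f_exter, rng), generation="founder_external"
    )
    external.ids = external.ids + cfg.n_existing
    external.family = external.family + cfg.n_existing
    return FounderSet(
        existing=existing,
        external=external,
        locus_map=locus_map,
        targets={"existing": f_exist, "external": f_exter},
    )


# ----------------------------------------------------------------------
def realized_allele_freqs(
    pop: Population,
    loci: np.ndarray,
    orientation: np.ndarray | None = None,
) -> tuple[np.ndarray, float]:
    """Favourable-allele frequency at each requested locus, and their mean.

    ``orientation`` gives the favourable allele per locus (+1: allele 1,
    -1: allele 0); if omitted, allele 1 is taken as favourable everywhere.
    """
    loci = np.asarray(loci)
    if loci.size == 0:
        raise ValueError("empty locus set")
    if orientation is None:
        orientation = np.ones(loci.size, dtype=np.int64)
    orientation = np.asarray(orientation)
    if orientation.size != loci.size:
        raise ValueError("orientation must cover every requested locus")
    f1 = pop.haplotypes[:, :, loci].reshape(-1, loci.size).mean(axis=0)
    fav = np.where(orientation == 1, f1, 1.0 - f1)
    return fav, float(fav.mean())


# ----------------------------------------------------------------------
_VCF_HEADER = "##fileformat=VCFv4.2"


def write_founders(fs: FounderSet, prefix: str | os.PathLike) -> None:
    """Write a FounderSet as VCF + sidecar map/label TSVs.

    Produces ``<prefix>.vcf`` (one homozygous sample per line),
    ``<prefix>.map.tsv`` and ``<prefix>.pops.tsv``.
    """
    prefix = os.fspath(prefix)
    lm = fs.locus_map
    samples, columns = [], []
    for label in ("existing", "external"):
        pop = fs.population(label)
        for i in range(pop.n):
            samples.append(f"{label}_{pop.ids[i]}")
        columns.append(pop.haplotypes[:, 0, :])  # inbred: haplotype 0 == 1
    geno = np.concatenate(columns, axis=0)  # (n_lines, n_loci)
    with open(prefix + ".vcf", "w") as fh:
        fh.write(_VCF_HEADER + "\n")
        for c in range(1, lm.n_chr + 1):
            fh.write(f"##contig=<ID={c},length={lm.chrom_lengths[c - 1]}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples) + "\n")
        gt_str = np.where(geno == 1, "1/1", "0/0")
        for j in range(lm.n_loci):
            row = "\t".join(gt_str[:, j])
            fh.write(f"{lm.chrom[j]}\t{lm.pos[j]}\tsnp{j}\tA\tT\t.\tPASS\t.\tGT\t{row}\n")
    lm.to_frame().to_csv(prefix + ".map.tsv", sep="\t", index=False)
    pd.DataFrame(
        {
            "sample": samples,
            "population": ["existing"] * fs.existing.n + ["external"] * fs.external.n,
        }
    ).to_csv(prefix + ".pops.tsv", sep="\t", index=False)


def read_founders(prefix: str | os.PathLike) -> FounderSet:
    """Read a FounderSet written by :func:`write_founders`.

    Rejects any heterozygous genotype: founders are inbred lines by
    construction and a 0/1 call indicates a corrupt or foreign file.
    """
    from cyvcf2 import VCF

    prefix = os.fspath(prefix)
    map_df = pd.read_csv(prefix + ".map.tsv", sep="\t")
    pops = pd.read_csv(prefix + ".pops.tsv", sep="\t")
    vcf = VCF(prefix + ".vcf")
    samples = list(vcf.samples)
    if samples != list(pops["sample"]):
        raise ValueError("sample order in VCF does not match population labels")
    lengths = {}
    for line in vcf.raw_header.splitlines():
        if line.startswith("##contig"):
            inner = line[len("##contig=<") : -1]
            d = dict(kv.split("=", 1) for kv in inner.split(","))
            lengths[int(d["ID"])] = int(d["length"])
    n_chr = max(lengths)
    chrom_lengths = np.array([lengths[c] for c in range(1, n_chr + 1)], dtype=np.int64)
    geno_cols = []
    chroms, positions = [], []
    for v_idx, variant in enumerate(vcf):
        gts = np.array(variant.genotypes, dtype=np.int64)[:, :2]
        if np.any(gts[:, 0] != gts[:, 1]):
            bad = samples[int(np.flatnonzero(gts[:, 0] != gts[:, 1])[0])]
            raise ValueError(
                f"heterozygous founder genotype at {variant.CHROM}:{variant.POS} "
                f"(sample {bad}); founders must be inbred"
            )
        geno_cols.append(gts[:, 0].astype(np.uint8))
        chroms.append(int(variant.CHROM))
        positions.append(int(variant.POS))
    lm = LocusMap(np.array(chroms), np.array(positions), chrom_lengths)
    if not np.array_equal(lm.chrom, map_df["chrom"].to_numpy()) or not np.array_equal(
        lm.pos, map_df["pos"].to_numpy()
    ):
        raise ValueError("VCF loci do not match the sidecar map")
    geno = np.stack(geno_cols, axis=1)  # (n_lines, n_loci)
    hap = np.repeat(geno[:, None, :], 2, axis=1)
    is_ext = (pops["population"] == "external").to_numpy()
    ids = np.array([int(s.rsplit("_", 1)[1]) for s in samples], dtype=np.int64)
    existing = Population(hap[~is_ext], ids=ids[~is_ext], generation="founder_existing")
    external = Population(hap[is_ext], ids=ids[is_ext], generation="founder_external")
    return FounderSet(existing=existing, external=external, locus_map=lm)
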