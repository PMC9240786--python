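"""Synthetic founder generation, allele-frequency accounting, VCF round-trip."""

import numpy as np
import pytest

from breedsim import (
    FounderConfig,
    LocusMap,
    Population,
    generate_founders,
    read_founders,
    realized_allele_freqs,
    write_founders,
)


def test_all_founders_homozygous(small_founders):
    assert small_founders.existing.is_homozygous().all()
    assert small_founders.external.is_homozygous().all()
    for pop in (small_founders.existing, small_founders.external):
        assert set(np.unique(pop.haplotypes)) <= {0, 1}


def test_qtl_class_frequencies_within_binomial_tolerance(small_map, small_arch):
    cfg = FounderConfig(n_existing=1000, n_external=400, minor_freq_mean=0.52)
    fs = generate_founders(cfg, small_map, small_arch, np.random.default_rng(3))
    maj = small_arch.major
    _, m_ext = realized_allele_freqs(
        fs.external, small_arch.loci[maj], small_arch.orientation[maj]
    )
    # 10 loci x 400 lines of target 0.65
    assert m_ext == pytest.approx(0.65, abs=3 * np.sqrt(0.65 * 0.35 / (400 * 10)))
    _, m_exist = realized_allele_freqs(
        fs.existing, small_arch.loci[maj], small_arch.orientation[maj]
    )
    assert m_exist == 0.0  # target 0 is exactly monomorphic
    minor = small_arch.minor_disease
    _, mn = realized_allele_freqs(
        fs.existing, small_arch.loci[minor], small_arch.orientation[minor]
    )
    assert mn == pytest.approx(0.52, abs=0.03)


def test_single_locus_frequency_binomial_oracle(small_map, small_arch):
    """Realized frequency of a 0.52-target locus stays within 3 binomial SE."""
    cfg = FounderConfig(n_existing=1000, n_external=10, minor_freq_mean=0.52, minor_halfwidth=0.0)
    fs = generate_founders(cfg, small_map, small_arch, np.random.default_rng(4))
    minor = small_arch.minor_disease
    fav, _ = realized_allele_freqs(
        fs.existing, small_arch.loci[minor], small_arch.orientation[minor]
    )
    se = np.sqrt(0.52 * 0.48 / 1000)  # inbred lines: one draw per line
    assert np.all(np.abs(fav - 0.52) <= 4 * se)


def test_generation_is_deterministic(small_map, small_arch):
    cfg = FounderConfig(n_existing=50, n_external=20)
    a = generate_founders(cfg, small_map, small_arch, np.random.default_rng(11))
    b = generate_founders(cfg, small_map, small_arch, np.random.default_rng(11))
    np.testing.assert_array_equal(a.existing.haplotypes, b.existing.haplotypes)
    np.testing.assert_array_equal(a.external.haplotypes, b.external.haplotypes)


def test_bad_founder_config_rejected():
    with pytest.raises(ValueError, match="outside"):
        FounderConfig(minor_freq_mean=1.2)
    with pytest.raises(ValueError, match="at least 2"):
        FounderConfig(n_external=1)


def test_realized_freqs_counting():
    hap = np.zeros((400, 2, 3), dtype=np.uint8)
    hap[:80, :, 0] = 1          # 80 of 400 lines fixed favourable at locus 0
    hap[:, :, 1] = 1            # all homozygous favourable at locus 1
    pop = Population(hap)
    fav, mean = realized_allele_freqs(pop, np.array([0, 1, 2]))
    np.testing.assert_allclose(fav, [0.2, 1.0, 0.0])
    assert mean == pytest.approx((0.2 + 1.0 + 0.0) / 3)


def test_realized_freqs_brute_force_oracle(rng):
    hap = (rng.random((50, 2, 5)) < 0.4).astype(np.uint8)
    pop = Population(hap)
    orient = np.array([1, -1, 1, -1, 1])
    fav, _ = realized_allele_freqs(pop, np.arange(5), orient)
    for j in range(5):
        tally = sum(
            int(hap[i, h, j] == (1 if orient[j] == 1 else 0))
            for i in range(50)
            for h in range(2)
        )
        assert fav[j] == pytest.approx(tally / 100)


def test_realized_freqs_error_cases(small_founders):
    with pytest.raises(ValueError, match="empty"):
        realized_allele_freqs(small_founders.existing, np.array([], dtype=int))
    with pytest.raises(ValueError, match="orientation"):
        realized_allele_freqs(small_founders.existing, np.array([0, 1]), np.array([1]))


def test_vcf_round_trip_identity(small_founders, tmp_path):
    prefix = str(tmp_path / "founders")
    write_founders(small_founders, prefix)
    back = read_founders(prefix)
    np.testing.assert_array_equal(back.existing.haplotypes, small_founders.existing.haplotypes)
    np.testing.assert_array_equal(back.external.haplotypes, small_founders.external.haplotypes)
    np.testing.assert_array_equal(back.locus_map.chrom, small_founders.locus_map.chrom)
    np.testing.assert_array_equal(back.locus_map.pos, small_founders.locus_map.pos)
    np.testing.assert_array_equal(back.existing.ids, small_founders.existing.ids)


def test_vcf_toy_genotype_coding(tmp_path):
    from breedsim.founders import FounderSet

    lm = LocusMap(np.array([1, 1, 1]), np.array([10, 20, 30]), np.array([100]))
    hap = np.zeros((2, 2, 3), dtype=np.uint8)
    hap[1] = 1  # line 2 is 1/1 everywhere
    fs = FounderSet(
        existing=Population(hap.copy()),
        external=Population(hap.copy()),
        locus_map=lm,
    )
    prefix = str(tmp_path / "toy")
    write_founders(fs, prefix)
    lines = [l for l in open(prefix + ".vcf") if not l.startswith("#")]
    assert len(lines) == 3
    fields = lines[0].rstrip("\n").split("\t")
    assert fields[9:] == ["0/0", "1/1", "0/0", "1/1"]
    back = read_founders(prefix)
    np.testing.assert_array_equal(back.existing.haplotypes, hap)


def test_heterozygous_vcf_rejected(small_founders, tmp_path):
    prefix = str(tmp_path / "bad")
    write_founders(small_founders, prefix)
    text = open(prefix + ".vcf").read().splitlines()
    for i, line in enumerate(text):
        if not line.startswith("#"):
            cols = line.split("\t")
            cols[9] = "0/1"
            text[i] = "\t".join(cols)
            break
    with open(prefix + ".vcf", "w") as fh:
        fh.write("\n".join(text) + "\n")
    with pytest.raises(ValueError, match="heterozygous"):
        read_founders(prefix)
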