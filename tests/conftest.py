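"""Shared fixtures: small engineered genotype panels and a toy reference."""

import numpy as np
import pytest

from snpanel.synthetic_data import make_toy_reference
from snpanel.variant_io import GenotypeMatrix, MarkerRecord, MISSING


def marker(i: int, chrom: str = "chr1", pos: int | None = None,
           ref: str = "A", alt: str = "C") -> MarkerRecord:
    return MarkerRecord(chrom=chrom, pos=pos or (i + 1) * 1000,
                        id=f"m{i:03d}", ref=ref, alt=alt)


@pytest.fixture
def toy_reference():
    return make_toy_reference(seed=11, n_chroms=2, chrom_len=20_000, n_genes=4)


@pytest.fixture
def small_gm():
    """4 accessions x 5 loci with hets and one missing call."""
    markers = [marker(i) for i in range(5)]
    dosage = np.array(
        [
            [0, 1, 2, 0, 1],
            [0, 1, 2, 1, MISSING],
            [2, 0, 0, 2, 1],
            [1, 2, 0, 0, 0],
        ],
        dtype=np.int8,
    )
    return GenotypeMatrix([f"a{i+1}" for i in range(4)], markers, dosage)


@pytest.fixture
def homozygous_gm():
    """6 accessions x 6 loci, fully homozygous and complete.

    Every locus splits 3 hom-ref / 3 hom-alt (MAF 0.5, zero heterozygosity),
    the regime the distance-0 duplicate grouping assumes.
    """
    markers = [marker(i, chrom=f"chr{i+1}") for i in range(6)]
    patterns = [
        (0, 1, 2), (0, 1, 3), (0, 2, 4), (1, 2, 5), (0, 3, 5), (1, 3, 4),
    ]
    dosage = np.zeros((6, 6), dtype=np.int8)
    for j, alt_rows in enumerate(patterns):
        dosage[list(alt_rows), j] = 2
    return GenotypeMatrix([f"a{i+1}" for i in range(6)], markers, dosage)


def engineered_cascade_gm() -> tuple[GenotypeMatrix, list[str]]:
    """A panel where exactly 12 loci meet every default core criterion.

    6 accessions.  Good loci: one per chromosome (so windowed LD pruning
    never pairs them), complete, homozygous 3/3 splits (MAF 0.5, PIC 0.375,
    HWE p = 0.0143), no neighbour within 100 bp.  Bad loci each trip one
    stage: high missingness and a monomorphic locus (prefilter), a rare
    allele (PIC), a perfect-LD twin pair (LD prune keeps one, which the het
    ceiling later rejects), a 50-bp-apart pair (flank uniqueness kills
    both), and an all-het locus (rejected by the mainly-homozygous core
    constraint).
    """
    n = 6
    markers: list[MarkerRecord] = []
    cols: list[np.ndarray] = []
    good_ids: list[str] = []

    def add(mid, chrom, pos, col):
        markers.append(MarkerRecord(chrom=chrom, pos=pos, id=mid, ref="A", alt="G"))
        cols.append(np.asarray(col, dtype=np.int8))

    hom_split = np.array([0, 0, 0, 2, 2, 2], dtype=np.int8)
    for i in range(12):
        mid = f"good{i:02d}"
        add(mid, f"chr{i+1}", 10_000, np.roll(hom_split, i % n))
        good_ids.append(mid)

    add("bad_missing", "chr1", 20_000, [0, 2, MISSING, MISSING, 2, 0])  # 33% missing
    add("bad_rare", "chr2", 20_000, [0, 0, 0, 0, 0, 0])                 # MAF 0 < 0.05
    add("bad_maf", "chr3", 20_000, [0, 0, 0, 0, 0, 2])                  # PIC 0.26 < 0.35
    add("bad_het", "chr4", 20_000, [1, 1, 1, 1, 1, 1])                  # all het: core ceiling
    add("ld_a", "chr13", 10_000, [0, 0, 1, 1, 2, 2])                    # het, kept by LD
    add("ld_b", "chr13", 30_000, [0, 0, 1, 1, 2, 2])                    # r^2 = 1 twin, pruned
    add("flank_a", "chr14", 10_000, [0, 0, 1, 1, 2, 2])                 # 50 bp apart:
    add("flank_b", "chr14", 10_050, [0, 2, 1, 1, 2, 0])                 # both fail flank rule

    order = sorted(range(len(markers)), key=lambda k: (markers[k].chrom, markers[k].pos))
    gm = GenotypeMatrix(
        [f"a{i+1}" for i in range(n)],
        [markers[k] for k in order],
        np.stack([cols[k] for k in order], axis=1),
    )
    return gm, sorted(good_ids)
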