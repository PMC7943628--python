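"""Genomic-region and exonic-effect annotation against a toy gene model.

Each variant gets exactly one region class under the precedence
EXONIC > SPLICING > UTR5/UTR3 > INTRONIC > UPSTREAM/DOWNSTREAM > INTERGENIC.
"Upstream" and "downstream" are 1-kb windows from the gene span, strand
aware; a position simultaneously upstream of one gene and downstream of
another is its own class.  Splicing means within 2 bp (intron side) of an
exon/intron junction.  Boundary ties at exactly 1,000 bp count as inside
the window.

Exonic variants inside a CDS are further classified by substituting the alt
base into its codon (reverse-complemented on minus-strand genes) and
translating with the standard genetic code.
"""

from __future__ import annotations

from enum import Enum

import pandas as pd
from Bio.Seq import Seq

from .synthetic_data import CoordinateError, ToyGene, ToyReference
from .variant_io import MarkerRecord

PROMOTER_WINDOW = 1000
SPLICE_WINDOW = 2


class RegionClass(str, Enum):
    EXONIC = "EXONIC"
    SPLICING = "SPLICING"
    UTR5 = "UTR5"
    UTR3 = "UTR3"
    INTRONIC = "INTRONIC"
    UPSTREAM = "UPSTREAM"
    DOWNSTREAM = "DOWNSTREAM"
    UPSTREAM_DOWNSTREAM = "UPSTREAM_DOWNSTREAM"
    INTERGENIC = "INTERGENIC"


class ExonicEffect(str, Enum):
    SYNONYMOUS = "SYNONYMOUS"
    NONSYNONYMOUS = "NONSYNONYMOUS"
    STOPGAIN = "STOPGAIN"
    STOPLOSS = "STOPLOSS"


class AnnotationError(ValueError):
    """Inconsistent gene model (e.g. variant claimed exonic but not in CDS)."""


_PRECEDENCE = [
    RegionClass.EXONIC,
    RegionClass.SPLICING,
    RegionClass.UTR5,
    RegionClass.UTR3,
    RegionClass.INTRONIC,
]


def _within(pos: int, interval: tuple[int, int]) -> bool:
    return interval[0] <= pos <= interval[1]


def _classify_within_gene(pos: int, gene: ToyGene) -> RegionClass:
    in_cds = any(_within(pos, c) for c in gene.cds)
    if in_cds:
        return RegionClass.EXONIC
    in_exon = any(_within(pos, e) for e in gene.exons)
    if in_exon:
        # exonic but non-coding: UTR, polarity by strand
        cds_lo = min(s for s, _ in gene.cds)
        cds_hi = max(e for _, e in gene.cds)
        if pos < cds_lo:
            return RegionClass.UTR5 if gene.strand == "+" else RegionClass.UTR3
        if pos > cds_hi:
            return RegionClass.UTR3 if gene.strand == "+" else RegionClass.UTR5
        raise AnnotationError(f"position {pos} in exon but inside CDS span of {gene.id}")
    # intron: splice junction if within SPLICE_WINDOW of an exon boundary
    for s, e in gene.exons:
        if 1 <= s - pos <= SPLICE_WINDOW or 1 <= pos - e <= SPLICE_WINDOW:
            return RegionClass.SPLICING
    return RegionClass.INTRONIC


def classify_region(variant: MarkerRecord, ref: ToyReference) -> RegionClass:
    """Single region class for one variant under the precedence rule."""
    if variant.chrom not in ref.chromosomes:
        raise CoordinateError(f"unknown chromosome {variant.chrom!r}")
    pos = variant.pos
    genic: list[RegionClass] = []
    upstream = downstream = False
    for gene in ref.genes:
        if gene.chrom != variant.chrom:
            continue
        if gene.start <= pos <= gene.end:
            genic.append(_classify_within_gene(pos, gene))
            continue
        if gene.strand == "+":
            before, after = RegionClass.UPSTREAM, RegionClass.DOWNSTREAM
        else:
            before, after = RegionClass.DOWNSTREAM, RegionClass.UPSTREAM
        if 1 <= gene.start - pos <= PROMOTER_WINDOW:
            flank = before
        elif 1 <= pos - gene.end <= PROMOTER_WINDOW:
            flank = after
        else:
            continue
        upstream |= flank is RegionClass.UPSTREAM
        downstream |= flank is RegionClass.DOWNSTREAM
    if genic:
        return min(genic, key=_PRECEDENCE.index)
    if upstream and downstream:
        return RegionClass.UPSTREAM_DOWNSTREAM
    if upstream:
        return RegionClass.UPSTREAM
    if downstream:
        return RegionClass.DOWNSTREAM
    return RegionClass.INTERGENIC


def _cds_sequence(gene: ToyGene, ref: ToyReference) -> str:
    chrom_seq = ref.chromosomes[gene.chrom]
    parts = [chrom_seq[s - 1:e] for s, e in sorted(gene.cds)]
    seq = "".join(parts)
    if gene.strand == "-":
        seq = str(Seq(seq).reverse_complement())
    return seq


def _cds_offset(pos: int, gene: ToyGene) -> int:
    """0-based offset of a genomic position within the spliced CDS."""
    offset = 0
    for s, e in sorted(gene.cds):
        if s <= pos <= e:
            offset += pos - s
            total = sum(e2 - s2 + 1 for s2, e2 in gene.cds)
            if gene.strand == "-":
                return total - 1 - offset
            return offset
        offset += e - s + 1
    raise AnnotationError(f"position {pos} not inside the CDS of {gene.id}")


def classify_exonic_effect(variant: MarkerRecord, ref: ToyReference) -> ExonicEffect:
    """Effect of a CDS substitution on the encoded amino acid."""
    gene = next(
        (
            g for g in ref.genes
            if g.chrom == variant.chrom and any(_within(variant.pos, c) for c in g.cds)
        ),
        None,
    )
    if gene is None:
        raise AnnotationError(f"variant {variant.id} is not inside any CDS")
    cds = _cds_sequence(gene, ref)
    if len(cds) % 3 != 0:
        raise AnnotationError(f"CDS frame inconsistent for {gene.id}")
    offset = _cds_offset(variant.pos, gene)
    base = variant.alt if gene.strand == "+" else str(Seq(variant.alt).complement())
    ref_base_expected = cds[offset]
    fwd_ref = variant.ref if gene.strand == "+" else str(Seq(variant.ref).complement())
    if ref_base_expected != fwd_ref:
        raise AnnotationError(
            f"reference allele {variant.ref} does not match CDS base at {variant.pos}"
        )
    codon_idx = offset // 3
    codon = cds[codon_idx * 3:codon_idx * 3 + 3]
    alt_codon = codon[: offset % 3] + base + codon[offset % 3 + 1:]
    aa_ref = str(Seq(codon).translate())
    aa_alt = str(Seq(alt_codon).translate())
    if aa_ref == "*" and aa_alt != "*":
        return ExonicEffect.STOPLOSS
    if aa_ref != "*" and aa_alt == "*":
        return ExonicEffect.STOPGAIN
    if aa_ref == aa_alt:
        return ExonicEffect.SYNONYMOUS
    return ExonicEffect.NONSYNONYMOUS


def annotate_panel(
    variants: list[MarkerRecord], ref: ToyReference
) -> pd.DataFrame:
    """Annotation table: marker id, region class, exonic effect (or NA)."""
    rows = []
    for v in variants:
        region = classify_region(v, ref)
        effect = (
            classify_exonic_effect(v, ref).value
            if region is RegionClass.EXONIC
            else None
        )
        rows.append({"marker": v.id, "region": region.value, "effect": effect})
    return pd.DataFrame(rows)


def region_fractions(annotation: pd.DataFrame) -> pd.Series:
    """Fraction of the panel in each region class (sums to 1)."""
    return annotation["region"].value_counts(normalize=True)
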