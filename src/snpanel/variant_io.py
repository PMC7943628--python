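"""Shared data model and standard-format I/O.

The central object is :class:`GenotypeMatrix`: accessions x biallelic SNP
loci with unordered diploid calls.  Because every locus is strictly
biallelic, an unordered pair over {ref, alt} is equivalent to an alt-allele
dosage in {0, 1, 2}; internally calls are stored as an ``int8`` dosage array
with ``MISSING`` (-1) for no-calls, and allele-pair views are derived on
demand.

Coordinates are 1-based inclusive throughout (VCF/GFF3 convention).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import pysam

logger = logging.getLogger(__name__)

#: Sentinel for a missing diploid call in the int8 genotype array.
MISSING: int = -1

_BASES = frozenset("ACGT")


class VcfParseError(ValueError):
    """Malformed VCF content; carries the offending line number if known."""


class MatrixError(ValueError):
    """Inconsistent genotype-matrix construction or lookup."""


@dataclass(frozen=True, order=True)
class MarkerRecord:
    """Identity of one biallelic SNP locus (1-based position)."""

    chrom: str
    pos: int
    id: str
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise MatrixError(f"position must be >= 1, got {self.pos}")
        if self.ref not in _BASES or self.alt not in _BASES:
            raise MatrixError(f"alleles must be single bases in ACGT: {self.ref}/{self.alt}")
        if self.ref == self.alt:
            raise MatrixError(f"ref and alt must differ at {self.chrom}:{self.pos}")


class GenotypeMatrix:
    """Accessions x loci diploid genotype calls with missing values.

    Parameters
    ----------
    accessions:
        Ordered unique accession identifiers (length N).
    markers:
        Ordered :class:`MarkerRecord` list (length L).
    dosage:
        N x L ``int8`` array of alt-allele counts in {0, 1, 2} or
        ``MISSING`` (-1).
    """

    def __init__(
        self,
        accessions: Sequence[str],
        markers: Sequence[MarkerRecord],
        dosage: np.ndarray,
    ) -> None:
        self.accessions = list(accessions)
        self.markers = list(markers)
        self.dosage = np.asarray(dosage, dtype=np.int8)
        if len(set(self.accessions)) != len(self.accessions):
            raise MatrixError("accession ids must be unique")
        if self.dosage.shape != (len(self.accessions), len(self.markers)):
            raise MatrixError(
                f"dosage shape {self.dosage.shape} != "
                f"({len(self.accessions)}, {len(self.markers)})"
            )
        valid = np.isin(self.dosage, (MISSING, 0, 1, 2))
        if not valid.all():
            raise MatrixError("dosage entries must be in {-1, 0, 1, 2}")
        self._acc_index = {a: i for i, a in enumerate(self.accessions)}

    # -- basic geometry ----------------------------------------------------

    @property
    def n_accessions(self) -> int:
        return len(self.accessions)

    @property
    def n_loci(self) -> int:
        return len(self.markers)

    def accession_index(self, accession: str) -> int:
        try:
            return self._acc_index[accession]
        except KeyError:
            raise MatrixError(f"unknown accession id: {accession!r}") from None

    # -- call views --------------------------------------------------------

    def call(self, accession: str, locus: int) -> tuple[str, str] | None:
        """Unordered allele pair at one cell, alphabetically sorted, or None."""
        d = int(self.dosage[self.accession_index(accession), locus])
        if d == MISSING:
            return None
        m = self.markers[locus]
        alleles = [m.ref] * (2 - d) + [m.alt] * d
        return tuple(sorted(alleles))  # type: ignore[return-value]

    def genotype_token(self, accession: str, locus: int) -> str:
        """Display string ``"X/Y"`` (alleles sorted) or ``"-"`` if missing."""
        pair = self.call(accession, locus)
        return "-" if pair is None else f"{pair[0]}/{pair[1]}"

    # -- subsetting --------------------------------------------------------

    def subset(
        self,
        accessions: Sequence[str] | None = None,
        loci: Sequence[int] | None = None,
    ) -> "GenotypeMatrix":
        """New matrix restricted to the given accessions and/or locus indices."""
        rows = (
            np.arange(self.n_accessions)
            if accessions is None
            else np.array([self.accession_index(a) for a in accessions])
        )
        cols = np.arange(self.n_loci) if loci is None else np.asarray(loci, dtype=int)
        return GenotypeMatrix(
            [self.accessions[i] for i in rows],
            [self.markers[j] for j in cols],
            self.dosage[np.ix_(rows, cols)],
        )

    def subset_marker_ids(self, marker_ids: Sequence[str]) -> "GenotypeMatrix":
        index = {m.id: j for j, m in enumerate(self.markers)}
        try:
            cols = [index[mid] for mid in marker_ids]
        except KeyError as exc:
            raise MatrixError(f"unknown marker id: {exc.args[0]!r}") from None
        return self.subset(loci=cols)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.accessions == other.accessions
            and self.markers == other.markers
            and np.array_equal(self.dosage, other.dosage)
        )

    def __repr__(self) -> str:
        return f"GenotypeMatrix({self.n_accessions} accessions x {self.n_loci} loci)"


@dataclass
class DosageMatrix:
    """Numeric N x L view: alt-allele counts as float with NaN for missing."""

    accessions: list[str]
    markers: list[MarkerRecord]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.accessions), len(self.markers)):
            raise MatrixError("dosage values shape mismatch")


def to_dosage(gm: GenotypeMatrix) -> DosageMatrix:
    """Numeric view of a genotype matrix (hom-ref 0, het 1, hom-alt 2)."""
    vals = gm.dosage.astype(float)
    vals[gm.dosage == MISSING] = np.nan
    return DosageMatrix(list(gm.accessions), list(gm.markers), vals)


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(path: str) -> GenotypeMatrix:
    """Read a multi-sample VCF into a :class:`GenotypeMatrix`.

    Multiallelic and non-SNP (indel) records are skipped; the skipped count
    is logged.  Phased ("|") and unphased ("/") separators are treated
    identically; any call containing a missing allele becomes MISSING.
    """
    try:
        vf = pysam.VariantFile(str(path))
    except (ValueError, OSError) as exc:
        raise VcfParseError(f"cannot parse VCF header of {path}: {exc}") from exc

    accessions = list(vf.header.samples)
    markers: list[MarkerRecord] = []
    rows: list[np.ndarray] = []
    n_skipped = 0
    with vf:
        for line_no, rec in enumerate(vf, start=1):
            try:
                alts = rec.alts or ()
                if len(alts) != 1 or len(rec.ref) != 1 or len(alts[0]) != 1 \
                        or rec.ref not in _BASES or alts[0] not in _BASES:
                    n_skipped += 1
                    continue
                marker = MarkerRecord(
                    chrom=rec.chrom,
                    pos=rec.pos,
                    id=rec.id or f"{rec.chrom}_{rec.pos}",
                    ref=rec.ref,
                    alt=alts[0],
                )
                col = np.full(len(accessions), MISSING, dtype=np.int8)
                for i, sample in enumerate(accessions):
                    gt = rec.samples[sample].get("GT")
                    if gt is None or len(gt) != 2 or None in gt:
                        continue
                    col[i] = gt[0] + gt[1]
            except VcfParseError:
                raise
            except Exception as exc:  # pragma: no cover - defensive
                raise VcfParseError(f"malformed VCF record {line_no} in {path}: {exc}") from exc
            markers.append(marker)
            rows.append(col)
    if n_skipped:
        logger.info("read_vcf: skipped %d multiallelic/indel records", n_skipped)
    dosage = (
        np.array(rows, dtype=np.int8).T
        if rows
        else np.zeros((len(accessions), 0), dtype=np.int8)
    )
    gm = GenotypeMatrix(accessions, markers, dosage)
    gm.n_skipped_records = n_skipped  # type: ignore[attr-defined]
    return gm


def write_vcf(gm: GenotypeMatrix, path: str) -> None:
    """Write the matrix as an uncompressed VCF v4.2 with GT fields."""
    header = pysam.VariantHeader()
    chrom_max: dict[str, int] = {}
    for m in gm.markers:
        chrom_max[m.chrom] = max(chrom_max.get(m.chrom, 0), m.pos)
    for chrom, mx in chrom_max.items():
        header.contigs.add(chrom, length=mx + 1000)
    header.formats.add("GT", 1, "String", "Genotype")
    for acc in gm.accessions:
        header.add_sample(acc)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for j, m in enumerate(gm.markers):
            rec = out.new_record(
                contig=m.chrom, start=m.pos - 1, stop=m.pos,
                alleles=(m.ref, m.alt), id=m.id,
            )
            for i, acc in enumerate(gm.accessions):
                d = int(gm.dosage[i, j])
                if d == MISSING:
                    rec.samples[acc]["GT"] = (None, None)
                else:
                    rec.samples[acc]["GT"] = (0, 1) if d == 1 else (d // 2, d // 2)
            out.write(rec)


# ---------------------------------------------------------------------------
# Genotype table (TSV)
# ---------------------------------------------------------------------------

def write_matrix_tsv(gm: GenotypeMatrix, path: str) -> None:
    """Write a marker x accession genotype table.

    Genotypes are rendered as ``"X/Y"`` with alleles sorted alphabetically
    and ``"-"`` for missing — the same encoding used by fingerprint codes.
    """
    data = {
        "marker": [m.id for m in gm.markers],
        "chrom": [m.chrom for m in gm.markers],
        "pos": [m.pos for m in gm.markers],
        "ref": [m.ref for m in gm.markers],
        "alt": [m.alt for m in gm.markers],
    }
    for acc in gm.accessions:
        data[acc] = [gm.genotype_token(acc, j) for j in range(gm.n_loci)]
    pd.DataFrame(data).to_csv(path, sep="\t", index=False)


def read_matrix_tsv(path: str) -> GenotypeMatrix:
    """Inverse of :func:`write_matrix_tsv`."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    meta_cols = ["marker", "chrom", "pos", "ref", "alt"]
    accessions = [c for c in df.columns if c not in meta_cols]
    markers = [
        MarkerRecord(chrom=row.chrom, pos=int(row.pos), id=row.marker,
                     ref=row.ref, alt=row.alt)
        for row in df.itertuples()
    ]
    dosage = np.full((len(accessions), len(markers)), MISSING, dtype=np.int8)
    for i, acc in enumerate(accessions):
        for j, (token, m) in enumerate(zip(df[acc], markers)):
            if token == "-":
                continue
            a, b = token.split("/")
            dosage[i, j] = (a == m.alt) + (b == m.alt)
    return GenotypeMatrix(accessions, markers, dosage)


def write_marker_json(markers: Iterable[MarkerRecord], path: str) -> None:
    """Dump marker metadata as JSON records."""
    pd.DataFrame(
        [
            {"id": m.id, "chrom": m.chrom, "pos": m.pos, "ref": m.ref, "alt": m.alt}
            for m in markers
        ]
    ).to_json(path, orient="records", indent=2)
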