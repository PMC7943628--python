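"""KASP (competitive allele-specific PCR) assay design.

For every selected SNP, an assay consists of two allele-specific primers —
one per allele, identical except for the 3' terminal base sitting on the
SNP — carrying the standard FAM and VIC fluorophore tails, plus one common
primer on the opposite strand.  Primer bodies (tails excluded) must satisfy
GC content < 60 %, melting temperature 55–62 °C, length 18–30 nt, and the
amplicon must span at most 120 bp.

The Tm model is a deliberately simple, reproducible hybrid: the Wallace
rule ``2(A+T) + 4(G+C)`` for oligos up to 13 nt and the GC-count formula
``64.9 + 41 (GC - 16.4)/N`` above that.  Nearest-neighbour thermodynamics
is an extension point, not the default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
from Bio.Seq import Seq

from .synthetic_data import ToyReference
from .variant_io import MarkerRecord

FAM_TAIL = "GAAGGTGACCAAGTTCATGCT"
VIC_TAIL = "GAAGGTCGGAGTCAACGGATT"

DEFAULT_FLANK_BP = 100


class SequenceError(ValueError):
    """Non-ACGT characters or otherwise invalid primer sequence."""


class FlankError(ValueError):
    """Marker too close to a chromosome end for flank extraction."""


@dataclass(frozen=True)
class DesignConstraints:
    max_gc_pct: float = 60.0
    min_tm: float = 55.0
    max_tm: float = 62.0
    min_primer_len: int = 18
    max_primer_len: int = 30
    max_product_bp: int = 120


@dataclass
class KaspAssay:
    """A designed assay; primer sequences include the fluorophore tails."""

    marker_id: str
    flank_5prime: str
    flank_3prime: str
    orientation: str                 # "forward" (5' flank) or "reverse" (3' flank)
    allele_fam_primer: str           # FAM tail + body ending in the REF allele base
    allele_vic_primer: str           # VIC tail + body ending in the ALT allele base
    common_primer: str
    gc_content: dict[str, float]     # per primer body, %
    tm: dict[str, float]             # per primer body, °C
    product_size: int


@dataclass
class AssayRejection:
    marker_id: str
    reasons: list[str] = field(default_factory=list)


def _check_dna(seq: str) -> str:
    seq = seq.upper()
    if not seq:
        raise SequenceError("empty sequence")
    if any(b not in "ACGT" for b in seq):
        raise SequenceError(f"non-ACGT character in {seq!r}")
    return seq


def gc_content(primer: str) -> float:
    """GC percentage of a primer body."""
    primer = _check_dna(primer)
    return 100.0 * sum(b in "GC" for b in primer) / len(primer)


def melting_temp(primer: str) -> float:
    """Tm in °C: Wallace rule up to 13 nt, GC-count formula above."""
    primer = _check_dna(primer)
    if len(primer) < 8:
        raise SequenceError("primer shorter than 8 nt")
    gc = sum(b in "GC" for b in primer)
    at = len(primer) - gc
    if len(primer) <= 13:
        return float(2 * at + 4 * gc)
    return 64.9 + 41.0 * (gc - 16.4) / len(primer)


def extract_flanks(
    marker: MarkerRecord, ref: ToyReference, flank_bp: int = DEFAULT_FLANK_BP,
) -> tuple[str, str]:
    """Reference sequence ``flank_bp`` before and after the SNP (SNP excluded)."""
    seq = ref.chromosomes.get(marker.chrom)
    if seq is None:
        raise FlankError(f"unknown chromosome {marker.chrom!r}")
    if marker.pos - flank_bp < 1 or marker.pos + flank_bp > len(seq):
        raise FlankError(
            f"{marker.id} at {marker.chrom}:{marker.pos} lacks {flank_bp} bp of flank"
        )
    five = seq[marker.pos - 1 - flank_bp:marker.pos - 1]
    three = seq[marker.pos:marker.pos + flank_bp]
    return five, three


def _revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def _body_ok(body: str, c: DesignConstraints) -> list[str]:
    reasons = []
    if gc_content(body) >= c.max_gc_pct:
        reasons.append("gc_too_high")
    tm = melting_temp(body)
    if tm < c.min_tm:
        reasons.append("tm_too_low")
    elif tm > c.max_tm:
        reasons.append("tm_too_high")
    return reasons


def design_assay(
    marker: MarkerRecord,
    ref: ToyReference,
    constraints: DesignConstraints = DesignConstraints(),
) -> KaspAssay | AssayRejection:
    """Design one KASP assay, or return a rejection listing failed constraints.

    The allele-specific primer may read off either flank: forward primers
    take the last ``n - 1`` bases of the 5' flank plus the allele base;
    reverse primers are the reverse complement of the allele base plus the
    first ``n - 1`` bases of the 3' flank.  The shortest feasible allele
    primer is taken (scan order: forward orientation first, length
    ascending).  The common primer is scanned on the opposite flank in
    order of increasing product size; the first feasible 18–30-mer wins.
    Deterministic throughout; infeasibility never raises.
    """
    try:
        five, three = extract_flanks(marker, ref, DEFAULT_FLANK_BP)
    except FlankError as exc:
        return AssayRejection(marker.id, [f"flank_error: {exc}"])

    c = constraints
    reasons: set[str] = set()
    for orientation in ("forward", "reverse"):
        allele_flank = five if orientation == "forward" else three
        common_flank = three if orientation == "forward" else five
        for n in range(c.min_primer_len, c.max_primer_len + 1):
            if n - 1 > len(allele_flank):
                reasons.add("allele_flank_too_short")
                break
            if orientation == "forward":
                body_ref = allele_flank[-(n - 1):] + marker.ref
                body_alt = allele_flank[-(n - 1):] + marker.alt
            else:
                body_ref = _revcomp(marker.ref + allele_flank[:n - 1])
                body_alt = _revcomp(marker.alt + allele_flank[:n - 1])
            fails = _body_ok(body_ref, c) + _body_ok(body_alt, c)
            if fails:
                reasons.update(f"allele_primer_{r}" for r in fails)
                continue
            common = _scan_common(common_flank, orientation, n, c, reasons)
            if common is None:
                continue
            common_body, product_size = common
            return KaspAssay(
                marker_id=marker.id,
                flank_5prime=five,
                flank_3prime=three,
                orientation=orientation,
                allele_fam_primer=FAM_TAIL + body_ref,
                allele_vic_primer=VIC_TAIL + body_alt,
                common_primer=common_body,
                gc_content={
                    "fam": gc_content(body_ref),
                    "vic": gc_content(body_alt),
                    "common": gc_content(common_body),
                },
                tm={
                    "fam": melting_temp(body_ref),
                    "vic": melting_temp(body_alt),
                    "common": melting_temp(common_body),
                },
                product_size=product_size,
            )
    if not reasons:
        reasons.add("no_feasible_primer_set")
    return AssayRejection(marker.id, sorted(reasons))


def _scan_common(
    common_flank: str, orientation: str, allele_len: int,
    c: DesignConstraints, reasons: set[str],
) -> tuple[str, int] | None:
    """First feasible common primer by increasing product size.

    Product size = allele primer length + offset into the opposite flank +
    common primer length (the allele primer covers the SNP base).
    """
    best: tuple[int, str] | None = None
    max_budget = c.max_product_bp - allele_len
    for product_rest in range(c.min_primer_len, max_budget + 1):
        for m in range(c.min_primer_len, min(c.max_primer_len, product_rest) + 1):
            offset = product_rest - m
            if offset + m > len(common_flank):
                continue
            window = common_flank[offset:offset + m]
            # common primer anneals to the opposite strand of the amplicon
            body = _revcomp(window) if orientation == "forward" else window
            fails = _body_ok(body, c)
            if fails:
                reasons.update(f"common_primer_{r}" for r in fails)
                continue
            return body, allele_len + product_rest
    reasons.add("no_common_primer_within_product_limit")
    return best


def conversion_rate(designed: int, attempted: int) -> float:
    """Percentage of attempted SNPs successfully converted, 1 decimal."""
    if attempted <= 0:
        raise ValueError("attempted must be positive")
    return round(100.0 * designed / attempted, 1)


def design_panel(
    markers: list[MarkerRecord],
    ref: ToyReference,
    constraints: DesignConstraints = DesignConstraints(),
) -> tuple[list[KaspAssay], list[AssayRejection]]:
    """Design assays for a whole panel; returns (assays, rejections)."""
    assays, rejections = [], []
    for m in markers:
        result = design_assay(m, ref, constraints)
        (assays if isinstance(result, KaspAssay) else rejections).append(result)
    return assays, rejections


def assay_table(
    assays: list[KaspAssay], rejections: list[AssayRejection]
) -> pd.DataFrame:
    """Flat TSV-ready table of designs and rejection reasons."""
    rows = []
    for a in assays:
        rows.append(
            {
                "marker": a.marker_id, "status": "designed",
                "orientation": a.orientation,
                "fam_primer": a.allele_fam_primer,
                "vic_primer": a.allele_vic_primer,
                "common_primer": a.common_primer,
                "product_size": a.product_size,
                "fam_tm": round(a.tm["fam"], 1),
                "common_tm": round(a.tm["common"], 1),
                "fam_gc": round(a.gc_content["fam"], 1),
                "common_gc": round(a.gc_content["common"], 1),
                "reasons": "",
            }
        )
    for r in rejections:
        rows.append(
            {"marker": r.marker_id, "status": "rejected", "orientation": "",
             "fam_primer": "", "vic_primer": "", "common_primer": "",
             "product_size": 0, "fam_tm": float("nan"), "common_tm": float("nan"),
             "fam_gc": float("nan"), "common_gc": float("nan"),
             "reasons": ";".join(r.reasons)}
        )
    return pd.DataFrame(rows)
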