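"""SNP fingerprints, 2D-barcode payloads, and duplicate-accession detection.

A fingerprint is the ordered genotype string of one accession over the core
panel (markers sorted by chromosome, then position): tokens ``"X/Y"`` with
alleles alphabetical, ``"-"`` for missing.  The barcode payload is plain
``key: value`` text carrying the variety name, type, botanical
classification and the fingerprint code; it round-trips losslessly.

Duplicate identification runs in two stages, mirroring a re-genotyping
workflow: stage 1 groups accessions at p-distance exactly 0 on the core
panel (with a minimum compared-locus floor so sparse overlap cannot fake
identity); stage 2 recomputes distances within each group on the disjoint
candidate panel and keeps only pairs that remain at 0.  The report labels
surviving groups "suspected identical" — final confirmation belongs to
field phenotyping, which is outside this package.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .popgen import DistanceMatrix, distance_matrix, pair_distance, UndefinedDistanceError
from .variant_io import GenotypeMatrix, MatrixError


class ValidationError(ValueError):
    """Missing or malformed fingerprint/payload fields."""


@dataclass
class Fingerprint:
    accession: str
    marker_ids: list[str]
    code: list[str]

    def __post_init__(self) -> None:
        if len(self.code) != len(self.marker_ids):
            raise ValidationError("code length must equal panel size")
        for token in self.code:
            if token == "-":
                continue
            if len(token) != 3 or token[1] != "/" or not (
                token[0] in "ACGT" and token[2] in "ACGT"
            ):
                raise ValidationError(f"bad genotype token {token!r}")

    @property
    def code_string(self) -> str:
        return " ".join(self.code)


def panel_order(gm: GenotypeMatrix, panel: list[str]) -> list[str]:
    """Panel marker ids sorted by (chrom, pos)."""
    by_id = {m.id: m for m in gm.markers}
    try:
        return sorted(panel, key=lambda mid: (by_id[mid].chrom, by_id[mid].pos))
    except KeyError as exc:
        raise MatrixError(f"panel marker {exc.args[0]!r} not in matrix") from None


def encode_fingerprint(gm: GenotypeMatrix, panel: list[str], accession: str) -> Fingerprint:
    """Fingerprint of one accession over the panel, in (chrom, pos) order."""
    ordered = panel_order(gm, panel)
    sub = gm.subset_marker_ids(ordered)
    code = [sub.genotype_token(accession, j) for j in range(sub.n_loci)]
    return Fingerprint(accession=accession, marker_ids=ordered, code=code)


def decode_fingerprint(fp: Fingerprint) -> list[str]:
    """The genotype tokens of a fingerprint (identity view; validates)."""
    return list(Fingerprint(fp.accession, fp.marker_ids, fp.code).code)


# ---------------------------------------------------------------------------
# Barcode payloads
# ---------------------------------------------------------------------------

@dataclass
class BarcodePayload:
    name: str
    type: str
    classification: str
    fingerprint: Fingerprint

    def render(self) -> str:
        return (
            f"Name: {self.name}\n"
            f"Type: {self.type}\n"
            f"Classification: {self.classification}\n"
            f"Markers: {' '.join(self.fingerprint.marker_ids)}\n"
            f"Code: {self.fingerprint.code_string}\n"
        )


def barcode_payload(fp: Fingerprint, metadata: dict[str, str]) -> BarcodePayload:
    """Structured payload text for one accession's 2D barcode."""
    if not metadata.get("name"):
        raise ValidationError("metadata must include a variety name")
    return BarcodePayload(
        name=metadata["name"],
        type=metadata.get("type", ""),
        classification=metadata.get("classification", ""),
        fingerprint=fp,
    )


def parse_payload(text: str, accession: str | None = None) -> BarcodePayload:
    """Inverse of :meth:`BarcodePayload.render`."""
    fields: dict[str, str] = {}
    for line in text.strip().splitlines():
        key, _, value = line.partition(": ")
        fields[key] = value
    for required in ("Name", "Markers", "Code"):
        if required not in fields:
            raise ValidationError(f"payload missing {required!r} line")
    fp = Fingerprint(
        accession=accession or fields["Name"],
        marker_ids=fields["Markers"].split(),
        code=fields["Code"].split(),
    )
    return BarcodePayload(
        name=fields["Name"], type=fields.get("Type", ""),
        classification=fields.get("Classification", ""), fingerprint=fp,
    )


# ---------------------------------------------------------------------------
# Duplicate detection
# ---------------------------------------------------------------------------

class _UnionFind:
    def __init__(self, items: list[str]) -> None:
        self.parent = {x: x for x in items}

    def find(self, x: str) -> str:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: str, b: str) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[max(ra, rb)] = min(ra, rb)

    def groups(self) -> list[set[str]]:
        comp: dict[str, set[str]] = {}
        for x in self.parent:
            comp.setdefault(self.find(x), set()).add(x)
        return [g for g in comp.values() if len(g) >= 2]


@dataclass
class DuplicateReport:
    stage1_groups: list[set[str]]
    stage2_groups: list[set[str]]
    suspected_identical: list[set[str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.suspected_identical:
            self.suspected_identical = [set(g) for g in self.stage2_groups]

    def to_json(self, path: str) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "stage1_groups": [sorted(g) for g in self.stage1_groups],
                    "stage2_groups": [sorted(g) for g in self.stage2_groups],
                    "suspected_identical": [sorted(g) for g in self.suspected_identical],
                },
                indent=2,
            )
            + "\n"
        )


def find_duplicates(dm: DistanceMatrix, min_overlap: int = 40) -> list[set[str]]:
    """Stage-1 duplicate groups: connected components of distance-0 pairs.

    A pair counts only when its distance is exactly 0 AND at least
    ``min_overlap`` loci were compared, preventing identity calls from
    sparse overlap.  Groups are transitive closures of such pairs.
    """
    uf = _UnionFind(list(dm.accessions))
    n = len(dm.accessions)
    for i in range(n):
        for j in range(i + 1, n):
            if dm.values[i, j] == 0.0 and dm.n_compared[i, j] >= min_overlap:
                uf.union(dm.accessions[i], dm.accessions[j])
    return sorted(uf.groups(), key=lambda g: sorted(g)[0])


def refine_duplicates(
    stage1_groups: list[set[str]],
    gm: GenotypeMatrix,
    candidate_panel: list[str],
    core_panel: list[str] | None = None,
    min_overlap: int = 20,
) -> DuplicateReport:
    """Stage-2 re-genotyping check on the candidate panel.

    Within each stage-1 group, pair distances are recomputed on the
    candidate markers (which must be disjoint from the core panel); only
    pairs that remain at distance 0 with enough compared loci stay
    grouped.  Stage-2 groups therefore refine stage-1 groups.
    """
    if core_panel is not None and set(candidate_panel) & set(core_panel):
        raise ValidationError("candidate panel must be disjoint from the core panel")
    sub = gm.subset_marker_ids(panel_order(gm, candidate_panel))
    stage2: list[set[str]] = []
    for group in stage1_groups:
        members = sorted(group)
        uf = _UnionFind(members)
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                try:
                    d, n = pair_distance(
                        sub.dosage[sub.accession_index(members[i])],
                        sub.dosage[sub.accession_index(members[j])],
                    )
                except UndefinedDistanceError:
                    continue
                if d == 0.0 and n >= min_overlap:
                    uf.union(members[i], members[j])
        stage2.extend(uf.groups())
    stage2 = sorted(stage2, key=lambda g: sorted(g)[0])
    return DuplicateReport(stage1_groups=stage1_groups, stage2_groups=stage2)


# ---------------------------------------------------------------------------
# Discrimination summary
# ---------------------------------------------------------------------------

def discrimination_summary(
    gm: GenotypeMatrix, panel: list[str]
) -> tuple[int, float, float]:
    """(n_distinct fingerprints, % accessions with a unique fingerprint,
    accessions resolved per panel locus)."""
    if not panel:
        raise ValidationError("panel must be non-empty")
    codes = [
        encode_fingerprint(gm, panel, acc).code_string for acc in gm.accessions
    ]
    counts = pd.Series(codes).value_counts()
    n_distinct = int(len(counts))
    n_unique = int((counts == 1).sum())
    accuracy_pct = 100.0 * n_unique / gm.n_accessions
    return n_distinct, accuracy_pct, gm.n_accessions / len(panel)


def fingerprint_table(gm: GenotypeMatrix, panel: list[str]) -> pd.DataFrame:
    """Marker-per-row, accession-per-column genotype table over the panel."""
    ordered = panel_order(gm, panel)
    sub = gm.subset_marker_ids(ordered)
    data = {"marker": ordered}
    for acc in sub.accessions:
        data[acc] = [sub.genotype_token(acc, j) for j in range(sub.n_loci)]
    return pd.DataFrame(data)
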