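"""Synthetic germplasm panels, toy reference genomes and ground truth.

The generator emulates the statistical structure of an admixed germplasm
collection: K ancestral populations whose allele frequencies are
differentiated from a common ancestral frequency under the Balding–Nichols
model, individuals whose ancestry proportions are Dirichlet-distributed,
binomial genotype sampling, MCAR missingness, and optional injected
duplicate accessions (the "same variety under two names" situation that
fingerprinting is meant to detect).

All randomness flows from one explicit integer seed through
``numpy.random.default_rng``; no global RNG state is touched.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .variant_io import GenotypeMatrix, MarkerRecord, MISSING


class ParameterError(ValueError):
    """Invalid simulation model parameters."""


class PlacementError(RuntimeError):
    """Toy genes cannot be placed without overlap."""


class CoordinateError(ValueError):
    """A position falls outside its chromosome."""


@dataclass(frozen=True)
class PopulationModel:
    """Generative model for an admixed diploid SNP panel.

    ``fst`` is the Balding–Nichols differentiation parameter F in (0, 1);
    population allele frequencies are drawn as
    ``Beta(p (1-F)/F, (1-p)(1-F)/F)`` around an ancestral frequency
    ``p ~ Uniform(0.05, 0.95)``.  ``dirichlet_alpha`` controls how admixed
    individuals are (small values give near-pure ancestry).
    """

    n_populations: int
    fst: float
    dirichlet_alpha: tuple[float, ...]
    n_accessions: int
    n_loci: int
    missing_rate: float = 0.0
    seed: int = 0
    n_chromosomes: int = 24

    def __post_init__(self) -> None:
        if self.n_populations < 1 or self.n_accessions < 1 or self.n_loci < 1:
            raise ParameterError("counts must be positive")
        if not 0.0 < self.fst < 1.0:
            raise ParameterError(f"fst must be strictly inside (0, 1): {self.fst}")
        if len(self.dirichlet_alpha) != self.n_populations:
            raise ParameterError("dirichlet_alpha length must equal n_populations")
        if any(a <= 0 for a in self.dirichlet_alpha):
            raise ParameterError("dirichlet_alpha entries must be positive")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ParameterError("missing_rate must be in [0, 1)")
        if self.n_chromosomes < 1:
            raise ParameterError("n_chromosomes must be positive")


@dataclass
class SyntheticTruth:
    """Ground truth retained from simulation for parameter-recovery tests."""

    ancestral_freqs: np.ndarray | None = None  # K x L population frequencies
    base_freqs: np.ndarray | None = None       # L ancestral frequencies p_l
    admixture_q: np.ndarray | None = None      # N x K, rows sum to 1
    duplicate_groups: list[set[str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.admixture_q is not None:
            if not np.allclose(self.admixture_q.sum(axis=1), 1.0, atol=1e-9):
                raise ParameterError("admixture_q rows must sum to 1")
        for g in self.duplicate_groups:
            if len(g) < 2:
                raise ParameterError("duplicate groups must have size >= 2")


@dataclass(frozen=True)
class ToyGene:
    """Gene model on the toy reference, 1-based inclusive coordinates."""

    id: str
    chrom: str
    start: int
    end: int
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        for s, e in self.exons + self.cds:
            if not (self.start <= s <= e <= self.end):
                raise ParameterError(f"interval ({s},{e}) outside gene {self.id}")
        cds_len = sum(e - s + 1 for s, e in self.cds)
        if cds_len % 3 != 0:
            raise ParameterError(f"CDS length of {self.id} not divisible by 3")


@dataclass
class ToyReference:
    """Small reference genome: chromosome sequences plus gene models."""

    chromosomes: dict[str, str]
    genes: list[ToyGene]

    def base(self, chrom: str, pos: int) -> str:
        seq = self.chromosomes.get(chrom)
        if seq is None:
            raise CoordinateError(f"unknown chromosome {chrom!r}")
        if not 1 <= pos <= len(seq):
            raise CoordinateError(f"position {pos} outside {chrom} (1..{len(seq)})")
        return seq[pos - 1]

    # -- serialization -------------------------------------------------------

    def write_fasta(self, path: str) -> None:
        records = [
            SeqRecord(Seq(seq), id=name, description="")
            for name, seq in self.chromosomes.items()
        ]
        SeqIO.write(records, str(path), "fasta")

    def write_gff3(self, path: str) -> None:
        lines = ["##gff-version 3"]
        for name, seq in self.chromosomes.items():
            lines.append(f"##sequence-region {name} 1 {len(seq)}")
        for g in self.genes:
            base = f"{g.chrom}\tsnpanel\t"
            tail = f"\t.\t{g.strand}\t"
            lines.append(f"{base}gene\t{g.start}\t{g.end}{tail}.\tID={g.id}")
            lines.append(f"{base}mRNA\t{g.start}\t{g.end}{tail}.\tID={g.id}.t1;Parent={g.id}")
            for s, e in g.exons:
                lines.append(f"{base}exon\t{s}\t{e}{tail}.\tParent={g.id}.t1")
            # phase: transcription order, first CDS segment phase 0
            segs = list(g.cds) if g.strand == "+" else list(g.cds)[::-1]
            cum = 0
            phased = []
            for s, e in segs:
                phased.append((s, e, (3 - cum % 3) % 3))
                cum += e - s + 1
            for s, e, phase in sorted(phased):
                lines.append(f"{base}CDS\t{s}\t{e}{tail}{phase}\tParent={g.id}.t1")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_files(cls, fasta_path: str, gff3_path: str) -> "ToyReference":
        import gffutils

        chromosomes = {
            rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")
        }
        db = gffutils.create_db(
            str(gff3_path), dbfn=":memory:", merge_strategy="create_unique",
            keep_order=True,
        )
        genes = []
        for gene in db.features_of_type("gene"):
            exons = tuple(
                sorted((f.start, f.end) for f in db.children(gene, featuretype="exon"))
            )
            cds = tuple(
                sorted((f.start, f.end) for f in db.children(gene, featuretype="CDS"))
            )
            genes.append(
                ToyGene(
                    id=gene.id, chrom=gene.seqid, start=gene.start, end=gene.end,
                    strand=gene.strand, exons=exons, cds=cds,
                )
            )
        return cls(chromosomes=chromosomes, genes=genes)


# ---------------------------------------------------------------------------
# Panel simulation
# ---------------------------------------------------------------------------

_BASES = "ACGT"

#: Minimum distance of a simulated marker from a chromosome end, leaving room
#: for 100-bp flank extraction.
_EDGE_MARGIN = 150
#: Default spacing between simulated markers (> 100 bp so that, absent
#: planted nuisance variants, markers pass the flank-uniqueness rule).
_MARKER_SPACING = 1000


def _simulate_markers(
    model: PopulationModel, rng: np.random.Generator,
    reference: ToyReference | None,
) -> list[MarkerRecord]:
    markers: list[MarkerRecord] = []
    if reference is None:
        chrom_names = [f"chr{c + 1}" for c in range(model.n_chromosomes)]
        for l in range(model.n_loci):
            chrom = chrom_names[l % len(chrom_names)]
            pos = (l // len(chrom_names) + 1) * _MARKER_SPACING
            ref = _BASES[rng.integers(4)]
            alt = rng.choice([b for b in _BASES if b != ref])
            markers.append(MarkerRecord(chrom=chrom, pos=pos, id=f"snp{l:05d}",
                                        ref=ref, alt=str(alt)))
    else:
        names = list(reference.chromosomes)
        counters = {c: _EDGE_MARGIN for c in names}
        for l in range(model.n_loci):
            chrom = names[l % len(names)]
            pos = counters[chrom] + int(rng.integers(_MARKER_SPACING // 2, _MARKER_SPACING))
            if pos > len(reference.chromosomes[chrom]) - _EDGE_MARGIN:
                raise ParameterError(
                    f"reference chromosome {chrom} too short for {model.n_loci} loci"
                )
            counters[chrom] = pos
            ref = reference.base(chrom, pos)
            alt = rng.choice([b for b in _BASES if b != ref])
            markers.append(MarkerRecord(chrom=chrom, pos=pos, id=f"snp{l:05d}",
                                        ref=ref, alt=str(alt)))
    # stable (chrom, pos) order expected by windowed LD pruning
    order = sorted(range(len(markers)), key=lambda i: (markers[i].chrom, markers[i].pos))
    return [markers[i] for i in order]


def simulate_panel(
    model: PopulationModel, reference: ToyReference | None = None,
) -> tuple[GenotypeMatrix, SyntheticTruth]:
    """Simulate an admixed diploid SNP panel.

    Per locus *l*: ancestral frequency ``p_l ~ U(0.05, 0.95)``; population
    frequencies ``f_kl ~ Beta(p_l (1-F)/F, (1-p_l)(1-F)/F)``.  Per accession
    *i*: ancestry ``q_i ~ Dirichlet(alpha)``; genotype dosage
    ``g_il ~ Binomial(2, sum_k q_ik f_kl)``.  Entries are then masked missing
    independently with ``missing_rate``.  Deterministic given ``model.seed``.

    When a :class:`ToyReference` is supplied, markers are placed on its
    chromosomes with the reference base as the REF allele, so KASP flank
    extraction is consistent with the genotypes.
    """
    rng = np.random.default_rng(model.seed)
    K, N, L = model.n_populations, model.n_accessions, model.n_loci

    p = rng.uniform(0.05, 0.95, size=L)
    ratio = (1.0 - model.fst) / model.fst
    f = rng.beta(p * ratio, (1.0 - p) * ratio, size=(K, L))
    f = np.clip(f, 1e-6, 1.0 - 1e-6)
    q = rng.dirichlet(np.asarray(model.dirichlet_alpha, dtype=float), size=N)
    pi = q @ f  # N x L expected alt-allele frequency per individual
    dosage = rng.binomial(2, pi).astype(np.int8)
    if model.missing_rate > 0:
        mask = rng.random(size=(N, L)) < model.missing_rate
        dosage[mask] = MISSING

    markers = _simulate_markers(model, rng, reference)
    accessions = [f"acc{i + 1:04d}" for i in range(N)]
    gm = GenotypeMatrix(accessions, markers, dosage)
    truth = SyntheticTruth(ancestral_freqs=f, base_freqs=p, admixture_q=q)
    return gm, truth


def inject_duplicates(
    gm: GenotypeMatrix,
    groups: dict[str, int],
    error_rate: float = 0.0,
    seed: int = 0,
) -> tuple[GenotypeMatrix, SyntheticTruth]:
    """Append near-copies of existing accessions.

    ``groups`` maps a source accession id to the number of copies to add;
    copies are named ``<src>_dup1``, ``<src>_dup2``, ...  Each non-missing
    genotype of a copy is independently replaced, with probability
    ``error_rate``, by one of the two other dosage values (so a perturbation
    always changes the call); ``error_rate=0`` yields exact copies.
    """
    if not 0.0 <= error_rate < 1.0:
        raise ParameterError("error_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    accessions = list(gm.accessions)
    rows = [gm.dosage]
    duplicate_groups: list[set[str]] = []
    for src, n_copies in groups.items():
        i = gm.accession_index(src)  # raises MatrixError for unknown ids
        group = {src}
        for c in range(1, n_copies + 1):
            row = gm.dosage[i].copy()
            if error_rate > 0:
                non_missing = np.flatnonzero(row != MISSING)
                hits = non_missing[rng.random(non_missing.size) < error_rate]
                for j in hits:
                    others = [v for v in (0, 1, 2) if v != row[j]]
                    row[j] = others[rng.integers(2)]
            name = f"{src}_dup{c}"
            accessions.append(name)
            rows.append(row[None, :])
            group.add(name)
        duplicate_groups.append(group)
    out = GenotypeMatrix(accessions, list(gm.markers), np.vstack(rows))
    return out, SyntheticTruth(duplicate_groups=duplicate_groups)


# ---------------------------------------------------------------------------
# Toy reference
# ---------------------------------------------------------------------------

#: Toy gene layout (offsets from gene start, lengths): two exons split by a
#: 100-bp intron, CDS inset 60 bp from the transcript 5' end and 50 bp from
#: the 3' end so that both UTR classes exist.  Total CDS length 390 (div. 3).
_GENE_LEN = 600


def _make_gene(gene_id: str, chrom: str, start: int, strand: str) -> ToyGene:
    s = start
    exons = ((s, s + 199), (s + 300, s + 599))
    if strand == "+":
        cds = ((s + 60, s + 199), (s + 300, s + 549))
    else:  # mirrored: transcription right-to-left
        cds = ((s + 50, s + 199), (s + 300, s + 539))
    return ToyGene(id=gene_id, chrom=chrom, start=s, end=s + _GENE_LEN - 1,
                   strand=strand, exons=exons, cds=cds)


def make_toy_reference(
    seed: int,
    n_chroms: int = 2,
    chrom_len: int = 20_000,
    n_genes: int = 4,
) -> ToyReference:
    """Random toy genome with non-overlapping two-exon genes.

    Genes are spread round-robin across chromosomes with at least 2.5 kb
    between gene spans, leaving clean intergenic and upstream/downstream
    territory for annotation tests.  Deterministic given ``seed``.
    """
    if chrom_len < 1000:
        raise ParameterError("chrom_len must be >= 1000")
    rng = np.random.default_rng(seed)
    chromosomes = {
        f"chr{c + 1}": "".join(rng.choice(list(_BASES), size=chrom_len))
        for c in range(n_chroms)
    }
    genes: list[ToyGene] = []
    spacing = _GENE_LEN + 2500
    per_chrom = -(-n_genes // n_chroms) if n_genes else 0
    if n_genes and 2000 + per_chrom * spacing > chrom_len:
        raise PlacementError(
            f"cannot place {n_genes} genes on {n_chroms} chromosomes of {chrom_len} bp"
        )
    for g in range(n_genes):
        chrom = f"chr{g % n_chroms + 1}"
        slot = g // n_chroms
        start = 2000 + slot * spacing + int(rng.integers(0, 500))
        strand = "+" if g % 2 == 0 else "-"
        genes.append(_make_gene(f"gene{g + 1:03d}", chrom, start, strand))
    return ToyReference(chromosomes=chromosomes, genes=genes)


def plant_flank_variants(
    ref: ToyReference,
    target_positions: list[tuple[str, int]],
    offsets: list[int],
) -> list[MarkerRecord]:
    """Nuisance SNPs at ``target +/- offset`` for flank-uniqueness tests."""
    if any(o == 0 for o in offsets):
        raise ParameterError("offsets must be nonzero")
    variants: list[MarkerRecord] = []
    for chrom, pos in target_positions:
        for off in offsets:
            p = pos + off
            base = ref.base(chrom, p)  # raises CoordinateError if off-chromosome
            alt = _BASES[(_BASES.index(base) + 1) % 4]
            variants.append(
                MarkerRecord(chrom=chrom, pos=p, id=f"nuis_{chrom}_{p}",
                             ref=base, alt=alt)
            )
    return variants


def write_manifest(path: str, model: PopulationModel, files: dict[str, str]) -> None:
    """Record model parameters and output file paths as JSON."""
    payload = {
        "model": {
            "n_populations": model.n_populations,
            "fst": model.fst,
            "dirichlet_alpha": list(model.dirichlet_alpha),
            "n_accessions": model.n_accessions,
            "n_loci": model.n_loci,
            "missing_rate": model.missing_rate,
            "seed": model.seed,
            "n_chromosomes": model.n_chromosomes,
        },
        "files": files,
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")
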