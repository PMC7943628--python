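"""End-to-end pipeline orchestration.

``run_full`` chains the stages in method order — simulate (optional) →
per-site statistics → annotation → selection cascade → KASP design →
population genetics → fingerprinting — writing each stage's artifact into
a run directory together with a manifest (config hash, seed, output file
hashes) so that a rerun with the same config and seed is bit-identical
and any downstream stage can be resumed from the stored artifacts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import fingerprinting, kasp_design, popgen, synthetic_data, variant_annotation
from .panel_selection import FilterCriteria, run_cascade
from .site_stats import site_stats_table
from .synthetic_data import PopulationModel, ToyReference
from .variant_io import read_vcf, to_dosage, write_matrix_tsv, write_vcf

logger = logging.getLogger("snpanel")


class ConfigError(ValueError):
    """Invalid or incomplete pipeline configuration."""


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception) -> None:
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class SyntheticConfig:
    n_populations: int = 3
    fst: float = 0.3
    dirichlet_alpha: list[float] = field(default_factory=lambda: [0.3, 0.3, 0.3])
    n_accessions: int = 60
    n_loci: int = 240
    missing_rate: float = 0.02
    n_chromosomes: int = 8
    duplicates: dict[str, int] = field(default_factory=lambda: {"acc0001": 1})
    reference_chrom_len: int = 40_000
    reference_n_genes: int = 8

    def model(self, seed: int) -> PopulationModel:
        return PopulationModel(
            n_populations=self.n_populations,
            fst=self.fst,
            dirichlet_alpha=tuple(self.dirichlet_alpha),
            n_accessions=self.n_accessions,
            n_loci=self.n_loci,
            missing_rate=self.missing_rate,
            seed=seed,
            n_chromosomes=self.n_chromosomes,
        )


@dataclass
class PipelineConfig:
    """Full pipeline configuration; synthetic model or real input paths."""

    output_dir: str = "snpanel_run"
    vcf: str | None = None
    reference_fasta: str | None = None
    gff3: str | None = None
    synthetic: SyntheticConfig | None = None
    criteria: FilterCriteria = field(default_factory=FilterCriteria)
    core_size: int = 47
    candidate_size: int = 24
    k_values: list[int] = field(default_factory=lambda: [1, 2, 3, 4])
    cv_masking_rate: float = 0.1
    seed: int = 0

    def validate(self) -> None:
        if self.core_size <= 0 or self.candidate_size < 0:
            raise ConfigError("panel sizes must be positive")
        if self.synthetic is None:
            if self.vcf is None:
                raise ConfigError("either a VCF path or a synthetic model is required")
            for path, label in ((self.vcf, "vcf"), (self.reference_fasta, "reference_fasta"),
                                (self.gff3, "gff3")):
                if path is not None and not Path(path).exists():
                    raise ConfigError(f"{label} path does not exist: {path}")

    @classmethod
    def from_yaml(cls, path: str, **overrides) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        if "criteria" in raw and isinstance(raw["criteria"], dict):
            raw["criteria"] = FilterCriteria(**raw["criteria"])
        if "synthetic" in raw and isinstance(raw["synthetic"], dict):
            raw["synthetic"] = SyntheticConfig(**raw["synthetic"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        def convert(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: convert(v) for k, v in dataclasses.asdict(obj).items()}
            return obj

        return convert(self)


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_full(config: PipelineConfig) -> Path:
    """Run every stage; returns the run directory."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    files: dict[str, str] = {}

    def artifact(name: str) -> Path:
        files[name] = str(out / name)
        return out / name

    stage = "inputs"
    try:
        if config.synthetic is not None:
            syn = config.synthetic
            reference = synthetic_data.make_toy_reference(
                seed=config.seed + 1,
                n_chroms=syn.n_chromosomes,
                chrom_len=syn.reference_chrom_len,
                n_genes=syn.reference_n_genes,
            )
            gm, truth = synthetic_data.simulate_panel(syn.model(config.seed), reference)
            if syn.duplicates:
                gm, dup_truth = synthetic_data.inject_duplicates(
                    gm, syn.duplicates, error_rate=0.0, seed=config.seed + 2
                )
            reference.write_fasta(str(artifact("reference.fa")))
            reference.write_gff3(str(artifact("genes.gff3")))
            write_vcf(gm, str(artifact("genotypes.vcf")))
            synthetic_data.write_manifest(
                str(artifact("synthetic_manifest.json")),
                syn.model(config.seed),
                {name: Path(p).name for name, p in files.items()},
            )
        else:
            gm = read_vcf(config.vcf)  # type: ignore[arg-type]
            reference = (
                ToyReference.from_files(config.reference_fasta, config.gff3)
                if config.reference_fasta and config.gff3
                else None
            )
        logger.info("inputs: %d accessions x %d loci", gm.n_accessions, gm.n_loci)

        stage = "stats"
        stats = site_stats_table(gm)
        stats.to_csv(artifact("site_stats.tsv"), sep="\t", index=False)
        logger.info("stats: %d loci summarised", len(stats))

        stage = "annotate"
        if reference is not None:
            annotation = variant_annotation.annotate_panel(gm.markers, reference)
            annotation.to_csv(artifact("annotation.tsv"), sep="\t", index=False)
            logger.info("annotate: %d variants classified", len(annotation))

        stage = "select"
        cascade = run_cascade(
            gm, criteria=config.criteria,
            core_size=config.core_size, candidate_size=config.candidate_size,
        )
        cascade.report.write(
            str(artifact("cascade_report.tsv")), str(artifact("cascade_report.json"))
        )
        (out / "core_panel.txt").write_text("\n".join(cascade.core_panel) + "\n")
        files["core_panel.txt"] = str(out / "core_panel.txt")
        (out / "candidate_panel.txt").write_text("\n".join(cascade.candidate_panel) + "\n")
        files["candidate_panel.txt"] = str(out / "candidate_panel.txt")
        logger.info(
            "select: core %d, candidate %d markers",
            len(cascade.core_panel), len(cascade.candidate_panel),
        )

        stage = "design"
        if reference is not None and cascade.core_panel:
            by_id = {m.id: m for m in gm.markers}
            panel_markers = [by_id[mid] for mid in cascade.core_panel]
            assays, rejections = kasp_design.design_panel(panel_markers, reference)
            kasp_design.assay_table(assays, rejections).to_csv(
                artifact("kasp_assays.tsv"), sep="\t", index=False
            )
            rate = kasp_design.conversion_rate(len(assays), len(panel_markers))
            logger.info("design: %d/%d assays designed (%.1f%%)",
                        len(assays), len(panel_markers), rate)

        stage = "popgen"
        dm = popgen.distance_matrix(gm)
        dm.to_frame().to_csv(artifact("distance_matrix.tsv"), sep="\t")
        tree = popgen.nj_tree(dm)
        (out / "nj_tree.nwk").write_text(tree.to_newick() + "\n")
        files["nj_tree.nwk"] = str(out / "nj_tree.nwk")
        dosage = to_dosage(gm)
        pca_res = popgen.pca(dosage, n_components=2)
        _write_pca(pca_res, artifact("pca_scores.tsv"))
        cv = popgen.cv_error_over_k(
            dosage, config.k_values, config.cv_masking_rate,
            seed=config.seed, n_folds=2, max_iter=200,
        )
        best_k = min(cv, key=cv.get)
        _write_cv(cv, artifact("cv_errors.tsv"))
        fit = popgen.admixture_fit(dosage, best_k, seed=config.seed)
        _write_q(fit, gm.accessions, artifact("admixture_Q.tsv"))
        logger.info("popgen: best K = %d (cv over %s)", best_k, config.k_values)

        stage = "fingerprint"
        panel = cascade.core_panel
        candidate = cascade.candidate_panel
        if not panel:
            # On outbred/admixed inputs the mainly-homozygous core constraint
            # can be infeasible; fall back to the top-PIC cascade survivors so
            # the fingerprinting stages still demonstrate on something real.
            logger.warning(
                "select: no marker met the strict core constraints; "
                "falling back to top-PIC cascade survivors"
            )
            ranked = (
                stats.set_index("marker").loc[cascade.survivors]
                .sort_values(["pic", "maf"], ascending=False, kind="mergesort")
                .index.tolist()
            )
            panel = ranked[: config.core_size]
            candidate = ranked[config.core_size:config.core_size + config.candidate_size]
        if not panel:
            raise StageError("fingerprint", RuntimeError("no markers survive the cascade"))
        fingerprinting.fingerprint_table(gm, panel).to_csv(
            artifact("fingerprints.tsv"), sep="\t", index=False
        )
        sub_dm = popgen.distance_matrix(gm.subset_marker_ids(panel))
        min_overlap = max(1, int(0.85 * len(panel)))
        stage1 = fingerprinting.find_duplicates(sub_dm, min_overlap=min_overlap)
        candidate = [m for m in candidate if m not in panel]
        if candidate:
            report = fingerprinting.refine_duplicates(
                stage1, gm, candidate, core_panel=panel,
                min_overlap=max(1, int(0.85 * len(candidate))),
            )
        else:
            report = fingerprinting.DuplicateReport(stage1_groups=stage1, stage2_groups=stage1)
        report.to_json(str(artifact("duplicates.json")))
        n_distinct, accuracy, per_locus = fingerprinting.discrimination_summary(gm, panel)
        write_matrix_tsv(gm, str(artifact("genotype_table.tsv")))
        logger.info(
            "fingerprint: %d distinct codes, %.1f%% unique, %.1f accessions/locus",
            n_distinct, accuracy, per_locus,
        )
    except (ConfigError, StageError):
        raise
    except Exception as exc:
        raise StageError(stage, exc) from exc

    manifest = {
        "seed": config.seed,
        "config": config.to_dict(),
        "config_hash": hashlib.sha256(
            json.dumps(config.to_dict(), sort_keys=True).encode()
        ).hexdigest(),
        "outputs": {name: _hash_file(Path(p)) for name, p in sorted(files.items())},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return out


def _write_pca(res, path: Path) -> None:
    import pandas as pd

    df = pd.DataFrame(
        res.scores, index=res.accessions,
        columns=[f"PC{i + 1}" for i in range(res.scores.shape[1])],
    )
    df.index.name = "accession"
    with open(path, "w") as fh:
        fh.write(
            "# explained_pct: "
            + " ".join(f"{v:.2f}" for v in res.explained_variance_pct) + "\n"
        )
        df.to_csv(fh, sep="\t")


def _write_cv(cv: dict[int, float], path: Path) -> None:
    import pandas as pd

    pd.DataFrame(
        {"K": list(cv.keys()), "cv_error": list(cv.values())}
    ).to_csv(path, sep="\t", index=False)


def _write_q(fit, accessions, path: Path) -> None:
    import pandas as pd

    df = pd.DataFrame(
        fit.Q, index=accessions, columns=[f"Q{k + 1}" for k in range(fit.K)]
    )
    df.index.name = "accession"
    df.to_csv(path, sep="\t")
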