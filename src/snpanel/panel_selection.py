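"""Marker-selection cascade: from a full SNP catalogue to a core panel.

Stages, run in order, each logged in a :class:`CascadeReport`:

1. prefilter        — drop loci with missing rate > 20% or MAF < 5%
2. PIC filter       — drop loci with PIC < 0.35
3. HWE filter       — drop loci with HWE p < 0.01
4. LD prune         — sliding window (50 SNPs, step 10), drop one of every
                      pair with genotype-dosage r^2 > 0.2
5. flank uniqueness — drop loci with any other catalogued variant within
                      100 bp on the same chromosome
6. core selection   — zero missingness, mainly-homozygous, MAF >= 0.34;
                      rank by PIC then MAF, round-robin across chromosomes

Removal thresholds are strict on the removal side: a locus at exactly the
threshold survives stages whose criterion is quoted as a strict inequality
(e.g. missing rate exactly 20% is kept).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .variant_io import DosageMatrix, GenotypeMatrix, MarkerRecord, to_dosage
from .site_stats import site_stats_table


@dataclass(frozen=True)
class FilterCriteria:
    """Thresholds of the selection cascade (defaults as published)."""

    max_missing_rate: float = 0.20
    min_maf_prefilter: float = 0.05
    min_maf_panel: float = 0.34
    min_pic: float = 0.35
    min_hwe_p: float = 0.01
    ld_window_snps: int = 50
    ld_step_snps: int = 10
    ld_r2_max: float = 0.2
    flank_bp: int = 100
    max_het_obs: float = 0.10
    per_chromosome_target: int | None = None

    def __post_init__(self) -> None:
        for name in ("max_missing_rate", "min_maf_prefilter", "min_maf_panel",
                     "min_hwe_p", "ld_r2_max", "max_het_obs"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]: {v}")
        if not 0.0 <= self.min_pic <= 0.375:
            raise ValueError(f"min_pic outside the biallelic range: {self.min_pic}")
        if not self.ld_window_snps >= self.ld_step_snps >= 1:
            raise ValueError("need ld_window_snps >= ld_step_snps >= 1")
        if self.flank_bp < 0:
            raise ValueError("flank_bp must be non-negative")


@dataclass
class CascadeStage:
    name: str
    criterion: str
    n_input: int
    n_surviving: int
    removed: list[str] = field(default_factory=list)


@dataclass
class CascadeReport:
    """Ordered audit trail of every filtering stage."""

    stages: list[CascadeStage] = field(default_factory=list)

    def add(self, name: str, criterion: str, before: list[str], after: list[str]) -> None:
        kept = set(after)
        self.stages.append(
            CascadeStage(
                name=name, criterion=criterion,
                n_input=len(before), n_surviving=len(after),
                removed=[m for m in before if m not in kept],
            )
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"stage": s.name, "criterion": s.criterion,
                 "n_input": s.n_input, "n_surviving": s.n_surviving,
                 "n_removed": s.n_input - s.n_surviving}
                for s in self.stages
            ]
        )

    def write(self, tsv_path: str, json_path: str | None = None) -> None:
        self.to_frame().to_csv(tsv_path, sep="\t", index=False)
        if json_path:
            Path(json_path).write_text(
                json.dumps(
                    [
                        {"stage": s.name, "criterion": s.criterion,
                         "n_input": s.n_input, "n_surviving": s.n_surviving,
                         "removed": s.removed}
                        for s in self.stages
                    ],
                    indent=2,
                )
                + "\n"
            )


def _stats_for(marker_ids: list[str], stats: pd.DataFrame) -> pd.DataFrame:
    return stats.set_index("marker").loc[marker_ids].reset_index()


def prefilter(
    stats: pd.DataFrame, criteria: FilterCriteria, report: CascadeReport | None = None,
) -> list[str]:
    """Missing-rate and MAF pre-filter over a site-stats table."""
    before = list(stats["marker"])
    keep = stats[
        (stats["missing_rate"] <= criteria.max_missing_rate)
        & (stats["maf"] >= criteria.min_maf_prefilter)
        & stats["maf"].notna()
    ]
    after = list(keep["marker"])
    if report is not None:
        report.add(
            "prefilter",
            f"missing_rate <= {criteria.max_missing_rate} and MAF >= {criteria.min_maf_prefilter}",
            before, after,
        )
    return after


def pic_hwe_filter(
    stats: pd.DataFrame, criteria: FilterCriteria, report: CascadeReport | None = None,
) -> list[str]:
    """Sequential PIC then HWE stages (logged separately)."""
    before = list(stats["marker"])
    pic_kept = stats[stats["pic"] >= criteria.min_pic]
    after_pic = list(pic_kept["marker"])
    if report is not None:
        report.add("pic", f"PIC >= {criteria.min_pic}", before, after_pic)
    hwe_kept = pic_kept[pic_kept["hwe_p"] >= criteria.min_hwe_p]
    after_hwe = list(hwe_kept["marker"])
    if report is not None:
        report.add("hwe", f"HWE p >= {criteria.min_hwe_p}", after_pic, after_hwe)
    return after_hwe


# ---------------------------------------------------------------------------
# LD pruning
# ---------------------------------------------------------------------------

def pairwise_r2(values: np.ndarray, i: int, j: int) -> float:
    """Squared Pearson correlation of two dosage columns over complete pairs."""
    x, y = values[:, i], values[:, j]
    ok = ~(np.isnan(x) | np.isnan(y))
    if ok.sum() < 2:
        return 0.0
    x, y = x[ok], y[ok]
    if x.std() == 0 or y.std() == 0:
        return 0.0
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def _prune_window(
    values: np.ndarray, idx: list[int], alive: np.ndarray, mafs: np.ndarray,
    r2_max: float,
) -> bool:
    """Greedily remove one member of every offending pair inside one window.

    Among offending pairs the one with the largest r^2 is resolved first
    (ties by index pair); the member with the lower MAF is removed, ties by
    removing the higher index.  Returns True if anything was removed.
    """
    changed = False
    while True:
        live = [k for k in idx if alive[k]]
        worst: tuple[float, int, int] | None = None
        for a in range(len(live)):
            for b in range(a + 1, len(live)):
                i, j = live[a], live[b]
                r2 = pairwise_r2(values, i, j)
                if r2 > r2_max and (worst is None or r2 > worst[0] + 1e-12):
                    worst = (r2, i, j)
        if worst is None:
            return changed
        _, i, j = worst
        if mafs[i] < mafs[j] or (mafs[i] == mafs[j] and i > j):
            alive[i] = False
        else:
            alive[j] = False
        changed = True


def ld_prune(
    dm: DosageMatrix, criteria: FilterCriteria, report: CascadeReport | None = None,
) -> list[str]:
    """Windowed LD pruning of a (chrom, pos)-sorted dosage matrix.

    Windows of ``ld_window_snps`` advance by ``ld_step_snps`` per chromosome;
    sweeps repeat until no window contains a pair with r^2 above the
    threshold, so the surviving set carries a global within-window
    certificate.
    """
    markers = dm.markers
    order = sorted(range(len(markers)), key=lambda k: (markers[k].chrom, markers[k].pos))
    if order != list(range(len(markers))):
        raise ValueError("ld_prune requires markers sorted by (chrom, pos)")
    n = len(markers)
    alive = np.ones(n, dtype=bool)
    with np.errstate(invalid="ignore"):
        mafs = np.nanmean(dm.values, axis=0) / 2.0
    mafs = np.minimum(mafs, 1.0 - mafs)
    mafs[np.isnan(mafs)] = 0.0

    by_chrom: dict[str, list[int]] = {}
    for k, m in enumerate(markers):
        by_chrom.setdefault(m.chrom, []).append(k)

    changed = True
    while changed:
        changed = False
        for chrom_idx in by_chrom.values():
            start = 0
            while True:
                window = chrom_idx[start:start + criteria.ld_window_snps]
                if len(window) >= 2:
                    changed |= _prune_window(
                        dm.values, window, alive, mafs, criteria.ld_r2_max
                    )
                if start + criteria.ld_window_snps >= len(chrom_idx):
                    break
                start += criteria.ld_step_snps
    before = [m.id for m in markers]
    after = [m.id for k, m in enumerate(markers) if alive[k]]
    if report is not None:
        report.add(
            "ld_prune",
            f"indep-pairwise {criteria.ld_window_snps} {criteria.ld_step_snps} "
            f"{criteria.ld_r2_max}",
            before, after,
        )
    return after


def flank_uniqueness_filter(
    survivors: list[MarkerRecord],
    all_variants: list[MarkerRecord],
    flank_bp: int = 100,
    report: CascadeReport | None = None,
) -> list[str]:
    """Keep survivors with no OTHER catalogued variant within ±flank_bp.

    The neighbour test runs against the full variant catalogue, not just the
    current survivors; a neighbour strictly more than ``flank_bp`` away does
    not disqualify.
    """
    by_chrom: dict[str, np.ndarray] = {}
    keys: dict[str, list[tuple[int, str]]] = {}
    for v in all_variants:
        keys.setdefault(v.chrom, []).append((v.pos, v.id))
    for chrom, entries in keys.items():
        entries.sort()
        by_chrom[chrom] = np.array([p for p, _ in entries])
    kept: list[str] = []
    for m in survivors:
        positions = by_chrom.get(m.chrom)
        if positions is None:
            kept.append(m.id)
            continue
        lo = np.searchsorted(positions, m.pos - flank_bp, side="left")
        hi = np.searchsorted(positions, m.pos + flank_bp, side="right")
        neighbours = [
            keys[m.chrom][t][1] for t in range(lo, hi) if keys[m.chrom][t][1] != m.id
        ]
        if not neighbours:
            kept.append(m.id)
    if report is not None:
        report.add(
            "flank_uniqueness",
            f"no other variant within ±{flank_bp} bp",
            [m.id for m in survivors], kept,
        )
    return kept


@dataclass
class PanelSelection:
    """Ranked panel pick with a feasibility flag."""

    marker_ids: list[str]
    infeasible: bool = False


def select_core_panel(
    stats: pd.DataFrame,
    criteria: FilterCriteria,
    n_total: int,
    report: CascadeReport | None = None,
) -> PanelSelection:
    """Pick the final panel from surviving markers.

    Hard constraints: zero missing genotypes, observed heterozygosity at or
    below ``max_het_obs`` (mainly-homozygous sites) and MAF >=
    ``min_maf_panel``.  Eligible markers are ranked by PIC descending, MAF
    descending, ties by (chrom, pos) ascending, then drawn round-robin
    across chromosomes until ``n_total`` are chosen.  If fewer are feasible,
    all feasible markers are returned with ``infeasible=True``.
    """
    before = list(stats["marker"])
    eligible = stats[
        (stats["missing_rate"] == 0.0)
        & (stats["het_obs"] <= criteria.max_het_obs)
        & (stats["maf"] >= criteria.min_maf_panel)
    ].copy()
    eligible = eligible.sort_values(
        by=["pic", "maf", "chrom", "pos"], ascending=[False, False, True, True],
        kind="mergesort",
    )
    queues: dict[str, list[str]] = {}
    for row in eligible.itertuples():
        queues.setdefault(row.chrom, []).append(row.marker)
    chosen: list[str] = []
    chrom_order = sorted(queues)
    while len(chosen) < n_total and any(queues.values()):
        for chrom in chrom_order:
            if queues[chrom] and len(chosen) < n_total:
                chosen.append(queues[chrom].pop(0))
    infeasible = len(chosen) < n_total
    if report is not None:
        report.add(
            "core_selection",
            f"no missing calls, het_obs <= {criteria.max_het_obs}, "
            f"MAF >= {criteria.min_maf_panel}; top {n_total} by PIC/MAF round-robin",
            before, chosen,
        )
    return PanelSelection(marker_ids=chosen, infeasible=infeasible)


@dataclass
class CascadeResult:
    core_panel: list[str]
    candidate_panel: list[str]
    report: CascadeReport
    survivors: list[str] = field(default_factory=list)  # post flank-uniqueness


def run_cascade(
    gm: GenotypeMatrix,
    all_variants: list[MarkerRecord] | None = None,
    criteria: FilterCriteria = FilterCriteria(),
    core_size: int = 47,
    candidate_size: int = 24,
) -> CascadeResult:
    """Execute the full selection cascade and split core/candidate panels.

    ``all_variants`` is the complete variant catalogue used by the
    flank-uniqueness stage; when omitted, the matrix's own markers stand in.
    The ranked selection is split by rank: the first ``core_size`` markers
    form the core panel, the next ``candidate_size`` the candidate panel.
    """
    report = CascadeReport()
    stats = site_stats_table(gm)
    catalogue = all_variants if all_variants is not None else list(gm.markers)

    kept = prefilter(stats, criteria, report)
    kept = pic_hwe_filter(_stats_for(kept, stats), criteria, report)

    sub = gm.subset_marker_ids(kept)
    kept = ld_prune(to_dosage(sub), criteria, report)

    marker_by_id = {m.id: m for m in gm.markers}
    kept = flank_uniqueness_filter(
        [marker_by_id[k] for k in kept], catalogue, criteria.flank_bp, report
    )

    n_chroms = len({m.chrom for m in gm.markers})
    if criteria.per_chromosome_target is not None:
        n_total = criteria.per_chromosome_target * n_chroms
    else:
        n_total = core_size + candidate_size
    selection = select_core_panel(_stats_for(kept, stats), criteria, n_total, report)
    ranked = selection.marker_ids
    return CascadeResult(
        core_panel=ranked[:core_size],
        candidate_panel=ranked[core_size:core_size + candidate_size],
        report=report,
        survivors=kept,
    )
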