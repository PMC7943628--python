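"""Selection cascade: boundary behaviour, LD certificate, end-to-end fixture."""

import numpy as np
import pandas as pd
import pytest

from snpanel.panel_selection import (
    CascadeReport,
    FilterCriteria,
    flank_uniqueness_filter,
    ld_prune,
    pairwise_r2,
    pic_hwe_filter,
    prefilter,
    run_cascade,
    select_core_panel,
)
from snpanel.variant_io import GenotypeMatrix, MarkerRecord, to_dosage

from conftest import engineered_cascade_gm, marker


def stats_frame(rows: list[dict]) -> pd.DataFrame:
    defaults = dict(chrom="chr1", pos=1000, maf=0.5, pic=0.375, het_obs=0.0,
                    het_exp=0.5, hwe_p=1.0, missing_rate=0.0)
    out = []
    for i, row in enumerate(rows):
        d = dict(defaults, marker=f"m{i:03d}", pos=(i + 1) * 1000)
        d.update(row)
        out.append(d)
    return pd.DataFrame(out)


class TestCriteriaValidation:
    def test_defaults_valid(self):
        FilterCriteria()

    @pytest.mark.parametrize(
        "kw",
        [dict(max_missing_rate=1.5), dict(min_pic=0.5),
         dict(ld_window_snps=5, ld_step_snps=10), dict(flank_bp=-1)],
    )
    def test_invalid(self, kw):
        with pytest.raises(ValueError):
            FilterCriteria(**kw)


class TestPrefilterBoundaries:
    def test_missing_rate_strictly_above_threshold_removed(self):
        stats = stats_frame([
            {"missing_rate": 0.25},   # removed
            {"missing_rate": 0.20},   # exactly at threshold: kept
            {"missing_rate": 0.0},
        ])
        kept = prefilter(stats, FilterCriteria())
        assert kept == ["m001", "m002"]

    def test_maf_below_threshold_removed(self):
        stats = stats_frame([
            {"maf": 0.0},     # monomorphic: removed
            {"maf": 0.04},    # removed
            {"maf": 0.05},    # exactly at threshold: kept
        ])
        kept = prefilter(stats, FilterCriteria())
        assert kept == ["m002"]

    def test_report_records_removals(self):
        report = CascadeReport()
        stats = stats_frame([{"maf": 0.0}, {}])
        prefilter(stats, FilterCriteria(), report)
        assert report.stages[0].name == "prefilter"
        assert report.stages[0].removed == ["m000"]
        assert report.stages[0].n_surviving == 1


class TestPicHweBoundaries:
    def test_pic_boundary(self):
        # strictly below 0.35 removed; exactly 0.35 kept
        stats = stats_frame([{"pic": 0.3481}, {"pic": 0.34}, {"pic": 0.35}])
        kept = pic_hwe_filter(stats, FilterCriteria())
        assert kept == ["m002"]

    def test_hwe_boundary(self):
        stats = stats_frame([{"hwe_p": 0.005}, {"hwe_p": 0.01}, {"hwe_p": 0.5}])
        report = CascadeReport()
        kept = pic_hwe_filter(stats, FilterCriteria(), report)
        assert kept == ["m001", "m002"]
        assert [s.name for s in report.stages] == ["pic", "hwe"]
        assert report.stages[1].removed == ["m000"]


def random_gm(seed: int, n: int = 30, loci: int = 40) -> GenotypeMatrix:
    rng = np.random.default_rng(seed)
    markers = [marker(i, pos=(i + 1) * 500) for i in range(loci)]
    dosage = rng.integers(0, 3, size=(n, loci)).astype(np.int8)
    return GenotypeMatrix([f"a{i}" for i in range(n)], markers, dosage)


class TestLdPrune:
    def test_survivors_carry_certificate(self):
        """Brute force: no surviving pair within a window exceeds r2_max."""
        gm = random_gm(seed=21)
        dm = to_dosage(gm)
        criteria = FilterCriteria()
        kept = ld_prune(dm, criteria)
        idx = {m.id: k for k, m in enumerate(dm.markers)}
        live = [idx[m] for m in kept]
        for a in range(len(live)):
            for b in range(a + 1, len(live)):
                assert pairwise_r2(dm.values, live[a], live[b]) <= criteria.ld_r2_max

    def test_identical_columns_leave_one(self):
        col = np.array([0, 0, 1, 1, 2, 2], dtype=np.int8)
        markers = [marker(i, pos=(i + 1) * 500) for i in range(3)]
        gm = GenotypeMatrix(
            [f"a{i}" for i in range(6)], markers, np.stack([col] * 3, axis=1)
        )
        kept = ld_prune(to_dosage(gm), FilterCriteria())
        assert kept == ["m000"]  # equal MAF ties remove the higher index

    def test_lower_maf_member_removed(self):
        x = np.array([0, 0, 0, 1, 2, 2, 2, 2], dtype=np.int8)  # MAF 0.4375
        y = np.array([0, 0, 0, 0, 2, 2, 2, 2], dtype=np.int8)  # MAF 0.5, r2 high
        markers = [marker(0, pos=500), marker(1, pos=1000)]
        gm = GenotypeMatrix(
            [f"a{i}" for i in range(8)], markers, np.stack([x, y], axis=1)
        )
        assert pairwise_r2(to_dosage(gm).values, 0, 1) > 0.2
        kept = ld_prune(to_dosage(gm), FilterCriteria())
        assert kept == ["m001"]

    def test_requires_sorted_markers(self):
        markers = [marker(0, pos=2000), marker(1, pos=1000)]
        gm = GenotypeMatrix(
            ["a1", "a2"], markers, np.array([[0, 2], [2, 0]], dtype=np.int8)
        )
        with pytest.raises(ValueError):
            ld_prune(to_dosage(gm), FilterCriteria())

    def test_deterministic(self):
        gm = random_gm(seed=22)
        assert ld_prune(to_dosage(gm), FilterCriteria()) == ld_prune(
            to_dosage(gm), FilterCriteria()
        )

    def test_r2_zero_variance_column(self):
        vals = np.array([[0.0, 1.0], [0.0, 2.0], [0.0, 0.0]])
        assert pairwise_r2(vals, 0, 1) == 0.0


class TestFlankUniqueness:
    def make(self, positions: list[int]) -> list[MarkerRecord]:
        return [
            MarkerRecord(chrom="chr1", pos=p, id=f"v{p}", ref="A", alt="C")
            for p in positions
        ]

    def test_neighbour_at_100_removes_both(self):
        cat = self.make([5000, 5100])
        assert flank_uniqueness_filter(cat, cat, flank_bp=100) == []

    def test_neighbour_at_101_keeps_both(self):
        cat = self.make([5000, 5101])
        assert flank_uniqueness_filter(cat, cat, flank_bp=100) == ["v5000", "v5101"]

    def test_catalogue_neighbour_counts_even_if_filtered_out(self):
        cat = self.make([5000, 5050, 9000])
        survivors = [cat[0], cat[2]]  # 5050 already dropped upstream
        assert flank_uniqueness_filter(survivors, cat, flank_bp=100) == ["v9000"]

    def test_different_chromosome_is_no_neighbour(self):
        a = MarkerRecord(chrom="chr1", pos=5000, id="a", ref="A", alt="C")
        b = MarkerRecord(chrom="chr2", pos=5010, id="b", ref="A", alt="C")
        assert flank_uniqueness_filter([a, b], [a, b], flank_bp=100) == ["a", "b"]


class TestCorePanelSelection:
    def test_hard_constraints(self):
        stats = stats_frame([
            {"missing_rate": 0.1},            # any missingness disqualifies
            {"het_obs": 0.2},                 # too heterozygous
            {"maf": 0.33},                    # below panel MAF floor
            {},                               # eligible
        ])
        sel = select_core_panel(stats, FilterCriteria(), n_total=4)
        assert sel.marker_ids == ["m003"]
        assert sel.infeasible

    def test_round_robin_across_chromosomes(self):
        stats = stats_frame([
            {"chrom": "chr1", "pic": 0.375},
            {"chrom": "chr1", "pic": 0.374},
            {"chrom": "chr2", "pic": 0.350},
        ])
        sel = select_core_panel(stats, FilterCriteria(), n_total=2)
        # one from each chromosome before the second chr1 marker
        assert sel.marker_ids == ["m000", "m002"]
        assert not sel.infeasible

    def test_rank_by_pic_then_maf(self):
        stats = stats_frame([
            {"pic": 0.36, "maf": 0.40},
            {"pic": 0.37, "maf": 0.34},
            {"pic": 0.36, "maf": 0.45},
        ])
        sel = select_core_panel(stats, FilterCriteria(), n_total=3)
        assert sel.marker_ids == ["m001", "m002", "m000"]


class TestRunCascade:
    def test_engineered_panel_recovers_exactly_the_good_loci(self):
        gm, good_ids = engineered_cascade_gm()
        result = run_cascade(gm)
        assert sorted(result.core_panel) == good_ids
        assert result.candidate_panel == []
        # each stage's survivor count never increases
        counts = [(s.n_input, s.n_surviving) for s in result.report.stages]
        assert all(a >= b for a, b in counts)
        by_name = {s.name: s for s in result.report.stages}
        assert "bad_missing" in by_name["prefilter"].removed
        assert "bad_rare" in by_name["prefilter"].removed
        assert "bad_maf" in by_name["pic"].removed
        assert by_name["ld_prune"].removed == ["ld_b"]
        assert set(by_name["flank_uniqueness"].removed) == {"flank_a", "flank_b"}
        assert set(result.survivors) == set(good_ids) | {"ld_a", "bad_het"}

    def test_rerun_is_deterministic(self):
        gm, _ = engineered_cascade_gm()
        r1, r2 = run_cascade(gm), run_cascade(gm)
        assert r1.core_panel == r2.core_panel
        assert r1.report.to_frame().equals(r2.report.to_frame())

    def test_core_candidate_split_by_rank(self):
        gm, good_ids = engineered_cascade_gm()
        result = run_cascade(gm, core_size=8, candidate_size=4)
        assert len(result.core_panel) == 8
        assert len(result.candidate_panel) == 4
        assert set(result.core_panel + result.candidate_panel) == set(good_ids)
        assert not set(result.core_panel) & set(result.candidate_panel)

    def test_report_round_trips_to_disk(self, tmp_path):
        gm, _ = engineered_cascade_gm()
        result = run_cascade(gm)
        tsv, js = tmp_path / "r.tsv", tmp_path / "r.json"
        result.report.write(str(tsv), str(js))
        frame = pd.read_csv(tsv, sep="\t")
        assert list(frame["stage"]) == [s.name for s in result.report.stages]
        import json
        payload = json.loads(js.read_text())
        assert payload[0]["stage"] == "prefilter"
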