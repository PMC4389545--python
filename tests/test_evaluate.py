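import numpy as np
import pytest
from scipy import stats

from agetpl.evaluate import (
    SOURCE_COHORT_COUNTS,
    VARIANT_LABELS,
    age_offset_analysis,
    anova_oneway,
    dice,
    dice_soft,
    expand_cohort_counts,
    five_year_offset_grid,
    offset_trend,
    run_variant_harness,
    summarize_cohort,
    tissue_volumes,
    volumetric_trend_report,
)
from agetpl.phantom import PhantomSpec, analytic_compartment_volumes, make_phantom
from agetpl.volume import GeometryError, PVEMap


class TestDice:
    def test_identical_nonempty(self):
        m = np.zeros((5, 5, 5), bool)
        m[1:3] = True
        assert dice(m, m) == 1.0

    def test_disjoint(self):
        a = np.zeros((5, 5, 5), bool)
        b = np.zeros((5, 5, 5), bool)
        a[0], b[4] = True, True
        assert dice(a, b) == 0.0

    def test_hand_counted(self):
        a = np.zeros((8,), bool).reshape(2, 2, 2)
        b = np.zeros((8,), bool).reshape(2, 2, 2)
        a.flat[:2] = True          # |A| = 2
        b.flat[:4] = True          # |B| = 4, |A n B| = 2
        assert dice(a, b) == pytest.approx(2 * 2 / (2 + 4), abs=1e-4)

    def test_symmetry(self):
        rng = np.random.default_rng(0)
        a = rng.random((6, 6, 6)) > 0.5
        b = rng.random((6, 6, 6)) > 0.5
        assert dice(a, b) == dice(b, a)

    def test_both_empty_is_one(self):
        z = np.zeros((3, 3, 3), bool)
        assert dice(z, z) == 1.0

    def test_grid_mismatch_rejected(self):
        with pytest.raises(GeometryError):
            dice(np.zeros((3, 3, 3), bool), np.zeros((4, 4, 4), bool))

    def test_soft_dice_identical(self, clean_case):
        assert dice_soft(clean_case.truth_pve, clean_case.truth_pve, "gm") == 1.0


class TestAnova:
    def test_identical_groups_f_zero(self):
        f, *_ = anova_oneway([1.0, 1.0, 2.0, 2.0], ["a", "a", "b", "b"])
        # groups {1,1} and {2,2}: no within variance -> inf; identical values
        f2, *_ = anova_oneway([3.0, 3.0, 3.0, 3.0], ["a", "a", "b", "b"])
        assert f2 == 0.0

    def test_hand_computed_f(self):
        f, dfb, dfw, p = anova_oneway([1, 2, 3, 4, 5, 6],
                                      ["a", "a", "a", "b", "b", "b"])
        assert f == pytest.approx(13.5)
        assert (dfb, dfw) == (1, 4)
        assert p == pytest.approx(stats.f.sf(13.5, 1, 4))

    def test_permutation_within_groups_invariant(self):
        vals = [1, 3, 2, 6, 4, 5]
        f1, *_ = anova_oneway(vals, ["a", "a", "a", "b", "b", "b"])
        f2, *_ = anova_oneway([3, 2, 1, 5, 6, 4], ["a", "a", "a", "b", "b", "b"])
        assert f1 == pytest.approx(f2)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            anova_oneway([1, 2], ["a", "a"])


class TestTissueVolumes:
    def _pve(self, gm_value, shape=(10, 10, 10)):
        maps = {"om": np.zeros(shape), "gm": np.full(shape, gm_value),
                "wm": np.zeros(shape)}
        maps["om"] = 1.0 - maps["gm"]
        return PVEMap(maps, np.ones(shape, bool), np.eye(4))

    def test_full_gm_cube(self):
        v = tissue_volumes(self._pve(1.0))
        assert v["gm"] == pytest.approx(1000.0)

    def test_half_gm_cube(self):
        v = tissue_volumes(self._pve(0.5))
        assert v["gm"] == pytest.approx(500.0)
        assert v["gm_wm"] == pytest.approx(500.0)

    def test_phantom_matches_analytic(self, clean_case):
        v = tissue_volumes(clean_case.truth_pve,
                           clean_case.head.voxel_volume)
        ana = analytic_compartment_volumes(clean_case.spec)
        for k in ("om", "gm", "wm"):
            assert v[k] == pytest.approx(ana[k], rel=0.02)


class TestDemographics:
    def test_published_counts_reproduced(self):
        table = summarize_cohort(expand_cohort_counts())
        assert table.loc["total", "total"] == 1162
        assert table.loc["total", "pct_female"] == 60
        assert table.loc["20-24", "total"] == 244
        row = table.loc["20-24"]
        assert [row[s] for s in ("ixi", "mcbi", "nihpd", "oasis_cs",
                                 "oasis_long")] == [42, 88, 26, 88, 0]
        assert table.loc["20-24", "pct_female"] == 57

    def test_empty_input_all_zero(self):
        table = summarize_cohort([])
        assert table["total"].sum() == 0

    def test_age_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            summarize_cohort([(95.0, "F", "ixi")])

    def test_counts_rows_internally_consistent(self):
        for row in SOURCE_COHORT_COUNTS:
            srcs = row["ixi"] + row["mcbi"] + row["nihpd"] + \
                row["oasis_cs"] + row["oasis_long"]
            assert srcs == row["total"]


class TestOffsetGrid:
    def test_26_distinct_nonzero_offsets(self):
        offsets = five_year_offset_grid()
        assert len(offsets) == 26
        assert 0 not in offsets
        assert min(offsets) == -13 and max(offsets) == 13


class TestVariantHarness:
    def test_closed_variant_set(self, harness_setup):
        records = run_variant_harness([harness_setup["case"]],
                                      harness_setup["library"])
        labels = {r.config_label for r in records}
        assert labels == set(VARIANT_LABELS)
        assert len(VARIANT_LABELS) == 11
        assert len(records) == 11 * 2  # GM and WM per variant

    def test_self_reference_dice_one(self, harness_setup):
        from agetpl.segment import classify_hard, label_mask, segment_em

        case = harness_setup["case"]
        res = segment_em(case.volume, case.mask)
        hard = classify_hard(res.pve)
        from dataclasses import replace

        self_case = replace(case, reference_labels=hard)
        records = run_variant_harness([self_case], harness_setup["library"])
        image_gm = [r for r in records
                    if r.config_label == "image" and r.tissue == "gm"][0]
        assert image_gm.dice == pytest.approx(1.0)

    def test_missing_library_entry_named(self, harness_setup):
        from dataclasses import replace

        stray = replace(harness_setup["case"], age=45.0)
        with pytest.raises(KeyError, match="45-49"):
            run_variant_harness([stray], harness_setup["library"])


class TestAgeOffsetAnalysis:
    def test_offset_zero_dice_one(self, offset_setup):
        records = age_offset_analysis(offset_setup["subsample"][:2],
                                      offset_setup["library"])
        zero = [r for r in records if r.template_offset == 0]
        assert zero and all(r.dice == 1.0 for r in zero)

    def test_youngest_case_offsets_all_positive(self, offset_setup):
        case = offset_setup["subsample"][0]
        assert 20 <= case.age <= 24
        records = age_offset_analysis([case], offset_setup["library"])
        assert all(r.template_offset >= 0 for r in records)
        assert {r.template_offset for r in records} == set(range(14))

    def test_dice_decays_with_offset(self, offset_setup):
        records = age_offset_analysis(offset_setup["subsample"],
                                      offset_setup["library"])
        rho, p = offset_trend(records, "gm")
        assert rho < 0
        assert p < 0.05
        by_abs = {}
        for r in records:
            if r.tissue == "gm" and r.template_offset != 0:
                by_abs.setdefault(abs(r.template_offset), []).append(r.dice)
        means = [np.mean(by_abs[k]) for k in sorted(by_abs)]
        # near offsets overlap far better than distant ones
        assert np.mean(means[:3]) > np.mean(means[-3:]) + 0.05


class TestTrendReport:
    def test_parameter_recovery_from_truth(self, offset_setup):
        cohort = offset_setup["cohort"]
        vols = [tissue_volumes(c.truth_pve, c.head.voxel_volume)
                for c in cohort]
        ages = [c.age for c in cohort]
        skulls = [float(c.inner_skull_mask.sum()) * c.head.voxel_volume
                  for c in cohort]
        rep = volumetric_trend_report(vols, ages, skulls)
        spec = cohort[0].spec
        v_brain = 4 / 3 * np.pi * spec.brain_radius**3
        true_slope = spec.gm_slope * v_brain
        lo, hi = rep.gm_slope_ci
        assert lo <= true_slope <= hi
        assert rep.wm_vertex_age == pytest.approx(spec.wm_peak_age, abs=5.0)

    def test_gm_wm_bounded_by_inner_skull(self, offset_setup):
        for c in offset_setup["cohort"]:
            v = tissue_volumes(c.truth_pve, c.head.voxel_volume)
            skull = float(c.inner_skull_mask.sum()) * c.head.voxel_volume
            assert v["gm_wm"] <= skull

    def test_table_has_sem_columns(self, offset_setup):
        cohort = offset_setup["cohort"][:8]
        vols = [tissue_volumes(c.truth_pve, c.head.voxel_volume) for c in cohort]
        rep = volumetric_trend_report(vols, [c.age for c in cohort])
        assert ("gm", "sem") in rep.table.columns
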