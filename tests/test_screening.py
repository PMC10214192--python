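import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from splicescreen import synthetic_fixtures as sf
from splicescreen.panel_store import ReferencePanel, mask_low_coverage
from splicescreen.screening import (ScreenConfig, ScreenRecord, cpm_matrix,
                                    determine_enriched_isoform_and_fc,
                                    fisher_exact_greater, run_screens,
                                    sj_cpm_screen, tumor_association_screen,
                                    tumor_recurrence_screen,
                                    tumor_specificity_screen, two_sample_t)
from splicescreen.types import SampleGroup

from .oracles import fisher_greater_bruteforce, t_test_closed_form


class TestTwoSampleT:
    # frozen vectors; expected values from the closed-form oracle
    X = [0.61, 0.58, 0.70, 0.66, 0.59, 0.72, 0.64]
    Y = [0.41, 0.44, 0.52, 0.38, 0.47, 0.50]

    @pytest.mark.parametrize("equal_var", [False, True])
    @pytest.mark.parametrize("alternative", ["two-sided", "greater", "less"])
    def test_matches_closed_form(self, equal_var, alternative):
        expected = t_test_closed_form(self.X, self.Y, equal_var, alternative)
        got = two_sample_t(np.array(self.X), np.array(self.Y),
                           equal_var=equal_var, alternative=alternative)
        assert got == pytest.approx(expected, abs=1e-10)

    def test_identical_groups_not_significant(self):
        x = np.array([0.2, 0.3, 0.4, 0.5])
        assert two_sample_t(x, x) == pytest.approx(1.0)

    def test_zero_variance_equal_means(self):
        assert two_sample_t(np.array([0.5] * 5), np.array([0.5] * 5)) == 1.0

    def test_zero_variance_different_means(self):
        assert two_sample_t(np.array([0.9] * 5), np.array([0.1] * 5)) == 0.0
        assert two_sample_t(np.array([0.1] * 5), np.array([0.9] * 5),
                            alternative="greater") == 1.0

    def test_nan_dropped(self):
        x = np.array([0.6, np.nan, 0.7, 0.65])
        y = np.array([0.4, 0.45, np.nan, 0.5])
        expected = t_test_closed_form([0.6, 0.7, 0.65], [0.4, 0.45, 0.5])
        assert two_sample_t(x, y) == pytest.approx(expected, abs=1e-12)

    def test_too_few_values_untestable(self):
        assert np.isnan(two_sample_t(np.array([0.5]), np.array([0.1, 0.2])))

    def test_null_calibration(self):
        # empirical type-I error at p < 0.01 within the binomial 99% CI
        rng = np.random.default_rng(42)
        reps = 10_000
        hits = 0
        for _ in range(reps):
            x = rng.normal(size=12)
            y = rng.normal(size=10)
            hits += two_sample_t(x, y) < 0.01
        rate = hits / reps
        ci = 2.5758 * math.sqrt(0.01 * 0.99 / reps)
        assert abs(rate - 0.01) <= ci


class TestFisher:
    def test_fully_disjoint_extreme_table(self):
        # 10/10 tumor expressing vs 0/50 normal: p = 1/C(60,10)
        p = fisher_exact_greater(10, 10, 0, 50)[0]
        assert p == pytest.approx(1 / math.comb(60, 10), rel=1e-12)
        assert p < 1e-6

    def test_no_expression_anywhere(self):
        assert fisher_exact_greater(0, 10, 0, 50)[0] == pytest.approx(1.0)

    @given(st.integers(1, 20), st.integers(1, 20),
           st.integers(0, 20), st.integers(0, 20), st.data())
    @settings(max_examples=200, deadline=None)
    def test_matches_bruteforce_enumeration(self, nt, nn, a_cap, c_cap, data):
        a = data.draw(st.integers(0, min(nt, a_cap)))
        c = data.draw(st.integers(0, min(nn, c_cap)))
        expected = fisher_greater_bruteforce(a, nt - a, c, nn - c)
        got = fisher_exact_greater(a, nt, c, nn)[0]
        assert got == pytest.approx(expected, abs=1e-12)

    def test_vectorized(self):
        p = fisher_exact_greater([10, 0], [10, 10], [0, 0], [50, 50])
        assert p.shape == (2,)
        assert p[1] == pytest.approx(1.0)


def _mini_panel(tumor_psi, normal_psis, tumor_counts=None, normal_counts=None,
                n_junc_counts=40):
    """One-event panel built directly from per-group PSI vectors."""
    events = sf._synthetic_events(1)
    ev = events[0]
    groups, psi_cols, psi_vals = {}, [], []
    sjc_cols = {}

    def add_group(gid, role, values, counts):
        ids = [f"{gid}_{i}" for i in range(len(values))]
        groups[gid] = SampleGroup(gid, role, ids,
                                  {s: 30_000_000 for s in ids})
        psi_cols.extend(ids)
        psi_vals.extend(values)
        for s, v, c in zip(ids, values, counts):
            inc = c if not np.isnan(v) else 0
            sjc_cols[s] = [inc, inc, max(n_junc_counts - inc, 0)]

    tcounts = tumor_counts or [n_junc_counts // 2] * len(tumor_psi)
    add_group("TUM", "tumor_query", tumor_psi, tcounts)
    for i, vals in enumerate(normal_psis):
        counts = (normal_counts[i] if normal_counts
                  else [n_junc_counts // 2] * len(vals))
        add_group(f"N{i}", "normal_reference", vals, counts)

    psi = pd.DataFrame([psi_vals], index=[ev.event_id], columns=psi_cols,
                       dtype=float)
    keys = [ev.inclusion_junctions[0].key(), ev.inclusion_junctions[1].key(),
            ev.skipping_junctions[0].key()]
    sjc = pd.DataFrame(sjc_cols, index=keys).astype(np.int64)
    return ReferencePanel(groups=groups, events={ev.event_id: ev},
                          psi=psi, sjc=sjc), ev


class TestAssociationScreen:
    def test_strong_inclusion_event(self):
        # tumor PSI ~0.27 vs ~0 in every normal tissue
        rng = np.random.default_rng(0)
        tumor = list(np.clip(rng.normal(0.27, 0.03, 12), 0, 1))
        normals = [list(np.abs(rng.normal(0.003, 0.002, 8))) for _ in range(11)]
        panel, ev = _mini_panel(tumor, normals)
        cfg = ScreenConfig()
        recs = tumor_association_screen(panel, panel.psi, "TUM", cfg)
        rec = recs[ev.event_id]
        assert rec.degree_of_association == 11
        assert rec.tumor_associated
        assert rec.tumor_enriched_isoform == "inclusion"
        assert all(c.delta_psi > 0.2 for c in rec.comparisons)

    def test_identical_groups_not_significant(self):
        vals = [0.31, 0.42, 0.55, 0.47, 0.39, 0.52]
        panel, ev = _mini_panel(vals, [vals] * 3)
        cfg = ScreenConfig(association_degree_min=1)
        rec = tumor_association_screen(panel, panel.psi, "TUM", cfg)[ev.event_id]
        assert rec.degree_of_association == 0
        assert not rec.tumor_associated

    def test_degree_counting_with_untestable_groups(self):
        rng = np.random.default_rng(1)
        tumor = list(rng.normal(0.7, 0.02, 10))
        low = [list(rng.normal(0.3, 0.02, 6)) for _ in range(9)]
        untestable = [[np.nan] * 6 for _ in range(2)]
        panel, ev = _mini_panel(tumor, low + untestable)
        rec = tumor_association_screen(panel, panel.psi, "TUM",
                                       ScreenConfig())[ev.event_id]
        assert rec.degree_of_association == 9
        assert rec.tumor_associated  # 9 >= 8; untestable is not disqualifying

    def test_opposite_direction_disqualifies(self):
        rng = np.random.default_rng(2)
        tumor = list(rng.normal(0.7, 0.02, 10))
        lower = [list(rng.normal(0.3, 0.02, 6)) for _ in range(9)]
        higher = [list(rng.normal(0.95, 0.01, 6))]
        panel, ev = _mini_panel(tumor, lower + higher)
        rec = tumor_association_screen(panel, panel.psi, "TUM",
                                       ScreenConfig())[ev.event_id]
        assert rec.degree_of_association == 9
        assert not rec.tumor_associated

    def test_min_tumor_nonmissing_enforced(self):
        tumor = [0.5, 0.6, np.nan, np.nan, np.nan, np.nan]
        panel, ev = _mini_panel(tumor, [[0.1] * 6] * 3)
        rec = tumor_association_screen(panel, panel.psi, "TUM",
                                       ScreenConfig())[ev.event_id]
        assert rec.skip_reason == "tumor_nonmissing_below_minimum"
        assert not rec.tumor_associated

    def test_delta_psi_threshold_is_strict(self):
        # means differ by exactly the threshold (binary-exact 0.0625) with
        # tiny variance: p is tiny but |dPSI| is not strictly greater, so
        # the comparison must not count as significant
        eps = 2.0 ** -12
        tumor = [0.5625 - eps, 0.5625, 0.5625 + eps]
        normal = [0.5 - eps, 0.5, 0.5 + eps]
        panel, ev = _mini_panel(tumor, [normal])
        cfg = ScreenConfig(association_degree_min=1,
                           delta_psi_threshold=0.0625)
        rec = tumor_association_screen(panel, panel.psi, "TUM", cfg)[ev.event_id]
        assert rec.comparisons[0].p_value < 0.01
        assert rec.comparisons[0].delta_psi == 0.0625
        assert not rec.comparisons[0].significant


class TestEnrichedIsoformAndFc:
    def _fc(self, tumor_mean_psi, normal_group_means, direction):
        rec = ScreenRecord(event_id="e")
        tumor = np.array([tumor_mean_psi] * 4)
        normal_mats = {f"g{i}": np.array([[m] * 4])
                       for i, m in enumerate(normal_group_means)}
        return determine_enriched_isoform_and_fc(rec, tumor, normal_mats, 0,
                                                 direction)

    def test_inclusion_enriched(self):
        isoform, fc, floored = self._fc(0.8, [0.2, 0.4], 1)
        assert isoform == "inclusion"
        assert fc == pytest.approx(0.8 / 0.3)
        assert not floored

    def test_skipping_enriched_uses_one_minus_psi(self):
        isoform, fc, _ = self._fc(0.1, [0.9, 0.9], -1)
        assert isoform == "skipping"
        assert fc == pytest.approx(0.9 / 0.1)

    def test_denominator_floor(self):
        isoform, fc, floored = self._fc(0.5, [0.0, 0.0], 1)
        assert fc == pytest.approx(0.5 / 0.01)
        assert floored

    def test_tissue_types_weighted_equally(self):
        # group means 0.2 (n=4) and 0.4 (n=4): pooled would differ if one
        # group had more samples; construct unequal sizes directly
        rec = ScreenRecord(event_id="e")
        tumor = np.array([0.8] * 3)
        normal_mats = {"small": np.array([[0.2, 0.2]]),
                       "large": np.array([[0.4] * 10])}
        _, fc, _ = determine_enriched_isoform_and_fc(rec, tumor, normal_mats,
                                                     0, 1)
        assert fc == pytest.approx(0.8 / 0.3)


class TestCpmScreen:
    def test_cpm_values(self):
        sjc = pd.DataFrame({"s1": [50], "s2": [0]}, index=["chr1:1-2:+"])
        totals = pd.Series({"s1": 25_000_000, "s2": 25_000_000})
        cpm = cpm_matrix(sjc, totals)
        assert cpm.loc["chr1:1-2:+", "s1"] == pytest.approx(2.0)
        assert cpm.loc["chr1:1-2:+", "s2"] == 0.0

    def test_missing_totals_error_names_samples(self):
        sjc = pd.DataFrame({"s1": [50]}, index=["chr1:1-2:+"])
        with pytest.raises(ValueError, match="s1"):
            cpm_matrix(sjc, pd.Series(dtype=float))

    def test_doubling_totals_halves_cpm(self):
        sjc = pd.DataFrame({"s1": [50]}, index=["chr1:1-2:+"])
        one = cpm_matrix(sjc, pd.Series({"s1": 25_000_000.0}))
        two = cpm_matrix(sjc, pd.Series({"s1": 50_000_000.0}))
        assert (two == one / 2).all().all()

    def test_event_pass_requires_all_enriched_junctions(self, planted_run):
        panel, truth, records, table = planted_run
        for rec in records.values():
            if rec.cpm_pass:
                cfg = ScreenConfig()
                assert all(d >= cfg.association_degree_min
                           for d in rec.cpm_degree.values())

    def test_scale_free_null_flags(self):
        # multiplying every R by 2 leaves pass/fail flags unchanged
        spec = sf.SyntheticSpec(n_normal_groups=4, samples_per_group=5,
                                n_tumor_samples=6, n_events=20,
                                n_planted_associated=2, seed=5)
        panel, truth = sf.generate_panel_with_cohort(spec)
        cfg = ScreenConfig(association_degree_min=3)
        masked = mask_low_coverage(panel)
        recs1 = tumor_association_screen(panel, masked, "TUMOR", cfg)
        sj_cpm_screen(panel, "TUMOR", cfg, recs1)
        flags1 = {e: r.cpm_pass for e, r in recs1.items()}

        groups2 = {
            gid: SampleGroup(gid, g.role, list(g.sample_ids),
                             {s: 2 * v for s, v in g.total_mapped_reads.items()})
            for gid, g in panel.groups.items()}
        panel2 = ReferencePanel(groups=groups2, events=dict(panel.events),
                                psi=panel.psi.copy(), sjc=panel.sjc.copy())
        recs2 = tumor_association_screen(panel2, masked, "TUMOR", cfg)
        sj_cpm_screen(panel2, "TUMOR", cfg, recs2)
        flags2 = {e: r.cpm_pass for e, r in recs2.items()}
        assert flags1 == flags2


class TestSpecificityScreen:
    def test_expressing_uses_at_or_above(self):
        # tumor counts exactly at threshold 5 count as expressing
        tumor = [0.5] * 10
        normals = [[0.5] * 10 for _ in range(3)]
        panel, ev = _mini_panel(tumor, normals,
                                tumor_counts=[5] * 10,
                                normal_counts=[[0] * 10] * 3)
        cfg = ScreenConfig(association_degree_min=1, specificity_degree_min=3)
        recs = tumor_association_screen(panel, panel.psi, "TUM", cfg)
        table = tumor_specificity_screen(panel, "TUM", cfg, recs)
        inc_key = ev.inclusion_junctions[0].key()
        assert table.loc[inc_key, "tumor_expressing_fraction"] == 1.0

    def test_event_specific_requires_all_isoform_junctions(self):
        rng = np.random.default_rng(3)
        tumor = list(rng.normal(0.7, 0.02, 10))
        normals = [list(rng.normal(0.2, 0.02, 30)) for _ in range(8)]
        panel, ev = _mini_panel(tumor, normals,
                                tumor_counts=[20] * 10,
                                normal_counts=[[0] * 30] * 8)
        # second inclusion junction expressed everywhere in normals
        j2 = ev.inclusion_junctions[1].key()
        panel.sjc.loc[j2, :] = 50
        cfg = ScreenConfig(specificity_degree_min=8)
        recs = tumor_association_screen(panel, panel.psi, "TUM", cfg)
        assert recs[ev.event_id].tumor_associated
        tumor_specificity_screen(panel, "TUM", cfg, recs)
        rec = recs[ev.event_id]
        assert rec.junction_specificity[ev.inclusion_junctions[0].key()]
        assert not rec.junction_specificity[j2]
        assert not rec.tumor_specific

    def test_specific_subset_of_associated(self, planted_run):
        _, _, records, _ = planted_run
        for rec in records.values():
            if rec.tumor_specific:
                assert rec.tumor_associated


class TestRecurrenceScreen:
    def _run(self, n_ref):
        spec = sf.SyntheticSpec(n_normal_groups=4, samples_per_group=12,
                                n_tumor_samples=14, n_events=30,
                                n_planted_associated=4, seed=13,
                                psi_noise_sd=0.25,
                                n_tumor_reference_groups=n_ref)
        panel, truth = sf.generate_panel_with_cohort(spec)
        cfg = ScreenConfig(association_degree_min=4, specificity_degree_min=4)
        masked = mask_low_coverage(panel)
        records = tumor_association_screen(panel, masked, "TUMOR", cfg)
        tumor_recurrence_screen(panel, masked, cfg, records)
        return truth, records

    def test_replicated_in_all_cohorts(self):
        truth, records = self._run(2)
        planted = truth.index[truth["planted_class"] == "associated"]
        flagged = [records[e].recurrent for e in planted
                   if records[e].tumor_associated]
        assert flagged and all(flagged)

    def test_no_cohorts_leaves_flags_none(self, caplog):
        with caplog.at_level("WARNING"):
            truth, records = self._run(0)
        assert all(r.recurrent is None for r in records.values())
        assert "skipped" in caplog.text


class TestMonotonicity:
    def test_tightening_thresholds_never_adds_events(self, planted_run):
        panel, truth, records, table = planted_run
        masked = mask_low_coverage(panel)
        base = int(table["tumor_associated"].sum())
        for tighter in (ScreenConfig(psi_p_threshold=0.001),
                        ScreenConfig(delta_psi_threshold=0.2),
                        ScreenConfig(association_degree_min=10)):
            recs = tumor_association_screen(panel, masked, "TUMOR", tighter)
            assert sum(r.tumor_associated for r in recs.values()) <= base

    def test_planted_recovery(self, planted_run):
        panel, truth, records, table = planted_run
        joined = truth.join(table)
        planted = joined[joined["planted_class"] == "specific"]
        nulls = joined[joined["planted_class"] == "null"]
        assert int(planted["tumor_specific"].sum()) >= 18
        assert int(nulls["tumor_specific"].sum()) == 0
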