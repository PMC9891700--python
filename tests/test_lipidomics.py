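"""Lipidomics QC chain: naming, drift, filtering, normalization, testing."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from siglipid import lipidomics as lq
from siglipid.io_formats import LipidFeatureTable, ValidationError


class TestParseLipidName:
    @pytest.mark.parametrize(
        "raw,cls,carbons,dbs",
        [
            ("PI 38:4", "PI", 38, 4),
            ("PI(38:4)", "PI", 38, 4),
            ("LPC 18:1", "LPC", 18, 1),
            ("TG 52:3", "TG", 52, 3),
        ],
    )
    def test_total_composition_form(self, raw, cls, carbons, dbs):
        name = lq.parse_lipid_name(raw)
        assert (name.lipid_class, name.total_carbons, name.total_double_bonds) == (
            cls, carbons, dbs,
        )
        assert name.chains is None

    def test_chain_level_form_sums(self):
        name = lq.parse_lipid_name("PI(18:0/20:4)")
        assert name.chains == ((18, 0), (20, 4))
        assert (name.total_carbons, name.total_double_bonds) == (38, 4)

    def test_unknown_class_errors(self):
        with pytest.raises(lq.LipidNameError, match="XYZ"):
            lq.parse_lipid_name("XYZ 1:2")

    def test_malformed_errors(self):
        with pytest.raises(lq.LipidNameError):
            lq.parse_lipid_name("PI 38")


class TestFitDrift:
    def test_constant_qc_gives_unit_factor(self, lipid_rows_factory, lipid_table_factory):
        table = lipid_table_factory(
            lipid_rows_factory(qc_areas=(100.0,) * 5, qc_indices=[1, 5, 10, 15, 20])
        )
        model = lq.fit_drift(table, "F1")
        np.testing.assert_allclose(model.factor(np.arange(1, 21)), 1.0, rtol=1e-9)

    def test_noiseless_linear_drift_corrected_to_tiny_cv(
        self, lipid_rows_factory, lipid_table_factory
    ):
        idx = [1, 5, 10, 15, 20, 25]
        areas = [100.0 * (1 + i / 25.0) for i in idx]  # 2x drift across the run
        table = lipid_table_factory(lipid_rows_factory(qc_areas=areas, qc_indices=idx))
        model = lq.fit_drift(table, "F1")
        corrected = lq.apply_drift_correction(table, {"F1": model})
        cv = lq.qc_cv_percent(corrected)["F1"]
        assert cv < 1e-6

    def test_three_qcs_flagged_uncorrectable(self, lipid_rows_factory, lipid_table_factory):
        table = lipid_table_factory(lipid_rows_factory(qc_areas=(90.0, 100.0, 110.0)))
        assert lq.fit_drift(table, "F1") is None
        assert "uncorrectable" in table.flags["F1"]

    def test_all_zero_qc_errors(self, lipid_rows_factory, lipid_table_factory):
        table = lipid_table_factory(lipid_rows_factory(qc_areas=(0.0,) * 4))
        with pytest.raises(ValidationError, match="zero"):
            lq.fit_drift(table, "F1")

    def test_spline_smoother_also_flattens_linear_drift(
        self, lipid_rows_factory, lipid_table_factory
    ):
        idx = [1, 5, 10, 15, 20, 25]
        areas = [100.0 * (1 + i / 25.0) for i in idx]
        table = lipid_table_factory(lipid_rows_factory(qc_areas=areas, qc_indices=idx))
        model = lq.fit_drift(table, "F1", smoother="spline")
        corrected = lq.apply_drift_correction(table, {"F1": model})
        assert lq.qc_cv_percent(corrected)["F1"] < 1.0


class TestApplyDriftCorrection:
    def test_missing_model_for_correctable_feature_errors(
        self, lipid_rows_factory, lipid_table_factory
    ):
        table = lipid_table_factory(lipid_rows_factory(qc_areas=(90.0, 100.0, 105.0, 110.0)))
        with pytest.raises(ValueError, match="no drift model"):
            lq.apply_drift_correction(table, {})

    def test_uncorrectable_feature_passes_through(
        self, lipid_rows_factory, lipid_table_factory
    ):
        table = lipid_table_factory(lipid_rows_factory(qc_areas=(90.0, 100.0, 110.0)))
        table.flags  # built in constructor
        lq.fit_drift(table, "F1")  # flags uncorrectable
        out = lq.apply_drift_correction(table, {})
        np.testing.assert_allclose(
            out.data["peak_area"].to_numpy(), table.data["peak_area"].to_numpy()
        )

    def test_audit_column_retains_raw_areas(self, lipid_rows_factory, lipid_table_factory):
        idx = [1, 5, 10, 15]
        areas = [100.0, 120.0, 140.0, 160.0]
        table = lipid_table_factory(lipid_rows_factory(qc_areas=areas, qc_indices=idx))
        out = lq.apply_drift_correction(table, lq.fit_drift_models(table))
        np.testing.assert_allclose(out.data["peak_area_raw"].to_numpy(), areas)

    def test_same_index_rank_order_preserved(self):
        # two features measured across shared injections: correction is a
        # per-(feature, index) scalar, so within-feature sample ranking at
        # equal index cannot change; check across a simulated run
        from siglipid.simulate import gen_lipid_run

        table, _ = gen_lipid_run(n_samples_per_group=4, drift_amplitude=1.8,
                                 noise_cv=0.05, seed=2, irreproducible_fraction=0.0,
                                 species=["PI 38:4", "PC 34:1"], species_folds={})
        out = lq.apply_drift_correction(table, lq.fit_drift_models(table))
        for fid in table.feature_ids:
            pre = table.data[table.data["feature_id"] == fid].sort_values("injection_index")
            post = out.data[out.data["feature_id"] == fid].sort_values("injection_index")
            assert (post["peak_area"].to_numpy() > 0).all()
            # factors positive -> sign of area differences within an index kept
            np.testing.assert_array_equal(
                pre["sample_id"].to_numpy(), post["sample_id"].to_numpy()
            )

    def test_refit_after_correction_is_near_identity(
        self, lipid_rows_factory, lipid_table_factory
    ):
        """Correcting a smoother-representable drift twice changes nothing.

        Noiseless linear 2x drift over 11 QCs: the second-pass factors
        must sit within 2% of unity.
        """
        idx = list(range(1, 45, 4))
        areas = [100.0 * (1 + (i - 1) / (idx[-1] - 1)) for i in idx]
        table = lipid_table_factory(lipid_rows_factory(qc_areas=areas, qc_indices=idx))
        out = lq.apply_drift_correction(table, lq.fit_drift_models(table))
        for fid, model in lq.fit_drift_models(out).items():
            factors = model.factor(model.qc_injection_indices)
            np.testing.assert_allclose(factors, 1.0, atol=0.02)


class TestCvFilter:
    def test_zero_cv_retained(self, lipid_rows_factory, lipid_table_factory):
        table = lipid_table_factory(lipid_rows_factory(qc_areas=(100.0, 100.0, 100.0)))
        kept, report = lq.cv_filter(table)
        assert kept.feature_ids == ["F1"] and report.empty

    def test_cv_50_removed(self, lipid_rows_factory, lipid_table_factory):
        table = lipid_table_factory(lipid_rows_factory(qc_areas=(50.0, 100.0, 150.0)))
        kept, report = lq.cv_filter(table)
        assert kept.feature_ids == []
        assert report.iloc[0]["qc_cv_percent"] == pytest.approx(50.0)

    def test_boundary_exactly_30_retained(self, lipid_rows_factory, lipid_table_factory):
        # areas chosen so sample SD/mean is exactly 0.30
        areas = (100.0 - 30.0, 100.0, 100.0 + 30.0)
        sd = np.std(areas, ddof=1)
        scaled = tuple(a * 30.0 / (sd / np.mean(areas) * 100.0) for a in areas)
        table = lipid_table_factory(lipid_rows_factory(qc_areas=scaled))
        cv = lq.qc_cv_percent(table)["F1"]
        assert cv == pytest.approx(30.0)
        kept, _ = lq.cv_filter(table, threshold_percent=30.0)
        assert kept.feature_ids == ["F1"]

    def test_single_qc_flagged_unassessable(self, lipid_rows_factory, lipid_table_factory):
        table = lipid_table_factory(lipid_rows_factory(qc_areas=(100.0,)))
        kept, _ = lq.cv_filter(table)
        assert kept.feature_ids == ["F1"]
        assert "cv_unassessable" in kept.flags["F1"]

    def test_monotone_in_threshold(self, lipid_rows_factory, lipid_table_factory):
        rng = np.random.default_rng(3)
        groups = [
            lipid_rows_factory(feature_id=f"F{i}",
                               qc_areas=tuple(rng.uniform(50, 150, size=5)),
                               start_index=1 + 10 * i)
            for i in range(12)
        ]
        table = lipid_table_factory(*groups)
        prev: set[str] = set()
        for thr in (10.0, 20.0, 30.0, 50.0, 100.0):
            kept, _ = lq.cv_filter(table, threshold_percent=thr)
            now = set(kept.feature_ids)
            assert prev <= now
            prev = now


class TestDilutionLinearity:
    def _table(self, factory_rows, factory_table, dilution):
        return factory_table(factory_rows(qc_areas=(100.0,) * 4, dilution=dilution))

    def test_proportional_series_passes(self, lipid_rows_factory, lipid_table_factory):
        dil = [(f, 1000 * f) for f in (1.0, 0.5, 0.25, 0.125, 0.0625)]
        table = self._table(lipid_rows_factory, lipid_table_factory, dil)
        res = lq.dilution_linearity(table, "F1")
        assert res.verdict == "pass" and res.r == pytest.approx(1.0)

    def test_flat_response_fails(self, lipid_rows_factory, lipid_table_factory):
        dil = [(f, 500.0) for f in (1.0, 0.5, 0.25, 0.125, 0.0625)]
        table = self._table(lipid_rows_factory, lipid_table_factory, dil)
        assert lq.dilution_linearity(table, "F1").verdict == "fail"

    def test_saturating_response_hand_pearson(self, lipid_rows_factory, lipid_table_factory):
        fracs = (1.0, 0.5, 0.25, 0.125, 0.0625)
        areas = (100.0, 99.0, 95.0, 60.0, 35.0)
        dil = list(zip(fracs, areas))
        table = self._table(lipid_rows_factory, lipid_table_factory, dil)
        res = lq.dilution_linearity(table, "F1", min_r=0.9)
        want_r = stats.pearsonr(fracs, areas).statistic
        assert res.r == pytest.approx(want_r, rel=1e-12)
        assert res.verdict == ("pass" if want_r >= 0.9 else "fail")

    def test_insufficient_points(self, lipid_rows_factory, lipid_table_factory):
        dil = [(1.0, 100.0), (0.5, 50.0), (0.25, 25.0)]
        table = self._table(lipid_rows_factory, lipid_table_factory, dil)
        assert lq.dilution_linearity(table, "F1").verdict == "insufficient"


class TestProteinNormalize:
    def test_unit_protein_unchanged(self, lipid_rows_factory, lipid_table_factory):
        table = lipid_table_factory(
            lipid_rows_factory(sample_areas=(100.0, 200.0), protein=(1.0, 1.0))
        )
        out = lq.protein_normalize(table)
        sample = out.data[out.data["sample_type"] == "sample"]
        np.testing.assert_allclose(sample["peak_area"].to_numpy(), [100.0, 200.0])

    def test_two_ug_halves(self, lipid_rows_factory, lipid_table_factory):
        table = lipid_table_factory(
            lipid_rows_factory(sample_areas=(100.0,), protein=(2.0,))
        )
        out = lq.protein_normalize(table)
        assert out.data[out.data["sample_type"] == "sample"]["peak_area"].iloc[0] == 50.0

    def test_qcs_exempt(self, lipid_rows_factory, lipid_table_factory):
        table = lipid_table_factory(
            lipid_rows_factory(qc_areas=(80.0, 90.0, 100.0, 110.0),
                               sample_areas=(100.0,), protein=(4.0,))
        )
        out = lq.protein_normalize(table)
        qc = out.data[out.data["sample_type"] == "qc"]
        np.testing.assert_allclose(qc["peak_area"].to_numpy(), [80.0, 90.0, 100.0, 110.0])

    def test_missing_protein_errors(self, lipid_rows_factory, lipid_table_factory):
        table = lipid_table_factory(
            lipid_rows_factory(sample_areas=(100.0,), protein=(np.nan,))
        )
        with pytest.raises(ValidationError, match="protein"):
            lq.protein_normalize(table)

    def test_commutes_with_drift_correction(self, lipid_rows_factory, lipid_table_factory):
        idx = [1, 5, 9, 13]
        table = lipid_table_factory(
            lipid_rows_factory(qc_areas=(100.0, 120.0, 140.0, 160.0), qc_indices=idx,
                               sample_areas=(100.0, 150.0), protein=(2.0, 4.0))
        )
        models = lq.fit_drift_models(table)
        a = lq.protein_normalize(lq.apply_drift_correction(table, models))
        b = lq.apply_drift_correction(lq.protein_normalize(table), models)
        np.testing.assert_allclose(
            a.data["peak_area"].to_numpy(), b.data["peak_area"].to_numpy(), rtol=1e-12
        )


class TestAggregation:
    def test_class_totals(self, lipid_rows_factory, lipid_table_factory):
        table = lipid_table_factory(
            lipid_rows_factory(feature_id="F1", lipid_name="PI 38:4",
                               sample_areas=(10.0,), start_index=1),
            lipid_rows_factory(feature_id="F2", lipid_name="PI 36:2",
                               sample_areas=(15.0,), start_index=20),
        )
        agg = lq.aggregate_by_class(table)
        pi = agg[agg["lipid_class"] == "PI"]
        assert pi["total_area"].iloc[0] == pytest.approx(25.0)
        assert pi["n_species"].iloc[0] == 2

    def test_sum_conservation_over_random_table(self):
        from siglipid.simulate import gen_lipid_run

        table, _ = gen_lipid_run(n_samples_per_group=3, seed=8, noise_cv=0.1,
                                 irreproducible_fraction=0.0)
        agg = lq.aggregate_by_class(table)
        total_species = table.data.loc[
            table.data["sample_type"] == "sample", "peak_area"
        ].sum()
        assert agg["total_area"].sum() == pytest.approx(total_species, rel=1e-9)


class TestDifferentialAbundance:
    def _two_group_table(self, factory_rows, factory_table, folds):
        groups = []
        start = 1
        for i, (name, fold) in enumerate(folds.items()):
            a_vals = (10.0, 11.0, 9.0)
            b_vals = tuple(v * fold for v in a_vals)
            groups.append(
                factory_rows(
                    feature_id=f"F{i+1}", lipid_name=name,
                    qc_areas=(100.0,) * 3,
                    sample_areas=a_vals + b_vals,
                    sample_ids=[f"A{k}" for k in range(3)] + [f"B{k}" for k in range(3)],
                    groups=["A"] * 3 + ["B"] * 3,
                    protein=(1.0,) * 6,
                    start_index=start,
                )
            )
            start += 20
        return factory_table(*groups)

    def test_identical_groups(self, lipid_rows_factory, lipid_table_factory):
        table = self._two_group_table(lipid_rows_factory, lipid_table_factory,
                                      {"PI 38:4": 1.0})
        res = lq.differential_abundance(table, "A", "B")[0]
        assert res.mean_fold == pytest.approx(1.0)
        assert res.percent_change == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_average_percent_increase_hand_example(
        self, lipid_rows_factory, lipid_table_factory
    ):
        """Two species at folds 1.5 and 2.0 average a +75% change."""
        table = self._two_group_table(lipid_rows_factory, lipid_table_factory,
                                      {"PI 38:4": 1.5, "PI 36:2": 2.0})
        species = lq.differential_abundance(table, "A", "B", level="species")
        summary = lq.class_change_summary(species, table)
        pi = [s for s in summary if s.lipid_class == "PI"][0]
        assert pi.avg_percent_change == pytest.approx(75.0, rel=1e-9)
        assert pi.n_increased == 2

    def test_bh_q_at_least_p(self, lipid_rows_factory, lipid_table_factory):
        table = self._two_group_table(
            lipid_rows_factory, lipid_table_factory,
            {"PI 38:4": 1.5, "PC 34:1": 0.8, "PE 36:2": 1.0},
        )
        for res in lq.differential_abundance(table, "A", "B"):
            assert res.q_value >= res.p_value - 1e-12

    def test_class_level_n_species(self, lipid_rows_factory, lipid_table_factory):
        table = self._two_group_table(lipid_rows_factory, lipid_table_factory,
                                      {"PI 38:4": 1.5, "PI 36:2": 2.0})
        cls = lq.differential_abundance(table, "A", "B", level="class")
        pi = [r for r in cls if r.key == "PI"][0]
        assert pi.n_species == 2
        assert pi.mean_fold == pytest.approx((1.5 + 2.0) / 2, rel=0.1)

    def test_missing_group_skipped_with_flag(self, lipid_rows_factory, lipid_table_factory):
        table = lipid_table_factory(
            lipid_rows_factory(sample_areas=(10.0, 11.0), groups=["A", "A"],
                               protein=(1.0, 1.0))
        )
        res = lq.differential_abundance(table, "A", "B")[0]
        assert res.flags == "insufficient_replicates"
        assert math.isnan(res.mean_fold)
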