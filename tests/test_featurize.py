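import numpy as np
import pandas as pd
import pytest

from ifptml.assaydb import DescriptorTable, HydrogelComponent, Ink
from ifptml.featurize import (
    MISSING_TOKEN,
    PTFeaturizer,
    assemble_assay_frame,
    build_design_matrix,
    fit_group_means,
    mix_descriptors,
    pt_operator,
    reference_function,
    scale_descriptors,
)
from ifptml.fusion import FusedRecord, fuse_dataset
from .conftest import make_record


class TestMixDescriptors:
    def test_single_component_is_identity(self, descriptor_table):
        ink = Ink((HydrogelComponent("monoA", "C", 2.7),))
        mixed = mix_descriptors(ink, descriptor_table)
        pd.testing.assert_series_equal(mixed, descriptor_table.row("monoA"))

    def test_weighted_sum(self, descriptor_table):
        # 1.5 : 0.5 concentrations weight W = 10 and 2 as 0.75/0.25
        ink = Ink((HydrogelComponent("monoA", "C", 1.5),
                   HydrogelComponent("monoB", "C", 0.5)))
        assert mix_descriptors(ink, descriptor_table)["W"] == pytest.approx(8.0)

    def test_equal_concentrations_midpoint(self, descriptor_table):
        ink = Ink((HydrogelComponent("monoA", "C", 1.0),
                   HydrogelComponent("monoB", "C", 1.0)))
        assert mix_descriptors(ink, descriptor_table)["W"] == pytest.approx(6.0)

    def test_permutation_and_scale_invariance(self, descriptor_table):
        a = HydrogelComponent("monoA", "C", 1.2)
        b = HydrogelComponent("monoB", "C", 0.4)
        a3 = HydrogelComponent("monoA", "C", 3.6)
        b3 = HydrogelComponent("monoB", "C", 1.2)
        m1 = mix_descriptors(Ink((a, b)), descriptor_table)
        m2 = mix_descriptors(Ink((b, a)), descriptor_table)
        m3 = mix_descriptors(Ink((a3, b3)), descriptor_table)
        pd.testing.assert_series_equal(m1, m2)
        pd.testing.assert_series_equal(m1, m3)

    def test_zero_concentration_rejected(self, descriptor_table):
        ink = Ink((HydrogelComponent("monoA", "C", 0.0),))
        with pytest.raises(ValueError, match="concentration"):
            mix_descriptors(ink, descriptor_table)


class TestScaling:
    def test_min_max_to_unit_interval(self):
        frame = pd.DataFrame({"d": [0.0, 5.0, 10.0]})
        scaled, mn, rng, const = scale_descriptors(frame)
        assert list(scaled["d"]) == [0.0, 0.5, 1.0]
        assert const == []

    def test_constant_column_flagged_and_zeroed(self):
        frame = pd.DataFrame({"d": [3.0, 3.0], "e": [0.0, 1.0]})
        scaled, _, _, const = scale_descriptors(frame)
        assert const == ["d"]
        assert (scaled["d"] == 0).all()

    def test_unseen_value_extrapolates_without_clipping(self):
        frame = pd.DataFrame({"d": [0.0, 10.0]})
        _, mn, rng, _ = scale_descriptors(frame)
        assert (20.0 - mn["d"]) / rng["d"] == pytest.approx(2.0)


class TestReferenceFunction:
    def _fused(self, outcomes, prop="U"):
        return [
            FusedRecord(make_record(f"r{i}", prop=prop, value=1.0), o)
            for i, o in enumerate(outcomes)
        ]

    def test_positive_fraction_per_group(self):
        ref = reference_function(self._fused([1, 1, 0, 0]))
        assert ref["U"] == pytest.approx(0.5)

    def test_no_positives_gives_zero(self):
        assert reference_function(self._fused([0, 0, 0]))["U"] == 0.0

    def test_curated_group_counts(self):
        # a 98-assay group with 36 good prints has prior 36/98
        fused = self._fused([1] * 36 + [0] * 62)
        assert reference_function(fused)["U"] == pytest.approx(36 / 98)

    def test_probabilities_in_unit_interval_and_sizes_sum(self):
        fused = self._fused([1, 0, 1], prop="A") + self._fused([0], prop="B")
        ref = reference_function(fused)
        assert all(0 <= p <= 1 for p in ref.values())


def test_pt_operator_is_plain_deviation():
    assert pt_operator(0.5, 0.3) == pytest.approx(0.2)
    assert pt_operator(0.3, 0.3) == 0.0


def test_fit_group_means_arithmetic():
    scaled = pd.DataFrame({"d": [0.2, 0.4, 0.9]})
    conds = [make_record(f"r{i}", c1_pressure=p, value=1.0).conditions
             for i, p in enumerate([25.0, 25.0, 30.0])]
    means, global_means = fit_group_means(scaled, conds, j_set=[1])
    assert means[1][25.0]["d"] == pytest.approx(0.3)
    assert means[1][30.0]["d"] == pytest.approx(0.9)
    assert global_means["d"] == pytest.approx(0.5)


class TestPTFeaturizer:
    @pytest.fixture()
    def fitted(self, small_db):
        from ifptml.evaluate import split_dataset

        fused, _ = fuse_dataset(small_db.records, small_db.cutoffs)
        frame = assemble_assay_frame(fused, small_db.descriptors)
        y = frame.pop("outcome").to_numpy()
        tr, va = split_dataset(fused, y, seed=3)
        feat = PTFeaturizer().fit(frame.iloc[tr], y[tr])
        return feat, frame, y, tr, va

    def test_column_arity_and_order(self, fitted):
        feat, frame, *_ = fitted
        n_desc = len(feat.descriptor_names_)
        assert len(feat.feature_names_out_) == 1 + n_desc * 10
        assert feat.feature_names_out_[0] == "f_ref"
        X = feat.transform(frame)
        assert list(X.columns) == feat.feature_names_out_
        assert not X.isna().any().any()

    def test_groupwise_centering_on_training_rows(self, fitted):
        """Every perturbation column has zero mean within every training
        group of its conditioning variable (the defining identity of the
        moving-average operator)."""
        feat, frame, y, tr, _ = fitted
        X = feat.transform(frame.iloc[tr])
        for j in range(10):
            keys = frame.iloc[tr][f"c{j}"].map(
                lambda v, j=j: feat._group_key(j, v)
            )
            for k in feat.descriptor_names_:
                col = X[f"{k}__c{j}"]
                for _, grp in col.groupby(keys.to_numpy()):
                    assert abs(grp.mean()) < 1e-9

    def test_unseen_condition_value_uses_global_fallback(self, fitted):
        feat, frame, *_ = fitted
        row = frame.iloc[[0]].copy()
        row["c1"] = 12345.0  # never seen in training
        X = feat.transform(row)
        k = feat.descriptor_names_[0]
        scaled = (row[k].iloc[0] - feat.scale_min_[k]) / feat.scale_range_[k]
        assert X[f"{k}__c1"].iloc[0] == pytest.approx(
            scaled - feat.global_means_[k]
        )

    def test_training_only_fit_differs_from_all_data_fit(self, fitted):
        """Conditional means must come from the training partition only;
        fitting them on everything yields a different matrix."""
        feat, frame, y, tr, va = fitted
        feat_all = PTFeaturizer().fit(frame, y)
        X_tr_fit = feat.transform(frame.iloc[va])
        X_all_fit = feat_all.transform(frame.iloc[va])
        assert not np.allclose(X_tr_fit.to_numpy(), X_all_fit.to_numpy())

    def test_json_round_trip_reproduces_transform(self, fitted):
        feat, frame, *_ = fitted
        clone = PTFeaturizer.from_json(feat.to_json())
        pd.testing.assert_frame_equal(
            feat.transform(frame), clone.transform(frame)
        )

    def test_missing_descriptor_column_raises(self, fitted):
        feat, frame, *_ = fitted
        with pytest.raises(KeyError, match="missing at transform"):
            feat.transform(frame.drop(columns=feat.descriptor_names_[:1]))


def test_build_design_matrix_five_by_ten_gives_51_columns(small_db):
    fused, _ = fuse_dataset(small_db.records, small_db.cutoffs)
    names = small_db.descriptors.descriptor_names[:5]
    frame = assemble_assay_frame(fused, small_db.descriptors)
    y = frame.pop("outcome").to_numpy()
    feat = PTFeaturizer(descriptor_names=names).fit(frame, y)
    assert len(feat.feature_names_out_) == 51
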