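"""Feature tables, ensemble training, median combination and evaluation."""

import numpy as np
import pandas as pd
import pytest

from fviiirin import (FeatureTable, MutantRecord, build_feature_table,
                      ensemble_predict, evaluate, train_members)
from fviiirin.classifier import median_prediction_frame
from fviiirin.structure import ResidueKey
from oracles import auc_rank_oracle, kappa_oracle

TINY_GRIDS = dict(svm_gamma_grid=[0.1, 0.5], xgb_depth_grid=[2],
                  xgb_eta_grid=[0.3], xgb_lambda_grid=[1.0])


def _keys(n, chain="A"):
    return [ResidueKey(chain, i + 1, "", "ALA") for i in range(n)]


def _centrality_frame(n, seed=0, informative=True):
    rng = np.random.default_rng(seed)
    x = rng.normal(size=(n, 2))
    t = pd.DataFrame({"closeness": x[:, 0], "degree": x[:, 1]},
                     index=pd.Index(_keys(n)))
    return t


def _separable_table(n=60, seed=0) -> FeatureTable:
    """Two well-separated blobs: any sensible member classifies them."""
    rng = np.random.default_rng(seed)
    half = n // 2
    x = np.vstack([rng.normal(-3.0, 0.4, size=(half, 2)),
                   rng.normal(3.0, 0.4, size=(n - half, 2))])
    t = pd.DataFrame(x, columns=["closeness", "degree"],
                     index=pd.Index(_keys(n)))
    mutants = [MutantRecord(k, "ALA", 10.0 if i < half else 90.0, 50.0)
               for i, k in enumerate(t.index)]
    return build_feature_table(t, mutants, ["closeness", "degree"])


class TestMutantRecord:
    @pytest.mark.parametrize("pct,expected", [
        (80.0, "High"), (20.0, "Low"), (50.0, "Low"),
    ])
    def test_fifty_percent_split_with_conservative_tie(self, pct, expected):
        m = MutantRecord(_keys(1)[0], "ALA", pct, 50.0)
        assert m.label == expected

    def test_tie_rule_configurable(self):
        m = MutantRecord(_keys(1)[0], "ALA", 50.0, 50.0, tie_rule="high")
        assert m.label == "High"

    def test_negative_percentage_rejected(self):
        with pytest.raises(ValueError):
            MutantRecord(_keys(1)[0], "ALA", -1.0, 50.0)


class TestBuildFeatureTable:
    def test_unresolvable_mutant_dropped(self):
        t = _centrality_frame(10)
        outside = MutantRecord(ResidueKey("Z", 99, "", "ALA"), "ALA", 80.0, 80.0)
        inside = [MutantRecord(k, "ALA", float(20 + 10 * i), 50.0)
                  for i, k in enumerate(t.index)]
        ft = build_feature_table(t, inside + [outside], ["closeness", "degree"])
        assert len(ft) == 10

    def test_constant_feature_column_named_in_error(self):
        t = _centrality_frame(10)
        t["kcore"] = 4.0
        mutants = [MutantRecord(k, "ALA", 80.0, 80.0) for k in t.index]
        with pytest.raises(ValueError, match="kcore"):
            build_feature_table(t, mutants, ["closeness", "kcore"])

    def test_constant_feature_droppable_by_config(self):
        t = _centrality_frame(10)
        t["kcore"] = 4.0
        mutants = [MutantRecord(k, "ALA", 80.0, 80.0) for k in t.index]
        ft = build_feature_table(t, mutants, ["closeness", "kcore"],
                                 on_constant="drop")
        assert list(ft.x.columns) == ["closeness"]

    def test_rows_with_missing_attribute_removed(self):
        t = _centrality_frame(10)
        t.iloc[0, 0] = np.nan
        mutants = [MutantRecord(k, "ALA", float(20 + 10 * i), 50.0)
                   for i, k in enumerate(t.index)]
        ft = build_feature_table(t, mutants, ["closeness", "degree"])
        assert len(ft) == 9

    def test_empty_result_rejected(self):
        t = _centrality_frame(5)
        ghost = [MutantRecord(ResidueKey("Z", 9, "", "ALA"), "ALA", 1.0, 1.0)]
        with pytest.raises(ValueError):
            build_feature_table(t, ghost, ["closeness"])


class TestTrainMembers:
    def test_same_seed_reproduces_params_and_metrics(self):
        ft = _separable_table(seed=1)
        e1 = train_members(ft, folds=5, seed=7, **TINY_GRIDS)
        e2 = train_members(ft, folds=5, seed=7, **TINY_GRIDS)
        assert e1.chosen_params == e2.chosen_params
        pd.testing.assert_frame_equal(e1.fold_metrics, e2.fold_metrics)
        pd.testing.assert_frame_equal(e1.oof_probabilities,
                                      e2.oof_probabilities)

    def test_members_learn_linearly_separable_data(self):
        ft = _separable_table(seed=2)
        ens = train_members(ft, folds=5, seed=0, **TINY_GRIDS)
        for member in ("svm", "naive_bayes", "xgboost"):
            oof_pred = (ens.oof_probabilities[member] >= 0.5).astype(int)
            acc = float((oof_pred == ft.y).mean())
            assert acc >= 0.95, f"{member} CV accuracy {acc}"

    def test_single_class_input_rejected(self):
        t = _centrality_frame(30)
        mutants = [MutantRecord(k, "ALA", 90.0, 90.0) for k in t.index]
        ft = build_feature_table(t, mutants, ["closeness", "degree"])
        with pytest.raises(ValueError, match="class"):
            train_members(ft, folds=5, seed=0, **TINY_GRIDS)

    def test_too_few_instances_rejected(self):
        ft = _separable_table(n=12, seed=3)
        with pytest.raises(ValueError):
            train_members(ft, folds=10, seed=0, **TINY_GRIDS)


class TestEnsemblePredict:
    def _fake_members(self, ft):
        return train_members(ft, folds=5, seed=0, **TINY_GRIDS).members

    def test_median_is_middle_order_statistic_and_band_flags(self):
        frame = pd.DataFrame({
            "svm": [0.2, 0.9, 0.1], "naive_bayes": [0.5, 0.8, 0.2],
            "xgboost": [0.9, 0.95, 0.3],
        })
        frame["median"] = frame.median(axis=1)
        preds = median_prediction_frame(frame)
        assert preds["median_probability"].tolist() == [0.5, 0.9, 0.2]
        assert preds["predicted_label"].tolist() == ["High", "High", "Low"]
        assert preds["flagged"].tolist() == [True, False, False]

    def test_median_bounded_by_member_probabilities(self):
        ft = _separable_table(seed=4)
        members = self._fake_members(ft)
        out = ensemble_predict(members, ft.x)
        member_cols = out[["svm", "naive_bayes", "xgboost"]]
        assert (out["median_probability"] >= member_cols.min(axis=1) - 1e-12).all()
        assert (out["median_probability"] <= member_cols.max(axis=1) + 1e-12).all()

    def test_schema_mismatch_rejected(self):
        ft = _separable_table(seed=5)
        members = self._fake_members(ft)
        wrong = ft.x.rename(columns={"closeness": "betweenness"})
        with pytest.raises(Exception, match="[Ff]eature"):
            ensemble_predict(members, wrong)

    def test_invalid_flag_band_rejected(self):
        ft = _separable_table(seed=5)
        members = self._fake_members(ft)
        with pytest.raises(ValueError):
            ensemble_predict(members, ft.x, flag_band=(0.6, 0.4))


class TestEvaluate:
    def test_perfect_predictions(self):
        truth = [1, 1, 0, 0]
        m = evaluate([0.9, 0.8, 0.1, 0.2], [False] * 4, truth)
        assert m["accuracy"] == 1.0
        assert m["kappa"] == pytest.approx(1.0)
        assert m["auc"] == pytest.approx(1.0)

    def test_all_one_class_prediction_gives_zero_kappa(self):
        truth = [1, 0, 1, 0]
        m = evaluate([0.9, 0.9, 0.9, 0.9], [False] * 4, truth)
        assert m["kappa"] == pytest.approx(0.0)

    def test_kappa_matches_direct_formula_on_printed_table(self):
        # confusion counts (40, 10; 10, 40) -> kappa 0.6
        truth = [1] * 50 + [0] * 50
        probs = [0.9] * 40 + [0.1] * 10 + [0.9] * 10 + [0.1] * 40
        m = evaluate(probs, [False] * 100, truth)
        assert m["kappa"] == pytest.approx(kappa_oracle(40, 10, 10, 40))
        assert m["kappa"] == pytest.approx(0.6)

    def test_auc_matches_rank_statistic(self):
        rng = np.random.default_rng(6)
        truth = rng.integers(0, 2, size=40).tolist()
        truth[0], truth[1] = 0, 1
        probs = rng.random(40)
        m = evaluate(probs, [False] * 40, truth)
        assert m["auc"] == pytest.approx(auc_rank_oracle(truth, probs))

    def test_all_flagged_reports_missing_unflagged_accuracy(self):
        m = evaluate([0.5, 0.5, 0.45, 0.55], [True] * 4, [1, 0, 1, 0])
        assert m["accuracy_unflagged"] is None

    def test_widening_flag_band_never_decreases_unflagged_accuracy(self):
        rng = np.random.default_rng(8)
        probs = rng.random(200)
        truth = (probs + rng.normal(0, 0.3, 200) > 0.5).astype(int)
        if len(set(truth)) < 2:
            truth[0], truth[1] = 0, 1
        prev = -1.0
        for half_width in (0.02, 0.05, 0.1, 0.2, 0.3):
            flagged = (probs >= 0.5 - half_width) & (probs <= 0.5 + half_width)
            if flagged.all():
                break
            m = evaluate(probs, flagged, truth)
            assert m["accuracy_unflagged"] >= prev - 1e-12
            prev = m["accuracy_unflagged"]
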