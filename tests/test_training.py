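"""Curation, balanced sampling, forest training, backward selection and
model packaging."""

import numpy as np
import pandas as pd
import pytest

from varguide.fixtures import ActivityRule, generate_training_table
from varguide.training import (ActivityModel, SamplingShortfall,
                               TrainingError, average_importance,
                               backward_select, concentration_correlation,
                               label_by_concentration, sample_inactive,
                               select_final_model, train_models)


@pytest.fixture(scope="module")
def table():
    # the pool must out-populate every active mismatch bin; totals of 3 are
    # the rarest inactive configuration, so the pool is generously sized
    return generate_training_table(40, 3000, seed=81,
                                   active_total_range=(3, 5))


@pytest.fixture(scope="module")
def datasets(table):
    active = table[table.label == "active"].reset_index(drop=True)
    pool = table[table.label == "inactive"].reset_index(drop=True)
    return sample_inactive(active, pool, n_repeats=3, seed=82)


def test_concentration_labeling_threshold():
    df = pd.DataFrame({
        "min_active_conc_nM": [16, 64, 256, None],
        "on_target": ["x"] * 4, "off_target": ["x"] * 4,
        "n_mismatches": [1] * 4,
    })
    out = label_by_concentration(df)
    assert list(out["label"]) == ["active", "active", "inactive", "inactive"]


class TestSampler:
    def test_histogram_matches_actives_exactly(self, table):
        active = table[table.label == "active"].reset_index(drop=True)
        pool = table[table.label == "inactive"].reset_index(drop=True)
        want = active["n_mismatches"].value_counts().to_dict()
        for ds in sample_inactive(active, pool, n_repeats=10, seed=83):
            sampled = ds[ds.label == "inactive"]
            assert sampled["n_mismatches"].value_counts().to_dict() == want
            assert len(sampled) == len(active)

    def test_repeats_are_distinct_and_reproducible(self, table):
        active = table[table.label == "active"].reset_index(drop=True)
        pool = table[table.label == "inactive"].reset_index(drop=True)
        a = sample_inactive(active, pool, n_repeats=10, seed=84)
        b = sample_inactive(active, pool, n_repeats=10, seed=84)
        idx_a = [tuple(ds.attrs["sampled_pool_indices"]) for ds in a]
        idx_b = [tuple(ds.attrs["sampled_pool_indices"]) for ds in b]
        assert idx_a == idx_b
        assert len(set(idx_a)) == 10

    def test_shortfall_reported_when_pool_bin_too_small(self):
        active = pd.DataFrame({
            "on_target": ["g"] * 5, "off_target": ["g"] * 5,
            "n_mismatches": [8] * 5, "label": ["active"] * 5,
        })
        pool = pd.DataFrame({
            "on_target": ["g"] * 2, "off_target": ["g"] * 2,
            "n_mismatches": [8] * 2, "label": ["inactive"] * 2,
        })
        with pytest.warns(SamplingShortfall):
            (ds,) = sample_inactive(active, pool, n_repeats=1, seed=85)
        assert ds.attrs["shortfalls"] == {8: 3}
        assert len(ds[ds.label == "inactive"]) == 2


class TestForests:
    def test_models_learn_planted_rule(self, datasets):
        triples = train_models(datasets, n_estimators=150, seed=86)
        for _rf, importances, oob in triples:
            assert oob < 0.2
            assert importances.sum() > 0 and np.isfinite(importances).all()

    def test_training_is_deterministic(self, datasets):
        t1 = train_models(datasets[:1], n_estimators=100, seed=87)
        t2 = train_models(datasets[:1], n_estimators=100, seed=87)
        assert t1[0][2] == t2[0][2]
        assert (t1[0][1] == t2[0][1]).all()

    def test_single_class_dataset_rejected(self, table):
        active = table[table.label == "active"].reset_index(drop=True)
        with pytest.raises(TrainingError):
            train_models([active], n_estimators=10)

    def test_average_importance_of_one_model_is_its_ranking(self, datasets):
        triples = train_models(datasets[:1], n_estimators=100, seed=88)
        ranked = average_importance(triples)
        series = triples[0][1].sort_values(ascending=False)
        assert ranked.iloc[0]["feature"] == series.index[0]
        assert ranked["importance"].is_monotonic_decreasing

    def test_average_importance_is_order_invariant(self, datasets):
        triples = train_models(datasets, n_estimators=100, seed=89)
        shuffled = [(rf, imp.sample(frac=1.0, random_state=1), oob)
                    for rf, imp, oob in triples]
        a = average_importance(triples)
        b = average_importance(shuffled)
        assert list(a["feature"]) == list(b["feature"])


@pytest.fixture(scope="module")
def toy_features():
    """Three informative features among 50 noise features."""
    rng = np.random.default_rng(90)
    n = 300
    X = pd.DataFrame(
        rng.random((n, 53)),
        columns=[f"info_{i}" for i in range(3)] +
                [f"noise_{i:02d}" for i in range(50)])
    y = ((X["info_0"] + X["info_1"] + X["info_2"]) > 1.5).astype(int)
    df = X.copy()
    df["label"] = np.where(y == 1, "active", "inactive")
    return df, X, y


class TestBackwardSelection:
    def test_selected_set_contains_informative_features(self, toy_features,
                                                        monkeypatch):
        df, X, y = toy_features
        import varguide.training as tr

        monkeypatch.setattr(tr, "_featurize",
                            lambda ds, schema: (X, y.to_numpy()))
        monkeypatch.setitem(tr.SCHEMAS, "toy", tuple(X.columns))
        ranking = average_importance(
            tr.train_models([df], schema="toy", n_estimators=150, seed=91))
        selected, curve = backward_select([df], ranking, schema="toy",
                                          n_estimators=150, seed=91)
        assert {"info_0", "info_1", "info_2"} <= set(selected)
        assert len(curve) == 53  # one entry per candidate set size
        full_oob = curve.loc[curve.n_features == 53, "oob_error"].iloc[0]
        best_oob = curve["oob_error"].min()
        assert best_oob <= full_oob


class TestFinalModel:
    def test_lowest_oob_repeat_chosen(self, datasets):
        features = tuple(average_importance(
            train_models(datasets, n_estimators=100, seed=92)
        )["feature"].head(30))
        model = select_final_model(datasets, features, n_estimators=100,
                                   seed=92)
        errs = model.metadata["oob_errors"]
        assert model.metadata["chosen_repeat"] == int(np.argmin(errs))
        assert model.feature_names == features

    def test_model_roundtrips_through_disk(self, datasets, tmp_path):
        from varguide.scoring import feature_matrix, predict_activity

        features = ("mm_total", "mm_seed", "mm_nonseed",
                    "mm_mean_pairwise_dist")
        model = select_final_model(datasets, features, n_estimators=100,
                                   seed=93)
        path = tmp_path / "model.joblib"
        model.save(path)
        loaded = ActivityModel.load(path)
        ds = datasets[0]
        X = feature_matrix(ds["on_target"], ds["off_target"])
        assert (predict_activity(model, X) ==
                predict_activity(loaded, X)).all()
        assert loaded.metadata == model.metadata


def test_concentration_correlation_handles_tiers(datasets):
    features = ("mm_total", "mm_seed", "mm_nonseed")
    model = select_final_model(datasets, features, n_estimators=100, seed=94)
    test = generate_training_table(60, 60, seed=95)
    out = concentration_correlation(model, test)
    assert set(out.index) <= {4, 16, 64, 256}
    single = test[test["min_active_conc_nM"] == 4]
    one = concentration_correlation(model, single)
    assert list(one.index) == [4]
    empty = concentration_correlation(
        model, test[test["min_active_conc_nM"].isna()])
    assert empty.empty
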