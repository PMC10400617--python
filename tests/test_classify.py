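"""SMOTE balancing, stratified splitting, and classifier contracts."""

import numpy as np
import pandas as pd
import pytest

from radiomet import BENIGN, MALIGNANT
from radiomet.classify import (
    GbtConfig,
    smote_balance,
    stratified_split,
    train_baselines,
    train_gbt,
    tune_random_search,
)


def _cohort(n_benign=14, n_malignant=19, p=4, seed=0):
    rng = np.random.default_rng(seed)
    n = n_benign + n_malignant
    labels = pd.Series([BENIGN] * n_benign + [MALIGNANT] * n_malignant,
                       index=[f"T{i:03d}" for i in range(n)], name="condition")
    shift = (labels == MALIGNANT).to_numpy()[:, None] * 1.5
    data = pd.DataFrame(rng.normal(size=(n, p)) + shift,
                        index=labels.index, columns=[f"f{j}" for j in range(p)])
    return data, labels


class TestSmote:
    def test_study_cohort_balances_to_twenty_each(self):
        data, labels = _cohort()
        bal = smote_balance(data, labels, target_per_class=20, seed=1)
        assert bal.class_counts == {BENIGN: 20, MALIGNANT: 20}
        assert int(bal.synthetic.sum()) == 6 + 1
        # real samples bitwise unchanged
        assert bal.data.loc[data.index].equals(data)
        assert not bal.synthetic.loc[data.index].any()

    def test_balanced_input_is_noop(self):
        data, labels = _cohort(20, 20)
        bal = smote_balance(data, labels, target_per_class=20, seed=3)
        assert bal.data.equals(data)
        assert not bal.synthetic.any()

    def test_synthetic_point_is_convex_combination(self):
        data = pd.DataFrame({"x": [0.0, 10.0]}, index=["a", "b"])
        labels = pd.Series([BENIGN, BENIGN], index=data.index)
        bal = smote_balance(data, labels, smote_k=1, target_per_class=3, seed=5)
        new = bal.data.loc[bal.synthetic, "x"].iloc[0]
        assert 0.0 <= new <= 10.0

    def test_synthetic_in_class_convex_hull(self):
        data, labels = _cohort(p=3)
        bal = smote_balance(data, labels, target_per_class=25, seed=2)
        for cls in (BENIGN, MALIGNANT):
            real = data.loc[labels == cls]
            synth = bal.data.loc[bal.synthetic & (bal.labels == cls)]
            lo, hi = real.min(axis=0), real.max(axis=0)
            assert ((synth >= lo - 1e-12).all().all()
                    and (synth <= hi + 1e-12).all().all())

    def test_small_class_rejected_with_name(self):
        data = pd.DataFrame({"x": np.arange(8.0)}, index=[f"s{i}" for i in range(8)])
        labels = pd.Series([BENIGN] * 6 + [MALIGNANT] * 2, index=data.index)
        with pytest.raises(ValueError, match="malignant"):
            smote_balance(data, labels, smote_k=5, target_per_class=8, seed=0)

    def test_seeded_determinism(self):
        data, labels = _cohort()
        b1 = smote_balance(data, labels, seed=9)
        b2 = smote_balance(data, labels, seed=9)
        assert b1.data.equals(b2.data)


class TestSplit:
    def test_sixty_forty_on_balanced_cohort(self):
        data, labels = _cohort(20, 20)
        split = stratified_split(data, labels, 0.6, seed=0)
        assert split.train_labels.value_counts().to_dict() == {BENIGN: 12, MALIGNANT: 12}
        assert split.val_labels.value_counts().to_dict() == {BENIGN: 8, MALIGNANT: 8}

    def test_partition(self):
        data, labels = _cohort()
        split = stratified_split(data, labels, 0.6, seed=4)
        train, val = set(split.train_data.index), set(split.val_data.index)
        assert train | val == set(data.index)
        assert not train & val

    def test_seeded_determinism(self):
        data, labels = _cohort()
        s1 = stratified_split(data, labels, seed=11)
        s2 = stratified_split(data, labels, seed=11)
        assert list(s1.train_data.index) == list(s2.train_data.index)

    def test_invalid_fraction(self):
        data, labels = _cohort()
        with pytest.raises(ValueError):
            stratified_split(data, labels, 1.2)


class TestTrainGbt:
    def test_separable_data_training_accuracy_one(self):
        rng = np.random.default_rng(0)
        n = 30
        labels = pd.Series([BENIGN] * 15 + [MALIGNANT] * 15,
                           index=[f"s{i}" for i in range(n)])
        x = rng.normal(size=(n, 2))
        x[15:, 0] += 6.0  # wide margin
        data = pd.DataFrame(x, index=labels.index, columns=["a", "b"])
        clf = train_gbt(data, labels, GbtConfig(early_stopping_rounds=None))
        pred = clf.predict_labels(data)
        assert (pred == labels).all()

    def test_seeded_determinism(self):
        rng = np.random.default_rng(1)
        labels = pd.Series([BENIGN] * 12 + [MALIGNANT] * 12,
                           index=[f"s{i}" for i in range(24)])
        data = pd.DataFrame(rng.normal(size=(24, 5)), index=labels.index)
        data.columns = [f"f{j}" for j in range(5)]
        p1 = train_gbt(data, labels, GbtConfig(seed=3)).predict_proba(data)
        p2 = train_gbt(data, labels, GbtConfig(seed=3)).predict_proba(data)
        assert np.array_equal(p1, p2)

    def test_probabilities_and_importances(self):
        data, labels = _cohort()
        clf = train_gbt(data, labels)
        p = clf.predict_proba(data)
        assert np.all((p >= 0) & (p <= 1))
        assert set(clf.feature_importances.index) == set(data.columns)

    def test_single_class_rejected(self):
        data, labels = _cohort()
        with pytest.raises(ValueError):
            train_gbt(data, labels.map(lambda _: BENIGN))

    def test_default_config_is_study_optimum(self):
        cfg = GbtConfig()
        assert (cfg.eta, cfg.gamma, cfg.max_depth) == (0.104, 0.0, 6)
        assert (cfg.min_child_weight, cfg.subsample, cfg.colsample_bytree) == \
            (5.31, 0.654, 0.564)


class TestRandomSearch:
    def test_single_draw_returned(self):
        data, labels = _cohort(10, 10)
        cfg = tune_random_search(data, labels, n_draws=1, cv_folds=2, seed=0,
                                 base=GbtConfig(n_rounds=10, early_stopping_rounds=None))
        assert isinstance(cfg, GbtConfig)

    def test_argmax_of_trace(self):
        data, labels = _cohort(12, 12, seed=5)
        cfg, trace = tune_random_search(
            data, labels, n_draws=8, cv_folds=3, seed=2,
            base=GbtConfig(n_rounds=15, early_stopping_rounds=None),
            return_trace=True,
        )
        best = trace["cv_auc"].max()
        assert trace["cv_auc"].iloc[int(trace["cv_auc"].idxmax())] == best
        assert cfg.eta == pytest.approx(
            trace.loc[trace["cv_auc"].idxmax(), "eta"])
        assert best >= trace["cv_auc"].median()

    def test_too_many_folds_rejected(self):
        data, labels = _cohort(3, 10)
        with pytest.raises(ValueError):
            tune_random_search(data, labels, n_draws=1, cv_folds=5)


class TestBaselines:
    def test_contract(self):
        rng = np.random.default_rng(0)
        labels = pd.Series([BENIGN] * 15 + [MALIGNANT] * 15,
                           index=[f"s{i}" for i in range(30)])
        x = rng.normal(size=(30, 2))
        x[15:] += 5.0
        data = pd.DataFrame(x, index=labels.index, columns=["a", "b"])
        models = train_baselines(data, labels, seed=0)
        assert set(models) == {"svm", "random_forest"}
        for clf in models.values():
            p = clf.predict_proba(data)
            assert np.all((p >= 0) & (p <= 1))
            assert (clf.predict_labels(data) == labels).all()
            assert np.array_equal(
                p, train_baselines(data, labels, seed=0)[clf.name].predict_proba(data))
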