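import numpy as np
import pytest

from thymixer.crossval import (STAGE1, STAGE2, TrainConfig, cohort_to_patches,
                               make_folds, run_fold, select_task_patches)
from thymixer.errors import (EmptyTaskError, LeakageError, ParameterError,
                             StratificationError)
from thymixer.mixer import ModelConfig
from thymixer.phantom import generate_cohort


def fake_labels(n_healthy, n_benign, n_malignant):
    labels = {}
    for name, n in (("healthy", n_healthy), ("benign", n_benign),
                    ("malignant", n_malignant)):
        for i in range(n):
            labels[f"{name}_{i:03d}"] = name
    return labels


class TestMakeFolds:
    def test_cohort_of_198_gives_40_40_40_39_39(self):
        plan = make_folds(fake_labels(120, 46, 32), k=5, seed=0)
        sizes = sorted(len(plan.test_patients(f)) for f in range(5))
        assert sizes == [39, 39, 40, 40, 40]

    def test_each_patient_in_exactly_one_test_fold(self):
        labels = fake_labels(10, 6, 6)
        plan = make_folds(labels, k=5, seed=1)
        seen = [p for f in range(5) for p in plan.test_patients(f)]
        assert sorted(seen) == sorted(labels)

    def test_deterministic_given_seed(self):
        labels = fake_labels(12, 7, 6)
        assert make_folds(labels, seed=3).assignments == \
            make_folds(labels, seed=3).assignments
        assert make_folds(labels, seed=3).assignments != \
            make_folds(labels, seed=4).assignments

    def test_stratification_error(self):
        with pytest.raises(StratificationError):
            make_folds(fake_labels(10, 3, 2), k=5)

    def test_randomized_cohorts_disjoint_covering_stratified(self):
        """Randomized cohorts: folds are disjoint, cover every patient, and
        each fold's per-class test count is within 1 of the ideal share."""
        rng = np.random.default_rng(0)
        for trial in range(30):
            nh, nb, nm = rng.integers(5, 40), rng.integers(5, 20), rng.integers(5, 20)
            labels = fake_labels(int(nh), int(nb), int(nm))
            k = 5
            plan = make_folds(labels, k=k, seed=trial)
            all_test = []
            for f in range(k):
                test = plan.test_patients(f)
                assert test.isdisjoint(plan.train_patients(f))
                all_test.extend(test)
                for cls, total in (("healthy", nh), ("benign", nb),
                                   ("malignant", nm)):
                    got = sum(1 for p in test if labels[p] == cls)
                    assert total // k <= got <= total // k + 1
            assert sorted(all_test) == sorted(labels)


class TestSelectTask:
    def test_stage1_relabels_everything(self, tiny_cohort):
        patches = cohort_to_patches(tiny_cohort)
        out = select_task_patches(patches, STAGE1)
        assert len(out) == len(patches)
        assert set(p.label for p in out) == {"healthy", "thymoma"}

    def test_stage2_restricts_to_thymoma(self, tiny_cohort):
        patches = cohort_to_patches(tiny_cohort)
        out = select_task_patches(patches, STAGE2)
        assert set(p.label for p in out) == {"benign", "malignant"}
        assert len(out) < len(patches)

    def test_stage2_without_thymoma_raises(self):
        cohort = generate_cohort(n_healthy=2, n_benign=0, n_malignant=0,
                                 slices_per_scan=(6, 8), seed=0)
        with pytest.raises(EmptyTaskError):
            select_task_patches(cohort_to_patches(cohort), STAGE2)

    def test_unknown_task_raises(self, tiny_cohort):
        with pytest.raises(EmptyTaskError):
            select_task_patches(cohort_to_patches(tiny_cohort), "stage3")


class TestTrainConfig:
    def test_defaults_match_reference_protocol(self):
        cfg = TrainConfig()
        assert (cfg.batch_size, cfg.learning_rate, cfg.epochs) == (64, 1e-4, 100)
        assert cfg.optimizer == "adam"

    def test_validation(self):
        with pytest.raises(ParameterError):
            TrainConfig(epochs=0)
        with pytest.raises(ParameterError):
            TrainConfig(optimizer="sgd")


@pytest.fixture(scope="module")
def smoke_patches():
    cohort = generate_cohort(n_healthy=4, n_benign=2, n_malignant=2,
                             slices_per_scan=(9, 12), lesion_contrast=0.5,
                             seed=3)
    patches = select_task_patches(cohort_to_patches(cohort), STAGE1)
    plan = make_folds(cohort.labels, k=2, seed=3)
    train = [p for p in patches if plan.assignments[p.patient_id] != 0]
    test = [p for p in patches if plan.assignments[p.patient_id] == 0]
    return train, test


class TestRunFold:
    MODEL = dict(backbone="small", channels=32)

    def test_leakage_guard(self, smoke_patches):
        train, test = smoke_patches
        with pytest.raises(LeakageError):
            run_fold(train + test[:1], test, ModelConfig(**self.MODEL),
                     TrainConfig(epochs=1))

    def test_two_epoch_smoke(self, smoke_patches):
        train, test = smoke_patches
        res = run_fold(train, test, ModelConfig(**self.MODEL),
                       TrainConfig(epochs=2, batch_size=16, seed=0))
        assert len(res.loss_history) == 2
        assert all(np.isfinite(l) for l in res.loss_history)
        assert len(res.predictions) == len(test)
        probs = res.predictions[[f"p_{c}" for c in res.classes]].to_numpy()
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-5)
        assert set(res.predictions["pred"]) <= set(res.classes)

    def test_reproducible_given_seed(self, smoke_patches):
        train, test = smoke_patches
        kw = dict(model_cfg=ModelConfig(**self.MODEL),
                  train_cfg=TrainConfig(epochs=1, batch_size=16, seed=5))
        r1 = run_fold(train, test, **kw)
        r2 = run_fold(train, test, **kw)
        assert r1.loss_history == r2.loss_history
        assert r1.predictions.equals(r2.predictions)
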