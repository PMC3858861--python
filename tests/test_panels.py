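"""Panel enumeration, CV scoring, argmax search, and the final model."""

import math

import numpy as np
import pytest
from sklearn.svm import SVC

from panelselect import (
    ClassifierSpec,
    LabeledExpressionMatrix,
    SimulationConfig,
    TrainedPanelModel,
    cv_panel_auc,
    enumerate_panels,
    find_optimal_panel,
    generate_dataset,
    predict,
    split_groups,
    train_final_model,
)
from panelselect._svm import RbfSvm
from panelselect.panels import cv_pooled_scores


@pytest.fixture(scope="module")
def search_setup():
    """Strong planted dataset restricted to group A, with a small marker set."""
    cfg = SimulationConfig(n_probes=300, effect_size=3.0, seed=11)
    m, truth = generate_dataset(cfg)
    split = split_groups(m, seed=11)
    group_a = m.subset_samples(split.group_a_sample_ids)
    rng = np.random.default_rng(99)
    nulls = sorted(set(m.probe_ids) - set(truth))
    markers = sorted(truth + [str(x) for x in rng.choice(nulls, 10, replace=False)])
    return m, truth, split, group_a, markers


class TestEnumeration:
    @pytest.mark.parametrize("m_size,n", [(5, 5), (6, 5), (8, 3), (10, 1)])
    def test_counts_match_binomial(self, m_size, n):
        markers = [f"G{i:02d}" for i in range(m_size)]
        panels = list(enumerate_panels(markers, n))
        assert len(panels) == math.comb(m_size, n)
        assert len(set(panels)) == len(panels)

    def test_lexicographic_order_of_sorted_tuples(self):
        panels = list(enumerate_panels(["b", "d", "a", "c"], 2))
        assert panels == [
            ("a", "b"), ("a", "c"), ("a", "d"),
            ("b", "c"), ("b", "d"), ("c", "d"),
        ]
        assert all(p == tuple(sorted(p)) for p in panels)

    def test_cap_exceeded_is_hard_error(self):
        markers = [f"G{i:02d}" for i in range(20)]
        with pytest.raises(ValueError, match="cap"):
            enumerate_panels(markers, 5, cap=1000)

    def test_bad_panel_size_errors(self):
        with pytest.raises(ValueError, match="panel size"):
            enumerate_panels(["a", "b"], 3)


class TestFastSvmBackend:
    def test_decisions_bit_identical_to_svc(self):
        """The low-level libsvm path must agree exactly with the public
        estimator for every random draw."""
        rng = np.random.default_rng(0)
        for _ in range(100):
            n = int(rng.integers(8, 50))
            X = rng.normal(size=(n, 4))
            y = rng.integers(0, 2, n).astype(float)
            if y.min() == y.max():
                y[0] = 1 - y[0]
            Xt = rng.normal(size=(9, 4))
            C, gamma = float(rng.uniform(0.1, 10)), float(rng.uniform(0.01, 2))
            ours = RbfSvm(c_penalty=C, gamma=gamma).fit(X, y).decision_function(Xt)
            ref = SVC(kernel="rbf", C=C, gamma=gamma).fit(X, y).decision_function(Xt)
            np.testing.assert_array_equal(ours, ref)


class TestCvPanelAuc:
    def test_separable_panel_scores_high(self, search_setup, default_spec):
        _, truth, split, group_a, _ = search_setup
        auc, fold_aucs = cv_panel_auc(group_a, truth, default_spec, split)
        assert auc >= 0.95
        assert len(fold_aucs) == 5
        assert auc == pytest.approx(np.mean(fold_aucs), abs=1e-15)

    def test_permuted_labels_score_near_chance(self, search_setup, default_spec):
        _, truth, split, group_a, _ = search_setup
        rng = np.random.default_rng(5)
        aucs = []
        for _ in range(5):
            shuffled = group_a.copy()
            shuffled.labels = rng.permutation(shuffled.labels)
            auc, _ = cv_panel_auc(shuffled, truth, default_spec, split)
            aucs.append(auc)
        assert 0.2 <= np.mean(aucs) <= 0.8

    def test_unknown_panel_probe_errors(self, search_setup, default_spec):
        _, _, split, group_a, _ = search_setup
        with pytest.raises(KeyError, match="NOPE"):
            cv_panel_auc(group_a, ("NOPE",), default_spec, split)

    def test_group_b_samples_rejected(self, search_setup, default_spec):
        m, truth, split, _, _ = search_setup
        with pytest.raises(ValueError, match="training-group"):
            cv_panel_auc(m, truth, default_spec, split)

    def test_pooled_scores_cover_each_sample_once(self, search_setup, default_spec):
        _, truth, split, group_a, _ = search_setup
        scores, ys = cv_pooled_scores(group_a, truth, default_spec, split)
        assert len(scores) == len(split.group_a_sample_ids)
        assert int(ys.sum()) == int(group_a.labels.sum())


class TestFindOptimalPanel:
    def test_single_candidate_when_m_equals_n(self, search_setup, default_spec):
        _, truth, split, group_a, _ = search_setup
        out = find_optimal_panel(group_a, truth, 5, default_spec, split)
        assert len(out) == 1
        assert out[0].rank == 1
        assert out[0].probe_ids == tuple(sorted(truth))

    def test_deterministic_ranking(self, search_setup, default_spec):
        _, _, split, group_a, markers = search_setup
        kw = dict(top_k=3)
        r1 = find_optimal_panel(group_a, markers[:8], 5, default_spec, split, **kw)
        r2 = find_optimal_panel(group_a, markers[:8], 5, default_spec, split, **kw)
        assert [(c.probe_ids, c.validation_auc) for c in r1] == [
            (c.probe_ids, c.validation_auc) for c in r2
        ]

    def test_descending_auc_with_ranks(self, search_setup, default_spec):
        _, _, split, group_a, markers = search_setup
        out = find_optimal_panel(group_a, markers[:8], 5, default_spec, split)
        aucs = [c.validation_auc for c in out]
        assert aucs == sorted(aucs, reverse=True)
        assert [c.rank for c in out] == list(range(1, len(out) + 1))

    def test_strong_planted_panel_recovered(self, search_setup, default_spec):
        """At 3-SD effects the argmax panel is dominated by planted probes."""
        _, truth, split, group_a, markers = search_setup
        out = find_optimal_panel(group_a, markers, 5, default_spec, split, top_k=1)
        assert len(set(out[0].probe_ids) & set(truth)) >= 3

    def test_worker_count_does_not_change_result(self, search_setup, default_spec):
        _, _, split, group_a, markers = search_setup
        small = markers[:7]
        seq = find_optimal_panel(group_a, small, 5, default_spec, split)
        par = find_optimal_panel(
            group_a, small, 5, default_spec, split, n_workers=2
        )
        assert [(c.probe_ids, c.validation_auc, c.per_fold_aucs) for c in seq] == [
            (c.probe_ids, c.validation_auc, c.per_fold_aucs) for c in par
        ]

    def test_checkpoint_resume_is_transparent(
        self, search_setup, default_spec, tmp_path
    ):
        _, _, split, group_a, markers = search_setup
        small = markers[:7]
        ckpt = tmp_path / "scores.tsv"
        full = find_optimal_panel(
            group_a, small, 5, default_spec, split, checkpoint_path=str(ckpt)
        )
        # truncate the checkpoint to simulate an interrupted run, then resume
        lines = ckpt.read_text().splitlines(keepends=True)
        ckpt.write_text("".join(lines[: len(lines) // 2]))
        resumed = find_optimal_panel(
            group_a, small, 5, default_spec, split, checkpoint_path=str(ckpt)
        )
        assert [(c.probe_ids, c.validation_auc) for c in full] == [
            (c.probe_ids, c.validation_auc) for c in resumed
        ]


class TestFinalModel:
    def test_training_auc_on_separable_data(self, search_setup, default_spec):
        from panelselect import compute_auc

        _, truth, split, group_a, _ = search_setup
        model = train_final_model(group_a, truth, default_spec)
        scores, _ = predict(model, group_a)
        assert compute_auc(scores, group_a.labels) >= 0.99

    def test_save_load_bit_identical(self, search_setup, default_spec, tmp_path):
        _, truth, split, group_a, _ = search_setup
        model = train_final_model(group_a, truth, default_spec)
        path = tmp_path / "model.json"
        model.save(path)
        loaded = TrainedPanelModel.load(path)
        probe = group_a.values[group_a.probe_indices(model.panel), :].T
        np.testing.assert_array_equal(
            model.decision_function(probe), loaded.decision_function(probe)
        )

    def test_unknown_probe_errors_by_name(self, search_setup, default_spec):
        _, truth, split, group_a, _ = search_setup
        with pytest.raises(KeyError, match="MISSING"):
            train_final_model(group_a, ("MISSING",) + tuple(truth[:4]), default_spec)

    def test_predict_contract(self, search_setup, default_spec):
        m, truth, split, group_a, _ = search_setup
        model = train_final_model(group_a, truth, default_spec)
        group_b = m.subset_samples(split.group_b_sample_ids)
        scores, labels = predict(model, group_b)
        assert np.all(np.isfinite(scores))
        assert set(np.unique(labels)) <= {0, 1}
        np.testing.assert_array_equal(labels, (scores > 0).astype(int))

    def test_duplicated_sample_gets_identical_score(
        self, search_setup, default_spec
    ):
        m, truth, split, group_a, _ = search_setup
        model = train_final_model(group_a, truth, default_spec)
        b_ids = split.group_b_sample_ids
        twice = m.subset_samples([b_ids[0], b_ids[1]])
        dup = LabeledExpressionMatrix(
            twice.probe_ids,
            ["X1", "X2"],
            np.column_stack([twice.values[:, 0], twice.values[:, 0]]),
            [twice.labels[0]] * 2,
            scale="log2",
        )
        scores, _ = predict(model, dup)
        assert scores[0] == scores[1]

    def test_case_direction_shift_does_not_lower_score(self, default_spec):
        """With a near-linear kernel (tiny gamma), pushing a sample further
        along the planted case direction cannot decrease its score."""
        rng = np.random.default_rng(3)
        n = 40
        labels = np.r_[np.ones(20, int), np.zeros(20, int)]
        values = rng.normal(size=(2, n)) + 2.0 * labels  # both probes case-shifted
        m = LabeledExpressionMatrix(
            ["A", "B"], [f"S{i}" for i in range(n)], values, labels, scale="log2"
        )
        spec = ClassifierSpec(gamma=1e-3)
        model = train_final_model(m, ("A", "B"), spec)
        x = values[:, :1].T.copy()
        base = model.decision_function(x)[0]
        shifted = model.decision_function(x + 1.0)[0]
        assert shifted >= base - 1e-9
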