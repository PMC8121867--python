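"""Monte-Carlo splits, training hygiene, ROC statistics, report plumbing."""

import numpy as np
import pandas as pd
import pytest

from aplsmear.io import CellImage, PatientSample
from aplsmear.training import (ClassMissingError, MonteCarloConfig, UndefinedAUCError,
                               ensemble_predict, mc_patient_split, prepare_patients,
                               promyelocyte_fraction, roc_auc, run_monte_carlo,
                               train_cell_classifier)


def _patients(n_per_class, cells=3, size=32):
    rng = np.random.default_rng(0)
    out = []
    for i in range(2 * n_per_class):
        label = int(i < n_per_class)
        pid = f"Q{i:03d}"
        out.append(PatientSample(
            patient_id=pid, label=label, cohort="discovery",
            cells=[CellImage(pixels=rng.integers(0, 255, (size, size, 3), dtype=np.uint8),
                             patient_id=pid, cell_type="blast", path=f"{pid}/c{j}.png")
                   for j in range(cells)]))
    return out


class TestSplit:
    def test_80_patients_cell_mode_60_10_10(self):
        split = mc_patient_split(_patients(40, cells=1), 0, MonteCarloConfig(seed=1),
                                 mode="cell")
        assert (len(split.train), len(split.validation), len(split.test)) == (60, 10, 10)

    def test_mil_mode_75_25(self):
        split = mc_patient_split(_patients(40, cells=1), 0, MonteCarloConfig(seed=1),
                                 mode="mil")
        assert (len(split.train), len(split.validation), len(split.test)) == (60, 0, 20)

    def test_deterministic_given_seed_and_rep(self):
        pts = _patients(10, cells=1)
        cfg = MonteCarloConfig(seed=3)
        a = mc_patient_split(pts, 5, cfg)
        b = mc_patient_split(pts, 5, cfg)
        assert (a.train, a.validation, a.test) == (b.train, b.validation, b.test)
        c = mc_patient_split(pts, 6, cfg)
        assert (a.train, a.validation, a.test) != (c.train, c.validation, c.test)

    @pytest.mark.parametrize("rep", [0, 3, 17])
    def test_partition_property(self, rep):
        pts = _patients(9, cells=1)
        split = mc_patient_split(pts, rep, MonteCarloConfig(seed=0))
        union = split.train | split.validation | split.test
        assert union == {p.patient_id for p in pts}
        assert len(split.train) + len(split.validation) + len(split.test) == len(pts)

    def test_both_classes_in_train(self):
        pts = _patients(2, cells=1)
        by_label = {p.patient_id: p.label for p in pts}
        for rep in range(10):
            split = mc_patient_split(pts, rep, MonteCarloConfig(seed=2))
            assert {by_label[p] for p in split.train} == {0, 1}

    def test_too_few_patients_rejected(self):
        with pytest.raises(ValueError, match="at least 4"):
            mc_patient_split(_patients(1, cells=1), 0, MonteCarloConfig(seed=0))


class TestRocAuc:
    def test_concordant_pair_example(self):
        assert roc_auc([0, 0, 1, 1], [0.1, 0.4, 0.35, 0.8]) == pytest.approx(0.75)

    def test_perfect_separation(self):
        assert roc_auc([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9]) == 1.0

    def test_all_ties_half(self):
        assert roc_auc([0, 1, 0, 1], [0.5, 0.5, 0.5, 0.5]) == 0.5

    def test_single_class_undefined(self):
        with pytest.raises(UndefinedAUCError):
            roc_auc([1, 1, 1], [0.1, 0.2, 0.3])

    def test_matches_exhaustive_pair_count(self, rng):
        """Oracle: count concordant pairs exhaustively, ties worth 1/2."""
        for _ in range(200):
            n = int(rng.integers(4, 12))
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                continue
            scores = np.round(rng.random(n), 1)  # coarse grid forces ties
            pos, neg = scores[labels == 1], scores[labels == 0]
            wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
            assert roc_auc(labels, scores) == pytest.approx(wins / (len(pos) * len(neg)))

    def test_invariant_under_monotone_transform(self, rng):
        labels = rng.integers(0, 2, 30)
        labels[:2] = [0, 1]
        scores = rng.random(30)
        assert roc_auc(labels, scores) == pytest.approx(
            roc_auc(labels, np.exp(5 * scores) + 3))


class TestPromyelocyteFraction:
    def test_fraction_arithmetic(self):
        rng = np.random.default_rng(0)
        cells = [CellImage(pixels=rng.integers(0, 255, (8, 8, 3), dtype=np.uint8),
                           patient_id="P", cell_type=t)
                 for t in ["promyelocyte"] * 20 + ["blast"] * 180]
        s = PatientSample(patient_id="P", label=1, cohort="discovery", cells=cells)
        assert promyelocyte_fraction(s) == pytest.approx(0.10)

    def test_zero_promyelocytes(self):
        rng = np.random.default_rng(0)
        cells = [CellImage(pixels=rng.integers(0, 255, (8, 8, 3), dtype=np.uint8),
                           patient_id="P", cell_type="lymphocyte")]
        s = PatientSample(patient_id="P", label=0, cohort="discovery", cells=cells)
        assert promyelocyte_fraction(s) == 0.0


class TestTraining:
    def test_class_missing_error(self, tiny_arch):
        pts = _patients(4, cells=2)
        prep = prepare_patients(pts, 32)
        cfg = MonteCarloConfig(seed=0, image_size=32, max_epochs=1)
        split = mc_patient_split(prep, 0, cfg)
        # relabel every patient to class 0
        for pid in prep:
            prep[pid]["label"] = 0
        with pytest.raises(ClassMissingError):
            train_cell_classifier(split, prep, "all_cells", cfg, tiny_arch)

    def test_run_monte_carlo_out_of_fold_audit(self, mini_patients, tiny_arch):
        """Every pooled discovery prediction comes from a repetition in which
        that patient was held out."""
        cfg = MonteCarloConfig(n_reps=4, image_size=32, max_epochs=1, seed=1)
        ens, report = run_monte_carlo(mini_patients, "cell", "all_cells", cfg, tiny_arch)
        assert len(ens) == 4
        split_by_rep = {s.rep_id: s for s in ens.splits}
        for row in report.per_cell.itertuples(index=False):
            assert row.patient_id in split_by_rep[row.rep_id].test
            assert row.patient_id not in split_by_rep[row.rep_id].train

    def test_mil_bag_probability_equals_mean_of_cells(self, mini_patients, tiny_arch):
        """End-to-end MIL identity: every returned out-of-fold bag score is
        the renormalized mean of that patient's per-cell softmax triples
        under the same repetition's model."""
        from aplsmear.models import apl_probability
        cfg = MonteCarloConfig(n_reps=2, image_size=32, mil_max_epochs=2, seed=2)
        ens, report = run_monte_carlo(mini_patients, "mil", "all_cells", cfg, tiny_arch)
        prep = prepare_patients(mini_patients, 32)
        raw = report.per_cell  # pooled rows carry rep_id
        checked = 0
        for (rep, pid), _ in raw.groupby(["rep_id", "patient_id"]):
            net = ens.models[rep].net
            bag = net.predict_probs(prep[pid]["x"]).mean(axis=0)
            expected = apl_probability(bag)
            # the per-rep bag score feeds the pooled per-sample mean; recompute it
            got = [r for r in _per_rep_scores(ens, prep) if r[:2] == (rep, pid)][0][2]
            assert got == pytest.approx(expected, abs=1e-9)
            checked += 1
        assert checked > 0
        # pooled per-sample score is the mean of that patient's per-rep scores
        per_rep = pd.DataFrame(_per_rep_scores(ens, prep),
                               columns=["rep", "patient_id", "score"])
        pooled = per_rep.groupby("patient_id")["score"].mean()
        for row in report.per_sample.itertuples(index=False):
            assert row.score == pytest.approx(pooled[row.patient_id], abs=1e-9)

    def test_ensemble_predict_of_identical_models(self, mini_patients, tiny_arch):
        cfg = MonteCarloConfig(n_reps=1, image_size=32, max_epochs=1, seed=3)
        ens, _ = run_monte_carlo(mini_patients, "cell", "all_cells", cfg, tiny_arch)
        single = ensemble_predict(ens, mini_patients)
        ens.models = ens.models * 3  # triplicate the same model
        triple = ensemble_predict(ens, mini_patients)
        np.testing.assert_allclose(single.per_cell["score"], triple.per_cell["score"],
                                   atol=1e-12)

    def test_ensemble_save_load_round_trip(self, mini_patients, tiny_arch, tmp_path):
        from aplsmear.training import EnsembleModel
        cfg = MonteCarloConfig(n_reps=2, image_size=32, max_epochs=1, seed=4)
        ens, _ = run_monte_carlo(mini_patients, "cell", "all_cells", cfg, tiny_arch)
        ens.save(tmp_path)
        back = EnsembleModel.load(tmp_path)
        r1 = ensemble_predict(ens, mini_patients)
        r2 = ensemble_predict(back, mini_patients)
        np.testing.assert_allclose(r1.per_cell["score"], r2.per_cell["score"], atol=1e-12)
        assert [s.test for s in back.splits] == [s.test for s in ens.splits]


def _per_rep_scores(ens, prep):
    """Recompute each repetition's out-of-fold MIL bag scores independently."""
    from aplsmear.models import apl_probability
    out = []
    for split, model in zip(ens.splits, ens.models):
        for pid in sorted(split.test):
            bag = model.net.predict_probs(prep[pid]["x"]).mean(axis=0)
            out.append((split.rep_id, pid, float(apl_probability(bag))))
    return out
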