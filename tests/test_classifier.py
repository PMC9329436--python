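"""CHI classifier: separation, parsimony selection, fingerprint semantics."""

import numpy as np
import pytest
from sklearn.metrics import roc_auc_score

from cellhealth.classifier import (DEFAULT_ENDPOINT_CHANNELS, ENDPOINT_ORDER,
                                   CellHealthClassifier, EndpointSpec,
                                   RiskModel, TrainingExample, chi_score,
                                   classify_compound_table,
                                   default_endpoint_specs, train_risk_model)
from cellhealth.errors import DegenerateTrainingError, SchemaError
from cellhealth.qf import PhenotypeVector, feature_names
from cellhealth.simulate import (EffectSpec, SimulationConfig,
                                 analytic_phenotype, endpoint_stressor,
                                 simulate_training_library)


def make_phenotype(features, compound="c"):
    return PhenotypeVector(compound_id=compound, features=np.asarray(features),
                           feature_names=feature_names())


def separated_gaussian_library(n_per_class, seed, shift=3.0, n_shifted=4):
    """Two classes differing by a mean shift of `shift` SD on a few features."""
    rng = np.random.default_rng(seed)
    names = feature_names()
    examples = []
    for label, mean in (("yes", shift), ("no", 0.0)):
        for i in range(n_per_class):
            x = rng.standard_normal(24)
            x[:n_shifted] += mean
            examples.append(TrainingExample(
                compound_id=f"{label}{i}", label=label,
                phenotype=PhenotypeVector(f"{label}{i}", x, names)))
    return examples


class TestTraining:
    def test_well_separated_classes_reach_high_holdout_auc(self):
        train = separated_gaussian_library(150, seed=1)
        test = separated_gaussian_library(100, seed=2)
        model = train_risk_model(train, cv=(5, 3), seed=5)
        scores = [chi_score(model, e.phenotype) for e in test]
        y = [1 if e.label == "yes" else 0 for e in test]
        assert roc_auc_score(y, scores) >= 0.95

    def test_permuted_labels_give_chance_auc(self):
        rng = np.random.default_rng(9)
        train = separated_gaussian_library(100, seed=3)
        labels = [e.label for e in train]
        rng.shuffle(labels)
        shuffled = [TrainingExample(e.compound_id, e.phenotype, lab)
                    for e, lab in zip(train, labels)]
        model = train_risk_model(shuffled, cv=(5, 3), seed=5)
        test = separated_gaussian_library(100, seed=4)
        scores = [chi_score(model, e.phenotype) for e in test]
        y = [1 if e.label == "yes" else 0 for e in test]
        assert 0.4 <= roc_auc_score(y, scores) <= 0.6

    def test_training_is_deterministic_given_seed(self):
        train = separated_gaussian_library(40, seed=6)
        m1 = train_risk_model(train, cv=(5, 2), seed=11)
        m2 = train_risk_model(train, cv=(5, 2), seed=11)
        assert m1.classifier.best_params_ == m2.classifier.best_params_
        np.testing.assert_array_equal(m1.classifier.coef_, m2.classifier.coef_)

    def test_single_class_input_rejected(self):
        train = [e for e in separated_gaussian_library(10, seed=7)
                 if e.label == "yes"]
        with pytest.raises(DegenerateTrainingError):
            train_risk_model(train, cv=(3, 1), seed=1)

    def test_sparse_support_recovery_from_planted_model(self):
        """With 6 truly informative features out of 24, the elastic-net
        1-SE model keeps most of the true support and discriminates well."""
        rng = np.random.default_rng(21)
        names = feature_names()
        beta = np.zeros(24)
        true_support = rng.choice(24, 6, replace=False)
        beta[true_support] = 2.0

        def draw(n, seed):
            r = np.random.default_rng(seed)
            X = r.standard_normal((n, 24))
            p = 1 / (1 + np.exp(-(X @ beta)))
            y = np.where(r.random(n) < p, "yes", "no")
            return [TrainingExample(f"c{i}", PhenotypeVector(f"c{i}", X[i], names),
                                    y[i]) for i in range(n)]

        model = train_risk_model(draw(300, 1), cv=(5, 3), seed=2)
        coef = model.classifier.coef_.ravel()
        recovered = np.flatnonzero(np.abs(coef) > 1e-8)
        assert len(set(true_support) & set(recovered)) >= 4
        test = draw(300, 99)
        scores = [chi_score(model, e.phenotype) for e in test]
        y = [1 if e.label == "yes" else 0 for e in test]
        assert roc_auc_score(y, scores) >= 0.9


class TestScoring:
    def test_chi_bounded_and_extreme_at_class_centroids(self, library_small,
                                                        fingerprint_model):
        model = fingerprint_model.full_model_
        X_yes = np.array([e.phenotype.features for e in library_small
                          if e.label == "yes"])
        X_no = np.array([e.phenotype.features for e in library_small
                         if e.label == "no"])
        names = library_small[0].phenotype.feature_names
        chi_yes = chi_score(model, PhenotypeVector("y", X_yes.mean(0), names))
        chi_no = chi_score(model, PhenotypeVector("n", X_no.mean(0), names))
        assert 0 <= chi_no < 0.2
        assert 0.8 < chi_yes <= 1

    def test_feature_permutation_invariance(self, library_small,
                                            fingerprint_model):
        model = fingerprint_model.full_model_
        phen = library_small[0].phenotype
        rng = np.random.default_rng(1)
        perm = rng.permutation(len(phen.features))
        shuffled = PhenotypeVector(
            phen.compound_id, phen.features[perm],
            tuple(np.asarray(phen.feature_names)[perm]))
        assert chi_score(model, shuffled) == pytest.approx(
            chi_score(model, phen), abs=1e-12)

    def test_feature_mismatch_rejected(self, fingerprint_model):
        model = fingerprint_model.full_model_
        bad = PhenotypeVector("b", np.zeros(4),
                              ("a:max_rate", "a:range", "b:max_rate", "b:range"))
        with pytest.raises(SchemaError):
            chi_score(model, bad)

    def test_chi_monotone_along_yes_direction(self, library_small,
                                              fingerprint_model):
        model = fingerprint_model.full_model_
        clf = model.classifier
        direction = clf.coef_.ravel() / clf.scaler_.scale_
        if clf.classes_[1] != "yes":  # coef_ is for classes_[1]
            direction = -direction
        names = library_small[0].phenotype.feature_names
        base = np.array([e.phenotype.features for e in library_small]).mean(0)
        chis = [chi_score(model, PhenotypeVector("m", base + t * direction,
                                                 names))
                for t in np.linspace(0, 3, 7)]
        assert all(b >= a - 1e-12 for a, b in zip(chis, chis[1:]))

    def test_json_round_trip_preserves_scores(self, library_small,
                                              fingerprint_model, tmp_path):
        model = fingerprint_model.full_model_
        path = tmp_path / "model.json"
        model.to_json(path)
        back = RiskModel.from_json(path)
        phen = library_small[5].phenotype
        assert chi_score(back, phen) == pytest.approx(chi_score(model, phen),
                                                      abs=1e-12)


class TestFingerprint:
    def test_cm_submodel_sees_four_scatter_features(self):
        spec = next(s for s in default_endpoint_specs() if s.code == "CM")
        assert spec.channels == ("FSC", "SSC")
        assert len(spec.feature_names) == 4

    def test_endpoint_with_no_channels_rejected(self):
        with pytest.raises(SchemaError):
            EndpointSpec(code="ROS", channels=())

    def test_all_scores_within_unit_interval(self, library_small,
                                             fingerprint_model):
        fp = fingerprint_model.fingerprint(library_small[0].phenotype)
        assert 0 <= fp.chi <= 1
        assert len(fp.endpoint_scores) == 8
        assert all(0 <= v <= 1 for v in fp.endpoint_scores.values())

    def test_ros_stressor_scores_ros_top(self, series10, fingerprint_model):
        cfg = SimulationConfig(seed=77)
        prof = endpoint_stressor(["MitoSOXRed"], compound_id="rosx")
        phen = analytic_phenotype(prof, cfg, series10)
        fp = fingerprint_model.fingerprint(phen)
        assert fp.top_endpoint() == "ROS"

    def test_negative_control_scores_below_no_class_upper_decile(
            self, series10, library_small, fingerprint_model):
        cfg = SimulationConfig(seed=88)
        from cellhealth.simulate import null_profile
        phen = analytic_phenotype(null_profile("veh"), cfg, series10)
        fp = fingerprint_model.fingerprint(phen)
        no_class = [e.phenotype for e in library_small if e.label == "no"]
        chi_no = [fingerprint_model.full_model_.score(p) for p in no_class]
        assert fp.chi <= np.quantile(chi_no, 0.9)

    def test_compound_table_shape_and_round_trip(self, library_small,
                                                 fingerprint_model, tmp_path):
        phens = [e.phenotype for e in library_small[:5]]
        table = classify_compound_table(fingerprint_model, phens)
        assert list(table.columns) == ["compound_id", *ENDPOINT_ORDER, "CHI"]
        assert len(table) == 5
        path = tmp_path / "table.csv"
        table.to_csv(path, index=False)
        import pandas as pd
        back = pd.read_csv(path)
        assert back.shape == table.shape
        np.testing.assert_allclose(back["CHI"], table["CHI"])
        empty = classify_compound_table(fingerprint_model, [])
        assert len(empty) == 0
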