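"""Signature training, tuning, locking, serialization, and prediction."""

import hashlib

import numpy as np
import pandas as pd
import pytest

from phenocopy import (
    ExpressionMatrix,
    SyntheticConfig,
    generate_cohort,
    normalize_expression,
    predict_phenocopy,
    train_from_bundle,
    train_signature,
)
from phenocopy.signatures import SignatureLockedError, pooled_auc

from conftest import SMALL_GRID


def pairwise_concordance_auc(labels, scores):
    """Brute-force AUC: fraction of positive/negative pairs correctly ordered,
    ties counting one half."""
    labels = np.asarray(labels)
    scores = np.asarray(scores)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = ties = 0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1
            elif p == q:
                ties += 1
    return (wins + 0.5 * ties) / (pos.size * neg.size)


def features_and_labels(bundle):
    from phenocopy import mutation_labels, restrict_to_pathway

    normalized = normalize_expression(bundle.expression)
    features = restrict_to_pathway(normalized, bundle.pathway_definition)
    return features, mutation_labels(bundle)["any_mutation"]


class TestAuc:
    def test_matches_pairwise_concordance_oracle(self, rng):
        for _ in range(30):
            n = int(rng.integers(6, 25))
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            scores = rng.choice([-1.5, -0.5, 0.0, 0.5, 1.5], size=n)  # force ties
            assert pooled_auc(labels, scores) == pytest.approx(
                pairwise_concordance_auc(labels, scores), abs=1e-12
            )


class TestTraining:
    def test_recovers_signal_on_clean_cohort(self, clean_signature):
        signature, _ = clean_signature
        assert signature.cv_auc >= 0.90
        assert signature.locked

    def test_tuning_metadata_recorded(self, clean_signature):
        signature, _ = clean_signature
        grid_seen = {(r["depth"], r["n_trees"]) for r in signature.cv_results}
        assert grid_seen == set(SMALL_GRID)
        assert (signature.tuned_depth, signature.tuned_n_trees) in grid_seen
        assert signature.cv_auc == max(r["auc"] for r in signature.cv_results)
        assert signature.normalization_dialect == "rank"

    def test_permuted_labels_give_chance_level_auc(self, clean_bundle):
        features, labels = features_and_labels(clean_bundle)
        rng = np.random.default_rng(5)
        permuted = pd.Series(
            rng.permutation(labels.to_numpy()), index=labels.index
        )
        sig = train_signature(features, permuted, grid=((2, 50),), folds=5, seed=0)
        assert 0.40 <= sig.cv_auc <= 0.60

    def test_single_class_labels_rejected(self, clean_bundle):
        features, labels = features_and_labels(clean_bundle)
        with pytest.raises(ValueError, match="single-class"):
            train_signature(features, labels * 0, grid=((2, 50),), folds=5)

    def test_folds_exceeding_minority_class_rejected(self, clean_bundle):
        features, labels = features_and_labels(clean_bundle)
        few = labels.copy()
        few[:] = 0
        few.iloc[:5] = 1
        with pytest.raises(ValueError, match="minority class"):
            train_signature(features, few, grid=((2, 50),), folds=10)

    def test_identical_inputs_give_byte_identical_serialization(self, tmp_path):
        bundle = generate_cohort(SyntheticConfig(seed=55, samples_per_type=60))
        features, labels = features_and_labels(bundle)
        digests = []
        for run in ("a", "b"):
            sig = train_signature(features, labels, grid=((2, 50), (3, 50)), folds=5, seed=3)
            out = sig.save(tmp_path / run)
            payload = (out / "model.json").read_bytes() + (out / "signature.json").read_bytes()
            digests.append(hashlib.sha256(payload).hexdigest())
        assert digests[0] == digests[1]


class TestLockAndSerialization:
    def test_locked_signature_rejects_mutation(self, clean_signature):
        signature, _ = clean_signature
        with pytest.raises(SignatureLockedError):
            signature.cv_auc = 1.0

    def test_metadata_round_trip_is_exact(self, clean_signature, tmp_path):
        from phenocopy import PhenocopySignature

        signature, _ = clean_signature
        out = signature.save(tmp_path / "sig")
        loaded = PhenocopySignature.load(out)
        for attr in (
            "pathway_name", "feature_genes", "normalization_dialect", "tuned_depth",
            "tuned_n_trees", "cv_auc", "training_fingerprint", "cv_results",
            "objective", "cv_score_pooling", "locked",
        ):
            assert getattr(loaded, attr) == getattr(signature, attr)

    def test_prediction_leaves_serialized_signature_untouched(self, clean_signature, tmp_path):
        signature, _ = clean_signature
        out = signature.save(tmp_path / "locked")
        before = hashlib.sha256((out / "model.json").read_bytes()).hexdigest()
        bundle = generate_cohort(SyntheticConfig(seed=56, samples_per_type=30))
        predict_phenocopy(signature, normalize_expression(bundle.expression))
        signature.save(tmp_path / "locked")
        after = hashlib.sha256((out / "model.json").read_bytes()).hexdigest()
        assert before == after


class TestPrediction:
    def test_held_out_calls_recover_latent_activation(self, clean_signature):
        signature, _ = clean_signature
        held_out = generate_cohort(
            SyntheticConfig(
                seed=202, pathogenic_fraction=1.0, penetrance=1.0,
                cnv_rate=0.0, annotation_error_rate=0.0,
            )
        )
        pred = predict_phenocopy(signature, normalize_expression(held_out.expression))
        truth = held_out.latent_activation
        tpr = pred.loc[truth == 1, "call"].mean()
        tnr = 1 - pred.loc[truth == 0, "call"].mean()
        assert (tpr + tnr) / 2 >= 0.85

    def test_prediction_is_pure(self, clean_signature, default_bundle):
        signature, _ = clean_signature
        normalized = normalize_expression(default_bundle.expression)
        first = predict_phenocopy(signature, normalized)
        second = predict_phenocopy(signature, normalized)
        pd.testing.assert_frame_equal(first, second)

    def test_constant_matrix_gives_identical_calls(self, clean_signature):
        signature, _ = clean_signature
        values = pd.DataFrame(
            1.0, index=signature.feature_genes, columns=[f"C{i}" for i in range(5)]
        )
        normalized = normalize_expression(ExpressionMatrix(values))
        pred = predict_phenocopy(signature, normalized)
        assert pred["call"].nunique() == 1
        assert pred["margin"].nunique() == 1

    def test_missing_feature_genes_imputed_up_to_threshold(self, clean_signature, default_bundle):
        signature, _ = clean_signature
        normalized = normalize_expression(default_bundle.expression)
        drop = signature.feature_genes[:20]  # 20% of 100 features
        truncated = ExpressionMatrix(
            normalized.values.drop(index=drop), normalization="rank"
        )
        pred = predict_phenocopy(signature, truncated)
        assert set(pred["call"].unique()) <= {0, 1}

    def test_excessive_missing_feature_genes_rejected(self, clean_signature, default_bundle):
        signature, _ = clean_signature
        normalized = normalize_expression(default_bundle.expression)
        drop = signature.feature_genes[:60]
        truncated = ExpressionMatrix(normalized.values.drop(index=drop), normalization="rank")
        with pytest.raises(ValueError, match="missing"):
            predict_phenocopy(signature, truncated)

    def test_normalization_dialect_mismatch_rejected(self, clean_signature, default_bundle):
        signature, _ = clean_signature
        with pytest.raises(ValueError, match="dialect"):
            predict_phenocopy(signature, default_bundle.expression)  # still raw
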