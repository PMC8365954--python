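"""Gradient-boosted stages: training, scoring, importances, from-open pipeline."""

import numpy as np
import pandas as pd
import pytest

from chromloop import dataset_builder as db
from chromloop.boosted_classifier import (
    GBModel,
    feature_importance_report,
    predict_from_open_chromatin,
    predict_pairs,
    train_gb,
)
from chromloop.evaluation import auprc, f_score_threshold_scan
from chromloop.motif_analysis import PWM
from chromloop.sequence_model import ExtractorConfig, build_extractor, feature_names, freeze
from chromloop.synthetic_data import default_planted_motif


def _motif_oracle_extractor(input_length=500):
    """Extractor whose kernel 0 scans the planted motif (forward) and kernel 1
    its reverse complement; the second layer is a width-1 pass-through so the
    global max sees every pooled frame. Stands in for an expensively trained
    stage-1 model in structural tests."""
    cfg = ExtractorConfig(
        input_length=input_length, conv_channels=(4, 4), conv_widths=(19, 1),
        pool_width=10, dense_units=8, seed=0,
    )
    ext = build_extractor(cfg)
    pwm = default_planted_motif()
    logodds = np.log(pwm.matrix / 0.25).astype(np.float32)
    rc = np.log(PWM(pwm.matrix[::-1, ::-1], "rc").matrix / 0.25).astype(np.float32)
    L1, L2 = ext.conv_layers
    L1.W[:] = 0.0
    L1.b[:] = 0.0
    L1.W[:, :, 0] = logodds
    L1.W[:, :, 1] = rc
    L2.W[:] = 0.0
    L2.b[:] = 0.0
    for k in range(2):
        L2.W[0, k, k] = 1.0
    return freeze(ext)


@pytest.fixture(scope="module")
def toy_table(request):
    rng = np.random.default_rng(5)
    n = 200
    X = pd.DataFrame(
        {
            "left_F_k000": rng.random(n),
            "right_RC_k000": rng.random(n),
            "distance": rng.integers(10_000, 1_000_000, n).astype(float),
        }
    )
    y = ((X["left_F_k000"] > 0.5) & (X["right_RC_k000"] > 0.5)).astype(int).to_numpy()
    return X, y


class TestTrainGB:
    def test_separable_table_perfect_training_auprc(self, toy_table):
        X, y = toy_table
        model = train_gb(X, y, seed=0)
        ap, _ = auprc(model.predict(X), y)
        assert ap == 1.0

    def test_single_class_rejected(self, toy_table):
        X, _ = toy_table
        with pytest.raises(ValueError, match="single class"):
            train_gb(X, np.ones(len(X), dtype=int), seed=0)

    def test_nan_feature_names_column(self, toy_table):
        X, y = toy_table
        X = X.copy()
        X.loc[3, "right_RC_k000"] = np.nan
        with pytest.raises(ValueError, match="right_RC_k000"):
            train_gb(X, y, seed=0)

    def test_deterministic_given_seed(self, toy_table):
        X, y = toy_table
        a = train_gb(X, y, seed=7).predict(X)
        b = train_gb(X, y, seed=7).predict(X)
        assert np.array_equal(a, b)

    def test_permuted_labels_score_near_prevalence(self, toy_table, rng):
        X, y = toy_table
        yp = rng.permutation(y)
        if yp.min() == yp.max():
            pytest.skip("degenerate permutation")
        n = len(yp)
        half = n // 2
        model = train_gb(X.iloc[:half], yp[:half], seed=0, num_rounds=50)
        ap, _ = auprc(model.predict(X.iloc[half:]), yp[half:])
        assert abs(ap - yp[half:].mean()) < 0.1

    def test_model_file_round_trip(self, toy_table, tmp_path):
        X, y = toy_table
        model = train_gb(X, y, seed=0)
        path = tmp_path / "model.ubj"
        model.save(path)
        back = GBModel.load(path)
        assert back.feature_names == model.feature_names
        assert np.allclose(back.predict(X), model.predict(X))


class TestImportances:
    def test_every_feature_has_exactly_one_record(self, toy_table):
        X, y = toy_table
        model = train_gb(X, y, seed=0)
        records = feature_importance_report(model)
        assert [r.feature_name for r in records] == list(X.columns)
        assert sum(r.importance for r in records) > 0

    def test_block_mapping_total(self, toy_table):
        X, y = toy_table
        model = train_gb(X, y, seed=0)
        for rec in feature_importance_report(model):
            if rec.feature_name == "distance":
                assert rec.block == "distance" and rec.kernel is None
            else:
                assert rec.block in ("left_F", "right_RC")
                assert rec.kernel == 0

    def test_distance_only_model_single_record(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame({"distance": rng.random(100) * 1e6})
        y = (X["distance"] > 5e5).astype(int).to_numpy()
        model = train_gb(X, y, seed=0, num_rounds=20)
        records = feature_importance_report(model)
        assert len(records) == 1 and records[0].block == "distance"


class TestPredictPairs:
    def test_scores_batch_order_invariant(self, small_study, small_datasets, rng):
        ext = _motif_oracle_extractor()
        pairs = small_datasets["positives"][:40] + small_datasets["negatives"][:80]
        g = small_study.genome
        from chromloop.sequence_model import extract_feature_matrix

        X = extract_feature_matrix(
            ext, [g.fetch(p.left) for p in pairs], [g.fetch(p.right) for p in pairs]
        )
        y = np.array([1 if p.label == "positive" else 0 for p in pairs])
        model = train_gb(X, y, feature_names=feature_names(ext.config), seed=0,
                         num_rounds=40)
        recs = predict_pairs(model, ext, pairs, g)
        order = rng.permutation(len(pairs))
        shuffled = predict_pairs(model, ext, [pairs[i] for i in order], g)
        by_key = {r.pair.key(): r.score for r in recs}
        assert all(by_key[r.pair.key()] == r.score for r in shuffled)

    def test_distance_manifest_mismatch_rejected(self, small_study, small_datasets):
        ext = _motif_oracle_extractor()
        pairs = small_datasets["positives"][:15] + small_datasets["negatives"][:25]
        g = small_study.genome
        from chromloop.sequence_model import extract_feature_matrix

        X = extract_feature_matrix(
            ext, [g.fetch(p.left) for p in pairs], [g.fetch(p.right) for p in pairs]
        )
        y = np.array([1 if p.label == "positive" else 0 for p in pairs])
        model = train_gb(X, y, feature_names=feature_names(ext.config), seed=0,
                         num_rounds=10)
        with pytest.raises(ValueError, match="manifest"):
            predict_pairs(model, ext, pairs, g, include_distance=True)


class TestFromOpenChromatin:
    """Functional checks on a sparse fixture where peak merging is rare, with
    a wide input window so anchors are seen whole."""

    @pytest.fixture(scope="class")
    def sparse_setup(self):
        from chromloop.synthetic_data import SimConfig, simulate_study
        from chromloop.sequence_model import extract_feature_matrix

        # sparse loops: cross-loop convergent re-pairings (the intrinsic
        # confounder of genome-wide enumeration) are rare at this density
        cfg = SimConfig(
            chrom_lengths={f"chr{i}": 3_000_000 for i in range(1, 5)},
            n_open_regions=400,
            n_positive_loops=36,
            distance_log_mean=float(np.log(60_000)),
            distance_log_sd=0.5,
            min_distance=20_000,
            seed=21,
        )
        study = simulate_study(cfg)
        g = study.genome
        positives = db.extract_positive_pairs(study.loops, study.regions)
        ext = _motif_oracle_extractor(input_length=3000)
        anchors = db.build_anchors_from_open_chromatin(
            study.regions, chrom_lengths=g.chrom_lengths
        )
        labeled = db.enumerate_and_label_pairs(anchors, positives, max_span=250_000)
        rng = np.random.default_rng(0)
        keep = [p for p in labeled if p.label == "positive" or rng.random() < 0.5]
        X = extract_feature_matrix(
            ext, [g.fetch(p.left) for p in keep], [g.fetch(p.right) for p in keep]
        )
        y = np.array([1 if p.label == "positive" else 0 for p in keep])
        model = train_gb(
            X, y, feature_names=feature_names(ext.config), seed=0, num_rounds=80
        )
        return study, positives, ext, model

    def test_high_threshold_yields_no_positives(self, sparse_setup):
        study, _, ext, model = sparse_setup
        records = predict_from_open_chromatin(
            study.regions[:100], study.genome, ext, model,
            max_span=300_000, threshold=1.0 + 1e-9,
        )
        assert records and not any(r.predicted for r in records)

    def test_pair_set_matches_enumeration(self, sparse_setup):
        study, _, ext, model = sparse_setup
        peaks = study.regions[:100]
        records = predict_from_open_chromatin(
            peaks, study.genome, ext, model, max_span=300_000, threshold=0.5
        )
        anchors = db.build_anchors_from_open_chromatin(
            peaks, chrom_lengths=study.genome.chrom_lengths
        )
        expected = db.enumerate_and_label_pairs(anchors, [], max_span=300_000)
        assert {r.pair.key() for r in records} == {p.key() for p in expected}

    def test_empty_peaks_empty_output(self, sparse_setup):
        study, _, ext, model = sparse_setup
        assert predict_from_open_chromatin([], study.genome, ext, model) == []

    def test_planted_loops_recovered_at_f_score_threshold(self, sparse_setup):
        """End-to-end: anchors from peaks, scores from the motif-informed
        model; at the F1-selected threshold most planted loops are recovered
        at moderate false discovery."""
        study, positives, ext, model = sparse_setup
        g = study.genome
        records = predict_from_open_chromatin(
            study.regions, g, ext, model, max_span=250_000, threshold=0.5
        )
        anchors = db.build_anchors_from_open_chromatin(
            study.regions, chrom_lengths=g.chrom_lengths
        )
        truth = {
            p.key()
            for p in db.enumerate_and_label_pairs(anchors, positives, max_span=250_000)
            if p.label == "positive"
        }
        scores = np.array([r.score for r in records])
        labels = np.array([1 if r.pair.key() in truth else 0 for r in records])
        threshold, _ = f_score_threshold_scan(scores, labels)
        called = scores >= threshold
        recall = labels[called].sum() / labels.sum()
        fdr = 1 - labels[called].mean()
        assert recall >= 0.7
        assert fdr <= 0.3


class TestDistanceFeature:
    def test_adding_distance_never_hurts_training_fit(self, toy_table):
        """Boosted trees can ignore an uninformative feature, so adding
        distance does not reduce training-set auPRC."""
        X, y = toy_table
        params = {"subsample": 1.0}
        with_d = train_gb(X, y, seed=0, params=params, num_rounds=200)
        without_d = train_gb(
            X.drop(columns="distance"), y, seed=0, params=params, num_rounds=200
        )
        ap_with = auprc(with_d.predict(X), y)[0]
        ap_without = auprc(
            without_d.predict(X.drop(columns="distance")), y
        )[0]
        assert ap_with >= ap_without - 1e-9


class TestCrossSampleGeneralization:
    def test_model_transfers_between_studies_sharing_the_motif(self):
        """A classifier trained on one synthetic study scores another study
        (same planted motif, different genome) above its prevalence."""
        from chromloop.evaluation import cross_sample_matrix
        from chromloop.sequence_model import extract_feature_matrix
        from chromloop.synthetic_data import SimConfig, simulate_study

        ext = _motif_oracle_extractor()
        names = feature_names(ext.config)

        def build(seed):
            cfg = SimConfig(
                chrom_lengths={f"chr{i}": 3_000_000 for i in range(1, 4)},
                n_open_regions=1200, n_positive_loops=150, seed=seed,
            )
            study = simulate_study(cfg)
            pos = db.extract_positive_pairs(study.loops, study.regions)
            pool = db.regions_without_loop_anchors(study.regions, pos)
            neg = db.sample_distance_matched_negatives(
                pos, ratio=5, seed=seed, anchors=pool
            )
            pairs = pos + neg
            g = study.genome
            X = extract_feature_matrix(
                ext,
                [g.fetch(p.left) for p in pairs],
                [g.fetch(p.right) for p in pairs],
            )
            y = np.array([1 if p.label == "positive" else 0 for p in pairs])
            return X, y

        Xa, ya = build(31)
        Xb, yb = build(32)
        model_a = train_gb(Xa, ya, feature_names=names, seed=0, num_rounds=80)
        model_b = train_gb(Xb, yb, feature_names=names, seed=0, num_rounds=80)
        mat = cross_sample_matrix(
            {"A": model_a.predict, "B": model_b.predict},
            {"A": (Xa, ya), "B": (Xb, yb)},
        )
        prevalence = ya.mean()
        assert mat.loc["A", "B"] > prevalence + 0.2
        assert mat.loc["B", "A"] > prevalence + 0.2
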