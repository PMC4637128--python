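"""Discriminant training, cell/image/sample classification and titer logic."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from clift.cells import CellRecord
from clift.classify import (
    CellCall,
    ImageCall,
    TrainedClassifier,
    classify_cell,
    classify_image,
    estimate_titer,
    merge_dilutions,
    profile_feature_names,
    train_classifier,
)
from clift.io import ChannelPair, ConfigError, RunConfig
from clift.pipeline import analyze_pair, build_training_table

from conftest import kineto_only_intensity, simulate_pair

FEATURES = profile_feature_names(32)


def _holdout_accuracy(table, model):
    """Accuracy of the full cell decision (dark rule + discriminant)."""
    pred = []
    for _, row in table.iterrows():
        if row["is_dark"]:
            pred.append(False)
        else:
            pred.append(bool(model.predict(row[FEATURES].to_numpy(float))[0]))
    truth = table["kinetoplast_fluorescent"].to_numpy(bool)
    return float((np.array(pred) == truth).mean())


class TestTraining:
    def test_holdout_accuracy_separable_regime(self, training_table, model):
        held = training_table.iloc[600:]
        assert _holdout_accuracy(held, model) >= 0.95

    def test_no_signal_gives_chance_accuracy(self, run_cfg):
        """With zero kinetoplast intensity the classes are identically
        distributed and accuracy collapses to coin flipping."""
        from clift.simulate import SimConfig

        sim = SimConfig(organelle_intensity={
            "kinetoplast": (0.0, 0.0), "nucleus": (0.55, 0.1),
            "basal_body": (0.45, 0.08)})
        table = build_training_table(400, run_cfg, sim, seed=3)
        m = train_classifier(table.iloc[:300], run_cfg)
        held = table.iloc[300:]
        held = held[~held["is_dark"]]
        acc = float((m.predict(held[FEATURES].to_numpy(float))
                     == held["kinetoplast_fluorescent"].to_numpy(bool)).mean())
        assert 0.3 < acc < 0.7

    def test_single_class_table_rejected(self, training_table, run_cfg):
        pos = training_table[training_table["kinetoplast_fluorescent"]]
        with pytest.raises(ValueError, match="both classes"):
            train_classifier(pos, run_cfg)

    def test_serialization_roundtrip_bit_stable(self, training_table, model,
                                                run_cfg, tmp_path):
        path = tmp_path / "model.json"
        model.save(path)
        loaded = TrainedClassifier.load(path)
        X = training_table.iloc[:100][FEATURES].to_numpy(float)
        assert np.array_equal(model.predict(X), loaded.predict(X))
        assert np.allclose(model.decision_scores(X), loaded.decision_scores(X))

    def test_agrees_with_reference_lda(self, training_table, model):
        """Independent cross-check against scikit-learn's LDA."""
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

        train = training_table.iloc[:600]
        train = train[~train["is_dark"]]
        X = train[FEATURES].to_numpy(float)
        y = train["kinetoplast_fluorescent"].to_numpy(bool)
        sk = LinearDiscriminantAnalysis(solver="lsqr").fit(X, y)
        held = training_table.iloc[600:]
        held = held[~held["is_dark"]]
        Xh = held[FEATURES].to_numpy(float)
        assert float((sk.predict(Xh) == model.predict(Xh)).mean()) >= 0.99


class TestClassifyCell:
    def test_dark_cell_bypasses_model(self, model):
        rec = CellRecord(cell_id=1, mask=np.zeros((4, 4), bool))
        rec.is_dark = True
        before = model.n_predict_calls
        call = classify_cell(None, rec, model)
        assert call.label == "negative"
        assert model.n_predict_calls == before

    def test_qc_failed_cell_excluded(self, model):
        rec = CellRecord(cell_id=2, mask=np.zeros((4, 4), bool))
        rec.fail("area")
        assert classify_cell(None, rec, model).label == "excluded"

    def test_feature_dimension_mismatch_raises(self, model):
        with pytest.raises(ValueError, match="dimension mismatch"):
            model.decision_scores(np.zeros(10))

    @pytest.mark.parametrize("nucleus,basal", [(1.0, 0.0), (0.0, 1.0), (1.0, 1.0)])
    def test_negative_archetypes_called_negative(self, run_cfg, model, nucleus, basal):
        """Kinetoplast dark: negative irrespective of fluorescent nuclei,
        basal bodies, or both."""
        pair, _ = simulate_pair(seed=60, positive_fraction=0.0,
                                nucleus_fluor_prob=nucleus, basal_fluor_prob=basal)
        analysis = analyze_pair(pair, run_cfg, model)
        labels = [c.label for c in analysis.cell_calls if c.label != "excluded"]
        assert labels and labels.count("positive") == 0
        assert analysis.image_call.verdict == "negative"

    @pytest.mark.parametrize("nucleus,basal", [(0.0, 0.0), (1.0, 0.0), (1.0, 1.0)])
    def test_positive_archetypes_called_positive(self, run_cfg, model, nucleus, basal):
        pair, _ = simulate_pair(seed=61, positive_fraction=1.0,
                                nucleus_fluor_prob=nucleus, basal_fluor_prob=basal)
        analysis = analyze_pair(pair, run_cfg, model)
        labels = [c.label for c in analysis.cell_calls if c.label != "excluded"]
        assert labels.count("positive") / len(labels) > 0.9
        assert analysis.image_call.verdict == "positive"


class TestKinetoplastBrightness:
    def _median_brightness(self, run_cfg, model, amp, nucleus=0.0, seed=62):
        pair, _ = simulate_pair(
            seed=seed, positive_fraction=1.0, nucleus_fluor_prob=nucleus,
            basal_fluor_prob=0.0,
            organelle_intensity={"kinetoplast": (amp, 0.02),
                                 "nucleus": (0.55, 0.1),
                                 "basal_body": (0.45, 0.08)},
        )
        analysis = analyze_pair(pair, run_cfg, model)
        vals = [c.kinetoplast_brightness for c in analysis.cell_calls
                if c.label == "positive"]
        return float(np.median(vals))

    def test_negative_cell_brightness_near_zero(self, run_cfg, model):
        pair, _ = simulate_pair(seed=63, positive_fraction=0.0,
                                nucleus_fluor_prob=0.0, basal_fluor_prob=0.0)
        analysis = analyze_pair(pair, run_cfg, model)
        vals = [c.kinetoplast_brightness for c in analysis.cell_calls
                if c.label != "excluded"]
        assert max(vals) < 3 * 0.01  # within read-noise scale

    def test_brightness_tracks_intensity_ratio(self, run_cfg, model):
        b1 = self._median_brightness(run_cfg, model, 0.3)
        b2 = self._median_brightness(run_cfg, model, 0.6)
        assert b2 / b1 == pytest.approx(2.0, rel=0.15)

    def test_brightness_invariant_to_nucleus(self, run_cfg, model):
        b0 = self._median_brightness(run_cfg, model, 0.5, nucleus=0.0)
        b1 = self._median_brightness(run_cfg, model, 0.5, nucleus=1.0)
        assert abs(b1 - b0) / b0 < 0.10


def _calls(n_pos, n_neg, brightness=0.3):
    calls = [CellCall(i, "positive", kinetoplast_brightness=brightness)
             for i in range(n_pos)]
    calls += [CellCall(100 + i, "negative") for i in range(n_neg)]
    return calls


class TestClassifyImage:
    def test_no_positives_negative_verdict(self, run_cfg):
        call = classify_image(_calls(0, 30), run_cfg)
        assert call.verdict == "negative" and call.fraction_positive == 0.0

    def test_exact_cutoff_resolves_positive(self, run_cfg):
        call = classify_image(_calls(15, 15), run_cfg)
        assert call.fraction_positive == 0.5
        assert call.verdict == "positive"

    def test_no_evaluable_cells_rejected(self, run_cfg):
        calls = [CellCall(1, "excluded"), CellCall(2, "excluded")]
        out = classify_image(calls, run_cfg)
        assert out.verdict == "rejected_qc"
        assert out.reject_reason == "no_evaluable_cells"

    def test_matches_exhaustive_decision_table(self, run_cfg):
        """Equivalence oracle: every (n_pos, n_neg) composition up to 10
        cells against the hand-computed >=-cutoff rule."""
        for n in range(1, 11):
            for n_pos in range(n + 1):
                verdict = classify_image(_calls(n_pos, n - n_pos), run_cfg).verdict
                expected = "positive" if n_pos / n >= 0.5 else "negative"
                assert verdict == expected, (n_pos, n)

    @given(st.permutations(list(range(12))))
    @settings(max_examples=30, derandomize=True, deadline=None)
    def test_cell_order_never_changes_verdict(self, order):
        cfg = RunConfig()
        base = _calls(5, 7)
        shuffled = [base[i] for i in order]
        a, b = classify_image(base, cfg), classify_image(shuffled, cfg)
        assert (a.verdict, a.fraction_positive, a.confidence, a.titer_estimate) == (
            b.verdict, b.fraction_positive, b.confidence, b.titer_estimate)

    def test_confidence_grows_with_distance_from_cutoff(self, run_cfg):
        c1 = classify_image(_calls(16, 14), run_cfg).confidence
        c2 = classify_image(_calls(25, 5), run_cfg).confidence
        assert 0.5 <= c1 < c2 <= 1.0


class TestTiter:
    def test_negative_image_titers_negative(self, run_cfg):
        assert estimate_titer(_calls(0, 30), run_cfg, image_verdict="negative") == "negative"

    def test_breakpoint_boundary_takes_higher_step(self, run_cfg):
        bp = run_cfg.brightness_to_titer_breakpoints[1]
        label = estimate_titer(_calls(10, 0, brightness=bp), run_cfg)
        assert label == run_cfg.titer_steps[1]
        label = estimate_titer(_calls(10, 0, brightness=bp - 1e-6), run_cfg)
        assert label == run_cfg.titer_steps[0]

    def test_breakpoint_step_length_mismatch_rejected(self):
        cfg = RunConfig()
        cfg.brightness_to_titer_breakpoints = [0.1, 0.2]
        with pytest.raises(ConfigError):
            estimate_titer(_calls(5, 0), cfg)

    @given(st.lists(st.floats(0.01, 0.9), min_size=1, max_size=20),
           st.floats(1.01, 20.0))
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_raising_brightness_never_lowers_titer(self, brightnesses, factor):
        cfg = RunConfig()
        steps = cfg.titer_steps
        calls = [CellCall(i, "positive", kinetoplast_brightness=b)
                 for i, b in enumerate(brightnesses)]
        brighter = [CellCall(i, "positive", kinetoplast_brightness=b * factor)
                    for i, b in enumerate(brightnesses)]
        assert steps.index(estimate_titer(brighter, cfg)) >= steps.index(
            estimate_titer(calls, cfg))


def _image_call(verdict, titer="negative", dilution=1.0, sample="s1", conf=0.9):
    return ImageCall(biochip_id="b", verdict=verdict, titer_estimate=titer,
                     sample_id=sample, dilution_factor=dilution, confidence=conf)


class TestMergeDilutions:
    def test_single_negative_image(self, run_cfg):
        res = merge_dilutions([_image_call("negative")], run_cfg)
        assert res.verdict == "negative" and res.final_titer == "negative"

    def test_positive_screening_with_negative_higher_dilution(self, run_cfg):
        res = merge_dilutions([
            _image_call("positive", "1:10", dilution=1.0),
            _image_call("negative", dilution=10.0),
        ], run_cfg)
        assert res.verdict == "positive"
        assert run_cfg.titer_steps.index(res.final_titer) >= 0

    def test_highest_positive_dilution_drives_titer(self, run_cfg):
        res = merge_dilutions([
            _image_call("positive", "1:10", dilution=1.0),
            _image_call("positive", "1:10", dilution=10.0),
            _image_call("negative", dilution=100.0),
        ], run_cfg)
        assert res.final_titer == "1:100"

    def test_confidence_is_minimum_over_images(self, run_cfg):
        res = merge_dilutions([
            _image_call("positive", "1:10", conf=0.95),
            _image_call("negative", conf=0.7, dilution=10.0),
        ], run_cfg)
        assert res.confidence == 0.7

    def test_conflicting_sample_ids_rejected(self, run_cfg):
        with pytest.raises(ValueError, match="conflicting sample_ids"):
            merge_dilutions([
                _image_call("negative", sample="a"),
                _image_call("negative", sample="b"),
            ], run_cfg)

    def test_empty_input_rejected(self, run_cfg):
        with pytest.raises(ValueError):
            merge_dilutions([], run_cfg)


class TestEndToEnd:
    def test_extreme_fractions_always_recovered(self, run_cfg, model):
        """positive_fraction 0 or 1 -> the image verdict must match ground
        truth in every seeded run of the separable regime."""
        for seed in range(10):
            for fraction, expected in ((0.0, "negative"), (1.0, "positive")):
                pair, _ = simulate_pair(seed=70 + seed, n_cells=12,
                                        image_width=306, image_height=256,
                                        positive_fraction=fraction)
                analysis = analyze_pair(pair, run_cfg, model)
                assert analysis.image_call.verdict == expected, (seed, fraction)
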