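"""Window feature extraction, the enhancer classifier, and boundary calls."""

import numpy as np
import pandas as pd
import pytest

from esnp.enhancer import (EnhancerError, EnhancerModel, TrackSet, call_esnps,
                           enhancer_boundaries, extract_features,
                           merge_intervals, train_classifier)


def _tracks(signal_rows, states_rows=None, peaks=None, tf_rows=None, marks=("h3k27ac",)):
    signals = {m: pd.DataFrame(signal_rows.get(m, []),
                               columns=["chrom", "start", "end", "value"])
               for m in marks}
    states = pd.DataFrame(states_rows or [], columns=["chrom", "start", "end", "name"])
    tf = pd.DataFrame(tf_rows or [], columns=["chrom", "start", "end", "name"])
    pk = {m: pd.DataFrame(peaks.get(m, []) if peaks else [],
                          columns=["chrom", "start", "end", "name"]) for m in marks}
    return TrackSet(signals=signals, peaks=pk, states=states, tf_peaks=tf, marks=marks)


def test_length_weighted_signal_mean():
    """Two intervals (100 bp at 2.0, 400 bp at 0.5) covering the window
    average to (100*2 + 400*0.5)/500 = 0.8."""
    # SNP at position 1251 (1-based): window [1000, 1500)
    tracks = _tracks({"h3k27ac": [("chr1", 1000, 1100, 2.0),
                                  ("chr1", 1100, 1500, 0.5)]})
    wf = extract_features("s", "chr1", 1251, tracks)
    assert wf.start == 1000 and wf.end == 1500
    assert wf.features["h3k27ac_mean"] == pytest.approx(0.8)


def test_zero_signal_gives_zero_features():
    tracks = _tracks({"h3k27ac": [("chr1", 90_000, 91_000, 3.0)]})
    wf = extract_features("s", "chr1", 1251, tracks)
    assert wf.features["h3k27ac_mean"] == 0.0
    assert wf.features["h3k27ac_peak_frac"] == 0.0


def test_state_fraction_is_one_inside_planted_window():
    tracks = _tracks({"h3k27ac": []},
                     states_rows=[("chr1", 900, 1600, "strong_enhancer")])
    wf = extract_features("s", "chr1", 1251, tracks)
    assert wf.features["state_strong_enhancer_frac"] == pytest.approx(1.0)
    total = sum(v for k, v in wf.features.items() if k.startswith("state_"))
    assert total == pytest.approx(1.0)


def test_uncovered_bases_count_as_quiescent():
    tracks = _tracks({"h3k27ac": []},
                     states_rows=[("chr1", 1000, 1250, "strong_enhancer")])
    wf = extract_features("s", "chr1", 1251, tracks)
    assert wf.features["state_strong_enhancer_frac"] == pytest.approx(0.5)
    assert wf.features["state_quiescent_frac"] == pytest.approx(0.5)


def test_feature_extraction_translation_equivariance():
    rows = [("chr1", 1000, 1100, 2.0), ("chr1", 1100, 1500, 0.5)]
    shift = 37_000
    shifted = [(c, s + shift, e + shift, v) for c, s, e, v in rows]
    wf0 = extract_features("s", "chr1", 1251, _tracks({"h3k27ac": rows}))
    wf1 = extract_features("s", "chr1", 1251 + shift, _tracks({"h3k27ac": shifted}))
    assert wf0.features == wf1.features


def test_unknown_contig_is_an_error():
    tracks = _tracks({"h3k27ac": [("chr1", 0, 100, 1.0)]})
    with pytest.raises(EnhancerError):
        extract_features("s", "chrUn", 1251, tracks)


def test_edge_window_is_truncated_and_flagged():
    tracks = _tracks({"h3k27ac": [("chr1", 0, 1000, 1.0)]})
    wf = extract_features("s", "chr1", 100, tracks)
    assert wf.truncated and wf.start == 0


# ---------------------------------------------------------------------------
# Classifier
# ---------------------------------------------------------------------------

def _labeled_windows(n_per_class, strength, seed):
    """Synthetic feature windows: enhancers get elevated mark means."""
    rng = np.random.default_rng(seed)
    windows, labels = [], []
    for i in range(2 * n_per_class):
        enh = i < n_per_class
        base = rng.lognormal(0, 0.4, size=3)
        feats = {
            "h3k27ac_mean": base[0] + (strength if enh else 0.0),
            "h3k4me1_mean": base[1] + (strength if enh else 0.0),
            "dnase_mean": base[2] + (strength if enh else 0.0),
        }
        from esnp.enhancer import WindowFeatures
        windows.append(WindowFeatures(f"w{i}", "chr1", 0, 500, False, feats))
        labels.append(enh)
    return windows, labels


def test_separable_planted_data_has_high_cv_accuracy():
    windows, labels = _labeled_windows(20, strength=8.0, seed=0)
    model = train_classifier(windows, labels, seed=0)
    assert np.mean(model.cv_accuracy) >= 0.95


def test_shuffled_labels_score_near_chance():
    windows, labels = _labeled_windows(40, strength=8.0, seed=0)
    rng = np.random.default_rng(1)
    shuffled = list(rng.permutation(labels))
    model = train_classifier(windows, shuffled, seed=0)
    acc = np.mean(model.cv_accuracy)
    assert abs(acc - 0.5) <= 3 * np.sqrt(0.25 / len(labels))


def test_duplicated_training_set_gives_identical_coefficients():
    windows, labels = _labeled_windows(15, strength=5.0, seed=2)
    m1 = train_classifier(windows, labels, seed=0)
    m2 = train_classifier(windows + windows, labels + labels, seed=0)
    assert np.allclose(m1.coef, m2.coef, atol=1e-4)


def test_single_class_labels_raise():
    windows, labels = _labeled_windows(10, strength=5.0, seed=3)
    with pytest.raises(EnhancerError):
        train_classifier(windows, [True] * len(windows), seed=0)


def test_esnp_call_cutoff_is_inclusive():
    windows, labels = _labeled_windows(15, strength=8.0, seed=4)
    model = train_classifier(windows, labels, seed=0)
    score = float(model.score_windows([windows[0]])[0])
    calls = call_esnps([windows[0]], model, cutoff=score)
    assert calls[0].is_esnp  # score == cutoff keeps the call
    calls = call_esnps([windows[0]], model, cutoff=min(score + 1e-9, 1.0))
    assert not calls[0].is_esnp


def test_model_json_roundtrip_reproduces_scores_exactly(tmp_path):
    windows, labels = _labeled_windows(15, strength=6.0, seed=5)
    model = train_classifier(windows, labels, seed=0)
    model.to_json(tmp_path / "model.json")
    back = EnhancerModel.from_json(tmp_path / "model.json")
    s1 = model.score_windows(windows)
    s2 = back.score_windows(windows)
    assert np.array_equal(s1, s2)


def test_score_invariant_to_feature_rescaling():
    """Standardization absorbs units: scaling a feature by a constant in
    both training and scoring leaves the scores unchanged."""
    windows, labels = _labeled_windows(15, strength=6.0, seed=6)
    from esnp.enhancer import WindowFeatures
    scaled = [WindowFeatures(w.snp_id, w.chrom, w.start, w.end, w.truncated,
                             {k: 1000.0 * v for k, v in w.features.items()})
              for w in windows]
    m1 = train_classifier(windows, labels, seed=0)
    m2 = train_classifier(scaled, labels, seed=0)
    assert np.allclose(m1.score_windows(windows), m2.score_windows(scaled), atol=1e-6)


def test_sensitivity_monotone_in_signature_strength():
    weak_w, labels = _labeled_windows(20, strength=0.0, seed=7)
    strong_w, _ = _labeled_windows(20, strength=8.0, seed=7)
    model = train_classifier(strong_w, labels, seed=0)
    weak_calls = call_esnps(weak_w[:20], model)
    strong_calls = call_esnps(strong_w[:20], model)
    assert sum(c.is_esnp for c in strong_calls) >= sum(c.is_esnp for c in weak_calls)


# ---------------------------------------------------------------------------
# Boundaries
# ---------------------------------------------------------------------------

def test_merge_intervals_handles_bookended():
    assert merge_intervals([(0, 5), (5, 9), (20, 30)]) == [(0, 9), (20, 30)]


def _bed(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])


def test_boundary_single_dhs():
    b, fb = enhancer_boundaries("chr1", 1200, _bed([("chr1", 1000, 1600, "d")]), _bed([]))
    assert b == (1000, 1600) and not fb


def test_boundary_union_of_overlapping_dhs_and_mark():
    b, fb = enhancer_boundaries("chr1", 1201,
                                _bed([("chr1", 1000, 1600, "d")]),
                                _bed([("chr1", 1500, 2200, "m")]))
    assert b == (1000, 2200) and not fb


def test_boundary_fallback_window_when_nothing_overlaps():
    b, fb = enhancer_boundaries("chr1", 50_001, _bed([("chr1", 0, 100, "d")]), _bed([]))
    assert fb and b == (49_750, 50_250)
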