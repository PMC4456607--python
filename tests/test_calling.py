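import numpy as np
import pytest

import unzipmap as um
from unzipmap.calling import ForceEvent


def _pipeline(trace, reference, layout, signature):
    base = um.estimate_baseline(trace, reference)
    events = um.detect_events(trace, base)
    clusters = um.segment_clusters(events)
    return (um.call_tf(events, clusters, layout, signature),
            um.call_nucleosome(clusters, signature), events, clusters)


class TestBaseline:
    def test_reference_against_itself_below_threshold(self, reference):
        base = um.estimate_baseline(reference, reference)
        assert um.detect_events(reference, base) == []

    def test_constant_reference_gives_flat_baseline(self, layout, quiet_models,
                                                    quiet_reference):
        base = um.estimate_baseline(quiet_reference, quiet_reference)
        assert np.allclose(base.baseline, 15.0)

    def test_mismatched_grids_rejected(self, layout, signature, instrument,
                                       reference):
        tr = um.simulate_trace(layout, (False, False), signature, instrument, 0)
        shifted = um.distort_trace(tr, 5.0, 1.0)
        with pytest.raises(ValueError):
            um.estimate_baseline(shifted, reference)

    def test_signature_windows_exceed_threshold_only(self, layout, quiet_models,
                                                     quiet_reference):
        sig, ins = quiet_models
        tr = um.simulate_trace(layout, (True, True), sig, ins, 0)
        base = um.estimate_baseline(tr, quiet_reference)
        above = tr.positions[(tr.forces - base.baseline) > base.floor]
        tf_peak = layout.tf_center_unzip - sig.tf_peak_offset
        c1 = layout.dyad0_unzip - 43
        c2 = layout.dyad0_unzip + 5
        in_signature = ((np.abs(above - tf_peak) <= 20)
                        | ((above >= c1 - 30) & (above <= c2 + 35)))
        assert np.all(in_signature)


class TestEventsAndClusters:
    def test_naked_trace_has_no_events(self, layout, signature, instrument,
                                       reference):
        for seed in range(5):
            tr = um.simulate_trace(layout, (False, False), signature,
                                   instrument, 300 + seed)
            base = um.estimate_baseline(tr, reference)
            assert um.detect_events(tr, base) == []

    def test_noiseless_tf_single_event(self, layout, quiet_models,
                                       quiet_reference):
        sig, ins = quiet_models
        tr = um.simulate_trace(layout, (True, False), sig, ins, 0)
        base = um.estimate_baseline(tr, quiet_reference)
        events = um.detect_events(tr, base)
        assert len(events) == 1
        assert events[0].position == layout.tf_center_unzip - 8
        assert 18.0 <= events[0].peak_force <= 20.0

    def test_nucleosome_events_form_two_groups(self, layout, signature,
                                               instrument, reference):
        tr = um.simulate_trace(layout, (False, True), signature, instrument, 4)
        base = um.estimate_baseline(tr, reference)
        events = um.detect_events(tr, base)
        assert len(events) >= 2
        clusters = um.segment_clusters(events)
        assert len(clusters) == 2

    def test_gap_rule(self):
        events = [ForceEvent(p, 25.0, 10.0) for p in (100, 105, 160, 163)]
        clusters = um.segment_clusters(events, gap_bp=15)
        assert [len(c.events) for c in clusters] == [2, 2]

    def test_single_event_cluster_width_zero(self):
        clusters = um.segment_clusters([ForceEvent(100.0, 25.0, 10.0)])
        assert len(clusters) == 1
        assert clusters[0].width == 0.0
        assert clusters[0].force_centroid == 100.0

    def test_sample_mode_centroid_needs_trace(self):
        with pytest.raises(ValueError):
            um.segment_clusters([ForceEvent(100.0, 25.0, 10.0)],
                                centroid_mode="sample")

    def test_sample_and_peak_centroids_agree_roughly(self, layout, quiet_models,
                                                     quiet_reference):
        sig, ins = quiet_models
        tr = um.simulate_trace(layout, (False, True), sig, ins, 0)
        base = um.estimate_baseline(tr, quiet_reference)
        events = um.detect_events(tr, base)
        peak = um.segment_clusters(events)
        sample = um.segment_clusters(events, centroid_mode="sample",
                                     trace=tr, baseline=base)
        assert sample[0].force_centroid == pytest.approx(
            peak[0].force_centroid, abs=3.0)


class TestCalls:
    def test_noiseless_calls_recover_truth_exactly(self, layout, quiet_models,
                                                   quiet_reference):
        sig, ins = quiet_models
        tr = um.simulate_trace(layout, (True, True), sig, ins, 0)
        tf, nuc, _, _ = _pipeline(tr, quiet_reference, layout, sig)
        assert tf.bound is True and not tf.masked
        assert tf.called_center == layout.tf_center_unzip
        assert nuc.present
        assert nuc.called_dyad == layout.dyad0_unzip
        assert nuc.features["intercluster_distance"] == pytest.approx(48.0)

    def test_naked_trace_called_unbound_and_nucleosome_free(
            self, layout, signature, instrument, reference):
        tr = um.simulate_trace(layout, (False, False), signature, instrument, 8)
        tf, nuc, _, _ = _pipeline(tr, reference, layout, signature)
        assert tf.bound is False
        assert not nuc.present

    def test_masked_when_nucleosome_covers_tf_window(self, layout, quiet_models,
                                                     quiet_reference):
        sig, ins = quiet_models
        moved = layout.with_dyad(layout.tf_center + 20)
        tr = um.simulate_trace(moved, (False, True), sig, ins, 0)
        base = um.estimate_baseline(tr, quiet_reference)
        events = um.detect_events(tr, base)
        clusters = um.segment_clusters(events)
        tf = um.call_tf(events, clusters, layout, sig)
        assert tf.masked and tf.bound is None

    def test_direction_symmetry_noiseless(self, quiet_models):
        sig, ins = quiet_models
        calls = {}
        for direction in (um.FROM_TF_SIDE, um.FROM_NUC_SIDE):
            lay = um.build_template(800, 10, direction=direction)
            tr = um.simulate_trace(lay, (True, True), sig, ins, 0)
            ref = um.simulate_naked_reference(lay, sig, ins, 1)
            tf, nuc, _, _ = _pipeline(tr, ref, lay, sig)
            calls[direction] = (lay.unzip_to_dyad_frame(tf.called_center),
                                lay.unzip_to_dyad_frame(nuc.called_dyad))
        assert calls[um.FROM_TF_SIDE] == calls[um.FROM_NUC_SIDE]

    def test_bound_unbound_classification_99pct(self, layout, signature,
                                                instrument, reference):
        fn = fp = 0
        n = 250
        for seed in range(n):
            bound = um.simulate_trace(layout, (True, False), signature,
                                      instrument, 1000 + seed)
            naked = um.simulate_trace(layout, (False, False), signature,
                                      instrument, 5000 + seed)
            tb, _, _, _ = _pipeline(bound, reference, layout, signature)
            tn, _, _, _ = _pipeline(naked, reference, layout, signature)
            fn += tb.bound is not True
            fp += tn.bound is not False
        assert fn / n <= 0.01
        assert fp / n <= 0.01

    def test_position_precision_near_base_pair(self, layout, signature,
                                               instrument, reference):
        tf_calls, dyad_calls = [], []
        for seed in range(200):
            tr = um.simulate_trace(layout, (True, True), signature,
                                   instrument, 9000 + seed)
            tf, nuc, _, _ = _pipeline(tr, reference, layout, signature)
            if tf.bound:
                tf_calls.append(tf.called_center)
            if nuc.present:
                dyad_calls.append(nuc.called_dyad)
        assert len(tf_calls) >= 195 and len(dyad_calls) >= 195
        for calls, expected in ((tf_calls, layout.tf_center_unzip),
                                (dyad_calls, layout.dyad0_unzip)):
            pa = um.precision_accuracy(calls, expected)
            assert abs(pa["bias"]) <= 1.0
            assert pa["sd"] <= 2.0


class TestDwellHistogram:
    def test_requires_time_channel(self, layout, signature, instrument):
        tr = um.simulate_trace(layout, (False, False), signature, instrument,
                               0, include_time=False)
        with pytest.raises(ValueError):
            um.compute_dwell_histogram(tr)

    def test_naked_dwell_near_uniform(self, layout, quiet_models):
        sig, ins = quiet_models
        tr = um.simulate_trace(layout, (False, False), sig, ins, 0)
        hist, _ = um.compute_dwell_histogram(tr, 5.0)
        inner = hist[1:-1]
        assert inner.max() <= 1.5 * inner[inner > 0].min()

    def test_tf_dwell_peak_at_disruption_site(self, layout, quiet_models):
        sig, ins = quiet_models
        tr = um.simulate_trace(layout, (True, False), sig, ins, 0)
        hist, edges = um.compute_dwell_histogram(tr, 2.0)
        centers = 0.5 * (edges[:-1] + edges[1:])
        peak = centers[np.argmax(hist)]
        assert abs(peak - (layout.tf_center_unzip - 8)) <= 2.0

    def test_nucleosome_dwell_peak_at_first_cluster_leading_edge(
            self, layout, quiet_models):
        sig, ins = quiet_models
        tr = um.simulate_trace(layout, (False, True), sig, ins, 0)
        hist, edges = um.compute_dwell_histogram(tr, 5.0)
        centers = 0.5 * (edges[:-1] + edges[1:])
        peak = centers[np.argmax(hist)]
        leading_edge = (layout.dyad0_unzip - 43
                        + min(sig.cluster_subpeak_offsets))
        assert abs(peak - leading_edge) <= 3.0
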