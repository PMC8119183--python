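"""Separation-threshold and hierarchical-gating debarcoders.

The key-wise scorer (min over key-positive channels minus max over
key-negative channels) is checked event-for-event against an independent
brute-force oracle: for a complete constant-weight scheme the best key is
the set of the k brightest channels and the separation is the gap between
the k-th and (k+1)-th brightest rescaled values.
"""

import numpy as np
import pytest

from cytobarcode import (
    UNASSIGNED,
    ChannelThresholds,
    DebarcodeParams,
    SimulationConfig,
    apply_threshold,
    arcsinh_transform,
    assign_events,
    debarcode_hierarchical,
    debarcode_separation,
    estimate_channel_thresholds,
    generate_complete_scheme,
    hierarchical_gate_debarcode,
    rescale_barcode_channels,
    score_concordance,
    simulate_barcoded_events,
)
from cytobarcode.debarcode import DebarcodeError


def top_k_oracle(rescaled, scheme):
    """Independent assignment rule for complete schemes: the k brightest
    channels are the key; separation is the k/(k+1) brightness gap."""
    k = scheme.k
    key_lookup = {
        frozenset(scheme.positive_channels(s)): s
        for s in range(scheme.n_samples)
    }
    assigned = np.empty(rescaled.shape[0], dtype=np.int64)
    separation = np.empty(rescaled.shape[0])
    for e in range(rescaled.shape[0]):
        order = np.argsort(rescaled[e])[::-1]
        kth, k1th = rescaled[e, order[k - 1]], rescaled[e, order[k]]
        if kth == k1th:  # ambiguous membership of the top-k set
            assigned[e] = UNASSIGNED
            separation[e] = 0.0
        else:
            assigned[e] = key_lookup[frozenset(order[:k].tolist())]
            separation[e] = kth - k1th
    return assigned, np.clip(separation, 0.0, 1.0)


def test_perfect_event_scores_one(scheme10):
    rescaled = np.array([[1.0, 1.0, 1.0, 0.0, 0.0]])
    a = assign_events(rescaled, scheme10)
    assert a.assigned_sample[0] == 0  # key {ch0,ch1,ch2} is row 0
    assert a.separation[0] == 1.0


def test_union_key_event_scores_zero(scheme10):
    """A doublet-like event positive on 4 channels violates every key's
    negative slot, so its best score is 0."""
    rescaled = np.array([[1.0, 1.0, 1.0, 1.0, 0.0]])
    a = assign_events(rescaled, scheme10)
    assert a.separation[0] == 0.0
    final = apply_threshold(a, DebarcodeParams(separation_threshold=0.05))
    assert final.assigned_sample[0] == UNASSIGNED


def test_tie_between_keys_is_unassigned(scheme10):
    rescaled = np.array([[0.5, 0.5, 0.5, 0.5, 0.5]])
    a = assign_events(rescaled, scheme10)
    assert a.assigned_sample[0] == UNASSIGNED
    assert a.separation[0] == 0.0


def test_assignment_matches_brute_force_oracle(scheme10):
    """Key-wise scoring equals the top-k rule event-for-event on 10,000
    simulated events (complete scheme)."""
    cfg = SimulationConfig(events_per_sample=1000, doublet_rate=0.0, seed=77)
    m, _ = simulate_barcoded_events(scheme10, cfg)
    transformed = arcsinh_transform(m.values[:, :5])
    rescaled = rescale_barcode_channels(transformed)
    a = assign_events(rescaled, scheme10)
    oracle_assigned, oracle_sep = top_k_oracle(rescaled, scheme10)
    assert np.array_equal(a.assigned_sample, oracle_assigned)
    assert np.allclose(a.separation, oracle_sep, atol=1e-12)


def test_oracle_equivalence_on_6_choose_3():
    scheme = generate_complete_scheme([f"c{i}" for i in range(6)], 3)
    cfg = SimulationConfig(events_per_sample=100, doublet_rate=0.05, seed=5)
    m, _ = simulate_barcoded_events(scheme, cfg)
    rescaled = rescale_barcode_channels(arcsinh_transform(m.values[:, :6]))
    a = assign_events(rescaled, scheme)
    oracle_assigned, oracle_sep = top_k_oracle(rescaled, scheme)
    assert np.array_equal(a.assigned_sample, oracle_assigned)
    assert np.allclose(a.separation, oracle_sep, atol=1e-12)


def test_threshold_zero_keeps_all_threshold_one_boundary(scheme10, rng):
    rescaled = rng.random((200, 5))
    prelim = assign_events(rescaled, scheme10)
    at0 = apply_threshold(prelim, DebarcodeParams(separation_threshold=0.0))
    assert np.array_equal(at0.assigned_sample, prelim.assigned_sample)
    at1 = apply_threshold(prelim, DebarcodeParams(separation_threshold=1.0))
    keep = at1.assigned_sample != UNASSIGNED
    assert (prelim.separation[keep] == 1.0).all()


def test_threshold_at_exact_separation_keeps_event(scheme10):
    rescaled = np.array([[0.9, 0.9, 0.9, 0.6, 0.0]])
    a = assign_events(rescaled, scheme10)
    sep = a.separation[0]
    kept = apply_threshold(a, DebarcodeParams(separation_threshold=float(sep)))
    assert kept.assigned_sample[0] != UNASSIGNED  # comparison is >=


def test_capture_rate_monotone_in_threshold(scheme10):
    cfg = SimulationConfig(events_per_sample=300, doublet_rate=0.05, seed=19)
    m, _ = simulate_barcoded_events(scheme10, cfg)
    rescaled = rescale_barcode_channels(arcsinh_transform(m.values[:, :5]))
    prelim = assign_events(rescaled, scheme10)
    counts = [
        int(
            apply_threshold(
                prelim, DebarcodeParams(separation_threshold=t)
            ).is_assigned.sum()
        )
        for t in np.linspace(0, 1, 21)
    ]
    assert all(a >= b for a, b in zip(counts, counts[1:]))


def test_assignments_partition_events(scheme10):
    cfg = SimulationConfig(events_per_sample=200, doublet_rate=0.1, seed=23)
    m, _ = simulate_barcoded_events(scheme10, cfg)
    a = debarcode_separation(m, scheme10)
    assert ((a.assigned_sample >= UNASSIGNED) & (a.assigned_sample < 10)).all()
    assert ((a.separation >= 0) & (a.separation <= 1)).all()


def test_parameter_recovery_default_conditions(scheme10):
    """At default noise with 5% doublets and threshold 0.3, assigned
    singlets are >= 99% correct and >= 95% of doublets are rejected."""
    cfg = SimulationConfig(events_per_sample=1000, doublet_rate=0.05, seed=101)
    m, t = simulate_barcoded_events(scheme10, cfg)
    a = debarcode_separation(m, scheme10, DebarcodeParams(separation_threshold=0.3))
    cr = score_concordance(a, t)
    assert cr.singlet_accuracy >= 0.99
    assert cr.doublet_rejection >= 0.95


def test_column_scheme_mismatch_is_error(scheme10):
    with pytest.raises(DebarcodeError, match="columns"):
        assign_events(np.zeros((3, 4)), scheme10)


class TestHierarchicalGating:
    def test_noiseless_simulation_fully_recovered(self, scheme10):
        cfg = SimulationConfig(
            events_per_sample=50, log_cv=0.0, doublet_rate=0.0, seed=2
        )
        m, t = simulate_barcoded_events(scheme10, cfg)
        transformed = arcsinh_transform(m.values[:, :5])
        mid = (arcsinh_transform(2.0) + arcsinh_transform(200.0)) / 2
        thr = ChannelThresholds(np.full(5, mid))
        a = hierarchical_gate_debarcode(transformed, scheme10, thr)
        assert np.array_equal(a.assigned_sample, t.true_sample)

    def test_all_below_threshold_unassigned(self, scheme10):
        transformed = np.full((4, 5), 0.1)
        thr = ChannelThresholds(np.full(5, 5.0))
        a = hierarchical_gate_debarcode(transformed, scheme10, thr)
        assert (a.assigned_sample == UNASSIGNED).all()

    def test_threshold_count_mismatch(self, scheme10):
        with pytest.raises(DebarcodeError, match="thresholds"):
            hierarchical_gate_debarcode(
                np.zeros((2, 5)), scheme10, ChannelThresholds(np.zeros(4))
            )

    def test_concordance_with_separation_method(self, scheme10):
        """On a well-separated default batch the two debarcoders agree on
        >= 99% of singlet events."""
        cfg = SimulationConfig(events_per_sample=500, doublet_rate=0.0, seed=55)
        m, t = simulate_barcoded_events(scheme10, cfg)
        sep = debarcode_separation(m, scheme10)
        gate = debarcode_hierarchical(m, scheme10)
        agree = (sep.assigned_sample == gate.assigned_sample).mean()
        assert agree >= 0.99


class TestThresholdEstimation:
    def test_two_point_masses_split_between(self):
        x = np.concatenate([np.full(50, 0.1), np.full(50, 0.9)]).reshape(-1, 1)
        thr = estimate_channel_thresholds(x)
        assert 0.1 < thr.values[0] < 0.9
        assert not thr.failed[0]

    def test_constant_channel_flagged_inf(self):
        x = np.column_stack([np.full(20, 3.0), np.arange(20.0)])
        thr = estimate_channel_thresholds(x)
        assert thr.failed[0] and np.isinf(thr.values[0])
        assert not thr.failed[1]

    def test_auto_thresholds_reproduce_oracle_midpoint_calls(self, scheme10):
        """Auto-estimated cutoffs match assignments made with the known
        mode-midpoint cutoffs on >= 99% of events."""
        cfg = SimulationConfig(events_per_sample=500, doublet_rate=0.0, seed=61)
        m, _ = simulate_barcoded_events(scheme10, cfg)
        transformed = arcsinh_transform(m.values[:, :5])
        mid = (arcsinh_transform(2.0) + arcsinh_transform(200.0)) / 2
        oracle = hierarchical_gate_debarcode(
            transformed, scheme10, ChannelThresholds(np.full(5, mid))
        )
        auto = hierarchical_gate_debarcode(
            transformed, scheme10, estimate_channel_thresholds(transformed)
        )
        agree = (oracle.assigned_sample == auto.assigned_sample).mean()
        assert agree >= 0.99

    def test_estimation_deterministic(self, rng):
        x = rng.normal(0, 1, size=(300, 2))
        a = estimate_channel_thresholds(x)
        b = estimate_channel_thresholds(x)
        assert np.array_equal(a.values, b.values)
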