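"""Gating, arcsinh transform, and barcode-channel rescaling."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cytobarcode import (
    GateConfig,
    SimulationConfig,
    arcsinh_transform,
    gate_cells,
    gate_live,
    generate_complete_scheme,
    rescale_barcode_channels,
    simulate_barcoded_events,
)
from cytobarcode.preprocess import PreprocessError


def test_arcsinh_closed_form_values():
    assert arcsinh_transform(0.0) == 0.0
    assert np.isclose(arcsinh_transform(5.0, cofactor=5.0), np.log(1 + np.sqrt(2)))
    with pytest.raises(PreprocessError):
        arcsinh_transform([1.0], cofactor=0.0)


@settings(max_examples=50, derandomize=True, deadline=None)
@given(
    st.lists(st.floats(min_value=0, max_value=1e6), min_size=2, max_size=50),
    st.floats(min_value=0.1, max_value=100),
)
def test_arcsinh_is_monotone(values, cofactor):
    x = np.array(values)
    y = arcsinh_transform(x, cofactor)
    order = np.argsort(x, kind="stable")
    assert (np.diff(y[order]) >= 0).all()


def test_vacuous_gate_keeps_everything(clean_batch):
    m, _ = clean_batch
    kept_m, idx = gate_cells(m, GateConfig(rh_min=0.0))
    assert kept_m.n_events == m.n_events
    assert np.array_equal(idx, np.arange(m.n_events))
    live_m, idx2 = gate_live(m, GateConfig(pd_max=np.inf))
    assert live_m.n_events == m.n_events


def test_live_gate_removes_dead_at_midpoint(scheme10):
    """At the midpoint between live and dead Pd modes (arcsinh units),
    >= 99% of dead events are removed and few live ones are lost."""
    cfg = SimulationConfig(events_per_sample=1000, dead_rate=0.2, seed=31)
    m, t = simulate_barcoded_events(scheme10, cfg)
    midpoint = (arcsinh_transform(10.0) + arcsinh_transform(500.0)) / 2
    live_m, kept = gate_live(m, GateConfig(pd_max=midpoint))
    removed = np.setdiff1d(np.arange(m.n_events), kept)
    dead_idx = np.flatnonzero(t.is_dead)
    frac_dead_removed = np.isin(dead_idx, removed).mean()
    assert frac_dead_removed >= 0.99
    assert np.isin(np.flatnonzero(~t.is_dead), kept).mean() >= 0.95


def test_all_dead_batch_fully_removed(scheme10):
    cfg = SimulationConfig(events_per_sample=200, dead_rate=0.999999, seed=32)
    m, t = simulate_barcoded_events(scheme10, cfg)
    assert t.is_dead.all()
    midpoint = (arcsinh_transform(10.0) + arcsinh_transform(500.0)) / 2
    live_m, _ = gate_live(m, GateConfig(pd_max=midpoint))
    assert live_m.n_events <= 0.01 * m.n_events


def test_gates_idempotent_and_order_independent(doublet_batch):
    m, _ = doublet_batch
    gate = GateConfig(rh_min=2.0, length_range=(10.0, 35.0), pd_max=3.4)
    once, idx1 = gate_cells(m, gate)
    twice, idx2 = gate_cells(once, gate)
    assert twice.n_events == once.n_events
    assert np.array_equal(idx2, np.arange(once.n_events))

    a, ia = gate_cells(m, gate)
    a2, ia2 = gate_live(a, gate)
    b, ib = gate_live(m, gate)
    b2, ib2 = gate_cells(b, gate)
    kept_ab = set(ia[ia2])
    kept_ba = set(ib[ib2])
    assert kept_ab == kept_ba


def test_empty_input_gates_to_empty(scheme10):
    m, _ = simulate_barcoded_events(
        scheme10, SimulationConfig(events_per_sample=0, seed=0)
    )
    out, idx = gate_cells(m, GateConfig())
    assert out.n_events == 0 and idx.size == 0


def test_missing_channel_is_error(clean_batch):
    m, _ = clean_batch
    with pytest.raises(Exception, match="not found"):
        gate_cells(m, GateConfig(rh_channel="Ir191Di"))


class TestRescale:
    def test_percentile_endpoints_map_to_0_and_1(self, rng):
        x = rng.normal(0, 1, size=(500, 1))
        out = rescale_barcode_channels(x, 0, 100)  # full-range percentiles
        # column min/max are the 0th/100th percentiles -> map to 0 and 1
        assert out[np.argmin(x[:, 0]), 0] == pytest.approx(0.0, abs=1e-12)
        assert out[np.argmax(x[:, 0]), 0] == pytest.approx(1.0, abs=1e-12)

    def test_all_values_in_unit_interval(self, rng):
        x = rng.lognormal(3, 1, size=(400, 5))
        out = rescale_barcode_channels(x)
        assert (out >= 0).all() and (out <= 1).all()

    def test_constant_column_is_zero_with_warning(self):
        x = np.column_stack([np.ones(100), np.arange(100.0)])
        with pytest.warns(UserWarning, match="constant"):
            out = rescale_barcode_channels(x)
        assert (out[:, 0] == 0).all()
        assert out[:, 1].max() == 1.0

    def test_rank_order_preserved(self, rng):
        x = rng.normal(0, 2, size=(300, 3))
        out = rescale_barcode_channels(x)
        for j in range(3):
            order = np.argsort(x[:, j], kind="stable")
            assert (np.diff(out[order, j]) >= 0).all()

    def test_too_few_events_rejected(self):
        with pytest.raises(PreprocessError, match=">= 2"):
            rescale_barcode_channels(np.ones((1, 3)))

    def test_bad_percentiles_rejected(self):
        with pytest.raises(PreprocessError):
            rescale_barcode_channels(np.ones((10, 2)), 50, 50)
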