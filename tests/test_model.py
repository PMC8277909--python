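"""Network integration: fixed points, determinism, boundaries, presets."""

import numpy as np
import pytest

import thalwave as tw
from thalwave.model import Modifier, Simulation, SimulationConfig
from thalwave.presets import make_config, preset_catalog


class TestConfigValidation:
    def test_dt_bounds(self):
        with pytest.raises(ValueError):
            SimulationConfig(dt=0.2)
        with pytest.raises(ValueError):
            SimulationConfig(dt=-0.01)

    def test_record_every_multiple_of_dt(self):
        with pytest.raises(ValueError):
            SimulationConfig(dt=0.015, record_every=2.0)

    def test_unknown_kind(self):
        with pytest.raises(ValueError):
            SimulationConfig(kind="five_layer")

    def test_unknown_preset(self):
        with pytest.raises(KeyError):
            make_config("does_not_exist")

    def test_open_loop_zeroes_feedback(self):
        cfg = make_config("open_loop")
        w = cfg.resolved_weights()
        assert w.w_cx_tc == 0.0 and w.w_cx_re == 0.0

    def test_weight_factors_applied(self):
        cfg = make_config("we_x2", factor=2.0)
        assert cfg.resolved_weights().w_e == pytest.approx(6.0)


class TestFixedPointAndDeterminism:
    def test_uncoupled_rest_is_stationary(self):
        # all couplings silent, no noise: every cell stays at rest
        cfg = SimulationConfig(kind="three_layer", rows=12, cols=12,
                               duration=20.0, sigma=0.0, triggers=(),
                               boundary_width=0, seed=0)
        sim = Simulation(cfg)
        before = {k: v.v.copy() for k, v in sim.layers.items()}
        traj = sim.run()
        for name, layer in sim.layers.items():
            assert np.allclose(layer.v, before[name], atol=1e-6)

    def test_same_seed_bit_identical(self):
        cfg = make_config("closed_loop_default", rows=16, cols=16,
                          duration=30.0, seed=42)
        a = tw.run(cfg)
        b = tw.run(cfg)
        for layer in a.movies:
            assert np.array_equal(a.movies[layer], b.movies[layer])
        assert a.manifest["wiring_hashes"] == b.manifest["wiring_hashes"]

    def test_different_seed_differs(self):
        a = tw.run(make_config("closed_loop_default", rows=16, cols=16,
                               duration=30.0, seed=1))
        b = tw.run(make_config("closed_loop_default", rows=16, cols=16,
                               duration=30.0, seed=2))
        assert not np.array_equal(a.movies["cx"], b.movies["cx"])

    def test_halving_dt_consistent(self):
        # one deterministic wave: refinement of the step must reproduce
        # the same recruitment (who spiked) and the same post-wave state
        kw = dict(kind="cortex_only", rows=24, cols=24, duration=24.0,
                  sigma=0.0, seed=3, intra_fraction=1.0, e_fraction=1.0,
                  record_every=1.0)
        a = tw.run(SimulationConfig(dt=0.01, **kw))
        b = tw.run(SimulationConfig(dt=0.005, **kw))

        def first_spike_frame(movie):
            mask = movie > 0.5
            hit = mask.any(axis=0)
            first = mask.argmax(axis=0)
            return np.where(hit, first, -1)

        fa = first_spike_frame(a.movies["cx"])
        fb = first_spike_frame(b.movies["cx"])
        same_recruitment = np.mean((fa >= 0) == (fb >= 0))
        assert same_recruitment > 0.99
        both = (fa >= 0) & (fb >= 0)
        # recruitment times shift by at most one recorded frame
        assert np.abs(fa[both] - fb[both]).max() <= 1

    def test_nonfinite_aborts_with_diagnostic(self):
        cfg = SimulationConfig(kind="cortex_only", rows=10, cols=10,
                               duration=5.0, sigma=0.0, e_fraction=1.0,
                               input_clamp=float("inf"),
                               weight_factors=(("w_e", 1e300),), seed=0)
        with pytest.raises(FloatingPointError):
            tw.run(cfg)


class TestBoundary:
    def test_boundary_never_spikes(self, small_closed_loop):
        for layer, movie in small_closed_loop.movies.items():
            ring = np.concatenate([
                movie[:, 0, :].ravel(), movie[:, -1, :].ravel(),
                movie[:, :, 0].ravel(), movie[:, :, -1].ravel(),
            ])
            assert ring.max() < tw.phaseplane.SPIKE_LEVEL

    def test_interior_does_spike(self, small_closed_loop):
        assert small_closed_loop.movies["cx"][:, 1:-1, 1:-1].max() > 2.0


class TestModifiers:
    def test_identity_modifier_no_effect(self):
        base = make_config("open_loop", rows=14, cols=14, duration=30.0,
                           seed=5)
        mod = tw.SimulationConfig(
            **{**_kw(base), "modifiers": (Modifier("identity", t=10.0),)})
        a = tw.run(base)
        b = tw.run(mod)
        assert np.array_equal(a.movies["cx"], b.movies["cx"])

    def test_weight_scale_takes_effect_at_time(self):
        base = make_config("closed_loop_default", rows=14, cols=14,
                           duration=40.0, seed=5, sigma=0.0)
        cut = tw.SimulationConfig(
            **{**_kw(base),
               "modifiers": (Modifier("weight_scale", t=20.0,
                                      factors=(("w_tc_cx", 0.0),
                                               ("w_re_cx", 0.0))),)})
        a = tw.run(base)
        b = tw.run(cut)
        frames_before = int(20.0 / 2.0) + 1
        assert np.array_equal(a.movies["cx"][:frames_before],
                              b.movies["cx"][:frames_before])

    def test_threshold_block_silences_cells(self):
        # a permanently blocked centre cell cannot launch the wave
        base = make_config("open_loop", rows=14, cols=14, duration=20.0,
                           seed=5, triggers=(("cx", "center"),))
        blocked = tw.SimulationConfig(
            **{**_kw(base),
               "modifiers": (Modifier("threshold_block", t=0.0,
                                      t_off=np.inf, cells=((7, 7),)),)})
        a = tw.run(base)
        b = tw.run(blocked)
        assert a.movies["cx"].max() > 2.0
        assert b.movies["cx"][:, 7, 7].max() < a.movies["cx"][:, 7, 7].max()

    def test_delay_switch_changes_chain(self):
        cfg = make_config("reduced_delay", rows=12, cols=12, duration=5.0,
                          delay_ms=4.0, seed=0)
        cfg = tw.SimulationConfig(
            **{**_kw(cfg),
               "modifiers": (Modifier("delay_switch", t=2.0,
                                      delay_ms=6.0),)})
        sim = Simulation(cfg)
        assert sim.chain.n_elements == 2
        while sim.t < 3.0:
            sim.step()
        assert sim.chain.n_elements == 3

    def test_stimulus_adds_drive(self):
        base = SimulationConfig(kind="cortex_only", rows=14, cols=14,
                                duration=20.0, sigma=0.0, triggers=(),
                                seed=0)
        stim = SimulationConfig(
            **{**_kw(base),
               "modifiers": (Modifier("stimulus", t=5.0, t_off=8.0,
                                      cells=((7, 7),), amplitude=3.0),)})
        a = tw.run(base)
        b = tw.run(stim)
        assert a.movies["cx"].max() < 0.5
        assert b.movies["cx"][:, 7, 7].max() > 2.0


class TestPresets:
    @pytest.mark.parametrize("name", preset_catalog())
    def test_preset_instantiates_and_steps(self, name):
        cfg = make_config(name, rows=30, cols=30, duration=1.0, seed=0)
        sim = Simulation(cfg)
        for _ in range(10):
            sim.step()
        assert np.isfinite(sim.layers["cx"].v).all()

    def test_default_wiring_audit(self):
        # full-size default: 3 layers x 3600 cells, 80% excitatory,
        # exact gate counts
        cfg = make_config("closed_loop_default")
        sim = Simulation(cfg)
        audit = sim.wiring.audit()
        assert audit["n_per_layer"] == 3600
        assert len(sim.layers) * audit["n_per_layer"] == 10_800
        assert audit["excitatory"] == 2880
        assert audit["m_gate_ones"] == 36
        assert audit["w_gate_ones"] == 360
        assert audit["intra_fraction"] == pytest.approx(0.99, abs=1e-3)

    def test_reduced_delay_is_fully_connected_all_excitatory(self):
        cfg = make_config("reduced_delay", rows=20, cols=20, delay_ms=4.0)
        sim = Simulation(cfg)
        audit = sim.wiring.audit()
        assert audit["intra_fraction"] == 1.0
        assert audit["excitatory"] == 400
        assert audit["th_connected_rows"] == 400

    def test_unconnected_rows_removed_never_added(self):
        full = Simulation(make_config("reduced_delay", rows=20, cols=20,
                                      delay_ms=2.0, seed=9))
        masked = Simulation(make_config("reduced_90pct_unconnected",
                                        rows=20, cols=20, delay_ms=2.0,
                                        seed=9))
        w_full = full.wiring.w_sparse_th
        w_mask = masked.wiring.w_sparse_th
        # masked rows are a subset of the full structure
        assert ((w_mask - w_full) > 0).nnz == 0
        rows = np.diff(w_mask.indptr)
        assert (rows == 0).sum() == round(0.1 * 400)


def _kw(cfg):
    from dataclasses import fields

    return {f.name: getattr(cfg, f.name) for f in fields(cfg)}
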