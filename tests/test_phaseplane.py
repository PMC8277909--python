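"""Single-cell dynamics and phase-plane analysis.

Expected values either follow directly from the rate equations
(hand-evaluated limits) or are checked against independent brute-force
oracles: a dense 2-D sign-change scan for equilibria and central
finite differences for the Jacobian.
"""

import numpy as np
import pytest

import thalwave as tw
from thalwave import phaseplane as pp
from thalwave.params import named_params

ALL_SETS = ["tc_table1", "cx_table1", "cx_table2", "th_table2"]


# ---------------------------------------------------------------------------
# rate functions
# ---------------------------------------------------------------------------

class TestRates:
    def test_voltage_rate_at_origin_is_offset(self):
        # with v = 0 every voltage term vanishes and a5 = 1.47 remains
        p = tw.TC_THREE_LAYER
        assert pp.voltage_rate(0.0, 0.3, p) == pytest.approx(1.47)

    def test_voltage_rate_additive_in_drive(self):
        p = tw.TC_THREE_LAYER
        base = pp.voltage_rate(0.0, 0.0, p)
        assert pp.voltage_rate(0.0, 0.0, p, r=2.0) == pytest.approx(base + 2.0)
        # unit slope in r at arbitrary states
        v, eta = 0.7, 1.3
        assert pp.voltage_rate(v, eta, p, 5.0) - pp.voltage_rate(v, eta, p) \
            == pytest.approx(5.0)

    @pytest.mark.parametrize("name", ALL_SETS)
    def test_rate_vanishes_on_v_nullcline(self, name):
        p = named_params(name)
        v = np.linspace(0.05, 2.0, 17)
        eta = pp.v_nullcline(v, p, r=0.3)
        assert np.allclose(pp.voltage_rate(v, eta, p, 0.3), 0.0, atol=1e-12)

    def test_type3_gating_zero_at_origin_and_on_nullcline(self):
        p = tw.TC_THREE_LAYER
        assert pp.gating_rate(0.0, 0.0, p) == 0.0
        v = 0.37
        assert pp.gating_rate(v, (p.c2 / p.c1) * v, p) == pytest.approx(0.0)

    def test_type1_gating_offset_survives_at_origin(self):
        # only the additive offset d4 = 0.18 remains at (0, 0)
        assert pp.gating_rate(0.0, 0.0, tw.CX_THREE_LAYER) \
            == pytest.approx(0.18)

    def test_synapse_rate_fixed_points_and_limit(self):
        p = tw.TC_THREE_LAYER
        # H(0.1) = 0.5 exactly; s = 0.5 is then stationary
        assert pp.synapse_rate(0.1, 0.5, p) == pytest.approx(0.0)
        assert pp.synapse_rate(-1.0, 0.0, p) == pytest.approx(0.0, abs=1e-12)
        # fully active limit: (1 - 0)/(t1*(s1 - 1)) = 1/0.09
        assert pp.synapse_rate(1.0, 0.0, p) == \
            pytest.approx(1.0 / (0.01 * 9.0), rel=1e-6)


# ---------------------------------------------------------------------------
# nullclines, equilibria, stability
# ---------------------------------------------------------------------------

def brute_force_equilibria(p, r, v_box=(-2.0, 3.0), n=2000):
    """Independent oracle: sign changes of the nullcline gap on a grid,
    refined by bisection."""
    found = []
    for lo, hi in ((v_box[0], -1e-6), (1e-6, v_box[1])):
        v = np.linspace(lo, hi, n)
        gap = pp.v_nullcline(v, p, r) - pp.gating_nullcline(v, p)
        sg = np.sign(gap)
        for i in np.flatnonzero(sg[:-1] * sg[1:] < 0):
            a, b = v[i], v[i + 1]
            for _ in range(200):
                m = 0.5 * (a + b)
                gm = pp.v_nullcline(m, p, r) - pp.gating_nullcline(m, p)
                if np.sign(gm) == np.sign(
                        pp.v_nullcline(a, p, r) - pp.gating_nullcline(a, p)):
                    a = m
                else:
                    b = m
            vm = 0.5 * (a + b)
            em = float(pp.gating_nullcline(vm, p))
            # a sign change can also be a pole of the type-1 gating
            # nullcline (d3 + v^3 = 0); keep genuine roots only
            if abs(pp.voltage_rate(vm, em, p, r)) < 1e-4 and \
                    abs(pp.gating_rate(vm, em, p)) < 1e-4:
                found.append((vm, em))
    return sorted(found)


class TestEquilibria:
    def test_raising_drive_lifts_v_nullcline(self):
        p = tw.TC_THREE_LAYER
        v = np.linspace(0.05, 2.0, 30)
        delta = pp.v_nullcline(v, p, r=0.5) - pp.v_nullcline(v, p, r=0.0)
        assert np.all(delta > 0)
        assert np.allclose(delta, 0.5 / (p.a2 * v))

    def test_v_nullcline_flags_singularity(self):
        with pytest.raises(ZeroDivisionError):
            pp.v_nullcline(np.array([0.0, 0.1]), tw.TC_THREE_LAYER)

    @pytest.mark.parametrize("name", ALL_SETS)
    def test_equilibria_match_scan_oracle(self, name):
        p = named_params(name)
        got = pp.find_equilibria(p, 0.0)
        want = brute_force_equilibria(p, 0.0)
        assert len(got) == len(want)
        for (gv, ge), (wv_, we) in zip(got, want):
            assert gv == pytest.approx(wv_, abs=1e-6)
            assert ge == pytest.approx(we, abs=1e-6)

    @pytest.mark.parametrize("name", ALL_SETS)
    def test_residuals_below_tolerance(self, name):
        p = named_params(name)
        for v, eta in pp.find_equilibria(p, 0.0):
            assert abs(pp.voltage_rate(v, eta, p)) < 1e-8
            assert abs(pp.gating_rate(v, eta, p)) < 1e-8

    def test_fold_point_matches_grid_scan(self):
        p = tw.TC_THREE_LAYER
        vp, ep = pp.fold_point(p)
        v = np.linspace(1e-4, 1.0, 2_000_000)
        eta = pp.v_nullcline(v, p)
        k = np.argmin(eta)
        assert vp == pytest.approx(v[k], abs=1e-6)
        assert ep == pytest.approx(eta[k], abs=1e-9)

    @pytest.mark.parametrize("name", ALL_SETS)
    def test_eigenvalues_match_finite_difference_jacobian(self, name):
        p = named_params(name)
        for eq in pp.find_equilibria(p, 0.0):
            eig, _ = pp.stability(p, eq)
            h = 1e-6
            v, eta = eq
            J = np.empty((2, 2))
            for j, (dv, de) in enumerate(((h, 0.0), (0.0, h))):
                J[0, j] = (pp.voltage_rate(v + dv, eta + de, p)
                           - pp.voltage_rate(v - dv, eta - de, p)) / (2 * h)
                J[1, j] = (pp.gating_rate(v + dv, eta + de, p)
                           - pp.gating_rate(v - dv, eta - de, p)) / (2 * h)
            want = np.sort_complex(np.linalg.eigvals(J))
            assert np.allclose(np.sort_complex(eig), want, atol=1e-5)

    def test_rest_left_of_fold_is_stable(self):
        p = tw.TC_THREE_LAYER
        vp, _ = pp.fold_point(p)
        rest = [q for q in pp.find_equilibria(p, 0.0) if 0 < q[0] < vp]
        assert rest
        _, stable = pp.stability(p, rest[0])
        assert stable

    def test_stability_warns_off_equilibrium(self):
        with pytest.warns(UserWarning):
            pp.stability(tw.TC_THREE_LAYER, (1.0, 1.0))


class TestThreshold:
    def test_threshold_nonincreasing_in_drive_and_vanishes_at_fold(self):
        # type-1 geometry: raising the drive lifts the voltage nullcline,
        # moving the fold toward the (nearly level) rest state
        p = tw.CX_THREE_LAYER
        rs = np.linspace(0.0, 0.72, 13)
        thresholds = []
        for r in rs:
            try:
                thresholds.append(pp.activation_threshold(p, r))
            except pp.NoStableEquilibrium:
                thresholds.append(None)
        seen = [t for t in thresholds if t is not None]
        assert all(b <= a + 1e-9 for a, b in zip(seen, seen[1:]))
        # past some drive the stable equilibrium is gone (oscillation)
        assert thresholds[-1] is None
        # approaching the fold the threshold becomes small
        assert seen[-1] < 0.25 * seen[0]

    def test_lowering_d4_lowers_threshold(self):
        # the offset d4 positions the cortical gating nullcline; lowering
        # it moves the rest state toward the fold
        base = tw.CX_THREE_LAYER
        d4s = [0.18, 0.17, 0.16]
        ths = [pp.activation_threshold(base.with_gating_offset(d)) for d in d4s]
        assert all(b < a for a, b in zip(ths, ths[1:]))
        # lowered far enough, the rest state destabilises entirely
        with pytest.raises(pp.NoStableEquilibrium):
            pp.activation_threshold(base.with_gating_offset(0.12))

    def test_type3_slope_scaling_changes_threshold(self):
        base = tw.TC_THREE_LAYER
        t1 = pp.activation_threshold(base)
        t2 = pp.activation_threshold(base.with_gating_slope_scale(0.8))
        assert t2 != pytest.approx(t1)

    def test_report_roundtrip_and_csv(self, tmp_path):
        rep = pp.phase_plane_report(tw.TC_THREE_LAYER, 0.0)
        assert rep.threshold is not None and rep.threshold > 0
        rep.to_csv(tmp_path / "null.csv", tmp_path / "eq.csv")
        rows = (tmp_path / "eq.csv").read_text().strip().splitlines()
        assert len(rows) == 1 + len(rep.equilibria)


# ---------------------------------------------------------------------------
# single-cell simulation
# ---------------------------------------------------------------------------

class TestSingleCell:
    def test_subthreshold_step_returns_to_rest(self):
        p = tw.TC_THREE_LAYER
        t, v, eta, s = pp.simulate_single(
            p, drive=lambda tt: 0.05 if 10 < tt < 30 else 0.0, duration=120)
        assert len(pp.spike_times(t, v)) == 0
        rest = pp.find_equilibria(p, 0.0)[-1]
        assert v[-1] == pytest.approx(rest[0], abs=1e-3)

    def test_type3_single_spike_to_sustained_step(self):
        # the type-3 signature: one spike at step onset, then quiet
        # accommodation at a depolarised stable state
        p = tw.TC_THREE_LAYER
        t, v, _, _ = pp.simulate_single(
            p, drive=lambda tt: 2.0 if tt > 10 else 0.0, duration=300)
        assert len(pp.spike_times(t, v)) == 1

    def test_type3_rebound_spike_after_inhibition_release(self):
        p = tw.TC_THREE_LAYER
        t, v, _, _ = pp.simulate_single(
            p, multiplicative_inhibition=lambda tt: 1.0 if 10 < tt < 20
            else 0.0, duration=60)
        spikes = pp.spike_times(t, v)
        assert len(spikes) == 1
        assert spikes[0] > 20.0  # the spike follows the release

    def test_fi_curves_type1_wide_range_type3_narrow(self):
        # type-1 cells reach arbitrarily low rates near onset and their
        # frequency grows steeply with drive; a type-3 cell pushed past
        # its bifurcation (gating-nullcline slope lowered) starts at a
        # finite frequency and stays comparatively flat
        def freq(p, r):
            t, v, _, _ = pp.simulate_single(p, drive=r, duration=400)
            sp = pp.spike_times(t, v)
            if len(sp) < 4:
                return len(sp) / 0.4  # spikes per 400 ms, in Hz
            return 1000.0 / np.mean(np.diff(sp))

        drives = [0.0, 1.0, 2.0, 3.0]
        p3 = tw.TC_THREE_LAYER.with_gating_slope_scale(0.25)
        f3 = [freq(p3, r) for r in drives]
        f1 = [freq(tw.CX_THREE_LAYER, 0.6 + r) for r in drives]
        assert all(b > a for a, b in zip(f1, f1[1:]))
        assert min(f3) > 25.0          # finite-frequency onset
        assert min(f1) < 5.0           # arbitrarily slow near onset
        spread3 = max(f3) / min(f3)
        spread1 = max(f1) / max(min(f1), 1e-9)
        assert spread3 < 0.5 * spread1

    def test_sustained_oscillation_past_fold(self):
        # with the equilibrium destabilised, the cell cycles indefinitely
        p = tw.CX_THREE_LAYER
        t, v, _, _ = pp.simulate_single(p, drive=0.8, duration=400)
        late = pp.spike_times(t, v)
        assert len(late[late > 200]) >= 3

    def test_nonfinite_state_aborts(self):
        with pytest.raises(FloatingPointError):
            pp.simulate_single(tw.TC_THREE_LAYER, drive=1e9, dt=0.05,
                               duration=10)
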