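"""Tests of the five-node leaky-integrator gap/coincidence network."""

import numpy as np
import pytest

from votcortex.network import (
    InputSchedule,
    NetworkSpec,
    UnitParams,
    check_constraints,
    default_spec,
    output_onset_cycle,
    peak_output,
    simulate,
    step,
    sweep_vots,
)

VOTS = [0, 10, 20, 30, 40, 50]


# ---------------------------------------------------------------------------
# independent oracle: a literal scalar transcription of the two-step update


def oracle_simulate(spec, schedule):
    names = spec.unit_names
    n = len(names)
    params = {names[i]: spec.unit_params[i] for i in range(n)}
    a = {name: [params[name].resting] for name in names}
    for t in range(1, spec.n_cycles):
        prev = {name: a[name][t - 1] for name in names}
        for i, name in enumerate(names):
            p = params[name]
            # step 1: decay toward resting level without overshooting
            x = prev[name]
            if x > p.resting:
                x = max(x - p.decay, p.resting)
            elif x < p.resting:
                x = min(x + p.decay, p.resting)
            # step 2: sum external input and gated internal input
            total = schedule.values[i, t]
            for j, pre in enumerate(names):
                w = spec.weights[j, i]
                if w != 0.0 and prev[pre] >= params[pre].threshold:
                    total += w * prev[pre]
            x = min(max(x + total, p.minimum), p.maximum)
            a[name].append(x)
    return np.array([a[name] for name in names])


def random_valid_spec(rng):
    names = ("burst_detector", "voicing_detector", "inhibitory", "gap", "coinc")
    params = tuple(
        UnitParams(
            resting=0.0,
            minimum=-float(rng.uniform(2, 8)),
            maximum=float(rng.uniform(2, 8)),
            decay=float(rng.uniform(0.05, 2.5)),
            threshold=float(rng.uniform(0.2, 1.5)),
        )
        for _ in names
    )
    w = np.zeros((5, 5))
    wb = rng.uniform(0.5, 1.5)
    wv = rng.uniform(1.0, 2.5)
    for post in (2, 3, 4):
        w[0, post] = wb
    for post in (3, 4):
        w[1, post] = wv
    w[2, 3] = -rng.uniform(1.0, 3.0)
    return NetworkSpec(
        unit_names=names, unit_params=params, weights=w, n_cycles=30, ms_per_cycle=10
    )


def test_trajectories_match_literal_oracle_on_random_specs(rng):
    """Full trajectories equal an independently coded literal transcription
    of the decay-then-sum algorithm on many random valid specs."""
    for _ in range(25):
        spec = random_valid_spec(rng)
        vot = float(rng.choice(VOTS[:3]))
        sched = InputSchedule.from_vot(spec, vot)
        res = simulate(spec, schedule=sched)
        expected = oracle_simulate(spec, sched)
        np.testing.assert_allclose(res.activation, expected, atol=1e-12)


def test_hand_rolled_three_cycle_propagation():
    """A suprathreshold burst at cycle 2 reaches the gap detector at cycle 3
    as decay(resting) + w_burst->gap * a_burst, per the two-step algorithm."""
    spec = default_spec()
    sched = InputSchedule.empty(spec)
    sched.values[spec.index("burst_detector"), 1] = 1.0
    res = simulate(spec, schedule=sched)
    gap = res.unit_activation("gap")
    rho = spec.params("gap").resting
    w = spec.weight("burst_detector", "gap")
    assert gap[0] == rho
    assert gap[1] == rho
    assert gap[2] == pytest.approx(rho + w * 1.0)


# ---------------------------------------------------------------------------
# step semantics


def test_resting_state_is_fixed_point():
    spec = default_spec()
    rest = np.array([p.resting for p in spec.unit_params])
    out = step(rest, spec, np.zeros(spec.n_units))
    np.testing.assert_array_equal(out, rest)


def test_decay_never_overshoots_resting_level():
    spec = default_spec()
    lam = spec.params("gap").decay
    rho = spec.params("gap").resting
    state = np.array([p.resting for p in spec.unit_params])
    g = spec.index("gap")
    state[g] = rho + 3 * lam
    out = step(state, spec, np.zeros(spec.n_units))
    assert out[g] == pytest.approx(rho + 2 * lam)
    state[g] = rho + 0.5 * lam
    out = step(state, spec, np.zeros(spec.n_units))
    assert out[g] == rho  # exact, no overshoot


def test_step_rejects_mismatched_shapes():
    spec = default_spec()
    with pytest.raises(ValueError, match="shape"):
        step(np.zeros(3), spec, np.zeros(spec.n_units))
    with pytest.raises(ValueError, match="shape"):
        step(np.zeros(spec.n_units), spec, np.zeros(4))


# ---------------------------------------------------------------------------
# simulation-level behavior


def test_empty_schedule_keeps_all_units_at_rest():
    spec = default_spec()
    res = simulate(spec)
    for i, p in enumerate(spec.unit_params):
        np.testing.assert_array_equal(res.activation[i], p.resting)


def test_simulation_is_deterministic():
    spec = default_spec()
    a = simulate(spec, 30).activation
    b = simulate(spec, 30).activation
    np.testing.assert_array_equal(a, b)


def test_activations_stay_within_bounds():
    spec = default_spec()
    for vot in VOTS:
        res = simulate(spec, vot)
        for i, p in enumerate(spec.unit_params):
            assert np.all(res.activation[i] >= p.minimum - 1e-12)
            assert np.all(res.activation[i] <= p.maximum + 1e-12)


def test_vot_must_be_cycle_multiple():
    with pytest.raises(ValueError, match="multiple"):
        simulate(default_spec(), 15)


def test_subthreshold_output_drawn_at_rest():
    spec = default_spec()
    res = simulate(spec, 40)
    for unit in spec.unit_names:
        i = spec.index(unit)
        p = spec.unit_params[i]
        sub = res.activation[i] < p.threshold
        np.testing.assert_array_equal(res.output[i][sub], p.resting)


def test_peak_output_of_quiet_unit_is_resting_level():
    spec = default_spec()
    res = simulate(spec)  # no input at all
    assert peak_output(res, "coinc") == spec.params("coinc").resting
    assert output_onset_cycle(res, "coinc") is None


def test_unknown_unit_raises():
    res = simulate(default_spec(), 0)
    with pytest.raises(KeyError):
        peak_output(res, "nonexistent")


# ---------------------------------------------------------------------------
# the gap/coincidence amplitude and latency code (default parameters)


@pytest.fixture(scope="module")
def sweep():
    return sweep_vots(default_spec(), VOTS)


def test_gap_amplitude_code(sweep):
    """Gap peaks are equal across voiced VOTs (0 vs 10 overlapping), strictly
    greater for every voiceless than every voiced VOT, and nondecreasing
    (here strictly increasing) over 30-50 ms."""
    gap = sweep[sweep.unit == "gap"].set_index("vot_ms").peak_output
    assert gap[0] == gap[10] == gap[20]
    assert min(gap[30], gap[40], gap[50]) > max(gap[0], gap[10], gap[20])
    assert gap[30] < gap[40] < gap[50]


def test_coinc_amplitude_code(sweep):
    """Coincidence peaks decrease strictly over the voiced range and are
    equal for all voiceless stimuli."""
    coinc = sweep[sweep.unit == "coinc"].set_index("vot_ms").peak_output
    assert coinc[0] > coinc[10] > coinc[20] > coinc[30]
    assert coinc[30] == coinc[40] == coinc[50]


def test_category_means(sweep):
    for unit, voiced_stronger in (("gap", False), ("coinc", True)):
        t = sweep[sweep.unit == unit].set_index("vot_ms").peak_output
        voiced = np.mean([t[0], t[10], t[20]])
        voiceless = np.mean([t[30], t[40], t[50]])
        assert (voiced > voiceless) == voiced_stronger


def test_onset_latency_code(sweep):
    """Gap onset is VOT-invariant (burst-locked); coincidence onset increases
    strictly with VOT (voicing-locked)."""
    gap = sweep[sweep.unit == "gap"].set_index("vot_ms").onset_cycle
    coinc = sweep[sweep.unit == "coinc"].set_index("vot_ms").onset_cycle
    assert gap.nunique() == 1
    assert np.all(np.diff(coinc[sorted(VOTS)]) > 0)


# ---------------------------------------------------------------------------
# constraints


def test_default_spec_satisfies_all_constraints():
    reports = check_constraints(default_spec())
    assert len(reports) == 4
    assert all(r.satisfied for r in reports)


def _with_threshold(spec, unit, value):
    d = spec.to_dict()
    d["units"][unit]["threshold"] = value
    return NetworkSpec.from_dict(d)


def test_low_coinc_threshold_breaks_coincidence_detection():
    """With theta_coinc <= w_burst->coinc the coincidence detector responds
    suprathreshold to the burst alone."""
    spec = default_spec()
    bad = _with_threshold(spec, "coinc", spec.weight("burst_detector", "coinc") - 0.1)
    reports = {r.name: r.satisfied for r in check_constraints(bad)}
    assert not reports["theta_coinc_gt_w_burst_coinc"]
    sched = InputSchedule.empty(bad)
    sched.values[bad.index("burst_detector"), 1] = 1.0
    res = simulate(bad, schedule=sched)
    assert output_onset_cycle(res, "coinc") is not None


def test_high_gap_threshold_removes_fast_burst_response():
    """With theta_gap >= w_burst->gap the gap detector loses the fast
    suprathreshold response characteristic of slow-IPSP circuits."""
    spec = default_spec()
    bad = _with_threshold(spec, "gap", spec.weight("burst_detector", "gap") + 0.1)
    reports = {r.name: r.satisfied for r in check_constraints(bad)}
    assert not reports["theta_gap_lt_w_burst_gap"]
    sched = InputSchedule.empty(bad)
    sched.values[bad.index("burst_detector"), 1] = 1.0
    res = simulate(bad, schedule=sched)
    assert output_onset_cycle(res, "gap") is None


# ---------------------------------------------------------------------------
# serialization and parameter validation


def test_spec_json_round_trip(tmp_path):
    spec = default_spec()
    path = tmp_path / "spec.json"
    spec.to_json(path)
    loaded = NetworkSpec.from_json(path)
    assert loaded.unit_names == spec.unit_names
    np.testing.assert_array_equal(loaded.weights, spec.weights)
    np.testing.assert_array_equal(
        simulate(loaded, 30).activation, simulate(spec, 30).activation
    )


def test_unit_params_invariants():
    with pytest.raises(ValueError):
        UnitParams(resting=2.0, minimum=0.0, maximum=1.0, decay=0.1, threshold=0.5)
    with pytest.raises(ValueError):
        UnitParams(resting=0.0, minimum=-1.0, maximum=1.0, decay=-0.1, threshold=0.5)


def test_default_weights_follow_minimalist_scheme():
    """Only the five stated edges are nonzero; burst-origin weights equal;
    voicing-origin weights equal and larger than burst-origin weights."""
    spec = default_spec()
    w = spec.weights
    nonzero = {(spec.unit_names[j], spec.unit_names[i])
               for j, i in zip(*np.nonzero(w))}
    assert nonzero == {
        ("burst_detector", "inhibitory"),
        ("burst_detector", "gap"),
        ("burst_detector", "coinc"),
        ("voicing_detector", "gap"),
        ("voicing_detector", "coinc"),
        ("inhibitory", "gap"),
    }
    wb = spec.weight("burst_detector", "gap")
    assert spec.weight("burst_detector", "coinc") == wb
    assert spec.weight("burst_detector", "inhibitory") == wb
    wv = spec.weight("voicing_detector", "gap")
    assert spec.weight("voicing_detector", "coinc") == wv
    assert wv > wb
    assert spec.weight("inhibitory", "gap") < 0
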