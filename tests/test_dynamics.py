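"""Tests of onset-latency bootstraps and constrained AEP peak analysis."""

import numpy as np
import pytest

from votcortex.dynamics import (
    AEP_PEAK_NAMES,
    bootstrap_aep_correlations,
    bootstrap_latency_correlation,
    find_aep_peaks,
    group_latency_tests,
    onset_latency,
)
from votcortex.synth import ClassSpec, SyntheticConfig, make_hg_dataset, make_lfp

TIMES = -500.0 + np.arange(600) * 2.5


def tiny(**over):
    base = dict(
        seed=3, n_participants=1, n_behavior_participants=1, trials_per_vot=15
    )
    base.update(over)
    return SyntheticConfig(**base)


# ---------------------------------------------------------------------------
# onset latency


def test_ramp_crosses_half_peak_at_expected_time():
    trace = np.interp(TIMES, [0.0, 200.0], [0.0, 2.0])  # ramps 0..2 over 0..200
    trace[TIMES < 0] = 0.0
    trace[TIMES > 200] = 2.0
    lat = onset_latency(trace, TIMES, grand_peak_amplitude=2.0)
    assert lat == pytest.approx(100.0, abs=2.5)


def test_flat_trace_has_undefined_latency():
    assert onset_latency(np.zeros_like(TIMES), TIMES, 1.0) is None


def test_onset_latency_matches_bruteforce_scan(rng):
    for _ in range(50):
        trace = np.cumsum(rng.standard_normal(len(TIMES))) * 0.05
        peak = rng.uniform(0.5, 2.0)
        lat = onset_latency(trace, TIMES, peak)
        # exhaustive first-crossing scan
        expected = None
        for t, v in zip(TIMES, trace):
            if t >= 0.0 and v > 0.5 * peak:
                expected = t
                break
        assert lat == expected


# ---------------------------------------------------------------------------
# latency bootstrap


@pytest.fixture(scope="module")
def hg_epochs():
    return make_hg_dataset(tiny()).hg["P01"]


def test_vplus_electrode_latency_tracks_vot(hg_epochs):
    """A V+ electrode with a 1 ms/ms latency slope yields a strongly positive
    bootstrapped latency-VOT correlation."""
    es = hg_epochs
    d = bootstrap_latency_correlation(es.data[:, 0, :], es.vots, es.times, 400, seed=1)
    assert d.mean > 0.8
    assert not d.excluded


def test_flat_amplitude_constant_latency_electrode_is_null():
    cfg = tiny(classes={"none": ClassSpec(1, (2.8,) * 6, 0.0)})
    es = make_hg_dataset(cfg).hg["P01"]
    d = bootstrap_latency_correlation(es.data[:, 0, :], es.vots, es.times, 400, seed=2)
    lo, hi = d.hdi95()
    assert lo < 0 < hi
    assert abs(d.mean) < 0.5


def test_latency_bootstrap_is_seed_deterministic(hg_epochs):
    es = hg_epochs
    a = bootstrap_latency_correlation(es.data[:, 0, :], es.vots, es.times, 100, seed=9)
    b = bootstrap_latency_correlation(es.data[:, 0, :], es.vots, es.times, 100, seed=9)
    np.testing.assert_array_equal(a.values, b.values)


def test_electrode_with_unreachable_condition_excluded():
    """When one VOT condition never crosses the half-peak threshold, every
    resample has an undefined latency and the electrode is excluded."""
    vots = np.tile([0.0, 10.0, 20.0, 30.0, 40.0, 50.0], 10)
    bump = np.exp(-0.5 * ((TIMES - 200.0) / 40.0) ** 2)
    trials = np.outer(np.where(vots == 50.0, 0.0, 3.0), bump)
    d = bootstrap_latency_correlation(trials, vots, TIMES, 100, seed=3)
    assert d.excluded
    assert d.n_excluded == 100


def test_too_few_trials_per_vot_rejected(hg_epochs):
    es = hg_epochs
    keep = np.ones(es.n_trials, dtype=bool)
    keep[np.nonzero(es.vots == 0.0)[0][1:]] = False  # one trial left at 0 ms
    with pytest.raises(ValueError, match="at least 2"):
        bootstrap_latency_correlation(
            es.data[keep, 0, :], es.vots[keep], es.times, 50, seed=0
        )


# ---------------------------------------------------------------------------
# group tests


def test_group_latency_tests_dissociate_classes(rng):
    vplus = rng.uniform(0.6, 0.95, 10)
    vminus = rng.normal(0.0, 0.15, 10)
    vminus -= vminus.mean()  # symmetric about zero
    out = group_latency_tests({"V+": vplus, "V-": vminus})
    assert out["per_class"]["V+"].p_value < 0.01
    assert out["per_class"]["V-"].p_value > 0.05
    assert out["between"].p_value < 0.01


def test_group_latency_between_test_refuses_single_electrode():
    out = group_latency_tests({"V+": np.array([0.8]), "V-": np.array([0.1])})
    assert out["between"] is None
    assert any("refused" in f for f in out["flags"])


# ---------------------------------------------------------------------------
# AEP peak search


def _gauss(t, mu, amp, sig):
    return amp * np.exp(-0.5 * ((t - mu) / sig) ** 2)


def test_planted_deflections_found_exactly():
    trace = (
        _gauss(TIMES, 90.0, 40.0, 8.0)
        + _gauss(TIMES, 130.0, -60.0, 10.0)
        + _gauss(TIMES, 200.0, 50.0, 14.0)
    )
    peaks = find_aep_peaks(trace, TIMES)
    assert [p.name for p in peaks] == list(AEP_PEAK_NAMES)
    assert all(p.valid for p in peaks)
    assert [p.latency_ms for p in peaks] == [90.0, 130.0, 200.0]
    assert peaks[1].amplitude < 0 < peaks[0].amplitude


def test_monotone_rising_trace_cascades_invalid():
    trace = np.linspace(0.0, 1.0, len(TIMES))
    peaks = find_aep_peaks(trace, TIMES)
    assert not peaks[0].valid  # P-alpha lands on the 150 ms edge
    assert not peaks[1].valid and not peaks[2].valid  # cascade


def test_sequential_ordering_holds_whenever_all_valid(rng):
    n_ordered = 0
    for _ in range(1000):
        trace = np.convolve(
            rng.standard_normal(len(TIMES)), np.ones(40) / 40, mode="same"
        )
        peaks = find_aep_peaks(trace, TIMES)
        if all(p.valid for p in peaks):
            n_ordered += 1
            assert peaks[0].latency_ms < peaks[1].latency_ms < peaks[2].latency_ms
    assert n_ordered > 50  # the property was actually exercised


def test_short_trace_rejected():
    t = np.arange(0.0, 200.0, 2.5)
    with pytest.raises(ValueError, match="250"):
        find_aep_peaks(np.zeros_like(t), t)


def test_nalpha_window_starts_at_palpha():
    """A spurious early minimum before P-alpha must not be picked as
    N-alpha: its effective window starts at the P-alpha latency."""
    trace = (
        _gauss(TIMES, 80.0, -30.0, 6.0)  # early negative dip (before P-alpha)
        + _gauss(TIMES, 100.0, 40.0, 8.0)
        + _gauss(TIMES, 150.0, -50.0, 10.0)
        + _gauss(TIMES, 210.0, 45.0, 12.0)
    )
    peaks = find_aep_peaks(trace, TIMES)
    assert peaks[0].latency_ms == pytest.approx(100.0, abs=2.5)
    assert peaks[1].latency_ms == pytest.approx(150.0, abs=2.5)


# ---------------------------------------------------------------------------
# AEP bootstrap


def test_planted_nalpha_latency_slope_recovered():
    cfg = tiny(aep_latency_slopes=(0.0, 1.0, 0.5), lfp_noise_sd_uv=20.0)
    es = make_lfp(cfg)["P01"]
    dists = bootstrap_aep_correlations(
        es.data[:, 0, :], es.vots, es.times, 300, seed=4
    )
    d = dists["Nalpha_latency"]
    assert not d.excluded
    assert d.mean > 0.8
    assert d.significant()


def test_vot_independent_aeps_are_mostly_null():
    cfg = tiny(trials_per_vot=12)
    es = make_lfp(cfg)["P01"]
    n_sig = 0
    n_stat = 0
    for j in range(0, 8):
        dists = bootstrap_aep_correlations(
            es.data[:, j, :], es.vots, es.times, 200, seed=j
        )
        for d in dists.values():
            if d.excluded or not len(d.values):
                continue
            n_stat += 1
            n_sig += d.significant()
    assert n_stat > 0
    assert n_sig / n_stat < 0.25


def test_excluded_peak_dropped_but_earlier_peaks_retained(rng):
    """When P-beta keeps landing on the edge of its window (>50% of
    resamples) it is excluded while P-alpha and N-alpha remain usable."""
    trials = np.tile(
        _gauss(TIMES, 90.0, 40.0, 8.0) + _gauss(TIMES, 130.0, -60.0, 10.0),
        (60, 1),
    )
    ramp = np.clip((TIMES - 150.0) / 100.0, 0.0, 1.0) * 80.0  # rising into 250
    trials += ramp
    trials += rng.standard_normal(trials.shape) * 5.0
    vots = np.tile([0.0, 10.0, 20.0, 30.0, 40.0, 50.0], 10)
    dists = bootstrap_aep_correlations(trials, vots, TIMES, 100, seed=5)
    assert dists["Pbeta_latency"].excluded
    assert not dists["Palpha_latency"].excluded
    assert not dists["Nalpha_latency"].excluded


def test_aep_bootstrap_deterministic():
    cfg = tiny(trials_per_vot=8)
    es = make_lfp(cfg)["P01"]
    a = bootstrap_aep_correlations(es.data[:, 0, :], es.vots, es.times, 50, seed=6)
    b = bootstrap_aep_correlations(es.data[:, 0, :], es.vots, es.times, 50, seed=6)
    for k in a:
        np.testing.assert_array_equal(a[k].values, b[k].values)
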