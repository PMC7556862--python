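"""Onset-latency and auditory-evoked-potential temporal analyses.

High-gamma onset latency: for each VOT condition, the first post-onset
timepoint at which the trial-averaged response exceeds 50% of the
electrode's grand-mean peak (across all VOTs).  A stratified bootstrap
(resampling trials with replacement within each VOT condition, 1000
resamples) yields a distribution of Spearman correlations between onset
latency and VOT per electrode; resamples in which any VOT's latency is
undefined are dropped, and an electrode is excluded when fewer than half of
its resamples are usable.

Auditory evoked potential (raw voltage): three peaks are sought under
sequential constraints -- P-alpha is the maximum mean voltage in 0-150 ms,
N-alpha the minimum in [max(75, t(P-alpha)), 200] ms, P-beta the maximum in
[max(150, t(N-alpha)), 250] ms.  A peak landing on either edge of its
effective search range is invalid, and invalidity cascades to the later
peaks of that trace.  Bootstrapped Pearson correlations between VOT and each
peak's latency and amplitude are summarized by 95% highest-density
intervals; a statistic is significant when its HDI excludes zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import EpochSet
from .stats import hdi, mann_whitney_z, signed_rank, spearman

__all__ = [
    "BootstrapDistribution",
    "AepPeak",
    "onset_latency",
    "bootstrap_latency_correlation",
    "group_latency_tests",
    "find_aep_peaks",
    "bootstrap_aep_correlations",
]

N_RESAMPLES = 1000
HALF_PEAK = 0.5
AEP_WINDOWS_MS = ((0.0, 150.0), (75.0, 200.0), (150.0, 250.0))
AEP_PEAK_NAMES = ("Palpha", "Nalpha", "Pbeta")
AEP_PEAK_SIGNS = (1, -1, 1)  # maxima for P-peaks, minimum for N-alpha


@dataclass(frozen=True)
class BootstrapDistribution:
    """Resampled statistic values with bookkeeping for exclusions."""

    values: np.ndarray
    n_requested: int
    n_excluded: int
    seed: int | None = None

    @property
    def excluded(self) -> bool:
        """True when more than half the requested resamples were unusable."""
        return self.n_excluded > self.n_requested / 2

    @property
    def mean(self) -> float:
        return float(np.mean(self.values)) if len(self.values) else np.nan

    def hdi95(self) -> tuple[float, float]:
        return hdi(self.values, 0.95)

    def significant(self) -> bool:
        lo, hi = self.hdi95()
        return bool(lo > 0.0 or hi < 0.0)


def onset_latency(
    mean_trace: np.ndarray,
    times_ms: np.ndarray,
    grand_peak_amplitude: float,
    threshold_frac: float = HALF_PEAK,
) -> float | None:
    """First post-onset time at which the trace exceeds the half-peak.

    ``grand_peak_amplitude`` is the electrode's peak of the grand average
    across all VOTs; returns None when the trace never exceeds the
    threshold.
    """
    mean_trace = np.asarray(mean_trace, dtype=float)
    times_ms = np.asarray(times_ms, dtype=float)
    post = times_ms >= 0.0
    above = mean_trace[post] > threshold_frac * grand_peak_amplitude
    idx = np.nonzero(above)[0]
    if idx.size == 0:
        return None
    return float(times_ms[post][idx[0]])


def _grand_peak(trials: np.ndarray, times: np.ndarray, window_ms=(0.0, 500.0)) -> float:
    post = (times >= window_ms[0]) & (times <= window_ms[1])
    return float(trials.mean(axis=0)[post].max())


def _resampled_means(
    trials: np.ndarray, idx: np.ndarray, n_resamples: int, rng: np.random.Generator
) -> np.ndarray:
    """Stratified bootstrap means (n_resamples x samples) via a count matrix,
    avoiding the large trials-by-draws intermediate."""
    k = len(idx)
    draws = rng.integers(0, k, size=(n_resamples, k))
    counts = np.zeros((n_resamples, k))
    np.add.at(counts, (np.arange(n_resamples)[:, None], draws), 1.0)
    return counts @ trials[idx] / k


def bootstrap_latency_correlation(
    trials: np.ndarray,
    vots: np.ndarray,
    times_ms: np.ndarray,
    n_resamples: int = N_RESAMPLES,
    seed: int | np.random.Generator = 0,
) -> BootstrapDistribution:
    """Bootstrap distribution of Spearman rho(onset latency, VOT).

    ``trials`` is trials x samples for a single electrode.  Resampling is
    stratified within VOT condition; a resample is dropped when any VOT's
    onset latency is undefined.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    trials = np.asarray(trials, dtype=float)
    vots = np.asarray(vots, dtype=float)
    levels = np.unique(vots)
    idx_by_vot = {v: np.nonzero(vots == v)[0] for v in levels}
    for v, idx in idx_by_vot.items():
        if len(idx) < 2:
            raise ValueError(f"need at least 2 trials per VOT; {v} ms has {len(idx)}")
    grand_peak = _grand_peak(trials, times_ms)
    mean_traces = {
        v: _resampled_means(trials, idx, n_resamples, rng) for v, idx in idx_by_vot.items()
    }

    values = []
    excluded = 0
    for b in range(n_resamples):
        lats = []
        ok = True
        for v in levels:
            lat = onset_latency(mean_traces[v][b], times_ms, grand_peak)
            if lat is None:
                ok = False
                break
            lats.append(lat)
        if not ok:
            excluded += 1
            continue
        rho = spearman(lats, levels).rho
        if np.isnan(rho):  # all latencies tied: correlation undefined
            excluded += 1
            continue
        values.append(rho)
    return BootstrapDistribution(
        values=np.asarray(values), n_requested=n_resamples, n_excluded=excluded
    )


def group_latency_tests(means_by_class: dict[str, np.ndarray]) -> dict:
    """Signed-rank vs 0 per electrode class, plus a between-class rank-sum.

    Expects the per-electrode mean bootstrapped correlations keyed by class
    (e.g. 'V+' and 'V-').  The between-class comparison refuses (returns
    None with a flag) when either class has fewer than 2 electrodes.
    """
    out: dict = {"per_class": {}, "flags": []}
    for cls, vals in means_by_class.items():
        vals = np.asarray(vals, dtype=float)
        if len(vals) < 1:
            out["flags"].append(f"{cls}: empty")
            continue
        out["per_class"][cls] = signed_rank(vals)
    classes = [c for c in means_by_class if len(means_by_class[c])]
    if len(classes) == 2:
        a, b = (np.asarray(means_by_class[c], dtype=float) for c in classes)
        if len(a) < 2 or len(b) < 2:
            out["between"] = None
            out["flags"].append("between-class test refused: fewer than 2 per class")
        else:
            out["between"] = mann_whitney_z(a, b)
            out["between_classes"] = tuple(classes)
    return out


@dataclass(frozen=True)
class AepPeak:
    name: str
    latency_ms: float
    amplitude: float
    valid: bool


def find_aep_peaks(trace: np.ndarray, times_ms: np.ndarray) -> list[AepPeak]:
    """Constrained sequential search for P-alpha, N-alpha, P-beta.

    Each peak's effective window starts at the later of its nominal lower
    bound and the previous peak's latency.  An extremum on either edge of
    its effective window is invalid and invalidates all later peaks.
    """
    trace = np.asarray(trace, dtype=float)
    times_ms = np.asarray(times_ms, dtype=float)
    if times_ms[-1] < AEP_WINDOWS_MS[-1][1]:
        raise ValueError("trace must extend to at least 250 ms post-onset")
    peaks: list[AepPeak] = []
    prev_latency = -np.inf
    cascade_invalid = False
    for name, (lo, hi), sign in zip(AEP_PEAK_NAMES, AEP_WINDOWS_MS, AEP_PEAK_SIGNS):
        if cascade_invalid:
            peaks.append(AepPeak(name, np.nan, np.nan, False))
            continue
        lo_eff = max(lo, prev_latency)
        mask = (times_ms >= lo_eff) & (times_ms <= hi)
        idx = np.nonzero(mask)[0]
        if idx.size < 3:
            peaks.append(AepPeak(name, np.nan, np.nan, False))
            cascade_invalid = True
            continue
        seg = trace[idx]
        k = int(np.argmax(sign * seg))
        lat = float(times_ms[idx[k]])
        valid = 0 < k < idx.size - 1
        peaks.append(AepPeak(name, lat, float(seg[k]), valid))
        if not valid:
            cascade_invalid = True
        prev_latency = lat
    return peaks


def bootstrap_aep_correlations(
    trials: np.ndarray,
    vots: np.ndarray,
    times_ms: np.ndarray,
    n_resamples: int = N_RESAMPLES,
    seed: int | np.random.Generator = 0,
) -> dict[str, BootstrapDistribution]:
    """Bootstrapped Pearson correlations of VOT with AEP peak latency and
    amplitude (six statistics: three peaks x {latency, amplitude}).

    Within each resample, per-VOT mean AEPs undergo the constrained peak
    search; a resample is excluded for a peak (and, by the sequential
    constraint, for all later peaks) if the peak is invalid for any VOT.
    Distributions whose exclusions exceed 50% report ``excluded = True`` and
    should be dropped from analysis.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    trials = np.asarray(trials, dtype=float)
    vots = np.asarray(vots, dtype=float)
    levels = np.unique(vots)
    idx_by_vot = {v: np.nonzero(vots == v)[0] for v in levels}
    for v, idx in idx_by_vot.items():
        if len(idx) < 2:
            raise ValueError(f"need at least 2 trials per VOT; {v} ms has {len(idx)}")

    mean_traces = {
        v: _resampled_means(trials, idx, n_resamples, rng) for v, idx in idx_by_vot.items()
    }

    vals: dict[str, list[float]] = {
        f"{p}_{w}": [] for p in AEP_PEAK_NAMES for w in ("latency", "amplitude")
    }
    excl = {p: 0 for p in AEP_PEAK_NAMES}
    for b in range(n_resamples):
        per_vot = [find_aep_peaks(mean_traces[v][b], times_ms) for v in levels]
        # peak k usable only if valid at every VOT; invalidity cascades
        usable_prev = True
        for k, pname in enumerate(AEP_PEAK_NAMES):
            usable = usable_prev and all(pk[k].valid for pk in per_vot)
            if not usable:
                excl[pname] += 1
                usable_prev = False
                continue
            lats = np.array([pk[k].latency_ms for pk in per_vot])
            amps = np.array([pk[k].amplitude for pk in per_vot])
            vals[f"{pname}_latency"].append(_pearson(levels, lats))
            vals[f"{pname}_amplitude"].append(_pearson(levels, amps))
    out = {}
    for pname in AEP_PEAK_NAMES:
        for which in ("latency", "amplitude"):
            key = f"{pname}_{which}"
            out[key] = BootstrapDistribution(
                values=np.asarray(vals[key]),
                n_requested=n_resamples,
                n_excluded=excl[pname],
            )
    return out


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    sx, sy = np.std(x), np.std(y)
    if sx == 0 or sy == 0:
        return 0.0
    return float(np.corrcoef(x, y)[0, 1])


def latency_analysis(
    epochs: EpochSet,
    profiles,
    n_resamples: int = N_RESAMPLES,
    seed: int = 0,
) -> dict:
    """Bootstrap latency correlations for every VOT-sensitive electrode."""
    rng = np.random.default_rng(seed)
    vots = epochs.vots
    results = {}
    for _, prof in profiles[profiles.selectivity.isin(["V+", "V-"])].iterrows():
        j = epochs.electrode_index(prof.electrode)
        dist = bootstrap_latency_correlation(
            epochs.data[:, j, :], vots, epochs.times, n_resamples, rng
        )
        results[prof.electrode] = {"class": prof.selectivity, "distribution": dist}
    return results
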