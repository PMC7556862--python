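"""Electrode selection and peak-amplitude encoding statistics.

Selection proceeds in stages: speech-responsive electrodes (grand mean
high-gamma in 100-300 ms exceeding one baseline SD), per-electrode peak
(grand-mean argmax within 0-500 ms), and VOT sensitivity (Spearman
correlation between per-trial peak amplitude and stimulus VOT, p < 0.05).
VOT-sensitive electrodes split by correlation sign into voiced-selective
(V+, rho < 0: stronger responses to short VOTs) and voiceless-selective
(V-, rho > 0).

Encoding statistics follow the same nonparametric toolkit: Mann-Whitney
rank-sum z for between-category discriminability at the peak, within-category
Spearman correlations converted to t-statistics, and Wilcoxon signed-rank
tests over electrodes.  For the pooled preferred/non-preferred tests, V+
electrodes' t-statistics are sign-flipped so that positive always means
"stronger toward the preferred-category endpoint".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import EpochSet
from .stats import (
    CorrelationResult,
    RankSumResult,
    SignedRankResult,
    correlation_t,
    mann_whitney_z,
    signed_rank,
    spearman,
)

__all__ = [
    "ElectrodeProfile",
    "select_speech_responsive",
    "find_peak",
    "peak_amplitudes",
    "vot_sensitivity",
    "profile_electrodes",
    "category_discriminability",
    "within_category_t",
    "group_signed_rank",
    "normalize_peak_curve",
    "encoding_summary",
    "VOICED_MAX_MS",
]

VOICED_MAX_MS = 20.0  # psychophysical boundary: voiced 0-20 ms, voiceless 30-50 ms
RESPONSIVE_WINDOW_MS = (100.0, 300.0)
PEAK_WINDOW_MS = (0.0, 500.0)
BASELINE_MS = (-500.0, -200.0)
ALPHA = 0.05


@dataclass(frozen=True)
class ElectrodeProfile:
    electrode: str
    speech_responsive: bool
    peak_time_ms: float
    peak_amplitude: float
    spearman_rho: float
    spearman_p: float
    selectivity: str  # 'V+' | 'V-' | 'none'


def select_speech_responsive(
    epochs: EpochSet,
    window_ms: tuple[float, float] = RESPONSIVE_WINDOW_MS,
    baseline_ms: tuple[float, float] = BASELINE_MS,
    threshold_sd: float = 1.0,
) -> np.ndarray:
    """Flag electrodes whose grand mean response exceeds the baseline SD.

    The grand mean pools all trials and all timepoints in ``window_ms``; the
    reference is ``threshold_sd`` times the SD of the baseline-window
    activity pooled over trials and timepoints, per electrode.
    """
    if epochs.times[0] > baseline_ms[0]:
        raise ValueError("epochs do not cover the baseline window")
    wsl = epochs.window_slice(*window_ms)
    bsl = epochs.window_slice(baseline_ms[0], baseline_ms[1] - 1e-6)
    grand = epochs.data[:, :, wsl].mean(axis=(0, 2))
    base_sd = epochs.data[:, :, bsl].std(axis=(0, 2))
    return grand > threshold_sd * base_sd


def find_peak(
    epochs: EpochSet,
    electrode: int | str,
    window_ms: tuple[float, float] = PEAK_WINDOW_MS,
) -> tuple[float, float]:
    """(peak_time_ms, peak_amplitude) of the grand-mean response.

    The search is constrained to ``window_ms`` (0-500 ms by default); ties
    resolve to the earliest sample.
    """
    if isinstance(electrode, str):
        electrode = epochs.electrode_index(electrode)
    wsl = epochs.window_slice(*window_ms)
    grand = epochs.data[:, electrode, wsl].mean(axis=0)
    i = int(np.argmax(grand))  # argmax returns the first maximum
    return float(epochs.times[wsl][i]), float(grand[i])


def peak_amplitudes(epochs: EpochSet, electrode: int | str, peak_time_ms: float) -> np.ndarray:
    """Per-trial amplitude at the electrode's peak sample."""
    if isinstance(electrode, str):
        electrode = epochs.electrode_index(electrode)
    i = int(np.argmin(np.abs(epochs.times - peak_time_ms)))
    return epochs.data[:, electrode, i].copy()


def vot_sensitivity(
    amps, vots, alpha: float = ALPHA, method: str = "t"
) -> tuple[CorrelationResult, str]:
    """Spearman correlation of per-trial peak amplitude with VOT, plus the
    selectivity class it implies (V+ for significant rho < 0, V- for
    significant rho > 0, 'none' otherwise or when rho is undefined)."""
    amps = np.asarray(amps, dtype=float)
    vots = np.asarray(vots, dtype=float)
    if len(amps) < 4:
        raise ValueError("need at least 4 trials")
    if len(np.unique(vots)) < 2:
        raise ValueError("need at least 2 distinct VOTs")
    res = spearman(vots, amps, method=method)
    if np.isnan(res.rho) or res.p_value >= alpha:
        cls = "none"
    else:
        cls = "V+" if res.rho < 0 else "V-"
    return res, cls


def profile_electrodes(epochs: EpochSet, alpha: float = ALPHA) -> pd.DataFrame:
    """One profile row per electrode: responsiveness, peak, VOT sensitivity."""
    responsive = select_speech_responsive(epochs)
    vots = epochs.vots
    rows = []
    for j, name in enumerate(epochs.electrodes):
        pt, pa = find_peak(epochs, j)
        if responsive[j]:
            amps = peak_amplitudes(epochs, j, pt)
            try:
                corr, cls = vot_sensitivity(amps, vots, alpha=alpha)
                rho, p = corr.rho, corr.p_value
            except ValueError:
                rho, p, cls = np.nan, np.nan, "none"
        else:
            rho, p, cls = np.nan, np.nan, "none"
        rows.append(
            {
                "electrode": name,
                "speech_responsive": bool(responsive[j]),
                "peak_time_ms": pt,
                "peak_amplitude": pa,
                "spearman_rho": rho,
                "spearman_p": p,
                "selectivity": cls,
            }
        )
    return pd.DataFrame(rows)


def category_discriminability(amps, is_voiceless) -> RankSumResult:
    """Rank-sum z for voiceless vs voiced peak amplitudes.

    Positive z means stronger responses to voiceless stimuli (the V-
    signature); negative z the V+ signature.
    """
    amps = np.asarray(amps, dtype=float)
    is_voiceless = np.asarray(is_voiceless, dtype=bool)
    x = amps[is_voiceless]
    y = amps[~is_voiceless]
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both voicing categories must be non-empty")
    return mann_whitney_z(x, y)


def within_category_t(amps, vots, category_mask) -> CorrelationResult:
    """Spearman rho of amplitude vs VOT among the masked trials, with
    t = rho * sqrt(n-2) / sqrt(1-rho^2) (+/-inf sentinel at |rho| = 1)."""
    amps = np.asarray(amps, dtype=float)[np.asarray(category_mask, dtype=bool)]
    vots = np.asarray(vots, dtype=float)[np.asarray(category_mask, dtype=bool)]
    n = len(amps)
    if n < 3:
        raise ValueError("need at least 3 trials in the category")
    res = spearman(vots, amps)
    # recompute t from rho for the sentinel semantics
    return CorrelationResult(res.rho, n, correlation_t(res.rho, n), res.p_value)


def group_signed_rank(statistics, mu: float = 0.0) -> SignedRankResult:
    """Wilcoxon signed-rank of electrode- or participant-level statistics
    against ``mu`` (exact null for small n, normal approximation beyond)."""
    statistics = np.asarray(statistics, dtype=float)
    statistics = statistics[np.isfinite(statistics)]
    if len(statistics) < 5:
        raise ValueError("need at least 5 finite values for the group test")
    return signed_rank(statistics, mu)


def normalize_peak_curve(means) -> np.ndarray:
    """Percent-of-max curve: subtract the min across VOTs, divide by the max
    of the shifted curve.  The result has min 0 and max 1 exactly."""
    means = np.asarray(means, dtype=float)
    shifted = means - means.min()
    peak = shifted.max()
    if peak == 0:
        raise ValueError("constant curve; percent-of-max undefined")
    return shifted / peak


def _per_electrode_tables(epochs: EpochSet, profiles: pd.DataFrame) -> pd.DataFrame:
    vots = epochs.vots
    voiced = vots <= VOICED_MAX_MS
    rows = []
    for _, prof in profiles[profiles.selectivity.isin(["V+", "V-"])].iterrows():
        amps = peak_amplitudes(epochs, prof.electrode, prof.peak_time_ms)
        z_cat = category_discriminability(amps, ~voiced).z
        t_voiced = within_category_t(amps, vots, voiced).t_statistic
        t_voiceless = within_category_t(amps, vots, ~voiced).t_statistic
        flip = -1.0 if prof.selectivity == "V+" else 1.0
        rows.append(
            {
                "electrode": prof.electrode,
                "selectivity": prof.selectivity,
                "z_category": z_cat,
                "t_voiced": t_voiced,
                "t_voiceless": t_voiceless,
                # sign convention: positive = stronger toward the preferred
                # category endpoint
                "t_preferred": flip * (t_voiced if prof.selectivity == "V+" else t_voiceless),
                "t_nonpreferred": flip * (t_voiceless if prof.selectivity == "V+" else t_voiced),
            }
        )
    return pd.DataFrame(rows)


def encoding_summary(
    epochs_by_participant: dict[str, EpochSet],
    profiles_by_participant: dict[str, pd.DataFrame],
) -> dict:
    """Group-level encoding statistics across all VOT-sensitive electrodes.

    Returns per-electrode statistics plus the signed-rank tests over
    electrodes: between-category discriminability per class, and the pooled
    within-category tests in the preferred and non-preferred categories.
    """
    tables = []
    for pid, epochs in epochs_by_participant.items():
        t = _per_electrode_tables(epochs, profiles_by_participant[pid])
        if len(t):
            t.insert(0, "participant", pid)
            tables.append(t)
    if not tables:
        raise ValueError("no VOT-sensitive electrodes")
    table = pd.concat(tables, ignore_index=True)

    out = {"per_electrode": table}
    vm = table[table.selectivity == "V-"]
    vp = table[table.selectivity == "V+"]
    tests = {}
    if len(vm) >= 5:
        tests["category_Vminus"] = group_signed_rank(vm.z_category)
        tests["within_Vminus_voiceless"] = group_signed_rank(vm.t_voiceless)
        tests["within_Vminus_voiced"] = group_signed_rank(vm.t_voiced)
    if len(vp) >= 5:
        tests["category_Vplus"] = group_signed_rank(vp.z_category)
        tests["within_Vplus_voiced"] = group_signed_rank(vp.t_voiced)
        tests["within_Vplus_voiceless"] = group_signed_rank(vp.t_voiceless)
    tests["pooled_preferred"] = group_signed_rank(table.t_preferred)
    tests["pooled_nonpreferred"] = group_signed_rank(table.t_nonpreferred)
    out["tests"] = tests
    return out
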