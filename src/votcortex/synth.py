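"""Seeded generators for synthetic VOT-continuum neurophysiology datasets.

The generators emulate the statistical structure the analysis stages assume:

* trial-epoched, z-scored high-gamma (400 Hz) at electrodes with
  voiced-selective (V+), voiceless-selective (V-), VOT-insensitive, or
  non-responsive tuning, including VOT-dependent onset latencies at V+ sites;
* raw-voltage epochs containing three planted auditory-evoked deflections
  (P-alpha, N-alpha, P-beta), optionally VOT-dependent;
* binary /ba/-/pa/ identification responses from a logistic psychometric
  model with per-participant category boundaries;
* an optional continuous broadband "raw mode" record whose 70-150 Hz
  envelope carries the same evoked structure, to exercise the preprocessing
  chain end to end.

Everything is deterministic under a fixed seed.  Evoked responses use a
half-raised-cosine rise followed by an exponential decay -- a smooth
unimodal kernel with a closed-form peak location (onset + rise time).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal as spsig

from .containers import EPOCH_WINDOW_MS, Dataset, EpochSet, RawRecording

__all__ = [
    "ClassSpec",
    "SyntheticConfig",
    "amplitude_coded_config",
    "latency_coded_config",
    "evoked_kernel",
    "ar1_noise",
    "make_events",
    "make_behavior",
    "make_hg_dataset",
    "make_lfp",
    "make_raw_recording",
    "make_dataset",
]

VOTS_MS = np.array([0.0, 10.0, 20.0, 30.0, 40.0, 50.0])


@dataclass(frozen=True)
class ClassSpec:
    """Tuning of one electrode class: count, peak-amplitude curve over the
    six VOTs (z-units), and onset-latency slope (ms of latency per ms VOT)."""

    n_electrodes: int
    amplitude_curve: tuple[float, ...]
    onset_slope: float = 0.0

    def __post_init__(self) -> None:
        if len(self.amplitude_curve) != len(VOTS_MS):
            raise ValueError("amplitude curve must give one value per VOT")


def _default_classes() -> dict[str, ClassSpec]:
    # V+ : graded within voiced (0-20 ms), flat within voiceless; onset
    # latency tracks voicing onset.  V- : mirror image, onset locked to the
    # burst.  Ratios follow the roughly 2:1 prevalence of V+ over V- sites.
    return {
        "V+": ClassSpec(5, (4.5, 3.8, 3.1, 1.8, 1.8, 1.8), onset_slope=1.0),
        "V-": ClassSpec(3, (1.8, 1.8, 1.8, 3.1, 3.8, 4.5), onset_slope=0.0),
        "none": ClassSpec(2, (2.8, 2.8, 2.8, 2.8, 2.8, 2.8), onset_slope=0.0),
        "silent": ClassSpec(2, (0.0, 0.0, 0.0, 0.0, 0.0, 0.0), onset_slope=0.0),
    }


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for the synthetic dataset.

    Defaults mirror the source study's design where stated (seven
    participants, four with behavioral responses, six VOT steps, 400 Hz
    epochs spanning -500..+1000 ms, psychometric boundary near 21 ms) and
    otherwise use values typical of ECoG speech experiments.
    """

    n_participants: int = 7
    n_behavior_participants: int = 4
    trials_per_vot: int = 50
    sfreq: float = 400.0
    epoch_window_ms: tuple[float, float] = EPOCH_WINDOW_MS
    classes: dict[str, ClassSpec] = field(default_factory=_default_classes)

    # evoked kernel (high-gamma); the peak sits at onset + rise = 140 ms so
    # that the amplitude-tuning ramp finishes before the 150-250 ms peak
    # analysis window -- inside the window the trace is proportional to the
    # tuned amplitude, carrying no residual shape/timing category structure
    onset_base_ms: float = 85.0
    rise_ms: float = 55.0
    plateau_ms: float = 100.0  # sustained response; decouples onset-latency
    # shifts from the amplitude read out at a fixed peak sample
    fall_tau_ms: float = 150.0
    tuned_ramp_ms: float = 15.0  # amplitude tuning blends in over the last
    # part of the rise; the earlier transient is common across VOTs

    # noise: additive Gaussian with first-order autocorrelation, in
    # baseline z-units
    noise_sd: float = 1.0
    ar_coef: float = 0.9
    amp_jitter_sd: float = 0.1  # multiplicative trial-to-trial gain SD

    # behavior (response 1 = /pa/)
    beta0: float = -4.2
    beta_vot: float = 0.2
    participant_intercept_sd: float = 0.5
    behavior_trials_per_vot: int = 100
    omission_rate: float = 0.02
    rt_outlier_rate: float = 0.01
    rt_log_mean: float = float(np.log(650.0))
    rt_log_sd: float = 0.25

    # auditory evoked potential (microvolts); peaks are (+, -, +)
    aep_latencies_ms: tuple[float, float, float] = (90.0, 130.0, 200.0)
    aep_amplitudes_uv: tuple[float, float, float] = (40.0, -60.0, 50.0)
    aep_widths_ms: tuple[float, float, float] = (15.0, 20.0, 30.0)
    aep_latency_slopes: tuple[float, float, float] = (0.0, 0.0, 0.0)
    aep_amplitude_slopes: tuple[float, float, float] = (0.0, 0.0, 0.0)
    lfp_noise_sd_uv: float = 30.0
    lfp_ar_coef: float = 0.97

    # raw mode (continuous broadband voltage)
    raw_sfreq: float = 1600.0
    line_amp_uv: float = 15.0
    hg_carrier_base_uv: float = 4.0
    hg_carrier_gain_uv: float = 3.0

    seed: int = 0

    def __post_init__(self) -> None:
        if self.trials_per_vot < 2:
            raise ValueError("need at least 2 trials per VOT condition")
        if self.n_behavior_participants > self.n_participants:
            raise ValueError("more behavioral participants than participants")

    def participant_ids(self) -> list[str]:
        return [f"P{p + 1:02d}" for p in range(self.n_participants)]

    def times_ms(self) -> np.ndarray:
        t0, t1 = self.epoch_window_ms
        n = int(round((t1 - t0) * self.sfreq / 1000.0))
        return t0 + np.arange(n) * 1000.0 / self.sfreq


def amplitude_coded_config(**overrides) -> SyntheticConfig:
    """Conditions where voicing category lives only in response amplitude:
    default tuning curves, zero onset-latency slopes, and strictly
    proportional amplitude scaling (no common-transient blend), so the
    evoked shape carries no residual timing structure anywhere."""
    classes = {
        name: replace(cs, onset_slope=0.0) for name, cs in _default_classes().items()
    }
    overrides.setdefault("tuned_ramp_ms", 0.0)
    return SyntheticConfig(classes=classes, **overrides)


def latency_coded_config(**overrides) -> SyntheticConfig:
    """Conditions where voicing category lives only in response timing:
    flat amplitude curves with a 1 ms/ms onset-latency slope."""
    flat = (3.0,) * 6
    classes = {
        "latency": ClassSpec(8, flat, onset_slope=1.0),
        "none": ClassSpec(2, (2.8,) * 6, onset_slope=0.0),
        "silent": ClassSpec(2, (0.0,) * 6, onset_slope=0.0),
    }
    return SyntheticConfig(classes=classes, **overrides)


# --------------------------------------------------------------------------
# primitives


def evoked_kernel(
    times_ms: np.ndarray,
    onset_ms: float,
    rise_ms: float,
    fall_tau_ms: float,
    plateau_ms: float = 0.0,
) -> np.ndarray:
    """Unit-peak evoked kernel: half-raised-cosine rise, optional sustained
    plateau, exponential fall.

    Reaches its maximum of 1 at exactly ``onset_ms + rise_ms`` and holds it
    for ``plateau_ms`` before decaying.  The plateau mimics the sustained
    high-gamma responses of auditory cortex and makes the value at a fixed
    peak sample insensitive to modest onset-latency shifts.
    """
    t = np.asarray(times_ms, dtype=float)
    out = np.zeros_like(t)
    rising = (t >= onset_ms) & (t < onset_ms + rise_ms)
    out[rising] = 0.5 * (1.0 - np.cos(np.pi * (t[rising] - onset_ms) / rise_ms))
    top = onset_ms + rise_ms + plateau_ms
    flat = (t >= onset_ms + rise_ms) & (t < top)
    out[flat] = 1.0
    falling = t >= top
    out[falling] = np.exp(-(t[falling] - top) / fall_tau_ms)
    return out


def evoked_response(
    times_ms: np.ndarray,
    onset_ms: float,
    peak_amp: float,
    base_amp: float,
    rise_ms: float,
    fall_tau_ms: float,
    ramp_ms: float,
    plateau_ms: float = 0.0,
) -> np.ndarray:
    """Evoked trace whose onset transient is amplitude-invariant.

    The response is the kernel scaled by an amplitude that blends smoothly
    (raised-cosine ramp over the last ``ramp_ms`` of the rise) from a common
    ``base_amp`` to the condition-specific ``peak_amp``, mimicking cortical
    responses whose early transient is stimulus-onset-locked while amplitude
    tuning is expressed at the peak.  The maximum is exactly ``peak_amp`` at
    ``onset_ms + rise_ms``; with ``peak_amp == base_amp`` this reduces to a
    plain scaled kernel.  Half-peak crossing times therefore do not depend
    on amplitude tuning (provided the common transient reaches the
    threshold before the ramp starts).
    """
    t = np.asarray(times_ms, dtype=float)
    k = evoked_kernel(t, onset_ms, rise_ms, fall_tau_ms, plateau_ms)
    if peak_amp == base_amp or ramp_ms <= 0:
        return peak_amp * k
    t0 = onset_ms + rise_ms - ramp_ms
    frac = np.clip((t - t0) / ramp_ms, 0.0, 1.0)
    m = 0.5 * (1.0 - np.cos(np.pi * frac))
    return k * (base_amp + (peak_amp - base_amp) * m)


def ar1_noise(rng: np.random.Generator, shape: tuple, coef: float, sd: float) -> np.ndarray:
    """Stationary AR(1) Gaussian noise along the last axis."""
    if sd == 0.0:
        return np.zeros(shape)
    warmup = 200
    full = shape[:-1] + (shape[-1] + warmup,)
    innov = rng.standard_normal(full) * sd * np.sqrt(max(1.0 - coef**2, 1e-12))
    out = spsig.lfilter([1.0], [1.0, -coef], innov, axis=-1)
    return out[..., warmup:]


def _rng(config: SyntheticConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed) % 2**31, stream])


def _logistic(x):
    from scipy.special import expit

    return expit(x)


def _participant_offsets(config: SyntheticConfig) -> dict[str, float]:
    rng = _rng(config, 11)
    ids = config.participant_ids()
    return {
        pid: float(rng.normal(0.0, config.participant_intercept_sd)) for pid in ids
    }


# --------------------------------------------------------------------------
# events and behavior


def make_events(config: SyntheticConfig) -> pd.DataFrame:
    """Per-trial event table for the neural recording sessions.

    Behavioral responses (1 = /pa/) and reaction times are filled in for the
    first ``n_behavior_participants``; the rest listened passively.
    """
    offsets = _participant_offsets(config)
    rng = _rng(config, 12)
    rows = []
    for p, pid in enumerate(config.participant_ids()):
        vots = np.repeat(VOTS_MS, config.trials_per_vot)
        rng.shuffle(vots)
        behav = p < config.n_behavior_participants
        for i, vot in enumerate(vots):
            if behav:
                resp, rt = _draw_response(config, rng, offsets[pid], vot)
            else:
                resp, rt = np.nan, np.nan
            rows.append(
                {
                    "participant": pid,
                    "trial": i,
                    "vot_ms": float(vot),
                    "response": resp,
                    "rt_ms": rt,
                }
            )
    return pd.DataFrame(rows)


def _draw_response(config, rng, offset, vot):
    if rng.random() < config.omission_rate:
        return np.nan, np.nan
    p_pa = _logistic(config.beta0 + offset + config.beta_vot * vot)
    resp = float(rng.random() < p_pa)
    rt = float(np.exp(rng.normal(config.rt_log_mean, config.rt_log_sd)))
    if rng.random() < config.rt_outlier_rate:
        rt *= 6.0
    return resp, rt


def make_behavior(config: SyntheticConfig) -> pd.DataFrame:
    """Standalone behavioral session: ``behavior_trials_per_vot`` trials per
    VOT for each behavioral participant, drawn from the logistic model
    P(/pa/) = logistic(beta0 + u_p + beta_vot * VOT)."""
    offsets = _participant_offsets(config)
    rng = _rng(config, 13)
    rows = []
    for pid in config.participant_ids()[: config.n_behavior_participants]:
        vots = np.repeat(VOTS_MS, config.behavior_trials_per_vot)
        rng.shuffle(vots)
        for i, vot in enumerate(vots):
            resp, rt = _draw_response(config, rng, offsets[pid], vot)
            rows.append(
                {
                    "participant": pid,
                    "trial": i,
                    "vot_ms": float(vot),
                    "response": resp,
                    "rt_ms": rt,
                }
            )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# high-gamma epochs


def _electrode_table(config: SyntheticConfig) -> pd.DataFrame:
    rows = []
    for pid in config.participant_ids():
        k = 0
        for cls, cs in config.classes.items():
            for _ in range(cs.n_electrodes):
                rows.append(
                    {
                        "participant": pid,
                        "electrode": f"{pid}_e{k:02d}",
                        "true_class": cls,
                        "onset_slope": cs.onset_slope,
                        **{
                            f"amp_{int(v)}": cs.amplitude_curve[j]
                            for j, v in enumerate(VOTS_MS)
                        },
                    }
                )
                k += 1
    return pd.DataFrame(rows)


def make_hg_dataset(config: SyntheticConfig) -> Dataset:
    """Generate z-scored high-gamma epochs for every participant.

    Per trial and electrode the trace is AR(1) baseline noise plus a smooth
    evoked bump whose peak amplitude follows the electrode class's tuning
    curve (with multiplicative trial-to-trial gain jitter) and whose onset is
    ``onset_base_ms + onset_slope * VOT``.
    """
    events = make_events(config)
    truth_el = _electrode_table(config)
    times = config.times_ms()
    hg: dict[str, EpochSet] = {}
    for p, pid in enumerate(config.participant_ids()):
        ev = events[events.participant == pid].reset_index(drop=True)
        el = truth_el[truth_el.participant == pid].reset_index(drop=True)
        rng = _rng(config, 100 + p)
        n_tr, n_el, n_s = len(ev), len(el), len(times)
        data = ar1_noise(rng, (n_tr, n_el, n_s), config.ar_coef, config.noise_sd)
        vots = ev.vot_ms.to_numpy()
        vot_idx = np.searchsorted(VOTS_MS, vots)
        gains = 1.0 + (
            rng.standard_normal((n_tr, n_el)) * config.amp_jitter_sd
            if config.amp_jitter_sd > 0
            else np.zeros((n_tr, n_el))
        )
        for j in range(n_el):
            curve = el.loc[j, [f"amp_{int(v)}" for v in VOTS_MS]].to_numpy(dtype=float)
            slope = float(el.loc[j, "onset_slope"])
            base = float(curve.min())
            for vi, vot in enumerate(VOTS_MS):
                mask = vot_idx == vi
                if not mask.any() or curve[vi] == 0.0:
                    continue
                resp = evoked_response(
                    times,
                    config.onset_base_ms + slope * vot,
                    curve[vi],
                    base,
                    config.rise_ms,
                    config.fall_tau_ms,
                    config.tuned_ramp_ms,
                    config.plateau_ms,
                )
                data[mask, j, :] += gains[mask, j][:, None] * resp[None, :]
        hg[pid] = EpochSet(
            data=data,
            sfreq=config.sfreq,
            times=times,
            events=ev,
            electrodes=list(el.electrode),
            kind="high-gamma-z",
        )
    truth = {"electrodes": truth_el, "behavior": _behavior_truth(config)}
    return Dataset(hg=hg, events=events, truth=truth)


def _behavior_truth(config: SyntheticConfig) -> pd.DataFrame:
    offsets = _participant_offsets(config)
    return pd.DataFrame(
        {
            "participant": config.participant_ids(),
            "beta0": config.beta0,
            "beta_vot": config.beta_vot,
            "intercept_offset": [offsets[p] for p in config.participant_ids()],
        }
    )


# --------------------------------------------------------------------------
# local field potential epochs


def _check_aep_ordering(config: SyntheticConfig) -> None:
    for vot in VOTS_MS:
        lats = [
            config.aep_latencies_ms[k] + config.aep_latency_slopes[k] * vot
            for k in range(3)
        ]
        if not (lats[0] < lats[1] < lats[2]):
            raise ValueError(
                f"AEP deflection latencies must keep P-alpha < N-alpha < P-beta; "
                f"violated at VOT {vot} ms: {lats}"
            )


def make_lfp(config: SyntheticConfig) -> dict[str, EpochSet]:
    """Raw-voltage epochs with three planted Gaussian-windowed deflections.

    Deflection latencies/amplitudes may depend linearly on VOT via
    ``aep_latency_slopes`` / ``aep_amplitude_slopes``; the default is
    VOT-independent.  Electrode layout and trial structure match
    :func:`make_hg_dataset` so the same selections apply.
    """
    _check_aep_ordering(config)
    events = make_events(config)
    truth_el = _electrode_table(config)
    times = config.times_ms()
    out: dict[str, EpochSet] = {}
    for p, pid in enumerate(config.participant_ids()):
        ev = events[events.participant == pid].reset_index(drop=True)
        el = truth_el[truth_el.participant == pid].reset_index(drop=True)
        rng = _rng(config, 300 + p)
        n_tr, n_el, n_s = len(ev), len(el), len(times)
        data = ar1_noise(rng, (n_tr, n_el, n_s), config.lfp_ar_coef, config.lfp_noise_sd_uv)
        vots = ev.vot_ms.to_numpy()
        gains = 1.0 + (
            rng.standard_normal((n_tr, n_el)) * config.amp_jitter_sd
            if config.amp_jitter_sd > 0
            else np.zeros((n_tr, n_el))
        )
        for vot in VOTS_MS:
            mask = vots == vot
            if not mask.any():
                continue
            wave = np.zeros(n_s)
            for k in range(3):
                lat = config.aep_latencies_ms[k] + config.aep_latency_slopes[k] * vot
                amp = config.aep_amplitudes_uv[k] + config.aep_amplitude_slopes[k] * vot
                sig = config.aep_widths_ms[k]
                wave += amp * np.exp(-0.5 * ((times - lat) / sig) ** 2)
            data[mask, :, :] += gains[mask, :][:, :, None] * wave[None, None, :]
        out[pid] = EpochSet(
            data=data,
            sfreq=config.sfreq,
            times=times,
            events=ev,
            electrodes=list(el.electrode),
            kind="raw-voltage",
        )
    return out


# --------------------------------------------------------------------------
# raw mode (continuous broadband voltage)


def make_raw_recording(
    config: SyntheticConfig, participant: str | None = None
) -> tuple[RawRecording, pd.DataFrame]:
    """Continuous broadband voltage for one participant (raw mode).

    The record contains pink-ish background noise, a 60 Hz line component
    shared across electrodes, and a 70-150 Hz narrowband carrier whose
    envelope is modulated by the same evoked-bump structure the direct
    high-gamma generator plants, so the full preprocessing chain (notch, CAR,
    Hilbert high-gamma, epoching, z-scoring) recovers the planted tuning.
    """
    pid = participant or config.participant_ids()[0]
    p = config.participant_ids().index(pid)
    events = make_events(config)
    ev = events[events.participant == pid].reset_index(drop=True)
    truth_el = _electrode_table(config)
    el = truth_el[truth_el.participant == pid].reset_index(drop=True)
    fs = config.raw_sfreq
    rng = _rng(config, 500 + p)

    pre_ms, post_ms = -config.epoch_window_ms[0], config.epoch_window_ms[1]
    spacing_ms = pre_ms + post_ms + 300.0
    n_tr = len(ev)
    onsets_ms = pre_ms + 300.0 + spacing_ms * np.arange(n_tr)
    total_ms = onsets_ms[-1] + post_ms + 500.0
    n_s = int(round(total_ms * fs / 1000.0))
    t_ms = np.arange(n_s) * 1000.0 / fs
    onsets = np.round(onsets_ms * fs / 1000.0).astype(int)

    n_el = len(el)
    data = ar1_noise(rng, (n_el, n_s), 0.99, 20.0)
    line = config.line_amp_uv * np.sin(
        2 * np.pi * 60.0 * t_ms / 1000.0 + rng.uniform(0, 2 * np.pi)
    )
    data += line[None, :]

    sos = spsig.butter(4, [70.0, 150.0], btype="bandpass", fs=fs, output="sos")
    vots = ev.vot_ms.to_numpy()
    for j in range(n_el):
        carrier = spsig.sosfiltfilt(sos, rng.standard_normal(n_s))
        carrier /= carrier.std()
        curve = el.loc[j, [f"amp_{int(v)}" for v in VOTS_MS]].to_numpy(dtype=float)
        slope = float(el.loc[j, "onset_slope"])
        base = float(curve.min())
        envelope = np.zeros(n_s)
        for i, onset in enumerate(onsets):
            vi = int(np.searchsorted(VOTS_MS, vots[i]))
            if curve[vi] == 0.0:
                continue
            seg = slice(onset, min(onset + int(post_ms * fs / 1000.0), n_s))
            rel_t = (np.arange(seg.stop - seg.start)) * 1000.0 / fs
            envelope[seg] += evoked_response(
                rel_t,
                config.onset_base_ms + slope * vots[i],
                curve[vi],
                base,
                config.rise_ms,
                config.fall_tau_ms,
                config.tuned_ramp_ms,
                config.plateau_ms,
            )
        data[j] += carrier * (
            config.hg_carrier_base_uv + config.hg_carrier_gain_uv * envelope
        )

    raw = RawRecording(
        data=data, sfreq=fs, event_onsets=onsets, electrodes=list(el.electrode)
    )
    return raw, ev


def make_dataset(config: SyntheticConfig, with_lfp: bool = True) -> Dataset:
    """High-gamma + (optionally) LFP + behavior, sharing one event table."""
    ds = make_hg_dataset(config)
    if with_lfp:
        ds.lfp = make_lfp(config)
    return ds
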