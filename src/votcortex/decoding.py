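"""Population decoding of voicing category with information corruption.

The 2x2 design asks which features of the peak response window (150-250 ms)
carry voicing-category information:

* timing corruption (-T): every trial's full time series is shifted by a
  uniform random integer jitter in [-20, +20] samples (+/-50 ms at 400 Hz),
  identical across electrodes of that trial, destroying reliable temporal
  patterns within and across electrodes;
* amplitude corruption (-A): per electrode, every trial's series is divided
  by the mean peak amplitude of that trial's voicing category, forcing the
  two category means to be exactly equal (1.0) at the electrode's peak while
  preserving single-trial variability and dynamics.

Features are the flattened electrodes x window-samples matrix, reduced by
spatiotemporal PCA to the components covering 90% of variance, and
classified by linear discriminant analysis under leave-one-out
cross-validation (chance = 0.5).  In the doubly corrupted condition
amplitude normalization precedes jittering.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from .containers import EpochSet
from .encoding import VOICED_MAX_MS
from .stats import SignedRankResult, signed_rank

__all__ = [
    "DecodingConfig",
    "CONDITIONS",
    "corrupt_amplitude",
    "corrupt_timing",
    "classify_voicing",
    "run_condition",
    "condition_battery",
]

CONDITIONS = ("+A+T", "+A-T", "-A+T", "-A-T")


@dataclass(frozen=True)
class DecodingConfig:
    window_ms: tuple[float, float] = (150.0, 250.0)
    jitter_samples: int = 20
    variance_retained: float = 0.90
    seed: int = 0
    pca_within_folds: bool = False
    peak_search_ms: tuple[float, float] = (0.0, 500.0)
    lda_shrinkage: float = 1e-6

    def validate(self, epochs: EpochSet) -> None:
        dt = 1000.0 / epochs.sfreq
        margin = self.jitter_samples * dt
        if (
            epochs.times[0] > self.window_ms[0] - margin
            or epochs.times[-1] < self.window_ms[1] + margin
        ):
            raise ValueError("epoch too short for the analysis window plus jitter")


def _voiceless_mask(epochs: EpochSet) -> np.ndarray:
    return epochs.vots > VOICED_MAX_MS


def corrupt_amplitude(
    epochs: EpochSet, is_voiceless: np.ndarray | None = None,
    peak_search_ms: tuple[float, float] = (0.0, 500.0),
) -> EpochSet:
    """Equalize the category-mean amplitudes at every electrode's peak.

    Per electrode: find the grand-mean peak sample, compute the mean
    amplitude of each voicing category there, and divide each trial's entire
    series by its category's mean.  Afterwards both category means at the
    peak equal exactly 1.
    """
    if is_voiceless is None:
        is_voiceless = _voiceless_mask(epochs)
    is_voiceless = np.asarray(is_voiceless, dtype=bool)
    data = epochs.data.copy()
    wsl = epochs.window_slice(*peak_search_ms)
    for j in range(epochs.n_electrodes):
        grand = data[:, j, wsl].mean(axis=0)
        peak = wsl.start + int(np.argmax(grand))
        for mask in (is_voiceless, ~is_voiceless):
            m = data[mask, j, peak].mean()
            if m <= 0:
                raise ValueError(
                    f"non-positive category mean at electrode {epochs.electrodes[j]}; "
                    "amplitude normalization is degenerate"
                )
            data[mask, j, :] /= m
    return epochs.copy_with(data)


def corrupt_timing(
    epochs: EpochSet, seed_or_rng, jitter_samples: int = 20
) -> tuple[EpochSet, np.ndarray]:
    """Shift every trial by one uniform random jitter in [-j, +j] samples.

    The jitter is drawn once per trial and applied identically to all
    electrodes; positive jitter delays the series (content at sample s moves
    to s + jitter).  Samples exposed at the epoch edges repeat the edge
    value; the analysis window must keep ``jitter_samples`` of margin from
    both edges, so filled samples never enter the features.
    """
    rng = (
        seed_or_rng
        if isinstance(seed_or_rng, np.random.Generator)
        else np.random.default_rng(seed_or_rng)
    )
    jitters = rng.integers(-jitter_samples, jitter_samples + 1, size=epochs.n_trials)
    n_s = epochs.n_samples
    pad = jitter_samples
    padded = np.pad(epochs.data, ((0, 0), (0, 0), (pad, pad)), mode="edge")
    data = np.empty_like(epochs.data)
    for i, j in enumerate(jitters):
        start = pad - j
        data[i] = padded[i, :, start : start + n_s]
    out = epochs.copy_with(data)
    out.info["jitters"] = jitters
    return out, jitters


def classify_voicing(epochs: EpochSet, config: DecodingConfig = DecodingConfig()) -> float:
    """Leave-one-out LDA accuracy for voiced vs voiceless, after PCA.

    PCA is fit once on all trials (matching the described ordering of
    steps); set ``pca_within_folds=True`` for the strictly leakage-free
    variant.  LDA uses a pooled covariance with a small shrinkage ridge.
    """
    config.validate(epochs)
    y = _voiceless_mask(epochs).astype(int)
    if len(np.unique(y)) < 2 or min(np.bincount(y)) < 2:
        raise ValueError("need at least 2 trials per category")
    wsl = epochs.window_slice(*config.window_ms)
    X = epochs.data[:, :, wsl].reshape(epochs.n_trials, -1)

    def make_lda():
        return LinearDiscriminantAnalysis(solver="lsqr", shrinkage=config.lda_shrinkage)

    n = len(y)
    correct = 0
    if config.pca_within_folds:
        for i in range(n):
            tr = np.arange(n) != i
            pca = PCA(n_components=config.variance_retained, svd_solver="full")
            Xt = pca.fit_transform(X[tr])
            clf = make_lda().fit(Xt, y[tr])
            correct += clf.predict(pca.transform(X[i : i + 1]))[0] == y[i]
    else:
        pca = PCA(n_components=config.variance_retained, svd_solver="full")
        Z = pca.fit_transform(X)
        for i in range(n):
            tr = np.arange(n) != i
            clf = make_lda().fit(Z[tr], y[tr])
            correct += clf.predict(Z[i : i + 1])[0] == y[i]
    return correct / n


def run_condition(
    epochs: EpochSet, condition: str, config: DecodingConfig = DecodingConfig()
) -> float:
    """Apply the corruption(s) of one condition and return LOO accuracy.

    ``-A-T`` applies amplitude normalization before temporal jittering.
    """
    if condition not in CONDITIONS:
        raise ValueError(f"condition must be one of {CONDITIONS}")
    work = epochs
    if "-A" in condition:
        work = corrupt_amplitude(work, peak_search_ms=config.peak_search_ms)
    if "-T" in condition:
        work, _ = corrupt_timing(work, config.seed, config.jitter_samples)
    return classify_voicing(work, config)


def condition_battery(
    epochs_by_participant: dict[str, EpochSet],
    config: DecodingConfig = DecodingConfig(),
) -> dict:
    """All four conditions for every participant, plus the group tests.

    Group tests are Wilcoxon signed-rank across participants: each condition
    against chance (0.5) and the paired comparisons of the corruption design.
    """
    rows = []
    base = np.random.SeedSequence(config.seed)
    keys = sorted(epochs_by_participant)
    children = base.spawn(len(keys))
    for pid, ss in zip(keys, children):
        epochs = epochs_by_participant[pid]
        seeds = ss.generate_state(len(CONDITIONS))
        for cond, s in zip(CONDITIONS, seeds):
            cfg = DecodingConfig(
                window_ms=config.window_ms,
                jitter_samples=config.jitter_samples,
                variance_retained=config.variance_retained,
                seed=int(s % 2**31),
                pca_within_folds=config.pca_within_folds,
                peak_search_ms=config.peak_search_ms,
                lda_shrinkage=config.lda_shrinkage,
            )
            rows.append(
                {
                    "participant": pid,
                    "condition": cond,
                    "accuracy": run_condition(epochs, cond, cfg),
                }
            )
    table = pd.DataFrame(rows)
    acc = table.pivot(index="participant", columns="condition", values="accuracy")

    tests: dict[str, SignedRankResult] = {}
    for cond in CONDITIONS:
        tests[f"{cond}_vs_chance"] = signed_rank(acc[cond].to_numpy(), mu=0.5)
    pairs = [("+A+T", "+A-T"), ("+A+T", "-A+T"), ("-A+T", "-A-T")]
    for a, b in pairs:
        tests[f"{a}_vs_{b}"] = signed_rank(acc[a].to_numpy() - acc[b].to_numpy())
    return {"accuracies": table, "by_participant": acc, "tests": tests}
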