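"""End-to-end pipeline: synthesize -> select -> encode -> decode -> latency
-> AEP -> behavior, with a reproducible JSON + Markdown report.

Every stochastic stage derives its seed from the single run seed, and the
report contains no timestamps, so identical configurations produce
byte-identical reports.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import behavior as beh
from . import decoding as dec
from . import dynamics as dyn
from . import encoding as enc
from . import network
from .synth import SyntheticConfig, make_behavior, make_dataset

__all__ = ["RunConfig", "run_pipeline", "write_report", "render_markdown"]


@dataclass(frozen=True)
class RunConfig:
    """Effective parameters of one pipeline run (echoed into the report)."""

    seed: int = 0
    n_participants: int = 7
    trials_per_vot: int = 50
    noise_sd: float = 1.0
    behavior_trials_per_vot: int = 100
    n_resamples: int = 1000
    decoding_window_ms: tuple[float, float] = (150.0, 250.0)
    jitter_samples: int = 20
    variance_retained: float = 0.90
    max_aep_electrodes: int = 10
    with_lfp: bool = True

    def synthetic_config(self) -> SyntheticConfig:
        return SyntheticConfig(
            seed=self.seed,
            n_participants=self.n_participants,
            n_behavior_participants=min(4, self.n_participants),
            trials_per_vot=self.trials_per_vot,
            noise_sd=self.noise_sd,
            behavior_trials_per_vot=self.behavior_trials_per_vot,
        )

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = json.load(fh)
        if "decoding_window_ms" in d:
            d["decoding_window_ms"] = tuple(d["decoding_window_ms"])
        return cls(**d)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2)


def _signed(res) -> dict:
    return {"w": res.w_plus, "z": round(res.z, 6), "p": _round_p(res.p_value), "n": res.n_used}


def _ranksum(res) -> dict:
    return {"u": res.u, "z": round(res.z, 6), "p": _round_p(res.p_value)}


def _round_p(p: float) -> float:
    return float(f"{p:.6g}") if np.isfinite(p) else p


def run_pipeline(config: RunConfig = RunConfig()) -> dict:
    """Execute every stage on a synthetic dataset and return the report."""
    report: dict = {"config": dataclasses.asdict(config)}

    # model sanity block: the deterministic network and its constraints
    spec = network.default_spec()
    constraints = network.check_constraints(spec)
    sweep = network.sweep_vots(spec)
    report["model"] = {
        "constraints": {c.name: bool(c.satisfied) for c in constraints},
        "gap_peaks": sweep[sweep.unit == "gap"].peak_output.round(6).tolist(),
        "coinc_peaks": sweep[sweep.unit == "coinc"].peak_output.round(6).tolist(),
        "gap_onsets": sweep[sweep.unit == "gap"].onset_cycle.tolist(),
        "coinc_onsets": sweep[sweep.unit == "coinc"].onset_cycle.tolist(),
    }

    synth_cfg = config.synthetic_config()
    dataset = make_dataset(synth_cfg, with_lfp=config.with_lfp)

    # electrode selection and encoding statistics
    profiles = {pid: enc.profile_electrodes(es) for pid, es in dataset.hg.items()}
    all_prof = pd.concat(
        [p.assign(participant=pid) for pid, p in profiles.items()], ignore_index=True
    )
    counts = {
        "n_electrodes": int(len(all_prof)),
        "n_speech_responsive": int(all_prof.speech_responsive.sum()),
        "n_vot_sensitive": int(all_prof.selectivity.isin(["V+", "V-"]).sum()),
        "n_V+": int((all_prof.selectivity == "V+").sum()),
        "n_V-": int((all_prof.selectivity == "V-").sum()),
    }
    report["electrodes"] = counts

    summary = enc.encoding_summary(dataset.hg, profiles)
    report["encoding"] = {k: _signed(v) for k, v in summary["tests"].items()}

    # decoding battery
    dconf = dec.DecodingConfig(
        window_ms=config.decoding_window_ms,
        jitter_samples=config.jitter_samples,
        variance_retained=config.variance_retained,
        seed=config.seed,
    )
    # classifiers see all speech-responsive electrodes of each participant
    responsive_sets = {
        pid: es.select_electrodes(profiles[pid].speech_responsive.to_numpy())
        for pid, es in dataset.hg.items()
    }
    battery = dec.condition_battery(responsive_sets, dconf)
    report["decoding"] = {
        "mean_accuracy": {
            c: round(float(battery["by_participant"][c].mean()), 6)
            for c in dec.CONDITIONS
        },
        "tests": {k: _signed(v) for k, v in battery["tests"].items()},
    }

    # onset-latency bootstrap
    lat_means: dict[str, list[float]] = {"V+": [], "V-": []}
    for pid, es in dataset.hg.items():
        res = dyn.latency_analysis(
            es, profiles[pid], n_resamples=config.n_resamples, seed=config.seed
        )
        for el, r in res.items():
            if not r["distribution"].excluded:
                lat_means[r["class"]].append(r["distribution"].mean)
    report["latency"] = {
        "mean_rho_V+": round(float(np.mean(lat_means["V+"])), 6) if lat_means["V+"] else None,
        "mean_rho_V-": round(float(np.mean(lat_means["V-"])), 6) if lat_means["V-"] else None,
    }
    if all(len(v) >= 5 for v in lat_means.values()):
        tests = dyn.group_latency_tests(lat_means)
        report["latency"]["tests"] = {
            cls: _signed(res) for cls, res in tests["per_class"].items()
        }
        if tests.get("between") is not None:
            report["latency"]["between"] = _ranksum(tests["between"])

    # AEP bootstrap on a capped number of VOT-sensitive electrodes
    if config.with_lfp:
        sig_counts = {k: 0 for k in (
            f"{p}_{w}" for p in dyn.AEP_PEAK_NAMES for w in ("latency", "amplitude")
        )}
        n_tested = 0
        for pid, es in dataset.lfp.items():
            sel = profiles[pid][profiles[pid].selectivity.isin(["V+", "V-"])]
            for el in sel.electrode:
                if n_tested >= config.max_aep_electrodes:
                    break
                j = es.electrode_index(el)
                dists = dyn.bootstrap_aep_correlations(
                    es.data[:, j, :], es.vots, es.times,
                    n_resamples=config.n_resamples, seed=config.seed,
                )
                n_tested += 1
                for k, d in dists.items():
                    if not d.excluded and d.significant():
                        sig_counts[k] += 1
        report["aep"] = {"n_electrodes_tested": n_tested, "n_significant": sig_counts}

    # behavior
    events = make_behavior(synth_cfg)
    clean, ex_log = beh.exclude_trials(events)
    fit = beh.fit_psychometric(clean)
    report["behavior"] = {
        "exclusions": ex_log,
        "beta0": round(fit.beta0, 6),
        "beta_vot": round(fit.beta_vot, 6),
        "boundary_ms": round(fit.boundary_ms, 6),
        "boundary_by_participant": {
            k: round(v, 6) for k, v in fit.boundary_by_participant.items()
        },
        "separation_flag": fit.separation_flag,
    }
    return report


def render_markdown(report: dict) -> str:
    lines = ["# votcortex pipeline report", ""]

    def walk(d: dict, depth: int):
        for k, v in d.items():
            if isinstance(v, dict):
                lines.append(f"{'#' * min(depth, 6)} {k}")
                walk(v, depth + 1)
            else:
                lines.append(f"- **{k}**: {v}")
        lines.append("")

    walk(report, 2)
    return "\n".join(lines)


def write_report(report: dict, out_dir) -> tuple[Path, Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    json_path = out / "report.json"
    md_path = out / "report.md"
    with open(json_path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    md_path.write_text(render_markdown(report))
    return json_path, md_path
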