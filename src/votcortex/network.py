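"""Five-node leaky-integrator network for gap and coincidence detection.

The network transforms the relative timing of two spectral events -- a stop
consonant's release burst and the onset of voicing -- into response
*amplitudes* at two temporal-integrator units:

* ``gap``  -- a slow-IPSP microcircuit: the burst excites the gap detector
  directly (fast suprathreshold response) and, one synapse later, inhibits it
  via a dedicated inhibitory unit.  Voicing input arriving while the
  inhibition is still decaying cannot drive a second suprathreshold response,
  so the unit responds weakly and uniformly to short voice-onset times (VOTs)
  and increasingly strongly to long ones.
* ``coinc`` -- a coincidence detector: the burst alone evokes a subthreshold
  EPSP which transiently boosts the unit's sensitivity; voicing arriving
  before the boost has decayed sums with it, so the response is strongest at
  0 ms VOT, graded over short VOTs, and flat across long VOTs.

Activations follow conventional leaky-integrator dynamics on a discrete cycle
clock (1 cycle = 10 ms by default).  Each cycle every unit first decays
toward its resting level and then sums clamped external input with weighted
input from presynaptic units whose *previous-cycle* activation exceeded their
propagation threshold; the result is clipped to the unit's [minimum, maximum]
range.  Simulations are fully deterministic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "UnitParams",
    "NetworkSpec",
    "InputSchedule",
    "SimulationResult",
    "ConstraintReport",
    "default_spec",
    "step",
    "simulate",
    "peak_output",
    "output_onset_cycle",
    "peak_output_cycle",
    "check_constraints",
    "sweep_vots",
]

VOT_GRID_MS = (0, 10, 20, 30, 40, 50)


@dataclass(frozen=True)
class UnitParams:
    """Activation parameters of a single rectified-linear leaky integrator.

    ``resting`` is the level the unit decays back to (by ``decay`` units per
    cycle, never overshooting); ``threshold`` is the propagation threshold a
    unit must reach before it can influence its postsynaptic targets (and
    before its own activation counts as output).
    """

    resting: float
    minimum: float
    maximum: float
    decay: float
    threshold: float

    def __post_init__(self) -> None:
        if not (self.minimum <= self.resting <= self.maximum):
            raise ValueError(
                f"resting level {self.resting} outside [{self.minimum}, {self.maximum}]"
            )
        if self.decay < 0:
            raise ValueError("decay rate must be nonnegative")
        if not (self.minimum <= self.threshold <= self.maximum):
            raise ValueError("propagation threshold outside activation bounds")


@dataclass(frozen=True)
class NetworkSpec:
    """Topology, weights, and per-unit parameters of the five-node network.

    ``weights[j, i]`` is the signed connection from presynaptic unit ``j`` to
    postsynaptic unit ``i`` (inhibitory connections negative).  ``inputs``
    holds the clamp magnitudes and timing used to build an
    :class:`InputSchedule` from a VOT value.
    """

    unit_names: tuple[str, ...]
    unit_params: tuple[UnitParams, ...]
    weights: np.ndarray
    n_cycles: int = 100
    ms_per_cycle: int = 10
    inputs: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.unit_names)
        if len(self.unit_params) != n:
            raise ValueError("one UnitParams required per unit")
        w = np.asarray(self.weights, dtype=float)
        if w.shape != (n, n):
            raise ValueError(f"weight matrix must be {n}x{n}, got {w.shape}")
        object.__setattr__(self, "weights", w)
        if self.n_cycles < 2:
            raise ValueError("need at least two cycles (cycle 1 is rest)")

    @property
    def n_units(self) -> int:
        return len(self.unit_names)

    def index(self, unit: str) -> int:
        try:
            return self.unit_names.index(unit)
        except ValueError:
            raise KeyError(f"unknown unit {unit!r}; have {self.unit_names}") from None

    def weight(self, pre: str, post: str) -> float:
        return float(self.weights[self.index(pre), self.index(post)])

    def params(self, unit: str) -> UnitParams:
        return self.unit_params[self.index(unit)]

    # -- serialization -----------------------------------------------------
    @classmethod
    def from_dict(cls, d: dict) -> "NetworkSpec":
        names = tuple(d["unit_names"])
        params = tuple(
            UnitParams(
                resting=u["resting"],
                minimum=u["minimum"],
                maximum=u["maximum"],
                decay=u["decay"],
                threshold=u["threshold"],
            )
            for u in (d["units"][name] for name in names)
        )
        w = np.zeros((len(names), len(names)))
        for pre, post, value in d["weights"]:
            w[names.index(pre), names.index(post)] = value
        return cls(
            unit_names=names,
            unit_params=params,
            weights=w,
            n_cycles=int(d.get("n_cycles", 100)),
            ms_per_cycle=int(d.get("ms_per_cycle", 10)),
            inputs=dict(d.get("inputs", {})),
        )

    def to_dict(self) -> dict:
        return {
            "unit_names": list(self.unit_names),
            "units": {
                name: {
                    "resting": p.resting,
                    "minimum": p.minimum,
                    "maximum": p.maximum,
                    "decay": p.decay,
                    "threshold": p.threshold,
                }
                for name, p in zip(self.unit_names, self.unit_params)
            },
            "weights": [
                [self.unit_names[j], self.unit_names[i], float(self.weights[j, i])]
                for j in range(self.n_units)
                for i in range(self.n_units)
                if self.weights[j, i] != 0.0
            ],
            "n_cycles": self.n_cycles,
            "ms_per_cycle": self.ms_per_cycle,
            "inputs": dict(self.inputs),
        }

    @classmethod
    def from_json(cls, path) -> "NetworkSpec":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def default_spec() -> NetworkSpec:
    """The packaged default parameter set.

    Values are hand-calibrated so that all four sensitivity constraints of
    :func:`check_constraints` hold and the voicing-category boundary of both
    integrator units falls between 20 and 30 ms VOT.
    """
    text = resources.files("votcortex").joinpath("data/default_network.json").read_text()
    return NetworkSpec.from_dict(json.loads(text))


@dataclass(frozen=True)
class InputSchedule:
    """Per-unit, per-cycle clamped external input (units x cycles)."""

    values: np.ndarray  # (n_units, n_cycles)

    @classmethod
    def empty(cls, spec: NetworkSpec) -> "InputSchedule":
        return cls(np.zeros((spec.n_units, spec.n_cycles)))

    @classmethod
    def from_vot(
        cls,
        spec: NetworkSpec,
        vot_ms: float,
        *,
        burst_magnitude: float | None = None,
        voicing_magnitude: float | None = None,
        burst_onset_cycle: int | None = None,
        voicing_lag_cycles: int | None = None,
    ) -> "InputSchedule":
        """Build the two-clamp schedule for a VOT stimulus.

        The burst input is clamped onto the burst detector at
        ``burst_onset_cycle`` (cycle 2 by default; cycle 1 is the resting
        initialization).  The voicing input is clamped onto the voicing
        detector ``voicing_lag_cycles + vot_ms / ms_per_cycle`` cycles later.
        The one-cycle base lag models the finite rise time of the voicing
        amplitude envelope relative to the transient burst: it guarantees
        that, for a 0 ms VOT, the burst-evoked slow IPSP reaches the gap
        detector no later than the voicing-evoked EPSP, which the slow-IPSP
        gap circuit requires.
        """
        cfg = spec.inputs
        burst_magnitude = cfg.get("burst_magnitude", 1.0) if burst_magnitude is None else burst_magnitude
        voicing_magnitude = (
            cfg.get("voicing_magnitude", 1.0) if voicing_magnitude is None else voicing_magnitude
        )
        burst_onset_cycle = (
            int(cfg.get("burst_onset_cycle", 2)) if burst_onset_cycle is None else burst_onset_cycle
        )
        voicing_lag_cycles = (
            int(cfg.get("voicing_lag_cycles", 1)) if voicing_lag_cycles is None else voicing_lag_cycles
        )

        if vot_ms < 0:
            raise ValueError("vot_ms must be nonnegative")
        lag, rem = divmod(float(vot_ms), spec.ms_per_cycle)
        if rem:
            raise ValueError(
                f"vot_ms={vot_ms} is not a multiple of ms_per_cycle={spec.ms_per_cycle}"
            )
        voicing_cycle = burst_onset_cycle + voicing_lag_cycles + int(lag)
        if voicing_cycle > spec.n_cycles:
            raise ValueError("VOT exceeds the simulation horizon")

        values = np.zeros((spec.n_units, spec.n_cycles))
        values[spec.index("burst_detector"), burst_onset_cycle - 1] = burst_magnitude
        values[spec.index("voicing_detector"), voicing_cycle - 1] = voicing_magnitude
        return cls(values)


@dataclass(frozen=True)
class SimulationResult:
    """Activation and output trajectories of one deterministic simulation.

    ``activation[i, t]`` is unit ``i`` at cycle ``t + 1`` (cycles are 1-based
    to match the convention that cycle 1 is the resting initialization).
    ``output`` equals ``activation`` wherever the unit is at or above its
    propagation threshold and the resting level elsewhere (subthreshold
    traces are drawn at rest).
    """

    spec: NetworkSpec
    activation: np.ndarray  # (n_units, n_cycles)
    output: np.ndarray  # (n_units, n_cycles)

    def unit_activation(self, unit: str) -> np.ndarray:
        return self.activation[self.spec.index(unit)]

    def unit_output(self, unit: str) -> np.ndarray:
        return self.output[self.spec.index(unit)]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, name in enumerate(self.spec.unit_names):
            for t in range(self.spec.n_cycles):
                rows.append(
                    {
                        "unit": name,
                        "cycle": t + 1,
                        "time_ms": t * self.spec.ms_per_cycle,
                        "activation": self.activation[i, t],
                        "output": self.output[i, t],
                    }
                )
        return pd.DataFrame(rows)


def _decay_toward_rest(state: np.ndarray, resting: np.ndarray, decay: np.ndarray) -> np.ndarray:
    delta = state - resting
    step_size = np.minimum(np.abs(delta), decay)
    return state - np.sign(delta) * step_size


def step(state: Sequence[float], spec: NetworkSpec, external: Sequence[float]) -> np.ndarray:
    """Advance all units by one cycle (decay, then input summation).

    Presynaptic units contribute ``w[j, i] * a_j`` only if their
    previous-cycle activation ``a_j`` is at or above their own propagation
    threshold.  External (clamped) input is added unconditionally.  The
    result is clipped once, after summation, to each unit's bounds.
    """
    state = np.asarray(state, dtype=float)
    external = np.asarray(external, dtype=float)
    n = spec.n_units
    if state.shape != (n,) or external.shape != (n,):
        raise ValueError(
            f"state/external must have shape ({n},); got {state.shape} and {external.shape}"
        )
    resting = np.array([p.resting for p in spec.unit_params])
    decay = np.array([p.decay for p in spec.unit_params])
    thresh = np.array([p.threshold for p in spec.unit_params])
    lo = np.array([p.minimum for p in spec.unit_params])
    hi = np.array([p.maximum for p in spec.unit_params])

    decayed = _decay_toward_rest(state, resting, decay)
    gate = state >= thresh  # previous-cycle activations gate propagation
    internal = (state * gate) @ spec.weights
    return np.clip(decayed + external + internal, lo, hi)


def simulate(
    spec: NetworkSpec,
    vot_ms: float | None = None,
    schedule: InputSchedule | None = None,
) -> SimulationResult:
    """Run the network for ``spec.n_cycles`` from the all-resting state.

    Either a VOT value (converted to the standard two-clamp schedule) or an
    explicit :class:`InputSchedule` may be given; with neither, the network
    receives no input and every trajectory is constant at rest.
    """
    if schedule is None:
        if vot_ms is None:
            schedule = InputSchedule.empty(spec)
        else:
            schedule = InputSchedule.from_vot(spec, vot_ms)
    values = np.asarray(schedule.values, dtype=float)
    if values.shape != (spec.n_units, spec.n_cycles):
        raise ValueError("schedule shape does not match spec")

    a = np.empty((spec.n_units, spec.n_cycles))
    a[:, 0] = [p.resting for p in spec.unit_params]
    for t in range(1, spec.n_cycles):
        a[:, t] = step(a[:, t - 1], spec, values[:, t])

    thresh = np.array([p.threshold for p in spec.unit_params])[:, None]
    resting = np.array([p.resting for p in spec.unit_params])[:, None]
    output = np.where(a >= thresh, a, resting)
    return SimulationResult(spec=spec, activation=a, output=output)


def peak_output(result: SimulationResult, unit: str) -> float:
    """Maximum output over cycles; the resting level if never suprathreshold."""
    return float(result.unit_output(unit).max())


def output_onset_cycle(result: SimulationResult, unit: str) -> int | None:
    """First 1-based cycle with activation at/above threshold, else None."""
    i = result.spec.index(unit)
    thresh = result.spec.unit_params[i].threshold
    above = np.nonzero(result.activation[i] >= thresh)[0]
    return int(above[0]) + 1 if above.size else None


def peak_output_cycle(result: SimulationResult, unit: str) -> int | None:
    """1-based cycle of the maximum output (earliest on ties); None if flat.

    Reported for completeness: the model predicts VOT-dependent peak latency
    in both integrator units, a prediction the analysis pipeline makes no
    claim about.
    """
    i = result.spec.index(unit)
    out = result.output[i]
    if np.all(out == result.spec.unit_params[i].resting):
        return None
    return int(np.argmax(out)) + 1


def sweep_vots(spec: NetworkSpec, vots_ms: Sequence[float] = VOT_GRID_MS) -> pd.DataFrame:
    """Simulate each VOT and tabulate per-unit peak output and onset cycle."""
    rows = []
    for vot in vots_ms:
        res = simulate(spec, vot)
        for unit in spec.unit_names:
            rows.append(
                {
                    "vot_ms": vot,
                    "unit": unit,
                    "peak_output": peak_output(res, unit),
                    "onset_cycle": output_onset_cycle(res, unit),
                    "peak_cycle": peak_output_cycle(res, unit),
                }
            )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class ConstraintReport:
    name: str
    satisfied: bool
    detail: str


def check_constraints(spec: NetworkSpec) -> list[ConstraintReport]:
    """Evaluate the four parameter-sensitivity constraints.

    1. The coincidence detector's propagation threshold must exceed the
       burst->coinc weight (burst alone stays subthreshold).
    2. The gap detector's threshold must be below the burst->gap weight
       (fast suprathreshold burst response of the slow-IPSP circuit).
    3. The coinc decay/weight balance must place the category boundary
       between 20 and 30 ms: peak outputs graded over 0-20 ms and flat over
       30-50 ms (checked behaviorally by simulation).
    4. The gap decay/inhibition/voicing-weight balance must place the gap
       boundary between 20 and 30 ms: uniform weak responses for 0-20 ms and
       graded stronger responses for 30-50 ms (checked by simulation).
    """
    w_bc = spec.weight("burst_detector", "coinc")
    w_bg = spec.weight("burst_detector", "gap")
    th_c = spec.params("coinc").threshold
    th_g = spec.params("gap").threshold

    reports = [
        ConstraintReport(
            "theta_coinc_gt_w_burst_coinc",
            th_c > w_bc,
            f"theta_coinc={th_c} vs w_burst->coinc={w_bc}",
        ),
        ConstraintReport(
            "theta_gap_lt_w_burst_gap",
            th_g < w_bg,
            f"theta_gap={th_g} vs w_burst->gap={w_bg}",
        ),
    ]

    table = sweep_vots(spec)
    gap = table[table.unit == "gap"].set_index("vot_ms").peak_output
    coinc = table[table.unit == "coinc"].set_index("vot_ms").peak_output
    voiced, voiceless = [0, 10, 20], [30, 40, 50]

    coinc_ok = (
        all(coinc[a] > coinc[b] for a, b in zip(voiced[:-1], voiced[1:]))
        and coinc[20] > coinc[30]
        and np.isclose(coinc[30], coinc[40])
        and np.isclose(coinc[40], coinc[50])
    )
    reports.append(
        ConstraintReport(
            "coinc_boundary_20_30",
            bool(coinc_ok),
            "coinc peaks " + ", ".join(f"{v}ms={coinc[v]:.3g}" for v in VOT_GRID_MS),
        )
    )

    gap_ok = (
        np.isclose(gap[0], gap[10])
        and np.isclose(gap[10], gap[20])
        and gap[30] > gap[20]
        and gap[30] <= gap[40] <= gap[50]
        and min(gap[v] for v in voiceless) > max(gap[v] for v in voiced)
    )
    reports.append(
        ConstraintReport(
            "gap_boundary_20_30",
            bool(gap_ok),
            "gap peaks " + ", ".join(f"{v}ms={gap[v]:.3g}" for v in VOT_GRID_MS),
        )
    )
    return reports
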