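"""Behavioral trial exclusion and psychometric category-boundary fitting.

The identification data are binary /ba/-/pa/ responses along the six-step
VOT continuum.  After excluding omissions and reaction-time outliers, a
logistic model

    P(/pa/) = logistic(beta0 + u_p + beta_vot * VOT)

is fit with a shared slope and per-participant intercept offsets u_p.  The
offsets carry a Gaussian (ridge) penalty, a penalized-likelihood
approximation to random participant intercepts; an unpenalized
fixed-intercept mode is also available.  The voicing category boundary is
the 50% crossover chi = -beta0 / beta_vot, per participant using the
adjusted intercept beta0 + u_p.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = ["PsychometricFit", "exclude_trials", "fit_psychometric"]

RT_SD_LIMIT = 3.0


def exclude_trials(events: pd.DataFrame, rt_sd_limit: float = RT_SD_LIMIT) -> tuple[pd.DataFrame, dict]:
    """Drop no-response trials and per-participant reaction-time outliers.

    A trial is an RT outlier when |RT - participant mean| exceeds
    ``rt_sd_limit`` participant SDs (SD computed over that participant's
    responded trials; zero SD means no outliers).  Participants left with
    fewer than 2 responded trials are flagged and removed entirely.
    """
    if "response" not in events or "rt_ms" not in events:
        raise ValueError("events must have 'response' and 'rt_ms' columns")
    responded = events[events.response.notna()].copy()
    n_omitted = len(events) - len(responded)

    keep_rows = []
    n_rt_outliers = 0
    flagged = []
    for pid, grp in responded.groupby("participant"):
        if len(grp) < 2:
            flagged.append(pid)
            continue
        mu, sd = grp.rt_ms.mean(), grp.rt_ms.std(ddof=1)
        if sd > 0:
            ok = (grp.rt_ms - mu).abs() <= rt_sd_limit * sd
        else:
            ok = pd.Series(True, index=grp.index)
        n_rt_outliers += int((~ok).sum())
        keep_rows.append(grp[ok])
    if not keep_rows:
        raise ValueError("no participants with enough responded trials")
    clean = pd.concat(keep_rows).sort_index().reset_index(drop=True)
    log = {
        "n_input": len(events),
        "n_omitted": n_omitted,
        "n_rt_outliers": n_rt_outliers,
        "excluded_participants": flagged,
        "n_kept": len(clean),
    }
    return clean, log


@dataclass(frozen=True)
class PsychometricFit:
    beta0: float
    beta_vot: float
    offsets: dict[str, float]
    boundary_ms: float
    boundary_by_participant: dict[str, float]
    mode: str
    converged: bool
    separation_flag: bool
    log: dict = field(default_factory=dict)


def fit_psychometric(
    events: pd.DataFrame,
    penalty: float = 1.0,
    mode: str = "penalized",
) -> PsychometricFit:
    """Fit the logistic psychometric model and derive category boundaries.

    ``penalty`` is the inverse variance of the Gaussian penalty on the
    per-participant offsets (mode='penalized'); mode='fixed' drops the
    penalty and anchors the first participant's offset at zero, making the
    remaining offsets fixed-effect contrasts.  Complete separation is
    flagged (implausibly steep penalized slope) rather than an error.
    """
    ev = events[events.response.notna()]
    if len(ev) == 0:
        raise ValueError("no responded trials to fit")
    vot = ev.vot_ms.to_numpy(dtype=float)
    y = ev.response.to_numpy(dtype=float)
    if len(np.unique(vot)) < 2:
        raise ValueError("need at least 2 VOT levels")
    pids = sorted(ev.participant.unique())
    p_idx = ev.participant.map({p: i for i, p in enumerate(pids)}).to_numpy()
    n_p = len(pids)

    if mode not in ("penalized", "fixed"):
        raise ValueError("mode must be 'penalized' or 'fixed'")
    free_offsets = n_p if mode == "penalized" else n_p - 1

    def unpack(theta):
        b0, bv = theta[0], theta[1]
        if mode == "penalized":
            u = theta[2:]
        else:
            u = np.concatenate([[0.0], theta[2:]])
        return b0, bv, u

    def negloglik(theta):
        b0, bv, u = unpack(theta)
        eta = b0 + bv * vot + u[p_idx]
        # stable log-likelihood of the Bernoulli-logistic model
        nll = np.sum(np.logaddexp(0.0, eta) - y * eta)
        if mode == "penalized":
            nll += 0.5 * penalty * np.sum(u**2)
        nll += 1e-8 * (b0**2 + bv**2)  # minute ridge for numeric stability
        return nll

    def grad(theta):
        b0, bv, u = unpack(theta)
        eta = b0 + bv * vot + u[p_idx]
        r = 1.0 / (1.0 + np.exp(-eta)) - y
        g0 = r.sum() + 2e-8 * b0
        gv = (r * vot).sum() + 2e-8 * bv
        gu = np.bincount(p_idx, weights=r, minlength=n_p)
        if mode == "penalized":
            gu = gu + penalty * u
            return np.concatenate([[g0, gv], gu])
        return np.concatenate([[g0, gv], gu[1:]])

    theta0 = np.zeros(2 + free_offsets)
    res = optimize.minimize(negloglik, theta0, jac=grad, method="L-BFGS-B")
    b0, bv, u = unpack(res.x)
    # a psychometric transition narrower than ~3 ms (|slope| > 1.5/ms) is far
    # outside the plausible range and signals (quasi-)complete separation
    separation = bool(abs(bv) > 1.5)

    if bv != 0:
        boundary = -b0 / bv
        by_p = {p: float(-(b0 + u[i]) / bv) for i, p in enumerate(pids)}
    else:
        boundary = np.nan
        by_p = {p: np.nan for p in pids}

    return PsychometricFit(
        beta0=float(b0),
        beta_vot=float(bv),
        offsets={p: float(u[i]) for i, p in enumerate(pids)},
        boundary_ms=float(boundary),
        boundary_by_participant=by_p,
        mode=mode,
        converged=bool(res.success),
        separation_flag=separation,
        log={"n_trials": len(ev), "n_participants": n_p, "nll": float(res.fun)},
    )
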