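"""Pseudo individual-patient data from digitized Kaplan-Meier curves.

Published survival figures report the Kaplan-Meier (KM) estimate and a
numbers-at-risk table, but not the underlying patient records.  This module
rebuilds per-subject ``(time, event)`` records from those two artifacts by
allocating events and censorings within each risk-table interval:

* events in interval *j* follow the relative drop of the digitized survival,
  counted against the censoring-depleted risk set
  (``e_j = round(n_{j+1} * (S(start_j)/S(end_j) - 1))``, the KM identity
  solved for the event count) and are placed at the digitized step times in
  proportion to the step drops;
* censorings are the residual decline in numbers at risk,
  ``c_j = n_j - n_{j+1} - e_j`` (floored at zero), spread uniformly across
  the interval;
* any rounding residue is absorbed as censorings at the end of follow-up so
  that the record count equals the initial cohort size exactly.

The reconstruction is validated by re-estimating the KM curve from the
pseudo-IPD and comparing it with the digitized input.

All times are in weeks internally; month-scaled inputs are converted at
1 month = 4.348 weeks so that 3-week model-cycle arithmetic stays exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter

__all__ = [
    "WEEKS_PER_MONTH",
    "months_to_weeks",
    "weeks_to_months",
    "DigitizedCurve",
    "RiskTable",
    "PseudoIPD",
    "KMCurve",
    "reconstruct_pseudo_ipd",
    "km_estimate",
    "km_median",
    "read_curve",
    "read_risk_table",
    "write_ipd",
    "read_ipd",
]

WEEKS_PER_MONTH = 4.348


def months_to_weeks(months):
    """Convert month-scaled times to weeks (1 month = 4.348 weeks)."""
    return np.asarray(months, dtype=float) * WEEKS_PER_MONTH


def weeks_to_months(weeks):
    return np.asarray(weeks, dtype=float) / WEEKS_PER_MONTH


def _as_float_array(x) -> np.ndarray:
    return np.atleast_1d(np.asarray(x, dtype=float))


@dataclass(frozen=True)
class DigitizedCurve:
    """An ordered set of (time, survival) points read off a published KM plot.

    Times are in weeks, strictly increasing, starting at ``(0, 1.0)``;
    survival is non-increasing within ``[0, 1]``.
    """

    times: np.ndarray
    survival: np.ndarray
    arm: str = ""
    endpoint: str = ""

    def __post_init__(self) -> None:
        t = _as_float_array(self.times)
        s = _as_float_array(self.survival)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "survival", s)
        if t.shape != s.shape or t.ndim != 1:
            raise ValueError("times and survival must be 1-d arrays of equal length")
        if t.size == 0:
            raise ValueError("digitized curve has no points")
        if not np.isclose(t[0], 0.0):
            raise ValueError("digitized curve must start at time 0")
        if not np.isclose(s[0], 1.0):
            raise ValueError("digitized curve must start at survival 1.0")
        if np.any(np.diff(t) <= 0):
            raise ValueError("digitized times must be strictly increasing")
        if np.any(np.diff(s) > 1e-12):
            raise ValueError("digitized survival must be non-increasing")
        if np.any(s < -1e-12) or np.any(s > 1 + 1e-12):
            raise ValueError("survival probabilities must lie in [0, 1]")

    def survival_at(self, t) -> np.ndarray:
        """Right-continuous step interpolation of the digitized curve."""
        t = np.asarray(t, dtype=float)
        if np.any(t < -1e-12):
            raise ValueError("negative evaluation time")
        idx = np.searchsorted(self.times, t, side="right") - 1
        idx = np.clip(idx, 0, self.times.size - 1)
        return self.survival[idx]


@dataclass(frozen=True)
class RiskTable:
    """Numbers at risk at the start of each reporting interval."""

    times: np.ndarray
    n_at_risk: np.ndarray

    def __post_init__(self) -> None:
        t = _as_float_array(self.times)
        n = np.atleast_1d(np.asarray(self.n_at_risk))
        if np.any(np.abs(n - np.round(n)) > 1e-9):
            raise ValueError("numbers at risk must be integers")
        n = np.round(n).astype(int)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "n_at_risk", n)
        if t.shape != n.shape or t.ndim != 1 or t.size == 0:
            raise ValueError("times and n_at_risk must be matching non-empty 1-d arrays")
        if np.any(np.diff(t) <= 0):
            raise ValueError("risk-table times must be strictly increasing")
        if np.any(np.diff(n) > 0):
            raise ValueError("numbers at risk must be non-increasing")
        if np.any(n < 0):
            raise ValueError("numbers at risk must be non-negative")

    @property
    def n(self) -> int:
        """Initial cohort size (first numbers-at-risk entry)."""
        return int(self.n_at_risk[0])


@dataclass(frozen=True)
class PseudoIPD:
    """Per-subject (time, event) records, real or reconstructed."""

    times: np.ndarray
    events: np.ndarray
    arm: str = ""
    endpoint: str = ""

    def __post_init__(self) -> None:
        t = _as_float_array(self.times)
        e = np.atleast_1d(np.asarray(self.events))
        if not np.all(np.isin(e, (0, 1))):
            raise ValueError("event flags must be 0 or 1")
        e = e.astype(int)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "events", e)
        if t.shape != e.shape or t.ndim != 1:
            raise ValueError("times and events must be 1-d arrays of equal length")
        if np.any(t <= 0):
            raise ValueError("all times must be positive")

    @property
    def n(self) -> int:
        return int(self.times.size)

    @property
    def n_events(self) -> int:
        return int(self.events.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.times,
                "event": self.events,
                "arm": self.arm,
                "endpoint": self.endpoint,
            }
        )


def _largest_remainder(quotas: np.ndarray, total: int) -> np.ndarray:
    """Integer allocation proportional to ``quotas`` summing exactly to ``total``."""
    if quotas.sum() <= 0:
        out = np.zeros(quotas.size, dtype=int)
        out[-1] = total
        return out
    scaled = total * quotas / quotas.sum()
    base = np.floor(scaled).astype(int)
    short = total - int(base.sum())
    if short > 0:
        frac = scaled - base
        idx = np.argsort(-frac, kind="stable")[:short]
        base[idx] += 1
    return base


def reconstruct_pseudo_ipd(curve: DigitizedCurve, risk: RiskTable) -> PseudoIPD:
    """Allocate events and censorings per risk-table interval.

    Within interval *j* (from one risk-table time to the next, the last
    interval extending to the end of the digitized curve), the event count
    follows the relative drop of the digitized survival and the censoring
    count the residual decline of the numbers at risk.  Events sit at the
    digitized step times; censorings are spread uniformly over the interval.
    The output always contains exactly ``risk.n`` records.
    """
    if risk.times[0] > curve.times[0] + 1e-9:
        raise ValueError("risk table must cover the curve from its first time point")
    t_max = float(curve.times[-1])
    starts = risk.times
    ends = np.append(risk.times[1:], max(t_max, risk.times[-1]))
    nj = risk.n_at_risk
    drops = -np.diff(curve.survival)  # >= 0 at each digitized step

    remaining = risk.n
    out_times: list[np.ndarray] = []
    out_events: list[np.ndarray] = []
    for j in range(starts.size):
        if remaining == 0:
            break
        start, end = float(starts[j]), float(ends[j])
        s0 = float(curve.survival_at(start))
        s1 = float(curve.survival_at(end)) if end >= start else s0
        last = j == starts.size - 1
        # Censorings inside an interval precede the digitized event steps in
        # time, so the event count is taken against the censoring-depleted
        # risk set: e = n_next * (S0/S1 - 1) reproduces the KM drop S1/S0
        # exactly once the records are re-estimated.  The final interval has
        # no next risk entry; its events follow the drop of the remaining
        # cohort and its censorings sit at the upper boundary (end of
        # follow-up), absorbing the rounding residue.
        if s0 <= 0:
            e_j = 0
        elif last:
            e_j = int(round(remaining * (1.0 - s1 / s0)))
        elif s1 <= 0:
            e_j = remaining  # curve exhausted: everyone left dies here
        else:
            e_j = int(round(int(nj[j + 1]) * (s0 - s1) / s1))
        e_j = min(max(e_j, 0), remaining)
        if not last:
            c_j = int(min(max(int(nj[j]) - int(nj[j + 1]) - e_j, 0), remaining - e_j))
        else:
            c_j = remaining - e_j
        if e_j > 0:
            in_interval = (curve.times[1:] > start + 1e-12) & (curve.times[1:] <= end + 1e-12)
            step_times = curve.times[1:][in_interval & (drops > 0)]
            step_drops = drops[in_interval & (drops > 0)]
            if step_times.size == 0:
                event_times = np.full(e_j, end)
            else:
                alloc = _largest_remainder(step_drops, e_j)
                event_times = np.repeat(step_times, alloc)
            out_times.append(event_times)
            out_events.append(np.ones(e_j, dtype=int))
        if c_j > 0:
            if last or end <= start + 1e-12:
                cens = np.full(c_j, max(end, 1e-9))
            else:
                cens = start + (np.arange(c_j) + 0.5) / c_j * (end - start)
            out_times.append(cens)
            out_events.append(np.zeros(c_j, dtype=int))
        remaining -= e_j + c_j
    if remaining > 0:  # defensive: risk table shorter than the curve
        out_times.append(np.full(remaining, max(t_max, float(ends[-1]))))
        out_events.append(np.zeros(remaining, dtype=int))

    times = np.concatenate(out_times)
    events = np.concatenate(out_events)
    times = np.maximum(times, 1e-9)
    order = np.argsort(times, kind="stable")
    return PseudoIPD(times[order], events[order], arm=curve.arm, endpoint=curve.endpoint)


@dataclass(frozen=True)
class KMCurve:
    """Right-continuous Kaplan-Meier step function."""

    times: np.ndarray
    survival: np.ndarray

    def __call__(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.times, t, side="right") - 1
        out = np.where(idx < 0, 1.0, self.survival[np.clip(idx, 0, self.times.size - 1)])
        return out if out.ndim else float(out)

    def median(self) -> float:
        """First time at which survival drops to 0.5 or below (nan if never)."""
        below = np.nonzero(self.survival <= 0.5)[0]
        return float(self.times[below[0]]) if below.size else float("nan")


def km_estimate(ipd: PseudoIPD) -> KMCurve:
    """Product-limit survival estimate of a pseudo-IPD sample."""
    if ipd.n == 0:
        raise ValueError("cannot estimate a survival curve from zero records")
    kmf = KaplanMeierFitter()
    kmf.fit(ipd.times, ipd.events)
    sf = kmf.survival_function_
    return KMCurve(sf.index.to_numpy(dtype=float), sf.iloc[:, 0].to_numpy(dtype=float))


def km_median(ipd: PseudoIPD) -> float:
    return km_estimate(ipd).median()


# ---------------------------------------------------------------------------
# delimited-text interfaces


def read_curve(path, arm: str = "", endpoint: str = "") -> DigitizedCurve:
    df = pd.read_csv(path)
    return DigitizedCurve(df["time"].to_numpy(), df["survival"].to_numpy(), arm=arm, endpoint=endpoint)


def write_curve(path, curve: DigitizedCurve) -> None:
    pd.DataFrame({"time": curve.times, "survival": curve.survival}).to_csv(path, index=False)


def read_risk_table(path) -> RiskTable:
    df = pd.read_csv(path)
    return RiskTable(df["time"].to_numpy(), df["n_at_risk"].to_numpy())


def write_risk_table(path, risk: RiskTable) -> None:
    pd.DataFrame({"time": risk.times, "n_at_risk": risk.n_at_risk}).to_csv(path, index=False)


def write_ipd(path, ipds: Iterable[PseudoIPD]) -> None:
    pd.concat([ipd.to_frame() for ipd in ipds], ignore_index=True).to_csv(path, index=False)


def read_ipd(path) -> dict[tuple[str, str], PseudoIPD]:
    """Read an IPD table back as ``{(arm, endpoint): PseudoIPD}``."""
    df = pd.read_csv(path)
    out = {}
    for (arm, endpoint), grp in df.groupby(["arm", "endpoint"], sort=True):
        out[(str(arm), str(endpoint))] = PseudoIPD(
            grp["time"].to_numpy(), grp["event"].to_numpy(), arm=str(arm), endpoint=str(endpoint)
        )
    return out
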