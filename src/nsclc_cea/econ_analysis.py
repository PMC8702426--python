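"""Incremental cost-effectiveness, tornado DSA, PSA and CEACs.

The incremental cost-effectiveness ratio (ICER) between two strategies is
``(cost_a - cost_b) / (qaly_a - qaly_b)``; a strategy that is cheaper and at
least as effective dominates.  One-way deterministic sensitivity analysis
re-evaluates the model at each parameter's low and high bound (tornado
entries sorted by ICER spread).  Probabilistic sensitivity analysis draws
costs from Gamma and probabilities/utilities from Beta distributions
moment-matched to the base value and an SD of (high - low)/3.92 (the printed
range read as a 95% interval), and summarizes the draws as a
cost-effectiveness acceptability curve: the fraction of draws with positive
net monetary benefit ``wtp * dQALY - dCost`` at each willingness-to-pay.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .markov_engine import EconOutcome

__all__ = [
    "IncrementalResult",
    "DsaSpec",
    "TornadoEntry",
    "ParamSpec",
    "PsaResult",
    "incremental",
    "one_way_dsa",
    "sample_psa_draw",
    "run_psa_ceac",
    "tornado_frame",
]


@dataclass(frozen=True)
class IncrementalResult:
    """Pairwise comparison a vs b: deltas plus an ICER or dominance label."""

    delta_cost: float
    delta_ly: float
    delta_qaly: float
    label: str  # "icer" | "dominant" | "dominated" | "undefined" | "equivalent"
    icer: Optional[float]


def incremental(a: EconOutcome, b: EconOutcome) -> IncrementalResult:
    """Componentwise difference ``a - b`` with ICER / dominance labelling.

    ``dominant``: a costs no more and yields no fewer QALYs (and differs);
    ``dominated``: the reverse; ``undefined``: a cost difference with zero
    QALY difference (no division performed).  In the remaining quadrants the
    ratio ``dCost/dQALY`` is reported (the northeast quadrant is the usual
    buy-more-health case; the southwest ratio reads as savings per QALY
    forgone).
    """
    dc = a.cost - b.cost
    dly = a.ly - b.ly
    dq = a.qaly - b.qaly
    if dc == 0.0 and dq == 0.0:
        return IncrementalResult(dc, dly, dq, "equivalent", None)
    if dc <= 0.0 and dq >= 0.0:
        return IncrementalResult(dc, dly, dq, "dominant", None)
    if dc >= 0.0 and dq <= 0.0:
        return IncrementalResult(dc, dly, dq, "dominated", None)
    if dq == 0.0:
        return IncrementalResult(dc, dly, dq, "undefined", None)
    return IncrementalResult(dc, dly, dq, "icer", dc / dq)


@dataclass(frozen=True)
class DsaSpec:
    """A one-way sensitivity range for a named parameter."""

    name: str
    base: float
    low: float
    high: float

    def __post_init__(self) -> None:
        if not self.low <= self.base <= self.high:
            raise ValueError(f"{self.name}: bounds must satisfy low <= base <= high")


@dataclass(frozen=True)
class TornadoEntry:
    name: str
    icer_low: float
    icer_high: float
    spread: float
    error: Optional[str] = None


def _icer_number(r: IncrementalResult) -> float:
    """Numeric ICER for tornado ordering; dominance maps to signed infinity."""
    if r.label == "icer":
        return float(r.icer)
    if r.label == "dominant":
        return -np.inf
    if r.label == "dominated":
        return np.inf
    return np.nan


def one_way_dsa(
    evaluator: Callable[[Mapping[str, float]], IncrementalResult],
    specs: Sequence[DsaSpec],
) -> list[TornadoEntry]:
    """Re-evaluate the model at each parameter bound, others held at base.

    ``evaluator`` maps a dict of parameter overrides to an
    :class:`IncrementalResult`; ``evaluator({})`` is the base case and must
    succeed.  Entries are sorted by decreasing ICER spread; evaluation
    failures are flagged on the entry rather than dropped.
    """
    evaluator({})  # base case must evaluate
    entries = []
    for spec in specs:
        values = []
        error = None
        for bound in (spec.low, spec.high):
            try:
                values.append(_icer_number(evaluator({spec.name: bound})))
            except Exception as exc:  # noqa: BLE001 - flagged, not dropped
                values.append(np.nan)
                error = f"{type(exc).__name__}: {exc}"
        lo, hi = values
        spread = abs(hi - lo) if np.isfinite(hi - lo) else np.inf
        if np.isnan(spread):
            spread = 0.0
        entries.append(TornadoEntry(spec.name, lo, hi, spread, error))
    return sorted(entries, key=lambda e: (e.error is not None, -e.spread))


def tornado_frame(entries: Sequence[TornadoEntry]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"parameter": e.name, "icer_low": e.icer_low, "icer_high": e.icer_high, "spread": e.spread, "error": e.error}
            for e in entries
        ]
    )


@dataclass(frozen=True)
class ParamSpec:
    """An uncertain model input with its PSA distribution family."""

    name: str
    base: float
    low: float
    high: float
    dist: str  # "gamma" | "beta" | "fixed"

    def __post_init__(self) -> None:
        if self.dist not in ("gamma", "beta", "fixed"):
            raise ValueError(f"{self.name}: unknown distribution {self.dist!r}")
        if not self.low <= self.base <= self.high:
            raise ValueError(f"{self.name}: bounds must satisfy low <= base <= high")
        if self.dist == "beta" and not (0.0 <= self.low and self.high <= 1.0):
            raise ValueError(f"{self.name}: beta-distributed inputs must lie in [0, 1]")

    @property
    def sd(self) -> float:
        # printed range read as a 95% interval
        return (self.high - self.low) / 3.92

    def to_dsa(self) -> DsaSpec:
        return DsaSpec(self.name, self.base, self.low, self.high)


def sample_psa_draw(specs: Sequence[ParamSpec], rng: np.random.Generator) -> dict[str, float]:
    """One joint parameter draw (Gamma for costs, Beta for probabilities).

    Moment matching: distribution mean equals the base value and SD equals
    (high - low)/3.92; a zero SD or a ``fixed`` tag reproduces the base
    value.  A Beta SD too large for its mean raises, naming the parameter.
    """
    draw: dict[str, float] = {}
    for spec in specs:
        mean, sd = spec.base, spec.sd
        if spec.dist == "fixed" or sd == 0.0:
            draw[spec.name] = mean
        elif spec.dist == "gamma":
            if mean <= 0:
                raise ValueError(f"{spec.name}: gamma moment matching needs a positive mean")
            shape = (mean / sd) ** 2
            scale = sd**2 / mean
            draw[spec.name] = float(rng.gamma(shape, scale))
        else:  # beta
            var = sd**2
            if mean <= 0.0 or mean >= 1.0 or var >= mean * (1.0 - mean):
                raise ValueError(f"{spec.name}: beta moment matching infeasible (mean {mean}, sd {sd})")
            nu = mean * (1.0 - mean) / var - 1.0
            draw[spec.name] = float(rng.beta(mean * nu, (1.0 - mean) * nu))
    return draw


@dataclass(frozen=True)
class PsaResult:
    """Per-draw incremental outcomes plus the acceptability curve."""

    draws: pd.DataFrame  # columns: draw, delta_cost, delta_ly, delta_qaly
    ceac: pd.DataFrame  # columns: wtp, probability
    n_requested: int
    n_failed: int

    def probability_at(self, wtp: float) -> float:
        i = int(np.argmin(np.abs(self.ceac["wtp"].to_numpy() - wtp)))
        return float(self.ceac["probability"].iloc[i])


def run_psa_ceac(
    evaluator: Callable[[Mapping[str, float]], IncrementalResult],
    specs: Sequence[ParamSpec],
    n_draws: int = 1000,
    wtp_grid: Optional[np.ndarray] = None,
    seed: int = 0,
) -> PsaResult:
    """Monte-Carlo PSA with a cost-effectiveness acceptability curve.

    Every draw is sampled before evaluation so the draw sequence depends on
    the seed only; failed evaluations are excluded and counted.
    """
    if wtp_grid is None:
        wtp_grid = np.arange(0.0, 100001.0, 1000.0)
    rng = np.random.default_rng(seed)
    rows = []
    n_failed = 0
    for i in range(n_draws):
        draw = sample_psa_draw(specs, rng)
        try:
            r = evaluator(draw)
        except Exception:  # noqa: BLE001 - excluded and reported
            n_failed += 1
            continue
        rows.append({"draw": i, "delta_cost": r.delta_cost, "delta_ly": r.delta_ly, "delta_qaly": r.delta_qaly})
    draws = pd.DataFrame(rows, columns=["draw", "delta_cost", "delta_ly", "delta_qaly"])
    dc = draws["delta_cost"].to_numpy()
    dq = draws["delta_qaly"].to_numpy()
    probs = [float(np.mean(wtp * dq - dc > 0)) if dc.size else np.nan for wtp in wtp_grid]
    ceac = pd.DataFrame({"wtp": wtp_grid, "probability": probs})
    return PsaResult(draws, ceac, n_requested=n_draws, n_failed=n_failed)
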