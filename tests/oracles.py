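"""Independent brute-force oracles used to validate the package's routines.

Everything here is deliberately written in the most transparent way possible
(per-event-time loops, explicit risk-set masks, plain Monte Carlo) and
shares no code with the implementation under test.
"""

from __future__ import annotations

import numpy as np


def km_oracle(times, events):
    """Hand-rolled product-limit estimator -> (times, survival) step arrays."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    event_times = np.unique(times[events == 1])
    s = 1.0
    out_t, out_s = [0.0], [1.0]
    for t in event_times:
        at_risk = int(np.sum(times >= t))
        d = int(np.sum((times == t) & (events == 1)))
        s *= 1.0 - d / at_risk
        out_t.append(float(t))
        out_s.append(s)
    return np.array(out_t), np.array(out_s)


def km_eval(step_t, step_s, t):
    """Right-continuous evaluation of a (times, survival) step function."""
    t = np.asarray(t, dtype=float)
    idx = np.searchsorted(step_t, t, side="right") - 1
    return step_s[np.clip(idx, 0, step_t.size - 1)]


def logrank_oracle(times1, events1, times2, events2):
    """Per-event-time 2x2 table accumulation of the log-rank statistic.

    Returns (E1 - O1) / sqrt(V): positive when group 1 fares better.
    """
    t1, e1 = np.asarray(times1, float), np.asarray(events1, int)
    t2, e2 = np.asarray(times2, float), np.asarray(events2, int)
    all_t = np.concatenate([t1, t2])
    all_e = np.concatenate([e1, e2])
    o1 = e1_exp = var = 0.0
    for t in np.unique(all_t[all_e == 1]):
        n1 = int(np.sum(t1 >= t))
        n2 = int(np.sum(t2 >= t))
        n = n1 + n2
        d1 = int(np.sum((t1 == t) & (e1 == 1)))
        d = d1 + int(np.sum((t2 == t) & (e2 == 1)))
        o1 += d1
        e1_exp += d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return (e1_exp - o1) / np.sqrt(var)


def cox_partial_loglik_oracle(times, events, group, beta):
    """Breslow partial log-likelihood for a binary covariate, per-event loop."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    group = np.asarray(group, int)
    ll = 0.0
    for i in np.nonzero(events == 1)[0]:
        risk = times >= times[i]
        denom = np.sum(np.exp(beta * group[risk]))
        ll += beta * group[i] - np.log(denom)
    return ll


def cox_grid_oracle(times, events, group, lo=-3.0, hi=3.0, step=1e-3):
    """Grid maximization of the partial likelihood over log-HR."""
    betas = np.arange(lo, hi + 0.5 * step, step)
    lls = np.array([cox_partial_loglik_oracle(times, events, group, b) for b in betas])
    return float(betas[np.argmax(lls)])


def markov_microsim_oracle(p_death, p_progress, n_subjects, n_cycles, rng):
    """Individual-level Monte Carlo of the 3-state model.

    Returns occupancy fractions (n_cycles + 1, 3); state 0 = PFS, 1 = PD,
    2 = Death.  Death competes first, matching a single death hazard applied
    from both alive states.
    """
    state = np.zeros(n_subjects, dtype=np.int8)
    occ = [np.array([1.0, 0.0, 0.0])]
    for k in range(n_cycles):
        u = rng.random(n_subjects)
        v = rng.random(n_subjects)
        alive = state != 2
        dying = alive & (u < p_death[k])
        progressing = (state == 0) & ~dying & (v < p_progress[k] / max(1.0 - p_death[k], 1e-300))
        state = np.where(dying, 2, np.where(progressing, 1, state))
        occ.append(np.array([np.mean(state == 0), np.mean(state == 1), np.mean(state == 2)]))
    return np.vstack(occ)
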