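"""Nonparametric estimators feeding the dynamic pseudo-observations.

Two routes to the windowed category probabilities at a landmark:

* **Ordered-event Kaplan-Meier**: the probability of exactly ``k`` recurrent
  events in ``(s, s+w]`` is the difference ``S*_{k+1}(w) - S*_k(w)`` of the
  product-limit survival curves of the relabeled k-th and (k+1)-th event
  times.  Valid when the terminal event is treated as censoring.
* **Aalen-Johansen product-integral**: state-occupation probabilities of the
  forward chain ``0 -> 1 -> ... -> k_max`` (optionally with an absorbing
  death state reachable from every transient state).  By the Datta-Satten
  result the product-integral estimates state occupation consistently even
  for non-Markov processes, so it is used here without a Markov assumption.

The leave-one-out variants required by the jackknife are computed by honest
re-estimation: every replica uses its own risk-set and transition counts.
They are evaluated for all replicas in one vectorised pass (``*_loo``
helpers), which is numerically identical to deleting each subject and
re-running the estimator from scratch — equality with the literal deletion
loop is asserted in the test suite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "SurvivalCurve",
    "TransitionMatrixPath",
    "km_curve",
    "km_survival",
    "ordered_event_probabilities",
    "aj_transition_path",
    "aj_state_occupation",
]


@dataclass
class SurvivalCurve:
    """Right-continuous product-limit step function."""

    times: np.ndarray  # distinct event times
    survival: np.ndarray  # S(t) just after each event time
    at_risk_counts: np.ndarray
    event_counts: np.ndarray
    max_followup: float  # largest observed duration, event or censored

    def evaluate(self, t: float) -> float:
        if t > self.max_followup:
            warnings.warn(
                f"evaluation time {t} beyond last observed time {self.max_followup}; "
                "carrying the last survival value forward",
                stacklevel=2,
            )
        idx = np.searchsorted(self.times, t, side="right")
        return 1.0 if idx == 0 else float(self.survival[idx - 1])


@dataclass
class TransitionMatrixPath:
    """Cumulative Aalen-Johansen transition matrices P(s, u) at each jump."""

    jump_times: np.ndarray
    matrices: list  # list of (C, C) arrays, cumulative products
    state_labels: list

    def occupation_row(self, t: float) -> np.ndarray:
        """Row 0 of P(s, t) — state occupation started from state 0."""
        n_states = len(self.state_labels)
        idx = np.searchsorted(self.jump_times, t, side="right")
        if idx == 0:
            row = np.zeros(n_states)
            row[0] = 1.0
            return row
        return self.matrices[idx - 1][0].copy()


def _as_arrays(durations):
    times, events = [], []
    for time, status in durations:
        times.append(float(time))
        if isinstance(status, str):
            if status not in ("event", "censored"):
                raise ValueError(f"unknown status {status!r}")
            events.append(status == "event")
        else:
            events.append(bool(status))
    return np.asarray(times), np.asarray(events)


def km_curve(durations) -> SurvivalCurve:
    """Kaplan-Meier product-limit curve from (time, status) pairs.

    Ties at a time are handled by the standard risk-set convention: subjects
    censored at ``t`` are still at risk for events at ``t`` (events are
    processed before censorings).
    """
    times, events = _as_arrays(durations)
    if times.size == 0:
        raise ValueError("empty duration input")
    if np.any(times < 0):
        raise ValueError("negative durations")
    ut = np.unique(times[events])
    d = np.array([np.sum(events & (times == t)) for t in ut], dtype=float)
    y = np.array([np.sum(times >= t) for t in ut], dtype=float)
    surv = np.cumprod(1.0 - d / y)
    return SurvivalCurve(
        times=ut,
        survival=surv,
        at_risk_counts=y,
        event_counts=d,
        max_followup=float(times.max()),
    )


def km_survival(durations, eval_time: float) -> float:
    """Product-limit survival probability at ``eval_time``."""
    return km_curve(durations).evaluate(eval_time)


def _km_loo_at(times: np.ndarray, events: np.ndarray, w: float) -> np.ndarray:
    """KM survival at ``w`` for the full sample and each leave-one-out replica.

    Returns an array of length ``n + 1``; entry 0 is the full-sample value and
    entry ``i + 1`` the estimate with subject ``i`` deleted.  Each replica's
    counts are recomputed from its own data (no jackknife shortcut).
    """
    n = times.size
    ut = np.unique(times[events & (times <= w)])
    out = np.ones(n + 1)
    if ut.size == 0:
        return out
    e_mat = (times[:, None] == ut[None, :]) & events[:, None]  # (n, M)
    ge_mat = times[:, None] >= ut[None, :]
    d_full = e_mat.sum(axis=0).astype(float)
    y_full = ge_mat.sum(axis=0).astype(float)
    d = np.vstack([d_full, d_full[None, :] - e_mat])
    y = np.vstack([y_full, y_full[None, :] - ge_mat])
    frac = np.divide(d, y, out=np.zeros_like(d), where=y > 0)
    return np.prod(1.0 - frac, axis=1)


def _order_k_durations(rows, k: int):
    """Durations of the relabeled k-th event; terminal endpoints censor."""
    times = np.empty(len(rows))
    events = np.empty(len(rows), dtype=bool)
    for i, r in enumerate(rows):
        if len(r.event_offsets) >= k:
            times[i] = r.event_offsets[k - 1]
            events[i] = True
        else:
            times[i] = r.end_offset
            events[i] = False
    return times, events


def _km_category_matrix(rows, window: float, k_max: int) -> np.ndarray:
    """(n+1, k_max+1) matrix of KM-difference category probabilities.

    Row 0 is the full-sample estimate, row ``i+1`` the leave-one-out estimate
    deleting subject ``i``.
    """
    n = len(rows)
    surv = np.empty((n + 1, k_max))
    for k in range(1, k_max + 1):
        times, events = _order_k_durations(rows, k)
        surv[:, k - 1] = _km_loo_at(times, events, window)
    probs = np.empty((n + 1, k_max + 1))
    probs[:, 0] = surv[:, 0]
    for k in range(1, k_max):
        probs[:, k] = surv[:, k] - surv[:, k - 1]
    probs[:, k_max] = 1.0 - surv[:, k_max - 1]
    return probs


def ordered_event_probabilities(rows, window: float, k_max: int) -> np.ndarray:
    """KM-difference estimates of the event-count category probabilities.

    Returns ``(F_0, ..., F_{k_max})`` at ``s + w``, where the top category
    pools counts ``>= k_max``.  Under heavy censoring crossing KM curves can
    make an interior category estimate negative; such values are returned as
    computed (pseudo-observations tolerate them) with a warning.
    """
    if len(rows) == 0:
        raise ValueError("empty risk set")
    probs = _km_category_matrix(rows, window, k_max)[0]
    if np.any(probs < 0):
        warnings.warn(
            "KM-difference produced a negative category probability "
            "(crossing product-limit curves); values returned unclipped",
            stacklevel=2,
        )
    return probs


# ---------------------------------------------------------------------------
# Aalen-Johansen machinery


def _n_states(k_max: int, terminal_mode: str) -> int:
    return k_max + 1 + (1 if terminal_mode == "present" else 0)


def _state_labels(k_max: int, terminal_mode: str) -> list:
    labels = [str(k) for k in range(k_max)] + [f"{k_max}+"]
    if terminal_mode == "present":
        labels.append("D")
    return labels


def _chain_structure(rows, k_max: int, terminal_mode: str):
    """Per-subject transient-state occupancy intervals and transition list.

    A subject is at risk in state ``q`` just before ``u`` iff
    ``enter[q] < u <= exit[q]``; a transition at ``u`` counts its subject in
    the risk set of the origin state.  Recurrent events past the pooled top
    state are ignored (the top count state is absorbing for event counting);
    from every transient state the terminal transition goes to ``D``.
    """
    n = len(rows)
    enter = np.full((k_max + 1, n), np.inf)
    exit_ = np.full((k_max + 1, n), -np.inf)
    transitions = []  # (time, from_state, to_state, subject_index)
    d_state = k_max + 1
    for i, r in enumerate(rows):
        state = 0
        t_enter = 0.0
        for e in r.event_offsets:
            if state == k_max:
                break
            enter[state, i] = t_enter
            exit_[state, i] = e
            transitions.append((e, state, state + 1, i))
            state += 1
            t_enter = e
        enter[state, i] = t_enter
        exit_[state, i] = r.end_offset
        if terminal_mode == "present" and r.end_is_terminal:
            transitions.append((r.end_offset, state, d_state, i))
    transitions.sort(key=lambda tr: tr[0])
    return enter, exit_, transitions


def aj_transition_path(rows, window: float, k_max: int, terminal_mode: str = "absent") -> TransitionMatrixPath:
    """Full product-integral path of cumulative transition matrices.

    ``P(s, u) = prod_{v in (s, u]} (I + dA(v))`` with Nelson-Aalen hazard
    increments ``dA_qr(v) = N_qr(v) / Y_q(v-)``.  All transitions at a tied
    time enter the same factor, with risk sets taken just before the time.
    """
    if len(rows) == 0:
        raise ValueError("empty risk set")
    n_states = _n_states(k_max, terminal_mode)
    enter, exit_, transitions = _chain_structure(rows, k_max, terminal_mode)
    cum = np.eye(n_states)
    jump_times, matrices = [], []
    idx = 0
    while idx < len(transitions):
        u = transitions[idx][0]
        if u > window:
            break
        group = []
        while idx < len(transitions) and transitions[idx][0] == u:
            group.append(transitions[idx])
            idx += 1
        factor = np.eye(n_states)
        by_qr: dict = {}
        for _, q, r, i in group:
            by_qr.setdefault((q, r), []).append(i)
        for (q, r), subs in by_qr.items():
            at_risk = np.sum((enter[q] < u) & (u <= exit_[q]))
            assert at_risk >= len(subs), "transition recorded with empty risk set"
            frac = len(subs) / at_risk
            factor[q, r] += frac
            factor[q, q] -= frac
        cum = cum @ factor
        jump_times.append(u)
        matrices.append(cum.copy())
    return TransitionMatrixPath(
        jump_times=np.asarray(jump_times),
        matrices=matrices,
        state_labels=_state_labels(k_max, terminal_mode),
    )


def aj_state_occupation(rows, window: float, k_max: int, terminal_mode: str = "absent") -> np.ndarray:
    """State-occupation probabilities at ``s + w`` starting from state 0."""
    return aj_transition_path(rows, window, k_max, terminal_mode).occupation_row(window)


def _aj_loo_occupation(rows, window: float, k_max: int, terminal_mode: str) -> np.ndarray:
    """(n+1, C) state-occupation rows: full sample then each deletion replica.

    Propagates the initial-state row vector of every replica through the
    shared sequence of jump times; each replica uses its own transition and
    risk-set counts, so this is exact leave-one-out re-estimation.
    """
    n = len(rows)
    n_states = _n_states(k_max, terminal_mode)
    enter, exit_, transitions = _chain_structure(rows, k_max, terminal_mode)
    p = np.zeros((n + 1, n_states))
    p[:, 0] = 1.0
    idx = 0
    while idx < len(transitions):
        u = transitions[idx][0]
        if u > window:
            break
        group = []
        while idx < len(transitions) and transitions[idx][0] == u:
            group.append(transitions[idx])
            idx += 1
        by_qr: dict = {}
        for _, q, r, i in group:
            by_qr.setdefault((q, r), []).append(i)
        p_old = p.copy()
        for (q, r), subs in by_qr.items():
            in_q = (enter[q] < u) & (u <= exit_[q])
            y_full = float(in_q.sum())
            y = np.empty(n + 1)
            y[0] = y_full
            y[1:] = y_full - in_q
            num = np.full(n + 1, float(len(subs)))
            for i in subs:
                num[i + 1] -= 1.0
            assert np.all((y > 0) | (num == 0)), "transition recorded with empty risk set"
            frac = np.divide(num, y, out=np.zeros(n + 1), where=y > 0)
            delta = p_old[:, q] * frac
            p[:, r] += delta
            p[:, q] -= delta
    return p
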