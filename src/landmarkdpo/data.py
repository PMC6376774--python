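"""Event-history containers, landmark-dataset construction and delimited I/O.

The central object of landmarking is the *risk set at s*: subjects who have
experienced neither the terminal event nor censoring by landmark time ``s``.
For each such subject the recurrent-event clock is restarted at ``s`` — the
k-th recurrent event strictly after ``s`` becomes the k-th *relabeled* event,
and the number of events up to and including ``s`` is carried along as a
covariate.

Conventions (continuous time, no binning):

* an event at exactly ``s`` counts as a *prior* event, not a window event;
* a terminal/censoring time exactly equal to ``s`` removes the subject from
  the risk set (being at risk requires ``min(T_D, C) > s`` strictly);
* window probabilities refer to the half-open interval ``(s, s + w]``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "EventHistory",
    "LandmarkRow",
    "LandmarkDataset",
    "ValidationError",
    "read_event_histories",
    "write_event_histories",
    "build_landmark_dataset",
    "read_landmark_dataset",
    "write_landmark_dataset",
]


class ValidationError(ValueError):
    """Raised when input event histories violate the data contract."""


@dataclass(frozen=True)
class EventHistory:
    """One subject's observed follow-up.

    Parameters
    ----------
    subject_id
        Opaque identifier.
    recurrent_times
        Strictly increasing positive times of observed recurrent events.
    terminal_time
        Time of the terminal event, ``math.inf`` when not observed (or not
        considered).
    censor_time
        Right-censoring time, ``math.inf`` when the terminal event was
        observed instead.
    covariates
        Mapping of covariate name to value, frozen at baseline.
    """

    subject_id: str
    recurrent_times: tuple[float, ...] = ()
    terminal_time: float = math.inf
    censor_time: float = math.inf
    covariates: dict = field(default_factory=dict)

    def __post_init__(self):
        object.__setattr__(self, "recurrent_times", tuple(float(t) for t in self.recurrent_times))
        times = self.recurrent_times
        if any(t <= 0 for t in times):
            raise ValidationError(f"nonpositive recurrent time for {self.subject_id}")
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValidationError(f"nonmonotone times for {self.subject_id}")
        # censor_time = inf with no terminal event means observation never
        # ends (complete data, e.g. a simulated cohort without censoring)
        if math.isfinite(self.terminal_time) and math.isfinite(self.censor_time):
            raise ValidationError(f"duplicate endpoint rows for {self.subject_id}")
        end = self.end_time
        if end <= 0:
            raise ValidationError(f"nonpositive endpoint time for {self.subject_id}")
        if times and times[-1] > end:
            raise ValidationError(f"recurrent time after endpoint for {self.subject_id}")
        if self.end_is_terminal and times and times[-1] == end:
            # the multi-state chain has no simultaneous recurrence+death step
            raise ValidationError(f"recurrent event coincides with terminal event for {self.subject_id}")

    @property
    def end_time(self) -> float:
        """End of observation, ``min(terminal_time, censor_time)``."""
        return min(self.terminal_time, self.censor_time)

    @property
    def end_is_terminal(self) -> bool:
        return math.isfinite(self.terminal_time) and self.terminal_time <= self.censor_time

    def n_events_by(self, t: float) -> int:
        """Number of recurrent events at or before time ``t``."""
        return sum(1 for x in self.recurrent_times if x <= t)


@dataclass(frozen=True)
class LandmarkRow:
    """A subject's contribution to the risk set at one landmark time.

    ``event_offsets`` are the relabeled event times counted *from* the
    landmark: the k-th entry is ``T*_k - s`` for the k-th recurrent event
    strictly after ``s``.  ``end_offset`` is ``min(T_D, C) - s`` and
    ``end_is_terminal`` records which endpoint it was.
    """

    subject_id: str
    landmark_time: float
    event_offsets: tuple[float, ...]
    end_offset: float
    end_is_terminal: bool
    prior_event_count: int
    covariates: dict = field(default_factory=dict)
    at_risk: bool = True


@dataclass
class LandmarkDataset:
    """Stacked risk sets over a landmark grid."""

    rows: list[LandmarkRow]
    grid: tuple[float, ...]
    window: float
    k_max: int
    terminal_mode: str  # "absent" | "present"

    def rows_at(self, s: float) -> list[LandmarkRow]:
        return [r for r in self.rows if r.landmark_time == s]

    def n_at_risk(self, s: float) -> int:
        return len(self.rows_at(s))

    def to_frame(self) -> pd.DataFrame:
        """Tidy export: one row per (subject, landmark) risk-set membership."""
        max_events = max((len(r.event_offsets) for r in self.rows), default=0)
        cov_names = sorted({k for r in self.rows for k in r.covariates})
        records = []
        for r in self.rows:
            rec = {
                "id": r.subject_id,
                "landmark": r.landmark_time,
                "at_risk": r.at_risk,
                "prior_events": r.prior_event_count,
                "end_offset": r.end_offset,
                "end_status": "terminal" if r.end_is_terminal else "censor",
            }
            for name in cov_names:
                rec[name] = r.covariates.get(name)
            for k in range(max_events):
                rec[f"event_{k + 1}"] = r.event_offsets[k] if k < len(r.event_offsets) else np.nan
            records.append(rec)
        return pd.DataFrame.from_records(records)


def read_event_histories(events_path, covariates_path=None) -> list[EventHistory]:
    """Read long-format event histories (``id,time,type``) and optional covariates.

    ``type`` must be one of ``recurrent``, ``terminal`` or ``censor``; each
    subject must have exactly one terminal-or-censor row, which ends
    observation.
    """
    events = pd.read_csv(events_path)
    required = {"id", "time", "type"}
    if not required.issubset(events.columns):
        raise ValidationError(f"events file must have columns {sorted(required)}")
    bad = set(events["type"]) - {"recurrent", "terminal", "censor"}
    if bad:
        raise ValidationError(f"unknown event type(s): {sorted(bad)}")

    cov_by_id: dict[str, dict] = {}
    if covariates_path is not None:
        cov = pd.read_csv(covariates_path)
        if "id" not in cov.columns:
            raise ValidationError("covariates file must have an 'id' column")
        cov["id"] = cov["id"].astype(str)
        if cov["id"].duplicated().any():
            dup = cov.loc[cov["id"].duplicated(), "id"].iloc[0]
            raise ValidationError(f"duplicate covariate row for {dup}")
        cov_by_id = cov.set_index("id").to_dict("index")

    histories = []
    events["id"] = events["id"].astype(str)
    for sid, grp in events.groupby("id", sort=True):
        endpoint = grp[grp["type"].isin(["terminal", "censor"])]
        if len(endpoint) == 0:
            raise ValidationError(f"no endpoint row for {sid}")
        if len(endpoint) > 1:
            raise ValidationError(f"duplicate endpoint rows for {sid}")
        end_type = endpoint["type"].iloc[0]
        end_time = float(endpoint["time"].iloc[0])
        rec = grp.loc[grp["type"] == "recurrent", "time"].to_numpy(dtype=float)
        if len(rec) > 1 and not np.all(np.diff(rec) > 0):
            raise ValidationError(f"nonmonotone times for {sid}")
        if covariates_path is not None and sid not in cov_by_id:
            raise ValidationError(f"id {sid} missing from covariates file")
        histories.append(
            EventHistory(
                subject_id=sid,
                recurrent_times=tuple(rec),
                terminal_time=end_time if end_type == "terminal" else math.inf,
                censor_time=end_time if end_type == "censor" else math.inf,
                covariates=dict(cov_by_id.get(sid, {})),
            )
        )
    extra = set(cov_by_id) - {h.subject_id for h in histories}
    if extra:
        raise ValidationError(f"covariate ids absent from events file: {sorted(extra)[:5]}")
    return histories


def write_event_histories(histories, events_path, covariates_path=None) -> None:
    """Inverse of :func:`read_event_histories`."""
    recs = []
    for h in histories:
        for t in h.recurrent_times:
            recs.append({"id": h.subject_id, "time": t, "type": "recurrent"})
        recs.append(
            {
                "id": h.subject_id,
                "time": h.end_time,
                "type": "terminal" if h.end_is_terminal else "censor",
            }
        )
    pd.DataFrame.from_records(recs).to_csv(events_path, index=False)
    if covariates_path is not None:
        names = sorted({k for h in histories for k in h.covariates})
        cov = pd.DataFrame.from_records(
            [{"id": h.subject_id, **{n: h.covariates.get(n) for n in names}} for h in histories]
        )
        cov.to_csv(covariates_path, index=False)


def build_landmark_dataset(
    histories,
    landmark_grid,
    window: float,
    k_max: int = 2,
    terminal_mode: str = "absent",
) -> LandmarkDataset:
    """Construct per-landmark risk sets with relabeled event times.

    A subject is at risk at ``s`` iff ``min(terminal_time, censor_time) > s``;
    their relabeled times are the recurrent events strictly after ``s``
    expressed as offsets from ``s``, and ``prior_event_count`` counts events
    at or before ``s``.
    """
    grid = [float(s) for s in landmark_grid]
    if len(grid) == 0:
        raise ValidationError("empty landmark grid")
    if any(b <= a for a, b in zip(grid, grid[1:])):
        raise ValidationError("landmark grid must be strictly increasing")
    if window <= 0:
        raise ValidationError("window must be positive")
    if k_max < 1:
        raise ValidationError("k_max must be >= 1")
    if terminal_mode not in ("absent", "present"):
        raise ValidationError("terminal_mode must be 'absent' or 'present'")

    rows: list[LandmarkRow] = []
    for s in grid:
        at_risk = [h for h in histories if h.end_time > s]
        if len(at_risk) < 2:
            raise ValidationError(f"fewer than 2 subjects at risk at landmark {s}; jackknife undefined")
        for h in at_risk:
            post = tuple(t - s for t in h.recurrent_times if t > s)
            rows.append(
                LandmarkRow(
                    subject_id=h.subject_id,
                    landmark_time=s,
                    event_offsets=post,
                    end_offset=h.end_time - s,
                    end_is_terminal=h.end_is_terminal,
                    prior_event_count=h.n_events_by(s),
                    covariates=dict(h.covariates),
                )
            )
    return LandmarkDataset(rows=rows, grid=tuple(grid), window=float(window), k_max=int(k_max), terminal_mode=terminal_mode)


def write_landmark_dataset(dataset: LandmarkDataset, path) -> None:
    frame = dataset.to_frame()
    frame.attrs = {}
    with open(path, "w") as fh:
        fh.write(
            f"# window={dataset.window} k_max={dataset.k_max} "
            f"terminal_mode={dataset.terminal_mode} grid={','.join(str(s) for s in dataset.grid)}\n"
        )
        frame.to_csv(fh, index=False)


def read_landmark_dataset(path) -> LandmarkDataset:
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("#"):
            raise ValidationError("landmark file missing metadata header")
        meta = dict(item.split("=", 1) for item in header[1:].split())
        frame = pd.read_csv(fh)
    grid = tuple(float(x) for x in meta["grid"].split(","))
    event_cols = sorted(
        (c for c in frame.columns if c.startswith("event_")), key=lambda c: int(c.split("_")[1])
    )
    fixed = {"id", "landmark", "at_risk", "prior_events", "end_offset", "end_status", *event_cols}
    cov_names = [c for c in frame.columns if c not in fixed]
    rows = []
    for rec in frame.to_dict("records"):
        offsets = tuple(rec[c] for c in event_cols if pd.notna(rec[c]))
        rows.append(
            LandmarkRow(
                subject_id=str(rec["id"]),
                landmark_time=float(rec["landmark"]),
                event_offsets=offsets,
                end_offset=float(rec["end_offset"]),
                end_is_terminal=rec["end_status"] == "terminal",
                prior_event_count=int(rec["prior_events"]),
                covariates={n: rec[n] for n in cov_names},
                at_risk=bool(rec["at_risk"]),
            )
        )
    return LandmarkDataset(
        rows=rows,
        grid=grid,
        window=float(meta["window"]),
        k_max=int(meta["k_max"]),
        terminal_mode=meta["terminal_mode"],
    )
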