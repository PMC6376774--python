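"""Dynamic pseudo-observations (DPOs) by leave-one-out jackknife.

For subject ``i`` at risk at landmark ``s`` the pseudo-observation for
category ``k`` is

    theta_ik(s) = n_s * F_k_hat - (n_s - 1) * F_k_hat^(-i),

where ``F_k_hat`` is the full-risk-set estimate of the windowed category
probability and ``F_k_hat^(-i)`` the same estimate with subject ``i``
deleted.  Without censoring every theta is the subject's own 0/1 category
indicator; with censoring the thetas may leave [0, 1], which is expected and
they are deliberately not clipped (clipping would bias the downstream GEE).

The reference category (zero window events) is computed explicitly and the
row-sum-to-one identity asserted, which catches estimator bugs early.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .estimators import _aj_loo_occupation, _km_category_matrix

__all__ = ["DPOMatrix", "dpo_km", "dpo_aj", "stack_dpos"]

_ROW_SUM_TOL = 1e-8


@dataclass
class DPOMatrix:
    """Per-subject pseudo-observations at one landmark."""

    landmark_time: float
    subject_ids: list
    theta: np.ndarray  # (n_s, C)
    estimator: str  # "aj" | "km"
    window: float
    k_max: int
    terminal_mode: str

    @property
    def categories(self) -> list:
        labels = [str(k) for k in range(self.k_max)] + [f"{self.k_max}+"]
        if self.terminal_mode == "present":
            labels.append("D")
        return labels

    def column_means(self) -> np.ndarray:
        """Mean pseudo-observation per category — the dynamic predicted value.

        For the KM-difference estimator (and the two-state chain, where AJ
        reduces to KM) this equals the full-sample estimate exactly; for a
        genuine multi-state AJ estimator the mean of leave-one-out estimates
        differs from the full-sample estimate by O(1/n_s), so the two agree
        only up to that order.
        """
        return self.theta.mean(axis=0)

    def to_frame(self) -> pd.DataFrame:
        cols = [f"theta_{c}" for c in self.categories]
        frame = pd.DataFrame(self.theta, columns=cols)
        frame.insert(0, "id", self.subject_ids)
        frame.insert(1, "landmark", self.landmark_time)
        frame.insert(2, "estimator", self.estimator)
        return frame


def _jackknife(estimates: np.ndarray) -> np.ndarray:
    """theta_i = n*full - (n-1)*loo_i from an (n+1, C) estimate stack."""
    n = estimates.shape[0] - 1
    return n * estimates[0][None, :] - (n - 1) * estimates[1:]


def _finalize(theta: np.ndarray, rows, s, estimator, window, k_max, terminal_mode) -> DPOMatrix:
    row_sums = theta.sum(axis=1)
    if not np.allclose(row_sums, 1.0, atol=_ROW_SUM_TOL):
        raise AssertionError("pseudo-observation rows do not sum to 1; estimator inconsistency")
    return DPOMatrix(
        landmark_time=s,
        subject_ids=[r.subject_id for r in rows],
        theta=theta,
        estimator=estimator,
        window=window,
        k_max=k_max,
        terminal_mode=terminal_mode,
    )


def dpo_km(rows, window: float, k_max: int) -> DPOMatrix:
    """KM-difference DPOs (terminal events, if any, treated as censoring)."""
    if len(rows) < 2:
        raise ValueError("jackknife undefined: fewer than 2 subjects at risk")
    s = rows[0].landmark_time
    estimates = _km_category_matrix(rows, window, k_max)
    theta = _jackknife(estimates)
    return _finalize(theta, rows, s, "km", window, k_max, "absent")


def dpo_aj(rows, window: float, k_max: int, terminal_mode: str = "absent") -> DPOMatrix:
    """Aalen-Johansen DPOs, with a terminal-event column when requested."""
    if len(rows) < 2:
        raise ValueError("jackknife undefined: fewer than 2 subjects at risk")
    s = rows[0].landmark_time
    estimates = _aj_loo_occupation(rows, window, k_max, terminal_mode)
    theta = _jackknife(estimates)
    return _finalize(theta, rows, s, "aj", window, k_max, terminal_mode)


def compute_dpos(dataset, estimator: str = "aj") -> list[DPOMatrix]:
    """One DPO matrix per landmark of a :class:`~landmarkdpo.data.LandmarkDataset`."""
    if estimator not in ("aj", "km"):
        raise ValueError("estimator must be 'aj' or 'km'")
    if estimator == "km" and dataset.terminal_mode == "present":
        raise ValueError("KM-difference DPOs require terminal_mode='absent'")
    out = []
    for s in dataset.grid:
        rows = dataset.rows_at(s)
        if estimator == "aj":
            out.append(dpo_aj(rows, dataset.window, dataset.k_max, dataset.terminal_mode))
        else:
            out.append(dpo_km(rows, dataset.window, dataset.k_max))
    return out


def stack_dpos(matrices) -> pd.DataFrame:
    """Stack per-landmark DPO matrices into a long table keyed by (id, landmark)."""
    matrices = list(matrices)
    if not matrices:
        raise ValueError("no DPO matrices to stack")
    ref = matrices[0]
    for m in matrices[1:]:
        if (m.window, m.k_max, m.estimator, m.terminal_mode) != (
            ref.window,
            ref.k_max,
            ref.estimator,
            ref.terminal_mode,
        ):
            raise ValueError("inconsistent window/k_max/estimator/terminal_mode across landmarks")
    return pd.concat([m.to_frame() for m in matrices], ignore_index=True)
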