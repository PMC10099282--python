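"""Growth-curve assembly, phase annotation and cross-modality agreement.

An adherent-cell cultivation with a finite nutrient budget passes through
attachment (cells settling onto the sensor in the first couple of hours),
lag, exponential growth, a stationary plateau, and — once nutrients run out —
a dying phase in which cells detach and fragment.  The impedance-derived
``C_cell(t)`` tracks all five; image-derived surface coverage tracks them
only while cells are alive and attached, after which debris makes coverage
erratic.  ``compare_modalities`` therefore reports rank correlation
separately before and after a cutoff (default 60 h) so the post-dying
divergence is exhibited rather than averaged away.

The phase classifier is an algorithmic stand-in for by-eye annotation: the
primary signal is smoothed, per-point slopes are computed, and a forward-only
state machine (attachment -> lag -> exponential -> stationary -> dying)
assigns labels from the slope sign relative to a flatness threshold expressed
as a fraction of the signal range per unit time — which makes the labels
invariant to affine rescaling of the signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

__all__ = [
    "PHASES",
    "GrowthTrajectory",
    "PhaseOptions",
    "ModalityAgreement",
    "annotate_phases",
    "combine_modalities",
    "compare_modalities",
]

#: Canonical phase order; labels never recur once left.
PHASES: tuple[str, ...] = ("attachment", "lag", "exponential", "stationary", "dying")


@dataclass(frozen=True)
class GrowthTrajectory:
    """Per-timepoint growth signals with optional phase labels.

    At least one of ``c_cell`` (farad) or ``coverage`` (percent) must be
    present for annotation; both for modality comparison.  ``sd`` holds
    per-timepoint spreads keyed by signal name.
    """

    timepoints: np.ndarray
    c_cell: np.ndarray | None = None
    coverage: np.ndarray | None = None
    phase_labels: tuple[str, ...] | None = None
    sd: dict | None = None
    annotation_meta: dict | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.timepoints, dtype=float)
        if t.ndim != 1 or t.size == 0:
            raise ValueError("timepoints must be a non-empty 1-D array")
        if np.any(np.diff(t) <= 0):
            raise ValueError("timepoints must be strictly increasing")
        object.__setattr__(self, "timepoints", t)
        for name in ("c_cell", "coverage"):
            sig = getattr(self, name)
            if sig is not None:
                sig = np.asarray(sig, dtype=float)
                if sig.shape != t.shape:
                    raise ValueError(f"{name} must match timepoints in length")
                object.__setattr__(self, name, sig)
        if self.phase_labels is not None:
            labels = tuple(self.phase_labels)
            if len(labels) != t.size:
                raise ValueError("phase_labels must match timepoints in length")
            order = [PHASES.index(p) for p in labels]
            if any(b < a for a, b in zip(order, order[1:])):
                raise ValueError("phase labels must follow the canonical order")
            object.__setattr__(self, "phase_labels", labels)

    def primary_signal(self) -> np.ndarray:
        if self.c_cell is not None:
            return self.c_cell
        if self.coverage is not None:
            return self.coverage
        raise ValueError("trajectory has neither c_cell nor coverage")

    def to_frame(self) -> pd.DataFrame:
        data = {"timepoint_h": self.timepoints}
        if self.c_cell is not None:
            data["c_cell_f"] = self.c_cell
        if self.coverage is not None:
            data["coverage_percent"] = self.coverage
        if self.phase_labels is not None:
            data["phase_label"] = list(self.phase_labels)
        return pd.DataFrame(data)


@dataclass(frozen=True)
class PhaseOptions:
    """Classifier settings.

    ``attach_window_h``: window at the start of the cultivation within which
    a steep change is labelled attachment (cells settling).
    ``flatness_frac`` per ``flatness_per_h`` hours defines the slope below
    which the signal counts as flat, relative to the signal's full range.
    """

    attach_window_h: float = 2.0
    smooth_window: int = 3
    flatness_frac: float = 0.05
    flatness_per_h: float = 12.0


def _moving_average(y: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return y.copy()
    pad = window // 2
    padded = np.pad(y, pad, mode="edge")
    kernel = np.ones(window) / window
    return np.convolve(padded, kernel, mode="valid")[: y.size]


def annotate_phases(
    trajectory: GrowthTrajectory, options: PhaseOptions | None = None
) -> GrowthTrajectory:
    """Label each timepoint with a growth phase.

    Deterministic: smoothing (moving average), per-point slope via centered
    differences, then a forward-only state machine on the slope sign.
    """
    options = options or PhaseOptions()
    t = trajectory.timepoints
    if t.size < 5:
        raise ValueError("phase annotation needs at least 5 timepoints")
    signal = trajectory.primary_signal()

    smooth = _moving_average(signal, options.smooth_window)
    # Backward interval slopes: the forward bias of the centered smoothing
    # window and the backward difference roughly cancel, so change-points are
    # localized to within about one sampling interval.
    slope = np.empty(t.size)
    slope[1:] = np.diff(smooth) / np.diff(t)
    slope[0] = slope[1]
    span = float(smooth.max() - smooth.min())
    thresh = options.flatness_frac * span / options.flatness_per_h
    if span == 0:
        sign = np.zeros(t.size, dtype=int)
    else:
        sign = np.where(slope > thresh, 1, np.where(slope < -thresh, -1, 0))

    n = t.size

    def sustained(i: int, pred) -> bool:
        # one-interval confirmation so a single noisy slope cannot flip the
        # forward-only state machine
        return bool(pred(sign[i]) and (i + 1 >= n or pred(sign[i + 1])))

    labels: list[str] = []
    state = "attachment" if sign[0] != 0 else "lag"
    window_end = t[0] + options.attach_window_h
    for i in range(n):
        if state == "attachment" and (t[i] > window_end or sign[i] == 0):
            state = "lag"
        if state == "lag" and t[i] > window_end and sustained(i, lambda s: s > 0):
            state = "exponential"
        if state == "exponential" and sustained(i, lambda s: s <= 0):
            state = "stationary"
        if state in ("exponential", "stationary") and sustained(i, lambda s: s < 0):
            state = "dying"
        labels.append(state)

    meta = {
        "classifier": "slope-sign state machine (algorithmic annotation)",
        "smooth_window": options.smooth_window,
        "flatness_frac": options.flatness_frac,
        "flatness_per_h": options.flatness_per_h,
        "attach_window_h": options.attach_window_h,
    }
    return replace(trajectory, phase_labels=tuple(labels), annotation_meta=meta)


def combine_modalities(
    eis_timepoints: np.ndarray,
    c_cell: np.ndarray,
    coverage_timepoints: np.ndarray,
    coverage: np.ndarray,
) -> GrowthTrajectory:
    """Merge the two readouts onto the impedance time grid.

    Coverage is linearly interpolated onto the impedance timepoints, with no
    extrapolation: impedance timepoints outside the imaging window are
    dropped.
    """
    te = np.asarray(eis_timepoints, dtype=float)
    tc = np.asarray(coverage_timepoints, dtype=float)
    keep = (te >= tc.min()) & (te <= tc.max())
    if not np.any(keep):
        raise ValueError("no overlap between the impedance and imaging time grids")
    t = te[keep]
    cov = np.interp(t, tc, np.asarray(coverage, dtype=float))
    return GrowthTrajectory(
        timepoints=t, c_cell=np.asarray(c_cell, dtype=float)[keep], coverage=cov
    )


@dataclass(frozen=True)
class ModalityAgreement:
    """Rank correlation of the two signals before/after the cutoff.

    ``nan`` marks a window with too few shared timepoints for a defined
    statistic — it is reported as undefined, never fabricated.
    """

    cutoff_h: float
    rho_pre: float
    rho_post: float
    n_pre: int
    n_post: int

    def to_dict(self) -> dict:
        return {
            "cutoff_h": self.cutoff_h,
            "rho_pre": None if np.isnan(self.rho_pre) else self.rho_pre,
            "rho_post": None if np.isnan(self.rho_post) else self.rho_post,
            "n_pre": self.n_pre,
            "n_post": self.n_post,
        }


def _window_rho(x: np.ndarray, y: np.ndarray) -> float:
    if x.size < 3:
        return float("nan")
    rho = spearmanr(x, y).statistic
    return float(rho)


def compare_modalities(
    trajectory: GrowthTrajectory, cutoff: float = 60.0
) -> ModalityAgreement:
    """Spearman rank correlation of C_cell vs coverage in two time windows.

    Rank (not Pearson) correlation because the signals live on unrelated
    scales (farad vs percent) and the claim under test is about shared
    trends.  Pre-window: t <= cutoff; post-window: t > cutoff.
    """
    if trajectory.c_cell is None or trajectory.coverage is None:
        raise ValueError("both c_cell and coverage are required")
    t = trajectory.timepoints
    pre = t <= cutoff
    post = ~pre
    return ModalityAgreement(
        cutoff_h=float(cutoff),
        rho_pre=_window_rho(trajectory.c_cell[pre], trajectory.coverage[pre]),
        rho_post=_window_rho(trajectory.c_cell[post], trajectory.coverage[post]),
        n_pre=int(pre.sum()),
        n_post=int(post.sum()),
    )
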