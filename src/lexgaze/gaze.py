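"""Looking-while-listening gaze preprocessing and the log-gaze statistic.

Raw 500 Hz gaze samples per trial are labeled against the target and
distractor areas of interest, binned into 50 ms intervals for plotting, and
reduced over the 300-2000 ms post-label-onset analysis window to a log-gaze
proportion ratio, ln(P_target / P_distractor).  Trials are excluded first if
the parent rated the target word below 2 (not comprehended) and then, among
the survivors, if the child viewed the screen for less than 20% of the
analysis window; both stages are recorded in an exclusion ledger so the
bookkeeping is auditable.

Sample states are stored as small integer codes (see :class:`GazeState`)
because cohort-scale simulation pushes millions of samples through this
module.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from enum import IntEnum

import numpy as np
import pandas as pd

SAMPLE_MS = 2  # 500 Hz
DEFAULT_WINDOW = (300, 2000)  # half-open, ms post label onset
DEFAULT_BIN_MS = 50
DEFAULT_MIN_RATING = 2
DEFAULT_MIN_ONSCREEN = 0.2
DEFAULT_SMOOTHING = 0.5


class GazeState(IntEnum):
    """Four-state gaze alphabet; values double as array codes."""

    TARGET = 0
    DISTRACTOR = 1
    OTHER_ONSCREEN = 2
    OFFSCREEN = 3


STATES = tuple(GazeState)
N_STATES = len(STATES)


@dataclass(frozen=True)
class AoiLayout:
    """Screen geometry: two 400x400 px interest areas on a 1280x1024 screen."""

    screen_w: int = 1280
    screen_h: int = 1024
    aoi_w: int = 400
    aoi_h: int = 400
    target_side: str = "left"
    #: top-left corners of the left and right interest areas
    left_xy: tuple[int, int] = (80, 312)
    right_xy: tuple[int, int] = (800, 312)

    def __post_init__(self) -> None:
        for x, y in (self.left_xy, self.right_xy):
            if not (0 <= x and x + self.aoi_w <= self.screen_w
                    and 0 <= y and y + self.aoi_h <= self.screen_h):
                raise ValueError("interest area falls off screen")
        lx, rx = sorted((self.left_xy[0], self.right_xy[0]))
        if lx + self.aoi_w > rx:
            raise ValueError("interest areas overlap")
        if self.target_side not in ("left", "right"):
            raise ValueError("target_side must be 'left' or 'right'")

    @property
    def target_xy(self) -> tuple[int, int]:
        return self.left_xy if self.target_side == "left" else self.right_xy

    @property
    def distractor_xy(self) -> tuple[int, int]:
        return self.right_xy if self.target_side == "left" else self.left_xy


@dataclass(frozen=True)
class GazeTrial:
    """One trial's labeled 500 Hz sample stream plus metadata.

    ``states`` is an int8 array of :class:`GazeState` codes aligned with
    ``times`` (ms relative to label onset, strictly increasing, 2 ms apart).
    """

    trial_id: str
    child_id: str
    condition: str  # "related" | "unrelated"
    target: str
    distractor: str
    comprehension_rating: int
    times: np.ndarray
    states: np.ndarray
    target_side: str = "left"

    def __post_init__(self) -> None:
        if self.condition not in ("related", "unrelated"):
            raise ValueError(f"bad condition {self.condition!r}")
        if not 1 <= self.comprehension_rating <= 4:
            raise ValueError("comprehension rating must be 1..4")
        t = np.asarray(self.times)
        s = np.asarray(self.states)
        if len(t) != len(s):
            raise ValueError("times and states differ in length")
        if len(t) > 1 and not np.all(np.diff(t) == SAMPLE_MS):
            raise ValueError("samples must be strictly increasing at 2 ms spacing")
        if len(s) and (s.min() < 0 or s.max() >= N_STATES):
            raise ValueError("states must be GazeState codes 0..3")

    def swap_labels(self) -> "GazeTrial":
        """Return the trial with target and distractor roles exchanged."""
        s = np.asarray(self.states).copy()
        tmask = s == GazeState.TARGET
        s[s == GazeState.DISTRACTOR] = GazeState.TARGET
        s[tmask] = GazeState.DISTRACTOR
        return replace(
            self, target=self.distractor, distractor=self.target, states=s
        )


@dataclass(frozen=True)
class TrialAccuracy:
    """Window-level summary of one trial."""

    trial_id: str
    n_target: int
    n_distractor: int
    n_onscreen: int
    n_window: int
    onscreen_prop: float
    log_gaze: float
    included: bool = True
    exclusion_reason: str = "none"


def label_samples(points, layout: AoiLayout) -> np.ndarray:
    """Label (t, x, y) gaze points; x or y None/NaN means offscreen.

    Interest-area membership is half-open, [x0, x0+w) x [y0, y0+h): a point
    exactly on a right or bottom edge is outside.  Returns int8 GazeState
    codes.
    """
    tx, ty = layout.target_xy
    dx, dy = layout.distractor_xy
    out = np.empty(len(points), dtype=np.int8)
    for i, (_, x, y) in enumerate(points):
        if x is None or y is None or (isinstance(x, float) and math.isnan(x)) \
                or (isinstance(y, float) and math.isnan(y)):
            out[i] = GazeState.OFFSCREEN
        elif not (0 <= x < layout.screen_w and 0 <= y < layout.screen_h):
            out[i] = GazeState.OFFSCREEN
        elif tx <= x < tx + layout.aoi_w and ty <= y < ty + layout.aoi_h:
            out[i] = GazeState.TARGET
        elif dx <= x < dx + layout.aoi_w and dy <= y < dy + layout.aoi_h:
            out[i] = GazeState.DISTRACTOR
        else:
            out[i] = GazeState.OTHER_ONSCREEN
    return out


def bin_timecourse(trial: GazeTrial, bin_ms: int = DEFAULT_BIN_MS) -> pd.DataFrame:
    """Per-bin state proportions; bin b covers [b*bin_ms, (b+1)*bin_ms).

    Non-empty bins have proportions summing to 1; empty bins get NaN and are
    flagged by ``n_samples == 0``.
    """
    t = np.asarray(trial.times)
    s = np.asarray(trial.states)
    end = int(t.max()) + SAMPLE_MS if len(t) else 0
    n_bins = int(np.ceil(end / bin_ms)) if end > 0 else 0
    bins = np.floor_divide(t, bin_ms).astype(np.intp)
    counts = np.zeros((n_bins, N_STATES), dtype=np.int64)
    np.add.at(counts, (bins, s.astype(np.intp)), 1)
    n = counts.sum(axis=1)
    with np.errstate(invalid="ignore"):
        props = counts / n[:, None]
    df = pd.DataFrame(
        props, columns=[f"p_{st.name.lower()}" for st in STATES]
    )
    df.insert(0, "bin_start_ms", np.arange(n_bins) * bin_ms)
    df["n_samples"] = n
    return df


def window_counts(trial: GazeTrial, window: tuple[int, int] = DEFAULT_WINDOW):
    """State counts over the half-open analysis window."""
    lo, hi = window
    t = np.asarray(trial.times)
    mask = (t >= lo) & (t < hi)
    if not mask.any():
        raise ValueError(
            f"{trial.trial_id}: analysis window [{lo}, {hi}) contains no samples"
        )
    counts = np.bincount(
        np.asarray(trial.states)[mask].astype(np.intp), minlength=N_STATES
    )
    return counts, int(mask.sum())


def log_gaze_from_counts(
    n_target: int, n_distractor: int, smoothing_c: float = DEFAULT_SMOOTHING
) -> float:
    """ln((n_target + c) / (n_distractor + c)); NaN if undefined at c = 0."""
    if smoothing_c == 0 and (n_target == 0 or n_distractor == 0):
        return math.nan
    return math.log((n_target + smoothing_c) / (n_distractor + smoothing_c))


def trial_log_gaze(
    trial: GazeTrial,
    window: tuple[int, int] = DEFAULT_WINDOW,
    smoothing_c: float = DEFAULT_SMOOTHING,
) -> TrialAccuracy:
    """Log-gaze proportion ratio over the analysis window.

    Positive values mean target preference, zero equivalent looking.  With
    ``smoothing_c = 0`` and a zero count on either side the ratio is
    undefined and the trial is flagged (reason ``undefined_ratio``).
    """
    counts, n_window = window_counts(trial, window)
    n_target = int(counts[GazeState.TARGET])
    n_distr = int(counts[GazeState.DISTRACTOR])
    n_onscreen = int(counts[: GazeState.OFFSCREEN].sum())
    lg = log_gaze_from_counts(n_target, n_distr, smoothing_c)
    undefined = math.isnan(lg)
    return TrialAccuracy(
        trial_id=trial.trial_id,
        n_target=n_target,
        n_distractor=n_distr,
        n_onscreen=n_onscreen,
        n_window=n_window,
        onscreen_prop=n_onscreen / n_window,
        log_gaze=lg,
        included=not undefined,
        exclusion_reason="undefined_ratio" if undefined else "none",
    )


def filter_trials(
    trials: list[GazeTrial],
    accuracies: list[TrialAccuracy],
    min_rating: int = DEFAULT_MIN_RATING,
    min_onscreen: float = DEFAULT_MIN_ONSCREEN,
) -> tuple[list[tuple[GazeTrial, TrialAccuracy]], pd.DataFrame]:
    """Comprehension filter first, then track-loss on the survivors.

    Returns retained (trial, accuracy) pairs and an exclusion ledger with one
    row per excluded trial; stage counts and percentages sit in
    ``ledger.attrs['stages']`` (percentages relative to each stage's input,
    matching sequential bookkeeping).
    """
    if len(trials) != len(accuracies):
        raise ValueError("trials and accuracies must align")
    rows = []
    survivors = []
    for tr, acc in zip(trials, accuracies):
        if tr.comprehension_rating < min_rating:
            rows.append({"trial_id": tr.trial_id, "stage": "comprehension",
                         "reason": "low_rating"})
        else:
            survivors.append((tr, acc))
    retained = []
    for tr, acc in survivors:
        if acc.onscreen_prop < min_onscreen:
            rows.append({"trial_id": tr.trial_id, "stage": "track_loss",
                         "reason": "track_loss"})
        elif acc.exclusion_reason == "undefined_ratio":
            rows.append({"trial_id": tr.trial_id, "stage": "track_loss",
                         "reason": "undefined_ratio"})
        else:
            retained.append((tr, acc))
    ledger = pd.DataFrame(rows, columns=["trial_id", "stage", "reason"])
    n_in = len(trials)
    n_low = int((ledger["stage"] == "comprehension").sum()) if len(ledger) else 0
    n_track = len(ledger) - n_low
    ledger.attrs["stages"] = {
        "input": n_in,
        "removed_comprehension": n_low,
        "after_comprehension": n_in - n_low,
        "removed_track_loss": n_track,
        "retained": n_in - n_low - n_track,
        "pct_comprehension": 100.0 * n_low / n_in if n_in else 0.0,
        "pct_track_loss": 100.0 * n_track / (n_in - n_low) if n_in - n_low else 0.0,
    }
    assert ledger.attrs["stages"]["retained"] == len(retained)
    return retained, ledger


def grand_timecourse(
    trials: list[GazeTrial],
    groups: dict[str, str] | None = None,
    bin_ms: int = DEFAULT_BIN_MS,
) -> pd.DataFrame:
    """Mean per-bin target/distractor fixation proportions per group.

    ``groups`` maps trial_id to a label (e.g. condition x metric split); None
    pools all trials.  Denominators include all samples, onscreen or not, so
    curves start near zero while the child leaves central fixation.
    """
    if groups is None:
        groups = {t.trial_id: "all" for t in trials}
    frames = []
    for label in sorted(set(groups.values())):
        members = [t for t in trials if groups.get(t.trial_id) == label]
        if not members:
            warnings.warn(f"empty timecourse group {label!r}, omitted", stacklevel=2)
            continue
        cat = pd.concat([bin_timecourse(t, bin_ms) for t in members])
        agg = (
            cat.groupby("bin_start_ms")[["p_target", "p_distractor"]]
            .mean()
            .reset_index()
        )
        agg.insert(0, "group", label)
        agg["n_trials"] = len(members)
        frames.append(agg)
    if not frames:
        return pd.DataFrame(
            columns=["group", "bin_start_ms", "p_target", "p_distractor", "n_trials"]
        )
    return pd.concat(frames, ignore_index=True)


def accuracy_table(accuracies: list[TrialAccuracy]) -> pd.DataFrame:
    return pd.DataFrame([vars(a) for a in accuracies])
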