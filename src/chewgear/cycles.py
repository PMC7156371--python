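"""Gape-cycle segmentation, phase detection and cycle standardisation.

A gape cycle runs from one maximum gape to the next.  Within a cycle the jaw
passes through four phases: fast close (FC), slow close (SC, tooth-food
contact and bite force), slow open (SO) and fast open (FO).  Phase
boundaries are located from jaw vertical acceleration, the second derivative
of gape: the FC/SC boundary is the acceleration maximum between peak closing
speed and minimum gape (the deceleration spike as the teeth meet the food);
the SO/FO boundary is the acceleration maximum between minimum gape and peak
opening speed (the jaw accelerating into fast opening).  The exact
acceleration criterion used upstream in the literature is not published in
reproducible detail, so the argmax rule here is this package's fixed,
testable operationalisation (see the methods note).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .kinematics import GapeSeries

__all__ = [
    "GapeCycle",
    "segment_cycles",
    "detect_phases",
    "extract_cycles",
    "standardize_cycle",
    "average_cycles",
]

PHASES = ("FC", "SC", "SO", "FO")


@dataclass
class GapeCycle:
    """One max-gape-to-max-gape cycle with its phase boundaries.

    All frame indices are absolute (into the recording).  ``fc_sc``,
    ``min_gape`` and ``so_fo`` split the cycle into FC [start, fc_sc),
    SC [fc_sc, min_gape), SO [min_gape, so_fo) and FO [so_fo, end].
    """

    start: int
    end: int
    fc_sc: int
    min_gape: int
    so_fo: int
    gape: np.ndarray
    frame_rate: float

    def __post_init__(self) -> None:
        if not (self.start < self.fc_sc < self.min_gape < self.so_fo < self.end):
            raise ValueError(
                "phase boundaries must be ordered start < fc_sc < min_gape < so_fo < end, "
                f"got {self.start}, {self.fc_sc}, {self.min_gape}, {self.so_fo}, {self.end}"
            )
        self.gape = np.asarray(self.gape, dtype=float)
        if self.gape.shape[0] != self.n_frames:
            raise ValueError("gape array length must match cycle span")

    @property
    def n_frames(self) -> int:
        return self.end - self.start + 1

    @property
    def duration_s(self) -> float:
        return (self.end - self.start) / self.frame_rate

    def phase_labels(self) -> np.ndarray:
        """Per-frame phase label array for the cycle (partition of the span)."""
        labels = np.empty(self.n_frames, dtype="<U2")
        rel = np.arange(self.start, self.end + 1)
        labels[rel < self.fc_sc] = "FC"
        labels[(rel >= self.fc_sc) & (rel < self.min_gape)] = "SC"
        labels[(rel >= self.min_gape) & (rel < self.so_fo)] = "SO"
        labels[rel >= self.so_fo] = "FO"
        return labels


def segment_cycles(
    gape_series: GapeSeries | np.ndarray,
    min_prominence: float | None = None,
) -> list[tuple[int, int]]:
    """Split a gape series into max-to-max cycle spans.

    Cycle boundaries are gape maxima with peak prominence of at least
    ``min_prominence`` (default: 20% of the series' gape range, which rejects
    within-chew jitter maxima).  Partial cycles touching the recording
    boundaries are not returned.  Fewer than two qualifying maxima yields an
    empty list.
    """
    g = gape_series.values if isinstance(gape_series, GapeSeries) else np.asarray(gape_series, float)
    finite = np.isfinite(g)
    if not finite.any():
        return []
    if min_prominence is None:
        rng = np.nanmax(g) - np.nanmin(g)
        min_prominence = 0.2 * rng
    peaks, _ = find_peaks(np.where(finite, g, -np.inf), prominence=min_prominence)
    return [(int(a), int(b)) for a, b in zip(peaks[:-1], peaks[1:])]


def _second_derivative(g: np.ndarray) -> np.ndarray:
    """Central-difference second derivative per frame^2 (ends replicated)."""
    a = np.empty_like(g)
    a[1:-1] = g[2:] - 2 * g[1:-1] + g[:-2]
    a[0] = a[1]
    a[-1] = a[-2]
    return a


def _accel_edge(a: np.ndarray, lo: int, hi: int, sign: float, w: int = 5) -> int:
    """Locate an acceleration step edge within [lo, hi].

    A phase junction is a jump discontinuity of jaw acceleration.  After
    low-pass filtering the jump becomes a smooth step whose centre stays at
    the junction, but a plain argmax on the smeared acceleration drifts
    toward the heavier side of the peak.  The difference of one-sided means
    (mean over ``w`` frames before minus after the candidate) peaks at the
    step centre, is unbiased under symmetric smearing, is insensitive to
    linear acceleration trends within the phases, and averages noise over
    2w frames.  ``sign`` +1 finds a downward step (high-to-low, FC/SC),
    -1 an upward step (SO/FO).  Ties resolve to the earliest frame.
    """
    n = a.shape[0]
    best_k, best_score = lo, -np.inf
    for k in range(lo, hi + 1):
        left = a[max(k - w, 0) : k]
        right = a[k : min(k + w, n)]
        if left.size == 0 or right.size == 0:
            continue
        score = sign * (left.mean() - right.mean())
        if score > best_score:
            best_score, best_k = score, k
    return best_k


def detect_phases(
    cycle_gape: np.ndarray,
    frame_rate: float = 150.0,
    accel_smooth: int = 5,
) -> tuple[int, int, int]:
    """Locate the FC/SC, minimum-gape (SC/SO) and SO/FO boundaries of a cycle.

    ``cycle_gape`` must span max gape -> min gape -> max gape.  Returns
    indices relative to the cycle start.  Jaw vertical acceleration is the
    central-difference second derivative of gape.  The FC/SC (SO/FO)
    boundary is the maximal acceleration step between the frame of peak
    closing (opening) speed and minimum gape, located with the one-sided
    means edge detector of :func:`_accel_edge`, which finds the argmax of
    the underlying (pre-filter) acceleration while staying unbiased under
    the low-pass filter's symmetric smearing of the acceleration jump.
    ``accel_smooth`` applies a centred moving average (odd window, frames)
    before the search to suppress marker-noise spikes (set 1 to disable).
    Ties resolve to the earliest frame.
    """
    g = np.asarray(cycle_gape, dtype=float)
    n = g.shape[0]
    if n < 8:
        raise ValueError(f"cycle too short for phase detection: {n} frames")
    if not np.isfinite(g).all():
        raise ValueError("cycle gape contains non-finite values")

    v = np.gradient(g)
    a = _second_derivative(g)
    if accel_smooth > 1:
        if accel_smooth % 2 == 0:
            raise ValueError("accel_smooth must be odd")
        k = np.ones(accel_smooth) / accel_smooth
        apad = np.pad(a, accel_smooth // 2, mode="edge")
        a = np.convolve(apad, k, mode="valid")

    min_gape = int(np.argmin(g))
    if min_gape < 2 or min_gape > n - 3:
        raise ValueError("minimum gape lies at the cycle boundary; not a full cycle")

    peak_close = int(np.argmin(v[: min_gape + 1]))
    lo = max(peak_close, 1)
    fc_sc = _accel_edge(a, lo, min_gape - 1, sign=+1.0)

    peak_open = min_gape + int(np.argmax(v[min_gape:]))
    hi = min(peak_open, n - 2)
    so_fo = _accel_edge(a, min_gape + 1, hi, sign=-1.0)

    return fc_sc, min_gape, so_fo


def extract_cycles(
    gape_series: GapeSeries,
    min_prominence: float | None = None,
    accel_smooth: int = 5,
) -> list[GapeCycle]:
    """Segment a gape series and detect phase boundaries for every cycle.

    Cycles whose gape contains untrackable frames, or that are too short for
    phase detection, are skipped with a warning.
    """
    out: list[GapeCycle] = []
    for start, end in segment_cycles(gape_series, min_prominence):
        g = gape_series.values[start : end + 1]
        try:
            fc_sc, min_g, so_fo = detect_phases(g, gape_series.frame_rate, accel_smooth)
        except ValueError as exc:
            warnings.warn(f"skipping cycle [{start}, {end}]: {exc}")
            continue
        out.append(
            GapeCycle(
                start=start,
                end=end,
                fc_sc=start + fc_sc,
                min_gape=start + min_g,
                so_fo=start + so_fo,
                gape=g,
                frame_rate=gape_series.frame_rate,
            )
        )
    return out


def standardize_cycle(series: np.ndarray, n_out: int = 50) -> np.ndarray:
    """Resample a per-frame series onto ``n_out`` equally spaced points.

    Linear interpolation over the full cycle span (0-100% cycle); the first
    and last values are preserved exactly.  Masked (NaN) input frames
    propagate: an output point whose bracketing input interval touches a NaN
    is NaN.
    """
    y = np.asarray(series, dtype=float)
    if n_out < 2:
        raise ValueError("n_out must be at least 2")
    if y.shape[0] < 2:
        raise ValueError("series must have at least 2 samples")
    xp = np.linspace(0.0, 1.0, y.shape[0])
    x = np.linspace(0.0, 1.0, n_out)
    good = np.isfinite(y)
    if not good.any():
        return np.full(n_out, np.nan)
    out = np.interp(x, xp[good], y[good])
    if not good.all():
        # propagate the mask: any output point influenced by a NaN sample
        bad_frac = np.interp(x, xp, (~good).astype(float))
        out[bad_frac > 0] = np.nan
    return out


def average_cycles(
    standardized_cycles: np.ndarray | list[np.ndarray],
    group_labels: list | None = None,
) -> dict[object, tuple[np.ndarray, np.ndarray, int]]:
    """Pointwise mean and SD curves per group of standardised cycles.

    Returns ``{group: (mean, sd, n)}``; with no labels all cycles form the
    single group ``"all"``.  Empty groups are excluded with a warning.  SD is
    the sample standard deviation (ddof=1; zero for singleton groups).
    """
    arr = np.asarray(standardized_cycles, dtype=float)
    if arr.ndim != 2:
        raise ValueError("expected a (n_cycles, n_points) stack of standardised cycles")
    if group_labels is None:
        group_labels = ["all"] * arr.shape[0]
    if len(group_labels) != arr.shape[0]:
        raise ValueError("one group label per cycle required")
    out: dict[object, tuple[np.ndarray, np.ndarray, int]] = {}
    for group in dict.fromkeys(group_labels):
        rows = arr[[i for i, gl in enumerate(group_labels) if gl == group]]
        if rows.shape[0] == 0:
            warnings.warn(f"group {group!r} is empty; excluded")
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            mean = np.nanmean(rows, axis=0)
            sd = np.nanstd(rows, axis=0, ddof=1) if rows.shape[0] > 1 else np.zeros(arr.shape[1])
        out[group] = (mean, sd, rows.shape[0])
    return out
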