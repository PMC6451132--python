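"""Single-molecule trace selection.

Implements the standard smFRET acceptance criteria for donor/acceptor traces:
a single catastrophic photobleaching event, signal/background-noise >= 8,
signal/signal-noise >= 6, fewer than four donor blinking events, a
donor-acceptor correlation coefficient < 0.5, and at least 50 frames spent at
FRET >= 0.15 before photobleaching.

Conventions the criteria leave open (and how they are resolved here):

* signal/background-noise = mean pre-bleach total intensity over the SD of the
  post-bleach total intensity; signal/signal-noise = the same mean over the SD
  of the pre-bleach total intensity (blink frames excluded).
* the correlation coefficient is computed on the raw pre-bleach intensities; a
  moving-average-detrended mode is available.
* the 50-frame lifetime counts pre-bleach frames whose frame-wise (raw,
  pre-idealization) FRET is >= the floor.
* a blink is a pre-bleach interval of >= 1 frame at background in both
  channels followed by recovery.

Photobleach and blink detection work on the total intensity (donor+acceptor)
with a two-sample mean-shift step scan; a downward step counts as a bleach
step only when the signal never recovers above the step midpoint afterwards,
so blinks are never mistaken for partial bleaching.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import median_filter

from .synthetic_data import Trace, TraceDataset

__all__ = [
    "QCError",
    "NoSignalError",
    "BackgroundUndefinedError",
    "QCCriteria",
    "QCMetrics",
    "detect_photobleach",
    "compute_trace_metrics",
    "apply_qc",
]


class QCError(ValueError):
    """Base class for per-trace QC failures that abort metric computation."""


class NoSignalError(QCError):
    """The trace never rises above background."""


class BackgroundUndefinedError(QCError):
    """No usable post-bleach segment to estimate the background from."""


@dataclass(frozen=True)
class QCCriteria:
    """Trace-selection thresholds.

    ``max_blink_events`` and ``max_donor_acceptor_corr`` are exclusive bounds
    (the trace must have strictly fewer blinks / a strictly smaller
    correlation); the SNR and lifetime thresholds are inclusive.
    """

    max_bleach_events: int = 1
    min_signal_background_snr: float = 8.0
    min_signal_signal_snr: float = 6.0
    max_blink_events: int = 4
    max_donor_acceptor_corr: float = 0.5
    min_state_lifetime_frames: int = 50
    fret_floor: float = 0.15
    # step-scan configuration
    step_k: float = 4.0
    step_window: int = 5
    corr_detrended: bool = False
    corr_detrend_window: int = 51

    def __post_init__(self) -> None:
        if min(self.max_bleach_events, self.min_signal_background_snr,
               self.min_signal_signal_snr, self.max_blink_events,
               self.min_state_lifetime_frames, self.step_k,
               self.step_window) <= 0:
            raise ValueError("QC thresholds must be positive")
        if not (0.0 < self.fret_floor < 1.0):
            raise ValueError("fret_floor must lie in (0, 1)")


@dataclass(frozen=True)
class QCMetrics:
    bleach_frame: int | None
    n_bleach_steps: int
    snr_background: float
    snr_signal: float
    n_blinks: int
    donor_acceptor_corr: float
    frames_above_floor: int
    passed: bool
    flags: dict = field(default_factory=dict)

    @property
    def failure_reasons(self) -> list[str]:
        return [name for name, ok in self.flags.items() if not ok]


# ---------------------------------------------------------------------------
# Photobleach / step detection
# ---------------------------------------------------------------------------

def _robust_noise_sd(x: np.ndarray) -> float:
    """Noise SD from the median absolute successive difference."""
    d = np.diff(x)
    if len(d) == 0:
        return 0.0
    return float(np.median(np.abs(d)) * 1.4826 / np.sqrt(2.0))


def _mean_shift(x: np.ndarray, w: int) -> np.ndarray:
    """d[t] = mean(x[t:t+w]) - mean(x[t-w:t]) for t in [w, n-w]; NaN elsewhere."""
    n = len(x)
    d = np.full(n, np.nan)
    cs = np.concatenate([[0.0], np.cumsum(x)])
    t = np.arange(w, n - w + 1)
    after = (cs[t + w] - cs[t]) / w
    before = (cs[t] - cs[t - w]) / w
    d[t[t < n]] = (after - before)[t < n]
    return d


def _downward_steps(total: np.ndarray, w: int, threshold: float) -> list[int]:
    """Positions of distinct downward mean-shift steps below -threshold."""
    d = _mean_shift(total, w)
    cand = np.where(d < -threshold)[0]
    if len(cand) == 0:
        return []
    steps = []
    group = [cand[0]]
    for t in cand[1:]:
        if t - group[-1] <= w:
            group.append(t)
        else:
            steps.append(group[int(np.argmin(d[group]))])
            group = [t]
    steps.append(group[int(np.argmin(d[group]))])
    return steps


def detect_photobleach(
    trace: Trace, k: float = 4.0, window: int = 5
) -> tuple[int | None, int]:
    """Locate the final photobleach and count distinct bleach steps.

    Returns ``(bleach_frame, n_bleach_steps)``: the first frame of the final
    sustained drop to background (None when the trace never bleaches) and the
    number of non-recovering downward steps exceeding ``k * background_sd``
    (a two-fluorophore staircase gives 2; blinks recover and are not counted).

    Raises :class:`NoSignalError` for traces that never rise above background.
    """
    total = np.asarray(trace.total, dtype=float)
    n = len(total)
    if n < 20:
        raise QCError("trace too short for bleach detection (< 20 frames)")

    sigma = _robust_noise_sd(total)
    # signal level from a smoothed maximum so that short-lived signal
    # segments (early bleach) still register
    smooth = np.convolve(total, np.ones(window) / window, mode="valid")
    hi = float(np.max(smooth))
    # background level: the lowest sustained intensity level in the trace
    tail = float(np.min(median_filter(total, size=max(3, window),
                                      mode="nearest")))

    if hi < 4 * sigma or (sigma == 0 and hi == 0 and tail == 0):
        raise NoSignalError("trace never rises above background")

    bleached = (hi - tail) > max(4 * sigma, 0.25 * hi)
    bleach_frame: int | None = None
    if bleached:
        cut = tail + 0.25 * (hi - tail)
        off = total < cut
        # trailing contiguous off-run
        last_on = int(np.max(np.where(~off)[0])) if np.any(~off) else -1
        bleach_frame = last_on + 1
        if bleach_frame >= n:
            bleach_frame = None

    if bleach_frame is not None and n - bleach_frame >= 2:
        bg_sd = float(np.std(total[bleach_frame:]))
    else:
        bg_sd = sigma
    threshold = max(k * bg_sd, 1e-9 * max(hi, 1.0))

    n_steps = 0
    for t in _downward_steps(total, window, threshold):
        pre = np.mean(total[max(0, t - window):t])
        post = np.mean(total[t:t + window])
        midpoint = 0.5 * (pre + post)
        later = total[min(n, t + window):]
        recovered = later.size > 0 and bool(np.max(later) > midpoint + 2 * bg_sd)
        if not recovered:
            n_steps += 1
    if bleach_frame is not None and n_steps == 0:
        n_steps = 1  # classification found a sustained drop the scan missed
    return bleach_frame, n_steps


def _off_mask(total: np.ndarray, bleach_frame: int) -> np.ndarray:
    """Pre-bleach frames at background level in the total-intensity channel."""
    pre = total[:bleach_frame]
    hi = float(np.percentile(pre, 95))
    bg = float(np.median(total[bleach_frame:]))
    cut = bg + 0.25 * max(hi - bg, 0.0)
    return pre < cut


def _blink_runs(off: np.ndarray) -> list[tuple[int, int]]:
    """Maximal [start, stop) runs of True strictly inside the pre-bleach span."""
    padded = np.concatenate([[False], off, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(int)))
    return [(int(edges[i]), int(edges[i + 1])) for i in range(0, len(edges), 2)]


def _detrend(x: np.ndarray, window: int) -> np.ndarray:
    w = min(window, len(x))
    if w < 2:
        return x - np.mean(x)
    kernel = np.ones(w) / w
    baseline = np.convolve(x, kernel, mode="same")
    return x - baseline


# ---------------------------------------------------------------------------
# Per-trace metrics and filtering
# ---------------------------------------------------------------------------

def compute_trace_metrics(trace: Trace, criteria: QCCriteria | None = None) -> QCMetrics:
    """All selection metrics plus pass/fail flags for one trace.

    Raises :class:`BackgroundUndefinedError` when fewer than two post-bleach
    frames are available (the background SD is then undefined) and
    :class:`NoSignalError` for background-only traces; callers reject such
    traces.
    """
    criteria = criteria or QCCriteria()
    bleach_frame, n_steps = detect_photobleach(
        trace, k=criteria.step_k, window=criteria.step_window)
    total = np.asarray(trace.total, dtype=float)
    n = len(total)
    if bleach_frame is None or n - bleach_frame < 2:
        raise BackgroundUndefinedError(
            "fewer than 2 post-bleach frames; background SD undefined")

    off = _off_mask(total, bleach_frame)
    blinks = [r for r in _blink_runs(off) if r[1] < bleach_frame]
    on_pre = ~off
    pre_total = total[:bleach_frame]

    signal_mean = float(np.mean(pre_total[on_pre])) if np.any(on_pre) else 0.0
    bg_sd = float(np.std(total[bleach_frame:]))
    sig_sd = float(np.std(pre_total[on_pre])) if np.count_nonzero(on_pre) > 1 else 0.0
    with np.errstate(divide="ignore"):
        snr_background = signal_mean / bg_sd if bg_sd > 0 else np.inf
        snr_signal = signal_mean / sig_sd if sig_sd > 0 else np.inf

    d_pre = np.asarray(trace.donor, dtype=float)[:bleach_frame]
    a_pre = np.asarray(trace.acceptor, dtype=float)[:bleach_frame]
    if criteria.corr_detrended:
        d_c, a_c = (_detrend(d_pre, criteria.corr_detrend_window),
                    _detrend(a_pre, criteria.corr_detrend_window))
    else:
        d_c, a_c = d_pre, a_pre
    if np.std(d_c) == 0 or np.std(a_c) == 0:
        corr = 0.0
    else:
        corr = float(np.corrcoef(d_c, a_c)[0, 1])

    floor_intensity = 0.25 * signal_mean
    valid = pre_total > max(floor_intensity, 1e-12)
    with np.errstate(divide="ignore", invalid="ignore"):
        fret = np.where(valid, a_pre / np.where(valid, pre_total, 1.0), np.nan)
    frames_above = int(np.sum(fret[valid] >= criteria.fret_floor))

    flags = {
        "single_bleach": n_steps <= criteria.max_bleach_events,
        "snr_background": snr_background >= criteria.min_signal_background_snr,
        "snr_signal": snr_signal >= criteria.min_signal_signal_snr,
        "blinks": len(blinks) < criteria.max_blink_events,
        "donor_acceptor_corr": corr < criteria.max_donor_acceptor_corr,
        "lifetime": frames_above >= criteria.min_state_lifetime_frames,
    }
    return QCMetrics(
        bleach_frame=bleach_frame,
        n_bleach_steps=n_steps,
        snr_background=snr_background,
        snr_signal=snr_signal,
        n_blinks=len(blinks),
        donor_acceptor_corr=corr,
        frames_above_floor=frames_above,
        passed=all(flags.values()),
        flags=flags,
    )


def apply_qc(
    dataset: TraceDataset, criteria: QCCriteria | None = None
) -> tuple[TraceDataset, pd.DataFrame]:
    """Filter a dataset, keeping traces that pass every criterion.

    Returns the surviving dataset and a per-trace report (one row per input
    trace with every metric, per-criterion flags and failure reasons).  The
    filter is a pure function of (trace, criteria): running it twice yields
    the identical survivor set.
    """
    criteria = criteria or QCCriteria()
    if len(dataset) == 0:
        raise ValueError("dataset is empty")

    rows = []
    survivors = []
    for i, tr in enumerate(dataset.traces):
        try:
            m = compute_trace_metrics(tr, criteria)
        except QCError as exc:
            rows.append({
                "trace_id": i, "passed": False,
                "error": type(exc).__name__,
                "failure_reasons": type(exc).__name__,
            })
            continue
        row = {
            "trace_id": i,
            "bleach_frame": m.bleach_frame,
            "n_bleach_steps": m.n_bleach_steps,
            "snr_background": m.snr_background,
            "snr_signal": m.snr_signal,
            "n_blinks": m.n_blinks,
            "donor_acceptor_corr": m.donor_acceptor_corr,
            "frames_above_floor": m.frames_above_floor,
            "passed": m.passed,
            "error": "",
            "failure_reasons": ";".join(m.failure_reasons),
        }
        for name, ok in m.flags.items():
            row[f"pass_{name}"] = ok
        rows.append(row)
        if m.passed:
            survivors.append(tr)

    report = pd.DataFrame(rows)
    if not survivors:
        warnings.warn("no traces passed QC", stacklevel=2)
    filtered = TraceDataset(traces=tuple(survivors),
                            concentration=dataset.concentration,
                            model=dataset.model, seed=dataset.seed)
    return filtered, report
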