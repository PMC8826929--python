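"""Oscillation counting and feature extraction for Fura-2 calcium traces.

Traces are phase-annotated 340/380 ratio series from perifused islet
cells (e.g. a 3 mM glucose baseline phase followed by a 15 mM stimulation
phase).  Peaks within a phase are local maxima whose percent difference
above the median of the baseline phase exceeds a threshold (20% by
default); the per-phase peak count is the glucose-induced oscillation
number used for group comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "CalciumTrace",
    "PeakSet",
    "median_baseline",
    "detect_peaks",
    "count_oscillations",
    "extract_features",
    "local_maxima",
    "read_traces_csv",
    "traces_to_frame",
    "FEATURE_SET_VERSION",
]

FEATURE_SET_VERSION = "v1"

TRACE_CSV_COLUMNS = (
    "cell_id",
    "mouse_id",
    "time_s",
    "ratio",
    "phase_label",
    "phase_glucose_mM",
)


class TraceSchemaError(ValueError):
    """A calcium-trace CSV violates the declared schema."""


@dataclass(frozen=True)
class CalciumTrace:
    """A phase-annotated Fura-2 ratio trace, uniformly sampled.

    ``phases`` maps each sample to its phase label (same length as
    ``times``); phases must be contiguous blocks.
    """

    times: np.ndarray
    ratio: np.ndarray
    phases: np.ndarray
    cell_id: str = ""
    mouse_id: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        r = np.asarray(self.ratio, dtype=float)
        ph = np.asarray(self.phases)
        if t.ndim != 1 or len(t) < 2:
            raise ValueError("trace needs at least 2 samples")
        dt = np.diff(t)
        if np.any(dt <= 0):
            raise ValueError("times must be strictly increasing")
        if not np.allclose(dt, dt[0], rtol=1e-6):
            raise ValueError("sampling must be uniform within a trace")
        if len(r) != len(t) or len(ph) != len(t):
            raise ValueError("ratio and phases must align with times")
        if np.any(~np.isfinite(r)) or np.any(r <= 0):
            raise ValueError("ratio values must be finite and > 0")
        # phases must be contiguous: each label occupies one block
        change = np.flatnonzero(ph[1:] != ph[:-1])
        labels = [ph[0], *ph[change + 1]]
        if len(set(map(str, labels))) != len(labels):
            raise ValueError("phase labels must form contiguous blocks")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "ratio", r)
        object.__setattr__(self, "phases", ph)

    @property
    def phase_labels(self) -> List[str]:
        out: List[str] = []
        for p in map(str, self.phases):
            if not out or out[-1] != p:
                out.append(p)
        return out

    def phase_slice(self, label: str) -> slice:
        idx = np.flatnonzero(self.phases.astype(str) == str(label))
        if idx.size == 0:
            raise KeyError(f"phase {label!r} not present in trace")
        return slice(int(idx[0]), int(idx[-1]) + 1)


@dataclass(frozen=True)
class PeakSet:
    """Detected peaks within one phase of a trace."""

    phase: str
    peak_indices: np.ndarray  # absolute sample positions in the trace
    peak_times: np.ndarray
    peak_values: np.ndarray
    baseline_median: float
    threshold_pct: float

    def __post_init__(self) -> None:
        idx = np.asarray(self.peak_indices, dtype=int)
        if np.any(np.diff(idx) <= 0):
            raise ValueError("peak indices must be strictly increasing")
        object.__setattr__(self, "peak_indices", idx)

    @property
    def count(self) -> int:
        return len(self.peak_indices)


def median_baseline(trace: CalciumTrace, baseline_phase_label: str) -> float:
    """Median ratio within the baseline (low-glucose) phase."""
    sl = trace.phase_slice(baseline_phase_label)
    seg = trace.ratio[sl]
    if len(seg) < 3:
        raise ValueError(
            f"baseline phase {baseline_phase_label!r} needs >= 3 samples, has {len(seg)}"
        )
    return float(np.median(seg))


def local_maxima(values: np.ndarray) -> np.ndarray:
    """Indices of interior local maxima, plateaus counted once (leftmost).

    A sample is a local maximum if it is strictly greater than the nearest
    differing values on both sides; runs of equal values higher than both
    flanks count once at their leftmost index.  Segment endpoints are
    never maxima.
    """
    v = np.asarray(values, dtype=float)
    n = len(v)
    out: List[int] = []
    i = 1
    while i < n - 1:
        if v[i] <= v[i - 1]:
            i += 1
            continue
        # v[i] > v[i-1]; absorb any plateau
        j = i
        while j + 1 < n and v[j + 1] == v[i]:
            j += 1
        if j + 1 < n and v[j + 1] < v[i]:
            out.append(i)
        i = j + 1
    return np.asarray(out, dtype=int)


def detect_peaks(
    trace: CalciumTrace,
    phase_label: str,
    baseline: float,
    threshold_pct: float = 20.0,
    smooth_window: Optional[int] = None,
    refractory_s: float = 0.0,
) -> PeakSet:
    """Peaks in a phase: local maxima > ``threshold_pct``% above baseline.

    The percent difference is 100·(v − baseline)/baseline against the
    baseline-phase median.  ``smooth_window`` applies an optional
    moving-median pre-filter (odd width, samples) and ``refractory_s`` an
    optional minimum inter-peak spacing; both default off, matching the
    bare counting rule.
    """
    if baseline <= 0:
        raise ValueError("undefined percent difference: baseline must be > 0")
    sl = trace.phase_slice(phase_label)
    seg = trace.ratio[sl]
    if smooth_window and smooth_window > 1:
        if smooth_window % 2 == 0:
            raise ValueError("smooth_window must be odd")
        pad = smooth_window // 2
        padded = np.pad(seg, pad, mode="edge")
        seg = np.array(
            [np.median(padded[i : i + smooth_window]) for i in range(len(seg))]
        )
    cand = local_maxima(seg)
    keep = cand[100.0 * (seg[cand] - baseline) / baseline > threshold_pct]
    if refractory_s > 0 and len(keep) > 1:
        dt = trace.times[1] - trace.times[0]
        pruned = [keep[0]]
        for idx in keep[1:]:
            if (idx - pruned[-1]) * dt >= refractory_s:
                pruned.append(idx)
        keep = np.asarray(pruned, dtype=int)
    abs_idx = keep + sl.start
    return PeakSet(
        phase=str(phase_label),
        peak_indices=abs_idx,
        peak_times=trace.times[abs_idx],
        peak_values=trace.ratio[abs_idx],
        baseline_median=baseline,
        threshold_pct=threshold_pct,
    )


def count_oscillations(
    trace: CalciumTrace,
    stimulation_phase_label: str,
    baseline_phase_label: str = "3mM",
    threshold_pct: float = 20.0,
) -> int:
    """Number of oscillation peaks within the stimulation phase."""
    base = median_baseline(trace, baseline_phase_label)
    return detect_peaks(trace, stimulation_phase_label, base, threshold_pct).count


def extract_features(
    trace: CalciumTrace,
    baseline_phase_label: str = "3mM",
    stimulation_phase_label: str = "15mM",
    threshold_pct: float = 20.0,
) -> Dict[str, float]:
    """Default per-trace feature record (feature set ``v1``).

    Features: stimulation-phase peak count, baseline median, mean peak
    amplitude over baseline, time to first peak (s from stimulation
    onset; NaN if none), stimulation-phase AUC above baseline, mean
    peak-to-peak interval (s; NaN with < 2 peaks), trace maximum ratio,
    and phase-end plateau level (mean of the last 10% of stimulation
    samples).  Shift (additive-offset) invariance holds only for the
    amplitude-over-baseline and AUC-above-baseline features plus the
    intervals/counts; the baseline, max and plateau levels shift with the
    trace.
    """
    base = median_baseline(trace, baseline_phase_label)
    peaks = detect_peaks(trace, stimulation_phase_label, base, threshold_pct)
    sl = trace.phase_slice(stimulation_phase_label)
    seg_t = trace.times[sl]
    seg_r = trace.ratio[sl]
    n_tail = max(1, int(round(0.1 * len(seg_r))))
    if peaks.count:
        first_peak_latency = float(peaks.peak_times[0] - seg_t[0])
        mean_amp = float(np.mean(peaks.peak_values - base))
    else:
        first_peak_latency = float("nan")
        mean_amp = 0.0
    if peaks.count >= 2:
        p2p = float(np.mean(np.diff(peaks.peak_times)))
    else:
        p2p = float("nan")
    return {
        "feature_set": FEATURE_SET_VERSION,
        "peak_count": float(peaks.count),
        "baseline_median": base,
        "mean_peak_amplitude": mean_amp,
        "time_to_first_peak_s": first_peak_latency,
        "auc_above_baseline": float(np.trapezoid(np.clip(seg_r - base, 0.0, None), seg_t)),
        "peak_interval_mean_s": p2p,
        "max_ratio": float(np.max(trace.ratio)),
        "plateau_level": float(np.mean(seg_r[-n_tail:])),
    }


def read_traces_csv(path) -> List[CalciumTrace]:
    """Read a long-format trace CSV into per-cell CalciumTrace objects."""
    df = pd.read_csv(path)
    missing = set(TRACE_CSV_COLUMNS) - set(df.columns)
    if missing:
        raise TraceSchemaError(f"trace CSV missing columns: {sorted(missing)}")
    traces = []
    for (cell, mouse), sub in df.groupby(["cell_id", "mouse_id"], sort=False):
        sub = sub.sort_values("time_s")
        traces.append(
            CalciumTrace(
                times=sub["time_s"].to_numpy(dtype=float),
                ratio=sub["ratio"].to_numpy(dtype=float),
                phases=sub["phase_label"].to_numpy(),
                cell_id=str(cell),
                mouse_id=str(mouse),
            )
        )
    return traces


def traces_to_frame(
    traces: Sequence[CalciumTrace], phase_glucose: Dict[str, float]
) -> pd.DataFrame:
    """Long-format frame in the trace CSV schema."""
    parts = []
    for tr in traces:
        parts.append(
            pd.DataFrame(
                {
                    "cell_id": tr.cell_id,
                    "mouse_id": tr.mouse_id,
                    "time_s": tr.times,
                    "ratio": tr.ratio,
                    "phase_label": tr.phases,
                    "phase_glucose_mM": [phase_glucose[str(p)] for p in tr.phases],
                }
            )
        )
    return pd.concat(parts, ignore_index=True)
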