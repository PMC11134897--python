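"""NN-interval derivation: artifact/ectopic exclusion and stable-segment selection.

The cleaning stage relabels intervals (exclusion, not correction): an interval
is non-normal if it was annotated ectopic/artifact upstream, lies outside an
absolute physiological window, or deviates from the running median of the
previous ``median_window`` normal intervals by more than a fractional
threshold.  The segment stage extracts the most stable (minimum-SDNN)
contiguous run of exactly L normal intervals that starts after an initial
skip period, covering ~5 min at typical heart rates.
"""
from __future__ import annotations

from collections import deque
from dataclasses import dataclass
from statistics import median

import numpy as np

from .config import FilterConfig
from .errors import ConfigurationError, InsufficientDataError
from .series import ARTIFACT, ECTOPIC, NNSegment, NORMAL, RRSeries


@dataclass(frozen=True)
class CleanResult:
    """Cleaned series plus the exclusion report."""

    series: RRSeries
    n_excluded: int
    n_annotated: int       # rule (a): upstream ectopic/artifact annotations
    n_window: int          # rule (c): outside the physiological window
    n_median: int          # rule (b): running-median deviation

    @property
    def n_normal(self) -> int:
        return int(np.sum(self.series.labels == NORMAL))


def clean_to_nn(series: RRSeries, config: FilterConfig = FilterConfig()) -> CleanResult:
    """Relabel a recording so only sinus-origin (normal) intervals remain NN.

    The running-median rule only engages once ``median_window`` normal
    predecessors have accumulated; flagged intervals never enter the median
    buffer, which makes the operation idempotent.
    """
    if series.n == 0:
        raise InsufficientDataError("empty series")
    if config.median_window > series.n:
        raise ConfigurationError(
            f"median_window={config.median_window} exceeds series length {series.n}")
    values = series.intervals_ms.tolist()
    labels = series.labels.copy()
    w = config.median_window
    thr = config.threshold
    lo, hi = config.min_rr_ms, config.max_rr_ms
    recent: deque = deque(maxlen=w)
    n_annot = n_win = n_med = 0
    for i, x in enumerate(values):
        lab = labels[i]
        if lab == ECTOPIC or lab == ARTIFACT:
            n_annot += 1
            continue
        if not lo <= x <= hi:
            labels[i] = ARTIFACT
            n_win += 1
            continue
        if len(recent) == w:
            med = median(recent)
            if abs(x - med) > thr * med:
                labels[i] = ARTIFACT
                n_med += 1
                continue
        labels[i] = NORMAL
        recent.append(x)
    cleaned = series.with_labels(labels)
    return CleanResult(series=cleaned, n_excluded=n_annot + n_win + n_med,
                       n_annotated=n_annot, n_window=n_win, n_median=n_med)


def select_segment(series: RRSeries, L: int = 300, skip_s: float = 180.0,
                   min_rr_ms: float = 300.0, max_rr_ms: float = 2000.0) -> NNSegment:
    """Select the minimum-SDNN run of L consecutive NN intervals after ``skip_s``.

    Candidate windows start at every normal interval whose onset beat time is
    at or after ``skip_s``; contiguity is in the NN (normal-only) sequence.
    On SDNN ties the earliest window wins.
    """
    if L < 2:
        raise ConfigurationError("L must be >= 2")
    starts = series.interval_start_times_s
    ends = series.interval_end_times_s
    normal_idx = np.flatnonzero(series.labels == NORMAL)
    eligible = normal_idx[starts[normal_idx] >= skip_s]
    if eligible.size < L:
        raise InsufficientDataError(
            f"subject {series.subject_id!r} {series.timepoint}/{series.condition}: "
            f"only {eligible.size} normal intervals after {skip_s} s, need {L}")
    xs = series.intervals_ms[eligible]
    c1 = np.concatenate(([0.0], np.cumsum(xs)))
    c2 = np.concatenate(([0.0], np.cumsum(xs * xs)))
    s1 = c1[L:] - c1[:-L]
    s2 = c2[L:] - c2[:-L]
    var = np.maximum(s2 - s1 * s1 / L, 0.0) / (L - 1)
    j = int(np.argmin(var))  # first occurrence == earliest on ties
    sel = eligible[j:j + L]
    return NNSegment(
        nn_ms=series.intervals_ms[sel].copy(),
        end_times_s=ends[sel],
        start_time_s=float(starts[sel[0]]),
        condition=series.condition,
        timepoint=series.timepoint,
        subject_id=series.subject_id,
        min_rr_ms=min_rr_ms,
        max_rr_ms=max_rr_ms,
    )
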