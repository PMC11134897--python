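"""Beat-interval containers and the plain-text tachogram dialect.

A tachogram file carries one RR interval (ms) per line, optionally followed
by a whitespace-separated beat label; ``#``-prefixed lines are comments.  The
writer emits ``# key: value`` headers for subject/condition/timepoint so a
file round-trips without external metadata.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np

from .errors import ConfigurationError, InsufficientDataError

LABELS = ("normal", "ectopic", "artifact", "unknown")
NORMAL, ECTOPIC, ARTIFACT, UNKNOWN = LABELS


@dataclass
class RRSeries:
    """Annotated beat-to-beat RR interval sequence for one recording.

    ``beat_times_s`` has ``n + 1`` entries (a beat at each interval boundary);
    interval ``i`` spans ``beat_times_s[i]`` .. ``beat_times_s[i + 1]``.
    """

    intervals_ms: np.ndarray
    labels: np.ndarray
    condition: str = ""
    timepoint: str = ""
    subject_id: str = ""
    start_time_s: float = 0.0

    def __post_init__(self) -> None:
        self.intervals_ms = np.asarray(self.intervals_ms, dtype=float)
        self.labels = np.asarray(self.labels, dtype="<U8")
        if self.intervals_ms.ndim != 1 or self.intervals_ms.size == 0:
            raise InsufficientDataError("RRSeries requires a non-empty 1-D interval array")
        if self.labels.shape != self.intervals_ms.shape:
            raise ConfigurationError("labels must align with intervals")
        if np.any(self.intervals_ms <= 0):
            raise ConfigurationError("all RR intervals must be positive")
        bad = set(np.unique(self.labels)) - set(LABELS)
        if bad:
            raise ConfigurationError(f"unknown beat labels: {sorted(bad)}")

    @property
    def n(self) -> int:
        return int(self.intervals_ms.size)

    @property
    def beat_times_s(self) -> np.ndarray:
        t = np.empty(self.n + 1)
        t[0] = self.start_time_s
        np.cumsum(self.intervals_ms, out=t[1:])
        t[1:] = self.start_time_s + t[1:] / 1000.0
        return t

    @property
    def interval_start_times_s(self) -> np.ndarray:
        return self.beat_times_s[:-1]

    @property
    def interval_end_times_s(self) -> np.ndarray:
        return self.beat_times_s[1:]

    @property
    def duration_s(self) -> float:
        return float(self.intervals_ms.sum() / 1000.0)

    def with_labels(self, labels: np.ndarray) -> "RRSeries":
        return replace(self, labels=np.asarray(labels, dtype="<U8"))


@dataclass
class NNSegment:
    """A standardized run of exactly L consecutive normal-to-normal intervals.

    ``end_times_s[i]`` is the beat time closing interval ``i``; these are the
    tachogram abscissae used for spectral resampling.
    """

    nn_ms: np.ndarray
    end_times_s: np.ndarray
    start_time_s: float
    condition: str = ""
    timepoint: str = ""
    subject_id: str = ""
    min_rr_ms: float = 300.0
    max_rr_ms: float = 2000.0

    def __post_init__(self) -> None:
        self.nn_ms = np.asarray(self.nn_ms, dtype=float)
        self.end_times_s = np.asarray(self.end_times_s, dtype=float)
        if self.nn_ms.ndim != 1 or self.nn_ms.size < 2:
            raise InsufficientDataError("NNSegment requires at least 2 intervals")
        if self.end_times_s.shape != self.nn_ms.shape:
            raise ConfigurationError("end_times_s must align with nn_ms")
        if np.any(np.diff(self.end_times_s) <= 0):
            raise ConfigurationError("end times must be strictly increasing")
        if np.any((self.nn_ms < self.min_rr_ms) | (self.nn_ms > self.max_rr_ms)):
            raise ConfigurationError(
                f"NN values outside physiological window [{self.min_rr_ms}, {self.max_rr_ms}] ms")

    @property
    def length(self) -> int:
        return int(self.nn_ms.size)


def write_tachogram(series: RRSeries, path) -> None:
    path = Path(path)
    lines = [
        f"# subject: {series.subject_id}",
        f"# timepoint: {series.timepoint}",
        f"# condition: {series.condition}",
        f"# start_time_s: {series.start_time_s!r}",
    ]
    for v, lab in zip(series.intervals_ms, series.labels):
        lines.append(f"{float(v)!r}\t{lab}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_tachogram(path, *, subject_id: Optional[str] = None,
                   condition: Optional[str] = None,
                   timepoint: Optional[str] = None) -> RRSeries:
    path = Path(path)
    meta = {"subject": "", "condition": "", "timepoint": "", "start_time_s": "0.0"}
    vals, labs = [], []
    for lineno, raw in enumerate(path.read_text(encoding="utf-8").splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if ":" in body:
                k, _, v = body.partition(":")
                if k.strip() in meta:
                    meta[k.strip()] = v.strip()
            continue
        parts = line.split()
        try:
            vals.append(float(parts[0]))
        except ValueError as exc:
            raise ConfigurationError(f"{path}:{lineno}: not a number: {parts[0]!r}") from exc
        labs.append(parts[1] if len(parts) > 1 else UNKNOWN)
    if not vals:
        raise InsufficientDataError(f"{path}: no intervals found")
    return RRSeries(
        intervals_ms=np.array(vals),
        labels=np.array(labs, dtype="<U8"),
        subject_id=subject_id if subject_id is not None else meta["subject"],
        condition=condition if condition is not None else meta["condition"],
        timepoint=timepoint if timepoint is not None else meta["timepoint"],
        start_time_s=float(meta["start_time_s"]),
    )
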