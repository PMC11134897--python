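"""Per-subject autonomic reactivity deltas between supine rest and each maneuver.

The default sign convention is delta = maneuver - supine, so an index that
rises during a maneuver yields a positive delta and blunted reactivity shows
up as a smaller (possibly negative) delta.  The opposite convention
(supine - maneuver) is available through ``convention``.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Mapping

from .config import BREATHING, MANEUVERS, STANDING, SUPINE
from .errors import ConfigurationError, MissingDataError
from .indexes import INDEX_FIELDS, HRVIndexSet

MANEUVER_MINUS_SUPINE = "maneuver_minus_supine"
SUPINE_MINUS_MANEUVER = "supine_minus_maneuver"


@dataclass(frozen=True)
class DeltaSet:
    """Reactivity deltas for one subject/timepoint; NaN marks missing."""

    subject_id: str
    timepoint: str
    deltas: Dict[str, Dict[str, float]]  # maneuver -> index -> delta
    convention: str = MANEUVER_MINUS_SUPINE

    @property
    def delta_standing(self) -> Dict[str, float]:
        return self.deltas[STANDING]

    @property
    def delta_breathing(self) -> Dict[str, float]:
        return self.deltas[BREATHING]

    def get(self, index: str, maneuver: str) -> float:
        return self.deltas[maneuver][index]


def compute_deltas(indexes: Mapping[str, HRVIndexSet],
                   subject_id: str = "", timepoint: str = "",
                   convention: str = MANEUVER_MINUS_SUPINE) -> DeltaSet:
    """Compute delta(index, maneuver) for every index field.

    ``indexes`` maps condition name -> HRVIndexSet.  Supine must be present;
    a missing maneuver yields NaN deltas for that maneuver.
    """
    if convention not in (MANEUVER_MINUS_SUPINE, SUPINE_MINUS_MANEUVER):
        raise ConfigurationError(f"unknown delta convention {convention!r}")
    if SUPINE not in indexes:
        raise MissingDataError(
            f"subject {subject_id!r} {timepoint}: supine recording missing")
    if not any(m in indexes for m in MANEUVERS):
        raise MissingDataError(
            f"subject {subject_id!r} {timepoint}: no maneuver recording present")
    supine = indexes[SUPINE].as_dict()
    sign = 1.0 if convention == MANEUVER_MINUS_SUPINE else -1.0
    deltas: Dict[str, Dict[str, float]] = {}
    for maneuver in MANEUVERS:
        if maneuver in indexes and indexes[maneuver] is not None:
            mv = indexes[maneuver].as_dict()
            deltas[maneuver] = {k: sign * (mv[k] - supine[k]) for k in INDEX_FIELDS}
        else:
            deltas[maneuver] = {k: math.nan for k in INDEX_FIELDS}
    return DeltaSet(subject_id=subject_id, timepoint=timepoint,
                    deltas=deltas, convention=convention)
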