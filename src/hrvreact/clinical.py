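"""Clinical data containers: echocardiographic strain panel and subject record."""
from __future__ import annotations

from dataclasses import dataclass, field, fields as dc_fields
from typing import Dict, Optional

from .errors import ConfigurationError

ECHO_FIELDS = (
    "lvef3d_pct", "lv_edv_ml", "lv_esv_ml",
    "gls_pct", "gcs_pct", "grs_pct",
    "las_pct", "lasr_pct", "lasp_pct", "lasc_pct",
    "ras_pct", "rasr_pct", "rasp_pct", "rasc_pct",
    "lv_md",
)

_STRAIN_FIELDS = ("gls_pct", "gcs_pct", "grs_pct", "las_pct", "lasr_pct",
                  "lasp_pct", "lasc_pct", "ras_pct", "rasr_pct", "rasp_pct",
                  "rasc_pct")


@dataclass(frozen=True)
class EchoPanel:
    """One echocardiographic assessment: 3D volumes/EF, LV strains (GLS/GCS/GRS),
    left and right atrial phase strains, and mechanical dyssynchrony."""

    lvef3d_pct: float
    lv_edv_ml: float
    lv_esv_ml: float
    gls_pct: float
    gcs_pct: float
    grs_pct: float
    las_pct: float
    lasr_pct: float
    lasp_pct: float
    lasc_pct: float
    ras_pct: float
    rasr_pct: float
    rasp_pct: float
    rasc_pct: float
    lv_md: float

    def __post_init__(self) -> None:
        if not 0.0 < self.lvef3d_pct < 100.0:
            raise ConfigurationError(f"lvef3d_pct={self.lvef3d_pct} outside (0, 100)")
        for name in _STRAIN_FIELDS:
            v = getattr(self, name)
            if abs(v) >= 100.0:
                raise ConfigurationError(f"|{name}|={abs(v)} must be < 100")

    def as_dict(self) -> Dict[str, float]:
        return {f.name: getattr(self, f.name) for f in dc_fields(self)}


@dataclass
class SubjectRecord:
    """Joined per-subject view used by the cohort statistics stage."""

    subject_id: str
    group: Optional[str] = None
    echo: Dict[str, EchoPanel] = field(default_factory=dict)       # timepoint -> panel
    troponin_positive: Dict[str, bool] = field(default_factory=dict)
    deltas: dict = field(default_factory=dict)                     # timepoint -> DeltaSet
    indexes: dict = field(default_factory=dict)                    # (timepoint, condition) -> HRVIndexSet
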