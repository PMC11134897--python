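"""Synthetic study cohort generator.

Emulates the data structure of a three-condition autonomic challenge protocol
(supine rest, active standing, 0.1 Hz paced breathing; ~10 min each) recorded
at two timepoints, together with echocardiographic strain panels and troponin
flags.  The beat process is a modulated point process: the instantaneous
interval

    m(t) = RR0 * (1 + a_lf*sin(2*pi*0.1*t + phi) + a_hf*sin(2*pi*f_resp*t + psi)) + jitter

is evaluated at the current beat time and beats are emitted at cumulative
interval sums.  Active standing shortens RR0 and shifts the LF/HF amplitude
balance toward LF; paced breathing moves the respiratory component to 0.1 Hz
and amplifies it.  In the cardiotoxicity arm every condition-induced parameter
change is multiplied by ``lambda_reactivity`` (attenuated autonomic
reactivity); ``lambda_reactivity = 1`` reproduces the control law exactly.

Randomness is counter-based: each (subject, timepoint, condition) recording
and each subject's parameter/clinical draw has its own ``SeedSequence``
substream, so subject ``k`` is bit-identical regardless of cohort size.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np

from .clinical import ECHO_FIELDS, EchoPanel
from .config import (BASELINE, BREATHING, CONDITIONS, FOLLOWUP, STANDING,
                     SUPINE, TIMEPOINTS, SimConfig)
from .errors import ConfigurationError
from .series import ECTOPIC, NORMAL, RRSeries

CARDIOTOX = "cardiotox"
CONTROL = "control"

# substream tags (arbitrary distinct constants below 2**16)
_TAG_PARAMS = 101
_TAG_CLINICAL = 102
_TAG_RECORDING = 103

_COND_INDEX = {SUPINE: 0, STANDING: 1, BREATHING: 2}
_TP_INDEX = {BASELINE: 0, FOLLOWUP: 1}

# Echo panel baseline means/SDs for a mid-life female cohort with preserved
# systolic function (units: % except volumes in ml; LV_MD unitless index).
ECHO_BASELINE = {
    "lvef3d_pct": (63.53, 6.71),
    "lv_edv_ml": (78.66, 18.26),
    "lv_esv_ml": (28.74, 11.97),
    "gls_pct": (-23.93, 3.26),
    "gcs_pct": (-30.78, 3.99),
    "grs_pct": (46.33, 10.62),
    "las_pct": (60.23, 22.3),
    "lasr_pct": (59.05, 22.01),
    "lasp_pct": (26.11, 10.76),
    "lasc_pct": (34.5, 17.23),
    "ras_pct": (65.68, 22.1),
    "rasr_pct": (64.85, 21.96),
    "rasp_pct": (27.18, 13.96),
    "rasc_pct": (37.63, 14.29),
    "lv_md": (51.44, 11.21),
}

# Follow-up = baseline + N(drift_mean, drift_sd), per variable.  Control
# drifts are mild; cardiotoxicity-arm subjects with an "echo event" receive a
# criterion-sized LVEF drop and GLS magnitude loss instead.
ECHO_DRIFT_CONTROL = {
    "lvef3d_pct": (-0.6, 2.0),
    "lv_edv_ml": (-1.1, 5.0),
    "lv_esv_ml": (0.4, 3.0),
    "gls_pct": (0.6, 0.8),
    "gcs_pct": (2.5, 1.5),
    "grs_pct": (-3.7, 3.5),
    "las_pct": (-6.7, 6.5),
    "lasr_pct": (-5.5, 6.5),
    "lasp_pct": (-4.2, 3.2),
    "lasc_pct": (-2.8, 5.0),
    "ras_pct": (-8.2, 6.5),
    "rasr_pct": (-7.9, 6.5),
    "rasp_pct": (-2.4, 4.0),
    "rasc_pct": (-5.5, 4.2),
    "lv_md": (-1.5, 3.3),
}
ECHO_DRIFT_EVENT = {
    "lvef3d_pct": (-6.5, 3.0),
    "gls_pct": (4.0, 1.0),
}


@dataclass(frozen=True)
class SubjectParams:
    """Per-subject generative parameters (supine law)."""

    subject_id: str
    group: str
    rr0_ms: float
    a_lf: float
    a_hf: float

    def __post_init__(self) -> None:
        if self.rr0_ms <= 0:
            raise ConfigurationError("rr0_ms must be positive")
        if self.group not in (CARDIOTOX, CONTROL):
            raise ConfigurationError(f"unknown group {self.group!r}")


@dataclass
class SyntheticSubject:
    subject_id: str
    group: str
    params: SubjectParams
    recordings: Dict[Tuple[str, str], RRSeries] = field(default_factory=dict)
    echo: Dict[str, EchoPanel] = field(default_factory=dict)
    troponin_positive: Dict[str, bool] = field(default_factory=dict)


def recording_rng(seed: int, subject_index: int, timepoint: str, condition: str) -> np.random.Generator:
    """Counter-based substream for one recording."""
    key = [int(seed), _TAG_RECORDING, int(subject_index),
           _TP_INDEX[timepoint], _COND_INDEX[condition]]
    return np.random.default_rng(np.random.SeedSequence(key))


def subject_rng(seed: int, subject_index: int, tag: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), tag, int(subject_index)]))


def draw_subject_params(config: SimConfig, subject_index: int) -> SubjectParams:
    rng = subject_rng(config.seed, subject_index, _TAG_PARAMS)
    group = CARDIOTOX if rng.random() < config.p_cardiotox else CONTROL
    rr0 = float(np.clip(rng.normal(config.base_rr_ms, config.subject_rr_sd_ms),
                        500.0, 1400.0))
    lf_scale = float(rng.lognormal(0.0, config.subject_amp_cv))
    hf_scale = float(rng.lognormal(0.0, config.subject_amp_cv))
    return SubjectParams(
        subject_id=f"S{subject_index + 1:03d}",
        group=group,
        rr0_ms=rr0,
        a_lf=min(config.a_lf * lf_scale, 0.2),
        a_hf=min(config.a_hf * hf_scale, 0.2),
    )


def _condition_params(config: SimConfig, params: SubjectParams, condition: str,
                      timepoint: str) -> Tuple[float, float, float, float]:
    """Effective (rr0, a_lf, a_hf, f_resp) for one recording.

    Condition-induced changes are attenuated by lambda_reactivity in the
    cardiotoxicity arm; the supine law itself is group-independent.
    """
    lam = config.lambda_reactivity if params.group == CARDIOTOX else 1.0
    rr0, a_lf, a_hf = params.rr0_ms, params.a_lf, params.a_hf
    f_resp = config.f_resp_spont
    if condition == STANDING:
        shorten, lf_gain, hf_gain = config.standing_effect
        rr0 = rr0 * (1.0 - lam * shorten)
        a_lf = a_lf * (1.0 + lam * (lf_gain - 1.0))
        a_hf = a_hf * (1.0 + lam * (hf_gain - 1.0))
    elif condition == BREATHING:
        paced_gain, total_gain = config.breathing_effect
        f_resp = config.f_resp_paced
        a_hf = a_hf * (1.0 + lam * (paced_gain - 1.0))
        a_lf = a_lf * (1.0 + lam * (total_gain - 1.0))
    elif condition != SUPINE:
        raise ConfigurationError(f"unknown condition {condition!r}")
    if timepoint == FOLLOWUP:
        rr0 = rr0 * config.followup_rr_scale
    return rr0, a_lf, a_hf, f_resp


def _emit_beats(duration_s: float, rr0: float, a_lf: float, a_hf: float,
                f_resp: float, phi: float, psi: float, noise: Sequence[float]) -> list:
    sin = math.sin
    w1 = 2.0 * math.pi * 0.1
    w2 = 2.0 * math.pi * f_resp
    t = 0.0
    out = []
    append = out.append
    i = 0
    n_noise = len(noise)
    while t < duration_s:
        if i >= n_noise:  # pragma: no cover - noise buffer sized with ample margin
            raise ConfigurationError("noise buffer exhausted")
        m = rr0 * (1.0 + a_lf * sin(w1 * t + phi) + a_hf * sin(w2 * t + psi)) + noise[i]
        if m <= 0:
            raise ConfigurationError("generated a non-positive interval; "
                                     "reduce amplitudes or noise_sd_ms")
        append(m)
        t += m * 1e-3
        i += 1
    return out


def _inject_ectopics(intervals: np.ndarray, labels: np.ndarray,
                     p_ectopic: float, rng: np.random.Generator) -> None:
    """Replace selected beats by an early ectopic (0.7x the local interval)
    plus a compensatory pause, preserving the local beat-time sum; both
    affected intervals are annotated ectopic."""
    n = intervals.size
    if p_ectopic <= 0 or n < 2:
        rng.random(n)  # keep the draw count fixed for determinism
        return
    u = rng.random(n)
    k = 0
    while k < n - 1:
        if u[k] < p_ectopic:
            shift = 0.3 * intervals[k]
            intervals[k] -= shift
            intervals[k + 1] += shift
            labels[k] = ECTOPIC
            labels[k + 1] = ECTOPIC
            k += 2
        else:
            k += 1


def generate_rr_series(config: SimConfig, subject_params: SubjectParams,
                       condition: str, timepoint: str,
                       rng: Optional[np.random.Generator] = None,
                       subject_index: Optional[int] = None) -> RRSeries:
    """Generate one annotated recording for a subject/condition/timepoint.

    Either pass an explicit ``rng`` or a ``subject_index`` from which the
    recording substream is derived (``recording_rng``).
    """
    if config.duration_s <= 0:
        raise ConfigurationError("duration_s must be positive")
    if rng is None:
        if subject_index is None:
            raise ConfigurationError("provide rng or subject_index")
        rng = recording_rng(config.seed, subject_index, timepoint, condition)
    rr0, a_lf, a_hf, f_resp = _condition_params(config, subject_params, condition, timepoint)
    if a_lf + a_hf >= 1.0:
        raise ConfigurationError(
            f"a_lf + a_hf = {a_lf + a_hf:.3f} >= 1 would allow non-positive intervals")
    phi, psi = rng.uniform(0.0, 2.0 * math.pi, size=2)
    if condition == BREATHING:
        # paced breathing entrains the 0.1 Hz baroreflex oscillation: both
        # components share the breathing phase (coherent cardiorespiratory
        # coupling) instead of cancelling at random phase offsets
        psi = phi
    n_buf = int(config.duration_s * 1000.0 / rr0 / max(1.0 - a_lf - a_hf, 0.5) * 1.5) + 64
    if config.noise_sd_ms > 0:
        noise = rng.normal(0.0, config.noise_sd_ms, size=n_buf).tolist()
    else:
        rng.normal(0.0, 1.0, size=n_buf)  # keep the draw count fixed
        noise = [0.0] * n_buf
    intervals = np.asarray(_emit_beats(config.duration_s, rr0, a_lf, a_hf,
                                       f_resp, phi, psi, noise))
    labels = np.full(intervals.size, NORMAL, dtype="<U8")
    _inject_ectopics(intervals, labels, config.p_ectopic, rng)
    return RRSeries(intervals_ms=intervals, labels=labels, condition=condition,
                    timepoint=timepoint, subject_id=subject_params.subject_id)


def _clip_echo(name: str, value: float) -> float:
    if name == "lvef3d_pct":
        return float(np.clip(value, 5.0, 95.0))
    if name.endswith("_ml"):
        return float(max(value, 5.0))
    if name == "lv_md":
        return float(value)
    return float(np.clip(value, -99.0, 99.0))


def draw_clinical(config: SimConfig, subject_index: int,
                  group: str) -> Tuple[Dict[str, EchoPanel], Dict[str, bool]]:
    """Draw baseline/follow-up echo panels and troponin flags for one subject."""
    rng = subject_rng(config.seed, subject_index, _TAG_CLINICAL)
    base = {name: _clip_echo(name, rng.normal(mu, sd))
            for name, (mu, sd) in ECHO_BASELINE.items()}
    echo_event = group == CARDIOTOX and rng.random() < config.p_echo_event
    follow = {}
    for name in ECHO_FIELDS:
        mu, sd = ECHO_DRIFT_CONTROL[name]
        if echo_event and name in ECHO_DRIFT_EVENT:
            mu, sd = ECHO_DRIFT_EVENT[name]
        follow[name] = _clip_echo(name, base[name] + rng.normal(mu, sd))
    trop_base = bool(rng.random() < config.p_troponin_baseline)
    p_conv = config.p_troponin_case if group == CARDIOTOX else config.p_troponin_control
    trop_follow = bool(trop_base or rng.random() < p_conv)
    echo = {BASELINE: EchoPanel(**base), FOLLOWUP: EchoPanel(**follow)}
    return echo, {BASELINE: trop_base, FOLLOWUP: trop_follow}


def generate_cohort(config: SimConfig,
                    timepoints: Sequence[str] = TIMEPOINTS,
                    conditions: Sequence[str] = CONDITIONS,
                    include_clinical: bool = True) -> list:
    """Generate the full synthetic cohort (optionally restricted to a subset
    of timepoints/conditions; substreams make the subset identical to the
    corresponding slice of a full cohort)."""
    if config.n_subjects < 2:
        raise ConfigurationError("n_subjects must be >= 2")
    subjects = []
    for k in range(config.n_subjects):
        params = draw_subject_params(config, k)
        subject = SyntheticSubject(subject_id=params.subject_id,
                                   group=params.group, params=params)
        for tp in timepoints:
            for cond in conditions:
                subject.recordings[(tp, cond)] = generate_rr_series(
                    config, params, cond, tp, subject_index=k)
        if include_clinical:
            subject.echo, subject.troponin_positive = draw_clinical(
                config, k, params.group)
        subjects.append(subject)
    return subjects
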