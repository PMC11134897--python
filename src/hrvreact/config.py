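"""Configuration objects for simulation, preprocessing, spectral analysis and
clinical classification.

Every tunable the pipeline uses lives here with its default, so that a run can
be reproduced from a flat YAML file plus a seed.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Tuple

import yaml

from .errors import ConfigurationError

# protocol vocabulary -------------------------------------------------------
SUPINE = "supine"
STANDING = "standing"
BREATHING = "breathing"
CONDITIONS: Tuple[str, ...] = (SUPINE, STANDING, BREATHING)
MANEUVERS: Tuple[str, ...] = (STANDING, BREATHING)

BASELINE = "baseline"
FOLLOWUP = "followup"
TIMEPOINTS: Tuple[str, ...] = (BASELINE, FOLLOWUP)


@dataclass(frozen=True)
class SimConfig:
    """Generative parameters for the synthetic three-condition HRV protocol.

    The beat process modulates an instantaneous RR interval
    ``m(t) = RR0 * (1 + a_lf*sin(2*pi*0.1*t + phi) + a_hf*sin(2*pi*f_resp*t + psi))``
    plus white jitter; beats are emitted at cumulative interval sums.

    Parameters
    ----------
    n_subjects : cohort size.
    p_cardiotox : probability a subject is assigned to the cardiotoxicity arm.
    seed : master seed; every subject/recording derives a counter-based
        substream from it, so subject ``k`` is invariant to ``n_subjects``.
    duration_s : recording length per condition, seconds.
    base_rr_ms : population mean supine RR interval, ms.
    a_lf, a_hf : fractional modulation amplitudes of the 0.1 Hz (baroreflex)
        and respiratory components in supine rest.
    f_resp_spont, f_resp_paced : spontaneous / paced breathing rates, Hz.
    standing_effect : (RR shortening fraction, LF amplitude gain, HF amplitude
        gain < 1) applied on active standing.
    breathing_effect : (paced-band amplitude gain applied to the respiratory
        component, total-variability gain applied to the LF component) during
        0.1 Hz paced breathing.
    lambda_reactivity : attenuation in [0, 1] multiplying condition-induced
        parameter changes in the cardiotoxicity arm; 1 reproduces the control
        generative law exactly.
    p_ectopic : per-beat probability of an inserted ectopic (early beat at
        0.7x the local interval followed by a compensatory pause preserving
        the local beat-time sum).
    noise_sd_ms : SD of white interval jitter, ms.
    followup_rr_scale : multiplicative RR shortening applied to every
        follow-up recording (higher mean HR after chemotherapy).
    subject_rr_sd_ms : between-subject SD of the supine RR mean.
    subject_amp_cv : lognormal sigma of per-subject amplitude multipliers.
    p_echo_event, p_troponin_case, p_troponin_control, p_troponin_baseline :
        probabilities governing the clinical-event layer (echo
        criterion-satisfying strain/LVEF shift in the cardiotoxicity arm;
        troponin conversion per arm; baseline troponin positivity).
    """

    n_subjects: int = 50
    p_cardiotox: float = 0.46
    seed: int = 0
    duration_s: float = 600.0
    base_rr_ms: float = 850.0
    a_lf: float = 0.03
    a_hf: float = 0.03
    f_resp_spont: float = 0.25
    f_resp_paced: float = 0.1
    standing_effect: Tuple[float, float, float] = (0.15, 1.5, 0.5)
    breathing_effect: Tuple[float, float] = (2.0, 1.3)
    lambda_reactivity: float = 0.3
    p_ectopic: float = 0.003
    noise_sd_ms: float = 10.0
    followup_rr_scale: float = 0.96
    subject_rr_sd_ms: float = 60.0
    subject_amp_cv: float = 0.2
    p_echo_event: float = 0.8
    p_troponin_case: float = 0.7
    p_troponin_control: float = 0.02
    p_troponin_baseline: float = 0.02

    def __post_init__(self) -> None:
        for name in ("p_cardiotox", "p_ectopic", "p_echo_event",
                     "p_troponin_case", "p_troponin_control",
                     "p_troponin_baseline", "lambda_reactivity"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name}={v} must lie in [0, 1]")
        if self.duration_s <= 0:
            raise ConfigurationError("duration_s must be positive")
        if not 400.0 <= self.base_rr_ms <= 1500.0:
            raise ConfigurationError("base_rr_ms must lie in [400, 1500] ms")
        for name in ("a_lf", "a_hf"):
            v = getattr(self, name)
            if not 0.0 <= v <= 0.2:
                raise ConfigurationError(f"{name}={v} must lie in [0, 0.2]")
        if self.f_resp_spont <= 0 or self.f_resp_paced <= 0:
            raise ConfigurationError("breathing rates must be positive")
        if len(self.standing_effect) != 3 or len(self.breathing_effect) != 2:
            raise ConfigurationError("standing_effect is a triple, breathing_effect a pair")


@dataclass(frozen=True)
class FilterConfig:
    """Ectopic/artifact exclusion rules for NN-interval derivation.

    An interval is flagged non-normal if it is annotated ectopic/artifact,
    deviates from the running median of the previous ``median_window`` normal
    intervals by more than ``threshold`` (fractional), or falls outside the
    absolute physiological window [min_rr_ms, max_rr_ms].
    """

    median_window: int = 11
    threshold: float = 0.20
    min_rr_ms: float = 300.0
    max_rr_ms: float = 2000.0

    def __post_init__(self) -> None:
        if self.median_window < 1:
            raise ConfigurationError("median_window must be >= 1")
        if not 0 < self.threshold < 1:
            raise ConfigurationError("threshold must lie in (0, 1)")
        if not 0 < self.min_rr_ms < self.max_rr_ms:
            raise ConfigurationError("need 0 < min_rr_ms < max_rr_ms")


@dataclass(frozen=True)
class WelchSettings:
    """Spectral estimation settings for the resampled tachogram.

    Defaults: linear interpolation to 3 Hz, Hann window of 256 samples
    (~85 s), 50% overlap, per-window constant detrend, one-sided density
    normalisation (integral of the PSD approximates the sample variance).
    ``nu_denominator`` selects what normalised units are relative to:
    ``"lf_hf"`` (LF+HF) or ``"total"`` (all power up to 0.4 Hz).
    """

    resample_hz: float = 3.0
    window: str = "hann"
    nperseg: int = 256
    overlap: float = 0.5
    detrend: str = "constant"
    nu_denominator: str = "lf_hf"
    lf_band: Tuple[float, float] = (0.04, 0.15)
    hf_band: Tuple[float, float] = (0.15, 0.4)

    def __post_init__(self) -> None:
        if self.resample_hz <= 0:
            raise ConfigurationError("resample_hz must be positive")
        if not 0 <= self.overlap < 1:
            raise ConfigurationError("overlap must lie in [0, 1)")
        if self.nu_denominator not in ("lf_hf", "total"):
            raise ConfigurationError("nu_denominator must be 'lf_hf' or 'total'")


@dataclass(frozen=True)
class CriteriaConfig:
    """Clinical classification thresholds (all configurable stand-ins).

    Echo criterion: follow-up LVEF 3D below ``lvef_threshold_pct`` together
    with an absolute drop of at least ``lvef_drop_pct`` points, OR a relative
    GLS magnitude reduction greater than ``gls_relative_reduction``.
    Troponin criterion: new follow-up positivity.
    LASr significant reduction uses ``lasr_normal_pct`` and
    ``lasr_relative_reduction``.
    """

    lvef_threshold_pct: float = 53.0
    lvef_drop_pct: float = 10.0
    gls_relative_reduction: float = 0.10
    lasr_normal_pct: float = 35.0
    lasr_relative_reduction: float = 0.10
    delta_convention: str = "maneuver_minus_supine"

    def __post_init__(self) -> None:
        if self.delta_convention not in ("maneuver_minus_supine", "supine_minus_maneuver"):
            raise ConfigurationError(
                "delta_convention must be 'maneuver_minus_supine' or 'supine_minus_maneuver'")


def _tuplify(cfg: SimConfig) -> SimConfig:
    return dataclasses.replace(
        cfg,
        standing_effect=tuple(cfg.standing_effect),
        breathing_effect=tuple(cfg.breathing_effect),
    )


def sim_config_to_yaml(cfg: SimConfig) -> str:
    d = dataclasses.asdict(cfg)
    d["standing_effect"] = list(cfg.standing_effect)
    d["breathing_effect"] = list(cfg.breathing_effect)
    return yaml.safe_dump(d, sort_keys=True)


def sim_config_from_yaml(text: str) -> SimConfig:
    raw = yaml.safe_load(text) or {}
    known = {f.name for f in dataclasses.fields(SimConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
    for key in ("standing_effect", "breathing_effect"):
        if key in raw:
            raw[key] = tuple(raw[key])
    return _tuplify(SimConfig(**raw))


def load_sim_config(path) -> SimConfig:
    with open(path, "r", encoding="utf-8") as fh:
        return sim_config_from_yaml(fh.read())
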