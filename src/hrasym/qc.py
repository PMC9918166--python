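"""Recording-level quality control and eligibility rules.

A 24-h recording enters the asymmetry analysis only if it is long enough,
predominantly sinus, and free of dense or repetitive ectopy: at least 18 h,
at least 90% sinus beats, fewer than 100 ectopics within any one hour, and
no ectopic pairs or runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .recording import RRRecording

__all__ = ["QCRules", "QCReport", "qc_recording"]

#: identifiers used in QCReport.reasons
RULE_SINUS_FRACTION = "sinus_fraction_below_min"
RULE_DURATION = "duration_below_min"
RULE_ECTOPIC_DENSITY = "ectopics_per_hour_at_threshold"
RULE_PAIR_OR_RUN = "ectopic_pair_or_run"


@dataclass(frozen=True)
class QCRules:
    """Eligibility thresholds for one Holter recording."""

    min_sinus_fraction: float = 0.90
    min_duration_h: float = 18.0
    max_ectopics_per_hour: int = 100  # recording excluded when reached
    exclude_on_runs: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.min_sinus_fraction <= 1:
            raise ValueError("min_sinus_fraction must be in (0, 1]")
        if not self.min_duration_h > 0:
            raise ValueError("min_duration_h must be positive")


@dataclass(frozen=True)
class QCReport:
    sinus_fraction: float
    duration_h: float
    worst_hour_ectopics: int
    has_pair: bool  # >=2 consecutive ectopic beats
    has_run: bool  # >=3 consecutive ectopic beats
    eligible: bool
    reasons: tuple[str, ...] = field(default_factory=tuple)


def _worst_hour_ectopics(rec: RRRecording) -> int:
    """Max number of ectopic beats inside any sliding 1-h window.

    Windows are anchored at beat times (end of each RR interval); the
    maximum over all windows is attained anchored at an ectopic beat, so
    only ectopic timestamps need scanning.
    """
    times = np.cumsum(rec.rr_ms)
    ect = times[rec.is_ectopic]
    if ect.size == 0:
        return 0
    # two-pointer over sorted ectopic times: count within [t_i, t_i + 1h)
    upper = np.searchsorted(ect, ect + 3.6e6, side="left")
    return int((upper - np.arange(ect.size)).max())


def _pair_and_run(rec: RRRecording) -> tuple[bool, bool]:
    ect = rec.is_ectopic
    if ect.size < 2:
        return False, False
    pair = bool(np.any(ect[:-1] & ect[1:]))
    run = bool(ect.size >= 3 and np.any(ect[:-2] & ect[1:-1] & ect[2:]))
    return pair, run


def qc_recording(rec: RRRecording, rules: QCRules = QCRules()) -> QCReport:
    """Apply the eligibility rules to one recording (pure function)."""
    if rec.n_beats == 0:
        raise ValueError("empty recording")
    sinus_fraction = rec.sinus_fraction
    duration_h = rec.duration_h
    worst = _worst_hour_ectopics(rec)
    has_pair, has_run = _pair_and_run(rec)

    reasons: list[str] = []
    if sinus_fraction < rules.min_sinus_fraction:
        reasons.append(RULE_SINUS_FRACTION)
    if duration_h < rules.min_duration_h:
        reasons.append(RULE_DURATION)
    if worst >= rules.max_ectopics_per_hour:
        reasons.append(RULE_ECTOPIC_DENSITY)
    if rules.exclude_on_runs and (has_pair or has_run):
        reasons.append(RULE_PAIR_OR_RUN)

    return QCReport(
        sinus_fraction=sinus_fraction,
        duration_h=duration_h,
        worst_hour_ectopics=worst,
        has_pair=has_pair,
        has_run=has_run,
        eligible=not reasons,
        reasons=tuple(reasons),
    )
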