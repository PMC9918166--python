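"""Poincaré-plot variance decomposition and heart rate asymmetry descriptors.

The Poincaré plot scatters each normal-to-normal interval RRn against its
successor RRn+1.  Points above the identity line are heart-rate
decelerations (RRn+1 > RRn), points below it accelerations.  Short-term
variability SD1² is the variance of the signed transverse distance to the
identity line, long-term variability SD2² the variance of the coordinate
along it, and total variability obeys 2·SDNN² = SD1² + SD2².  Each variance
splits exactly into a deceleration and an acceleration part:

    SD1² = SD1d² + SD1a²,   SD2² = SD2d² + SD2a²,   SDNN² = SDNNd² + SDNNa²

and the asymmetry indices are the deceleration shares

    C1d = SD1d²/SD1²  (Guzik's index),  C2d = SD2d²/SD2²,  CTd = SDNNd²/SDNN²,
    Nd  = nd/(nd + na)  (Porta's index; counts of decelerations/accelerations).

Conventions (stated because the identities above are asserted exactly):

* every component variance is normalised by the total number of plot points
  n (population convention), so the additive identities hold exactly;
* points on the identity line contribute zero to the SD1 parts (their
  transverse distance is zero) and are split half-and-half between SD2d²
  and SD2a², preserving SD2d² + SD2a² = SD2²;
* SDNN² := (SD1² + SD2²)/2 over plot points, and SDNNd² := (SD1d² + SD2d²)/2,
  making 2·SDNN² = SD1² + SD2² an identity rather than an asymptotic fact;
* a ratio whose denominator is zero is undefined (NaN + validity flag),
  never coerced to 0.5 or 0.

HRA phenotypes (all strict inequalities): HRA1 when C1d > 0.5, HRA2 when
C2d < 0.5, HRAT when CTd < 0.5, HRAcomp when HRA1 and HRA2 both hold, and
HRAN when Nd < 0.5.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .qc import QCReport, QCRules, qc_recording
from .recording import RRRecording, normal_pairs

__all__ = [
    "PoincarePlot",
    "HRADescriptors",
    "HRAFlags",
    "build_poincare",
    "descriptors",
    "classify_hra",
    "analyze_recording",
]

_SQRT2 = math.sqrt(2.0)


@dataclass(frozen=True)
class PoincarePlot:
    """Paired (RRn, RRn+1) points with deceleration/acceleration labels."""

    x: np.ndarray  # RRn, ms
    y: np.ndarray  # RRn+1, ms

    def __post_init__(self) -> None:
        object.__setattr__(self, "x", np.asarray(self.x, dtype=float))
        object.__setattr__(self, "y", np.asarray(self.y, dtype=float))
        if self.x.shape != self.y.shape or self.x.ndim != 1:
            raise ValueError("x and y must be equal-length 1-D arrays")
        if self.x.size < 2:
            raise ValueError("a Poincaré plot needs at least 2 points")

    @property
    def n_points(self) -> int:
        return int(self.x.size)

    @property
    def decelerations(self) -> np.ndarray:
        """Points above the identity line (RRn+1 > RRn)."""
        return self.y > self.x

    @property
    def accelerations(self) -> np.ndarray:
        """Points below the identity line (RRn+1 < RRn)."""
        return self.y < self.x

    @property
    def nochange(self) -> np.ndarray:
        """Points on the identity line (RRn+1 = RRn)."""
        return self.y == self.x


def build_poincare(pairs: tuple[np.ndarray, np.ndarray]) -> PoincarePlot:
    """Build the plot from ``(RRn, RRn+1)`` pair arrays; no point is discarded."""
    x, y = pairs
    return PoincarePlot(x=np.asarray(x, float), y=np.asarray(y, float))


@dataclass(frozen=True)
class HRADescriptors:
    """The full descriptor set for one recording.

    Dispersions are in ms (square roots of their variance counterparts);
    contribution indices are unitless ratios in [0, 1], NaN when undefined.
    """

    sd1d: float
    sd1a: float
    sd1: float
    sd2d: float
    sd2a: float
    sd2: float
    sdnnd: float
    sdnna: float
    sdnn: float
    c1d: float
    c2d: float
    ctd: float
    nd: float
    nd_count: int
    na_count: int
    n_nochange: int
    n_points: int

    # -- validity ------------------------------------------------------
    @property
    def c1d_defined(self) -> bool:
        return not math.isnan(self.c1d)

    @property
    def c2d_defined(self) -> bool:
        return not math.isnan(self.c2d)

    @property
    def ctd_defined(self) -> bool:
        return not math.isnan(self.ctd)

    @property
    def nd_defined(self) -> bool:
        return not math.isnan(self.nd)

    @property
    def all_defined(self) -> bool:
        return self.c1d_defined and self.c2d_defined and self.ctd_defined and self.nd_defined

    # -- complements ---------------------------------------------------
    @property
    def c1a(self) -> float:
        return 1.0 - self.c1d

    @property
    def c2a(self) -> float:
        return 1.0 - self.c2d

    @property
    def cta(self) -> float:
        return 1.0 - self.ctd

    def as_dict(self) -> dict[str, float]:
        return {
            "sd1d": self.sd1d, "sd1a": self.sd1a, "sd1": self.sd1,
            "sd2d": self.sd2d, "sd2a": self.sd2a, "sd2": self.sd2,
            "sdnnd": self.sdnnd, "sdnna": self.sdnna, "sdnn": self.sdnn,
            "c1d": self.c1d, "c2d": self.c2d, "ctd": self.ctd, "nd": self.nd,
            "nd_count": self.nd_count, "na_count": self.na_count,
            "n_nochange": self.n_nochange, "n_points": self.n_points,
        }


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else float("nan")


def descriptors(plot: PoincarePlot) -> HRADescriptors:
    """Compute every variance-based and count-based asymmetry descriptor."""
    x, y = plot.x, plot.y
    n = plot.n_points
    dec = plot.decelerations
    acc = plot.accelerations
    noc = plot.nochange

    # signed transverse distance to the identity line and coordinate along it
    d2 = ((x - y) / _SQRT2) ** 2
    ell = (x + y) / _SQRT2
    ell2 = (ell - ell.mean()) ** 2

    sd1d2 = float(d2[dec].sum()) / n
    sd1a2 = float(d2[acc].sum()) / n
    sd1_2 = sd1d2 + sd1a2  # no-change points have d = 0

    half_noc = 0.5 * float(ell2[noc].sum())
    sd2d2 = (float(ell2[dec].sum()) + half_noc) / n
    sd2a2 = (float(ell2[acc].sum()) + half_noc) / n
    sd2_2 = sd2d2 + sd2a2

    sdnnd2 = 0.5 * (sd1d2 + sd2d2)
    sdnna2 = 0.5 * (sd1a2 + sd2a2)
    sdnn2 = sdnnd2 + sdnna2

    nd_count = int(dec.sum())
    na_count = int(acc.sum())

    return HRADescriptors(
        sd1d=math.sqrt(sd1d2), sd1a=math.sqrt(sd1a2), sd1=math.sqrt(sd1_2),
        sd2d=math.sqrt(sd2d2), sd2a=math.sqrt(sd2a2), sd2=math.sqrt(sd2_2),
        sdnnd=math.sqrt(sdnnd2), sdnna=math.sqrt(sdnna2), sdnn=math.sqrt(sdnn2),
        c1d=_ratio(sd1d2, sd1_2),
        c2d=_ratio(sd2d2, sd2_2),
        ctd=_ratio(sdnnd2, sdnn2),
        nd=_ratio(float(nd_count), float(nd_count + na_count)),
        nd_count=nd_count,
        na_count=na_count,
        n_nochange=int(noc.sum()),
        n_points=n,
    )


@dataclass(frozen=True)
class HRAFlags:
    """Presence of the five asymmetry phenotypes for one recording."""

    hra1: bool
    hra2: bool
    hrat: bool
    hran: bool
    hracomp: bool
    defined: bool

    def as_dict(self) -> dict[str, bool]:
        return {
            "hra1": self.hra1, "hra2": self.hra2, "hrat": self.hrat,
            "hran": self.hran, "hracomp": self.hracomp, "defined": self.defined,
        }


def classify_hra(desc: HRADescriptors) -> HRAFlags:
    """Strict-threshold phenotype calls; unusable when any ratio is undefined."""
    defined = desc.all_defined
    hra1 = defined and desc.c1d > 0.5
    hra2 = defined and desc.c2d < 0.5
    hrat = defined and desc.ctd < 0.5
    hran = defined and desc.nd < 0.5
    return HRAFlags(
        hra1=hra1, hra2=hra2, hrat=hrat, hran=hran,
        hracomp=hra1 and hra2, defined=defined,
    )


def analyze_recording(
    rec: RRRecording, rules: QCRules = QCRules()
) -> tuple[QCReport, HRADescriptors | None, HRAFlags | None]:
    """QC a recording and, if eligible, compute one whole-recording
    descriptor set (no windowing) and its phenotype flags."""
    report = qc_recording(rec, rules)
    if not report.eligible:
        return report, None, None
    try:
        plot = build_poincare(normal_pairs(rec))
    except ValueError as exc:
        report = QCReport(
            sinus_fraction=report.sinus_fraction,
            duration_h=report.duration_h,
            worst_hour_ectopics=report.worst_hour_ectopics,
            has_pair=report.has_pair,
            has_run=report.has_run,
            eligible=False,
            reasons=report.reasons + (f"analysis_failed:{exc}",),
        )
        return report, None, None
    desc = descriptors(plot)
    return report, desc, classify_hra(desc)
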