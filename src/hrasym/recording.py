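"""Annotated RR-interval recordings and their plain-text exchange format.

A Holter analysis system exports one beat per line: the RR interval in
milliseconds followed by a beat-type annotation (sinus, supraventricular,
ventricular, or technical artifact).  Subject metadata (id, age, sex) is
carried in a sidecar CSV, never in the RR file itself.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BeatAnnotation",
    "RRRecording",
    "RRParseError",
    "read_rr_file",
    "write_rr_file",
    "read_manifest",
    "normal_pairs",
    "DEFAULT_CODES",
]


class BeatAnnotation(enum.Enum):
    """Beat type attached to each RR interval by the Holter analysis."""

    SINUS = "N"
    SUPRAVENTRICULAR = "S"
    VENTRICULAR = "V"
    ARTIFACT = "A"


#: single-letter dialect used in exported text files; remappable per vendor
DEFAULT_CODES: Mapping[str, BeatAnnotation] = {
    "N": BeatAnnotation.SINUS,
    "S": BeatAnnotation.SUPRAVENTRICULAR,
    "V": BeatAnnotation.VENTRICULAR,
    "A": BeatAnnotation.ARTIFACT,
}


class RRParseError(ValueError):
    """Raised for malformed or invalid RR-interval files."""


@dataclass
class RRRecording:
    """An ordered, annotated RR-interval series for one subject.

    ``rr_ms`` holds the interval durations in acquisition order;
    ``annotations`` holds the matching single-letter beat codes
    (``N``/``S``/``V``/``A``).  All intervals are strictly positive.
    """

    subject_id: str
    rr_ms: np.ndarray
    annotations: np.ndarray
    age: float | None = None
    sex: str | None = None

    def __post_init__(self) -> None:
        self.rr_ms = np.asarray(self.rr_ms, dtype=float)
        self.annotations = np.asarray(self.annotations, dtype="U1")
        if self.rr_ms.ndim != 1:
            raise ValueError("rr_ms must be one-dimensional")
        if self.rr_ms.shape != self.annotations.shape:
            raise ValueError("rr_ms and annotations must have equal length")
        if self.rr_ms.size and not np.all(self.rr_ms > 0):
            raise RRParseError("all RR intervals must be strictly positive")
        valid = {a.value for a in BeatAnnotation}
        bad = set(np.unique(self.annotations)) - valid
        if bad:
            raise RRParseError(f"unknown beat annotation codes: {sorted(bad)}")
        if self.age is not None and not self.age > 0:
            raise ValueError("age must be positive")
        if self.sex is not None and self.sex not in ("girl", "boy"):
            raise ValueError("sex must be 'girl' or 'boy'")

    @property
    def n_beats(self) -> int:
        return int(self.rr_ms.size)

    @property
    def duration_ms(self) -> float:
        """Total recording time, from summed RR intervals."""
        return float(self.rr_ms.sum())

    @property
    def duration_h(self) -> float:
        return self.duration_ms / 3.6e6

    @property
    def is_sinus(self) -> np.ndarray:
        return self.annotations == BeatAnnotation.SINUS.value

    @property
    def is_ectopic(self) -> np.ndarray:
        """Supraventricular or ventricular beats (artifacts are not ectopics)."""
        return (self.annotations == BeatAnnotation.SUPRAVENTRICULAR.value) | (
            self.annotations == BeatAnnotation.VENTRICULAR.value
        )

    @property
    def sinus_fraction(self) -> float:
        if self.n_beats == 0:
            raise ValueError("empty recording")
        return float(self.is_sinus.mean())


def read_rr_file(
    path: str | Path,
    *,
    codes: Mapping[str, BeatAnnotation] = DEFAULT_CODES,
    subject_id: str | None = None,
    age: float | None = None,
    sex: str | None = None,
) -> RRRecording:
    """Parse a plain-text RR export: one beat per line, ``rr_ms [annotation]``.

    Lines starting with ``#`` and blank lines are skipped.  A file without an
    annotation column is the annotation-free dialect: every beat is sinus.
    Malformed lines raise :class:`RRParseError` naming the line number.
    """
    path = Path(path)
    rr: list[float] = []
    ann: list[str] = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) > 2:
                raise RRParseError(f"{path.name}:{lineno}: expected 'rr_ms [annotation]', got {line!r}")
            try:
                value = float(fields[0])
            except ValueError:
                raise RRParseError(f"{path.name}:{lineno}: RR interval {fields[0]!r} is not a number") from None
            if not value > 0:
                raise RRParseError(f"{path.name}:{lineno}: non-positive RR interval {value}")
            if len(fields) == 2:
                code = fields[1]
                if code not in codes:
                    raise RRParseError(f"{path.name}:{lineno}: unknown annotation code {code!r}")
                ann.append(codes[code].value)
            else:
                ann.append(BeatAnnotation.SINUS.value)
            rr.append(value)
    return RRRecording(
        subject_id=subject_id or path.stem,
        rr_ms=np.array(rr, dtype=float),
        annotations=np.array(ann, dtype="U1"),
        age=age,
        sex=sex,
    )


def write_rr_file(rec: RRRecording, path: str | Path) -> None:
    """Write the one-beat-per-line text dialect (exact round-trip of values)."""
    path = Path(path)
    with path.open("w") as fh:
        for v, a in zip(rec.rr_ms.tolist(), rec.annotations):
            # repr() is the shortest decimal that round-trips the float
            fh.write(f"{int(v)} {a}\n" if v.is_integer() else f"{v!r} {a}\n")


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read a cohort metadata sidecar: subject_id, age_years, sex, rr_file."""
    df = pd.read_csv(path)
    required = {"subject_id", "age_years", "sex", "rr_file"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"manifest {path} missing columns: {sorted(missing)}")
    return df


def normal_pairs(rec: RRRecording) -> tuple[np.ndarray, np.ndarray]:
    """Adjacent sinus-to-sinus (NN) interval pairs ``(RRn, RRn+1)``.

    A pair is emitted only when both beats are sinus and adjacent in the
    original sequence; every non-sinus beat breaks the chain, so no pair
    spans a removed beat.
    """
    if rec.n_beats == 0:
        raise ValueError("empty recording")
    ok = rec.is_sinus
    usable = ok[:-1] & ok[1:]
    if usable.sum() < 2:
        raise ValueError("insufficient normal pairs (need at least 2 adjacent sinus pairs)")
    x = rec.rr_ms[:-1][usable]
    y = rec.rr_ms[1:][usable]
    return x, y
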