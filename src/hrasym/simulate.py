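"""Synthetic 24-h pediatric RR-interval recordings and cohorts.

The generator is phenomenological: it does not model the autonomic nervous
system, it superposes processes chosen to reproduce, simultaneously, the
four asymmetry signatures a healthy-children cohort shows in 24-h Holter
recordings (short-term deceleration dominance C1d > 0.5, long-term
acceleration dominance C2d < 0.5 and CTd < 0.5, and an acceleration
majority Nd < 0.5), at realistic dispersion magnitudes.

Ingredients, per recording:

* a circadian baseline (slow cosine, RR longest at night) plus a few
  random-phase ultradian waves — the label-neutral bulk of long-term
  variability;
* an asymmetric respiratory sawtooth: each breathing cycle raises RR in a
  few large steps and lowers it in more, smaller steps (zero net drift), so
  decelerations are rarer but individually larger — this creates C1d > 0.5
  together with Nd < 0.5;
* orientation mixing: a fraction of breathing cycles is mirrored
  (many small rises, few large drops).  The mirror probability grows with
  the squared deviation of the slow baseline from its mean, so
  deceleration-majority cycles concentrate where the long-term coordinate
  is far from its mean; this raises C2d above the raw count fraction
  without changing the overall count balance much;
* beat-to-beat Gaussian jitter with a rare large-variance "burst"
  component (sighs, movement): bursts add label-symmetric short-term
  variance, pulling C1d toward 0.5 while leaving beat counts almost
  untouched — the knob that lets C1d and 1 − Nd differ;
* sparse activity transients: a fast linear RR drop followed by a slow
  exponential recovery;
* optional ectopic beats (premature beat + compensatory pause) and
  technical artifacts, injected as annotation replacements at configured
  rates and kept mutually non-adjacent.

Everything is driven by one numpy Generator per recording, so a fixed seed
reproduces the series byte for byte.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .recording import RRRecording, write_rr_file

__all__ = [
    "SynthConfig",
    "CohortConfig",
    "generate_recording",
    "generate_cohort",
    "calibration_report",
    "write_cohort",
    "REFERENCE_MEDIANS",
    "REFERENCE_PREVALENCE_PCT",
]

#: cohort medians of the asymmetry indices the default configuration is
#: calibrated to reproduce (healthy children, 24-h recordings)
REFERENCE_MEDIANS = {"c1d": 0.56, "c2d": 0.48, "ctd": 0.48, "nd": 0.42}
#: reference prevalence (%) of the phenotypes in the same population
REFERENCE_PREVALENCE_PCT = {"hra1": 93.7, "hra2": 88.5, "hrat": 88.5, "hran": 99.0, "hracomp": 88.5}


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of one synthetic recording (defaults are calibrated)."""

    duration_h: float = 24.0
    mean_rr_ms: float = 650.0
    #: circadian cosine amplitude; RR peaks circadian_phase_h after midnight
    circadian_amp_ms: float = 120.0
    circadian_phase_h: float = 2.0
    #: total amplitude budget of the random-phase ultradian waves
    ultradian_amp_ms: float = 140.0
    n_ultradian: int = 6
    ultradian_period_h: tuple[float, float] = (0.4, 4.0)
    #: breathing cycle: rsa_decel_beats rising steps then falling steps,
    #: total rise rsa_amp_ms, zero net drift per cycle
    rsa_cycle_beats: int = 6
    rsa_decel_beats: int = 2
    rsa_amp_ms: float = 110.0
    rsa_amp_jitter: float = 0.3  # lognormal sigma of per-cycle amplitude
    #: orientation mixing: P(mirrored cycle) = clip(mirror_prob +
    #: mirror_extremity_gain * (e - 1)) with e the standardised squared
    #: slow-baseline deviation at the cycle start
    mirror_prob: float = 0.07
    mirror_extremity_gain: float = 0.24
    #: white beat-level jitter plus a rare heavy "burst" component
    jitter_sd_ms: float = 12.0
    burst_prob: float = 0.035
    burst_sd_ms: float = 110.0
    #: sparse activity transients: linear drop then exponential recovery
    activity_event_rate_per_h: float = 4.0
    activity_drop_ms: float = 120.0
    activity_onset_beats: int = 20
    activity_recovery_beats: int = 200
    #: beat-replacement rates
    ectopics_per_h: float = 0.0
    artifact_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_h <= 0 or self.mean_rr_ms <= 0:
            raise ValueError("duration_h and mean_rr_ms must be positive")
        if not 0 < self.rsa_decel_beats < self.rsa_cycle_beats:
            raise ValueError("require 0 < rsa_decel_beats < rsa_cycle_beats")
        for name in ("circadian_amp_ms", "ultradian_amp_ms", "rsa_amp_ms",
                     "jitter_sd_ms", "burst_sd_ms", "activity_event_rate_per_h",
                     "activity_drop_ms", "ectopics_per_h"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if not 0 <= self.burst_prob <= 1 or not 0 <= self.artifact_rate <= 1:
            raise ValueError("burst_prob and artifact_rate must be in [0, 1]")
        if not 0 <= self.mirror_prob <= 1:
            raise ValueError("mirror_prob must be in [0, 1]")


def _slow_baseline(cfg: SynthConfig, t_h: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    slow = cfg.circadian_amp_ms * np.cos(2 * np.pi * (t_h - cfg.circadian_phase_h) / 24.0)
    if cfg.ultradian_amp_ms > 0 and cfg.n_ultradian > 0:
        lo, hi = cfg.ultradian_period_h
        periods = np.exp(rng.uniform(np.log(lo), np.log(hi), cfg.n_ultradian))
        phases = rng.uniform(0, 2 * np.pi, cfg.n_ultradian)
        amp = cfg.ultradian_amp_ms / np.sqrt(cfg.n_ultradian)
        for p, ph in zip(periods, phases):
            slow = slow + amp * np.sin(2 * np.pi * t_h / p + ph)
    return slow


def _rsa_component(cfg: SynthConfig, slow: np.ndarray, n: int, rng: np.random.Generator) -> np.ndarray:
    c, k = cfg.rsa_cycle_beats, cfg.rsa_decel_beats
    ncyc = n // c + 1
    up = cfg.rsa_amp_ms / k
    down = cfg.rsa_amp_ms / (c - k)
    pattern = np.concatenate([np.full(k, up), np.full(c - k, -down)])

    # standardised squared deviation of the slow baseline, per cycle start
    dev = slow - slow.mean()
    var = dev.var()
    e = dev[np.arange(ncyc) * c % n] ** 2 / var if var > 0 else np.zeros(ncyc)
    q = np.clip(cfg.mirror_prob + cfg.mirror_extremity_gain * (e - 1.0), 0.0, 1.0)
    sign = np.where(rng.random(ncyc) < q, -1.0, 1.0)
    mult = rng.lognormal(mean=-0.5 * cfg.rsa_amp_jitter**2, sigma=cfg.rsa_amp_jitter, size=ncyc)

    steps = pattern[None, :] * (sign * mult)[:, None]
    level = np.concatenate([np.zeros((ncyc, 1)), np.cumsum(steps, axis=1)[:, :-1]], axis=1)
    return level.ravel()[:n]


def _activity_component(cfg: SynthConfig, n: int, rng: np.random.Generator) -> np.ndarray:
    out = np.zeros(n)
    rate = cfg.activity_event_rate_per_h
    if rate <= 0 or cfg.activity_drop_ms <= 0:
        return out
    n_events = rng.poisson(rate * cfg.duration_h)
    if n_events == 0:
        return out
    # onset/recovery are specified in beats of a 650-ms heart; rescale so an
    # event spans the same clock time regardless of the subject's mean RR
    scale = 650.0 / cfg.mean_rr_ms
    onset = max(2, int(round(cfg.activity_onset_beats * scale)))
    recovery = max(4, int(round(cfg.activity_recovery_beats * scale)))
    tau = max(recovery / 3.0, 1.0)
    template = -np.concatenate([
        np.arange(1, onset + 1) / onset,
        np.exp(-np.arange(1, recovery + 1) / tau),
    ])
    span = template.size
    if n <= span + 2:
        return out
    starts = rng.integers(0, n - span - 1, n_events)
    amps = cfg.activity_drop_ms * rng.lognormal(-0.5 * 0.09, 0.3, n_events)
    for s, a in zip(starts, amps):
        out[s:s + span] += a * template
    return out


def _inject_beat_labels(cfg: SynthConfig, rr: np.ndarray, ann: np.ndarray,
                        rng: np.random.Generator) -> None:
    """Replace beats with ectopics/artifacts, mutually separated by >= 5
    beats so no pairs or runs arise (in-place)."""
    n = rr.size
    n_ect = rng.poisson(cfg.ectopics_per_h * cfg.duration_h)
    n_art = rng.poisson(cfg.artifact_rate * n)
    total = n_ect + n_art
    if total == 0:
        return
    grid = np.arange(5, n - 5, 5)
    total = min(total, grid.size)
    pos = rng.choice(grid, size=total, replace=False)
    ect_pos, art_pos = pos[:min(n_ect, total)], pos[min(n_ect, total):]
    if ect_pos.size:
        kinds = rng.choice(["S", "V"], size=ect_pos.size, p=[0.6, 0.4])
        ann[ect_pos] = kinds
        rr[ect_pos] *= 0.55          # premature beat
        rr[ect_pos + 1] *= 1.30      # compensatory pause (still sinus)
    if art_pos.size:
        ann[art_pos] = "A"
        rr[art_pos] *= rng.uniform(0.4, 1.8, art_pos.size)


def generate_recording(
    cfg: SynthConfig,
    subject_id: str = "synthetic",
    age: float | None = None,
    sex: str | None = None,
) -> RRRecording:
    """Generate one annotated recording; deterministic for a fixed seed."""
    rng = np.random.default_rng(cfg.seed)
    duration_ms = cfg.duration_h * 3.6e6
    n0 = int(duration_ms / cfg.mean_rr_ms * 1.10) + 64

    t_h = np.arange(n0) * (cfg.mean_rr_ms / 3.6e6)  # nominal beat times
    slow = _slow_baseline(cfg, t_h, rng)
    rsa = _rsa_component(cfg, slow, n0, rng)
    activity = _activity_component(cfg, n0, rng)
    jitter = rng.normal(0.0, cfg.jitter_sd_ms, n0)
    if cfg.burst_prob > 0 and cfg.burst_sd_ms > 0:
        burst = rng.random(n0) < cfg.burst_prob
        jitter[burst] = rng.normal(0.0, cfg.burst_sd_ms, int(burst.sum()))

    rr = cfg.mean_rr_ms + (slow - slow.mean()) + (rsa - rsa.mean()) + activity + jitter
    # floor relative to the subject's mean so that the shape of the RR
    # distribution does not depend on resting heart rate
    rr = np.clip(rr, 0.25 * cfg.mean_rr_ms, None)
    # pin the mean over the nominal 24-h span (the oversized candidate tail
    # would otherwise bias it); the asymmetry ratios are scale-free
    m0 = min(int(round(duration_ms / cfg.mean_rr_ms)), n0)
    rr *= cfg.mean_rr_ms / rr[:m0].mean()

    # keep the beats completed within the nominal duration
    n = int(np.searchsorted(np.cumsum(rr), duration_ms, side="right"))
    n = max(n, 2)
    rr = rr[:n].copy()
    ann = np.full(n, "N", dtype="U1")
    _inject_beat_labels(cfg, rr, ann, rng)

    return RRRecording(subject_id=subject_id, rr_ms=rr, annotations=ann, age=age, sex=sex)


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortConfig:
    """A cohort of synthetic subjects with per-subject parameter variation.

    Ages are drawn from a Beta(2.23, 1) shape over ``age_range`` (median
    near 14 y); the slow-variability amplitudes scale with age through
    ``age_sd2_coef`` (per year, around age 12) to induce a positive age
    correlation of the long-term dispersion descriptors.
    """

    n_subjects: int = 96
    n_girls: int = 50
    age_range: tuple[float, float] = (3.0, 18.0)
    age_beta_a: float = 2.23
    #: relative change of slow-variability amplitude per year of age
    age_sd2_coef: float = 0.028
    #: multiplicative boost of the respiratory amplitude in boys (affects C1d)
    boys_rsa_boost: float = 1.08
    #: lognormal sigmas of per-subject multiplicative variation
    sd_slow_amp: float = 0.22
    sd_rsa_scale: float = 0.25      # scales RSA and jitter together (SD1 size)
    sd_asym_ratio: float = 0.08     # scales RSA alone (asymmetry strength)
    sd_burst: float = 1.0           # spread of the burst rate (widens C1d)
    sd_mirror_shift: float = 0.02   # additive spread of mirror_prob
    sd_mean_rr: float = 30.0        # ms, around the age trend
    ectopics_per_h: float = 1.0
    artifact_rate: float = 2e-5
    base: SynthConfig = field(default_factory=SynthConfig)
    master_seed: int = 42

    def __post_init__(self) -> None:
        if not 0 <= self.n_girls <= self.n_subjects:
            raise ValueError("require 0 <= n_girls <= n_subjects")
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")


def _subject_configs(cfg: CohortConfig) -> pd.DataFrame:
    """Draw per-subject demographics and generator parameters."""
    rng = np.random.default_rng(cfg.master_seed)
    n = cfg.n_subjects
    lo, hi = cfg.age_range
    ages = lo + (hi - lo) * rng.beta(cfg.age_beta_a, 1.0, n)
    sexes = np.array(["girl"] * cfg.n_girls + ["boy"] * (n - cfg.n_girls))
    rng.shuffle(sexes)
    seeds = rng.integers(0, 2**31 - 1, n)

    # mean RR varies between subjects but is kept independent of age, so
    # that age_sd2_coef is the only built-in age channel (see methods note)
    mean_rr = np.clip(rng.normal(650.0, cfg.sd_mean_rr, n), 500.0, 850.0)
    slow_scale = (1.0 + cfg.age_sd2_coef * (ages - 12.0)) * rng.lognormal(0.0, cfg.sd_slow_amp, n)
    slow_scale = np.clip(slow_scale, 0.2, None)
    rsa_scale = rng.lognormal(0.0, cfg.sd_rsa_scale, n)
    asym_ratio = rng.lognormal(0.0, cfg.sd_asym_ratio, n)
    asym_ratio = np.where(sexes == "boy", asym_ratio * cfg.boys_rsa_boost, asym_ratio)
    mirror = np.clip(cfg.base.mirror_prob + rng.normal(0.0, cfg.sd_mirror_shift, n), 0.0, 1.0)
    burst = np.clip(cfg.base.burst_prob * rng.lognormal(0.0, cfg.sd_burst, n), 0.0, 0.25)

    return pd.DataFrame({
        "subject_id": [f"S{i + 1:03d}" for i in range(n)],
        "age_years": ages,
        "sex": sexes,
        "seed": seeds,
        "mean_rr_ms": mean_rr,
        "slow_scale": slow_scale,
        "rsa_scale": rsa_scale,
        "asym_ratio": asym_ratio,
        "mirror_prob": mirror,
        "burst_prob": burst,
    })


def _subject_synth_config(cfg: CohortConfig, row: pd.Series) -> SynthConfig:
    base = cfg.base
    return replace(
        base,
        mean_rr_ms=float(row.mean_rr_ms),
        circadian_amp_ms=base.circadian_amp_ms * float(row.slow_scale),
        ultradian_amp_ms=base.ultradian_amp_ms * float(row.slow_scale),
        activity_drop_ms=base.activity_drop_ms * float(row.slow_scale),
        rsa_amp_ms=base.rsa_amp_ms * float(row.rsa_scale) * float(row.asym_ratio),
        jitter_sd_ms=base.jitter_sd_ms * float(row.rsa_scale),
        burst_sd_ms=base.burst_sd_ms * float(row.rsa_scale),
        mirror_prob=float(row.mirror_prob),
        burst_prob=float(row.burst_prob),
        ectopics_per_h=cfg.ectopics_per_h,
        artifact_rate=cfg.artifact_rate,
        seed=int(row.seed),
    )


def generate_cohort(cfg: CohortConfig = CohortConfig()) -> tuple[list[RRRecording], pd.DataFrame]:
    """Generate all recordings plus the metadata sidecar (one row each)."""
    table = _subject_configs(cfg)
    recordings = []
    for _, row in table.iterrows():
        sub_cfg = _subject_synth_config(cfg, row)
        recordings.append(
            generate_recording(sub_cfg, subject_id=row.subject_id,
                               age=float(row.age_years), sex=str(row.sex))
        )
    meta = table[["subject_id", "age_years", "sex", "seed"]].copy()
    return recordings, meta


def write_cohort(cfg: CohortConfig, out_dir: str | Path) -> Path:
    """Write RR text files, the metadata sidecar CSV, and a manifest JSON
    with every per-subject configuration; returns the sidecar path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    table = _subject_configs(cfg)
    manifest = []
    rows = []
    for _, row in table.iterrows():
        sub_cfg = _subject_synth_config(cfg, row)
        rec = generate_recording(sub_cfg, subject_id=row.subject_id,
                                 age=float(row.age_years), sex=str(row.sex))
        rr_file = f"{row.subject_id}.rr.txt"
        write_rr_file(rec, out_dir / rr_file)
        rows.append({"subject_id": row.subject_id, "age_years": row.age_years,
                     "sex": row.sex, "rr_file": rr_file})
        manifest.append({"subject_id": row.subject_id, "config": asdict(sub_cfg)})
    sidecar = out_dir / "cohort_metadata.csv"
    pd.DataFrame(rows).to_csv(sidecar, index=False)
    (out_dir / "cohort_manifest.json").write_text(json.dumps(manifest, indent=1))
    return sidecar


def calibration_report(
    cfg: CohortConfig = CohortConfig(), records: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Run the full pipeline on a generated cohort and compare the observed
    asymmetry medians and phenotype prevalences against the reference
    values the defaults are calibrated to.  Pass ``records`` (a per-subject
    record set already computed from this configuration) to skip
    regeneration."""
    from .pipeline import analyze_cohort  # local import to avoid a cycle

    if records is None:
        recordings, _ = generate_cohort(cfg)
        records = analyze_cohort(recordings)
    eligible = records[records["eligible"]]
    rows = []
    for key, ref in REFERENCE_MEDIANS.items():
        obs = float(eligible[key].median())
        rows.append({"quantity": f"median_{key}", "observed": obs,
                     "reference": ref, "abs_deviation": abs(obs - ref)})
    defined = eligible[eligible["defined"]]
    for key, ref in REFERENCE_PREVALENCE_PCT.items():
        obs = 100.0 * float(defined[key].mean())
        rows.append({"quantity": f"prevalence_{key}_pct", "observed": obs,
                     "reference": ref, "abs_deviation": abs(obs - ref)})
    return pd.DataFrame(rows).set_index("quantity")
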