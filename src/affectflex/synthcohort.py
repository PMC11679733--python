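"""Synthetic RR/BVP cohort generation.

The study data (per-subject pulse recordings and questionnaires) are not
public, so this module generates cohorts with the statistical structure the
analysis assumes, making every downstream stage testable.

RR model
--------
Beat-to-beat intervals are directly modulated sinusoids plus white noise::

    RR_n = mean_rr + lf_amp*sin(2*pi*lf_freq*t_n)
                   + hf_amp*sin(2*pi*hf_freq*t_n) + eps_n

with ``eps_n ~ N(0, noise_sd^2)`` and ``t_n`` the cumulative time of beat
``n``. This is deliberately *not* an integral-pulse-frequency-modulation
model: direct modulation keeps band powers analytically predictable
(a sinusoid of amplitude ``a`` contributes ``a^2/2`` ms^2 to its band),
which makes the generator its own oracle for the spectral pipeline.

BVP model
---------
One raised-cosine bump of configurable width per beat, so the clean
waveform has exactly one local maximum per beat at the beat time.

Cohort calibration
------------------
``DEFAULT_CELL_PARAMS`` maps each (group, phase) cell of the two-group
pre/post design to generator parameters whose expected SDNN, RMSSD and
LF/HF reproduce the published cell means; the mapping was fitted once by
solving the moment equations and refining against the package's own index
pipeline, and is shipped as constants. Per-subject heterogeneity uses two
lognormal factors shared across phases: an overall variability scale
(drives between-subject SDNN spread) and an LF/HF balance factor (drives
between-subject spread of the spectral ratio); both have unit mean so cell
means are preserved.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ConfigError, EmptyInputError, InvalidParameterError
from .flexgroup import SCALES, QuestionnaireScores
from .pulse import BvpRecord, IbiSeries

log = logging.getLogger(__name__)

#: physiologic RR truncation bounds, ms
RR_BOUNDS_MS = (300.0, 2000.0)

GROUPS = ("Average", "Extreme")
PHASES = ("T0", "T1")


@dataclass(frozen=True)
class RrGenParams:
    """Generator parameters for one RR series (ms, Hz, s)."""

    mean_rr: float
    lf_amp: float = 0.0
    hf_amp: float = 0.0
    lf_freq: float = 0.10
    hf_freq: float = 0.25
    noise_sd: float = 0.0
    duration: float = 120.0

    def __post_init__(self) -> None:
        if self.mean_rr <= 0:
            raise InvalidParameterError(f"mean_rr must be > 0, got {self.mean_rr}")
        if self.duration <= 0:
            raise InvalidParameterError(f"duration must be > 0, got {self.duration}")
        for name in ("lf_amp", "hf_amp", "noise_sd"):
            if getattr(self, name) < 0:
                raise InvalidParameterError(f"{name} must be >= 0")
        if not (0.04 <= self.lf_freq < 0.15):
            raise InvalidParameterError("lf_freq must lie in [0.04, 0.15)")
        if not (0.15 <= self.hf_freq <= 0.40):
            raise InvalidParameterError("hf_freq must lie in [0.15, 0.4]")
        if self.lf_amp + self.hf_amp + 4 * self.noise_sd >= self.mean_rr:
            raise InvalidParameterError(
                "amplitudes + 4*noise_sd must stay below mean_rr "
                "(would produce non-positive intervals)"
            )


def gen_rr_series(params: RrGenParams, seed: int) -> IbiSeries:
    """Generate one RR series; beats accumulate until *duration* is spanned."""
    rng = np.random.default_rng(seed)
    two_pi_lf = 2 * math.pi * params.lf_freq
    two_pi_hf = 2 * math.pi * params.hf_freq
    mean_s = params.mean_rr / 1000.0
    # rough upper bound on beat count, +8 margin for noise
    n_max = int(params.duration / (mean_s * 0.5)) + 8
    noise = rng.normal(0.0, params.noise_sd, size=n_max) if params.noise_sd > 0 else np.zeros(n_max)
    times = [0.0]
    intervals = []
    t = 0.0
    n_trunc = 0
    i = 0
    while t < params.duration:
        if i >= n_max:  # pragma: no cover - margin exhausted
            extra = rng.normal(0.0, params.noise_sd, size=n_max) if params.noise_sd > 0 else np.zeros(n_max)
            noise = np.concatenate([noise, extra])
            n_max *= 2
        rr = (
            params.mean_rr
            + params.lf_amp * math.sin(two_pi_lf * t)
            + params.hf_amp * math.sin(two_pi_hf * t)
            + noise[i]
        )
        if rr < RR_BOUNDS_MS[0] or rr > RR_BOUNDS_MS[1]:
            rr = min(max(rr, RR_BOUNDS_MS[0]), RR_BOUNDS_MS[1])
            n_trunc += 1
        intervals.append(rr)
        t += rr / 1000.0
        times.append(t)
        i += 1
    if len(intervals) < 2:
        raise InvalidParameterError(
            "duration too short to produce at least 2 beats"
        )
    if n_trunc:
        log.warning("truncated %d interval(s) to physiologic bounds %s",
                    n_trunc, RR_BOUNDS_MS)
    return IbiSeries(beat_times=np.asarray(times), intervals=np.asarray(intervals))


def gen_bvp(
    rr: IbiSeries,
    fs: float = 1024.0,
    pulse_width_ms: float = 300.0,
    amplitude: float = 1.0,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> BvpRecord:
    """Synthesize a pulse waveform: one raised-cosine bump per beat.

    The clean signal's local maxima fall on the beat times (within one
    sample); optional additive white noise with *noise_sd* (same a.u. as
    *amplitude*).
    """
    if len(rr) == 0:
        raise EmptyInputError("empty RR series")
    width_s = pulse_width_ms / 1000.0
    if fs < 4.0 / width_s:
        raise InvalidParameterError(
            f"fs={fs} too low for pulse width {pulse_width_ms} ms"
        )
    t0 = rr.beat_times[0]
    span = rr.span_s
    n = int(round(span * fs))
    x = np.zeros(n)
    half = width_s / 2.0
    for tb in rr.beat_times:
        lo = max(0, int(math.ceil((tb - t0 - half) * fs)))
        hi = min(n, int(math.floor((tb - t0 + half) * fs)) + 1)
        if lo >= hi:
            continue
        tt = np.arange(lo, hi) / fs + t0
        x[lo:hi] += amplitude * 0.5 * (1.0 + np.cos(2 * math.pi * (tt - tb) / width_s))
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        x = x + rng.normal(0.0, noise_sd, size=n)
    return BvpRecord(samples=x, fs=fs)


# ---------------------------------------------------------------------------
# questionnaires


@dataclass(frozen=True)
class ScaleGenConfig:
    """Normal-with-truncation generator for one scale score.

    *delta_extreme* is the +/- offset applied to Extreme-group subjects
    (high half +delta, low half -delta); it decomposes the published
    Extreme-group SD into a within-half SD plus a between-half separation.
    """

    mean: float
    sd: float
    delta_extreme: float = 0.0

    def __post_init__(self) -> None:
        if self.sd < 0 or self.delta_extreme < 0:
            raise InvalidParameterError("sd and delta_extreme must be >= 0")


#: published questionnaire calibration: Average-group mean and SD per scale,
#: plus the Extreme-half offset sqrt(SD_ext^2 - SD_avg^2)
DEFAULT_QUESTIONNAIRE_CONFIG: dict[str, ScaleGenConfig] = {
    "cfi_alt": ScaleGenConfig(mean=5.40, sd=0.555, delta_extreme=0.654),
    "cfi_ctrl": ScaleGenConfig(mean=4.93, sd=0.544, delta_extreme=1.198),
    "cfs": ScaleGenConfig(mean=4.47, sd=0.442, delta_extreme=0.566),
    "ccfq_cce": ScaleGenConfig(mean=35.63, sd=4.915, delta_extreme=10.15),
    "ccfq_acf": ScaleGenConfig(mean=45.46, sd=5.634, delta_extreme=9.35),
}


def _validate_qconfig(config: dict[str, ScaleGenConfig]) -> None:
    missing = set(SCALES) - set(config)
    if missing:
        raise InvalidParameterError(f"questionnaire config missing scales: {sorted(missing)}")
    for name, c in config.items():
        sd = SCALES[name]
        if not (sd.score_min <= c.mean <= sd.score_max):
            raise InvalidParameterError(
                f"{name} mean {c.mean} outside scale bounds "
                f"[{sd.score_min}, {sd.score_max}]"
            )


def gen_questionnaires(
    config: dict[str, ScaleGenConfig] | None,
    n: int,
    seed: int,
    offsets: np.ndarray | None = None,
) -> list[QuestionnaireScores]:
    """Draw *n* sets of scale scores, truncating to scale bounds (logged).

    *offsets*, if given, is a per-subject vector of signed multiples of each
    scale's ``delta_extreme`` (e.g. +1/-1 for Extreme halves, 0 otherwise).
    """
    if n < 1:
        raise InvalidParameterError(f"n must be >= 1, got {n}")
    config = config or DEFAULT_QUESTIONNAIRE_CONFIG
    _validate_qconfig(config)
    if offsets is None:
        offsets = np.zeros(n)
    offsets = np.asarray(offsets, dtype=float)
    if offsets.size != n:
        raise InvalidParameterError("offsets must have length n")
    rng = np.random.default_rng(seed)
    cols: dict[str, np.ndarray] = {}
    n_trunc = 0
    for name, c in config.items():
        lo, hi = SCALES[name].score_min, SCALES[name].score_max
        vals = c.mean + offsets * c.delta_extreme + rng.normal(0.0, c.sd, size=n)
        clipped = np.clip(vals, lo, hi)
        n_trunc += int(np.sum(clipped != vals))
        cols[name] = clipped
    if n_trunc:
        log.warning("truncated %d questionnaire score(s) to scale bounds", n_trunc)
    return [
        QuestionnaireScores(**{name: float(cols[name][i]) for name in SCALES})
        for i in range(n)
    ]


# ---------------------------------------------------------------------------
# cohort


#: generator parameters per (group, phase) cell, fitted once so that the
#: index pipeline recovers the published cell means of SDNN, RMSSD and LF/HF
#: (2-min recordings, mean RR 850 ms); see the methods note for the fit
DEFAULT_CELL_PARAMS: dict[tuple[str, str], RrGenParams] = {
    ("Average", "T0"): RrGenParams(mean_rr=850, lf_amp=52.81, hf_amp=40.26, noise_sd=26.62),
    ("Average", "T1"): RrGenParams(mean_rr=850, lf_amp=73.84, hf_amp=30.71, noise_sd=29.07),
    ("Extreme", "T0"): RrGenParams(mean_rr=850, lf_amp=59.01, hf_amp=29.90, noise_sd=19.96),
    ("Extreme", "T1"): RrGenParams(mean_rr=850, lf_amp=73.89, hf_amp=40.82, noise_sd=29.59),
}

#: lognormal sigma of the per-subject overall variability scale
SUBJECT_SCALE_SIGMA = 0.40
#: lognormal sigma of the per-subject LF/HF balance factor
SUBJECT_BALANCE_SIGMA = 0.60


@dataclass
class CohortSpec:
    """Specification of a two-group pre/post synthetic cohort."""

    n_average: int = 23
    n_extreme: int = 20
    params_by_cell: dict = field(
        default_factory=lambda: dict(DEFAULT_CELL_PARAMS)
    )
    questionnaire_config: dict = field(
        default_factory=lambda: dict(DEFAULT_QUESTIONNAIRE_CONFIG)
    )
    seed: int = 0
    subject_scale_sigma: float = SUBJECT_SCALE_SIGMA
    subject_balance_sigma: float = SUBJECT_BALANCE_SIGMA

    def __post_init__(self) -> None:
        if self.n_average < 2 or self.n_extreme < 2:
            raise InvalidParameterError("group sizes must be >= 2")
        for group in GROUPS:
            for phase in PHASES:
                if (group, phase) not in self.params_by_cell:
                    raise ConfigError(f"params_by_cell missing cell {(group, phase)}")


@dataclass
class SubjectRecord:
    """One synthetic subject: truth label, scores, and both RR recordings."""

    subject_id: str
    group_truth: str
    scores: QuestionnaireScores
    rr_t0: IbiSeries
    rr_t1: IbiSeries


@dataclass
class CohortDataset:
    """A generated cohort plus the spec that produced it."""

    subjects: list[SubjectRecord]
    spec: CohortSpec

    def __len__(self) -> int:
        return len(self.subjects)

    def scores_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.subjects:
            row = {"subject_id": s.subject_id, "group_truth": s.group_truth}
            row.update(s.scores.as_dict())
            rows.append(row)
        return pd.DataFrame(rows)


def _subject_params(
    base: RrGenParams, scale: float, balance: float
) -> RrGenParams:
    """Apply per-subject heterogeneity factors to a cell's base parameters."""
    return replace(
        base,
        lf_amp=base.lf_amp * scale * math.sqrt(balance),
        hf_amp=base.hf_amp * scale / math.sqrt(balance),
        noise_sd=base.noise_sd * scale,
    )


def gen_cohort(spec: CohortSpec) -> CohortDataset:
    """Generate the full two-group pre/post cohort (reproducible by seed)."""
    rng = np.random.default_rng(spec.seed)
    n_total = spec.n_average + spec.n_extreme
    groups = ["Average"] * spec.n_average + ["Extreme"] * spec.n_extreme
    # Extreme halves: alternate high/low so both halves are populated
    offsets = np.zeros(n_total)
    sign = 1.0
    for i in range(spec.n_average, n_total):
        offsets[i] = sign
        sign = -sign
    scores = gen_questionnaires(
        spec.questionnaire_config,
        n_total,
        seed=int(rng.integers(2**31)),
        offsets=offsets,
    )
    # unit-mean lognormal heterogeneity, shared across phases
    scale = np.exp(rng.normal(-spec.subject_scale_sigma**2 / 2,
                              spec.subject_scale_sigma, size=n_total))
    balance = np.exp(rng.normal(-spec.subject_balance_sigma**2 / 2,
                                spec.subject_balance_sigma, size=n_total))
    subjects = []
    for i in range(n_total):
        group = groups[i]
        rr = {}
        for phase in PHASES:
            params = _subject_params(
                spec.params_by_cell[(group, phase)], scale[i], balance[i]
            )
            rr[phase] = gen_rr_series(params, seed=int(rng.integers(2**31)))
        subjects.append(
            SubjectRecord(
                subject_id=f"S{i + 1:03d}",
                group_truth=group,
                scores=scores[i],
                rr_t0=rr["T0"],
                rr_t1=rr["T1"],
            )
        )
    return CohortDataset(subjects=subjects, spec=spec)


# ---------------------------------------------------------------------------
# on-disk layout


def write_rr_csv(rr: IbiSeries, path) -> None:
    """RR CSV: ``beat_time_s, rr_ms`` (row 0 has no preceding interval)."""
    vals = np.concatenate([[np.nan], rr.intervals])
    pd.DataFrame({"beat_time_s": rr.beat_times, "rr_ms": vals}).to_csv(
        path, index=False
    )


def read_rr_csv(path) -> IbiSeries:
    df = pd.read_csv(path)
    return IbiSeries(
        beat_times=df["beat_time_s"].to_numpy(),
        intervals=df["rr_ms"].to_numpy()[1:],
    )


def write_cohort(cohort: CohortDataset, outdir, write_bvp: bool = False) -> dict:
    """Write per-subject RR CSVs, a scores table, and a manifest JSON."""
    from pathlib import Path

    from .pulse import write_bvp_csv

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    entries = []
    for s in cohort.subjects:
        files = {}
        for phase, rr in (("T0", s.rr_t0), ("T1", s.rr_t1)):
            fname = f"rr_{s.subject_id}_{phase}.csv"
            write_rr_csv(rr, outdir / fname)
            files[phase] = fname
            if write_bvp:
                bname = f"bvp_{s.subject_id}_{phase}.csv"
                write_bvp_csv(gen_bvp(rr), outdir / bname)
                files[f"{phase}_bvp"] = bname
        entries.append(
            {"subject_id": s.subject_id, "group_truth": s.group_truth,
             "files": files}
        )
    cohort.scores_frame().to_csv(outdir / "scores.csv", index=False)
    manifest = {
        "seed": cohort.spec.seed,
        "n_average": cohort.spec.n_average,
        "n_extreme": cohort.spec.n_extreme,
        "scores_file": "scores.csv",
        "subjects": entries,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
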