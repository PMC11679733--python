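"""Blood-volume-pulse preprocessing.

Takes a raw BVP waveform through power-line notch filtering, a
Pan-Tompkins-style beat detector re-parameterized for the pulse-wave band,
inter-beat-interval (IBI) extraction, and automated artifact correction by
spline interpolation.

The Pan-Tompkins stages (band-pass -> derivative -> squaring ->
moving-window integration -> adaptive dual-threshold peak picking with a
refractory period) were designed for ECG QRS complexes; here the band-pass
is 0.5-8 Hz to match pulse-wave bandwidth and the fiducial point is refined
to the local maximum of the band-passed signal (the pulse peak). All
filtering is zero-phase (forward-backward) so beat times carry no filter
delay.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal
from scipy.interpolate import CubicSpline

from .errors import (
    EmptyInputError,
    InsufficientDataError,
    InvalidParameterError,
    NoBeatsError,
    QualityError,
    SamplingRateError,
)

log = logging.getLogger(__name__)

#: refractory period between accepted beats, seconds
REFRACTORY_S = 0.25
#: beats this close to the record edges are discarded (zero-phase filter
#: transients and truncated pulses make edge fiducials unreliable)
EDGE_GUARD_S = 0.5
#: moving-window integration length, seconds
MWI_WINDOW_S = 0.150
#: pulse-wave band-pass edges, Hz
BAND_HZ = (0.5, 8.0)


@dataclass
class BvpRecord:
    """Raw pulse waveform with its sampling rate (a.u. samples, Hz)."""

    samples: np.ndarray
    fs: float = 1024.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise InvalidParameterError(f"fs must be > 0, got {self.fs}")
        if self.samples.ndim != 1:
            raise InvalidParameterError("samples must be one-dimensional")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs

    @property
    def t(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.fs


@dataclass
class BeatTimes:
    """Detected beat fiducial times in seconds from record start."""

    times: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.times.size and np.any(np.diff(self.times) <= 0):
            raise InvalidParameterError("beat times must be strictly increasing")

    def __len__(self) -> int:
        return self.times.size


@dataclass
class IbiSeries:
    """Beat times (s) and inter-beat intervals (ms).

    Interval ``n`` is the time between beats ``n`` and ``n+1``; a per-interval
    boolean flag records whether the value was replaced during artifact
    correction.
    """

    beat_times: np.ndarray
    intervals: np.ndarray
    corrected_flags: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.beat_times = np.asarray(self.beat_times, dtype=float)
        self.intervals = np.asarray(self.intervals, dtype=float)
        if self.corrected_flags is None:
            self.corrected_flags = np.zeros(self.intervals.size, dtype=bool)
        self.corrected_flags = np.asarray(self.corrected_flags, dtype=bool)
        if self.beat_times.size == 0 or self.intervals.size == 0:
            raise EmptyInputError("IbiSeries requires at least two beats")
        if self.intervals.size != self.beat_times.size - 1:
            raise InvalidParameterError(
                "intervals length must be number of beats minus one"
            )
        if self.corrected_flags.size != self.intervals.size:
            raise InvalidParameterError("flags must match intervals length")
        if np.any(np.diff(self.beat_times) <= 0):
            raise InvalidParameterError("beat times must be strictly increasing")
        if np.any(self.intervals <= 0):
            raise InvalidParameterError("all intervals must be positive")

    def __len__(self) -> int:
        return self.intervals.size

    @property
    def span_s(self) -> float:
        """Time from first to last beat."""
        return float(self.beat_times[-1] - self.beat_times[0])

    @property
    def duration_s(self) -> float:
        """Approximate recording duration: beat span plus one mean interval."""
        return self.span_s + float(np.mean(self.intervals)) / 1000.0

    @property
    def instantaneous_hr(self) -> np.ndarray:
        """Per-interval heart rate, bpm (60000/RR)."""
        return 60000.0 / self.intervals


def notch50(bvp: BvpRecord, f0: float = 50.0, q: float = 30.0) -> BvpRecord:
    """Remove power-line interference with a zero-phase IIR notch at *f0* Hz."""
    if bvp.fs <= 2 * f0:
        raise SamplingRateError(
            f"fs={bvp.fs} Hz must exceed twice the notch frequency {f0} Hz"
        )
    b, a = signal.iirnotch(f0, q, fs=bvp.fs)
    out = signal.filtfilt(b, a, bvp.samples)
    return BvpRecord(samples=out, fs=bvp.fs)


def _bandpass(x: np.ndarray, fs: float) -> np.ndarray:
    sos = signal.butter(2, BAND_HZ, btype="bandpass", fs=fs, output="sos")
    # generous odd-reflection padding: the 0.5 Hz high-pass edge has a long
    # transient that would otherwise skew peak positions near the ends
    padlen = min(x.size - 1, int(3 * fs))
    return signal.sosfiltfilt(sos, x, padlen=padlen)


def detect_beats(bvp: BvpRecord) -> BeatTimes:
    """Detect pulse peaks with a Pan-Tompkins-style chain adapted to BVP.

    Raises :class:`NoBeatsError` for flat or ineffective signals, mirroring
    how a participant with unusable acquisition is excluded from analysis.
    """
    if bvp.fs < 100:
        raise SamplingRateError(f"fs={bvp.fs} Hz too low; need >= 100 Hz")
    if bvp.duration_s < 3.0:
        raise InsufficientDataError("need at least 3 s of signal")
    x = bvp.samples
    if np.ptp(x) == 0:
        raise NoBeatsError("flat signal: no beats detectable")

    band = _bandpass(x, bvp.fs)
    deriv = np.gradient(band) * bvp.fs
    sq = deriv**2
    win = max(1, int(round(MWI_WINDOW_S * bvp.fs)))
    # centered moving average keeps the integrated energy peak aligned with
    # the (symmetric) pulse, so no systematic detection lag
    mwi = np.convolve(sq, np.ones(win) / win, mode="same")

    refractory = int(round(REFRACTORY_S * bvp.fs))
    cand, _ = signal.find_peaks(mwi, distance=refractory)
    if cand.size == 0:
        raise NoBeatsError("no candidate peaks in integrated signal")

    # adaptive dual-threshold pass (classic signal/noise running estimates)
    head = mwi[: int(2 * bvp.fs)]
    spki = float(np.max(head))
    npki = float(np.mean(head))
    accepted = []
    for p in cand:
        thr = npki + 0.25 * (spki - npki)
        if mwi[p] > thr:
            accepted.append(p)
            spki = 0.125 * mwi[p] + 0.875 * spki
        else:
            npki = 0.125 * mwi[p] + 0.875 * npki
    if not accepted:
        raise NoBeatsError("adaptive thresholding rejected all candidates")

    # refine each fiducial to the local maximum of the band-passed pulse,
    # with parabolic sub-sample interpolation
    half = int(round(0.2 * bvp.fs))
    times = []
    n = band.size
    for p in accepted:
        lo, hi = max(0, p - half), min(n, p + half + 1)
        k = lo + int(np.argmax(band[lo:hi]))
        t = k / bvp.fs
        if 0 < k < n - 1:
            y0, y1, y2 = band[k - 1], band[k], band[k + 1]
            denom = y0 - 2 * y1 + y2
            if denom != 0:
                delta = 0.5 * (y0 - y2) / denom
                if abs(delta) <= 1:
                    t = (k + delta) / bvp.fs
        times.append(t)

    # enforce strict increase, refractory, and the edge guard after refinement
    out = []
    for t in sorted(times):
        if t < EDGE_GUARD_S or t > bvp.duration_s - EDGE_GUARD_S:
            continue
        if not out or t - out[-1] >= REFRACTORY_S:
            out.append(t)
    if not out:
        raise NoBeatsError("no beats survived refinement")
    return BeatTimes(times=np.asarray(out))


def extract_ibi(beats: BeatTimes) -> IbiSeries:
    """Convert beat times to an inter-beat-interval series (ms)."""
    if len(beats) < 2:
        raise InsufficientDataError("need at least 2 beats to form an interval")
    intervals = np.diff(beats.times) * 1000.0
    return IbiSeries(beat_times=beats.times.copy(), intervals=intervals)


def correct_artifacts(
    ibi: IbiSeries,
    rel_threshold: float = 0.3,
    window: int = 5,
    max_flagged_frac: float = 0.2,
) -> IbiSeries:
    """Flag and interpolate ectopic/missed-beat intervals.

    An interval deviating from the local *window*-beat running median by more
    than *rel_threshold* (relative) is flagged and replaced by a cubic spline
    through the unflagged neighbors. Unflagged intervals are returned
    bit-identical. More than *max_flagged_frac* flagged intervals marks the
    recording unusable (:class:`QualityError`).
    """
    if rel_threshold <= 0:
        raise InvalidParameterError("rel_threshold must be > 0")
    n = len(ibi)
    if n < window + 1:
        raise InsufficientDataError(
            f"need at least {window + 1} intervals, got {n}"
        )
    x = ibi.intervals
    med = (
        pd.Series(x)
        .rolling(window, center=True, min_periods=1)
        .median()
        .to_numpy()
    )
    flagged = np.abs(x - med) > rel_threshold * med
    # clustered artifacts can capture the running median; a loose check
    # against the global median catches those (double the local threshold
    # so genuine slow drift is never flagged by it)
    gmed = float(np.median(x))
    flagged |= np.abs(x - gmed) > 2.0 * rel_threshold * gmed
    frac = flagged.mean()
    if frac > max_flagged_frac:
        raise QualityError(
            f"{frac:.0%} of intervals flagged (> {max_flagged_frac:.0%}); "
            "recording marked unusable"
        )
    out = x.copy()
    if flagged.any():
        good = ~flagged
        if good.sum() < 4:
            raise QualityError("too few clean intervals to interpolate over")
        idx = np.arange(n)
        spline = CubicSpline(idx[good], x[good])
        out[flagged] = spline(idx[flagged])
        log.warning("corrected %d of %d intervals by interpolation",
                    int(flagged.sum()), n)
    return IbiSeries(
        beat_times=ibi.beat_times.copy(),
        intervals=out,
        corrected_flags=flagged | ibi.corrected_flags,
    )


# ---------------------------------------------------------------------------
# file I/O


def read_bvp_csv(path, fs: float | None = None) -> BvpRecord:
    """Read a BVP CSV with columns ``t_s, bvp`` or a single sample column.

    A single-column file requires an explicit *fs*.
    """
    df = pd.read_csv(path)
    if {"t_s", "bvp"} <= set(df.columns):
        t = df["t_s"].to_numpy()
        if t.size > 1:
            fs_est = 1.0 / np.median(np.diff(t))
        elif fs is None:
            raise InvalidParameterError("cannot infer fs from a single sample")
        else:
            fs_est = fs
        return BvpRecord(samples=df["bvp"].to_numpy(), fs=fs if fs else fs_est)
    if df.shape[1] == 1:
        if fs is None:
            raise InvalidParameterError("single-column BVP input requires fs")
        return BvpRecord(samples=df.iloc[:, 0].to_numpy(), fs=fs)
    raise InvalidParameterError(f"unrecognized BVP file layout in {path}")


def write_bvp_csv(bvp: BvpRecord, path) -> None:
    pd.DataFrame({"t_s": bvp.t, "bvp": bvp.samples}).to_csv(path, index=False)


def read_ibi_csv(path) -> IbiSeries:
    """Read an IBI CSV with columns ``beat_time_s, rr_ms[, corrected]``."""
    df = pd.read_csv(path)
    beat_times = df["beat_time_s"].to_numpy()
    rr = df["rr_ms"].to_numpy()[1:]  # first row has no preceding interval
    flags = None
    if "corrected" in df.columns:
        flags = df["corrected"].to_numpy()[1:].astype(bool)
    return IbiSeries(beat_times=beat_times, intervals=rr, corrected_flags=flags)


def write_ibi_csv(ibi: IbiSeries, path) -> None:
    """Write ``beat_time_s, rr_ms, corrected``; row 0 has no interval (NaN)."""
    rr = np.concatenate([[np.nan], ibi.intervals])
    corr = np.concatenate([[False], ibi.corrected_flags])
    pd.DataFrame(
        {"beat_time_s": ibi.beat_times, "rr_ms": rr, "corrected": corr}
    ).to_csv(path, index=False)
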