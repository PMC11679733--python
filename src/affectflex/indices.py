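"""HRV index computation for one recording.

Three families:

* time domain -- RMSSD, SDNN, SD HR, HR mean, RR mean, computed from the
  (artifact-corrected) beat-to-beat interval series;
* spectral -- autoregressive (Burg) band powers in VLF (<=0.04 Hz),
  LF (0.04-0.15 Hz) and HF (0.15-0.4 Hz), normalized units over LF+HF, and
  the LF/HF ratio, computed from the detrended 4 Hz tachogram;
* Poincare -- SD1 (short-term, perpendicular to the identity line of the
  lag-1 return map), SD2 (long-term, along it), and SD2/SD1, computed as
  the SDs of the rotated return-map coordinates (x_{n+1} -+ x_n)/sqrt(2);
  SD1^2 equals Var(dRR)/2 exactly, and SD2^2 equals the familiar
  2 Var(RR) - SD1^2 closed form up to O(1/n) edge terms.

Sample (n-1) variances are used throughout. Time-domain and Poincare
indices deliberately come from the beat-to-beat series, not the detrended
tachogram (standard HRV practice); only the spectral family uses the
tachogram.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal
from statsmodels.regression.linear_model import burg

from .errors import InsufficientDataError, InvalidParameterError
from .pulse import IbiSeries
from .tachogram import (
    DEFAULT_RATE_HZ,
    DEFAULT_SMOOTH_PARAM,
    EvenTachogram,
    detrend_smoothness_priors,
    resample_even,
)

log = logging.getLogger(__name__)

VLF_BAND = (0.0, 0.04)
LF_BAND = (0.04, 0.15)
HF_BAND = (0.15, 0.40)
DEFAULT_AR_ORDER = 16
#: frequency-grid size for AR PSD band integration; dense because near-pure
#: oscillations give very sharp AR peaks
PSD_GRID = 2**17 + 1
#: recordings shorter than this are spectrally unreliable (warning only)
MIN_RELIABLE_S = 120.0


@dataclass
class HrvTimeIndices:
    rmssd: float  # ms
    sdnn: float  # ms
    sd_hr: float  # bpm
    hr_mean: float  # bpm
    rr_mean: float  # ms


@dataclass
class SpectralIndices:
    lf_abs: float  # ms^2
    hf_abs: float  # ms^2
    vlf_abs: float  # ms^2
    lf_nu: float  # % of (LF+HF)
    hf_nu: float  # % of (LF+HF)
    lf_hf_ratio: float
    ar_order: int


@dataclass
class PoincareIndices:
    sd1: float  # ms
    sd2: float  # ms
    sd2_sd1_ratio: float  # NaN when SD1 == 0
    degenerate: bool = False  # True when the ratio is undefined


@dataclass
class HrvConfig:
    """Parameters of the index-computation chain."""

    resample_rate: float = DEFAULT_RATE_HZ
    smooth_param: float = DEFAULT_SMOOTH_PARAM
    ar_order: int = DEFAULT_AR_ORDER
    detrend_before_time_domain: bool = False


@dataclass
class HrvIndexSet:
    """All indices for one recording (one baseline phase of one subject)."""

    time: HrvTimeIndices
    spectral: SpectralIndices
    poincare: PoincareIndices
    config: HrvConfig = field(default_factory=HrvConfig)

    def as_row(self) -> dict:
        """Flat dict with the canonical output column names."""
        return {
            "rmssd_ms": self.time.rmssd,
            "sdnn_ms": self.time.sdnn,
            "sd_hr_bpm": self.time.sd_hr,
            "hr_mean_bpm": self.time.hr_mean,
            "rr_mean_ms": self.time.rr_mean,
            "lf_nu": self.spectral.lf_nu,
            "hf_nu": self.spectral.hf_nu,
            "lf_hf": self.spectral.lf_hf_ratio,
            "sd1_ms": self.poincare.sd1,
            "sd2_ms": self.poincare.sd2,
            "sd2_sd1": self.poincare.sd2_sd1_ratio,
        }


INDEX_COLUMNS = [
    "rmssd_ms", "sdnn_ms", "sd_hr_bpm", "hr_mean_bpm", "rr_mean_ms",
    "lf_nu", "hf_nu", "lf_hf", "sd1_ms", "sd2_ms", "sd2_sd1",
]


def _time_domain_from_rr(rr: np.ndarray) -> HrvTimeIndices:
    if rr.size < 3:
        raise InsufficientDataError("need at least 3 intervals")
    rmssd = float(np.sqrt(np.mean(np.diff(rr) ** 2)))
    sdnn = float(np.std(rr, ddof=1))
    hr = 60000.0 / rr
    sd_hr = float(np.std(hr, ddof=1))
    rr_mean = float(np.mean(rr))
    return HrvTimeIndices(
        rmssd=rmssd, sdnn=sdnn, sd_hr=sd_hr,
        hr_mean=60000.0 / rr_mean, rr_mean=rr_mean,
    )


def time_domain(ibi: IbiSeries) -> HrvTimeIndices:
    """RMSSD, SDNN, SD HR (all with n-1 variances), HR mean, RR mean."""
    return _time_domain_from_rr(ibi.intervals)


def ar_psd(
    t: EvenTachogram, order: int = DEFAULT_AR_ORDER, n_freq: int = PSD_GRID
) -> tuple[np.ndarray, np.ndarray]:
    """One-sided Burg AR power spectral density on [0, Nyquist]."""
    if not t.detrended:
        raise InvalidParameterError("spectral indices require a detrended tachogram")
    n = len(t)
    if order < 1 or order >= n / 2:
        raise InvalidParameterError(
            f"AR order {order} invalid for series of length {n}"
        )
    ar, sigma2 = burg(t.values, order=order, demean=True)
    freqs, h = signal.freqz(1.0, np.concatenate([[1.0], -ar]),
                            worN=n_freq, fs=t.rate)
    return freqs, 2.0 * (sigma2 / t.rate) * np.abs(h) ** 2


def ar_band_powers(
    t: EvenTachogram, order: int = DEFAULT_AR_ORDER, n_freq: int = PSD_GRID
) -> SpectralIndices:
    """Burg AR spectrum integrated over the VLF/LF/HF bands.

    The AR(p) model is fitted with Burg's method; the parametric PSD is
    evaluated on a dense uniform frequency grid up to Nyquist and integrated
    by the trapezoid rule per band. Normalized units use LF+HF as the
    denominator (VLF is unreliable on 2-min records).
    """
    freqs, psd = ar_psd(t, order=order, n_freq=n_freq)

    def band_power(lo: float, hi: float) -> float:
        mask = (freqs >= lo) & (freqs <= hi)
        return float(np.trapezoid(psd[mask], freqs[mask]))

    vlf = band_power(*VLF_BAND)
    lf = band_power(*LF_BAND)
    hf = band_power(*HF_BAND)
    total = lf + hf
    lf_nu = 100.0 * lf / total
    hf_nu = 100.0 * hf / total
    return SpectralIndices(
        lf_abs=lf, hf_abs=hf, vlf_abs=vlf,
        lf_nu=lf_nu, hf_nu=hf_nu, lf_hf_ratio=lf / hf, ar_order=order,
    )


def _poincare_from_rr(rr: np.ndarray) -> PoincareIndices:
    if rr.size < 3:
        raise InsufficientDataError("need at least 3 intervals")
    # rotated lag-1 return-map coordinates: SD1 perpendicular to the
    # identity line (equals sqrt(Var(dRR)/2) exactly), SD2 along it
    x, y = rr[:-1], rr[1:]
    sd1_sq = float(np.var((y - x) / np.sqrt(2.0), ddof=1))
    sd2_sq = float(np.var((y + x) / np.sqrt(2.0), ddof=1))
    if sd2_sq < 0:  # pragma: no cover - variance cannot go negative here
        warnings.warn(
            "SD2^2 negative by rounding; floored at 0", RuntimeWarning,
            stacklevel=2,
        )
        sd2_sq = 0.0
    sd1 = float(np.sqrt(sd1_sq))
    sd2 = float(np.sqrt(sd2_sq))
    if sd1 == 0.0:
        return PoincareIndices(sd1=sd1, sd2=sd2, sd2_sd1_ratio=float("nan"),
                               degenerate=True)
    return PoincareIndices(sd1=sd1, sd2=sd2, sd2_sd1_ratio=sd2 / sd1)


def poincare(ibi: IbiSeries) -> PoincareIndices:
    """SD1/SD2 as ellipse half-axes of the lag-1 return map (n-1 variances)."""
    return _poincare_from_rr(ibi.intervals)


def compute_all(ibi: IbiSeries, config: HrvConfig | None = None) -> HrvIndexSet:
    """Full index set for one recording; bundles all three families."""
    config = config or HrvConfig()
    if ibi.duration_s < MIN_RELIABLE_S:
        warnings.warn(
            f"recording spans {ibi.duration_s:.1f} s < {MIN_RELIABLE_S:.0f} s; "
            "LF estimates may be unreliable",
            RuntimeWarning,
            stacklevel=2,
        )
    even = resample_even(ibi, rate=config.resample_rate)
    detrended = detrend_smoothness_priors(even, smooth_param=config.smooth_param)
    if config.detrend_before_time_domain:
        # non-default path: beat-domain indices from the detrended tachogram
        # with the mean interval restored (detrending removes it)
        rr = detrended.values + float(np.mean(ibi.intervals))
        td = _time_domain_from_rr(rr)
        pc = _poincare_from_rr(rr)
    else:
        td = time_domain(ibi)
        pc = poincare(ibi)
    return HrvIndexSet(
        time=td,
        spectral=ar_band_powers(detrended, order=config.ar_order),
        poincare=pc,
        config=config,
    )


def write_index_csv(rows: list[dict], path) -> None:
    """One row per (subject, phase) with all canonical index columns."""
    df = pd.DataFrame(rows)
    ordered = [c for c in ("subject_id", "phase") if c in df.columns]
    df = df[ordered + INDEX_COLUMNS]
    df.to_csv(path, index=False)
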