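"""Shared fixtures and independent oracles used across the suite."""

import warnings

import numpy as np
import pytest

from affectflex import synthcohort as sc
from affectflex.pulse import IbiSeries


@pytest.fixture(autouse=True)
def _quiet_short_recording_warnings():
    """Short synthetic recordings legitimately trip the duration warning."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        yield


@pytest.fixture
def clean_rr_60bpm():
    """Metronomic 1000 ms RR series spanning 60 s."""
    return sc.gen_rr_series(sc.RrGenParams(mean_rr=1000, duration=60), seed=1)


@pytest.fixture
def modulated_rr():
    """Realistic two-tone + noise RR series spanning 120 s."""
    params = sc.RrGenParams(
        mean_rr=850, lf_amp=50, hf_amp=40, noise_sd=20, duration=120
    )
    return sc.gen_rr_series(params, seed=5)


def ibi_from_intervals(intervals_ms) -> IbiSeries:
    """Build an IbiSeries directly from interval values (ms)."""
    intervals_ms = np.asarray(intervals_ms, dtype=float)
    times = np.concatenate([[0.0], np.cumsum(intervals_ms) / 1000.0])
    return IbiSeries(beat_times=times, intervals=intervals_ms)


def periodogram_lf_hf(values: np.ndarray, rate: float) -> float:
    """Plain-periodogram LF/HF band-power ratio (independent spectral oracle)."""
    from scipy.signal import periodogram

    f, pxx = periodogram(values, fs=rate)
    lf = pxx[(f >= 0.04) & (f <= 0.15)].sum()
    hf = pxx[(f > 0.15) & (f <= 0.40)].sum()
    return lf / hf


def glm_mixed_anova_oracle(y0, y1, group):
    """Split-plot ANOVA by explicit design matrices and error strata.

    Fixed effects are effect-coded (sum to zero), so dropped-term SS are
    Type III; the within stratum tests time and interaction against the
    subject-by-time residual, the between stratum tests group against
    subjects-within-groups. Returns (F_time, F_group, F_interaction).
    """
    y0 = np.asarray(y0, float)
    y1 = np.asarray(y1, float)
    group = np.asarray(group)
    levels = list(dict.fromkeys(group.tolist()))
    n = y0.size
    big_n = 2 * n
    y = np.concatenate([y0, y1])
    subj = np.tile(np.arange(n), 2)
    time = np.repeat([-1.0, 1.0], n)
    grp = np.where(group == levels[0], 1.0, -1.0)
    inter = np.concatenate([grp, grp]) * time

    subj_dummies = np.zeros((big_n, n))
    subj_dummies[np.arange(big_n), subj] = 1.0

    def rss(design):
        beta, *_ = np.linalg.lstsq(design, y, rcond=None)
        r = y - design @ beta
        return float(r @ r)

    full = np.column_stack([subj_dummies, time, inter])
    ss_full = rss(full)
    df_err = big_n - (n + 2)
    ms_err = ss_full / df_err
    f_time = (rss(np.column_stack([subj_dummies, inter])) - ss_full) / ms_err
    f_inter = (rss(np.column_stack([subj_dummies, time])) - ss_full) / ms_err

    m = (y0 + y1) / 2.0
    x_full = np.column_stack([np.ones(n), grp])
    beta, *_ = np.linalg.lstsq(x_full, m, rcond=None)
    ss_err_b = float(np.sum((m - x_full @ beta) ** 2))
    ss_red = float(np.sum((m - m.mean()) ** 2))
    f_group = (ss_red - ss_err_b) / (ss_err_b / (n - 2))
    return f_time, f_group, f_inter
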