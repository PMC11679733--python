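"""Inferential statistics for the two-group pre/post design.

The workhorse is the 2 (group: Average vs Extreme) x 2 (time: T0 vs T1)
mixed (split-plot) ANOVA. With only two within-subject levels the design
decomposes exactly: per subject let ``m = (y0 + y1)/2`` and ``d = y1 - y0``;
the group effect is a between-subjects one-way ANOVA on ``m``, the time
effect tests the unweighted grand mean of ``d`` against zero, and the
time-by-group interaction tests the group difference of ``d``. All three
effects have df (1, N - 2); sphericity is vacuous with two levels. Unequal
group sizes use unweighted marginal means (the Type-III convention of
common statistics packages). Partial eta squared comes from the identity
``eta_p^2 = F * df1 / (F * df1 + df2)``.

Also here: Shapiro-Wilk and Lilliefors-corrected Kolmogorov-Smirnov
normality tests, the JZS two-sample Bayes factor (Cauchy prior on the
standardized effect size, evaluated by adaptive quadrature), the SE = SD /
sqrt(n) helper, and the a-priori sample size for the within-between
interaction via the noncentral F distribution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import integrate
from scipy import stats as sps
from statsmodels.stats.diagnostic import lilliefors

from .errors import (
    DegenerateInputError,
    DesignError,
    InsufficientDataError,
    InvalidParameterError,
    MissingDataError,
)

DEFAULT_PRIOR_SCALE = math.sqrt(2) / 2


def normality_tests(x) -> dict[str, float]:
    """Shapiro-Wilk plus Kolmogorov-Smirnov with estimated parameters.

    The KS variant is the Lilliefors correction, appropriate when the
    normal's mean/SD are estimated from the sample.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 5:
        raise InsufficientDataError("need n >= 5 for both normality tests")
    if np.ptp(x) == 0:
        raise DegenerateInputError("constant input has no distribution to test")
    w, p_w = sps.shapiro(x)
    d, p_d = lilliefors(x, dist="norm")
    return {
        "shapiro_W": float(w),
        "shapiro_p": float(p_w),
        "ks_D": float(d),
        "ks_p": float(p_d),
    }


@dataclass
class EffectResult:
    F: float
    df1: int
    df2: int
    p: float
    eta_p2: float


@dataclass
class MixedAnovaResult:
    """F tests for the three effects of the 2x2 mixed design."""

    time: EffectResult
    group: EffectResult
    interaction: EffectResult
    n_by_group: dict = field(default_factory=dict)

    @property
    def effects(self) -> dict[str, EffectResult]:
        return {
            "time": self.time,
            "group": self.group,
            "time_x_group": self.interaction,
        }


def partial_eta_sq(F: float, df1: int, df2: int) -> float:
    """Partial eta squared from an F statistic and its degrees of freedom."""
    if F < 0:
        raise InvalidParameterError("F must be >= 0")
    if df1 < 1 or df2 < 1:
        raise InvalidParameterError("degrees of freedom must be >= 1")
    return F * df1 / (F * df1 + df2)


def _f_effect(num: float, mse: float, df2: int) -> EffectResult:
    """Assemble one effect from its numerator MS and error MS (df1 = 1)."""
    if num == 0.0:
        f = 0.0
    elif mse == 0.0:
        f = float("inf")
    else:
        f = num / mse
    p = float(sps.f.sf(f, 1, df2)) if np.isfinite(f) else 0.0
    eta = partial_eta_sq(f, 1, df2) if np.isfinite(f) else 1.0
    return EffectResult(F=float(f), df1=1, df2=df2, p=p, eta_p2=eta)


def mixed_anova_2x2(
    y_t0, y_t1, group, listwise: bool = False
) -> MixedAnovaResult:
    """Exact 2x2 mixed ANOVA via the means/differences decomposition."""
    y0 = np.asarray(y_t0, dtype=float)
    y1 = np.asarray(y_t1, dtype=float)
    g = np.asarray(group)
    if not (y0.size == y1.size == g.size):
        raise DesignError("y_t0, y_t1 and group must have equal length")
    bad = ~(np.isfinite(y0) & np.isfinite(y1))
    if bad.any():
        if not listwise:
            raise MissingDataError(
                f"{int(bad.sum())} subject(s) with missing values; "
                "enable listwise deletion to drop them"
            )
        y0, y1, g = y0[~bad], y1[~bad], g[~bad]
    levels = list(dict.fromkeys(g.tolist()))
    if len(levels) != 2:
        raise DesignError(f"need exactly 2 groups, got {len(levels)}")
    masks = [g == lev for lev in levels]
    n1, n2 = int(masks[0].sum()), int(masks[1].sum())
    if min(n1, n2) < 2:
        raise DesignError("each group needs at least 2 subjects")
    n = n1 + n2
    df2 = n - 2
    m = (y0 + y1) / 2.0
    d = y1 - y0
    inv_n = 1.0 / n1 + 1.0 / n2

    def pooled_var(x: np.ndarray) -> float:
        ss = sum(
            float(np.sum((x[mask] - x[mask].mean()) ** 2)) for mask in masks
        )
        return ss / df2

    # group: between-subjects contrast on subject means
    m1, m2 = float(m[masks[0]].mean()), float(m[masks[1]].mean())
    group_eff = _f_effect((m1 - m2) ** 2 / inv_n, pooled_var(m), df2)
    # time: unweighted grand mean of the differences against zero
    d1, d2 = float(d[masks[0]].mean()), float(d[masks[1]].mean())
    s2d = pooled_var(d)
    time_eff = _f_effect(((d1 + d2) / 2.0) ** 2 / (inv_n / 4.0), s2d, df2)
    # interaction: group contrast on the differences
    inter_eff = _f_effect((d1 - d2) ** 2 / inv_n, s2d, df2)
    return MixedAnovaResult(
        time=time_eff,
        group=group_eff,
        interaction=inter_eff,
        n_by_group={str(levels[0]): n1, str(levels[1]): n2},
    )


def anova_table(result: MixedAnovaResult) -> pd.DataFrame:
    rows = []
    for name, eff in result.effects.items():
        rows.append(
            {"effect": name, "F": eff.F, "df1": eff.df1, "df2": eff.df2,
             "p": eff.p, "eta_p2": eff.eta_p2}
        )
    return pd.DataFrame(rows)


@dataclass
class BayesResult:
    bf10: float
    bf01: float
    prior_scale: float
    t: float
    df: int


def jzs_ttest_bf(x, y, prior_scale: float = DEFAULT_PRIOR_SCALE) -> BayesResult:
    """JZS two-sample Bayes factor (Cauchy prior of scale *prior_scale*).

    The alternative places a Cauchy prior on the standardized effect size;
    marginalizing uses the equivalent normal-given-g mixture with g ~
    InverseGamma(1/2, r^2/2), reducing the Bayes factor to a
    one-dimensional integral over g evaluated by adaptive quadrature.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise InsufficientDataError("each sample needs n >= 2")
    if prior_scale <= 0:
        raise InvalidParameterError("prior_scale must be > 0")
    n1, n2 = x.size, y.size
    nu = n1 + n2 - 2
    sp2 = (
        (n1 - 1) * np.var(x, ddof=1) + (n2 - 1) * np.var(y, ddof=1)
    ) / nu
    if sp2 == 0:
        raise DegenerateInputError("zero pooled variance")
    neff = n1 * n2 / (n1 + n2)
    t = float((x.mean() - y.mean()) / math.sqrt(sp2 / neff))
    t2 = t * t
    r2 = prior_scale**2
    log_m0 = -(nu + 1) / 2.0 * math.log1p(t2 / nu)

    def integrand(g: float) -> float:
        c = 1.0 + neff * g
        log_m1 = -0.5 * math.log(c) - (nu + 1) / 2.0 * math.log1p(t2 / (c * nu))
        # InverseGamma(1/2, r^2/2) density
        log_pg = (
            0.5 * math.log(r2 / 2.0)
            - math.lgamma(0.5)
            - 1.5 * math.log(g)
            - r2 / (2.0 * g)
        )
        return math.exp(log_m1 - log_m0 + log_pg)

    bf10, _ = integrate.quad(
        integrand, 0.0, np.inf, epsrel=1e-8, epsabs=0.0, limit=200
    )
    return BayesResult(
        bf10=float(bf10), bf01=1.0 / float(bf10),
        prior_scale=prior_scale, t=t, df=nu,
    )


def se_of_mean(sd: float, n: int) -> float:
    """Standard error of a mean from its SD and sample size."""
    if sd < 0:
        raise InvalidParameterError("sd must be >= 0")
    if n < 1:
        raise InvalidParameterError("n must be >= 1")
    return sd / math.sqrt(n)


def interaction_power(
    n_total: int,
    f_effect: float,
    alpha: float,
    n_groups: int = 2,
    n_measures: int = 2,
    corr: float = 0.5,
) -> float:
    """Power of the within-between interaction F test at total size *n_total*."""
    df1 = (n_groups - 1) * (n_measures - 1)
    df2 = (n_total - n_groups) * (n_measures - 1)
    if df2 < 1:
        return 0.0
    lam = n_total * f_effect**2 * n_measures / (1.0 - corr)
    crit = sps.f.ppf(1.0 - alpha, df1, df2)
    return float(sps.ncf.sf(crit, df1, df2, lam))


def required_n_interaction(
    f_effect: float,
    alpha: float = 0.05,
    power: float = 0.95,
    n_groups: int = 2,
    n_measures: int = 2,
    corr: float = 0.5,
    n_max: int = 10_000,
) -> int:
    """Smallest total N (multiple of *n_groups*) reaching *power*.

    Noncentrality lambda = N * f^2 * m / (1 - rho), df1 = (g-1)(m-1),
    df2 = (N-g)(m-1); the standard G*Power-style convention for a mixed
    within-between interaction with repeated-measures correlation *rho*.
    """
    if f_effect <= 0:
        raise InvalidParameterError("f_effect must be > 0")
    if not (0 < alpha < 1) or not (0 < power < 1):
        raise InvalidParameterError("alpha and power must lie in (0, 1)")
    if not (-1 < corr < 1):
        raise InvalidParameterError("corr must lie in (-1, 1)")
    n = n_groups * 2
    while n <= n_max:
        if interaction_power(n, f_effect, alpha, n_groups, n_measures, corr) >= power:
            return n
        n += n_groups
    raise InvalidParameterError("no feasible N below n_max")
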