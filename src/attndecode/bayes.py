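"""Group-level inference: interval-null Cauchy-prior Bayes factors, onset
detection, and bootstrap confidence intervals.

At every timepoint the group evidence is summarised by a one-sample t
statistic over participants (accuracy against the 50% chance level, or a
paired difference against 0) and converted to a Bayes factor

    BF10 = [ integral f_nct(t; nu, delta * sqrt(n)) pi(delta) d delta ]
           / f_t(t; nu)

where ``f_nct`` is the noncentral-t density, ``f_t`` the central-t density
under the point null, and ``pi`` a Cauchy(0, r) prior on the standardised
effect size delta, truncated to exclude small effects (|delta| < 0.5 by
default) and renormalised.  Directional contrasts truncate to delta >= 0.5
(half-Cauchy); the attention x expectation interaction, for which no
direction is predicted, keeps both tails.  The prior scale defaults to the
conventional r = 0.707.

Onset latency of an effect is the second of the first pair of consecutive
post-stimulus timepoints whose BF10 exceeds 10 (strong evidence), so a
single stray suprathreshold timepoint never counts as an onset.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import integrate, stats

DEFAULT_PRIOR_SCALE: float = 0.707
DEFAULT_EXCLUDED_HALF_WIDTH: float = 0.5
#: Conventional evidence thresholds (strong null .. strong alternative).
EVIDENCE_THRESHOLDS: tuple[float, ...] = (1 / 10, 1 / 3, 3.0, 10.0)
ONSET_BF_THRESHOLD: float = 10.0

DIRECTIONAL = "positive_only"
TWO_SIDED = "two_sided"


@dataclass(frozen=True)
class PriorSpec:
    """Truncated Cauchy prior on the standardised effect size."""

    scale: float = DEFAULT_PRIOR_SCALE
    excluded_half_width: float = DEFAULT_EXCLUDED_HALF_WIDTH
    direction: str = DIRECTIONAL

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValueError("prior scale must be positive")
        if self.excluded_half_width < 0:
            raise ValueError("excluded interval bound must be >= 0")
        if self.direction not in (DIRECTIONAL, TWO_SIDED):
            raise ValueError(f"unknown prior direction: {self.direction!r}")

    @property
    def mass(self) -> float:
        """Prior mass retained after truncation (normalising constant)."""
        tail = stats.cauchy.sf(self.excluded_half_width, scale=self.scale)
        return tail if self.direction == DIRECTIONAL else 2.0 * tail


@dataclass
class GroupSample:
    """One number per participant plus the null value it is tested against."""

    values: np.ndarray
    null_value: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size < 2:
            raise ValueError("need a 1-D sample of at least 2 participants")

    @property
    def n(self) -> int:
        return self.values.size

    @property
    def df(self) -> int:
        return self.n - 1

    @property
    def t_statistic(self) -> float:
        x = self.values - self.null_value
        sd = x.std(ddof=1)
        if sd == 0:
            raise ValueError("zero variance: t statistic undefined")
        t = x.mean() / (sd / math.sqrt(self.n))
        if not np.isfinite(t):
            raise ValueError("non-finite t statistic")
        return float(t)


@dataclass
class BayesFactorTimecourse:
    """Group-level BF10 per timepoint for a named contrast."""

    contrast: str
    times_ms: np.ndarray
    bf10: np.ndarray
    n_participants: int
    prior: PriorSpec
    evidence_thresholds: tuple[float, ...] = EVIDENCE_THRESHOLDS


def _bf10_from_t(t: float, n: int, prior: PriorSpec) -> float:
    """Bayes factor from the t statistic by adaptive quadrature.

    The half-line delta in [a, inf) is mapped to u in (0, 1) via
    ``delta = a + u / (1 - u)`` before integrating; the two-sided prior adds
    the mirrored tail.
    """
    nu = n - 1
    a = prior.excluded_half_width
    sqrt_n = math.sqrt(n)

    def integrand(u: float, sign: float) -> float:
        delta = sign * (a + u / (1.0 - u))
        jac = 1.0 / (1.0 - u) ** 2
        val = (
            stats.nct.pdf(t, nu, delta * sqrt_n)
            * stats.cauchy.pdf(delta, scale=prior.scale)
            * jac
        )
        # the noncentral-t density underflows (0 * inf -> nan) at extreme
        # noncentrality, where the true contribution is 0
        return val if np.isfinite(val) else 0.0

    num, _ = integrate.quad(
        integrand, 0.0, 1.0, args=(1.0,), epsabs=1e-14, epsrel=1e-10, limit=200
    )
    if prior.direction == TWO_SIDED:
        neg, _ = integrate.quad(
            integrand, 0.0, 1.0, args=(-1.0,), epsabs=1e-14, epsrel=1e-10,
            limit=200,
        )
        num += neg
    return (num / prior.mass) / stats.t.pdf(t, nu)


def bf10(sample: GroupSample, prior: PriorSpec | None = None) -> float:
    """Interval-null Bayes factor for one group sample."""
    prior = prior or PriorSpec()
    return _bf10_from_t(sample.t_statistic, sample.n, prior)


def evidence_category(bf: float) -> str:
    """Classify a BF10 against the conventional 1/10, 1/3, 3, 10 thresholds."""
    t1, t2, t3, t4 = EVIDENCE_THRESHOLDS
    if bf < t1:
        return "strong_null"
    if bf < t2:
        return "substantial_null"
    if bf <= t3:
        return "inconclusive"
    if bf <= t4:
        return "substantial_alternative"
    return "strong_alternative"


# ---------------------------------------------------------------------------
# Contrast wiring from the tidy decoding table

#: contrast -> (measure, isi_condition, null value, prior direction)
CONTRASTS: dict[str, tuple[str, str, float, str]] = {
    "cued_vs_chance": ("cued", "all", 0.5, DIRECTIONAL),
    "uncued_vs_chance": ("uncued", "all", 0.5, DIRECTIONAL),
    "constant_vs_chance": ("cued+uncued", "constant", 0.5, DIRECTIONAL),
    "varied_vs_chance": ("cued+uncued", "varied", 0.5, DIRECTIONAL),
    "attention_effect": ("attention", "all", 0.0, DIRECTIONAL),
    "attention_effect_constant": ("attention", "constant", 0.0, DIRECTIONAL),
    "attention_effect_varied": ("attention", "varied", 0.0, DIRECTIONAL),
    "expectation_effect": ("expectation", "all", 0.0, DIRECTIONAL),
    "interaction": ("interaction", "all", 0.0, TWO_SIDED),
}


def contrast_matrix(
    curves: pd.DataFrame, contrast: str
) -> tuple[np.ndarray, np.ndarray, float]:
    """Participants x timepoints value matrix for a contrast.

    `curves` is the concatenated tidy output of
    :func:`attndecode.decode.run_all_conditions` over participants.  Returns
    (matrix, times_ms, null_value).
    """
    if contrast not in CONTRASTS:
        raise ValueError(f"unknown contrast: {contrast!r}")
    measure, isi, null_value, _ = CONTRASTS[contrast]

    def pivot(meas: str, isi_cond: str) -> pd.DataFrame:
        sub = curves[
            (curves["measure"] == meas) & (curves["isi_condition"] == isi_cond)
        ]
        if sub.empty:
            raise ValueError(f"no rows for measure {meas!r} / ISI {isi_cond!r}")
        return sub.pivot_table(
            index="participant", columns="time_ms", values="value", sort=True
        )

    if measure == "cued+uncued":
        wide = (pivot("cued", isi) + pivot("uncued", isi)) / 2.0
    elif measure == "interaction":
        wide = pivot("attention", "varied") - pivot("attention", "constant")
    else:
        wide = pivot(measure, isi)
    if wide.isna().any().any():
        raise ValueError("participants do not share a common time axis")
    return (
        wide.to_numpy(),
        wide.columns.to_numpy(dtype=float),
        null_value,
    )


def bf_timecourse(
    curves: pd.DataFrame,
    contrast: str,
    prior_scale: float = DEFAULT_PRIOR_SCALE,
    excluded_half_width: float = DEFAULT_EXCLUDED_HALF_WIDTH,
) -> BayesFactorTimecourse:
    """BF10 per timepoint for a named contrast.

    The prior is directional (half-Cauchy above the excluded interval) for
    every contrast except the attention x expectation interaction, which has
    no predicted direction and keeps both Cauchy tails.
    """
    matrix, times, null_value = contrast_matrix(curves, contrast)
    direction = CONTRASTS[contrast][3]
    prior = PriorSpec(
        scale=prior_scale,
        excluded_half_width=excluded_half_width,
        direction=direction,
    )
    values = np.array(
        [
            bf10(GroupSample(matrix[:, j], null_value=null_value), prior)
            for j in range(matrix.shape[1])
        ]
    )
    return BayesFactorTimecourse(
        contrast=contrast,
        times_ms=times,
        bf10=values,
        n_participants=matrix.shape[0],
        prior=prior,
    )


def onset_time(
    bf: BayesFactorTimecourse,
    threshold: float = ONSET_BF_THRESHOLD,
    restrict_nonnegative: bool = True,
) -> float | None:
    """Onset latency: second point of the first consecutive suprathreshold
    pair of post-stimulus timepoints, or None."""
    keep = bf.times_ms >= 0 if restrict_nonnegative else slice(None)
    times = bf.times_ms[keep]
    values = bf.bf10[keep]
    for i in range(len(values) - 1):
        if values[i] > threshold and values[i + 1] > threshold:
            return float(times[i + 1])
    return None


def bootstrap_ci(
    values: np.ndarray,
    n_boot: int = 10_000,
    level: float = 0.95,
    rng: np.random.Generator | int | None = None,
) -> tuple[float, float]:
    """Percentile bootstrap CI of the group mean (resampling participants)."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("need at least 2 participants to bootstrap")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    idx = rng.integers(0, values.size, size=(n_boot, values.size))
    means = values[idx].mean(axis=1)
    alpha = (1.0 - level) / 2.0
    low, high = np.quantile(means, [alpha, 1.0 - alpha])
    return float(low), float(high)


def contrast_summary(
    curves: pd.DataFrame,
    contrast: str,
    prior_scale: float = DEFAULT_PRIOR_SCALE,
    excluded_half_width: float = DEFAULT_EXCLUDED_HALF_WIDTH,
    n_boot: int = 10_000,
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """Per-timepoint group mean, bootstrap CI, BF10 and evidence category."""
    matrix, times, _ = contrast_matrix(curves, contrast)
    bf = bf_timecourse(curves, contrast, prior_scale, excluded_half_width)
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    rows = []
    for j, t in enumerate(times):
        low, high = bootstrap_ci(matrix[:, j], n_boot=n_boot, rng=rng)
        rows.append(
            {
                "time_ms": float(t),
                "mean": float(matrix[:, j].mean()),
                "ci_low": low,
                "ci_high": high,
                "bf10": float(bf.bf10[j]),
                "evidence": evidence_category(float(bf.bf10[j])),
            }
        )
    return pd.DataFrame(rows)
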