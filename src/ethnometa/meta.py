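"""Inverse-variance meta-analysis with DerSimonian–Laird random effects.

Heterogeneity is quantified with Cochran's Q (fixed-effect weights), the
I² proportion of variation attributable to between-study differences, and
the method-of-moments between-study variance τ² (truncated at zero).  When
τ² = 0 the random-effects pool coincides exactly with the fixed-effect
pool.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
from scipy import stats

from ._util import two_sided_normal_p, z_quantile
from .effects import EffectEstimate
from .exceptions import PoolingError

#: I² thresholds (fractions) bounding the qualitative heterogeneity bands.
DEFAULT_I2_THRESHOLDS = (0.25, 0.50, 0.75)
_I2_LABELS = ("negligible", "minimal", "moderate", "high")


class HeterogeneityResult(NamedTuple):
    q_stat: float
    q_df: int
    q_p: float | None
    i2: float
    tau2: float
    label: str


@dataclass
class MetaResult:
    """Pooled effect with heterogeneity diagnostics.

    CI bounds are on the OR scale; ``q_p`` is absent (None) for a single
    study, where Q has zero degrees of freedom.
    """

    pooled_log_or: float
    pooled_se: float
    ci_low: float
    ci_high: float
    z: float
    p_value: float
    q_stat: float
    q_df: int
    q_p: float | None
    i2: float
    tau2: float
    k: int
    model: str
    label: str

    @property
    def pooled_or(self) -> float:
        return math.exp(self.pooled_log_or)


def i2_label(
    i2: float, thresholds: Sequence[float] = DEFAULT_I2_THRESHOLDS
) -> str:
    """Qualitative band for an I² value given increasing thresholds."""
    if len(thresholds) != 3 or list(thresholds) != sorted(thresholds):
        raise ValueError("thresholds must be three increasing fractions")
    for cut, name in zip(reversed(thresholds), reversed(_I2_LABELS[1:])):
        if i2 >= cut:
            return name
    return _I2_LABELS[0]


def _validated(estimates: Sequence[EffectEstimate]) -> tuple[np.ndarray, np.ndarray]:
    if len(estimates) == 0:
        raise PoolingError("cannot pool an empty list of estimates")
    theta = np.array([e.log_or for e in estimates], dtype=float)
    se = np.array([e.se for e in estimates], dtype=float)
    if np.any(se <= 0):
        raise PoolingError("all standard errors must be positive")
    return theta, se


def heterogeneity(
    estimates: Sequence[EffectEstimate],
    thresholds: Sequence[float] = DEFAULT_I2_THRESHOLDS,
) -> HeterogeneityResult:
    """Cochran's Q, I² and DerSimonian–Laird τ² from fixed-effect weights."""
    theta, se = _validated(estimates)
    k = len(theta)
    if k == 1:
        return HeterogeneityResult(0.0, 0, None, 0.0, 0.0, i2_label(0.0, thresholds))
    w = 1.0 / se**2
    theta_fe = float(np.sum(w * theta) / np.sum(w))
    q = float(np.sum(w * (theta - theta_fe) ** 2))
    df = k - 1
    q_p = float(stats.chi2.sf(q, df))
    i2 = max(0.0, (q - df) / q) if q > 0 else 0.0
    denom = float(np.sum(w) - np.sum(w**2) / np.sum(w))
    tau2 = max(0.0, (q - df) / denom) if denom > 0 else 0.0
    return HeterogeneityResult(q, df, q_p, i2, tau2, i2_label(i2, thresholds))


def pool(
    estimates: Sequence[EffectEstimate],
    model: str = "random",
    thresholds: Sequence[float] = DEFAULT_I2_THRESHOLDS,
) -> MetaResult:
    """Pool log-OR estimates by inverse-variance weighting.

    ``model="fixed"`` weights by 1/SE²; ``model="random"`` adds the
    DerSimonian–Laird τ² to every study variance before weighting.  A single
    study passes through unchanged with Q = 0 and I² = 0.
    """
    if model not in ("fixed", "random"):
        raise ValueError(f"model must be 'fixed' or 'random', got {model!r}")
    theta, se = _validated(estimates)
    k = len(theta)
    het = heterogeneity(estimates, thresholds)
    tau2 = het.tau2 if model == "random" else 0.0
    w = 1.0 / (se**2 + tau2)
    pooled = float(np.sum(w * theta) / np.sum(w))
    pooled_se = float(1.0 / math.sqrt(np.sum(w)))
    z975 = z_quantile(0.975)
    z = pooled / pooled_se
    return MetaResult(
        pooled_log_or=pooled,
        pooled_se=pooled_se,
        ci_low=math.exp(pooled - z975 * pooled_se),
        ci_high=math.exp(pooled + z975 * pooled_se),
        z=z,
        p_value=two_sided_normal_p(z),
        q_stat=het.q_stat,
        q_df=het.q_df,
        q_p=het.q_p,
        i2=het.i2,
        tau2=tau2,
        k=k,
        model=model,
        label=het.label,
    )
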