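"""Small shared numeric helpers."""

from __future__ import annotations

from scipy.special import ndtr, ndtri


def z_quantile(p: float) -> float:
    """Standard-normal quantile rounded to 6 decimals.

    The rounding keeps CI <-> (log-OR, SE) round-trips bit-stable across
    modules (e.g. z_quantile(0.975) == 1.959964).
    """
    return round(float(ndtri(p)), 6)


def two_sided_normal_p(z: float) -> float:
    """Two-sided tail probability of a standard-normal statistic."""
    return min(1.0, float(2.0 * ndtr(-abs(z))))
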