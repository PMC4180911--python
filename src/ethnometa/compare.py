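"""Cross-population comparison of effect sizes for the same SNP.

Two pooled (or single-study) log odds ratios for the same harmonized risk
allele are contrasted with a Z test: z = (θ_a − θ_b) / sqrt(SE_a² + SE_b²),
two-sided normal p.  This is the "p_heterogeneity" between populations,
distinct from the within-population Cochran's Q.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from ._util import two_sided_normal_p
from .effects import EffectEstimate
from .exceptions import HarmonizationError


@dataclass
class PopulationComparison:
    """Z-test contrast of one SNP's effect between two populations."""

    snp_id: str | None
    delta_log_or: float
    se_delta: float
    z: float
    p_value: float
    raf_a: float | None = None
    raf_b: float | None = None


def compare_log_or(
    est_a: EffectEstimate,
    est_b: EffectEstimate,
    *,
    raf_a: float | None = None,
    raf_b: float | None = None,
) -> PopulationComparison:
    """Compare two log-OR estimates of the same SNP with a Z test.

    Raises :class:`HarmonizationError` if the estimates carry conflicting
    SNP identities or risk alleles (both tags optional, checked when both
    sides carry them).
    """
    if est_a.snp_id and est_b.snp_id and est_a.snp_id != est_b.snp_id:
        raise HarmonizationError(
            f"cannot compare different SNPs: {est_a.snp_id} vs {est_b.snp_id}"
        )
    if (
        est_a.risk_allele
        and est_b.risk_allele
        and est_a.risk_allele != est_b.risk_allele
    ):
        raise HarmonizationError(
            f"{est_a.snp_id or 'SNP'}: risk alleles not harmonized "
            f"({est_a.risk_allele} vs {est_b.risk_allele})"
        )
    delta = est_a.log_or - est_b.log_or
    se_delta = math.sqrt(est_a.se**2 + est_b.se**2)
    z = delta / se_delta
    return PopulationComparison(
        snp_id=est_a.snp_id or est_b.snp_id,
        delta_log_or=delta,
        se_delta=se_delta,
        z=z,
        p_value=two_sided_normal_p(z),
        raf_a=raf_a,
        raf_b=raf_b,
    )
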