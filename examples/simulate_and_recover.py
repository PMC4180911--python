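"""Simulate heterogeneous case-control studies and recover the truth.

Eight studies of 2,000 cases each are generated at nominal per-allele OR
1.2 with between-study variance tau2 = 0.01 on the log-OR scale, then fed
back through allele-count reconstruction and DerSimonian-Laird pooling.

Note the estimation target: an allelic 2x2 analysis estimates the realized
case-vs-control allelic OR, which at 10% prevalence is slightly larger
than the nominal per-genotype OR (controls are depleted of risk alleles).
"""

import math

from ethnometa import (
    SimulationConfig,
    estimate_from_record,
    implied_allelic_log_or,
    pool,
    simulate_studies,
)

config = SimulationConfig(
    true_or=1.2, raf=0.30, tau2=0.01, prevalence=0.10,
    n_cases_per_study=[2000] * 8, seed=2024,
)
records = simulate_studies(config)
estimates = [estimate_from_record(rec) for rec in records]
result = pool(estimates, model="random")

target = implied_allelic_log_or(0.30, 1.2, 0.10)
print(f"nominal OR 1.20 -> realized allelic OR {math.exp(target):.4f}")
print(f"pooled OR {result.pooled_or:.4f} (95% CI {result.ci_low:.4f}-{result.ci_high:.4f})")
print(f"tau2-hat {result.tau2:.5f} (generating tau2 0.01 on the nominal scale)")
print(f"I2 = {result.i2:.2f} ({result.label} heterogeneity)")
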