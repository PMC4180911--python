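"""Pool two studies of one SNP with random-effects meta-analysis.

The ST6GAL1 signal was reported by a large discovery scan (18,731 cases,
OR 1.09) and a smaller replication (1,256 cases, OR 1.14).  Inverse-variance
pooling is dominated by the precise large study.
"""

from ethnometa import estimate_from_ci, pool

discovery = estimate_from_ci(1.09, 1.06, 1.12)
replication = estimate_from_ci(1.14, 0.99, 1.31)

result = pool([discovery, replication], model="random")
print(f"pooled OR   {result.pooled_or:.4f}  (95% CI {result.ci_low:.4f}-{result.ci_high:.4f})")
print(f"Q = {result.q_stat:.3f} on {result.q_df} df, I2 = {result.i2:.2f}, tau2 = {result.tau2:.5f}")
print(f"heterogeneity: {result.label}")
# The pooled OR (1.09) sits on the large study; Q < df, so the
# DerSimonian-Laird tau2 truncates to 0 and random = fixed effects.
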