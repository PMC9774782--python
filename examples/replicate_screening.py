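"""Screen replicate rate constants with Dixon's Q-test before averaging."""

from pseudophase import aggregate

# Triplicate k_obs values with one suspicious datum.
replicates = [0.100, 0.101, 0.150]
rs = aggregate(replicates, confidence=0.95)

print(f"replicates: {rs.values}")
print(f"Q = {rs.q_statistic:.3f}; rejected index: {rs.rejected_index}")
print(f"retained: {rs.retained}")
print(f"mean = {rs.mean:.4f} 1/s, sd = {rs.sd:.5f}, CV = {rs.cv_percent:.2f}%")
print(f"precision flag (CV > 9%): {rs.precision_flag}")
# 0.150 gives Q = 0.98 > 0.970 (the 95% critical value for n = 3) and is
# excluded; the reported mean is that of the two concordant runs.
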