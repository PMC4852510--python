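"""Probe-level change calls with the Wilcoxon signed-rank test.

Builds one transcript with 11 probes, shifts it 4-fold between two samples
and shows the per-comparison call, then collapses replicate calls.
"""

import numpy as np

from tfinet.stats import Thresholds, change_call, consistent_call

rng = np.random.default_rng(0)

# 11 probes with probe-specific affinities, shared between samples
affinity = rng.normal(0, 0.5, 11)
control = 2 ** (8 + affinity + rng.normal(0, 0.25, 11))
treated = 2 ** (10 + affinity + rng.normal(0, 0.25, 11))  # +2 in log2

call = change_call(control, treated, Thresholds(), transcript_id="t1",
                   comparison="treated_vs_control")
print(f"call={call.call}  p={call.p:.5f}  log2_ratio={call.log2_ratio:.2f}")
# call=I: a consistent positive shift across all 11 probe pairs gives the
# smallest achievable one-sided p (1/2^11 ~ 0.0005); the log2 ratio is the
# difference of the summarized (mean log2) values, ~2.

replicate_calls = [call.call, "I"]
print("consistent over replicates:", consistent_call(replicate_calls))
# 'I' only if every replicate comparison agrees; any disagreement gives NC.
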