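"""The four-step thresholding pipeline on a synthetic cohort.

Simulates 20 subjects with planted four-block structure and subject-level
coupling jitter, then: (1) group-averages, (2) finds the weak-recoverability
interval [a_w, b_w] from the binarized group average, (3) sweeps weighted
SNR per subject and for the group average, (4) reports optimal thresholds
and their membership in the interval.
"""

import numpy as np

from prominet import planted_partition, run_cohort, sample_cohort

stack = sample_cohort(gamma=20, sizes=[30] * 4, seed=7)
part = planted_partition([30] * 4)
report = run_cohort(stack, part)

iv = report.interval
print(f"weak-recoverability interval: [{iv.a_w}, {iv.b_w}]")
print(f"tau_opt(GA) = {report.tau_opt_ga}  (max SNR {report.ga_max_snr:.2f}, "
      f"inside interval: {report.ga_in_interval})")

taus = [s.tau_opt for s in report.per_subject]
print(f"individual tau_opt: mean {np.mean(taus):.3f}, sd {np.std(taus):.3f}, "
      f"range [{min(taus)}, {max(taus)}]")
print(f"subjects inside interval: {sum(s.in_interval for s in report.per_subject)}/20")

print(
    "\nEvery threshold in [a_w, b_w] keeps the a priori partition weakly "
    "recoverable on the group average; tau_opt maximizes its prominence, and "
    "subject-level optima scatter around the group value with the coupling jitter."
)
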