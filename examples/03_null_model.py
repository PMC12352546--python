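"""Null model: shuffled partitions never look prominent.

Samples one planted-partition graph (n=400, four equal blocks, within-block
edge probability 0.25, between 0.02), then compares the SNR of the true
partition with the SNR distribution over 100 size-preserving shuffles of
the node-to-community assignment.
"""

import numpy as np

from prominet import graph_snr, graph_to_connectome, null_snr, sample_sbm

w = np.full((4, 4), 0.02)
np.fill_diagonal(w, 0.25)
graph, part = sample_sbm([100] * 4, w, seed=1)

true = graph_snr(graph, part).snr
ens = null_snr(graph_to_connectome(graph), part, n_shuffles=100, seed=0, mode="binary")

print(f"SNR with the planted partition: {true:.2f}")
print(f"null ensemble over 100 shuffles: min {ens.min_snr:.4f}, max {ens.max_snr:.4f}")
print(f"ordering 0 <= SNR_null < 1 < SNR_true holds: "
      f"{0 <= ens.min_snr and ens.max_snr < 1 < true}")

print(
    "\nShuffling destroys the block alignment, so every null SNR sits far "
    "below the weak-recovery threshold of 1 while the planted partition is "
    "strongly prominent — SNR responds to real structure, not to chance."
)
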