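# prominet

How well does a fixed, a priori set of communities — for instance the Yeo
resting-state networks mapped onto a brain parcellation — actually fit a
given weighted connectivity matrix? `prominet` quantifies that fit with an
information-theoretic **prominence statistic** built on stochastic block
models (SBMs), and uses it to drive a principled thresholding pipeline for
functional connectomes (FCs).

## The statistic

For a graph `G` on `n` nodes and a fixed partition `σ` with `k` communities
of sizes `Ω`, the SBM parameters are inferred in closed form:

```
p = Ω / n                    community occupancy probabilities
W = C / C_max                per-block-pair edge probability (binary mode)
                             or mean absolute edge weight (weighted mode)
PQ = n · diag(p) · W         community profile matrix
```

`PQ[i, j]` is the expected number of neighbors a community-`i` node has in
community `j`. With eigenvalues of `PQ` ordered by descending magnitude,

```
SNR = λ₂² / λ₁
```

is the prominence of `σ` on `G`. **SNR > 1** is the Kesten–Stigum condition:
the partition is weakly recoverable (better than chance) by an efficient
algorithm. For the symmetric two-equal-block model with within/between
degree parameters `a`, `b`, SNR has the closed form `(a − b)² / (2(a + b))`.

## The pipeline

Given a cohort of subject FCs and an a priori partition:

1. group-average the FCs and binarize at each threshold `τ` on a grid
   (default 0:1:0.05, magnitude convention `|a_uv| ≥ τ`);
2. **vetting** — compute the binary-mode SNR per `τ` and extract the
   weak-recoverability sub-interval `[a_w, b_w]` where SNR > 1;
3. sweep the weighted-mode SNR per subject and for the group average;
4. take `τ_opt = argmax_τ SNR` per matrix and check `τ_opt ∈ [a_w, b_w]`.

Validation utilities include size-preserving partition shuffles (null
models), Newman modularity `Q` with tuning parameter `α`, a Louvain-style
Q-maximization back-test, and adjusted mutual information (AMI).

## Worked example

```python
import numpy as np
from prominet import planted_partition, run_cohort, sample_cohort

stack = sample_cohort(gamma=20, sizes=[30] * 4, seed=7)   # 20 subjects, n=120
part = planted_partition([30] * 4)
report = run_cohort(stack, part)
```

Running `python examples/02_threshold_pipeline.py` (which does exactly this)
prints:

```
weak-recoverability interval: [0.1, 0.55]
tau_opt(GA) = 0.15  (max SNR 17.71, inside interval: True)
individual tau_opt: mean 0.190, sd 0.044, range [0.1, 0.25]
subjects inside interval: 20/20
```

The planted four-block structure is weakly recoverable for every threshold
in `[0.10, 0.55]`; the group-average FC is most prominent at `τ = 0.15`,
and each subject's individual optimum lies inside the vetted interval, with
the mean individual optimum within one grid step of the group value. The
other scripts in `examples/` walk through the closed-form oracle, the null
model, and the modularity back-test.

The same workflows are available from the shell:

```sh
prominet simulate --gamma 20 --blocks 30,30,30,30 --seed 7 --out-dir sim/
prominet fit --cohort sim/manifest.txt --partition sim/partition.tsv --out-dir fit/
prominet null --fc sim/subj_000.txt --partition sim/partition.tsv --shuffles 100
prominet backtest --fc sim/subj_000.txt --partition sim/partition.tsv
```

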