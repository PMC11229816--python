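# recbreak

How accurately can recombination detection methods *localize* breakpoints,
which features of the sequence data drive that accuracy, and how much does
breakpoint-based alignment slicing improve local phylogeny reconstruction?
`recbreak` is a simulation-and-evaluation pipeline built to answer these
questions for three classic detector families, aimed at researchers in
phylogenetics and molecular evolution who need to choose a detection
method or partition alignments into recombination-free segments.

## What it does

**Simulation.** Ancestral recombination graphs (ARGs) are simulated under
the back-in-time coalescent with recombination (Hudson's algorithm) for
1,000 bp genomes with Ne = 1 and equal base frequencies, optionally
conditioned by rejection on the number of recombination events. Each event
is classified by where the recombinant's two parent lineages next
coalesce: **Type I** (immediately with each other — invisible in the
data), **Type II** (via one intermediate coalescence — branch lengths
change, topology does not) or **Type III** (with different lineages —
local-tree topology changes). Sequences evolve along each local tree under
the single-rate equal-frequency (Jukes–Cantor) model with μ = π/(2Ne) and
are concatenated, so alignments are exact mosaics of the local
genealogies.

**Detection.** Three natively implemented detector families:

- *Pairwise χ² scan* (MaxChi family): at every boundary k the 2×2 table of
  (differing, matching) site counts left/right of k gives
  χ²(k) = N(ad−bc)² / ((a+b)(c+d)(a+c)(b+d)); the maximizing boundary is the
  candidate breakpoint, with significance by permuting site order and
  recursion into flanks on detection.
- *Triplet exact test* (3SEQ family): sites where a candidate child C
  matches exactly one of two parents P/Q define a ±1 walk; the statistic is
  the walk's maximum descent, with the exact p-value
  P(max descent ≥ k | m up-steps, n down-steps) computed by dynamic
  programming over the hypergeometric random walk.
- *AICc incongruence scan* (GARD family): neighbor-joining trees from
  JC-corrected distances are fit to the flanks of each candidate boundary,
  segment log-likelihoods come from Felsenstein pruning, and the two-tree
  model is accepted when its small-sample-corrected AIC
  (AICc = AIC + 2p(p+1)/(N−p−1)) beats the single-tree model; multiple
  breakpoints are added greedily.

**Evaluation.** Localization error in bp (nearest-visible-breakpoint
matching through sub-ARG extraction in the multiple-breakpoint setting),
detection power and specificity by event type, and localization precision
as the reciprocal positional variance of each detector's normalized
site-wise breakpoint-probability profile.

**Feature regression.** A NIPALS partial least squares regression of
localization error on five predictors (realized diversity, recombination
type, mean informative-site distance to the breakpoint, and log counts of
consistent and inconsistent informative sites), with the per-predictor
explained variance p_j = Σᵢ (w²ᵢⱼ/wᵢ)πᵢ and case-resampling bootstrap
intervals for the coefficients.

**Phylogenetic evaluation.** Alignments are sliced at true or detected
breakpoints with an exclusion window of W sites centered on each
breakpoint; maximum-likelihood local trees (NJ start, branch-length
optimization, NNI hill climbing) are reconstructed per segment; accuracy
is the per-site Robinson–Foulds distance to the true local tree,
normalized by 2(n−3), with neighbor-tree interpolation across excluded
windows.

## Worked example

```python
import numpy as np
from recbreak import SimulationConfig, simulate_arg, simulate_sequences
from recbreak.detect import run_all_detectors

rng = np.random.default_rng(33)
cfg = SimulationConfig(sample_size=3, diversity=0.2, recomb_rate=1e-3,
                       min_events=1, max_events=1, child_is_sample=True)
arg = simulate_arg(cfg, rng)
aln = simulate_sequences(arg, rng=rng)
ev = arg.events[0]
print("true:", ev.breakpoint, ev.event_type)
for method, events in run_all_detectors(aln, rng=rng).items():
    for e in events:
        print(method, e.point, e.interval, e.pvalue)
```

prints

```
true: 708 III
maxchi 721.0 (721, 721) 0.000999000999000999
threeseq 711.0 (710, 712) 6.390414646656736e-08
gardlike 711.0 (711, 711) None
```

A Type III event at position 708 is detected by all three methods: the
triplet exact test places it in the uninformative gap (710, 712] (3 bp
off), the AICc scan at 711, and the χ² scan at 721. The same machinery is
available from the shell (`recbreak simulate`, `recbreak detect`,
`recbreak run-study`, `recbreak make-fixtures`).

The full analyses live under `analysis/` as numbered drivers
(`01_single_breakpoint.py` … `04_phylo_reconstruction.py`); each writes
its tables under `results/`.

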