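# flagmot

Bacterial swimming is powered by the flagellar motor, a rotary machine built
from ~50 conserved proteins (rotor C-ring, MS/P/L rings, rod and hook, H/T
rings, filament, stators, a type-III export apparatus, and regulators).
`flagmot` implements a genome-to-phenotype-to-phylogeny pipeline around that
machine, for comparative genomicists who want to:

1. **Screen** raw homology hit tables (HMMER-style) for 54 flagellar query
   proteins — e-value threshold (1e-10), per-protein subject-length ranges,
   and structural-verdict propagation through CD-HIT-style sequence clusters
   — into a binary genomes × proteins presence/absence matrix.
2. **Classify motility** from the single count feature
   N_FP = number of distinct flagellar proteins detected:
   non-motile if N_FP ≤ 15, motile if N_FP ≥ 32, "partial" flagellar sets in
   between; validate calls against observed phenotypes
   (accuracy/sensitivity/specificity with motile as the positive class); and
   summarize doubly-normalized functional-class abundances,
   value(group, class) = presences ⁄ (n_genomes × n_proteins).
3. **Infer trait evolution** on a rooted phylogeny with continuous-time
   Markov chains: the 2-state model with gain rate q01 and loss rate q10
   (generator Q with rows summing to 0, likelihood via Felsenstein pruning),
   Metropolis–Hastings posterior sampling under uniform(0, 100) rate priors,
   stepping-stone log marginal likelihoods, model choice by
   logBF = 2·(log ML₁ − log ML₀) with logBF > 2 read as positive support,
   marginal ancestral-state reconstruction, and Pagel's 4-state
   dependent/independent test for correlated evolution of two binary traits
   (states 00/01/10/11, simultaneous double transitions forbidden).

A first-class synthetic-data module generates every input the pipeline
consumes — pure-birth (Yule) trees, binary and paired traits evolved under
known rates, bimodal genome-scale hit tables with planted filter violations,
and noisy phenotype labels — with ground truth carried separately, so the
whole pipeline is testable offline.

## Worked example

```python
import numpy as np
from flagmot import simulate, ctmc
from flagmot.screen import HomologScreen
from flagmot.classify import MotilityClassifier, summarize_group_composition
from flagmot.bayes import MCMCSettings, RateAsymmetryTest
from flagmot.registry import default_class_map

# genomes -> screen -> classify
sim = simulate.simulate_hit_tables(simulate.HitTableSpec(n_genomes=1000), seed=8)
matrix = HomologScreen().presence_absence(sim.hits,
                                          genome_universe=sim.truth_labels["genome_id"])
calls = MotilityClassifier().calls(matrix)
merged = calls.merge(sim.truth_labels, on="genome_id")
print(f"recovery: {100 * (merged.label_x == merged.label_y).mean():.1f}%")
comp = summarize_group_composition(matrix, calls, default_class_map())
print(comp.set_index("functional_class").loc["filament", ["motile_pct", "nonmotile_pct"]])

# trait evolution on a 2,000-tip tree with loss-biased rates
tree = simulate.simulate_yule_tree(2000, seed=1)
trait = simulate.simulate_binary_trait(tree, q01=0.22, q10=0.81, seed=2)
test = RateAsymmetryTest(iterations=50_000, burn_in=10_000, seed=7).fit(
    trait.tree_arrays, trait.tip_dict())
print(f"logBF(free vs equal) = {test.log_bf_:.1f}  ({test.direction_})")
print({k: round(v, 3) for k, v in test.rates_.items()})
```

prints

```
recovery: 99.4%
motile_pct       100.0
nonmotile_pct      0.0
Name: filament, dtype: float64
logBF(free vs equal) = 91.3  (loss-biased)
{'q01': 0.236, 'q10': 0.868}
```

The classifier recovers essentially all generator truth labels (the ~0.5%
misses fall into the "partial" band between the thresholds); filament
proteins occur exclusively in motile genomes by construction; and on the
simulated tree the free-rates model is decisively preferred, with posterior
means close to the generating gain/loss rates and loss ≈ 3.7× faster than
gain.

There is also a CLI mirroring these stages:

```sh
flagmot simulate --n-genomes 1000 --n-tips 200 --seed 3 --outdir run/
flagmot screen   --hits run/hits.tsv --outdir run/
flagmot classify --matrix run/presence_absence.tsv --phenotypes run/phenotypes.tsv --outdir run/
flagmot fit      --tree run/tree.nwk --trait run/trait.tsv --model asymmetry-test --outdir run/
flagmot correlate --tree run/tree.nwk --trait-a a.tsv --trait-b b.tsv --outdir run/
```

Every subcommand drops a JSON manifest (settings + seed) sufficient to
reproduce its outputs byte-for-byte.

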