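# transmitbias

Simulation-based estimation of social-learning biases in two-variant
cultural-transmission experiments.

## The problem

A participant learns two alternative strategies for the same task — one from
an **expert**, one from a **peer**, in counterbalanced order — and must pass
exactly one of them on, either to a novice (expert-to-novice context) or to a
peer (peer-to-peer context). The data are production counts per condition.
How strong are the forces shaping that choice: the model-based (prestige)
bias toward the expert's variant, the context-congruence bias toward the
variant learned in a matching context, and the order (primacy/recency) bias?

`transmitbias` answers this with a probabilistic choice model, a forward
simulator of the experiment, a grid-search rejection estimator of the bias
magnitudes, an exact analytic oracle for that estimator, the chi-squared
count analyses, and a synthetic-cohort generator for end-to-end validation.

## The model

Each bias *b* ∈ [−1, 1] (0 = neutral) maps to a weight *w(b)* = (1 + *b*)/2.
A variant's production weight is the product of its source factor
(*w*(ExpertBias) for the expert's variant), its congruence factor
(*w*(CongruentBias) if its source is the context-congruent one) and its
order factor (*w*(PrimacyBias) for the last-learned variant — positive
PrimacyBias favours the last-learned variant by this sign convention). The
produced variant is drawn with probability proportional to its weight (Luce
choice rule). With a neutral primacy bias the per-condition expert count is
Binomial(*n*, *p*), which gives the estimator a closed-form oracle.

The estimator is rejection sampling on a parameter lattice: simulate *S*
experiments per parameter combination, keep the combinations whose simulated
count tables match the observed one cell-for-cell (within an integer
tolerance), and summarize the match-weighted parameter distributions.

## Worked example

Estimate the expert and congruence biases from the production counts
(expert-to-novice: 27 expert / 3 peer; peer-to-peer: 14 expert / 18 peer):

```python
import transmitbias as tb

observed = tb.CountTable.from_four_counts(27, 3, 14, 18)
design = tb.ExperimentDesign(n_e2n=30, n_p2p=32)

# hypothesis tests on the counts
report = tb.analyze_counts(observed)
print(report["tests"]["overall_expert_vs_peer"])
# {'statistic': 6.451612903225806, 'df': 1, 'p_value': 0.011085...,
#  'alpha': 0.016666666666666666, 'significant': True}

# grid rejection estimation: -1..1 in steps of 0.01, 5000 sims per cell
grid = tb.run_grid(observed, design, tb.GridSpec.two_parameter(), seed=1)
summary = tb.summarize_matches(grid)
for name, p in summary.parameters.items():
    print(f"{name}: mean {p.mean:.4f}  sd {p.sd:.4f}  n {p.n}")
# expert_bias: mean 0.4328  sd 0.1346  n 152570
# congruent_bias: mean 0.5276  sd 0.1196  n 152570

# exact infinite-simulation limit of the same summary
exact = tb.exact_weighted_moments(observed, design, tb.GridSpec.two_parameter())
print({k: round(v["mean"], 4) for k, v in exact["parameters"].items()})
# {'expert_bias': 0.4322, 'congruent_bias': 0.5273}
```

The overall expert-vs-peer production difference (41 vs 21) is significant
at the Bonferroni-corrected threshold 0.05/3; the estimated congruence bias
(≈0.53) exceeds the expert bias (≈0.43), i.e. the variant learned in the
matching context is favoured even more strongly than the expert's variant.

The same pipeline is scriptable from the shell:

```sh
transmitbias generate --params 0.4,0.5 --n 32 --exclude 2 --seed 7 --out cohort.csv
transmitbias analyze  --observed cohort.csv --out report.json
transmitbias estimate --observed counts.json --step 0.01 --reps 5000 --seed 1 \
    --out summary.json --grid-csv grid.csv --heatmap grid.png
transmitbias oracle   --observed counts.json --step 0.01 --out moments.json
```

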