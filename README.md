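# exprdriver

Per-patient functional somatic-mutation calling from expression-profile
similarity.

Tumor cohorts carry far more somatic mutations than drivers: recurrence
alone is misleading because very long genes (TTN, MUC6, ...) accumulate
passengers at high rates. `exprdriver` separates functional from
non-functional mutations patient by patient using one idea: a mutation
that matters reshapes the carrier's expression profile, so its gene should
be *enriched among the patient's expression neighbors*. It is written for
cancer genomicists who have a normalized expression matrix and a gene-level
somatic mutation matrix (or MAF) for the same cohort and want per-patient
driver calls — not just cohort-level gene rankings.

## The statistic

For each patient P, the n most-correlated patients (Pearson r over the top
2000 highest-variance features, r ≥ 0.6, P included) form P's
neighborhood. For each mutated gene g of P, with k mutated neighborhood
members, K cohort-wide carriers and N patients, the enrichment p-value is
the upper hypergeometric tail — the one-sided Fisher exact test of

    [[k, n − k], [K − k, N − n − K + k]]

and the mutation is called functional for P when p < 0.01. The same
machinery annotates each patient with over-represented gene-set terms
(GMT) from the neighborhood's pooled mutated genes, contrasts variant-class
composition between functional and non-functional carriers, and links
functionally co-mutated genes into a synergy network weighted by
s(a,b) = |A ∩ B| / max(|A|, |B|) over functional-carrier sets.

A full account of the model, its defaults, the synthetic-cohort generator
and known limitations is in [docs/methods.md](docs/methods.md).

## Worked example

Simulate the reference cohort (300 patients, 5 planted drivers whose
mutations imprint expression signatures, random passengers, and one
TTN-like high-rate passenger gene), run the caller, and score against
ground truth:

```python
from exprdriver import (CallerParams, call_functional_mutations, calls_table,
                        evaluate_recovery, recurrence_table, summarize_recurrence)
from exprdriver.synthetic import SimulationConfig, simulate_cohort

cohort = simulate_cohort(SimulationConfig(seed=7))
res = call_functional_mutations(cohort.expression, cohort.mutations, CallerParams())

print(calls_table(res.calls).query("functional").head(5).to_string(index=False))
print(recurrence_table(summarize_recurrence(res.calls, cohort.mutations))
      .head(7).to_string(index=False))
rep = evaluate_recovery(res.calls, cohort.truth)
print(f"precision={rep.precision:.3f} recall={rep.recall:.3f}")
```

Output:

```
patient gene  k  n  K   N            p  functional
  P0001 G005 10 10 46 300 2.915177e-09        True
  P0004 G003 10 10 57 300 3.088207e-08        True
  P0005 G003 10 10 57 300 3.088207e-08        True
  P0007 G001 10 10 47 300 3.703062e-09        True
  P0007 G004 10 10 51 300 9.137901e-09        True
gene  somatic  functional  percentage
G003       57          57       100.0
G004       51          49        96.1
G001       47          43        91.5
G005       46          43        93.5
G002       37          37       100.0
G063        4           2        50.0
G078        5           1        20.0
precision=0.983 recall=0.991
```

Reading it: each functional call reports the neighborhood count k of n,
the cohort recurrence K of N and the tail p. The five planted drivers
(G001–G005) are recovered in >90% of their carriers, while the TTN-like
gene G100 — the most recurrent non-driver (50 carriers) — receives zero
functional calls: recurrence without an expression footprint is filtered
out, which is the point of the method.

The same pipeline runs from the shell on tab-separated files:

```sh
exprdriver simulate --out sim --seed 7
exprdriver run --expression sim/expression.tsv --mutations sim/mutations.tsv \
               --gmt sim/gene_sets.gmt --out results
exprdriver evaluate --calls results/calls.tsv --truth sim/truth.tsv
```

`run` writes the calls table, recurrence summary, neighbor table,
per-patient term annotations and coverage, the synergy network
(GraphML + edge list), a skipped-patients list and a manifest that
reproduces the run bit-identically.

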