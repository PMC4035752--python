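# callstack

Combine somatic SNV calls from multiple mutation callers into a single,
probability-ranked call list.

## The problem

Somatic mutation calling from paired tumor/normal sequencing is hard
enough that no single caller dominates: a liberal caller finds nearly all
true mutations but drowns them in false positives, a strict caller is
clean but blind to much of the signal. When the calls of K callers over
the same samples have been *impartially validated* — every site detected
by at least one caller re-sequenced and labeled somatic or not — that
validation set can be used to learn how to combine the callers, and the
learned combiner can then rank calls in a wider dataset produced with the
same protocol.

`callstack` implements three combiners of increasing sophistication, plus
the evaluation conventions that make them comparable:

1. **Set operations** — intersections, unions, at-least-m-of-K.
2. **Cumulative subset ranking** — the union of calls is partitioned into
   the `2^K - 1` disjoint caller-combination subsets ("detected by A and C
   but not B", ...); subsets are sorted by their training validation rate
   and added cumulatively, tracing a step-wise ROC of combined callers of
   decreasing stringency.
3. **Feature-weighted stacking (FWLS)** — a logistic model for

   `P(y_i = 1 | c_i, g_i) = sigmoid( b + Σ_l γ_l x_il )`

   where the expanded features `x_il` are the combination-status
   indicators, genomic features `g_ij` (tumor/normal sequencing depth,
   tumor/normal variant allele fraction, substitution type), and all
   status × feature products — equivalent to letting each caller
   pattern's weight vary linearly with the site's features. The γ are
   estimated with an ℓ1 penalty `λ Σ_l |γ_l|` along a decreasing λ path;
   λ is chosen by 10-fold cross-validated binomial deviance with the
   one-standard-error rule, then the model is refit on the whole training
   set at that λ.

A fourth mode refines a *single* caller that exposes a mutation quality
score and per-filter pass/fail flags: a logistic model on
{quality, filter indicators} re-ranks the caller's candidate set, often
recovering true mutations discarded by an over-aggressive filter.

All evaluation uses **union ascertainment**: only sites detected by ≥1
caller exist, so the union holds every true and every false positive, and
TP/FP rates of any sub-caller are computed against those union totals.

## Worked example

The package ships the published seven-subset validation counts of a
three-caller endometrial tumor study (4,438 union-ascertained sites,
977 false / 3,461 true positives) as `callstack.reference_data`:

```python
>>> from callstack.reference_data import endometrial_subset_stats
>>> from callstack.cumulative import order_by_validation_rate, cumulative_rates
>>> stats = endometrial_subset_stats()
>>> ordering = order_by_validation_rate(stats)
>>> [s.label for s in ordering.ordered_statuses]
['A+B+C', 'A+C', 'A+B', 'B+C', 'C', 'A', 'B']
>>> [round(r, 1) for r in ordering.train_val_rates]
[99.4, 96.4, 96.3, 94.4, 79.6, 59.7, 15.9]
>>> [(round(f, 1), round(t, 1)) for f, t in cumulative_rates(ordering, stats)]
[(1.2, 55.3), (2.4, 63.8), (3.1, 69.1), (3.3, 70.1), (4.4, 71.3), (69.1, 98.4), (100.0, 100.0)]
```

Reading: calls detected by all three callers validate at 99.4%; accepting
the top four subsets already recovers 70.1% of all true mutations at only
3.3% of the false positives, while the last two subsets ("A only",
"B only") carry nearly all the noise.

The same pipeline runs end to end on synthetic data from the shell:

```bash
callstack simulate --seed 5 --out-dir data/          # 3 callers, ~4,400 sites, 78% somatic
callstack venn --calls A=data/caller_A.vcf --calls B=data/caller_B.vcf \
    --calls C=data/caller_C.vcf --validation data/validation.tsv --out venn.tsv
callstack stack train --calls A=data/caller_A.vcf --calls B=data/caller_B.vcf \
    --calls C=data/caller_C.vcf --validation data/validation.tsv \
    --features data/features.tsv --seed 1 --out model.json
callstack stack predict --model model.json --calls A=data/caller_A.vcf \
    --calls B=data/caller_B.vcf --calls C=data/caller_C.vcf \
    --features data/features.tsv --out ranked.tsv
callstack eval --ranked ranked.tsv --validation data/validation.tsv --out roc.tsv
```

`eval` prints the ranked list's AUC (≈0.99 on the default synthetic
conditions) and writes the ROC points; `stack train` reports the selected
penalty and the number of active columns (typically ~20 of 111).

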