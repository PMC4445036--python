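# oscal

Overlap-significance scoring of entity pairs from shared annotations.

Many questions in systems biology reduce to the same primitive: two genes
(or transcription factors, proteins, miRNAs, gene sets, ...) are each
described by a set of properties — regulatory targets, GO terms,
interaction partners — and the strength of their relationship is read off
the overlap of those two sets.  This package scores such overlaps with
the **OScal** model and seven classical alternatives, turns whole
annotation tables into ranked pair lists, and provides the
parameter-space and precision-vs-cutoff machinery needed to compare
scoring models against a gold standard.

## The model

An overlap is the integer triple `(m, n, d)` — the two set sizes and
their intersection — against a universe of `N` properties.  Its
*characteristic parameters* are

```
d                  intersection size
R = sqrt(m·n) / d  average expansion ratio  (R ≥ 1)
r = max(m,n) / min(m,n)   set-size imbalance (1 ≤ r ≤ R²)
```

and the random expectation of `d` is `λ = m·n/N`.  Only `d > λ` counts as
a real overlap; in the d-R plane the boundary is the curve `d = N/R²`.

The classical scores split into two classes: similarity coefficients
(Jaccard `J`, Ochiai `K = 1/R`, overlap coefficient `C`), which ignore
`d` given `(R, r)`, and significance scores (mutual information `I`,
Poisson `P`, hypergeometric `H`, binomial `B`), reported as `-log10` of
the point probability of observing exactly `d` shared properties.  All
probability scores are computed in log space with log-gamma, so they stay
finite where probability-first arithmetic underflows to zero (the
classical failure of `H`/`B` on large overlaps).  The Poisson score uses
the Stirling-simplified closed form

```
P = [ d·ln(d/λ) − (d−λ) + ½·ln(2πd) ] / ln 10 ,
```

whose error versus the exact Poisson mass is below `1/(12·d·ln 10)`.

OScal balances the two classes.  Similarity models fall into a trap
beyond the boundary (hub sets overlap heavily by chance alone);
significance models overestimate small-`d` overlaps because `λ` is then
tiny.  OScal is the three-item score

```
OS = Ps + M_J − M_r
```

where `Ps` (model id `OS_B`) is the Stirling-Poisson score at an
*enlarged* expectation `λ' = c(d, R)·λ` that deflates small-`d`/large-`R`
cases, `M_J` adds a small imbalance-sensitive term so that at equal
`(d, R)` the more lopsided pair ranks slightly higher (as the
hypergeometric model does), and `M_r` penalizes sets that approach the
whole universe.  The result is finite for every valid overlap, ranks
reference cases like the hypergeometric model, and is pure closed-form
algebra — millions of pairs score in well under a second.

## Worked example

The six reference overlaps (`N = 22507`, roughly the human gene count):

```
$ oscal table1 --models K,C,J,P,H,OS
case  m    n    d    R     r     K          C          J         P        H        OS
O1    25   25   20   1.25  1     0.8        0.8        0.666667  49.5251  59.2064  50.16
O2    250  250  200  1.25  1     0.8        0.8        0.666667  287.39   388.971  287.39
O3    250  250  100  2.5   1     0.4        0.4        0.25      114.819  134.04   114.36
O4    625  100  100  2.5   6.25  0.4        1          0.16      114.819  159.186  114.44
O5    520  520  200  2.6   1     0.384615   0.384615   0.238095  164.177  199.157  163.38
O6    520  520  40   13    1     0.0769231  0.0769231  0.04      9.94081  10.5974  1.66
```

Reading the rows: O1 and O2 share the same similarity profile
(`K = C = 0.8`) but O2's overlap of 200 against an expectation of 2.8 is
astronomically less probable, which only the significance scores see.
O4's fully contained 100-set maxes out `C = 1` while `J` drops to 0.16 —
the imbalance `r = 6.25` pulls the two coefficients apart, and OScal
nudges O4 (114.44) above the balanced O3 (114.36) just as `H` does
(159 vs 134).  O6 shares 40 properties, but its expectation is already
12, so OScal deflates the Poisson score from 9.9 to 1.66.

Scoring an annotation file end to end:

```
$ oscal simulate --seed 11 --outdir synth/
$ oscal score-pairs --annotations synth/annotations.tsv --models K,P,OS \
      --out scores.tsv
$ oscal evaluate --scores scores.tsv --gold synth/gold_pairs.tsv \
      --model OS --matched-k 50 --out curve.tsv
```

`score-pairs` emits one row per entity pair sharing at least one
property, with the overlap geometry (`d, m, n, R, r, λ`, boundary flag)
followed by one column per model; `evaluate` writes the cutoff-PPV curve
(`PPV = TP/PC`, the fraction of positive calls present in the gold
standard) and prints a matched-call table comparing all score columns at
the same call depth.

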