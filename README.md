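# srmdesign

In-silico design of targeted proteomics (SRM/MRM) assays: starting from
target protein sequences alone — optionally merged with pre-existing
transition repositories — `srmdesign` produces an optimally *scheduled*
transition list for a triple-quadrupole instrument by solving an integer
linear program.

## Who this is for

Selected reaction monitoring quantifies a predefined set of proteins by
monitoring *transitions*: (precursor m/z, product m/z) pairs for proteotypic
peptides, each inside a retention-time window. An instrument can only follow
a few dozen transitions concurrently, so the hard part of assay development
is not listing plausible transitions but *scheduling* them: choosing which
transitions to monitor, and when, so that every target protein is covered by
enough peptides and every peptide by enough transitions, without exceeding
the concurrency limit anywhere in the LC gradient. `srmdesign` automates the
entire path from FASTA to scheduled transition list.

## The scheduling model

Given proteins *S*, their tryptic peptides *P*, and candidate transitions
*T* — each transition *t* carrying a joint detectability *d_t* ∈ [0,1]
(proteotypicity × predicted fragment intensity) and an RT window of length
2δ — the gradient is divided into *N* slots and binary variables are
introduced: *x_t* (transition scheduled), *y_p* (peptide *p* **not** covered
by τ transitions), *z_sj* (protein *s* **not** represented by *j*+1
peptides). The program is

```
maximize   Σ_t x_t d_t  −  ω^p Σ_p y_p  −  ω^s Σ_s Σ_{j=0}^{ρ−1} z_sj (ρ−j)²

s.t.       τ·y_p + Σ_{t∈T_p} x_t         ≥ τ         ∀ p ∈ P
           (j+1)·z_sj + Σ_{p∈P_s}(1−y_p) ≥ j+1       ∀ s ∈ S, 0 ≤ j < ρ
           Σ_{t∈T_Si} x_t                ≤ C         ∀ slots i = 1..N
           x, y, z binary
```

where *T_Si* are the transitions whose RT window intersects slot *i* and
*C* is the instrument's concurrency limit. The program is solved to proven
optimality with branch-and-bound (HiGHS, via `scipy.optimize.milp`); a
brute-force enumerator and a greedy baseline are included for verification.

Peptide annotations come from pluggable predictors — a trainable linear
retention-time model, a logistic proteotypicity model, and a rule-based
fragment-intensity table — all of which can be overridden with externally
computed values, so the optimizer is equally usable with experimentally
validated repository transitions (the hybrid approach).

## Worked example

Generate a synthetic 12-protein study (proteome + identification table with
known retention-time structure), then design a scheduled assay:

```sh
srmdesign fixtures --seed 7 --n-proteins 12 --out-fasta t.fasta --out-table train.tsv
srmdesign design t.fasta --train-table train.tsv \
    --out-tsv out.tsv --out-traml out.traml --report rep.json
```

which prints

```
selected 161 of 880 candidate transitions; covered 12/12 proteins; occupancy 0.657; objective 36.328 (optimal)
```

meaning: of 880 candidate transitions that passed the mass-range,
proteotypicity and interference filters, the optimizer scheduled 161, every
target protein ended up covered by at least one fully-covered peptide
(τ = 3 transitions), 65.7% of the total slot-capacity units (N slots × C)
of the gradient are in use, and the solution is provably optimal. `out.tsv`
holds the scheduled transition list (protein, peptide, Q1/Q3 m/z, ion,
RT window, detectability); `out.traml` the same in a TraML subset for
exchange with other design tools; `rep.json` the design report (filter
counts, proteins without candidates, solver status).

Other subcommands: `digest` (in-silico tryptic digestion), `train-rt` /
`train-pt` (fit predictors from identification tables), `schedule`
(re-schedule an existing transition list), `merge` (hybrid merge of
predicted and repository lists), `report` (pretty-print a design report).

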