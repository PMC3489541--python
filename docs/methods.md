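# Methods

## Problem and model

`srmdesign` formalises SRM assay development as a selection-and-scheduling
problem. Candidate transitions are enumerated from the tryptic peptides of
the target proteins; each transition *t* gets a joint detectability
*d_t* ∈ [0,1] and a retention-time window [RT−δ, RT+δ). The gradient
[0, G) is discretised into N = ⌈G / w⌉ half-open slots (slot width w
defaults to δ, so a window of length 2δ spans two to three slots), and the
integer linear program in the README is solved exactly.

Key modelling points:

* **Linearised protein coverage.** The natural protein-coverage constraint
  counts peptides whose selected transitions reach τ — a nonlinear
  indicator. We replace that indicator with (1 − y_p). This is exact: the
  peptide constraint τ·y_p + Σ x ≥ τ forces y_p = 1 whenever coverage is
  below τ, and because y_p carries the positive penalty ω^p (and relaxing
  y_p to 0 is otherwise always feasible when coverage is met), every
  optimum has y_p = 0 exactly on covered peptides. Hence (1 − y_p) equals
  the coverage indicator at any optimum, and the z constraints see the
  correct counts. When ω^p = 0 the solver may leave y_p slack; reported
  indicators are therefore always recomputed canonically from the selected
  set, which preserves the objective value (indicator terms are weightless
  exactly when the recomputation could differ).
* **Quadratic shortfall penalty.** A protein missing its ρ-peptide target
  is penalised by ω^s·Σ_j z_sj (ρ−j)², j ∈ {0,…,ρ−1}: missing the first
  peptide costs far more than missing the ρ-th, pushing solutions toward
  breadth of protein coverage before depth. The j-index range is the same
  in the objective and the constraints (a j = ρ term would carry zero
  weight).
* **Proteins with few or no candidates.** Proteins whose candidate peptides
  all fail the filters keep their z variables — the penalty then reflects
  genuinely unreachable coverage — and are listed in the design report
  rather than silently dropped.

## Solving

The program is solved with HiGHS branch-and-bound (`scipy.optimize.milp`)
to proven optimality; on timeout (default 300 s) the incumbent is returned
with status `feasible`. Variables are ordered deterministically
(transitions, peptides, proteins — each sorted by id), and HiGHS is
deterministic under a fixed ordering, so repeated runs are byte-identical.
Among multiple optima the returned selection is the solver's deterministic
choice; the brute-force oracle additionally breaks ties toward the
lexicographically smallest id set (encoding a strict lexicographic
tie-break inside the MILP would need exponential objective weights, which
is numerically untenable). The oracle enumerates capacity-feasible subsets
depth-first — capacity violations are monotone under supersets, so pruning
is exact — and is guarded to |T| ≤ 20. A greedy baseline (descending d_t,
first-fit into residual slot capacity) bounds the value of exact
optimisation from below.

## Predictors

The pipeline needs RT(p), PT(p) and fragment intensities FI(p). Full-power
predictors for these are substantial machine-learning systems (kernel
support-vector regressors for RT and proteotypicity, generative models of
peptide fragmentation); this package deliberately ships simple, documented
models behind a pluggable interface, and every prediction can be overridden
from a file of externally computed values — so the optimizer is decoupled
from the quality of any particular predictor.

* **Retention time**: RT ≈ b₀ + Σ_aa coef_aa·count_aa + c_len·L, fitted by
  ridge-regularised least squares (λ = 1.0, intercept unpenalised,
  features centred). Requires ≥ 40 annotated peptides — the size of a
  small calibration run. The count/length design is rank-deficient
  (L = Σ counts), so only the per-residue *effective* contributions
  coef_aa + c_len are identifiable; at λ = 0 the minimum-norm fit
  interpolates noiseless realizable data, which is how identifiability is
  tested.
* **Proteotypicity**: L2-regularised logistic regression on z-scored
  physicochemical features (length, monoisotopic mass, mean Kyte–Doolittle
  hydropathy, acidic/basic/aromatic fractions, 20 composition fractions);
  the sigmoid output is the calibrated probability. Constant features get
  unit scale (they carry no information either way).
* **Fragment intensities**: deterministic rule table over singly-charged
  b/y ions encoding qualitative mobile-proton behaviour — y ions over b
  (1.0 vs 0.5), b1 suppressed, ×3 for cleavage N-terminal to proline, ×2
  for cleavage C-terminal to D/E when R+K+H ≥ precursor charge (proton
  sequestered), a monotone length-fraction factor (0.6 + 0.4·ℓ/(L−1)) so
  series members are distinct, normalised to max 1.0 with exactly one base
  peak (ties resolved toward y, then the lowest position, by an O(1e−9)
  demotion of the non-preferred ion).

Training-data preparation follows standard shotgun practice: one record
per (sequence, charge) keeping the highest-TIC spectrum; positives are the
best 1,000 identifications at q ≤ 0.01; negatives are never-identified
tryptic peptides with in-range doubly-charged m/z from proteins with ≥ 15%
identified-residue coverage.

## Parameter defaults

| parameter | default | meaning |
|---|---|---|
| δ | 2.5 min | RT tolerance; windows are RT ± δ |
| w (slot width) | δ | gradient discretisation |
| G | 60 min | gradient length |
| C | 30 | concurrency limit per slot |
| τ | 3 | transitions required per covered peptide |
| ρ | 2 | peptides required per covered protein |
| ω^p, ω^s | 1, 10 | peptide / protein shortfall penalties |
| Q1, Q3 | 400–1000, 400–1200 Th | precursor / product mass ranges |
| charges | {2, 3} | precursor charge states considered |
| top-k | 5 | fragments kept per precursor (> τ, so the ILP has slack) |
| pt_min | 0.2 | proteotypicity candidacy threshold |
| peptide length | 6–30 | candidacy bounds |
| q1/q3 interference tol | 0.7 Th | co-elution interference radii |

Masses are monoisotopic throughout (proton 1.007276 Da, water 18.010565 Da,
carbamidomethyl-C +57.021464 Da fixed, on by default), the convention for
triple-quadrupole transition lists. Uniqueness is exact tryptic-string
matching against the reference digest with I ≠ L (an I/L-equivalence flag
exists); when no background proteome is supplied, the target set is its own
reference. Interference is resolved *before* scheduling, keeping the
higher-d_t transition of a clashing co-eluting pair (removing both could
silently lose peptides); the filter is idempotent. Imported transitions
missing a detectability get the experimentally-validated ceiling d_t = 1.0,
and duplicates of predicted transitions collapse keeping the imported one.

## Synthetic study conditions

The fixture generator emulates, at desk scale, a calibration/training run
plus a 48-protein standard mixture:

* proteomes of random sequences with K/R boosted to ~10% combined so
  fully-cleaved tryptic peptides are typically 6–25 residues;
* identification tables whose RT follows a known linear composition model
  (intercept 20 min; coefficients spanning ≈ −3 to +5.7 min/residue,
  scaled so peptides spread across a 60-min gradient) with Gaussian noise
  σ = 0.5 min, clipped to the gradient; q-values uniform on [0, 0.011]
  (≈ 9% above the 0.01 cutoff); TIC log-uniform over [1e4, 1e7]; 10%
  duplicate records to exercise deduplication; peptide detection follows a
  hydropathy-dependent logistic (shotgun runs miss peptides,
  preferentially hydrophilic ones), which both supplies proteotypicity
  negatives and gives the PT model real signal;
* random scheduling instances (uniform RT, Beta(2,2) detectability) for
  the oracle-equivalence sweep, a dense variant where every slot is
  overlapped by ≥ C disjoint-peptide transitions (full-supply saturation),
  and a constructed instance where the greedy baseline provably
  underperforms the ILP.

What passing on this data does *not* show: real retention behaviour is not
linear in composition, real fragmentation is far richer than the rule
table, real proteomes have homology structure that makes uniqueness
genuinely hard, and real q-values are not uniform. The synthetic suite
validates the *optimisation and plumbing* end to end, not predictor
accuracy on real spectra — which is exactly why the predictor interface
accepts external overrides.

## Problem sizes and numerics

The test suite and acceptance script use a 48-protein synthetic study
(≈ 3,600 candidate transitions; the ILP solves in a few seconds), a
200-instance oracle-equivalence sweep at |T| ≤ 12 spanning τ ∈ {1,2,3},
ρ ∈ {1,2}, C ∈ {1,2,3} (objective agreement to 1e−9), and capacity
monotonicity checks at C = 1..5. Floating-point comparisons use absolute
tolerances: 1e−9 for objectives, 1e−6 min for noiseless RT interpolation,
5e−5 Th for 4-decimal m/z round-trips. All file writers are deterministic
(fixed column order and float formats, no timestamps); all generators are
pure functions of their seed.

## Known limitations

* Doubly/triply charged fragment ions, neutral losses, variable
  modifications and non-tryptic enzymes are out of scope.
* Transition lists are designed for a single LC-MS run; splitting across
  injections and dwell-time optimisation within a cycle are not modelled.
* The slot-occupancy metric (selected slot-memberships / N·C) is one
  reasonable reading of "filling the gradient"; occupancy of real
  instruments additionally depends on dwell and cycle times.
* Repository retrieval is file-based (TSV / TraML subset import); there is
  no live querying of online transition databases.
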