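# Methods

## Model

The mutation process is a homogeneous, stationary continuous-time Markov
chain on nucleotides with unrestricted rates (UNREST).  For a prescribed
stationary distribution π, the balance conditions πQ = 0 reduce to three
independent linear equations `V βᵀ = 0` in the 12-vector of off-diagonal
rates β (the fourth balance row is dependent).  The solution space has
dimension 9; we compute an orthonormal basis by SVD with a deterministic
sign convention, and represent every candidate process by its 9 basis
coefficients.  Feasibility (all 12 rates strictly positive) is enforced by
rejection; because the transition matrix is invariant to a positive rescaling
of β, coefficients are normalized to give unit-norm rate vectors.

Uniformization uses the global rate `q = Σ_i |q_ii|` — the sum of leaving
rates, not the more common max — so the resulting stochastic matrix P has
off-diagonal mass exactly one.  The codon chain assigns each
single-nucleotide change probability `p_xy / 3`, i.e. a uniformly chosen
position is given one P-step per epoch.  Without the 1/3 factor the diagonal
completion can go negative (off-diagonal row mass reaches `3 − Σ p_aa`);
with it the chain is always stochastic and the product measure
`π_a π_b π_c` is its stationary vector, which is what makes π itself the
correct mutation-only expectation for within-family third-position usage.
Any uniform factor ≤ 1/3 yields the same stationary vector, so this choice
only fixes time scale, not the statistic.

Selection multiplies nonsynonymous transition probabilities by a symmetric
acceptance `d_{m→n} ∈ [0, 1]` built from the packaged Grantham (1974)
distance table via the default transform `d = 1 − G/215`.  Stop-codon
policy: SL sets sense↔stop acceptance to zero, which disconnects the three
stop codons, so the SL chain lives on the 61 sense codons (this is exactly
equivalent to restricting the 64-state selection chain to its sense block);
SM keeps 64 states and uses the smallest *positive* off-diagonal acceptance
(1 − 205/215 ≈ 0.0465, the Cys–Phe pair) for sense↔stop changes.  The
literal minimum of the default matrix is zero (Cys–Trp), and a zero stop
acceptance would collapse SM onto SL; taking the smallest positive entry
preserves the intended distinction and keeps the 64-state chain irreducible.

Stationary vectors are obtained by left eigendecomposition cross-checked
against a bordered linear solve (agreement asserted at 1e-8); the
optimizer's hot path uses the linear solve alone, and the test suite pins
its agreement with the step-by-step chain.

A caveat the tests document: the stationary vector of the 61-state
*mutation* chain is not exactly the restricted product measure (removing
stop states folds their flux into the diagonal, perturbing family usage by
up to a few percent).  This does not affect any reported statistic — the
mutation-only expectation is always π, and the SL selection chain on 61
states is exact — but the product-form identity should only ever be
asserted on the full 64-state chain.

## Deviation statistic and family conventions

`F_{π|s}` normalizes the post-selection shift of each third-position
frequency by its expectation and sums over the four nucleotides; `F_π` sums
over families.  The package defaults to the five canonical 4FD families
(Gly, Val, Thr, Ala, Pro — amino acids encoded by a single fourfold box).
The eight-box variant (adding the Leu CTN, Ser TCN and Arg CGN sub-boxes)
is available everywhere via `family_set="boxes8"`.

The two conventions matter more than they might seem.  On the packaged
reference matrix the SM pipeline gives F = 4.90 over five families and
F = 9.23 over eight boxes, and published headline values for the same
construction (a maximum of 9.10 for this matrix; an SL maximum of 9.22)
match only the eight-box reading, while the published pre-optimization
baseline (≈0.3) matches only the five-family reading (we compute 0.29
five-family, 0.55 eight-box).  The two published anchors therefore imply
different conventions; we keep the five-family default uniformly rather
than switching per quantity, and report the eight-box numbers in
`analysis/02_reference_chain.py`.

Comparator divergences (per-family KL and total variation, summed) and a
Spearman concordance utility guard against the conclusion depending on the
specific statistic; at the scales run here the rank correlations with F
exceed 0.96.

## Acceptance-matrix calibration

The original acceptance values (from Morton's mutation–selection scheme)
were never published; only two class means over the 120-case fourfold
census are quoted: 0.538 for transitions, 0.409 for transversions.  The
linear Grantham reconstruction gives 0.667 / 0.643.  The gap is not a
tuning problem: over the census the transition and transversion Grantham
distances overlap so strongly that the largest class-mean separation any
monotone map into [0, 1] can produce is 0.118 (attained by a hard
threshold, and at the wrong levels), short of the required 0.129.  The same
holds when averaging over all 392 nonsynonymous single-nucleotide codon
changes or over unique amino-acid pairs.  The quoted means therefore cannot
derive from any monotone function of Grantham distance under any of these
weightings, and the original matrix cannot be reconstructed from the
published information.  Consequences: the calibration check fails at its
published values, and every downstream quantity that scales with selection
strength (the deterministic reference-chain F, the ES maxima at strong
selection distributions) lands well below its published counterpart —
consistently about a factor of two under the five-family convention.  The
transform is pluggable (`linear_transform`, `clipped_linear_transform`,
`power_transform`, or any monotone callable) and
`selection.calibration_report()` tabulates candidate transforms under both
census weightings.

One reverse direction is informative: at the C-rich distribution where the
published *smallest* maximum (0.26) is quoted, our ES finds 0.86 — larger,
which a weaker selection layer cannot explain.  The published per-π maxima
in weak-selection regions were evidently limited by the original search
budget rather than by the model.

## Evolutionary strategy

Generational ES with population 100, binary tournament selection, one
elite, linear (BLX-style) crossover with α ~ U(−0.25, 1.25) at rate 0.7,
and Gaussian mutation of the 9 coefficients with σ = 0.05, decayed ×0.95
after every 50 stalled generations.  Offspring violating rate positivity
are retried up to 50 times, then fall back to the parent, so fitness is
only ever evaluated on feasible matrices and the best-so-far trajectory is
monotone.  Runs stop at 1,000 generations or 200 generations without an
improvement above 1e-6.  All randomness flows through one numpy Generator
per run; sweep workers derive per-distribution seeds from
`SeedSequence(master_seed, index)`, making parallel, serial and resumed
sweeps identical.

Problem sizes used by the shipped experiments: single-distribution runs use
the full default budget (≤ 100k evaluations, tens of seconds); the
acceptance harness runs one seed at the T-rich optimum and three seeds at
each of the other two quoted distributions; the baseline averages one
random feasible matrix over a 200-point uniform subsample of the 91,881
lattice distributions; trend and concordance summaries use 7-point
equal-complementary profiles and 200 random models.

## Grid

The lattice of stationary distributions (components 0.05–0.85, step 0.01,
summing to 1) is enumerated exactly in integer percent units; it has
C(83,3) = 91,881 members.  The published sweep reports 88,560 = C(82,3);
no pruning rule recoverable from the published description reproduces that
count, so the package enumerates the natural lattice and surfaces both
numbers instead of silently reconciling them.

## Synthetic data

The generator draws interior codons i.i.d. from a specified sense-codon
distribution (every statistic in scope is a function of codon counts, so
codon autocorrelation is deliberately absent), wraps them in ATG…TAA, with
lengths uniform on 100–400 codons.  The toy genome concatenates genes into
two arcs with configurable per-arc codon usage, arc 2 reverse-complemented;
giving both arcs the same GT-rich usage emulates leading-strand composition
flipping at replication boundaries, and the true boundaries are recorded for
oracle tests.  What passing tests show is that the statistics and their
estimators behave correctly on count data of realistic size; they say
nothing about gene-length distributions, intragenic codon correlation, or
real annotation noise, none of which the statistics depend on.

Strand segmentation detrends the cumulative [G−C] and [A−T] walks so they
close around the circle, aligns their signs (leading strands are typically
G-rich but T-rich, so the raw walks may oppose), sums them, and places
boundaries at the global extrema.  The result is flagged unreliable when
the amplitude is under 6 random-walk standard deviations (an i.i.d. genome
scores ≈1).  This is the plain cumulative-skew-extremum method; windowed or
segmentation-based variants are out of scope.

The sequence-level expectation `e_i` is the unweighted mean over the five
families of within-family relative third-position frequency; a pooled-count
variant sits behind `pooled_expected=True`.  The absolute-value form of F
makes the estimator biased upward by O(n^−1/2) when true deviations are
comparable to counting noise; the consistency experiment therefore uses a
deliberately asymmetric model and compares against a multinomial-bootstrap
Monte-Carlo standard error.

## Numerical choices and limitations

- Exact integer lattice arithmetic for grids; 1e-12/1e-10/1e-8 tolerances
  for stochasticity, row sums and stationarity respectively.
- `sample_coefficients` caps rejection at 500,000 batched draws; the
  all-positive acceptance rate falls to ~1e-4 at strongly skewed π.
- Reference-matrix TSVs are renormalized row-wise on read (printed matrices
  carry 4-decimal rounding); the stationary vector is recomputed, not
  trusted.
- Standard genetic code only; no branch lengths, no phylogenies, no
  site-heterogeneous or time-varying selection; PAM/BLOSUM-style acceptance
  matrices are out of scope because they are contaminated by mutation.
- The ES is a stochastic search: per-π maxima are lower bounds, and in flat
  (weak-selection) regions different budgets move them noticeably.
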