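# Methods

## The model

`cellfrust` simulates a deliberately *unstable* bipartite matching between
`N` antigen-presenting cells (APCs) and `N` T cells, each split into two
equal subtypes.  Each APC displays one real-valued ligand; each T cell
compresses every APC's value into one of two perceived signals — frequent
(`F_i`) or rare (`R_i`) — and carries a total preference order (interaction
list, IList) over the `2K` perceived symbols of its connectivity.  APCs have
a two-entry preference: T cells of their own subtype strictly first,
anything else second.

Dynamics are discrete contacts: per elementary step one of the `2N` cells
is drawn uniformly and meets a uniformly drawn cell of the opposite type
from its connectivity list.  Each side that *strictly* prefers the candidate
over its current partner re-directs its synapse — it detaches from its
current conjugate whether or not the candidate reciprocates — and a new
conjugate forms only when both sides are willing (a free cell accepts
anything).  Equal rank keeps the current partner.  The unilateral
detachment is essential: it makes conjugates destabilizable by *conjugated*
third parties, not only by free cells.  Without it, same-subtype matchings
are absorbing states, the population crystallizes, and conjugation
durations decouple from IList content; with it, a same-subtype conjugation
whose partner symbol is ranked below `m` displayed symbols has lifetime
`~ N/(2m)` sweeps — the reciprocal-destabilization-pressure law the rest of
the framework builds on.

**Clock.**  One protocol iteration is a sweep of `2N` elementary contacts
(each cell drawn once in expectation).  Under this unit the activation
lifetime `tau_act = 5` iterations sits at the ~1–2% upper tail of the
self-configuration lifetime distribution of a maximally frustrated
population, i.e. long conjugations are rare events under self conditions —
the regime the detection protocol requires.

## Detection protocol

* **Anergy.**  During calibration and detection any conjugation reaching
  `tau_A = 5` iterations is force-terminated and the T cell is replaced by
  the repertoire member drawn for its slot (same connectivity).  Anergy
  keeps the dynamics churning and converts "a cell can hold long
  conjugations" into a *rate* of capped terminations.
* **Counts.**  Per sample the dynamics runs `W_c` iterations and records,
  per APC `i`, the number of conjugations of duration `>= tau_act`
  (`c_i(tau_act)`) and the total turnover `c_i(0)`.
* **Thresholds.**  Calibration on `N_s` self samples sets
  `n_i^0 = ` the value at 1-based position `ceil(N_s * f)` of the
  descending-sorted `c_{i,s}(tau_act)`; default `f = 0.1`.
* **Response.**  `R_s = sum_i (c_{i,s} - n_i^0)/c_{i,s}(0) * theta(c_{i,s} - n_i^0)`
  with a strict Heaviside (`theta(0) = 0`).  The `1/c(0)` normalization
  stands in for positive selection (it homogenizes conjugation turnover
  across APCs).
* **TPR at fixed FPR.**  The self responses' descending value at position
  `ceil(N_self * FPR)` is the detection threshold; abnormal samples count
  as detected when strictly above it.

Defaults follow the protocol's reference values (`W_c = 10^4` iterations,
1000 calibration samples); the packaged experiments run scaled problem
sizes, noted below.

## Maximally frustrated populations (block data)

For the block-structured case study (subtype-I APCs split into two blocks
of `N_B = N/4`; a self configuration shows `N_r` rare ligands inside one
block, the "contextual" abnormal pattern splits them across the half-blocks
at the boundary) ILists are built in segments: `N_top` frequent
opposite-subtype ligands (LOCS) on top, then rare same-subtype ligands
(LSCS), frequent LSCS, rare LOCS, and the leftover frequent LOCS.  ILists
come in identical pairs (`N/4` distinct lists per subtype); within-segment
order is shuffled per distinct list so each cell's stable contacts
concentrate on its own preferred APCs.

The top segments are **margin-regular** random windows — `N_top/2` ligands
per block, with every ligand surveyed by equally many distinct ILists.
Regularity is what makes population-level tolerance behave like independent
per-IList draws, which the binomial tolerance analysis assumes; with
arbitrary iid subsets the cross-IList correlations inflate the self count
quantile and the analysis misses.  The two block windows of one IList are
associated so that its central top counts split roughly evenly across the
boundary ("half left, half right").  The association strength (rank
matching with Gaussian noise, sd 1.5 ranks) is calibrated once by an
internal-consistency criterion: the exact placement law of split-pattern
activation, computed combinatorially on the built structures, must
reproduce the independent-Bernoulli convolution of the analytic theory on
the same structures.  No simulation output or reported value enters that
calibration.

## Activation theory

With `N_r` rare ligands inside one block, the number of a cell's
top-ranked frequent LOCS that go missing is hypergeometric
(`P(f)`, per-block top pool `N_top/2`, block pool `N_L/2`); a cell
activates when at least two are missing, `P_act = 1 - P(0) - P(1)`.  The
whole-system threshold `N_a` is the smallest count of activated distinct
ILists whose binomial(`N_L/2`, `P_act`) upper tail is at most the tolerated
false-positive rate `alpha`; the damped fixed-point iteration
(`lambda = 0.1`, floor step) converges to the same integer as a direct tail
search, and the convention "activation means count >= N_a" is the one that
yields the worked-example threshold of 9 at
`N_L = 48, N_top = 24, N_r = 2, alpha = 0.1`.  For split patterns each
IList misses two top LOCS with probability `(2 N_c / N_L)^2` where `N_c` is
its central top count; the whole-system activation probability is the
Poisson-binomial tail at `N_a`, computed by Monte Carlo over placements
and/or structures.

## Negative selection (education)

Education eliminates any T cell whose conjugation age reaches the adaptive
threshold `tau_n` (checked once per sweep) and replaces it with a naive
cell (same connectivity, random IList).  Every `W_tau` iterations `tau_n`
is lowered to the window's largest displacement-terminated duration,
provided at most `elim_tol` eliminations occurred in that window (default
`N/16`); it is recorded with a population snapshot, and education stops
when `tau_n` is stable for `stop_window` iterations.  Two deliberate
deviations from a literal zero-elimination quiet-window reading:

* the window maximum is taken over *terminated* durations only — cells
  still holding a conjugate are handled by the age-based elimination once
  `tau_n` drops below their age; including open ages pins `tau_n ~ W_tau`
  and provably stalls the ratchet;
* a small elimination tolerance is required because replacement is random:
  freshly introduced cells frequently re-develop over-threshold
  conjugations (they are often "eliminated again in an upcoming
  configuration"), so a standing elimination/replacement mill never fully
  quiets.  The tolerance lets the ratchet move while still demanding
  near-tolerance.

The displayed configuration changes every `T_s` iterations.  Short `T_s`
requires failures in consecutive configurations for elimination — a ligand
rare with frequency `p_R` recurs consecutively with probability `p_R^2`
(2% at 15%) — so fast switching tolerates a few rare same-subtype symbols
near IList tops, and measurably keeps the first same-subtype symbol higher
than slow switching does.

`W_tau` must sit well above the conjugation-lifetime tail or no window can
ever qualify; scaled runs use `W_tau = 1000` iterations, `T_s = 50`,
`stop_window = 15000–25000`, under which `tau_n` ratchets from ~1700 to
~80–110 iterations and educated populations rank markedly fewer
same-subtype symbols on top than naive ones.

## Synthetic data

The generators emulate the three benchmark families: sorted rows of 80
Gaussian draws (mean 50, sd 10; abnormal rows shift the mean by `delta`),
moment-matched lognormal rows (same mean and sd), and unsorted Gaussian
rows whose abnormal elements deviate by `±delta` independently.  The block
case study generates its configurations internally.  What these share with
real antigen-presentation data is only the abstraction the model consumes —
exchangeable samples of per-APC values with a stable self law; they have
none of the temporal drift, measurement error or cross-feature dependence
of biological data, so passing benchmarks here demonstrates the detection
mechanism, not field performance.

## Problem sizes and numerical choices

* Simulations are batched in a compiled kernel with an inline
  xorshift64 generator; a pure-python reference implementation consumes
  identical draw streams and is held to bit-identical event logs in tests.
  All randomness derives from one seed per run.
* Packaged experiment scales (chosen once as study conditions):
  contextual block experiment — 24 population realizations, 150
  calibration + 150/150 detection samples, `W_c = 500` iterations;
  perturbation experiments — 100 realizations, windows of 500–2000
  iterations; statistical benchmarks — 300 training samples, 200
  evaluation samples per arm, repertoires of 8 educated populations,
  `W_c = 2000`.
* Ties: equal preference keeps the current conjugate; a count exactly at
  threshold does not contribute to the response; a response exactly at the
  FPR threshold does not count as a detection; perception exactly at a
  tail quantile stays frequent.
* Degenerate inputs are rejected at construction (odd population sizes,
  rare counts above the block size, `v_max >= 0.5`, empty connectivity).

## Known limitations

* The per-cell contextual signal is weak by construction — two missing
  ligands change a destabilization pressure of 24 by ~8% — so the
  split-pattern true-positive rate approaches its structural value only as
  `sqrt(W_c)`.  At the packaged scaled windows the measured mean TPR is
  ~10% against a structural (infinite-window) value of ~14%; reproducing
  the latter requires reference-scale windows and sample counts (roughly
  two orders of magnitude more compute).
* The count-increment experiments respond more strongly than the
  missing-ligand analysis predicts: rare same-subtype ligands are ranked
  directly below the top segment, so rare-displaying APCs also *attract*
  stable conjugations.  This direct channel adds to (and for added-rare
  perturbations dominates) the missing-LOCS channel; the analytic curve is
  a lower envelope, not a match, in this implementation.
* The scaled statistical benchmarks reach detector AUCs a few points below
  the matched z baseline and close to the KS baseline; repertoire size and
  window length saturate before closing the remaining gap.
* Education leaves a standing fraction of recently replaced, untested
  cells; tolerance of educated populations is therefore a strong relative
  improvement over naive ones rather than an absolute guarantee.
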