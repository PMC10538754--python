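# Methods

## Model and problem statement

A metabolic network with m metabolites and r reactions is described by its
stoichiometric matrix S (substrates negative, products positive) and flux
bounds v_min ≤ v ≤ v_max in mmol gDW⁻¹ h⁻¹. Steady states satisfy S·v = 0.
The left- and right-hand sides of reactions are *complexes*; collecting
their compositions in Y (metabolite × complex, non-negative) and the
directed complex graph's incidence matrix A (complex × reaction, one −1 and
one +1 per column) gives the exact factorization S = Y·A. The activity of
complex i under v is A_i·v; complex i is balanced over a flux space when its
activity is zero at every feasible point, and balanced in a particular v
when |A_i·v| ≤ ε.

cbFBA chooses v by minimizing the total absolute complex activity
Σ_i |A_i·v| over the steady-state box — an L1 surrogate for maximizing the
number of balanced complexes, which as a zero-norm problem is not tractable
directly. pFBA minimizes Σ_i |v_i|. Both are solved on the irreversible
(split) network, so the pFBA objective is linear and the cbFBA objective is
linearized with auxiliary variables t_i ≥ ±A_i·v, objective Σ t_i; at the
minimum t_i = |A_i·v| automatically. The summation in the cbFBA objective
runs over all c complexes (rows of A): activities are defined per complex,
not per metabolite.

## Decomposition S = Y·A

The construction walks reaction columns: the substrate complex collects
|S[i,j]| over negative entries, the product complex the positive entries;
identical compositions across reactions are merged into one node, so all
exchange reactions share a single empty "environment" complex (labelled O).
Two details matter:

- A new composition column is appended only when no existing column equals
  it; equality uses exact comparison with absolute/relative tolerance 1e-9
  so that float stoichiometries (e.g. fractional biomass coefficients) merge
  deterministically. Y is stored with non-negative *real* entries for the
  same reason, although stoichiometries in the bundled fixtures are integer.
- Each incidence column receives −1 at the substrate complex and +1 at the
  product complex, making every column sum to zero and S = Y·A hold
  entrywise. A reaction whose substrate complex equals its product complex
  (only possible for an all-zero stoichiometry column) is excluded with a
  warning; its incidence column is zero and the factorization still holds.

Conservation ties the two layers together: for any v, Y·(A·v) = S·v, so
metabolite balances are linear combinations of complex activities. One
consequence worth knowing: if a metabolite occurs in exactly two complexes,
their activities are proportional with opposite sign in every steady state,
so balancing one forces the other. On the toy network this means any
distribution balancing the singleton complexes B and C necessarily balances
B+C as well — the cbFBA optimum there balances the entire catalogue.

## Balanced-complex identification

Over a flux space (the cone, a budget-constrained space, or a space
intersected with per-reaction intervals such as experimental confidence
intervals), each complex's activity is bounded by 2c LPs
(min/max A_i·v); a complex is balanced iff the range lies within ±ε.
Structurally never-balanced complexes — all incident reactions incoming, or
all outgoing — are classified purely topologically; they can only have zero
activity when their incident fluxes vanish, never in a strictly positive
distribution. Cone-balanced complexes are balanced in every subset of the
cone and in every feasible distribution; the converse fails, which is
exactly the distinction cbFBA exploits.

## Variability and sampling at the fixed optimum

With z the optimal budget, flux variability solves 2r LPs min/max v_j
subject to steady state, bounds and the budget constraint. The printed
formulations fix the budget by equality; because z is the minimum of the
constraint set, the lower side is automatic and exact equality is
numerically brittle, so the implementation enforces
budget ≤ z·(1 + τ) with τ = 1e-6 by default (a CLI flag). Ranges shrink
monotonically as τ decreases.

Sampling draws v_rand componentwise uniform on [v_min, v_max] (the
distribution is pluggable) and projects it onto the budget-constrained
steady-state space by the QP min ‖v − v_rand‖₂². The QP is solved by OSQP
(eps 1e-10, polishing on); the solution is then refined by re-solving the
equality-constrained least-squares projection on the detected active set
(steady state, bounds at their limits, zero-activity complexes, and the
linearized budget hyperplane when tight), accepted only if it is feasible
and no farther from v_rand. The refinement pins the steady-state residual to
~1e-12 while the audit recorded with every sample set checks
‖S·v‖∞ ≤ 1e-9, bound violations ≤ 1e-9 and budget ≤ z·(1+τ). A single
integer seed drives all draws up front, so sample sets are bitwise
reproducible and order-independent.

"Robust" flux means are trimmed means (trim fraction configurable; default
0 for fluxes, 5% for metabolic-adjustment distances).

## Preprocessing

Scenario tables (per-strain uptake/secretion/growth bounds) are intersected
with model bounds; the intersection must be non-empty per reaction.
Reversible reactions are split with forward bounds (max(0, lb), max(0, ub))
and reverse bounds (max(0, −ub), −lb); net flux is forward − reverse and
splitting/merging is the identity on net fluxes. Pruning then iterates to a
fixed point: metabolites lacking a producer or a consumer are removed with
their incident reactions, and reactions whose flux cannot exceed 1e-6 in
magnitude in any feasible steady state (checked by per-reaction LP
maximization at feasibility tolerance 1e-9) are removed. Reactions with a
strictly positive lower bound encode measurements and are never pruned; if
they are incident to a dead end the scenario is reported infeasible instead.
Pruning is applied per scenario, not globally. Unbounded SBML bounds are
capped at ±1000 mmol gDW⁻¹ h⁻¹ (configurable), because variability and
sampling need a finite box.

## Parameters that matter

| parameter | default | meaning |
| --- | --- | --- |
| ε (activity threshold) | 1e-6 mmol gDW⁻¹ h⁻¹ | complex counted balanced when \|A_i·v\| ≤ ε; same scale as the blocked-reaction threshold so activity and flux classifications cannot drift apart |
| blocked threshold | 1e-6 mmol gDW⁻¹ h⁻¹ | reaction counted active when \|v\| ≥ threshold |
| τ (budget tolerance) | 1e-6 | relative slack on the fixed optimum in variability/sampling |
| feasibility tolerance | 1e-9 | LP solver primal tolerance and steady-state audit bound |
| bound cap | 1000 mmol gDW⁻¹ h⁻¹ | replacement for infinite SBML bounds |
| n samples | 1000 | default sample-set size |
| FDR level | 0.05 | Benjamini–Hochberg level in the mean-difference test |

## Evaluation statistics

Active/blocked calls use the threshold above (for ranges: the maximal
absolute flux over the interval). Confusion metrics treat
experimentally-active as the positive class and report undefined ratios as
NaN. Interval overlap uses closed intervals (confidence intervals are closed
sets, so touching endpoints overlap). Range categories compare the pFBA
interval to the cbFBA interval — same-min/higher-max, strict containment,
upward shift with/without overlap, identical, other — with tie tolerance
1e-9. Log-flux concordance is the Pearson correlation of log₁₀|v| over
reactions active in both vectors (≥ 3 required); zeros never enter the
logarithm by construction of the mask.

The mean-difference procedure is a per-reaction one-sample location test of
the sampled flux distribution against the experimental mean — a t-test by
default, with an empirical-quantile variant available — adjusted across
reactions by Benjamini–Hochberg at the configured level; reactions with
degenerate (zero-variance) sampling distributions are compared with an
absolute tolerance and flagged. This is a documented interpretation: the
procedure is deliberately pluggable, and the report records which test and
adjustment were used. Outlier detection fits one OLS line to
(log₁₀ predicted, log₁₀ experimental), computes
s = sqrt(Σ(ŷ−y)²/(n−2)) and flags |residual| > 2s in a single pass (no
refitting). Metabolic-adjustment distances are Euclidean norms of the flux
difference between randomly paired mutant/wild-type samples over the shared
reaction universe (seeded pairing; universes are intersected with a
warning). Subsystem summaries report the mean of log₁₀(range width) per
pathway label, counting degenerate widths separately instead of taking their
logarithm; no enrichment statistics are attached.

## Synthetic data

The toy fixture encodes a six-metabolite, nine-reaction network with one
uptake (E1: O → A), a splitting route (R1: A → B+C with separate drains E2,
E3 and the shortcut R5: C → F) and a chain route (R2–R4: A → D → E → F with
drain E4), under the scenario E1 = 1. Its expected balance structure — eight
complexes, cone-balanced {A, D, E, F}, B+C never balanced in positive
distributions, pFBA balancing exactly the cone set, cbFBA balancing at least
{A, B, C, D, E, F, O} with strictly more balanced complexes than pFBA — is
carried on the fixture object and checked by `ToyFixture.verify()`, which
fails loudly rather than adjusting anything if a change breaks the contract.

The random generator lays reactions along closed walks over a pool of
complexes (the environment, all singletons, and a few random multi-metabolite
complexes with integer coefficients ≤ 3 to keep the decomposition exact);
each reaction belongs to exactly one walk carrying unit flux, so the
all-ones vector is an explicit strictly positive steady-state witness and
every generated model is feasible with no blocked reactions. The planted
generator builds chains O → X → D → Y → O whose middle metabolite occurs in
exactly one (singleton) complex — that complex's activity coincides with the
metabolite's steady-state constraint and is therefore cone-balanced by
construction — plus a source/sink distractor motif (O → G → P+Q with
separate drains) that can never be balanced in positive distributions.

What the generators do *not* emulate: genome-scale degree distributions,
currency metabolites, compartments, fractional biomass stoichiometries, or
correlated measurement error in experimental tables. Passing tests therefore
certify the algebra, the optimization stages and the statistics on networks
whose ground truth is known exactly — not predictive accuracy on any real
organism, which additionally depends on model curation and measured
constraints.

## Test-problem sizes and independent oracles

The suite cross-checks the LP optima against a pure-linear-algebra
enumeration oracle: the cbFBA objective is piecewise linear, so its minimum
over the flux polytope sits at a vertex of the subdivision induced by the
kink hyperplanes {A_i·v = 0}; all such vertices are enumerated from
active-set systems solved by least squares. This is exact but exponential,
so oracle networks are kept at ≤ 8 reactions (20 seeds). Decomposition
exactness runs on 100 networks of up to ~14 reactions, planted recovery on
50 seeds, the sampler audit on 1000 toy samples, and the FDR calibration on
100 repetitions of 1000 null reactions with 30 samples each — sizes chosen
so the whole suite and the acceptance script each finish in about a minute
on one CPU while every check retains an independent ground truth.

## Known limitations

- The cbFBA optimum, like any LP optimum, need not be unique; downstream
  known-answer checks depend only on budgets, balanced sets and ranges,
  never on a particular optimal vertex.
- Balance classification at threshold ε is scale-dependent; models in units
  far from mmol gDW⁻¹ h⁻¹ need a rescaled ε.
- The projection sampler characterizes the budget-constrained optimum space
  but is not a uniform sampler of it; it matches the stated two-step
  procedure (random box point, Euclidean projection), not hit-and-run.
- Gene–protein–reaction rules are not evaluated; pFBA is applied over all
  reactions rather than gene-associated ones.
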