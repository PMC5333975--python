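# Methods

## The model

The object of study is a metabolic autocatalytic cycle: a set of reactions
whose net application, at positive integer multiplicities, increases at
least one of its own intermediate metabolites without decreasing any. The
didactic case has a single intermediate X, an assimilating reaction fa that
consumes one X (together with an external metabolite A held at constant
concentration) and returns 1+δ copies, and a branch reaction fb that drains
X toward biomass:

    dX/dt = δ·fa(X) + fi − fb(X),

with fi an optional constant input flux. Both fluxes are irreversible
Michaelis-Menten laws, which makes every result closed-form. The δ
generalization (e.g. δ = 1/5 for the CBB cycle's 5:6 stoichiometry) enters
everywhere by replacing Vmax,a with δ·Vmax,a; the package applies that
scaling uniformly, including in domain classification and in the
bisubstrate bounds.

Assumptions worth stating explicitly: A is constant (the cycle does not
deplete its substrate), fluxes are irreversible unless a reversible
extension is invoked, enzyme levels enter only through Vmax, and stability
always means *local* stability of a steady state under small perturbations
— no global basins are claimed.

## Formal verification of autocatalysis

A reaction set R with intermediate set M is certified autocatalytic when

1. every row and column of the stoichiometric submatrix (M × R) contains a
   positive and a negative entry;
2. positive integer multipliers i_1..i_k exist with Σ i_l·V_l ≥ 0 on M and
   > 0 somewhere (optionally: on a requested intermediate, e.g. ATP);
3. no proper nonempty subset of R admits such multipliers (this excludes
   unions of disjoint cycles).

The search is exhaustive when `max_multiplier^k` is small (exact, with the
minimal total multiplier and lexicographic tie-break) and a MILP otherwise
(minimal total multiplier; the lexicographic preference is encoded as tiny
rank weights, so ties at equal total are broken approximately). Condition 3
is checked by subset enumeration up to 12 reactions; beyond that the result
carries `minimality_verified=False` rather than an unbounded search.
Stoichiometric coefficients are exact rationals throughout; rows are
rescaled to integers before the search, which changes no sign.

The graph route (bipartite metabolite/reaction digraph, simple-cycle
enumeration bounded at 12 reaction nodes, three classification rules)
assumes unit stoichiometry, as stated in its derivation; cycles containing
non-unit reactions (CBB 5:6, glycolysis priming) skip classification and
are kept only with a formal certificate. For the branch-product rule the
package accepts a cycle when the external product can re-enter the cycle at
*some* intermediate through a path avoiding the cycle's reactions and any
reaction consuming a cycle intermediate: one re-entry point suffices
because the cycle's own reactions redistribute the gain, which is exactly
what the multiplier definition requires. A strict variant demanding a
bypass to every intermediate is available (`return_path_mode="all"`).
Reversible reactions are split into two directed copies and a cycle may use
at most one direction of each.

## Parameters that matter

| parameter | meaning | default | why |
|---|---|---|---|
| `max_len` | cycle length bound (reaction nodes) | 12 | compact cycles of interest are ~10 reactions or fewer |
| `max_multiplier` | multiplier search bound | 12 | covers all worked stoichiometries with margin |
| δ (`delta`) | gain per unit consumed | 1 | the 1:2 didactic ratio; multi-reaction analysis requires δ ≤ 1 |
| `fi` | constant input flux | 0 | inputs are modeled only when a bypass reaction exists |
| `similar_band` | audit "similar" band | 0.1 (relative) | saturation comparisons on noisy data need a dead zone; configurable |
| `noise_cv` | generator measurement noise | caller-set | lognormal, mean-1 multiplicative |

Concentrations, rates and enzyme abundances are unit-agnostic positive
reals; internal consistency is the caller's contract.

## Numerical conventions

* Strict inequalities are classified with relative tolerance 1e-12; closer
  than that is reported `degenerate`, never silently resolved.
* Analytic/numeric agreement (substitution residuals, closed form vs
  root-finding) is asserted at relative 1e-9.
* Eigenvalue stability: leading real part < −1e-10 is stable, within
  ±1e-10 marginal. Near an existence threshold all derivatives shrink like
  1/X*², so the synthetic generator judges instability relative to the
  local rate scale max(α_i+β_i) instead of the absolute cutoff.
* ODE integration uses LSODA with rtol 1e-9 / atol 1e-12. Divergence is
  declared at 1e3 × the largest KM (every MM flux is then within 0.1% of
  Vmax, so no further structure exists; a much larger cap would make slowly
  escaping trajectories undecidable in any reasonable horizon). The default
  horizon is 1e4 characteristic times KM/Vmax of the first cycle reaction;
  both cap and horizon are per-call overridable. Trajectories that end
  without a verdict are `undecided`, not guessed.
* Steady states of n-reaction chains are solved in log-concentration space
  (iterates stay positive) with multi-start initial guesses; roots that
  collapse onto X = 0 are rejected.
* Domain errors (negative concentrations, A below its bound) raise; nothing
  is clipped, because the stability analysis is sign-sensitive. The single
  exception is the ODE right-hand side, where the integrator may probe
  infinitesimally negative states; these are clamped to 0.

## The synthetic-data generator

`empirics.generate_synthetic_tables` emulates the structure of a
fluxomics + proteomics compendium for a cycle operating across growth
conditions: conditions differ in branch-enzyme expression, whose common
scale factor is swept log-uniformly from 1 down toward the existence
threshold of the positive steady state. Each condition's steady state is
solved numerically (with continuation between neighboring scales) and
eigenvalue-checked; fluxes are the steady-state fluxes and enzyme
abundances the applied scale factors, both multiplied by independent
lognormal measurement noise of the requested CV. Base Vmax values play the
role of kcat × unit abundance.

The default subject is a two-reaction 1:2 cycle whose parameters are
balanced so that both existence-threshold conditions share one critical
branch scale (s* = 0.4): approaching it drives *both* intermediates jointly
toward saturation. This matters because the capacity estimator (max across
conditions of flux per enzyme) is only a lower bound on the true maximal
rate; the quantity identifiable from the tables alone is the saturation
normalized by each reaction's best-condition saturation. With the balanced
design the best condition sits at saturation ≈ 1 for every reaction, so the
identifiable and the true saturations coincide to ~1e-3 in noiseless runs.
The ground-truth object records both (`true_saturation`,
`estimable_saturation`) plus kcats, steady states and branch points, so
tests can distinguish estimator bias from noise.

What the generator does *not* emulate: condition-specific kcat changes
(temperature, post-translational modification), correlated noise between
flux and enzyme measurements, thermodynamic (reversible) flux corrections,
and any absolute units — so passing audits demonstrate the estimator
pipeline's correctness and calibration on data with the right structure,
not the biology of any particular organism.

## Design choices that were genuinely open

* **Network formats.** No standard input existed for this kind of analysis;
  the JSON schema mirrors the internal types, the TSV dialect is one
  reaction per line with `2*mal`-style coefficients, and SBML import
  (level-3 core stoichiometry, kinetics ignored) goes through `cobra`.
* **External metabolites** are kept in reaction vectors but excluded from
  cycle-intermediate candidacy — an assimilated nutrient must not count as
  an intermediate.
* **Cofactor list.** Stripping is user-controlled; the packaged default
  covers the conventional currency metabolites (ATP/ADP/AMP, NAD(P)(H),
  CoA, Pi, water, protons, CO2).
* **Branch points with several branches** from one intermediate would sum
  their derivatives into a single β_i; the packaged topologies have one
  branch per position, matching the single-assimilation chain analyzed.
* **Degenerate equalities** (e.g. Vmax,b = δ·Vmax,a with equal KMs) are
  reported as `degenerate` and never classified into a quadrant.
* **Reversible-branch units.** The branch equilibrium constant is fixed to
  1 by measuring Y in units of Keq·X; KY stays free.

## Known limitations

* The cycle search is bounded (length 12, multipliers 12 by default) and
  therefore not exhaustive over all of a genome-scale network.
* The MILP route's lexicographic tie-break is approximate (rank weights);
  the exhaustive route is exact.
* Stability verdicts are local; escape from basins under finite
  perturbations or noise is out of scope.
* The multi-reaction product criterion and flux-ordering inequalities hold
  for autocatalytic ratios up to 1:2 (δ ≤ 1); larger gains are rejected
  rather than extrapolated.
* Saturation audits inherit the lower-bound bias of the capacity estimator;
  on real compendia where no condition saturates an enzyme, estimated
  saturations are systematically inflated relative to truth.
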